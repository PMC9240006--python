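"""Maternal/fetal origin classification by a Mahalanobis-distance ratio.

Model
-----
Training cells of known origin (labels from an external demultiplexer or a
simulator) yield two Gaussian class summaries in difference-ratio feature
space: the fetal centroid/covariance ``(mu1, S1)`` estimated from the fetal
rows of the feature matrix and the maternal pair ``(mu2, S2)`` from the
maternal rows (column means and sample covariances, as in R's ``colMeans`` /
``var``). A cell with feature vector x is scored by the ratio of squared
Mahalanobis distances

    Ratio(x) = D^2(x; mu2, S2) / D^2(x; mu1, S1),

which is large when x sits far from the maternal class relative to the fetal
class. Because the published decision rule reads "Ratio below the fetal cut
=> fetal", the fitted model records an *orientation*: if labelled fetal
cells land on the large-ratio side, the reciprocal is taken so that fetal
cells always occupy the low end of the oriented axis. Two cuts are then
chosen on a candidate grid by tabulating sensitivity, specificity and
accuracy (fetal = positive class) at every cut; cells below the fetal cut
are called fetal, above the maternal cut maternal, otherwise — or when they
cover too few reference sites — unknown.

The ratio of squared distances is a monotone transform of the ratio of
distances, and the cuts are calibrated on the same scale, so calls are
unaffected by the squaring convention; plain distances are available via
``squared=False``.

Usage
-----
>>> model = CellOriginModel(drm, labels)          # doctest: +SKIP
>>> res = model.fit()                             # doctest: +SKIP
>>> calls = res.predict(drm_new)                  # doctest: +SKIP
>>> print(res.summary())                          # doctest: +SKIP
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .features import DifferenceRatioMatrix

FETAL, MATERNAL, UNKNOWN = "fetal", "maternal", "unknown"

DEFAULT_CAP = 1e6
_DENOM_TOL = 1e-12


class TrainingError(ValueError):
    """The labelled training data cannot support model estimation."""


class SelectionError(ValueError):
    """Threshold selection was handed a degenerate grid or one class."""


class EvaluationError(ValueError):
    """Calls and truth labels share no barcodes."""


# ---------------------------------------------------------------------------
# distance primitives
# ---------------------------------------------------------------------------


def mahalanobis_sq(
    x: np.ndarray, mu: np.ndarray, S: np.ndarray, ridge: float = 0.0
) -> np.ndarray | float:
    """Squared Mahalanobis distance (x-mu)' (S + ridge*I)^-1 (x-mu).

    ``x`` may be a single vector or an (n, d) batch; scalars are accepted in
    one dimension. Raises ``numpy.linalg.LinAlgError`` with a diagnostic if
    the ridged covariance is singular.
    """
    single = np.asarray(x).ndim < 2
    x = np.atleast_2d(np.asarray(x, dtype=float))
    mu = np.asarray(mu, dtype=float).ravel()
    S = np.atleast_2d(np.asarray(S, dtype=float))
    d = mu.size
    if x.shape[1] != d or S.shape != (d, d):
        raise ValueError(
            f"dimension mismatch: x has {x.shape[1]} features, mu {d}, S {S.shape}"
        )
    A = S + ridge * np.eye(d)
    diff = x - mu
    try:
        sol = np.linalg.solve(A, diff.T)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"covariance singular after ridge={ridge:g} (trace={np.trace(S):g}); "
            "increase the ridge"
        ) from exc
    out = np.einsum("ij,ji->i", diff, sol)
    out = np.maximum(out, 0.0)  # guard tiny negative round-off
    return float(out[0]) if single else out


def _ratio_from_distances(num: np.ndarray, den: np.ndarray, cap: float) -> np.ndarray:
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    out = np.where(den > _DENOM_TOL, num / np.maximum(den, _DENOM_TOL), cap)
    return np.minimum(out, cap)


def compute_ratio(
    x: np.ndarray,
    model: "CellOriginResults",
    cap: float = DEFAULT_CAP,
    oriented: bool = True,
) -> np.ndarray | float:
    """Mahalanobis-distance ratio of one or more feature vectors.

    Returns D^2(x; mu2, S2)/D^2(x; mu1, S1) capped at ``cap``; with
    ``oriented`` (default) the fitted orientation is applied afterwards
    (inverted => reciprocal), so fetal-like cells always score low.
    """
    x2 = np.atleast_2d(np.asarray(x, dtype=float))
    num = np.atleast_1d(
        mahalanobis_sq(x2, model.mu_maternal, model.cov_maternal, model.ridge)
    )
    den = np.atleast_1d(
        mahalanobis_sq(x2, model.mu_fetal, model.cov_fetal, model.ridge)
    )
    if not model.squared:
        num, den = np.sqrt(num), np.sqrt(den)
    r = _ratio_from_distances(num, den, cap)
    if oriented and model.orientation == "inverted":
        r = _ratio_from_distances(np.ones_like(r), r, cap)
    return float(r[0]) if np.ndim(x) == 1 else r


# ---------------------------------------------------------------------------
# threshold selection
# ---------------------------------------------------------------------------


def threshold_metrics(
    ratios: np.ndarray, labels: Sequence[str], grid: np.ndarray
) -> pd.DataFrame:
    """Sensitivity/specificity/accuracy at every candidate cut.

    At a cut c the two-way rule is: ratio < c => fetal, otherwise maternal;
    fetal is the positive class. Integer confusion counts are included so
    selection can rank without floating-point ties.
    """
    ratios = np.asarray(ratios, dtype=float)
    y = np.asarray([lab == FETAL for lab in labels], dtype=bool)
    P, N = int(y.sum()), int((~y).sum())
    rows = []
    for c in grid:
        pred_fetal = ratios < c
        tp = int((pred_fetal & y).sum())
        fn = P - tp
        fp = int((pred_fetal & ~y).sum())
        tn = N - fp
        rows.append(
            {
                "cut": float(c),
                "tp": tp,
                "fn": fn,
                "fp": fp,
                "tn": tn,
                "sensitivity": tp / P if P else np.nan,
                "specificity": tn / N if N else np.nan,
                "accuracy": (tp + tn) / (P + N),
                "youden": (tp / P + tn / N - 1.0) if P and N else np.nan,
            }
        )
    return pd.DataFrame(rows)


def select_thresholds(
    ratios: np.ndarray,
    labels: Sequence[str],
    grid: Optional[np.ndarray] = None,
    criterion: str = "accuracy",
) -> tuple[float, float, pd.DataFrame]:
    """Choose (fetal_cut, maternal_cut) from a candidate grid.

    Every cut is scored on the training labels; the optimum is the cut(s)
    maximising the criterion — ``"accuracy"`` (ties broken by Youden's J) or
    ``"youden"`` (ties broken by accuracy). Ranking uses integer confusion
    counts, so results are exactly reproducible: for fixed class sizes P and
    N, accuracy orders as TP+TN and Youden's J as TP*N + TN*P. The fetal cut
    is the smallest optimal cut and the maternal cut the largest, so
    fetal_cut <= maternal_cut always holds and ratios between the two are
    left unknown. The full metrics table is returned for audit.
    """
    ratios = np.asarray(ratios, dtype=float)
    labels = list(labels)
    y = np.asarray([lab == FETAL for lab in labels], dtype=bool)
    P, N = int(y.sum()), int((~y).sum())
    if P == 0 or N == 0:
        raise SelectionError("both classes must be present to select thresholds")
    if grid is None:
        grid = np.unique(np.quantile(ratios, np.linspace(0.0, 1.0, 101)))
    grid = np.unique(np.asarray(grid, dtype=float))
    if grid.size < 2:
        raise SelectionError("degenerate candidate grid (fewer than 2 unique cuts)")
    if criterion not in ("accuracy", "youden"):
        raise SelectionError(f"unknown criterion {criterion!r}")

    table = threshold_metrics(ratios, labels, grid)
    acc_key = table["tp"].to_numpy() + table["tn"].to_numpy()
    youden_key = table["tp"].to_numpy() * N + table["tn"].to_numpy() * P
    if criterion == "accuracy":
        keys = list(zip(acc_key, youden_key))
    else:
        keys = list(zip(youden_key, acc_key))
    best = max(keys)
    opt = [i for i, k in enumerate(keys) if k == best]
    fetal_cut = float(table["cut"].iloc[min(opt)])
    maternal_cut = float(table["cut"].iloc[max(opt)])
    return fetal_cut, maternal_cut, table


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------


def _default_ridge(S1: np.ndarray, S2: np.ndarray) -> float:
    d = S1.shape[0]
    tr = max(np.trace(S1), np.trace(S2))
    return 1e-6 * tr / d if tr > 0 else 1e-12


class CellOriginModel:
    """Mahalanobis-ratio origin classifier, fitted to labelled cells.

    Parameters
    ----------
    drm
        Difference-ratio feature matrix (cells x panels).
    labels
        Barcode -> {"fetal", "maternal"} for the training cells; barcodes
        absent from ``drm`` are ignored. Low-coverage cells (every feature
        under ``drm.min_sites`` covered sites) are excluded from training.
    ridge
        Covariance regularisation added to both class covariances; default
        1e-6 * trace(S)/dim, enough to invert near-degenerate features.
    squared
        Use squared Mahalanobis distances (default) or plain distances.
    """

    def __init__(
        self,
        drm: DifferenceRatioMatrix,
        labels: Mapping[str, str] | pd.Series,
        ridge: Optional[float] = None,
        squared: bool = True,
    ):
        labels = pd.Series(dict(labels)) if not isinstance(labels, pd.Series) else labels
        usable = drm.cells.intersection(labels.index)
        usable = usable[~drm.low_coverage.loc[usable]]
        if len(usable) == 0:
            raise TrainingError("no labelled cell with adequate coverage")
        X = drm.values.loc[usable].to_numpy(dtype=float)
        X = np.nan_to_num(X, nan=0.0)  # a feature with no covered site
        y = labels.loc[usable].to_numpy()
        bad = ~np.isin(y, [FETAL, MATERNAL])
        if bad.any():
            raise TrainingError(f"unrecognised labels: {set(y[bad])}")
        self.drm = drm
        self.exog = X
        self.labels = pd.Series(y, index=usable)
        self.ridge = ridge
        self.squared = squared

    @classmethod
    def from_observations(
        cls,
        obs,
        reference,
        labels: Optional[Mapping[str, str]] = None,
        min_sites: int = 10,
        mode: str = "alt_support",
        **kwargs,
    ) -> "CellOriginModel":
        """Build the model straight from allele observations and a reference.

        ``labels`` defaults to the observations' truth labels when present
        (simulated data); external label tables can be passed instead.
        """
        from .features import compute_difference_ratios

        drm = compute_difference_ratios(obs, reference, min_sites=min_sites, mode=mode)
        if labels is None:
            labels = obs.truth
        return cls(drm, labels, **kwargs)

    def fit(
        self,
        criterion: str = "accuracy",
        grid: Optional[np.ndarray] = None,
        cap: float = DEFAULT_CAP,
    ) -> "CellOriginResults":
        """Estimate class centroids/covariances, orientation and cuts."""
        y = self.labels.to_numpy()
        Xf = self.exog[y == FETAL]
        Xm = self.exog[y == MATERNAL]
        for name, Xc in ((FETAL, Xf), (MATERNAL, Xm)):
            if Xc.shape[0] < 2:
                raise TrainingError(
                    f"class {name!r} has {Xc.shape[0]} cells; covariance needs >= 2"
                )
        mu1, S1 = Xf.mean(axis=0), np.atleast_2d(np.cov(Xf, rowvar=False))
        mu2, S2 = Xm.mean(axis=0), np.atleast_2d(np.cov(Xm, rowvar=False))
        ridge = self.ridge if self.ridge is not None else _default_ridge(S1, S2)
        if ridge == 0.0 and (
            np.any(np.diag(S1) == 0.0) or np.any(np.diag(S2) == 0.0)
        ):
            raise TrainingError("zero-variance feature requires ridge > 0")

        res = CellOriginResults(
            model=self,
            mu_fetal=mu1,
            cov_fetal=S1,
            mu_maternal=mu2,
            cov_maternal=S2,
            ridge=float(ridge),
            squared=self.squared,
            orientation="as_printed",
            cap=float(cap),
        )
        # orientation: labelled fetal cells must occupy the low-ratio side
        raw = np.atleast_1d(compute_ratio(self.exog, res, cap=cap, oriented=False))
        if np.median(raw[y == FETAL]) > np.median(raw[y == MATERNAL]):
            res.orientation = "inverted"
        oriented = np.atleast_1d(compute_ratio(self.exog, res, cap=cap))
        fetal_cut, maternal_cut, table = select_thresholds(
            oriented, list(y), grid=grid, criterion=criterion
        )
        res.fetal_cut = fetal_cut
        res.maternal_cut = maternal_cut
        res.metrics_table = table
        res.criterion = criterion
        res.training_ratios = pd.Series(oriented, index=self.labels.index)
        return res


@dataclass
class CellOriginResults:
    """Fitted centroids, covariances, orientation and discriminant cuts."""

    model: Optional[CellOriginModel]
    mu_fetal: np.ndarray
    cov_fetal: np.ndarray
    mu_maternal: np.ndarray
    cov_maternal: np.ndarray
    ridge: float
    squared: bool = True
    orientation: str = "as_printed"
    cap: float = DEFAULT_CAP
    fetal_cut: float = np.nan
    maternal_cut: float = np.nan
    criterion: str = "accuracy"
    metrics_table: Optional[pd.DataFrame] = None
    training_ratios: Optional[pd.Series] = None

    def predict(
        self, drm: DifferenceRatioMatrix, min_sites: Optional[int] = None
    ) -> pd.DataFrame:
        """Three-way origin calls for every cell of a feature matrix.

        Returns a DataFrame indexed by barcode with columns ratio (oriented),
        call in {fetal, maternal, unknown}, covered_sites. A cell is unknown
        when its oriented ratio falls between the cuts or when no feature
        reaches ``min_sites`` covered sites (default: the matrix's own
        min_sites).
        """
        if np.isnan(self.fetal_cut) or np.isnan(self.maternal_cut):
            raise ValueError("thresholds not set; fit the model first")
        min_sites = drm.min_sites if min_sites is None else min_sites
        X = np.nan_to_num(drm.values.to_numpy(dtype=float), nan=0.0)
        ratios = np.atleast_1d(compute_ratio(X, self, cap=self.cap))
        low = (drm.covered < min_sites).all(axis=1).to_numpy()
        call = np.where(
            ratios < self.fetal_cut,
            FETAL,
            np.where(ratios > self.maternal_cut, MATERNAL, UNKNOWN),
        )
        call = np.where(low, UNKNOWN, call)
        return pd.DataFrame(
            {
                "ratio": ratios,
                "call": call,
                "covered_sites": drm.max_covered().to_numpy(),
            },
            index=drm.cells,
        )

    def summary(self) -> str:
        """Plain-text fit summary in the spirit of statsmodels results."""
        d = self.mu_fetal.size
        n = len(self.training_ratios) if self.training_ratios is not None else 0
        lines = [
            "Cell origin model (Mahalanobis-distance ratio)",
            "=" * 54,
            f"features (panels):        {d}",
            f"training cells:           {n}",
            f"distance convention:      {'squared' if self.squared else 'plain'}",
            f"ridge:                    {self.ridge:.3e}",
            f"orientation:              {self.orientation}",
            f"criterion:                {self.criterion}",
            f"fetal cut / maternal cut: {self.fetal_cut:.4g} / {self.maternal_cut:.4g}",
            "",
            "centroids (fetal | maternal):",
        ]
        for j in range(d):
            lines.append(
                f"  f{j}: {self.mu_fetal[j]:.4f} | {self.mu_maternal[j]:.4f}"
            )
        if self.metrics_table is not None:
            best = self.metrics_table.loc[
                self.metrics_table["accuracy"].idxmax()
            ]
            lines += [
                "",
                "training metrics at the best cut:",
                f"  sensitivity {best['sensitivity']:.3f}  "
                f"specificity {best['specificity']:.3f}  "
                f"accuracy {best['accuracy']:.3f}",
            ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "mu_fetal": self.mu_fetal.tolist(),
            "cov_fetal": self.cov_fetal.tolist(),
            "mu_maternal": self.mu_maternal.tolist(),
            "cov_maternal": self.cov_maternal.tolist(),
            "ridge": self.ridge,
            "squared": self.squared,
            "orientation": self.orientation,
            "cap": self.cap,
            "fetal_cut": self.fetal_cut,
            "maternal_cut": self.maternal_cut,
            "criterion": self.criterion,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "CellOriginResults":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            model=None,
            mu_fetal=np.asarray(d["mu_fetal"]),
            cov_fetal=np.asarray(d["cov_fetal"]),
            mu_maternal=np.asarray(d["mu_maternal"]),
            cov_maternal=np.asarray(d["cov_maternal"]),
            ridge=d["ridge"],
            squared=d["squared"],
            orientation=d["orientation"],
            cap=d["cap"],
            fetal_cut=d["fetal_cut"],
            maternal_cut=d["maternal_cut"],
            criterion=d["criterion"],
        )


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def evaluate_calls(
    calls: pd.DataFrame, truth: Mapping[str, str] | pd.Series
) -> dict:
    """Confusion-table metrics for three-way origin calls against truth.

    Fetal is the positive class. Unknown calls are excluded from
    sensitivity/specificity/accuracy and reported as ``unknown_fraction``;
    metrics undefined on the called subset are reported as None.
    """
    truth = pd.Series(dict(truth)) if not isinstance(truth, pd.Series) else truth
    common = calls.index.intersection(truth.index)
    if len(common) == 0:
        raise EvaluationError("calls and truth share no barcodes")
    sub = calls.loc[common]
    t = truth.loc[common]
    unknown = sub["call"] == UNKNOWN
    called = sub.loc[~unknown]
    tc = t.loc[~unknown]
    tp = int(((called["call"] == FETAL) & (tc == FETAL)).sum())
    fn = int(((called["call"] == MATERNAL) & (tc == FETAL)).sum())
    tn = int(((called["call"] == MATERNAL) & (tc == MATERNAL)).sum())
    fp = int(((called["call"] == FETAL) & (tc == MATERNAL)).sum())
    n_called = len(called)
    return {
        "n": int(len(sub)),
        "n_called": n_called,
        "unknown_fraction": float(unknown.mean()),
        "sensitivity": tp / (tp + fn) if (tp + fn) else None,
        "specificity": tn / (tn + fp) if (tn + fp) else None,
        "accuracy": (tp + tn) / n_called if n_called else None,
        "confusion": {"tp": tp, "fn": fn, "fp": fp, "tn": tn},
    }
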