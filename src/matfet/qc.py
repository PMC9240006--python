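"""Expression-level quality control and prevalence rules.

Operates on AnnData (cells x genes, raw counts in ``X``; boolean ``var["mito"]``
flags mitochondrial genes; ``obs["library_id"]`` identifies libraries). The
rules, with strict comparisons exactly as stated:

* gene prevalence filter — drop genes detected in < 0.1% of cells;
* cell QC — drop cells with < 800 detected genes OR > 10% mitochondrial counts;
* per-library Tukey-fence outlier removal on detected-gene counts
  (quartiles +/- 1.5 x IQR; high-side outliers are labelled potential doublets);
* highly-expressed genes — prevalence > 20%, CV < 1 and mean > 0 of
  log-normalised expression;
* one-vs-rest Wilcoxon rank-sum markers with Benjamini-Hochberg correction,
  kept at adjusted p < 0.05 and log fold change > 0.25;
* ligand-receptor pair calling at > 40% prevalence in each of two distinct
  cell types.

Normalisation for the CV/mean and marker rules is counts-per-10k followed by
log1p, recorded in every report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

NORMALIZATION = "CP10K+log1p"


@dataclass
class QcReport:
    """Per-step record of what each filter removed and why."""

    steps: list[dict] = field(default_factory=list)

    def add(self, name: str, removed_ids: list, thresholds: dict, shape_after):
        self.steps.append(
            {
                "step": name,
                "n_removed": len(removed_ids),
                "removed_ids": list(map(str, removed_ids)),
                "thresholds": thresholds,
                "shape_after": tuple(int(s) for s in shape_after),
            }
        )

    def to_dict(self) -> dict:
        return {"normalization": NORMALIZATION, "steps": self.steps}


def _dense_col(X) -> np.ndarray:
    return X.toarray() if sparse.issparse(X) else np.asarray(X)


def _detected_per_cell(adata) -> np.ndarray:
    X = adata.X
    if sparse.issparse(X):
        return np.asarray((X > 0).sum(axis=1)).ravel()
    return (np.asarray(X) > 0).sum(axis=1)


def filter_genes(
    adata, min_cell_fraction: float = 0.001, report: Optional[QcReport] = None
):
    """Remove genes expressed in less than ``min_cell_fraction`` of cells.

    A gene at exactly the threshold prevalence is retained (strict "less
    than"). Returns (filtered AnnData view copy, QcReport).
    """
    report = report or QcReport()
    n_cells = adata.n_obs
    X = adata.X
    detected_cells = (
        np.asarray((X > 0).sum(axis=0)).ravel()
        if sparse.issparse(X)
        else (np.asarray(X) > 0).sum(axis=0)
    )
    prevalence = detected_cells / n_cells
    keep = prevalence >= min_cell_fraction
    removed = adata.var_names[~keep].tolist()
    if not keep.any():
        warnings.warn("gene prevalence filter removed every gene")
    out = adata[:, keep].copy()
    report.add(
        "filter_genes",
        removed,
        {"min_cell_fraction": min_cell_fraction},
        out.shape,
    )
    return out, report


def filter_cells(
    adata,
    min_genes: int = 800,
    max_mito: float = 0.10,
    report: Optional[QcReport] = None,
):
    """Remove cells with < ``min_genes`` detected genes or mitochondrial
    count fraction > ``max_mito`` (both strict, as stated).

    Cells with zero total counts are removed under their own reason code.
    """
    report = report or QcReport()
    if "mito" not in adata.var:
        raise ValueError("var['mito'] mitochondrial flags are required")
    detected = _detected_per_cell(adata)
    X = adata.X
    total = np.asarray(X.sum(axis=1)).ravel()
    mito_mask = adata.var["mito"].to_numpy(bool)
    mito_counts = np.asarray(X[:, mito_mask].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito_counts / np.maximum(total, 1), 0.0)

    zero = total == 0
    low_genes = (detected < min_genes) & ~zero
    high_mito = (mito_frac > max_mito) & ~zero
    drop = zero | low_genes | high_mito
    reasons = {
        "zero_counts": adata.obs_names[zero].tolist(),
        "low_gene_count": adata.obs_names[low_genes].tolist(),
        "high_mito": adata.obs_names[high_mito].tolist(),
    }
    out = adata[~drop].copy()
    report.add(
        "filter_cells",
        adata.obs_names[drop].tolist(),
        {"min_genes": min_genes, "max_mito": max_mito, "reasons": reasons},
        out.shape,
    )
    return out, report


def detect_outlier_cells(
    adata,
    group_by: str = "library_id",
    whisker: float = 1.5,
    min_group_size: int = 5,
    report: Optional[QcReport] = None,
):
    """Flag per-library Tukey-fence outliers on detected-gene counts.

    Within each library, cells whose detected-gene count falls outside
    [Q1 - 1.5*IQR, Q3 + 1.5*IQR] are removed; high-side outliers are labelled
    potential doublets in the report. Libraries with fewer than
    ``min_group_size`` cells are skipped with a warning.
    """
    report = report or QcReport()
    if group_by not in adata.obs:
        raise ValueError(f"obs[{group_by!r}] is required")
    detected = pd.Series(_detected_per_cell(adata), index=adata.obs_names)
    drop = pd.Series(False, index=adata.obs_names)
    doublets: list[str] = []
    fences = {}
    for lib, idx in adata.obs.groupby(group_by, observed=True).groups.items():
        vals = detected.loc[idx]
        if len(vals) < min_group_size:
            warnings.warn(f"library {lib!r} has {len(vals)} cells; fence skipped")
            continue
        q1, q3 = np.percentile(vals, [25, 75])
        iqr = q3 - q1
        lo, hi = q1 - whisker * iqr, q3 + whisker * iqr
        out_mask = (vals < lo) | (vals > hi)
        drop.loc[idx] = out_mask
        doublets.extend(vals.index[vals > hi].tolist())
        fences[str(lib)] = {"low": float(lo), "high": float(hi)}
    out = adata[~drop.to_numpy()].copy()
    report.add(
        "detect_outlier_cells",
        drop.index[drop].tolist(),
        {
            "group_by": group_by,
            "whisker": whisker,
            "fences": fences,
            "potential_doublets": doublets,
        },
        out.shape,
    )
    return out, report


def run_qc(
    adata,
    min_cell_fraction: float = 0.001,
    min_genes: int = 800,
    max_mito: float = 0.10,
    group_by: str = "library_id",
):
    """Declared pipeline order: gene prevalence -> cell QC -> outlier fences."""
    report = QcReport()
    adata, report = filter_genes(adata, min_cell_fraction, report)
    adata, report = filter_cells(adata, min_genes, max_mito, report)
    adata, report = detect_outlier_cells(adata, group_by, report=report)
    return adata, report


# ---------------------------------------------------------------------------
# normalisation and gene selection
# ---------------------------------------------------------------------------


def lognorm(adata, target_sum: float = 1e4) -> np.ndarray:
    """Counts-per-``target_sum`` + log1p, returned as a dense array."""
    X = _dense_col(adata.X).astype(float)
    total = X.sum(axis=1, keepdims=True)
    total[total == 0] = 1.0
    return np.log1p(X / total * target_sum)


def highly_expressed_genes(
    adata,
    min_prevalence: float = 0.20,
    max_cv: float = 1.0,
    layer: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Genes with prevalence > 20%, CV < 1 and mean > 0 (all strict).

    CV and mean are computed on log-normalised expression (CP10K+log1p unless
    a pre-normalised ``layer`` is given). Returns a DataFrame indexed by gene
    with prevalence, mean, cv and the boolean ``selected``.
    """
    norm = lognorm(adata) if layer is None else np.asarray(layer, float)
    prevalence = (_dense_col(adata.X) > 0).mean(axis=0)
    mean = norm.mean(axis=0)
    sd = norm.std(axis=0, ddof=1) if adata.n_obs > 1 else np.zeros(adata.n_vars)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean > 0, sd / np.where(mean > 0, mean, 1.0), np.inf)
    selected = (prevalence > min_prevalence) & (cv < max_cv) & (mean > 0)
    return pd.DataFrame(
        {
            "prevalence": prevalence,
            "mean": mean,
            "cv": cv,
            "selected": selected,
        },
        index=adata.var_names,
    )


# ---------------------------------------------------------------------------
# markers
# ---------------------------------------------------------------------------


def rank_sum_markers(
    adata,
    groupby: str,
    p_adj_max: float = 0.05,
    min_lfc: float = 0.25,
    min_group_size: int = 3,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum marker genes per group.

    Per group and gene, a two-sided Mann-Whitney U test compares
    log-normalised expression of the group's cells against all other cells;
    p-values are Benjamini-Hochberg adjusted across genes within each group.
    The log fold change is ln(mean_in + 1) - ln(mean_out + 1) on normalised
    expression (pseudocount 1). The returned table carries every gene x group
    with ``significant`` marking adjusted p < ``p_adj_max`` and
    lfc > ``min_lfc``; constant genes get p = 1 by convention.
    """
    if groupby not in adata.obs:
        raise ValueError(f"obs[{groupby!r}] is required")
    groups = adata.obs[groupby].astype(str)
    counts = groups.value_counts()
    if len(counts) < 2:
        raise ValueError("at least two groups are required")
    if (counts < min_group_size).any():
        small = counts[counts < min_group_size]
        raise ValueError(f"groups below {min_group_size} cells: {dict(small)}")
    norm = lognorm(adata)
    rows = []
    for g in counts.index:
        mask = (groups == g).to_numpy()
        a, b = norm[mask], norm[~mask]
        pvals = np.ones(adata.n_vars)
        for j in range(adata.n_vars):
            col_a, col_b = a[:, j], b[:, j]
            if np.ptp(np.concatenate([col_a, col_b])) == 0.0:
                continue  # constant gene: p = 1
            pvals[j] = mannwhitneyu(col_a, col_b, alternative="two-sided").pvalue
        p_adj = multipletests(pvals, method="fdr_bh")[1]
        lfc = np.log(a.mean(axis=0) + 1.0) - np.log(b.mean(axis=0) + 1.0)
        rows.append(
            pd.DataFrame(
                {
                    "group": g,
                    "gene": adata.var_names,
                    "p_value": pvals,
                    "p_adj": p_adj,
                    "lfc": lfc,
                    "significant": (p_adj < p_adj_max) & (lfc > min_lfc),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# ligand-receptor prevalence calling
# ---------------------------------------------------------------------------


def call_lr_pairs(
    adata,
    cell_type_key: str,
    pairs: pd.DataFrame,
    min_prevalence: float = 0.40,
) -> pd.DataFrame:
    """Call ligand-receptor interactions between distinct cell types.

    For every ordered pair of distinct cell types (A, B) and every
    (ligand, receptor) row of ``pairs``, an interaction is emitted when the
    ligand is expressed in more than ``min_prevalence`` of type-A cells and
    the receptor in more than ``min_prevalence`` of type-B cells (strict >).
    Same-type pairs are never emitted. Pair genes absent from the matrix are
    skipped with a warning.
    """
    if cell_type_key not in adata.obs:
        raise ValueError(f"obs[{cell_type_key!r}] is required")
    if not {"ligand", "receptor"}.issubset(pairs.columns):
        raise ValueError("pairs must have 'ligand' and 'receptor' columns")
    types = adata.obs[cell_type_key].astype(str)
    type_names = sorted(types.unique())
    if len(type_names) < 2:
        raise ValueError("at least two cell types are required")
    X = _dense_col(adata.X)
    gene_pos = {g: j for j, g in enumerate(adata.var_names)}
    prevalence = {
        t: (X[(types == t).to_numpy()] > 0).mean(axis=0) for t in type_names
    }
    calls = []
    for _, row in pairs.iterrows():
        lig, rec = str(row["ligand"]), str(row["receptor"])
        if lig not in gene_pos or rec not in gene_pos:
            missing = [g for g in (lig, rec) if g not in gene_pos]
            warnings.warn(f"pair ({lig}, {rec}): gene(s) {missing} not in matrix")
            continue
        jl, jr = gene_pos[lig], gene_pos[rec]
        for ta in type_names:
            for tb in type_names:
                if ta == tb:
                    continue
                pl = float(prevalence[ta][jl])
                pr = float(prevalence[tb][jr])
                if pl > min_prevalence and pr > min_prevalence:
                    calls.append(
                        {
                            "ligand": lig,
                            "receptor": rec,
                            "ligand_cell_type": ta,
                            "receptor_cell_type": tb,
                            "ligand_prevalence": pl,
                            "receptor_prevalence": pr,
                        }
                    )
    return pd.DataFrame(
        calls,
        columns=[
            "ligand",
            "receptor",
            "ligand_cell_type",
            "receptor_cell_type",
            "ligand_prevalence",
            "receptor_prevalence",
        ],
    )
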