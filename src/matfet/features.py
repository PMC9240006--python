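"""Per-cell difference-ratio features against a fetal SNP reference.

For every cell and every reference panel, the feature is the fraction of the
cell's covered panel sites whose observed allele disagrees with the panel.
Two disagreement definitions are supported:

``alt_support`` (default)
    A covered site is discordant when the observed allele fails to support
    the panel's variant call: it differs from the panel ALT allele where the
    panel genotype carries the ALT, and from REF at a hom-ref site. This is
    the reading under which maternal cells — which lack the fetus-specific
    ALT at informative sites — accumulate discordance against a fetal SNP
    reference, giving the classifier its signal.

``allele_presence``
    A covered site is discordant when the observed allele is absent from the
    panel's diploid genotype. Stricter and weaker: at a heterozygous panel
    site both alleles are concordant, so only alleles outside the panel pair
    count.

The resulting cell x panel matrix is the classifier's feature space (one
column per panel by default, one per chromosome as an alternative).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .reference import FetalReference
from .simulate import CellAlleleObservations, InputError

MODES = ("alt_support", "allele_presence")


@dataclass
class DifferenceRatioMatrix:
    """Cell x feature discordance fractions with per-entry coverage.

    ``values`` and ``covered`` are aligned DataFrames (cells x features);
    values are in [0, 1] (NaN where a cell covers no site of a feature).
    ``low_coverage`` flags cells whose every feature has < min_sites covered
    sites; they are retained, never dropped.
    """

    values: pd.DataFrame
    covered: pd.DataFrame
    min_sites: int
    low_coverage: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.low_coverage is None:
            self.low_coverage = (self.covered < self.min_sites).all(axis=1)

    @property
    def cells(self) -> pd.Index:
        return self.values.index

    @property
    def features(self) -> pd.Index:
        return self.values.columns

    def max_covered(self) -> pd.Series:
        """Per-cell maximum covered-site count across features."""
        return self.covered.max(axis=1)


def _discordant(observed: np.ndarray, genotype: tuple[int, int], mode: str) -> np.ndarray:
    g0, g1 = genotype
    if mode == "alt_support":
        expected = 1 if (g0 == 1 or g1 == 1) else 0
        return observed != expected
    if mode == "allele_presence":
        return (observed != g0) & (observed != g1)
    raise ValueError(f"unknown difference mode {mode!r}; choose from {MODES}")


def compute_difference_ratios(
    obs: CellAlleleObservations,
    reference: FetalReference,
    min_sites: int = 10,
    mode: str = "alt_support",
    features: str = "panel",
    site_chroms: Optional[Mapping[int, str]] = None,
) -> DifferenceRatioMatrix:
    """Compute the difference-ratio feature matrix for a set of cells.

    Parameters
    ----------
    obs
        Per-cell allele observations (records: cell, site_idx, allele).
    reference
        Fetal reference panels (site -> genotype per panel).
    min_sites
        Cells whose every feature covers fewer sites are flagged low-coverage.
    mode
        Disagreement definition; see the module docstring.
    features
        ``"panel"`` (one column per reference panel, default) or ``"chrom"``
        (one column per chromosome, panels merged first-panel-wins; requires
        ``site_chroms``).
    """
    if mode not in MODES:
        raise ValueError(f"unknown difference mode {mode!r}; choose from {MODES}")
    if features not in ("panel", "chrom"):
        raise ValueError("features must be 'panel' or 'chrom'")
    if features == "chrom" and site_chroms is None:
        raise ValueError("features='chrom' requires site_chroms")

    if features == "panel":
        feature_maps = {label: dict(panel) for label, panel in reference.panels.items()}
    else:
        merged: dict[int, tuple[int, int]] = {}
        for panel in reference.panels.values():
            for site, gt in panel.items():
                merged.setdefault(site, gt)
        feature_maps = {}
        for site, gt in merged.items():
            chrom = site_chroms[site]  # type: ignore[index]
            feature_maps.setdefault(chrom, {})[site] = gt

    cells = obs.barcodes
    rec = obs.records
    labels = list(feature_maps)
    n_cells = len(cells)
    disc = np.zeros((n_cells, len(labels)), dtype=np.int64)
    cov = np.zeros((n_cells, len(labels)), dtype=np.int64)

    site_idx = rec["site_idx"].to_numpy()
    allele = rec["allele"].to_numpy()
    code = pd.Categorical(rec["cell"], categories=cells).codes

    for col, label in enumerate(labels):
        panel = feature_maps[label]
        if not panel:
            continue
        sites = np.fromiter(panel.keys(), dtype=np.int64, count=len(panel))
        gts = np.array([panel[s] for s in sites], dtype=np.int8)
        order = np.argsort(sites)
        sites, gts = sites[order], gts[order]
        j = np.searchsorted(sites, site_idx)
        j_safe = np.minimum(j, sites.size - 1)
        in_panel = (j < sites.size) & (sites[j_safe] == site_idx)
        g = gts[j_safe]
        if mode == "alt_support":
            expected = (g == 1).any(axis=1).astype(np.int8)
            d = (allele != expected) & in_panel
        else:  # allele_presence
            d = (allele != g[:, 0]) & (allele != g[:, 1]) & in_panel
        np.add.at(cov[:, col], code[in_panel], 1)
        np.add.at(disc[:, col], code[d], 1)

    if cov.sum() == 0:
        raise InputError("no cell covers any reference site")

    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(cov > 0, disc / np.maximum(cov, 1), np.nan)
    values = pd.DataFrame(vals, index=cells, columns=labels)
    covered = pd.DataFrame(cov, index=cells, columns=labels)
    return DifferenceRatioMatrix(values=values, covered=covered, min_sites=min_sites)
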