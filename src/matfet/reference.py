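"""Fetal SNP reference construction from one or more evidence panels.

A panel is a body of genotype evidence for the fetal genome — in the study
design, single-cell data from umbilical cord tissue; here, any per-site
collection of genotype observations. Per panel, a site enters the reference
when it has at least ``min_support`` observations and a strict-majority
consensus genotype; ties are excluded.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .simulate import CellAlleleObservations, GenotypeTable, FETUS

Genotype = tuple[int, int]


class ReferenceConstructionError(ValueError):
    """All panels were empty after support/consensus filtering."""


@dataclass
class FetalReference:
    """One consensus genotype map per panel, keyed by site index.

    ``panels`` maps panel label -> {site_idx: (allele, allele)} with unphased
    genotypes in sorted allele order. ``section_id`` carries the tissue
    section the reference serves (FS / Mid_S / Mat_S) or a generic label.
    """

    panels: Mapping[str, Mapping[int, Genotype]]
    section_id: str = "generic"
    params: dict = field(default_factory=dict)

    @property
    def panel_names(self) -> list[str]:
        return list(self.panels)

    def site_universe(self) -> set[int]:
        out: set[int] = set()
        for p in self.panels.values():
            out.update(p)
        return out


def _normalize(gt: Sequence[int]) -> Genotype:
    a, b = int(gt[0]), int(gt[1])
    return (a, b) if a <= b else (b, a)


def build_fetal_reference(
    fetal_sources: Mapping[str, Iterable[tuple[int, Sequence[int]]]],
    min_support: int = 1,
    section_id: str = "generic",
) -> FetalReference:
    """Build a consensus reference from per-panel genotype observations.

    Parameters
    ----------
    fetal_sources
        Panel label -> iterable of (site_idx, genotype) observations, where a
        genotype is an allele pair (unphased). Multiple observations per site
        are expected; a single curated map can be passed as one observation
        per site.
    min_support
        Minimum number of observations a site needs to be retained.

    A site's consensus is the strict-majority genotype among its
    observations; sites whose top genotypes tie are excluded.
    """
    if not fetal_sources:
        raise ReferenceConstructionError("no panels supplied")
    panels: dict[str, dict[int, Genotype]] = {}
    for label, obs in fetal_sources.items():
        per_site: dict[int, Counter] = {}
        for site_idx, gt in obs:
            per_site.setdefault(int(site_idx), Counter())[_normalize(gt)] += 1
        consensus: dict[int, Genotype] = {}
        for site_idx, counts in per_site.items():
            total = sum(counts.values())
            if total < min_support:
                continue
            top = counts.most_common(2)
            if len(top) > 1 and top[0][1] == top[1][1]:
                continue  # no strict majority
            consensus[site_idx] = top[0][0]
        panels[label] = consensus
    if all(len(p) == 0 for p in panels.values()):
        raise ReferenceConstructionError(
            "every panel is empty after support/consensus filtering"
        )
    return FetalReference(
        panels=panels, section_id=section_id, params={"min_support": min_support}
    )


def panels_from_cord_cells(
    obs_by_panel: Mapping[str, CellAlleleObservations],
    min_support: int = 3,
    section_id: str = "generic",
    variant_sites_only: bool = True,
) -> FetalReference:
    """Build a reference from simulated (or parsed) cord-cell observations.

    Per panel and site, the variant-supporting observations (ALT reported
    when any read carries the ALT allele) are aggregated into a biallelic
    genotype call. Because that reporting depletes REF observations at
    heterozygous sites, the caller uses asymmetric evidence thresholds: the
    ALT allele is called present when ALT observations exceed 20% of the
    site's observations (well above the error floor), the REF allele when
    REF observations exceed 8% (above the near-zero REF rate of a hom-ALT
    site, below the ~(1-p)^depth rate of a true heterozygote). With
    ``variant_sites_only`` (default) hom-ref calls are dropped — a SNP
    reference only contains sites where the fetus differs from the genome
    reference.
    """
    sources: dict[str, list[tuple[int, Genotype]]] = {}
    for label, obs in obs_by_panel.items():
        pairs: list[tuple[int, Genotype]] = []
        grouped = obs.records.groupby("site_idx")["allele"]
        for site_idx, alleles in grouped:
            arr = np.asarray(alleles)
            if arr.size < min_support:
                continue
            frac_alt = float((arr == 1).mean())
            if frac_alt > 0.2:
                gt: Genotype = (0, 1) if (1.0 - frac_alt) > 0.08 else (1, 1)
            else:
                gt = (0, 0)
            if variant_sites_only and gt == (0, 0):
                continue
            pairs.append((int(site_idx), gt))
        sources[label] = pairs
    return build_fetal_reference(sources, min_support=1, section_id=section_id)


def panels_from_genotype_table(
    genotypes: GenotypeTable,
    panel_names: Sequence[str] = ("panel1",),
    variant_sites_only: bool = True,
) -> FetalReference:
    """Reference panels taken directly from a trio's true fetal genotype.

    Convenience for tests and noise-free pipelines; each named panel is an
    identical copy of the fetal genotype (restricted to variant sites by
    default).
    """
    fetal = genotypes.genotypes[FETUS]
    entries = []
    for i in range(genotypes.n_sites):
        gt = _normalize(fetal[i])
        if variant_sites_only and gt == (0, 0):
            continue
        entries.append((i, gt))
    sources = {name: list(entries) for name in panel_names}
    return build_fetal_reference(sources, min_support=1)
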