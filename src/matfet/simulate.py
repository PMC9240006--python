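"""Synthetic trio genotypes, per-cell allele observations, annotated variant
records and sparse expression matrices.

These generators emulate the statistical structure the downstream analysis
assumes — a mother/father/fetus genotype trio with Mendelian inheritance,
sparse error-prone single-cell allele observations from cells of known origin,
variant records whose annotations straddle the hard-filter thresholds, and a
count matrix with controllable per-cell gene detection and mitochondrial
content — so every stage of the pipeline is testable without sequencing data.

Alleles are encoded 0 = REF, 1 = ALT; genotypes are unphased diploid pairs.
All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import _dist

_NUCS = np.array(list("ACGT"))

MOTHER, FATHER, FETUS = "mother", "father", "fetus"


class ParameterError(ValueError):
    """A simulator was called with an out-of-range parameter."""


class InputError(ValueError):
    """A simulator was handed unusable input data."""


# ---------------------------------------------------------------------------
# trio genotypes
# ---------------------------------------------------------------------------


@dataclass
class GenotypeTable:
    """Site-by-individual diploid genotypes for a mother/father/fetus trio.

    ``sites`` columns: chrom, pos (1-based, strictly increasing within a
    chromosome), ref, alt, maf, informative. ``genotypes`` maps individual
    name to an (n_sites, 2) int8 array of 0/1 allele codes.
    """

    sites: pd.DataFrame
    genotypes: Mapping[str, np.ndarray]
    params: dict = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def alleles(self, individual: str) -> np.ndarray:
        return self.genotypes[individual]

    def mendelian_violations(self) -> np.ndarray:
        """Indices of sites where the fetus cannot be a mother x father child.

        A site is consistent when the fetal pair can be split into one allele
        present in the mother's pair and one present in the father's pair.
        """
        m, f, c = (self.genotypes[k] for k in (MOTHER, FATHER, FETUS))
        bad = []
        for i in range(self.n_sites):
            ms, fs = set(m[i]), set(f[i])
            a, b = c[i]
            ok = (a in ms and b in fs) or (b in ms and a in fs)
            if not ok:
                bad.append(i)
        return np.asarray(bad, dtype=np.int64)

    def informative_sites(self) -> np.ndarray:
        """Sites where the fetus carries an allele absent from the mother."""
        m = self.genotypes[MOTHER]
        c = self.genotypes[FETUS]
        mother_has = np.stack([(m == a).any(axis=1) for a in (0, 1)], axis=1)
        fetus_has = np.stack([(c == a).any(axis=1) for a in (0, 1)], axis=1)
        return np.where((fetus_has & ~mother_has).any(axis=1))[0]


def simulate_trio_genotypes(
    n_sites: int,
    informative_fraction: float,
    maf_spec: _dist.DistSpec | None = None,
    seed: int = 0,
    chroms: Sequence[str] = ("chr1",),
    span_bp: int = 1_000_000,
) -> GenotypeTable:
    """Simulate a Mendelian-consistent mother/father/fetus genotype trio.

    Each site is independently flagged informative with probability
    ``informative_fraction``. Informative sites are built as mother 0/0 with a
    paternally transmitted ALT (fetus 0/1): the fetus carries an allele the
    mother lacks, which is the only biallelic configuration with that
    property. Remaining sites draw the mother from Hardy-Weinberg proportions
    at the site's minor-allele frequency and constrain the paternal
    transmission so the fetal pair stays within the maternal allele set.
    """
    if n_sites < 1:
        raise ParameterError(f"n_sites must be >= 1, got {n_sites}")
    if not 0.0 <= informative_fraction <= 1.0:
        raise ParameterError(
            f"informative_fraction must be in [0, 1], got {informative_fraction}"
        )
    if maf_spec is None:
        maf_spec = {"dist": "uniform", "low": 0.1, "high": 0.5}

    rng = np.random.default_rng(seed)

    # positions: strictly increasing within each chromosome
    per_chrom = np.array_split(np.arange(n_sites), len(chroms))
    chrom_col, pos_col = [], []
    for chrom, idx in zip(chroms, per_chrom):
        k = len(idx)
        if k == 0:
            continue
        pos = np.sort(rng.choice(np.arange(1, span_bp + 1), size=k, replace=False))
        chrom_col.extend([chrom] * k)
        pos_col.append(pos)
    pos_col = np.concatenate(pos_col) if pos_col else np.array([], dtype=int)

    ref_idx = rng.integers(0, 4, n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, n_sites)) % 4

    maf = np.clip(np.asarray(_dist.sample(maf_spec, n_sites, rng), float), 0.0, 0.5)
    informative = rng.random(n_sites) < informative_fraction

    mother = np.zeros((n_sites, 2), dtype=np.int8)
    father = np.zeros((n_sites, 2), dtype=np.int8)
    fetus = np.zeros((n_sites, 2), dtype=np.int8)

    # non-informative sites: mother ~ HWE(maf); fetus alleles constrained to
    # the maternal allele set (paternal transmission forced compatible).
    hwe = rng.random((n_sites, 2)) < maf[:, None]
    mother[:] = hwe.astype(np.int8)
    father[:] = (rng.random((n_sites, 2)) < maf[:, None]).astype(np.int8)
    mat_transmit = mother[np.arange(n_sites), rng.integers(0, 2, n_sites)]
    pat_choice = father[np.arange(n_sites), rng.integers(0, 2, n_sites)]
    mother_set_has = (mother == pat_choice[:, None]).any(axis=1)
    # where the drawn paternal allele is outside the maternal set, force the
    # father to carry (and transmit) a maternal allele instead
    forced = ~mother_set_has
    forced_allele = mother[np.arange(n_sites), rng.integers(0, 2, n_sites)]
    pat_transmit = np.where(forced, forced_allele, pat_choice)
    father[forced, rng.integers(0, 2, forced.sum())] = forced_allele[forced]
    fetus[:, 0] = mat_transmit
    fetus[:, 1] = pat_transmit

    # informative sites: mother hom-ref, father carries ALT and transmits it
    inf = informative
    mother[inf] = 0
    father[inf, 0] = 1
    father[inf, 1] = (rng.random(inf.sum()) < maf[inf]).astype(np.int8)
    fetus[inf, 0] = 0  # maternal allele
    fetus[inf, 1] = 1  # paternal ALT, absent from the mother

    # shuffle allele order so pairs are unphased
    swap = rng.random(n_sites) < 0.5
    for g in (mother, father, fetus):
        g[swap] = g[swap][:, ::-1]

    sites = pd.DataFrame(
        {
            "chrom": chrom_col,
            "pos": pos_col,
            "ref": _NUCS[ref_idx],
            "alt": _NUCS[alt_idx],
            "maf": maf,
            "informative": informative,
        }
    )
    return GenotypeTable(
        sites=sites,
        genotypes={MOTHER: mother, FATHER: father, FETUS: fetus},
        params={
            "n_sites": n_sites,
            "informative_fraction": informative_fraction,
            "seed": seed,
        },
    )


# ---------------------------------------------------------------------------
# per-cell allele observations
# ---------------------------------------------------------------------------


@dataclass
class CellAlleleObservations:
    """Sparse per-cell, per-site observed alleles with truth origin labels.

    ``records`` columns: cell (barcode), site_idx (row index into the parent
    GenotypeTable), allele (0/1), depth. ``truth`` maps barcode -> origin in
    {"fetal", "maternal"}.
    """

    records: pd.DataFrame
    truth: pd.Series
    params: dict = field(default_factory=dict)

    @property
    def barcodes(self) -> pd.Index:
        return self.truth.index


def simulate_cell_allele_counts(
    genotypes: GenotypeTable,
    n_cells: int,
    fetal_fraction: float = 0.5,
    sites_per_cell: _dist.DistSpec | None = None,
    error_rate: float = 0.01,
    mean_depth: float = 3.0,
    seed: int = 0,
    barcode_prefix: str = "cell",
) -> CellAlleleObservations:
    """Simulate sparse allele observations from cells of known origin.

    Each cell is fetal with probability ``fetal_fraction`` (its truth label is
    recorded); it covers a random subset of sites whose size is drawn from
    ``sites_per_cell`` (default negative binomial, mean 30). At each covered
    site, ``depth`` reads are drawn from the originating individual's
    genotype (mother for maternal cells, fetus for fetal cells), each read
    flipped to the other allele with probability ``error_rate``; the recorded
    observation is the variant-supporting call a per-cell variant caller
    would make — ALT when at least one read carries the ALT allele, REF
    otherwise. With ``error_rate`` 0 the observed allele is therefore always
    one of the individual's own alleles at that site.
    """
    if genotypes.n_sites == 0:
        raise InputError("empty genotype table")
    if not 0.0 <= error_rate < 1.0:
        raise ParameterError(f"error_rate must be in [0, 1), got {error_rate}")
    if not 0.0 <= fetal_fraction <= 1.0:
        raise ParameterError(f"fetal_fraction must be in [0, 1], got {fetal_fraction}")
    if n_cells < 1:
        raise ParameterError(f"n_cells must be >= 1, got {n_cells}")
    if sites_per_cell is None:
        sites_per_cell = {"dist": "negbin", "mean": 30, "dispersion": 30}

    rng = np.random.default_rng(seed)
    n_sites = genotypes.n_sites

    is_fetal = rng.random(n_cells) < fetal_fraction
    barcodes = [f"{barcode_prefix}{i:05d}" for i in range(n_cells)]
    n_cov = np.asarray(_dist.sample(sites_per_cell, n_cells, rng))
    n_cov = np.clip(n_cov.astype(np.int64), 0, n_sites)

    cells, site_idx, alleles, depths = [], [], [], []
    for i in range(n_cells):
        k = int(n_cov[i])
        if k == 0:
            continue
        idx = rng.choice(n_sites, size=k, replace=False)
        idx.sort()
        gt = genotypes.genotypes[FETUS if is_fetal[i] else MOTHER][idx]
        depth = 1 + rng.poisson(max(mean_depth - 1.0, 0.0), k)
        # per-read ALT probability: allele dosage with symmetric error flips
        p_alt = gt.mean(axis=1) * (1.0 - 2.0 * error_rate) + error_rate
        n_alt = rng.binomial(depth, p_alt)
        obs = (n_alt > 0).astype(np.int8)
        cells.extend([barcodes[i]] * k)
        site_idx.append(idx)
        alleles.append(obs)
        depths.append(depth)

    records = pd.DataFrame(
        {
            "cell": pd.Series(cells, dtype="string"),
            "site_idx": np.concatenate(site_idx) if site_idx else np.array([], int),
            "allele": np.concatenate(alleles) if alleles else np.array([], np.int8),
            "depth": np.concatenate(depths) if depths else np.array([], int),
        }
    )
    truth = pd.Series(
        np.where(is_fetal, "fetal", "maternal"), index=pd.Index(barcodes, name="cell")
    )
    return CellAlleleObservations(
        records=records,
        truth=truth,
        params={
            "n_cells": n_cells,
            "fetal_fraction": fetal_fraction,
            "error_rate": error_rate,
            "seed": seed,
        },
    )


# ---------------------------------------------------------------------------
# annotated variant records
# ---------------------------------------------------------------------------


@dataclass
class AnnotatedVariantRecord:
    """A variant call with the annotations the hard filters inspect.

    Any annotation may be missing (None); a missing annotation never fires a
    filter predicate.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    annotations: dict

    def __post_init__(self):
        if self.pos < 1:
            raise ParameterError(f"position must be >= 1, got {self.pos}")
        dp = self.annotations.get("DP")
        if dp is not None and dp < 0:
            raise ParameterError(f"DP must be >= 0, got {dp}")


def simulate_variant_records(
    n_records: int,
    threshold_spec: str = "cell_snv",
    seed: int = 0,
    missing_rate: float = 0.1,
    indel_rate: float = 0.1,
) -> tuple[list[AnnotatedVariantRecord], np.ndarray]:
    """Simulate variant records whose annotations straddle a filter profile.

    For every annotation in the named profile, values are drawn to land below,
    at, and above the threshold (plus missing values at ``missing_rate``), so
    a filter implementation is exercised on both sides of every boundary.
    Returns the records together with ground-truth pass labels computed by a
    direct evaluation of the profile's OR-of-predicates expression.
    """
    from .filters import BUILTIN_PROFILES  # local import to avoid a cycle

    if n_records < 1:
        raise ParameterError(f"n_records must be >= 1, got {n_records}")
    if threshold_spec not in BUILTIN_PROFILES:
        raise ParameterError(
            f"unknown filter profile {threshold_spec!r}; "
            f"choose from {sorted(BUILTIN_PROFILES)}"
        )
    profile = BUILTIN_PROFILES[threshold_spec]
    rng = np.random.default_rng(seed)

    records: list[AnnotatedVariantRecord] = []
    truth_pass = np.zeros(n_records, dtype=bool)
    pos_cursor = 0
    for i in range(n_records):
        ann: dict = {}
        for name, (op, thr) in profile.thresholds.items():
            u = rng.random()
            if u < missing_rate:
                continue  # annotation absent
            elif u < missing_rate + 0.15:
                ann[name] = float(thr)  # exact boundary: never fires
            else:
                # half below / half above the threshold
                delta = abs(thr) * rng.uniform(0.05, 0.8) + rng.uniform(0.1, 2.0)
                ann[name] = float(thr - delta if rng.random() < 0.5 else thr + delta)
            if name == "DP":
                ann[name] = max(0.0, round(ann[name]))
        pos_cursor += int(rng.integers(1, 60))
        ref = str(rng.choice(_NUCS))
        alt = str(rng.choice([n for n in "ACGT" if n != ref]))
        if rng.random() < indel_rate:
            alt = alt + str(rng.choice(_NUCS))  # simple insertion
        rec = AnnotatedVariantRecord("chr1", pos_cursor, ref, alt, ann)
        records.append(rec)
        truth_pass[i] = not any(
            name in ann
            and ((op == "<" and ann[name] < thr) or (op == ">" and ann[name] > thr))
            for name, (op, thr) in profile.thresholds.items()
        )
    return records, truth_pass


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------


def simulate_expression_matrix(
    n_genes: int,
    n_cells: int,
    genes_per_cell: _dist.DistSpec | None = None,
    mito_fraction: _dist.DistSpec | float = 0.05,
    n_mito_genes: int = 13,
    mean_count: float = 2.0,
    library_ids: Optional[Sequence[str]] = None,
    seed: int = 0,
):
    """Simulate a sparse gene x cell count matrix as an AnnData.

    The first ``n_mito_genes`` features are named ``MT-*`` and flagged
    mitochondrial (matching the 13 protein-coding genes of the human
    mitochondrial genome). Per cell, the number of detected genes is drawn
    from ``genes_per_cell`` and counts from a shifted Poisson; mitochondrial
    counts are then set so the cell's mitochondrial count fraction matches a
    draw from ``mito_fraction``.

    Returns an AnnData with obs columns ``library_id`` and var columns
    ``mito``; X is CSR int64, cells x genes.
    """
    import anndata as ad
    from scipy import sparse

    if n_genes < 1 or n_cells < 1:
        raise ParameterError("n_genes and n_cells must be positive")
    if n_mito_genes < 1:
        is_pos = isinstance(mito_fraction, (int, float)) and mito_fraction > 0
        if is_pos or isinstance(mito_fraction, Mapping):
            raise ParameterError("mito_fraction > 0 requires a mitochondrial gene set")
    if genes_per_cell is None:
        genes_per_cell = {"dist": "negbin", "mean": min(1500, n_genes // 2 or 1),
                         "dispersion": 8}

    rng = np.random.default_rng(seed)
    n_mito = min(n_mito_genes, n_genes)
    gene_ids = [f"MT-G{j}" for j in range(n_mito)] + [
        f"GENE{j:05d}" for j in range(n_genes - n_mito)
    ]
    mito_flag = np.zeros(n_genes, dtype=bool)
    mito_flag[:n_mito] = True

    detect = np.clip(
        np.asarray(_dist.sample(genes_per_cell, n_cells, rng)).astype(np.int64),
        1,
        n_genes,
    )
    mito_target = np.clip(
        np.asarray(_dist.sample(mito_fraction, n_cells, rng), float), 0.0, 0.95
    )

    rows, cols, vals = [], [], []
    non_mito = np.arange(n_mito, n_genes)
    for i in range(n_cells):
        k = int(detect[i])
        genes = rng.choice(non_mito, size=min(k, len(non_mito)), replace=False)
        counts = 1 + rng.poisson(max(mean_count - 1.0, 0.0), genes.size)
        total_nm = int(counts.sum())
        rows.extend([i] * genes.size)
        cols.append(genes)
        vals.append(counts)
        # mito counts to hit the target fraction: m / (m + total) = f
        f = float(mito_target[i])
        if f > 0 and n_mito > 0:
            m_total = int(round(f * total_nm / (1.0 - f)))
            if m_total > 0:
                mg = rng.choice(n_mito, size=min(n_mito, max(1, m_total)), replace=False)
                alloc = rng.multinomial(m_total, np.ones(mg.size) / mg.size)
                keep = alloc > 0
                rows.extend([i] * int(keep.sum()))
                cols.append(mg[keep])
                vals.append(alloc[keep])

    X = sparse.csr_matrix(
        (
            np.concatenate(vals) if vals else np.array([], int),
            (np.asarray(rows, int), np.concatenate(cols) if cols else np.array([], int)),
        ),
        shape=(n_cells, n_genes),
        dtype=np.int64,
    )
    if library_ids is None:
        library_ids = ["lib1"]
    lib = np.asarray(library_ids)[np.arange(n_cells) % len(library_ids)]
    obs = pd.DataFrame(
        {"library_id": lib},
        index=pd.Index([f"BC{i:06d}" for i in range(n_cells)], name="cell"),
    )
    var = pd.DataFrame(
        {"mito": mito_flag}, index=pd.Index(gene_ids, name="gene")
    )
    adata = ad.AnnData(X=X, obs=obs, var=var)
    adata.uns["sim_params"] = {"seed": seed, "n_genes": n_genes, "n_cells": n_cells}
    return adata
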