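"""Hard-filter predicates and the windowed SNP-cluster flag for variant calls.

Two built-in profiles mirror the filtration expressions used when calling
variants from bulk WGS and from single cells:

* ``wgs_site``:  QD < 2.0 || MQ < 40.0 || FS > 200.0 || SOR > 10.0
                 || MQRankSum < -12.5 || ReadPosRankSum < -8.0
* ``cell_snv``:  DP < 6 || QD < 2.0 || MQ < 40.0 || FS > 60.0 || SOR > 3.0
                 || MQRankSum < -12.5 || ReadPosRankSum < -8.0,
                 plus a 35-bp / 3-SNP cluster window.

Semantics follow the variant-filtration tool these expressions are written
for: a record FAILS if any single predicate fires (OR), comparisons are
strict as printed, and a missing annotation never fires a predicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .simulate import AnnotatedVariantRecord


class RecordParseError(ValueError):
    """An annotation value could not be interpreted as a number."""


class UnsortedPositionsError(ValueError):
    """Positions handed to the cluster flagger were not sorted ascending."""


@dataclass(frozen=True)
class FilterProfile:
    """A named set of (comparator, threshold) predicates plus an optional
    SNP-cluster window."""

    name: str
    thresholds: Mapping[str, tuple[str, float]]
    window_bp: Optional[int] = None
    cluster_size: Optional[int] = None


BUILTIN_PROFILES: dict[str, FilterProfile] = {
    "wgs_site": FilterProfile(
        name="wgs_site",
        thresholds={
            "QD": ("<", 2.0),
            "MQ": ("<", 40.0),
            "FS": (">", 200.0),
            "SOR": (">", 10.0),
            "MQRankSum": ("<", -12.5),
            "ReadPosRankSum": ("<", -8.0),
        },
    ),
    "cell_snv": FilterProfile(
        name="cell_snv",
        thresholds={
            "DP": ("<", 6.0),
            "QD": ("<", 2.0),
            "MQ": ("<", 40.0),
            "FS": (">", 60.0),
            "SOR": (">", 3.0),
            "MQRankSum": ("<", -12.5),
            "ReadPosRankSum": ("<", -8.0),
        },
        window_bp=35,
        cluster_size=3,
    ),
}


@dataclass
class FilterVerdict:
    """Outcome of applying a profile to one record: fail iff reasons fired."""

    record_id: str
    status: str  # "pass" | "fail"
    reasons: list[str] = field(default_factory=list)

    def __post_init__(self):
        if (self.status == "fail") != bool(self.reasons):
            raise ValueError("status must be 'fail' iff reasons are non-empty")


def get_profile(profile: str | FilterProfile) -> FilterProfile:
    if isinstance(profile, FilterProfile):
        return profile
    try:
        return BUILTIN_PROFILES[profile]
    except KeyError:
        raise KeyError(
            f"unknown profile {profile!r}; built-ins: {sorted(BUILTIN_PROFILES)}"
        ) from None


def apply_hard_filter(
    record: AnnotatedVariantRecord, profile: str | FilterProfile
) -> FilterVerdict:
    """Evaluate the profile's OR-of-predicates expression on one record.

    Missing annotations never fire; a non-numeric annotation raises
    :class:`RecordParseError` rather than being dropped silently.
    """
    prof = get_profile(profile)
    record_id = f"{record.chrom}:{record.pos}"
    reasons = []
    for name, (op, thr) in prof.thresholds.items():
        raw = record.annotations.get(name)
        if raw is None:
            continue
        try:
            value = float(raw)
        except (TypeError, ValueError):
            raise RecordParseError(
                f"{record_id}: annotation {name}={raw!r} is not numeric"
            ) from None
        if np.isnan(value):
            continue
        fired = value < thr if op == "<" else value > thr
        if fired:
            reasons.append(name)
    status = "fail" if reasons else "pass"
    return FilterVerdict(record_id=record_id, status=status, reasons=reasons)


def flag_snp_clusters(
    positions: Sequence[int] | Mapping[str, Sequence[int]],
    window_bp: int = 35,
    cluster_size: int = 3,
) -> np.ndarray | dict[str, np.ndarray]:
    """Flag variants lying in dense clusters within one chromosome.

    A position is flagged iff it belongs to some set of >= ``cluster_size``
    variants whose span (max - min + 1) is <= ``window_bp``. Accepts either
    one sorted position array or a {chrom: positions} mapping (processed per
    chromosome). Runs in O(n) with a sliding window: for every run of
    ``cluster_size`` consecutive variants within the window, all members are
    flagged.

    Raises :class:`UnsortedPositionsError` on unsorted input rather than
    re-sorting, so flags stay aligned with the caller's record order.
    """
    if isinstance(positions, Mapping):
        return {
            chrom: flag_snp_clusters(pos, window_bp, cluster_size)
            for chrom, pos in positions.items()
        }
    pos = np.asarray(positions, dtype=np.int64)
    if np.any(np.diff(pos) < 0):
        raise UnsortedPositionsError("positions must be sorted ascending")
    n = pos.size
    flags = np.zeros(n, dtype=bool)
    if n < cluster_size:
        return flags
    k = cluster_size
    # window of k consecutive sorted variants is the tightest set of size k
    span = pos[k - 1 :] - pos[: n - k + 1] + 1
    hit = span <= window_bp
    for start in np.where(hit)[0]:
        flags[start : start + k] = True
    return flags


def select_snps(
    records: Iterable[AnnotatedVariantRecord],
) -> list[AnnotatedVariantRecord]:
    """Keep biallelic single-nucleotide records (drop indels), order kept."""
    bases = set("ACGT")
    return [
        r
        for r in records
        if len(r.ref) == 1 and len(r.alt) == 1 and r.ref in bases and r.alt in bases
    ]


def filter_records(
    records: Sequence[AnnotatedVariantRecord],
    profile: str | FilterProfile,
) -> list[FilterVerdict]:
    """Apply the hard filter plus (if the profile defines one) the SNP-cluster
    window to an ordered list of records.

    Records must be position-sorted within each chromosome for the cluster
    flag; the returned verdicts align with the input order, with
    ``"snp_cluster"`` appended to the reasons of clustered records.
    """
    prof = get_profile(profile)
    verdicts = [apply_hard_filter(r, prof) for r in records]
    if prof.window_bp is not None and prof.cluster_size is not None:
        by_chrom: dict[str, list[int]] = {}
        for i, r in enumerate(records):
            by_chrom.setdefault(r.chrom, []).append(i)
        for chrom, idx in by_chrom.items():
            pos = [records[i].pos for i in idx]
            flags = flag_snp_clusters(pos, prof.window_bp, prof.cluster_size)
            for i, flagged in zip(idx, flags):
                if flagged:
                    verdicts[i].reasons.append("snp_cluster")
                    verdicts[i].status = "fail"
    return verdicts
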