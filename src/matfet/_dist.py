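"""Small distribution-spec vocabulary shared by the simulators.

A spec is either a plain number (degenerate distribution) or a mapping with a
``"dist"`` key::

    {"dist": "fixed",   "value": 30}
    {"dist": "uniform", "low": 0.1, "high": 0.5}
    {"dist": "beta",    "a": 1.0, "b": 3.0}
    {"dist": "poisson", "mean": 30}
    {"dist": "negbin",  "mean": 30, "dispersion": 10}
    {"dist": "values",  "values": [12, 40, 7, ...]}   # one value per draw

``values`` cycles if fewer entries than draws are requested, which lets tests
plant exact per-cell quantities.
"""

from __future__ import annotations

from typing import Mapping, Union

import numpy as np

DistSpec = Union[int, float, Mapping]


class DistSpecError(ValueError):
    """Raised for an unknown or ill-formed distribution spec."""


def sample(spec: DistSpec, size: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``size`` values from a distribution spec.

    Integer-valued families (poisson, negbin, fixed/values with ints) return
    int64 arrays; continuous families return float64.
    """
    if isinstance(spec, (int, float, np.integer, np.floating)):
        return np.full(size, spec)
    if not isinstance(spec, Mapping):
        raise DistSpecError(f"not a distribution spec: {spec!r}")
    try:
        kind = spec["dist"]
    except KeyError:
        raise DistSpecError(f"spec missing 'dist' key: {spec!r}") from None

    if kind == "fixed":
        return np.full(size, spec["value"])
    if kind == "values":
        vals = np.asarray(spec["values"])
        if vals.size == 0:
            raise DistSpecError("'values' spec is empty")
        reps = int(np.ceil(size / vals.size))
        return np.tile(vals, reps)[:size]
    if kind == "uniform":
        return rng.uniform(spec["low"], spec["high"], size)
    if kind == "beta":
        return rng.beta(spec["a"], spec["b"], size)
    if kind == "poisson":
        return rng.poisson(spec["mean"], size).astype(np.int64)
    if kind == "negbin":
        mean = float(spec["mean"])
        r = float(spec.get("dispersion", 10.0))
        if mean <= 0 or r <= 0:
            raise DistSpecError("negbin requires positive mean and dispersion")
        p = r / (r + mean)
        return rng.negative_binomial(r, p, size).astype(np.int64)
    raise DistSpecError(f"unknown distribution kind: {kind!r}")


def spawn_seed(seed: int, stage: str) -> int:
    """Derive a stage-specific seed (< 2**31) from a top-level seed.

    Uses numpy's SeedSequence entropy-mixing keyed on a stable digest of the
    stage name, so stages can be re-run in isolation without sharing streams
    and the derivation is identical across processes.
    """
    import hashlib

    stage_key = int.from_bytes(hashlib.sha256(stage.encode()).digest()[:4], "big")
    ss = np.random.SeedSequence([seed, stage_key])
    return int(ss.generate_state(1)[0] % (2**31))
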