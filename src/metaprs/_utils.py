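"""Shared helpers: seeded sub-stream management and small numerics."""

from __future__ import annotations

import zlib

import numpy as np

#: Median of the chi-square distribution with 1 degree of freedom, fixed to a
#: 10-figure constant so lambda_GC is reproducible across platforms.
CHI2_1_MEDIAN = 0.4549364

def rng_for(seed: int, *key: str) -> np.random.Generator:
    """Return a Generator for sub-stream ``key`` of run ``seed``.

    Sub-streams are keyed by (module, purpose) strings so that adding a new
    consumer never perturbs the draws of an existing one.
    """
    spawn_key = tuple(zlib.crc32(k.encode()) for k in key)
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=spawn_key))

def as_1d_float(x, name: str = "values") -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size and not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    return arr
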