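"""Shared helpers: seed fan-out, standardization, Pearson p-values."""

from __future__ import annotations

import hashlib

import numpy as np
from scipy import stats

MAX_SEED = 2**31 - 1


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage RNG seed from a global seed and a stage name.

    Uses a SHA-256 hash so stages can be rerun independently and adding a
    stage never shifts the seeds of existing ones.  Result is < 2**31.
    """
    h = hashlib.sha256(f"{int(global_seed)}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % MAX_SEED


def standardize(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Z-score along `axis` (ddof=1).  Raises on zero variance."""
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=axis, keepdims=True)
    sd = x.std(axis=axis, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("zero-variance vector cannot be standardized")
    return (x - mu) / sd


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and two-sided p via the t-transform; nan-safe on constant input."""
    r, p = stats.pearsonr(np.asarray(x, float), np.asarray(y, float))
    return float(r), float(p)
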