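"""Small shared numerics: fold protocol, R-squared definitions, rounding helpers."""

from __future__ import annotations

import math

import numpy as np


def kfold_indices(n: int, folds: int, seed: int) -> list[np.ndarray]:
    """Seeded random partition of ``range(n)`` into ``folds`` test sets.

    Fold sizes differ by at most one. The same (n, folds, seed) triple always
    yields the same partition, which is what lets GBLUP and the network be
    compared on identical held-out genotypes.
    """
    if folds < 2:
        raise ValueError("need at least 2 folds")
    if n < folds:
        raise ValueError(f"cannot split {n} samples into {folds} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(part) for part in np.array_split(perm, folds)]


def pearson_r2(obs: np.ndarray, pred: np.ndarray) -> float:
    """Squared Pearson correlation; 0.0 when either vector is degenerate."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.std() == 0 or pred.std() == 0:
        return 0.0
    r = np.corrcoef(obs, pred)[0, 1]
    if not np.isfinite(r):
        return 0.0
    return float(r * r)


def mse_r2(obs: np.ndarray, pred: np.ndarray) -> float:
    """1 - MSE/Var definition of prediction R^2 (can be negative)."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    var = obs.var()
    if var == 0:
        return 0.0
    return float(1.0 - np.mean((obs - pred) ** 2) / var)


def truncate_significant(x: float, digits: int = 2) -> float:
    """Truncate (toward zero) to the given number of significant figures.

    ``truncate_significant(8.8627e-9, 2) == 8.8e-9``.
    """
    if x == 0 or not math.isfinite(x):
        return x
    exp = math.floor(math.log10(abs(x)))
    scale = 10.0 ** (exp - digits + 1)
    return math.trunc(x / scale) * scale


def derive_seed(master: int, *salts: int) -> int:
    """Deterministic child seed below 2**31 derived from a master seed."""
    s = int(master) & 0x7FFFFFFF
    for salt in salts:
        s = (s * 1_000_003 + int(salt) + 12345) & 0x7FFFFFFF
    return s
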