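"""Orthonormal Haar wavelet transform.

One Haar analysis step maps a signal of even length n onto two sub-signals of
length n/2: a *trend* (pairwise running average) and a *fluctuation* (pairwise
running difference), both carrying the 1/sqrt(2) orthonormal normalisation so
that energy is conserved exactly:

    trend[j] = (z[2j-1] + z[2j]) / sqrt(2)
    fluct[j] = (z[2j-1] - z[2j]) / sqrt(2)      (1-based pairs)

Cascading the step on successive trends yields the multi-level decomposition
(cA^1..cA^k, cD^1..cD^k) used to build the coefficient trees in
:mod:`hwks.tree`.  The sign convention is left-minus-right.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["HaarDecomposition", "haar_step", "haar_multilevel", "reconstruct"]

_SQRT2 = np.sqrt(2.0)


def _as_signal(values, *, name: str = "signal") -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if arr.size < 2:
        raise ValueError(f"{name} must have at least 2 samples, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        bad = int(np.flatnonzero(~np.isfinite(arr))[0]) + 1
        raise ValueError(f"{name} contains a non-finite value at position {bad} (1-based)")
    return arr


@dataclass
class HaarDecomposition:
    """Multi-level Haar coefficients of a signal.

    ``trend[i]`` and ``fluct[i]`` hold the level-(i+1) approximation and detail
    coefficient vectors cA^(i+1), cD^(i+1), each of length n / 2^(i+1).
    """

    n: int
    depth: int
    trend: list[np.ndarray] = field(default_factory=list)
    fluct: list[np.ndarray] = field(default_factory=list)

    def level_trend(self, level: int) -> np.ndarray:
        """cA^level, 1-based level."""
        return self.trend[level - 1]

    def level_fluct(self, level: int) -> np.ndarray:
        """cD^level, 1-based level."""
        return self.fluct[level - 1]


def haar_step(signal) -> tuple[np.ndarray, np.ndarray]:
    """One orthonormal Haar analysis step.

    Returns ``(trend, fluct)``, each of length n/2.  Raises ``ValueError`` for
    odd-length input.
    """
    z = _as_signal(signal)
    if z.size % 2:
        raise ValueError(f"Haar step requires an even length, got {z.size}")
    pairs = z.reshape(-1, 2)
    trend = pairs.sum(axis=1) / _SQRT2
    fluct = (pairs[:, 0] - pairs[:, 1]) / _SQRT2
    return trend, fluct


def haar_multilevel(signal, depth: int) -> HaarDecomposition:
    """Cascade ``haar_step`` ``depth`` times, retaining every level.

    Requires ``1 <= depth <= log2(n)`` and n divisible by 2**depth.
    """
    z = _as_signal(signal)
    n = z.size
    if depth < 1:
        raise ValueError(f"depth must be >= 1, got {depth}")
    max_depth = int(np.log2(n)) if n >= 2 else 0
    if depth > max_depth or n % (2 ** depth):
        raise ValueError(
            f"depth {depth} invalid for length {n}: length must be divisible by 2**depth"
        )
    dec = HaarDecomposition(n=n, depth=depth)
    current = z
    for _ in range(depth):
        current, fluct = haar_step(current)
        dec.trend.append(current)
        dec.fluct.append(fluct)
    return dec


def reconstruct(dec: HaarDecomposition) -> np.ndarray:
    """Invert :func:`haar_multilevel` (multiresolution synthesis).

    Successively adds detail back onto each coarser trend.  Round-trips the
    analysis to ~1e-9 relative error.
    """
    if len(dec.trend) != dec.depth or len(dec.fluct) != dec.depth:
        raise ValueError("decomposition has inconsistent number of levels")
    current = np.asarray(dec.trend[-1], dtype=float)
    for level in range(dec.depth, 0, -1):
        fluct = np.asarray(dec.fluct[level - 1], dtype=float)
        if fluct.size != current.size or fluct.size * 2 ** level != dec.n:
            raise ValueError(f"level {level} coefficient length {fluct.size} inconsistent with n={dec.n}")
        upper = np.empty(current.size * 2)
        upper[0::2] = (current + fluct) / _SQRT2
        upper[1::2] = (current - fluct) / _SQRT2
        current = upper
    return current
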