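"""Binary coefficient trees over a dyadic signal.

For a series of length n = 2**k the approximation tree ``TcA`` and detail tree
``TcD`` are full binary trees of depth k.  A node at ``(level, position)``
(level 0 = leaves, 1-based positions) covers the sample block
``[(position-1)*2**level + 1, position*2**level]``.  Level-0 nodes of both
trees are the original samples; non-leaf nodes are the multi-level Haar
coefficients, so that

    approx(l, j) = (approx(l-1, 2j-1) + approx(l-1, 2j)) / sqrt(2)
    detail(l, j) = (approx(l-1, 2j-1) - approx(l-1, 2j)) / sqrt(2)

An approximation node rescales to the arithmetic mean of its block:
``block mean = 2**(-level/2) * approx(level, j)``, and the left-half-block
mean is ``2**(-level/2) * (approx + detail)`` at the same address — both are
used as probe points by the node statistic in :mod:`hwks.ks`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .haar import _as_signal, haar_multilevel

__all__ = ["CoeffTree", "build_trees", "block_mean"]


def _check_pow2(n: int) -> int:
    k = int(n).bit_length() - 1
    if n < 2 or (1 << k) != n:
        raise ValueError(
            f"series length {n} is not a power of two >= 2; "
            "truncate or reflect-pad explicitly (CLI --fit) before building trees"
        )
    return k


@dataclass
class CoeffTree:
    """One coefficient tree (``kind`` 'approximation' or 'detail').

    ``levels[l]`` is the array of level-l node values; ``levels[0]`` is the
    original signal.
    """

    kind: str
    depth: int
    levels: list[np.ndarray]

    @property
    def n(self) -> int:
        return self.levels[0].size

    def _check(self, level: int, position: int) -> None:
        if not 0 <= level <= self.depth:
            raise IndexError(f"level {level} out of range [0, {self.depth}]")
        width = self.n >> level
        if not 1 <= position <= width:
            raise IndexError(
                f"position {position} out of range [1, {width}] at level {level}"
            )

    def node(self, level: int, position: int) -> float:
        """Coefficient value at ``(level, position)``; level 0 = sample."""
        self._check(level, position)
        return float(self.levels[level][position - 1])

    def block(self, level: int, position: int) -> tuple[int, int]:
        """1-based inclusive sample index range covered by the node."""
        self._check(level, position)
        lo = (position - 1) * (1 << level) + 1
        return lo, lo + (1 << level) - 1


def build_trees(signal) -> tuple[CoeffTree, CoeffTree]:
    """Build ``(TcA, TcD)`` at full depth k = log2(n); n must be 2**k."""
    z = _as_signal(signal)
    k = _check_pow2(z.size)
    dec = haar_multilevel(z, k)
    tca = CoeffTree("approximation", k, [z.copy()] + [a.copy() for a in dec.trend])
    tcd = CoeffTree("detail", k, [z.copy()] + [d.copy() for d in dec.fluct])
    return tca, tcd


def block_mean(tree: CoeffTree, level: int, position: int) -> float:
    """Arithmetic mean of the samples covered by an approximation node.

    Equals ``2**(-level/2)`` times the node value under the orthonormal
    normalisation; at level 0 it is the sample itself.
    """
    if tree.kind != "approximation":
        raise ValueError("block_mean is defined on the approximation tree")
    return tree.node(level, position) * 2.0 ** (-level / 2.0)
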