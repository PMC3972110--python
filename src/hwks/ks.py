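"""Empirical CDFs, the Kolmogorov distribution and the node statistic RS.

The two-sample machinery here follows the classical scaled form: an e.c.d.f.
difference between the reference series X and the diagnosed series Z is
multiplied by sqrt(n_x * n_z / (n_x + n_z)) so that it is comparable with
quantiles of the Kolmogorov distribution

    K(x) = 1 - 2 * sum_{j>=1} (-1)^(j-1) exp(-2 j^2 x^2),  x > 0.

The tree-node statistic RS evaluates that scaled pointwise distance at two
probe points recoverable from the coefficient trees — the node's whole-block
mean and its left-half-block mean — and reports the larger distance when it
exceeds the threshold Ca (default 1.3258, i.e. a ~5.9% level), else 0.  Exact
equality of the two distances also yields 0; that three-branch rule is what
hands tied nodes over to the detail-tree search criterion in
:mod:`hwks.detector`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .haar import _as_signal
from .tree import CoeffTree

__all__ = [
    "KSConfig",
    "NodeStatistic",
    "ecdf_eval",
    "kolmogorov_cdf",
    "critical_value",
    "scaled_ks_point_distance",
    "node_rs",
    "ks_global_test",
]

DEFAULT_CA = 1.3258


def kolmogorov_cdf(x: float) -> float:
    """CDF of the Kolmogorov distribution (0 for x <= 0).

    The alternating series is truncated once a term drops below 1e-12.
    """
    if x <= 0:
        return 0.0
    total = 0.0
    sign = 1.0
    for j in range(1, 1000):
        term = np.exp(-2.0 * j * j * x * x)
        total += sign * term
        if term < 1e-12:
            break
        sign = -sign
    return float(min(1.0, max(0.0, 1.0 - 2.0 * total)))


def critical_value(alpha: float) -> float:
    """Kolmogorov quantile c with K(c) = 1 - alpha, by bisection to 1e-10."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    target = 1.0 - alpha
    lo, hi = 1e-8, 10.0
    while hi - lo > 1e-10:
        mid = 0.5 * (lo + hi)
        if kolmogorov_cdf(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass(frozen=True)
class KSConfig:
    """Threshold configuration for the node statistic and detection rule.

    ``ca`` is the critical value the scaled distances are compared against;
    ``alpha`` is the corresponding significance level 1 - K(ca) unless set
    explicitly.
    """

    ca: float = DEFAULT_CA
    alpha: float | None = None

    def __post_init__(self):
        if self.ca <= 0:
            raise ValueError(f"ca must be positive, got {self.ca}")
        if self.alpha is None:
            object.__setattr__(self, "alpha", 1.0 - kolmogorov_cdf(self.ca))
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")


def _sorted_sample(sample, name: str) -> np.ndarray:
    arr = np.sort(np.asarray(sample, dtype=float).ravel())
    if arr.size == 0:
        raise ValueError(f"{name} sample is empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} sample contains non-finite values")
    return arr


def ecdf_eval(sample, t: float) -> float:
    """Proportion of sample values <= t (right-continuous e.c.d.f.)."""
    srt = _sorted_sample(sample, "e.c.d.f.")
    return float(np.searchsorted(srt, t, side="right")) / srt.size


def _scale(nx: int, nz: int) -> float:
    return float(np.sqrt(nx * nz / (nx + nz)))


def _point_dist(sorted_x: np.ndarray, sorted_z: np.ndarray, t: float) -> float:
    fx = np.searchsorted(sorted_x, t, side="right") / sorted_x.size
    fz = np.searchsorted(sorted_z, t, side="right") / sorted_z.size
    return _scale(sorted_x.size, sorted_z.size) * abs(fz - fx)


def scaled_ks_point_distance(ref_x, diag_z, t: float) -> float:
    """sqrt(nx*nz/(nx+nz)) * |F_Z(t) - F_X(t)| at a single point t."""
    return _point_dist(_sorted_sample(ref_x, "reference"), _sorted_sample(diag_z, "diagnosed"), t)


@dataclass(frozen=True)
class NodeStatistic:
    """RS at one approximation-tree node.

    ``probe_main`` is the whole-block mean, ``probe_alt`` the left-half-block
    mean; ``d_main``/``d_alt`` the scaled pointwise distances there.  ``rs`` is
    max(d_main, d_alt) when that max exceeds Ca and the two distances differ,
    else 0.
    """

    rs: float
    probe_main: float
    probe_alt: float
    d_main: float
    d_alt: float


def _node_rs_sorted(
    sorted_x: np.ndarray,
    sorted_z: np.ndarray,
    tca: CoeffTree,
    tcd: CoeffTree,
    level: int,
    position: int,
    cfg: KSConfig,
) -> NodeStatistic:
    ca = tca.node(level, position)
    scale2 = 2.0 ** (-level / 2.0)
    probe_main = ca * scale2
    if level == 0:
        # A leaf has no halves; the companion probe degenerates to the sample
        # itself, so d_alt == d_main and RS is 0 by the equality branch.
        probe_alt = probe_main
    else:
        probe_alt = (ca + tcd.node(level, position)) * scale2
    d_main = _point_dist(sorted_x, sorted_z, probe_main)
    d_alt = _point_dist(sorted_x, sorted_z, probe_alt)
    if d_alt > d_main and d_alt > cfg.ca:
        rs = d_alt
    elif d_main > d_alt and d_main > cfg.ca:
        rs = d_main
    else:
        rs = 0.0
    return NodeStatistic(rs=rs, probe_main=probe_main, probe_alt=probe_alt,
                         d_main=d_main, d_alt=d_alt)


def node_rs(
    ref_x,
    diag_z,
    tca: CoeffTree,
    level: int,
    position: int,
    cfg: KSConfig | None = None,
    tcd: CoeffTree | None = None,
) -> NodeStatistic:
    """Distribution distance RS between X and Z at one TcA node.

    ``tcd`` may be omitted, in which case the companion (left-half-mean) probe
    is recomputed from the covered samples of Z directly.
    """
    cfg = cfg or KSConfig()
    sx = _sorted_sample(ref_x, "reference")
    z = _as_signal(diag_z, name="diagnosed")
    sz = np.sort(z)
    if tcd is not None:
        return _node_rs_sorted(sx, sz, tca, tcd, level, position, cfg)
    # Reconstruct the detail coefficient from the covered block of Z.
    ca = tca.node(level, position)
    scale2 = 2.0 ** (-level / 2.0)
    probe_main = ca * scale2
    if level == 0:
        probe_alt = probe_main
    else:
        lo, hi = tca.block(level, position)
        half = (hi - lo + 1) // 2
        probe_alt = float(np.mean(z[lo - 1: lo - 1 + half]))
    d_main = _point_dist(sx, sz, probe_main)
    d_alt = _point_dist(sx, sz, probe_alt)
    if d_alt > d_main and d_alt > cfg.ca:
        rs = d_alt
    elif d_main > d_alt and d_main > cfg.ca:
        rs = d_main
    else:
        rs = 0.0
    return NodeStatistic(rs=rs, probe_main=probe_main, probe_alt=probe_alt,
                         d_main=d_main, d_alt=d_alt)


def ks_global_test(ref_x, diag_z, alpha: float = 0.05) -> tuple[bool, float]:
    """Two-sample KS test of X against Z with the scaled sup statistic.

    Returns ``(reject, statistic)`` where the statistic is the supremum over
    all pooled sample points of the scaled e.c.d.f. difference, and rejection
    compares it with the asymptotic Kolmogorov quantile at ``alpha``.
    """
    sx = _sorted_sample(ref_x, "reference")
    sz = _sorted_sample(diag_z, "diagnosed")
    pooled = np.unique(np.concatenate([sx, sz]))
    fx = np.searchsorted(sx, pooled, side="right") / sx.size
    fz = np.searchsorted(sz, pooled, side="right") / sz.size
    stat = _scale(sx.size, sz.size) * float(np.max(np.abs(fz - fx)))
    return stat > critical_value(alpha), stat
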