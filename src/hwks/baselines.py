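"""Exhaustive comparison detectors: KS scan, one-level Haar, Welch-T scan.

All three return a :class:`~hwks.detector.DetectionResult` whose ``est_cp`` is
the size of the estimated pre-change segment, the same convention as the tree
detector.  Ties in any argmax break to the smallest index.

* ``detect_ks_scan`` — for every split m the scaled two-sample KS statistic
  sqrt(m(n-m)/n) * sup_t |F_{Z<=m}(t) - F_{Z>m}(t)| between the two segments;
  the full profile is evaluated with one vectorised pass over the sorted
  sample.
* ``detect_hw_onelevel`` — one Haar analysis step; the pair with the largest
  absolute detail coefficient locates the change; a change is flagged when
  that coefficient exceeds the universal threshold sd_hat * sqrt(2 ln(n/2))
  with sd_hat the MAD estimate of the detail-coefficient scale.
* ``detect_welch_t`` — Welch's unequal-variance t statistic at every split;
  pure locator (no significance decision is attached).
"""

from __future__ import annotations

import numpy as np

from .detector import DetectionResult
from .haar import _as_signal, haar_step
from .ks import critical_value

__all__ = ["detect_ks_scan", "detect_hw_onelevel", "detect_welch_t", "ks_scan_profile", "welch_t_profile"]

_SPLIT_MIN = 2  # both segments keep >= 2 points so Welch variances exist


def _split_positions(n: int) -> np.ndarray:
    if n < 4:
        raise ValueError(f"scan detectors require n >= 4, got {n}")
    return np.arange(_SPLIT_MIN, n - _SPLIT_MIN + 1)


def ks_scan_profile(diag_z) -> tuple[np.ndarray, np.ndarray]:
    """Scaled two-sample KS statistic at every split m in [2, n-2].

    Returns ``(split_positions, statistic_values)``.  The sup over thresholds
    is taken at the distinct sample values (run ends of the sorted sample), so
    tied values are handled exactly.
    """
    z = _as_signal(diag_z, name="diagnosed")
    n = z.size
    ms = _split_positions(n)
    order = np.argsort(z, kind="stable")
    pos = order + 1  # original 1-based position of each sorted value
    # indicator[m_idx, i]: sorted value i belongs to the left segment under split ms[m_idx]
    left = np.cumsum(pos[None, :] <= ms[:, None], axis=1, dtype=np.float64)
    ranks = np.arange(1, n + 1, dtype=np.float64)
    diff = np.abs(left / ms[:, None] - (ranks - left) / (n - ms)[:, None])
    zs = z[order]
    valid = np.ones(n, dtype=bool)
    valid[:-1] = zs[:-1] != zs[1:]
    sup = diff[:, valid].max(axis=1)
    stats = np.sqrt(ms * (n - ms) / n) * sup
    return ms, stats


def detect_ks_scan(diag_z, alpha: float = 0.05) -> DetectionResult:
    """Exhaustive two-sample KS scan over all splits."""
    ms, stats = ks_scan_profile(diag_z)
    i = int(np.argmax(stats))
    stat = float(stats[i])
    res = DetectionResult(
        method="ks",
        est_cp=int(ms[i]),
        changed=stat > critical_value(alpha),
        statistic=stat,
        n=int(ms[-1] + _SPLIT_MIN),
    )
    res.aux["split_positions"] = ms
    res.aux["statistic_values"] = stats
    return res


def detect_hw_onelevel(diag_z) -> DetectionResult:
    """One-level Haar detail-coefficient detector.

    The winning pair j* maps to ``est_cp = 2 j* - 1`` (its left element), so a
    clean step inside a pair — odd change point — is recovered exactly; a step
    at a pair boundary leaves every detail coefficient blind to it.
    """
    z = _as_signal(diag_z, name="diagnosed")
    if z.size % 2:
        raise ValueError(f"one-level Haar detector requires even length, got {z.size}")
    _, fluct = haar_step(z)
    mag = np.abs(fluct)
    j = int(np.argmax(mag))  # smallest index on ties
    stat = float(mag[j])
    med = np.median(fluct)
    sd_est = 1.4826 * float(np.median(np.abs(fluct - med)))
    gamma = sd_est * np.sqrt(2.0 * np.log(z.size / 2.0))
    res = DetectionResult(
        method="hw",
        est_cp=2 * (j + 1) - 1,
        changed=stat > gamma,
        statistic=stat,
        n=z.size,
    )
    res.aux["detail"] = fluct
    res.aux["gamma"] = float(gamma)
    return res


def welch_t_profile(diag_z) -> tuple[np.ndarray, np.ndarray]:
    """Welch t statistic (left mean minus right mean) at every split in [2, n-2]."""
    z = _as_signal(diag_z, name="diagnosed")
    n = z.size
    ms = _split_positions(n)
    c1 = np.cumsum(z)
    c2 = np.cumsum(z * z)
    sl, s2l = c1[ms - 1], c2[ms - 1]
    nl = ms.astype(float)
    nr = n - nl
    ml = sl / nl
    mr = (c1[-1] - sl) / nr
    # unbiased variances with a small floor so noiseless steps stay finite
    vl = np.maximum((s2l - nl * ml * ml) / (nl - 1.0), 1e-12)
    vr = np.maximum(((c2[-1] - s2l) - nr * mr * mr) / (nr - 1.0), 1e-12)
    t = (ml - mr) / np.sqrt(vl / nl + vr / nr)
    return ms, t


def detect_welch_t(diag_z) -> DetectionResult:
    """Welch-T scan; ranks splits by |T| and returns the argmax location."""
    ms, t = welch_t_profile(diag_z)
    i = int(np.argmax(np.abs(t)))
    res = DetectionResult(
        method="t",
        est_cp=int(ms[i]),
        changed=True,  # locator only; no significance rule is defined for it
        statistic=float(abs(t[i])),
        n=int(ms[-1] + _SPLIT_MIN),
    )
    res.aux["split_positions"] = ms
    res.aux["statistic_values"] = t
    return res
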