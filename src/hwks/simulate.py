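"""Synthetic study data: Gaussian mean-shift series and ECG-like fixtures.

The mean-shift generator reproduces the benchmark's statistical design: a
diagnosed series of dyadic length N whose first k samples are i.i.d.
Normal(0, sd^2) and whose remaining N - k samples have the constant shift v
added (defaults v = 2, sd = 1).  The paired reference series is an
independent full-length draw from the null Normal(0, sd^2) model.

The ECG-like fixture emulates the assembled normal/abnormal protocol in shape
only: a quasi-periodic spike-train template (one Gaussian bump per period of
~N/16 samples) with small jitter stands in for the normal rhythm, and the
post-change regime amplifies the spikes and adds broadband noise, standing in
for a noise-stressed recording.  It is not a model of cardiac
electrophysiology.

All randomness flows through ``numpy.random.default_rng`` seeded from
``(seed, rep, stream)`` so any single replicate can be replayed in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SimConfig", "gen_step_series", "gen_pair", "gen_ecg_fixture"]


def _is_pow2(n: int) -> bool:
    return n >= 2 and (n & (n - 1)) == 0


@dataclass(frozen=True)
class SimConfig:
    """One Monte-Carlo cell: series length N, change position k, shift v."""

    N: int
    k: int
    v: float = 2.0
    sd: float = 1.0
    seed: int = 0
    reps: int = 600

    def __post_init__(self):
        if not _is_pow2(self.N):
            raise ValueError(f"N must be a power of two >= 2, got {self.N}")
        if not 1 <= self.k <= self.N - 1:
            raise ValueError(f"k must lie in [1, N-1], got k={self.k}, N={self.N}")
        if self.sd <= 0:
            raise ValueError(f"sd must be positive, got {self.sd}")
        if self.reps < 1:
            raise ValueError(f"reps must be >= 1, got {self.reps}")


def _rng(seed: int, rep: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(rep), int(stream)]))


def gen_step_series(cfg: SimConfig, rep: int = 0) -> np.ndarray:
    """Diagnosed series: Normal(0, sd^2) for 1..k, Normal(v, sd^2) after."""
    rng = _rng(cfg.seed, rep, 0)
    z = rng.normal(0.0, cfg.sd, cfg.N)
    z[cfg.k:] += cfg.v
    return z


def gen_pair(cfg: SimConfig, rep: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """(reference X, diagnosed Z): X is an independent null draw of length N."""
    x = _rng(cfg.seed, rep, 1).normal(0.0, cfg.sd, cfg.N)
    return x, gen_step_series(cfg, rep)


def _spike_template(n: int, period: int) -> np.ndarray:
    phase = np.arange(n) % period
    centre = period / 4.0
    width = max(period / 20.0, 0.75)
    return np.exp(-0.5 * ((phase - centre) / width) ** 2)


def gen_ecg_fixture(
    n: int,
    k: int,
    seed: int = 0,
    *,
    amp_factor: float = 3.0,
    noise_sd: float = 0.5,
    jitter_sd: float = 0.02,
) -> tuple[np.ndarray, np.ndarray]:
    """ECG-like pair with a regime switch after sample k.

    The reference is the clean jittered template; the diagnosed series follows
    it up to k, then switches to spikes amplified by ``amp_factor`` with
    broadband Gaussian noise of ``noise_sd`` added.  ``k = n`` means no
    abnormal part.
    """
    if not _is_pow2(n):
        raise ValueError(f"n must be a power of two >= 2, got {n}")
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, n], got k={k}, n={n}")
    period = max(8, n // 16)
    template = _spike_template(n, period)
    x = template + _rng(seed, 0, 2).normal(0.0, jitter_sd, n)
    rng_z = _rng(seed, 0, 3)
    z = template + rng_z.normal(0.0, jitter_sd, n)
    if k < n:
        tail = slice(k, n)
        z[tail] = amp_factor * template[tail] + rng_z.normal(0.0, noise_sd, n - k)
    return x, z
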