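"""Monte-Carlo benchmark of the four detectors.

For each (method, configuration) cell the benchmark runs seeded replicates of
the pair generator and the chosen detector and summarises:

* ``mean_err`` — mean over replicates of ``est_cp - k`` (signed);
* ``abs_err`` — ``|mean_err|``;
* ``accuracy`` — ``1 - abs_err / N``;
* ``hit`` — fraction of replicates with ``est_cp == k`` exactly.

An averaged row per method takes the arithmetic mean of abs_err, accuracy and
hit over configurations.  The preset grid pairs each dyadic size from 2^3 to
2^10 with one change position near a boundary, half on the left and half on
the right, with shift v = 2 and unit noise.
"""

from __future__ import annotations

import json
import sys
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from .baselines import detect_hw_onelevel, detect_ks_scan, detect_welch_t
from .detector import detect_hwks
from .ks import KSConfig
from .simulate import SimConfig, gen_pair

__all__ = ["MetricRecord", "BenchmarkTable", "run_cell", "run_benchmark",
           "SINGLE_POSITION_GRID", "table_positions", "METHODS"]

#: (N, k) pairs of the single-change-position study design (v = 2, sd = 1).
SINGLE_POSITION_GRID: tuple[tuple[int, int], ...] = (
    (8, 2), (16, 3), (32, 5), (64, 9),
    (128, 113), (256, 225), (512, 449), (1024, 897),
)

COLUMNS = ["method", "N", "k", "v", "reps", "mean_err", "abs_err", "accuracy", "hit"]


def table_positions(n: int, count: int = 16) -> list[int]:
    """Evenly spread change positions k_i = round(i*N/(count+1)), i = 1..count."""
    ks = sorted({min(max(round(i * n / (count + 1)), 1), n - 1) for i in range(1, count + 1)})
    return ks


@dataclass(frozen=True)
class MetricRecord:
    method: str
    N: int
    k: int
    v: float
    reps: int
    mean_err: float
    abs_err: float
    accuracy: float
    hit: float


@dataclass
class BenchmarkTable:
    records: list[MetricRecord]
    averaged: list[MetricRecord]

    def to_frame(self) -> pd.DataFrame:
        rows = [asdict(r) for r in self.records] + [asdict(r) for r in self.averaged]
        return pd.DataFrame(rows, columns=COLUMNS)


def _detect(method: str, x, z, cfg: KSConfig):
    if method == "hwks":
        return detect_hwks(x, z, cfg)
    if method == "ks":
        return detect_ks_scan(z)
    if method == "hw":
        return detect_hw_onelevel(z)
    if method == "t":
        return detect_welch_t(z)
    raise ValueError(f"unknown method {method!r}; expected one of hwks, ks, hw, t")


METHODS = ("hwks", "ks", "hw", "t")


def run_cell(method: str, cfg: SimConfig, ks_cfg: KSConfig | None = None) -> MetricRecord:
    """Run one Monte-Carlo cell: ``cfg.reps`` replicates of one detector."""
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    ks_cfg = ks_cfg or KSConfig()
    err_sum = 0.0
    hits = 0
    for rep in range(cfg.reps):
        x, z = gen_pair(cfg, rep)
        res = _detect(method, x, z, ks_cfg)
        err_sum += res.est_cp - cfg.k
        hits += res.est_cp == cfg.k
    mean_err = err_sum / cfg.reps
    abs_err = abs(mean_err)
    return MetricRecord(
        method=method, N=cfg.N, k=cfg.k, v=cfg.v, reps=cfg.reps,
        mean_err=mean_err, abs_err=abs_err,
        accuracy=1.0 - abs_err / cfg.N, hit=hits / cfg.reps,
    )


def run_benchmark(
    methods,
    configs,
    out: str | Path | None = None,
    ks_cfg: KSConfig | None = None,
    progress: bool = False,
) -> BenchmarkTable:
    """One record per (method, config) plus an averaged row per method.

    ``out`` (optional) writes the table as TSV and, with suffix swapped, JSON.
    """
    methods = list(methods)
    configs = list(configs)
    if not methods or not configs:
        raise ValueError("methods and configs must be nonempty")
    records: list[MetricRecord] = []
    averaged: list[MetricRecord] = []
    for method in methods:
        cells = []
        for cfg in configs:
            if progress:
                print(f"[bench] {method} N={cfg.N} k={cfg.k} v={cfg.v} reps={cfg.reps}",
                      file=sys.stderr, flush=True)
            cells.append(run_cell(method, cfg, ks_cfg))
        records.extend(cells)
        m = len(cells)
        averaged.append(MetricRecord(
            method=method, N=0, k=0,
            v=cells[0].v, reps=cells[0].reps,
            mean_err=sum(c.mean_err for c in cells) / m,
            abs_err=sum(c.abs_err for c in cells) / m,
            accuracy=sum(c.accuracy for c in cells) / m,
            hit=sum(c.hit for c in cells) / m,
        ))
    table = BenchmarkTable(records=records, averaged=averaged)
    if out is not None:
        out = Path(out)
        table.to_frame().to_csv(out, sep="\t", index=False)
        payload = {
            "records": [asdict(r) for r in records],
            "averaged": [asdict(r) for r in averaged],
        }
        out.with_suffix(".json").write_text(json.dumps(payload, indent=2))
    return table
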