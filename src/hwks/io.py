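"""Reading and writing single-channel series and result files.

A series file holds one numeric value per line (plain text, CSV or TSV; for
delimited files the first column is used).  An optional single header line is
auto-detected.  Missing or non-numeric entries raise a line-numbered error.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np

from .haar import HaarDecomposition

__all__ = ["read_series", "write_series", "fit_length", "decomposition_to_json"]


def _first_field(line: str) -> str:
    for sep in ("\t", ","):
        if sep in line:
            return line.split(sep)[0].strip()
    return line.strip()


def read_series(path: str | Path) -> np.ndarray:
    """Load a series; tolerates one header line; rejects NaN/missing values."""
    path = Path(path)
    values: list[float] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            text = _first_field(raw)
            if not text:
                continue
            try:
                val = float(text)
            except ValueError:
                if lineno == 1 and not values:
                    continue  # header line
                raise ValueError(f"{path}:{lineno}: not a number: {text!r}") from None
            if not math.isfinite(val):
                raise ValueError(f"{path}:{lineno}: non-finite value {text!r}")
            values.append(val)
    if not values:
        raise ValueError(f"{path}: no numeric data found")
    return np.asarray(values, dtype=float)


def write_series(values, path: str | Path) -> None:
    np.savetxt(Path(path), np.asarray(values, dtype=float), fmt="%.12g")


def fit_length(values, mode: str) -> tuple[np.ndarray, dict]:
    """Coerce a series to a power-of-two length.

    ``mode='truncate'`` keeps the leading 2**floor(log2 n) samples;
    ``mode='reflect'`` reflect-pads to the next power of two.  Returns the
    fitted series and a mapping dict with ``original_n`` and ``mode`` so
    detected indices can be interpreted (indices beyond ``original_n`` after
    reflect padding map back as ``2*original_n - index``).
    """
    z = np.asarray(values, dtype=float)
    n = z.size
    if n < 2:
        raise ValueError("series must have at least 2 samples")
    if n & (n - 1) == 0:
        return z, {"original_n": n, "mode": "none"}
    if mode == "truncate":
        m = 1 << (n.bit_length() - 1)
        return z[:m], {"original_n": n, "mode": "truncate", "fitted_n": m}
    if mode == "reflect":
        m = 1 << n.bit_length()
        pad = m - n
        return np.concatenate([z, z[-2: -2 - pad: -1]]), \
            {"original_n": n, "mode": "reflect", "fitted_n": m}
    raise ValueError(
        f"length {n} is not a power of two; pass mode 'truncate' or 'reflect'"
    )


def map_index_back(index: int, mapping: dict) -> int:
    """Map a 1-based detected index on a fitted series back to the original."""
    n0 = mapping["original_n"]
    if mapping.get("mode") == "reflect" and index > n0:
        return 2 * n0 - index
    return min(index, n0)


def decomposition_to_json(dec: HaarDecomposition) -> str:
    return json.dumps({
        "n": dec.n,
        "depth": dec.depth,
        "trend": [a.tolist() for a in dec.trend],
        "fluct": [d.tolist() for d in dec.fluct],
    }, indent=2)
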