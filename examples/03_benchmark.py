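"""Run a reduced Monte-Carlo benchmark and print the summary table.

Uses 100 replicates per cell on three series lengths; the full study design
(8 lengths, 600 replicates) is available via `hwks bench --table2` or
`scripts/acceptance.py`.

Run:  python examples/03_benchmark.py
"""

from hwks import SimConfig, run_benchmark

configs = [SimConfig(N=n, k=k, v=2.0, sd=1.0, seed=0, reps=100)
           for n, k in ((32, 5), (128, 113), (512, 449))]

table = run_benchmark(["hwks", "ks", "hw", "t"], configs, progress=True)
frame = table.to_frame()
print()
print(frame.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print("\nrows with N = 0 are the per-method averages over the grid")
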