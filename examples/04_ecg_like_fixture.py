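"""Segment an ECG-like spike train with a regime switch.

The fixture is a quasi-periodic Gaussian-bump spike train; after sample k the
spikes triple in amplitude and broadband noise appears.  The tree detector
flags the switch against the clean reference and localises it; a no-change
control keeps the flag down.

Run:  python examples/04_ecg_like_fixture.py
"""

from hwks import detect_hwks, detect_ks_scan, gen_ecg_fixture

n = 512
k = 5 * n // 16 + 1  # an off-boundary switch position

x, z = gen_ecg_fixture(n, k, seed=4)
res = detect_hwks(x, z)
print(f"regime switch at k = {k}:")
print(f"  tree detector: est_cp {res.est_cp}, changed {res.changed}")
print(f"  KS scan      : est_cp {detect_ks_scan(z).est_cp}")

x, z = gen_ecg_fixture(n, n, seed=4)  # k = n means no abnormal part
res = detect_hwks(x, z)
print(f"no-change control: changed {res.changed} "
      f"(statistic {res.statistic:.3f} < 1.3258)")
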