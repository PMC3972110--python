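"""Anatomy of the Haar coefficient trees on a tiny noiseless step.

Shows how a clean step after sample 5 of 16 lights up exactly one detail
coefficient per level, and how the descent follows those coefficients down to
the correct leaf.

Run:  python examples/02_coefficient_trees.py
"""

import numpy as np

from hwks import block_mean, build_trees, descend

z = np.zeros(16)
z[5:] = 10.0  # step after sample 5
x = np.zeros(16)

tca, tcd = build_trees(z)
print("level-by-level detail coefficients (|cD|, '.' = 0):")
for level in range(tca.depth, 0, -1):
    row = [abs(tcd.node(level, j)) for j in range(1, (16 >> level) + 1)]
    print(f"  level {level}: " + "  ".join(
        f"{v:5.2f}" if v else "    ." for v in row))

print("\nblock means along the left spine:")
for level in range(tca.depth, -1, -1):
    lo, hi = tca.block(level, 1)
    print(f"  level {level}: samples {lo}-{hi}, mean {block_mean(tca, level, 1):.3f}")

b, path = descend(x, z, tca, tcd)
print(f"\ndescent reaches leaf {b} -> est_cp = {b - 1} (true k = 5)")
for s in path:
    print(f"  level {s.level}: chose position {s.chosen_position} "
          f"by criterion {s.criterion_used} "
          f"(|cD| {s.cd_left_abs:.2f} vs {s.cd_right_abs:.2f})")
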