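"""Select the rank by entry-holdout cross-validation (PRESS).

Masks 5% of the entries of a noiseless rank-3 matrix, refits NMF on the
rest, and scores the squared prediction error on the held-out entries.
Below the true rank the model cannot predict what it never saw; at and
above it, held-out entries are completed to numerical precision, and the
smallest such rank is reported.
"""

import uiknmf as u

V = u.make_lowrank_fixture(40, 15, 3, noise_sd=0.0, seed=11)
result = u.select_rank_press(
    V, ranks=[1, 2, 3, 4, 5, 6],
    scheme=u.HoldoutScheme(fraction=0.05, n_repeats=5, seed=2),
)

print(f"{'rank':>4} {'PRESS per held-out entry':>26}")
for r, p in zip(result.ranks, result.press_curve):
    print(f"{r:>4} {p:>26.3e}")
print(f"\noptimal rank: {result.optimal} (true rank 3)")
print("PRESS falls by ~8 orders of magnitude once the rank can represent the "
      "data; ranks 3-6 all sit at the exact-completion floor and parsimony "
      "picks the smallest.")
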