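"""Simulate a 60-line x 2-tester multi-environment testcross trial.

Generates a plot-level field book (31 x 4 alpha-lattice, 2 replicates,
8 environments for agronomic traits, 4 for carotenoids) together with
the ground-truth effects that produced it, and writes both to CSV.
"""

import lxt

config = lxt.default_config(seed=1)
book, truth = lxt.simulate_trial(config)
print(book)

means = lxt.testcross_means(book, "provitamin_a").values
print(f"testcross provitamin A means: {means.min().min():.1f}"
      f"-{means.max().max():.1f} ug/g (grand {means.mean().mean():.1f})")
gy = lxt.testcross_means(book, "grain_yield").values
print(f"testcross grain yields: {gy.min().min():.0f}-{gy.max().max():.0f} "
      "kg/ha")
# The true tester GCA for total carotenoid is fixed by the two testers'
# branch profiles; everything else is drawn at the configured variances.
g_t = truth.effects["total_carotenoid"].gca_testers
print(f"true tester GCA, total carotenoid: T1 {g_t[0]:+.2f}, "
      f"T2 {g_t[1]:+.2f} ug/g")

lxt.write_fieldbook(book, "trial_book.csv")
print("wrote trial_book.csv (one row per plot; re-read with "
      "lxt.read_fieldbook)")
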