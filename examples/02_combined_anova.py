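"""Combined multi-environment line x tester ANOVA of provitamin A.

Partitions the hybrid variation into line (GCA), tester (GCA) and
line x tester (SCA) sources with their environment interactions, then
derives the summary statistics a breeder reads off such a table: CV%,
entry-mean repeatability, Baker's predictability ratio and the
proportional source contributions.
"""

import lxt

book, _ = lxt.simulate_trial(lxt.default_config(seed=1))
at = lxt.combined_anova(book, "provitamin_a")
print(at.to_frame(decimals=2)[["source", "df", "ms", "F", "sig"]]
      .to_string(index=False))

vc = lxt.variance_components(at)
print(f"\nCV = {lxt.cv_percent(at):.2f}%  (plot-to-plot noise relative "
      "to the grand mean)")
print(f"repeatability H = {lxt.repeatability(vc):.2f}  "
      "(fraction of entry-mean variance that is genetic)")
baker = lxt.baker_ratio(at.ms("Line"), at.ms("Tester"),
                        at.ms("Line x Tester"))
print(f"Baker ratio = {baker:.2f}  (near 1: hybrid performance is "
      "predictable from GCA alone)")
c = lxt.proportional_contributions(at, vc)
print(f"SS shares of the testcross variation: line {c.ss_line:.1f}%, "
      f"tester {c.ss_tester:.1f}%, line x tester {c.ss_lxt:.1f}%")
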