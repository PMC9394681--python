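"""Yield-provitamin A correlations and the tester-suitability summary.

Phenotypic correlations use pooled testcross means; genotypic
correlations are method-of-moments estimates from the ANOVA identities
(the classic dilution effect makes both negative for yield vs
provitamin A).  The tester summary gathers, per tester, the spread of
testcross means, the GCA sign and the genetic variance among its
testcrosses -- the evidence used to pick a tester.
"""

import lxt

book, _ = lxt.simulate_trial(lxt.default_config(seed=1))

r_p = lxt.phenotypic_correlation(book, "grain_yield", "provitamin_a")
r_g = lxt.genotypic_correlation(book, "grain_yield", "provitamin_a")
print(f"yield vs provitamin A (this trial): phenotypic r = {r_p:+.2f}, "
      f"genotypic r = {r_g.value:+.2f}"
      + (" (out of bounds)" if r_g.out_of_bounds else ""))

# a single trial estimates r_g noisily; averaging over independent trials
# shows the dilution effect the generator builds in (about -0.25)
import numpy as np
rgs = [lxt.genotypic_correlation(
    lxt.simulate_trial(lxt.default_config(seed=s))[0],
    "grain_yield", "provitamin_a").value for s in range(2, 42)]
print(f"mean genotypic r over 40 independent trials: {np.mean(rgs):+.2f}")

for tester in book.testers:
    gv = lxt.per_tester_genetic_variance(book, tester, "provitamin_a")
    print(f"{tester}: genetic variance among its testcrosses "
          f"{gv.value:.2f} +/- {gv.se:.2f} (ug/g)^2"
          + (" [truncated]" if gv.truncated else ""))

ev = lxt.tester_summary(book, ["provitamin_a", "grain_yield"])
print(ev.table.round(2).to_string(index=False))
print(ev.notes)
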