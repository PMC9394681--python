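"""Standard heterosis against the inter-tester hybrid T1 x T2.

Expresses each testcross mean as the percent deviation from the T1 x T2
reference (H = 100 (F1 - CK)/CK) and classifies every hybrid against the
best commercial check with an LSD from the combined-analysis error.
"""

import lxt
from lxt.heterosis import compare_to_check, count_in_interval

book, _ = lxt.simulate_trial(lxt.default_config(seed=1))

tab = lxt.heterosis_table(book, "T1xT2", ["grain_yield", "provitamin_a"])
for trait in ("grain_yield", "provitamin_a"):
    pos = count_in_interval(tab, trait, lo=0.0)
    ten = count_in_interval(tab, trait, lo=10.0)
    sub = tab[tab.trait == trait]
    print(f"{trait}: {pos}/120 testcrosses with positive heterosis, "
          f"{ten} with >= 10% (range {sub.h_percent.min():.0f}% to "
          f"{sub.h_percent.max():.0f}%)")

cmp_ = compare_to_check(book, "CHK1", "grain_yield")
counts = cmp_.counts()
print(f"\nvs check CHK1 (LSD {cmp_.lsd:.0f} kg/ha at alpha=0.05): "
      f"{counts.get('higher', 0)} higher, {counts.get('equal', 0)} equal, "
      f"{counts.get('lower', 0)} lower")
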