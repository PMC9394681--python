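"""GCA/SCA combining ability and the additive/non-additive partition.

Estimates tester and line general combining ability and the specific
combining ability of each cross from pooled testcross means, with
standard errors from the environment-interaction mean squares, then
splits the genetic variance into additive (2 v_GCA) and non-additive
(v_SCA) shares.
"""

import lxt

book, _ = lxt.simulate_trial(lxt.default_config(seed=1))

for trait in ("provitamin_a", "grain_yield"):
    ca = lxt.combining_ability(book, trait)
    tt = ca.tester_table()
    print(f"\n{trait}: tester GCA (+/- se)")
    for tester, row in tt.iterrows():
        print(f"  {tester}: {row.gca:+8.2f} +/- {row.se:.2f} {row.sig}")
    lines = ca.line_table().sort_values("gca", ascending=False)
    print(f"  best line GCAs: "
          + ", ".join(f"{i} {r.gca:+.2f}{r.sig}"
                      for i, r in lines.head(3).iterrows()))
    vc = lxt.variance_components(lxt.combined_anova(book, trait))
    add, non = lxt.additive_nonadditive_partition(vc)
    print(f"  genetic variance: {add:.0f}% additive, {non:.0f}% non-additive")

# positive-GCA lines for both target traits are candidate parents
gy = lxt.combining_ability(book, "grain_yield").gca_lines
pva = lxt.combining_ability(book, "provitamin_a").gca_lines
both = [i for i in gy.index if gy[i] > 0 and pva[i] > 0]
print(f"\nlines with positive GCA for both yield and provitamin A: "
      f"{len(both)} ({', '.join(both[:6])}, ...)")
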