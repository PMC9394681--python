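"""GCA/SCA effect estimation and the additive/non-additive partition.

On a complete l x t matrix of pooled testcross means the least-squares
estimates under sum-to-zero constraints are the classical marginal
deviations:

    g_i  = row mean    - grand mean        (line GCA)
    g_j  = column mean - grand mean        (tester GCA)
    s_ij = cell - row mean - column mean + grand mean   (SCA)

so mu + g_i + g_j + s_ij reconstructs every cell exactly.  Standard
errors use the random-environment denominators (each effect's source x
environment mean square), consistent with the ANOVA F tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .anova import AnovaTable, UndefinedStatisticError, VarianceComponents, \
    combined_anova, significance_code
from .fieldbook import FieldBook, FieldBookError, TestcrossMeanMatrix, \
    testcross_means

__all__ = [
    "CombiningAbilityResult",
    "EffectStandardErrors",
    "gca_sca_effects",
    "effect_standard_errors",
    "additive_nonadditive_partition",
    "combining_ability",
]


@dataclass
class EffectStandardErrors:
    """SEs of GCA/SCA effects with the denominator MS and df used."""

    se_gca_line: float
    se_gca_tester: float
    se_sca: float
    df_gca_line: int
    df_gca_tester: int
    df_sca: int


@dataclass
class CombiningAbilityResult:
    """GCA effects, SCA matrix, grand mean and (optionally) significance."""

    trait: str
    grand_mean: float
    gca_lines: pd.Series
    gca_testers: pd.Series
    sca: pd.DataFrame
    se: EffectStandardErrors | None = None

    def _stars(self, effects, se: float, df: int):
        tstat = effects / se
        p = 2.0 * stats.t.sf(np.abs(tstat), df)
        return p

    def line_table(self) -> pd.DataFrame:
        out = pd.DataFrame({"gca": self.gca_lines})
        if self.se is not None:
            out["se"] = self.se.se_gca_line
            out["p"] = self._stars(self.gca_lines, self.se.se_gca_line,
                                   self.se.df_gca_line)
            out["sig"] = [significance_code(p) for p in out["p"]]
        return out

    def tester_table(self) -> pd.DataFrame:
        out = pd.DataFrame({"gca": self.gca_testers})
        if self.se is not None:
            out["se"] = self.se.se_gca_tester
            out["p"] = self._stars(self.gca_testers, self.se.se_gca_tester,
                                   self.se.df_gca_tester)
            out["sig"] = [significance_code(p) for p in out["p"]]
        return out

    def sca_table(self) -> pd.DataFrame:
        long = self.sca.stack().rename("sca").reset_index()
        long.columns = ["line", "tester", "sca"]
        if self.se is not None:
            long["se"] = self.se.se_sca
            long["p"] = self._stars(long["sca"], self.se.se_sca,
                                    self.se.df_sca)
            long["sig"] = [significance_code(p) for p in long["p"]]
        return long


def gca_sca_effects(means: TestcrossMeanMatrix | pd.DataFrame,
                    trait: str = "") -> CombiningAbilityResult:
    """Closed-form GCA/SCA decomposition of a complete testcross mean matrix."""
    if isinstance(means, TestcrossMeanMatrix):
        trait = trait or means.trait
        values = means.values
    else:
        values = means
    if values.isna().any().any():
        cells = [(i, j) for i in values.index for j in values.columns
                 if pd.isna(values.loc[i, j])]
        raise FieldBookError(f"incomplete testcross mean matrix; missing "
                             f"cells {cells[:5]}")
    m = values.to_numpy(float)
    grand = m.mean()
    g_l = m.mean(axis=1) - grand
    g_t = m.mean(axis=0) - grand
    sca = m - m.mean(axis=1, keepdims=True) - m.mean(axis=0, keepdims=True) \
        + grand
    return CombiningAbilityResult(
        trait=trait,
        grand_mean=float(grand),
        gca_lines=pd.Series(g_l, index=values.index, name="gca"),
        gca_testers=pd.Series(g_t, index=values.columns, name="gca"),
        sca=pd.DataFrame(sca, index=values.index, columns=values.columns),
    )


def effect_standard_errors(anova: AnovaTable) -> EffectStandardErrors:
    """SEs of GCA/SCA effects from the random-environment denominators.

    se(g_line)   = sqrt(MS_LxE   / (r e t))
    se(g_tester) = sqrt(MS_TxE   / (r e l))
    se(s_ij)     = sqrt(MS_LxTxE / (r e))

    each with the denominator's degrees of freedom.  With one
    environment the pooled error replaces the interaction MS.
    """
    d = anova.dims
    l, t, e, r = d.n_lines, d.n_testers, d.n_envs, d.n_reps

    def ms_df(source: str) -> tuple[float, int]:
        if e == 1:
            return anova.ms("Error"), anova.df("Error")
        return anova.ms(source), anova.df(source)

    ms_le, df_le = ms_df("Line x Env")
    ms_te, df_te = ms_df("Tester x Env")
    ms_se, df_se = ms_df("Line x Tester x Env")
    for name, dfree in (("Line x Env", df_le), ("Tester x Env", df_te),
                        ("Line x Tester x Env", df_se)):
        if dfree <= 0:
            raise UndefinedStatisticError(
                f"zero degrees of freedom in denominator {name}")
    return EffectStandardErrors(
        se_gca_line=math.sqrt(ms_le / (r * e * t)),
        se_gca_tester=math.sqrt(ms_te / (r * e * l)),
        se_sca=math.sqrt(ms_se / (r * e)),
        df_gca_line=df_le, df_gca_tester=df_te, df_sca=df_se,
    )


def additive_nonadditive_partition(vc: VarianceComponents
                                   ) -> tuple[float, float]:
    """Percent additive vs non-additive genetic variance.

    Additive share = 2 (v_gca_line + v_gca_tester) /
                     (2 (v_gca_line + v_gca_tester) + v_sca), as percent;
    uses zero-truncated components.
    """
    v = vc.values
    add = 2.0 * (v["v_gca_line"] + v["v_gca_tester"])
    tot = add + v["v_sca"]
    if tot == 0:
        raise UndefinedStatisticError("all genetic variance components zero")
    return 100.0 * add / tot, 100.0 * (1.0 - add / tot)


def combining_ability(book: FieldBook, trait: str,
                      anova: AnovaTable | None = None
                      ) -> CombiningAbilityResult:
    """One-stop GCA/SCA analysis of a field book trait with SEs attached."""
    if anova is None:
        anova = combined_anova(book, trait)
    envs = sorted(book.plots.dropna(subset=[trait])["env"].unique())
    means = testcross_means(book.subset_envs(envs), trait)
    result = gca_sca_effects(means, trait)
    result.se = effect_standard_errors(anova)
    return result
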