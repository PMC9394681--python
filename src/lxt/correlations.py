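"""Genotypic and phenotypic trait correlations and tester evaluation.

Phenotypic correlations are product-moment correlations of pooled
testcross entry means.  Genotypic correlations are method-of-moments
estimates: genetic variances come from the balanced expected-mean-square
identities and the genetic covariance from the sum-trait identity

    cov_g(x, y) = ( v_g(x + y) - v_g(x) - v_g(y) ) / 2,

which equals the mean-cross-product computation on balanced data.  Both
restrict to the environments where *both* traits were scored, so traits
recorded in different environment subsets are compared on their common
environments.

The tester evaluation summarises, per tester, the genetic variance among
its testcrosses (one-way line x environment analysis), the spread of
testcross means, and GCA signs -- the quantities a breeder weighs when
judging tester suitability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .anova import UndefinedStatisticError, combined_anova, \
    variance_components
from .combining import gca_sca_effects
from .fieldbook import FieldBook, FieldBookError, testcross_means

__all__ = [
    "CorrelationResult",
    "GeneticVariance",
    "TesterEvaluation",
    "phenotypic_correlation",
    "genotypic_correlation",
    "per_tester_genetic_variance",
    "tester_summary",
]


def _common_env_book(book: FieldBook, trait_x: str, trait_y: str) -> FieldBook:
    for t in (trait_x, trait_y):
        if t not in book.traits:
            raise FieldBookError(f"unknown trait {t!r}")
    envs_x = set(book.plots.dropna(subset=[trait_x])["env"])
    envs_y = set(book.plots.dropna(subset=[trait_y])["env"])
    common = sorted(envs_x & envs_y)
    if not common:
        raise FieldBookError(
            f"no common environments for {trait_x!r} and {trait_y!r}")
    return book.subset_envs(common)


def phenotypic_correlation(book: FieldBook, trait_x: str,
                           trait_y: str) -> float:
    """Pearson correlation of pooled testcross means on common environments."""
    sub = _common_env_book(book, trait_x, trait_y)
    mx = testcross_means(sub, trait_x).values.to_numpy(float).ravel()
    my = testcross_means(sub, trait_y).values.to_numpy(float).ravel()
    ok = ~(np.isnan(mx) | np.isnan(my))
    if ok.sum() < 3:
        raise FieldBookError("need at least 3 testcross entries with both "
                             "trait means")
    if np.std(mx[ok]) == 0 or np.std(my[ok]) == 0:
        raise UndefinedStatisticError("zero variance in one trait")
    return float(stats.pearsonr(mx[ok], my[ok]).statistic)


@dataclass
class CorrelationResult:
    """A genotypic correlation with its bookkeeping.

    ``value`` may fall outside [-1, 1] because the component estimates
    are noisy; it is reported as computed with ``out_of_bounds`` set.
    """

    value: float
    out_of_bounds: bool
    cov_g: float
    v_g_x: float
    v_g_y: float


def genotypic_correlation(book: FieldBook, trait_x: str,
                          trait_y: str) -> CorrelationResult:
    """Method-of-moments genotypic correlation between two traits.

    Genetic variances v_g = v_gca_line + v_gca_tester + v_sca of x, y and
    the sum trait x+y are estimated from combined ANOVAs on the common
    environments (untruncated estimates, so the sum-trait identity stays
    exact); raises when either genetic variance is non-positive.
    """
    sub = _common_env_book(book, trait_x, trait_y)
    if trait_x == trait_y:
        return CorrelationResult(1.0, False, float("nan"), float("nan"),
                                 float("nan"))
    sum_name = "__sum__"
    sub.plots[sum_name] = sub.plots[trait_x] + sub.plots[trait_y]
    from .fieldbook import TraitSpec
    sub.traits[sum_name] = TraitSpec(sum_name, kind="derived",
                                     derived_from="sum")

    def v_g(trait: str) -> float:
        vc = variance_components(combined_anova(sub, trait))
        return vc.raw["v_gca_line"] + vc.raw["v_gca_tester"] + vc.raw["v_sca"]

    vx, vy, vxy = v_g(trait_x), v_g(trait_y), v_g(sum_name)
    if vx <= 0 or vy <= 0:
        raise UndefinedStatisticError(
            f"non-positive genetic variance (v_g(x)={vx:.4g}, "
            f"v_g(y)={vy:.4g}); genotypic correlation undefined")
    cov = (vxy - vx - vy) / 2.0
    r_g = cov / math.sqrt(vx * vy)
    return CorrelationResult(value=float(r_g), out_of_bounds=abs(r_g) > 1,
                             cov_g=float(cov), v_g_x=float(vx),
                             v_g_y=float(vy))


@dataclass
class GeneticVariance:
    """Per-tester genetic variance with its large-sample standard error."""

    tester: str
    trait: str
    value: float        # zero-truncated
    raw: float
    se: float
    truncated: bool


def per_tester_genetic_variance(book: FieldBook, tester: str,
                                trait: str) -> GeneticVariance:
    """Genetic variance among one tester's testcross means.

    One-way line x environment analysis of that tester's testcrosses:
    v_g = (MS_line - MS_line_x_env) / (r e), with the standard
    large-sample SE of a difference of independent mean squares
    sqrt( (2/(re)^2) (MS_L^2/(df_L+2) + MS_LxE^2/(df_LxE+2)) ).
    """
    if tester not in book.testers:
        raise FieldBookError(f"unknown tester {tester!r}")
    ids = [e.entry_id for e in book.testcrosses if e.tester_parent == tester]
    line_of = {e.entry_id: e.line_parent for e in book.testcrosses}
    df = book.plots[book.plots["entry"].isin(ids)][["env", "rep", "entry",
                                                    trait]].dropna(
                                                        subset=[trait])
    df = df.assign(line=df["entry"].map(line_of))
    l = df["line"].nunique()
    if l < 2:
        raise FieldBookError("need at least 2 lines per tester")
    e = df["env"].nunique()
    r = int(df.groupby(["env", "line"]).size().max())
    y = df[trait].to_numpy(float)
    grand = y.mean()
    lm = df.groupby("line")[trait].transform("mean").to_numpy()
    em = df.groupby("env")[trait].transform("mean").to_numpy()
    lem = df.groupby(["line", "env"])[trait].transform("mean").to_numpy()
    ss_line = float(((lm - grand) ** 2).sum())
    ss_lxe = float(((lem - lm - em + grand) ** 2).sum())
    df_line = l - 1
    df_lxe = (l - 1) * (e - 1)
    ms_line = ss_line / df_line
    if e > 1:
        ms_lxe = ss_lxe / df_lxe
    else:  # single environment: residual is the only error stratum
        resid = float(((y - lem) ** 2).sum())
        df_lxe = len(y) - l
        ms_lxe = resid / df_lxe
    c = r * e
    raw = (ms_line - ms_lxe) / c
    se = math.sqrt((2.0 / c ** 2) * (ms_line ** 2 / (df_line + 2)
                                     + ms_lxe ** 2 / (df_lxe + 2)))
    return GeneticVariance(tester=tester, trait=trait, value=max(raw, 0.0),
                           raw=raw, se=se, truncated=raw < 0)


@dataclass
class TesterEvaluation:
    """Per-tester trait summaries plus a textual suitability note."""

    table: pd.DataFrame   # tester, trait, min, mean, max, gca, v_g, v_g_se
    notes: str


def tester_summary(book: FieldBook, traits: list[str] | None = None,
                   target_traits: tuple[str, ...] = ("provitamin_a",
                                                     "grain_yield")
                   ) -> TesterEvaluation:
    """Min/mean/max of testcross means, GCA sign and genetic variance per tester.

    The suitability note ranks testers by (a) positive GCA for the target
    traits and (b) genetic variance among their testcrosses (a tester
    that spreads the lines apart is more informative).
    """
    traits = traits or book.trait_names
    recs = []
    for trait in traits:
        means = testcross_means(book, trait)
        gca = gca_sca_effects(means, trait) if \
            not means.values.isna().any().any() else None
        for tester in book.testers:
            col = means.values[tester].dropna()
            if col.empty:
                continue
            try:
                gv = per_tester_genetic_variance(book, tester, trait)
                v_g, v_g_se, v_tr = gv.value, gv.se, gv.truncated
            except FieldBookError:   # e.g. a single-line tester
                v_g = v_g_se = float("nan")
                v_tr = False
            recs.append({
                "tester": tester, "trait": trait,
                "min": float(col.min()), "mean": float(col.mean()),
                "max": float(col.max()),
                "gca": float(gca.gca_testers[tester]) if gca else float("nan"),
                "v_g": v_g, "v_g_se": v_g_se,
                "v_g_truncated": v_tr,
            })
    table = pd.DataFrame(recs)
    notes = []
    for tester in book.testers:
        sub = table[table["tester"] == tester]
        pos = [t for t in target_traits
               if t in set(sub["trait"])
               and float(sub.loc[sub["trait"] == t, "gca"].iloc[0]) > 0]
        vg_rank = []
        for t in set(sub["trait"]):
            row = table[table["trait"] == t].sort_values(
                "v_g", ascending=False)
            if len(row) and row.iloc[0]["tester"] == tester:
                vg_rank.append(t)
        notes.append(
            f"{tester}: positive GCA for {', '.join(pos) if pos else 'none'} "
            f"of the target traits; largest testcross genetic variance for "
            f"{len(vg_rank)} of {sub['trait'].nunique()} traits.")
    return TesterEvaluation(table=table, notes="\n".join(notes))
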