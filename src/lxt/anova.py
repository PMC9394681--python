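"""Combined multi-environment line x tester analysis of variance.

Implements the balanced-design source decomposition

    Env, Rep(Env), Block(Env:Rep), Hybrid, Testcross, Line, Tester,
    Line x Tester, Hybrid x Env, Line x Env, Tester x Env,
    Line x Tester x Env, Error

with closed-form sums of squares from plot data, F tests of each genetic
source against its environment-interaction term (environments random),
and the derived summary statistics: CV%, entry-mean repeatability,
Baker's predictability ratio, proportional source contributions and
method-of-moments variance components.

The lattice incomplete blocks enter as a single Block(Env:Rep) stratum,
fitted sequentially after all entry terms (intra-block adjustment), so
the genetic mean squares are identical with and without blocking; only
the error term is purified.  Environments without any observation for
the analysed trait are dropped (a trait measured in a subset of
environments is analysed over that subset).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .fieldbook import Design, FieldBook, FieldBookError

__all__ = [
    "AnovaTable",
    "VarianceComponents",
    "BalanceError",
    "UndefinedStatisticError",
    "combined_anova",
    "variance_components",
    "baker_ratio",
    "cv_percent",
    "repeatability",
    "proportional_contributions",
    "significance_code",
]

#: row order of the combined analysis, mirroring published testcross tables
SOURCE_ORDER = [
    "Env", "Rep(Env)", "Block(Env:Rep)", "Hybrid", "Testcross", "Line",
    "Tester", "Line x Tester", "Hybrid x Env", "Line x Env", "Tester x Env",
    "Line x Tester x Env", "Error",
]


class BalanceError(FieldBookError):
    """Raised when testcross x environment cells are incomplete."""


class UndefinedStatisticError(ValueError):
    """Raised when a ratio statistic is undefined (zero denominator)."""


def significance_code(p: float | None) -> str:
    """``**`` at p<0.01, ``*`` at p<0.05, empty otherwise."""
    if p is None or (isinstance(p, float) and math.isnan(p)):
        return ""
    return "**" if p < 0.01 else "*" if p < 0.05 else ""


@dataclass
class AnovaTable:
    """Ordered ANOVA rows plus the quantities the summaries need."""

    trait: str
    table: pd.DataFrame          # source, df, ss, ms, F, p, error_term
    grand_mean: float            # over all hybrid plots used
    n_plots: int
    dims: Design                 # l, t, e (used for this trait), r
    testcross_mean: float = float("nan")
    extra_ms: dict[str, tuple[float, int]] = field(default_factory=dict)

    def row(self, source: str) -> pd.Series:
        m = self.table["source"] == source
        if not m.any():
            raise KeyError(f"no source {source!r}")
        return self.table[m].iloc[0]

    def ms(self, source: str) -> float:
        return float(self.row(source)["ms"])

    def df(self, source: str) -> int:
        return int(self.row(source)["df"])

    def to_frame(self, decimals: int | None = None) -> pd.DataFrame:
        """Render with significance suffixes, publication-table style."""
        out = self.table.copy()
        out["sig"] = [significance_code(p) for p in out["p"]]
        if decimals is not None:
            for col in ("ss", "ms", "F"):
                out[col] = np.round(out[col].astype(float), decimals)
        return out


def _named_cells(cells: list[tuple]) -> str:
    head = ", ".join(map(str, cells[:5]))
    more = f" (+{len(cells) - 5} more)" if len(cells) > 5 else ""
    return head + more


def combined_anova(book: FieldBook, trait: str) -> AnovaTable:
    """Combined ANOVA of one trait across the environments where it was scored.

    Requires complete, balanced data: every hybrid entry observed once per
    replicate in every included environment.  Incomplete cells abort with
    an error naming them (no imputation).
    """
    if trait not in book.traits:
        raise FieldBookError(f"unknown trait {trait!r}")
    hybrids = [e.entry_id for e in book.entries.values()
               if e.role in ("testcross", "check", "tester_cross")]
    df = book.plots[book.plots["entry"].isin(hybrids)].copy()
    df = df[["env", "rep", "block", "entry", trait]]
    envs = sorted(df.dropna(subset=[trait])["env"].unique())
    if not envs:
        raise BalanceError(f"no observations for trait {trait!r}")
    df = df[df["env"].isin(envs)]

    missing = df[df[trait].isna()]
    if len(missing):
        cells = list(missing[["env", "rep", "entry"]].itertuples(
            index=False, name=None))
        raise BalanceError(
            f"missing cells for {trait!r}: {_named_cells(cells)}")
    counts = df.groupby(["env", "rep", "entry"]).size()
    expected = {(ev, rp, en) for ev in envs
                for rp in df["rep"].unique() for en in hybrids}
    absent = sorted(expected - set(counts.index))
    bad = counts[counts != 1].index.tolist()
    if bad or absent:
        raise BalanceError(
            f"unbalanced testcross x environment cells for {trait!r}: "
            f"{_named_cells(bad + absent)}")

    e = len(envs)
    reps = sorted(df["rep"].unique())
    r = len(reps)
    n_entries = len(hybrids)
    y = df[trait].to_numpy(float)
    N = len(y)
    grand = y.mean()

    # orthogonal strata under balance
    env_mean = df.groupby("env")[trait].transform("mean").to_numpy()
    rep_mean = df.groupby(["env", "rep"])[trait].transform("mean").to_numpy()
    ent_mean = df.groupby("entry")[trait].transform("mean").to_numpy()
    cell_mean = df.groupby(["entry", "env"])[trait].transform("mean").to_numpy()

    ss_total = float(((y - grand) ** 2).sum())
    ss_env = float(((env_mean - grand) ** 2).sum())
    ss_rep = float(((rep_mean - env_mean) ** 2).sum())
    ss_hybrid = float(((ent_mean - grand) ** 2).sum())
    ss_hxe = float(((cell_mean - ent_mean - env_mean + grand) ** 2).sum())

    # intra-block partition of the remainder: block after all entry terms
    eps = y - cell_mean - (rep_mean - env_mean)
    ss_remainder = float((eps ** 2).sum())
    blocks = (df["env"] + "|" + df["rep"].astype(str) + "|" + df["block"])
    n_blocks = blocks.groupby([df["env"], df["rep"]]).nunique()
    df_block = int((n_blocks - 1).sum())
    if df_block > 0:
        b_codes = pd.factorize(blocks)[0]
        B = np.zeros((N, b_codes.max() + 1))
        B[np.arange(N), b_codes] = 1.0

        def _group_mean(M: np.ndarray, key) -> np.ndarray:
            codes = pd.factorize(key)[0]
            G = np.zeros((len(codes), codes.max() + 1))
            G[np.arange(len(codes)), codes] = 1.0
            cnt = np.bincount(codes).astype(float)
            return G @ ((G.T @ M) / cnt[:, None])

        # project block dummies off the entry-mean and replicate strata
        cm = _group_mean(B, (df["entry"] + "@" + df["env"]).to_numpy())
        rm = _group_mean(B, (df["env"] + "|" + df["rep"].astype(str)).to_numpy())
        em = _group_mean(B, df["env"].to_numpy())
        Bt = B - cm - (rm - em)
        rhs = Bt.T @ eps
        coef, *_ = np.linalg.lstsq(Bt.T @ Bt, rhs, rcond=None)
        ss_block = float(rhs @ coef)
    else:
        ss_block = 0.0
    ss_error = max(ss_remainder - ss_block, 0.0)
    # within-cell df e*(n-1)*(r-1), minus the block stratum
    df_error = (n_entries - 1) * (r - 1) * e - df_block

    # genetic partition among testcrosses only
    parent = {x.entry_id: (x.line_parent, x.tester_parent)
              for x in book.testcrosses}
    tcd = df[df["entry"].isin(parent)].copy()
    tcd["line"] = tcd["entry"].map(lambda x: parent[x][0])
    tcd["tester"] = tcd["entry"].map(lambda x: parent[x][1])
    l = tcd["line"].nunique()
    t = tcd["tester"].nunique()
    yt = tcd[trait].to_numpy(float)
    g_t = yt.mean()
    lm = tcd.groupby("line")[trait].transform("mean").to_numpy()
    tm = tcd.groupby("tester")[trait].transform("mean").to_numpy()
    cm_lt = tcd.groupby(["line", "tester"])[trait].transform("mean").to_numpy()
    em_t = tcd.groupby("env")[trait].transform("mean").to_numpy()
    lem = tcd.groupby(["line", "env"])[trait].transform("mean").to_numpy()
    tem = tcd.groupby(["tester", "env"])[trait].transform("mean").to_numpy()
    cem = tcd.groupby(["line", "tester", "env"])[trait].transform("mean").to_numpy()

    ss_tc = float(((cm_lt - g_t) ** 2).sum())
    ss_line = float(((lm - g_t) ** 2).sum())
    ss_tester = float(((tm - g_t) ** 2).sum())
    ss_lxt = float(((cm_lt - lm - tm + g_t) ** 2).sum())
    ss_lxe = float(((lem - lm - em_t + g_t) ** 2).sum())
    ss_txe = float(((tem - tm - em_t + g_t) ** 2).sum())
    ss_lte = float(((cem - lem - tem - cm_lt + lm + tm + em_t - g_t) ** 2).sum())

    rows = {
        "Env": (e - 1, ss_env, "Error"),
        "Rep(Env)": (e * (r - 1), ss_rep, "Error"),
        "Block(Env:Rep)": (df_block, ss_block, "Error"),
        "Hybrid": (n_entries - 1, ss_hybrid, "Hybrid x Env"),
        "Testcross": (l * t - 1, ss_tc, "Testcross x Env"),
        "Line": (l - 1, ss_line, "Line x Env"),
        "Tester": (t - 1, ss_tester, "Tester x Env"),
        "Line x Tester": ((l - 1) * (t - 1), ss_lxt, "Line x Tester x Env"),
        "Hybrid x Env": ((n_entries - 1) * (e - 1), ss_hxe, "Error"),
        "Line x Env": ((l - 1) * (e - 1), ss_lxe, "Error"),
        "Tester x Env": ((t - 1) * (e - 1), ss_txe, "Error"),
        "Line x Tester x Env": ((l - 1) * (t - 1) * (e - 1), ss_lte, "Error"),
        "Error": (df_error, ss_error, ""),
    }
    if df_error <= 0:
        raise BalanceError("zero error degrees of freedom "
                           "(single replicate without blocking)")

    # pooled testcross x env denominator for the Testcross row
    df_tce = (l * t - 1) * (e - 1)
    ms_tce = (ss_lxe + ss_txe + ss_lte) / df_tce if e > 1 and df_tce else np.nan
    ms_err = ss_error / df_error

    def denom(label: str) -> tuple[float, int]:
        if label == "Testcross x Env":
            return ms_tce, df_tce
        if label == "":
            return np.nan, 0
        d, s, _ = rows[label]
        return (s / d if d > 0 else np.nan), d

    recs = []
    for source in SOURCE_ORDER:
        dfree, ss, err_label = rows[source]
        ms = ss / dfree if dfree > 0 else np.nan
        if e == 1 and source.endswith("x Env"):
            continue
        f = p = np.nan
        if err_label and dfree > 0:
            dms, ddf = denom(err_label)
            if np.isfinite(dms) and dms > 0 and ddf > 0:
                f = ms / dms
                p = float(stats.f.sf(f, dfree, ddf))
        recs.append((source, dfree, ss, ms, f, p, err_label))
    table = pd.DataFrame(recs, columns=["source", "df", "ss", "ms", "F", "p",
                                        "error_term"])
    return AnovaTable(trait=trait, table=table, grand_mean=float(grand),
                     n_plots=N, dims=Design(l, t, e, r),
                     testcross_mean=float(g_t),
                     extra_ms={"Testcross x Env": (float(ms_tce), df_tce),
                               "Error": (float(ms_err), df_error)})


# ---------------------------------------------------------------------------
# variance components (method of moments on balanced expected mean squares)
# ---------------------------------------------------------------------------

@dataclass
class VarianceComponents:
    """Method-of-moments component estimates with SEs and truncation flags.

    ``raw`` holds the unbiased estimates (possibly negative); ``values``
    the zero-truncated ones used for reporting; ``truncated`` flags which
    components were clipped -- truncation is never silent.
    """

    trait: str
    raw: dict[str, float]
    se: dict[str, float]
    truncated: dict[str, bool]
    dims: Design

    @property
    def values(self) -> dict[str, float]:
        return {k: max(v, 0.0) for k, v in self.raw.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "component": list(self.raw),
            "estimate": [self.values[k] for k in self.raw],
            "raw": list(self.raw.values()),
            "se": [self.se[k] for k in self.raw],
            "truncated": [self.truncated[k] for k in self.raw],
        })


def _ms_var(ms: float, df: int) -> float:
    # large-sample Var(MS) = 2 MS^2 / (df + 2)
    return 2.0 * ms ** 2 / (df + 2) if df > 0 else np.nan


def variance_components(anova: AnovaTable) -> VarianceComponents:
    """Equate observed to expected mean squares of the balanced design.

    With environments random and effects identified by the sum-to-zero
    convention, the solving identities are::

        v_sca        = (MS_LxT - MS_LxTxE) / (r e)
        v_gca_line   = (MS_L   - MS_LxE)   / (r e t)
        v_gca_tester = (MS_T   - MS_TxE)   / (r e l)
        v_line_env   = (MS_LxE   - MS_err) / (r t)
        v_tester_env = (MS_TxE   - MS_err) / (r l)
        v_sca_env    = (MS_LxTxE - MS_err) / r
        v_residual   =  MS_err

    Standard errors use the large-sample variance of linear combinations
    of independent mean squares.
    """
    d = anova.dims
    l, t, e, r = d.n_lines, d.n_testers, d.n_envs, d.n_reps
    one_env = e == 1

    def ms_df(source: str) -> tuple[float, int]:
        if one_env and source.endswith("x Env"):
            return anova.ms("Error"), anova.df("Error")
        return anova.ms(source), anova.df(source)

    pairs = {
        "v_gca_line": ("Line", "Line x Env", r * e * t),
        "v_gca_tester": ("Tester", "Tester x Env", r * e * l),
        "v_sca": ("Line x Tester", "Line x Tester x Env", r * e),
        "v_line_env": ("Line x Env", "Error", r * t),
        "v_tester_env": ("Tester x Env", "Error", r * l),
        "v_sca_env": ("Line x Tester x Env", "Error", r),
    }
    raw, se = {}, {}
    for name, (num, den, c) in pairs.items():
        if one_env and name.endswith("_env"):
            raw[name], se[name] = 0.0, np.nan
            continue
        ms1, df1 = ms_df(num)
        ms2, df2 = ms_df(den)
        raw[name] = (ms1 - ms2) / c
        se[name] = math.sqrt((_ms_var(ms1, df1) + _ms_var(ms2, df2)) / c ** 2)
    ms_err, df_err = anova.ms("Error"), anova.df("Error")
    raw["v_residual"] = ms_err
    se["v_residual"] = math.sqrt(_ms_var(ms_err, df_err))
    truncated = {k: v < 0 for k, v in raw.items()}
    return VarianceComponents(trait=anova.trait, raw=raw, se=se,
                              truncated=truncated, dims=d)


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def baker_ratio(ms_line: float, ms_tester: float, ms_sca: float) -> float:
    """Baker's predictability ratio 2*MS_GCA / (2*MS_GCA + MS_SCA).

    MS_GCA is the combined GCA mean square (line + tester).  A ratio near
    one means hybrid performance is predictable from GCA alone.
    """
    for name, v in (("ms_line", ms_line), ("ms_tester", ms_tester),
                    ("ms_sca", ms_sca)):
        if v <= 0:
            raise UndefinedStatisticError(f"{name} must be positive, got {v}")
    ms_gca = ms_line + ms_tester
    return 2.0 * ms_gca / (2.0 * ms_gca + ms_sca)


def cv_percent(anova: AnovaTable) -> float:
    """Coefficient of variation: 100 * sqrt(MS_error) / grand mean."""
    if anova.grand_mean == 0:
        raise UndefinedStatisticError("grand mean is zero; CV undefined")
    return 100.0 * math.sqrt(anova.ms("Error")) / anova.grand_mean


def repeatability(vc: VarianceComponents, e: int | None = None,
                  r: int | None = None) -> float:
    """Broad-sense repeatability on an entry-mean basis.

    H = v_g / (v_g + v_gxe / e + v_residual / (e r)) with
    v_g = v_gca_line + v_gca_tester + v_sca and v_gxe the sum of the three
    interaction components (zero-truncated estimates).
    """
    e = e if e is not None else vc.dims.n_envs
    r = r if r is not None else vc.dims.n_reps
    if e < 1 or r < 1:
        raise UndefinedStatisticError("need e, r >= 1")
    v = vc.values
    v_g = v["v_gca_line"] + v["v_gca_tester"] + v["v_sca"]
    v_ge = v["v_line_env"] + v["v_tester_env"] + v["v_sca_env"]
    denom = v_g + v_ge / e + v["v_residual"] / (e * r)
    if denom == 0:
        raise UndefinedStatisticError("all variance components are zero")
    return v_g / denom


@dataclass
class SourceContributions:
    """Proportional contributions of line, tester, line x tester.

    Two labelled definitions: shares of the testcross sum of squares
    (``ss_*``, additive, sum to 100) and shares of the genetic variance
    components (``vc_*``).
    """

    ss_line: float
    ss_tester: float
    ss_lxt: float
    vc_line: float
    vc_tester: float
    vc_sca: float


def proportional_contributions(anova: AnovaTable,
                               vc: VarianceComponents | None = None
                               ) -> SourceContributions:
    ss_tc = anova.row("Testcross")["ss"]
    if ss_tc == 0:
        raise UndefinedStatisticError("zero testcross sum of squares")
    ss = {s: float(anova.row(s)["ss"]) for s in
          ("Line", "Tester", "Line x Tester")}
    if vc is None:
        vc = variance_components(anova)
    v = vc.values
    v_g = v["v_gca_line"] + v["v_gca_tester"] + v["v_sca"]
    vshare = (lambda x: 100.0 * x / v_g) if v_g > 0 else (lambda x: float("nan"))
    return SourceContributions(
        ss_line=100.0 * ss["Line"] / ss_tc,
        ss_tester=100.0 * ss["Tester"] / ss_tc,
        ss_lxt=100.0 * ss["Line x Tester"] / ss_tc,
        vc_line=vshare(v["v_gca_line"]),
        vc_tester=vshare(v["v_gca_tester"]),
        vc_sca=vshare(v["v_sca"]),
    )
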