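"""Combined ANOVA: df bookkeeping, SS identities, oracle equivalence,
Baker ratio, CV, repeatability and proportional contributions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import lxt
from lxt.anova import (BalanceError, UndefinedStatisticError, baker_ratio,
                       combined_anova, cv_percent, proportional_contributions,
                       repeatability)
from lxt.simulate import simulate_trial

from conftest import sequential_ss, small_config


def test_df_bookkeeping_small_dims(small_book):
    at = combined_anova(small_book, "grain_yield")
    df = {r.source: r.df for r in at.table.itertuples()}
    # l=4, t=2, e=2, r=2, no checks
    assert df["Line"] == 3 and df["Tester"] == 1 and df["Line x Tester"] == 3
    assert df["Testcross"] == 7 == df["Hybrid"]
    assert df["Line x Env"] == 3 and df["Tester x Env"] == 1
    assert df["Line x Tester x Env"] == 3
    assert df["Error"] == (8 - 1) * (2 - 1) * 2
    # the non-overlapping strata partition the total df
    strata = ["Env", "Rep(Env)", "Block(Env:Rep)", "Hybrid", "Hybrid x Env",
              "Error"]
    assert sum(df[s] for s in strata) + 1 == at.n_plots


def test_ms_equals_ss_over_df(small_book):
    at = combined_anova(small_book, "grain_yield")
    for r in at.table.itertuples():
        if r.df > 0:
            assert r.ms == pytest.approx(r.ss / r.df)


def test_testcross_ss_additivity(default_book):
    at = combined_anova(default_book, "provitamin_a")
    assert at.row("Testcross")["ss"] == pytest.approx(
        at.row("Line")["ss"] + at.row("Tester")["ss"]
        + at.row("Line x Tester")["ss"], rel=1e-10)
    # and the same for the interaction stratum
    tce = at.extra_ms["Testcross x Env"]
    assert tce[0] * tce[1] == pytest.approx(
        at.row("Line x Env")["ss"] + at.row("Tester x Env")["ss"]
        + at.row("Line x Tester x Env")["ss"], rel=1e-10)


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_oracle_equivalence_sequential_least_squares(seed):
    """Closed-form SS match brute-force sequential least squares."""
    cfg = small_config(seed=seed, l=int(np.random.default_rng(seed).integers(2, 5)))
    book, _ = simulate_trial(cfg)
    at = combined_anova(book, "grain_yield")
    parent = {e.entry_id: (e.line_parent, e.tester_parent)
              for e in book.testcrosses}
    df = book.plots.copy()
    df["line"] = df["entry"].map(lambda x: parent[x][0])
    df["tester"] = df["entry"].map(lambda x: parent[x][1])
    ss = sequential_ss(df, "grain_yield",
                       [["env"], ["env", "rep"], ["line"], ["tester"],
                        ["line", "tester"], ["line", "env"],
                        ["tester", "env"], ["line", "tester", "env"]])
    labels = ["Env", "Rep(Env)", "Line", "Tester", "Line x Tester",
              "Line x Env", "Tester x Env", "Line x Tester x Env"]
    for lab, want in zip(labels, ss):
        got = float(at.row(lab)["ss"])
        assert got == pytest.approx(want, rel=1e-8, abs=1e-8), lab


def test_single_env_toy_matches_oracle():
    book, _ = simulate_trial(small_config(seed=9, l=2, e=1))
    at = combined_anova(book, "grain_yield")
    df = book.plots.copy()
    parent = {e.entry_id: (e.line_parent, e.tester_parent)
              for e in book.testcrosses}
    df["line"] = df["entry"].map(lambda x: parent[x][0])
    df["tester"] = df["entry"].map(lambda x: parent[x][1])
    ss = sequential_ss(df, "grain_yield",
                       [["rep"], ["line"], ["tester"], ["line", "tester"]])
    for lab, want in zip(["Rep(Env)", "Line", "Tester", "Line x Tester"], ss):
        assert float(at.row(lab)["ss"]) == pytest.approx(want, rel=1e-8,
                                                         abs=1e-8)


def test_missing_cell_aborts_with_named_cell(small_book):
    plots = small_book.plots.copy()
    plots.loc[plots.index[3], "grain_yield"] = np.nan
    book = lxt.FieldBook(small_book.entries.values(),
                         small_book.traits.values(), plots)
    with pytest.raises(BalanceError, match="missing cells"):
        combined_anova(book, "grain_yield")


def test_unbalanced_cells_abort(small_book):
    book = lxt.FieldBook(small_book.entries.values(),
                         small_book.traits.values(),
                         small_book.plots.iloc[1:])
    with pytest.raises(BalanceError, match="unbalanced"):
        combined_anova(book, "grain_yield")


def test_block_stratum_purifies_error_not_genetics():
    """Genetic MS are identical with and without the lattice blocks."""
    cfg = lxt.default_config(seed=3)
    book, _ = simulate_trial(cfg)
    at = combined_anova(book, "grain_yield")
    flat = book.plots.copy()
    flat["block"] = "B1"
    book2 = lxt.FieldBook(book.entries.values(), book.traits.values(), flat)
    at2 = combined_anova(book2, "grain_yield")
    for lab in ("Line", "Tester", "Line x Tester", "Hybrid"):
        assert at.ms(lab) == pytest.approx(at2.ms(lab), rel=1e-12)
    assert at.df("Block(Env:Rep)") == 480 and at2.df("Block(Env:Rep)") == 0
    assert at.df("Error") + 480 == at2.df("Error")
    assert at.row("Error")["ss"] <= at2.row("Error")["ss"]


# ---------------------------------------------------------------------------
# Baker ratio
# ---------------------------------------------------------------------------

def test_baker_pure_gca_limit():
    assert baker_ratio(10.0, 5.0, 1e-12) == pytest.approx(1.0)


def test_baker_rejects_nonpositive():
    with pytest.raises(UndefinedStatisticError):
        baker_ratio(0.0, 1.0, 1.0)


@settings(max_examples=50, deadline=None)
@given(st.floats(0.1, 1e6), st.floats(0.1, 1e6), st.floats(0.1, 1e6),
       st.floats(1.01, 2.0))
def test_baker_monotonicity(ms_l, ms_t, ms_s, bump):
    base = baker_ratio(ms_l, ms_t, ms_s)
    assert baker_ratio(ms_l * bump, ms_t, ms_s) > base
    assert baker_ratio(ms_l, ms_t * bump, ms_s) > base
    assert baker_ratio(ms_l, ms_t, ms_s * bump) < base
    assert 0 < base <= 1


# ---------------------------------------------------------------------------
# CV, repeatability, contributions
# ---------------------------------------------------------------------------

def test_cv_simple_cases(small_book):
    at = combined_anova(small_book, "grain_yield")
    at.grand_mean = 20.0
    at.table.loc[at.table["source"] == "Error", "ss"] = \
        4.0 * at.df("Error")
    at.table.loc[at.table["source"] == "Error", "ms"] = 4.0
    assert cv_percent(at) == pytest.approx(10.0)
    at.table.loc[at.table["source"] == "Error", "ms"] = 0.0
    assert cv_percent(at) == 0.0
    at.grand_mean = 0.0
    with pytest.raises(UndefinedStatisticError):
        cv_percent(at)


def test_cv_tracks_configured_noise():
    """With residual sd = 10% of the mean, CV estimates approach 10%."""
    cfg = small_config(seed=2, l=30, e=4, v_line=0, v_tester=0, v_sca=0,
                       v_env=0, v_rep=0, v_line_env=0, v_tester_env=0,
                       v_sca_env=0, v_residual=(0.1 * 6190.0) ** 2)
    book, _ = simulate_trial(cfg)
    at = combined_anova(book, "grain_yield")
    assert cv_percent(at) == pytest.approx(10.0, rel=0.1)


class _VC:
    def __init__(self, **kw):
        from lxt.anova import VarianceComponents
        from lxt.fieldbook import Design
        raw = {"v_gca_line": 0.0, "v_gca_tester": 0.0, "v_sca": 0.0,
               "v_line_env": 0.0, "v_tester_env": 0.0, "v_sca_env": 0.0,
               "v_residual": 0.0}
        raw.update(kw)
        self.vc = VarianceComponents("x", raw, {k: 0.0 for k in raw},
                                     {k: False for k in raw},
                                     Design(2, 2, 2, 2))


def test_repeatability_limits():
    assert repeatability(_VC(v_gca_line=1.0).vc, e=4, r=2) == 1.0
    assert repeatability(_VC(v_residual=3.0).vc, e=4, r=2) == 0.0
    with pytest.raises(UndefinedStatisticError):
        repeatability(_VC().vc, e=4, r=2)


def test_repeatability_closed_form():
    vc = _VC(v_gca_line=2.0, v_sca=1.0, v_line_env=4.0, v_residual=8.0).vc
    want = 3.0 / (3.0 + 4.0 / 4 + 8.0 / 8)
    assert repeatability(vc, e=4, r=2) == pytest.approx(want)


def test_contributions_sum_to_100(default_book):
    at = combined_anova(default_book, "provitamin_a")
    c = proportional_contributions(at)
    assert c.ss_line + c.ss_tester + c.ss_lxt == pytest.approx(100.0)


def test_contributions_line_only_variation():
    cfg = small_config(seed=4, l=10, v_tester=0, v_sca=0, v_tester_env=0,
                       v_sca_env=0, v_line_env=0, v_residual=10.0,
                       v_line=1e8)
    book, _ = simulate_trial(cfg)
    c = proportional_contributions(combined_anova(book, "grain_yield"))
    assert c.ss_line > 99.0 and c.ss_tester < 1.0 and c.ss_lxt < 1.0


def test_published_pva_mean_squares_give_known_ss_shares():
    """SS shares recomputed from a printed carotenoid ANOVA (MS x df)."""
    ss_line, ss_tester, ss_lxt = 59 * 45.35, 1 * 1498.54, 59 * 5.94
    total = ss_line + ss_tester + ss_lxt
    assert 100 * ss_line / total == pytest.approx(59.1, abs=0.05)
    assert 100 * ss_tester / total == pytest.approx(33.1, abs=0.05)
    assert 100 * ss_lxt / total == pytest.approx(7.7, abs=0.05)
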