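"""Field-book I/O, validation and testcross-mean conventions."""

import io
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import lxt
from lxt.fieldbook import (Entry, FieldBook, FieldBookError, TraitSpec,
                           read_fieldbook, write_fieldbook)
from lxt.fieldbook import testcross_means as tc_means

TOY = textwrap.dedent("""\
    env,rep,block,entry,role,line_parent,tester_parent,gy
    E1,1,B1,L1xT1,testcross,L1,T1,4.0
    E1,1,B1,CHK1,check,,,3.5
    E2,1,B1,L1xT1,testcross,L1,T1,6.0
    E2,1,B1,CHK1,check,,,3.0
    """)


def test_toy_roundtrip_identity(tmp_path):
    book = read_fieldbook(io.StringIO(TOY))
    assert len(book.plots) == 4
    d = book.design
    assert (d.n_lines, d.n_testers, d.n_envs, d.n_reps) == (1, 1, 2, 1)
    out = tmp_path / "book.csv"
    write_fieldbook(book, out)
    again = read_fieldbook(out)
    pd.testing.assert_frame_equal(book.plots, again.plots)


def test_duplicate_plot_key_names_rows():
    dup = TOY + "E2,1,B1,CHK1,check,,,3.1\n"
    with pytest.raises(FieldBookError, match="duplicate plot key"):
        read_fieldbook(io.StringIO(dup))


def test_unknown_role_rejected():
    bad = TOY.replace("check", "controll")
    with pytest.raises(FieldBookError, match="role"):
        read_fieldbook(io.StringIO(bad))


def test_non_numeric_trait_cell_located():
    bad = TOY.replace("6.0", "6,0".replace(",", ";"))
    with pytest.raises(FieldBookError, match="non-numeric.*row"):
        read_fieldbook(io.StringIO(bad))


def test_missing_cell_preserved_not_zero(tmp_path):
    txt = TOY.replace("6.0", "")
    book = read_fieldbook(io.StringIO(txt))
    assert book.plots["gy"].isna().sum() == 1
    out = tmp_path / "b.csv"
    write_fieldbook(book, out)
    again = read_fieldbook(out)
    assert again.plots["gy"].isna().sum() == 1


def test_simulated_book_roundtrips_bit_identically(tmp_path, default_book):
    path = tmp_path / "sim.csv"
    write_fieldbook(default_book, path)
    again = read_fieldbook(path)
    for trait in default_book.trait_names:
        a = default_book.plots[trait].to_numpy()
        b = again.plots[trait].to_numpy()
        assert np.array_equal(a, b, equal_nan=True), trait
    assert {e.entry_id: e.role for e in again.entries.values()} == \
        {e.entry_id: e.role for e in default_book.entries.values()}


def test_tab_separator_accepted(tmp_path):
    path = tmp_path / "tabbed.tsv"
    path.write_text(TOY.replace(",", "\t"))
    book = read_fieldbook(path)
    assert len(book.plots) == 4


# ---------------------------------------------------------------------------
# testcross means
# ---------------------------------------------------------------------------

def _one_cell_book(values, envs=None):
    entries = [Entry("L1xT1", "testcross", "L1", "T1")]
    envs = envs or ["E1"] * len(values)
    plots = pd.DataFrame({
        "env": envs, "rep": range(1, len(values) + 1),
        "block": "B1", "entry": "L1xT1", "gy": values})
    # rep numbers must make plot keys unique within env
    plots["rep"] = plots.groupby("env").cumcount() + 1
    return FieldBook(entries, [TraitSpec("gy")], plots)


def test_single_cell_mean():
    book = _one_cell_book([4.0, 6.0])
    assert tc_means(book, "gy").values.iloc[0, 0] == 5.0


def test_balanced_pooling_commutes_with_env_averaging(default_book):
    plot = tc_means(default_book, "grain_yield", convention="plot")
    env = tc_means(default_book, "grain_yield", convention="env_mean")
    np.testing.assert_allclose(plot.values.to_numpy(), env.values.to_numpy(),
                               rtol=1e-12)


def test_unbalanced_pooling_conventions_differ():
    # cell supports 2 (E1) and 1 (E2): plot mean (4+6+9)/3, env-mean mean (5+9)/2
    book = _one_cell_book([4.0, 6.0, 9.0], envs=["E1", "E1", "E2"])
    plot = tc_means(book, "gy", convention="plot")
    env = tc_means(book, "gy", convention="env_mean")
    assert plot.values.iloc[0, 0] == pytest.approx(19 / 3)
    assert env.values.iloc[0, 0] == pytest.approx(7.0)
    assert plot.counts.iloc[0, 0] == 3


def test_fully_missing_cell_flagged():
    entries = [Entry("L1xT1", "testcross", "L1", "T1"),
               Entry("L2xT1", "testcross", "L2", "T1")]
    plots = pd.DataFrame({"env": "E1", "rep": [1, 1], "block": "B1",
                          "entry": ["L1xT1", "L2xT1"],
                          "gy": [5.0, np.nan]})
    book = FieldBook(entries, [TraitSpec("gy")], plots)
    mm = tc_means(book, "gy")
    assert mm.missing_cells == [("L2", "T1")]


# ---------------------------------------------------------------------------
# validation rejects corrupted books (property test)
# ---------------------------------------------------------------------------

@settings(max_examples=25, deadline=None)
@given(st.sampled_from(["dup_key", "unknown_entry", "score_out_of_range",
                        "negative_concentration"]),
       st.integers(min_value=0, max_value=10_000))
def test_validation_rejects_corrupted_books(corruption, seed):
    rng = np.random.default_rng(seed)
    entries = [Entry(f"L{i}xT1", "testcross", f"L{i}", "T1") for i in range(3)]
    plots = pd.DataFrame({
        "env": "E1", "rep": [1, 1, 1], "block": "B1",
        "entry": [e.entry_id for e in entries],
        "score": rng.uniform(1, 5, 3), "conc": rng.uniform(0, 9, 3)})
    traits = [TraitSpec("score", score_range=(1, 5)),
              TraitSpec("conc", bounds=(0, np.inf))]
    row = int(rng.integers(0, 3))
    if corruption == "dup_key":
        plots = pd.concat([plots, plots.iloc[[row]]], ignore_index=True)
    elif corruption == "unknown_entry":
        plots.loc[row, "entry"] = "GHOST"
    elif corruption == "score_out_of_range":
        plots.loc[row, "score"] = rng.choice([0.2, 6.5])
    else:
        plots.loc[row, "conc"] = -abs(rng.normal()) - 0.1
    with pytest.raises(FieldBookError):
        FieldBook(entries, traits, plots)
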