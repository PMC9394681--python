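"""Shared fixtures: small seeded trial books and brute-force oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import lxt
from lxt.simulate import SimulationConfig, TraitConfig


def yield_trait(v_line=250_000, v_tester=12_000, v_sca=30_000,
                v_env=2.5e6, v_rep=1e5, v_block=0.0, v_line_env=150_000,
                v_tester_env=100_000, v_sca_env=80_000,
                v_residual=1.14e6) -> TraitConfig:
    return TraitConfig(mean=6190.0, v_line=v_line, v_tester=v_tester,
                       v_sca=v_sca, v_env=v_env, v_rep=v_rep,
                       v_block=v_block, v_line_env=v_line_env,
                       v_tester_env=v_tester_env, v_sca_env=v_sca_env,
                       v_residual=v_residual, units="kg/ha")


def small_config(seed: int, l: int = 4, t: int = 2, e: int = 2, r: int = 2,
                 include_checks: bool = False, **trait_kw) -> SimulationConfig:
    """A small yield-only trial without incomplete blocks."""
    return SimulationConfig(
        n_lines=l, n_testers=t, n_envs=e, n_reps=r, block_size=1,
        traits={"grain_yield": yield_trait(**trait_kw)},
        include_checks=include_checks, seed=seed)


@pytest.fixture(scope="session")
def default_book_truth():
    return lxt.simulate_trial(lxt.default_config(seed=1))


@pytest.fixture(scope="session")
def default_book(default_book_truth):
    return default_book_truth[0]


@pytest.fixture()
def small_book():
    book, _ = lxt.simulate_trial(small_config(seed=7))
    return book


# ---------------------------------------------------------------------------
# brute-force oracles (independent of the closed-form implementation)
# ---------------------------------------------------------------------------

def sequential_ss(df: pd.DataFrame, y_col: str, term_columns: list[list[str]]
                  ) -> list[float]:
    """Sequential least-squares sums of squares from explicit dummies.

    ``term_columns`` lists, per term, the plot-table columns whose
    interaction defines the term's dummies; SS are reductions in RSS as
    each term is appended to the design matrix.
    """
    y = df[y_col].to_numpy(float)
    n = len(y)
    X = np.ones((n, 1))

    def rss(M):
        coef, *_ = np.linalg.lstsq(M, y, rcond=None)
        resid = y - M @ coef
        return float(resid @ resid)

    out = []
    prev = rss(X)
    for cols in term_columns:
        key = df[cols].astype(str).agg("|".join, axis=1)
        D = pd.get_dummies(key, dtype=float).to_numpy()
        X = np.hstack([X, D])
        cur = rss(X)
        out.append(prev - cur)
        prev = cur
    return out


def constrained_lsq_gca_sca(m: np.ndarray):
    """GCA/SCA by explicit constrained least squares on a mean matrix.

    Fits mu + a_i + b_j + c_ij with sum-to-zero constraints enforced by a
    Helmert-contrast parameterisation; returns (mu, a, b, c).
    """
    l, t = m.shape

    def helmert(k):
        H = np.zeros((k, k - 1))
        for j in range(1, k):
            H[:j, j - 1] = 1.0
            H[j, j - 1] = -j
        return H

    Hl, Ht = helmert(l), helmert(t)
    cols = [np.ones((l, t)).ravel()]
    for j in range(l - 1):
        cols.append(np.repeat(Hl[:, j], t))
    for j in range(t - 1):
        cols.append(np.tile(Ht[:, j], l))
    for a in range(l - 1):
        for b in range(t - 1):
            cols.append(np.outer(Hl[:, a], Ht[:, b]).ravel())
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, m.ravel(), rcond=None)
    mu = beta[0]
    a = Hl @ beta[1:l]
    b = Ht @ beta[l:l + t - 1]
    c = np.zeros((l, t))
    idx = l + t - 1
    for ai in range(l - 1):
        for bi in range(t - 1):
            c += beta[idx] * np.outer(Hl[:, ai], Ht[:, bi])
            idx += 1
    return mu, a, b, c
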