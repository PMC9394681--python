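"""Synthetic multi-environment line x tester trial generator.

Simulates plot-level field books with the exact statistical structure the
downstream analyses assume, alongside the ground truth that generated
them, so every estimator in the package can be checked by parameter
recovery.  The plot model for each trait is

    y = mu + g_line + g_tester + s_(line,tester) + E_env + R_rep(env)
        + B_block(rep,env) + (gE)_line,env + (tE)_tester,env
        + (sE)_line,tester,env + eps_plot

with every effect Gaussian, zero-mean and independent at its configured
variance.  Main-effect vectors are centered to sum to zero exactly and
interaction effects are centered over their genetic margins within each
environment slice; this makes the balanced-design expected-mean-square
identities (and hence the method-of-moments estimators) exactly unbiased
and the ground truth identifiable.

Carotenoids are generated through a latent total-carotenoid trait with
the same linear structure, split into the five compounds by per-genotype
branch proportions (testers differ in their xanthophyll vs beta-branch
allocation); the line GCA for total carotenoid is linked to the line GCA
for grain yield through a negative dilution coefficient, producing the
negative genotypic yield-provitamin A correlation seen in biofortified
maize.  Provitamin A and total-carotenoid columns are then *derived*
from the compound columns, so the defining identities hold exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .fieldbook import Design, Entry, FieldBook, TraitSpec
from .traits import CAROTENOID_COMPOUNDS, add_derived_traits

__all__ = [
    "TraitConfig",
    "CarotenoidConfig",
    "SimulationConfig",
    "TraitTruth",
    "GroundTruth",
    "alpha_lattice_layout",
    "simulate_trial",
    "default_config",
    "save_config",
    "load_config",
    "truth_to_frame",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class TraitConfig:
    """Variance-component specification of one simulated trait (units²)."""

    mean: float
    v_line: float = 0.0          # line GCA variance
    v_tester: float = 0.0        # tester GCA variance
    v_sca: float = 0.0           # line x tester SCA variance
    v_env: float = 0.0
    v_rep: float = 0.0
    v_block: float = 0.0
    v_line_env: float = 0.0
    v_tester_env: float = 0.0
    v_sca_env: float = 0.0
    v_residual: float = 0.0
    n_envs: int | None = None    # measured in the first n environments only
    units: str = ""
    score_clip: tuple[float, float] | None = None  # latent Gaussian clipped

    def variances(self) -> dict[str, float]:
        return {k: v for k, v in dataclasses.asdict(self).items()
                if k.startswith("v_")}

    def validate(self) -> None:
        for k, v in self.variances().items():
            if v < 0:
                raise ValueError(f"negative variance {k}={v}")


@dataclass
class CarotenoidConfig:
    """Latent total-carotenoid model plus branch-partition parameters.

    ``tester_compound_means`` gives, per tester, the target testcross-mean
    concentration of each of the five compounds (µg/g DW); they define
    both the fixed tester effects on the latent total and the tester
    branch proportions.  ``dilution`` links the line GCA for grain yield
    to the line GCA for total carotenoid (µg/g per kg/ha; negative means
    high-yield genetics dilute carotenoid concentration).
    """

    total: TraitConfig
    tester_compound_means: dict[str, dict[str, float]] = field(default_factory=dict)
    dilution: float = 0.0
    proportion_jitter_sd: float = 0.0   # per-line log-scale branch jitter
    compound_residual_sd: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        self.total.validate()
        for t, means in self.tester_compound_means.items():
            for c in CAROTENOID_COMPOUNDS:
                if means.get(c, 0.0) < 0:
                    raise ValueError(f"negative compound mean {t}/{c}")


@dataclass
class SimulationConfig:
    """Full generator configuration; fixed seed implies bit-identical output."""

    n_lines: int = 60
    n_testers: int = 2
    n_envs: int = 8
    n_reps: int = 2
    block_size: int = 4
    traits: dict[str, TraitConfig] = field(default_factory=dict)
    carotenoids: CarotenoidConfig | None = None
    include_checks: bool = True
    n_checks: int = 3
    seed: int = 0
    truth_seed: int | None = None   # separate stream for genetic truth

    def validate(self) -> None:
        if self.n_lines < 1 or self.n_testers < 1:
            raise ValueError("need at least one line and one tester")
        if self.n_envs < 1 or self.n_reps < 1:
            raise ValueError("need at least one environment and replicate")
        for name, tc in self.traits.items():
            try:
                tc.validate()
            except ValueError as err:
                raise ValueError(f"trait {name!r}: {err}") from None
        if self.carotenoids is not None:
            self.carotenoids.validate()
        n_field = self.n_field_entries
        if self.block_size > 1 and n_field % self.block_size != 0:
            raise ValueError(
                f"block size {self.block_size} does not divide the "
                f"{n_field} field entries")

    @property
    def n_field_entries(self) -> int:
        n = self.n_lines * self.n_testers
        if self.include_checks:
            n += self.n_checks + (1 if self.n_testers >= 2 else 0)
        return n


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class TraitTruth:
    """True effects and components that generated one trait."""

    gca_lines: np.ndarray
    gca_testers: np.ndarray
    sca: np.ndarray                    # l x t
    components: dict[str, float]

    def check_zero_sums(self, atol: float = 1e-9) -> None:
        assert abs(self.gca_lines.sum()) < atol
        assert abs(self.gca_testers.sum()) < atol
        assert np.abs(self.sca.sum(axis=0)).max() < atol
        assert np.abs(self.sca.sum(axis=1)).max() < atol


@dataclass
class GroundTruth:
    """Everything the generator knows: effects, components, correlations."""

    lines: list[str]
    testers: list[str]
    effects: dict[str, TraitTruth]
    genetic_corr: pd.DataFrame   # empirical correlation of true cell values

    def repeatability(self, trait: str, e: int, r: int) -> float:
        """Closed-form entry-mean repeatability implied by true components."""
        c = self.effects[trait].components
        v_g = c["v_line"] + c["v_tester"] + c["v_sca"]
        v_ge = c["v_line_env"] + c["v_tester_env"] + c["v_sca_env"]
        return v_g / (v_g + v_ge / e + c["v_residual"] / (e * r))


# ---------------------------------------------------------------------------
# layout
# ---------------------------------------------------------------------------

def alpha_lattice_layout(n_entries: int, k: int, r: int,
                         seed: int | np.random.Generator = 0) -> list[list[list[int]]]:
    """Resolvable incomplete-block layout: r replicates of n/k blocks of size k.

    Every entry appears exactly once per replicate; the grouping of
    entries into blocks is re-randomized independently in each replicate
    (randomized resolvable blocking, the randomization structure of an
    alpha-lattice).  Returns ``layout[rep][block] -> list of entry indices``.
    """
    if k <= 1:
        raise ValueError("block size k must be at least 2")
    if n_entries < k:
        raise ValueError("fewer entries than the block size")
    if n_entries % k != 0:
        raise ValueError(f"k={k} does not divide n_entries={n_entries}")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    layout = []
    for _ in range(r):
        perm = rng.permutation(n_entries)
        layout.append([perm[b * k:(b + 1) * k].tolist()
                       for b in range(n_entries // k)])
    return layout


# ---------------------------------------------------------------------------
# effect machinery
# ---------------------------------------------------------------------------

def _center(x: np.ndarray) -> np.ndarray:
    return x - x.mean() if x.size else x

def _center2(m: np.ndarray) -> np.ndarray:
    """Double-center a matrix so all row and column sums are zero."""
    return m - m.mean(axis=0, keepdims=True) - m.mean(axis=1, keepdims=True) \
        + m.mean()

def _draw(rng: np.random.Generator, sd: float, shape) -> np.ndarray:
    if sd == 0:
        return np.zeros(shape)
    return rng.normal(0.0, sd, shape)


class _LinearTraitEffects:
    """Realized effects for one trait under the plot model."""

    def __init__(self, cfg: TraitConfig, dims: Design, rng, truth_rng,
                 gca_lines: np.ndarray | None = None,
                 gca_testers: np.ndarray | None = None,
                 n_checks: int = 0):
        l, t, e, r = dims.n_lines, dims.n_testers, dims.n_envs, dims.n_reps
        e_used = min(cfg.n_envs or e, e)
        self.cfg, self.e_used = cfg, e_used
        # genetic truth (optionally supplied, e.g. fixed tester effects)
        self.g_l = (_center(_draw(truth_rng, np.sqrt(cfg.v_line), l))
                    if gca_lines is None else np.asarray(gca_lines, float))
        self.g_t = (_center(_draw(truth_rng, np.sqrt(cfg.v_tester), t))
                    if gca_testers is None else np.asarray(gca_testers, float))
        self.sca = _center2(_draw(truth_rng, np.sqrt(cfg.v_sca), (l, t)))
        check_sd = np.sqrt(cfg.v_line + cfg.v_sca)
        self.g_check = _draw(truth_rng, check_sd, n_checks)
        # non-genetic effects
        self.env = _center(_draw(rng, np.sqrt(cfg.v_env), e_used))
        self.rep = _draw(rng, np.sqrt(cfg.v_rep), (e_used, r))
        self.rep -= self.rep.mean(axis=1, keepdims=True)
        # interactions: centered over genetic margins within each env slice
        le = _draw(rng, np.sqrt(cfg.v_line_env), (l, e_used))
        self.le = le - le.mean(axis=0, keepdims=True)
        te = _draw(rng, np.sqrt(cfg.v_tester_env), (t, e_used))
        self.te = te - te.mean(axis=0, keepdims=True)
        se = _draw(rng, np.sqrt(cfg.v_sca_env), (l, t, e_used))
        self.se = se - se.mean(axis=0, keepdims=True) \
            - se.mean(axis=1, keepdims=True) + se.mean(axis=(0, 1), keepdims=True)
        # entry-by-env wobble for checks (no line/tester decomposition)
        self.check_env = _draw(rng, np.sqrt(cfg.v_line_env + cfg.v_sca_env),
                               (n_checks, e_used))


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _entry_table(config: SimulationConfig):
    l, t = config.n_lines, config.n_testers
    wl = max(2, len(str(l)))
    lines = [f"L{i + 1:0{wl}d}" for i in range(l)]
    testers = [f"T{j + 1}" for j in range(t)]
    entries, kinds = [], []
    for i, li in enumerate(lines):
        for j, tj in enumerate(testers):
            entries.append(Entry(f"{li}x{tj}", "testcross", li, tj))
            kinds.append(("testcross", i, j, -1))
    if config.include_checks:
        if t >= 2:
            entries.append(Entry(f"{testers[0]}x{testers[1]}", "tester_cross"))
            kinds.append(("tester_cross", -1, -1, -1))
        for c in range(config.n_checks):
            entries.append(Entry(f"CHK{c + 1}", "check"))
            kinds.append(("check", -1, -1, c))
    return lines, testers, entries, kinds


def simulate_trial(config: SimulationConfig) -> tuple[FieldBook, GroundTruth]:
    """Generate a field book and its ground truth from ``config``.

    The same seed always yields a bit-identical book; ``truth_seed``
    (when set) pins the genetic truth while the non-genetic noise still
    follows ``seed``, which lets repeated simulations share one truth.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth_rng = (np.random.default_rng(config.truth_seed)
                 if config.truth_seed is not None else rng)

    l, t = config.n_lines, config.n_testers
    e, r, k = config.n_envs, config.n_reps, config.block_size
    lines, testers, entries, kinds = _entry_table(config)
    n_field = len(entries)
    dims = Design(l, t, e, r, k)
    envs = [f"E{x + 1}" for x in range(e)]

    # realize effects trait by trait (order matters: grain yield first so
    # the carotenoid dilution link can reuse its line GCA)
    trait_names = list(config.traits)
    if "grain_yield" in trait_names:
        trait_names.remove("grain_yield")
        trait_names.insert(0, "grain_yield")
    effects: dict[str, _LinearTraitEffects] = {}
    n_checks = config.n_checks if config.include_checks else 0
    for name in trait_names:
        effects[name] = _LinearTraitEffects(
            config.traits[name], dims, rng, truth_rng, n_checks=n_checks)

    carot = config.carotenoids
    proportions = None
    if carot is not None:
        ctm = carot.tester_compound_means
        tester_totals = np.array(
            [sum(ctm[tj][c] for c in CAROTENOID_COMPOUNDS) for tj in testers])
        mu_total = tester_totals.mean()
        g_t_total = tester_totals - mu_total
        # line GCA for total carotenoid: dilution share from yield + free part
        dil = carot.dilution
        v_line_total = carot.total.v_line
        if dil != 0.0 and "grain_yield" in effects:
            g_y = effects["grain_yield"].g_l
            v_free = v_line_total - dil ** 2 * config.traits["grain_yield"].v_line
            if v_free < 0:
                raise ValueError("dilution implies more line variance than "
                                 "v_line of total carotenoid allows")
            g_l_total = dil * g_y + _center(_draw(truth_rng, np.sqrt(v_free), l))
        else:
            g_l_total = _center(_draw(truth_rng, np.sqrt(v_line_total), l))
        cfg_total = dataclasses.replace(carot.total, mean=mu_total)
        effects["total_carotenoid_latent"] = _LinearTraitEffects(
            cfg_total, dims, rng, truth_rng, gca_lines=g_l_total,
            gca_testers=g_t_total, n_checks=n_checks)
        # branch proportions per genotype: tester base + per-line log jitter
        base = np.array([[ctm[tj][c] for c in CAROTENOID_COMPOUNDS]
                         for tj in testers]) / tester_totals[:, None]
        eta = _draw(truth_rng, carot.proportion_jitter_sd,
                    (l, len(CAROTENOID_COMPOUNDS)))
        eta_check = _draw(truth_rng, carot.proportion_jitter_sd,
                          (n_checks, len(CAROTENOID_COMPOUNDS)))
        logp = np.log(base)[None, :, :] + eta[:, None, :]   # l x t x 5
        pi = np.exp(logp)
        pi /= pi.sum(axis=2, keepdims=True)
        pi_tc = np.exp(np.log(base[:2]).mean(axis=0)) if t >= 2 else base[0]
        pi_tc /= pi_tc.sum()
        pi_check = np.exp(np.log(base).mean(axis=0)[None, :] + eta_check)
        pi_check /= pi_check.sum(axis=1, keepdims=True)
        proportions = (pi, pi_tc, pi_check)

    # field layout: blocks re-randomized per environment and replicate
    rows = {c: [] for c in ("env", "rep", "block")}
    idx_entry: list[int] = []
    for env_i in range(e):
        layout = alpha_lattice_layout(n_field, k, r, rng) if k > 1 else \
            [[list(range(n_field))] for _ in range(r)]
        for rep_i in range(r):
            for b_i, block in enumerate(layout[rep_i]):
                for ent in block:
                    rows["env"].append(envs[env_i])
                    rows["rep"].append(rep_i + 1)
                    rows["block"].append(f"B{b_i + 1:02d}")
                    idx_entry.append(ent)
    plots = pd.DataFrame(rows)
    plots["entry"] = [entries[i].entry_id for i in idx_entry]
    env_idx = plots["env"].map({env: i for i, env in enumerate(envs)}).to_numpy()
    rep_idx = plots["rep"].to_numpy() - 1
    kind_code = np.array([{"testcross": 0, "tester_cross": 1, "check": 2}
                          [kinds[i][0]] for i in idx_entry])
    i_arr = np.array([kinds[i][1] for i in idx_entry])
    j_arr = np.array([kinds[i][2] for i in idx_entry])
    c_arr = np.array([kinds[i][3] for i in idx_entry])
    block_str = (plots["env"] + "|" + plots["rep"].astype(str)
                 + "|" + plots["block"]).to_numpy()

    def realize(name: str, eff: _LinearTraitEffects) -> np.ndarray:
        cfg = eff.cfg
        y = np.full(len(plots), np.nan)
        sub = np.flatnonzero(env_idx < eff.e_used)
        ev, rp = env_idx[sub], rep_idx[sub]
        kc, ii, jj, cc = kind_code[sub], i_arr[sub], j_arr[sub], c_arr[sub]
        tc, tx, ck = kc == 0, kc == 1, kc == 2
        gen = np.zeros(len(sub))
        gxe = np.zeros(len(sub))
        gen[tc] = eff.g_l[ii[tc]] + eff.g_t[jj[tc]] + eff.sca[ii[tc], jj[tc]]
        gxe[tc] = (eff.le[ii[tc], ev[tc]] + eff.te[jj[tc], ev[tc]]
                   + eff.se[ii[tc], jj[tc], ev[tc]])
        if tx.any():
            gen[tx] = eff.g_t[0] + eff.g_t[1]
            gxe[tx] = eff.te[0, ev[tx]] + eff.te[1, ev[tx]]
        if ck.any():
            gen[ck] = eff.g_check[cc[ck]]
            gxe[ck] = eff.check_env[cc[ck], ev[ck]]
        # block effects: one draw per (env, rep, block), centered within rep
        uniq, inv = np.unique(block_str[sub], return_inverse=True)
        b_eff = _draw(rng, np.sqrt(cfg.v_block), len(uniq))
        er_key = np.array([u.rsplit("|", 1)[0] for u in uniq])
        for er in np.unique(er_key):
            m = er_key == er
            b_eff[m] -= b_eff[m].mean()
        eps = _draw(rng, np.sqrt(cfg.v_residual), len(sub))
        vals = (cfg.mean + gen + eff.env[ev] + eff.rep[ev, rp]
                + b_eff[inv] + gxe + eps)
        if cfg.score_clip is not None:
            vals = np.clip(vals, *cfg.score_clip)
        y[sub] = vals
        return y

    specs: list[TraitSpec] = []
    for name in trait_names:
        cfg = config.traits[name]
        plots[name] = realize(name, effects[name])
        specs.append(TraitSpec(name, units=cfg.units,
                               score_range=cfg.score_clip))

    if carot is not None:
        eff_T = effects["total_carotenoid_latent"]
        latent = realize("total_carotenoid_latent", eff_T)
        pi, pi_tc, pi_check = proportions
        sub = np.flatnonzero(env_idx < eff_T.e_used)
        kc, ii, jj, cc = kind_code[sub], i_arr[sub], j_arr[sub], c_arr[sub]
        tc, tx, ck = kc == 0, kc == 1, kc == 2
        res_sd = np.array([carot.compound_residual_sd.get(c, 0.0)
                           for c in CAROTENOID_COMPOUNDS])
        for ci, comp in enumerate(CAROTENOID_COMPOUNDS):
            col = np.full(len(plots), np.nan)
            p = np.empty(len(sub))
            p[tc] = pi[ii[tc], jj[tc], ci]
            p[tx] = pi_tc[ci]
            p[ck] = pi_check[cc[ck], ci]
            noise = _draw(rng, 1.0, len(sub)) * res_sd[ci]
            col[sub] = np.clip(p * latent[sub] + noise, 0.0, None)
            plots[comp] = col
            specs.append(TraitSpec(comp, units="µg/g DW", bounds=(0, np.inf)))

    book = FieldBook(entries, specs, plots)
    add_derived_traits(book)

    # ---- ground truth -----------------------------------------------------
    truth_effects: dict[str, TraitTruth] = {}
    for name in trait_names:
        eff = effects[name]
        truth_effects[name] = TraitTruth(
            eff.g_l.copy(), eff.g_t.copy(), eff.sca.copy(),
            dict(config.traits[name].variances()))
    if carot is not None:
        eff = effects["total_carotenoid_latent"]
        comp = dict(carot.total.variances())
        comp["v_tester"] = float(np.sum(eff.g_t ** 2) / max(t - 1, 1))
        truth_effects["total_carotenoid"] = TraitTruth(
            eff.g_l.copy(), eff.g_t.copy(), eff.sca.copy(), comp)

    cell_values: dict[str, np.ndarray] = {}
    for name, tt in truth_effects.items():
        cell_values[name] = (tt.gca_lines[:, None] + tt.gca_testers[None, :]
                             + tt.sca)
    if carot is not None:
        eff = effects["total_carotenoid_latent"]
        pi, _, _ = proportions
        pi_pva = (pi[:, :, CAROTENOID_COMPOUNDS.index("beta_carotene")]
                  + 0.5 * (pi[:, :, CAROTENOID_COMPOUNDS.index("beta_cryptoxanthin")]
                           + pi[:, :, CAROTENOID_COMPOUNDS.index("alpha_carotene")]))
        g_total = cell_values["total_carotenoid"] + eff.cfg.mean
        cell_values["provitamin_a"] = pi_pva * g_total - (pi_pva * g_total).mean()
    corr_names = list(cell_values)
    flat = np.column_stack([cell_values[nm].ravel() for nm in corr_names])
    with np.errstate(invalid="ignore", divide="ignore"):
        cmat = np.corrcoef(flat, rowvar=False) if flat.shape[0] > 1 else \
            np.eye(len(corr_names))
    genetic_corr = pd.DataFrame(cmat, index=corr_names, columns=corr_names)

    truth = GroundTruth(lines=lines, testers=testers, effects=truth_effects,
                        genetic_corr=genetic_corr)
    return book, truth


# ---------------------------------------------------------------------------
# defaults: a 60-line x 2-tester provitamin A testcross program
# ---------------------------------------------------------------------------

def default_config(seed: int = 0) -> SimulationConfig:
    """Default conditions: 60 lines x 2 testers (+ T1xT2 and 3 checks),
    31 x 4 alpha-lattice, 2 replicates, 8 environments for agronomic
    traits and 4 for carotenoids.

    Trait means and variance components are set to the magnitudes typical
    of tropical provitamin A testcross trials (yield around 6.2 t/ha with
    CV ~17%, provitamin A means of 10-13 µg/g); SCA variance is kept well
    below GCA variance so additive effects dominate, and the dilution
    coefficient gives an expected genotypic yield-PVA correlation near
    -0.25.
    """
    traits = {
        "grain_yield": TraitConfig(
            mean=6190.0, v_line=250_000, v_tester=12_000, v_sca=30_000,
            v_env=2.5e6, v_rep=1.0e5, v_block=1.0e4, v_line_env=150_000,
            v_tester_env=100_000, v_sca_env=80_000, v_residual=1.14e6,
            units="kg/ha"),
        "days_to_anthesis": TraitConfig(
            mean=56.97, v_line=0.86, v_tester=0.52, v_sca=0.20, v_env=16.0,
            v_rep=0.10, v_block=0.17, v_line_env=0.23, v_tester_env=0.04,
            v_sca_env=0.10, v_residual=1.43, units="days"),
        "days_to_silking": TraitConfig(
            mean=58.55, v_line=0.93, v_tester=0.48, v_sca=0.25, v_env=14.0,
            v_rep=0.12, v_block=0.21, v_line_env=0.24, v_tester_env=0.05,
            v_sca_env=0.15, v_residual=1.57, units="days"),
        "plant_height": TraitConfig(
            mean=191.3, v_line=85.0, v_tester=14.0, v_sca=16.0, v_env=384.0,
            v_rep=7.0, v_block=16.0, v_line_env=28.0, v_tester_env=34.0,
            v_sca_env=39.0, v_residual=98.0, units="cm"),
        "ear_height": TraitConfig(
            mean=92.9, v_line=48.0, v_tester=10.0, v_sca=10.0, v_env=34.0,
            v_rep=5.0, v_block=13.0, v_line_env=17.0, v_tester_env=5.0,
            v_sca_env=8.0, v_residual=70.0, units="cm"),
        "plant_aspect": TraitConfig(
            mean=2.53, v_line=0.027, v_tester=0.0003, v_sca=0.010,
            v_env=0.023, v_rep=0.003, v_block=0.010, v_line_env=0.023,
            v_tester_env=0.008, v_sca_env=0.045, v_residual=0.18,
            units="score", score_clip=(1.0, 5.0)),
        "ear_aspect": TraitConfig(
            mean=2.55, v_line=0.035, v_tester=0.003, v_sca=0.015,
            v_env=0.060, v_rep=0.007, v_block=0.002, v_line_env=0.018,
            v_tester_env=0.0016, v_sca_env=0.005, v_residual=0.16,
            units="score", score_clip=(1.0, 5.0)),
    }
    carotenoids = CarotenoidConfig(
        total=TraitConfig(
            mean=0.0,  # replaced by the tester-mean implied grand total
            v_line=18.0, v_tester=0.0, v_sca=2.3, v_env=27.0, v_rep=3.4,
            v_block=3.1, v_line_env=7.0, v_tester_env=5.0, v_sca_env=7.7,
            v_residual=10.0, n_envs=4, units="µg/g DW"),
        tester_compound_means={
            # high-PVA tester: beta-branch rich; low-PVA tester: xanthophyll rich
            "T1": {"lutein": 8.53, "zeaxanthin": 7.30,
                   "beta_cryptoxanthin": 3.32, "alpha_carotene": 0.79,
                   "beta_carotene": 10.69},
            "T2": {"lutein": 7.31, "zeaxanthin": 11.95,
                   "beta_cryptoxanthin": 4.59, "alpha_carotene": 0.89,
                   "beta_carotene": 7.49},
        },
        dilution=-3.7e-3,
        proportion_jitter_sd=0.06,
        compound_residual_sd={"lutein": 0.8, "zeaxanthin": 0.9,
                              "beta_cryptoxanthin": 0.25,
                              "alpha_carotene": 0.08, "beta_carotene": 0.5},
    )
    return SimulationConfig(traits=traits, carotenoids=carotenoids, seed=seed)


# ---------------------------------------------------------------------------
# config / truth serialization
# ---------------------------------------------------------------------------

def save_config(config: SimulationConfig, path) -> None:
    """Write a configuration as structured YAML (documented keys)."""
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=False)


def load_config(path) -> SimulationConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    traits = {name: TraitConfig(**{**tc, "score_clip": tuple(tc["score_clip"])
                                   if tc.get("score_clip") else None})
              for name, tc in (raw.pop("traits", {}) or {}).items()}
    car = raw.pop("carotenoids", None)
    carotenoids = None
    if car:
        total = car.pop("total")
        total["score_clip"] = tuple(total["score_clip"]) \
            if total.get("score_clip") else None
        carotenoids = CarotenoidConfig(total=TraitConfig(**total), **car)
    cfg = SimulationConfig(traits=traits, carotenoids=carotenoids, **raw)
    cfg.validate()
    return cfg


def truth_to_frame(truth: GroundTruth) -> pd.DataFrame:
    """Long-format table of true effects (trait, term, line, tester, value)."""
    recs = []
    for trait, tt in truth.effects.items():
        for li, g in zip(truth.lines, tt.gca_lines):
            recs.append((trait, "gca_line", li, "", g))
        for tj, g in zip(truth.testers, tt.gca_testers):
            recs.append((trait, "gca_tester", "", tj, g))
        for i, li in enumerate(truth.lines):
            for j, tj in enumerate(truth.testers):
                recs.append((trait, "sca", li, tj, tt.sca[i, j]))
        for comp, v in tt.components.items():
            recs.append((trait, comp, "", "", v))
    return pd.DataFrame(recs, columns=["trait", "term", "line", "tester",
                                       "value"])
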