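"""Data model, validation and delimited-text I/O for line x tester field books.

A *field book* holds plot-level observations from a multi-environment
testcross trial: one row per plot, keyed by (environment, replicate,
incomplete block, entry), with one column per trait.  Entries carry a
role -- ``testcross`` (line x tester hybrid), ``check`` (commercial
hybrid), or ``tester_cross`` (the single T1 x T2 reference hybrid) --
plus parent identifiers for testcrosses.

All downstream analyses (ANOVA, combining ability, heterosis,
correlations) consume a validated :class:`FieldBook` and nothing else.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TraitSpec",
    "Entry",
    "Design",
    "FieldBook",
    "FieldBookError",
    "TestcrossMeanMatrix",
    "read_fieldbook",
    "write_fieldbook",
    "testcross_means",
    "entry_means",
]

#: plot-table columns that are not trait measurements
RESERVED_COLUMNS = ("env", "rep", "block", "entry", "role",
                    "line_parent", "tester_parent")

VALID_ROLES = frozenset({"line", "tester", "testcross", "check", "tester_cross"})

#: entry roles that occupy plots in a testcross trial
HYBRID_ROLES = frozenset({"testcross", "check", "tester_cross"})


class FieldBookError(ValueError):
    """Raised when a field book violates a structural invariant."""


@dataclass(frozen=True)
class TraitSpec:
    """Declaration of a trait column.

    Parameters
    ----------
    name : str
        Column identifier.
    units : str
        Free-text units (kg/ha, µg/g DW, days, cm, score).
    kind : {"measured", "derived"}
        Derived traits must name the operation that produces them.
    score_range : tuple of (float, float), optional
        Inclusive bounds for ordinal scores (e.g. ``(1, 5)`` aspect scores).
    bounds : tuple of (float, float), optional
        Inclusive physical bounds (e.g. ``(0, 100)`` for moisture %,
        ``(0, inf)`` for concentrations).
    derived_from : str, optional
        Name of the producing operation, required when ``kind="derived"``.
    """

    name: str
    units: str = ""
    kind: str = "measured"
    score_range: tuple[float, float] | None = None
    bounds: tuple[float, float] | None = None
    derived_from: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("measured", "derived"):
            raise FieldBookError(f"trait {self.name!r}: unknown kind {self.kind!r}")
        if self.kind == "derived" and not self.derived_from:
            raise FieldBookError(
                f"derived trait {self.name!r} must name the operation that "
                "produces it (derived_from)")
        for rng in (self.score_range, self.bounds):
            if rng is not None and rng[0] > rng[1]:
                raise FieldBookError(f"trait {self.name!r}: empty range {rng}")


@dataclass(frozen=True)
class Entry:
    """A trial entry (genotype) and its pedigree role."""

    entry_id: str
    role: str
    line_parent: str | None = None
    tester_parent: str | None = None

    def __post_init__(self) -> None:
        if self.role not in VALID_ROLES:
            raise FieldBookError(
                f"entry {self.entry_id!r}: unknown role {self.role!r} "
                f"(expected one of {sorted(VALID_ROLES)})")
        if self.role == "testcross" and not (self.line_parent and self.tester_parent):
            raise FieldBookError(
                f"testcross {self.entry_id!r} must declare both parents")


@dataclass(frozen=True)
class Design:
    """Trial dimensions: l lines, t testers, e environments, r replicates, block size k."""

    n_lines: int
    n_testers: int
    n_envs: int
    n_reps: int
    block_size: int | None = None


class FieldBook:
    """Validated container of entries, trait specs and plot records.

    Parameters
    ----------
    entries : iterable of :class:`Entry`
    traits : iterable of :class:`TraitSpec`
    plots : pandas.DataFrame
        One row per plot with columns ``env, rep, block, entry`` followed
        by one column per declared trait; missing cells are NaN.
    """

    def __init__(self, entries: Iterable[Entry], traits: Iterable[TraitSpec],
                 plots: pd.DataFrame, validate: bool = True) -> None:
        self.entries: dict[str, Entry] = {e.entry_id: e for e in entries}
        self.traits: dict[str, TraitSpec] = {t.name: t for t in traits}
        plots = plots.copy()
        plots["rep"] = plots["rep"].astype(int)
        for col in ("env", "block", "entry"):
            plots[col] = plots[col].astype(str)
        self.plots = plots.reset_index(drop=True)
        if validate:
            self.validate()

    # -- derived structure -------------------------------------------------

    @property
    def trait_names(self) -> list[str]:
        return list(self.traits)

    @property
    def testcrosses(self) -> list[Entry]:
        return [e for e in self.entries.values() if e.role == "testcross"]

    @property
    def lines(self) -> list[str]:
        return sorted({e.line_parent for e in self.testcrosses})

    @property
    def testers(self) -> list[str]:
        return sorted({e.tester_parent for e in self.testcrosses})

    @property
    def environments(self) -> list[str]:
        return sorted(self.plots["env"].unique())

    @property
    def design(self) -> Design:
        per_block = self.plots.groupby(["env", "rep", "block"]).size()
        k = int(per_block.max()) if len(per_block) else None
        return Design(
            n_lines=len(self.lines),
            n_testers=len(self.testers),
            n_envs=len(self.environments),
            n_reps=int(self.plots["rep"].nunique()),
            block_size=k,
        )

    def entry_for(self, entry_id: str) -> Entry:
        try:
            return self.entries[entry_id]
        except KeyError:
            raise FieldBookError(f"unknown entry {entry_id!r}") from None

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        """Check every structural invariant; raise :class:`FieldBookError`."""
        plots = self.plots
        missing_cols = [c for c in ("env", "rep", "block", "entry") if c not in plots]
        if missing_cols:
            raise FieldBookError(f"plot table lacks columns {missing_cols}")

        unknown = sorted(set(plots["entry"]) - set(self.entries))
        if unknown:
            raise FieldBookError(f"plots reference unknown entries: {unknown[:5]}")

        extra = [c for c in plots.columns
                 if c not in RESERVED_COLUMNS and c not in self.traits]
        if extra:
            raise FieldBookError(f"plot columns without a TraitSpec: {extra}")

        key = ["env", "rep", "block", "entry"]
        dup = plots.duplicated(key, keep=False)
        if dup.any():
            rows = plots.index[dup].tolist()
            first = plots.loc[rows[0], key].tolist()
            raise FieldBookError(
                f"duplicate plot key {tuple(first)} at rows {rows[:6]}")

        # at most l*t testcrosses, unique parent pairs, single tester_cross
        pairs = [(e.line_parent, e.tester_parent) for e in self.testcrosses]
        if len(pairs) != len(set(pairs)):
            raise FieldBookError("duplicate (line, tester) pair among testcrosses")
        n_tc_ref = sum(e.role == "tester_cross" for e in self.entries.values())
        if n_tc_ref > 1:
            raise FieldBookError("more than one tester_cross reference entry")

        for name, spec in self.traits.items():
            if name not in plots.columns:
                continue
            vals = pd.to_numeric(plots[name], errors="coerce")
            bad = plots[name].notna() & vals.isna()
            if bad.any():
                raise FieldBookError(
                    f"non-numeric value for trait {name!r} at rows "
                    f"{plots.index[bad].tolist()[:5]}")
            for rng, label in ((spec.score_range, "score_range"),
                               (spec.bounds, "bounds")):
                if rng is None:
                    continue
                out = vals.notna() & ((vals < rng[0]) | (vals > rng[1]))
                if out.any():
                    raise FieldBookError(
                        f"trait {name!r} outside {label} {rng} at rows "
                        f"{plots.index[out].tolist()[:5]}")

    # -- convenience -------------------------------------------------------

    def subset_envs(self, envs: Sequence[str]) -> "FieldBook":
        keep = self.plots["env"].isin(list(envs))
        return FieldBook(self.entries.values(), self.traits.values(),
                         self.plots.loc[keep], validate=False)

    def __repr__(self) -> str:
        d = self.design
        return (f"FieldBook({len(self.entries)} entries, {len(self.traits)} traits, "
                f"{len(self.plots)} plots; l={d.n_lines}, t={d.n_testers}, "
                f"e={d.n_envs}, r={d.n_reps})")


# ---------------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------------

def read_fieldbook(path, schema: Mapping[str, str] | None = None,
                   sep: str | None = None,
                   trait_specs: Iterable[TraitSpec] | None = None) -> FieldBook:
    """Read a delimited field book (comma default, tab accepted).

    One row per plot; required columns ``env, rep, block, entry, role``
    (``line_parent``/``tester_parent`` for testcrosses); every remaining
    column is a trait.  Empty cells are preserved as missing, never zero.

    Parameters
    ----------
    schema : mapping, optional
        Rename map from file column names to the canonical names above.
    trait_specs : iterable of TraitSpec, optional
        Declarations for trait columns; defaults to plain measured traits.
    """
    if sep is None:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str,
                         skipinitialspace=True)
    else:
        df = pd.read_csv(path, sep=sep, dtype=str, skipinitialspace=True)
    if schema:
        df = df.rename(columns=dict(schema))

    required = ("env", "rep", "block", "entry", "role")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FieldBookError(f"field book lacks required columns {missing}")

    bad_roles = sorted(set(df["role"].dropna()) - VALID_ROLES)
    if bad_roles:
        raise FieldBookError(f"unknown role token(s) {bad_roles}")

    key = ["env", "rep", "block", "entry"]
    dup = df.duplicated(key, keep=False)
    if dup.any():
        rows = (df.index[dup] + 2).tolist()  # 1-based incl. header
        raise FieldBookError(
            f"duplicate plot key {tuple(df.loc[df.index[dup][0], key])}: "
            f"file rows {rows[:6]}")

    # entry metadata: role/parents must be constant per entry
    meta_cols = ["entry", "role"] + [c for c in ("line_parent", "tester_parent")
                                     if c in df.columns]
    meta = df[meta_cols].drop_duplicates()
    if meta["entry"].duplicated().any():
        which = meta.loc[meta["entry"].duplicated(), "entry"].tolist()
        raise FieldBookError(f"inconsistent role/parents for entries {which[:5]}")
    entries = []
    for _, row in meta.iterrows():
        entries.append(Entry(
            entry_id=str(row["entry"]),
            role=str(row["role"]),
            line_parent=(str(row["line_parent"])
                         if row.get("line_parent") not in (None, "", np.nan)
                         and pd.notna(row.get("line_parent")) else None),
            tester_parent=(str(row["tester_parent"])
                           if row.get("tester_parent") not in (None, "", np.nan)
                           and pd.notna(row.get("tester_parent")) else None),
        ))

    trait_cols = [c for c in df.columns if c not in RESERVED_COLUMNS]
    for col in trait_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & (df[col].str.strip() != "") & vals.isna()
        if bad.any():
            r = int(df.index[bad][0]) + 2
            raise FieldBookError(
                f"non-numeric value {df.loc[df.index[bad][0], col]!r} for trait "
                f"{col!r} at file row {r}")
        # parse through float() for exact (correctly rounded) round-trips
        df[col] = [float(x) if isinstance(x, str) and x.strip() != ""
                   else np.nan for x in df[col]]

    specs = {t.name: t for t in (trait_specs or [])}
    traits = [specs.get(c, TraitSpec(c)) for c in trait_cols]
    plots = df[list(key) + trait_cols].copy()
    return FieldBook(entries, traits, plots)


def write_fieldbook(book: FieldBook, path, sep: str = ",") -> None:
    """Write a field book as delimited text that :func:`read_fieldbook` inverts.

    Values are printed at full (shortest round-trip) precision; missing
    cells become empty fields.
    """
    df = book.plots.copy()
    roles = df["entry"].map(lambda e: book.entries[e].role)
    lp = df["entry"].map(lambda e: book.entries[e].line_parent or "")
    tp = df["entry"].map(lambda e: book.entries[e].tester_parent or "")
    df.insert(4, "role", roles)
    df.insert(5, "line_parent", lp)
    df.insert(6, "tester_parent", tp)
    cols = ["env", "rep", "block", "entry", "role", "line_parent",
            "tester_parent"] + book.trait_names
    out = df[cols].copy()
    for name in book.trait_names:
        # shortest round-trip representation, so read(write(book)) is identity
        out[name] = [("" if pd.isna(v) else repr(float(v)))
                     for v in out[name]]
    out.to_csv(path, sep=sep, index=False, na_rep="")


# ---------------------------------------------------------------------------
# testcross means
# ---------------------------------------------------------------------------

@dataclass
class TestcrossMeanMatrix:
    """Lines x testers table of testcross means with cell support counts.

    ``values`` is an l x t DataFrame (rows = lines, columns = testers);
    ``counts`` the matching number of plots per cell.  ``per_env`` holds
    the per-environment matrices when requested.  ``convention`` records
    whether pooled means are plot-level means (default) or means of
    environment means; the two coincide only on balanced data.
    """

    trait: str
    level: str
    values: pd.DataFrame
    counts: pd.DataFrame
    convention: str = "plot"
    per_env: dict[str, pd.DataFrame] | None = None

    @property
    def missing_cells(self) -> list[tuple[str, str]]:
        """Cells with zero non-missing observations (flagged, never dropped)."""
        mask = self.counts == 0
        return [(i, j) for i in mask.index for j in mask.columns if mask.loc[i, j]]


def testcross_means(book: FieldBook, trait: str, level: str = "pooled",
                    convention: str = "plot") -> TestcrossMeanMatrix:
    """Arithmetic testcross means per (line, tester) cell.

    Parameters
    ----------
    level : {"pooled", "per_environment"}
        ``pooled`` averages over replicates and environments;
        ``per_environment`` returns one matrix per environment.
    convention : {"plot", "env_mean"}
        Pooling convention: plain mean of plot values (default) or mean of
        per-environment means.  Identical on balanced data.
    """
    if trait not in book.traits:
        raise FieldBookError(f"unknown trait {trait!r}")
    if level not in ("pooled", "per_environment"):
        raise FieldBookError(f"unknown level {level!r}")
    if convention not in ("plot", "env_mean"):
        raise FieldBookError(f"unknown pooling convention {convention!r}")

    tc = book.testcrosses
    lines, testers = book.lines, book.testers
    parent = {e.entry_id: (e.line_parent, e.tester_parent) for e in tc}
    df = book.plots[book.plots["entry"].isin(parent)][["env", "entry", trait]].copy()
    df["line"] = df["entry"].map(lambda x: parent[x][0])
    df["tester"] = df["entry"].map(lambda x: parent[x][1])
    obs = df.dropna(subset=[trait])

    def pivot(frame: pd.DataFrame, agg: str) -> pd.DataFrame:
        out = frame.pivot_table(index="line", columns="tester", values=trait,
                                aggfunc=agg, dropna=False)
        return out.reindex(index=lines, columns=testers)

    counts = pivot(obs.assign(**{trait: 1.0}), "sum").fillna(0).astype(int)
    per_env = None
    if level == "per_environment":
        per_env = {env: pivot(g, "mean") for env, g in obs.groupby("env")}
        values = pivot(obs, "mean")
    elif convention == "plot":
        values = pivot(obs, "mean")
    else:  # env_mean: average the per-environment cell means
        env_means = (obs.groupby(["line", "tester", "env"])[trait].mean()
                     .groupby(["line", "tester"]).mean().reset_index())
        values = env_means.pivot(index="line", columns="tester", values=trait)
        values = values.reindex(index=lines, columns=testers)
    return TestcrossMeanMatrix(trait=trait, level=level, values=values,
                               counts=counts, convention=convention,
                               per_env=per_env)


def entry_means(book: FieldBook, trait: str,
                roles: Iterable[str] = HYBRID_ROLES) -> pd.Series:
    """Pooled (plot-level) mean per entry for the given roles."""
    if trait not in book.traits:
        raise FieldBookError(f"unknown trait {trait!r}")
    keep = book.plots["entry"].map(lambda e: book.entries[e].role in set(roles))
    df = book.plots.loc[keep, ["entry", trait]].dropna(subset=[trait])
    return df.groupby("entry")[trait].mean()
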