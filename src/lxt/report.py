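"""Publication-style report bundle: every analysis rendered to delimited text.

``run`` executes the full pipeline on a field book and writes one CSV
per surface (ANOVA tables, variance components, tester and line GCA
tables, SCA table, heterosis, correlation matrix, tester summary,
additive/non-additive partition) plus a run log recording the seed,
package version and every analysis setting, so a bundle is regenerable
from its config alone.  Rendered numbers are the module outputs under a
single global rounding rule (round-half-even, two decimals by default);
the renderer never recomputes anything.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .anova import combined_anova, cv_percent, proportional_contributions, \
    repeatability, variance_components
from .combining import additive_nonadditive_partition, combining_ability
from .correlations import genotypic_correlation, phenotypic_correlation, \
    tester_summary
from .fieldbook import FieldBook
from .heterosis import heterosis_table

log = logging.getLogger("lxt")

__all__ = ["RunConfig", "run"]


@dataclass
class RunConfig:
    """Settings for a full analysis run."""

    traits: list[str] = field(default_factory=list)
    reference: str | None = None        # tester_cross entry for heterosis
    alpha: tuple[float, float] = (0.05, 0.01)
    decimals: int = 2                   # round-half-even rendering rule
    seed: int = 0
    out_dir: str = "lxt_report"
    stages: dict[str, bool] = field(default_factory=lambda: {
        "anova": True, "gca": True, "heterosis": True,
        "correlations": True, "testers": True})


def _round(df: pd.DataFrame, decimals: int) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = np.round(out[col], decimals)  # numpy rounds half-even
    return out


def _write(df: pd.DataFrame, path: Path, decimals: int) -> None:
    _round(df, decimals).to_csv(path, index=False)


def run(book: FieldBook, config: RunConfig) -> dict[str, Path]:
    """Run every enabled stage and write the report bundle; returns paths."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    traits = config.traits or book.trait_names
    dec = config.decimals
    written: dict[str, Path] = {}
    anovas = {}

    reference = config.reference
    if reference is None:
        tx = [e.entry_id for e in book.entries.values()
              if e.role == "tester_cross"]
        reference = tx[0] if tx else None

    if config.stages.get("anova", True):
        summary_rows = []
        for trait in traits:
            at = combined_anova(book, trait)
            anovas[trait] = at
            path = out / f"anova_{trait}.csv"
            _write(at.to_frame(), path, dec)
            written[f"anova_{trait}"] = path
            vc = variance_components(at)
            contrib = proportional_contributions(at, vc)
            add, nonadd = additive_nonadditive_partition(vc)
            summary_rows.append({
                "trait": trait,
                "grand_mean": at.grand_mean,
                "cv_percent": cv_percent(at),
                "repeatability": repeatability(vc),
                "baker_ratio": _baker(at),
                "ss_pct_line": contrib.ss_line,
                "ss_pct_tester": contrib.ss_tester,
                "ss_pct_lxt": contrib.ss_lxt,
                "pct_additive": add,
                "pct_nonadditive": nonadd,
            })
            vpath = out / f"variance_components_{trait}.csv"
            _write(vc.to_frame(), vpath, max(dec, 4))
            written[f"variance_components_{trait}"] = vpath
        spath = out / "trait_summary.csv"
        _write(pd.DataFrame(summary_rows), spath, dec)
        written["trait_summary"] = spath

    if config.stages.get("gca", True):
        tester_rows, line_frames, sca_frames = [], [], []
        for trait in traits:
            at = anovas.get(trait) or combined_anova(book, trait)
            ca = combining_ability(book, trait, anova=at)
            tt = ca.tester_table().reset_index(names="tester")
            tt.insert(0, "trait", trait)
            tester_rows.append(tt)
            lt = ca.line_table().reset_index(names="line")
            lt.insert(0, "trait", trait)
            line_frames.append(lt)
            st = ca.sca_table()
            st.insert(0, "trait", trait)
            sca_frames.append(st)
        for name, frames in (("gca_testers", tester_rows),
                             ("gca_lines", line_frames),
                             ("sca", sca_frames)):
            path = out / f"{name}.csv"
            _write(pd.concat(frames, ignore_index=True), path, dec)
            written[name] = path

    if config.stages.get("heterosis", True) and reference is not None:
        path = out / "heterosis.csv"
        _write(heterosis_table(book, reference, traits), path, dec)
        written["heterosis"] = path

    if config.stages.get("correlations", True) and len(traits) > 1:
        mat = pd.DataFrame(np.nan, index=traits, columns=traits)
        for i, x in enumerate(traits):
            mat.loc[x, x] = 1.0
            for y_ in traits[i + 1:]:
                # phenotypic upper triangle, genotypic lower triangle
                mat.loc[x, y_] = phenotypic_correlation(book, x, y_)
                try:
                    mat.loc[y_, x] = genotypic_correlation(book, x, y_).value
                except Exception as err:  # undefined r_g stays blank
                    log.warning("genotypic correlation %s/%s undefined: %s",
                                x, y_, err)
        path = out / "correlations.csv"
        _write(mat.reset_index(names="trait"), path, dec)
        written["correlations"] = path

    if config.stages.get("testers", True):
        ev = tester_summary(book, traits)
        path = out / "testers.csv"
        _write(ev.table, path, dec)
        written["testers"] = path
        (out / "testers_notes.txt").write_text(ev.notes + "\n")

    logpath = out / "run_log.txt"
    settings = dataclasses.asdict(config)
    settings.pop("out_dir", None)   # keep bundles byte-identical across dirs
    lines = [f"lxt {__version__}", f"seed: {config.seed}",
             f"book: {book!r}"]
    lines += [f"{k}: {v}" for k, v in settings.items()]
    lines += ["significance codes: * p<%.2f, ** p<%.2f (two-sided)"
              % config.alpha,
              f"rounding: half-even, {dec} decimals"]
    logpath.write_text("\n".join(lines) + "\n")
    written["run_log"] = logpath
    return written


def _baker(at) -> float:
    from .anova import baker_ratio
    try:
        return baker_ratio(at.ms("Line"), at.ms("Tester"),
                           at.ms("Line x Tester"))
    except Exception:
        return float("nan")


def additive_partition_figure(summary: pd.DataFrame, path) -> None:
    """Stacked-bar export of the additive/non-additive partition per trait."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1 + 0.6 * len(summary), 4))
    x = np.arange(len(summary))
    ax.bar(x, summary["pct_additive"], label="additive")
    ax.bar(x, summary["pct_nonadditive"], bottom=summary["pct_additive"],
           label="non-additive")
    ax.set_xticks(x, summary["trait"], rotation=60, ha="right")
    ax.set_ylabel("% of genetic variance")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
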