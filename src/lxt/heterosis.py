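"""Standard heterosis against the inter-tester reference hybrid.

Standard heterosis expresses a testcross mean as the percent deviation
from a designated reference hybrid (here the cross between the two
testers, T1 x T2):  H = 100 (F1 - CK) / CK.  A least-significant-
difference test from the combined-analysis error term classifies each
entry as lower / equal / higher than a check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .anova import AnovaTable, combined_anova
from .fieldbook import FieldBook, FieldBookError, entry_means

__all__ = [
    "standard_heterosis",
    "heterosis_table",
    "count_in_interval",
    "compare_to_check",
]


def standard_heterosis(f1: float, ck: float) -> float:
    """H = 100 (F1 - CK) / CK, percent; scale-invariant in (f1, ck)."""
    if ck == 0:
        raise ValueError("reference (CK) mean is zero; heterosis undefined")
    return 100.0 * (f1 - ck) / ck


def heterosis_table(book: FieldBook, reference: str,
                    traits: list[str] | None = None) -> pd.DataFrame:
    """One heterosis record per testcross x trait.

    Columns: entry, trait, f1, ck, h_percent.  ``reference`` is normally
    the tester_cross entry; means are pooled plot-level means over the
    environments where each trait was scored.
    """
    if reference not in book.entries:
        raise FieldBookError(f"reference entry {reference!r} not in book")
    traits = traits or book.trait_names
    recs = []
    for trait in traits:
        means = entry_means(book, trait)
        if reference not in means.index:
            raise FieldBookError(
                f"reference {reference!r} has no data for {trait!r}")
        ck = float(means[reference])
        for e in book.testcrosses:
            if e.entry_id not in means.index:
                continue
            f1 = float(means[e.entry_id])
            recs.append((e.entry_id, trait, f1, ck,
                         standard_heterosis(f1, ck)))
    return pd.DataFrame(recs, columns=["entry", "trait", "f1", "ck",
                                       "h_percent"])


def count_in_interval(table: pd.DataFrame, trait: str,
                      lo: float = 0.0, hi: float = math.inf) -> int:
    """Number of testcrosses with lo <= H% <= hi for a trait."""
    sub = table[table["trait"] == trait]
    return int(((sub["h_percent"] >= lo) & (sub["h_percent"] <= hi)).sum())


@dataclass
class CheckComparison:
    """LSD classification of entries against a check entry."""

    check: str
    trait: str
    lsd: float
    alpha: float
    classification: pd.Series   # entry -> {"lower", "equal", "higher"}

    def counts(self) -> dict[str, int]:
        return self.classification.value_counts().to_dict()


def compare_to_check(book: FieldBook, check_id: str, trait: str,
                     anova: AnovaTable | None = None,
                     alpha: float = 0.05) -> CheckComparison:
    """Two-sided LSD test of every hybrid entry against ``check_id``.

    LSD = t(1 - alpha/2, df_error) * sqrt(2 MS_error / (r e)); entries
    whose pooled mean differs from the check mean by more than the LSD
    are classified higher/lower by sign, otherwise equal.  No
    multiplicity correction is applied (single-check star convention).
    """
    if check_id not in book.entries:
        raise FieldBookError(f"check entry {check_id!r} not in book")
    if anova is None:
        anova = combined_anova(book, trait)
    ms_err, df_err = anova.extra_ms["Error"]
    n_per_mean = anova.dims.n_envs * anova.dims.n_reps
    lsd = float(stats.t.ppf(1 - alpha / 2, df_err)
                * math.sqrt(2.0 * ms_err / n_per_mean))
    means = entry_means(book, trait)
    if check_id not in means.index:
        raise FieldBookError(f"check {check_id!r} has no data for {trait!r}")
    ck = float(means[check_id])
    diff = means - ck
    cls = pd.Series(
        np.where(diff > lsd, "higher", np.where(diff < -lsd, "lower",
                                                "equal")),
        index=means.index, name="class")
    return CheckComparison(check=check_id, trait=trait, lsd=lsd,
                           alpha=alpha, classification=cls)
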