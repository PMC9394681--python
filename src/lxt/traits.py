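"""Deterministic per-plot derived-trait formulas.

Carotenoid aggregates follow the standard biofortification conventions:
provitamin A is the sum of beta-carotene plus half of each of
beta-cryptoxanthin and alpha-carotene (the two compounds with half the
retinol activity of beta-carotene); total carotenoid is the sum of the
five quantified compounds.  Agronomic derivations are the anthesis-
silking interval and grain yield adjusted to 15% moisture on a per-
hectare basis.

All operations work on scalars, numpy arrays or pandas Series alike.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fieldbook import FieldBook, TraitSpec

__all__ = [
    "CarotenoidProfile",
    "CAROTENOID_COMPOUNDS",
    "provitamin_a",
    "total_carotenoid",
    "anthesis_silking_interval",
    "yield_at_15pct",
    "add_derived_traits",
]

#: the five quantified carotenoid compounds, µg/g dry weight
CAROTENOID_COMPOUNDS = ("lutein", "zeaxanthin", "beta_cryptoxanthin",
                        "alpha_carotene", "beta_carotene")


@dataclass(frozen=True)
class CarotenoidProfile:
    """Concentrations of the five quantified carotenoids, µg/g dry weight."""

    lutein: float
    zeaxanthin: float
    beta_cryptoxanthin: float
    alpha_carotene: float
    beta_carotene: float


def _check_nonnegative(name, value) -> None:
    arr = np.asarray(value, dtype=float)
    if np.any(arr[~np.isnan(arr)] < 0):
        raise ValueError(f"negative {name} concentration")


def provitamin_a(profile=None, *, beta_carotene=None, beta_cryptoxanthin=None,
                 alpha_carotene=None):
    """Provitamin A content: BC + 0.5*(BCX + AC), µg/g dry weight.

    Accepts a :class:`CarotenoidProfile` or the three provitamin A
    compounds as keyword arguments (scalars or arrays).
    """
    if profile is not None:
        beta_carotene = profile.beta_carotene
        beta_cryptoxanthin = profile.beta_cryptoxanthin
        alpha_carotene = profile.alpha_carotene
    for name, v in (("beta_carotene", beta_carotene),
                    ("beta_cryptoxanthin", beta_cryptoxanthin),
                    ("alpha_carotene", alpha_carotene)):
        _check_nonnegative(name, v)
    return beta_carotene + 0.5 * (beta_cryptoxanthin + alpha_carotene)


def total_carotenoid(profile=None, **compounds):
    """Total carotenoid: sum of the five compound concentrations, µg/g DW."""
    if profile is not None:
        compounds = {c: getattr(profile, c) for c in CAROTENOID_COMPOUNDS}
    missing = [c for c in CAROTENOID_COMPOUNDS if c not in compounds]
    if missing:
        raise ValueError(f"missing compound(s) {missing}")
    for name in CAROTENOID_COMPOUNDS:
        _check_nonnegative(name, compounds[name])
    return sum(compounds[c] for c in CAROTENOID_COMPOUNDS)


def anthesis_silking_interval(days_to_silking, days_to_anthesis):
    """ASI in days: silking date minus anthesis date (negative = protandry)."""
    return days_to_silking - days_to_anthesis


def yield_at_15pct(grain_weight, moisture, plot_area):
    """Grain yield adjusted to 15% moisture, kg/ha.

    ``grain_weight`` in kg per plot, ``moisture`` in percent at harvest,
    ``plot_area`` in m².  Dry-matter scaling (100 - M)/85 then conversion
    to a hectare basis -- the universal maize-trial convention.
    """
    moisture = np.asarray(moisture, dtype=float)
    if np.any(moisture[~np.isnan(moisture)] >= 100) or np.any(
            moisture[~np.isnan(moisture)] < 0):
        raise ValueError("moisture must be in [0, 100)%")
    if np.any(np.asarray(plot_area, dtype=float) <= 0):
        raise ValueError("plot area must be positive")
    out = np.asarray(grain_weight, dtype=float) * (100.0 - moisture) / 85.0 \
        * 10000.0 / np.asarray(plot_area, dtype=float)
    return float(out) if out.ndim == 0 else out


def add_derived_traits(book: FieldBook) -> FieldBook:
    """Attach derivable columns (provitamin_a, total_carotenoid, asi) in place.

    Each derivation is applied only when its source columns are present;
    missing source cells propagate to missing derived cells.  Returns the
    book for chaining.
    """
    plots = book.plots
    if all(c in plots.columns for c in CAROTENOID_COMPOUNDS):
        comp = {c: plots[c] for c in CAROTENOID_COMPOUNDS}
        plots["provitamin_a"] = provitamin_a(
            beta_carotene=comp["beta_carotene"],
            beta_cryptoxanthin=comp["beta_cryptoxanthin"],
            alpha_carotene=comp["alpha_carotene"])
        plots["total_carotenoid"] = total_carotenoid(**comp)
        book.traits.setdefault("provitamin_a", TraitSpec(
            "provitamin_a", units="µg/g DW", kind="derived",
            derived_from="provitamin_a", bounds=(0, np.inf)))
        book.traits.setdefault("total_carotenoid", TraitSpec(
            "total_carotenoid", units="µg/g DW", kind="derived",
            derived_from="total_carotenoid", bounds=(0, np.inf)))
    if all(c in plots.columns for c in ("days_to_silking", "days_to_anthesis")):
        plots["asi"] = anthesis_silking_interval(
            plots["days_to_silking"], plots["days_to_anthesis"])
        book.traits.setdefault("asi", TraitSpec(
            "asi", units="days", kind="derived",
            derived_from="anthesis_silking_interval"))
    return book
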