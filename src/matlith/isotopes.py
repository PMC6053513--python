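"""Stable carbon isotope arithmetic and the label mass balance.

Converts between the three coordinates used in tracer work —
delta notation (per mil vs VPDB), the isotope ratio R = 13C/12C, and the
fractional abundance F = 13C/(12C + 13C) — and evaluates the two-endmember
mass balance that turns label uptake into percent new carbon.

Fractional abundance is the mixing-linear coordinate: when a fraction
``x`` of a carbon pool is newly formed from a labeled source, the pool's F
is exactly ``(1 - x) * F_initial + x * F_label``, assuming the new carbon
carries the label's isotopic composition without fractionation.  The mass
balance inverts that relation.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "R_VPDB",
    "InvalidIsotopeValueError",
    "DegenerateMixingError",
    "NewCarbonResult",
    "delta_to_ratio",
    "ratio_to_delta",
    "delta_to_fraction",
    "fraction_to_delta",
    "percent_new_carbon",
    "rate_per_day",
    "new_carbon",
]

#: 13C/12C ratio of the Vienna Pee Dee Belemnite reference.
R_VPDB = 0.0112372


class InvalidIsotopeValueError(ValueError):
    """A delta or fractional abundance outside its physical range."""


class DegenerateMixingError(ValueError):
    """Baseline and label endmembers coincide: no isotopic contrast."""


def delta_to_ratio(delta: float, reference_ratio: float = R_VPDB) -> float:
    """13C/12C ratio for a delta value (per mil) on the given reference.

    delta = -1000 per mil corresponds to a pool with no 13C (R = 0);
    lower values are unphysical.
    """
    if delta < -1000.0:
        raise InvalidIsotopeValueError(
            f"delta13C = {delta} per mil implies a negative 13C/12C ratio"
        )
    if reference_ratio <= 0:
        raise InvalidIsotopeValueError("reference ratio must be positive")
    return (delta / 1000.0 + 1.0) * reference_ratio


def ratio_to_delta(ratio: float, reference_ratio: float = R_VPDB) -> float:
    """Delta value (per mil) for a 13C/12C ratio."""
    if ratio < 0:
        raise InvalidIsotopeValueError("isotope ratio must be non-negative")
    if reference_ratio <= 0:
        raise InvalidIsotopeValueError("reference ratio must be positive")
    return (ratio / reference_ratio - 1.0) * 1000.0


def delta_to_fraction(delta: float, reference_ratio: float = R_VPDB) -> float:
    """Fractional abundance F = 13C/(12C + 13C) for a delta value."""
    r = delta_to_ratio(delta, reference_ratio)
    return r / (1.0 + r)


def fraction_to_delta(f: float, reference_ratio: float = R_VPDB) -> float:
    """Delta value (per mil) for a fractional abundance; inverse of
    :func:`delta_to_fraction`."""
    if not 0.0 <= f < 1.0:
        raise InvalidIsotopeValueError(
            f"fractional abundance must lie in [0, 1); got {f}"
        )
    r = f / (1.0 - f)
    return ratio_to_delta(r, reference_ratio)


def percent_new_carbon(
    f_sample: float,
    f_baseline: float,
    f_label: float,
    *,
    on_ratios: bool = False,
) -> float:
    """Percent of a carbon pool newly formed from a labeled source.

    Evaluates ``(1 - (f_sample - f_label) / (f_baseline - f_label)) * 100``
    on fractional abundances.  For the biogenic comparison the sample is the
    living incubation and the baseline the poisoned control; for the
    abiogenic comparison the sample is the poisoned control and the baseline
    the un-incubated negative control.

    Parameters
    ----------
    f_sample, f_baseline, f_label
        Fractional abundances of the measured pool, the no-process baseline,
        and the labeled carbon source.
    on_ratios
        Evaluate on 13C/12C ratios instead of fractional abundances.  At
        tracer enrichments of a few thousand per mil the two conventions
        differ by well under 0.1 % new carbon; the fractional-abundance form
        is the default because it is the exactly mixing-linear coordinate.

    Returns
    -------
    float
        Percent new carbon.  May be negative when the sample is isotopically
        lighter than its baseline (measurement noise around zero uptake);
        negative values are reported, not clamped, so downstream
        significance testing sees the full distribution.
    """
    if on_ratios:
        f_sample = f_sample / (1.0 - f_sample)
        f_baseline = f_baseline / (1.0 - f_baseline)
        f_label = f_label / (1.0 - f_label)
    denom = f_baseline - f_label
    if denom == 0.0:
        raise DegenerateMixingError(
            "baseline and label fractional abundances are equal; "
            "the mass balance is undefined without label contrast"
        )
    return (1.0 - (f_sample - f_label) / denom) * 100.0


def rate_per_day(percent_new: float, duration_hours: float) -> float:
    """Convert percent new carbon over an incubation to % new carbon/day."""
    if duration_hours <= 0:
        raise ValueError(f"incubation duration must be positive, got {duration_hours} h")
    return percent_new / (duration_hours / 24.0)


@dataclass(frozen=True)
class NewCarbonResult:
    """Label-uptake mass-balance outcome for one layer and comparison.

    ``mode`` names the comparison: ``"gross-fixation"`` (organic, living vs
    poisoned), ``"biogenic"`` (inorganic, living vs poisoned) or
    ``"abiogenic"`` (inorganic, poisoned vs negative control).
    ``below_detection`` flags a negative percent-new value.
    """

    percent_new: float
    rate: float
    mode: str
    below_detection: bool


def new_carbon(
    f_sample: float,
    f_baseline: float,
    f_label: float,
    duration_hours: float = 24.0,
    mode: str = "gross-fixation",
    *,
    on_ratios: bool = False,
) -> NewCarbonResult:
    """Mass balance plus rate conversion in one step."""
    pct = percent_new_carbon(f_sample, f_baseline, f_label, on_ratios=on_ratios)
    return NewCarbonResult(
        percent_new=pct,
        rate=rate_per_day(pct, duration_hours),
        mode=mode,
        below_detection=pct < 0,
    )
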