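"""Deterministic physiological formulas.

Harvard Step Test fitness index, age-predicted maximal heart rate
(Tanaka), training intensity bands and body-mass index. All functions are
pure and return unrounded floats; rounding is opt-in at the presentation
layer (round-half-away-from-zero for heart rates, since that is how the
printed integer values in the sports-science literature are obtained).
"""

from __future__ import annotations

import math

__all__ = [
    "MAX_STEP_TEST_SECONDS",
    "fitness_index",
    "hrmax_tanaka",
    "intensity_band",
    "bmi",
]

#: Maximum duration of the Harvard Step Test in seconds. The fitness-index
#: formula is defined for tests up to five minutes; a subject completing the
#: full test records exactly 300 s.
MAX_STEP_TEST_SECONDS = 300.0


def _round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (not banker's)."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def fitness_index(duration_s: float, recovery_pulse: float) -> float:
    """Harvard Step Test fitness index, FI = 100*L / (5.5*p).

    Parameters
    ----------
    duration_s
        Test duration L in seconds, 0 <= L <= 300. (The classical formula
        is quoted for L < 300 s, but a subject who completes the full
        five-minute test records exactly 300 s and is accepted.)
    recovery_pulse
        Pulse count p within 1.5 min after stopping; must be positive.
    """
    if recovery_pulse <= 0:
        raise ValueError(
            f"recovery pulse must be positive, got {recovery_pulse!r}"
        )
    if duration_s < 0:
        raise ValueError(f"test duration must be >= 0 s, got {duration_s!r}")
    if duration_s > MAX_STEP_TEST_SECONDS:
        raise ValueError(
            f"test duration {duration_s!r} s exceeds the {MAX_STEP_TEST_SECONDS:.0f} s "
            "domain of the fitness-index formula FI = 100*L/(5.5*p)"
        )
    return 100.0 * duration_s / (5.5 * recovery_pulse)


def hrmax_tanaka(age_years: float, *, rounded: bool = False) -> float | int:
    """Age-predicted maximal heart rate, HRmax = 208 - 0.7 * age (Tanaka).

    With ``rounded=True`` the value is rounded half-away-from-zero to an
    integer bpm, e.g. 196.8 -> 197 at age 16.
    """
    if age_years <= 0:
        if age_years == 0:
            # the intercept itself is occasionally useful; allow it
            return 208 if rounded else 208.0
        raise ValueError(f"age must be non-negative, got {age_years!r}")
    hr = 208.0 - 0.7 * age_years
    return _round_half_away(hr) if rounded else hr


def intensity_band(
    hrmax: float,
    lo_frac: float,
    hi_frac: float | None = None,
    *,
    rounded: bool = False,
) -> tuple[float, float] | tuple[int, int]:
    """Target heart-rate band as fractions of HRmax.

    ``lo_frac``/``hi_frac`` are proportions in (0, 1]; a single fraction
    gives a degenerate band. Returns ``(lo_frac*hrmax, hi_frac*hrmax)``.
    """
    if hi_frac is None:
        hi_frac = lo_frac
    if not (0 < lo_frac <= hi_frac <= 1):
        raise ValueError(
            f"need 0 < lo_frac <= hi_frac <= 1, got ({lo_frac!r}, {hi_frac!r})"
        )
    lo, hi = lo_frac * hrmax, hi_frac * hrmax
    if rounded:
        return _round_half_away(lo), _round_half_away(hi)
    return lo, hi


def bmi(weight_kg: float, height_cm: float) -> float:
    """Body-mass index in kg/m^2 from weight in kg and height in cm."""
    if weight_kg <= 0 or height_cm <= 0:
        raise ValueError(
            f"weight and height must be positive, got {weight_kg!r} kg, {height_cm!r} cm"
        )
    return weight_kg / (height_cm / 100.0) ** 2
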