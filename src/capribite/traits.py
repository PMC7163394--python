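"""The eleven aggregate feed-intake-pattern traits per goat-day.

Quantity traits (g DM/kg BW): DDMI (22-h intake), DMI90, DMI180, DMI900
(cumulative intake at 90, 180 and 900 min after the afternoon delivery) and
the first-meal intake.  Shape traits: P90 = DMI90/DMI900 and
P180 = DMI180/DMI900 (how front-loaded the 15-h intake is), the exponential
model's asymptote ``a``, initial rate ``a*b`` and residual error RMSE.
Composition trait: the NDF sorting index — NDF content of what was eaten
over NDF content of what was offered; below 1 the goat sorted against fibre.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .expmodel import ExpFit
from .profiles import IntakeProfile
from .segmentation import MealResult

TRAIT_NAMES = [
    "ddmi", "dmi90", "dmi180", "dmi900", "p90", "p180",
    "a", "ab", "rmse_ab", "first_meal_dmi", "ndf_sorting",
]


def ndf_sorting(offered_dm: float, offered_ndf: float,
                refusal_dm: float, refusal_ndf: float) -> float:
    """NDF sorting index by mass balance.

    The NDF mass eaten is offered NDF mass minus refusal NDF mass; dividing
    by the DM eaten gives the NDF fraction of the intake, and dividing that
    by the offered diet's NDF fraction gives the index.  1 means unselective
    eating, below 1 sorting against fibre.  Undefined (NaN) at zero intake.
    """
    if refusal_dm > offered_dm:
        raise ValueError("refusal cannot exceed offer")
    if not (0 < offered_ndf < 1) or not (0 <= refusal_ndf < 1):
        raise ValueError("NDF fractions must lie in (0, 1)")
    intake_dm = offered_dm - refusal_dm
    if intake_dm <= 0:
        return float("nan")
    intake_ndf = (offered_dm * offered_ndf - refusal_dm * refusal_ndf) / intake_dm
    return float(intake_ndf / offered_ndf)


def compute_traits(profile22: IntakeProfile, profile15: IntakeProfile,
                   fit: ExpFit, meal: MealResult,
                   offered_dm: float | None = None,
                   offered_ndf: float | None = None,
                   refusal_dm: float | None = None,
                   refusal_ndf: float | None = None) -> dict:
    """Assemble the trait record for one goat-day.

    Boundary reads use the last grid sample strictly before 90, 180 and
    900 min (half-open window convention).  Composition arguments may be
    omitted, leaving ``ndf_sorting`` NaN for that day.  A day with zero
    15-h intake is flagged (``valid=False``) since the ratio traits are
    undefined.
    """
    dmi90 = profile15.value_before(90.0)
    dmi180 = profile15.value_before(180.0)
    dmi900 = profile15.value_before(900.0)
    ddmi = float(profile22.y[-1])
    valid = dmi900 > 0
    sorting = float("nan")
    if offered_dm is not None and refusal_dm is not None:
        sorting = ndf_sorting(offered_dm, offered_ndf, refusal_dm, refusal_ndf)
    return {
        "goat_id": profile15.goat_id,
        "breed": profile15.breed,
        "period": profile15.period,
        "day": profile15.day,
        "ddmi": ddmi,
        "dmi90": dmi90,
        "dmi180": dmi180,
        "dmi900": dmi900,
        "p90": dmi90 / dmi900 if valid else float("nan"),
        "p180": dmi180 / dmi900 if valid else float("nan"),
        "a": fit.a,
        "ab": fit.ab,
        "rmse_ab": fit.rmse,
        "first_meal_dmi": meal.first_meal_intake,
        "ndf_sorting": sorting,
        "converged": fit.converged,
        "valid": bool(valid),
    }


def goat_period_means(records: pd.DataFrame) -> pd.DataFrame:
    """Average the daily trait records per goat and period.

    Each trait is the arithmetic mean of its available days (NDF sorting may
    rest on fewer days than the rest when composition was only measured on
    some days).  Cells built from fewer than two days carry ``n_days`` so
    callers can flag them; invalid days are excluded first.
    """
    df = records[records.get("valid", True) != False]  # noqa: E712
    if df.empty:
        warnings.warn("no valid trait records to average")
        return pd.DataFrame(columns=["goat_id", "breed", "period", *TRAIT_NAMES])
    grouped = df.groupby(["goat_id", "breed", "period"], sort=True)
    means = grouped[TRAIT_NAMES].mean().reset_index()
    means["n_days"] = grouped.size().to_numpy()
    few = means["n_days"] < 2
    if few.any():
        warnings.warn(f"{int(few.sum())} goat-period cells have < 2 days")
    return means
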