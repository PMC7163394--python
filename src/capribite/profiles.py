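"""Trough-weight series and cumulative dry-matter-intake profiles.

A trough scale under each goat's feeder records the as-fed mass of feed
remaining every ``interval`` minutes from the afternoon feed delivery until
refusals are removed 22 h later.  Subtracting the running weight from the
delivered weight and scaling by the dry-matter fraction and the goat's body
weight gives a cumulative intake curve in g DM per kg BW, the unit every
downstream analysis works in.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

TROUGH_COLUMNS = ["goat_id", "breed", "period", "day", "t_min", "trough_weight_g"]


class ValidationError(ValueError):
    """Raised when an input table violates the documented schema."""


@dataclass
class TroughSeries:
    """One goat-day of raw trough-weight recordings.

    ``t`` is minutes since afternoon feed delivery on a regular grid starting
    at 0; ``weight`` is the as-fed mass (g) left in the trough at each tick.
    ``dm_fraction`` converts as-fed mass to dry matter for that day's ration.
    """

    goat_id: str
    breed: str
    period: str
    day: str
    t: np.ndarray
    weight: np.ndarray
    dm_fraction: float = 1.0
    n_interpolated: int = 0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.weight = np.asarray(self.weight, dtype=float)
        if self.t.shape != self.weight.shape:
            raise ValidationError("t and weight must have the same length")
        if self.t.size < 2:
            raise ValidationError("a trough series needs at least two samples")
        steps = np.diff(self.t)
        if np.any(steps <= 0):
            raise ValidationError(
                f"timestamps must be strictly increasing for goat {self.goat_id}"
            )
        if not np.allclose(steps, steps[0]):
            raise ValidationError(
                f"irregular sampling grid for goat {self.goat_id} "
                f"period {self.period} day {self.day}"
            )
        if np.any(self.weight < 0):
            raise ValidationError(f"negative trough weight for goat {self.goat_id}")
        if not 0 < self.dm_fraction <= 1:
            raise ValidationError("dm_fraction must lie in (0, 1]")

    @property
    def interval(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.goat_id, self.period, self.day)


@dataclass
class IntakeProfile:
    """Monotone cumulative DM intake (g DM/kg BW) on a regular grid.

    The grid covers the half-open window ``[0, total_window)`` so a 900-min
    window at 2-min sampling holds exactly 450 measures.
    """

    goat_id: str
    period: str
    day: str
    t: np.ndarray
    y: np.ndarray
    bw: float
    breed: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.shape != self.y.shape:
            raise ValidationError("t and y must have the same length")
        if self.y[0] != 0:
            raise ValidationError("cumulative intake must start at 0")
        if np.any(np.diff(self.y) < 0):
            raise ValidationError("cumulative intake must be non-decreasing")
        if self.bw <= 0:
            raise ValidationError("body weight must be positive")

    @property
    def interval(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def total_window(self) -> float:
        """Length of the half-open window covered by the grid, in minutes."""
        return float(self.t[-1] + self.interval)

    def value_before(self, minute: float) -> float:
        """Cumulative intake at the last grid point strictly before ``minute``."""
        idx = int(np.searchsorted(self.t, minute, side="left")) - 1
        if idx < 0:
            raise ValueError(f"no sample before t={minute}")
        return float(self.y[idx])


def read_trough_series(
    path, *, max_gap: int = 3, return_excluded: bool = False
) -> list[TroughSeries] | tuple[list[TroughSeries], list[tuple]]:
    """Read a long-format trough-weight CSV into one series per goat-day.

    The CSV must carry the columns ``goat_id, breed, period, day, t_min,
    trough_weight_g`` and optionally ``dm_fraction``.  Gaps of up to
    ``max_gap`` missing samples are filled by linear interpolation; a goat-day
    with a larger gap is excluded (and reported when ``return_excluded``).
    Duplicated timestamps or negative weights raise :class:`ValidationError`
    naming the offending cell.
    """
    df = pd.read_csv(path, dtype={"goat_id": str, "period": str, "day": str})
    missing = [c for c in TROUGH_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing columns in {path}: {missing}")
    series: list[TroughSeries] = []
    excluded: list[tuple] = []
    for key, grp in df.groupby(["goat_id", "period", "day"], sort=True):
        grp = grp.sort_values("t_min")
        t = grp["t_min"].to_numpy(dtype=float)
        w = grp["trough_weight_g"].to_numpy(dtype=float)
        if np.any(np.diff(t) == 0):
            dup = t[np.where(np.diff(t) == 0)[0][0]]
            raise ValidationError(
                f"duplicated timestamp t={dup} for goat {key[0]} "
                f"period {key[1]} day {key[2]}"
            )
        if np.any(w < 0):
            bad = t[np.where(w < 0)[0][0]]
            raise ValidationError(
                f"negative weight at t={bad} for goat {key[0]} "
                f"period {key[1]} day {key[2]}"
            )
        interval = float(np.min(np.diff(t)))
        if interval <= 0:
            raise ValidationError(f"non-increasing timestamps for goat {key[0]}")
        # regularize onto the implied grid, interpolating short gaps
        n_grid = int(round((t[-1] - t[0]) / interval)) + 1
        grid = t[0] + interval * np.arange(n_grid)
        off_grid = ~np.isclose((t - t[0]) / interval, np.round((t - t[0]) / interval))
        if np.any(off_grid):
            raise ValidationError(
                f"irregular timestamps for goat {key[0]} period {key[1]} "
                f"day {key[2]}: t={t[off_grid][0]}"
            )
        idx = np.round((t - t[0]) / interval).astype(int)
        present = np.zeros(n_grid, dtype=bool)
        present[idx] = True
        gap_run = _longest_gap(present)
        if gap_run > max_gap:
            excluded.append(key)
            continue
        w_grid = np.interp(grid, t, w)
        dm = float(grp["dm_fraction"].iloc[0]) if "dm_fraction" in grp else 1.0
        series.append(
            TroughSeries(
                goat_id=key[0],
                breed=str(grp["breed"].iloc[0]),
                period=key[1],
                day=key[2],
                t=grid - grid[0],
                weight=w_grid,
                dm_fraction=dm,
                n_interpolated=int(n_grid - present.sum()),
            )
        )
    if return_excluded:
        return series, excluded
    return series


def _longest_gap(present: np.ndarray) -> int:
    run = best = 0
    for p in present:
        run = 0 if p else run + 1
        best = max(best, run)
    return best


def write_trough_series(series: list[TroughSeries], path) -> None:
    """Write series to the long CSV schema read by :func:`read_trough_series`."""
    frames = []
    for s in series:
        frames.append(
            pd.DataFrame(
                {
                    "goat_id": s.goat_id,
                    "breed": s.breed,
                    "period": s.period,
                    "day": s.day,
                    "t_min": s.t,
                    "trough_weight_g": s.weight,
                    "dm_fraction": s.dm_fraction,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def cumulative_intake(series: TroughSeries, bw: float) -> IntakeProfile:
    """Convert a trough-weight series into a clean cumulative intake profile.

    Raw cumulative intake is ``(weight(0) - weight(t)) * dm_fraction / bw``.
    Load-cell noise occasionally makes the trough weight tick upward, which
    would make the cumulative curve dip; a running maximum restores
    monotonicity without touching already-monotone stretches.
    """
    if bw <= 0:
        raise ValueError("body weight must be positive")
    raw = (series.weight[0] - series.weight) * series.dm_fraction / bw
    clean = np.maximum.accumulate(np.maximum(raw, 0.0))
    clean[0] = 0.0
    return IntakeProfile(
        goat_id=series.goat_id,
        period=series.period,
        day=series.day,
        t=series.t.copy(),
        y=clean,
        bw=float(bw),
        breed=series.breed,
    )


def clip_window(profile: IntakeProfile, duration: float) -> IntakeProfile:
    """Restrict a profile to the half-open window ``[0, duration)`` minutes."""
    interval = profile.interval
    if duration <= 0 or abs(duration / interval - round(duration / interval)) > 1e-9:
        raise ValueError(
            f"duration {duration} must be a positive multiple of the "
            f"{interval}-min sampling interval"
        )
    if duration > profile.total_window:
        raise ValueError("cannot clip beyond the recorded window")
    if duration < 2 * interval:
        raise ValueError("clipped window must keep at least two samples")
    keep = profile.t < duration
    return replace(profile, t=profile.t[keep].copy(), y=profile.y[keep].copy())
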