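"""Seeded synthetic herds of trough-weight recordings with known ground truth.

The generator emulates the measurement setup of an indoor goat phenotyping
trial: individually penned goats of two breeds (Alpine ``A`` and Saanen
``S``), a trough scale sampling every 2 min at 5-g resolution, a 22-h
recording window after the afternoon feed delivery, four measurement days in
each of four physiological periods.  Each goat carries latent behavioural
traits (intake level, initial eating rate, eagerness — the fraction of the
15-h intake taken in the first meal — and fibre-sorting intensity); feeding
is realized as a first large bout followed by a small number of later bouts
separated by pauses, plus an optional late-night bout.  The realized bout
schedule is kept as truth so detection methods can be scored exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .profiles import TroughSeries

LATENT_TRAITS = ("mean_dmi900", "initial_rate", "eagerness", "sorting_intensity")


class ConfigurationError(ValueError):
    """Raised for invalid herd designs or variance specifications."""


@dataclass
class HerdDesign:
    """Dimensions of the simulated trial.

    Defaults reproduce the reference design: 35 goats (13 Alpine, 22 Saanen),
    4 periods x 4 days, 2-min sampling over a 1320-min (22-h) window, 5-g
    scale resolution.
    """

    n_goats: int = 35
    n_alpine: int = 13
    n_periods: int = 4
    n_days_per_period: int = 4
    sampling_interval: float = 2.0
    window_total: float = 1320.0
    scale_resolution: float = 5.0

    def __post_init__(self) -> None:
        if self.n_goats < 2:
            raise ConfigurationError("need at least 2 goats")
        if not 0 <= self.n_alpine <= self.n_goats:
            raise ConfigurationError("n_alpine must lie in [0, n_goats]")
        if self.n_periods < 1 or self.n_days_per_period < 1:
            raise ConfigurationError("periods and days must be positive")
        if self.sampling_interval <= 0:
            raise ConfigurationError("sampling_interval must be positive")
        ratio = self.window_total / self.sampling_interval
        if abs(ratio - round(ratio)) > 1e-9:
            raise ConfigurationError(
                "window_total must be a multiple of sampling_interval"
            )
        if self.scale_resolution <= 0:
            raise ConfigurationError("scale_resolution must be positive")

    @property
    def n_samples(self) -> int:
        """Samples on the half-open window [0, window_total)."""
        return int(round(self.window_total / self.sampling_interval))

    @property
    def breeds(self) -> list[str]:
        return ["A"] * self.n_alpine + ["S"] * (self.n_goats - self.n_alpine)

    @property
    def goat_ids(self) -> list[str]:
        return [f"G{i + 1:02d}" for i in range(self.n_goats)]

    @property
    def periods(self) -> list[str]:
        return [f"P{i + 1}" for i in range(self.n_periods)]

    @property
    def days(self) -> list[str]:
        return [f"D{i + 1}" for i in range(self.n_days_per_period)]


@dataclass
class VarianceSpec:
    """Variance components of the latent-trait model, per trait.

    ``sd_goat`` is the between-goat SD, ``sd_goat_period`` the SD of the
    random goat-by-period deviation (the component that makes goats re-rank
    between periods and keeps the between-period repeatability below 1),
    ``sd_day`` the within-goat-between-day SD, and ``sd_noise`` the additive
    scale noise in grams applied before quantization.  ``period_shift`` holds
    the deterministic period effects, mirroring a fixed-effect treatment of
    period.  ``bump_prob`` is the per-sample probability of a transient
    positive weight bump, exercising monotone cleaning downstream.
    """

    sd_goat: dict[str, float] = field(
        default_factory=lambda: {
            "mean_dmi900": 7.0,
            "initial_rate": 0.06,
            "eagerness": 0.10,
            "sorting_intensity": 0.12,
        }
    )
    sd_goat_period: dict[str, float] = field(
        default_factory=lambda: {
            "mean_dmi900": 5.0,
            "initial_rate": 0.04,
            "eagerness": 0.07,
            "sorting_intensity": 0.08,
        }
    )
    sd_day: dict[str, float] = field(
        default_factory=lambda: {
            "mean_dmi900": 2.5,
            "initial_rate": 0.03,
            "eagerness": 0.05,
            "sorting_intensity": 0.05,
        }
    )
    period_shift: dict[str, tuple] = field(
        default_factory=lambda: {
            # intake highest mid first lactation; sorting strengthens with age
            "mean_dmi900": (0.0, 4.0, -2.0, 2.0),
            "initial_rate": (0.0, 0.02, 0.04, 0.06),
            "eagerness": (0.0, -0.08, -0.02, 0.0),
            "sorting_intensity": (0.0, 0.05, 0.10, 0.15),
        }
    )
    sd_noise: float = 2.0
    bump_prob: float = 0.002

    def __post_init__(self) -> None:
        for d in (self.sd_goat, self.sd_goat_period, self.sd_day):
            if any(v < 0 for v in d.values()):
                raise ConfigurationError("variance components must be >= 0")
        if self.sd_noise < 0 or not 0 <= self.bump_prob < 1:
            raise ConfigurationError("invalid noise specification")


#: Breed-level means of the latent traits (baseline = first period).
#: Alpine goats eat more per kg BW but start more slowly than Saanen.
BREED_MEANS = {
    "A": {
        "mean_dmi900": 34.8,
        "initial_rate": 0.24,
        "eagerness": 0.52,
        "sorting_intensity": 0.35,
        "bw": 51.5,
    },
    "S": {
        "mean_dmi900": 29.8,
        "initial_rate": 0.30,
        "eagerness": 0.60,
        "sorting_intensity": 0.35,
        "bw": 56.3,
    },
}

#: Offered DM as a multiple of the day's expected 15-h intake (ad libitum
#: feeding leaves refusals), and the NDF fraction of the offered TMR.
OFFER_MARGIN = 1.35
OFFERED_NDF = 0.40
DM_FRACTION = 0.55
BW_PERIOD_SHIFT = (-3.0, 0.0, 2.0, 4.0)  # growth across the two cycles, kg


@dataclass
class GoatLatentTraits:
    goat_id: str
    breed: str
    mean_dmi900: float  # g DM/kg BW over the 15-h window
    initial_rate: float  # g DM/kg BW per min in the first bout
    eagerness: float  # fraction of the 15-h intake taken in the first bout
    sorting_intensity: float  # >= 0; 0 means unselective refusals
    bw: float  # kg, baseline

    def __post_init__(self) -> None:
        if min(self.mean_dmi900, self.initial_rate, self.sorting_intensity + 1e-12,
               self.bw) <= 0:
            raise ConfigurationError("latent traits must be positive")
        if not 0 < self.eagerness <= 1:
            raise ConfigurationError("eagerness must lie in (0, 1]")


@dataclass
class SyntheticDataset:
    """A simulated herd: recordings plus the tables a real trial would keep."""

    design: HerdDesign
    trough_series: list[TroughSeries]
    bw_table: pd.DataFrame  # goat_id, period, bw_kg
    feed_table: pd.DataFrame  # goat_id, period, day, offered_dm_g, offered_ndf, dm_fraction
    refusal_table: pd.DataFrame  # goat_id, period, day, refusal_dm_g, refusal_ndf
    truth_goats: pd.DataFrame  # per-goat latent traits
    truth_days: pd.DataFrame  # per goat-day realized trait values
    truth_bouts: pd.DataFrame  # realized bout schedule (start, duration, rate, intake)
    missing_cells: list[tuple]


def configured_icc(variances: VarianceSpec, design: HerdDesign, trait: str) -> float:
    """Repeatability implied by the variance components for one latent trait.

    Between-goat variance over between plus within-goat-between-period
    variance of the true goat-period means (period shifts are deterministic
    and excluded): ``s2_g / (s2_g + s2_gp + s2_day / n_days)``.
    """
    s2g = variances.sd_goat[trait] ** 2
    s2gp = variances.sd_goat_period[trait] ** 2
    s2d = variances.sd_day[trait] ** 2 / design.n_days_per_period
    return s2g / (s2g + s2gp + s2d)


def draw_goat_traits(design: HerdDesign, variances: VarianceSpec,
                     rng: np.random.Generator) -> list[GoatLatentTraits]:
    goats = []
    for gid, breed in zip(design.goat_ids, design.breeds):
        bm = BREED_MEANS[breed]
        goats.append(
            GoatLatentTraits(
                goat_id=gid,
                breed=breed,
                mean_dmi900=max(8.0, bm["mean_dmi900"]
                                + rng.normal(0, variances.sd_goat["mean_dmi900"])),
                initial_rate=max(0.05, bm["initial_rate"]
                                 + rng.normal(0, variances.sd_goat["initial_rate"])),
                eagerness=float(np.clip(
                    bm["eagerness"] + rng.normal(0, variances.sd_goat["eagerness"]),
                    0.15, 0.95)),
                sorting_intensity=max(0.0, bm["sorting_intensity"]
                                      + rng.normal(0, variances.sd_goat["sorting_intensity"])),
                bw=max(30.0, bm["bw"] + rng.normal(0, 4.0)),
            )
        )
    return goats


def _realize_day_traits(traits: GoatLatentTraits, gp_dev: dict[str, float],
                        period_idx: int, variances: VarianceSpec,
                        rng: np.random.Generator) -> dict[str, float]:
    out = {}
    for name in LATENT_TRAITS:
        val = (getattr(traits, name)
               + variances.period_shift[name][period_idx % 4]
               + gp_dev[name]
               + rng.normal(0, variances.sd_day[name]))
        out[name] = val
    out["mean_dmi900"] = max(5.0, out["mean_dmi900"])
    out["initial_rate"] = max(0.04, out["initial_rate"])
    out["eagerness"] = float(np.clip(out["eagerness"], 0.10, 0.97))
    out["sorting_intensity"] = max(0.0, out["sorting_intensity"])
    return out


#: Rate bands of the bout model, g DM/kg BW per min.  Eating bouts are
#: bounded below and background nibbling bounded above so that "eating" and
#: "almost no intake" are separated classes on the slope axis — the
#: structure the eight-cluster rule (clusters 1-2 = near-zero slope)
#: presumes of real recordings.
MIN_BOUT_RATE = 0.10
MAX_NIBBLE_RATE = 0.04
NIBBLE_PROB = 0.7


def _draw_bout_schedule(day: dict[str, float], design: HerdDesign,
                        rng: np.random.Generator, max_tries: int = 50):
    """Draw eating bouts and background nibbling (g DM/kg BW per min).

    A first bout from t=0 holding ``eagerness`` of the 15-h intake at the
    goat's initial rate; 0-6 later bouts at lower (but still clearly
    eating) rates separated by pauses, a quarter of which are shorter than
    30 min so they belong to the same meal under the detection rule; slow
    nibbling fills some of the pauses; an optional slow late-night bout
    after the 15-h mark.  Schedules that overrun the window are redrawn.
    Returns ``(bouts, nibbles)``, each a list of (start, duration, rate).
    """
    dmi900 = day["mean_dmi900"]
    window15 = 900.0
    r1 = max(day["initial_rate"], MIN_BOUT_RATE)
    bouts = None
    for _ in range(max_tries):
        cand = []
        first_intake = day["eagerness"] * dmi900
        d1 = first_intake / r1
        if d1 > 0.6 * window15:
            d1 = 0.6 * window15
        cand.append((0.0, d1, first_intake / d1))
        remaining = dmi900 - first_intake
        n_later = int(rng.integers(0, 7)) if remaining > 0.5 else 0
        if n_later > 0:
            shares = rng.dirichlet(np.ones(n_later) * 2.0) * remaining
            t_cursor = d1
            ok = True
            for share in shares:
                if share < 0.2:
                    continue
                if rng.random() < 0.25:
                    gap = rng.uniform(8.0, 25.0)
                else:
                    gap = 30.0 + rng.exponential(60.0)
                rate = max(MIN_BOUT_RATE, r1 * rng.uniform(0.4, 0.8))
                dur = share / rate
                if dur < 12.0:  # too brief to register as a distinct bout
                    continue
                start = t_cursor + gap
                if start + dur > window15 - 10.0:
                    ok = False
                    break
                cand.append((start, dur, rate))
                t_cursor = start + dur
            if not ok:
                continue
        bouts = cand
        break
    if bouts is None:  # fallback: single-bout day (always fits)
        bouts = [(0.0, 0.6 * window15, dmi900 / (0.6 * window15))]
    # optional slow late-night bout beyond the 15-h window
    if rng.random() < 0.7 and design.window_total > window15 + 80:
        late_intake = dmi900 * rng.uniform(0.04, 0.12)
        rate = max(0.03, 0.12 * r1)
        dur = min(late_intake / rate, design.window_total - window15 - 60.0)
        start = rng.uniform(window15 + 40.0,
                            design.window_total - dur - 10.0)
        bouts.append((start, dur, rate))
    # background nibbling in some of the pauses of the 15-h window
    nibbles = []
    ends = [s + d for s, d, _ in bouts if s < window15]
    starts = [s for s, _, _ in bouts if s < window15]
    gaps = list(zip(ends[:-1], starts[1:])) + [(ends[-1], window15)]
    for lo, hi in gaps:
        if hi - lo > 12.0 and rng.random() < NIBBLE_PROB:
            # the nibble spans the whole pause: a pause is one homogeneous
            # near-zero stretch, not a zero/nibble/zero sandwich
            rate = rng.uniform(0.1 * MAX_NIBBLE_RATE, MAX_NIBBLE_RATE)
            nibbles.append((lo, hi - lo, rate))
    # nibbling is incidental: cap its total at 10% of the day's target so it
    # never competes with the bout budget (or the offered amount)
    nibble_total = sum(d * r for _, d, r in nibbles)
    cap = 0.10 * dmi900
    if nibble_total > cap:
        f = cap / nibble_total
        nibbles = [(s, d, r * f) for s, d, r in nibbles]
    return bouts, nibbles


def _cumulative_from_bouts(bouts, t: np.ndarray) -> np.ndarray:
    y = np.zeros_like(t)
    for start, dur, rate in bouts:
        y += rate * np.clip(t - start, 0.0, dur)
    return y


def simulate_day_profile(traits: GoatLatentTraits, day_values: dict[str, float],
                         design: HerdDesign, rng: np.random.Generator,
                         *, bw: float, offered_asfed: float,
                         sd_noise: float, bump_prob: float,
                         labels: tuple[str, str] = ("P1", "D1")):
    """Simulate one goat-day: trough series plus the true bout schedule.

    Returns ``(series, bouts, nibbles, true_intake_dm_g)`` where ``bouts``
    and ``nibbles`` are lists of (start_min, duration_min,
    rate_gDM_per_kgBW_min) and the trough weight is quantized to the scale
    resolution after additive noise.
    """
    bouts, nibbles = _draw_bout_schedule(day_values, design, rng)
    t = design.sampling_interval * np.arange(design.n_samples)
    y_dm_per_kg = _cumulative_from_bouts(bouts + nibbles, t)
    intake_asfed = y_dm_per_kg * bw / DM_FRACTION
    total_asfed = float(intake_asfed[-1])
    if total_asfed > offered_asfed:  # never eat more than offered
        scale = 0.98 * offered_asfed / total_asfed
        bouts = [(s, d, r * scale) for s, d, r in bouts]
        nibbles = [(s, d, r * scale) for s, d, r in nibbles]
        y_dm_per_kg *= scale
        intake_asfed *= scale
    weight = offered_asfed - intake_asfed
    if sd_noise > 0:
        weight = weight + rng.normal(0, sd_noise, size=weight.shape)
    if bump_prob > 0:
        bumps = rng.random(weight.shape) < bump_prob
        weight = weight + bumps * rng.uniform(5.0, 50.0, size=weight.shape)
    res = design.scale_resolution
    weight = np.maximum(np.round(weight / res) * res, 0.0)
    weight[0] = np.round(offered_asfed / res) * res
    series = TroughSeries(
        goat_id=traits.goat_id, breed=traits.breed,
        period=labels[0], day=labels[1],
        t=t, weight=weight, dm_fraction=DM_FRACTION,
    )
    true_intake_dm = y_dm_per_kg[-1] * bw
    return series, bouts, nibbles, float(true_intake_dm)


def simulate_refusal(traits_or_intensity, offered_dm: float, offered_ndf: float,
                     intake_dm: float, rng: np.random.Generator | None = None):
    """Compose the refusal left after a day of (possibly selective) eating.

    The refusal DM is the mass balance ``offered - intake``; its NDF fraction
    is enriched above the offered diet's in proportion to the goat's sorting
    intensity and how much of the offer was eaten, capped so the implied
    intake NDF mass stays non-negative.  With zero sorting intensity the
    refusal has exactly the offered composition (sorting index 1).
    """
    intensity = (traits_or_intensity.sorting_intensity
                 if hasattr(traits_or_intensity, "sorting_intensity")
                 else float(traits_or_intensity))
    if not 0 <= intake_dm <= offered_dm:
        raise ValueError("intake must lie in [0, offered]")
    refusal_dm = offered_dm - intake_dm
    if refusal_dm == 0:
        return {"refusal_dm": 0.0, "refusal_ndf": offered_ndf}
    eaten_frac = intake_dm / offered_dm
    jitter = rng.normal(0, 0.01) if rng is not None else 0.0
    enrich = max(0.0, intensity * eaten_frac + jitter)
    refusal_ndf = offered_ndf * (1.0 + enrich)
    # caps: intake NDF mass >= 0 and fraction <= 1
    refusal_ndf = min(refusal_ndf, offered_ndf * offered_dm / refusal_dm, 0.99)
    return {"refusal_dm": float(refusal_dm), "refusal_ndf": float(refusal_ndf)}


def default_missing_cells(design: HerdDesign, rng: np.random.Generator) -> list[tuple]:
    """The reference trial's missing-record pattern: 19 goat-days over 13
    goats (4 goats missing 2 days, 1 goat missing 3, 8 goats missing 1)."""
    if design.n_goats < 13 or design.n_periods * design.n_days_per_period < 3:
        raise ConfigurationError("design too small for the reference missing pattern")
    goats = rng.choice(design.goat_ids, size=13, replace=False)
    counts = [2, 2, 2, 2, 3, 1, 1, 1, 1, 1, 1, 1, 1]
    cells = []
    for gid, k in zip(goats, counts):
        pd_pairs = [(p, d) for p in design.periods for d in design.days]
        picks = rng.choice(len(pd_pairs), size=k, replace=False)
        for i in picks:
            cells.append((gid, *pd_pairs[i]))
    return cells


def simulate_herd(design: HerdDesign | None = None,
                  variances: VarianceSpec | None = None,
                  seed: int = 0,
                  missing_cells: list[tuple] | None = None) -> SyntheticDataset:
    """Simulate a full herd; deterministic given ``seed``.

    ``missing_cells`` is a list of ``(goat_id, period, day)`` tuples dropped
    from the output (default: none), emulating lost recordings.
    """
    design = design or HerdDesign()
    variances = variances or VarianceSpec()
    missing = set(missing_cells or [])
    rng = np.random.default_rng(seed)
    goats = draw_goat_traits(design, variances, rng)

    series_list, bw_rows, feed_rows, refusal_rows = [], [], [], []
    truth_day_rows, truth_bout_rows = [], []
    for traits in goats:
        for p_idx, period in enumerate(design.periods):
            bw = traits.bw + BW_PERIOD_SHIFT[p_idx % 4] + rng.normal(0, 0.8)
            bw_rows.append({"goat_id": traits.goat_id, "period": period,
                            "bw_kg": round(bw, 1)})
            gp_dev = {name: rng.normal(0, variances.sd_goat_period[name])
                      for name in LATENT_TRAITS}
            for day in design.days:
                day_vals = _realize_day_traits(traits, gp_dev, p_idx, variances, rng)
                offered_dm = OFFER_MARGIN * day_vals["mean_dmi900"] * bw
                offered_asfed = offered_dm / DM_FRACTION
                dropped = (traits.goat_id, period, day) in missing
                series, bouts, nibbles, intake_dm = simulate_day_profile(
                    traits, day_vals, design, rng, bw=bw,
                    offered_asfed=offered_asfed,
                    sd_noise=variances.sd_noise, bump_prob=variances.bump_prob,
                    labels=(period, day),
                )
                refusal = simulate_refusal(traits, offered_dm, OFFERED_NDF,
                                           intake_dm, rng)
                if not dropped:
                    series_list.append(series)
                    feed_rows.append({
                        "goat_id": traits.goat_id, "period": period, "day": day,
                        "offered_dm_g": offered_dm, "offered_ndf": OFFERED_NDF,
                        "dm_fraction": DM_FRACTION,
                    })
                    refusal_rows.append({
                        "goat_id": traits.goat_id, "period": period, "day": day,
                        "refusal_dm_g": refusal["refusal_dm"],
                        "refusal_ndf": refusal["refusal_ndf"],
                    })
                truth_day_rows.append({
                    "goat_id": traits.goat_id, "breed": traits.breed,
                    "period": period, "day": day, "dropped": dropped,
                    **{f"true_{k}": v for k, v in day_vals.items()},
                    "true_intake_dm_g": intake_dm, "bw_kg": bw,
                })
                for b_idx, (start, dur, rate) in enumerate(bouts + nibbles):
                    truth_bout_rows.append({
                        "goat_id": traits.goat_id, "period": period, "day": day,
                        "bout": b_idx, "start_min": start, "duration_min": dur,
                        "rate_g_per_kg_min": rate, "intake_g_per_kg": rate * dur,
                        "kind": "bout" if b_idx < len(bouts) else "nibble",
                    })
    expected = design.n_goats * design.n_periods * design.n_days_per_period
    if len(series_list) != expected - len(missing):
        warnings.warn("missing-cell list referenced cells outside the design")
    truth_goats = pd.DataFrame([{
        "goat_id": g.goat_id, "breed": g.breed, "bw_kg": g.bw,
        **{name: getattr(g, name) for name in LATENT_TRAITS},
    } for g in goats])
    return SyntheticDataset(
        design=design,
        trough_series=series_list,
        bw_table=pd.DataFrame(bw_rows),
        feed_table=pd.DataFrame(feed_rows),
        refusal_table=pd.DataFrame(refusal_rows),
        truth_goats=truth_goats,
        truth_days=pd.DataFrame(truth_day_rows),
        truth_bouts=pd.DataFrame(truth_bout_rows),
        missing_cells=sorted(missing),
    )


def true_first_meal(bouts: pd.DataFrame, min_pause: float = 30.0) -> pd.DataFrame:
    """Apply the 30-min pause rule to the true bout schedule of each goat-day.

    The first meal runs from the first bout until the first inter-bout pause
    of at least ``min_pause`` minutes; its intake is the summed bout intakes
    up to that pause (background nibbling is not eating and is excluded).
    Used to score meal detection against ground truth.
    """
    rows = []
    if "kind" in bouts:
        bouts = bouts[bouts["kind"] == "bout"]
    for key, grp in bouts.groupby(["goat_id", "period", "day"], sort=True):
        grp = grp.sort_values("start_min")
        starts = grp["start_min"].to_numpy()
        ends = starts + grp["duration_min"].to_numpy()
        intakes = grp["intake_g_per_kg"].to_numpy()
        total = intakes[0]
        meal_end = ends[0]
        for i in range(1, len(starts)):
            if starts[i] - ends[i - 1] >= min_pause:
                break
            total += intakes[i]
            meal_end = ends[i]
        rows.append({"goat_id": key[0], "period": key[1], "day": key[2],
                     "true_first_meal_intake": total,
                     "true_first_meal_end": meal_end})
    return pd.DataFrame(rows)
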