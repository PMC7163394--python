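"""End-to-end pipeline: simulate -> profiles -> fits/segmentation -> traits
-> statistics, with persisted intermediates so any stage can be re-run.

Every output is a CSV with a documented header (see README); ``manifest.json``
records the package version, seed, and a hash of the resolved configuration.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .expmodel import fit_exponential
from .pca import goat_barycentres, run_pca, score_anova
from .profiles import (TroughSeries, clip_window, cumulative_intake,
                       read_trough_series, write_trough_series)
from .repeatability import (between_period_correlations, fit_full_anova,
                            fit_simplified_anova, repeatability_ratio,
                            within_period_repeatability)
from .segmentation import (assign_clusters, first_meal, fit_cluster_model,
                           segment_profile)
from .synthetic import (HerdDesign, VarianceSpec, default_missing_cells,
                        simulate_herd)
from .traits import TRAIT_NAMES, compute_traits, goat_period_means


@dataclass
class RunConfig:
    """Resolved run configuration; defaults follow the reference protocol:
    90/180/900-min trait windows inside a 1320-min recording, 8 slope
    clusters, a 30-min pause rule and a 0.95 repeatability threshold."""

    seed: int = 0
    design: HerdDesign = field(default_factory=HerdDesign)
    variances: VarianceSpec = field(default_factory=VarianceSpec)
    use_reference_missing_pattern: bool = False
    analysis_window: float = 900.0
    trait_windows: tuple = (90.0, 180.0, 900.0)
    n_clusters: int = 8
    min_pause: float = 30.0
    segmentation_penalty: float | None = None  # None -> BIC grid
    repeatability_threshold: float = 0.95

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        design = HerdDesign(**raw.pop("design", {}))
        var_kwargs = raw.pop("variances", {})
        variances = VarianceSpec(**var_kwargs)
        return cls(design=design, variances=variances, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["design"] = asdict(self.design)
        d["variances"] = {k: (dict(v) if isinstance(v, dict) else v)
                          for k, v in asdict(self.variances).items()}
        return d


def stage_simulate(config: RunConfig, out: Path) -> None:
    """Simulate a herd and persist its tables under ``out``."""
    out.mkdir(parents=True, exist_ok=True)
    missing = None
    if config.use_reference_missing_pattern:
        missing = default_missing_cells(
            config.design, np.random.default_rng(config.seed + 1))
    ds = simulate_herd(config.design, config.variances, seed=config.seed,
                       missing_cells=missing)
    write_trough_series(ds.trough_series, out / "trough.csv")
    ds.bw_table.to_csv(out / "bw.csv", index=False)
    ds.feed_table.to_csv(out / "feed.csv", index=False)
    ds.refusal_table.to_csv(out / "refusals.csv", index=False)
    ds.truth_goats.to_csv(out / "truth_goats.csv", index=False)
    ds.truth_days.to_csv(out / "truth_days.csv", index=False)
    ds.truth_bouts.to_csv(out / "truth_bouts.csv", index=False)
    (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict()))


def compute_trait_table(series_list: list[TroughSeries], bw_table: pd.DataFrame,
                        feed_table: pd.DataFrame, refusal_table: pd.DataFrame,
                        config: RunConfig) -> pd.DataFrame:
    """Fit, segment and aggregate every goat-day into the trait table.

    The slope-cluster model is fitted once on the pooled segments of the
    whole run so cluster labels are comparable across goats and days.
    """
    bw_map = {(r.goat_id, r.period): r.bw_kg for r in bw_table.itertuples()}
    feed_map = {(r.goat_id, r.period, r.day): r for r in feed_table.itertuples()}
    ref_map = {(r.goat_id, r.period, r.day): r for r in refusal_table.itertuples()}

    per_day = []
    all_segments = []
    for series in series_list:
        bw = bw_map.get((series.goat_id, series.period))
        if bw is None:
            raise ValueError(f"no BW for goat {series.goat_id} period {series.period}")
        profile22 = cumulative_intake(series, bw)
        profile15 = clip_window(profile22, config.analysis_window)
        fit = fit_exponential(profile15)
        segments = segment_profile(profile15, penalty=config.segmentation_penalty)
        per_day.append((series, profile22, profile15, fit, segments))
        all_segments.extend(segments)

    cluster_model = fit_cluster_model(all_segments, k=config.n_clusters,
                                      seed=config.seed)
    records = []
    for series, profile22, profile15, fit, segments in per_day:
        assign_clusters(segments, cluster_model)
        meal = first_meal(segments, min_pause=config.min_pause)
        key = (series.goat_id, series.period, series.day)
        feed = feed_map.get(key)
        ref = ref_map.get(key)
        kwargs = {}
        if feed is not None and ref is not None:
            kwargs = {"offered_dm": feed.offered_dm_g,
                      "offered_ndf": feed.offered_ndf,
                      "refusal_dm": ref.refusal_dm_g,
                      "refusal_ndf": ref.refusal_ndf}
        rec = compute_traits(profile22, profile15, fit, meal, **kwargs)
        rec["first_meal_end"] = meal.first_meal_end
        rec["n_segments"] = len(segments)
        records.append(rec)
    return pd.DataFrame(records)


def stage_traits(config: RunConfig, out: Path) -> None:
    """Read persisted recordings, compute daily traits and goat-period means."""
    series_list = read_trough_series(out / "trough.csv")
    bw = pd.read_csv(out / "bw.csv", dtype={"goat_id": str, "period": str})
    feed = pd.read_csv(out / "feed.csv",
                       dtype={"goat_id": str, "period": str, "day": str})
    refusals = pd.read_csv(out / "refusals.csv",
                           dtype={"goat_id": str, "period": str, "day": str})
    traits = compute_trait_table(series_list, bw, feed, refusals, config)
    traits.to_csv(out / "traits.csv", index=False)
    goat_period_means(traits).to_csv(out / "trait_means.csv", index=False)


def stage_stats(config: RunConfig, out: Path) -> None:
    """Statistical layer on the persisted trait tables."""
    traits = pd.read_csv(out / "traits.csv",
                         dtype={"goat_id": str, "period": str, "day": str})
    means = pd.read_csv(out / "trait_means.csv",
                        dtype={"goat_id": str, "period": str})
    full_rows, rep_rows, simple_rows, corr_frames = [], [], [], []
    for trait in TRAIT_NAMES:
        full = fit_full_anova(traits.dropna(subset=[trait]), trait)
        decision = within_period_repeatability(
            full, threshold=config.repeatability_threshold)
        tab = full.table.reset_index()
        tab.insert(0, "trait", trait)
        full_rows.append(tab)
        simple = fit_simplified_anova(means.dropna(subset=[trait]), trait)
        stab = simple.table.reset_index()
        stab.insert(0, "trait", trait)
        simple_rows.append(stab)
        ratio = repeatability_ratio(means, trait)
        rep_rows.append({"trait": trait, "day_p": decision["day_p"],
                         "repeatable_within_period": decision["repeatable"],
                         "sigma2_between": ratio.sigma2_between,
                         "sigma2_within": ratio.sigma2_within,
                         "ratio": ratio.ratio})
        corr_frames.append(between_period_correlations(means, trait))
    pd.concat(full_rows).to_csv(out / "anova_full.csv", index=False)
    pd.concat(simple_rows).to_csv(out / "anova_simplified.csv", index=False)
    pd.concat(corr_frames).to_csv(out / "correlations.csv", index=False)

    pca = run_pca(means)
    pca.loadings.to_csv(out / "pca_loadings.csv")
    scores = pca.scores.copy()
    scores.to_csv(out / "pca_scores.csv", index=False)
    pd.DataFrame({"component": [f"PC{i+1}" for i in
                                range(len(pca.explained_variance_pct))],
                  "explained_pct": pca.explained_variance_pct}
                 ).to_csv(out / "pca_explained.csv", index=False)
    sc_anova = score_anova(pca)
    sc_rows = []
    for comp, res in sc_anova.items():
        tab = res.table.reset_index()
        tab.insert(0, "component", comp)
        sc_rows.append(tab)
        rep = repeatability_ratio(pca.scores, comp)
        rep_rows.append({"trait": comp, "day_p": np.nan,
                         "repeatable_within_period": np.nan,
                         "sigma2_between": rep.sigma2_between,
                         "sigma2_within": rep.sigma2_within,
                         "ratio": rep.ratio})
    pd.concat(sc_rows).to_csv(out / "score_anova.csv", index=False)
    pd.DataFrame(rep_rows).to_csv(out / "repeatability.csv", index=False)
    goat_barycentres(pca).to_csv(out / "pca_barycentres.csv", index=False)

    manifest = {
        "package": "capribite",
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()).hexdigest(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def run_pipeline(config: RunConfig, out) -> Path:
    """Run simulate -> traits -> stats into ``out``; deterministic per seed."""
    out = Path(out)
    stage_simulate(config, out)
    stage_traits(config, out)
    stage_stats(config, out)
    return out


def validate_inputs(trough_path, bw_path, feed_path, refusal_path) -> list[str]:
    """Schema and key-consistency checks across the four input tables.

    Returns the list of violations (empty = valid): missing columns, BW
    missing for a recorded goat-period, refusals exceeding offers, refusal
    rows without a matching feed row.
    """
    violations: list[str] = []
    try:
        series = read_trough_series(trough_path)
    except Exception as exc:  # surfaced as a violation, not a crash
        return [f"trough table: {exc}"]
    bw = pd.read_csv(bw_path, dtype={"goat_id": str, "period": str})
    feed = pd.read_csv(feed_path, dtype={"goat_id": str, "period": str, "day": str})
    refusals = pd.read_csv(refusal_path,
                           dtype={"goat_id": str, "period": str, "day": str})
    for name, df, cols in [
        ("bw", bw, {"goat_id", "period", "bw_kg"}),
        ("feed", feed, {"goat_id", "period", "day", "offered_dm_g", "offered_ndf"}),
        ("refusals", refusals,
         {"goat_id", "period", "day", "refusal_dm_g", "refusal_ndf"}),
    ]:
        missing = cols - set(df.columns)
        if missing:
            violations.append(f"{name} table: missing columns {sorted(missing)}")
    if violations:
        return violations
    bw_keys = set(zip(bw.goat_id, bw.period))
    for s in series:
        if (s.goat_id, s.period) not in bw_keys:
            violations.append(f"BW missing for goat {s.goat_id} period {s.period}")
    feed_keys = {(r.goat_id, r.period, r.day): r.offered_dm_g
                 for r in feed.itertuples()}
    for r in refusals.itertuples():
        key = (r.goat_id, r.period, r.day)
        if key not in feed_keys:
            violations.append(f"refusal without feed row for {key}")
        elif r.refusal_dm_g > feed_keys[key] + 1e-9:
            violations.append(
                f"refusal_dm > offered_dm for goat {r.goat_id} "
                f"period {r.period} day {r.day}")
    return violations
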