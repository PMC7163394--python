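import numpy as np
import pandas as pd
import pytest

import capribite as cb
from capribite.synthetic import (BREED_MEANS, ConfigurationError, DM_FRACTION,
                                 MAX_NIBBLE_RATE, MIN_BOUT_RATE)


class TestDesign:
    def test_reference_design_counts(self):
        d = cb.HerdDesign()
        assert d.n_goats == 35 and d.n_alpine == 13
        assert d.n_samples == 660
        assert d.breeds.count("A") == 13 and d.breeds.count("S") == 22

    @pytest.mark.parametrize("kw", [
        dict(n_goats=1), dict(sampling_interval=0),
        dict(window_total=1321.0), dict(scale_resolution=0),
        dict(n_alpine=99),
    ])
    def test_invalid_designs_rejected(self, kw):
        with pytest.raises(ConfigurationError):
            cb.HerdDesign(**kw)


class TestSimulateHerd:
    def test_determinism_same_seed_identical_datasets(self, small_design):
        a = cb.simulate_herd(small_design, seed=5)
        b = cb.simulate_herd(small_design, seed=5)
        for sa, sb in zip(a.trough_series, b.trough_series):
            assert np.array_equal(sa.weight, sb.weight)
        pd.testing.assert_frame_equal(a.truth_days, b.truth_days)
        pd.testing.assert_frame_equal(a.refusal_table, b.refusal_table)

    def test_series_count_bookkeeping(self, small_design, small_herd):
        d = small_design
        assert len(small_herd.trough_series) == d.n_goats * d.n_periods * d.n_days_per_period

    def test_missing_cells_reduce_series_count(self, small_design):
        missing = [("G01", "P1", "D1"), ("G02", "P2", "D2")]
        ds = cb.simulate_herd(small_design, seed=5, missing_cells=missing)
        assert len(ds.trough_series) == 6 * 2 * 2 - 2
        keys = {s.key for s in ds.trough_series}
        assert not keys & set(missing)

    def test_reference_missing_pattern_is_19_cells_over_13_goats(self):
        rng = np.random.default_rng(0)
        cells = cb.default_missing_cells(cb.HerdDesign(), rng)
        assert len(cells) == 19
        per_goat = pd.Series([c[0] for c in cells]).value_counts()
        assert len(per_goat) == 13
        assert sorted(per_goat) == [1] * 8 + [2] * 4 + [3]

    def test_dm_mass_conservation_every_goat_day(self, small_herd):
        feed = small_herd.feed_table.set_index(["goat_id", "period", "day"])
        ref = small_herd.refusal_table.set_index(["goat_id", "period", "day"])
        truth = small_herd.truth_days.set_index(["goat_id", "period", "day"])
        for key in feed.index:
            offered = feed.loc[key, "offered_dm_g"]
            refusal = ref.loc[key, "refusal_dm_g"]
            intake = truth.loc[key, "true_intake_dm_g"]
            assert refusal <= offered + 1e-9
            assert np.isclose(offered, intake + refusal, rtol=1e-9)

    def test_trough_weight_nonincreasing_before_noise(self, small_design):
        var = cb.VarianceSpec(sd_noise=0.0, bump_prob=0.0)
        ds = cb.simulate_herd(small_design, var, seed=3)
        for s in ds.trough_series:
            assert np.all(np.diff(s.weight) <= 0)
            assert np.all(s.weight >= 0)

    def test_weights_quantized_to_scale_resolution(self, small_herd):
        res = small_herd.design.scale_resolution
        for s in small_herd.trough_series:
            assert np.allclose(s.weight % res, 0.0)

    def test_mass_balance_truth_vs_series(self, small_design):
        """Quantization aside, the series-implied intake matches the
        recorded bout schedule."""
        var = cb.VarianceSpec(sd_noise=0.0, bump_prob=0.0)
        ds = cb.simulate_herd(small_design, var, seed=3)
        truth = ds.truth_days.set_index(["goat_id", "period", "day"])
        for s in ds.trough_series:
            implied_asfed = s.weight[0] - s.weight[-1]
            true_asfed = truth.loc[s.key, "true_intake_dm_g"] / DM_FRACTION
            assert abs(implied_asfed - true_asfed) <= small_design.scale_resolution

    def test_breed_mean_dmi900_in_printed_range_at_lactation(self):
        """At the mid-first-lactation period the configured breed means fall
        in the 30-40 g DM/kg BW band."""
        var = cb.VarianceSpec()
        for breed in ("A", "S"):
            m = BREED_MEANS[breed]["mean_dmi900"] + var.period_shift["mean_dmi900"][1]
            assert 30.0 <= m <= 40.0

    def test_bout_rates_separated_from_nibbles(self, small_herd):
        tb = small_herd.truth_bouts
        eating = tb[(tb.kind == "bout") & (tb.start_min < 900)]
        nibbles = tb[tb.kind == "nibble"]
        assert (eating.rate_g_per_kg_min >= MIN_BOUT_RATE - 1e-9).all()
        assert (nibbles.rate_g_per_kg_min <= MAX_NIBBLE_RATE + 1e-9).all()

    def test_pauses_between_meals_at_least_30_min_or_merged(self, small_herd):
        """Consecutive eating bouts are either close (<30 min, same meal) or
        separated by a genuine pause; no zero-length gaps."""
        tb = small_herd.truth_bouts
        for _, grp in tb[tb.kind == "bout"].groupby(["goat_id", "period", "day"]):
            grp = grp.sort_values("start_min")
            gaps = grp.start_min.to_numpy()[1:] - (
                grp.start_min + grp.duration_min).to_numpy()[:-1]
            assert (gaps > 7.0).all()


class TestSimulateRefusal:
    def test_zero_sorting_intensity_gives_offered_composition(self):
        r = cb.simulate_refusal(0.0, offered_dm=2000, offered_ndf=0.4,
                                intake_dm=1500)
        assert r["refusal_dm"] == 500
        assert r["refusal_ndf"] == 0.4
        assert cb.ndf_sorting(2000, 0.4, r["refusal_dm"], r["refusal_ndf"]) == 1.0

    def test_positive_sorting_enriches_refusal_ndf(self):
        r = cb.simulate_refusal(0.4, offered_dm=2000, offered_ndf=0.4,
                                intake_dm=1500)
        assert r["refusal_ndf"] > 0.4
        assert cb.ndf_sorting(2000, 0.4, r["refusal_dm"], r["refusal_ndf"]) < 1.0

    def test_intake_exceeding_offer_rejected(self):
        with pytest.raises(ValueError):
            cb.simulate_refusal(0.0, offered_dm=100, offered_ndf=0.4,
                                intake_dm=150)

    def test_ndf_mass_conserved_by_construction(self):
        r = cb.simulate_refusal(0.3, offered_dm=1800, offered_ndf=0.45,
                                intake_dm=1200)
        intake_ndf_mass = 1800 * 0.45 - r["refusal_dm"] * r["refusal_ndf"]
        assert intake_ndf_mass >= 0
        assert np.isclose(intake_ndf_mass + r["refusal_dm"] * r["refusal_ndf"],
                          1800 * 0.45)

    def test_herd_level_sorting_index_below_one(self, small_herd):
        feed = small_herd.feed_table.merge(small_herd.refusal_table,
                                           on=["goat_id", "period", "day"])
        idx = [cb.ndf_sorting(r.offered_dm_g, r.offered_ndf,
                              r.refusal_dm_g, r.refusal_ndf)
               for r in feed.itertuples()]
        assert np.nanmean(idx) < 1.0


class TestCalibration:
    def test_single_bout_day_flat_after_bout_end(self):
        design = cb.HerdDesign(n_goats=2, n_alpine=1, n_periods=1,
                               n_days_per_period=1)
        traits = cb.GoatLatentTraits(goat_id="G1", breed="A", mean_dmi900=30.0,
                                     initial_rate=0.3, eagerness=1.0,
                                     sorting_intensity=0.0, bw=50.0)
        day = {"mean_dmi900": 30.0, "initial_rate": 0.3, "eagerness": 1.0,
               "sorting_intensity": 0.0}
        rng = np.random.default_rng(0)
        series, bouts, nibbles, _ = cb.simulate_day_profile(
            traits, day, design, rng, bw=50.0, offered_asfed=6000.0,
            sd_noise=0.0, bump_prob=0.0)
        end = bouts[0][0] + bouts[0][1]
        after = series.weight[series.t > end + 2]
        eating_window = after[series.t[series.t > end + 2] < 900]
        # flat until any late-night bout
        assert np.ptp(eating_window) <= 2 * design.scale_resolution + 1e-9 \
            or len(nibbles) > 0

    def test_configured_icc_recovered_from_truth_means(self):
        """Monte-Carlo: the one-way ratio of true goat-period latent means
        matches the variance-component prediction (period shifts zeroed so
        only the random components enter)."""
        # single breed so only the random components drive the ratio
        design = cb.HerdDesign(n_goats=20, n_alpine=0, n_periods=4,
                               n_days_per_period=4)
        var = cb.VarianceSpec(period_shift={k: (0.0,) * 4 for k in
                                            cb.synthetic.LATENT_TRAITS})
        target = cb.configured_icc(var, design, "mean_dmi900")
        est = []
        for seed in range(25):
            ds = cb.simulate_herd(design, var, seed=seed)
            means = (ds.truth_days.groupby(["goat_id", "period"])
                     ["true_mean_dmi900"].mean().reset_index())
            res = cb.repeatability_ratio(means, "true_mean_dmi900")
            est.append(res.ratio)
        assert abs(np.mean(est) - target) < 0.05
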