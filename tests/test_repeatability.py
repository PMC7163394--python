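import itertools

import numpy as np
import pandas as pd
import pytest

import capribite as cb


def balanced_records(effects, n_breeds=2, goats_per_breed=2, n_periods=2,
                     n_days=2, noise=0.0, seed=0):
    """Fully balanced daily records with additive configured effects."""
    rng = np.random.default_rng(seed)
    rows = []
    for b in range(n_breeds):
        for g in range(goats_per_breed):
            gid = f"B{b}G{g}"
            for p in range(n_periods):
                for d in range(n_days):
                    y = (effects.get("mu", 10.0)
                         + effects.get("breed", 0.0) * b
                         + effects.get("goat", {}).get(gid, 0.0)
                         + effects.get("day", 0.0) * d
                         + effects.get("period", 0.0) * p
                         + noise * rng.normal())
                    rows.append({"goat_id": gid, "breed": f"BR{b}",
                                 "period": f"P{p}", "day": f"D{d}", "y": y})
    return pd.DataFrame(rows)


def hand_anova_balanced(df):
    """Cell-mean sums of squares for the balanced nested 2x2x2x2 design,
    written out from the classical formulas (independent of the package's
    projection-based computation)."""
    y = df.set_index(["breed", "goat_id", "period", "day"])["y"]
    grand = y.mean()
    n = len(y)
    breeds = df.breed.unique()
    goats = df.goat_id.unique()
    periods = df.period.unique()
    days = df.day.unique()
    nb = n / len(breeds)
    ss_breed = nb * sum((y.xs(b, level="breed").mean() - grand) ** 2
                        for b in breeds)
    ng = n / len(goats)
    ss_goat = ng * sum((y.xs(g, level="goat_id").mean() - grand) ** 2
                       for g in goats) - ss_breed
    # day within goat (pooled over periods)
    ss_gd = 0.0
    for g in goats:
        sub = y.xs(g, level="goat_id")
        gmean = sub.mean()
        for d in days:
            ss_gd += len(sub.xs(d, level="day")) * \
                (sub.xs(d, level="day").mean() - gmean) ** 2
    np_ = n / len(periods)
    ss_period = np_ * sum((y.xs(p, level="period").mean() - grand) ** 2
                          for p in periods)
    ss_bp = 0.0
    for b, p in itertools.product(breeds, periods):
        sub = y.xs((b, p), level=("breed", "period"))
        exp = (y.xs(b, level="breed").mean() + y.xs(p, level="period").mean()
               - grand)
        ss_bp += len(sub) * (sub.mean() - exp) ** 2
    return {"breed": ss_breed, "goat_id": ss_goat, "goat_id:day": ss_gd,
            "period": ss_period, "breed:period": ss_bp}


class TestFullAnova:
    def test_ss_decomposition_matches_hand_formulas_balanced(self):
        effects = {"breed": 2.0, "day": 1.5, "period": 3.0,
                   "goat": {"B0G0": 0.0, "B0G1": 1.0, "B1G0": -0.5, "B1G1": 2.0}}
        df = balanced_records(effects, noise=1.0, seed=4)
        res = cb.fit_full_anova(df, "y")
        hand = hand_anova_balanced(df)
        for term, ss in hand.items():
            assert np.isclose(res.table.loc[term, "ss"], ss, rtol=1e-8), term
        total = df.y.var(ddof=0) * len(df)
        assert np.isclose(sum(hand.values()) + res.residual_ss, total, rtol=1e-8)

    def test_location_invariance_of_f_statistics(self):
        df = balanced_records({"breed": 1.0, "day": 0.5}, noise=1.0, seed=1)
        res1 = cb.fit_full_anova(df, "y")
        df2 = df.assign(y=df.y + 100.0)
        res2 = cb.fit_full_anova(df2, "y")
        assert np.allclose(res1.table.F, res2.table.F)

    def test_day_effect_null_p_values_approximately_uniform(self):
        """With no simulated day effect the day-within-goat p-value is
        uniform; check mean and rejection rate over replicates."""
        ps = []
        for seed in range(60):
            df = balanced_records({"goat": {"B0G0": 1.0, "B1G1": -1.0}},
                                  goats_per_breed=3, n_periods=2, n_days=3,
                                  noise=1.0, seed=seed)
            ps.append(cb.fit_full_anova(df, "y").p_value("goat_id:day"))
        ps = np.array(ps)
        assert abs(ps.mean() - 0.5) < 0.15
        assert (ps < 0.05).mean() < 0.15

    def test_one_day_per_cell_is_saturated_error(self):
        df = balanced_records({}, n_days=1, noise=1.0)
        with pytest.raises(ValueError):
            cb.fit_full_anova(df, "y")

    def test_degrees_of_freedom_add_up(self):
        df = balanced_records({}, goats_per_breed=3, n_periods=3, n_days=4,
                              noise=1.0, seed=2)
        res = cb.fit_full_anova(df, "y")
        assert res.table.df.sum() + res.residual_df == len(df) - 1


class TestSimplifiedAnova:
    def mean_table(self, noise=1.0, breed_effect=0.0, seed=0, goats=6,
                   periods=4):
        rng = np.random.default_rng(seed)
        rows = []
        for g in range(goats):
            breed = "A" if g < goats // 2 else "S"
            goat_dev = rng.normal(0, 1.0)
            for p in range(periods):
                rows.append({
                    "goat_id": f"G{g}", "breed": breed, "period": f"P{p}",
                    "y": 10 + breed_effect * (breed == "A") + goat_dev
                    + noise * rng.normal()})
        return pd.DataFrame(rows)

    def test_breed_tested_on_goat_within_breed(self):
        res = cb.fit_simplified_anova(self.mean_table(seed=3), "y")
        assert res.table.loc["breed", "error_term"] == "goat_id"
        ms_goat = res.table.loc["goat_id", "ms"]
        assert np.isclose(res.table.loc["breed", "F"],
                          res.table.loc["breed", "ms"] / ms_goat)

    def test_breed_null_type_I_error_near_nominal(self):
        rejections = [cb.fit_simplified_anova(
            self.mean_table(seed=s, goats=10), "y").p_value("breed") < 0.05
            for s in range(100)]
        assert 0.0 <= np.mean(rejections) <= 0.13

    def test_duplicating_rows_leaves_estimates_unchanged(self):
        df = self.mean_table(seed=5)
        res1 = cb.fit_simplified_anova(df, "y")
        res2 = cb.fit_simplified_anova(
            pd.concat([df, df], ignore_index=True), "y")
        # mean squares ratios (estimates) are invariant; SS double
        assert np.allclose(res2.table.ss, 2 * res1.table.ss)


class TestBetweenPeriodCorrelations:
    def test_identical_periods_give_r_one(self):
        df = pd.DataFrame({
            "goat_id": list("abcde") * 2,
            "period": ["P1"] * 5 + ["P2"] * 5,
            "y": [1.0, 2, 3, 4, 5] * 2})
        out = cb.between_period_correlations(df, "y")
        assert np.isclose(out.r.iloc[0], 1.0)

    def test_symmetry_and_pair_count(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "goat_id": [f"g{i}" for i in range(8)] * 3,
            "period": ["P1"] * 8 + ["P2"] * 8 + ["P3"] * 8,
            "y": rng.normal(size=24)})
        out = cb.between_period_correlations(df, "y")
        assert len(out) == 3  # P1P2, P1P3, P2P3

    def test_independent_periods_mean_r_near_zero(self):
        rs = []
        for seed in range(60):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame({
                "goat_id": [f"g{i}" for i in range(15)] * 2,
                "period": ["P1"] * 15 + ["P2"] * 15,
                "y": rng.normal(size=30)})
            rs.append(cb.between_period_correlations(df, "y").r.iloc[0])
        assert abs(np.mean(rs)) < 0.1

    def test_too_few_pairs_flagged_nan(self):
        df = pd.DataFrame({"goat_id": ["a", "b", "a", "b"],
                           "period": ["P1", "P1", "P2", "P2"],
                           "y": [1.0, 2, 3, 4]})
        out = cb.between_period_correlations(df, "y")
        assert np.isnan(out.r.iloc[0])


class TestRepeatabilityRatio:
    def make(self, goat_sd, within_sd, goats=35, periods=4, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for g in range(goats):
            dev = rng.normal(0, goat_sd)
            for p in range(periods):
                rows.append({"goat_id": f"G{g}", "period": f"P{p}",
                             "y": 10 + dev + rng.normal(0, within_sd)})
        return pd.DataFrame(rows)

    def test_pure_between_goat_variation_gives_one(self):
        df = self.make(goat_sd=2.0, within_sd=0.0, seed=1)
        assert cb.repeatability_ratio(df, "y").ratio == pytest.approx(1.0)

    def test_identical_goats_give_zero(self):
        df = self.make(goat_sd=0.0, within_sd=1.0, seed=1)
        res = cb.repeatability_ratio(df, "y")
        assert 0.0 <= res.ratio < 0.3  # MoM truncates at 0; small by chance

    def test_affine_invariance(self):
        df = self.make(1.0, 1.0, seed=2)
        r1 = cb.repeatability_ratio(df, "y").ratio
        df2 = df.assign(y=3.0 * df.y - 7.0)
        assert np.isclose(cb.repeatability_ratio(df2, "y").ratio, r1)

    def test_icc_recovery_at_reference_scale(self):
        """True ratio 0.6 (between 0.6, within 0.4 variance): mean estimate
        over seeds within 0.05."""
        est = [cb.repeatability_ratio(
            self.make(np.sqrt(0.6), np.sqrt(0.4), seed=s), "y").ratio
            for s in range(100)]
        assert abs(np.mean(est) - 0.6) < 0.05

    def test_single_period_rejected(self):
        df = self.make(1.0, 1.0).query("period == 'P0'")
        with pytest.raises(ValueError):
            cb.repeatability_ratio(df, "y")


class TestWithinPeriodDecision:
    def test_threshold_logic(self):
        df = balanced_records({"goat": {"B0G0": 2.0}}, noise=1.0,
                              goats_per_breed=3, n_days=3, seed=9)
        res = cb.fit_full_anova(df, "y")
        dec = cb.within_period_repeatability(res, threshold=0.95)
        assert dec["repeatable"] == (dec["day_p"] > 0.95)
        dec_low = cb.within_period_repeatability(res, threshold=0.0)
        assert dec_low["repeatable"]
        assert dec_low["threshold"] == 0.0
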