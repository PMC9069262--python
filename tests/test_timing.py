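"""Passage-date models: PC regressions, weekly trajectories, nested LRTs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import chronoscan as cs
from chronoscan.datatypes import validate_metadata


def migrant_meta(days, sexes=None, ids=None):
    n = len(days)
    return validate_metadata(
        pd.DataFrame(
            {
                "sample_id": ids or [f"m{i}" for i in range(n)],
                "group": "migratory",
                "capture_day": days,
                "sex": sexes if sexes is not None else ["F", "M"] * (n // 2) + ["F"] * (n % 2),
            }
        )
    )


class TestPcTiming:
    def test_orthogonal_pc_has_zero_slope(self):
        days = [240, 250, 260, 270] * 10
        pc = np.tile([1.0, -1.0, -1.0, 1.0], 10)  # orthogonal to the day pattern
        meta = migrant_meta(days)
        fit = cs.fit_pc_timing(pd.Series(pc, index=meta["sample_id"]), meta, terms=("pc",))
        assert fit.params["pc"] == pytest.approx(0.0, abs=1e-10)
        assert fit.tvalues["pc"] == pytest.approx(0.0, abs=1e-10)

    def test_exact_linear_limit_recovers_slope(self):
        rng = np.random.default_rng(0)
        pc = rng.normal(0, 5, 60)
        days = 260 + 2 * pc + rng.normal(0, 1e-6, 60)
        meta = migrant_meta(np.clip(np.round(days), 1, 366).astype(int))
        scores = pd.Series(pc, index=meta["sample_id"])
        fit = cs.fit_pc_timing(scores, meta, terms=("pc",))
        # capture days are rounded to integers, so slope/R2 are near-exact
        assert fit.params["pc"] == pytest.approx(2.0, abs=0.02)
        assert fit.r_squared > 0.99

    def test_interaction_term_available(self):
        rng = np.random.default_rng(1)
        pc = rng.normal(0, 2, 80)
        meta = migrant_meta(rng.integers(240, 300, 80))
        fit = cs.fit_pc_timing(pd.Series(pc, index=meta["sample_id"]), meta,
                               terms=("pc", "sex", "interaction"))
        assert "pc:sex" in fit.pvalues and 0 <= fit.pvalues["pc:sex"] <= 1

    def test_constant_predictor_named_in_error(self):
        meta = migrant_meta([240, 250, 260, 270, 280, 290])
        with pytest.raises(ValueError, match="pc"):
            cs.fit_pc_timing(pd.Series(1.0, index=meta["sample_id"]), meta, terms=("pc",))

    def test_power_on_chronotype_series(self):
        """PC1 predicts passage date in nearly all simulated replicates."""
        hits = 0
        for seed in range(20):
            ds = cs.simulate_scenario("chronotype", seed=seed)
            gm = ds.migrant_gm.subset_loci(ds.timing_loci)
            res = cs.fix_sign(cs.fit_ordinal_pca(gm))
            scores = pd.Series(res.object_scores[:, 0], index=res.sample_ids)
            fit = cs.fit_pc_timing(scores, ds.migrant_meta, terms=("pc", "sex"))
            hits += fit.pvalues["pc"] < 0.001
        assert hits >= 19


class TestRepolarize:
    def make_gm(self, codes):
        codes = np.asarray(codes, dtype=np.int8)
        return cs.GenotypeMatrix(
            [f"m{i}" for i in range(codes.shape[0])],
            [f"l{j}" for j in range(codes.shape[1])],
            codes,
            ["A"] * codes.shape[1],
        )

    def test_minor_allele_flipped_to_major(self):
        gm = self.make_gm([[0], [1], [0], [0], [1]])  # freq 0.2
        out = cs.repolarize_major(gm, gm.sample_ids)
        assert out.allele_freq()[0] == pytest.approx(0.8)

    def test_exact_half_unchanged(self):
        gm = self.make_gm([[2], [0], [1], [1]])  # freq 0.5
        out = cs.repolarize_major(gm, gm.sample_ids)
        np.testing.assert_array_equal(out.codes, gm.codes)

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        codes = rng.integers(0, 3, (30, 8)).astype(np.int8)
        gm = self.make_gm(codes)
        once = cs.repolarize_major(gm, gm.sample_ids)
        twice = cs.repolarize_major(once, gm.sample_ids)
        np.testing.assert_array_equal(once.codes, twice.codes)

    def test_weekly_frequencies_complement_after_flip(self):
        rng = np.random.default_rng(3)
        codes = rng.binomial(2, 0.25, (60, 1)).astype(np.int8)
        gm = self.make_gm(codes)
        meta = migrant_meta(rng.integers(240, 290, 60), ids=gm.sample_ids)
        before = cs.weekly_frequencies(gm, meta, "l0")
        flipped = cs.repolarize_major(gm, gm.sample_ids)
        assert flipped.allele_freq()[0] >= 0.5
        after = cs.weekly_frequencies(flipped, meta, "l0")
        np.testing.assert_allclose(after["frequency"], 1 - before["frequency"], atol=1e-12)


class TestWeeklyFrequencies:
    def test_direct_count_one_week(self):
        gm = cs.GenotypeMatrix(["a", "b", "c", "d"], ["l0"], np.array([[2], [2], [1], [1]], dtype=np.int8), ["A"])
        meta = migrant_meta([240, 241, 243, 246], ids=["a", "b", "c", "d"])
        wf = cs.weekly_frequencies(gm, meta, "l0")
        assert len(wf) == 1
        row = wf.iloc[0]
        assert row["frequency"] == pytest.approx(0.75)
        assert row["n_called_alleles"] == 8
        assert row["midpoint_day"] == 243  # bin start 240 + 3

    def test_fixed_locus_has_zero_se(self):
        gm = cs.GenotypeMatrix(["a", "b"], ["l0"], np.full((2, 1), 2, dtype=np.int8), ["A"])
        meta = migrant_meta([240, 244], ids=["a", "b"])
        wf = cs.weekly_frequencies(gm, meta, "l0")
        assert wf.iloc[0]["frequency"] == 1.0 and wf.iloc[0]["se"] == 0.0

    def test_bins_match_bruteforce_tally(self):
        ds = cs.simulate_scenario("chronotype", seed=7)
        gm, meta = ds.migrant_gm, ds.migrant_meta
        locus = ds.timing_loci[0]
        wf = cs.weekly_frequencies(gm, meta, locus)
        days = meta.set_index("sample_id")["capture_day"]
        j = gm.locus_index([locus])[0]
        origin = int(days.min())
        for _, row in wf.iterrows():
            w = int(row["week_index"])
            lo, hi = origin + 7 * w, origin + 7 * (w + 1)
            total = count = 0
            for i, sid in enumerate(gm.sample_ids):
                d = days.loc[sid]
                if lo <= d < hi and gm.codes[i, j] != cs.MISSING:
                    total += 2
                    count += gm.codes[i, j]
            assert row["n_called_alleles"] == total
            assert row["frequency"] == pytest.approx(count / total)

    def test_no_migrants_is_error(self):
        gm = cs.GenotypeMatrix(["a"], ["l0"], np.array([[1]], dtype=np.int8), ["A"])
        meta = validate_metadata(pd.DataFrame({"sample_id": ["a"]}))
        with pytest.raises(ValueError, match="capture_day"):
            cs.weekly_frequencies(gm, meta, "l0")


def weekly_frame(day, freq, n_alleles=40):
    return pd.DataFrame(
        {
            "week_index": range(len(day)),
            "midpoint_day": day,
            "n_individuals": n_alleles // 2,
            "n_called_alleles": n_alleles,
            "frequency": freq,
            "se": 0.05,
        }
    )


class TestTrendLrt:
    def test_identical_models_give_zero_statistic(self):
        day = 230.0 + 7 * np.arange(8)
        wf = weekly_frame(day, 0.5 + 0.01 * np.arange(8))
        _, _, lrt = cs.fit_trend_lrt(wf, degree_full=1)
        assert lrt.statistic == pytest.approx(0.0, abs=1e-10)
        assert lrt.p_chisq == pytest.approx(1.0)

    def test_quadratic_truth_rejected_linear(self):
        rng = np.random.default_rng(4)
        day = 230.0 + 7 * np.arange(12)
        x = (day - day.mean()) / day.std()
        freq = 0.6 - 0.1 * x - 0.08 * x**2 + rng.normal(0, 1e-3, 12)
        _, _, lrt = cs.fit_trend_lrt(weekly_frame(day, freq), degree_full=2)
        assert lrt.p_value < 0.05 and lrt.p_chisq < 0.05

    def test_full_loglik_at_least_reduced(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            day = 230.0 + 7 * np.arange(10)
            freq = np.clip(rng.normal(0.5, 0.1, 10), 0.05, 0.95)
            _, _, lrt = cs.fit_trend_lrt(weekly_frame(day, freq), degree_full=2)
            assert lrt.ll_full >= lrt.ll_reduced - 1e-9
            assert lrt.statistic >= 0

    def test_insufficient_points_rejected(self):
        day = 230.0 + 7 * np.arange(3)
        with pytest.raises(ValueError, match="weekly points"):
            cs.fit_trend_lrt(weekly_frame(day, [0.5, 0.5, 0.5]), degree_full=2)

    def test_weighted_and_binomial_variants_run(self):
        rng = np.random.default_rng(6)
        day = 230.0 + 7 * np.arange(10)
        freq = np.clip(0.6 - 0.02 * np.arange(10) + rng.normal(0, 0.02, 10), 0.05, 0.95)
        for weighting in ("samplesize", "binomial"):
            _, _, lrt = cs.fit_trend_lrt(weekly_frame(day, freq), degree_full=2, weighting=weighting)
            assert np.isfinite(lrt.statistic) and 0 <= lrt.p_chisq <= 1

    def test_planted_timing_loci_rank_lower_pvalues(self):
        """Planted chronotype loci beat background loci in LRT rank.

        The planted weekly shift is a sigmoid, odd about mid-season, so
        its departure from a straight line loads on the cubic term; the
        nonlinearity test here therefore uses the cubic alternative.
        """
        timing_p, background_p = [], []
        for seed in range(8):
            ds = cs.simulate_scenario("chronotype", seed=seed)
            gm = cs.repolarize_major(ds.migrant_gm, list(ds.migrant_gm.sample_ids))
            background = [l for l in gm.locus_ids if l not in ds.timing_loci][:8]
            for lid in ds.timing_loci + background:
                wf = cs.weekly_frequencies(gm, ds.migrant_meta, lid)
                if len(wf) < 5:
                    continue
                _, _, lrt = cs.fit_trend_lrt(wf, degree_full=3)
                (timing_p if lid in ds.timing_loci else background_p).append(lrt.p_value)
        res = stats.mannwhitneyu(timing_p, background_p, alternative="less")
        assert res.pvalue < 0.01


class TestSexTiming:
    def test_null_slope_near_zero(self):
        days = np.r_[np.full(40, 250), np.full(40, 250)]
        meta = migrant_meta(days, sexes=["F"] * 40 + ["M"] * 40)
        fit = cs.sex_timing_test(meta)
        assert fit.params["sex"] == pytest.approx(0.0, abs=1e-10)

    def test_planted_shift_detected(self):
        """10-day mean sex difference, n = 80/80, sd = 5: always detected."""
        rng = np.random.default_rng(7)
        rejections = 0
        for _ in range(20):
            f_days = np.round(rng.normal(255, 5, 80)).astype(int)
            m_days = np.round(rng.normal(265, 5, 80)).astype(int)
            meta = migrant_meta(np.r_[f_days, m_days], sexes=["F"] * 80 + ["M"] * 80)
            fit = cs.sex_timing_test(meta)
            rejections += fit.pvalues["sex"] < 0.05
        assert rejections == 20

    def test_single_sex_rejected(self):
        meta = migrant_meta([240, 250], sexes=["F", "F"])
        with pytest.raises(ValueError, match="both sexes"):
            cs.sex_timing_test(meta)

    def test_permutation_preserves_null_slope_distribution(self):
        rng = np.random.default_rng(8)
        days = rng.integers(240, 300, 60)
        sexes = ["F"] * 30 + ["M"] * 30
        observed = abs(cs.sex_timing_test(migrant_meta(days, sexes=sexes)).params["sex"])
        perm = []
        for _ in range(200):
            perm_sexes = list(rng.permutation(sexes))
            perm.append(abs(cs.sex_timing_test(migrant_meta(days, sexes=perm_sexes)).params["sex"]))
        # observed slope is a typical draw from the permutation distribution
        rank = np.mean([p >= observed for p in perm])
        assert 0.01 < rank <= 1.0
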