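"""Chronotype vs population-passage disambiguation logic."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import chronoscan as cs
from chronoscan.chronotype import LatitudeTest, MinoritySpread
from chronoscan.datatypes import validate_metadata
from chronoscan.gsi import MixtureResult


def breeding_meta(lats, ids=None):
    n = len(lats)
    return validate_metadata(
        pd.DataFrame(
            {"sample_id": ids or [f"b{i}" for i in range(n)], "site": "w", "latitude": lats}
        )
    )


def make_assignments(labels, probs, days, threshold=0.8):
    n = len(labels)
    pops = sorted(set(labels) | {"west", "east"})
    probs = np.asarray(probs, dtype=float)
    posteriors = np.zeros((n, len(pops)))
    for i, (lab, p) in enumerate(zip(labels, probs)):
        k = pops.index(lab)
        posteriors[i] = (1 - p) / (len(pops) - 1)
        posteriors[i, k] = p
    res = MixtureResult(
        populations=pops,
        sample_ids=[f"m{i}" for i in range(n)],
        pi=np.full(len(pops), 1 / len(pops)),
        posteriors=posteriors,
        map_label=list(labels),
        map_prob=probs,
        certainty_flag=probs >= threshold,
        threshold=threshold,
        n_iter=1,
        loglik_trace=[0.0],
    )
    meta = validate_metadata(
        pd.DataFrame(
            {"sample_id": res.sample_ids, "group": "migratory", "capture_day": days}
        )
    )
    return res, meta


class TestLatitudeAssociation:
    def test_orthogonal_response_zero_slope(self):
        lats = np.tile([40.0, 45.0, 50.0], 10)
        resp = np.tile([1.0, -2.0, 1.0], 10)  # orthogonal to centred latitude
        meta = breeding_meta(lats)
        slope, p, n = cs.latitude_association(pd.Series(resp, index=meta["sample_id"]), meta)
        assert slope == pytest.approx(0.0, abs=1e-10)
        assert n == 30

    def test_identity_response_perfect_fit(self):
        rng = np.random.default_rng(0)
        lats = rng.uniform(35, 55, 40)
        meta = breeding_meta(lats)
        slope, p, _ = cs.latitude_association(pd.Series(lats, index=meta["sample_id"]), meta)
        assert slope == pytest.approx(1.0, abs=1e-10)
        assert p < 1e-12

    def test_constant_latitude_rejected(self):
        meta = breeding_meta([45.0] * 12)
        with pytest.raises(ValueError, match="constant"):
            cs.latitude_association(pd.Series(np.arange(12.0), index=meta["sample_id"]), meta)

    def test_confound_breeding_data_shows_cline(self):
        """Planted frequency differential across latitude bands is detected."""
        hits = 0
        for seed in range(10):
            spec = cs.simulate.confound_baseline_spec(seed=seed)
            gm, meta, truth = cs.gen_baseline(spec)
            lid = truth["outlier_loci"][0]
            j = gm.locus_index([lid])[0]
            codes = gm.codes[:, j].astype(float)
            codes[codes < 0] = np.nan
            _, p, _ = cs.latitude_association(pd.Series(codes, index=gm.sample_ids), meta)
            hits += p < 0.05
        assert hits >= 9


class TestMinoritySpread:
    def test_clustered_minority_detected(self):
        labels = ["west"] * 40 + ["east"] * 6
        days = list(range(240, 280)) + [240, 241, 241, 242, 243, 243]
        res, meta = make_assignments(labels, np.full(46, 0.95), days)
        ms = cs.minority_spread_test(res, meta)
        assert ms.status == "tested" and ms.p_value < 0.05

    def test_spread_minority_not_flagged(self):
        labels = ["west"] * 40 + ["east"] * 6
        days = list(range(240, 280)) + [242, 250, 258, 266, 270, 278]
        res, meta = make_assignments(labels, np.full(46, 0.95), days)
        ms = cs.minority_spread_test(res, meta)
        assert ms.status == "tested" and ms.p_value > 0.05

    def test_no_minority_not_applicable(self):
        res, meta = make_assignments(["west"] * 20, np.full(20, 0.95), list(range(240, 260)))
        assert cs.minority_spread_test(res, meta).status == "not_applicable"

    def test_tiny_minority_low_power_coverage(self):
        labels = ["west"] * 20 + ["east"] * 2
        days = list(range(240, 260)) + [240, 259]
        res, meta = make_assignments(labels, np.full(22, 0.95), days)
        ms = cs.minority_spread_test(res, meta)
        assert ms.status == "low_power"
        assert ms.day_range_coverage == pytest.approx(1.0)

    def test_null_pvalues_calibrated(self):
        """Same-distribution minority days: rejection near nominal, p near uniform."""
        rng = np.random.default_rng(1)
        pvals = []
        for _ in range(1000):
            days = rng.integers(240, 320, 60)
            labels = ["west"] * 50 + ["east"] * 10
            res, meta = make_assignments(labels, np.full(60, 0.95), days)
            ms = cs.minority_spread_test(res, meta)
            pvals.append(ms.p_value)
        rate = np.mean(np.array(pvals) < 0.05)
        assert 0.02 <= rate <= 0.08
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestClassifyScenario:
    def lat_tests(self, ps):
        return [LatitudeTest(f"t{i}", 0.1, p, n=50) for i, p in enumerate(ps)]

    def test_rule_application_chronotype(self):
        res, _ = make_assignments(
            ["west"] * 19 + ["east"], np.full(20, 0.95), list(range(240, 260))
        )
        report = cs.classify_scenario(
            res, self.lat_tests([0.5, 0.8, 0.41]), MinoritySpread("not_applicable")
        )
        assert report.fraction_confident_modal == pytest.approx(0.95)
        assert report.verdict == "chronotype_consistent"

    def test_rule_application_population_passage(self):
        res, _ = make_assignments(
            ["west"] * 12 + ["east"] * 8, np.full(20, 0.95), list(range(240, 260))
        )
        minority = MinoritySpread("tested", 10.0, 0.001, 8, 12)
        report = cs.classify_scenario(res, self.lat_tests([1e-6, 0.5, 0.7]), minority)
        assert report.verdict == "population_passage_consistent"

    def test_mixed_evidence_indeterminate(self):
        res, _ = make_assignments(
            ["west"] * 12 + ["east"] * 8, np.full(20, 0.95), list(range(240, 260))
        )
        report = cs.classify_scenario(
            res, self.lat_tests([0.5, 0.6, 0.7]), MinoritySpread("tested", 10.0, 0.001, 8, 12)
        )
        assert report.verdict == "indeterminate"

    def test_verdict_recomputable_from_report(self):
        """The verdict is a pure function of the recorded statistics."""
        res, _ = make_assignments(
            ["west"] * 18 + ["east"] * 2, np.full(20, 0.95), list(range(240, 260))
        )
        minority = MinoritySpread("tested", 5.0, 0.3, 3, 17)
        report = cs.classify_scenario(res, self.lat_tests([0.2, 0.9]), minority)
        again = cs.classify_scenario(
            res,
            [LatitudeTest(t.name, t.slope, t.p_value, n=t.n) for t in report.latitude_tests],
            report.minority_spread,
            modal_min=report.modal_min,
            alpha=report.alpha,
        )
        assert again.verdict == report.verdict

    def test_holm_adjustment_applied(self):
        res, _ = make_assignments(["west"] * 20, np.full(20, 0.95), list(range(240, 260)))
        report = cs.classify_scenario(
            res, self.lat_tests([0.02, 0.03, 0.04, 0.05, 0.011]), MinoritySpread("not_applicable")
        )
        # all raw p < 0.05 but none survives Holm over five tests
        assert all(t.p_holm >= 0.05 for t in report.latitude_tests)
        assert report.verdict == "chronotype_consistent"

    def test_modal_min_monotonicity(self):
        """Raising modal_min can only move verdicts away from chronotype."""
        res, _ = make_assignments(
            ["west"] * 18 + ["east"] * 2, np.full(20, 0.95), list(range(240, 260))
        )
        args = (self.lat_tests([0.5, 0.6]), MinoritySpread("not_applicable"))
        verdicts = [
            cs.classify_scenario(res, *args, modal_min=mm).verdict
            for mm in (0.5, 0.85, 0.95, 0.99)
        ]
        seen_non_chrono = False
        for v in verdicts:
            if v != "chronotype_consistent":
                seen_non_chrono = True
            else:
                assert not seen_non_chrono  # once lost, never regained
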