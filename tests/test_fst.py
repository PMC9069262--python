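"""Weir-Cockerham components, outlier percentile rule, gene annotation."""

import numpy as np
import pandas as pd
import pytest

import chronoscan as cs
from oracles import wc_brute


class TestWcFstLocus:
    def test_complete_fixation_gives_theta_one(self):
        a, b, c, theta = cs.wc_fst_locus([np.full(10, 2), np.zeros(10, dtype=int)])
        assert theta == pytest.approx(1.0)
        assert b == pytest.approx(0.0) and c == pytest.approx(0.0)

    def test_monomorphic_locus_is_nan(self):
        _, _, _, theta = cs.wc_fst_locus([np.full(8, 2), np.full(8, 2)])
        assert np.isnan(theta)

    def test_hand_worksheet_value(self):
        """Frozen from a scalar variance-components worksheet (nbar, n_c, pbar, s2, hbar)."""
        a, b, c, theta = cs.wc_fst_locus([np.array([2, 2, 1, 0, 1]), np.array([0, 0, 1, 0, 1])])
        assert a == pytest.approx(0.055, abs=1e-12)
        assert b == pytest.approx(0.025, abs=1e-12)
        assert c == pytest.approx(0.2, abs=1e-12)
        assert theta == pytest.approx(0.1964285714285714, abs=1e-12)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            cs.wc_fst_locus([np.array([0, 1, 2])])

    def test_missing_codes_excluded_within_groups(self):
        with_missing = cs.wc_fst_locus(
            [np.array([2, 2, 1, 0, 1, cs.MISSING]), np.array([cs.MISSING, 0, 0, 1, 0, 1])]
        )
        clean = cs.wc_fst_locus([np.array([2, 2, 1, 0, 1]), np.array([0, 0, 1, 0, 1])])
        assert with_missing == pytest.approx(clean)

    def test_matches_bruteforce_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            g1 = rng.integers(0, 3, rng.integers(3, 15)).tolist()
            g2 = rng.integers(0, 3, rng.integers(3, 15)).tolist()
            got = cs.wc_fst_locus([np.array(g1), np.array(g2)])
            want = wc_brute([g1, g2])
            for x, y in zip(got, want):
                if np.isnan(y):
                    assert np.isnan(x)
                else:
                    assert x == pytest.approx(y, abs=1e-12)


class TestFstScan:
    def test_excluding_site_removes_exactly_its_samples(self):
        spec = cs.BaselineSpec(
            n_pops=3,
            n_per_pop=20,
            n_loci=50,
            target_fst=0.02,
            pop_names=["FL", "CA1", "ID"],
            pop_groups=["resident", "migratory", "migratory"],
            seed=1,
        )
        gm, meta, _ = cs.gen_baseline(spec)
        full = cs.fst_scan(gm, meta, min_calls=1)
        excl = cs.fst_scan(gm, meta, exclude_sites=["CA1"], min_calls=1)
        assert (full["n_migratory"] == 40).all()
        assert (excl["n_migratory"] == 20).all()
        assert (excl["n_resident"] == full["n_resident"]).all()

    def test_group_vanishing_after_exclusion_is_fatal(self):
        spec = cs.BaselineSpec(
            n_pops=2, n_per_pop=10, n_loci=20,
            pop_names=["FL", "ID"], pop_groups=["resident", "migratory"], seed=2,
        )
        gm, meta, _ = cs.gen_baseline(spec)
        with pytest.raises(ValueError, match="group"):
            cs.fst_scan(gm, meta, exclude_sites=["FL"])

    def test_label_permutation_destroys_enrichment(self):
        """Permuted group labels select planted loci at the background rate."""
        spec = cs.BaselineSpec(
            n_pops=2, n_per_pop=50, n_loci=1000, target_fst=0.05,
            n_outliers=50, outlier_delta=0.4,
            pop_groups=["resident", "migratory"], seed=3,
        )
        gm, meta, truth = cs.gen_baseline(spec)
        real = cs.select_outliers(cs.fst_scan(gm, meta), 0.9)
        real_hit = len(set(real.locus_ids) & set(truth["outlier_loci"])) / 50
        assert real_hit > 0.8

        rng = np.random.default_rng(4)
        perm_hits = []
        for _ in range(5):
            shuffled = meta.copy()
            shuffled["group"] = rng.permutation(shuffled["group"].to_numpy())
            cand = cs.select_outliers(cs.fst_scan(gm, shuffled), 0.9)
            perm_hits.append(len(set(cand.locus_ids) & set(truth["outlier_loci"])) / 50)
        assert np.mean(perm_hits) < 0.3  # ~10% expected under no association


class TestSelectOutliers:
    def test_exactly_ten_of_hundred_distinct(self):
        theta = np.linspace(0.01, 0.99, 100)
        fst = pd.DataFrame({"locus_id": [f"l{i}" for i in range(100)], "a": theta,
                            "b": 0.0, "c": 1.0, "theta": theta, "status": "ok"})
        cand = cs.select_outliers(fst, 0.90)
        assert len(cand.locus_ids) == 10
        assert set(cand.locus_ids) == {f"l{i}" for i in range(90, 100)}

    def test_all_tied_selects_all(self):
        fst = pd.DataFrame({"locus_id": [f"l{i}" for i in range(20)], "a": 1.0,
                            "b": 0.0, "c": 1.0, "theta": 0.5, "status": "ok"})
        cand = cs.select_outliers(fst, 0.90)
        assert len(cand.locus_ids) == 20

    def test_matches_sort_based_oracle_on_scan(self):
        spec = cs.BaselineSpec(n_pops=2, n_per_pop=40, n_loci=2000, target_fst=0.05,
                               pop_groups=["resident", "migratory"], seed=5)
        gm, meta, _ = cs.gen_baseline(spec)
        fst = cs.fst_scan(gm, meta)
        cand = cs.select_outliers(fst, 0.90)
        ok = fst[fst["status"] == "ok"]["theta"].to_numpy()
        q = np.quantile(ok, 0.9)
        assert len(cand.locus_ids) == int((ok >= q).sum())
        assert all(
            fst.set_index("locus_id").loc[l, "theta"] >= cand.threshold_value
            for l in cand.locus_ids
        )

    def test_too_few_ok_loci_rejected(self):
        fst = pd.DataFrame({"locus_id": ["a", "b"], "a": 1.0, "b": 0.0, "c": 1.0,
                            "theta": [0.1, 0.2], "status": "ok"})
        with pytest.raises(ValueError):
            cs.select_outliers(fst, 0.9)


class TestAnnotateGenes:
    def test_counts_match_hand_overlap_table(self, tmp_path):
        """20 loci vs 5 intervals, overlaps enumerated by hand."""
        bed = tmp_path / "g.bed"
        bed.write_text(
            "chr1\t0\t100\tgA\n"      # 1-based 1..100
            "chr1\t50\t150\tgB\n"     # 1-based 51..150 (overlaps gA on 51..100)
            "chr1\t300\t400\tgC\n"
            "chr2\t0\t1000\tgD\n"
            "chr3\t10\t20\tgE\n"
        )
        idx = cs.read_gene_intervals(bed)
        positions = [
            ("chr1", 10, ["gA"]), ("chr1", 60, ["gA", "gB"]), ("chr1", 100, ["gA", "gB"]),
            ("chr1", 101, ["gB"]), ("chr1", 150, ["gB"]), ("chr1", 151, []),
            ("chr1", 350, ["gC"]), ("chr1", 400, ["gC"]), ("chr1", 401, []),
            ("chr2", 1, ["gD"]), ("chr2", 2, ["gD"]), ("chr2", 500, ["gD"]),
            ("chr2", 1000, ["gD"]), ("chr3", 11, ["gE"]), ("chr3", 20, ["gE"]),
            ("chr3", 21, []), ("chr1", 250, []), ("chr2", 1500, []),
            ("chr4", 10, []), ("chr1", 75, ["gA", "gB"]),
        ]
        ann = cs.annotation_frame(
            [cs.LocusAnnotation(f"l{i}", chrom, pos, "A", "C") for i, (chrom, pos, _) in enumerate(positions)]
        )
        cand = cs.CandidateSet(0.0, 0.9, [f"l{i}" for i in range(len(positions))])
        cand = cs.annotate_genes(cand, idx, ann)
        for i, (_, _, want) in enumerate(positions):
            assert cand.gene_map[f"l{i}"] == want, f"locus l{i}"
        assert cand.genes == ["gA", "gB", "gC", "gD", "gE"]

    def test_missing_annotation_maps_to_empty(self, tmp_path):
        bed = tmp_path / "g.bed"
        bed.write_text("chr1\t0\t100\tgA\n")
        idx = cs.read_gene_intervals(bed)
        ann = cs.annotation_frame([cs.LocusAnnotation("known", "chr1", 50, "A", "C")])
        cand = cs.annotate_genes(cs.CandidateSet(0.0, 0.9, ["known", "mystery"]), idx, ann)
        assert cand.gene_map == {"known": ["gA"], "mystery": []}
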