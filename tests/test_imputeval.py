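"""Masking-CV imputation harness: folds, the flanking-SNP imputer,
accuracy pooling, summaries and SV selection."""

import numpy as np
import pandas as pd
import pytest

import svgblup as sg
from svgblup.imputeval import merge_selected_sets, snps_in_interval
from svgblup.sv_catalog import SVRecord


def simple_maps(n_snp, spacing=1000):
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.arange(n_snp) * spacing,
            "end": np.arange(n_snp) * spacing + 1,
            "id": [f"snp{i}" for i in range(n_snp)],
            "type": "SNP",
        }
    )


def sv_map_at(pos, end=None, n=1):
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "start": [pos] * n,
            "end": [end or pos + 100] * n,
            "id": [f"sv{i}" for i in range(n)],
            "type": "DEL",
        }
    )


class TestFolds:
    def test_sizes_differ_by_at_most_one(self):
        plan = sg.make_folds(478, k=5, seed=0)
        sizes = np.bincount(plan.assignment)
        assert sizes.max() - sizes.min() <= 1
        assert sizes.sum() == 478

    def test_partition_properties(self):
        plan = sg.make_folds(10, k=5, seed=1)
        all_test = np.concatenate([plan.test_indices(f) for f in range(5)])
        assert sorted(all_test) == list(range(10))
        for f in range(5):
            assert plan.test_indices(f).size == 2
            assert np.intersect1d(plan.test_indices(f), plan.reference_indices(f)).size == 0

    def test_deterministic_under_seed(self):
        a = sg.make_folds(100, k=5, seed=7)
        b = sg.make_folds(100, k=5, seed=7)
        assert np.array_equal(a.assignment, b.assignment)

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError):
            sg.make_folds(3, k=5, seed=0)


class TestMaskAndImpute:
    def test_perfect_ld_sv_recovered_exactly(self, rng):
        n = 200
        snps = rng.binomial(2, 0.4, (n, 10)).astype(np.int8)
        sv = snps[:, [4]].copy()  # SV identical to a flanking SNP
        plan = sg.make_folds(n, k=5, seed=0)
        _, acc = sg.run_masking_cv(snps, sv, simple_maps(10), sv_map_at(4500), plan)
        assert acc.r2[0] == pytest.approx(1.0)

    def test_independent_sv_low_accuracy(self, rng):
        n = 500
        snps = rng.binomial(2, 0.4, (n, 20)).astype(np.int8)
        sv = rng.binomial(2, 0.3, (n, 30)).astype(np.int8)  # unrelated to SNPs
        plan = sg.make_folds(n, k=5, seed=0)
        sv_map = sv_map_at(9500, n=30)
        _, acc = sg.run_masking_cv(snps, sv, simple_maps(20), sv_map, plan)
        assert (acc.r2 < 0.1).mean() >= 0.95

    def test_exclusion_removes_exactly_snps_in_interval(self, rng):
        n_snp = 50
        snp_map = simple_maps(n_snp)
        start, end = 12_000, 18_500
        idx = snps_in_interval(snp_map, "chr1", start, end)
        # brute-force position scan oracle
        expected = [j for j in range(n_snp) if start <= j * 1000 < end]
        assert list(idx) == expected
        # and the imputer's scaffold drops exactly those columns
        imp = sg.FlankingSNPImputer(w=100)
        cols = imp.select_snps(snp_map, "chr1", (start + end) // 2, exclude=idx)
        assert set(cols).isdisjoint(expected)
        assert set(cols) | set(expected) == set(range(n_snp))

    def test_nearest_snp_ties_break_to_lower_position(self):
        snp_map = simple_maps(5)
        imp = sg.FlankingSNPImputer(w=3)
        cols = imp.select_snps(snp_map, "chr1", 2000)  # snp2 at 0bp; snp1/snp3 tie
        assert list(cols[:2]) == [2, 1]

    def test_too_few_flanking_snps_gives_na(self, rng):
        n = 100
        snps = rng.binomial(2, 0.4, (n, 1)).astype(np.int8)
        sv = rng.binomial(2, 0.4, (n, 1)).astype(np.int8)
        out = sg.mask_and_impute(snps, sv, simple_maps(1), sv_map_at(100), np.arange(10))
        assert np.isnan(out).all()

    def test_no_reference_leakage(self, rng):
        """The imputer must never be fit on a test individual's SV genotypes."""
        n = 60
        snps = rng.binomial(2, 0.4, (n, 10)).astype(np.int8)
        sv = rng.binomial(2, 0.4, (n, 2)).astype(np.int8)
        plan = sg.make_folds(n, k=5, seed=0)
        seen: list[np.ndarray] = []

        class RecordingImputer(sg.FlankingSNPImputer):
            def impute_one(self, x_ref, y_ref, x_test):
                seen.append(y_ref.copy())
                return super().impute_one(x_ref, y_ref, x_test)

        for fold in range(plan.k):
            test = plan.test_indices(fold)
            seen.clear()
            sg.mask_and_impute(snps, sv, simple_maps(10), sv_map_at(4500, n=2), test,
                               imputer=RecordingImputer(w=5))
            ref = plan.reference_indices(fold)
            for y_ref in seen:
                assert y_ref.size == ref.size  # only reference rows were seen

    def test_anchor_modes(self, rng):
        n = 50
        snps = rng.binomial(2, 0.4, (n, 10)).astype(np.int8)
        sv = rng.binomial(2, 0.4, (n, 1)).astype(np.int8)
        for anchor in ("start", "middle", "end"):
            out = sg.mask_and_impute(snps, sv, simple_maps(10), sv_map_at(4500), np.arange(5),
                                     anchor=anchor)
            assert out.shape == (5, 1)
        with pytest.raises(ValueError):
            sg.mask_and_impute(snps, sv, simple_maps(10), sv_map_at(4500), np.arange(5),
                               anchor="centre")


class TestAccuracy:
    def test_perfect_and_mirrored_predictions(self, rng):
        true = rng.integers(0, 3, (100, 2)).astype(np.int8)
        acc = sg.accuracy_table(true, true.astype(float))
        assert np.allclose(acc.r2, 1.0)
        acc2 = sg.accuracy_table(true, 2.0 - true)  # r^2 is sign-blind
        assert np.allclose(acc2.r2, 1.0)

    def test_matches_correlation_oracle(self, rng):
        true = rng.integers(0, 3, (200, 5)).astype(np.int8)
        pred = true + rng.normal(0, 0.7, true.shape)
        acc = sg.accuracy_table(true, pred)
        for j in range(5):
            expected = np.corrcoef(true[:, j], pred[:, j])[0, 1] ** 2
            assert acc.r2[j] == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_gives_na(self):
        true = np.zeros((50, 1), dtype=np.int8)
        acc = sg.accuracy_table(true, np.random.default_rng(0).normal(size=(50, 1)))
        assert np.isnan(acc.r2[0])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sg.accuracy_table(np.zeros((5, 2), dtype=np.int8), np.zeros((5, 3)))


class TestSummaries:
    def test_threshold_summary_values(self):
        acc = pd.DataFrame({"sv_id": list("abc"), "r2": [0.4, 0.6, 0.9], "maf": 0.2, "n_used": 10})
        summary = sg.threshold_summary(acc)
        assert summary.percent_above.tolist() == pytest.approx([66.7, 33.3], abs=0.05)

    def test_all_perfect(self):
        acc = pd.DataFrame({"sv_id": ["a"], "r2": [1.0], "maf": [0.3], "n_used": [10]})
        assert (sg.threshold_summary(acc).percent_above == 100.0).all()

    def test_na_excluded_from_denominator(self):
        acc = pd.DataFrame({"sv_id": list("ab"), "r2": [0.9, np.nan], "maf": 0.2, "n_used": 10})
        summary = sg.threshold_summary(acc)
        assert summary.n_eval.iloc[0] == 1 and summary.n_na.iloc[0] == 1
        assert summary.percent_above.iloc[0] == 100.0

    def test_accuracy_by_maf_groupby_oracle(self, rng):
        acc = pd.DataFrame(
            {"sv_id": [f"s{i}" for i in range(200)],
             "r2": rng.random(200),
             "maf": rng.uniform(0, 0.5, 200),
             "n_used": 10}
        )
        binned = sg.accuracy_by_maf(acc)
        cut = pd.cut(acc.maf, np.round(np.arange(0, 0.55, 0.05), 10), right=False)
        oracle = acc.groupby(cut, observed=False)["r2"].mean()
        got = binned.mean_r2.to_numpy()
        assert np.allclose(got, oracle.to_numpy(), equal_nan=True)

    def test_single_bin_is_overall_mean(self, rng):
        acc = pd.DataFrame(
            {"sv_id": list("abcd"), "r2": [0.1, 0.4, 0.7, 0.9], "maf": [0.1, 0.2, 0.3, 0.4],
             "n_used": 10}
        )
        binned = sg.accuracy_by_maf(acc, bins=np.array([0.0, 0.5]))
        assert binned.mean_r2.iloc[0] == pytest.approx(acc.r2.mean())

    def test_high_ld_beats_low_ld_under_same_seed(self):
        # the same SV set imputes better when LD is strong than when absent
        pct = {}
        for label, rho in (("high", 0.0), ("low", 1.0)):
            cfg = sg.SimConfig(n_individuals=200, n_snp=600, n_sv=40, n_chrom=2,
                               ld_rho=rho, seed=21, n_duplicates=0)
            ds = sg.simulate_dataset(cfg)
            plan = sg.make_folds(len(ds.samples), k=5, seed=2)
            _, acc = sg.run_masking_cv(ds.snp_genotypes, ds.sv_truth, ds.snp_map, ds.sv_map, plan)
            pct[label] = sg.threshold_summary(acc).percent_above.iloc[0]
        assert pct["high"] > pct["low"]

    def test_common_svs_at_least_as_accurate_as_rare(self):
        cfg = sg.SimConfig(n_individuals=300, n_snp=900, n_sv=60, n_chrom=2,
                           ld_rho=1e-6, seed=22, n_duplicates=0, maf_shape=0.4)
        ds = sg.simulate_dataset(cfg)
        plan = sg.make_folds(len(ds.samples), k=5, seed=3)
        _, acc = sg.run_masking_cv(ds.snp_genotypes, ds.sv_truth, ds.snp_map, ds.sv_map, plan)
        common = acc[(acc.maf > 0.2) & np.isfinite(acc.r2)].r2.mean()
        rare = acc[(acc.maf < 0.05) & np.isfinite(acc.r2)].r2.mean()
        assert common >= rare


class TestSelection:
    def test_strictly_above_threshold(self):
        acc = pd.DataFrame({"sv_id": list("abc"), "r2": [0.5, 0.51, np.nan], "maf": 0.2, "n_used": 10})
        assert sg.select_svs(acc) == ["b"]  # exactly 0.5 is excluded

    def test_all_below_gives_empty(self):
        acc = pd.DataFrame({"sv_id": list("ab"), "r2": [0.1, 0.2], "maf": 0.2, "n_used": 10})
        assert sg.select_svs(acc) == []

    def test_cross_set_union_matches_overlap_oracle(self, rng):
        def rand_set(seed, n):
            r = np.random.default_rng(seed)
            out = []
            for _ in range(n):
                s = int(r.integers(0, 3000))
                out.append(SVRecord("chr1", s, s + int(r.integers(20, 300)), "DEL", ("s",)))
            return out

        sets = [rand_set(1, 30), rand_set(2, 30), rand_set(3, 30)]
        merged = merge_selected_sets(sets)
        pool = [r for s in sets for r in s]
        # oracle: connected components of the pairwise overlap graph
        from tests.test_sv_catalog import brute_force_components

        assert len(merged) == len(brute_force_components(pool))


def test_near_perfect_ld_gives_high_accuracy_for_common_svs():
    cfg = sg.SimConfig(n_individuals=300, n_snp=900, n_sv=60, n_chrom=2,
                       ld_rho=0.0, seed=31, n_duplicates=0)
    ds = sg.simulate_dataset(cfg)
    plan = sg.make_folds(len(ds.samples), k=5, seed=4)
    _, acc = sg.run_masking_cv(ds.snp_genotypes, ds.sv_truth, ds.snp_map, ds.sv_map, plan)
    common = acc[(acc.maf >= 0.1) & np.isfinite(acc.r2)]
    assert (common.r2 > 0.8).mean() >= 0.9
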