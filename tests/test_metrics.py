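"""clr-MAE, RA post-processing, diversity metrics, zero metrics, benchmark."""

import numpy as np
import pytest

import microgen as mg
from microgen.datasets import MicrogenError
from microgen.metrics import (benchmark, bray_curtis, diversity_comparison,
                              mae_clr, postprocess_to_ra, shannon_index,
                              zero_metrics)
from tests.conftest import make_cohort


class TestMaeClr:
    def test_perfect_imputation_zero(self, rng):
        x = rng.normal(size=(3, 4, 5))
        mask = np.ones((3, 4), dtype=int)
        mask[0, 1] = 0
        assert mae_clr(x, x, mask) == 0.0

    def test_arithmetic_mean_of_errors(self):
        true = np.zeros((1, 2, 2))
        imp = np.array([[[0.0, 0.0], [0.5, 1.5]]])
        mask = np.array([[1, 0]])
        assert mae_clr(true, imp, mask) == pytest.approx(1.0)

    def test_invariant_to_joint_taxon_permutation(self, rng):
        true = rng.normal(size=(2, 3, 6))
        imp = rng.normal(size=(2, 3, 6))
        mask = rng.integers(0, 2, size=(2, 3))
        mask[0, 0] = 0
        perm = rng.permutation(6)
        assert mae_clr(true, imp, mask) == pytest.approx(
            mae_clr(true[:, :, perm], imp[:, :, perm], mask), rel=1e-12)

    def test_translation_invariance(self, rng):
        true = rng.normal(size=(2, 2, 4))
        imp = rng.normal(size=(2, 2, 4))
        mask = np.array([[1, 0], [0, 1]])
        assert mae_clr(true + 3.5, imp + 3.5, mask) == pytest.approx(
            mae_clr(true, imp, mask), rel=1e-9)

    def test_no_missing_samples_rejected(self, rng):
        x = rng.normal(size=(1, 2, 2))
        with pytest.raises(MicrogenError):
            mae_clr(x, x, np.ones((1, 2)))


class TestPostprocessToRa:
    def test_uniform_clr_gives_uniform_composition(self):
        out = postprocess_to_ra(np.zeros((1, 1, 4)), pseudo_count=0.01)
        np.testing.assert_allclose(out[0, 0], 0.25, atol=1e-12)

    def test_round_trip_of_positive_sample(self, rng):
        ra = rng.dirichlet(np.ones(6) * 2, size=(2, 3))
        clr = np.log(ra) - np.log(ra).mean(axis=-1, keepdims=True)
        out = postprocess_to_ra(clr, pseudo_count=1e-6)
        np.testing.assert_allclose(out, ra, atol=1e-9)

    def test_hand_redistribution(self):
        target = np.array([0.6, 0.399, 0.001])
        clr = np.log(target) - np.log(target).mean()
        out = postprocess_to_ra(clr[None, None, :], pseudo_count=0.01)
        np.testing.assert_allclose(out[0, 0], [0.6005, 0.3995, 0.0], atol=1e-9)

    def test_output_is_valid_composition(self, rng):
        clr = rng.normal(scale=3, size=(4, 5, 8))
        out = postprocess_to_ra(clr, pseudo_count=1e-3)
        assert np.all(out >= 0)
        np.testing.assert_allclose(out.sum(axis=-1), 1.0, atol=1e-9)

    def test_all_below_threshold_rejected(self):
        with pytest.raises(MicrogenError):
            postprocess_to_ra(np.zeros((1, 1, 3)), pseudo_count=0.9)


def _shannon_oracle(p):
    p = np.asarray(p, dtype=float)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def _bray_curtis_oracle(a, b):
    return float(np.abs(a - b).sum() / (a + b).sum())


class TestDiversity:
    def test_shannon_uniform(self):
        assert shannon_index(np.full(4, 0.25)) == pytest.approx(np.log(4), abs=1e-10)

    def test_shannon_single_taxon(self):
        assert shannon_index(np.array([1.0, 0.0, 0.0])) == pytest.approx(0.0, abs=1e-12)

    def test_shannon_bounded_by_log_n(self, rng):
        for _ in range(20):
            p = rng.dirichlet(np.ones(7))
            assert shannon_index(p) <= np.log(7) + 1e-9

    def test_bray_curtis_identical_and_disjoint(self):
        a = np.array([0.5, 0.5, 0.0])
        assert bray_curtis(a, a) == pytest.approx(0.0, abs=1e-12)
        assert bray_curtis(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == pytest.approx(1.0)

    def test_bray_curtis_direct_evaluation(self):
        assert bray_curtis(np.array([1.0, 0.0]), np.array([0.5, 0.5])) == pytest.approx(0.5)

    def test_both_match_textbook_oracles_on_random_compositions(self, rng):
        for _ in range(100):
            a = rng.dirichlet(np.ones(9) * 0.8)
            b = rng.dirichlet(np.ones(9) * 0.8)
            assert shannon_index(a) == pytest.approx(_shannon_oracle(a), abs=1e-12)
            assert bray_curtis(a, b) == pytest.approx(_bray_curtis_oracle(a, b),
                                                      abs=1e-12)


class TestZeroMetrics:
    def test_perfect_prediction(self):
        ra = np.array([[[0.0, 0.5, 0.5, 0.0]]])
        mask = np.array([[0]])
        symdiff, recall = zero_metrics(ra, ra, mask)
        assert symdiff == 0 and recall == 1.0

    def test_no_predicted_zeros(self):
        true = np.array([[[0.0, 0.0, 0.6, 0.4]]])
        imp = np.array([[[0.1, 0.2, 0.3, 0.4]]])
        symdiff, recall = zero_metrics(true, imp, np.array([[0]]))
        assert symdiff == 2 and recall == 0.0

    def test_toy_set_arithmetic(self):
        true = np.array([[[0.0, 0.0, 0.5, 0.5]]])
        imp = np.array([[[0.4, 0.0, 0.0, 0.6]]])
        symdiff, recall = zero_metrics(true, imp, np.array([[0]]))
        assert symdiff == 2 and recall == pytest.approx(0.5)

    def test_no_true_zeros_reports_absent_recall(self):
        true = np.array([[[0.5, 0.5]]])
        symdiff, recall = zero_metrics(true, true, np.array([[0]]))
        assert recall is None


def _paired_t_oracle(a, b):
    d = np.asarray(a) - np.asarray(b)
    n = len(d)
    return d.mean() / (d.std(ddof=1) / np.sqrt(n))


class TestDiversityComparison:
    def _random_pair(self, seed, m=8, n=10):
        rng = np.random.default_rng(seed)
        true = rng.dirichlet(np.ones(n), size=(m, 1)).transpose(1, 0, 2)
        imp = rng.dirichlet(np.ones(n), size=(m, 1)).transpose(1, 0, 2)
        mask = np.zeros((1, m), dtype=int)
        return true, imp, mask

    def test_identical_inputs_flagged_degenerate(self):
        true, _, mask = self._random_pair(0)
        out = diversity_comparison(true, true, mask, seed=0)
        assert out["alpha_pearson_r"] == 1.0
        assert out["alpha_t_stat"] == 0.0
        assert out["bray_curtis_corr"] == 1.0

    def test_correlations_in_unit_interval(self):
        true, imp, mask = self._random_pair(3)
        out = diversity_comparison(true, imp, mask, seed=0)
        assert -1.0 <= out["alpha_pearson_r"] <= 1.0
        assert -1.0 <= out["bray_curtis_corr"] <= 1.0
        assert out["nmds_coords"].shape[1] == 2

    def test_paired_t_matches_textbook_oracle(self):
        from scipy import stats as sps
        rng = np.random.default_rng(6)
        for _ in range(20):
            a = rng.normal(size=12)
            b = a + rng.normal(scale=0.3, size=12)
            t_impl = sps.ttest_rel(a, b).statistic
            assert t_impl == pytest.approx(_paired_t_oracle(a, b), abs=1e-10)

    def test_too_few_missing_samples_rejected(self):
        true, imp, _ = self._random_pair(1, m=2)
        with pytest.raises(MicrogenError):
            diversity_comparison(true, imp, np.zeros((1, 2), dtype=int))


class TestEvaluate:
    def test_full_report_on_baseline_imputation(self):
        truth = make_cohort(seed=61, n_subjects=8, n_taxa=15, n_phyla=3,
                            n_timepoints=6)
        observed = mg.ampute(truth, mg.MissingnessSpec(mechanism="MCAR",
                                                       rate=0.25, seed=62))
        clr = mg.clr_transform(mg.add_pseudocount(observed))
        res = mg.impute_baseline(clr, spec=mg.BaselineSpec(method="locf"))
        report = mg.evaluate(truth, res, clr.pseudo_count, seed=0)
        assert report.mae_clr >= 0 and np.isfinite(report.mae_clr)
        assert report.mae_ra is not None and report.mae_ra >= 0
        assert report.zero_recall is None or 0 <= report.zero_recall <= 1
        assert report.shannon_true is not None


@pytest.fixture(scope="module")
def small_truth():
    return make_cohort(seed=71, n_subjects=8, n_taxa=12, n_phyla=2,
                       n_timepoints=5)


class TestBenchmark:
    def test_oracle_method_scores_zero_in_every_fold(self, small_truth):
        truth = small_truth
        c_holder = {}

        def oracle(clr, mask):
            c = clr.pseudo_count
            true_clr = mg.clr_with_pseudocount(truth, c).clr_values
            return mg.ImputationResult(clr_values=true_clr, mask=mask,
                                       method="oracle")

        result = benchmark(truth, [("oracle", oracle), "locf"], folds=4, seed=0)
        oracle_rows = result.per_fold[result.per_fold.method == "oracle"]
        assert len(oracle_rows) == 4
        np.testing.assert_allclose(oracle_rows.mae_clr, 0.0, atol=1e-12)

    def test_one_row_per_method_per_fold(self, small_truth):
        result = benchmark(small_truth, ["locf", "mean"], folds=4, seed=1)
        counts = result.per_fold.groupby("method").size()
        assert (counts == 4).all()

    def test_fold_assignments_partition_subjects(self, small_truth):
        rng = np.random.default_rng(5)
        assignment = rng.permutation(8) % 4
        assert sorted(np.unique(assignment)) == [0, 1, 2, 3]

    def test_more_folds_than_subjects_rejected(self, small_truth):
        with pytest.raises(MicrogenError):
            benchmark(small_truth, ["locf"], folds=20, seed=0)

    def test_summary_lists_methods(self, small_truth):
        result = benchmark(small_truth, ["locf", "mean"], folds=2, seed=2)
        text = result.summary()
        assert "locf" in text and "mean" in text
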