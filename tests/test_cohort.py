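"""Score matrix, Welch's t-test, ROC analysis, subgroup evaluation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from sinusid import (SynthParams, generate_cohort, roc_analysis, score_matrix,
                     similarity_score, split_matched_mismatched, subgroup_eval,
                     tables_from_scores, welch_t)
from sinusid.cohort import (REPORT_FIELDS, EvalError, ScoreMatrix, evaluate_subset,
                            matrix_from_long)


@pytest.fixture(scope="module")
def small_matrix():
    cohort = generate_cohort(4, SynthParams(seed=11))
    return cohort, score_matrix(cohort, "orb")


class TestScoreMatrix:
    def test_counts(self, small_matrix):
        _, mat = small_matrix
        assert mat.scores.shape == (4, 4)
        matched, mismatched = split_matched_mismatched(mat)
        assert matched.size == 4
        assert mismatched.size == 12

    def test_entries_equal_independent_similarity_calls(self, small_matrix):
        cohort, mat = small_matrix
        rng = np.random.default_rng(0)
        ids = mat.case_ids
        for _ in range(5):
            i, j = rng.integers(0, 4, size=2)
            s = similarity_score(cohort.image(ids[i], "AM"), cohort.image(ids[j], "PM"), "orb")
            assert mat.scores[i, j] == pytest.approx(s.value)

    def test_long_format_roundtrip(self, small_matrix):
        _, mat = small_matrix
        long = mat.to_long()
        assert len(long) == 16
        back = matrix_from_long(long, "orb")
        np.testing.assert_allclose(back.scores, mat.scores)

    def test_singleton_subset_refused_downstream(self, small_matrix):
        _, mat = small_matrix
        matched, mismatched = split_matched_mismatched(mat, [mat.case_ids[0]])
        assert matched.size == 1 and mismatched.size == 0
        with pytest.raises(EvalError):
            evaluate_subset(mat, [mat.case_ids[0]], "singleton")


class TestWelch:
    def test_identical_groups(self):
        x = np.array([3.0, 4.0, 5.0])
        r = welch_t(x, x)
        assert r.t == 0.0
        assert r.p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        """x={1,2,3}, y={2,4,6}: t = -2/sqrt(5/3) = -1.549, df = 50/17
        (hand-evaluated Welch and Satterthwaite formulas)."""
        r = welch_t([1, 2, 3], [2, 4, 6])
        assert r.t == pytest.approx(-2.0 / np.sqrt(5.0 / 3.0), abs=1e-9)
        assert r.t == pytest.approx(-1.549, abs=1e-3)
        assert r.df == pytest.approx(50.0 / 17.0, abs=1e-9)
        from scipy import stats
        assert r.p == pytest.approx(2 * stats.t.sf(abs(r.t), r.df), abs=1e-12)

    def test_swap_flips_sign(self):
        r1 = welch_t([1, 2, 3], [2, 4, 6])
        r2 = welch_t([2, 4, 6], [1, 2, 3])
        assert r1.t == pytest.approx(-r2.t)
        assert r1.p == pytest.approx(r2.p)

    def test_degenerate_sizes_rejected(self):
        with pytest.raises(EvalError):
            welch_t([1.0], [2.0, 3.0])

    def test_p_uniform_under_null(self):
        """Two same-mean normal samples: p-values are uniform on (0,1)
        (Kolmogorov-Smirnov sanity check at alpha = 0.01)."""
        from scipy import stats
        rng = np.random.default_rng(42)
        ps = []
        for _ in range(500):
            x = rng.normal(0.0, 1.0, 60)
            y = rng.normal(0.0, 2.0, 40)
            ps.append(welch_t(x, y).p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestROC:
    def test_perfect_separation(self):
        r = roc_analysis([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
        assert r.auc == 1.0
        assert r.tpr == 1.0
        assert r.fpr == 0.0
        assert r.cutoff == 3.0  # smallest threshold attaining maximal J

    def test_interleaved_pair_enumeration(self):
        """matched={1,3}, mismatched={2,4}: 3 of 4 cross pairs ordered
        correctly -> AUC = 3/4 (exhaustive enumeration oracle)."""
        r = roc_analysis([1.0, 3.0], [2.0, 4.0])
        assert r.auc == pytest.approx(0.75)

    def test_identical_distributions_tie_convention(self):
        r = roc_analysis([1.0, 2.0], [1.0, 2.0])
        assert r.auc == pytest.approx(0.5)

    @pytest.mark.parametrize("trial", range(10))
    def test_pair_count_equals_trapezoid_and_sklearn(self, trial):
        """The Mann-Whitney pair-count AUC equals the trapezoid rule over
        the threshold-sweep curve (<= 1e-9) and sklearn's roc_auc_score."""
        rng = np.random.default_rng(trial)
        m = np.round(rng.normal(50, 8, 40), 1)  # rounding forces ties
        u = np.round(rng.normal(60, 10, 60), 1)
        r = roc_analysis(m, u)
        trap = np.trapezoid(r.curve["tpr"], r.curve["fpr"])
        assert abs(r.auc - trap) < 1e-9
        # sklearn oracle: positive class = matched, score = -similarity
        y = np.r_[np.ones(40), np.zeros(60)]
        sk = roc_auc_score(y, -np.r_[m, u])
        assert r.auc == pytest.approx(sk, abs=1e-12)

    def test_curve_monotone_and_bounded(self):
        rng = np.random.default_rng(5)
        r = roc_analysis(rng.normal(50, 5, 30), rng.normal(70, 9, 50))
        assert r.curve["tpr"].is_monotonic_increasing
        assert r.curve["fpr"].is_monotonic_increasing
        assert r.curve["tpr"].between(0, 1).all()
        assert r.curve["fpr"].between(0, 1).all()

    def test_youden_cutoff_matches_explicit_sweep(self):
        rng = np.random.default_rng(6)
        m = np.round(rng.normal(50, 7, 25), 0)
        u = np.round(rng.normal(75, 12, 35), 0)
        r = roc_analysis(m, u)
        best_j, best_t = -np.inf, None
        for t in np.unique(np.r_[m, u]):
            j = (m <= t).mean() - (u <= t).mean()
            if j > best_j:
                best_j, best_t = j, t
        assert r.cutoff == best_t
        assert r.tpr == pytest.approx((m <= best_t).mean())
        assert r.fpr == pytest.approx((u <= best_t).mean())


def _manifest(n, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "case_id": [f"c{i:03d}" for i in range(n)],
        "sex": rng.permutation(["M"] * (3 * n // 4) + ["F"] * (n - 3 * n // 4)),
        "age_years": rng.integers(20, 95, n),
        "interval_days": rng.integers(3, 400, n),
    })


def _separated_matrix(manifest, seed=0, method="akaze"):
    """Synthetic score matrix: matched ~ N(54, 7), mismatched ~ N(80, 13)."""
    n = len(manifest)
    rng = np.random.default_rng(seed)
    scores = rng.normal(80, 13, (n, n))
    scores[np.diag_indices(n)] = rng.normal(54, 7, n)
    return ScoreMatrix(scores=scores, case_ids=list(manifest["case_id"]), method=method)


class TestSubgroupEval:
    def test_subgroup_boundaries(self):
        """Interval 29 vs 30 days and age 59 vs 60 years land on opposite
        sides of the subgroup splits."""
        manifest = _manifest(12)
        manifest.loc[0, "interval_days"] = 29
        manifest.loc[1, "interval_days"] = 30
        manifest.loc[0, "age_years"] = 59
        manifest.loc[1, "age_years"] = 60
        mat = _separated_matrix(manifest)
        report = subgroup_eval(manifest, mat).to_frame()
        short = report[report["sample"] == "Interval <30 days"].iloc[0]
        long = report[report["sample"] == "Interval >=30 days"].iloc[0]
        assert short["n"] == (manifest["interval_days"] < 30).sum()
        assert long["n"] == (manifest["interval_days"] >= 30).sum()
        young = report[report["sample"] == "Age <60 years"].iloc[0]
        assert young["n"] == (manifest["age_years"] < 60).sum()

    def test_partition_property(self):
        """Binary groupings partition the matched pairs: subgroup matched
        counts sum to the total."""
        manifest = _manifest(16, seed=3)
        mat = _separated_matrix(manifest)
        total_matched, _ = split_matched_mismatched(mat)
        for grouping in ("sex", "interval_30d", "age_60y"):
            from sinusid.cohort import _subgroup_subsets
            sizes = 0
            for _, subset in _subgroup_subsets(manifest, grouping):
                matched, mismatched = split_matched_mismatched(mat, subset)
                sizes += matched.size
                # within-subgroup mismatched pairs only
                assert mismatched.size == len(subset) * (len(subset) - 1)
            assert sizes == total_matched.size

    def test_report_schema(self):
        manifest = _manifest(10, seed=4)
        report = subgroup_eval(manifest, _separated_matrix(manifest))
        assert report.rows
        for row in report.rows:
            assert tuple(row.keys()) == REPORT_FIELDS


class TestTablesFromScores:
    def test_large_separation_sanity(self):
        """180 matched N(54,7) vs 32220 mismatched N(80,13) scores give
        Welch p < 1e-10 and AUC > 0.9."""
        manifest = _manifest(180, seed=7)
        mat = _separated_matrix(manifest, seed=7)
        scores = mat.to_long()
        report = tables_from_scores(scores, manifest).to_frame()
        allrow = report[report["sample"] == "All"].iloc[0]
        matched, mismatched = split_matched_mismatched(mat)
        assert matched.size == 180 and mismatched.size == 180 * 179
        assert allrow["p"] < 1e-10
        assert allrow["auc"] > 0.9
        assert allrow["matched_mean"] == pytest.approx(matched.mean())

    def test_single_group_file_rejected(self):
        manifest = _manifest(6, seed=8)
        rows = [{"am_id": c, "pm_id": c, "method": "akaze", "score": 50.0 + i}
                for i, c in enumerate(manifest["case_id"])]
        with pytest.raises(EvalError):
            tables_from_scores(pd.DataFrame(rows), manifest)

    def test_missing_columns_rejected(self):
        with pytest.raises(EvalError):
            tables_from_scores(pd.DataFrame({"a": [1]}), _manifest(4))
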