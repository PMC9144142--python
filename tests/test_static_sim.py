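"""Static similarity: per-feature rules, weighted aggregation, distances."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import psnfuse as pf
from psnfuse.static_sim import pairwise_distance_matrix

# the published weighted-scoring prioritization grid: six features, ten
# candidate weight options scored 1-4, with the known totals and ranking
SCORING_WEIGHTS = [0.1, 0.15, 0.2, 0.15, 0.2, 0.2]
SCORING_OPTIONS = {
    "Option1": ([1, 1, 3, 3, 3, 1], 2.1, 4),
    "Option2": ([1, 1, 3, 2, 3, 3], 2.35, 2),
    "Option3": ([1, 1, 4, 3, 2, 2], 2.3, 3),
    "Option4": ([1, 1, 3, 3, 3, 3], 2.5, 1),
    "Option5": ([1, 1, 3, 1, 1, 1], 1.4, 5),
    "Option6": ([2, 1, 1, 2, 1, 1], 1.25, 9),
    "Option7": ([1, 1, 1, 1, 1, 1], 1.0, 10),
    "Option8": ([1, 2, 2, 1, 1, 1], 1.35, 6),
    "Option9": ([1, 1, 1, 2, 1, 2], 1.35, 7),
    "Option10": ([1, 1, 1, 2, 2, 1], 1.35, 8),
}


class TestAgeSimilarity:
    @pytest.mark.parametrize(
        "ai,aj,expected",
        [(40, 40, 1.0), (25, 50, 0.5), (0, 30, 0.0), (0, 0, 1.0), (30, 0, 0.0)],
    )
    def test_min_max_ratio(self, ai, aj, expected):
        assert pf.age_similarity(ai, aj) == pytest.approx(expected)

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            pf.age_similarity(-1, 30)

    @given(st.floats(0, 120), st.floats(0, 120))
    @settings(max_examples=100, derandomize=True)
    def test_symmetric_and_bounded(self, a, b):
        s = pf.age_similarity(a, b)
        assert 0.0 <= s <= 1.0
        assert s == pf.age_similarity(b, a)


class TestMatchSimilarity:
    @pytest.mark.parametrize(
        "vi,vj,expected",
        [("male", "male", 1), ("diabetic", "nondiabetic", 0), (True, True, 1), (False, True, 0)],
    )
    def test_exact_match(self, vi, vj, expected):
        assert pf.match_similarity(vi, vj) == expected


class TestWeightedScore:
    @pytest.mark.parametrize("name", list(SCORING_OPTIONS))
    def test_scoring_grid_totals(self, name):
        scores, expected, _ = SCORING_OPTIONS[name]
        assert pf.weighted_score(scores, SCORING_WEIGHTS) == pytest.approx(expected)

    def test_scoring_grid_rank_order(self):
        names = list(SCORING_OPTIONS)
        totals = [pf.weighted_score(SCORING_OPTIONS[n][0], SCORING_WEIGHTS) for n in names]
        # stable sort: descending total, ties keep option order
        computed_rank = {
            name: r + 1
            for r, name in enumerate(
                sorted(names, key=lambda n: (-round(totals[names.index(n)], 9), names.index(n)))
            )
        }
        for name, (_, _, rank) in SCORING_OPTIONS.items():
            assert computed_rank[name] == rank

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pf.weighted_score([1, 2], [0.5])

    def test_stps_form_is_dot_product(self, rng):
        s = rng.random(6)
        w = pf.normalize_weights(rng.random(6))
        assert pf.weighted_score(s, w) == pytest.approx(float(s @ w))


class TestStaticSimilarityMatrix:
    def _cohort(self, ages, genders):
        ids = [f"P{i}" for i in range(len(ages))]
        data = pd.DataFrame({"age": ages, "gender": genders}, index=ids)
        return pf.StaticCohort(
            ids, data, {"age": "numeric", "gender": "categorical"},
            pd.Series(["x"] * len(ids), index=ids),
        )

    SPECS = [pf.FeatureSpec("age", "age_ratio", 0.5), pf.FeatureSpec("gender", "exact_match", 0.5)]

    def test_hand_computed_three_patients(self):
        m = pf.static_similarity_matrix(self._cohort([20, 40, 40], ["F", "F", "M"]), self.SPECS)
        assert m.values[0, 1] == pytest.approx(0.75)   # 0.5*(20/40) + 0.5*1
        assert m.values[1, 2] == pytest.approx(0.5)    # 0.5*1 + 0.5*0
        assert m.values[0, 2] == pytest.approx(0.25)   # 0.5*(20/40) + 0.5*0

    def test_identical_patients_score_one(self):
        m = pf.static_similarity_matrix(self._cohort([30, 30], ["F", "F"]), self.SPECS)
        assert m.values[0, 1] == pytest.approx(1.0)

    def test_single_patient(self):
        m = pf.static_similarity_matrix(self._cohort([30], ["F"]), self.SPECS)
        assert m.values.shape == (1, 1)
        assert m.values[0, 0] == 1.0

    def test_empty_specs_rejected(self):
        with pytest.raises(ValueError):
            pf.static_similarity_matrix(self._cohort([30], ["F"]), [])

    def test_symmetric_unit_diagonal_bounded(self, static4):
        m = pf.static_similarity_matrix(static4, pf.default_static_specs(static4))
        assert m.is_symmetric()
        np.testing.assert_allclose(np.diag(m.values), 1.0)
        assert (m.values >= 0).all() and (m.values <= 1 + 1e-12).all()


class TestPairwiseDistance:
    @pytest.mark.parametrize(
        "x,y,metric,expected",
        [
            ((0, 0), (3, 4), "euclidean", 5.0),
            ((1, 5), (4, 1), "chebyshev", 4.0),
            ((0, 0), (3, 4), "manhattan", 7.0),
            ((1, 2), (2, 4), "cosine", 0.0),
        ],
    )
    def test_known_values(self, x, y, metric, expected):
        assert pf.pairwise_distance(x, y, pf.DistanceMetric(metric)) == pytest.approx(expected)

    def test_weighted_manhattan(self):
        m = pf.DistanceMetric("weighted_manhattan", weights=[2.0, 0.5])
        assert pf.pairwise_distance((0, 0), (1, 4), m) == pytest.approx(2 + 2)

    def test_weighted_manhattan_requires_weights(self):
        with pytest.raises(ValueError):
            pf.pairwise_distance((0,), (1,), pf.DistanceMetric("weighted_manhattan"))

    def test_cosine_double_zero_warns_and_is_zero(self):
        with pytest.warns(UserWarning):
            assert pf.pairwise_distance((0, 0), (0, 0), pf.DistanceMetric("cosine")) == 0.0

    def test_metric_axioms_and_triangle_inequality(self, rng):
        """d(x,x)=0 and symmetry for all metrics; triangle inequality for the
        three Minkowski-type metrics on 1,000 random triples."""
        metrics = [pf.DistanceMetric(n) for n in ("euclidean", "manhattan", "chebyshev")]
        wm = pf.DistanceMetric("weighted_manhattan", weights=rng.random(4) + 0.1)
        cos = pf.DistanceMetric("cosine")
        for _ in range(1000):
            x, y, z = rng.normal(size=(3, 4))
            for metric in (*metrics, wm, cos):
                assert pf.pairwise_distance(x, x, metric) == pytest.approx(0.0, abs=1e-12)
                assert pf.pairwise_distance(x, y, metric) == pytest.approx(
                    pf.pairwise_distance(y, x, metric)
                )
            for metric in metrics:
                dxy = pf.pairwise_distance(x, y, metric)
                dyz = pf.pairwise_distance(y, z, metric)
                dxz = pf.pairwise_distance(x, z, metric)
                assert dxz <= dxy + dyz + 1e-9

    @pytest.mark.parametrize("name", ["euclidean", "manhattan", "cosine", "chebyshev", "weighted_manhattan"])
    def test_matrix_agrees_with_scalar_function(self, name, rng):
        v = rng.normal(size=(6, 3))
        metric = pf.DistanceMetric(name, weights=rng.random(3) + 0.1)
        m = pairwise_distance_matrix(v, [f"P{i}" for i in range(6)], metric)
        for i in range(6):
            for j in range(6):
                assert m.values[i, j] == pytest.approx(
                    pf.pairwise_distance(v[i], v[j], metric), abs=1e-9
                )


class TestDistanceToSimilarity:
    def test_inverse_kernel_values(self):
        d = pf.SimilarityMatrix(np.array([[0.0, 1.0], [1.0, 0.0]]), ["a", "b"], "distance")
        s = pf.distance_matrix_to_similarity(d)
        assert s.values[0, 0] == 1.0
        assert s.values[0, 1] == pytest.approx(0.5)

    def test_monotone_decreasing(self, rng):
        d1, d2 = sorted(rng.random(2) + 0.01)
        m = pf.SimilarityMatrix(np.array([[0, d1, d2], [d1, 0, 0], [d2, 0, 0]]), list("abc"), "distance")
        s = pf.distance_matrix_to_similarity(m)
        assert s.values[0, 1] > s.values[0, 2]

    def test_negative_distance_rejected(self):
        d = pf.SimilarityMatrix.__new__(pf.SimilarityMatrix)
        d.values, d.patient_ids, d.kind = np.array([[0.0, -1.0], [-1.0, 0.0]]), ["a", "b"], "distance"
        with pytest.raises(ValueError):
            pf.distance_matrix_to_similarity(d)

    def test_gaussian_kernel_unit_diagonal(self, rng):
        v = rng.normal(size=(5, 3))
        d = pairwise_distance_matrix(v, [f"P{i}" for i in range(5)], pf.DistanceMetric("euclidean"))
        s = pf.distance_matrix_to_similarity(d, kernel="gaussian")
        np.testing.assert_allclose(np.diag(s.values), 1.0)
        assert ((s.values >= 0) & (s.values <= 1)).all()


class TestNormalizeWeights:
    def test_sums_to_one(self, rng):
        w = pf.normalize_weights(rng.random(6) + 0.01)
        assert w.sum() == pytest.approx(1.0, abs=1e-9)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            pf.normalize_weights([-0.1, 1.0])
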