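"""Composite index, ranking, end-to-end pipeline, and amplitude sensitivity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecovuln import (
    AggregationMode,
    AggregationModeError,
    AssessmentConfig,
    IndicatorDescriptor,
    IndicatorMatrix,
    Orientation,
    amplitude_sensitivity,
    assess,
    composite_index,
    rank_regions,
)

CON = Orientation.CONTRARIAN
POS = Orientation.POSITIVE


def _matrix(values, orientations=None):
    values = np.asarray(values, dtype=float)
    m = values.shape[1]
    orientations = orientations or [CON] * m
    return IndicatorMatrix(
        regions=[f"R{j}" for j in range(values.shape[0])],
        indicators=[
            IndicatorDescriptor(id=f"I{i}", orientation=orientations[i])
            for i in range(m)
        ],
        values=values,
    )


class TestCompositeIndex:
    def test_all_contrarian_is_weighted_complement_sum(self):
        p = np.array([[0.2, 0.7], [0.8, 0.3]])
        w = np.array([0.4, 0.6])
        V = composite_index(p, w, [CON, CON])
        np.testing.assert_allclose(V, (w * (1 - p)).sum(axis=1))

    def test_mixed_orientations(self):
        p = np.array([[0.2, 0.7], [0.8, 0.3]])
        w = np.array([0.4, 0.6])
        V = composite_index(p, w, [POS, CON])
        np.testing.assert_allclose(V, w[0] * p[:, 0] + w[1] * (1 - p[:, 1]))

    def test_literal_ratio(self):
        p = np.array([[0.2, 0.7], [0.8, 0.3]])
        w = np.array([0.4, 0.6])
        V = composite_index(p, w, [POS, CON], mode="literal_ratio")
        np.testing.assert_allclose(V, (w[0] * p[:, 0]) / (w[1] * (1 - p[:, 1])))

    def test_literal_ratio_needs_both_orientations(self):
        p = np.array([[0.5], [0.5]])
        with pytest.raises(AggregationModeError, match="undefined"):
            composite_index(p, np.array([1.0]), [CON], mode="literal_ratio")

    def test_equal_weights_on_published_proportions(self, table_proportions):
        # Fuyu's composite under w_i = 0.1 equals 1 - (row sum)/10,
        # computable by hand from the published proportion table
        V = composite_index(table_proportions, np.full(10, 0.1), [CON] * 10)
        fuyu = 1 - table_proportions[6].sum() / 10
        assert V[6] == pytest.approx(fuyu, abs=1e-12)
        assert V[6] == pytest.approx(0.9368, abs=5e-4)


class TestRanking:
    def test_descending_with_stable_ties(self):
        assert rank_regions(["B", "A"], np.array([0.5, 0.5])) == ["B", "A"]
        assert rank_regions(["a", "b", "c"], np.array([0.1, 0.9, 0.5])) == [
            "b", "c", "a",
        ]

    def test_singleton(self):
        assert rank_regions(["only"], np.array([0.3])) == ["only"]


class TestPipeline:
    def test_jilin_reproduces_published_results(self, jilin_matrix, jilin_config):
        std, weighting, result = assess(jilin_matrix, jilin_config)
        assert result.amplitude == 2.2
        assert result.composite.max() == pytest.approx(0.9376, abs=3e-3)
        assert result.composite.min() == pytest.approx(0.8636, abs=3e-3)
        assert result.composite.mean() == pytest.approx(8 / 9, abs=1e-9)
        assert result.ranking == [
            "Fuyu", "Changling", "Da'an", "Qian'an", "Qianguo",
            "Zhenlai", "Tiaonan", "Tongyu", "Tiaobei",
        ]

    def test_auto_amplitude_matches_explicit(self, jilin_matrix, jilin_config):
        _, _, explicit = assess(jilin_matrix, jilin_config)
        _, _, auto = assess(jilin_matrix, AssessmentConfig())
        assert auto.amplitude == explicit.amplitude == 2.2
        np.testing.assert_allclose(auto.composite, explicit.composite)
        assert auto.provenance["amplitude_source"] == "auto"

    def test_two_regions_smaller_share_gets_larger_v(self):
        _, _, result = assess(_matrix([[1.0], [5.0]]))
        # region with the smaller shifted share scores higher under V = 1 - p
        assert result.composite[0] > result.composite[1]
        assert result.ranking == ["R0", "R1"]

    def test_region_permutation_equivariance(self, jilin_matrix):
        _, _, base = assess(jilin_matrix, AssessmentConfig(amplitude=2.2))
        perm = np.random.default_rng(5).permutation(9)
        m2 = IndicatorMatrix(
            regions=[jilin_matrix.regions[j] for j in perm],
            indicators=list(jilin_matrix.indicators),
            values=jilin_matrix.values[perm],
        )
        _, _, out = assess(m2, AssessmentConfig(amplitude=2.2))
        np.testing.assert_allclose(out.composite, base.composite[perm], atol=1e-12)
        assert out.ranking == base.ranking

    @settings(max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(3, 8), st.integers(2, 5))
    def test_analytic_mean_all_contrarian(self, seed, n, m):
        # mean V = (n-1)/n for any weights summing to 1, since each
        # proportion column sums to 1
        rng = np.random.default_rng(seed)
        values = rng.uniform(0.5, 50, size=(n, m))
        if (values.std(axis=0) < 1e-9).any():
            return
        _, _, result = assess(_matrix(values))
        assert result.composite.mean() == pytest.approx((n - 1) / n, abs=1e-9)

    @settings(max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_full_pipeline_column_rescale_invariance(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.uniform(1.0, 100.0, size=(5, 4))
        scale = rng.uniform(0.01, 100.0, size=4)
        _, w1, r1 = assess(_matrix(values))
        _, w2, r2 = assess(_matrix(values * scale))
        np.testing.assert_allclose(w2.weights, w1.weights, atol=1e-9)
        np.testing.assert_allclose(r2.composite, r1.composite, atol=1e-9)

    def test_step_by_step_oracle_equivalence(self):
        # independent plain-Python re-evaluation of the whole chain on 5x4
        rng = np.random.default_rng(23)
        for _ in range(5):
            X = rng.uniform(0.5, 30, size=(5, 4))
            std, weighting, result = assess(_matrix(X))
            n, m = 5, 4
            z = [
                [
                    (X[j, i] - sum(X[:, i]) / n)
                    / (sum((X[j2, i] - sum(X[:, i]) / n) ** 2 for j2 in range(n)) / n)
                    ** 0.5
                    for i in range(m)
                ]
                for j in range(n)
            ]
            A = result.amplitude
            xp = [[z[j][i] + A for i in range(m)] for j in range(n)]
            p = [
                [xp[j][i] / sum(xp[j2][i] for j2 in range(n)) for i in range(m)]
                for j in range(n)
            ]
            e = [
                -sum(p[j][i] * np.log(p[j][i]) for j in range(n)) / np.log(n)
                for i in range(m)
            ]
            g = [1 - ei for ei in e]
            w = [gi / sum(g) for gi in g]
            V = [sum(w[i] * (1 - p[j][i]) for i in range(m)) for j in range(n)]
            np.testing.assert_allclose(result.composite, V, atol=1e-12)

    def test_stage_errors_carry_stage_name(self):
        flat = _matrix([[1.0], [1.0]])
        with pytest.raises(Exception, match="standardization"):
            assess(flat)
        with pytest.raises(Exception, match="translation"):
            assess(_matrix([[1.0], [2.0]]), AssessmentConfig(amplitude=0.5))


class TestAmplitudeSensitivity:
    def test_discrimination_decays_with_large_amplitude(self, jilin_matrix):
        rows = amplitude_sensitivity(
            jilin_matrix, AssessmentConfig(), [2.2, 5.0, 50.0]
        )
        spreads = [r["weight_spread"] for r in rows]
        assert spreads[2] < spreads[0]
        assert spreads[2] < spreads[1] < spreads[0]

    def test_rank_stability_on_fixture(self, jilin_matrix):
        rows = amplitude_sensitivity(jilin_matrix, AssessmentConfig(), [2.2, 3.0])
        assert rows[0]["ranking"] == rows[1]["ranking"]

    def test_single_default_amplitude_matches_assess(self, jilin_matrix, jilin_config):
        _, _, base = assess(jilin_matrix, jilin_config)
        rows = amplitude_sensitivity(jilin_matrix, jilin_config, [2.2])
        np.testing.assert_allclose(rows[0]["composite"], base.composite, atol=1e-15)
        assert rows[0]["ranking"] == base.ranking

    def test_invalid_amplitude_reported_others_run(self, jilin_matrix):
        rows = amplitude_sensitivity(
            jilin_matrix, AssessmentConfig(), [1.0, 2.2]
        )
        assert "error" in rows[0] and "A > |min z|" in rows[0]["error"]
        assert "ranking" in rows[1]
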