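"""Reliability prediction, structural fidelity, alignment, prediction error."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import sim_from_pairs, sim_from_values
from taxaudit import (
    SimilarityMatrix,
    ValidationError,
    alignment_score,
    cronbach_alpha,
    empirical_fidelity_ratio,
    mean_alignment,
    pairwise_cosine,
    predict_alpha,
    prediction_error,
    structural_fidelity,
    within_scale_similarity,
)
from taxaudit.corpus import Scale
from taxaudit.psychometrics import FidelityResult


def _scales(spec, inventory="inv"):
    """spec: {scale_id: [item ids]} -> list of Scale."""
    return [
        Scale(sid, inventory, tuple(items), sid) for sid, items in spec.items()
    ]


class TestWithinScaleSimilarity:
    def test_mean_of_three_pairs(self):
        S = sim_from_pairs(
            ["a", "b", "c"], {("a", "b"): 0.2, ("a", "c"): 0.4, ("b", "c"): 0.6}
        )
        scale = Scale("s", "v", ("a", "b", "c"), "l")
        assert within_scale_similarity(S, scale) == pytest.approx(0.4)

    def test_two_items_single_pair(self):
        S = sim_from_pairs(["a", "b"], {("a", "b"): 0.35})
        scale = Scale("s", "v", ("a", "b"), "l")
        assert within_scale_similarity(S, scale) == pytest.approx(0.35)

    def test_all_ones(self):
        S = sim_from_pairs(["a", "b"], {("a", "b"): 1.0})
        assert within_scale_similarity(S, Scale("s", "v", ("a", "b"), "l")) == 1.0


class TestPredictAlpha:
    def test_boundaries(self):
        assert predict_alpha(0.0, 7) == 0.0
        assert predict_alpha(1.0, 7) == 1.0

    def test_worked_example(self):
        assert predict_alpha(0.3, 10) == pytest.approx(3 / 3.7, abs=1e-12)

    def test_requires_two_items(self):
        with pytest.raises(ValidationError):
            predict_alpha(0.5, 1)

    def test_negative_similarity_domain_error(self):
        with pytest.raises(ValidationError, match="denominator"):
            predict_alpha(-0.5, 10)

    @settings(derandomize=True, max_examples=50)
    @given(
        st.floats(0.01, 0.98),
        st.floats(0.005, 0.019),
        st.integers(2, 40),
    )
    def test_strictly_increasing_in_s_and_n(self, s, ds, n):
        assert predict_alpha(s + ds, n) > predict_alpha(s, n)
        assert predict_alpha(s, n + 1) > predict_alpha(s, n)


class TestCronbachAlpha:
    def test_identical_columns_give_one(self):
        R = pd.DataFrame({"i1": [1, 2, 3, 4], "i2": [1, 2, 3, 4]})
        scale = Scale("s", "v", ("i1", "i2"), "l")
        assert cronbach_alpha(R, scale) == pytest.approx(1.0)

    def test_four_respondent_worked_example(self):
        R = pd.DataFrame({"i1": [1, 2, 3, 4], "i2": [2, 1, 4, 3]})
        scale = Scale("s", "v", ("i1", "i2"), "l")
        assert cronbach_alpha(R, scale) == pytest.approx(0.75, abs=1e-12)

    def test_uncorrelated_columns_alpha_near_zero(self):
        rng = np.random.default_rng(5)
        R = pd.DataFrame(rng.standard_normal((100_000, 2)), columns=["i1", "i2"])
        scale = Scale("s", "v", ("i1", "i2"), "l")
        assert abs(cronbach_alpha(R, scale)) < 0.02

    def test_listwise_deletion_and_min_rows(self):
        R = pd.DataFrame({"i1": [1, 2, np.nan, 4], "i2": [2, 1, 4, 3]})
        scale = Scale("s", "v", ("i1", "i2"), "l")
        cronbach_alpha(R, scale)  # 3 complete rows is the minimum
        R.loc[3, "i2"] = np.nan
        with pytest.raises(ValidationError, match="fewer than 3"):
            cronbach_alpha(R, scale)

    def test_zero_variance_rejected(self):
        R = pd.DataFrame({"i1": [1, 1, 1], "i2": [2, 2, 2]})
        with pytest.raises(ValidationError, match="variance"):
            cronbach_alpha(R, Scale("s", "v", ("i1", "i2"), "l"))


def _block_similarity(within, cross):
    """4 scales x 2 items with constant within- and cross-block sims.

    cross[(j, j2)] gives the constant similarity between items of scales
    j and j2.
    """
    ids = [f"s{j}_i{k}" for j in range(4) for k in range(2)]
    pairs = {}
    for j in range(4):
        pairs[(f"s{j}_i0", f"s{j}_i1")] = within[j]
    for (j, j2), v in cross.items():
        for a in range(2):
            for b in range(2):
                pairs[(f"s{j}_i{a}", f"s{j2}_i{b}")] = v
    return sim_from_pairs(ids, pairs)


class TestStructuralFidelity:
    def _fixture(self):
        # scale s0: within 0.5, cross means {0.1, 0.2, 0.3} -> z = 3.0
        within = [0.5, 0.5, 0.5, 0.5]
        cross = {
            (0, 1): 0.1, (0, 2): 0.2, (0, 3): 0.3,
            (1, 2): 0.15, (1, 3): 0.25, (2, 3): 0.35,
        }
        S = _block_similarity(within, cross)
        scales = _scales({f"s{j}": [f"s{j}_i0", f"s{j}_i1"] for j in range(4)})
        return S, scales

    def test_z_from_hand_arithmetic(self):
        S, scales = self._fixture()
        res = {r.scale_id: r for r in structural_fidelity(S, scales)}
        assert res["s0"].z == pytest.approx(3.0, abs=1e-12)
        assert res["s0"].status == "full"

    def test_z_zero_when_within_equals_cross_mean(self):
        within = [0.2, 0.5, 0.5, 0.5]
        cross = {
            (0, 1): 0.1, (0, 2): 0.2, (0, 3): 0.3,
            (1, 2): 0.15, (1, 3): 0.25, (2, 3): 0.35,
        }
        S = _block_similarity(within, cross)
        scales = _scales({f"s{j}": [f"s{j}_i0", f"s{j}_i1"] for j in range(4)})
        res = {r.scale_id: r for r in structural_fidelity(S, scales)}
        assert res["s0"].z == pytest.approx(0.0, abs=1e-12)

    def test_status_thresholds(self):
        assert FidelityResult.classify(2.5) == "full"
        assert FidelityResult.classify(1.5) == "partial"
        assert FidelityResult.classify(0.5) == "none"
        assert FidelityResult.classify(float("nan")) == "undefined"

    def test_requires_three_scales(self):
        S = sim_from_pairs(
            ["a", "b", "c", "d"],
            {("a", "b"): 0.5, ("c", "d"): 0.5, ("a", "c"): 0.1,
             ("a", "d"): 0.1, ("b", "c"): 0.1, ("b", "d"): 0.1},
        )
        scales = _scales({"s0": ["a", "b"], "s1": ["c", "d"]})
        with pytest.raises(ValidationError, match="3 scales"):
            structural_fidelity(S, scales)

    def test_zero_spread_flagged_undefined(self):
        within = [0.5] * 4
        cross = {pair: 0.2 for pair in
                 [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]}
        S = _block_similarity(within, cross)
        scales = _scales({f"s{j}": [f"s{j}_i0", f"s{j}_i1"] for j in range(4)})
        res = structural_fidelity(S, scales)
        assert all(r.status == "undefined" and np.isnan(r.z) for r in res)

    def test_invariant_to_additive_shift(self):
        S, scales = self._fixture()
        shifted = SimilarityMatrix(S.row_ids, S.col_ids, S.values + 0.17)
        z0 = [r.z for r in structural_fidelity(S, scales)]
        z1 = [r.z for r in structural_fidelity(shifted, scales)]
        assert np.allclose(z0, z1, atol=1e-9)

    def test_random_item_permutation_destroys_fidelity(self, planted6):
        # permuting item->scale assignments drives the expected z toward 0
        S = pairwise_cosine(planted6.item_embeddings)
        scales = list(planted6.pool.scales.values())
        true_mean = np.mean([r.z for r in structural_fidelity(S, scales)])
        rng = np.random.default_rng(0)
        item_ids = [i for s in scales for i in s.item_ids]
        perm_means = []
        for _ in range(100):
            shuffled = list(item_ids)
            rng.shuffle(shuffled)
            it = iter(shuffled)
            perm_scales = [
                Scale(s.scale_id, s.inventory_id,
                      tuple(next(it) for _ in s.item_ids), s.label_compound)
                for s in scales
            ]
            perm_means.append(
                np.mean([abs(r.z) for r in structural_fidelity(S, perm_scales)])
            )
        assert np.mean(perm_means) < true_mean


class TestEmpiricalFidelityRatio:
    def test_within_strongest_gives_one(self):
        within = [0.4, 0.4, 0.4, 0.4]
        cross = {pair: 0.2 for pair in
                 [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]}
        S = _block_similarity(within, cross)
        scales = _scales({f"s{j}": [f"s{j}_i0", f"s{j}_i1"] for j in range(4)})
        ratios = empirical_fidelity_ratio(S, scales)
        assert all(r == pytest.approx(1.0) for r in ratios.values())

    def test_cross_strongest_gives_fraction(self):
        within = [0.2, 0.2, 0.2, 0.2]
        cross = {pair: 0.2 for pair in [(0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]}
        cross[(0, 1)] = 0.4
        S = _block_similarity(within, cross)
        scales = _scales({f"s{j}": [f"s{j}_i0", f"s{j}_i1"] for j in range(4)})
        ratios = empirical_fidelity_ratio(S, scales)
        assert ratios["s0"] == pytest.approx(0.5)

    def test_absolute_values_used(self):
        within = [0.3, 0.3, 0.3, 0.3]
        cross = {pair: -0.6 for pair in
                 [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]}
        S = _block_similarity(within, cross)
        scales = _scales({f"s{j}": [f"s{j}_i0", f"s{j}_i1"] for j in range(4)})
        assert empirical_fidelity_ratio(S, scales)["s0"] == pytest.approx(0.5)

    def test_single_scale_rejected(self):
        S = sim_from_pairs(["a", "b"], {("a", "b"): 0.5})
        with pytest.raises(ValidationError):
            empirical_fidelity_ratio(S, _scales({"s0": ["a", "b"]}))


def _item_label_sims(items, labels, value_map):
    V = np.array([[value_map[(i, l)] for l in labels] for i in items], float)
    return SimilarityMatrix(tuple(items), tuple(labels), V)


class TestAlignment:
    def _fixture(self):
        items = ["i0", "i1"]
        labels = ["good", "l1", "l2", "l3"]
        sims = {"good": 0.6, "l1": 0.1, "l2": 0.2, "l3": 0.3}
        vm = {(i, l): sims[l] for i in items for l in labels}
        S = _item_label_sims(items, labels, vm)
        return S, Scale("s", "v", ("i0", "i1"), "good"), labels

    def test_z_from_hand_arithmetic(self):
        S, scale, labels = self._fixture()
        res = alignment_score(S, scale, "good", labels)
        assert res.z == pytest.approx(4.0, abs=1e-12)

    def test_zero_when_assigned_equals_reference_mean(self):
        S, scale, labels = self._fixture()
        V = S.values.copy()
        V[:, 0] = 0.2  # assigned similarity = mean of {0.1, 0.2, 0.3}
        S2 = SimilarityMatrix(S.row_ids, S.col_ids, V)
        assert alignment_score(S2, scale, "good", labels).z == pytest.approx(0.0)

    def test_reference_set_excludes_assigned(self):
        S, scale, labels = self._fixture()
        with_dup = alignment_score(S, scale, "good", labels + ["good"])
        assert with_dup.z == pytest.approx(4.0, abs=1e-12)

    def test_too_few_references_rejected(self):
        S, scale, _ = self._fixture()
        with pytest.raises(ValidationError):
            alignment_score(S, scale, "good", ["good", "l1", "l2"])

    def test_mean_alignment_and_subset(self):
        S, scale, labels = self._fixture()
        r1 = alignment_score(S, scale, "good", labels)
        r2 = alignment_score(S, Scale("s2", "v", ("i0", "i1"), "l1"), "l1", labels)
        assert mean_alignment([r1]) == pytest.approx(r1.z)
        assert mean_alignment([r1, r2]) == pytest.approx((r1.z + r2.z) / 2)
        assert mean_alignment([r1, r2], {"good"}) == pytest.approx(r1.z)
        with pytest.raises(ValidationError):
            mean_alignment([r1], {"nope"})


class TestPredictionError:
    def test_perfect_prediction(self):
        P = sim_from_pairs(["a", "b", "c"],
                           {("a", "b"): 0.2, ("a", "c"): 0.4, ("b", "c"): 0.6})
        res = prediction_error(P, P)
        assert res["mae"] == pytest.approx(0.0)
        assert res["pearson_r"] == pytest.approx(1.0)

    def test_mae_by_hand_with_absolute_observed(self):
        P = sim_from_pairs(["a", "b", "c"],
                           {("a", "b"): 0.1, ("a", "c"): 0.5, ("b", "c"): 0.3})
        O = sim_from_pairs(["a", "b", "c"],
                           {("a", "b"): -0.2, ("a", "c"): 0.4, ("b", "c"): 0.3})
        res = prediction_error(P, O)
        assert res["mae"] == pytest.approx((0.1 + 0.1 + 0.0) / 3, abs=1e-12)

    def test_diagonal_excluded(self):
        # self-similarity mismatch must not contribute
        P = sim_from_pairs(["a", "b", "c"],
                           {("a", "b"): 0.1, ("a", "c"): 0.5, ("b", "c"): 0.3})
        O = sim_from_pairs(["a", "b", "c"],
                           {("a", "b"): 0.1, ("a", "c"): 0.5, ("b", "c"): 0.3},
                           diag=0.0)
        assert prediction_error(P, O)["mae"] == pytest.approx(0.0)

    def test_mismatched_ids_rejected(self):
        P = sim_from_pairs(["a", "b", "c"],
                           {("a", "b"): 0.1, ("a", "c"): 0.5, ("b", "c"): 0.3})
        O = sim_from_pairs(["a", "b", "x"],
                           {("a", "b"): 0.1, ("a", "x"): 0.5, ("b", "x"): 0.3})
        with pytest.raises(ValidationError):
            prediction_error(P, O)
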