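import numpy as np
import pandas as pd
import pytest

import scor
from scor.signature import (
    Signature,
    evaluate_stratification,
    kmeans_stratify,
    multi_gene_score,
    stratification_agreement,
)

from oracles import best_1d_split, km_naive


def _matrix(values, gene_ids=None):
    values = np.atleast_2d(np.asarray(values, float))
    return scor.ExpressionMatrix(
        gene_ids or [f"g{i}" for i in range(values.shape[0])],
        [f"s{j}" for j in range(values.shape[1])],
        values,
    )


class TestSignatureType:
    def test_overlapping_lists_rejected(self):
        with pytest.raises(ValueError, match="both lists"):
            Signature(["a", "b"], ["b", "c"])

    def test_empty_signature_rejected(self):
        with pytest.raises(ValueError):
            Signature([], [])


class TestMultiGeneScore:
    def test_sum_arithmetic(self):
        # two good and two poor genes whose normalized values are known:
        # score = sum(good) - sum(poor) per sample
        rng = np.random.default_rng(0)
        m = _matrix(rng.normal(size=(4, 30)))
        sig = Signature(["g0", "g1"], ["g2", "g3"])
        scores = multi_gene_score(m, sig)
        norm = scor.normalize_center_scale(m).values
        expected = norm[0] + norm[1] - norm[2] - norm[3]
        np.testing.assert_allclose(scores.to_numpy(), expected, atol=1e-12)

    def test_mean_variant_divides_by_list_sizes(self):
        rng = np.random.default_rng(1)
        m = _matrix(rng.normal(size=(3, 20)))
        sig = Signature(["g0", "g1"], ["g2"])
        norm = scor.normalize_center_scale(m).values
        expected = (norm[0] + norm[1]) / 2 - norm[2]
        scores = multi_gene_score(m, sig, mean=True)
        np.testing.assert_allclose(scores.to_numpy(), expected, atol=1e-12)

    def test_antisymmetric_under_swap(self):
        rng = np.random.default_rng(2)
        m = _matrix(rng.normal(size=(5, 25)))
        sig = Signature(["g0", "g1"], ["g2", "g3", "g4"])
        np.testing.assert_allclose(
            multi_gene_score(m, sig).to_numpy(),
            -multi_gene_score(m, sig.swapped()).to_numpy(),
            atol=1e-12,
        )

    def test_invariant_to_per_gene_positive_affine_transform(self):
        rng = np.random.default_rng(3)
        raw = rng.normal(size=(4, 40))
        a = rng.uniform(0.1, 5.0, size=(4, 1))
        b = rng.uniform(-10, 10, size=(4, 1))
        sig = Signature(["g0", "g2"], ["g1", "g3"])
        s1 = multi_gene_score(_matrix(raw), sig)
        s2 = multi_gene_score(_matrix(a * raw + b), sig)
        np.testing.assert_allclose(s1.to_numpy(), s2.to_numpy(), atol=1e-9)

    def test_missing_gene_policies(self):
        m = _matrix(np.random.default_rng(4).normal(size=(2, 10)))
        sig = Signature(["g0"], ["g1", "ghost"])
        with pytest.raises(KeyError, match="ghost"):
            multi_gene_score(m, sig)
        with pytest.warns(UserWarning, match="skipping"):
            scores = multi_gene_score(m, sig, missing="skip")
        assert len(scores) == 10


class TestKmeansStratify:
    def test_obvious_separation(self):
        res = kmeans_stratify(np.array([-1.1, -1.0, 2.0, 2.2]), seed=0)
        assert res.group.tolist() == ["low", "low", "high", "high"]

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_split_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = np.concatenate(
            [rng.normal(-1, 0.7, rng.integers(5, 30)), rng.normal(1.5, 0.7, rng.integers(5, 30))]
        )
        res = kmeans_stratify(x, seed=seed)
        oracle_high = best_1d_split(x)
        np.testing.assert_array_equal(np.asarray(res.group) == "high", oracle_high)

    def test_symmetric_bimodal_threshold_near_zero(self):
        rng = np.random.default_rng(9)
        half = rng.normal(2.0, 0.4, 100)
        x = np.concatenate([half, -half])
        res = kmeans_stratify(x, seed=1)
        high = np.asarray(res.group) == "high"
        boundary = (x[high].min() + x[~high].max()) / 2
        assert abs(boundary) < 0.3

    def test_two_samples_split_apart(self):
        res = kmeans_stratify(np.array([0.0, 1.0]), seed=0)
        assert sorted(res.group) == ["high", "low"]

    def test_identical_scores_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            kmeans_stratify(np.ones(5), seed=0)

    def test_series_index_becomes_sample_ids(self):
        s = pd.Series([0.0, 5.0, 5.1], index=["a", "b", "c"])
        res = kmeans_stratify(s, seed=0)
        assert res.sample_ids == ["a", "b", "c"]


class TestEvaluateStratification:
    def _groups(self, labels, ids=None):
        labels = np.asarray(labels, dtype=object)
        ids = ids or [f"s{i}" for i in range(len(labels))]
        score = np.where(labels == "high", 1.0, -1.0)
        return scor.SignatureScore(ids, score, labels)

    def test_km_curves_start_at_one_and_never_rise(self):
        rng = np.random.default_rng(5)
        n = 80
        t = rng.exponential(10, n)
        e = rng.integers(0, 2, n)
        e[:4] = 1
        surv = scor.SurvivalData([f"s{i}" for i in range(n)], t, e)
        groups = self._groups(["high"] * 40 + ["low"] * 40)
        res = evaluate_stratification(groups, surv)
        for curve in res.km_curves.values():
            s = curve["survival"].to_numpy()
            assert s[0] == pytest.approx(1.0)
            assert (np.diff(s) <= 1e-12).all()

    def test_km_matches_naive_product_limit(self):
        rng = np.random.default_rng(6)
        t = rng.integers(1, 15, 30).astype(float)
        e = rng.integers(0, 2, 30)
        e[:2] = 1
        surv = scor.SurvivalData([f"s{i}" for i in range(30)], t, e)
        groups = self._groups(["high"] * 30, [f"s{i}" for i in range(30)])
        # evaluate_stratification needs both groups; test km on one group
        # via a 29/1 split is awkward, so check against lifelines through a
        # clean two-group call and the naive estimator on the high group
        groups = self._groups(["high"] * 25 + ["low"] * 5)
        res = evaluate_stratification(groups, surv)
        ref = dict(km_naive(t[:25], e[:25]))
        curve = res.km_curves["high"]["survival"]
        for tau, s in ref.items():
            assert curve.loc[:tau].iloc[-1] == pytest.approx(s, abs=1e-10)

    def test_label_permutation_p_is_uniform(self):
        rng = np.random.default_rng(7)
        n = 60
        t = rng.exponential(10, n)
        e = (t <= rng.uniform(0, 20, n)).astype(int)
        t = np.minimum(t, 20)
        e[:3] = 1
        surv = scor.SurvivalData([f"s{i}" for i in range(n)], t, e)
        ps = []
        for _ in range(200):
            labels = np.array(["high"] * (n // 2) + ["low"] * (n - n // 2), dtype=object)
            rng.shuffle(labels)
            res = evaluate_stratification(self._groups(labels), surv)
            ps.append(res.logrank_p)
        assert 0.35 < np.median(ps) < 0.65

    def test_doubled_times_give_hazard_ratio_two(self):
        rng = np.random.default_rng(8)
        n = 150
        t1 = rng.exponential(5, n)
        t = np.concatenate([t1, 2 * t1])
        e = np.ones(2 * n, dtype=int)
        surv = scor.SurvivalData([f"s{i}" for i in range(2 * n)], t, e)
        groups = self._groups(["high"] * n + ["low"] * n)
        res = evaluate_stratification(groups, surv)
        # "high" group has doubled... no: first block is high with original
        # times, so hazard(high)/hazard(low) = 2
        assert res.hazard_ratio == pytest.approx(2.0, rel=0.25)

    def test_empty_group_rejected(self):
        surv = scor.SurvivalData(["a", "b"], [1, 2], [1, 1])
        with pytest.raises(ValueError, match="non-empty"):
            evaluate_stratification(self._groups(["high", "high"], ["a", "b"]), surv)

    def test_zero_event_group_flagged_unreliable(self):
        surv = scor.SurvivalData(
            [f"s{i}" for i in range(10)], np.arange(1.0, 11.0), [1] * 5 + [0] * 5
        )
        groups = self._groups(["high"] * 5 + ["low"] * 5)
        res = evaluate_stratification(groups, surv)
        assert not res.reliable
        assert "low" in res.km_curves


class TestAgreement:
    def test_matching_fraction(self):
        a = ["high", "low", "high", "low"]
        b = ["high", "high", "high", "low"]
        assert stratification_agreement(a, b) == pytest.approx(0.75)
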