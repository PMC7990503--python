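"""RDM, IS-RSA, pattern-similarity and LOSO-decoding tests."""

import numpy as np
import pytest

from moralcost import similarity as sim
from moralcost import synth
from moralcost.similarity import RDM, LosoPatternDecoder


def _pm(values, ids=None):
    values = np.asarray(values, float)
    ids = ids or tuple(f"sub{i + 1:03d}" for i in range(values.shape[0]))
    return synth.PatternMatrix(tuple(ids), values)


class TestParameterRDM:
    def test_hand_computed_distances(self):
        r = sim.parameter_rdm([5, 8, 5], [1, 1, 5], standardize=False)
        assert r.matrix[0, 1] == pytest.approx(3.0)
        assert r.matrix[0, 2] == pytest.approx(4.0)

    def test_identical_subjects_have_zero_distance(self):
        r = sim.parameter_rdm([2, 2, 7], [1, 1, 3])
        assert r.matrix[0, 1] == pytest.approx(0.0)

    def test_symmetric_zero_diagonal(self, rng):
        r = sim.parameter_rdm(rng.normal(size=9), rng.normal(size=9))
        assert np.allclose(r.matrix, r.matrix.T)
        assert np.allclose(np.diag(r.matrix), 0)

    def test_standardization_equalizes_scales(self):
        theta = [0, 10, 20]  # 10x the spread of omega
        omega = [0.0, 1.0, 2.0]
        z = sim.parameter_rdm(theta, omega, standardize=True)
        raw = sim.parameter_rdm(theta, omega, standardize=False)
        # standardized: both axes contribute equally
        assert z.matrix[0, 1] == pytest.approx(z.matrix[1, 2])
        assert raw.matrix[0, 2] == pytest.approx(np.hypot(20, 2))

    def test_zero_variance_with_standardize_raises(self):
        with pytest.raises(ValueError, match="zero variance"):
            sim.parameter_rdm([1, 1, 1], [0, 1, 2])

    def test_too_few_subjects(self):
        with pytest.raises(ValueError, match="3 subjects"):
            sim.parameter_rdm([1, 2], [3, 4])


class TestNeuralRDM:
    def test_identical_flipped_and_orthogonal_vectors(self, rng):
        base = rng.normal(size=40)
        other = rng.normal(size=40)
        other -= other @ base / (base @ base) * base  # orthogonalize
        pm = _pm([base, base, -base, other])
        r = sim.neural_rdm(pm).matrix
        assert r[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert r[0, 2] == pytest.approx(2.0, abs=1e-12)
        assert r[0, 3] == pytest.approx(1.0, abs=0.05)

    def test_constant_vector_reported(self):
        pm = _pm([np.ones(10), np.arange(10.0), np.arange(10.0) ** 2])
        with pytest.raises(ValueError, match="sub001"):
            sim.neural_rdm(pm)

    def test_rdm_validation(self):
        with pytest.raises(ValueError, match="symmetric"):
            RDM(("a", "b"), np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError, match="diagonal"):
            RDM(("a", "b"), np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestISRSA:
    def test_identical_rdms_give_rho_one(self, rng):
        r = sim.parameter_rdm(rng.normal(size=10), rng.normal(size=10))
        res = sim.isrsa(r, r, n_perm=200, seed=0)
        assert res["rho"] == pytest.approx(1.0)
        assert res["p"] == pytest.approx(1 / 201)

    def test_rank_statistic_invariant_to_monotone_transform(self, rng):
        a = sim.parameter_rdm(rng.normal(size=12), rng.normal(size=12))
        m = a.matrix
        b = RDM(a.subject_ids, np.sqrt(m) + 3 * m)  # monotone on entries
        base = sim.isrsa(a, a, n_perm=100, seed=1)
        trans = sim.isrsa(a, b, n_perm=100, seed=1)
        assert trans["rho"] == pytest.approx(base["rho"])

    def test_p_value_range_and_low_perm_warning(self, rng):
        a = sim.parameter_rdm(rng.normal(size=8), rng.normal(size=8))
        b = sim.parameter_rdm(rng.normal(size=8), rng.normal(size=8))
        with pytest.warns(UserWarning, match="n_perm"):
            res = sim.isrsa(a, b, n_perm=50, seed=2)
        assert 1 / 51 <= res["p"] <= 1.0

    def test_subject_order_mismatch_rejected(self, rng):
        a = sim.parameter_rdm(rng.normal(size=5), rng.normal(size=5))
        b = sim.parameter_rdm(
            rng.normal(size=5), rng.normal(size=5), subject_ids=list("abcde")
        )
        with pytest.raises(ValueError, match="ordering"):
            sim.isrsa(a, b, n_perm=100)

    def test_planted_coupling_detected(self, planted_patterns):
        pat_a, pat_b, truth, pop = planted_patterns
        contrast = _pm(pat_a.values - pat_b.values, pat_a.subject_ids)
        prdm = sim.parameter_rdm(
            truth["theta"], truth["omega"], subject_ids=pat_a.subject_ids
        )
        res = sim.isrsa(prdm, sim.neural_rdm(contrast), n_perm=500, seed=3)
        assert res["rho"] > 0
        assert res["p"] < 0.05


class TestPatternSimilarity:
    def test_shared_signal_detected(self, planted_patterns):
        pat_a, pat_b, _, _ = planted_patterns
        res = sim.pattern_similarity(pat_a, pat_b, n_perm=500, seed=1)
        assert res["mean_z"] > 0
        assert res["p"] < 0.05

    def test_independent_patterns_centered_at_zero(self, rng):
        a = _pm(rng.normal(size=(14, 80)))
        b = _pm(rng.normal(size=(14, 80)))
        res = sim.pattern_similarity(a, b, n_perm=500, seed=2)
        assert abs(res["mean_z"]) < 0.2
        assert res["p"] > 0.01

    def test_perfect_correlation_clipped_and_flagged(self):
        v = np.vstack([np.arange(8.0) + i for i in range(4)])
        with pytest.warns(UserWarning, match="clipping"):
            res = sim.pattern_similarity(_pm(v), _pm(2 * v), n_perm=100, seed=3)
        assert np.isfinite(res["per_subject_z"]).all()

    def test_two_voxels_runs_with_warning(self, rng):
        a = _pm(rng.normal(size=(5, 2)))
        b = _pm(rng.normal(size=(5, 2)))
        with pytest.warns(UserWarning, match="voxels"):
            res = sim.pattern_similarity(a, b, n_perm=100, seed=4)
        assert "p" in res


class TestLosoDecoding:
    def test_separable_classes_decode_perfectly(self, planted_patterns):
        pat_a, pat_b, _, _ = planted_patterns
        res = sim.loso_decode(pat_a, pat_b, n_perm=100, seed=0)
        assert res["forced_choice_accuracy"] == 1.0
        assert res["auc"] > 0.9
        assert res["p"] < 0.05

    def test_null_patterns_near_chance(self, rng):
        accs = []
        for s in range(6):
            a = _pm(rng.normal(size=(10, 30)))
            b = _pm(rng.normal(size=(10, 30)))
            accs.append(
                sim.loso_decode(a, b, n_perm=30, seed=s)["forced_choice_accuracy"]
            )
        assert abs(np.mean(accs) - 0.5) < 0.2

    def test_swapping_conditions_preserves_accuracy(self, planted_patterns):
        pat_a, pat_b, _, _ = planted_patterns
        fwd = sim.loso_decode(pat_a, pat_b, n_perm=20, seed=1)
        rev = sim.loso_decode(pat_b, pat_a, n_perm=20, seed=1)
        assert fwd["forced_choice_accuracy"] == rev["forced_choice_accuracy"]

    def test_accuracy_invariant_to_global_scaling(self, planted_patterns):
        pat_a, pat_b, _, _ = planted_patterns
        res1 = sim.loso_decode(pat_a, pat_b, n_perm=10, seed=2)
        big_a = _pm(7.0 * pat_a.values, pat_a.subject_ids)
        big_b = _pm(7.0 * pat_b.values, pat_b.subject_ids)
        res2 = sim.loso_decode(big_a, big_b, n_perm=10, seed=2)
        assert res1["forced_choice_accuracy"] == res2["forced_choice_accuracy"]

    def test_input_validation(self, planted_patterns, rng):
        pat_a, pat_b, _, _ = planted_patterns
        with pytest.raises(ValueError, match="c_value"):
            sim.loso_decode(pat_a, pat_b, c_value=0.0, n_perm=10)
        tiny = _pm(rng.normal(size=(2, 5)))
        with pytest.raises(ValueError, match="3 subjects"):
            sim.loso_decode(tiny, tiny, n_perm=10)

    def test_estimator_wrapper(self, planted_patterns):
        pat_a, pat_b, _, _ = planted_patterns
        dec = LosoPatternDecoder(C=1.0, n_perm=20, seed=0).fit(pat_a, pat_b)
        assert dec.accuracy_ == 1.0
        assert dec.get_params()["C"] == 1.0
        assert dec.roc_points_.shape[1] == 2
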