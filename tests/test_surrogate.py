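"""Multi-fidelity GP: kernel algebra, posterior correctness, scaling contract."""

from __future__ import annotations

import numpy as np
import pytest

from conftest import make_state, random_fps
from mfbo.chemio import tanimoto_matrix
from mfbo.surrogate import (
    FidelitySchedule,
    Observation,
    SurrogateConfig,
    SurrogateState,
    fit_surrogate,
    kernel_matrix,
    pool_posterior,
    predict,
    predict_batch,
    scale_prediction_arrays,
    scaled_prediction,
    _nll_and_grad,
)


def dense_posterior_oracle(X, f, y, Xq, fq, amplitude, B, noises):
    """Textbook GP posterior via an explicit matrix inverse (independent route)."""
    K = amplitude * B[np.ix_(f, f)] * tanimoto_matrix(X, X)
    K = K + np.diag(noises[f])
    Ks = amplitude * B[np.ix_(fq, f)] * tanimoto_matrix(Xq, X)
    Kinv = np.linalg.inv(K)
    mean = Ks @ Kinv @ y
    prior = amplitude * B[fq, fq]
    var = prior - np.einsum("ij,jk,ik->i", Ks, Kinv, Ks)
    return mean, var


class TestSchedule:
    def test_default_costs(self):
        s = FidelitySchedule.default()
        assert tuple(s.costs) == (0.01, 0.2, 1.0) and s.budget == 10.0

    @pytest.mark.parametrize(
        "levels",
        [
            (("a", 0.5), ("b", 0.2), ("c", 1.0)),  # not increasing
            (("a", 0.1), ("b", 0.5)),  # top cost not 1.0
        ],
    )
    def test_invalid_levels(self, levels):
        with pytest.raises(ValueError):
            FidelitySchedule(levels=levels, budget=1.0)

    def test_nonpositive_budget(self):
        with pytest.raises(ValueError):
            FidelitySchedule(levels=(("a", 1.0),), budget=0.0)


class TestKernel:
    def test_single_pair_unit_B(self):
        fp = random_fps(1, seed=0)
        K = kernel_matrix(fp, fp, 2.5, np.ones((1, 1)), [0], [0])
        assert K.shape == (1, 1) and K[0, 0] == pytest.approx(2.5)

    def test_identity_B_blocks_cross_fidelity(self):
        fps = random_fps(2, seed=1)
        K = kernel_matrix(fps, fps, 1.0, np.eye(2), [0, 0], [1, 1])
        assert np.allclose(K, 0.0)

    def test_psd_on_random_fingerprints(self):
        fps = random_fps(20, seed=2)
        f = np.arange(20) % 3
        L = np.array([[1.0, 0.1], [0.8, 0.3], [0.5, 0.6]])
        B = L @ L.T + 0.1 * np.eye(3)
        K = kernel_matrix(fps, fps, 1.3, B, f, f)
        assert np.linalg.eigvalsh(K).min() >= -1e-8


class TestFit:
    def test_requires_observations(self):
        with pytest.raises(ValueError):
            fit_surrogate([], {}, 3)

    def test_lml_beats_default_start(self, tiny_library):
        fps = tiny_library.fingerprint_map()
        rng = np.random.default_rng(0)
        obs = []
        for mid in tiny_library.ids[:12]:
            for fid in range(3):
                obs.append(Observation(mid, fid, float(rng.normal())))
        state = fit_surrogate(obs, fps, 3, config=SurrogateConfig(n_restarts=2), seed=0)
        # optimizer contract: final log marginal likelihood >= a fixed reference
        X = np.vstack([fps[o.molecule_id] for o in obs])
        f = np.array([o.fidelity for o in obs])
        y = np.array([o.value for o in obs])
        y = (y - y.mean()) / y.std(ddof=1)
        theta0 = np.zeros(1 + 3 * 2 + 3 + 3)
        theta0[-3:] = np.log(0.1)
        ref_nll, _ = _nll_and_grad(theta0, tanimoto_matrix(X), f, y, 3, 2, 1e-6)
        assert state.log_marginal_likelihood >= -ref_nll - 1e-6

    def test_correlated_B_likelier_for_duplicated_values(self):
        # one molecule observed at two fidelities with identical values:
        # an all-ones coupling explains the data better than independence
        X = np.tile(random_fps(1, seed=3), (6, 1))
        X = np.vstack([X[:3], random_fps(3, seed=4)])
        f = np.array([0, 1, 0, 0, 1, 1])
        rng = np.random.default_rng(5)
        shared = rng.normal(size=3)
        y = np.array([shared[0], shared[0], shared[1], shared[2], shared[1], shared[2]])
        T = tanimoto_matrix(X)

        def nll_for_B(l_val):
            theta = np.zeros(1 + 2 * 2 + 2 + 2)
            theta[1:5] = [l_val, 0.0, l_val, 0.0]  # rank factor -> B off-diag
            theta[5:7] = np.log(1e-3)
            theta[7:9] = np.log(1e-4)
            return _nll_and_grad(theta, T, f, y, 2, 2, 1e-6)[0]

        assert nll_for_B(0.0) > nll_for_B(1.0)  # all-ones beats identity

    def test_single_fidelity_standardization(self):
        X = random_fps(3, seed=6)
        obs = [Observation(f"m{i}", 0, 4.2) for i in range(3)]
        fps = {f"m{i}": X[i] for i in range(3)}
        state = fit_surrogate(obs, fps, 1, config=SurrogateConfig(n_restarts=1), seed=0)
        # constant training values: prior mean equals the training mean, so a
        # far-away query returns that mean
        far = np.zeros((1, X.shape[1]), dtype=np.uint8)
        far[0, -1] = 1
        assert not np.array_equal(far[0], X[0])
        m, _ = predict_batch(state, far, [0])
        assert m[0] == pytest.approx(4.2, abs=1e-6)


class TestPosterior:
    def test_matches_dense_solve_oracle(self):
        X = random_fps(8, seed=10)
        f = np.array([0, 0, 1, 1, 2, 2, 0, 1])
        rng = np.random.default_rng(11)
        y = rng.normal(size=8)
        L = np.array([[1.0, 0.0], [0.7, 0.4], [0.5, 0.5]])
        B = L @ L.T + np.diag([0.2, 0.1, 0.3])
        noises = np.array([0.05, 0.02, 0.01])
        state = make_state(X, f, y, amplitude=1.4, B=B, noises=noises)
        Xq = random_fps(5, seed=12)
        fq = np.array([0, 1, 2, 1, 0])
        mean, var = predict_batch(state, Xq, fq)
        om, ov = dense_posterior_oracle(X, f, y, Xq, fq, 1.4, B, noises)
        assert np.allclose(mean, om, atol=1e-8)
        assert np.allclose(var, ov, atol=1e-8)

    def test_noise_floor_interpolates_training_points(self):
        X = random_fps(6, seed=13)
        f = np.array([0, 1, 2, 0, 1, 2])
        y = np.random.default_rng(14).normal(size=6)
        state = make_state(X, f, y, B=np.ones((3, 3)) + np.eye(3) * 0.01,
                           noises=np.full(3, 1e-8))
        mean, _ = predict_batch(state, X, f)
        assert np.allclose(mean, y, atol=1e-3)

    def test_unrelated_molecule_gets_prior(self):
        X = random_fps(4, seed=15)
        X[:, :8] = 0
        state = make_state(X, np.zeros(4, dtype=int), np.ones(4), amplitude=2.0,
                           B=np.ones((1, 1)), noises=np.array([0.1]), n_levels=1)
        far = np.zeros((1, X.shape[1]), dtype=np.uint8)
        far[0, 0] = 1  # shares no on-bit with any training molecule
        mean, var = predict_batch(state, far, [0])
        assert mean[0] == pytest.approx(0.0, abs=1e-12)
        assert var[0] == pytest.approx(2.0, abs=1e-12)

    def test_variance_nonnegative_everywhere(self):
        X = random_fps(10, seed=16)
        f = np.arange(10) % 3
        state = make_state(X, f, np.random.default_rng(17).normal(size=10))
        _, var = predict_batch(state, random_fps(50, seed=18), np.zeros(50, dtype=int))
        assert (var >= 0).all()

    def test_monotone_information(self):
        """Adding an observation at (x, f) never increases variance there."""
        X = random_fps(5, seed=19)
        f = np.array([0, 1, 2, 0, 1])
        y = np.zeros(5)
        state = make_state(X, f, y, B=np.ones((3, 3)) + 0.1 * np.eye(3))
        xq = random_fps(1, seed=20)
        before = predict(state, xq[0], 2).variance
        fps_map = {"new": xq[0]}
        state2 = state.with_observations([Observation("new", 2, 0.5)], fps_map)
        after = predict(state2, xq[0], 2).variance
        assert after <= before + 1e-12

    def test_cross_fidelity_transfer_stronger_with_coupling(self):
        """A low-fidelity observation at x cuts high-fidelity variance at x
        more under perfect coupling than under independence."""
        X = random_fps(3, seed=21)
        xq = random_fps(1, seed=22)[0]
        fps_map = {"new": xq}

        def high_var_after_low_obs(B):
            state = make_state(X, np.zeros(3, dtype=int), np.zeros(3), B=B)
            before = predict(state, xq, 2).variance
            state2 = state.with_observations([Observation("new", 0, 0.3)], fps_map)
            return before, predict(state2, xq, 2).variance

        b_ones, a_ones = high_var_after_low_obs(np.ones((3, 3)) + 1e-6 * np.eye(3))
        b_eye, a_eye = high_var_after_low_obs(np.eye(3))
        assert (b_ones - a_ones) > (b_eye - a_eye) + 1e-6

    def test_pool_posterior_consistent_with_predict(self):
        X = random_fps(6, seed=23)
        f = np.arange(6) % 3
        state = make_state(X, f, np.random.default_rng(24).normal(size=6),
                           B=np.ones((3, 3)) + 0.2 * np.eye(3))
        mols = random_fps(4, seed=25)
        pm = np.array([0, 1, 2, 3, 0, 1])
        pf = np.array([0, 0, 1, 1, 2, 2])
        mean, cov = pool_posterior(state, mols, pm, pf)
        m2, v2 = predict_batch(state, mols[pm], pf)
        assert np.allclose(mean, m2, atol=1e-10)
        assert np.allclose(np.diag(cov), v2, atol=1e-10)

    def test_unfitted_state_raises(self):
        state = SurrogateState(
            observations=[], ids=[], X=np.zeros((0, 8)), f=np.zeros(0, dtype=int),
            amplitude=1.0, B=np.eye(3), noises=np.full(3, 1e-6),
            y_mean=np.zeros(3), y_sd=np.ones(3), n_levels=3,
        )
        with pytest.raises(ValueError, match="not fitted"):
            predict_batch(state, random_fps(1), [0])


class TestScaling:
    def test_pool_max_scales_to_one(self):
        sm, _ = scale_prediction_arrays(
            np.array([8.0]), np.array([0.0]), np.array([2]),
            pool_min=np.array([0, 0, 4.0]), pool_max=np.array([1, 1, 8.0]),
            costs=np.array([0.01, 0.2, 1.0]),
        )
        assert sm[0] == 1.0

    def test_variance_cost_ratio(self):
        _, sv = scale_prediction_arrays(
            np.zeros(2), np.array([2.0, 2.0]), np.array([0, 2]),
            pool_min=np.zeros(3), pool_max=np.ones(3),
            costs=np.array([0.01, 0.2, 1.0]),
        )
        assert sv[0] / sv[1] == pytest.approx(100.0)

    def test_degenerate_pool_gives_half(self):
        sm, _ = scale_prediction_arrays(
            np.array([3.0]), np.array([1.0]), np.array([0]),
            pool_min=np.array([2.0]), pool_max=np.array([2.0]), costs=np.array([1.0]),
        )
        assert sm[0] == 0.5

    def test_scaled_prediction_wrapper(self):
        X = random_fps(4, seed=26)
        state = make_state(X, np.zeros(4, dtype=int), np.ones(4), n_levels=1,
                           B=np.ones((1, 1)))
        sched = FidelitySchedule(levels=(("high", 1.0),), budget=1.0)
        p = scaled_prediction(state, (np.array([0.0]), np.array([2.0])), X[0], 0, sched)
        assert 0.0 <= p.scaled_mean <= 1.0 and p.scaled_variance >= 0


class TestPersistence:
    def test_save_load_bit_identical(self, tmp_path, tiny_library):
        fps = tiny_library.fingerprint_map()
        rng = np.random.default_rng(1)
        obs = [
            Observation(mid, fid, float(rng.normal()))
            for mid in tiny_library.ids[:8]
            for fid in range(3)
        ]
        state = fit_surrogate(obs, fps, 3, config=SurrogateConfig(n_restarts=1), seed=3)
        state.save(tmp_path / "state")
        loaded = SurrogateState.load(tmp_path / "state")
        Xq = tiny_library.fingerprints[:10]
        fq = np.arange(10) % 3
        m1, v1 = predict_batch(state, Xq, fq)
        m2, v2 = predict_batch(loaded, Xq, fq)
        assert np.array_equal(m1, m2) and np.array_equal(v1, v2)
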