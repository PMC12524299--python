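import numpy as np
import pytest
import scipy.sparse.linalg

import tdsliking as tk
from tdsliking.esn import ESNParams, fit_readout, init_weights, readout_predict, run_reservoir


def loop_reservoir(w_in, w, u, leak, x0=None):
    """Hand-rolled recurrence oracle in exact per-step arithmetic order."""
    n = w.shape[0]
    x = np.zeros(n) if x0 is None else np.array(x0, float)
    out = []
    for t in range(u.shape[0]):
        x = (1.0 - leak) * x + leak * np.tanh(w @ x + w_in @ u[t])
        out.append(x.copy())
    return np.array(out)


class TestInitWeights:
    @pytest.mark.parametrize("n", [64, 128])
    def test_spectral_radius_enforced(self, n):
        params = ESNParams(n_neurons=n, spectral_radius=0.9, seed=3)
        _, w = init_weights(params, 12)
        # independent eigenvalue routine (ARPACK, largest magnitude)
        lam = scipy.sparse.linalg.eigs(w, k=1, which="LM", return_eigenvectors=False)
        assert abs(abs(lam[0]) - 0.9) < 1e-6

    def test_full_density_has_all_nonzeros(self):
        params = ESNParams(n_neurons=64, recurrent_density=1.0, seed=0)
        _, w = init_weights(params, 12)
        assert np.count_nonzero(w) == 64 * 64

    def test_sparse_density_roughly_matches(self):
        params = ESNParams(n_neurons=128, recurrent_density=0.1, seed=1)
        _, w = init_weights(params, 12)
        frac = np.count_nonzero(w) / w.size
        assert 0.07 < frac < 0.13

    def test_seed_determinism(self):
        params = ESNParams(n_neurons=32, seed=7)
        a_in, a = init_weights(params, 13)
        b_in, b = init_weights(params, 13)
        np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(a_in, b_in)
        c_in, c = init_weights(ESNParams(n_neurons=32, seed=8), 13)
        assert not np.array_equal(a, c)

    def test_param_validation(self):
        for bad in (
            dict(n_neurons=0),
            dict(spectral_radius=-1),
            dict(leak_rate=0),
            dict(leak_rate=1.5),
            dict(recurrent_density=0),
            dict(ridge=-1),
        ):
            with pytest.raises(ValueError):
                ESNParams(**bad)


class TestRunReservoir:
    def test_zero_input_stays_at_origin(self):
        w_in, w = init_weights(ESNParams(n_neurons=16, seed=0), 3)
        states = run_reservoir(w_in, w, np.zeros((20, 3)), leak_rate=1.0)
        np.testing.assert_array_equal(states, np.zeros((20, 16)))

    def test_one_step_closed_form(self):
        w_in, w = init_weights(ESNParams(n_neurons=16, seed=1), 5)
        u = np.zeros((1, 5))
        k = 2
        u[0, k] = 1.0
        states = run_reservoir(w_in, w, u, leak_rate=1.0)
        np.testing.assert_allclose(states[0], np.tanh(w_in[:, k]), atol=1e-15)

    @pytest.mark.parametrize("leak", [1.0, 0.6])
    def test_matches_loop_oracle(self, leak):
        # brute-force recurrence oracle on a small random model
        rng = np.random.default_rng(9)
        w_in, w = init_weights(ESNParams(n_neurons=5, seed=2), 4)
        u = rng.normal(size=(30, 4))
        got = run_reservoir(w_in, w, u, leak_rate=leak)
        want = loop_reservoir(w_in, w, u, leak)
        assert np.max(np.abs(got - want)) < 1e-12

    def test_batch_equals_sequential(self):
        rng = np.random.default_rng(4)
        w_in, w = init_weights(ESNParams(n_neurons=8, seed=5), 3)
        batch = rng.random((6, 15, 3))
        got = run_reservoir(w_in, w, batch)
        for s in range(6):
            # gemm vs gemv kernels differ at machine precision only
            np.testing.assert_allclose(
                got[s], run_reservoir(w_in, w, batch[s]), rtol=0, atol=1e-12
            )

    def test_nan_input_rejected(self):
        w_in, w = init_weights(ESNParams(n_neurons=4, seed=0), 2)
        u = np.zeros((5, 2))
        u[3, 1] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            run_reservoir(w_in, w, u)

    def test_width_mismatch_rejected(self):
        w_in, w = init_weights(ESNParams(n_neurons=4, seed=0), 2)
        with pytest.raises(ValueError, match="width"):
            run_reservoir(w_in, w, np.zeros((5, 3)))

    def test_echo_state_contractivity_probe(self):
        # two runs from different initial states on the same input converge
        rng = np.random.default_rng(77)
        params = ESNParams(n_neurons=128, spectral_radius=0.9, seed=11)
        w_in, w = init_weights(params, 13)
        for probe in range(3):
            u = rng.random((101, 13))  # dominance-proportion-scale inputs
            xa = rng.uniform(-1, 1, 128)
            xb = rng.uniform(-1, 1, 128)
            sa = run_reservoir(w_in, w, u, 1.0, initial_state=xa)
            sb = run_reservoir(w_in, w, u, 1.0, initial_state=xb)
            assert np.linalg.norm(sa[-1] - sb[-1]) < 1e-6


class TestFitReadout:
    def test_exact_interpolation_at_zero_ridge(self):
        rng = np.random.default_rng(0)
        states = rng.normal(size=(80, 10))
        coef = rng.normal(size=11)
        y = states @ coef[:-1] + coef[-1]
        w_out = fit_readout(states, y, ridge=0.0)
        resid = readout_predict(w_out, states) - y
        assert np.max(np.abs(resid)) < 1e-8

    def test_matches_normal_equations_oracle(self):
        # independent closed-form oracle via generic least squares on the
        # ridge-augmented system [X; sqrt(l) I]
        rng = np.random.default_rng(1)
        states = rng.normal(size=(60, 7))
        y = rng.normal(size=60)
        lam = 0.37
        x = np.hstack([states, np.ones((60, 1))])
        aug = np.vstack([x, np.sqrt(lam) * np.eye(8)])
        target = np.concatenate([y, np.zeros(8)])
        oracle, *_ = np.linalg.lstsq(aug, target, rcond=None)
        got = fit_readout(states, y, ridge=lam)
        assert np.max(np.abs(got - oracle)) < 1e-8

    def test_matches_sklearn_ridge(self):
        from sklearn.linear_model import Ridge

        rng = np.random.default_rng(2)
        states = rng.normal(size=(100, 12))
        y = rng.normal(size=100)
        lam = 1e-2
        x = np.hstack([states, np.ones((100, 1))])
        ref = Ridge(alpha=lam, fit_intercept=False, solver="cholesky").fit(x, y)
        got = fit_readout(states, y, ridge=lam)
        assert np.max(np.abs(got - ref.coef_)) < 1e-8

    def test_shrinkage_limit(self):
        rng = np.random.default_rng(3)
        states = rng.normal(size=(50, 5))
        y = rng.normal(size=50)
        w_out = fit_readout(states, y, ridge=1e12)
        assert np.max(np.abs(w_out)) < 1e-6

    def test_singular_system_advises_ridge(self):
        states = np.zeros((10, 3))  # rank-deficient with the bias column
        y = np.ones(10)
        with pytest.raises(ValueError, match="ridge"):
            fit_readout(states, y, ridge=0.0)

    def test_underdetermined_warns(self, caplog):
        import logging

        rng = np.random.default_rng(4)
        with caplog.at_level(logging.WARNING, logger="tdsliking.esn"):
            fit_readout(rng.normal(size=(5, 10)), rng.normal(size=5), ridge=1e-3)
        assert any("under-determined" in r.message for r in caplog.records)


class TestModelResults:
    def fit_small(self, small_dataset, **kw):
        replicates, conditions, _ = small_dataset
        train = [cs for cid in sorted(replicates) if cid != "plain-peanut"
                 for cs in replicates[cid]]
        model = tk.TemporalLikingESN(
            train, conditions, encoding="combo", n_neurons=32, seed=5, **kw
        )
        return model, model.fit(), replicates["plain-peanut"]

    def test_constant_memorization(self, small_dataset, conditions):
        # constant input + constant target 5 must be reproduced
        replicates, conditions, _ = small_dataset
        grid = tk.TimeGrid(101)
        flat = np.full((12, 101), 1 / 24)
        cs = tk.CurveSet(
            "plain",
            tk.TDSCurve(grid, flat, 1 - flat.sum(axis=0), n_trials=1),
            tk.TLCurve(grid, np.full(101, 5.0)),
            provenance="bootstrap-replicate",
        )
        model = tk.TemporalLikingESN([cs] * 4, conditions, encoding="none", n_neurons=16, seed=1)
        res = model.fit()
        pred = res.predict(cs)
        assert np.max(np.abs(np.asarray(pred) - 5.0)) < 1e-3

    def test_training_order_invariance(self, small_dataset):
        replicates, conditions, _ = small_dataset
        train = [cs for cid in sorted(replicates) if cid != "plain-peanut"
                 for cs in replicates[cid]]
        m1 = tk.TemporalLikingESN(train, conditions, encoding="combo", n_neurons=32, seed=5)
        r1 = m1.fit()
        rng = np.random.default_rng(0)
        perm = list(train)
        rng.shuffle(perm)
        m2 = tk.TemporalLikingESN(perm, conditions, encoding="combo", n_neurons=32, seed=5)
        r2 = m2.fit()
        np.testing.assert_allclose(r1.w_out, r2.w_out, rtol=1e-6, atol=1e-9)

    def test_predict_shapes_and_clipping(self, small_dataset):
        model, res, test = self.fit_small(small_dataset)
        raw = res.predict(test[0])
        assert isinstance(raw, np.ndarray) and raw.shape == (101,)
        clipped = res.predict(test[0], clip=True)
        assert isinstance(clipped, tk.TLCurve)
        assert clipped.liking.min() >= 0 and clipped.liking.max() <= 9
        batch = res.predict_many(test[:3])
        np.testing.assert_allclose(batch[0], raw, rtol=0, atol=1e-10)

    def test_summary_mentions_architecture(self, small_dataset):
        _, res, _ = self.fit_small(small_dataset)
        text = res.summary()
        assert "reservoir neurons" in text and "32" in text
        assert "combo" in text and "training RMSE" in text

    def test_save_load_round_trip(self, tmp_path, small_dataset):
        _, res, test = self.fit_small(small_dataset)
        path = tmp_path / "model.npz"
        res.save(path)
        back = tk.ESNResults.load(path, res.model.conditions)
        np.testing.assert_array_equal(back.w_out, res.w_out)
        np.testing.assert_array_equal(back.model.w, res.model.w)
        np.testing.assert_array_equal(back.predict(test[0]), res.predict(test[0]))

    def test_linear_target_recovery_beats_constant(self, small_dataset):
        # end-to-end parameter recovery at reduced scale: TL is a linear
        # functional of the current TDS vector plus small noise
        ds, conds = tk.linear_liking_dataset(seed=2, n_replicates=10)
        res = tk.evaluate_architecture(64, "combo", ds, conds, seed=2)
        base = tk.constant_baseline_result(ds, conds)
        assert res.pooled_median < 0.5 * base.pooled_median

    def test_empty_training_set_rejected(self, conditions):
        with pytest.raises(ValueError):
            tk.TemporalLikingESN([], conditions)
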