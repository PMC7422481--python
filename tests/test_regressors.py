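import numpy as np
import pytest
from sklearn.linear_model import Ridge

from tdlsr.label_codec import encode_labels
from tdlsr.regressors import (
    IncompatibleDomainsError,
    SourceKnowledge,
    centering_matrix,
    dlsr_update_W,
    dlsr_update_Zp,
    extract_source_knowledge,
    fit_dlsr,
    fit_lsr,
    fit_tdlsr,
    load_model,
    predict,
    save_model,
    solve_lsr,
    tdlsr_update_Z,
)

from .oracles import is_linearly_separable, numeric_offset_ridge, numeric_ridge


class TestCenteringMatrix:
    def test_small_cases(self):
        np.testing.assert_allclose(centering_matrix(1), [[0.0]])
        np.testing.assert_allclose(
            centering_matrix(2), [[0.5, -0.5], [-0.5, 0.5]]
        )

    def test_projector_identities(self):
        H = centering_matrix(7)
        np.testing.assert_allclose(H @ np.ones(7), np.zeros(7), atol=1e-12)
        np.testing.assert_allclose(H @ H, H, atol=1e-12)

    def test_rejects_nonpositive_size(self):
        with pytest.raises(ValueError):
            centering_matrix(0)


class TestSolveLSR:
    def test_identity_problem(self):
        model = solve_lsr(np.eye(2), np.eye(2), lam=1.0)
        np.testing.assert_allclose(model.Z, 0.5 * np.eye(2))
        np.testing.assert_allclose(model.p, 0.0)

    def test_huge_ridge_shrinks_to_zero(self, rng):
        X = rng.standard_normal((10, 3))
        Y = rng.standard_normal((10, 2))
        model = solve_lsr(X, Y, lam=1e8)
        assert np.linalg.norm(model.Z) < 1e-5

    def test_matches_numeric_minimizer(self, rng):
        X = rng.standard_normal((20, 5))
        Y = rng.standard_normal((20, 3))
        model = solve_lsr(X, Y, lam=0.1)
        np.testing.assert_allclose(model.Z, numeric_ridge(X, Y, 0.1), atol=1e-5)

    def test_matches_sklearn_ridge(self, rng):
        X = rng.standard_normal((25, 4))
        Y = rng.standard_normal((25, 2))
        ref = Ridge(alpha=0.7, fit_intercept=False).fit(X, Y)
        model = solve_lsr(X, Y, lam=0.7)
        np.testing.assert_allclose(model.Z, ref.coef_.T, atol=1e-8)

    def test_input_validation(self, rng):
        X = rng.standard_normal((5, 2))
        Y = np.eye(5)[:, :2]
        with pytest.raises(ValueError):
            solve_lsr(X, Y, lam=0.0)
        with pytest.raises(ValueError):
            solve_lsr(X, Y[:4], lam=1.0)
        with pytest.raises(ValueError):
            solve_lsr(X * np.nan, Y, lam=1.0)


class TestDlsrUpdateZp:
    def test_zero_features_give_column_means(self, rng):
        L = rng.standard_normal((6, 3))
        Z, p = dlsr_update_Zp(np.zeros((6, 2)), L, lam=0.5)
        np.testing.assert_allclose(Z, 0.0, atol=1e-12)
        np.testing.assert_allclose(p, L.mean(axis=0))

    def test_constant_targets_absorbed_by_offset(self, rng):
        X = rng.standard_normal((8, 3))
        r = np.array([2.0, -1.0])
        L = np.tile(r, (8, 1))
        Z, p = dlsr_update_Zp(X, L, lam=0.5)
        np.testing.assert_allclose(Z, 0.0, atol=1e-10)
        np.testing.assert_allclose(p, r, atol=1e-10)

    def test_matches_numeric_joint_minimizer(self, rng):
        X = rng.standard_normal((30, 4))
        L = rng.standard_normal((30, 2))
        Z, p = dlsr_update_Zp(X, L, lam=0.5)
        Z0, p0 = numeric_offset_ridge(X, L, 0.5)
        np.testing.assert_allclose(Z, Z0, atol=1e-5)
        np.testing.assert_allclose(p, p0, atol=1e-5)

    def test_stationarity(self, rng):
        X = rng.standard_normal((15, 3))
        L = rng.standard_normal((15, 2))
        Z, p = dlsr_update_Zp(X, L, lam=0.3)
        R = X @ Z + p[None, :] - L
        gZ = 2 * X.T @ R + 2 * 0.3 * Z
        gp = 2 * R.sum(axis=0)
        assert np.linalg.norm(gZ) + np.linalg.norm(gp) < 1e-8


class TestDlsrUpdateW:
    def test_signed_clamp_examples(self):
        Y = np.zeros((1, 2))
        # G values arranged via X@Z + p - Y with X = identity-free shortcut
        G = np.array([[0.5, -0.3]])
        B = np.array([[1.0, -1.0]])
        W = np.maximum(B * G, 0)
        np.testing.assert_allclose(W, [[0.5, 0.3]])
        G = np.array([[-0.2, 0.4]])
        np.testing.assert_allclose(np.maximum(B * G, 0), [[0.0, 0.0]])

    def test_through_public_interface(self, rng):
        X = rng.standard_normal((10, 3))
        Z = rng.standard_normal((3, 2))
        p = rng.standard_normal(2)
        enc = encode_labels(rng.integers(0, 2, size=10).tolist() + [0, 1])
        Y, B = enc.Y[:10], enc.B[:10]
        W = dlsr_update_W(X, Z, p, Y, B)
        G = X @ Z + p[None, :] - Y
        assert np.all(W >= 0)
        np.testing.assert_array_equal(W, np.maximum(B * G, 0))


class TestFitDlsr:
    def test_first_iteration_is_plain_ridge_on_Y(self, rng):
        from .conftest import random_instance

        X, labels = random_instance(rng)
        enc = encode_labels(labels)
        model, trace = fit_dlsr(X, labels, lam=0.5, max_iter=1)
        Z0, p0 = dlsr_update_Zp(X, enc.Y, lam=0.5)
        np.testing.assert_array_equal(model.Z, Z0)
        np.testing.assert_array_equal(model.p, p0)
        assert trace.n_iterations == 1 and not trace.converged

    def test_separable_blobs_reach_perfect_training_accuracy(self):
        rng = np.random.default_rng(7)
        X = np.vstack([
            rng.standard_normal((20, 2)) * 0.3 + [3, 0],
            rng.standard_normal((20, 2)) * 0.3 + [-3, 0],
        ])
        y = np.repeat([0, 1], 20)
        assert is_linearly_separable(X, y)
        model, _ = fit_dlsr(X, y, lam=0.01)
        assert np.mean(model.predict(X) == y) == 1.0

    def test_trace_converges_and_is_monotone(self, rng):
        from .conftest import random_instance

        X, labels = random_instance(rng)
        model, trace = fit_dlsr(X, labels, lam=0.1, max_iter=200, tol=1e-10)
        J = np.asarray(trace.objective_values)
        assert np.all(np.diff(J) <= 1e-9 * np.maximum(1.0, J[:-1]))
        assert trace.converged

    def test_stationarity_at_convergence(self, rng):
        from .conftest import random_instance

        X, labels = random_instance(rng)
        enc = encode_labels(labels)
        model, _ = fit_dlsr(X, labels, lam=0.1, max_iter=500, tol=1e-14)
        W = dlsr_update_W(X, model.Z, model.p, enc.Y, enc.B)
        L = enc.Y + enc.B * W
        R = X @ model.Z + model.p[None, :] - L
        gZ = 2 * X.T @ R + 2 * 0.1 * model.Z
        gp = 2 * R.sum(axis=0)
        gnorm = np.sqrt(np.linalg.norm(gZ) ** 2 + np.linalg.norm(gp) ** 2)
        assert gnorm <= 1e-6 * (1 + np.linalg.norm(L))


class TestTdlsrUpdateZ:
    def test_eta_zero_reduces_to_dlsr_update(self, rng):
        X = rng.standard_normal((12, 3))
        L = rng.standard_normal((12, 2))
        Z_s = rng.standard_normal((3, 2))
        Z0, p0 = dlsr_update_Zp(X, L, lam=0.4)
        Z1, p1 = tdlsr_update_Z(X, L, lam=0.4, eta=0.0, Z_s=Z_s)
        np.testing.assert_array_equal(Z0, Z1)
        np.testing.assert_array_equal(p0, p1)

    def test_huge_eta_pins_Z_to_source(self, rng):
        X = rng.standard_normal((12, 3))
        L = rng.standard_normal((12, 2))
        Z_s = rng.standard_normal((3, 2))
        Z, _ = tdlsr_update_Z(X, L, lam=0.4, eta=1e8, Z_s=Z_s)
        np.testing.assert_allclose(Z, Z_s, atol=1e-4)

    def test_matches_numeric_three_term_minimizer(self, rng):
        X = rng.standard_normal((18, 4))
        L = rng.standard_normal((18, 3))
        Z_s = rng.standard_normal((4, 3))
        Z, p = tdlsr_update_Z(X, L, lam=0.7, eta=2.0, Z_s=Z_s)
        Z0, p0 = numeric_offset_ridge(X, L, 0.7, eta=2.0, Z_s=Z_s)
        np.testing.assert_allclose(Z, Z0, atol=1e-5)
        np.testing.assert_allclose(p, p0, atol=1e-5)

    def test_source_gap_shrinks_with_eta(self, rng):
        X = rng.standard_normal((20, 4))
        L = rng.standard_normal((20, 2))
        Z_s = rng.standard_normal((4, 2))
        gaps = []
        for eta in 10.0 ** np.arange(-4, 9):
            Z, _ = tdlsr_update_Z(X, L, lam=0.5, eta=eta, Z_s=Z_s)
            gaps.append(np.linalg.norm(Z - Z_s))
        assert all(b <= a + 1e-12 for a, b in zip(gaps, gaps[1:]))

    def test_bad_source_shape_rejected(self, rng):
        X = rng.standard_normal((10, 3))
        L = rng.standard_normal((10, 2))
        with pytest.raises(ValueError, match="Z_s"):
            tdlsr_update_Z(X, L, lam=0.5, eta=1.0, Z_s=np.zeros((4, 2)))


class TestFitTdlsr:
    def test_eta_zero_reproduces_dlsr_run(self, rng):
        from .conftest import random_instance

        X, labels = random_instance(rng)
        Z_s = rng.standard_normal((X.shape[1], len(set(labels.tolist()))))
        m0, t0 = fit_dlsr(X, labels, lam=0.2)
        m1, t1 = fit_tdlsr(X, labels, Z_s, lam=0.2, eta=0.0)
        np.testing.assert_array_equal(m0.Z, m1.Z)
        np.testing.assert_array_equal(m0.p, m1.p)
        np.testing.assert_array_equal(t0.objective_values, t1.objective_values)

    def test_zero_source_knowledge_acts_as_extra_ridge(self, rng):
        from .conftest import random_instance

        X, labels = random_instance(rng)
        C = len(set(labels.tolist()))
        m0, t0 = fit_tdlsr(X, labels, np.zeros((X.shape[1], C)), lam=0.3, eta=0.7)
        m1, t1 = fit_dlsr(X, labels, lam=1.0)
        np.testing.assert_allclose(m0.Z, m1.Z, atol=1e-12)
        np.testing.assert_allclose(
            t0.objective_values, t1.objective_values, rtol=1e-12
        )

    def test_class_set_mismatch_raises(self, rng):
        X = rng.standard_normal((10, 3))
        sk = SourceKnowledge(
            Z_s=np.zeros((3, 2)), class_index_map={"a": 0, "b": 1}
        )
        with pytest.raises(IncompatibleDomainsError):
            fit_tdlsr(X, [0, 1] * 5, sk, lam=0.5, eta=1.0)
        with pytest.raises(IncompatibleDomainsError):
            fit_tdlsr(X, [0, 1, 2] + [0] * 7, np.zeros((3, 2)), lam=0.5, eta=1.0)

    def test_transfer_helps_when_target_data_scarce(self):
        """With 2 target points/class from the source distribution, pulling
        toward Z_s beats fitting the tiny target sample alone (20 seeds)."""
        from tdlsr.synthetic import make_domain_pair

        gain = []
        for seed in range(20):
            pair = make_domain_pair(
                C=2, d=8, n_source_per_class=75, n_target_per_class=10,
                shift_kind="identical", test_fraction=0.8, seed=seed,
            )
            sk = extract_source_knowledge(
                pair.source.X, pair.source.labels, lam=0.01
            )
            td, _ = fit_tdlsr(
                pair.target_train.X, pair.target_train.labels, sk,
                lam=0.01, eta=1.0,
            )
            dl, _ = fit_dlsr(pair.target_train.X, pair.target_train.labels, lam=0.01)
            y = pair.target_test.labels
            gain.append(
                np.mean(td.predict(pair.target_test.X) == y)
                - np.mean(dl.predict(pair.target_test.X) == y)
            )
        assert np.mean(gain) >= 0.0


class TestSourceKnowledgeAndPredict:
    def test_extraction_is_deterministic_with_provenance(self, rng):
        X = rng.standard_normal((30, 4))
        labels = np.tile([0, 1, 2], 10)
        a = extract_source_knowledge(X, labels, lam=0.1)
        b = extract_source_knowledge(X, labels, lam=0.1)
        np.testing.assert_array_equal(a.Z_s, b.Z_s)
        assert a.Z_s.shape == (4, 3)
        assert a.provenance["estimator"] == "dlsr"
        c = extract_source_knowledge(X, labels, lam=0.1, estimator="lsr")
        assert c.provenance["estimator"] == "lsr"

    def test_zero_model_predicts_first_class(self, rng):
        model = fit_lsr(rng.standard_normal((6, 2)), [0, 1] * 3, lam=1.0)
        model.Z[:] = 0.0
        model.p[:] = 0.0
        assert set(predict(model, rng.standard_normal((4, 2)))) == {0}

    def test_empty_input_gives_empty_output(self, rng):
        model = fit_lsr(rng.standard_normal((6, 2)), [0, 1] * 3, lam=1.0)
        assert len(predict(model, np.zeros((0, 2)))) == 0

    def test_dimension_mismatch_raises(self, rng):
        model = fit_lsr(rng.standard_normal((6, 2)), [0, 1] * 3, lam=1.0)
        with pytest.raises(ValueError):
            predict(model, np.zeros((3, 5)))


class TestSerialization:
    def test_round_trip(self, rng, tmp_path):
        X = rng.standard_normal((20, 3))
        labels = np.tile([2, 5], 10)
        sk = extract_source_knowledge(X, labels, lam=0.1)
        model, _ = fit_tdlsr(X, labels.tolist(), sk, lam=0.1, eta=0.5)
        path = tmp_path / "model.json"
        save_model(model, path, provenance={"note": "unit test"})
        loaded = load_model(path)
        np.testing.assert_allclose(loaded.Z, model.Z)
        np.testing.assert_allclose(loaded.p, model.p)
        assert loaded.class_index_map == model.class_index_map
        assert loaded.model_kind == "tdlsr"
        assert loaded.lam == 0.1 and loaded.eta == 0.5
        np.testing.assert_array_equal(
            loaded.predict(X), model.predict(X)
        )
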