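import numpy as np
import pytest

from concord.outliers import (
    ARCHITECTURES,
    Autoencoder,
    OutlierModelSpec,
    fit_and_flag,
    make_autoencoder,
    select_clean_by_error,
)


def lof_brute_force(X: np.ndarray, k: int) -> np.ndarray:
    """Direct transliteration of the local-outlier-factor definition:
    k-distance, reachability distance, local reachability density, LOF."""
    n = len(X)
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(D, np.inf)
    kdist = np.sort(D, axis=1)[:, k - 1]
    neighborhoods = [np.where(D[i] <= kdist[i])[0] for i in range(n)]

    def reachdist(p, o):
        return max(kdist[o], D[p, o])

    lrd = np.empty(n)
    for p in range(n):
        Np = neighborhoods[p]
        lrd[p] = 1.0 / (np.mean([reachdist(p, o) for o in Np]))
    lof = np.empty(n)
    for p in range(n):
        Np = neighborhoods[p]
        lof[p] = np.mean([lrd[o] for o in Np]) / lrd[p]
    return lof


class TestTraditionalDetectors:
    def test_isolation_forest_flags_far_row(self, rng):
        X = np.vstack([np.tile(rng.random(7), (99, 1)),
                       np.full((1, 7), 10.0)])
        _, flags, scores = fit_and_flag(
            OutlierModelSpec("isolation_forest"), X, seed=0
        )
        assert flags[99]
        assert scores[99] == scores.max()

    def test_contamination_sets_flag_fraction(self, rng):
        X = rng.normal(size=(100, 7))
        _, flags, _ = fit_and_flag(
            OutlierModelSpec("isolation_forest", contamination=0.1), X, seed=0
        )
        assert 5 <= flags.sum() <= 20  # ~10 rows at the threshold rule

    def test_lof_matches_direct_transliteration(self, rng):
        # brute-force oracle on <= 30 points, via the sklearn-backed path
        from sklearn.neighbors import LocalOutlierFactor

        for trial in range(3):
            X = rng.normal(size=(25, 3))
            k = 5
            det = LocalOutlierFactor(n_neighbors=k)
            det.fit(X)
            ours = -det.negative_outlier_factor_
            ref = lof_brute_force(X, k)
            np.testing.assert_allclose(ours, ref, rtol=1e-8)

    def test_lof_isolates_distant_point(self):
        X = np.array([[0.0], [1.0], [2.0], [100.0]])
        ref = lof_brute_force(X, 2)
        assert ref[3] > 10
        assert np.all(ref[:3] < 2)

    def test_too_few_rows_advises_accumulation(self):
        with pytest.raises(ValueError, match="accumulate"):
            fit_and_flag(OutlierModelSpec("ocsvm"), np.zeros((4, 7)))

    def test_refit_reproduces_flags(self, rng):
        X = rng.random((80, 7))
        for family in ("isolation_forest", "ocsvm", "lof"):
            _, f1, s1 = fit_and_flag(OutlierModelSpec(family), X, seed=3)
            _, f2, s2 = fit_and_flag(OutlierModelSpec(family), X, seed=3)
            assert (f1 == f2).all()
            np.testing.assert_allclose(s1, s2)

    def test_invalid_contamination_rejected(self):
        with pytest.raises(ValueError):
            OutlierModelSpec("isolation_forest", contamination=0.7)


class TestAutoencoder:
    def test_identical_rows_reconstructed_near_zero_error(self, rng):
        X = np.tile(rng.random(7), (1024, 1))
        ae = make_autoencoder("AE1", "small", random_state=1).fit(X)
        assert ae.reconstruction_errors(X).mean() < 0.01

    @pytest.mark.parametrize(
        "name,latent", [("AE1", 3), ("AE1_L1", 7), ("AE2", 3), ("AE3", 3)]
    )
    def test_bottleneck_width(self, name, latent, rng):
        X = rng.random((64, 7))
        ae = make_autoencoder(name, "small", random_state=0).fit(X)
        assert ae.transform(X).shape == (64, latent)

    def test_architecture_table(self):
        assert ARCHITECTURES["AE2"] == (7, 5, 3, 5, 7)
        assert ARCHITECTURES["AE2_L1"] == (7, 7, 7, 7, 7)
        assert ARCHITECTURES["AE3"] == (7, 6, 5, 3, 5, 6, 7)

    def test_deep_architecture_encodes_to_three(self, rng):
        X = rng.random((50, 7))
        ae = Autoencoder((7, 6, 5, 3, 5, 6, 7), epochs=5, random_state=0).fit(X)
        assert ae.transform(X).shape[1] == 3

    def test_sparsity_penalty_shrinks_bottleneck(self, rng):
        X = rng.random((300, 7))
        kw = dict(epochs=100, learning_rate=0.01, random_state=3)
        sparse = Autoencoder((7, 7, 7), l1_weight=1e-3, **kw).fit(X)
        plain = Autoencoder((7, 7, 7), l1_weight=0.0, **kw).fit(X)
        assert (
            np.abs(sparse.transform(X)).mean() < np.abs(plain.transform(X)).mean()
        )

    def test_reconstruction_errors_nonnegative_and_zero_on_fixed_point(self, rng):
        X = rng.random((40, 7))
        ae = make_autoencoder("AE1", "small", random_state=2).fit(X)
        err = ae.reconstruction_errors(X)
        assert (err >= 0).all()
        recon = ae.reconstruct(X)
        np.testing.assert_allclose(
            ae.reconstruction_errors(recon),
            np.mean((recon - ae.reconstruct(recon)) ** 2, axis=1),
        )

    def test_planted_far_rows_rank_highest(self, rng):
        X = np.clip(rng.normal(0.3, 0.05, size=(95, 7)), 0, 1)
        planted = np.clip(rng.normal(0.9, 0.02, size=(5, 7)), 0, 1)
        ae = make_autoencoder("AE1", "small", random_state=2).fit(np.vstack([X, planted]))
        err = ae.reconstruction_errors(np.vstack([X, planted]))
        assert set(np.argsort(-err)[:5]) == {95, 96, 97, 98, 99}

    def test_training_reproducible_from_seed(self, rng):
        X = rng.random((100, 7))
        e1 = make_autoencoder("AE2", "small", random_state=5).fit(X).reconstruction_errors(X)
        e2 = make_autoencoder("AE2", "small", random_state=5).fit(X).reconstruction_errors(X)
        np.testing.assert_allclose(e1, e2)

    def test_loss_decreases_overall(self, rng):
        X = rng.random((200, 7))
        ae = make_autoencoder("AE2", "small", random_state=1).fit(X)
        assert ae.loss_history_[-1] < ae.loss_history_[0]

    def test_asymmetric_architecture_rejected(self, rng):
        with pytest.raises(ValueError, match="symmetric"):
            Autoencoder((7, 3, 5, 7)).fit(rng.random((20, 7)))

    def test_wrong_width_rejected(self, rng):
        with pytest.raises(ValueError):
            Autoencoder((7, 3, 7)).fit(rng.random((20, 5)))


class TestSelectCleanByError:
    def test_keeps_lowest_errors(self):
        mask = select_clean_by_error(np.array([0.1, 0.2, 0.9, 0.05]), 0.75)
        assert list(np.where(mask)[0]) == [0, 1, 3]

    def test_keep_all(self):
        assert select_clean_by_error(np.array([3.0, 1.0]), 1.0).all()

    def test_tie_at_boundary_prefers_lower_index(self):
        mask = select_clean_by_error(np.array([0.5, 0.5, 0.5, 0.5]), 0.5)
        assert list(np.where(mask)[0]) == [0, 1]

    def test_empty_input(self):
        assert select_clean_by_error(np.array([]), 0.5).size == 0

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            select_clean_by_error(np.array([1.0]), 0.0)


class TestPersistence:
    def test_save_load_preserves_reconstruction(self, tmp_path, rng):
        from concord.outliers import load_autoencoder, save_autoencoder

        X = rng.random((60, 7))
        ae = make_autoencoder("AE2", "small", random_state=4).fit(X)
        p = tmp_path / "model.json"
        save_autoencoder(ae, p)
        back = load_autoencoder(p)
        np.testing.assert_allclose(
            back.reconstruction_errors(X), ae.reconstruction_errors(X)
        )
        assert back.layer_dims == ae.layer_dims
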