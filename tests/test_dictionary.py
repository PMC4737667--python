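"""Online dictionary learning: init, constrained updates, convergence, recovery."""

import numpy as np
import pytest

from sparsenets import (
    Dictionary,
    InsufficientDataError,
    ODLConfig,
    SurrogateStats,
    default_lam,
    init_dictionary,
    learn_dictionary,
    sparse_code_all,
    update_dictionary,
)
from sparsenets.dictionary import surrogate_value


def planted_factorization(rng, m=20, k0=4, n=300, noise=0.01):
    """S = D0 @ A0 + noise with well-separated unit atoms and sparse codes."""
    D0 = rng.normal(size=(m, k0))
    D0, _ = np.linalg.qr(D0)  # orthonormal -> maximally separated
    A0 = np.zeros((k0, n))
    which = rng.integers(k0, size=n)
    A0[which, np.arange(n)] = rng.uniform(1.0, 3.0, size=n)
    S = D0 @ A0 + noise * rng.normal(size=(m, n))
    return S, D0, A0


class TestInit:
    def test_k_equals_n_is_column_permutation(self):
        rng = np.random.default_rng(0)
        S = rng.normal(size=(6, 8))
        D = init_dictionary(S, 8, seed=1)
        normalized = S / np.maximum(np.linalg.norm(S, axis=0), 1.0)
        # every atom appears among the normalized columns
        for j in range(8):
            dists = np.linalg.norm(normalized - D.atoms[:, j : j + 1], axis=0)
            assert dists.min() < 1e-12

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(1)
        S = rng.normal(size=(10, 100))
        D1 = init_dictionary(S, 5, seed=7)
        D2 = init_dictionary(S, 5, seed=7)
        np.testing.assert_array_equal(D1.atoms, D2.atoms)

    def test_atom_norms_in_unit_ball(self):
        rng = np.random.default_rng(2)
        S = rng.normal(size=(10, 100))
        norms = init_dictionary(S, 5, seed=3).atom_norms()
        assert np.all(norms > 0)
        assert np.all(norms <= 1 + 1e-12)

    def test_too_few_columns_rejected(self):
        with pytest.raises(InsufficientDataError):
            init_dictionary(np.ones((4, 3)), 5, seed=0)


class TestUpdate:
    def test_fixed_point_at_exact_codes(self):
        """Orthonormal D coding its own exact signals is stationary (λ→0)."""
        rng = np.random.default_rng(3)
        D0, _ = np.linalg.qr(rng.normal(size=(8, 4)))
        A0 = rng.uniform(1.0, 2.0, size=(4, 50)) * (rng.random((4, 50)) < 0.4)
        S = D0 @ A0
        stats = SurrogateStats.zeros(8, 4)
        stats.accumulate(S, A0)
        D1 = update_dictionary(Dictionary(atoms=D0), stats)
        np.testing.assert_allclose(D1.atoms, D0, atol=1e-6)

    def test_unused_atom_unchanged(self):
        rng = np.random.default_rng(4)
        D = Dictionary(atoms=rng.normal(size=(6, 3)) / 3.0)
        codes = np.zeros((3, 20))
        codes[0] = rng.normal(size=20)
        codes[2] = rng.normal(size=20)
        S = D.atoms @ codes
        stats = SurrogateStats.zeros(6, 3)
        stats.accumulate(S, codes)
        assert stats.A[1, 1] == 0.0
        D1 = update_dictionary(D, stats)
        np.testing.assert_array_equal(D1.atoms[:, 1], D.atoms[:, 1])

    @pytest.mark.parametrize("seed", range(5))
    def test_surrogate_never_increases(self, seed):
        rng = np.random.default_rng(20 + seed)
        D = Dictionary(atoms=rng.normal(size=(7, 5)) / 3.0)
        codes = rng.normal(size=(5, 40)) * (rng.random((5, 40)) < 0.5)
        S = rng.normal(size=(7, 40))
        stats = SurrogateStats.zeros(7, 5)
        stats.accumulate(S, codes)
        before = surrogate_value(D, stats)
        after = surrogate_value(update_dictionary(D, stats), stats)
        assert after <= before + 1e-8

    def test_norm_constraint_after_update(self):
        rng = np.random.default_rng(6)
        D = Dictionary(atoms=rng.normal(size=(7, 5)))
        codes = rng.normal(size=(5, 40))
        stats = SurrogateStats.zeros(7, 5)
        stats.accumulate(rng.normal(size=(7, 40)), codes)
        norms = update_dictionary(D, stats).atom_norms()
        assert np.all(norms <= 1 + 1e-10)

    def test_non_finite_stats_rejected(self):
        D = Dictionary(atoms=np.eye(3))
        stats = SurrogateStats(A=np.full((3, 3), np.nan), B=np.zeros((3, 3)), t=1)
        with pytest.raises(ValueError):
            update_dictionary(D, stats)


class TestLearn:
    def test_recovers_planted_atoms(self):
        rng = np.random.default_rng(7)
        S, D0, _ = planted_factorization(rng)
        cfg = ODLConfig(k=4, lam=0.05, batch_size=50, n_epochs=8, seed=0)
        fit = learn_dictionary(S, cfg)
        # compare up to permutation and sign via greedy max-|cosine|
        sims = np.abs(D0.T @ fit.dictionary.atoms)
        matched = []
        free = set(range(4))
        for i in range(4):
            j = max(free, key=lambda j: sims[i, j])
            matched.append(sims[i, j])
            free.remove(j)
        assert min(matched) >= 0.95

    def test_zero_epochs_returns_initial_dictionary(self):
        rng = np.random.default_rng(8)
        S = rng.normal(size=(10, 60))
        cfg = ODLConfig(k=5, lam=0.1, n_epochs=0, seed=3)
        fit = learn_dictionary(S, cfg)
        np.testing.assert_array_equal(
            fit.dictionary.atoms, init_dictionary(S, 5, seed=3).atoms
        )
        np.testing.assert_allclose(
            fit.coefficients, sparse_code_all(S, fit.dictionary, 0.1), atol=1e-12
        )

    def test_deterministic_trajectory(self):
        rng = np.random.default_rng(9)
        S = rng.normal(size=(12, 120))
        cfg = ODLConfig(k=6, lam=0.1, batch_size=40, n_epochs=3, seed=5)
        f1 = learn_dictionary(S, cfg)
        f2 = learn_dictionary(S, cfg)
        np.testing.assert_array_equal(f1.dictionary.atoms, f2.dictionary.atoms)
        np.testing.assert_array_equal(f1.coefficients, f2.coefficients)

    def test_unpacks_as_tuple(self):
        rng = np.random.default_rng(10)
        S = rng.normal(size=(8, 40))
        D, alpha = learn_dictionary(S, ODLConfig(k=4, lam=0.1, n_epochs=1, seed=0))
        assert D.atoms.shape == (8, 4)
        assert alpha.shape == (4, 40)

    def test_norm_constraint_throughout_training(self):
        rng = np.random.default_rng(11)
        S, _, _ = planted_factorization(rng, n=200)
        max_norms = []
        learn_dictionary(
            S,
            ODLConfig(k=4, lam=0.05, batch_size=64, n_epochs=3, seed=1),
            callback=lambda D: max_norms.append(D.atom_norms().max()),
        )
        assert max_norms  # callback fired after every update
        assert max(max_norms) <= 1 + 1e-10

    def test_objective_non_increasing_across_epochs(self, small_signals):
        from sparsenets import normalize_signals

        S = normalize_signals(small_signals)
        cfg = ODLConfig(k=12, batch_size=256, n_epochs=4, seed=2)
        fit = learn_dictionary(S, cfg)
        objs = fit.epoch_objectives
        assert len(objs) == 4
        for a, b in zip(objs, objs[1:]):
            assert b <= a * 1.01

    def test_warns_outside_overcomplete_regime(self):
        rng = np.random.default_rng(12)
        S = rng.normal(size=(20, 30))
        with pytest.warns(UserWarning):
            learn_dictionary(S, ODLConfig(k=4, lam=0.1, n_epochs=0, seed=0))


def test_default_lam_formula():
    rng = np.random.default_rng(13)
    S = rng.normal(size=(16, 50))
    expected = np.median(np.linalg.norm(S, axis=0)) / 4.0
    assert default_lam(S) == pytest.approx(expected, rel=1e-12)
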