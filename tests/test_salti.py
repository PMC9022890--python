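"""Spatial mixture model, decay grid, and the Lambda scan."""

import numpy as np
import pytest

from saltiscan.lassi import distorted_spectrum, epsilon_grid, lassi_T
from saltiscan.salti import (
    build_A_grid,
    decay_alpha,
    loglik_alt,
    loglik_null,
    make_grids,
    mixture_spectrum,
    salti_scan,
)

from _oracle import oracle_fit
from conftest import random_background


class TestDecayAlpha:
    def test_unity_at_the_target(self):
        assert decay_alpha(0.5, 3.0, 3.0) == 1.0

    def test_slow_decay_endpoint_definition(self):
        # A_min is defined so that alpha at the closest window pair is 0.99999
        d_min = 7.3
        A_min = -np.log(0.99999) / d_min
        assert decay_alpha(A_min, 0.0, d_min) == pytest.approx(0.99999, abs=1e-12)

    def test_half_life(self):
        assert decay_alpha(np.log(2) / 5.0, 0.0, 5.0) == pytest.approx(0.5)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            decay_alpha(0.0, 0.0, 1.0)

    def test_monotone_in_distance_and_rate(self):
        d = np.linspace(0, 10, 11)
        a1 = [decay_alpha(0.3, x, 0.0) for x in d]
        a2 = [decay_alpha(0.6, x, 0.0) for x in d]
        assert np.all(np.diff(a1) <= 0)
        assert np.all(np.asarray(a2)[1:] <= np.asarray(a1)[1:])


class TestAGrid:
    def test_unit_spacing_endpoints(self):
        g = build_A_grid(coords=np.arange(10.0))
        assert g.d_min == 1.0
        assert g.A_min == pytest.approx(-np.log(0.99999), rel=1e-12)
        assert g.A_max == pytest.approx(-np.log(0.00001), rel=1e-12)
        assert g.A_min == pytest.approx(1.0000050000e-5, abs=1e-14)
        assert g.A_max == pytest.approx(11.5129254650, abs=1e-9)
        assert len(g.values) == 100
        assert np.all(np.diff(g.values) > 0)

    def test_endpoints_scale_inversely_with_spacing(self):
        g1 = build_A_grid(coords=np.arange(5.0))
        g1000 = build_A_grid(coords=np.arange(5.0) * 1000)
        assert g1000.A_min == pytest.approx(g1.A_min / 1000, rel=1e-12)
        assert g1000.A_max == pytest.approx(g1.A_max / 1000, rel=1e-12)

    def test_d_min_is_minimum_adjacent_gap(self):
        g = build_A_grid(coords=np.array([0.0, 10.0, 13.0, 30.0]))
        assert g.d_min == 3.0

    def test_duplicate_coordinates_rejected(self):
        with pytest.raises(ValueError, match="dedup"):
            build_A_grid(coords=np.array([0.0, 1.0, 1.0]))


class TestMixtureAndLikelihoods:
    def test_mixture_endpoints_and_midpoint(self):
        p = np.array([0.6, 0.4])
        q = np.array([0.9, 0.1])
        np.testing.assert_allclose(mixture_spectrum(p, q, 1.0), q)
        np.testing.assert_allclose(mixture_spectrum(p, q, 0.0), p)
        np.testing.assert_allclose(mixture_spectrum(p, q, 0.5), [0.75, 0.25])

    def test_null_loglik_hand_value(self):
        ll = loglik_null(np.array([[3.0, 1.0]]), np.array([0.75, 0.25]))
        assert ll == pytest.approx(3 * np.log(0.75) + np.log(0.25), abs=1e-9)

    def test_null_loglik_zero_counts_and_additivity(self):
        p = np.array([0.7, 0.3])
        assert loglik_null(np.zeros((3, 2)), p) == 0.0
        one = loglik_null(np.array([[5.0, 2.0]]), p)
        two = loglik_null(np.array([[5.0, 2.0], [5.0, 2.0]]), p)
        assert two == pytest.approx(2 * one, rel=1e-14)

    def test_alt_single_window_reduces_to_distorted_loglik(self):
        p = np.array([0.5, 0.3, 0.2])
        q = distorted_spectrum(p, 1, 0.1)
        x = np.array([[30.0, 6.0, 4.0]])
        ll = loglik_alt(x, np.array([0.0]), p, q, A=0.7, i_star=0)
        assert ll == pytest.approx(float(x[0] @ np.log(q)), rel=1e-14)

    def test_alt_approaches_null_far_from_target_at_fast_decay(self):
        # at A_max every non-target window has alpha <= 1e-5: per-window
        # mixtures converge to p, so L1 - (target term) approaches L0 - (target null term)
        p = np.array([0.5, 0.3, 0.2])
        q = distorted_spectrum(p, 1, 0.1)
        z = np.arange(6.0)
        X = np.tile(40 * p, (6, 1))
        grid = build_A_grid(coords=z)
        ll = loglik_alt(X, z, p, q, A=grid.A_max, i_star=0)
        target_term = float(X[0] @ np.log(q))
        off_null = float(X[1:].sum(axis=0) @ np.log(p))
        assert ll == pytest.approx(target_term + off_null, abs=1e-2)
        mix = np.exp(-grid.A_max * 1.0) * q + (1 - np.exp(-grid.A_max * 1.0)) * p
        assert np.max(np.abs(mix - p)) < 1e-5

    def test_expected_counts_maximize_at_true_parameters(self, rng):
        # Gibbs inequality on a 10-window instance, exhaustive grid evaluation
        p = random_background(rng, 4)
        z = np.arange(10.0)
        grids = make_grids(p, coords=z)
        m0, a0, e0 = 2, 50, 60
        q0 = grids.Q[m0 - 1, e0]
        A0 = grids.A.values[a0]
        alpha = np.exp(-A0 * np.abs(z - z[4]))
        X = 500 * (alpha[:, None] * q0 + (1 - alpha)[:, None] * p)
        lam, m_hat, ai, ei = oracle_fit(X, z, p, grids.eps_grid, grids.A.values, 4)
        assert (m_hat, ai, ei) == (m0, a0, e0)


class TestScan:
    def test_expected_counts_recover_grid_point_exactly(self, rng):
        p = random_background(rng, 5)
        z = np.arange(51.0)
        grids = make_grids(p, coords=z)
        m0, a0, e0 = 2, 50, 30
        q0 = grids.Q[m0 - 1, e0]
        A0 = float(grids.A.values[a0])
        alpha = np.exp(-A0 * np.abs(z - z[25]))
        X = 200 * (alpha[:, None] * q0 + (1 - alpha)[:, None] * p)
        fit = salti_scan(X, z, p, grids, targets=[25])[0]
        assert fit.m_hat == m0
        assert fit.A_hat == A0
        assert fit.eps_hat == grids.eps_grid[e0]

    def test_matches_triple_loop_oracle_on_random_instances(self, rng):
        for _ in range(5):
            K = int(rng.integers(3, 6))
            I = int(rng.integers(5, 15))
            p = random_background(rng, K)
            z = np.cumsum(rng.uniform(0.5, 2.0, size=I))
            grids = make_grids(p, coords=z)
            X = np.stack(
                [np.sort(rng.multinomial(40, p))[::-1].astype(float) for _ in range(I)]
            )
            t = int(rng.integers(0, I))
            fit = salti_scan(X, z, p, grids, targets=[t])[0]
            lam, m_hat, ai, ei = oracle_fit(X, z, p, grids.eps_grid, grids.A.values, t)
            assert fit.Lambda == pytest.approx(lam, abs=1e-9)
            assert fit.m_hat == m_hat
            assert fit.A_hat == grids.A.values[ai]
            assert fit.eps_hat == grids.eps_grid[ei]

    def test_single_window_set_equals_lassi_T(self, rng):
        for _ in range(10):
            K = int(rng.integers(3, 8))
            p = random_background(rng, K)
            x = np.sort(rng.multinomial(50, p))[::-1].astype(float)
            grids = make_grids(p, coords=np.array([0.0, 1.0]))
            fit = salti_scan(x[None, :], np.array([0.0]), p, grids, targets=[0])[0]
            T, m_T, eps_T = lassi_T(x, p, grids.Q, grids.eps_grid)
            assert fit.Lambda == pytest.approx(T, abs=1e-12)
            assert (fit.m_hat, fit.eps_hat) == (m_T, eps_T)

    def test_invariant_to_coordinate_shift_and_chromosome_labels(self, rng):
        p = random_background(rng, 4)
        I = 20
        z = np.arange(float(I))
        X = np.stack(
            [np.sort(rng.multinomial(30, p))[::-1].astype(float) for _ in range(I)]
        )
        grids = make_grids(p, coords=z)
        base = salti_scan(X, z, p, grids, targets=[10])[0]
        shifted = salti_scan(X, z + 1e4, p, grids, targets=[10])[0]
        assert shifted.Lambda == pytest.approx(base.Lambda, abs=1e-9)
        relabeled = salti_scan(
            X, z, p, grids, targets=[10], chroms=np.array(["chrX"] * I, dtype=object)
        )[0]
        assert relabeled.Lambda == base.Lambda

    def test_other_chromosomes_cancel_in_lambda(self, rng):
        p = random_background(rng, 4)
        X1 = np.stack(
            [np.sort(rng.multinomial(30, p))[::-1].astype(float) for _ in range(8)]
        )
        X2 = np.stack(
            [np.sort(rng.multinomial(30, p))[::-1].astype(float) for _ in range(6)]
        )
        z = np.concatenate([np.arange(8.0), np.arange(6.0)])
        chroms = np.array(["1"] * 8 + ["2"] * 6, dtype=object)
        grids = make_grids(p, coords=np.arange(8.0))
        both = salti_scan(
            np.vstack([X1, X2]), z, p, grids, targets=[3], chroms=chroms
        )[0]
        alone = salti_scan(X1, np.arange(8.0), p, grids, targets=[3])[0]
        assert both.Lambda == alone.Lambda
        assert (both.m_hat, both.A_hat, both.eps_hat) == (
            alone.m_hat,
            alone.A_hat,
            alone.eps_hat,
        )

    def test_target_out_of_range(self, rng):
        p = random_background(rng, 3)
        grids = make_grids(p, coords=np.arange(3.0))
        with pytest.raises(ValueError, match="out of range"):
            salti_scan(np.ones((3, 3)), np.arange(3.0), p, grids, targets=[5])

    def test_nested_null_at_fast_decay(self):
        # far windows' mixture weight is <= 1e-5 at A_max: neutrality is nested
        g = build_A_grid(coords=np.arange(4.0))
        assert np.exp(-g.A_max * 1.0) == pytest.approx(1e-5, rel=1e-9)


def test_epsilon_grid_respects_anchor():
    p = np.array([0.55, 0.25, 0.15, 0.05])
    eg = epsilon_grid(4, float(p[-1]))
    assert eg[-1] == pytest.approx(p[-1])
    assert np.all(eg <= p[-1] + 1e-15)
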