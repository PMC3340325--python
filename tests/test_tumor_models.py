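import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glioshadow.errors import DomainError, NumericalBlowupError
from glioshadow.tissue_geometry import TissueGrid, expand_parameters
from glioshadow.tumor_models import (
    SwansonParams,
    Tendency,
    TumorState,
    TwoPhenotypeParams,
    diffusive_flux_divergence,
    haptotaxis_divergence,
    heun_step,
    integrate,
    integrate_swanson_ensemble,
    logistic_transition_time,
    seed_tumor,
    smooth_seed_state,
    swanson_rhs,
    total_population,
    two_phenotype_rhs,
)


def dense_diffusion_matrix(D, mask, h=1.0):
    """Brute-force assembly of the flux-form divergence operator."""
    n = mask.size
    idx = np.arange(n).reshape(mask.shape)
    A = np.zeros((n, n))
    rows, cols = mask.shape
    for r in range(rows):
        for c in range(cols):
            if not mask[r, c]:
                continue
            for dr, dc in ((1, 0), (0, 1)):
                r2, c2 = r + dr, c + dc
                if r2 >= rows or c2 >= cols or not mask[r2, c2]:
                    continue
                d_face = 0.5 * (D[r, c] + D[r2, c2]) / h**2
                i, j = idx[r, c], idx[r2, c2]
                A[i, i] -= d_face
                A[i, j] += d_face
                A[j, j] -= d_face
                A[j, i] += d_face
    return A


def dense_haptotaxis(g, w, chi, mask, h=1.0):
    """Brute-force upwind divergence of the haptotactic flux chi*g*grad(w)."""
    out = np.zeros_like(g, dtype=float)
    rows, cols = mask.shape
    for r in range(rows):
        for c in range(cols):
            for dr, dc in ((1, 0), (0, 1)):
                r2, c2 = r + dr, c + dc
                if r2 >= rows or c2 >= cols or not (mask[r, c] and mask[r2, c2]):
                    continue
                v = 0.5 * (chi[r, c] + chi[r2, c2]) * (w[r2, c2] - w[r, c]) / h
                g_up = g[r, c] if v > 0 else g[r2, c2]
                flux = v * g_up
                out[r, c] += flux / h
                out[r2, c2] -= flux / h
    out[~mask] = 0.0
    return out


class TestDiffusionOperator:
    def test_uniform_field_has_zero_tendency(self, open_grid):
        mask = open_grid.brain_mask
        f = np.where(mask, 5.0, 0.0)
        D = expand_parameters(open_grid, {"white": 0.01, "gray": 0, "csf": 0})
        out = diffusive_flux_divergence(f, D, mask)
        assert np.abs(out).max() < 1e-12

    def test_conserves_mass_from_impulse(self, phantom48):
        mask = phantom48.brain_mask
        f = np.zeros(phantom48.shape)
        rr, cc = np.nonzero(mask)
        f[rr[len(rr) // 2], cc[len(cc) // 2]] = 1e4
        D = expand_parameters(phantom48, {"white": 0.0065, "gray": 0.0013, "csf": 0.001})
        out = diffusive_flux_divergence(f, D, mask)
        assert abs(out.sum()) < 1e-9 * np.abs(out).sum()

    def test_matches_dense_assembly(self, rng):
        mask = np.ones((5, 5), dtype=bool)
        mask[0, 0] = mask[4, 2] = False          # irregular no-flux boundary
        D = rng.uniform(1e-3, 1e-1, size=(5, 5))
        f = np.where(mask, rng.uniform(0, 100, size=(5, 5)), 0.0)
        A = dense_diffusion_matrix(D, mask)
        expected = (A @ f.ravel()).reshape(5, 5)
        got = diffusive_flux_divergence(f, D, mask)
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(DomainError):
            diffusive_flux_divergence(
                np.zeros((3, 3)), np.zeros((4, 4)), np.ones((3, 3), dtype=bool)
            )

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_conservation_property(self, seed):
        """Flux-form conservation holds for arbitrary fields, D, and masks."""
        r = np.random.default_rng(seed)
        mask = r.random((6, 6)) < 0.8
        mask[2:4, 2:4] = True                    # keep the mask non-empty
        f = np.where(mask, r.uniform(0, 1e4, (6, 6)), 0.0)
        D = r.uniform(0, 0.1, (6, 6))
        out = diffusive_flux_divergence(f, D, mask)
        assert abs(out.sum()) <= 1e-9 * max(np.abs(out).sum(), 1.0)
        assert (out[~mask] == 0).all()


class TestHaptotaxisOperator:
    def test_constant_ecm_gives_zero(self, open_grid):
        mask = open_grid.brain_mask
        g = np.where(mask, 100.0, 0.0)
        chi = np.where(mask, 0.25, 0.0)
        out = haptotaxis_divergence(g, np.where(mask, 0.7, 0.0), chi, mask)
        assert np.abs(out[mask]).max() < 1e-12

    def test_zero_cells_give_zero(self, open_grid):
        mask = open_grid.brain_mask
        w = np.where(mask, np.linspace(0, 1, 12)[None, :], 0.0)
        out = haptotaxis_divergence(np.zeros((12, 12)), w, np.full((12, 12), 0.25), mask)
        assert np.abs(out).max() == 0.0

    def test_matches_dense_upwind_oracle(self, rng):
        mask = np.ones((5, 5), dtype=bool)
        mask[1, 4] = False
        g = np.where(mask, rng.uniform(0, 1e3, (5, 5)), 0.0)
        w = np.where(mask, rng.uniform(0, 1, (5, 5)), 0.0)
        chi = rng.uniform(0, 0.3, (5, 5))
        expected = dense_haptotaxis(g, w, chi, mask)
        got = haptotaxis_divergence(g, w, chi, mask)
        np.testing.assert_allclose(got, expected, atol=1e-12)


class TestSwansonRHS:
    def test_carrying_capacity_is_fixed_point(self, open_grid):
        p = SwansonParams()
        g = np.where(open_grid.brain_mask, p.T_max, 0.0)
        out = swanson_rhs(TumorState(g), p, open_grid)
        assert np.abs(out.dg[open_grid.brain_mask]).max() < 1e-9

    def test_logistic_maximum_without_diffusion(self, open_grid):
        p = SwansonParams(alpha=0.2, T_max=1e4, D={"white": 0, "gray": 0, "csf": 0})
        g = np.zeros(open_grid.shape)
        g[5, 5] = p.T_max / 2
        out = swanson_rhs(TumorState(g), p, open_grid)
        assert out.dg[5, 5] == pytest.approx(p.alpha * p.T_max / 4)

    def test_decomposes_into_diffusion_plus_logistic(self, rng):
        labels = np.full((6, 6), 3, dtype=np.int16)
        labels[0, :3] = 2
        labels[5, :2] = 1
        grid = TissueGrid(labels)
        p = SwansonParams()
        g = np.where(grid.brain_mask, rng.uniform(0, 1e4, (6, 6)), 0.0)
        out = swanson_rhs(TumorState(g), p, grid)
        D = expand_parameters(grid, p.D)
        expected = diffusive_flux_divergence(g, D, grid.brain_mask) + np.where(
            grid.brain_mask, p.alpha * g * (1 - g / p.T_max), 0.0
        )
        np.testing.assert_allclose(out.dg, expected, rtol=1e-12)


class TestTwoPhenotypeRHS:
    def test_disease_free_equilibrium(self, open_grid):
        mask = open_grid.brain_mask
        state = TumorState(
            np.zeros(open_grid.shape), np.zeros(open_grid.shape),
            np.where(mask, 1.0, 0.0),
        )
        out = two_phenotype_rhs(state, TwoPhenotypeParams(), open_grid)
        for field in (out.dg, out.dm, out.dw):
            assert np.abs(field).max() < 1e-12

    def test_ecm_saturation_limit(self, open_grid):
        """For g+m >> theta_W the ECM tendency approaches
        -rho_ecm*w + alpha_W*w*(1-w) voxelwise."""
        p = TwoPhenotypeParams()
        mask = open_grid.brain_mask
        big = 1e6
        state = TumorState(
            np.where(mask, big, 0.0), np.where(mask, big, 0.0),
            np.where(mask, 0.5, 0.0),
        )
        out = two_phenotype_rhs(state, p, open_grid)
        expected = -p.rho_ecm * 0.5 + p.alpha_W * 0.5 * 0.5
        np.testing.assert_allclose(out.dw[mask], expected, rtol=1e-3)

    def test_haptotaxis_cancels_in_total_population(self, rng):
        """The phenotype-transfer terms are equal and opposite, so the
        g+m tendency contains no haptotaxis contribution."""
        labels = np.full((6, 6), 3, dtype=np.int16)
        labels[2, 2] = 2
        grid = TissueGrid(labels)
        p = TwoPhenotypeParams()
        mask = grid.brain_mask
        g = np.where(mask, rng.uniform(0, 5e3, (6, 6)), 0.0)
        m = np.where(mask, rng.uniform(0, 5e3, (6, 6)), 0.0)
        w = np.where(mask, rng.uniform(0.1, 1.0, (6, 6)), 0.0)
        out = two_phenotype_rhs(TumorState(g, m, w), p, grid)
        DG = expand_parameters(grid, p.D_G)
        DM = expand_parameters(grid, p.D_M)
        expected_sum = (
            diffusive_flux_divergence(g, DG, mask)
            + diffusive_flux_divergence(m, DM, mask)
            + np.where(mask, p.alpha * g * (1 - (g + m) / p.T_max), 0.0)
        )
        np.testing.assert_allclose(out.dg + out.dm, expected_sum, atol=1e-10)


class TestHeunIntegration:
    def test_linear_ode_single_step_exact(self, open_grid):
        """One Heun step on u' = alpha*u reproduces the quadratic Taylor
        polynomial exactly (RK2 on a linear ODE)."""
        alpha, dt = 0.3, 0.25
        g0 = np.where(open_grid.brain_mask, 2.0, 0.0)
        rhs = lambda s: Tendency(alpha * s.g)
        out = heun_step(TumorState(g0.copy()), rhs, dt)
        factor = 1 + alpha * dt + (alpha * dt) ** 2 / 2
        np.testing.assert_allclose(
            out.g[open_grid.brain_mask], 2.0 * factor, rtol=1e-14
        )
        assert out.t == pytest.approx(dt)

    def test_logistic_is_second_order_accurate(self, open_grid):
        """Global error against the closed-form logistic solution shrinks
        ~4x when dt is halved."""
        p = SwansonParams(alpha=0.05, T_max=1e4, D={"white": 0, "gray": 0, "csf": 0})
        g0 = np.zeros(open_grid.shape)
        g0[5, 5] = 100.0
        T = 50.0
        exact = p.T_max / (1 + (p.T_max / 100.0 - 1) * math.exp(-p.alpha * T))
        errors = []
        for dt in (2.0, 1.0, 0.5):
            out = integrate(TumorState(g0.copy()), p, open_grid, T, dt)
            errors.append(abs(out.g[5, 5] - exact))
        ratios = [errors[i] / errors[i + 1] for i in range(2)]
        for ratio in ratios:
            assert 3.0 < ratio < 5.0, f"convergence ratios {ratios}"

    def test_negative_densities_clamped(self, open_grid):
        state = TumorState(np.where(open_grid.brain_mask, -5.0, 0.0))
        out = heun_step(state, lambda s: Tendency(np.zeros_like(s.g)), 0.1)
        assert (out.g >= 0).all()

    def test_nonfinite_state_raises_with_time(self, open_grid):
        state = TumorState(np.full(open_grid.shape, 1.0), t=4.0)
        rhs = lambda s: Tendency(np.full_like(s.g, np.inf))
        with pytest.raises(NumericalBlowupError) as err:
            heun_step(state, rhs, 0.1)
        assert err.value.t_days == pytest.approx(4.1)


class TestIntegrate:
    def test_zero_days_is_identity(self, open_grid):
        state = TumorState(np.where(open_grid.brain_mask, 3.0, 0.0), t=1.0)
        out = integrate(state, SwansonParams(), open_grid, 0.0)
        assert (out.g == state.g).all() and out.t == state.t

    def test_pure_diffusion_conserves_mass_90_days(self, phantom48):
        p = SwansonParams(alpha=1e-12, D={"white": 0.0065, "gray": 0.0013, "csf": 0.001})
        state = smooth_seed_state(phantom48)
        swanson = TumorState(state.g.copy())
        m0 = swanson.g.sum()
        out = integrate(swanson, p, phantom48, 90.0, dt=0.5)
        assert abs(out.g.sum() - m0) < 1e-9 * m0

    def test_snapshot_cadence(self, open_grid):
        state = TumorState(np.where(open_grid.brain_mask, 10.0, 0.0))
        snaps = integrate(state, SwansonParams(), open_grid, 10.0, dt=0.5,
                          snapshot_every=5.0)
        assert [s.t for s in snaps] == pytest.approx([0.0, 5.0, 10.0])

    def test_ensemble_stepper_matches_per_member_path(self, phantom48, rng):
        """The vectorised ensemble integrator reproduces the reference
        per-member Heun path to roundoff."""
        params = [
            SwansonParams(alpha=a, T_max=K, D={"white": Dw, "gray": 0.0013, "csf": 0.001})
            for a, K, Dw in [(0.03, 9000.0, 0.005), (0.06, 11000.0, 0.015)]
        ]
        states = []
        for _ in params:
            g = np.where(phantom48.brain_mask, rng.uniform(0, 500, phantom48.shape), 0.0)
            states.append(TumorState(g))
        fast = integrate_swanson_ensemble(states, params, phantom48, 5.0, 0.1)
        for s, p, f in zip(states, params, fast):
            ref = integrate(s, p, phantom48, 5.0, 0.1)
            np.testing.assert_allclose(f.g, ref.g, rtol=1e-10, atol=1e-10)
            assert f.t == pytest.approx(ref.t)


class TestSeedTumor:
    def test_zero_seed_stays_zero(self, phantom48):
        out = seed_tumor(phantom48, (24, 24), 0.0, 0.0, TwoPhenotypeParams(), 30.0)
        assert out.g.sum() == 0.0 and out.m.sum() == 0.0

    def test_seed_outside_mask_rejected(self, phantom48):
        with pytest.raises(DomainError):
            seed_tumor(phantom48, (0, 0), 100.0, 10.0, TwoPhenotypeParams(), 1.0)

    def test_population_grows_from_seed(self, phantom48):
        out = seed_tumor(phantom48, (24, 24), 100.0, 10.0, TwoPhenotypeParams(), 60.0)
        pop = total_population(out, phantom48.spacing_mm)
        assert pop > 110.0
        assert (out.g >= 0).all() and (0 <= out.w).all() and (out.w <= 1).all()


class TestLogisticTransitionTime:
    @pytest.mark.parametrize(
        "alpha,expected",
        [(0.01767, 520.1), (0.035347, 260.0)],
    )
    def test_closed_form_matches_ode_crossing(self, alpha, expected):
        """The 1%-to-99% transition time matches direct integration of the
        scalar logistic ODE."""
        t = logistic_transition_time(alpha)
        assert t == pytest.approx(2 * math.log(99) / alpha, rel=1e-12)
        assert t == pytest.approx(expected, abs=0.5)
        # independent check: time the threshold crossings of the exact
        # logistic solution on a fine time grid
        K, g0 = 1e4, 1.0
        tt = np.linspace(0, 1500, 3_000_001)
        g = K / (1 + (K / g0 - 1) * np.exp(-alpha * tt))
        t01 = tt[np.searchsorted(g, 0.01 * K)]
        t99 = tt[np.searchsorted(g, 0.99 * K)]
        assert t == pytest.approx(t99 - t01, abs=0.01)

    def test_degenerate_interval_vanishes(self):
        for eps in (1e-3, 1e-6):
            assert logistic_transition_time(0.02, 0.5, 0.5 + eps) < 1.0
        assert logistic_transition_time(0.02, 0.5, 0.5) == 0.0

    def test_domain_violations_rejected(self):
        with pytest.raises(ValueError):
            logistic_transition_time(-0.1)
        with pytest.raises(ValueError):
            logistic_transition_time(0.02, 0.99, 0.01)
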