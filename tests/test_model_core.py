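"""Coordinate maps, Morse/solvent potentials and the total Hamiltonian."""

import math

import numpy as np
import pytest

from pbhsolv.errors import (
    DegenerateProfileError,
    InvalidParameterError,
    ShapeMismatchError,
)
from pbhsolv.fixtures import toy_lattice
from pbhsolv.model import (
    SQRT2,
    BarrierMetrics,
    LatticeConfiguration,
    MicroscopicParameters,
    angle_projection,
    barrier_metrics,
    hbond_stretch,
    inverse_reduced_coordinates,
    morse_energy,
    onsite_potential_profile,
    onsite_stretch_derivative,
    onsite_stretch_energy,
    reduced_coordinates,
    solvent_energy,
    solvent_shifted_minimum,
    total_energy,
)


@pytest.mark.parametrize("u, v, w_exp, lam_exp", [
    (1.0, 1.0, SQRT2, 0.0),
    (1.0, -1.0, 0.0, SQRT2),
    (0.3, 0.1, 0.4 / SQRT2, 0.2 / SQRT2),
])
def test_reduced_coordinates_examples(u, v, w_exp, lam_exp):
    w, lam = reduced_coordinates(u, v)
    assert w == pytest.approx(w_exp, abs=1e-15)
    assert lam == pytest.approx(lam_exp, abs=1e-15)


def test_reduced_coordinates_involution():
    rng = np.random.default_rng(0)
    u, v = rng.normal(size=(2, 200))
    w, lam = reduced_coordinates(u, v)
    u2, v2 = inverse_reduced_coordinates(w, lam)
    np.testing.assert_allclose(u2, u, atol=1e-15)
    np.testing.assert_allclose(v2, v, atol=1e-15)


@pytest.mark.parametrize("phi, theta, r, expected", [
    (math.pi / 2, math.pi / 2, 0.3, 0.0),
    (0.0, 0.0, 0.3, 0.6),
    (math.pi / 5, math.pi / 4, 1.3, 1.3 * (math.cos(math.pi / 5) + math.cos(math.pi / 4))),
])
def test_angle_projection_examples(phi, theta, r, expected):
    assert angle_projection(phi, theta, r) == pytest.approx(expected, abs=1e-15)


def test_angle_projection_bounds():
    rng = np.random.default_rng(1)
    phi, theta = rng.uniform(-math.pi, math.pi, size=(2, 500))
    g = angle_projection(phi, theta, 0.7)
    assert np.all(np.abs(g) <= 2 * 0.7 + 1e-14)


class TestHbondStretch:
    params = MicroscopicParameters(r=0.3, d=0.4)

    def test_rest_configuration(self):
        y = hbond_stretch(0.0, 0.0, math.pi / 2, math.pi / 2, self.params)
        assert y == pytest.approx(self.params.y0, abs=1e-15)

    def test_closed_discs(self):
        assert hbond_stretch(0.0, 0.0, 0.0, 0.0, self.params) == pytest.approx(0.4)

    def test_direct_evaluation(self):
        y = hbond_stretch(0.1, -0.1, math.pi / 2, math.pi / 2, self.params)
        assert y == pytest.approx(1.2, abs=1e-15)

    def test_identity_vs_reduced_coordinates(self):
        # y - y0 = sqrt(2) lambda - g for 1000 random configurations
        rng = np.random.default_rng(2)
        u, v = rng.normal(scale=0.5, size=(2, 1000))
        theta, phi = rng.uniform(0, math.pi, size=(2, 1000))
        y = hbond_stretch(u, v, theta, phi, self.params)
        _, lam = reduced_coordinates(u, v)
        g = angle_projection(phi, theta, self.params.r)
        np.testing.assert_allclose(y - self.params.y0, SQRT2 * lam - g, atol=1e-14)


class TestPotentials:
    params = MicroscopicParameters(D=4.05, a=4.41, f_s=1.0, l_s=1.0)

    def test_morse_zero_on_manifold(self):
        rng = np.random.default_rng(3)
        lam = rng.normal(size=100)
        g = SQRT2 * lam  # the zero manifold sqrt(2) lambda = g
        np.testing.assert_allclose(morse_energy(lam, g, self.params), 0.0, atol=1e-14)

    def test_morse_nonnegative_and_positive_off_manifold(self):
        rng = np.random.default_rng(4)
        lam, g = rng.normal(size=(2, 100))
        e = morse_energy(lam, g, self.params)
        assert np.all(e >= 0)
        off = np.abs(SQRT2 * lam - g) > 1e-8
        assert np.all(e[off] > 0)

    def test_morse_examples(self):
        p = self.params
        assert morse_energy(0.0, 0.0, p) == 0.0
        assert morse_energy(50.0, 0.0, p) == pytest.approx(p.D, rel=1e-12)
        expected = p.D * (math.exp(-p.a * SQRT2 * 0.1) - 1.0) ** 2
        assert morse_energy(0.1, 0.0, p) == pytest.approx(expected, rel=1e-14)

    def test_solvent_limits(self):
        p = self.params
        assert solvent_energy(0.0, 0.0, p) == pytest.approx(-p.D * p.f_s, abs=1e-15)
        assert solvent_energy(100.0, 0.0, p) == pytest.approx(0.0, abs=1e-15)
        assert solvent_energy(-100.0, 0.0, p) == pytest.approx(-2 * p.D * p.f_s, abs=1e-12)
        off = p.with_(f_s=0.0)
        assert solvent_energy(1.234, 0.0, off) == 0.0

    def test_solvent_bounds_and_monotonicity(self):
        lam = np.linspace(-3, 3, 301)
        e = solvent_energy(lam, 0.0, self.params)
        assert np.all(e <= 0) and np.all(e >= -2 * self.params.D * self.params.f_s)
        assert np.all(np.diff(e) > 0)

    def test_invalid_solvent_range_rejected(self):
        with pytest.raises(InvalidParameterError):
            MicroscopicParameters(l_s=0.0)
        with pytest.raises(InvalidParameterError):
            MicroscopicParameters(l_s=-1.0)

    @pytest.mark.parametrize("order", [1, 2, 3, 4, 5])
    def test_stretch_derivatives_match_finite_differences(self, order):
        # closed-form well derivatives vs high-order central differences
        h = 5e-3
        x = np.array([-0.4, -0.1, 0.0, 0.2, 0.7])
        stencil = np.arange(-4, 5)
        vals = np.stack([onsite_stretch_energy(x + k * h, self.params) for k in stencil])
        # derivative via polynomial fit through the 9-point stencil
        num = []
        for i in range(x.size):
            c = np.polyfit(stencil * h, vals[:, i], 8)
            num.append(math.factorial(order) * c[8 - order])
        analytic = onsite_stretch_derivative(x, self.params, order)
        np.testing.assert_allclose(analytic, num, rtol=5e-5, atol=5e-4)

    def test_solvent_shifted_minimum_is_stationary(self):
        x_star = solvent_shifted_minimum(self.params)
        assert x_star < 0
        assert onsite_stretch_derivative(x_star, self.params, 1) == pytest.approx(0.0, abs=1e-10)
        assert solvent_shifted_minimum(self.params.with_(f_s=0.0)) == 0.0


class TestProfileAndBarrier:
    fig4 = MicroscopicParameters(D=4.04, a=4.5, r=1.3, f_s=2.0, l_s=1.0)
    grid = np.linspace(0.5, 8.0, 4001)
    angles = (math.pi / 5, math.pi / 4)  # (phi, theta)

    def test_solvent_off_equals_pure_morse(self):
        p0 = self.fig4.with_(f_s=0.0)
        prof = onsite_potential_profile(self.grid, *self.angles, p0)
        g = angle_projection(self.angles[0], self.angles[1], p0.r)
        np.testing.assert_allclose(
            prof.energy, morse_energy(prof.lambda_grid, g, p0), atol=1e-14)

    def test_barrier_present_with_solvent_absent_without(self):
        prof = onsite_potential_profile(self.grid, *self.angles, self.fig4)
        metrics = barrier_metrics(prof)
        assert metrics.has_barrier and metrics.barrier_height > 0
        prof0 = onsite_potential_profile(self.grid, *self.angles,
                                         self.fig4.with_(f_s=0.0))
        assert not barrier_metrics(prof0).has_barrier

    def test_exactly_one_interior_maximum(self):
        prof = onsite_potential_profile(self.grid, *self.angles, self.fig4)
        e = prof.energy
        interior_max = np.sum((e[1:-1] > e[:-2]) & (e[1:-1] > e[2:]))
        assert interior_max == 1

    def test_printed_orientation_monotone_past_well(self):
        prof = onsite_potential_profile(self.grid, *self.angles, self.fig4,
                                        solvent_orientation="printed")
        e = prof.energy
        i_min = int(np.argmin(e))
        assert np.all(np.diff(e[i_min:]) > 0)
        assert not barrier_metrics(prof).has_barrier

    def test_barrier_height_monotone_in_fs(self):
        # at l_s = 1 the barrier grows with f_s until the closed-state well
        # is washed out (solvent slope f_s D / l_s exceeds the peak Morse
        # slope a D / 2 near f_s ~ a l_s / 2)
        heights = []
        for f_s in (0.5, 1.0, 2.0):
            prof = onsite_potential_profile(self.grid, *self.angles,
                                            self.fig4.with_(f_s=f_s))
            heights.append(barrier_metrics(prof).barrier_height)
        assert np.all(np.diff(heights) > 0)
        washed = onsite_potential_profile(self.grid, *self.angles,
                                          self.fig4.with_(f_s=4.0))
        assert not barrier_metrics(washed).has_barrier

    def test_barrier_height_linear_in_fs_for_wide_solvent(self):
        """In the solvent-dominated regime (l_s >> 1/a) the barrier top sits
        where the Morse term is already flat, so its height above the
        plateau scales as f_s * D."""
        wide = self.fig4.with_(l_s=10.0)
        grid = np.linspace(0.5, 40.0, 8001)
        heights = []
        for f_s in (1.0, 2.0, 4.0):
            prof = onsite_potential_profile(grid, *self.angles, wide.with_(f_s=f_s))
            heights.append(barrier_metrics(prof).barrier_height)
        normalized = np.array(heights) / np.array([1.0, 2.0, 4.0])
        assert np.max(normalized) / np.min(normalized) - 1.0 < 0.05

    def test_degenerate_grid_rejected(self):
        prof = onsite_potential_profile(np.array([0.0, 1.0]), *self.angles, self.fig4)
        with pytest.raises(DegenerateProfileError):
            barrier_metrics(prof)

    def test_monotone_profile_flagged_no_barrier(self):
        grid = np.linspace(0.0, 1.0, 50)
        prof = onsite_potential_profile(grid, *self.angles, self.fig4)
        prof.energy = np.linspace(0.0, 1.0, 50)  # force monotone samples
        assert not barrier_metrics(prof).has_barrier


def _energy_oracle(cfg: LatticeConfiguration, p: MicroscopicParameters) -> float:
    """Independent per-term re-summation with plain loops."""
    n = cfg.n_sites
    total = 0.0
    for j in range(n):
        w_j = (cfg.u[j] + cfg.v[j]) / math.sqrt(2)
        lam_j = (cfg.u[j] - cfg.v[j]) / math.sqrt(2)
        w_jm = (cfg.u[j - 1] + cfg.v[j - 1]) / math.sqrt(2)
        lam_jm = (cfg.u[j - 1] - cfg.v[j - 1]) / math.sqrt(2)
        total += cfg.p_w[j] ** 2 / (2 * p.m) + cfg.p_lambda[j] ** 2 / (2 * p.m)
        total += cfg.p_phi[j] ** 2 / (2 * p.inertia) + cfg.p_theta[j] ** 2 / (2 * p.inertia)
        total += p.k_stack / 2 * ((w_j - w_jm) ** 2 + (lam_j - lam_jm) ** 2)
        total += p.xi_stack / 2 * ((cfg.phi_angle[j] - cfg.phi_angle[j - 1]) ** 2
                                   + (cfg.theta[j] - cfg.theta[j - 1]) ** 2)
        x = math.sqrt(2) * lam_j - p.r * (math.cos(cfg.phi_angle[j]) + math.cos(cfg.theta[j]))
        total += p.D * (math.exp(-p.a * x) - 1.0) ** 2
        total += p.D * p.f_s * (math.tanh(x / p.l_s) - 1.0)
        total += -p.V_hop * (np.conj(cfg.B[j]) * (cfg.B[(j + 1) % n] + cfg.B[j - 1])).real
        total += p.chi * lam_j * abs(cfg.B[j]) ** 2
    return total


class TestTotalEnergy:
    def test_rest_state_energy_is_solvent_offset(self, fig3_params):
        n = 24
        cfg = LatticeConfiguration.rest(n, fig3_params)
        expected = -n * fig3_params.D * fig3_params.f_s
        assert total_energy(cfg, fig3_params) == pytest.approx(expected, rel=1e-14)

    def test_single_site_periodic_convention(self):
        p = MicroscopicParameters(f_s=0.0, V_hop=0.37)
        cfg = LatticeConfiguration.rest(1, p, B=np.array([1.0 + 0j]))
        # each site is its own neighbour under periodicity: <H2> = -2 V
        assert total_energy(cfg, p) == pytest.approx(-2 * p.V_hop, rel=1e-14)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_independent_loop_oracle(self, seed, fig3_params):
        cfg = toy_lattice(12, seed=seed, amplitude=0.1, params=fig3_params)
        h = total_energy(cfg, fig3_params)
        assert h == pytest.approx(_energy_oracle(cfg, fig3_params), rel=1e-12)

    def test_cyclic_relabeling_invariance(self, fig3_params, small_lattice):
        h0 = total_energy(small_lattice, fig3_params)
        for s in (1, 5, 11):
            hs = total_energy(small_lattice.shifted(s), fig3_params)
            assert hs == pytest.approx(h0, rel=1e-12)

    def test_reduces_to_classical_pb_without_charge_and_solvent(self, fig3_params):
        p = fig3_params.with_(f_s=0.0)
        cfg = toy_lattice(10, seed=3, amplitude=0.08, params=p)
        cfg.B[:] = 0.0
        assert total_energy(cfg, p) == pytest.approx(_energy_oracle(cfg, p), rel=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ShapeMismatchError):
            LatticeConfiguration(
                u=np.zeros(4), v=np.zeros(4), theta=np.zeros(4), phi_angle=np.zeros(4),
                p_w=np.zeros(4), p_lambda=np.zeros(3), p_theta=np.zeros(4),
                p_phi=np.zeros(4), B=np.zeros(4, dtype=complex))


class TestPropertyBased:
    from hypothesis import given, settings, strategies as st

    finite = st.floats(-50.0, 50.0, allow_nan=False)
    angles_st = st.floats(-math.pi, math.pi, allow_nan=False)

    @given(u=finite, v=finite)
    @settings(derandomize=True, max_examples=50)
    def test_reduced_map_is_an_isometry(self, u, v):
        w, lam = reduced_coordinates(u, v)
        assert w ** 2 + lam ** 2 == pytest.approx(u ** 2 + v ** 2, rel=1e-12, abs=1e-12)
        u2, v2 = inverse_reduced_coordinates(w, lam)
        assert (u2, v2) == pytest.approx((u, v), abs=1e-10)

    @given(u=finite, v=finite, theta=angles_st, phi=angles_st)
    @settings(derandomize=True, max_examples=50)
    def test_stretch_identity(self, u, v, theta, phi):
        p = MicroscopicParameters(r=0.3, d=0.4)
        y = hbond_stretch(u, v, theta, phi, p)
        _, lam = reduced_coordinates(u, v)
        g = angle_projection(phi, theta, p.r)
        assert y - p.y0 == pytest.approx(SQRT2 * lam - g, abs=1e-12)

    @given(lam=st.floats(-5.0, 5.0, allow_nan=False),
           g=st.floats(-1.0, 1.0, allow_nan=False),
           f_s=st.floats(0.0, 4.0, allow_nan=False))
    @settings(derandomize=True, max_examples=50)
    def test_potential_bounds(self, lam, g, f_s):
        p = MicroscopicParameters(D=4.05, a=4.41, f_s=f_s, l_s=1.0)
        assert morse_energy(lam, g, p) >= 0.0
        s = solvent_energy(lam, g, p)
        assert -2 * p.D * f_s - 1e-12 <= s <= 1e-12


def test_parameter_invariants_enforced():
    with pytest.raises(InvalidParameterError):
        MicroscopicParameters(m=-1.0)
    with pytest.raises(InvalidParameterError):
        MicroscopicParameters(D=0.0)
    with pytest.raises(InvalidParameterError):
        MicroscopicParameters(f_s=-0.5)


def test_parameter_roundtrip_and_unknown_keys():
    p = MicroscopicParameters(f_s=0.7, l_s=2.0)
    assert MicroscopicParameters.from_dict(p.to_dict()) == p
    with pytest.raises(InvalidParameterError):
        MicroscopicParameters.from_dict({"m": 300.0, "bogus": 1.0})


def test_y0_is_derived():
    p = MicroscopicParameters(r=0.4, d=0.2)
    assert p.y0 == pytest.approx(1.0)
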