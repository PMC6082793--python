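"""Time-domain integration of the coupled lattice + charge system.

The discrete equations of motion follow from the semiclassical Hamiltonian:
harmonic stacking for the in-phase/out-of-phase displacements and the two
angle fields, the Morse + solvent on-site force acting on the stretch and
(through the disc geometry) on the angles, the Holstein back-reaction
-chi |B_j|^2 on the stretch, and a tight-binding Schroedinger equation
i hbar dB/dt = -V (B_{j+1} + B_{j-1}) + chi lambda_j B_j for the charge.

Two integration schemes are provided: a norm-preserving split-step scheme
(exact spectral propagation of the hopping term, pointwise phase rotation
for the Holstein term, symplectic leapfrog for the lattice) and a classical
RK4 stepping of all fields jointly as a validation path.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .errors import (
    AllZeroFrameError,
    InvalidParameterError,
    NoGrowthDetectedError,
    NumericalBlowupError,
    ShapeMismatchError,
)
from .model import (
    SQRT2,
    LatticeConfiguration,
    MicroscopicParameters,
    angle_projection,
    inverse_reduced_coordinates,
    onsite_stretch_derivative,
    reduced_coordinates,
    total_energy,
)

__all__ = [
    "SimulationSettings",
    "InitialWave",
    "Trajectory",
    "GrowthRateFit",
    "equations_of_motion",
    "resonant_wavenumber",
    "init_modulated_plane_wave",
    "integrate",
    "charge_density",
    "localization_metrics",
    "mode_amplitude_series",
    "measure_growth_rate",
]

logger = logging.getLogger(__name__)

Scheme = Literal["split_step_spectral", "rk4_full"]

#: any field magnitude beyond this aborts the run (Morse overflow guard)
BLOWUP_GUARD_DEFAULT = 1e6


@dataclass(frozen=True)
class SimulationSettings:
    """Run-length, step and scheme choices for :func:`integrate`."""

    n_sites: int = 400
    dt: float = 0.055
    n_steps: int = 1000
    record_stride: int = 10
    scheme: Scheme = "split_step_spectral"
    seed: int = 0
    noise_amplitude: float = 0.0
    blowup_guard: float = BLOWUP_GUARD_DEFAULT

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise InvalidParameterError(f"n_sites must be >= 1, got {self.n_sites}")
        if not self.dt > 0:
            raise InvalidParameterError(f"dt must be > 0, got {self.dt}")
        if self.n_steps < 1:
            raise InvalidParameterError(f"n_steps must be >= 1, got {self.n_steps}")
        if self.record_stride < 1 or self.n_steps % self.record_stride != 0:
            raise InvalidParameterError(
                f"record_stride ({self.record_stride}) must divide n_steps ({self.n_steps})")
        if self.noise_amplitude < 0:
            raise InvalidParameterError("noise_amplitude must be >= 0")


@dataclass(frozen=True)
class InitialWave:
    """Coherently modulated plane-wave initial data.

    lambda_n = lambda0 (1 + depth cos(K n)) cos(K0 n) for the stretch,
    B_n = phi0 (1 + depth exp(iKn)) exp(iK0 n) for the charge amplitude and
    the analogous psi envelope mapped onto the in-phase rotational
    combination; K0 is the carrier and K the perturbation wavenumber
    (rad/site).
    """

    lambda0: float = 0.0035
    phi0_amp: float = 0.002
    psi0_amp: float = 0.002
    K: float = 0.71 * math.pi
    K0: float = 0.55 * math.pi
    modulation_depth: float = 0.01

    def __post_init__(self) -> None:
        if self.modulation_depth < 0:
            raise InvalidParameterError("modulation_depth must be >= 0")


@dataclass
class Trajectory:
    """Recorded time series of the lattice fields and charge amplitudes.

    Field arrays have shape (n_sites, n_frames) with
    n_frames = 1 + n_steps // record_stride.
    """

    times: np.ndarray
    lambda_field: np.ndarray
    w_field: np.ndarray
    theta_field: np.ndarray
    phi_field: np.ndarray
    B_field: np.ndarray
    energy_series: np.ndarray
    norm_series: np.ndarray

    @property
    def n_sites(self) -> int:
        return self.lambda_field.shape[0]

    @property
    def n_frames(self) -> int:
        return self.lambda_field.shape[1]


def _forces(w, lam, theta, phi, B, params: MicroscopicParameters):
    """Force on every momentum: -dH/dq with periodic neighbours."""
    k, xi = params.k_stack, params.xi_stack
    lap = lambda f: np.roll(f, -1) - 2.0 * f + np.roll(f, 1)
    g = angle_projection(phi, theta, params.r)
    x = SQRT2 * lam - g
    wp = onsite_stretch_derivative(x, params, 1)
    f_w = k * lap(w)
    f_lam = k * lap(lam) - SQRT2 * wp - params.chi * np.abs(B) ** 2
    f_theta = xi * lap(theta) - wp * params.r * np.sin(theta)
    f_phi = xi * lap(phi) - wp * params.r * np.sin(phi)
    return f_w, f_lam, f_theta, f_phi


def _b_dot(lam, B, params: MicroscopicParameters):
    hop = -params.V_hop * (np.roll(B, -1) + np.roll(B, 1))
    return (-1j / params.hbar_eff) * (hop + params.chi * lam * B)


def equations_of_motion(config: LatticeConfiguration,
                        params: MicroscopicParameters) -> dict:
    """Time derivative of every field of the configuration.

    Returns a dict keyed like the configuration fields.  Note that with
    f_s > 0 the printed solvent term exerts a nonzero force at zero stretch,
    so the undistorted lattice is a fixed point only for f_s = 0.
    """
    w, lam = reduced_coordinates(config.u, config.v)
    f_w, f_lam, f_theta, f_phi = _forces(
        w, lam, config.theta, config.phi_angle, config.B, params)
    w_dot = config.p_w / params.m
    lam_dot = config.p_lambda / params.m
    u_dot, v_dot = inverse_reduced_coordinates(w_dot, lam_dot)
    return {
        "u": u_dot,
        "v": v_dot,
        "theta": config.p_theta / params.inertia,
        "phi_angle": config.p_phi / params.inertia,
        "p_w": f_w,
        "p_lambda": f_lam,
        "p_theta": f_theta,
        "p_phi": f_phi,
        "B": _b_dot(lam, config.B, params),
    }


def resonant_wavenumber(K: float, n_sites: int) -> float:
    """Nearest wavenumber commensurate with the periodic lattice."""
    return 2.0 * math.pi * round(K * n_sites / (2.0 * math.pi)) / n_sites


def init_modulated_plane_wave(settings: SimulationSettings, wave: InitialWave,
                              params: MicroscopicParameters | None = None,
                              ) -> LatticeConfiguration:
    """Build the modulated plane-wave initial configuration.

    K and K0 are rounded to the nearest lattice-resonant values (integer
    multiples of 2 pi / n_sites) and the rounding is logged.  Momenta start
    at zero; the psi envelope is mapped onto the in-phase rotational
    combination (theta + phi)/sqrt(2) about the rest angles.  Optional
    seeded white noise of amplitude ``settings.noise_amplitude`` is added to
    the stretch and charge fields.
    """
    if params is None:
        params = MicroscopicParameters()
    n = settings.n_sites
    K = resonant_wavenumber(wave.K, n)
    K0 = resonant_wavenumber(wave.K0, n)
    if not (math.isclose(K, wave.K, abs_tol=1e-12)
            and math.isclose(K0, wave.K0, abs_tol=1e-12)):
        logger.info("rounded wavenumbers to lattice-resonant values: "
                    "K %.6f -> %.6f, K0 %.6f -> %.6f", wave.K, K, wave.K0, K0)
    sites = np.arange(n)
    depth = wave.modulation_depth
    lam = wave.lambda0 * (1.0 + depth * np.cos(K * sites)) * np.cos(K0 * sites)
    B = wave.phi0_amp * (1.0 + depth * np.exp(1j * K * sites)) * np.exp(1j * K0 * sites)
    psi = wave.psi0_amp * (1.0 + depth * np.exp(1j * K * sites)) * np.exp(1j * K0 * sites)
    if settings.noise_amplitude > 0:
        rng = np.random.default_rng(settings.seed)
        lam = lam + settings.noise_amplitude * rng.standard_normal(n)
        B = B + settings.noise_amplitude * (
            rng.standard_normal(n) + 1j * rng.standard_normal(n)) / SQRT2
    angle_dev = psi.real / SQRT2
    u, v = inverse_reduced_coordinates(np.zeros(n), lam)
    z = np.zeros(n)
    return LatticeConfiguration(
        u=u, v=v,
        theta=params.rest_angle + angle_dev,
        phi_angle=params.rest_angle + angle_dev,
        p_w=z.copy(), p_lambda=z.copy(), p_theta=z.copy(), p_phi=z.copy(),
        B=B.astype(complex))


def _check_finite(settings: SimulationSettings, *arrays) -> None:
    for arr in arrays:
        m = np.max(np.abs(arr))
        if not np.isfinite(m) or m > settings.blowup_guard:
            raise NumericalBlowupError(
                f"field magnitude {m!r} exceeds guard {settings.blowup_guard:g}; "
                "reduce dt")


def integrate(config: LatticeConfiguration, params: MicroscopicParameters,
              settings: SimulationSettings) -> Trajectory:
    """Advance the coupled system and record observables.

    ``split_step_spectral``: Strang splitting — half phase rotation of B by
    the Holstein term, leapfrog kick-drift-kick for the lattice, exact
    spectral propagation of the hopping term (unitary, hence exactly
    norm-preserving), half phase rotation with the updated stretch.
    ``rk4_full``: classical 4th-order stepping of all fields jointly.
    """
    n = config.n_sites
    if n != settings.n_sites:
        raise ShapeMismatchError(
            f"configuration has {n} sites but settings expect {settings.n_sites}")
    n_frames = 1 + settings.n_steps // settings.record_stride
    lam_f = np.empty((n, n_frames))
    w_f = np.empty((n, n_frames))
    th_f = np.empty((n, n_frames))
    ph_f = np.empty((n, n_frames))
    B_f = np.empty((n, n_frames), dtype=complex)
    energy = np.empty(n_frames)
    norm = np.empty(n_frames)
    times = np.empty(n_frames)

    w, lam = reduced_coordinates(config.u, config.v)
    theta = config.theta.copy()
    phi = config.phi_angle.copy()
    p_w, p_lam = config.p_w.copy(), config.p_lambda.copy()
    p_th, p_ph = config.p_theta.copy(), config.p_phi.copy()
    B = config.B.astype(complex).copy()
    dt = settings.dt
    m, inertia, hbar = params.m, params.inertia, params.hbar_eff
    hop_phase = np.exp(1j * 2.0 * params.V_hop * np.cos(
        2.0 * np.pi * np.fft.fftfreq(n)) * dt / hbar)

    def snapshot(config_time: float, frame: int) -> None:
        u_, v_ = inverse_reduced_coordinates(w, lam)
        cfg = LatticeConfiguration(u=u_, v=v_, theta=theta, phi_angle=phi,
                                   p_w=p_w, p_lambda=p_lam, p_theta=p_th,
                                   p_phi=p_ph, B=B, time=config_time)
        lam_f[:, frame] = lam
        w_f[:, frame] = w
        th_f[:, frame] = theta
        ph_f[:, frame] = phi
        B_f[:, frame] = B
        energy[frame] = total_energy(cfg, params)
        norm[frame] = float(np.sum(np.abs(B) ** 2))
        times[frame] = config_time

    snapshot(config.time, 0)
    frame = 1
    if settings.scheme == "split_step_spectral":
        for step in range(1, settings.n_steps + 1):
            B *= np.exp(-0.5j * params.chi * lam * dt / hbar)
            f_w, f_lam, f_th, f_ph = _forces(w, lam, theta, phi, B, params)
            p_w += 0.5 * dt * f_w
            p_lam += 0.5 * dt * f_lam
            p_th += 0.5 * dt * f_th
            p_ph += 0.5 * dt * f_ph
            w += dt * p_w / m
            lam += dt * p_lam / m
            theta += dt * p_th / inertia
            phi += dt * p_ph / inertia
            B = np.fft.ifft(hop_phase * np.fft.fft(B))
            f_w, f_lam, f_th, f_ph = _forces(w, lam, theta, phi, B, params)
            p_w += 0.5 * dt * f_w
            p_lam += 0.5 * dt * f_lam
            p_th += 0.5 * dt * f_th
            p_ph += 0.5 * dt * f_ph
            B *= np.exp(-0.5j * params.chi * lam * dt / hbar)
            if step % settings.record_stride == 0:
                _check_finite(settings, lam, w, theta, phi, p_lam, B)
                snapshot(config.time + step * dt, frame)
                frame += 1
    elif settings.scheme == "rk4_full":
        state = [w, lam, theta, phi, p_w, p_lam, p_th, p_ph, B]

        def deriv(s):
            w_, lam_, th_, ph_, pw_, plam_, pth_, pph_, B_ = s
            fw, flam, fth, fph = _forces(w_, lam_, th_, ph_, B_, params)
            return [pw_ / m, plam_ / m, pth_ / inertia, pph_ / inertia,
                    fw, flam, fth, fph, _b_dot(lam_, B_, params)]

        for step in range(1, settings.n_steps + 1):
            k1 = deriv(state)
            k2 = deriv([s + 0.5 * dt * k for s, k in zip(state, k1)])
            k3 = deriv([s + 0.5 * dt * k for s, k in zip(state, k2)])
            k4 = deriv([s + dt * k for s, k in zip(state, k3)])
            state = [s + dt / 6.0 * (a + 2.0 * b + 2.0 * c + d)
                     for s, a, b, c, d in zip(state, k1, k2, k3, k4)]
            if step % settings.record_stride == 0:
                w, lam, theta, phi, p_w, p_lam, p_th, p_ph, B = state
                _check_finite(settings, lam, w, theta, phi, p_lam, B)
                snapshot(config.time + step * dt, frame)
                frame += 1
        w, lam, theta, phi, p_w, p_lam, p_th, p_ph, B = state
    else:
        raise InvalidParameterError(f"unknown scheme {settings.scheme!r}")

    return Trajectory(times=times, lambda_field=lam_f, w_field=w_f,
                      theta_field=th_f, phi_field=ph_f, B_field=B_f,
                      energy_series=energy, norm_series=norm)


def charge_density(traj: Trajectory) -> np.ndarray:
    """|B|^2 per site per frame."""
    if traj.n_frames == 0:
        raise InvalidParameterError("trajectory has no frames")
    return np.abs(traj.B_field) ** 2


def localization_metrics(density: np.ndarray):
    """Participation ratio and peak fraction per frame.

    participation_ratio = (sum rho)^2 / (N sum rho^2): 1 for a uniform
    density, 1/N for a single-site spike.  peak_fraction = max rho / sum rho.
    """
    rho = np.asarray(density, dtype=float)
    if rho.ndim == 1:
        rho = rho[:, None]
    total = rho.sum(axis=0)
    if np.any(total <= 0):
        raise AllZeroFrameError("charge density vanishes on at least one frame")
    n = rho.shape[0]
    pr = total ** 2 / (n * np.sum(rho ** 2, axis=0))
    peak = rho.max(axis=0) / total
    return pr, peak


_FIELD_ATTR = {"lambda": "lambda_field", "charge": "B_field",
               "theta": "theta_field", "phi": "phi_field", "w": "w_field"}


def mode_amplitude_series(traj: Trajectory, k: float,
                          field: str = "lambda") -> np.ndarray:
    """|Fourier amplitude| of the lattice-resonant mode nearest k, per frame."""
    n = traj.n_sites
    idx = round(k * n / (2.0 * math.pi)) % n
    try:
        data = getattr(traj, _FIELD_ATTR[field])
    except KeyError:
        raise InvalidParameterError(
            f"unknown field {field!r}; choose from {sorted(_FIELD_ATTR)}") from None
    return np.abs(np.fft.fft(data, axis=0)[idx, :]) / n


@dataclass(frozen=True)
class GrowthRateFit:
    """Least-squares exponential growth rate of one Fourier mode."""

    rate: float
    t_start: float
    t_end: float
    n_points: int
    mode_index: int
    field: str


def measure_growth_rate(traj: Trajectory, K1: float,
                        field: str = "lambda",
                        fold_limit: float = 10.0) -> GrowthRateFit:
    """Exponential growth rate of the K1 Fourier mode.

    Fits the slope of log|amplitude| versus time over the auto-selected
    linear-growth window: growth is considered over until the amplitude
    first reaches ``fold_limit`` times its initial value (or peaks), and the
    fit starts once the amplitude has cleared sqrt(fold_limit) times the
    initial value, which discards the mode-mixing transient at the start.
    Raises :class:`NoGrowthDetectedError` if the amplitude never exceeds
    twice its initial value.
    """
    n = traj.n_sites
    idx = round(K1 * n / (2.0 * math.pi)) % n
    amp = mode_amplitude_series(traj, K1, field)
    a0 = amp[0]
    if a0 <= 0:
        a0 = float(np.max(amp[:2])) or 1e-300
    if float(np.max(amp)) < 2.0 * a0:
        raise NoGrowthDetectedError(
            f"mode {idx} amplitude never exceeded twice its initial value")
    above = np.nonzero(amp >= fold_limit * a0)[0]
    end = int(above[0]) if above.size else int(np.argmax(amp))
    end = max(end, 2)
    start_factor = math.sqrt(fold_limit) if fold_limit > 4.0 else 1.0
    started = np.nonzero(amp[:end] >= start_factor * a0)[0]
    start = int(started[0]) if started.size else 0
    if end - start < 2:
        start = max(0, end - 2)
    window = slice(start, end + 1)
    t = traj.times[window]
    y = np.log(np.maximum(amp[window], 1e-300))
    slope = float(np.polyfit(t, y, 1)[0])
    return GrowthRateFit(rate=slope, t_start=float(t[0]), t_end=float(t[-1]),
                         n_points=int(t.size), mode_index=idx, field=field)
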