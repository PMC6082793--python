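"""Time-domain integration of the linearized envelope system.

The modulational-instability gain is a property of the three coupled
continuum envelope equations.  This module integrates their linearization
about the plane-wave background — five real fields
(u, v) = (Re, Im) of the charge-envelope perturbation, the stretch
perturbation lambda1, and (u1, v2) = (Re, Im) of the rotational-envelope
perturbation — on a periodic grid with spectral spatial derivatives and RK4
time stepping.  A perturbation seeded at wavenumber K1 then grows at
max |Im Omega(K1)|, providing a time-domain route to the gain that is
independent of the determinant-interpolation / root-finding route of
:mod:`pbhsolv.mi`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .continuum import ContinuumCoefficients, PlaneWaveBackground
from .dynamics import Trajectory, resonant_wavenumber
from .errors import InvalidParameterError, NumericalBlowupError

__all__ = ["integrate_linearized", "suggest_time_step"]


def _spectral_operators(n_sites: int):
    q = 2.0 * np.pi * np.fft.fftfreq(n_sites)
    return 1j * q, -(q ** 2)


def suggest_time_step(coeffs: ContinuumCoefficients,
                      background: PlaneWaveBackground, n_sites: int,
                      safety: float = 0.1) -> float:
    """Stable RK4 step from the largest resolvable mode frequency.

    The stiffest terms are the K1^2 pieces of the diagonal entries at the
    grid's Nyquist wavenumber.
    """
    k_max = math.pi
    scale = max(abs(coeffs.P1) * k_max ** 2 + abs(coeffs.Q1),
                abs(coeffs.c0) * k_max ** 2 + abs(coeffs.A),
                abs(coeffs.c1) * k_max ** 2 + background.w0 ** 2 + abs(coeffs.Q5),
                1.0)
    return safety / math.sqrt(scale)


def integrate_linearized(coeffs: ContinuumCoefficients,
                         background: PlaneWaveBackground,
                         n_sites: int, K1: float, dt: float, n_steps: int,
                         record_stride: int = 1,
                         perturbation_amplitude: float = 1e-4,
                         seed: int = 0,
                         blowup_guard: float = 1e12) -> Trajectory:
    """Integrate the linearized envelope equations seeded at wavenumber K1.

    The five fields are initialized with independent seeded random phases on
    the lattice-resonant mode nearest K1 (amplitude
    ``perturbation_amplitude``), so a generic mixture of the eight
    eigenmodes is excited and the fastest-growing one dominates after a
    transient.  The returned :class:`~pbhsolv.dynamics.Trajectory` maps
    u + i v onto ``B_field``, lambda1 onto ``lambda_field`` and (u1, v2)
    onto (``theta_field``, ``phi_field``); ``norm_series`` holds the total
    squared amplitude of all five fields.
    """
    if n_steps < 1 or record_stride < 1 or n_steps % record_stride != 0:
        raise InvalidParameterError("record_stride must divide n_steps")
    c, bg = coeffs, background
    n = int(n_sites)
    d1, d2 = _spectral_operators(n)
    K1r = resonant_wavenumber(K1, n)
    sites = np.arange(n)
    rng = np.random.default_rng(seed)

    def seeded_mode():
        phase = rng.uniform(0.0, 2.0 * math.pi)
        return perturbation_amplitude * np.cos(K1r * sites + phase)

    # state: u, v, lam1, lam1_t, u1, u1_t, v2, v2_t
    state = np.zeros((8, n))
    state[0] = seeded_mode()
    state[1] = seeded_mode()
    state[2] = seeded_mode()
    state[4] = seeded_mode()
    state[6] = seeded_mode()

    a1, a2, b1, b2 = bg.a1, bg.a2, bg.b1, bg.b2
    lam0, w0, K = bg.lambda0, bg.w0, bg.K
    m33_onsite = c.A - 2.0 * c.B_nl * lam0 + 3.0 * c.W_g * lam0 ** 2
    # per-row rotational couplings, literally from the linearized equations
    slope = -c.Q3 + 2.0 * c.Q4 * lam0 - 3.0 * c.gamma * lam0 ** 2
    diag_rot = w0 ** 2 + c.c1 * K ** 2 + c.Q3 * lam0 + c.beta_gamma * lam0 ** 3 - c.Q5

    def dxx(f):
        return np.fft.ifft(d2 * np.fft.fft(f)).real

    def dx(f):
        return np.fft.ifft(d1 * np.fft.fft(f)).real

    def deriv(s):
        u, v, lam1, lam1_t, u1, u1_t, v2, v2_t = s
        u_t = -(c.P1 * dxx(v) + c.Q1 * v + c.Q2 * a2 * lam1)
        v_t = c.P1 * dxx(u) + c.Q1 * u + c.Q2 * a1 * lam1
        lam1_tt = -(c.c0 * dxx(lam1) + m33_onsite * lam1
                    + 2.0 * c.c2 * (a1 * u + a2 * v))
        u1_tt = (-2.0 * w0 * v2_t + diag_rot * u1
                 - c.c1 * (dxx(u1) - 2.0 * K * dx(v2))
                 - slope * b1 * lam1)
        v2_tt = (2.0 * w0 * u1_t + diag_rot * v2
                 - c.c1 * (dxx(v2) + 2.0 * K * dx(u1))
                 - slope * b2 * lam1)
        return np.array([u_t, v_t, lam1_t, lam1_tt, u1_t, u1_tt, v2_t, v2_tt])

    n_frames = 1 + n_steps // record_stride
    times = np.empty(n_frames)
    lam_f = np.empty((n, n_frames))
    w_f = np.zeros((n, n_frames))
    th_f = np.empty((n, n_frames))
    ph_f = np.empty((n, n_frames))
    B_f = np.empty((n, n_frames), dtype=complex)
    norm = np.empty(n_frames)
    energy = np.empty(n_frames)

    def snapshot(t, frame, s):
        times[frame] = t
        lam_f[:, frame] = s[2]
        th_f[:, frame] = s[4]
        ph_f[:, frame] = s[6]
        B_f[:, frame] = s[0] + 1j * s[1]
        norm[frame] = float(np.sum(s[0] ** 2 + s[1] ** 2 + s[2] ** 2
                                   + s[4] ** 2 + s[6] ** 2))
        energy[frame] = norm[frame]

    snapshot(0.0, 0, state)
    frame = 1
    for step in range(1, n_steps + 1):
        k1 = deriv(state)
        k2 = deriv(state + 0.5 * dt * k1)
        k3 = deriv(state + 0.5 * dt * k2)
        k4 = deriv(state + dt * k3)
        state = state + dt / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if step % record_stride == 0:
            m = float(np.max(np.abs(state)))
            if not np.isfinite(m) or m > blowup_guard:
                raise NumericalBlowupError(
                    f"envelope field magnitude {m!r} exceeds guard; reduce dt")
            snapshot(step * dt, frame, state)
            frame += 1
    return Trajectory(times=times, lambda_field=lam_f, w_field=w_f,
                      theta_field=th_f, phi_field=ph_f, B_field=B_f,
                      energy_series=energy, norm_series=norm)
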