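"""Extended Peyrard-Bishop lattice with solvent interaction and charge coupling.

Each base pair j carries two strand displacements (u_j, v_j), two rotation
angles (theta_j, phi_j) of the base discs, and a complex charge amplitude B_j.
The on-site hydrogen-bond energy is a Morse well in the bond stretch

    y_j - y_0 = sqrt(2) * lambda_j - g(phi_j, theta_j),
    g(phi, theta) = r * (cos(phi) + cos(theta)),

supplemented by a solvent term D * f_s * (tanh(x / l_s) - 1) that saturates
for widely opened pairs.  Neighbouring sites are coupled harmonically
(stacking constants k and xi) and the charge hops with transfer integral V
while its on-site energy shifts linearly with lambda_j (Holstein coupling
chi).  All energies are in eV, lengths in angstrom, masses in amu, angles in
rad; see :mod:`pbhsolv.units` for the derived time unit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Literal

import numpy as np

from .errors import (
    DegenerateProfileError,
    InvalidParameterError,
    ShapeMismatchError,
)
from .units import HBAR_EFF_DEFAULT

__all__ = [
    "MicroscopicParameters",
    "LatticeConfiguration",
    "PotentialProfile",
    "BarrierMetrics",
    "reduced_coordinates",
    "inverse_reduced_coordinates",
    "angle_projection",
    "hbond_stretch",
    "morse_energy",
    "solvent_energy",
    "onsite_stretch_energy",
    "onsite_stretch_derivative",
    "solvent_shifted_minimum",
    "onsite_potential_profile",
    "barrier_metrics",
    "total_energy",
]

SQRT2 = math.sqrt(2.0)

SolventOrientation = Literal["printed", "barrier"]


@dataclass(frozen=True)
class MicroscopicParameters:
    """Physical constants of the extended PB model with charge coupling.

    Attributes
    ----------
    m : nucleotide mass (amu)
    inertia : moment of inertia of a base disc (amu * A**2)
    k_stack : longitudinal/transverse stacking constant (eV / A**2)
    xi_stack : angular stacking constant (eV / rad**2)
    D : Morse dissociation energy (eV)
    a : Morse inverse width (1/A)
    r : disc radius (A)
    d : inter-disc gap (A); cancels from all energies, default 0
    f_s : solvent amplitude factor (dimensionless)
    l_s : solvent range (A)
    V_hop : charge transfer integral (eV)
    chi : charge-lattice (Holstein) coupling (eV / A)
    hbar_eff : reduced action constant (eV * t*); set to 1 for
        dimensionless studies
    rest_angle : equilibrium disc angle (rad).  The default pi/2 puts the
        Morse minimum at lambda = 0 for the undistorted lattice
        (g(pi/2, pi/2) = 0).
    """

    m: float = 300.0
    inertia: float = 300.0
    k_stack: float = 2.04
    xi_stack: float = 2.04
    D: float = 4.05
    a: float = 4.41
    r: float = 0.3
    d: float = 0.0
    f_s: float = 0.0
    l_s: float = 1.0
    V_hop: float = 0.05
    chi: float = 1.2
    hbar_eff: float = HBAR_EFF_DEFAULT
    rest_angle: float = math.pi / 2.0

    def __post_init__(self) -> None:
        positive = ("m", "inertia", "D", "a", "l_s", "hbar_eff")
        nonneg = ("r", "d", "f_s", "k_stack", "xi_stack")
        for name in positive:
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be > 0, got {getattr(self, name)!r}")
        for name in nonneg:
            if not getattr(self, name) >= 0:
                raise InvalidParameterError(f"{name} must be >= 0, got {getattr(self, name)!r}")

    @property
    def y0(self) -> float:
        """Equilibrium disc-centre separation 2r + d (derived, never stored)."""
        return 2.0 * self.r + self.d

    def with_(self, **kwargs) -> "MicroscopicParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, data: dict) -> "MicroscopicParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidParameterError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in data.items()})


@dataclass
class LatticeConfiguration:
    """Per-site state of the lattice: displacements, angles, momenta, charge.

    Boundary conditions are periodic; all index arithmetic is modulo
    ``n_sites``.
    """

    u: np.ndarray
    v: np.ndarray
    theta: np.ndarray
    phi_angle: np.ndarray
    p_w: np.ndarray
    p_lambda: np.ndarray
    p_theta: np.ndarray
    p_phi: np.ndarray
    B: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        arrays = [self.u, self.v, self.theta, self.phi_angle,
                  self.p_w, self.p_lambda, self.p_theta, self.p_phi, self.B]
        n = len(self.u)
        for arr in arrays:
            if len(arr) != n:
                raise ShapeMismatchError(
                    f"per-site arrays must all have length {n}, got {len(arr)}")
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        self.phi_angle = np.asarray(self.phi_angle, dtype=float)
        self.p_w = np.asarray(self.p_w, dtype=float)
        self.p_lambda = np.asarray(self.p_lambda, dtype=float)
        self.p_theta = np.asarray(self.p_theta, dtype=float)
        self.p_phi = np.asarray(self.p_phi, dtype=float)
        self.B = np.asarray(self.B, dtype=complex)

    @property
    def n_sites(self) -> int:
        return len(self.u)

    @property
    def w(self) -> np.ndarray:
        return reduced_coordinates(self.u, self.v)[0]

    @property
    def lam(self) -> np.ndarray:
        return reduced_coordinates(self.u, self.v)[1]

    @property
    def charge_norm(self) -> float:
        return float(np.sum(np.abs(self.B) ** 2))

    @classmethod
    def rest(cls, n_sites: int, params: MicroscopicParameters,
             B: np.ndarray | None = None) -> "LatticeConfiguration":
        """Undistorted lattice at the rest angles with zero momenta."""
        z = np.zeros(n_sites)
        ang = np.full(n_sites, params.rest_angle)
        if B is None:
            B = np.zeros(n_sites, dtype=complex)
        return cls(u=z.copy(), v=z.copy(), theta=ang.copy(), phi_angle=ang.copy(),
                   p_w=z.copy(), p_lambda=z.copy(), p_theta=z.copy(), p_phi=z.copy(),
                   B=np.asarray(B, dtype=complex))

    def copy(self) -> "LatticeConfiguration":
        return LatticeConfiguration(
            u=self.u.copy(), v=self.v.copy(), theta=self.theta.copy(),
            phi_angle=self.phi_angle.copy(), p_w=self.p_w.copy(),
            p_lambda=self.p_lambda.copy(), p_theta=self.p_theta.copy(),
            p_phi=self.p_phi.copy(), B=self.B.copy(), time=self.time)

    def shifted(self, s: int) -> "LatticeConfiguration":
        """Cyclically relabel all sites by offset ``s``."""
        roll = lambda arr: np.roll(arr, s)
        return LatticeConfiguration(
            u=roll(self.u), v=roll(self.v), theta=roll(self.theta),
            phi_angle=roll(self.phi_angle), p_w=roll(self.p_w),
            p_lambda=roll(self.p_lambda), p_theta=roll(self.p_theta),
            p_phi=roll(self.p_phi), B=roll(self.B), time=self.time)


def reduced_coordinates(u, v):
    """Map strand displacements to in-phase/out-of-phase coordinates.

    w = (u + v)/sqrt(2),  lambda = (u - v)/sqrt(2).
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    return (u + v) / SQRT2, (u - v) / SQRT2


def inverse_reduced_coordinates(w, lam):
    """Inverse of :func:`reduced_coordinates`: recovers (u, v) exactly."""
    w = np.asarray(w, dtype=float)
    lam = np.asarray(lam, dtype=float)
    return (w + lam) / SQRT2, (w - lam) / SQRT2


def angle_projection(phi_angle, theta, r: float):
    """g(phi, theta) = r (cos phi + cos theta), bounded in [-2r, 2r]."""
    if r < 0:
        raise InvalidParameterError(f"r must be >= 0, got {r}")
    return r * (np.cos(phi_angle) + np.cos(theta))


def hbond_stretch(u, v, theta, phi_angle, params: MicroscopicParameters):
    """Hydrogen-bond length y = (u - v + d + 2r) - r(cos theta + cos phi).

    Satisfies y - y0 = sqrt(2)*lambda - g identically.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    return (u - v + params.d + 2.0 * params.r) - angle_projection(phi_angle, theta, params.r)


# ---------------------------------------------------------------------------
# on-site potentials as functions of the stretch x = sqrt(2)*lambda - g

def _morse_x(x, D: float, a: float):
    return D * (np.exp(-a * np.asarray(x, dtype=float)) - 1.0) ** 2


def _solvent_x(x, D: float, f_s: float, l_s: float,
               orientation: SolventOrientation = "printed"):
    if l_s <= 0:
        raise InvalidParameterError(f"l_s must be > 0, got {l_s}")
    base = np.tanh(np.asarray(x, dtype=float) / l_s) - 1.0
    if orientation == "printed":
        return D * f_s * base
    if orientation == "barrier":
        return -D * f_s * base
    raise InvalidParameterError(f"unknown solvent orientation {orientation!r}")


def morse_energy(lam, g, params: MicroscopicParameters):
    """Morse energy D [exp(-a (sqrt(2) lambda - g)) - 1]^2.

    Zero exactly on the manifold sqrt(2)*lambda = g; tends to D as the
    stretch -> +inf.
    """
    return _morse_x(SQRT2 * np.asarray(lam, dtype=float) - np.asarray(g, dtype=float),
                    params.D, params.a)


def solvent_energy(lam, g, params: MicroscopicParameters):
    """Solvent energy D f_s (tanh((sqrt(2) lambda - g)/l_s) - 1).

    Monotone nondecreasing in lambda; ranges over [-2 D f_s, 0] with value
    -D f_s at zero stretch.
    """
    x = SQRT2 * np.asarray(lam, dtype=float) - np.asarray(g, dtype=float)
    return _solvent_x(x, params.D, params.f_s, params.l_s, "printed")


def onsite_stretch_energy(x, params: MicroscopicParameters,
                          orientation: SolventOrientation = "printed"):
    """Total on-site energy U(x) + V_sol(x) as a function of the stretch x."""
    return _morse_x(x, params.D, params.a) + _solvent_x(
        x, params.D, params.f_s, params.l_s, orientation)


def onsite_stretch_derivative(x, params: MicroscopicParameters, order: int = 1,
                              orientation: SolventOrientation = "printed"):
    """d^order/dx^order of the on-site energy U(x) + V_sol(x), closed form.

    Orders 1..5 are supported (the continuum reduction needs up to the 5th
    derivative of the well).
    """
    x = np.asarray(x, dtype=float)
    D, a, f_s, l_s = params.D, params.a, params.f_s, params.l_s
    if l_s <= 0:
        raise InvalidParameterError(f"l_s must be > 0, got {l_s}")
    e = np.exp(-a * x)
    # U(x) = D(e - 1)^2 = D(e^2 - 2e + 1); d^n/dx^n e^{-kax} = (-ka)^n e^{-kax}
    if order < 1 or order > 5:
        raise InvalidParameterError(f"derivative order must be in 1..5, got {order}")
    morse = D * ((-2.0 * a) ** order * e ** 2 - 2.0 * (-a) ** order * e)
    t = np.tanh(x / l_s)
    s2 = 1.0 - t ** 2  # sech^2
    if order == 1:
        tanh_d = s2
    elif order == 2:
        tanh_d = -2.0 * t * s2
    elif order == 3:
        tanh_d = s2 * (6.0 * t ** 2 - 2.0)
    elif order == 4:
        tanh_d = s2 * t * (24.0 * s2 - 8.0)
    else:  # order == 5
        tanh_d = s2 * (16.0 - 120.0 * s2 + 120.0 * s2 ** 2)
    sol = D * f_s * tanh_d / l_s ** order
    if orientation == "barrier":
        sol = -sol
    elif orientation != "printed":
        raise InvalidParameterError(f"unknown solvent orientation {orientation!r}")
    return morse + sol


def solvent_shifted_minimum(params: MicroscopicParameters,
                            orientation: SolventOrientation = "printed") -> float:
    """Stretch x* minimizing U + V_sol (the true static equilibrium).

    With the printed solvent sign the constant force D f_s / l_s at x = 0
    shifts the minimum to x* < 0; returns 0 when f_s = 0.
    """
    if params.f_s == 0:
        return 0.0
    from scipy.optimize import brentq

    fun = lambda x: float(onsite_stretch_derivative(x, params, 1, orientation))
    lo, hi = -2.0 / params.a, 1.0 / params.a
    # widen the bracket until the derivative changes sign
    for _ in range(60):
        if fun(lo) < 0 < fun(hi) or fun(lo) > 0 > fun(hi):
            break
        lo *= 1.5
        hi *= 1.5
    else:  # pragma: no cover - pathological parameters
        raise InvalidParameterError("could not bracket the on-site minimum")
    return float(brentq(fun, lo, hi, xtol=1e-14))


@dataclass
class PotentialProfile:
    """Sampled on-site potential U + V_sol along a lambda grid at fixed angles."""

    lambda_grid: np.ndarray
    energy: np.ndarray
    phi_angle: float
    theta: float
    params: MicroscopicParameters
    solvent_orientation: SolventOrientation = "barrier"


@dataclass(frozen=True)
class BarrierMetrics:
    """Location/height of the solvent barrier beyond the Morse well."""

    has_barrier: bool
    barrier_position: float = math.nan
    barrier_height: float = math.nan
    plateau_level: float = math.nan


def onsite_potential_profile(lambda_grid, phi_angle: float, theta: float,
                             params: MicroscopicParameters,
                             solvent_orientation: SolventOrientation = "barrier",
                             ) -> PotentialProfile:
    """Evaluate U(lambda) + V_sol(lambda) at fixed disc angles.

    The default ``barrier`` orientation uses the hydration-barrier form
    D f_s (1 - tanh(x/l_s)) so that, for f_s > 0, the profile exhibits a
    local maximum of height ~ f_s * D above the dissociation plateau; with
    ``printed`` the literal tanh - 1 form is used instead (monotone past the
    well, no barrier).  With f_s = 0 both coincide with the pure Morse
    profile.
    """
    grid = np.asarray(lambda_grid, dtype=float)
    if grid.size == 0:
        raise InvalidParameterError("lambda grid must be nonempty")
    if grid.size > 1 and not np.all(np.diff(grid) > 0):
        raise InvalidParameterError("lambda grid must be strictly increasing")
    g = float(angle_projection(phi_angle, theta, params.r))
    x = SQRT2 * grid - g
    energy = onsite_stretch_energy(x, params, solvent_orientation)
    return PotentialProfile(lambda_grid=grid, energy=np.asarray(energy, dtype=float),
                            phi_angle=phi_angle, theta=theta, params=params,
                            solvent_orientation=solvent_orientation)


def barrier_metrics(profile: PotentialProfile) -> BarrierMetrics:
    """Quantify the interior maximum (barrier) of a sampled profile.

    The barrier is the argmax of the profile restricted to the region beyond
    the closed-state well — the leftmost interior local minimum (for large
    f_s * D the solvent-stabilised open state at large stretch can lie lower
    than the well, so the global minimum is not the right bracket).  Its
    height is measured above the plateau level (the last grid value, which
    approaches D for a sufficiently wide grid).  Returns a flagged
    no-barrier result when the restricted profile has no interior local
    maximum.
    """
    grid, energy = profile.lambda_grid, profile.energy
    if grid.size < 3:
        raise DegenerateProfileError(
            f"need at least 3 grid points to bracket an extremum, got {grid.size}")
    interior_minima = np.nonzero((energy[1:-1] < energy[:-2])
                                 & (energy[1:-1] < energy[2:]))[0] + 1
    i_min = int(interior_minima[0]) if interior_minima.size else int(np.argmin(energy))
    seg = energy[i_min:]
    if seg.size < 3:
        return BarrierMetrics(has_barrier=False)
    j = int(np.argmax(seg))
    # interior strict local maximum within the post-well segment
    if j == 0 or j == seg.size - 1:
        return BarrierMetrics(has_barrier=False)
    if not (seg[j] > seg[j - 1] and seg[j] > seg[j + 1]):
        return BarrierMetrics(has_barrier=False)
    i = i_min + j
    # parabolic refinement of position/height through the three bracketing samples
    x0, x1, x2 = grid[i - 1:i + 2]
    y0_, y1_, y2_ = energy[i - 1:i + 2]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a_coef = (x2 * (y1_ - y0_) + x1 * (y0_ - y2_) + x0 * (y2_ - y1_)) / denom
    b_coef = (x2 ** 2 * (y0_ - y1_) + x1 ** 2 * (y2_ - y0_) + x0 ** 2 * (y1_ - y2_)) / denom
    if a_coef < 0:
        pos = -b_coef / (2.0 * a_coef)
        c_coef = y1_ - a_coef * x1 ** 2 - b_coef * x1
        height_at = a_coef * pos ** 2 + b_coef * pos + c_coef
    else:  # flat to machine precision; keep the sampled point
        pos, height_at = float(x1), float(y1_)
    plateau = float(energy[-1])
    return BarrierMetrics(has_barrier=True, barrier_position=float(pos),
                          barrier_height=float(height_at - plateau),
                          plateau_level=plateau)


def total_energy(config: LatticeConfiguration, params: MicroscopicParameters) -> float:
    """Total semiclassical energy H1 + <H2> + <H3> with periodic boundaries.

    H1 is the classical lattice Hamiltonian (kinetic + stacking + on-site
    Morse and solvent terms), <H2> = -V sum_j (B_j* B_{j+1} + B_j* B_{j-1})
    is the charge hopping expectation (real by construction; for a single
    site the periodic convention makes each site its own neighbour), and
    <H3> = chi sum_j lambda_j |B_j|^2 is the Holstein coupling.
    """
    w, lam = reduced_coordinates(config.u, config.v)
    kinetic = (np.sum(config.p_w ** 2) + np.sum(config.p_lambda ** 2)) / (2.0 * params.m) \
        + (np.sum(config.p_phi ** 2) + np.sum(config.p_theta ** 2)) / (2.0 * params.inertia)
    dw = w - np.roll(w, 1)
    dlam = lam - np.roll(lam, 1)
    dphi = config.phi_angle - np.roll(config.phi_angle, 1)
    dtheta = config.theta - np.roll(config.theta, 1)
    stacking = 0.5 * params.k_stack * (np.sum(dw ** 2) + np.sum(dlam ** 2)) \
        + 0.5 * params.xi_stack * (np.sum(dphi ** 2) + np.sum(dtheta ** 2))
    g = angle_projection(config.phi_angle, config.theta, params.r)
    onsite = float(np.sum(morse_energy(lam, g, params) + solvent_energy(lam, g, params)))
    hop = -params.V_hop * np.sum(
        np.conj(config.B) * (np.roll(config.B, -1) + np.roll(config.B, 1)))
    holstein = params.chi * np.sum(lam * np.abs(config.B) ** 2)
    return float(kinetic + stacking + onsite + hop.real + holstein)
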