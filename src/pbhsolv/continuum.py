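"""Continuum envelope coefficients and plane-wave backgrounds.

In the continuum limit the discrete lattice reduces to three coupled envelope
equations for the charge envelope phi, the stretch field lambda and the
in-phase rotational envelope psi:

    i phi_t + P1 phi_xx + Q1 phi + Q2 lambda phi = 0
    lambda_tt + c0 lambda_xx + (A - 2 B_nl lambda0 + 3 W_g lambda0^2) lambda1
        + 2 c2 (a1 u + a2 v) = 0                       (linearized form)
    psi_tt +- 2 w0 psi-cross terms + c1 (psi_xx ...) + on-site terms = 0

with on-site rotational coefficients Q3, Q4, Q5 and the cubic pair
beta*gamma.  The plane-wave background phi = phi0 exp(i(kx - w0 t)),
lambda = lambda0, psi = psi0 exp(i(kx - w0 t)) must satisfy the quadratic
dispersion relation w0^2 - w0 + Q' = 0 and the biquadratic
k^4 - mu k^2 + mu1 = 0.

The mapping from microscopic lattice constants to these coefficients
(:func:`derive_continuum_coefficients`) is this package's own reconstruction
of the gradient-expansion / Taylor-expansion reduction; every derived value
carries a provenance note and can be overridden.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Literal

import numpy as np

from .errors import InvalidParameterError
from .model import (
    SQRT2,
    MicroscopicParameters,
    onsite_stretch_derivative,
    solvent_shifted_minimum,
)

__all__ = [
    "ContinuumCoefficients",
    "PlaneWaveBackground",
    "derive_continuum_coefficients",
    "q_prime",
    "background_frequencies",
    "background_wavenumbers",
    "make_background",
]


@dataclass(frozen=True)
class ContinuumCoefficients:
    """Coefficients of the three coupled envelope equations (internal units).

    P1, Q1, Q2 govern the charge envelope; c0, c1, c2 are the
    second-derivative/coupling coefficients of the lattice and rotational
    equations; A, B_nl, W_g are the linear/quadratic/cubic on-site lattice
    force coefficients; Q3, Q4, Q5 and beta*gamma are the rotational
    on-site expansion coefficients.
    """

    P1: float
    Q1: float = 0.0
    Q2: float = 0.0
    Q3: float = 0.0
    Q4: float = 0.0
    Q5: float = 0.0
    c0: float = 0.0
    c1: float = 0.0
    c2: float = 0.0
    A: float = 0.0
    B_nl: float = 0.0
    W_g: float = 0.0
    beta: float = 0.0
    gamma: float = 1.0

    def __post_init__(self) -> None:
        for f in fields(self):
            val = getattr(self, f.name)
            if not math.isfinite(val):
                raise InvalidParameterError(f"{f.name} must be finite, got {val!r}")
        if self.P1 == 0:
            raise InvalidParameterError("P1 must be nonzero (it divides Q')")

    @property
    def beta_gamma(self) -> float:
        return self.beta * self.gamma

    def with_(self, **kwargs) -> "ContinuumCoefficients":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, data: dict) -> "ContinuumCoefficients":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidParameterError(f"unknown coefficient keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in data.items()})


def derive_continuum_coefficients(
    params: MicroscopicParameters,
    lattice_spacing: float = 1.0,
    expand_about: Literal["zero", "minimum"] = "zero",
    with_provenance: bool = False,
):
    """Map microscopic lattice constants to envelope coefficients.

    This is a reconstruction of the continuum reduction (the gradient
    expansion of the stacking differences plus Taylor expansion of the
    on-site well), not a transcription of a published table:

    * charge envelope (from i hbar B_t = -V(B_+ + B_-) + chi lambda B with
      B ~ phi exp(...)): ``P1 = V l^2 / hbar``, ``Q1 = 2 V / hbar``,
      ``Q2 = -chi / hbar``;
    * gradient coefficients: ``c0 = k l^2 / m``, ``c1 = xi l^2 / I``,
      ``c2 = chi / m`` (charge back-reaction on the stretch);
    * lattice on-site force per unit mass, f = A*dl - B_nl*dl^2 + W_g*dl^3,
      from derivatives of W(x) = U + V_sol at the reference stretch x_ref:
      ``A = 2 W''/m``, ``B_nl = -sqrt(2)^3 W'''/(2m)``, ``W_g = 4 W''''/(6m)``
      (the sqrt(2)^n factors convert x-derivatives to lambda-derivatives);
    * rotational on-site stiffness S(dl) = (2 r^2 / I) W''(x_ref + sqrt(2) dl)
      expanded as Q5 - Q3*dl + Q4*dl^2 - beta*gamma*dl^3, so
      ``Q5 = 2 r^2 W''/I``, ``Q3 = -2 sqrt(2) r^2 W'''/I``,
      ``Q4 = 2 r^2 W''''/I``, ``beta*gamma = -(2 sqrt(2) r^2 / (3 I)) W'''''``
      (gamma is fixed at 1 and beta carries the product).

    ``expand_about="zero"`` (default) expands about zero stretch, treating
    lambda0 as a free background the way the plane-wave analysis does (the
    solvent's static tilt is ignored); ``"minimum"`` expands about the
    solvent-shifted static equilibrium instead.  ``lattice_spacing`` is in
    angstrom per site; the default 1 measures x in sites, matching
    wavenumbers quoted in rad/site.
    """
    ell = float(lattice_spacing)
    if ell <= 0:
        raise InvalidParameterError(f"lattice_spacing must be > 0, got {ell}")
    x_ref = solvent_shifted_minimum(params) if expand_about == "minimum" else 0.0
    d2, d3, d4, d5 = (float(onsite_stretch_derivative(x_ref, params, n))
                      for n in (2, 3, 4, 5))
    m, inertia, r = params.m, params.inertia, params.r
    hbar = params.hbar_eff
    coeffs = ContinuumCoefficients(
        P1=params.V_hop * ell ** 2 / hbar,
        Q1=2.0 * params.V_hop / hbar,
        Q2=-params.chi / hbar,
        c0=params.k_stack * ell ** 2 / m,
        c1=params.xi_stack * ell ** 2 / inertia,
        c2=params.chi / m,
        A=2.0 * d2 / m,
        B_nl=-(SQRT2 ** 3) * d3 / (2.0 * m),
        W_g=4.0 * d4 / (6.0 * m),
        Q5=2.0 * r ** 2 * d2 / inertia,
        Q3=-2.0 * SQRT2 * r ** 2 * d3 / inertia,
        Q4=2.0 * r ** 2 * d4 / inertia,
        beta=-(2.0 * SQRT2 * r ** 2 / (3.0 * inertia)) * d5,
        gamma=1.0,
    )
    if not with_provenance:
        return coeffs
    provenance = {
        "expand_about": expand_about,
        "x_ref": x_ref,
        "lattice_spacing": ell,
        "well_derivatives": {"d2": d2, "d3": d3, "d4": d4, "d5": d5},
        "note": "reconstructed gradient/Taylor continuum reduction; overridable",
    }
    return coeffs, provenance


def q_prime(coeffs: ContinuumCoefficients, lambda0: float, chi: float) -> float:
    """Q' = -((Q1 + Q2 lambda0 chi)/P1 + Q3 lambda0 + Q4 lambda0^2 + Q5
    - beta gamma lambda0^3)."""
    if coeffs.P1 == 0:
        raise InvalidParameterError("P1 must be nonzero")
    return -((coeffs.Q1 + coeffs.Q2 * lambda0 * chi) / coeffs.P1
             + coeffs.Q3 * lambda0 + coeffs.Q4 * lambda0 ** 2 + coeffs.Q5
             - coeffs.beta_gamma * lambda0 ** 3)


def background_frequencies(qp: float):
    """Roots (1 +- sqrt(1 - 4 Q'))/2 of w0^2 - w0 + Q' = 0.

    Returns ``(w0_plus, w0_minus, complex_background)``; the flag is True
    when Q' > 1/4 and the roots are a complex-conjugate pair.
    """
    disc = 1.0 - 4.0 * qp
    complex_background = disc < 0
    root = np.sqrt(complex(disc)) if complex_background else math.sqrt(disc)
    w_plus = (1.0 + root) / 2.0
    w_minus = (1.0 - root) / 2.0
    if not complex_background:
        w_plus, w_minus = float(w_plus), float(w_minus)
    return w_plus, w_minus, complex_background


def background_wavenumbers(coeffs: ContinuumCoefficients, lambda0: float, chi: float):
    """Roots k+-^2 of k^4 - mu k^2 + mu1 = 0, with (mu, mu1) exposed.

    mu = -(1 + 2 P1 Q1 + 2 P1 Q2 chi lambda0)/P1^2 and
    mu1 = (-P1 mu / 2 - 1/(2 P1))^2 + Q3 lambda0 + Q4 lambda0^2 + Q5
    - beta gamma lambda0^3.  Returns
    ``(k_plus_sq, k_minus_sq, mu, mu1, complex_wavenumber)``.
    """
    P1 = coeffs.P1
    if P1 == 0:
        raise InvalidParameterError("P1 must be nonzero")
    mu = -(1.0 + 2.0 * P1 * coeffs.Q1 + 2.0 * P1 * coeffs.Q2 * chi * lambda0) / P1 ** 2
    mu1 = (-P1 * mu / 2.0 - 1.0 / (2.0 * P1)) ** 2 \
        + coeffs.Q3 * lambda0 + coeffs.Q4 * lambda0 ** 2 + coeffs.Q5 \
        - coeffs.beta_gamma * lambda0 ** 3
    disc = mu ** 2 - 4.0 * mu1
    complex_wavenumber = disc < 0
    root = np.sqrt(complex(disc)) if complex_wavenumber else math.sqrt(disc)
    k_plus_sq = (mu + root) / 2.0
    k_minus_sq = (mu - root) / 2.0
    if not complex_wavenumber:
        k_plus_sq, k_minus_sq = float(k_plus_sq), float(k_minus_sq)
    return k_plus_sq, k_minus_sq, mu, mu1, complex_wavenumber


@dataclass(frozen=True)
class PlaneWaveBackground:
    """Plane-wave background of the coupled envelope system.

    Conventions: phi0 = a1 (1 + i) and psi0 = b1 (1 + i) (the a1 = a2,
    b1 = b2 simplification); w0 is the selected root of the background
    dispersion relation and K is the carrier wavenumber entering the
    linearized rotational equations.
    """

    a1: float
    b1: float
    lambda0: float
    w0: float
    K: float = 0.0
    k_carrier: float = 0.0
    branch: Literal["plus", "minus"] = "plus"
    qp: float = 0.0

    @property
    def a2(self) -> float:
        return self.a1

    @property
    def b2(self) -> float:
        return self.b1

    def dispersion_residual(self) -> float:
        """|w0^2 - w0 + Q'| — zero for a consistent background."""
        return abs(self.w0 ** 2 - self.w0 + self.qp)


def make_background(coeffs: ContinuumCoefficients, lambda0: float, chi: float,
                    phi0_amp: float, psi0_amp: float, K: float = 0.0,
                    branch: Literal["plus", "minus"] = "plus") -> PlaneWaveBackground:
    """Build a consistent background: w0 from the dispersion relation,
    a1 = |phi0|/sqrt(2), b1 = |psi0|/sqrt(2), carrier wavenumber from the
    biquadratic when it has a real root (0 otherwise)."""
    qp = q_prime(coeffs, lambda0, chi)
    w_plus, w_minus, complex_bg = background_frequencies(qp)
    w0 = w_plus if branch == "plus" else w_minus
    if complex_bg:
        w0 = w0.real  # real part of the complex pair; flagged by qp > 1/4
    kp, km, _, _, complex_k = background_wavenumbers(coeffs, lambda0, chi)
    k_carrier = 0.0
    if not complex_k:
        for k2 in (kp, km):
            if k2 >= 0:
                k_carrier = math.sqrt(k2)
                break
    return PlaneWaveBackground(a1=phi0_amp / SQRT2, b1=psi0_amp / SQRT2,
                               lambda0=lambda0, w0=float(w0), K=K,
                               k_carrier=k_carrier, branch=branch, qp=qp)
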