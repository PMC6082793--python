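"""Linear-stability (modulational instability) analysis.

A modulated perturbation exp(i(K1 x - Omega t)) on the plane-wave background
couples five amplitudes (Re/Im of the charge envelope, the stretch
perturbation, and Re/Im of the rotational envelope) through a 5x5 matrix
whose determinant must vanish; the resulting degree-8 polynomial in Omega is
the dispersion relation of the perturbation.  Temporal gain is max |Im Omega|
over the eight branches at real K1; spatial gain is max |Im K1| at real
Omega.

Two matrix modes are supported: ``printed`` assembles the matrix entries in
their published closed forms; ``derived`` regenerates the rotational block
directly from the linearized envelope equations (which carry the 2*w0*Omega
and 2*c1*K*K1 cross terms the printed block drops).  The dispersion
polynomial is always obtained from the determinant itself (interpolation at
Chebyshev nodes); the published coefficient formulas are retained only as an
audit target for :func:`coefficient_discrepancy_report`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np

from .continuum import ContinuumCoefficients, PlaneWaveBackground
from .errors import (
    InterpolationFailureError,
    InvalidParameterError,
    RootRefinementError,
    UnknownModeError,
)

__all__ = [
    "MatrixMode",
    "PerturbationProblem",
    "GainCurve",
    "GainSurface",
    "StabilityMap",
    "matrix_entries",
    "perturbation_matrix",
    "determinant",
    "polynomial_from_determinant",
    "printed_polynomial_coefficients",
    "printed_dispersion_polynomial",
    "coefficient_discrepancy_report",
    "solve_omega",
    "temporal_gain",
    "spatial_gain",
    "stability_map",
]

MatrixMode = Literal["printed", "derived"]

#: default gain threshold separating numerical noise from genuine instability
STABILITY_THRESHOLD_DEFAULT = 1e-6


@dataclass(frozen=True)
class PerturbationProblem:
    """Entries of the 5x5 linearized perturbation matrix at one wavenumber K1."""

    K1: float
    m11: float
    m13: float
    m23: float
    m31: float
    m32: float
    m33: float
    m43_row4: float
    m43_row5: float
    m44: float
    m45: float
    w0: float
    mode: MatrixMode = "derived"

    def entries(self) -> dict:
        return {k: getattr(self, k) for k in
                ("m11", "m13", "m23", "m31", "m32", "m33",
                 "m43_row4", "m43_row5", "m44", "m45")}


def matrix_entries(coeffs: ContinuumCoefficients, background: PlaneWaveBackground,
                   K1: float, mode: MatrixMode = "derived") -> PerturbationProblem:
    """Populate the perturbation-matrix entries at wavenumber K1.

    Common entries: m11 = -P1 K1^2 + Q1, m13 = Q2 a1, m23 = Q2 a2,
    m31 = 2 c2 a1, m32 = 2 c2 a2, m45 = -c1 K K1 and
    m33 = A - 2 B_nl lambda0 + 3 W_g lambda0^2 - c0 K1^2 (the published
    alpha0 read as lambda0).  The rotational entries differ between modes:
    the printed forms carry +Q3*lambda0 in m44 and mix b1/b2 in a single
    m43, while the derived forms follow the linearized envelope equations
    literally (-Q3*lambda0, per-row b1/b2).
    """
    c = coeffs
    bg = background
    lam0 = bg.lambda0
    common = dict(
        K1=float(K1),
        m11=-c.P1 * K1 ** 2 + c.Q1,
        m13=c.Q2 * bg.a1,
        m23=c.Q2 * bg.a2,
        m31=2.0 * c.c2 * bg.a1,
        m32=2.0 * c.c2 * bg.a2,
        m33=c.A - 2.0 * c.B_nl * lam0 + 3.0 * c.W_g * lam0 ** 2 - c.c0 * K1 ** 2,
        m45=-c.c1 * bg.K * K1,
        w0=bg.w0,
        mode=mode,
    )
    if mode == "printed":
        m43 = -c.Q3 * bg.b1 + 2.0 * c.Q4 * lam0 * bg.b2 \
            - 3.0 * c.beta * lam0 ** 2 * c.gamma * bg.b2
        m44 = -bg.w0 ** 2 - c.c1 * K1 ** 2 - c.c1 * bg.K ** 2 \
            - c.beta_gamma * lam0 ** 3 + c.Q3 * lam0 + c.Q5
        return PerturbationProblem(m43_row4=m43, m43_row5=m43, m44=m44, **common)
    if mode == "derived":
        slope = -c.Q3 + 2.0 * c.Q4 * lam0 - 3.0 * c.gamma * lam0 ** 2
        m44 = -bg.w0 ** 2 - c.c1 * K1 ** 2 - c.c1 * bg.K ** 2 \
            - c.Q3 * lam0 - c.beta_gamma * lam0 ** 3 + c.Q5
        return PerturbationProblem(m43_row4=slope * bg.b1, m43_row5=slope * bg.b2,
                                   m44=m44, **common)
    raise UnknownModeError(f"unknown matrix mode {mode!r}")


def perturbation_matrix(prob: PerturbationProblem, Omega: complex) -> np.ndarray:
    """Assemble the 5x5 complex perturbation matrix at frequency Omega."""
    O = complex(Omega)
    p = prob
    M = np.zeros((5, 5), dtype=complex)
    M[0, :3] = (p.m11, 1j * O, p.m13)
    M[1, :3] = (-1j * O, p.m11, p.m23)
    M[2, :3] = (p.m31, p.m32, -O ** 2 + p.m33)
    if p.mode == "printed":
        off = O + p.m45
    elif p.mode == "derived":
        # 2 w0 Omega + 2 c1 K K1 = 2 w0 Omega - 2 m45
        off = 2.0 * p.w0 * O - 2.0 * p.m45
    else:
        raise UnknownModeError(f"unknown matrix mode {p.mode!r}")
    M[3, 2] = p.m43_row4
    M[4, 2] = p.m43_row5
    M[3, 3] = -O ** 2 + p.m44
    M[4, 4] = -O ** 2 + p.m44
    M[3, 4] = -1j * off
    M[4, 3] = 1j * off
    return M


def determinant(matrix: np.ndarray) -> complex:
    """LU determinant of an assembled matrix."""
    return complex(np.linalg.det(np.asarray(matrix, dtype=complex)))


def _interpolate_polynomial(fun: Callable[[complex], complex], degree: int,
                            scale: float, n_probes: int = 100,
                            rtol: float = 1e-8, rng_seed: int = 0) -> np.ndarray:
    """Reconstruct a polynomial from point evaluations at Chebyshev nodes.

    Returns ascending coefficients; validates reproduction at random probes
    relative to the largest sampled magnitude, enlarging the interval twice
    before giving up.
    """
    rng = np.random.default_rng(rng_seed)
    last_err = math.inf
    for attempt in range(3):
        s = scale * (2.0 ** attempt)
        n_nodes = 2 * degree + 1
        z = np.cos(np.pi * (np.arange(n_nodes) + 0.5) / n_nodes)  # Chebyshev nodes
        omega = s * z
        y = np.array([fun(o) for o in omega], dtype=complex)
        V = np.vander(z, degree + 1, increasing=True).astype(complex)
        cz, *_ = np.linalg.lstsq(V, y, rcond=None)
        coeff = cz / s ** np.arange(degree + 1)
        # validate at probes
        zp = rng.uniform(-1.0, 1.0, size=n_probes)
        op = s * zp
        ref = np.array([fun(o) for o in op], dtype=complex)
        fit = np.polyval(coeff[::-1], op)
        norm = max(np.max(np.abs(ref)), np.max(np.abs(y)), 1e-300)
        last_err = float(np.max(np.abs(fit - ref)) / norm)
        if last_err < rtol:
            return coeff
    raise InterpolationFailureError(
        f"polynomial interpolation residual {last_err:.3e} exceeds {rtol:.1e}")


def _entry_scale(prob: PerturbationProblem) -> float:
    mags = [abs(v) for v in prob.entries().values()] + [prob.w0 ** 2]
    return 2.0 * math.sqrt(max(mags + [1.0])) + 1.0


def polynomial_from_determinant(prob: PerturbationProblem,
                                w0: float | None = None) -> np.ndarray:
    """Degree-8 dispersion polynomial in Omega from determinant sampling.

    The determinant is evaluated at Chebyshev nodes and the unique degree-8
    interpolant is recovered; the leading coefficient is normalized to +1.
    Coefficients are returned in ascending order (constant term first).
    """
    if w0 is not None and w0 != prob.w0:
        prob = PerturbationProblem(**{**prob.__dict__, "w0": float(w0)})
    fun = lambda O: determinant(perturbation_matrix(prob, O))
    coeff = _interpolate_polynomial(fun, degree=8, scale=_entry_scale(prob))
    lead = coeff[-1]
    if abs(lead - 1.0) > 1e-6:
        raise InterpolationFailureError(
            f"leading dispersion coefficient {lead!r} differs from +1")
    return coeff / lead


def printed_polynomial_coefficients(prob: PerturbationProblem,
                                    w0: float | None = None):
    """The published closed-form coefficients (P, T, M, N, R, Z, Q).

    Evaluated literally, including the mutually cancelling
    +-m11^2 m33 m45^2 terms of the constant coefficient.  These are audit
    targets only; the solver path always uses the determinant.
    """
    w0 = prob.w0 if w0 is None else float(w0)
    m11, m13, m23 = prob.m11, prob.m13, prob.m23
    m31, m32, m33 = prob.m31, prob.m32, prob.m33
    m44, m45 = prob.m44, prob.m45
    P = m11 ** 2 + m33 + 2.0 * m44 - 4.0 * w0 ** 2
    T = 4.0 * w0 * m45
    N = w0 * (4.0 * m33 * m45 - 4.0 * m11 ** 2 * m45)
    M = (2.0 * m33 * m44 - 2.0 * m31 * m11 * m13
         + m11 ** 2 * (2.0 * m44 + m33 - 4.0 * w0 ** 2)
         + m44 ** 2 + 4.0 * m33 * w0 ** 2 - m45 ** 2)
    R = (2.0 * m11 ** 2 * m33 * m44 + 4.0 * m23 * m44 * m32 * m11
         - m33 * m44 ** 2 - (m11 * m44) ** 2
         + 8.0 * m11 * m31 * m13 * w0 ** 2
         - m33 * m45 ** 2 - (m11 * m45) ** 2
         - 4.0 * w0 ** 2 * m11 ** 2 * m33)
    Z = w0 * m45 * (8.0 * m11 * m13 * m31 - 4.0 * m11 ** 2 * m33)
    Q = (2.0 * m45 ** 2 * m11 * m13 * m31
         - m11 ** 2 * m33 * m45 ** 2
         - 2.0 * m11 * m13 * m31 * m44 ** 2
         + m11 ** 2 * m33 * m45 ** 2)
    return P, T, M, N, R, Z, Q


def printed_dispersion_polynomial(prob: PerturbationProblem,
                                  w0: float | None = None) -> np.ndarray:
    """Ascending coefficients of Omega^8 - P Omega^6 - T Omega^5 + M Omega^4
    + N Omega^3 + R Omega^2 + Z Omega + Q (the published sign pattern)."""
    P, T, M, N, R, Z, Q = printed_polynomial_coefficients(prob, w0)
    return np.array([Q, Z, R, N, M, -T, -P, 0.0, 1.0], dtype=complex)


def coefficient_discrepancy_report(prob: PerturbationProblem,
                                   companion: PerturbationProblem | None = None) -> dict:
    """Audit the published coefficient formulas against the determinant.

    Compares the published coefficient arrangement with the
    determinant-interpolated polynomial of ``prob`` (and of ``companion``,
    typically the same entries in the other matrix mode).  Reports
    per-coefficient absolute/relative differences and a verdict; no
    agreement is asserted.
    """
    names = ["Omega^0", "Omega^1", "Omega^2", "Omega^3", "Omega^4",
             "Omega^5", "Omega^6", "Omega^7", "Omega^8"]
    printed = printed_dispersion_polynomial(prob)

    def compare(p: PerturbationProblem) -> dict:
        det_poly = polynomial_from_determinant(p)
        norm = float(np.max(np.abs(det_poly)))
        out = {}
        for i, name in enumerate(names):
            a, b = printed[i], det_poly[i]
            abs_diff = abs(a - b)
            rel = abs_diff / max(abs(b), 1e-300)
            out[name] = {
                "printed": _c2j(a), "determinant": _c2j(b),
                "abs_diff": abs_diff, "rel_diff": rel,
                "verdict": "agree" if abs_diff <= 1e-8 * max(norm, 1.0) else "disagree",
            }
        return out

    report = {
        "K1": prob.K1,
        "w0": prob.w0,
        "entries": prob.entries(),
        "modes": {prob.mode: compare(prob)},
    }
    if companion is not None:
        report["modes"][companion.mode] = compare(companion)
    return report


def _c2j(z):
    z = complex(z)
    if z.imag == 0:
        return z.real
    return {"re": z.real, "im": z.imag}


def solve_omega(prob: PerturbationProblem, w0: float | None = None,
                residual_rtol: float = 1e-8) -> np.ndarray:
    """All eight roots of the dispersion polynomial, polished on the
    determinant itself.

    Roots are sorted by descending imaginary part, then ascending real part,
    then ascending magnitude.  Each root must zero the assembled determinant
    to ``residual_rtol`` times the determinant magnitude at a unit-offset
    probe.
    """
    coeff = polynomial_from_determinant(prob, w0)
    roots = np.roots(coeff[::-1])
    fun = lambda O: determinant(perturbation_matrix(prob, O))
    polished = []
    for root in roots:
        z = complex(root)
        for _ in range(8):
            h = 1e-7 * (1.0 + abs(z))
            f = fun(z)
            df = (fun(z + h) - fun(z - h)) / (2.0 * h)
            if df == 0:
                break
            step = f / df
            if abs(step) > 0.5 * (1.0 + abs(z)):  # reject wild Newton steps
                break
            z -= step
            if abs(step) < 1e-14 * (1.0 + abs(z)):
                break
        polished.append(z)
    polished = np.array(polished, dtype=complex)
    scale = max(abs(fun(polished[0] + 1.0)), 1e-300)
    residuals = np.array([abs(fun(z)) for z in polished])
    if np.any(residuals > residual_rtol * scale):
        worst = float(np.max(residuals) / scale)
        raise RootRefinementError(
            f"dispersion root residual {worst:.3e} exceeds {residual_rtol:.1e}")
    order = np.lexsort((np.abs(polished), polished.real, -polished.imag))
    return polished[order]


@dataclass
class GainCurve:
    """Temporal MI gain max|Im Omega| over a K1 grid, with all roots kept."""

    k1: np.ndarray
    gain: np.ndarray
    roots: np.ndarray  # shape (len(k1), 8)
    mode: MatrixMode = "derived"


def temporal_gain(K1_grid, coeffs: ContinuumCoefficients,
                  background: PlaneWaveBackground,
                  mode: MatrixMode = "derived") -> GainCurve:
    """Temporal gain curve: for each K1, max over the eight dispersion roots
    of |Im Omega|; NaN where the per-point solve fails."""
    k1 = np.atleast_1d(np.asarray(K1_grid, dtype=float))
    if k1.size == 0:
        raise InvalidParameterError("K1 grid must be nonempty")
    gain = np.full(k1.size, np.nan)
    roots = np.full((k1.size, 8), np.nan, dtype=complex)
    for i, K1 in enumerate(k1):
        try:
            prob = matrix_entries(coeffs, background, K1, mode)
            r = solve_omega(prob)
        except (InterpolationFailureError, RootRefinementError):
            continue
        roots[i] = r
        gain[i] = float(np.max(np.abs(r.imag)))
    return GainCurve(k1=k1, gain=gain, roots=roots, mode=mode)


@dataclass
class GainSurface:
    """Spatial MI gain: complex K1 branches per real Omega.

    ``gain`` holds |Im K1| per branch (rows: Omega grid, columns: branches
    sorted by |Im|); ``per_omega_max`` is the largest |Im K1| among branches
    whose real part lies inside the K1 window.
    """

    omega_grid: np.ndarray
    k1_window: tuple
    k1_branches: np.ndarray  # complex, shape (len(omega), degree)
    gain: np.ndarray
    per_omega_max: np.ndarray
    definition: str = "spatial"
    mode: MatrixMode = "derived"


def _k1_polynomial_degree() -> int:
    # det is degree 6 in K1 through the charge/stretch block (m11^2 * m33)
    # and degree 4 through the rotational block ((m44 - O^2)^2): total 10.
    return 10


def spatial_gain(Omega_grid, K1_window, coeffs: ContinuumCoefficients,
                 background: PlaneWaveBackground,
                 mode: MatrixMode = "derived") -> GainSurface:
    """Spatial gain G(Omega) = max |Im K1(Omega)| over dispersion branches.

    For each real Omega the determinant is a degree-10 polynomial in K1
    (reconstructed by interpolation); its roots are the spatial branches.
    """
    omegas = np.atleast_1d(np.asarray(Omega_grid, dtype=float))
    if omegas.size == 0:
        raise InvalidParameterError("Omega grid must be nonempty")
    lo, hi = float(min(K1_window)), float(max(K1_window))
    deg = _k1_polynomial_degree()
    branches = np.full((omegas.size, deg), np.nan, dtype=complex)
    gain = np.full((omegas.size, deg), np.nan)
    per_max = np.full(omegas.size, np.nan)
    scale = max(abs(lo), abs(hi), 1.0)
    for i, O in enumerate(omegas):
        # entries are polynomial in K1, so the determinant continues to
        # complex K1 through its closed-form block factorization
        fun = lambda K1, O=O: _det_at_complex_k1(coeffs, background, K1, O, mode)
        try:
            coeff = _interpolate_polynomial(fun, degree=deg, scale=scale)
        except InterpolationFailureError:
            continue
        lead = coeff[-1]
        if lead == 0:
            continue
        r = np.roots((coeff / lead)[::-1])
        order = np.argsort(np.abs(r.imag))
        r = r[order]
        branches[i, :r.size] = r
        gain[i, :r.size] = np.abs(r.imag)
        inside = (r.real >= lo) & (r.real <= hi)
        per_max[i] = float(np.max(np.abs(r[inside].imag))) if np.any(inside) else 0.0
    return GainSurface(omega_grid=omegas, k1_window=(lo, hi), k1_branches=branches,
                       gain=gain, per_omega_max=per_max, mode=mode)


def _det_at_complex_k1(coeffs: ContinuumCoefficients, background: PlaneWaveBackground,
                       K1: complex, Omega: float, mode: MatrixMode) -> complex:
    """Determinant with the entries' closed forms continued to complex K1."""
    c, bg = coeffs, background
    lam0 = bg.lambda0
    m11 = -c.P1 * K1 ** 2 + c.Q1
    m13, m23 = c.Q2 * bg.a1, c.Q2 * bg.a2
    m31, m32 = 2.0 * c.c2 * bg.a1, 2.0 * c.c2 * bg.a2
    m33 = c.A - 2.0 * c.B_nl * lam0 + 3.0 * c.W_g * lam0 ** 2 - c.c0 * K1 ** 2
    m45 = -c.c1 * bg.K * K1
    if mode == "printed":
        m44 = -bg.w0 ** 2 - c.c1 * K1 ** 2 - c.c1 * bg.K ** 2 \
            - c.beta_gamma * lam0 ** 3 + c.Q3 * lam0 + c.Q5
        off = Omega + m45
    elif mode == "derived":
        m44 = -bg.w0 ** 2 - c.c1 * K1 ** 2 - c.c1 * bg.K ** 2 \
            - c.Q3 * lam0 - c.beta_gamma * lam0 ** 3 + c.Q5
        off = 2.0 * bg.w0 * Omega - 2.0 * m45
    else:
        raise UnknownModeError(f"unknown matrix mode {mode!r}")
    O = Omega
    # block-triangular structure: det = det(3x3) * det(2x2)
    c33 = -O ** 2 + m33
    det_a = (c33 * (m11 ** 2 - O ** 2)
             - m11 * (m23 * m32 + m13 * m31)
             + 1j * O * (m23 * m31 - m13 * m32))
    det_d = (-O ** 2 + m44) ** 2 - off ** 2
    return det_a * det_d


@dataclass
class StabilityMap:
    """Boolean instability map over a (parameter, K1) plane."""

    axis_name: str
    axis_values: np.ndarray
    k1: np.ndarray
    gain: np.ndarray       # shape (len(axis_values), len(k1))
    unstable: np.ndarray   # boolean, same shape
    threshold: float
    unstable_fraction: np.ndarray  # per axis value
    mode: MatrixMode = "derived"


def stability_map(axis_name: str, axis_values, K1_grid,
                  coeffs_factory: Callable[[float], tuple],
                  threshold: float = STABILITY_THRESHOLD_DEFAULT,
                  mode: MatrixMode = "derived") -> StabilityMap:
    """Map of (parameter value, K1) -> instability (temporal gain > threshold).

    ``coeffs_factory(value)`` must return a ``(coeffs, background)`` pair for
    each value of the swept parameter (f_s, l_s or chi).  The unstable-area
    fraction is reported per parameter value.
    """
    if not threshold > 0:
        raise InvalidParameterError(f"threshold must be > 0, got {threshold}")
    values = np.atleast_1d(np.asarray(axis_values, dtype=float))
    k1 = np.atleast_1d(np.asarray(K1_grid, dtype=float))
    gain = np.full((values.size, k1.size), np.nan)
    for i, val in enumerate(values):
        coeffs, background = coeffs_factory(float(val))
        gain[i] = temporal_gain(k1, coeffs, background, mode).gain
    unstable = gain > threshold
    frac = np.mean(unstable, axis=1)
    return StabilityMap(axis_name=axis_name, axis_values=values, k1=k1, gain=gain,
                        unstable=unstable, threshold=threshold,
                        unstable_fraction=frac, mode=mode)
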