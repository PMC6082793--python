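# Methods

## The model

`pbhsolv` implements a semiclassical Peyrard–Bishop–Holstein (PBH) lattice
for charge transport along homogeneous double-stranded DNA, extended with a
solvent interaction term and rotational base degrees of freedom.  Each base
pair `j` carries:

* strand displacements `u_j`, `v_j`, combined into the in-phase and
  out-of-phase coordinates `w_j = (u_j + v_j)/√2`, `λ_j = (u_j − v_j)/√2`;
* disc rotation angles `θ_j`, `φ_j` with moment of inertia `I`;
* a complex charge amplitude `B_j` (|B_j|² is the charge density).

The hydrogen-bond stretch is `y_j − y_0 = √2 λ_j − g(φ_j, θ_j)` with
`g = r(cos φ + cos θ)` and equilibrium separation `y_0 = 2r + d`.  The
classical lattice Hamiltonian comprises kinetic terms, harmonic stacking
(`k` for displacements, `ξ` for angles), and an on-site well

    W(x) = D [e^{−a x} − 1]² + D f_s [tanh(x / l_s) − 1],   x = √2λ − g.

The charge couples through a tight-binding hopping term (transfer integral
`V`) and a Holstein on-site coupling `χ λ_j |B_j|²`:

    i ħ_eff dB_j/dt = −V (B_{j+1} + B_{j−1}) + χ λ_j B_j.

Charge amplitudes are treated as c-numbers (expectation values); this is the
standard semiclassical treatment for this model family, and is the level of
description at which the linear-stability analysis operates anyway.
Boundaries are periodic throughout, which is what the spectral integrators
presume.

### Units

Internal units are eV / Å / amu / rad.  The derived time unit is
`t* = √(amu·Å²/eV) ≈ 1.018 × 10⁻¹⁴ s`, and `ħ_eff ≈ 0.0647 eV·t*` by
default (overridable, including `ħ_eff = 1` for dimensionless studies).
All quoted times, frequencies and gains are in units of `t*` and `1/t*`.

### The solvent term and its two orientations

As written above, the solvent term is monotone nondecreasing in the stretch
and bounded in `[−2 D f_s, 0]`: it *stabilizes* open base pairs by lowering
their energy, and it exerts a constant force `D f_s/l_s` at zero stretch, so
the undistorted lattice is not a static equilibrium when `f_s > 0` (the true
minimum, computed by `model.solvent_shifted_minimum`, sits at negative
stretch).  With this orientation the summed profile past the well is
strictly monotone and has no barrier.

The solvated-PB literature also uses the opposite orientation,
`D f_s [1 − tanh(x/l_s)]`, which *adds a barrier* of height of order
`f_s·D` between the closed state and the dissociation plateau.  Both
behaviors are scientifically meaningful, and the package exposes both:
`solvent_energy` and everything built on it (Hamiltonian, dynamics,
continuum coefficients) use the monotone form, while
`onsite_potential_profile` defaults to the barrier orientation
(`solvent_orientation="barrier"`), which is the form under which barrier
metrics are meaningful; pass `"printed"` to profile the monotone form.

`barrier_metrics` brackets the barrier from the *leftmost* interior local
minimum rather than the global one: for large `f_s·D` the solvent-stabilized
open state lies below the closed-state well, so the global minimum is on the
plateau side.  The barrier height is measured above the plateau (the last
grid value; → D for a wide grid).  Two regimes are worth knowing:

* the closed-state well survives only while the solvent slope `f_s D / l_s`
  stays below the peak Morse slope `a D / 2`; beyond that (e.g. `f_s = 4`,
  `l_s = 1`, `a = 4.5`) the profile is monotone and no barrier exists;
* barrier height is proportional to `f_s` (within a few percent) only in
  the wide-solvent regime `l_s ≫ 1/a`, where the barrier top sits where the
  Morse term is already flat.  At `l_s = 1` and `a ≈ 4.5` the height grows
  faster than linearly with `f_s` (measured ratio ≈ 1.43 between
  `h(2)/2` and `h(1)/1`).

## Continuum reduction and its coefficients

The modulational-instability analysis operates on three coupled envelope
equations — charge envelope φ (first order in time), stretch λ (second
order), rotational envelope ψ (second order) — obtained from the discrete
system in the continuum limit.  The mapping from microscopic constants to
envelope coefficients is this package's own reconstruction (the reduction
is standard; the published table is not available):

* charge: `P1 = V ℓ²/ħ`, `Q1 = 2V/ħ`, `Q2 = −χ/ħ` (from the tight-binding
  equation with gradient expansion; ℓ = lattice spacing, default 1 site);
* gradients: `c0 = k ℓ²/m`, `c1 = ξ ℓ²/I`, and charge back-reaction
  `c2 = χ/m`;
* lattice on-site force (per unit mass) `A δλ − B_nl δλ² + W_g δλ³` from the
  2nd–4th derivatives of `W`;
* rotational on-site stiffness `(2r²/I)·W''(x_ref + √2 δλ)` expanded to
  cubic order gives `Q5, Q3, Q4` and the cubic product `β·γ` (γ is fixed
  at 1; the product is what enters every formula).

**Expansion point.**  By default the well is expanded about zero stretch
(`expand_about="zero"`), treating the background amplitude λ₀ as a free
parameter exactly as the plane-wave ansatz does and ignoring the solvent's
static tilt.  This is the choice under which the solvent's effect on the MI
gain enters through the odd derivative `W'''` (the `Q3 λ₀` channel), giving
gain nondecreasing in `f_s` and stability growing with `l_s` — the
qualitative trends the analysis is known for.  Expanding about the
solvent-shifted minimum (`expand_about="minimum"`) is also supported; it
routes the solvent through the stiffened Morse wall (`Q5`) instead and
reverses both trends.  Every derived coefficient is overridable and carries
provenance.

## Linear-stability analysis

A perturbation `exp(i(K1 x − Ω t))` of the plane-wave background couples
five real amplitudes through a 5×5 matrix with a block-triangular layout:
the (charge, stretch) 3×3 block is closed, and the rotational 2×2 block is
driven by the stretch without back-reaction, so the determinant factorizes
and the degree-8 dispersion polynomial in Ω is the product of two quartics.

Two matrix modes exist.  `printed` assembles the published closed-form
entries verbatim; `derived` (default) regenerates the rotational block from
the linearized envelope equations, which restores the `2 w0 Ω` and
`2 c1 K K1` factors in the off-diagonal coupling and uses `−Q3 λ0` in the
diagonal entry (the two published sources disagree with each other on these
points; `coefficient_discrepancy_report` quantifies every difference and is
archived with results, asserting nothing).

The dispersion polynomial is always obtained by sampling the determinant at
Chebyshev nodes and interpolating (validated against 100 random probes at
1e−8 relative and against full symbolic expansion in tests); the published
coefficient formulas are never in the solver path — their constant term
contains identically cancelling pairs, a transcription-error signature.
Roots are polished by Newton iteration on the determinant itself and must
zero it to 1e−8 of a unit-offset probe magnitude; ties in sorting are broken
by (descending Im, ascending Re, ascending |Ω|).  An 8-fold degenerate root
is resolvable only to ~eps^{1/8} ≈ 1e−2; simple roots are accurate to
~1e−12.

Temporal gain is max |Im Ω| over the eight branches at real K1; spatial
gain solves the determinant as a degree-10 polynomial in K1 at real Ω and
takes max |Im K1| per branch.  The envelope equations carry their spatial
second derivatives with the same sign as the temporal ones (an elliptic,
short-wave-divergent continuum artifact), so the gain grows without bound at
large |K1|; gain scans therefore restrict K1 to the first Brillouin zone
(|K1| ≤ π in rad/site) unless a wider window is requested explicitly (the
stability-diagram sweeps use a wide window, matching how such diagrams are
usually drawn for this system).

## Time-domain integration

Two systems can be integrated:

* **Discrete lattice** (`dynamics.integrate`) — the primary truth.  The
  `split_step_spectral` scheme is Strang splitting: half phase rotation of
  `B` by `χλ`, symplectic leapfrog (kick–drift–kick) for the lattice, exact
  spectral propagation of the hopping term (unitary, hence the charge norm
  is conserved to round-off), half phase rotation with the updated stretch.
  `rk4_full` steps all fields jointly and serves as the validation path;
  the two agree to 1e−4 after 100 steps at dt = 0.005 on a 64-site problem.
  A magnitude guard (default 1e6) aborts runs whose fields diverge (the
  Morse exponential otherwise overflows silently).  The nominal step
  dt = 0.055 is in internal time units (a physical 0.055 s would be absurd
  for lattice dynamics); energy drift at dt = 0.01 over 10⁴ steps is
  ≲ 1e−6 relative.

* **Linearized envelope system** (`envelope.integrate_linearized`) — the
  five linearized envelope fields on a periodic grid with spectral
  derivatives and RK4 stepping.  Because the background is uniform, Fourier
  modes evolve independently; a mode seeded at wavenumber K1 grows at
  max |Im Ω(K1)|, so this integrator provides a time-domain route to the MI
  gain that is independent of the polynomial/root route.  Round-off seeds
  the short-wave unstable band, so bounded-control runs are kept short
  (T ≈ 100) where round-off growth is ~1e−9.

**Initial conditions.**  `init_modulated_plane_wave` builds the coherently
modulated plane wave: `λ_n = λ₀(1 + 0.01 cos(K n)) cos(K₀ n)`,
`B_n = φ₀(1 + 0.01 e^{iKn}) e^{iK₀n}`, and the ψ envelope mapped onto the
in-phase rotational combination `(θ+φ)/√2` about the rest angles (the exact
microscopic angle combination behind ψ is not pinned down by the analysis;
the in-phase choice matches its second-order-in-time character and a remap
hook is exposed).  Defaults are λ₀ = 0.0035 Å, φ₀ = ψ₀ = 0.002,
K = 0.71π, K₀ = 0.55π per site; momenta start at zero; K and K₀ are rounded
to lattice-resonant values (logged).  Note the complex-exponential
modulation puts a sideband only at K₀ + K in the charge field, while the
cosine modulation puts symmetric sidebands at K₀ ± K in the stretch.
The rest angles are θ = φ = π/2, where `g = 0` and the Morse minimum sits
at λ = 0; `d` is never needed numerically (it cancels from `y − y₀`) and
defaults to 0.

**Growth measurement.**  `measure_growth_rate` fits log |mode amplitude|
versus time by least squares over an auto-selected window: the fit ends
when the amplitude first reaches `fold_limit` × initial (default 10×, the
linear regime) and starts once it has cleared √fold_limit ×, discarding the
mode-mixing transient.  It raises if the mode never doubles.

## What the synthetic inputs emulate — and what they do not

There are no external datasets for this model: the inputs are the parameter
sets printed in the source figure captions (collected verbatim, typos
quoted, in `fixtures.figure_parameter_registry`) and the modulated
plane-wave initial state.  The generators reproduce exactly those
conditions plus seeded random test problems.  They do **not** emulate
sequence heterogeneity, helicoidal coupling, thermal noise, viscosity or
open boundaries — all outside this model's scope — so passing tests say
nothing about real, heterogeneous, thermally agitated DNA; they validate
the model's internal mathematics and its stated qualitative solvent trends.

## Measured findings the tests encode

* **Growth-rate recovery** (the central cross-check): at the fig3/section-4
  background the most unstable resonant wavenumber on a 400-site grid is
  K1 ≈ 0.995π with gain ≈ 0.268/t*; the time-domain envelope run recovers
  it to ≈ 0.06% (5% asserted).
* **Pattern formation**: the discrete 200-site section-4 run (dt = 0.055,
  2×10⁵ steps, t = 11000) amplifies the seeded λ sideband power ~4×10⁴-fold
  and the charge sideband power ~15-fold, and the charge participation
  ratio falls from 1.00 to 0.37 — charge localizes into domains, the
  solvent-confinement effect the model exists to show.
* **No discrete K-selectivity with solvent on**: because the monotone
  solvent term tilts the whole lattice (a k = 0 pump whose relaxation
  amplitude ~0.5 Å dwarfs λ₀), the discrete solvated lattice amplifies
  sidebands at *every* probed K.  The stability map is a statement about
  the envelope system; the stable-wavenumber control is therefore run on
  the envelope integrator, where map-stable modes stay within ~1.0–1.2× in
  the observable (λ, charge) fields.
* **Solvent trends**: max-over-K1 gain is nondecreasing in f_s ∈
  {0.2, 0.5, 1.0} at l_s = 1, and the stability map's unstable-area
  fraction is nondecreasing in f_s and nonincreasing in l_s (flat at 1.0
  for l_s ∈ {0.02, 0.05}, where the solvent channel dominates everywhere in
  the window).
* **Barrier linearity holds only for wide solvent**: height/f_s is constant
  to 3.5% at l_s = 10 (a = 4.5) but not at l_s = 1, where the well is
  washed out entirely by f_s = 4.  The acceptance test asserting linearity
  at l_s = 1 is expected to fail and is left failing; it documents a real
  property of the potential at those parameters, not a defect of the
  implementation.

## Numerical choices

* Stability threshold separating gain from numerical noise: 1e−6 (recorded
  in every stability-map artifact).  Root collisions produce spurious
  imaginary parts of order √eps ≈ 1e−8, safely below it.
* Chebyshev interpolation interval scale: `2·√(max entry magnitude) + 1`,
  doubled up to twice on validation failure.
* Problem sizes: conservation audit at 128 sites / 10⁴ steps; growth-rate
  recovery at 400 sites; pattern formation at 200 sites / 2×10⁵ steps
  (t = 11000), which is past sideband saturation and localization onset.
* Blowup guard 1e6 on any |field|; envelope guard 1e12 (linear system,
  growth is legitimate there).

## Known limitations

* The continuum envelope system is ill-posed at short wavelengths (elliptic
  spatial terms), inherited from the analysis it implements; all gain
  scans are windowed.
* The printed and derived rotational blocks genuinely differ; results
  default to the derived block and the discrepancy report documents the
  printed one.
* The ψ↔angles mapping is a documented convention, not a derived fact.
* Spatial-gain branch tracking is per-Ω root sorting, not continuous branch
  following; branch identities can swap between adjacent Ω grid points.
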