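# Methods

This note records the models, conventions, numerical choices and known
limitations behind `aptapore`, in the order a user meets them.

## Rectification and response analysis (`aptapore.iv`)

A charged conical nanopore passes unequal currents at equal and opposite
biases (ion current rectification).  The rectification coefficient is

    r = log10( |I(+V_eval)| / |I(−V_eval)| ),   V_eval = 0.5 V by default.

Base-10 is used throughout: typical quoted values (−0.2 for bare quartz,
+0.3 after aminosilane coating, −0.5 for aptamer-coated pores) correspond to
current ratios of 0.6–3, which only a base-10 reading yields for plausible
currents.  Currents at ±V_eval are linearly interpolated between samples;
when a cyclic voltammogram contains forward and backward branches that both
cover the bias, the branch currents are averaged *before* the logarithm.
Averaging `r` across separately recorded curves is left to the caller.

Sensor response is `100 × (I_target − I_baseline)/|I_baseline|` at +V_eval;
the sign convention is physical (decrease negative, the dopamine direction;
increase positive, the serotonin direction) with a `magnitude` flag for
quoting unsigned percentages.

The limit of detection uses the 3σ blank rule: threshold = |blank mean| +
3 × blank SD; the LOD is the lowest concentration whose mean response
magnitude exceeds the threshold, refined by linear interpolation of response
against log10(concentration) between the bracketing points, because
calibration curves for these sensors live on a log-concentration axis.  A
series that never crosses returns a "not detected" sentinel rather than a
number.

Real-time traces are normalized by the mean current over a baseline window,
defaulting to all samples before the first recorded injection event.

## Sauerbrey analysis (`aptapore.qcmd`)

For a rigid film the areal mass tracks the harmonic-normalized frequency
shift linearly, `Δm = −C·Δf`.  Defaults are `C = 17.7 ng cm⁻² Hz⁻¹` (the
standard 5 MHz AT-cut constant, applied to harmonic-normalized Δf without a
further overtone division) and a hydrated-DNA layer density of
1.02 g cm⁻³.  This constant pair maps the monolayer-assembly step of
−23.7 Hz to a 4.1 nm layer and the dopamine-binding step of +3.3 Hz to a
0.6 nm compression simultaneously, which is how the pair was chosen; both
remain user-overridable (`SauerbreyParams`) since instrument constants vary.

Step extraction fits a straight drift line to the pre-injection window only
(injections perturb post-step slopes), extrapolates it, and differences the
window means of the residual.  The ΔD/Δf ratio classifies films as rigid
below 0.4 × 10⁻⁶ per Hz; above that the film is viscoelastic and the
Sauerbrey height is flagged as an underestimate.  No Voigt-type viscoelastic
modelling is attempted.

## The PNP model (`aptapore.pnp`)

### Equations and domain

Steady-state Poisson–Nernst–Planck on an axisymmetric cone:

    −∇·(ε∇φ) = F Σᵢ zᵢcᵢ + ρ_layer(x)
    ∇·( −Dᵢ(x)∇cᵢ − (zᵢF/RT) Dᵢ(x) cᵢ ∇φ ) = 0

with `ρ_layer` the fixed volume charge density inside the aptamer wall layer
and `Dᵢ` multiplied by `diffusivity_scale` there.  Temperature 298.15 K,
relative permittivity 78.4, no electroosmotic flow (transport and
electrostatics only), no transient or noise modelling.

The cone is the natural domain of spherical coordinates centred at its apex,
so the solver meshes the spherical shell {R_tip ≤ R ≤ R_tip + taper_length,
0 ≤ ϑ ≤ half_cone_angle}: the grid is orthogonal, the wall and axis are
coordinate surfaces (zero-flux, zero normal field), and the spherical caps
at both ends carry bulk Dirichlet values (bath cap grounded, barrel cap at
the applied bias — the bias convention of pipette measurements).  The
unmeshed bath half-space outside the tip is uncharged and Ohmic; its
classical spreading resistance `1/(4κa)` is available as an analytic series
correction in `resistance`/`pore_size_from_resistance` (off by default so
closed-form checks on the meshed domain alone are clean).  The
`reservoir_radius` field documents the nominal bath extent; it is not
meshed.

The aptamer layer is the set of cells within `thickness` of the wall and
within `extent` (default 200 nm) of the tip.  Where the layer is thicker
than the local pore radius it fills the entire cross-section — for the
study pore (4.6 nm tip radius, 5.5 nm layer) the tip is fully occupied,
as in the experimental picture.  A full-wall layer (`extent = inf`) is
supported but makes strong rectification unreachable in this geometry (see
"Parameter provenance").

### Discretization and iteration

Two-point-flux finite volumes on the graded (R, ϑ) grid: cells shrink
geometrically toward the tip (default first cell = tip_radius/5) and toward
the wall (default first wall cell = tip_radius/8, enforced at the far end of
the tip region where the constraint is most severe; the solver warns when
this exceeds λ_D/3).  Ion fluxes use Scharfetter–Gummel exponential fitting,

    J(P→N) = (D_f A_f/d) [ B(u) c_P − B(−u) c_N ],  u = z(φ_N−φ_P)/V_T,

which yields an M-matrix and hence strictly positive concentrations; face
diffusivities are harmonic means across the layer edge.  Because each
species' continuity equation is solved exactly per outer iteration, the
integrated current through every axial cross-section agrees to solver
precision (the conservation diagnostic typically reads ~1e−11).

The outer loop is a Gummel iteration whose Poisson step is solved by Newton
with Boltzmann damping (`cᵢ·exp(−zᵢδφ/V_T)`), the standard stabilization at
biases of many thermal voltages.  Two measures make 0.5 V solves routine:
the applied bias is ramped in ≤0.1 V continuation steps re-using the fields,
and each step is seeded with the superposed unit-Laplace (Ohmic) profile,
which the damped Poisson step preserves exactly in electroneutral regions —
without it the electrolyte screens the boundary bias within one Debye length
and the iteration stagnates.  Convergence requires both max |δφ| < 1e−7 V
and relative current change < 1e−6 (waived below 1e−14 A, e.g. at zero
bias); non-convergence raises an error carrying the residual history.

Default mesh: 90 × 36 cells.  Halving the spacings (180 × 72) changes the
0.5 V current of the charged study pore by well under 2 %, and a ±0.5 V
solve pair takes ~20 s on one CPU, so the defaults are the accuracy/runtime
compromise used for all reported numbers.

### Parameter provenance (the study conditions)

- **Electrolyte**: 1× PBS is reduced to a binary 1:1 electrolyte at its
  ionic strength (171.5 mol m⁻³) with Na⁺/Cl⁻ diffusivities; bulk
  conductivity is the controlling parameter and the full multi-species set
  is accepted wherever a species list is taken.  The Nernst–Einstein
  conductivity of this reduction is 2.15 S m⁻¹ (the ideal-solution value;
  measured saline runs ~25 % lower, activity corrections being out of
  scope).
- **Geometry**: tip radius 4.6 nm (9.2 nm opening); half-cone angle 0.0926
  rad (5.3°), pinned once via `calibrate_half_cone_angle` so the uncharged
  9.2 nm pore shows the measured 367 MΩ (access correction included); taper
  length 5 µm, beyond which the taper no longer contributes to the
  tip-dominated resistance.
- **Layer charge**: the free-layer volume charge density is pinned via
  `calibrate_charge_density` so the simulated free-state rectification at
  ±0.5 V equals the measured −0.5; this gives ≈ −1.6 × 10⁷ C m⁻³
  (≈ 0.17 M of elementary charges, a plausible DNA-brush value).
- **Layer extent**: 200 nm from the tip.  The chemistry coats the whole
  wall, but axially localized charge is what produces strong rectification
  in this reduced geometry: with a full-wall layer the model's |r|
  saturates near 0.33 regardless of charge density and the −0.5 calibration
  has no solution, whereas the response magnitude grows with extent (−8.3 %
  at 100 nm, −8.5 % at 200 nm, −11.3 % at 1 µm for the dopamine
  parameterization).  The default keeps the calibration feasible; the
  sensitivity is worth remembering when comparing with the experiments.
- **Free-layer permeability**: `diffusivity_scale = 1` (the free brush
  fully ion-permeable; binding introduces the hindrance).  The computed
  response is insensitive to this choice and slightly smaller for hindered
  free layers (−8.5/−8.2/−7.7 % at scales 1.0/0.7/0.5).

### Binding bookkeeping and results

`layer_from_md` converts MD layer heights into the bound-state layer:
compression from t_free to t_bound conserves total charge (density ×
t_free/t_bound) and scales in-layer diffusivity proportionally the other way
(× t_bound/t_free, clipped at 1), the "denser bundle is less permeable"
mechanism.  The reported fractional density change follows the
Δt/t_free convention, under which 5.5 → 4.9 nm reads as ~11 %; the charge
conserved internally corresponds to t_free/t_bound − 1 = 12.2 %.

With all conditions pinned as above, the model computes a **−8.5 %** current
change at +0.5 V for the dopamine parameterization (free +0.5 V current
0.819 nA), compared with ~−11 % in the experiments: correct sign, correct
bias asymmetry (the −0.5 V response is smaller and of opposite sign, +3.9 %,
matching the observed cancellation at negative bias), with the magnitude
understated by the reduced geometry.  The charge-density change alone gives
−5.1 %, so both mechanisms — charge concentration and permeability loss —
are needed, again as observed.

Sweeping the initial layer thickness at fixed fractional compression
(`optimal_layer_thickness`, 2–8 nm grid, fixed volume charge density — DNA's
charge per volume is a material property, so hypothetical aptamers of
different heights share it) yields a genuine interior optimum, but at 7 nm
and shallow (−8.97 % at 7 nm vs −8.85 % at 8 nm), rather than the ~5 nm
(≈ tip radius) the original finite-element study reported.  The
non-monotonicity is robust; the optimum's location in this reduced geometry
is not, and should be treated as qualitative.

`pore_size_from_resistance` inverts the measured low-bias resistance to a
tip diameter by bisection on the uncharged pore; it is self-consistent to
<1 % round-trip and returns 9.2 nm for 367 MΩ by construction of the angle
pinning.

## Closed-form electrokinetics (`aptapore.electrokinetics`)

Ionic strength treats phosphates as fully dissociated at nominal valences
(no speciation equilibrium), which reproduces the ~0.7 nm PBS Debye length;
`λ_D = 0.304/√I` nm at 298 K.  The Dukhin number uses the Bikerman form
`Du = |σ|μ/(κa)` with the layer collapsed to an equivalent surface charge
σ = ρ·t and a single counterion mobility.  The current partition into
excluded and in-layer contributions implements one explicit variant
("access-field-v1": annulus-fraction exclusion and counterion conduction
under the mouth access field), named in its result so alternative published
formulas can replace it without API change.  Aptamer packing tiles the
MD-footprint rectangle on a one-footprint-deep band of the tip wall.

## Synthetic data (`aptapore.synth`)

The generators emulate the *statistical structure* the analyses assume, not
the physics: the rectifying I–V fixture `I(V) = (V/R)·exp(αV)` with
`α = r_true·ln10/(2·v_eval)` has an exactly dialled rectification
coefficient and origin slope 1/R; QCM-D traces are steps + linear drift +
Gaussian noise with an optional proportional ΔD channel; real-time traces
apply multiplicative injection steps; dose–response series follow a logistic
in log-concentration between a 1 fM floor and 1 nM saturation (hard-clipped
to zero below the floor), with a pure-noise scrambled-control mode.  Every
generator takes one integer seed and is bit-for-bit reproducible; noiseless
round-trips through the matching analyzers recover truth parameters to
1e−10 or better.  What passing these tests shows is that the estimators are
correct and unbiased at the modelled noise level — not that real traces
(1/f noise, drifting baselines, serum matrix effects) will behave as well.

## File formats and pipeline (`aptapore.io`)

Comma-delimited UTF-8, `.` decimals, `#` comments, SI base units in files
with unit-suffixed headers (`voltage_V,current_A` etc.); floats are written
at 17 significant digits and parsed with correctly-rounded conversion, so
write→read round-trips are exact.  Unknown columns are preserved in
`metadata`.  `run_pipeline` validates its YAML config against a closed key
set, executes the requested stages, and always writes a `summary.json`
containing a provenance block (config hash, seed, package version); stage
failures are recorded there and re-raised after partial outputs are
persisted.

## Known limitations

- The PNP geometry is a single linear cone with cap reservoirs; the bath is
  represented by an analytic access resistance rather than meshed, and the
  EM-derived taper profile of real pipettes is replaced by the
  resistance-pinned angle.
- No electroosmosis, no surface-site chemistry (wall charge outside the
  layer is zero), no activity corrections, no transient response.
- The binding-response magnitude and especially the optimal-thickness
  location are sensitive to the layer-extent choice (see above) and should
  be read as mechanism demonstrations, not instrument calibrations.
- Sauerbrey constants are calibrated to the published worked examples, not
  taken from an instrument datasheet; rigid-film classification uses a
  single-harmonic heuristic threshold.
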