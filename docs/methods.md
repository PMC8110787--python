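# Methods

This note documents the models, conventions and numerical choices behind
`cellindent`, in the order data flows through the package: force-curve
analysis, per-specimen statistics, the worm stiffness map, the synthetic
generators, and the thin-shell FEM.

Units are fixed package-wide: displacement µm, force µN, pressure and
moduli MPa. With these, a slope in µN/µm is numerically a stiffness in N/m
and 1 MPa·µm² = 1 µN, which keeps all assembled matrices well scaled.

## Apparent stiffness from force curves

An indentation record is a sampled approach curve F(z) of force against
stage displacement. The apparent stiffness is the slope k = ΔF/Δz of the
post-contact branch. It is *apparent* because it convolves wall material,
internal (turgor) pressure, local curvature and probe geometry; none of the
analysis here interprets it as a material constant.

**Contact point.** The baseline level and its scatter are estimated from
the first 25% of samples. Contact is the first sample exceeding
baseline + 5·SD *and* sustained above half that threshold for the next few
samples (a lone noise spike is not contact). The crossing is refined by
fitting a line just past it and extrapolating back to the baseline level,
which reduces to the exact kink for noiseless data. The noise multiplier is
a parameter; 5 is the default because at the generator's baseline noise it
gives a false-trigger probability per curve well below 1%.

**Slope fit.** The default fit window is the upper half of the force range,
(0.5, 1.0] of F_max, where measured curves are closest to linear; the
window is configurable since instruments and tissues differ. A fit needs at
least five samples in the window.

**Compliance correction.** The probe, sensor and mounting deform in series
with the sample, so the measured slope underestimates the sample stiffness.
With the instrument-chain stiffness k_system calibrated on a rigid surface,

    k_sample = (1/k_measured − 1/k_system)⁻¹.

The correction can only increase the slope and diverges as k_measured
approaches k_system; a measured slope at or above k_system is rejected as a
calibration error. When an indentation depth (rather than stage travel) is
needed, it is z − z0 − F/k_system, consistent with the same series model.

## Per-specimen statistics

Apparent stiffness varies severalfold between pollen grains, but the ratio
of a grain's mean colpus (intine) stiffness to its mean exine stiffness is
much more stable. The package always forms this ratio per grain — the mean
of per-grain ratios, never the ratio of pooled means; the two differ
whenever grains differ in overall stiffness (asserted in the tests on a
fixture where they do).

Conventions, chosen once and recorded in every report:

- Normality: D'Agostino–Pearson omnibus test (n ≥ 8 required).
- Two-group comparison: a two-sided F-test on the variances at α = 0.05
  selects pooled (Student) versus unequal-variance (Welch) two-sample
  t-tests, both double-sided. Both forms can also be forced.
- Repeatability: coefficient of variation = sample SD / mean.
- Quantiles: linear interpolation between order statistics (the convention
  behind the 5th/95th-percentile whiskers in the summary tables).

## Worm stiffness map

The nematode body is idealized as a cylinder. Each indentation line (up to
11 sites, 20 µm apart along the body axis) is taken at a declared rotation
angle; θ = 0° is the first line's orientation. Because the animal can creep
between lines, a per-line angular offset is estimated from a tracked
surface fiducial: the offset is the difference between the fiducial's
observed angle and the angle implied by the declared rotation, wrapped to
(−180°, 180°]. No taper or pose model is attempted.

The map unfolds onto a sparse (s, θ) grid with holes left as holes —
no interpolation is applied by default. Band membership (soft/stiff) is
user-supplied; an optional 1-D 2-means split is provided but never applied
silently, since with overlapping group distributions its agreement with any
ground truth is bounded by the Bayes error (≈ 0.89 for the default group
parameters). Band geometry is summarized by clustering the angular
positions of each label (merge gap 60°, above the typical line spacing and
below the band separation) and reporting adjacent-center spacings.

## Synthetic generators

The generators stand in for the instrument so every pipeline stage can be
tested end-to-end; they are first-class, seeded, and always return ground
truth.

**Force curves.** Flat Gaussian baseline, then a linear ramp with slope
(1/k_true + 1/k_system)⁻¹ — the series instrument compliance is baked into
the data so the analysis correction is genuinely exercised. Default
k_system = 300 N/m (a stiff MEMS sensor chain relative to hydrated-tissue
stiffnesses of 0.5–30 N/m); sampling step 0.02 µm (4 µm/s at 200 S/s);
curves end at the 10 µN force limit used for pollen. No adhesion,
hysteresis, or retraction branch is modelled.

**Pollen populations.** Per grain, the exine stiffness is drawn from an
equal-weight two-component normal mixture with components at 0.7× and 1.4×
the marginal mean (16.5 N/m) and a common component SD chosen to match the
marginal SD (6.6 N/m); a ratio r ~ N(0.56, 0.10) (water) or N(0.66, 0.10)
(CaCl₂) truncated positive sets the intine stiffness k_i = r·k_e. This
couples the layers (stiff-exine grains also present stiff intine) and makes
both marginals bimodal, hence non-normal. Measurement replicates get 4.8%
multiplicative repeatability noise. The component layout and the CaCl₂
ratio SD are assumptions (only means and marginal SDs are constrained);
both are exposed as parameters. Truncation is by resampling.

**Worm maps.** Five lines of ten sites by default, rotated 72° apart, with
stiff bands centered at 0° and 180° (half-width 54°), which yields exactly
20 soft and 30 stiff sites with soft/stiff alternation roughly every
quarter turn. Soft sites draw from N(0.53, 0.07) N/m, stiff from
N(0.75, 0.11) N/m. Optional per-line drift is applied to the true angles
and leaks into the fiducial observations. The fiducial read-off noise is
0.5°, the sub-degree precision of image-based landmark tracking; it sets
the accuracy floor of drift recovery (a single observation per line, so
recovered offsets are within 2° with near certainty at this noise).

What passing tests on these generators show is that the *pipeline* is
unbiased and correctly calibrated under the stated population model; they
cannot show that real instruments are free of drift, adhesion, or
non-linear contact, none of which are generated.

## Thin-shell FEM

### Model

The pollen grain is an ellipsoid of revolution (unpressurized axes
128 × 97 µm) whose wall has two layers, both isotropic
Saint-Venant–Kirchhoff solids (second Piola–Kirchhoff stress linear in
Green–Lagrange strain): intine 1.5 µm (E_i, inner) and exine 0.5 µm (E_e,
outer), ν = 0.3 for both. The colpus — where exine is absent — is a band of
angular half-width 25° about one side, aligned with the major axis and
truncated at 80% of the axial extent; in the colpus the exposed surface is
the intine outer face, recessed by the exine thickness, so the small
curvature difference between regions arises naturally. Both the half-width
and the extent are parameters; the default response is insensitive to
moderate width changes because the band (≈ ±21 µm) is much wider than the
indentation dimple.

Turgor is a follower pressure on the current inner surface, with its
consistent (unsymmetric) load stiffness. During inflation the shell is
supported isostatically (six constraints at symmetry points); since the net
pressure load on a closed surface vanishes, this support carries no force
and does not bias the inflated shape. After inflation, all nodes below the
equatorial plane normal to the indentation axis are frozen at their
inflated positions, and a rigid sphere (radius 1 µm, configurable) advances
along the inward surface normal in displacement control. Contact is a
frictionless node-to-sphere penalty (default 1000 µN/µm per node),
C¹-smoothed over the first 0.02 µm of penetration to keep the Newton
active set stable; maximum penetration is recorded per run and stays well
below 1% of a depth step at the default settings. Depth is the advance past
first contact with the site apex; the reaction force is the contact
resultant along the indentation axis.

The reduced model is a sphere (diameter 100 µm) with one wedge layer
(thickness 0.5 or 1.5 µm) or, for the membrane variant (0.2 µm), constant-
strain triangles with plane-stress Saint-Venant–Kirchhoff response and no
bending resistance. Membrane tangents get a small diagonal regularization
(10⁻⁴ µN/µm, never added to the residual) so the initially unstressed
normal modes do not stall the first Newton steps.

### Discretization

Wedge (6-node prism) elements, one per layer through the thickness, full
3 × 2 Gauss integration. The surface triangulation is graded: a
deterministic density-weighted point set (inverse-CDF sampling in the polar
angle, a few weighted Lloyd iterations, convex hull) with two Gaussian
refinement scales around each indentation site — a broad 12° bump for the
indentation dimple and a sharp 3.5° bump that resolves the probe-scale
contact patch (~0.5 µm edges at the sites at the default 3000 triangles).
The mesh seed is fixed: the mesh is part of the model definition.

Apparent stiffness from a simulated curve is the central-difference tangent
over ±0.1 µm around the stated depth ("computed at" a depth); a secant mode
F(d)/d is also exposed. Linearity classification fits a line over
0.1–0.5 µm of depth and classifies by the sign of the mean deviation of the
curve beyond the range midpoint, with a 1% relative dead band.

### Solver

Newton iteration with a residual-norm backtracking line search; convergence
at relative residual 10⁻⁶ of the external force norm; load stepping (10
inflation steps, 25–30 indentation steps in the shipped configurations)
with automatic step halving to 1/16 of the nominal increment and a secant
predictor between accepted increments. Static Saint-Venant–Kirchhoff
equilibria are path-independent, so step counts affect robustness and
runtime, not converged values. Linear solves use sparse LU with symmetric-
mode ordering.

### Verification and known behavior

- Element kernels are verified against closed forms: affine deformations
  reproduce the analytic Cauchy stress exactly; assembled tangents match
  finite differences of the residual including pressure and contact terms;
  the pressure load does work P·dV under a radial virtual displacement and
  has zero resultant on a closed surface.
- Small-pressure inflation of a sphere matches linear thin-shell theory
  u/R = PR(1−ν)/(2Et) to within discretization error (≈ 10% at 1500
  triangles, shrinking with refinement).
- The unpressurized thin-sphere point-load stiffness converges to the
  classical closed form k = 4Et²/(R√(3(1−ν²))) from above; linear wedges
  carry residual transverse-shear stiffening, so the agreement benchmark
  uses 8000 triangles with the refinement bumps widened to cover the
  bending boundary layer √(Rt) (measured excess ≈ 8.6%).
- Pressurized contact quantities converge slowly under uniform refinement:
  doubling the sphere mesh from 3000 to 6000 triangles still moves the
  tangent stiffness at 0.6 µm by ≈ 9% (softening), because the probe-scale
  compression field and the discrete contact set keep resolving. Shipped
  values therefore carry a discretization uncertainty of that order, and
  the mesh-doubling stability ambition of < 3% is not met at desk-scale
  resolutions for these quantities.
- Probe-scale wall compression is real and resolved. With a compliant wall
  (E ≈ 10 MPa) and a 1 µm probe, a large fraction of the probe advance is
  absorbed by local through-thickness compression under the tip (a Hertz
  estimate at these forces gives tenths of µm), and the deep-indentation
  tangent stiffness of the two-layer model is therefore well below the
  membrane-tension estimate 2πT/ln(R/r). Discretizations that do not
  resolve the probe scale — or membrane models, which have no thickness
  degree of freedom — give up to ~2× stiffer tangents. This sensitivity
  dominates any comparison of simulated colpus stiffness against published
  values computed with coarser solid meshes; the antipodal (exine-backed)
  site is much less affected. Both regimes are reachable here: the wedge
  model with the default refined mesh resolves the compression; the
  membrane sphere reproduces the tension-dominated limit.
- Saint-Venant–Kirchhoff softens in compression, so a pressurized sphere
  has a limit pressure: with E = 10 MPa and t = 1.5 µm there is no stable
  equilibrium at 0.3 MPa. Property checks that sweep pressure to 0.3 MPa
  therefore use E = 30 MPa (inside the moduli range the model family is
  used with), where the whole sweep is stable.
- Inflation at the compliant defaults is large (hoop strain ~10–20%), so
  the deformed axes depend strongly on E_e; the shipped axis measurement is
  reported at E_e = 100 MPa, the configuration of the tested range whose
  inflated geometry is closest to the nominal hydrated-grain dimensions.
  Measured: 130.9 × 105.0 µm at E_e = 100 versus 139.7 × 115.6 µm at
  E_e = 20 (major × minor, from the unpressurized 128 × 97 µm).

### Problem sizes

The shipped configurations use ~3000 surface triangles for the two-layer
pollen model (≈ 13,500 dof), 1500–3000 for the reduced spheres, and 8000
for the thin-sphere closed-form benchmark. Monte-Carlo calibrations use
100–1000 seeded replicates depending on the check, with population sizes
(n = 30 grains × m = 10 curves; 20 + 30 worm sites) matching the study
design the generators emulate.

## Limitations

- The wall model is elastic, isotropic, and layer-homogeneous: no
  viscoelasticity, plasticity, anisotropy, growth, or exine
  micro-ornamentation.
- Turgor is held constant during indentation (the dimple volume is
  negligible against the cell volume at these depths).
- The probe is a rigid sphere; real tips are sphere-tipped cones whose
  shank engages at depths beyond the tip radius, stiffening the deep
  response.
- The worm model is a rigid cylinder with per-line angular offsets; no
  taper, bending, or image-based pose estimation.
- Generators draw independent Gaussians within groups; real repeated
  indentations can show history effects the repeatability noise does not
  capture.
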