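# Methods

This note records the models, parameter choices and numerical decisions
behind `lungeit`, and what the synthetic studies do and do not establish.

## Forward model

The domain is 2D. Potentials solve `∇·(γ∇u) = 0` with per-element complex
admittance `γ = σ + jωεε₀` on linear (P1) triangles. Two electrode models
are assembled:

* **CEM** — finite contact impedance `z_l`; the variational system couples
  nodal potentials with one voltage unknown per electrode through the
  electrode-edge mass terms. `z_l` is not reported for the reference
  studies; the default is a uniform 1e−3 in normalized units (small but
  non-zero, configurable).
* **Shunt** — perfectly conducting electrodes; the nodes under each
  electrode arc are condensed to one unknown. Point electrodes attach to
  the single nearest boundary node. The reconstruction domain uses the
  shunt model with point electrodes.

The gauge is `Σ U_l = 0`, enforced by a symmetric Lagrange-multiplier row;
because injected currents sum to zero the multiplier is exactly zero and
the constrained solution solves the original system. Injection amplitude
defaults to 1 (unit current); every normalized metric is invariant to it.

Sensitivities use the adjoint identity for dimensionless electrodes,
`J[dm, i] = −∫_{Ωᵢ} ∇u(I_d)·∇u(I_m) dA`, evaluated from the per-element
P1 gradients. Because adjacent-protocol drive and measurement pairs
coincide as a set, one solve per adjacent pair serves both roles. The
columns agree with central finite differences of the forward map to ~1e−6
relative (tested far tighter than needed).

Channel noise is additive i.i.d. Gaussian with RMS
`RMS(frame) × 10^(−|SNR_dB|/20)`, scaled against the raw (absolute) frame,
not the difference frame. A quoted "−50 dB" noise figure is read as noise
power 50 dB below signal; a literal SNR of −50 dB would bury the signal
entirely.

## The method-of-moments system

For background conductivity `σ₀`, the potential obeys the integral
equation `u = u0 + ∫ G ∇ln σ·∇u0 dA` with `G` the Neumann Green's function
(`−ΔG = δ − 1/|Ω|`, insulating boundary, mean-zero gauge) and
`u0 = (I/σ₀)(G(·, r⁺) − G(·, r⁻))` the homogeneous drive potential. On
the unit disk `G` is analytic — free-space logarithm, Kelvin image and a
quadratic sink term, with the gauge constant `−3/(8π)` making the disk
mean exactly zero. On thorax-shaped domains `G` is solved by FEM, one
solve per electrode, with the compensating uniform sink and a mean-zero
constraint; the Green's values match the analytic disk solution to ~0.1%
away from the source.

`ln σ` is expanded over generalized-exponential RBFs on the pixel grid.
The paper-family parameters `p1, p2, D` are not prescribed anywhere we
could find; the defaults are the canonical Gaussian member `p1 = 2, p2 = 1`
with width `D` equal to one pixel pitch, which ties the basis resolution
to the grid density. All three are configurable.

Two numerical choices matter and were settled by testing against the FEM
forward difference on a 16-electrode disk:

1. **Quadrature.** A per-pixel midpoint rule (even with 2×2 sub-sampling)
   integrates only the union of pixel squares, which does not cover the
   domain: boundary slivers are missed exactly where `∇u0` is largest, and
   the near-boundary system columns came out tens of percent wrong. The
   volume integral is instead evaluated over the centroids and areas of a
   fine auxiliary triangulation of the same boundary (the mesh the
   numeric Green's function already uses; ~8000 elements by default).
   With it, `Mo·c` matches the FEM voltage difference for random small
   coefficient vectors (‖c‖∞ ≤ 0.05) to 4–10% relative ℓ2.

2. **Boundary-source term.** The injected currents enter the domain as
   point sources of weight `I/σ(r_e)`. When the log-conductivity expansion
   does not vanish at a drive electrode this contributes, to first order,
   `−(I/σ₀)·G(r_obs, r_e)·θⱼ(r_e)` per signed drive electrode. The term is
   absent from the usual statement of the integral equation (which tacitly
   assumes background conductivity at the electrodes) but is essential for
   a collocation grid whose basis functions reach the boundary: without it
   the predictor decorrelates from the physics (cosine ≈ 0.2).

Pixel centers are kept half a pitch clear of the boundary so each pixel's
square is essentially interior and its basis function is resolvable by the
quadrature.

## Inverse solvers

All single-step solvers share the closed form
`x* = (AᵀA + λ²Q)⁻¹AᵀδV` with uniform channel weighting (equal channel
noise). Defaults follow the reference study's heuristic selections:
Gauss–Newton λ = 8e−3, TV λ = 1e−6 with β = 1e−3, difference of absolutes
λ = 5e−2, PM-MoM Laplace λ = 0.2, SBL cluster size h = 4 with
ε_min = 1e−5 and κ_max = 5. Hyperparameter search (L-curve and friends) is
deliberately out of scope.

* **Gauss–Newton** re-solves the forward problem and re-assembles the
  Jacobian each iterate, starting from the closed-form solution, with
  backtracking halving (up to 8) accepted only on objective decrease. On
  an exactly linear map it terminates at the closed-form solution.
* **TV (PD-IPM)** minimizes `‖Jx − δV‖² + λ²Σ√((Lx)ᵢ² + β)` with the
  anisotropically weighted primal Newton system, a dual kept feasible by
  the smoothed-gradient scaling `y = Lx/√((Lx)² + β)`, and backtracking on
  the true objective. λ = 0 reduces to least squares.
* **Difference of absolutes** runs absolute Gauss–Newton per frame
  (Laplace prior on σ itself), initialized at the best-fit homogeneous
  conductivity — a closed-form one-parameter fit, since voltages scale as
  1/σ on a homogeneous domain — and subtracts the two images.
* **SBL** implements the overlapping-cluster EM described in the README.
  The posterior mean is `μx = Σ₀ΦᵀΣu⁻¹δV` (the printed step omits the data
  vector; this is the standard E-step consistent with the residual in the
  noise update). The scale update is the majoration–minimization form
  `γᵢ ← γᵢ‖BᵢΦᵢᵀΣu⁻¹δV‖₂ / √tr(ΦᵢᵀΣu⁻¹ΦᵢBᵢ)`. Only the h×h diagonal
  blocks of the posterior covariance are propagated (they are all the
  updates need); the full covariance is available densely for small
  problems and is what the closed-form conjugate-Gaussian test checks.
  Numerical guards: γ floors at 1e−12, correlation magnitude capped at
  0.99, Σu factorization retried with jitter 1e−10·tr/Nm. Clustering is a
  1D sliding window over row-major pixel order.

The solvers are exposed as scikit-learn-style estimators (`fit` binds the
system matrix or forward problem, `transform` maps frames to images) so
they compose with pipelines and grid search; the functional cores remain
directly callable.

### Background conductivity

The linearization point σ₀ is unknown in practice and the study default is
the normalized σ₀ = 1. The full pipeline fits a homogeneous background to
the reference frame (closed-form ratio) for the methods whose output scale
is physical — Gauss–Newton, difference of absolutes, and both MoM methods,
whose exponential conductivity map is not scale-invariant: at σ₀ = 1
against a ~0.38 S/m muscle background the inflated coefficients produce
one-sided exponential artifacts. The purely linear FEM baselines stay on
the σ₀ = 1 Jacobian, matching the convention their default λ values were
selected under; their ranking metrics are amplitude-invariant either way.

## Synthetic dynamic thorax

Three subject-like cases (superellipse boundaries with a posterior
flattening, differing in aspect ratio and lung separation; case 2 has the
narrowest inter-lung gap, case 3 lungs closest to the chest wall) are
observed at P = 5 breath states. Chest width grows 6.5% in total from
end-expiration to end-inspiration (the physiological range is 5–8%) and
lung width grows 12.5% (range 10–15%), both linear in the state index;
the heart and vertebra are geometrically state-invariant and carved clear
of the fully-inflated lungs so the six tissue regions stay disjoint at
every state. Electrode angles get 3% (of the spacing) Gaussian jitter,
drawn once per case and re-projected on each state's boundary — the belt
follows the chest. The 2D model has no electrode height, so the height
jitter of 3D belts has no analogue here.

Tissue admittances at 100 kHz: heart 0.215, vertebra 0.021, skin 0.045,
muscle 0.380 S/m with ωεε₀ 0.0548, 0.001, 0.043, 0.024 F·Hz/m, and
per-element Gaussian inhomogeneity of 1% (skin), 2% (heart, muscle), 3%
(lungs); non-positive draws are resampled, not truncated, so means are
preserved. Lung admittance follows the volume model described in the
README: relative volume `F_i = 3i/(P+1) + 3/(P−1) + 4`, conductivity shape
`0.85·sb/w + 0.03·si·(3F/2 + 4.5)/(3F/2 + 9)²` with sb = 0.5, w = 1.5,
si = 2, affine-calibrated exactly to 0.272/0.107 S/m. The permittivity
analogue carries an extra `780·F^{1/3}·erm` factor (erb = 1e4, erm = 10)
and is calibrated to 0.029/0.014; it is not monotone in F — it rises
slightly before falling — which mirrors the non-monotone published
per-state values and is left as the model gives it.

A note on fidelity: the published intermediate conductivities
(0.225, 0.179, 0.145) have non-monotone second differences, which no
smooth monotone model affine-calibrated to the endpoints on a linear
volume grid can reproduce; the calibrated model gives 0.228, 0.186, 0.146.
The model, not the printed intermediate values, is treated as the source
of truth, and the corresponding acceptance test records the discrepancy
honestly rather than adjusting the model.

Simulation runs on a fine per-state mesh of the deformed boundary;
reconstruction runs on a generic thorax-shaped domain with a different
boundary and coarser discretizations (inverse-crime avoidance — the CLI
refuses to reconstruct when the geometry hashes coincide). Frames carry
complex admittance end-to-end; reconstruction and scoring use real parts.

What the phantom does *not* emulate: 3D current spreading (a 2D model
systematically misestimates absolute sensitivity), cardiac-cycle
conductivity changes, CT-derived anatomy, electrode height effects, and
real contact-impedance drift. Passing the end-to-end tests therefore
shows correct implementation and the expected *relative* behaviour of the
methods under controlled conditions, not clinical performance.

## Figures of merit

Reference images are painted on the reconstruction discretization from
per-pixel tissue area fractions (exact shapely clipping by default; an
n×n sub-sampling mode exists) times per-state mean tissue admittances,
differenced against state 1. Both geometries are x-normalized to [−1, 1]
before clipping. Lungs are detected by thresholding at −1/4 of the
maximum absolute amplitude (the air-filled lungs are the conductivity
*drop*); left/right inclusions split at the x = 0 line.

Two printed-versus-intended ambiguities are exposed as options rather than
silently resolved: `sd_convention` ('printed': out-of-lung over in-lung
filtered area, the default; 'fraction': out-of-lung over total) and
`rng_convention` ('opposite': out-of-lung amplitude of sign opposite to
the dominant in-lung sign, the default, since a same-sign numerator would
count the lung response itself as ringing; 'printed': literal negative
out-of-lung amplitude). FR normalization divides by max|value|
(zero-preserving), appropriate for signed difference images. The position
error's "true center" is the polygon centroid of each true lung.

The full battery is verified against an independent straight-loop
re-implementation to 1e−10 on random images.

## Problem sizes

The scaled-down study sizes used by the tests and examples — fine phantom
meshes of ~1200–1800 elements, reconstruction meshes of ~400 elements,
pixel grids of ~300, Green's/quadrature meshes of ~2000–8000 elements —
were chosen as the smallest at which the discretization-sensitive checks
(forward convergence, MoM linear-regime fidelity) are comfortably inside
their tolerances; the library accepts the full-scale settings (L = 1024
mesh / L = 1060 grid) through the same parameters.

## Known limitations

* The MoM quadrature cost is dense: O(Q·L) memory for the RBF gradient
  table (~100 MB at Q = 8000, L = 1060). Gaussian locality would sparsify
  it; not implemented.
* `numeric_green` represents point sources by nodal deltas; its near-field
  (within a few elements of a source) is inaccurate, which is harmless for
  collocation observations but caps the numeric-table MoM accuracy below
  the analytic disk table's.
* Gauss–Newton and TV inherit the linear Jacobian's σ₀ = 1 scale
  convention; their default λ values do not transfer across drastically
  different voltage scales.
* The movement-prior solver, multiple-priors non-linear difference
  imaging, TSVD, D-Bar and GREIT-matrix training are out of scope, as are
  3D meshes and AMP-accelerated SBL variants.
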