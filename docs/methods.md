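# Methods

## The two transport formalisms

Both models describe incompressible Darcy flow of infusate through porous
brain tissue followed by advection–diffusion of the drug, and both are
solved by identical machinery; they differ only in the tensor fields
supplied.

* **D-model.** `v = −K∇p`, `φ ∂C/∂t = −∇·(vC) + ∇·(φD∇C)`, where `D` and
  the hydraulic conductivity `K` are calibrated from the water diffusion
  tensor `D_w`, the Gaussian (monoexponential) fit to the diffusion MR
  signal.
* **R-model.** The same equations with `D → R` and `K → T` (effective
  permeability), calibrated from the displacement-covariance tensor
  `R_w`: one half the second moment of the diffusion propagator divided
  by the diffusion time Δ. For Gaussian diffusion `R_w = D_w`; where
  diffusion is restricted or hindered, `R_w` retains second-order
  structure the monoexponential fit cannot represent.

Assumptions shared by both: rigid tissue (no poroelastic deformation), no
clearance or metabolism, a point-like source occupying one mesh cell, and
a weak coupling in which the steady velocity field is solved first and
frozen during transport. These match the modelling scope of the
CED-simulation literature this package follows; all are listed under
limitations below.

Subtracting the two transport equations gives an evolution equation for
`ΔC = C_R − C_D` whose source terms are proportional to `R − D` (and to
the velocity difference it induces). Two consequences are used as
oracles: `ΔC ≡ 0` when the fields coincide, and the discrete residual of
the difference identity must vanish to solver precision when assembled
from the two operators (`tests/test_solver.py`).

## Water tensor estimation

* `D_w`: ordinary linear least squares of `log S` on the standard
  7-parameter design over both shells and the b0 volumes (WLS with
  signal² weights available for noisy data). Exact for a single-Gaussian
  voxel. Voxels with non-positive signals are flagged and dropped from
  the mask.
* `R_w`, ground-truth mode: the phantom's mixture second moment
  `Σ w_i D_i` in closed form.
* `R_w`, cumulant mode: with exactly two shells plus b0, the quadratic
  `log S = log S0 − b·a_g + b²·c_g` is determined exactly per gradient
  direction; the b→0 apparent diffusivity `a_g` is the directional
  second moment / 2Δ, and a symmetric tensor is least-squares fitted to
  the 61 directional values (negative `a_g` clamped to zero and
  counted). The residual against ground truth is the O(b³) truncation of
  the cumulant expansion — below 1% for the two-pool fixtures used here
  and bounded at 5% in the tests.

The RBF-based propagator estimator used with real scans is out of scope;
the two estimators above fill its contract (same tensor, same units,
same downstream use) and are themselves testable against closed forms.

## The DC map

The Difference in Covariances is defined as the minimal expected squared
discrepancy `E‖r̃‖²` between the actual displacement and its Gaussian
model over all couplings of the two distributions. At second order this
is the squared Bures–Wasserstein (Gaussian optimal-transport) distance
between `N(0, 2ΔR)` and `N(0, 2ΔD)`:

    DC = Tr(2ΔR) + Tr(2ΔD) − 2 Tr[(Σ_D^{1/2} (2ΔR) Σ_D^{1/2})^{1/2}],  Σ_D = 2ΔD

in mm². This closed form satisfies every property required of DC — it is
non-negative, zero iff the covariances coincide, and grows with the
covariance discrepancy — and the test suite ties it to the coupling
definition with an entropy-debiased optimal-transport oracle on a
discretized 3-D grid (13³ points, agreement within grid error ~10%).
The diffusion time Δ is never stated by the acquisition description we
emulate; it defaults to 0.03 s (typical PGSE) and is carried explicitly
by every Δ-dependent quantity. DC maps are reported at that Δ.

## Calibration

Per voxel, each water tensor is eigendecomposed, the eigenvalues divided
by their mean (so they average exactly 1; near-zero tensors are flagged
isotropic-unit), and the unit-trace shape rescaled by tissue constants:
`D_drug = D_cal·ξ_D Λ̄_D ξ_Dᵀ`, `K_drug = K_cal·ξ_D Λ̄_D ξ_Dᵀ`, and the
analogous `R_drug`, `T_drug` from `ξ_R, Λ̄_R`. Constants: `D_cal = 1e-12`,
`K_cal` `1.3e-12` (WM), `0.013e-12` (GM) — interstitial flow up to 100×
faster in WM — porosity 0.21 (GM) and 0.19 (WM). CSF values are not
established in the source literature; the package treats CSF as
free-fluid-like (`K_cal_CSF = K_cal_WM`, porosity 0.9) to avoid
artificial barriers at ventricle boundaries, and exposes both in config.
These CSF values are a documented, unvalidated choice.

On units: the calibration constants are used exactly as printed, in the
package's mm-based unit system. In the primary fixed-rate source mode
the transport prediction is invariant to the overall conductivity scale
(Darcy linearity: halving `K` doubles `p − p_b` and leaves `v`, hence
`C`, unchanged), so this convention affects only the scale of the
reported pressures, which are therefore calibration-relative.

## Voxelized mesh and discretization

Mesh cells coincide with image voxels (0-based indices, centers at
`(i+½)h`, `h = 1.2` mm by default); properties transfer voxel-by-voxel
with no interpolation. Connectivity is 6-neighbor; 18/26-neighbor
couplings enter only through the tensor cross-derivative terms of the
flux, not the mesh graph. If a mask is not 6-connected the largest
component is kept with a warning.

**Pressure.** Finite-volume fluxes across each face carry the full
tensor: the face-normal part `−κ_nn (Δp/h)A` is assembled into a
symmetric positive-definite 7-point matrix (Dirichlet `p = p_b` imposed
at boundary faces at distance h/2); the cross terms
`−κ_nt (∂p/∂t)A` — with tangential gradients from averaged central
differences of the two adjacent cells — are applied by deferred
correction from the previous iterate until the pressure changes by less
than the solver tolerance (relative 1e-10). Face tensors are arithmetic
means (harmonic available by flag for high-contrast interfaces). The
face fluxes are assembled consistently with the last linear solve, so
the discrete divergence vanishes to solver precision in every non-source
cell and the boundary outflux equals `Q` exactly.

**Transport.** Backward-Euler steps (default dt = 1 s; analysis runs at
the sizes below use 5–10 s, with results shown insensitive to dt at
these Courant numbers) of the finite-volume discretization: first-order
upwind advective fluxes against the stored volumetric face fluxes,
implicit; diffusive normal fluxes on `φR` (or `φD`), implicit; diffusive
cross terms deferred to the previous step. Boundary condition: advective
outflow where the face flux is outward, zero diffusive flux — this
closes the mass ledger (infused = in-domain + out-fluxed) to solver
precision, verified at 1e-6 relative in every analysis run. The implicit
upwind matrix is an M-matrix, so concentrations remain in
`[0, max(C_in, C_max,0)]`. A van-Leer-limited anti-diffusive correction
(deferred, face-conservative) is available behind the `advection`
flag for front-sharpening studies; an unlimited second-order upwind
variant was evaluated and rejected because it violates positivity at the
infusion front.

**Source.** One mesh cell receives the volumetric rate `Q` (µl/min
accepted at the boundary, converted once: 0.3 µl/min = 0.005 mm³/s);
piecewise-constant schedules re-solve the pressure per segment. The
primary mode fixes the rate (the clinically controlled quantity) with
`p_b = 0`, letting the source pressure emerge; a fixed-Δp mode
(Dirichlet at the source cell, emergent rate defined as the total
boundary outflux) is provided because the literature quotes both a rate
and a 3.5 kPa (site-dependent 1.5/4.5 kPa) pressure difference, which
over-determine the linear problem; neither mode is asserted as "what was
actually done" with real scans. A source may span a set of cells sharing
the rate; mesh refinement maps a source voxel to its 8 children so the
catheter opening keeps its physical size.

**Linear solvers.** The SPD pressure system is solved by
Jacobi-preconditioned conjugate gradients; the diagonally dominant
transport system by BiCGStab, ILU-preconditioned above ~40k cells, warm
started from the previous step, with the matrix assembled and
factorized once per (flux field, dt). Every solve is accepted only if
the true relative residual meets the contract (1e-10 pressure, 1e-8
transport; in practice ~1e-12); a sparse LU fallback covers Krylov
stagnation.

## The digital phantom

The phantom supplies what a segmented scan would: tissue labels (default
32³ at 1.2 mm — an ellipsoidal brain with CSF rim, GM shell, and an
interior WM slab with a smoothly bending fiber tract and an embedded
90°-crossing region), per-voxel displacement propagators, and two-shell
signals.

Propagator recipes (diffusivities mm²/s; per-voxel lognormal jitter
σ=0.03 on component diffusivities and ~3° orientation jitter make
distinct seeds distinct phantoms):

| tissue | mixture | non-Gaussianity |
|---|---|---|
| CSF | single isotropic Gaussian, 2.0e-3 | none (exactly Gaussian) |
| GM | isotropic pools 1.0e-3 (w=0.65) + 0.55e-3 | mild |
| WM | hindered axial 1.5e-3 / radial 0.5e-3 (w=0.65, along tract) + near-isotropic restricted 0.12e-3 | strong |
| WM crossing | two hindered populations at 90° + restricted pool | strong, low net anisotropy |

The recipes are chosen so the qualitative contrasts reported for real
tissue hold by construction: non-Gaussianity (DC) concentrates in WM,
`FA(R_w) ≥ FA(D_w)` voxelwise in ≥90% of WM, and `Tr(R_w)/Tr(D_w) > 1`
where restriction depresses the monoexponential fit. The restricted WM
pool is nearly isotropic (a "dot-like" compartment): this places the
mixture heterogeneity — and hence the DT-fit bias — preferentially along
the fiber axis, which is what makes the covariance tensor *more*
anisotropic than the fitted DT, as observed in vivo.

What the phantom does **not** emulate: imaging noise floors and
artifacts (Rician noise is available but analyses default to noiseless),
partial-volume mixing at tissue interfaces, realistic gyral geometry,
orientation dispersion within voxels, exchange between compartments,
and any participant-specific anatomy. Passing tests therefore
demonstrate correctness of the estimators, solvers and statistics under
controlled microstructure — not agreement with any individual brain.
Signals use deterministic Fibonacci-sphere directions (61/shell), which
are isotropically distributed but not the scanner's actual set.

## Analysis conventions

* Fractional difference `f = (C_R − C_D)/C_D`, evaluated where
  `C_D ≥ 1e-3·max(C_D)`; the floor only masks, never alters values, and
  keeps the spreading front (where f is largest and most meaningful)
  while excluding numerical zeros.
* Distribution volume `V_d`: voxels with `C ≥ 5%` of the maximum, times
  `h³`.
* Path non-Gaussianity: the 26-connected Bresenham line from the source
  to each voxel (driving axis = largest |Δ|, ties broken x>y>z; classic
  integer error accumulators), summing DC over the line's in-mask
  voxels. The digital line approximates, and does not claim to be, the
  fluid path.
* Correlation: Pearson r of |f| against the path-DC sums over the
  voxels inside the union of the two models' distribution volumes (and
  above the f floor); the paired t-test compares `C_R` and `C_D` over
  that union. Statistics are per (site, schedule) with no
  multiple-testing correction, matching how such tables are reported.
* Rate comparisons at matched infused volume scale the time step
  inversely with the rate, so each step infuses the same volume and the
  time discretization contributes identically per infused mm³;
  otherwise the faster rate would carry a small spurious excess of
  numerical front spread.

## Mesh-refinement check

The refinement study splits every cell in 8 (h 1.2 → 0.6 mm), maps all
tensors and porosity voxel-wise, halves dt, keeps the physical source
region (the coarse source voxel's 8 children share the rate), and
re-runs the standard scenario: 8 h of white-matter infusion at
1.8 µl/min on the default phantom (dt 10 → 5 s). The distribution volume
changes by well under 10% (and the concentration fields agree to ~13%
relative L2 on the common grid). The long horizon matters: the 5%-of-max
contour lies on the infusion front, whose width is set by the upwind
scheme at O(h) in this strongly advection-dominated regime
(cell Péclet ≫ 1), so at short horizons — plateau radius of only a few
cells — V_d is front-dominated and changes by ~15% under refinement
regardless of limiter. The long-infusion configuration, where the
plateau dominates the front as it does in multi-day clinical infusions,
is the regime in which mesh-independence of V_d is a meaningful claim.

## Problem sizes used in the shipped analyses

Default phantom 32³ (≈13k mesh cells); correlation analysis 2 h at
dt = 5 s per model and seed, 10 seeds; V_d-vs-infused runs up to 2 h;
refinement check 8 h coarse (13k cells, dt 10 s) vs fine (106k cells,
dt 5 s); Darcy oracle 41³ ball (33k cells); heat-kernel oracle 32³.

## Known limitations

* First-order upwind advection is diffusive at fronts; the limited
  scheme sharpens the mid-front but the 5%-contour foot remains O(h).
* The weak coupling neglects any feedback of concentration on flow.
* Calibration constants (and especially the CSF row) carry substantial
  literature uncertainty; predictions should be read as
  calibration-relative.
* No catheter geometry or backflow, no tissue elasticity, no
  clearance/metabolism — identical in both models, so comparisons
  between them are unaffected, but absolute concentrations are
  idealised.
* The phantom's Δ (0.03 s) and direction set are conventions, not
  acquisition ground truth; all Δ-dependent quantities scale
  accordingly.
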