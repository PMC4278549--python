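# Methods

## Protocol

The acquisition model is pulsed-gradient spin echo: two gradient lobes of
magnitude G and width δ separated by Δ, giving b = γ²G²δ²(Δ − δ/3) with
γ = 2.6752×10⁸ rad s⁻¹ T⁻¹. The reference protocol crosses
δ ∈ {6, 10, 15, 22} ms, Δ ∈ {30, 50, 70, 90} ms and |G| ∈ {55, 60} mT/m —
one shell per combination, 32 shells — with 45 gradient directions and
three interleaved b = 0 rows per shell: 32 × (3 + 45) = 1536 measurements,
b from 218 to 10308 s/mm². The gradient-strength pair {55, 60} mT/m is the
two-level set that completes the 32-shell grid and reproduces both extreme
b-values exactly; it is configurable.

Each shell's directions are a common 45-vector electrostatic-repulsion
point set under an independent uniform random rotation (quaternion
sampling), stored per shell so the base set can be recovered exactly.
Schemes round-trip through Camino-style `VERSION: STEJSKALTANNER` text
files (g_x g_y g_z |G| Δ δ TE, SI units). The echo-time column is carried
through I/O but ignored by all computation: per-shell b = 0 normalization
removes TE-dependent scaling. Everything internal is SI; s/mm², ms and μm
appear only in reports.

The "effective diffusion time range" reported by the protocol driver is
the (Δ − δ/3) of the minimum-b and maximum-b shells (28 and 82.67 ms).
These are *not* the extrema of (Δ − δ/3) over the full timing grid (22.67
and 88 ms); the b-extreme convention is the one the protocol summary
quotes.

## Compartment signals

Hindered pools are Gaussian: Ball exp(−b d_iso), Zeppelin
exp(−b[d⊥ + (d∥ − d⊥)(ĝ·n)²]), full Tensor exp(−b ĝᵀDĝ) with eigenframe
(θ, φ, α). Restricted pools use the Gaussian-phase-distribution (GPD)
series: for a cylinder of radius R (van Gelderen form),

ln S⊥ = −2γ²G⊥² Σₘ [2dαₘ²δ − 2 + 2e^(−dαₘ²δ) + 2e^(−dαₘ²Δ)
        − e^(−dαₘ²(Δ−δ)) − e^(−dαₘ²(Δ+δ))] / [d²αₘ⁶(R²αₘ² − 1)],

αₘ = βₘ/R with βₘ the m-th positive root of J₁′; the sphere (Murday–Cotts)
replaces the roots by those of j₁′ and the denominator factor by
(R²αₘ² − 2), with the full G². Twenty roots with a 10⁻¹⁰ relative
truncation are the default; doubling the root count changes no
protocol-level signal by more than 10⁻⁸. The series kernel is
numba-compiled and evaluated once per unique (G, δ, Δ) triple (32 per
scheme), not per row.

GDR-cylinders integrate the cylinder signal over a Gamma(κ, θ) radius
distribution with *volume* (R²) weighting — axon signal fraction scales
with cross-sectional area — on 16 Gauss–Legendre nodes spanning the
[10⁻⁵, 1 − 10⁻⁵] quantile range; 16- and 64-node quadratures agree to
10⁻⁴ at κ = 2. Volume weighting is this package's choice; number weighting is the
plausible alternative and differs only for broad distributions.
Astrosticks has the closed form √π·erf(√(bd))/(2√(bd)); Astrocylinders
reduces the orientation average to a 1-D integral over u = cos(angle to
the gradient) on [0, 1] (32 Gauss–Legendre nodes), exact by azimuthal
symmetry. Dot returns 1 identically.

An independent Monte-Carlo oracle (`mc_oracle`) random-walks spins in a
reflecting disc/sphere accumulating PGSE phase and is used only for
validation. At the strongest shell (60 mT/m, δ = 22 ms, Δ = 90 ms) the GPD
series matches the oracle to well under 1% at R = 1 and 2.5 μm, but at
R = 10 μm the attenuation is deep (E ≈ 0.08) and the Gaussian-phase
approximation overestimates the signal by ~70% (cylinder) / ~20% (sphere).
This is a property of the approximation, not the implementation: at the
same radius under weak gradients the series and the oracle agree to
0.01–0.03%. Fits on this protocol live in the shallow-attenuation regime
(axonal radii of a few μm), where the approximation is accurate.

## Model space and parametrization

The taxonomy crosses 3 intracellular × 3 extracellular compartments
(9 two-compartment models), × 4 isotropic third compartments (36
three-compartment models), plus Bizeppelin, Tensor, Zeppelin, Ball:
49 models, named Extra+Intra(+Iso). Conventions:

* One shared axial/intrinsic diffusivity `d_par` serves the intracellular
  compartment (parallel free diffusion and the GPD intrinsic diffusivity),
  the anisotropic extracellular axial eigenvalue, and the Sphere/Astro*
  third-compartment intrinsic diffusivity. The isotropic-restricted radius
  is a separate symbol `R_iso` so a model can hold both a cylinder and a
  sphere radius.
* Radial diffusivities are fitted as ratios of their parent eigenvalue
  (d⊥ ≤ d∥, and d⊥₂ ≤ d⊥ for the Tensor), so eigenvalue ordering holds by
  construction.
* Volume fractions use stick-breaking (two logits); f_ec is the simplex
  remainder.
* S₀ ∈ [0.5, 1.5] is free in every model even though data are
  b=0-normalized: it absorbs residual normalization error and inflates
  every K equally, leaving rankings unchanged.
* Bounds: diffusivities [10⁻¹¹, 10⁻⁸] m²/s, radii [10⁻⁷, 2×10⁻⁵] m,
  κ ∈ [10⁻², 10], θ ∈ [10⁻⁸, 10⁻⁵] m — physiological ranges. Bounded
  positives map to unconstrained space by a logit on their log-scale
  position; angles are unconstrained; values on a closed bound are nudged
  inward by 10⁻⁸ of the range and reported with a bound-hit flag (κ
  pinning at 10 is the canonical case: there the Gamma distribution is
  nearly a spike and GDR-cylinders degenerate to the single Cylinder).

## Fitting

The objective is the offset-Gaussian LSE, Σ(Ŝᵢ − √(Sᵢ² + σ²))², with
σ = 0.05 fixed a priori (the noise level of the emulated acquisition,
estimable from b = 0 signals; never re-estimated per fit). √(S² + σ²) approximates the
Rician mean, so the objective stays consistent on voxel-averaged data,
whose noise shrinks but whose Rician bias (set by the per-measurement σ)
does not. A single global σ is used; per-shell echo-time-dependent noise
is out of scope.

Minimization is Levenberg–Marquardt (scipy `least_squares`, method `lm`,
finite-difference Jacobian) in the unconstrained space. Restart 1 is the
warm start — the best fit of the model's simpler parent (GDR→Cylinder→
Stick, Tensor→Zeppelin, Sphere→Dot, Astrocylinders→Astrosticks, drop-iso,
drop-intra), with symbols the parent lacks at physiological defaults and
the orientation seeded from a quick log-linear DT fit of the data.
Subsequent restarts perturb the start by Normal(0, 0.3) in transformed
space — large enough to escape κ/R local minima, small enough that most
restarts converge. Convergence: relative objective decrease < 10⁻¹⁰ or 500
iterations. Non-finite signals from wild steps are mapped to large
residuals so the optimizer backs off instead of aborting. Fits are
bit-reproducible given (data, seed).

## Selection

With fixed known σ, −2 ln L equals LSE/σ² up to model-independent
constants, so BIC = LSE/σ² + K ln N ranks identically to any full-constant
convention; the likelihood term is pluggable (a full Rician −2 ln L can be
swapped in). Ties break by smaller K, then name, making positional
variance diagrams deterministic.

Bootstrap replicates resample the 45 weighted rows of every shell with
replacement, independently per shell, keeping the three b = 0 rows intact
(they define the normalization). Each replicate is refitted (warm-started
from the full-data fits) and ranked; the positional-variance matrix counts
models × rank positions and is doubly stochastic after division by B.

Cross-validation quarters the 32 shells: for each δ, the four low-Δ
(30, 50 ms) shells are randomly assigned one per quarter, likewise the
four high-Δ (70, 90 ms) shells, so every quarter holds one low-Δ and one
high-Δ shell per δ — 8 shells per quarter. The two gradient strengths of a
matched (δ, Δ) pair therefore land in different quarters; keeping them
together is incompatible with the one-low-one-high-per-δ constraint. The
assignment policy is isolated in a single function. Models are fitted on
three quarters and scored by offset-Gaussian LSE on the held-out rows;
train and test shells are disjoint by construction.

## Voxel screening

A diffusion tensor is fitted by weighted linear least squares on
log-signals (weights S², the first-order error propagation) on the reference shell — the
shell with b closest to 1202 s/mm², configurable. Voxels pass if
FA > 0.6 and the principal eigenvector lies within a cone of half-angle η
about the presumed fiber axis; the cone is axial (absolute dot product),
since fiber orientation is sign-ambiguous. The pipeline order is
normalize → select → average; at σ = 0.05 the alternative
average-then-normalize order agrees to < 1%.

## Synthetic data

`generate_voxel` applies Rician corruption √((S + ε₁)² + ε₂²),
ε ~ N(0, σ), to every row including b = 0. The phantom is a pre-aligned
slab (registration is out of scope): an ROI band of ZeppelinCylinderDot
voxels with left-right fiber axis and per-voxel angular jitter
(SD 6° by default) in an isotropic Ball background, with a truth table
per voxel. Default generating parameters follow typical in vivo human
corpus-callosum scales: d∥ = 2×10⁻⁹ m²/s, d⊥ = 0.7×10⁻⁹ m²/s, cylinder
radius 2.5 μm (diameter 5 μm), f_ic = 0.3, f_iso = 0.1 (intracellular
about half the extracellular fraction), σ = 0.05 relative to b = 0.
Orientation jitter is the only dispersion mechanism — no model in the
taxonomy represents intra-voxel dispersion, so the generator does not
either. What the phantom does not emulate: EPI artifacts, motion, field
drift, TE-dependent decay, partial volume with CSF; passing tests
demonstrate pipeline correctness under the stated statistical model, not
robustness to those effects.

Analysis datasets mirror the study's averaging: 24 Rician-noisy voxels at
σ = 0.05 averaged into one signal vector. Single-voxel data at this noise
level carries almost no axon-diameter information at 60 mT/m (the R = 2.5
μm vs R → 0 contrast is ~0.5% of S₀, the known diameter resolution floor
on clinical gradients); averaging restores it, and diameter recovery lands
in the 3–7 μm window in ~90% of draws.

## Problem sizes

Scaled-down defaults keep every analysis on one CPU in minutes while
preserving the study's conclusions: restart pools of 3–12 (the restart
robustness test shows a small pool's best LSE within 0.1% of a 4× pool),
bootstrap B = 20 on a 12-model list spanning all ranking groups, 10–20
noise draws for recovery, 5–10 seeds for the full 49-model ranking.
Full-scale settings (250 restarts, B = 100, all 49 models everywhere)
are plain arguments.

## Known limitations

* The GPD approximation degrades in the deep-attenuation regime (large
  radii at the strongest shells); see the Monte-Carlo comparison above.
* BIC uses the offset-Gaussian likelihood convention; a full Rician
  likelihood would shift absolute BIC values (not, in our checks, the
  group structure).
* No exchange/permeability, no orientation dispersion within a voxel, no
  crossing fibers — the taxonomy is the scope.
* The fitted "axon diameter index" is an effective single-radius summary,
  biased toward large axons by volume weighting.
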