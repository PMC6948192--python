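# Methods

This note documents the models, algorithms, numerical choices and known
limitations of the package, stage by stage.

## Scattering model and units

All scattering vectors *q* are in Å⁻¹ (analysis range 0.00621–0.333 Å⁻¹ by
default, matching a typical BioSAXS detector configuration), distances in Å,
intensities in arbitrary units. Bead models use one bead per residue with a
3.8 Å virtual bond and a uniform Gaussian dummy-bead form factor
f(q) = V·exp(−(q·r_b)²/2) with bead radius r_b = 1.9 Å. No hydration layer
or excluded-volume correction is applied: every comparison in the pipeline
is between profiles computed with the same form factor, so the ensemble
logic is form-factor agnostic. Consequently absolute intensities and fits
against profiles computed by atomistic predictors are out of scope.

The Debye sum I(q) = f² [N + 2 Σ_{i<j} sinc(q d_ij)] is evaluated exactly
for models up to 200 beads and via a 0.5 Å distance histogram above that,
with each occupied bin contributing at its *mean* pair distance (first-order
error cancellation); measured agreement with the exact double sum is better
than 0.1% for 300-bead models over the default q range.

## SEC-SAXS decomposition (SVD-LC)

Each elution frame is modeled as c_p(f)·I_protein(q) + c_b(f)·I_buffer(q) +
noise. The frames of the elution main peak and of a post-peak buffer region
are stacked and decomposed by SVD. Components are deemed significant when
their singular value exceeds 5% of the largest *and* the lag-1
autocorrelation of their q-space singular vector exceeds 0.5 — physical
spectra are smooth in q while noise components decorrelate point to point.

The protein profile is the unit-norm linear combination of the significant
components that optimizes Guinier-region linearity: the mean squared
residual of a straight-line fit of ln I vs q² over the Guinier window. Two
safeguards matter in practice:

* **Frozen window.** The window (number of leading points with q·R_G below
  1.3) is fixed once, from the plain buffer-subtracted estimate, and reused
  for every candidate direction. A self-consistent per-candidate window
  lets a candidate shrink its own window to a handful of points and appear
  spuriously linear.
* **Noise-aware selection.** For particles whose ln I vs q² is intrinsically
  curved (any non-Gaussian body, e.g. a sphere), admixing buffer can
  *straighten* the window and the raw minimizer is biased. The sub-rank SVD
  residual provides a per-point noise estimate, from which a noise floor for
  the objective is derived; among directions whose objective lies within
  that floor of the minimum, the one closest to the plain-subtraction
  direction (which is statistically unbiased) is selected, by bisection on
  the admissibility boundary. On noiseless data the floor is zero and the
  pure minimizer is used, which recovers an exactly Guinier-law protein
  component to machine precision on rank-2 mixtures.

The result is scaled by projecting the buffer-subtracted peak frames onto
the found direction and taking the largest coefficient ("matching the peak
frame scale"); a joint two-basis fit is avoided because it is unstable when
the found direction is nearly collinear with the buffer (protein-free
series).

## Maximum-entropy inversion

Both P(r) inversion and pool weighting solve the same problem: among all
non-negative solutions fitting the data to a target reduced χ², pick the one
closest to a prior by informational entropy.

* **P(r).** The transform I(q) = 4π Σ P(r) sinc(qr) Δr is discretized on a
  1 Å grid starting at r = 1 Å (the r → 0 limit of sinc is 1; starting at 0
  would add a column indistinguishable from a constant). The grid extends to
  D_max, or 10–20% beyond a D_max *hint* when the support is uncertain (the
  error-estimation path uses 15%). The prior is m(r) ∝ sin(π r/D_max) on
  0–π, scaled so its forward transform matches the data magnitude; it
  vanishes at both ends of the support, encoding soft endpoint decay without
  a hard constraint. The generalized (unnormalized) entropy
  S = Σ (p − m − p ln(p/m)) is used so the overall amplitude is free.
* **Pool weights.** The prior is uniform (unbiased) over the M pool models,
  the entropy is S = −Σ w ln(wM) (0 at uniform, ≥ −ln M), the weights live
  on the simplex, and a single global intensity scale is refit inside every
  χ² evaluation (the gradient treats it as fixed at its optimum — envelope
  theorem). Feasibility of a χ² target is checked against the non-negative
  least-squares solution over the simplex before solving.

**Solver.** The constrained problem is solved via its Lagrangian
λ·χ²/2 − S with bisection on λ against the χ² constraint (relative
tolerance 10⁻³). The textbook multiplicative fixed-point update
p ← m·exp(−λ·∂(χ²/2)/∂p) is the stationarity condition of this Lagrangian
but diverges as λ grows (tight constraints); the inner solve therefore
minimizes the Lagrangian directly by L-BFGS in log-amplitude coordinates
(P(r); positivity preserved by construction) or softmax coordinates (pool
weights; the simplex constraint disappears). Both objectives are convex in
the original variables. When no χ² target is meaningful (error estimation on
data without trusted σ), λ is doubled until the residual RMS improves by
less than 0.5% per doubling, and σ is set to the RMSD of the final
residuals, constant across q (a q-binned variant is available).

The regularization path is monotone: lowering the χ² target never increases
the entropy (verified as a property test).

## Guinier, Kratky, D_max

The Guinier fit is a weighted linear fit of ln I vs q² with the upper window
limit chosen self-consistently so q_last·R_G ≤ 1.3 (configurable), at least
5 points, optional rejection of up to 3 low-q outliers beyond 4σ
studentized residuals. Note the systematic truncation bias: for a sphere
the Guinier estimate at s·R_G ≤ 1.3 is ~1.8% above √(3/5)·R — this is a
property of the approximation, not the fitter, and is why R_G comparisons
between a reconstruction and a ground truth are made Guinier-to-Guinier.

D_max is estimated by scanning candidates, running the MEM fit to its
plateau at each, and returning the smallest candidate whose χ² is within 5%
of the scan minimum and whose P(r) tail is clean (less than 1% of the mass
beyond the last crossing of the 10⁻³·max(p) level). A scan whose plateau is
not established inside the range raises an error carrying the χ² trace.

## Conformer pools

The dimer stand-in: a rigid rod of two straight bead strands (3.8 Å
spacing, 5 Å lateral separation, default span 54 Å) in parallel or
antiparallel orientation; two rigid arm templates, A (spherical blob,
radius 14 Å) and B (prolate 2:1 blob of equal volume), representing the two
hinge conformations; self-avoiding linker walks of 3.8 Å steps connecting
rod ends to arms. In the antiparallel topology the two linker exits sit at
opposite rod ends (elongated dimers); in the parallel topology both sit at
the same end. Pool composition follows the requested AA/BB/AB and topology
mixes by largest-remainder allocation; everything is reproducible from one
seed.

Arm orientation is sampled within a 30° cone of the outward direction with
a free axial spin. The cone keeps clash rejection low *and* keeps the pool's
R_G spread driven by linker flexibility (a fully random orientation swamps
the linker signal with arm-orientation variance). With zero-length linkers
the arm placement is deterministic (straight continuation of the rod), so
such pools are rigid; zero-linker parallel topology is geometrically
infeasible (both arms at one rod end always clash) and generation reports
the acceptance rate when the retry cap (100 per linker) is exhausted.

Clash distance is 3.0 Å between non-bonded beads. Compact / intermediate /
extended labels are assigned at pool mean ± 0.5 standard deviations.

This generator is a statistical stand-in for atomistic pool generation: it
reproduces the *roles* (rigid cores, flexible linkers, hinge-conformer and
topology combinatorics, broad R_G distributions) but not protein geometry,
Ramachandran statistics or side chains. Sizes are desk-scale (hundreds of
beads, pools of 10³ rather than 3×10⁴).

## Ensemble selection

Weights for a fixed member set are non-negative least squares (the
unnormalized amplitudes absorb the global scale; fractions are reported).
Exact duplicate members are collapsed onto the lowest pool index for
reproducibility. The reduced χ² divides by the number of points N.

The minimal-ensemble search is exhaustive for pools ≤ 50 with k ≤ 3 and a
deterministic beam search (width 100) otherwise: every beam member of size
k−1 is extended with *every* pool model and refit by NNLS. Extending with
every model rather than a random subset makes restarts unnecessary and
guarantees χ²(k) is non-increasing in k (the best (k−1)-set plus any member
is always examined). Equality with exhaustive enumeration is asserted on
small instances.

MEM weighting of the full pool is conventionally terminated at the ES6 χ²
(`EnsembleModel.fit_mem(target_from_k=6)`), balancing fit quality against
over-concentration; any explicit target can be supplied.

## EM rendering and projection matching

Beads are rendered as isotropic Gaussians with σ = resolution/(2√(2 ln 2))·0.5,
i.e. the rendered blob's FWHM is half the nominal resolution, each blob of
unit integral (density ∝ bead count). Defaults: 6.5 Å voxels, 40 Å
resolution. Volume projection rotates the grid (ZYZ Euler angles, linear
interpolation) and sums along z, conserving total density to ~1%. Because
the line integral of an isotropic 3-D Gaussian is a 2-D Gaussian of the same
σ, projection matching uses the exact bead-space path (rotate coordinates,
splat 2-D Gaussians); the two paths agree to interpolation error.

Matching maximizes Pearson correlation (mean-subtracted, scale-free,
bounded in [−1, 1]) over a (φ, θ) grid at the angular step (default 10°),
exhaustive in-plane rotation at the same step, and integer translations
within ±3 pixels; the per-class best model is the argmax over the pool. The
correlation is computed as a single normalized matrix product in float32
for memory and speed on one CPU.

## Synthetic data

The generator emulates: a Gaussian elution envelope multiplying a hidden
weighted mixture of pool conformer profiles; a smooth positive buffer curve
(flat background plus a low-q excess, default level 0.5 relative to the
unit-normalized protein peak — buffer scattering in real SEC-SAXS is a
large fraction of the total, and the SVD rank detection relies on that);
Poisson-like noise σ(q) = a·√I + floor (default a = 0.01); and class
averages drawn from the truth weights, projected at random orientations,
with Gaussian noise scaled so mean-signal-over-support / σ equals the
requested SNR. A master seed fans out to per-stage seeds by fixed offsets;
the whole pipeline is bitwise reproducible.

What it does *not* emulate: detector geometry and CTF, stain artifacts,
capillary fouling, inter-particle interference, concentration-dependent
effects, and real protein form factors. Passing tests therefore demonstrate
the *statistical* correctness of the analysis chain under its stated model,
not beamline-grade robustness.

## Default problem sizes

Tests and the acceptance script use pools of 15–1,000 models, 50-frame
series, 150–220-point q grids, 48-pixel class images and 10⁶-pair
Monte-Carlo oracles. These sizes were chosen so each stage's statistical
behavior (recovery errors well inside tolerance bands) is established while
the whole suite remains desk-scale; they are smaller than the study-scale
pools (30,000 models, 53 classes) by design, with the search and solver
code paths identical.

## Known limitations

* The Guinier-optimized direction is identifiable only up to the noise
  floor of the linearity objective; heavily curved low-q regions (strong
  aggregation, inter-particle effects) would defeat it.
* MEM weight distributions inherit the pool's coverage: conformations
  absent from the pool are invisible, and weights for profile-degenerate
  conformers are split by entropy, not physics.
* The two-bead P(r) "dominant peak" refers to the inter-bead peak at
  r > 10 Å; the Debye self-term necessarily places comparable mass near the
  origin.
* Projection-matching scores use global (not locally-masked) normalization;
  with very low SNR and large empty regions a masked score would
  discriminate better.
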