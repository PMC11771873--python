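# Methods

This note documents the model, the numerical and design choices behind
`oriadapt`, what the synthetic-data generators do and do not emulate, and
the package's known limitations.

## Observer model

**Angle convention.** Stimulus orientation is 180°-periodic; a stimulus
angle of d degrees (0° = vertical, d ∈ [−90, 90)) is mapped to the circle
as θ = d·π/90, so the two cardinal orientations sit at 0 and ±π and the
obliques at ±π/2. All public I/O (CSV columns, JSON, CLI) is in stimulus
degrees; all internal mathematics is in circle radians. This makes standard
von Mises machinery directly applicable to axial data.

**Allocation and normalization.** The square root of Fisher information
("coding capacity density") under stationary conditions is a symmetric
mixture of a uniform component and two identical von Mises peaks at the
cardinals, with weight k ∈ [0, 0.5] per peak and concentration κ. Every
√J field — stationary or adapted — is normalized to unit circular integral.
This resolves the model's proportionality constants in one place: the field
carries only the *shape* of the allocation, while the *amount* of total
capacity is carried by the sensory noise concentration κᵢ, as
J_vm(κᵢ)·(2π)² with J_vm(κ) = κ·I₁(κ)/I₀(κ), the exact Fisher information
of a von Mises location parameter. The model itself does not pin down a
particular normalization of "total Fisher information"; this definition is
exact, reduces to κᵢ·(2π)² for large κᵢ, and any monotone alternative would
only rescale capacity comparisons, not reorder them.

**Transforms.** Sensory space is the normalized cumulative of √J,
F(θ) = −π + 2π·∫₋π^θ √J, a strictly increasing circular map with fixed
endpoints F(±π) = ±π. The adapted field √J_a lives in sensory space: the
reallocation kernel (uniform + von Mises peaks at 0 and π) is recentered at
the adaptor's sensory position θ̃_a, its second peak therefore at θ̃_a + π
*in sensory space* (not at the stimulus-space orthogonal mapped through F;
the two coincide when the stationary allocation is symmetric, as here).
Kernel shape is shared across adaptors — the model's isomorphism
assumption — so the adapted fields for different adaptors are circular
shifts of one another.

**Measurement densities.** The measurement is von Mises with concentration
κᵢ around the encoded position in the final space (κᵢᵃ for the
variant that relaxes the fixed-resource assumption). Stimulus-space
densities follow by pushing through the inverse transform chain with the
change-of-variables Jacobian taken from the interpolated transforms
themselves, which makes the pushforward conservative by construction; the
gridded density is additionally renormalized to remove the O(h²)
quadrature residue (≈10⁻⁶ at the default grid).

**Decision rule.** The observer reports "reference clockwise" when the
wrapped difference between the reference and test measurements lies in
(−π, 0); clockwise means decreasing stimulus degrees. The response
probability depends only on the encoded separation Δ = μ_r − μ_t and is
computed as P(Δ) = ∫ vm(y; 0, κ) H(y − Δ) dy with H the half-circle
von Mises mass — a circular cross-correlation evaluated by FFT once per
model and interpolated per trial. At Δ = 0 the comparison is symmetric and
P = 1/2 is returned exactly. The comparison is evaluated in the final
sensory space, where both measurements are von Mises. Formally, a
half-circle comparison in stimulus space differs from one in sensory space
for antipodal measurement pairs, because a monotone circular map does not
preserve half-circle arcs; at the noise concentrations of interest
(κᵢ ≈ 8 and above) the probability mass involved is negligible
(< 10⁻⁴), and the generative sampler uses the same space so the
integral and simulation routes are mutually consistent.

**Model-implied thresholds** are two-sided: the mean of the clockwise-side
and counter-clockwise-side offsets at which the corresponding report
reaches 75%. This matches how thresholds are read off symmetric
cumulative-Gaussian psychometric fits. A one-sided threshold picks up the
first-order gradient of the allocation and visibly degrades the
threshold–Fisher duality (product CV ≈ 10% instead of ≈ 2.4% at κᵢ = 20).

## Fitting

Fitting is staged: (1) the control condition determines (k, κ, κᵢ); (2)
with those frozen, the oblique conditions determine the kernel, jointly
across the 45° and 22.5° adaptors for the shared-kernel variants, and
separately per adaptor for `two_peak_kernel`. The likelihood is the
Bernoulli product over trials; trials are grouped by unique (test,
reference) pair so each probability is evaluated once (verified against a
per-trial reference path to 10⁻⁹). Probabilities are clamped at 10⁻¹²
with a reported clamp counter.

Optimization uses L-BFGS-B from Latin-hypercube starts (default 10
restarts; the surface is mildly multimodal in the kernel concentrations).
Bounds: k ∈ [0, 0.5]; concentrations κ, κ₁, κ₂ ∈ [0.1, 100] and
κᵢ ∈ [0.1, 200], optimized in log space; the simplex constraint
k₁ + k₂ ≤ 1 is enforced by the reparameterization k₁ = a, k₂ = b(1 − a)
with a, b ∈ [0, 1]. BIC = p·ln n − 2·ln L with n the number of oblique
trials; free-parameter counts are 3 (control), 2 (one_peak), 4 (two_peak),
5 (two_peak_fisher), 8 (two_peak_kernel).

**Identifiability.** Two parameter pairs are weakly identified at the
experiment's scale (192 trials per test orientation), a property of the
model-design combination rather than of the optimizer. First, the
uniform-plus-von-Mises mixture is nearly degenerate along a (k, κ) ridge:
raising k while lowering κ changes the allocation shape by only a few
percent, below the measurement noise of threshold estimates at this trial
count. Second, the width κ₂ of the orthogonal kernel peak is constrained
only by the single test orientation exactly orthogonal to the adaptor, so
(k₂, κ₂) trade off against each other and the uniform weight. Derived
quantities — the noise level κᵢ, the adaptor-peak parameters (k₁, κ₁),
thresholds and BIC orderings — are well identified; recovered (k, κ) and
(k₂, κ₂) should be interpreted as ridge coordinates unless the design
samples the flanks of the relevant peaks. Simulation-based recovery rates
are recomputed by `scripts/acceptance.py`.

## Psychometric analysis

Per test orientation, p(counter-clockwise | Δ) = Φ(Δ/σ) with
Δ = θ_r − θ_t wrapped to (−90°, 90°] (at the 90° test orientation the wrap
matters and is applied before fitting); zero mean and no lapse rate. σ is
fit by 1-D bounded likelihood maximization over log σ ∈ [log 10⁻³, log 50]
(the 1-D likelihood is unimodal); perfectly separable data are detected
directly and reported at the σ floor with a boundary flag. Threshold
D = σ·z(0.75) ≈ 0.6745·σ; discriminability 1/D. Intervals are percentile
bootstrap over trials (the natural unit for staircase data; resampling
blocks instead would be the alternative — the choice is recorded in the
output metadata), with a warning flag when more than 10% of refits are
degenerate.

## Synthetic experiment generator

The generator reproduces the experiment's structure: two parts, one per
oblique adaptor (45° and 22.5°), each pairing an oblique condition with a
control condition at the same test orientations; test offsets relative to
the adaptor [0, ±10, ±30, ±45, 90]° (45° part) and [0, ±10, ±22.5, ±45,
90]° (22.5° part); 192 trials per test orientation (6144 trials total);
reference offsets driven by a 2-up-1-down staircase on 25 equally spaced
magnitude levels within a ±range (default ±15°, one of the ranges used in
the experiment; the middle of the four options, appropriate for the default
observer's thresholds). The staircase state indexes the magnitude lattice
linspace(0, range, 25); it starts at the middle level, the offset's sign is
randomized per trial, and correctness for the staircase bookkeeping is
defined by the sign of the true offset (no feedback was given to subjects;
the adaptive procedure still needs an internal correctness signal).
Responses are drawn from the generative decision rule with numpy's
von Mises sampler (Best–Fisher rejection sampling) under a single seeded
generator, so regenerated CSVs are byte-identical.

What it does not emulate: lapses, response bias, learning or drift across
blocks, the interleaved clockwise/counter-clockwise instruction blocks
(mirror-combination renders them equivalent under the symmetric decision
rule), and subject-specific asymmetries between vertical and horizontal.

## Synthetic gaze video and scene statistics

The video generator tiles a 96-px (6°) gaze-centered patch with 32-px
regions in a checkerboard of "stable" and "random" regions. Each region
carries a latent orientation on the doubled-angle circle: a per-region
anchor persists between frames with probability `persistence` (default 1
for stable regions, 0 for random ones) and is otherwise redrawn uniformly;
the rendered orientation jitters around the anchor with von Mises
concentration 200. An anchor process (rather than a random walk) is used so
that a persistent region's orientation history has near-zero circular
variance over any window length. Regions are rendered as band-pass
(0.03–0.2 cycles/px) noise filtered by a wrapped-Laplace orientation
profile (σ = 1.4°, the psychophysical stimulus filter); each region's noise
pattern is fixed across frames, so a frozen latent scene produces
byte-identical frames and all temporal variation traces back to the latent
dynamics. The band spans the passbands of pyramid levels 2–4.

The analysis crops a 6° patch at gaze (border-clamped, flagged), estimates
orientation at levels 2–4 (each level at half the previous level's
resolution) with first-order steerable filters — Gaussian derivative pairs
(σ = 1.5 px) on a band-passed level image; the maximal-response orientation
follows from the two basis responses in closed form, which is
mathematically identical to rotating a first-order filter — and computes
sliding mean/variance over 72-frame (3 s at 24 Hz) windows on doubled
angles. Next-frame conditional histograms pool positions, times and levels
whose window variance falls in a band (below 0.1 or above 0.9), with 37
bins over (−90°, 90°] so one bin is centered at zero; pooling is unweighted
with an optional response-magnitude threshold (orientation is undefined
where the filter response vanishes; such positions are flagged).

What the video generator does not emulate: photorealistic scene content,
broadband 1/f spectra, occlusions, eye movements (gaze is scripted in the
sidecar), motion blur, and compression artifacts of field recordings.
Passing tests therefore demonstrate the correctness of the estimator and
the history-conditioned analysis, not the statistics of real forests.
Neighboring samples within a filter support are correlated, so the
"multinomial noise" scale for the pooled high-variance histogram is
approximate at large sample counts.

## Response-based Fisher estimator

For a units × orientations response matrix on a uniform 1° grid,
J(θ) = Σᵢ (∂rᵢ/∂θ)², assuming independent unit-variance Gaussian noise.
Derivatives are periodic central differences with respect to the
orientation circle in radians (O(Δ²); < 0.2% error for the analytic cosine
fixture at 1° spacing); √J is normalized to unit sum over the probe grid,
per curve, before any averaging (normalizing after pooling would weight
sequences by their overall response energy). Degenerate (all-flat) response
sets are flagged rather than normalized. The toy fixture — von Mises-tuned
rectified energy units probed with wrapped-Laplace orientation-filtered
noise whose pattern is rotated rigidly across probe orientations — stands
in for a network's first representation layer; any response matrix with
the same layout can be substituted unchanged.

## Numerical choices

- Grid: 2048 points over [−π, π) for model objects (1024 in the fitting
  hot path; transform interpolation error is far below trial noise at
  either size), trapezoidal integration, PCHIP (monotone piecewise-cubic)
  interpolation for transforms and inverses, with a strict-monotonicity
  guard (10⁻¹² ramp) for allocations that vanish over long arcs.
- Decision tables are built once per model by FFT cross-correlation and
  interpolated periodically; probabilities are clipped to [0, 1].
- Multi-start fitting: 10 restarts by default; the test suite and
  acceptance script use 6, which finds the same optima on these surfaces
  at lower cost. Convergence tolerance 10⁻⁹ on the NLL.
- Simulation sizes in tests: the full experiment scale (6144 trials) for
  recovery and model selection with 10 replicate seeds; 10⁵–10⁶ samples
  for Monte Carlo oracles; 160-frame default videos (88 sliding windows).

## Limitations

- Symmetric stationary allocation only (equal cardinal peaks); subjects
  with strong vertical/horizontal asymmetry would need an extended model.
- The (k, κ) and (k₂, κ₂) likelihood ridges above: point estimates of
  these pairs are design-limited at the experiment's trial counts.
- No lapse/guess parameters in either the observer or the psychometric
  stage; data with attentional lapses will inflate fitted noise.
- The kernel model addresses narrow-band adaptors; broadly distributed
  adaptor orientations (which would warp differently through F) are out of
  scope.
- Scene statistics assume the TIFF+JSON interchange format; decoding of
  compressed field recordings is left to the user.
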