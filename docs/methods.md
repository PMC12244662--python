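# Methods

This note records the model implemented by `gcfuse`, the parameter choices
that matter, and the places where the design was genuinely open.

## Pipeline model

The method fuses two co-registered grayscale rasters normalised to [0, 1].
Edge structure is measured with the eight-direction Sobel compass; because
the four masks at 180°-opposed angles are negations of the first four, the
maximum absolute response over `E0, E45, E90, E135` equals the maximum over
all eight signed responses, and only four correlations are evaluated.
Responses are computed in difference form,
`Σ_i k_i (x_i − x_center)`, which is algebraically identical to plain
correlation for zero-sum kernels but returns exact zeros on constant
images. Borders use replicate padding throughout, so every raster keeps
the input shape.

Detail images cross-subtract: `DI1 = I2 − EI1` carries what the second
modality adds beyond the first's edges, and vice versa. Detail images are
signed and are deliberately not clamped — the windowed covariance of the
next stage is shift-invariant, so the sign convention is immaterial.

Pixel weights are the eigen-sums of the horizontal and vertical covariance
matrices of the `W×W` window around each pixel (`Ch` from the window as-is
with columns as variables, `Cv` from the transposed window; normalisation
by `W−1`). Eigen-sum equals trace, so the production path computes traces
directly — vectorised over the image with a sliding-window view — while the
eigendecomposition route is kept as a test oracle. Windows are pre-shifted
by their centre value before centring; this changes nothing analytically
(covariance is shift-invariant) and makes flat windows produce exact zeros.

The merge `F = (I1·wt1 + I2·wt2)/(wt1 + wt2)` is a convex combination
per pixel; where `wt1 + wt2 < ε` (default `ε = 10⁻¹²`) the arithmetic mean
is used. Fused pixels therefore always lie within the per-pixel envelope
of the sources, and fusing an image with itself is the identity.

## What the optimizer searches

Optimising all `2·H·W` per-pixel weights directly would be both intractable
and contrary to the constructive covariance definition of the weights, so
the swarm searches a 6-dimensional reshaping instead:

| component | range | meaning |
|---|---|---|
| `w_idx1, w_idx2` | [0, 3] → {3,5,7,9} | covariance window per source |
| `g1, g2` | [0.1, 10] | multiplicative gain per weight map |
| `γ1, γ2` | [0.25, 4] | contrast exponent per weight map |

so that `wt_i = g_i · base_map(DI_i, W_i)^{γ_i}`. Gains cancel in the merge
when applied to both maps equally, but the *ratio* `g1/g2` and the
exponents reshape the local balance between modalities. The base maps for
the four window sizes are precomputed once per image pair, making one
objective evaluation a cheap power/merge/score operation.

Objectives (both minimised):

* `Fitness1 = 1 − (ENT/8 + FMI + Qabf)`. Entropy is divided by its 8-bit
  cap so all three terms share the [0, 1] scale; otherwise a 6–8-bit
  entropy would dominate the sum. Raw ENT is still reported.
* Cost: by default the deterministic operation-count proxy
  `(W1² + W2²)·H·W` — hardware-independent, so runs and tests are exactly
  reproducible; a wall-clock mode measures seconds instead.

The final deliverable is the knee point: the archive member closest to the
ideal point after normalising both objectives to [0, 1] over the archive.
The baseline decision (W = 3 for both maps, unit gains and exponents) is
always injected into the initial swarm as a warm start; since it also has
the minimum possible cost, the archive always holds a member at that cost
whose quality is at least as good, which makes "optimised ≥ baseline
quality" a structural property of the search rather than a matter of luck.

## Swarm mechanics

* Velocity update: fractional memory term plus three leader pulls
  (global archive leader, personal best, ring neighbourhood of radius 1)
  with weights `ρ1 = ρ2 = ρ3 = 0.8` and fresh uniform draws per component.
* The global leader is picked by binary tournament on crowding distance;
  the personal leader uniformly from the particle's bounded personal
  archive (capacity 5); the neighbourhood leader from the nondominated
  members of `{i−1, i, i+1}`.
* Positions are clipped to the box with velocity reflection on clipped
  components; velocities are clamped to 20% of the box width.
* Archive: capacity defaults to the population size; insertions keep the
  set mutually nondominated, and overflow drops the smallest crowding
  distance (boundary members, having infinite distance, are never
  dropped).
* Darwinian rules (fractional variant only, by default): a particle whose
  personal archive has not accepted a new entry for 5 iterations is
  deleted (never below a population floor of 10); each iteration one new
  particle may spawn uniformly in bounds with probability
  `SCc_max·(1 − 1/(Nkill+1))`, `SCc_max = 0.9`, population ceiling 60.
* Termination: max iterations, or hypervolume improvement over a
  50-iteration window below 0.01, or mean range-normalised pairwise
  distance of archive objectives below 0.2, or a wall-clock limit
  (default 3600 s). The logged HV uses a reference fixed at the initial
  population's nadir plus a 10% margin, so the trace is non-decreasing
  whenever the archive capacity is not binding.
* Determinism: a single `numpy` generator seeded from the config drives
  initialisation, leader selection, spawning and resampling, so identical
  config + seed replays bit-identically.

## Fractional memory

The velocity inertia is replaced by the truncated Grünwald–Letnikov series
`Σ_{k=1..r} c_k(α) v_{t−k+1}` with `c_1 = α`,
`c_{k+1} = c_k (k−α)/(k+1)` and memory depth `r = 4` (a common truncation:
the weights decay fast, and depth 4 keeps >99% of the series mass for
α ≥ 0.6). The order decreases linearly from `α_hi = 1.0` at the start to
`α_lo = 0.6` at the final iteration: a full-inertia exploratory start that
slides into a longer-memory, smoother exploitation phase. At `α = 1` and
depth 1 the update reduces exactly to the classic rule with unit inertia,
which is the lever used to verify the fractional variant replays the plain
one bit for bit.

A frequency-domain route to the same operator ships alongside: the
Oustaloup recursive ladder approximates `s^α` over a band (default
[0.01, 100] rad/s; order `2N+1` with `N = 2`), its gain normalised so the
magnitude at the geometric centre frequency is exactly `ω_c^α`; the
2N+2 numerator and denominator coefficients are fitted as degree-5
polynomials in `α` over `M−1 = 19` sampled orders (`M = 20`), so the
transfer function is available for any order without rebuilding the
ladder. Because applying a rational transfer function to powers of a
velocity *vector* is not a well-defined operation, the optimizer's default
path is the GL series; an adapter (`oustaloup_memory_weights`) discretises
the rational filter by Tustin's method and truncates its impulse response
to supply memory weights of the same shape, with the leading weight scaled
to the GL normalisation `c_1 = α`, for anyone who prefers the
frequency-domain derivation.

## Quality metrics

* ENT, MI: 256-level uniform quantisation of [0, 1]; MI is
  `H(a) + H(b) − H(a,b)` on the 256×256 joint histogram.
* FMI: normalised MI (`2·MI/(H_f + H_s)`, averaged over sources) between
  range-normalised Sobel gradient-magnitude images, using a coarser
  64-level histogram: MI plug-in estimators carry a positive bias of order
  `(K−1)²/(2N ln 2)` for K bins and N pixels, and 64 bins keeps that bias
  negligible at the image sizes this package targets while leaving the
  identities (self-fusion = 1, featureless = 0) intact.
* Qabf: Xydeas–Petrović edge preservation with the canonical sigmoid
  constants (Γ_g = 0.9994, κ_g = −15, σ_g = 0.5; Γ_α = 0.9879, κ_α = −22,
  σ_α = 0.8), gradient-strength weighting, orientation folded to
  (−π/2, π/2]. The per-pixel preservation product is divided by its value
  at perfect preservation `Q(1, 1) ≈ 0.9748`, so an image fused with
  itself scores exactly 1; without this normalisation the metric's own
  ceiling depends only on the sigmoid constants, which makes scores
  incomparable across constant choices.
* SSIM: mean local SSIM with an 11×11 Gaussian window (σ = 1.5),
  `C1 = 0.01²`, `C2 = 0.03²` at data range 1 (delegated to scikit-image,
  whose defaults implement exactly this).
* IGD: mean distance from reference-front points to the nearest
  approximation point. HV: exact 2-D sweep over the sorted front;
  inclusion–exclusion for 3–4 objectives (small sets only).

## Synthetic phantoms

The generator emulates the one property the method depends on —
complementary, co-registered content — not anatomy: a shared elliptical
geometry layer gives the CT image a bright skull ring (intensity 0.97)
with dense bone inserts over flat soft tissue, and the MR image a dark
ring (0.03) with Gaussian-smoothed soft-tissue texture and bright focal
lesions. Texture, lesions and noise come from independent RNG streams
spawned from one seed, so toggling lesion count changes only lesion
pixels. What the phantoms do **not** model: partial-volume effects, bias
fields, anisotropic resolution, registration error, modality-specific
noise statistics. Passing tests therefore demonstrate correctness of the
pipeline's mechanics and its behaviour under controlled complementarity —
not clinical fusion quality on real scans.

The toy optimisation problem (`f1 = x², f2 = (x−2)²`, x ∈ [−2, 4]) has the
closed-form front `{(t², (t−2)²) : t ∈ [0, 2]}`, which is sampled densely
as the IGD reference.

## Problem sizes and numerical choices

Tests and the acceptance script run the toy problem at population 50 for
200 iterations (the HV-window criterion typically stops runs near
iteration 55 with median IGD ≈ 0.033), and full-image fusion at 256×256
with population 12–16 for 15–25 iterations — ample for a 6-dimensional,
partly discrete search space whose base maps are precomputed. The
library defaults for a standalone run are larger (1000 iterations,
population 50) and every threshold is configurable.

Degenerate inputs are defined, not errors: constant images have zero
entropy and zero weight maps; all-flat triples score 0 on Qabf and FMI;
zero total weight falls back to the pixel mean. Dominance is strict
(`a` must improve somewhere), duplicate objective vectors are kept once,
and archive pruning never removes boundary points.

## Known limitations

* The Oustaloup-derived memory weights are an adapter, not the default
  update; the two routes agree in normalisation but not coefficient by
  coefficient.
* The cost proxy counts window arithmetic only; it ignores the metric
  evaluation inside `Fitness1`, which in wall-clock terms is not free.
* Single-swarm Darwinian rules; no multi-swarm spawning hierarchy.
* 2-D exact hypervolume only; higher dimensions use inclusion–exclusion
  and are limited to small archives.
* Grayscale, pre-registered, equal-size pairs only.
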