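# Methods

## Coordinate and unit conventions

Coordinates are 0-based with the origin at the **centre of the top-left
pixel**; `x` is the column index, `y` the row index, and the physical field
extends half a pixel beyond the outermost pixel centres
(`[-0.5, dim - 0.5]`). All physical distances are pixel distances times
`pixel_size_nm`. Two pixel-size presets are provided, back-derived from the
stated threshold equivalences of the supported optics: 107.5 nm/px
(×60 objective / CoolSnap HQ, where the 2 px threshold equals 215 nm) and
64.5 nm/px (×100 / CoolSnap ES, where 3 px equals 193.5 nm). The threshold
is deliberately a required parameter rather than a default: the appropriate
value (~200 nm) depends on the optics, and the two presets give 215 or
193.5 nm respectively.

## Spot detection

**Candidate finding.** The image is band-pass filtered with a difference of
Gaussians at scales `radius/2` and `2·radius`, where `radius` (default
2 px) is the expected particle radius. Local maxima (window
`2·round(radius)+1`) whose filtered amplitude exceeds
`brightness × σ_noise` are kept; `σ_noise` is the robust standard deviation
`1.4826 × MAD` of the band-passed image, which is insensitive to the
punctae themselves and makes the criterion invariant to global intensity
scaling. `brightness` (default 5) and `radius` are the two knobs a user
tunes to separate particles from noise. Seeds within `border_margin`
(default `ceil(2·radius)+1` px) of an edge are discarded: a truncated PSF
biases the fit, and losing a thin border strip is preferable.

**Subpixel refinement.** Around each seed, intensities in a window of
half-width `2·radius` are background-subtracted (background = median of the
window's perimeter ring, a local and robust estimate) and fitted with a
full second-order 2D polynomial under Gaussian weights
`exp(−r²/2σ_w²)` centred on the current position estimate. The new estimate
is the stationary point of the fitted quadratic; the weights are recentred
and the fit repeated until the update is below `convergence_tol`
(0.01 px) or 20 iterations. If the fitted quadratic has no interior
maximum (non-concave Hessian) the position falls back to the
Gaussian-weighted centroid and the particle is flagged; estimates drifting
more than `radius` from their seed are rejected. Refined positions closer
than `radius` to a brighter one are merged (two estimates converging on one
spot must not double-count).

**Weight scale.** `σ_w` defaults to `radius/2`. For a visible spot radius
of ~2 PSF σ this matches the weight scale to the PSF standard deviation,
which measurably minimises the pixel-phase bias of the quadratic
approximation: on noiseless integrated-Gaussian spots (PSF σ = 0.93 px)
the fixed point of the iteration deviates from the analytic centre by at
most 0.0014 px across a 10×10 grid of subpixel phases, versus ~0.15 px
when the weight scale equals `radius`. Both the weight scale and all other
fit constants are configurable.

**Accuracy.** Under the synthetic benchmark (below) the RMS localisation
error is ≈3 nm at 107.5 nm/px — comfortably inside the <20 nm regime
expected of polynomial-fit/Gaussian-weight localisation. The error grows as
the amplitude drops (a property-tested monotonicity).

## Colocalisation

For a directed channel pair (source → target), every source particle's
nearest target particle is found (KD-tree, Euclidean distance in nm) and
the particle is flagged when that distance is **strictly** below the
threshold τ; ties at exactly τ do not count (a measure-zero case in
practice, resolved literally). No one-to-one constraint is applied —
several source particles may share a target — matching the per-particle
scoring semantics of the method. The raw percentage requires a non-empty
source map; an empty map is an explicit error rather than a silent 0,
because a 0 would bias pooled statistics.

**Scramble null.** The chance level is estimated by displacing each target
particle by independent uniform offsets in `[-m, +m]` per axis (default
m = 20 px) with toroidal wrapping inside the analysis bounds (full field,
or the ROI bounding box). Wrapping preserves global density; the offsets
destroy short-range correlation. The default of 100 repeats reports
mean ± sd; a single-scramble analysis is recoverable with `n_repeats=1`.
The *target* map of each directed pair is scrambled; scrambling the source
instead is equivalent in expectation under CSR (asserted by test). The net
percentage `raw − mean(scrambled)` may be negative and is reported as-is —
clipping would bias aggregates.

Two known small biases of the finite-magnitude scramble are worth stating.
(i) A scrambled particle remains within a `2m × 2m` box of its original
position, so scrambling a map against *itself* retains a residual
`≈ πτ²/(2m)²` self-term above the CSR level; this vanishes as m grows (the
test suite demonstrates convergence to the closed form
`100·(1 − e^(−ρπτ²))` at large m). (ii) For genuinely colocalised data the
scrambled target stays mildly correlated with the source through the true
pairs, inflating the estimated chance level by the same `πτ²/(2m)²` per
paired particle (≈0.2% per 25% true fraction at the defaults) and hence
slightly deflating the net percentage. At the default m = 20 px and
τ = 2 px both effects are an order of magnitude below the Monte Carlo
noise of a single field.

**ROIs and aggregation.** ROI polygons (≥3 vertices, validity checked;
self-intersecting outlines rejected) restrict analysis to their strict
interior (even–odd rule; boundary points excluded). Per-cell results are
combined either **pooled** (default: flagged and total counts summed
across cells, so every particle carries equal weight — the `n = ...` style
of reporting) or as an unweighted **mean** of per-cell percentages.

**Multi-channel scoring.** With three or more channels, each particle of a
reference channel receives one flag per other channel (same
strict-threshold nearest-neighbour rule); the conjunction column gives
triple-positive scoring.

## Synthetic scenes

The simulator emulates the relevant features of deconvolved/projected
widefield images of labelled endosomes: sparse diffraction-limited spots on
a flat noisy background.

* **Positions**: complete spatial randomness within the field, subject to a
  minimum within-channel separation (default 400 nm = 4× a typical 100 nm
  PSF σ, keeping spots individually resolvable; crowded scenes are
  available by overriding). Placement is rejection sampling with a bounded
  attempt budget; infeasible packings raise an error reporting the achieved
  count.
* **Pairing**: a directed pair (a, b) with colocalised fraction f places
  `round(f·n_a)` channel-b spots at their channel-a partner plus an
  isotropic Gaussian displacement of sd `jitter_nm` (default 0 = perfect
  colocalisation; the truth object records the realised displacements).
  `true_coloc_fraction(a→b) = |pairs| / n_a` by construction.
* **Rendering**: each spot contributes its isotropic Gaussian PSF
  *integrated over each pixel* (erf form), so a spot of peak amplitude A
  and width σ carries `A·2πσ²` photons in total; plus a flat background
  (default 100 photons/px). Noise is Poisson on signal + background with
  optional additive Gaussian read noise — the standard camera model, and a
  controllable SNR dial. Output is quantised to 16 bits; a float path
  exists for analytic tests. Spots whose PSF support lies outside the field
  are silently clipped.

What the simulator does **not** model: the 3D PSF and z-projection,
deconvolution artefacts, spectral bleed-through, non-uniform background,
spot-size heterogeneity, and clustering of structures. Passing tests
therefore certify the *algorithmic* chain (detection accuracy, matching
correctness, null calibration, fraction recovery) under a favourable,
well-specified imaging model — not performance on any particular real
dataset, where parameter choice (`brightness`, `radius`, τ) remains the
user's responsibility.

## Benchmark problem sizes

The quantitative guarantees are computed at sizes chosen to keep Monte
Carlo error well below the tolerances they are checked against: detection
accuracy on 10 fields × 200 spots (≈1,900 matched spots; RMS error ≈3 nm);
the CSR chance law on 512² px fields with 150–300 particles and 60
scrambles per condition (3 standard errors ≈ 0.3 percentage points);
fraction recovery on 100 spots/channel × 10 seeds per true fraction
(standard error of the mean net percentage ≈ 1.6 points against a ±5-point
tolerance); oracle equivalence on 100 random instances of up to 50
particles per channel, checked exactly.

## Numerical and design notes

* Determinism: all randomness flows through `numpy` `SeedSequence`
  spawning; fixed-seed scene generation, rendering, scrambling and the CLI
  pipeline are bit-reproducible, and reports contain no timestamps (the run
  manifest carries the clock instead).
* The KD-tree matching, shapely point-in-polygon filtering and multi-channel
  flags are each validated against independent brute-force
  reimplementations (exhaustive O(n²) scan, ray casting) on random
  instances.
* Degenerate inputs: empty images yield empty maps; empty channels make
  the affected pair *undefined* (with a warning), not zero; flat fit
  windows reject the particle; an exactly threshold-distant pair is not
  colocalised.
* Multi-channel TIFF stacks are read channel-first; interleaved RGB is
  refused rather than guessed.
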