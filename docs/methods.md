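# Methods

This note documents the models and procedures implemented in `iimtseg`,
the parameter conventions, the numerical choices, and what the synthetic
phantom studies do and do not show about real brain MR data.

## Multilevel Otsu search

An 8-bit image induces a 256-bin histogram with probabilities
`P_j = n_j / (M·N)`. K strictly increasing integer thresholds
`0 ≤ t_1 < … < t_K ≤ 254` partition the gray levels into K+1 contiguous
classes (a pixel equal to a threshold belongs to the class below it; a
threshold at 255 would create an empty top class and is excluded). The
between-class variance

    σ_B²(t) = Σ_{i=1}^{K+1} ω_i (μ_i − μ_T)²

is maximized exactly by a dynamic program over per-segment scores
`s²/w` computed from prefix sums of `P_j` and `j·P_j` (using
`Σ ω_i μ_i² = σ_B² + μ_T²`). A backward value table plus forward greedy
reconstruction (first-argmax) gives the global optimum and, among tied
maximizers, the lexicographically smallest tuple — a deterministic,
reproducible convention; the criterion itself does not distinguish ties.
The same DP serves every K (cost `O(K·256²)`), and the test suite checks
it against an independent brute-force enumeration for K ≤ 4.

Conventions: a class with zero probability mass has its mean defined as 0
and contributes nothing to σ_B² (the mean formula is 0/0 there; this
choice keeps σ_B² finite and continuous). A histogram must have at least
K+1 occupied bins, otherwise the search raises an infeasibility error.

## Interval iteration (IIMT)

Global multilevel Otsu is biased toward classes with large variance
because it optimizes all thresholds jointly over the full histogram.
Interval iteration refines each threshold locally:

1. Global Otsu gives thresholds `T_i` and class means `μ_1 … μ_{K+1}`.
2. Track i re-runs single-threshold Otsu on the histogram restricted to
   `[μ_i, μ_{i+1}]` (inclusive real bounds; the restricted histogram is
   renormalized). The two within-interval class means become the next,
   strictly nested interval.
3. A track freezes when its threshold moves by less than δ between
   consecutive iterations. Thresholds are integers, so with the default
   δ = 0.01 (any δ < 1) this is exact repetition. If a restricted
   interval contains fewer than two occupied bins, the track freezes at
   `floor((lo+hi)/2)` (degenerate rule).

Because class means of a sub-interval lie inside it, intervals are nested
and interval widths non-increasing; with integer thresholds the iteration
must terminate, and `max_iterations` (default 100, accepting 1 so the
procedure degrades to plain global Otsu) is only a safety cap. A track
that converges keeps the interval its final threshold was computed from,
which makes every returned threshold exactly reproducible by re-running
the within-interval step on the stored interval. Tracks are refined
independently after the first iteration; the final label map is obtained
by applying the final thresholds to the image, which is equivalent to the
incremental class-growing view of the iteration and simpler to reason
about.

K = 1 is supported (one interval, identical refinement) since
single-threshold results are part of the standard comparisons.

## Hybrid L1–L0 layer decomposition

On the [0, 1] intensity scale the base layer `b` of image `i` minimizes

    Σ (i − b)²  +  λ₁ Σ |∇b|  +  λ₂ Σ F(∇(i − b)),

with forward-difference gradients under circular boundary conditions and
`F` the nonzero indicator. λ₁ (default 1) sets the strength of the
total-variation prior on the base layer; λ₂ (default 0.1·λ₁) penalizes
the number of nonzero detail-layer gradients, concentrating the residual
on sparse edges. The [0, 1] scale is chosen because the noise model
N(0, 0.001) is only meaningful there; the λ defaults apply on that scale.

The solver is ADMM on the augmented Lagrangian with auxiliary variables
`c1 ≈ ∇b`, `c2 ≈ ∇d` and duals `y1, y2`: soft-thresholding for `c1`
(threshold λ₁/ρ), hard-thresholding for `c2` (keep-threshold
`sqrt(2λ₂/ρ)`, the exact prox of the scalar L0 penalty), an exact
Fourier-domain solve of the quadratic `b`-subproblem (with `d = i − b`
substituted, which preserves exact reconstruction by construction), and
dual ascent. Initialization is `b = i` with all auxiliaries zero.

ρ is not part of the model; it controls the nonconvex alternation.
Measured behavior guided the default ρ = 10 with 50 sweeps: much smaller
ρ makes the iteration oscillate without ever settling (the soft threshold
λ₁/ρ then exceeds any realizable gradient and every sweep flattens and
re-sharpens the image), much larger ρ freezes the iterate at the input,
and over-running the alternation past its settling point can drop
moderate-contrast interior structures (a worse local minimum of the
nonconvex objective). At the default setting the iterate settles at the
model's fixed point: clean piecewise-constant inputs (class contrast down
to ~20 gray levels) are returned unchanged with exactly sparse gradients
— the model's global minimum, since flattening any structure costs more
in fidelity and detail-gradient count than it saves in TV — while i.i.d.
noise, whose gradients fall below the effective thresholds, is flattened
(mean |Laplacian| roughly halved at noise σ ≈ 8 gray levels).

Solver precision: on a clean fixture where the initialization is itself
the minimizer, the objective of the settled iterate exceeds the optimum
by ~1e-4 (relative ~1e-6 of the objective value) at the default sweep
count; tests treat differences below 1e-3 absolute as numerical equality.
The objective's L0 term is evaluated with a zero tolerance of 1e-6 on
gradient magnitude for the same reason. The returned base layer is
clipped to [0, 1]; `detail = input − base` afterwards, so reconstruction
is exact by definition. For downstream thresholding the base is rounded
to 8-bit.

## Segmentation fusion

Two label maps of the same image are compared pixelwise. Agreeing
("uncontested") pixels keep their label. Each disagreeing
("controversial") pixel p, with candidate labels `l_a` (first map) and
`l_b` (second map), is re-voted: among uncontested pixels q with
`‖p−q‖ ≤ r` (Euclidean disc, default r = 12, p excluded, clipped at the
border; a square neighborhood is available by flag), the similarity

    SIM(p, q) = exp(−(‖p−q‖² / 2α² + |I(p)−I(q)|² / 2β²))

is summed separately over neighbors labeled `l_a` and `l_b`; p receives
`l_a` iff its sum is strictly greater, otherwise `l_b` (ties and empty
neighborhoods fall to `l_b` — the literal "otherwise" branch). Distances
are in pixel units and intensities on the 0–255 scale; with the defaults
α = β = 1 the vote is effectively decided by the nearest uncontested
neighbors of nearly equal intensity. Only uncontested pixels vote:
controversial neighbors have no defined label at voting time, and
excluding them makes the result independent of visit order. Label
correspondence between the maps is by construction: both come from
threshold sets with the same K, so label k means "k-th darkest class" in
both.

## Quality measures

* **Uniformity** `U = 1 − 2K·Σ_j Σ_{i∈S_j}(I_i − Ave(S_j))² / (MN·(Imax−Imin)²)`.
  The squared dynamic range in the denominator keeps U in [0, 1] and
  dimensionally consistent with the squared numerator; the first-power
  normalization seen in parts of the thresholding literature is available
  via `squared_range=False`. A constant image has U defined as 1.
* **Misclassification error**: binary, one class against the rest.
* **Hausdorff distance**: on region pixel sets by default (boundary-pixel
  mode by flag), via `scipy.spatial.distance.directed_hausdorff` in both
  directions; undefined (error) for empty sets.
* **Jaccard index**: intersection over union; two empty regions count as
  identical (J = 1).

ME, H and J are binary notions; the multilevel aggregate reported here is
the unweighted mean of one-vs-rest values over classes (background
optionally excluded; classes empty in either map are skipped in the
Hausdorff aggregate with a warning). This aggregation is a convention of
this package, stated rather than inherited.

A note on what U can show: for a fixed image, the within-class sum in U
is the 1-D k-means objective, whose optimum over all labelings is
intensity-contiguous — exactly what an exact multilevel Otsu search
returns. No segmentation of an image can therefore beat exact Otsu on U
*scored against that same image*. In the noisy phantom study U is scored
against the noise-free reference intensities (segmentation still runs on
the noisy image): that version rewards labels matching the true structure
rather than the noise realization, which is the property the pipeline's
denoising and fusion stages are designed to improve, and is only
available because phantoms have a known clean reference.

## Synthetic phantoms

`generate_phantom` renders piecewise-constant images of K+1 nested
regions (concentric ellipses, slightly taller than wide, or nested
rectangles) at prescribed strictly increasing class means — a stand-in
for background / skull / CSF / GM / WM-style structures with known
ground-truth labels. Every region must cover at least 1% of pixels, or
the spec is rejected. Optional uniform within-class jitter and the
Gaussian noise model (variance on the [0, 1] scale, then rescaled,
clipped to [0, 255] and rounded, clipping before rounding) emulate
acquisition noise. All randomness is explicitly seeded.

Study conditions used by the tests and the acceptance script:

* *Noiseless recovery*: 96×96 phantoms, K = 1…5, class gaps ≥ 20 gray
  levels (e.g. means 15…240); the full pipeline must reproduce the ground
  truth exactly.
* *Noisy comparison*: noise variance 0.001 (σ ≈ 8 gray levels); K = 4 on
  a 160×160 five-shell phantom with means (30, 60, 95, 130, 170), K = 1
  on a 128×128 two-region phantom with means (90, 125). Adjacent-class
  contrasts of 30–40 gray levels are comparable to realistic tissue
  contrast relative to this noise level — the regime in which denoising
  and fusion matter — and shells are kept ≥ ~12 px wide so structures
  remain resolvable by an edge-preserving smoother. Ten noise seeds per
  study.

What the phantoms do **not** emulate: bias fields, partial-volume voxels,
Rician noise statistics, anatomical shape variability, or texture within
tissue classes. Passing these studies shows the pipeline's components
interact correctly and improve over plain Otsu under controlled
conditions; it does not by itself establish accuracy on clinical MR data.

## Known limitations

* The decomposition objective is nonconvex (L0 term); the solver's
  settled point depends on ρ and the sweep count, and pathological
  settings can delete low-contrast structures. The defaults are validated
  on the study conditions above and both knobs are exposed.
* Fusion assumes the two input maps are mostly in agreement; when one map
  is grossly wrong, the uncontested set is small and the vote unreliable.
* Thresholding is histogram-based: spatial context enters only through
  the base layer and the fusion vote, so heavily overlapping class
  intensity distributions cannot be separated.
* 2-D only; volumetric segmentation and entropy-based threshold criteria
  are out of scope.
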