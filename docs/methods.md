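# Methods

`vesselseg` localizes GLUT1-stained microvessels in single-plane 16-bit
brightfield IHC images and characterizes its own error rates on an
entropy-controlled synthetic benchmark. This note records the models, the
parameters that matter, and the design decisions taken where the problem
left the design open.

## Pipeline

### Gabor texture features

Candidate vasculature is texture: locally oriented, band-limited intensity
structure. Each pixel is described by the response magnitudes of a bank of
40 complex Gabor filters

    G(x, y) = (f^2 / (pi·gamma·eta)) · exp(-(x'^2 + gamma^2 y'^2) / (2 sigma^2))
              · exp(j(2·pi·f·x' + phi)),
    x' =  x cos(theta) + y sin(theta),
    y' = -x sin(theta) + y cos(theta)

with five frequencies in a geometric series f = 0.25·(1/2)^k cycles/pixel
(k = 0..4, all sub-Nyquist) crossed with eight orientations 0..7π/8 in π/8
steps; `gamma = eta = 2`, `phi = 0`. The envelope scale is tied to frequency
as `sigma = 0.56/f` (approximately a one-octave half-response bandwidth);
kernels are truncated at 3·sigma with odd side length. The per-pixel feature
is the magnitude of the complex response — phase-invariant, which is what a
segmentation (rather than edge-localization) task wants — optionally
smoothed by a Gaussian of 0.5·sigma per channel (Gabor-energy convention;
the modest factor keeps masks from bleeding far beyond structure borders).
Images are standardized (zero mean, unit variance) before filtering so the
DC level cannot dominate; a constant image yields an all-zero feature stack
and an empty segmentation. Convolution is frequency-domain with explicit
zero padding over a reflect-padded image, equal to direct spatial
convolution to floating-point accuracy.

### k-means presegmentation

Pixels are split into foreground (candidate stained structure) and
background by k = 2 k-means minimizing the squared-error objective
J = Σ_j Σ_{i∈j} ‖x_i − c_j‖², iterated until no assignment changes
(`max_iter` 300 as a guard). Three representation choices matter:

* **Log compression.** Magnitudes are mapped through
  `log1p(m / (0.1·mean(m)))` before clustering. Without it, rare
  very-strong responders (dense stained clutter, sharp debris) dominate the
  squared-error metric and the two clusters split *clutter vs. everything*,
  expelling the vessels; log compression makes the split
  *stained-structure vs. background*.
* **Per-channel z-scoring** after compression, so low-frequency channels
  (largest raw magnitudes) do not out-vote the rest.
* **Stain-supervised seeding.** Centroids are initialized from an automatic
  exemplar annotation: the mean feature vector of pixels inside/outside the
  optical-density stain gate (below). With no usable gate the code falls
  back to deterministic farthest-point seeding from the configured seed.
  Explicit user-provided exemplar pixels enter through the same
  `supervised_init` path.

An emptied cluster is re-seeded at the point farthest from its assigned
centroid (deterministic). The foreground cluster is the one whose centroid
has the larger L2 norm in *raw* magnitude space — stained, textured
structures respond more strongly across the bank; an exact tie breaks to
cluster 0 with a warning, and the rule is invariant to cluster relabeling.

### Mask refinement: the optical-density gate

Brightfield chromogen (DAB/Nickel) attenuates light multiplicatively, so
staining is measured as optical density `OD = −log(I / I_bg)` against a
local background `I_bg` estimated by a 31-px median filter (computed on a
2×-decimated image; the approximation is negligible at this window). The
k-means foreground is intersected with `OD > 0.10` — trimming the bright
halo that band-limited filtering spreads around structures — then pixels
with `OD > 0.22` (deep stain) are restored even where clustering missed
them: flat interiors of wide structures respond only at their edges.
Finally fully enclosed holes are filled. All thresholds are config keys
(`mask.*`).

### Structures and features

Foreground pixels are grouped into candidate structures by two-pass
8-connected component labeling with union-find equivalence resolution
(run-length variant of the classic minimum-neighbor-label algorithm;
a BFS flood fill and `scipy.ndimage.label` serve as test oracles).
Structures below 10 px (≈2.5 µm² at 0.5 µm/px) are dropped as noise.

Each structure is summarized by six features: pixel area; equivalent
circular diameter √(4A/π); major-axis length and aspect ratio of the
second-moment-equivalent ellipse (axis = 4√eigenvalue of the coordinate
covariance; the minor axis is floored at 1 px before the ratio); solidity;
and mean 16-bit intensity over the structure. Solidity is area over the
area of the convex hull taken over **pixel corners** (each pixel as a unit
square): the hull then always contains the pixel region, so solidity ≤ 1
with equality exactly for convex pixel sets, and a single pixel scores 1
with no special case. (A hull over pixel *centers* would give a 5×5 square
solidity 25/16 — the corner convention is the one that makes the quantity a
well-defined ratio.)

### Interval-split decision forest

Candidates are classified microvessel (M) vs. non-vessel (N) by a forest of
T = 64 trees whose internal nodes apply the two-threshold test
`tau1 > f(x|w) > tau2` on one feature: strictly-inside samples go left, the
rest right. The interval test isolates a *band* of a feature in a single
node — e.g. microvessel diameters, which sit between speck noise and
arteries — where an ordinary single-threshold node needs two levels.

Training: each tree grows on an independent bootstrap replica; at each node
3 of the 6 features (⌈√6⌉) are drawn without replacement; per feature the
best (tau2, tau1) pair over candidate thresholds (midpoints of consecutive
distinct values, capped at 32 quantile midpoints) is found by exhaustive
pair search maximizing Shannon information gain in bits; growth stops when
the best gain falls below 1e−6 bits, the node is pure or smaller than 2, or
depth reaches 16. Ties break deterministically (wider interval, lower tau2;
lower feature index). Leaf labels are the majority class and the forest
predicts the mode of tree votes; both ties resolve to N — the conservative
call, since false positives are the error this pipeline most needs to
avoid. Records are canonically sorted before any seeded resampling, so
training is invariant to input order. Out-of-bag accuracy is recorded in
the model metadata; models serialize to versioned JSON.

For the benchmark the forest is trained on *presegmentation-produced*
candidates labeled by IoU-matching against ground truth — the same noisy
candidate population it will classify at test time — rather than on clean
truth shapes.

## Synthetic benchmark

### What the generator emulates

One 256×256 scene contains: dark curvilinear tubes 3–10 px wide and
30–200 px long along quadratic Bézier paths (microvessels; flat-cored
profile, half maximum at the nominal half-width); wide tubes 20–40 px
(arteries/veins) and irregular star-shaped blobs 8–20 px across with
concave lobes (neurons) as distractor classes; and a background of
smooth gradient + band-limited noise + speckle, rank-uniformized so its
marginal is exactly uniform. Structures attenuate the background
multiplicatively (transmittance of an absorbing stain — dark pixels never
clip), with per-structure depth ~N(0.42, 0.07) clipped to [0.25, 0.6] on
the unit scale. Structures are placed largest-first with a dilated
no-contact zone so each is individually resolvable; a structure that fails
placement 25 times is skipped.

### Entropy control

Background complexity is summarized by the Shannon entropy of the 256-bin
gray-level histogram over the full 16-bit range (log base 2; 0·log 0 = 0).
A single amplitude dial `a` scales the background texture spread and the
coverage of a *stained clutter* field (debris/neuropil specks, σ≈2.5 px,
attenuation uniform in [0.12, 0.88]); the dial is solved by bisection so
the *measured* entropy of the rendered scene hits the target, typically
within a few hundredths of a bit (tolerance 0.15). Near-flat scenes sit at
≈1–2.7 bits; at full amplitude scenes reach ≈7.7–7.85 bits. Two
consequences are deliberate:

* At high entropy most histogram spread in the dark half comes from
  *stained content* (clutter), exactly as in densely stained tissue —
  a background alone cannot reach 7.8+ bits while staying brighter than
  the stain.
* Clutter (and the dark half of the texture) is excluded from a 6-px
  margin around true structures ("perivascular clearing"; the texture
  there is remapped to its bright half). Without this, dense clutter fuses
  with vessels into single candidates and structure-level matching becomes
  meaningless at exactly the entropies the characterization needs.

A standalone `shape_histogram_to_entropy` operation is also provided:
monotone histogram specification toward a tilted-uniform reference
(p_i ∝ exp(−β(1 − i/255))) whose temperature β is bisected against the
achieved entropy; the monotone map preserves level sets, hence geometry.

### What the generator does not emulate

Optics (depth of field, z-blur), uneven illumination beyond a smooth
gradient, stain batch variation, anastomosing vessel networks (structures
never touch), and partial-volume effects. Passing the benchmark therefore
demonstrates the pipeline's behavior under controlled complexity, not
clinical performance on real tissue.

## Evaluation

Predicted and truth structures are matched one-to-one by greedy descending
IoU with threshold 0.3 (configurable). Counts: predicted-M matched to truth
microvessel → TP, otherwise → FP; predicted-N matched to a truth
microvessel → FN; other predicted-N → TN; truth microvessels with no
candidate at all are presegmentation misses, counted into FN and also
reported separately (`n_missed`), so tp+fp+tn+fn = candidates + misses.
FPR = FP/(FP+TN) over candidates reaching the classifier (the denominator
choice changes the numbers and is stated here deliberately);
FNR = FN/(FN+TP). A zero denominator reports the rate as missing, never 0.
Scenes are binned by achieved entropy (0.5-bit bins) and per-bin means of
per-image rates are the headline curves; per-image averages are the
primary statistic, pooled rates are reported alongside.

The default characterization uses 200 scenes with entropy targets evenly
spaced on [3.2, 7.8] and a 70/30 scene-level train/test split drawn by
seeded permutation — a desk-scale problem size chosen so the whole
benchmark (generation, training, evaluation) completes in minutes on one
CPU while every 0.5-bit bin keeps multiple test scenes.

## Numerical and degenerate-input choices

* Entropy bins: equal width over the full range [0, 65535]; the paper-style
  256-bin count is a config default, any n ≥ 2 is accepted.
* 8-bit TIFFs are promoted by a left shift of 8 bits; multi-plane or RGB
  files are rejected, never silently truncated.
* Constant images: features are all-zero and the pipeline returns an empty
  labelmap rather than clustering indistinguishable points.
* k-means runs in float32 (the in-loop expanded-form distances are subject
  to cancellation, so the reported objective is recomputed in exact
  difference form at convergence); the objective history is asserted
  non-increasing every iteration.
* All randomness flows from explicit integer seeds; per-scene seeds are
  spawned from the master seed and recorded in the dataset manifest, and
  reports embed the package version, config hash, and seed.

## Known limitations

* Above ≈7.3 bits the presegmentation increasingly fragments or misses
  vessels, so FNR climbs steeply near the top of the entropy range; the
  false-positive rate stays controlled because the forest is trained on
  the same candidate population and rejects fragments.
* The two-threshold node search is quadratic in candidate thresholds; the
  32-quantile cap keeps it cheap at a small cost in split resolution.
* The stain gate's median background window (31 px) under-estimates OD in
  the interior of structures wider than the window; the deep-stain OR term
  and hole filling compensate, but structures much wider than 40 px would
  need a larger window.
* Structure-level IoU matching at 0.3 is a benchmark convention; the
  numbers reported are sensitive to it and it is exposed in config.
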