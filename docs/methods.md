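# Methods

`clawtrack` locates the leg-claw (tip) positions of a freely walking
arthropod in high-speed backlit video and derives gait and tremor statistics
from the tracked trajectories. The design premise is that the recordings are
silhouettes — a dark body and legs on a bright, static background — so that
every stage from training-set generation to claw detection can be driven by
the geometry of the binary foreground, with no human-annotated training data
anywhere in the pipeline.

## Imaging model and silhouette extraction

Frames are grayscale TIFF/PNG sequences with a frame rate (default
1,000 fps) and a field of view (default 10 mm across a 512-px frame,
0.0195 mm/px). The foreground is

    silhouette = |image(x, y) − background| > threshold.

The background is estimated automatically as the per-pixel **median over
every 20th frame**; the estimator is only sound when the animal traverses at
least ~1.5 body lengths, so a pixel is animal-free in most samples —
otherwise the result carries a `stationary_warning` and the caller should
splice (first/last frame mosaicked along the perpendicular bisector of the
two body centroids) or load a background instead. The threshold defaults to
Otsu's method on the absolute difference image; after thresholding, only the
largest connected component plus components within 5 px of it survive
(dust suppression — the downstream pose model assumes a single animal).

Pixel coordinates are 0-based, origin top-left, x = column, y = row. The
body-centred frame translates by the silhouette centroid and rotates the
anterior direction onto +y; the lateral +x axis is `(−a_y, a_x)` for
anterior unit vector `(a_x, a_y)`. The anterior ambiguity of the principal
axis is resolved by the direction of travel, falling back to
frame-to-frame continuity and, for a single frame, to the broader
(head + thorax) end.

## Self-generated training data

High-confidence **leg** pixels are the intersection of the silhouette's
medial-axis skeleton with its (1-px-dilated) boundary: the two coincide only
where the structure is thin, i.e. on legs. Two refinements matter in
practice:

- The body's rounded head and tail caps also bring the medial axis near the
  boundary; positives falling inside the extended body core (below) are
  removed, so positives come from thin structures only.
- High-confidence **non-leg** pixels are an even mix of (a) the body core —
  pixels whose distance to the mask boundary exceeds half the leg width
  (default bound 5 px), dilated 3 px back out to the mask edge so the body's
  own boundary ring is supervised (otherwise the classifier has no training
  signal on boundary-appearance pixels and tends to call them legs) — and
  (b) background pixels in a 3–20 px band around the silhouette.

Everything else on the foreground is a low-confidence "grey" zone excluded
from learning. Samples are 41×41 grayscale patches (intensities scaled to
[0, 1]) centred on the chosen pixels, zero-padded at borders, labelled ±1.
Default sample sizes are 30,000 per class, drawn uniformly without
replacement (with replacement when a pool is smaller than the request).
The harvest is a deterministic function of the mask (the medial-axis
tie-break rng is pinned); sampling is deterministic given the pipeline seed.

## The boosted kernel classifier

The pixel classifier is gradient boosting with a quadratic (Newton)
approximation of the exponential margin loss `L(y, φ) = exp(−yφ)`, giving
per-round weights `w_i = exp(−y_i φ_i)` and pseudo-residuals `r_i = y_i`.
Each weak learner is a depth-≤5 decision tree whose internal nodes own a
learned convolution kernel: a square window of side 4–19 px at a fixed
anchor inside the patch. At every node, 100 candidate kernels (random size,
random anchor, smoothness penalty λ drawn from {100, 500, 1000}) are fit on
one half of the training data (T1, default 10,000 samples) by regularized
weighted least squares with a 4-neighbour graph-Laplacian penalty, solved
via the normal equations (a singular system gets a 1e−8 ridge jitter). The
split threshold is found by exhaustive search over sorted-response midpoints
on the remaining half (T2); leaf values are the weighted residual means; the
candidate with the smallest weighted split cost wins (ties: lowest candidate
index, then lowest threshold). The T1/T2 split is redrawn each round.

The model is `φ = γ Σ h_j` with shrinkage γ = 0.1 over M = 100 rounds;
scores are clipped to ±30 to keep the exponential weights finite, and the
mean training loss per round is recorded (it is non-increasing, a property
the test suite asserts). Confidence is the logistic transform
`1 / (1 + exp(−2φ))`; prediction runs on every silhouette-foreground pixel,
with background fixed at 0.

**Self-training.** Round 1 trains on the morphological harvest. Each later
round (default: 2 rounds total) predicts on the sampled training frames,
adds foreground pixels with confidence ≥ 0.9 to the positive pool and ≤ 0.1
to the negative pool, resamples patches, and retrains; it stops early when
the pools grow by less than 1%. The gates are deliberately conservative:
the harvest's precision is what the first classifier amplifies, and loose
gates would feed back its own false positives.

Numerical choices: per-candidate kernel fits subsample at most 2,000 node
samples (deterministically, from the pipeline rng) — the split search still
uses every T2 sample; patches are float32, solves are float64.

## Segmentation and tracking

Confidence maps are thresholded at 0.65 (the precision-favouring end of the
useful 0.6–0.65 range; false leg pixels cause identity errors downstream
while false negatives only produce gaps) and 8-connected components smaller
than 4 px are dropped — 3-px-wide leg tips survive. Per component, a
single-pixel skeleton is computed and the skeleton endpoint farthest from
the body centroid is the claw candidate; closed loops yield none.

Identities are initialized at the first frame with exactly the expected
number of tips splitting evenly left/right by body-frame x sign, ranked
front→hind by body-frame y. (Eight-legged mode accepts a user-provided
first-frame labelling instead.) Tracking is then a per-frame
minimum-total-squared-distance assignment (Hungarian algorithm /
`linear_sum_assignment`) in body-frame coordinates under a hard gate of
20 px per frame (scaled by 512/image-width): pairs beyond the gate are
infeasible. Legs that find no tip are carried as missing; a second
assignment pass matches missing legs' last-seen positions against leftover
tips, which is what re-acquires a leg after occlusion. Extra tips are
discarded.

Manual corrections (CSV: frame, leg, x, y or `ABSENT`) overwrite a position
and re-run tracking forward from that frame; the standard repair for a
misidentification is a correction placed more than one gate from the wrong
site and within one gate of where the leg will reappear. After corrections,
out-and-back displacement spikes completing within 1 ms are filtered from
analysis (marked missing).

## Gait parameters

Swing/stance segmentation thresholds the **arena-frame** claw speed with
hysteresis: swing starts above v_on = 4 mm/s, ends below v_off = 2 mm/s,
minimum swing 3 frames; stance is ground contact, i.e. near-zero arena
velocity. (Detection in the body frame is not viable: a planted claw moves
at body speed — above any such threshold for a walking animal.) Because
tracked tips are pixel-quantized, a planted claw jitters by ~1 px between
frames, which at 1,000 fps reads as tens of mm/s; positions are therefore
median-filtered over 7 ms before the speed is computed (a median shifts a
swing ramp's two edges equally, so stride timing and counts survive), and
a 5-ms median on the speed removes the isolated steps left at jitter
transitions. Gaps up to 5 frames are interpolated first; longer gaps split
strides. Each swing is
one stride; PEP/AEP (take-off/landing) are the body-frame positions at the
swing's first/last frame, in mm.

Per stride: duration; period (start-to-start, empty for the last stride);
displacement |AEP − PEP|; path (summed body-frame steps, ≥ displacement);
amplitude (projection of AEP − PEP on anterior +y); stance linearity (RMS
deviation of the arena-frame stride path from a natural cubic spline
through control points sampled every 20 ms); stretch (distance from the
body centre at the stride's temporal midpoint). Per leg: instantaneous
speed; movement % (swing frames / tracked frames); mean stride period;
footprint regularity (mean of the RMS spreads of the AEP and PEP clouds);
the trajectory domain — convex hull of the body-frame trajectory — with
area and length/width via peak-to-peak projections on the principal axes.
Domain overlaps are polygon intersections (Shapely), reported raw and
normalized by the mean strides per leg. Stance width pairs the k-th strides
of the two mid legs and averages the AEP–AEP and PEP–PEP distances.

The gait index scores each frame's swinging set: +1 for a canonical tripod
set ({L1,R2,L3} / {R1,L2,R3}), −1 for a canonical tetrapod (diagonal
contralateral) pair, 0 otherwise; the series is smoothed by a centred
120-ms moving average and clipped to [−1, 1], so a sustained alternating
tripod sits at +1 and a tetrapod wave at −1.

Body parameters: per-frame body length (silhouette extent along the body
axis; the median is the normalizing length), centroid velocity, and turning
points — vertices of the Douglas–Peucker-simplified centroid path
(tolerance 5 px) where adjacent segments differ by more than 50°.

## Tremor analysis

The deviation signal of a claw is the offset of its body-frame trace from a
50-ms moving-average centreline, projected on the fixed axis perpendicular
to the trace's dominant direction of motion (the minor principal axis of
the centreline's frame-to-frame steps). The projection matters twice over:
per-axis detrending would fire on the stride cycle itself, and an
instantaneous tangent flips sign at every swing/stance reversal and would
destroy peak/valley alternation. A **shaking event** is an alternating
local extremum whose signed deviation reaches at least 3 px (about one
leg-tip width, and the tracker's noise floor); a **tremor event** is any
shake inside a run of ≥ 3 shakes with consecutive gaps under 100 ms (well
clear of the ~10 Hz stride rhythm). The tremor frequency is read from the
10-ms-binned histogram of intervals between consecutive same-polarity
tremor extrema, pooled per leg across runs (episodic tremor means the
intervals separating bursts belong to the distribution too) — full
periods, so a 20–30 ms dominant bin means 33–50 Hz — and an excess in a bin is tested by a permutation test whose
null redraws the same number of intervals uniformly over the observed
interval range (p uses the add-one convention; the discrete statistic makes
the test conservative rather than exactly uniform under the null).

Cliff's delta between a test and a control sample is
`(#{a>b} − #{a<b}) / (n_a n_b)`, computed by rank counting (identical to
the double loop); 95% confidence intervals are percentile bootstrap over
10,000 paired resamples, clipped to [−1, 1].

## The synthetic walker

The fixture generator renders what the pipeline expects to see: a dark body
(ellipse plus posterior wing lobe, ~133 px long at default scale) with six
tapering two-segment legs ending in ~3-px tips, walking on a bright
background at 512×512 px / 10 mm / 1,000 fps. Kinematics: stance pins the
claw in the arena; swing moves it, in the body frame, to the anterior
extreme position along a smooth-step path with a 2-px lateral bow; the body
advances one stride per gait cycle (default 1 mm per 100 ms, i.e.
~2.3 body lengths over 600 frames — comfortably above the 1.5-body-length
minimum the background estimator needs). Gait schedules are alternating
canonical tripod sets, a three-pair tetrapod wave (cycle rounded to a
multiple of the three slots), or custom tables. Options add fore-leg
occlusion episodes (the leg vanishes and its truth is flagged hidden),
lateral tremor oscillation on chosen claws, contrast regimes and Gaussian
pixel noise. Rendering is 2× supersampled and box-downsampled to 8 bits,
producing the partially covered, blurred leg-edge pixels real backlit
recordings show; those partial pixels (and leg pixels overlapping the body)
are excluded from pixel-level scoring, because their true label is not
defined. Identical parameters and seed give bit-identical stacks.

What the generator does **not** emulate: leg-over-leg crossings, body
pitch/roll, motion blur, non-uniform illumination, shadows, or the
appearance statistics of real cuticle. Passing the synthetic acceptance
suite therefore demonstrates the correctness of the machinery (harvest,
learning, assignment, parameter computation) under the stated recording
geometry, not performance on any particular real recording.

## Problem sizes used by the test suite

The full-scale defaults (30,000 patches per class, M = 100 rounds, 100
candidate kernels per split, 2 self-training rounds) are the package
defaults. The test suite exercises the identical code paths at reduced
sizes chosen once for the end-to-end fixtures: 2,000 patches per class,
T1 = 1,000, M = 30 boosting rounds, 40 candidates per split, kernel fits
capped at 1,000 samples, one self-training round, on three seeded
600-frame default-regime walker videos with fore-leg occlusions. Under
those sizes the tracker reaches ≥ 95% of claws within 3 px of ground truth
with ≤ 8% missing data on every video, and the learned segmentation beats
the morphological harvest baseline on recall and F0.5 — the qualitative
ordering the method is built on. The boosting-monotonicity check runs the
full 100 rounds on a small two-class texture fixture.

## Known limitations

- Two touching legs segment as one component and yield one claw; the other
  leg goes missing until separation (by design — the ambiguity is handled
  as missing data plus, if needed, a manual correction).
- Initialization requires a clean stance frame with the expected number of
  tips split evenly left/right; animals that cross the midline in every
  frame need the manual first-frame labelling path.
- The automated background needs ≥ 1.5 body lengths of travel; below that,
  splice or load a background.
- Swing detection assumes stance means a planted claw; on a treadmill or
  slipping substrate the arena-frame criterion would need re-tuning.
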