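# Methods

## Pipeline model

A whole-slide image is modelled as a multiresolution pyramid `{I_m}`,
level 0 at full magnification, every level `ceil`-halving the previous
one. Boxes are 0-based, half-open, top-left origin. Three coordinate
mappings connect the stages:

* **Detection level** ξ: the smallest level whose longest side fits in
  2048 px. The source method says only that detection runs "at low
  magnification"; 2048 px is a practical bound for a single detector
  input patch and is configurable.
* **Forward mapping**: all four box components scale by `2^ξ`, clipped
  to level-0 bounds.
* **Backward (medium) level**: `l = log2(w0*h0*10^(-2*rho)) / 2` with
  `rho = 3`, rounded to nearest and clamped to the pyramid. The printed
  form of this expression is typographically ambiguous about the
  exponent grouping; this reading is adopted because it sends a 2 mm
  core scanned at 20x (~4000 px square) to level 2 — a sensible medium
  magnification — and a 1000 px-square footprint exactly to level 0.
  Rounding (rather than flooring) is our choice; the source is silent on
  non-integer `l`.

## Core detection

The cascade contract fixes what any detector backend must satisfy:
`eta = 3` stages with strictly increasing IoU thresholds
`(0.5, 0.6, 0.7)`, each stage a (box regressor, box classifier) pair;
proposals are relabelled per stage against the stage's threshold, the
last classifier scores, then greedy NMS (IoU 0.3, our choice) and a 0.5
score floor. The classification/localisation tradeoff weight
`lambda = 1` is carried in the config for backend trainers. Deep
backbones are out of scope by design — the contract, not the network,
is the portable part.

The shipped classical backend needs no training: Gaussian smoothing
(sigma 1), Otsu thresholding (tissue is darker than glass), a
morphological opening + hole fill to de-crinkle the boundary, connected
components, an area filter at [0.25, 4]x the median component area, and
a circularity filter `4*pi*A/P^2 >= 0.6` whose value doubles as the
detection score. Area/circularity bounds are our choices for disc-shaped
TMA cores; all are parameters.

## Tumor tile selection

Cores are cut into a non-overlapping `M x M` grid (M = 512 for
full-scale slides; the desk-scale pipeline default is 64), edge tiles
zero-padded with a validity mask. A segmenter backend returns per-pixel
probabilities over {background, others, tumorlike}; the class map is the
per-pixel argmax with ties broken toward the lowest class index.
Suppression keeps pixels with class > 1 and nulls the rest to 0,
carrying a boolean mask so downstream code can distinguish suppressed
from dark pixels; the operation is idempotent.

Qualification: a tile survives iff its tumorlike-pixel fraction strictly
exceeds `alpha = 0.05`, counted over the full `M x M` cardinality
(padding counts as background). The qualification statistic's original
algebraic form sums raw class codes over the tile; read literally that
weights "others" pixels at half a tumor pixel. The fraction-of-tumor
reading is the default because it matches the suppression keep-rule and
the attention-weight fraction; the literal mode is retained behind
`mode="literal"`.

Backends shipped: a ground-truth oracle (tests, calibration) and a
color-threshold segmenter keying on brightness (glass background) and
the DAB-brown index `(R+G)/2 - B` with logistic soft probabilities whose
argmax equals the hard rules.

## Weakly supervised boosting

Pixel labels are three-state: positive, negative, unknown. The loop:

* init: `w_j = 1` iff the positive-pixel fraction over the tile
  cardinality is `>= alpha`, else 0 — zero-weight tiles contribute
  nothing to round 1 (verified by the stump's invariance to them);
* update: `w_j += chi` when the misclassified fraction (unknown pixels
  can never count as errors; denominator is the full tile) is
  `>= alpha`. `chi` is not specified by the source; default 1.0 so a
  weight reads as "times this tile was hard";
* focusing sampling: the ignore mask is exactly the unknown pixels, and
  every loss/error in the package excludes them;
* boosted augmentation: tiles whose weight exceeds their initial weight
  get 10 deterministic geometric variants — the description "rotation
  per 5 degrees and 5 times and increment of 90 degrees" is read as five
  small rotations (+5..+25) plus {90, 180, 270}, with both flips; other
  readings are expressible through the recipe — each variant receiving
  photometric jitter (contrast/saturation +-20%, brightness +-12.5%)
  drawn from a stream seeded by (seed, sample, variant), so results are
  order-independent and reproducible. Labels and ignore masks undergo
  the same geometric op (nearest-neighbour, out-of-frame pixels become
  unknown) and no photometric op.

The final model is the last round's base model — sequential refinement
of a single segmenter, not an ensemble vote; the number of rounds `U`
defaults to 3. Both are open choices of this package (the source names
`U` but gives no value and does not state a combination rule). The
shipped base learner is a weighted decision stump on the brown index;
any learner honouring the weighted/ignore-masked contract plugs in.

## Core-level prediction

Selected tiles are fetched at the medium level `l` computed from the
core footprint; their suppression masks are block-averaged by `2^l` into
per-pixel tumor coverage weights, which conserves tumor-area fraction
across resampling (verified to 2%). Tile features are tumor-weighted
RGB means/SDs, brown-index mean/SD and the tumor fraction; the
reference classifier is a standardised logistic regression over them
(scikit-learn estimator, so it composes with sklearn model selection).
The aggregation of tile probabilities into `beta_d` is not specified at
the tile/core boundary by the source; the mean is the default (smooth,
order-free), median and max selectable. `beta_d >= delta` with
`delta = 0.5` gives the decision; a core with no qualified tiles is
reported Invalid with a `no_tumor_tiles` flag rather than erroring, so
slide-scale runs complete.

## Model selection and early stop

Checkpoints are evaluated every `eval_period` iterations (default 1000);
derivatives are forward differences per grid step, so the bounds
`epsilon = 0.003` (loss) and `tau = 0.1` (F-measure) cap the change per
evaluation. The "continuous period" is `run_length` consecutive
evaluations, default 3 (unspecified in the source; configurable). The
stable-loss run opens the window at `k_s`; the F-measure run — searched
only from `k_s` on — triggers the early stop. `k_e` is the evaluation at
which that run is confirmed online (the run's last point plus the
two-evaluation lookahead the second difference needs), which makes the
selection invariant to any evaluations after `k_e`; without a stable
F-measure, `k_e` is the final iteration. The selected checkpoint
maximises F on `[k_s, k_e]`, ties to the largest iteration. No smoothing
is applied to the derivative series before thresholding.

## Evaluation

Positive class is Effective throughout. Precision/recall with empty
denominators are reported absent, never 0. AUC is the trapezoidal area
under the ROC (equivalently the tie-aware Mann-Whitney statistic, which
the tests verify independently). Kaplan-Meier, the two-sample log-rank
test and the Cox partial-likelihood fit delegate to lifelines — standard
statistics, not contributions of this package — behind interfaces that
validate degenerate inputs (no events, zero-variance covariates).

## Synthetic data: what it does and does not emulate

`generate_slide` emulates: the 6 x 10 jittered grid (12 slides -> 720
cores, the study scale), separated circular cores on bright glass,
57.2% effective prevalence, tumor blobs (thresholded band-limited
noise) covering 15-45% of a core, and an outcome signal carried by the
DAB-brown intensity of tumor pixels — a mean shift of
`effect_size * noise_sd` on the brown index, `effect_size = 2` by
default, `noise_sd = 12` grey levels. Cores are drawn at 128 px
diameter rather than ~4000 px so a 12-slide corpus renders in seconds;
the pyramid geometry, coordinate maps and statistics are unchanged by
that scaling, which is why the unit tests exercise the 4000 px mapping
arithmetic separately.

It does not emulate: realistic tissue morphology, the four antibodies'
distinct staining chemistry, scanner artefacts, touching or fragmented
cores, or patient-level correlation between cores. Consequently a
perfect AUC on the fixture shows the pipeline recovers a planted,
cleanly-carried signal — not that real-slide accuracy would match.

`generate_trace` produces a loss/F-measure pair that decays/rises
exponentially (time constant `plateau_start / 5`) and is exactly flat
from `plateau_start`, plus seeded Gaussian noise, so the true window
start is known by construction. `generate_survival` draws exponential
event times with group-1 hazard = `hazard_ratio` x baseline (default
0.18, a strongly protective prediction; baseline median 12 months),
with optional uniform censoring.

## Numerical choices and degenerate inputs

Downsampling is 2x2 block averaging with edge replication (ceil-halved
dims). Probability stacks must sum to 1 within 1e-6 per pixel. Boundary
rules follow the source's inequalities exactly: weight init and update
use `>=` at alpha, tile qualification is strict `>`, the decision is
`beta >= delta`. Blank images yield zero detections (not an error); a
fully unannotated training set raises "no supervised signal"; a one-class
ROC, an event-free survival comparison and empty selection windows all
raise.

## Problem sizes

The test suite and the acceptance script run the full pipeline at the
720-core study scale (12 slides x 60 cores) for one to five seeds,
power simulations at 200 replicates of 50 subjects per arm, and oracle
agreement checks at 1000 random traces/boxes.
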