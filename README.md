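# tmaboost

Weakly supervised prediction of treatment effectiveness from immunostained
tissue-microarray (TMA) whole-slide images.

## The problem

Anti-angiogenic therapy (bevacizumab) helps only a subset of ovarian-cancer
patients, and no routine biomarker selects them. One candidate readout is the
immunohistochemical staining pattern of inflammasome/complement proteins
(e.g. AIM2) on TMA cores: hundreds of 2 mm patient tissue cores arrayed on a
slide, scanned at 20× into a gigapixel multiresolution pyramid. The labels
available for learning are weak — one treatment outcome per core (Effective /
Invalid) and sparse pixel annotations on a handful of cores — so the pipeline
has to localise tumor tissue and score it without dense supervision.

`tmaboost` implements that pipeline for engineers and computational
pathologists who want its mechanics testable on a laptop:

1. **Core detection** on a low-magnification level `I_ξ` of the pyramid
   `{I_m}`, either via the classical disc detector shipped here or via a
   multi-stage cascade contract (stages with strictly increasing IoU
   thresholds `φ = {0.5, 0.6, 0.7}`) into which trained detectors plug.
2. **Forward mapping** `b_0 = 2^ξ · b_ξ` of each detected core box to full
   magnification.
3. **Tumor-like tile selection**: the core is cut into `M×M` tiles, a 3-class
   segmenter yields per-pixel probabilities over {background, others,
   tumorlike}, the class map `κ = argmax_c p_c` suppresses non-tumor pixels,
   and a tile survives iff its tumorlike-pixel fraction exceeds `α = 0.05`.
4. **Weakly supervised training** of the segmenter by boosting: tile weights
   start at `w_j = 1` iff the annotated-positive fraction `ϖ ≥ α`; after each
   round a tile whose misclassified-pixel fraction reaches `α` gains `χ`;
   unannotated pixels are ignore-masked out of the loss (focusing sampling);
   boosted tiles receive 10 deterministic geometric variants with seeded
   photometric jitter (boosted augmentation).
5. **Backward mapping** to a medium level `l = log₂(w₀·h₀·10^(−2ρ))/2`
   (`ρ = 3`) and **core scoring**: a probabilistic classifier scores each
   tumor tile, the mean gives `β_d`, and `β_d ≥ δ` (δ = 0.5) declares the
   core Effective.
6. **Checkpoint selection with early stop**: first and second finite
   differences of the training loss opening a stable window at `k_s`
   (`|ω′|,|ω″| ≤ ε = 0.003` for a run of evaluations), the F-measure
   derivatives closing it at `k_e` (`τ = 0.1`), and the best-F checkpoint in
   `[k_s, k_e]` selected, ties to the latest iteration.
7. **Evaluation**: accuracy/precision/recall/F, ROC AUC over `β_d`, and
   survival comparison of the predicted groups (Kaplan–Meier + log-rank, Cox
   proportional hazards).

Because no public dataset with per-core outcome labels exists, the package
ships a seeded synthetic TMA generator whose slides have the statistical
structure the pipeline assumes (6×10 jittered core grids, 57.2% effective
prevalence, tumor blobs whose DAB-brown staining encodes the outcome at a
configurable effect size), plus generators for training traces with a known
plateau and survival records with a known hazard ratio.

## Worked example

```python
import tmaboost as tb

# 3 synthetic slides of 60 cores, outcome encoded at effect size 2.0
slides = tb.generate_dataset(tb.TmaSpec(seed=0, effect_size=2.0), num_slides=3)
res = tb.run_effect_experiment(slides, seed=0)
print(f"detection recall : {res['detection_recall']:.3f}")
print(f"test AUC         : {res['auc']:.3f}")

trace = tb.generate_trace(num_iters=12_000, plateau_start=5_000,
                          noise_sd=1e-4, seed=0)
sel = tb.select_from_trace(trace, epsilon=0.003, tau=0.1)
print(f"stable window [{sel.ks}, {sel.ke}], selected iteration: {sel.i_star}")

records = tb.generate_survival(50, hazard_ratio=0.18, seed=0)
km = tb.km_logrank(records)
print(f"log-rank chi2 = {km['chi2']:.1f}, p = {km['p']:.2e}")
```

prints

```
detection recall : 1.000
test AUC         : 1.000
stable window [5000, 9000], selected iteration: 8000
log-rank chi2 = 51.4, p = 7.42e-13
```

Detection recall 1.000 means every generated core was found at IoU ≥ 0.5;
test AUC 1.000 reflects that at effect size 2 (a two-noise-SD brown-intensity
shift) the core score `β_d` separates the outcome classes completely on the
held-out 34% split. The model-selection window opens at iteration 5000 —
exactly where the synthetic loss plateaus — and the strongly protective
hazard ratio (0.18) is detected by the log-rank test far below p = 0.005.

A CLI mirrors the library: `tmaboost simulate|detect|select-tumor|
model-select|evaluate` (see `tmaboost --help`).

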