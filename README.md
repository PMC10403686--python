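# focalmargin

Margin planning for prostate focal therapy from voxel-level cancer
probability maps.

MRI-visible prostate lesions (PI-RADS ROIs) systematically underestimate
true tumor extent, so treating only the visible lesion leaves cancer
behind, while conventional fallbacks — a uniform 10-mm expansion or
ablating an entire hemigland — either miss asymmetric extensions or treat
large volumes of benign tissue. `focalmargin` implements the alternative:
start from a **cancer estimation map** (CEM), a per-voxel probability
`p(x) ∈ [0,1]` of clinically significant prostate cancer (csPCa, ISUP
grade group ≥ 2), and turn it into patient-specific 3D treatment margins
with a calibrated probability of success.

The core objects:

- **Treatment margin at threshold t** — the smoothed superlevel set
  `M_t = smooth({x : p(x) ≥ t}) ∩ gland`. Gaussian-blur-rethreshold
  smoothing is order-preserving, so `t' > t ⇒ M_t' ⊆ M_t`.
- **Encapsulation confidence score (ECS)** — calibrated over a cohort with
  ground-truth cancer labels: `ECS(t)` is the fraction of cases whose
  margin at threshold `t` enclosed *all* csPCa (a negative margin), made
  monotone nonincreasing in `t`. For a new patient it reads off the
  predicted negative-margin probability at any threshold.
- **Default margin** — the margin at
  `t* = argmax_t [ ECS(t) − V(t) ]`, where `V(t)` is margin volume as a
  fraction of the prostate: the best trade-off between expected
  encapsulation and treatment burden.
- **Evaluation** — voxel-level sensitivity/specificity, margin volume,
  penetration depth of missed cancer (mm), negative-margin rates for all
  csPCa and for the index lesion (largest csPCa region; discontinuous foci
  ≥ 2 mm away are satellites), all restricted to the apex-to-base slab
  where ground truth exists; plus a predicted-vs-observed calibration
  curve for the ECS on an independent cohort.

Because the clinical datasets behind such pipelines are proprietary, the
package ships a **synthetic phantom generator** that reproduces the
statistical structure the method relies on — deformed-ellipsoid glands
(median 33.4 cc), an index lesion with optional midline crossing and 0–2
satellites (some ISUP grade 1, i.e. upgrade-risk decoys), an ROI that is a
strict erosion of the index lesion, a CEM with tunable voxel-level
discrimination, a 12-core systematic + targeted biopsy scheme, PSA, and a
focal-therapy eligibility screen — so every stage is testable offline.
A stand-in five-fold gradient-boosted-tree ensemble over engineered
spatial features (distances to cores, ROIs and the capsule, plus PSA)
plays the role of the production model; externally produced CEMs can be
attached from NIfTI via `load_external_cem`.

## Worked example

```bash
python examples/calibrate_and_default_margin.py
```

calibrates the ECS on a 20-case phantom cohort and plans a margin for a
new patient:

```
ECS lookup (excerpt):
  threshold 0.00 -> ECS 1.00
  threshold 0.30 -> ECS 1.00
  threshold 0.40 -> ECS 0.50
  threshold 0.50 -> ECS 0.00

new patient pt00001:
  selected threshold t* = 0.37
  predicted negative-margin probability (ECS) = 0.80
  margin volume = 40.2% of the prostate
  against ground truth: sensitivity 0.99, negative margin: False
```

Reading: margins thresholded below 0.30 enclosed all cancer in every
calibration case; by 0.50 none did. For this patient the
ECS-minus-volume objective picks `t* = 0.37`, predicting an 80% chance of
a negative margin while treating 40% of the gland — and the ground truth
shows the 20% risk materializing here (sensitivity 0.99, a sliver
missed). `examples/compare_margins.py` builds the four margin families
(default AI, raw ROI, 10-mm ROI expansion, hemigland) and prints the
cohort comparison table; `examples/generate_cohort.py` and
`examples/standin_predictor.py` demonstrate the phantom generator and the
stand-in model. The same stages run end-to-end via
`focalmargin.run_pipeline(RunConfig(...), out_dir=...)`.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the calibration-transfer analysis from scratch: it generates
two independent 500-case phantom cohorts, calibrates the ECS lookup on
the first, measures observed negative-margin rates on the second across
the 101-point threshold grid, and writes the R² of the observed-on-
predicted linear fit and the median absolute prediction error (percentage
points) to the output JSON. Runtime is roughly 10 minutes on one CPU.
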