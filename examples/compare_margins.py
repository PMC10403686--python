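"""Compare AI default margins with conventional margin strategies.

Builds four margin families per case — the ECS-selected default margin,
the raw biopsy-confirmed ROI, a 10-mm uniform ROI expansion, and the
hemigland margin — and reports sensitivity, margin volume, missed-cancer
extent and negative-margin rates over a small test cohort.
"""

import focalmargin as fm
from focalmargin import margins

config = fm.PhantomConfig()
calibration, _ = fm.generate_cohort(config, n=20, seed=5, id_prefix="cal")
lookup = fm.calibrate_ecs(calibration)

test, _ = fm.generate_cohort(config, n=12, seed=6, filtered=True,
                             id_prefix="test")
defaults = {c.case_id: fm.default_margin(lookup, c)[0] for c in test}

table = fm.cohort_table(test, {
    "default_ai": lambda c: defaults[c.case_id],
    "roi": margins.roi_margin,
    "roi_expanded": margins.expanded_roi_margin,
    "hemigland": margins.hemigland_margin,
})

cols = ["n", "sensitivity_mean", "specificity_mean", "extent_missed_mean_mm",
        "volume_fraction_mean", "negative_margin_any_rate",
        "negative_margin_index_rate"]
print(table[cols].round(3).to_string())
print("\nRaw ROIs miss most cancer (low sensitivity); the AI default margin "
      "recovers it\nat a volume comparable to a hemigland but with higher "
      "negative-margin rates.")
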