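"""Fit the stand-in voxel-wise cancer-probability model and predict a CEM.

The stand-in mirrors the structure of the production model (five-fold
ensemble of gradient-boosted trees, averaged to one probability) but uses
only engineered spatial features — distances to biopsy cores, ROIs and
the prostate capsule — plus PSA, since phantoms carry no MRI intensities.
"""

import numpy as np
from sklearn.metrics import roc_auc_score

import focalmargin as fm

config = fm.PhantomConfig()
train, _ = fm.generate_cohort(config, n=25, seed=301, id_prefix="train")
model = fm.fit_standin(train, folds=5, seed=0)
print(f"fitted ensemble with {len(model.fold_models)} fold models")

test, _ = fm.generate_cohort(config, n=5, seed=302, id_prefix="test")
aucs = []
for case in test:
    cem = fm.predict_cem(model, case)  # attaches to the case
    gland = case.gland.values
    auc = roc_auc_score(case.truth_cs.values[gland], cem[gland])
    aucs.append(auc)
    print(f"  {case.case_id}: voxel-level AUC vs ground truth = {auc:.3f}")
print(f"mean AUC = {np.mean(aucs):.3f} "
      "(probability of ranking a cancer voxel above a benign one)")
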