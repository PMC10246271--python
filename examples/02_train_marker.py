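"""Train a sparse-logistic marker ensemble and evaluate it out of fold.

Simulates a discovery dataset plus an independent validation dataset that
shares the same planted diagnosis effects, trains the 10x10 classifier
ensemble on the (harmonized) discovery set, and reports out-of-fold and
external performance.
"""

import warnings
from dataclasses import replace

import fcmarker as fm

warnings.simplefilter("ignore")

sim = replace(
    fm.default_config(seed=7),
    roi_count=20,
    sites=tuple(fm.SiteSpec(f"site{k}", 40, 16) for k in range(3)),
    n_effect_edges=30,
    effect_d=1.0,
)
discovery, validation = fm.simulate_family(sim, n_validation=1)
discovery, _ = fm.harmonize(discovery)
validation, _ = fm.harmonize(validation)  # separately, never jointly

ensemble = fm.train_ensemble(discovery, k_folds=10, n_subsamples=10, seed=7)
print(f"trained {ensemble.n_classifiers} classifiers "
      f"(median nonzero weights: {sorted(c.n_nonzero for c in ensemble.classifiers)[50]})")

oof = fm.compute_metrics(ensemble.diagnosis, ensemble.oof_probability)
print(f"discovery (out-of-fold): AUC={oof.auc:.2f}  MCC={oof.mcc:.2f}  "
      f"sens={oof.sensitivity:.2f}  spec={oof.specificity:.2f}")

result = fm.predict(ensemble, validation)
ext = fm.compute_metrics(validation.diagnosis, result.probability)
print(f"validation:              AUC={ext.auc:.2f}  MCC={ext.mcc:.2f}")
# AUC near 1 out of fold and a smaller but clearly above-chance external AUC
# is the expected pattern: the planted effect generalizes, attenuated by
# fresh sites and subjects
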