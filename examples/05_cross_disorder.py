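"""Project a second disorder onto a marker's axis.

Simulates two disorders whose effect-edge sets partially overlap (sharing
one control cohort), trains a marker per disorder, measures how sensitive
each marker is to the other disorder's patients, and places every subject
on the two-marker plane.
"""

import warnings
from dataclasses import replace

import numpy as np

import fcmarker as fm

warnings.simplefilter("ignore")

cfg = replace(
    fm.default_config(seed=9),
    roi_count=15,
    sites=(fm.SiteSpec("s1", 40, 20, additive_sd=0.2),),
    n_effect_edges=10,
    effect_d=1.0,
)
pair = fm.simulate_disorders(cfg, overlap=0.6, size_b=30)
a, b = pair["disorder_a"], pair["disorder_b"]
shared = len(set(a.truth["effect_edges"]) & set(b.truth["effect_edges"]))
print(f"disorder A: {len(a.truth['effect_edges'])} effect edges; "
      f"disorder B: {len(b.truth['effect_edges'])}; shared: {shared}")

marker_a = fm.train_ensemble(a, k_folds=5, n_subsamples=2, seed=9)
marker_b = fm.train_ensemble(b, k_folds=5, n_subsamples=2, seed=10)

a_to_b = np.mean(fm.predict(marker_a, b.subset(b.diagnosis == 1)).probability > 0.5)
b_to_a = np.mean(fm.predict(marker_b, a.subset(a.diagnosis == 1)).probability > 0.5)
print(f"sensitivity of A's marker to B patients: {a_to_b:.2f}")
print(f"sensitivity of B's marker to A patients: {b_to_a:.2f}")
# B shares most of A's axis but A covers little of B's, so transfer is
# asymmetric: the A marker 'sees' disorder B more than the reverse

cmap = fm.dimensional_map(
    marker_a,
    marker_b,
    {
        "controls": a.subset(a.diagnosis == 0),
        "disorder_a": a.subset(a.diagnosis == 1),
        "disorder_b": b.subset(b.diagnosis == 1),
    },
    name_a="A",
    name_b="B",
)
for group, quad in cmap.modal_quadrant.items():
    print(f"modal quadrant for {group}: {quad} (axes: P_A-P_B, split at 0.5)")
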