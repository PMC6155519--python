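"""Recurrence quantification of preictal vs interictal RR windows.

Before a seizure the tachogram becomes more regular: its phase-space
trajectory revisits the same neighborhoods, producing longer diagonal
and vertical structures in the recurrence plot.  This shows up as higher
determinism (DET), laminarity (LAM) and longest-diagonal (LMAX).
"""

import numpy as np

import hrvseizure as hs
from hrvseizure.features import znormalize
from hrvseizure.rqa import rqa_features

config = hs.SimulationConfig(seed=15)
rr_ms, annotations, truth = hs.simulate_preictal_dataset(config, n_seizures=1)
beats = truth.beat_times_s
onset = annotations[0].onset_s

z, _ = znormalize(rr_ms)
pre = z[(beats >= onset - 900) & (beats < onset)][:180]
inter = z[beats < onset - 3000][:180]

# a denser threshold (5% recurrence rate) makes the line structures easy
# to see; the feature pipeline uses the sparser default eps = 0.2 SD
from hrvseizure.rqa import EpsilonRule

rule = EpsilonRule(sd_fraction=None, target_rec=5.0)
m_pre = rqa_features(pre, rule=rule)
m_int = rqa_features(inter, rule=rule)
print(f"{'measure':>8} {'interictal':>12} {'preictal':>10}")
for k in ("REC", "DET", "LMAX", "LAM", "TT", "ENT"):
    print(f"{k:>8} {m_int[k]:>12.2f} {m_pre[k]:>10.2f}")
print()
print("The longest diagonal (LMAX) and the laminarity (LAM) jump in the")
print("preictal window: the rhythm repeats itself and dwells in the same")
print("states — the added regularity the classifier exploits.")
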