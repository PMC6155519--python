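"""Extract the 20-feature HRV vector per 180-beat window.

Each window yields time-domain statistics (meanNN, SDNN, pNN50, the
Poincaré indices SD1/SD2/CSI/CSV), nonlinear measures (Katz fractal
dimension, coefficient of sample entropy), six recurrence measures and
three spectral features from the 4 Hz tachogram (LFn, HFn, LF/HF).
"""

import hrvseizure as hs
from hrvseizure.records import RRSeries

config = hs.SimulationConfig(duration_s=900, seed=21)
rr_ms, _ = hs.simulate_rr(config)
matrix = hs.extract_features(RRSeries(rr_ms))

cols = ["meanNN", "SDNN", "pNN50", "CoSEn", "DET", "LAM", "LFn", "HFn",
        "LF_HF"]
print(f"{len(matrix)} windows x 20 features; a selection:")
print(matrix[["start_s", "end_s", *cols]].round(3).to_string(index=False))
print()
print("meanNN/SDNN are in ms; pNN50, DET and LAM in percent; LFn/HFn are")
print("band powers normalized to LF+HF, so they sum to one per window.")
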