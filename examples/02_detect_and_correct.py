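"""Clean an ECG, detect QRS complexes and build a corrected RR series.

Simulates a noisy recording, runs the preprocessing chain (impulse
removal, 50 Hz notch, baseline subtraction), detects beats with the
multi-channel adaptive-threshold detector, then corrects the RR series
for injected ectopic beats and reports how close it lands to the truth.
"""

import numpy as np

import hrvseizure as hs
from hrvseizure.records import RRSeries
from hrvseizure.rrcorrect import resample_rr

config = hs.SimulationConfig(duration_s=300, baseline_amp=0.5,
                             powerline_amp=0.2, seed=7)
rr_true, _ = hs.simulate_rr(config)

# inject 5% ectopic/missed-beat corruption before rendering the ECG
rr_bad, corrupted = hs.corrupt_rr(rr_true, 0.025, 0.025, seed=8)
record = hs.add_white_noise(hs.synthesize_ecg(rr_bad, config), 20.0, seed=9)

clean = hs.preprocess(record)
beats = hs.detect_qrs(hs.resample_ecg(clean, 1024.0))
corrected = hs.correct_rr(beats.rr_series())

u_true = resample_rr(RRSeries(rr_true))


def rmse_vs_truth(series):
    u = resample_rr(series)
    n = min(len(u_true), len(u))
    return np.sqrt(np.mean((u_true.values_ms[:n] - u.values_ms[:n]) ** 2))


print(f"beats detected: {len(beats)} (true sinus beats: {rr_true.size})")
print(f"intervals flagged by correction: "
      f"{int(np.sum(corrected.corrected_flags > 0))} "
      f"(injected corruptions: {corrupted.size})")
print(f"4 Hz tachogram RMSE vs truth: corrupted {rmse_vs_truth(RRSeries(rr_bad)):.1f} ms"
      f" -> corrected {rmse_vs_truth(corrected):.1f} ms")
print("Correction shrinks the tachogram error several-fold: the recovered")
print("series follows the sinus rhythm rather than the injected ectopy.")
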