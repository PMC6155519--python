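"""ECG cleaning: impulsive artifacts, power-line interference, baseline wander.

All linear stages run zero-phase (forward–backward filtering), so QRS
fiducial timing downstream is not biased by filter delay.  Stage order is
impulsive-artifact removal, then the power-line notch, then baseline
subtraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, ndimage

from .records import ECGRecord

__all__ = [
    "PreprocessConfig",
    "remove_impulsive",
    "cancel_powerline",
    "remove_baseline",
    "preprocess",
]


@dataclass
class PreprocessConfig:
    impulsive: bool = True
    powerline: bool = True
    baseline: bool = True
    window_ms: float = 60.0
    k_thresh: float = 0.35
    abs_floor_mv: float = 1.0      # minimum spike amplitude worth removing
    notch_freq: float = 50.0
    notch_bandwidth: float = 1.0   # Hz, -3 dB width of the notch
    baseline_cutoff: float = 3.1   # Hz, composite forward-backward cutoff
    residual_median_s: float = 0.26
    residual_k_mad: float = 5.0
    residual_min_duration_s: float = 0.5


def _odd(n: int) -> int:
    return n if n % 2 == 1 else n + 1


def remove_impulsive(ecg: ECGRecord, window_ms: float = 60.0,
                     k_thresh: float = 0.35,
                     abs_floor_mv: float = 1.0) -> ECGRecord:
    """Remove short high-amplitude spikes.

    Per channel, ``d = |x - median_filter(x, window_ms)|`` is compared to
    ``k_thresh * max(d)`` (with an absolute floor so that clean channels,
    whose maximum deviation is just QRS sharpness, are left untouched).
    Flagged segments are replaced by the average of the original signal
    immediately before and after the segment.
    """
    w = _odd(max(int(round(window_ms / 1000.0 * ecg.fs)), 3))
    out = ecg.copy()
    altered: list[tuple[int, float, float]] = []
    for c in range(out.n_channels):
        x = out.samples[c]
        med = ndimage.median_filter(x, size=w, mode="nearest")
        d = np.abs(x - med)
        dmax = d.max()
        if dmax == 0:
            continue
        thr = max(k_thresh * dmax, abs_floor_mv)
        mask = d > thr
        if not mask.any():
            continue
        # contiguous flagged segments
        idx = np.flatnonzero(mask)
        splits = np.flatnonzero(np.diff(idx) > 1)
        seg_starts = np.concatenate(([idx[0]], idx[splits + 1]))
        seg_ends = np.concatenate((idx[splits], [idx[-1]]))
        y = x.copy()
        for s, e in zip(seg_starts, seg_ends):
            before = x[s - 1] if s > 0 else x[min(e + 1, x.size - 1)]
            after = x[e + 1] if e + 1 < x.size else before
            y[s:e + 1] = 0.5 * (before + after)
            altered.append((c, s / ecg.fs, (e + 1) / ecg.fs))
        out.samples[c] = y
    out.meta.setdefault("processing_log", []).append(
        {"stage": "remove_impulsive", "altered_spans": altered})
    return out


def cancel_powerline(ecg: ECGRecord, f0: float = 50.0,
                     bandwidth: float = 1.0) -> ECGRecord:
    """Zero-phase IIR notch at the mains frequency (>= 40 dB rejection)."""
    if f0 >= ecg.fs / 2:
        raise ValueError("notch frequency must be below Nyquist")
    q = f0 / bandwidth
    b, a = signal.iirnotch(f0, q, fs=ecg.fs)
    # a narrow notch has a long transient; pad well beyond it
    padlen = min(ecg.n_samples - 1, int(3 * ecg.fs / bandwidth))
    out = ecg.copy()
    out.samples = signal.filtfilt(b, a, out.samples, axis=1, padlen=padlen)
    out.meta.setdefault("processing_log", []).append(
        {"stage": "cancel_powerline", "f0": f0, "bandwidth": bandwidth})
    return out


def _baseline_estimate(x: np.ndarray, fs: float, cutoff: float) -> np.ndarray:
    # per-pass cutoff chosen so the two-pass (squared) magnitude response
    # crosses -3 dB at `cutoff`: |H|^4 = 1/2 at fc_pass => fc_pass =
    # cutoff / sqrt(sqrt(2) - 1) for a first-order Butterworth.
    fc_pass = cutoff / np.sqrt(np.sqrt(2.0) - 1.0)
    b, a = signal.butter(1, fc_pass, btype="low", fs=fs)
    padlen = min(x.shape[-1] - 1, int(fs))
    return signal.filtfilt(b, a, x, padlen=padlen)


def remove_baseline(ecg: ECGRecord, cutoff: float = 3.1,
                    residual_median_s: float = 0.26,
                    residual_k_mad: float = 5.0,
                    residual_min_duration_s: float = 0.5) -> ECGRecord:
    """Subtract a zero-phase first-order low-pass baseline estimate.

    The forward–backward first-order Butterworth is tuned so the composite
    -3 dB point sits at ``cutoff``.  Where the baseline estimate shows
    residual fast excursions (amplitude above ``residual_k_mad`` MADs for
    longer than ``residual_min_duration_s``), a short median filter is
    applied to the estimate over those spans before subtraction.
    """
    if ecg.fs <= 2 * cutoff:
        raise ValueError("sampling rate too low for the baseline cutoff")
    out = ecg.copy()
    spans: list[tuple[int, float, float]] = []
    for c in range(out.n_channels):
        x = out.samples[c]
        base = _baseline_estimate(x, ecg.fs, cutoff)
        dev = np.abs(base - np.median(base))
        mad = np.median(dev)
        if mad > 0:
            mask = dev > residual_k_mad * mad
            min_len = int(residual_min_duration_s * ecg.fs)
            idx = np.flatnonzero(mask)
            if idx.size:
                splits = np.flatnonzero(np.diff(idx) > 1)
                seg_starts = np.concatenate(([idx[0]], idx[splits + 1]))
                seg_ends = np.concatenate((idx[splits], [idx[-1]]))
                w = _odd(max(int(residual_median_s * ecg.fs), 3))
                med = None
                for s, e in zip(seg_starts, seg_ends):
                    if e - s + 1 >= min_len:
                        if med is None:
                            med = ndimage.median_filter(base, size=w,
                                                        mode="nearest")
                        base[s:e + 1] = med[s:e + 1]
                        spans.append((c, s / ecg.fs, (e + 1) / ecg.fs))
        out.samples[c] = x - base
    out.meta.setdefault("processing_log", []).append(
        {"stage": "remove_baseline", "residual_spans": spans})
    return out


def preprocess(ecg: ECGRecord,
               config: PreprocessConfig | None = None) -> ECGRecord:
    """Full cleaning chain with per-stage enable flags."""
    cfg = config or PreprocessConfig()
    out = ecg
    if cfg.impulsive:
        out = remove_impulsive(out, cfg.window_ms, cfg.k_thresh, cfg.abs_floor_mv)
    if cfg.powerline:
        out = cancel_powerline(out, cfg.notch_freq, cfg.notch_bandwidth)
    if cfg.baseline:
        out = remove_baseline(out, cfg.baseline_cutoff, cfg.residual_median_s,
                              cfg.residual_k_mad, cfg.residual_min_duration_s)
    if out is ecg:
        out = ecg.copy()
    return out
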