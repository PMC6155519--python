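"""Per-window HRV feature extraction: time domain, nonlinear, frequency.

The corrected RR series is cut into windows of 180 intervals with 60
intervals of overlap (step 120).  Each window yields a 20-dimensional
feature vector:

time domain   meanNN, SDNN, RMSSD, pNN50, VAR, SD1, SD2, CSI = SD2/SD1,
              CSV = log10(SD1*SD2)
nonlinear     KFD (Katz fractal dimension), CoSEn (coefficient of sample
              entropy), and the six recurrence measures %REC, DET, LMAX,
              ENT, LAM, TT from :mod:`hrvseizure.rqa`
frequency     LFn, HFn (band powers 0.04-0.15 / 0.15-0.40 Hz of the 4 Hz
              tachogram, normalized to LF+HF) and LF/HF, from a
              frequency-dependent-window ("generalized") STFT whose
              Gaussian window narrows sigmoidally with frequency.

To reduce inter-individual scale effects the whole-recording z-scored
series feeds the shape-sensitive features (RQA, KFD); features whose
definition needs physical milliseconds (meanNN, pNN50, CoSEn with its
ln(meanNN) correction, ...) use the raw intervals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .records import RRSeries, UniformRRSeries
from .rrcorrect import resample_rr
from .rqa import EpsilonRule, rqa_features

__all__ = [
    "FEATURE_NAMES",
    "AnalysisWindow",
    "GSTFTConfig",
    "FeatureConfig",
    "TimeFrequencyMap",
    "make_windows",
    "znormalize",
    "time_domain",
    "sampen",
    "cosen",
    "katz_fd",
    "gstft",
    "band_powers",
    "extract_features",
]

# classifier feature vector (20), in the conventional reporting order
FEATURE_NAMES = (
    "meanNN", "SDNN", "RMSSD", "pNN50", "VAR", "SD1", "SD2", "CSI", "CSV",
    "KFD", "CoSEn", "REC", "DET", "LMAX", "ENT", "LAM", "TT",
    "LFn", "HFn", "LF_HF",
)

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)


@dataclass
class AnalysisWindow:
    start_beat_index: int
    rr_ms: np.ndarray
    time_span_s: tuple[float, float]


@dataclass
class GSTFTConfig:
    """Gaussian-window STFT with sigmoidally frequency-dependent width.

    sigma(f) = sigma_min + (sigma_max - sigma_min) / (1 + exp((f - f_c)/s)),
    long windows (sigma_max) at low frequency, short at high frequency.
    """

    sigma_max_s: float = 12.5
    sigma_min_s: float = 2.5
    f_c: float = 0.15
    s: float = 0.04
    f_min: float = 0.01
    f_max: float = 0.5
    f_step: float = 0.005

    def sigma(self, f: np.ndarray | float) -> np.ndarray | float:
        return self.sigma_min_s + (self.sigma_max_s - self.sigma_min_s) / (
            1.0 + np.exp((np.asarray(f) - self.f_c) / self.s))

    @property
    def freqs(self) -> np.ndarray:
        return np.arange(self.f_min, self.f_max + self.f_step / 2, self.f_step)


@dataclass
class FeatureConfig:
    width: int = 180
    overlap: int = 60
    rqa_m: int = 3
    rqa_tau: int = 1
    rqa_rule: EpsilonRule = field(default_factory=EpsilonRule)
    cosen_m: int = 1
    cosen_r_fraction: float = 0.03
    cosen_r_floor_ms: float = 3.0
    gstft: GSTFTConfig = field(default_factory=GSTFTConfig)
    znorm_nonlinear: bool = True  # z-score inputs of RQA and KFD


@dataclass
class TimeFrequencyMap:
    power: np.ndarray    # (n_freqs, n_times)
    freqs: np.ndarray
    times: np.ndarray


def make_windows(rr: RRSeries, width: int = 180,
                 overlap: int = 60) -> list[AnalysisWindow]:
    """Cut the series into windows of ``width`` intervals, step width-overlap."""
    if overlap >= width:
        raise ValueError("overlap must be smaller than the window width")
    n = len(rr)
    if n < width:
        warnings.warn("series shorter than one analysis window")
        return []
    step = width - overlap
    # boundary times: start of interval i is the time of its opening beat
    bounds = np.concatenate(([rr.t0_s], rr.beat_times_s))
    windows = []
    for s in range(0, n - width + 1, step):
        windows.append(AnalysisWindow(
            start_beat_index=s,
            rr_ms=rr.rr_ms[s:s + width],
            time_span_s=(float(bounds[s]), float(bounds[s + width])),
        ))
    return windows


def znormalize(values: np.ndarray) -> tuple[np.ndarray, bool]:
    """Zero-mean unit-SD scaling; returns (scaled, degenerate_flag)."""
    x = np.asarray(values, dtype=float)
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x), True
    return (x - x.mean()) / sd, False


def time_domain(rr_ms: np.ndarray) -> dict[str, float]:
    """Classical short-term statistics and Poincaré descriptors.

    SD1/SD2 use the lag-1 Poincaré identities SD1 = RMSSD/sqrt(2),
    SD2 = sqrt(2 SDNN^2 - SD1^2).  CSI (SD2/SD1) and CSV
    (log10(SD1*SD2)) are NaN for a constant window.
    """
    x = np.asarray(rr_ms, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 intervals")
    d = np.diff(x)
    sdnn = float(x.std())
    rmssd = float(np.sqrt(np.mean(d ** 2)))
    nn50 = int(np.sum(np.abs(d) > 50.0))
    sd1 = rmssd / math.sqrt(2.0)
    sd2 = math.sqrt(max(2.0 * sdnn ** 2 - sd1 ** 2, 0.0))
    csi = sd2 / sd1 if sd1 > 0 else float("nan")
    csv = math.log10(sd1 * sd2) if sd1 > 0 and sd2 > 0 else float("nan")
    return {
        "meanNN": float(x.mean()),
        "SDNN": sdnn,
        "RMSSD": rmssd,
        "NN50": nn50,
        "pNN50": 100.0 * nn50 / d.size,
        "VAR": sdnn ** 2,
        "SD1": sd1,
        "SD2": sd2,
        "CSI": csi,
        "CSV": csv,
    }


def sampen(x: np.ndarray, m: int = 1, r: float = 0.2) -> float:
    """Sample entropy -ln(A/B) with Chebyshev distance, self-matches excluded."""
    x = np.asarray(x, dtype=float)
    n = x.size

    nt = n - m  # both template lengths use the same starting indices
    if nt < 2:
        return float("nan")

    def count(mm: int) -> int:
        tmpl = np.stack([x[i:i + nt] for i in range(mm)], axis=1)
        c = 0
        for i in range(nt - 1):
            d = np.max(np.abs(tmpl[i + 1:] - tmpl[i]), axis=1)
            c += int(np.sum(d <= r))
        return c

    b = count(m)
    a = count(m + 1)
    if a == 0 or b == 0:
        return float("nan")
    return -math.log(a / b)


def cosen(rr_ms: np.ndarray, m: int = 1, r: float | None = None,
          r_fraction: float = 0.03, r_floor_ms: float = 3.0) -> float:
    """Coefficient of sample entropy for very short RR windows.

    CoSEn = SampEn(m, r) + ln(2r) - ln(meanNN); the mean-RR term makes
    the measure density-based and comparable across heart rates.  The
    tolerance defaults to ``r_fraction`` of the window SD with a floor.
    """
    x = np.asarray(rr_ms, dtype=float)
    if x.size < 10:
        raise ValueError("window too short for CoSEn")
    if r is None:
        r = max(r_fraction * float(x.std()), r_floor_ms)
    se = sampen(x, m=m, r=r)
    if math.isnan(se):
        return float("nan")
    return se + math.log(2 * r) - math.log(float(x.mean()))


def katz_fd(values: np.ndarray) -> float:
    """Katz fractal dimension with unit abscissa steps.

    KFD = log10(n) / (log10(n) + log10(d/L)) with L the total ordinate
    curve length and d the maximum excursion from the first point; 1 for
    a monotone (or constant, by convention) series.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    steps = np.abs(np.diff(x))
    L = float(steps.sum())
    if L == 0:
        return 1.0
    d = float(np.max(np.abs(x - x[0])))
    if d == 0:
        return 1.0
    n = x.size - 1
    return math.log10(n) / (math.log10(n) + math.log10(d / L))


def gstft(uniform: UniformRRSeries,
          config: GSTFTConfig | None = None) -> TimeFrequencyMap:
    """Time-frequency power map with frequency-dependent Gaussian windows.

    For each analysis frequency the demeaned tachogram is convolved with
    a unit-area Gaussian window of width sigma(f) modulated at f.  The
    squared magnitude is normalized by the window's equivalent noise
    bandwidth so the map is a power density: without this, the
    frequency-dependent window width would tilt a white-noise spectrum
    toward the short-window (high-frequency) end.
    """
    cfg = config or GSTFTConfig()
    x = uniform.values_ms - np.mean(uniform.values_ms)
    rate = uniform.rate_hz
    freqs = cfg.freqs
    longest = 4.0 * float(cfg.sigma(freqs[0]))
    if x.size / rate < longest:
        raise ValueError("series shorter than the analysis window at the "
                         "lowest frequency")
    power = np.empty((freqs.size, x.size))
    for i, f in enumerate(freqs):
        sig = float(cfg.sigma(f)) * rate        # samples
        half = int(math.ceil(4 * sig))
        u = np.arange(-half, half + 1)
        g = np.exp(-0.5 * (u / sig) ** 2)
        g /= g.sum()
        kern = g * np.exp(-2j * np.pi * f * u / rate)
        enbw = float(g @ g) * rate  # Hz, since sum(g) == 1
        s = fftconvolve(x, kern, mode="same")
        power[i] = np.abs(s) ** 2 / enbw
    return TimeFrequencyMap(power=power, freqs=freqs, times=uniform.times)


def band_powers(tf: TimeFrequencyMap,
                time_span: tuple[float, float]) -> dict[str, float]:
    """LFn, HFn and LF/HF over a window's time span.

    Band power is the frequency-integrated power averaged over the span;
    the normalizing total is LF + HF (0.04-0.40 Hz), so LFn + HFn = 1.
    """
    t0, t1 = time_span
    cols = (tf.times >= t0) & (tf.times <= t1)
    if not cols.any():
        raise ValueError("time-frequency map does not cover the window span")
    df = float(np.median(np.diff(tf.freqs)))
    sub = tf.power[:, cols]

    def band(lo: float, hi: float) -> float:
        rows = (tf.freqs >= lo) & (tf.freqs < hi)
        return float(sub[rows].sum(axis=0).mean()) * df

    lf = band(*LF_BAND)
    hf = band(*HF_BAND)
    total = lf + hf
    if total == 0:
        return {"LFn": float("nan"), "HFn": float("nan"),
                "LF_HF": float("nan")}
    return {"LFn": lf / total, "HFn": hf / total,
            "LF_HF": lf / hf if hf > 0 else float("inf")}


def extract_features(rr: RRSeries,
                     config: FeatureConfig | None = None) -> pd.DataFrame:
    """Window the corrected series and compute the 20 features per window.

    Returns a DataFrame with ``start_s``/``end_s`` spans, the features in
    :data:`FEATURE_NAMES` order and a ``valid`` flag (False when any
    feature is undefined on a degenerate window).
    """
    cfg = config or FeatureConfig()
    windows = make_windows(rr, cfg.width, cfg.overlap)
    if not windows:
        return pd.DataFrame(columns=["start_s", "end_s", *FEATURE_NAMES,
                                     "valid"])

    z_all, degenerate = znormalize(rr.rr_ms)
    uniform = resample_rr(rr)
    tf = gstft(uniform, cfg.gstft)

    rows = []
    for w in windows:
        feats: dict[str, float] = {}
        feats.update(time_domain(w.rr_ms))
        feats.pop("NN50")  # intermediate; the classifier uses pNN50
        feats["CoSEn"] = cosen(w.rr_ms, m=cfg.cosen_m,
                               r_fraction=cfg.cosen_r_fraction,
                               r_floor_ms=cfg.cosen_r_floor_ms)
        sl = slice(w.start_beat_index, w.start_beat_index + cfg.width)
        shape_in = z_all[sl] if cfg.znorm_nonlinear and not degenerate \
            else w.rr_ms
        feats["KFD"] = katz_fd(shape_in)
        rq = rqa_features(shape_in, m=cfg.rqa_m, tau=cfg.rqa_tau,
                          rule=cfg.rqa_rule)
        # a window with no qualifying lines has undefined TT/ENT; for the
        # classifier this is "no trapping, no line diversity", coded as 0
        for k in ("TT", "ENT"):
            if math.isnan(rq[k]):
                rq[k] = 0.0
        feats.update(rq)
        feats.update(band_powers(tf, w.time_span_s))
        row = {"start_s": w.time_span_s[0], "end_s": w.time_span_s[1]}
        row.update({k: feats[k] for k in FEATURE_NAMES})
        row["valid"] = all(np.isfinite(feats[k]) for k in FEATURE_NAMES)
        rows.append(row)
    return pd.DataFrame(rows)
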