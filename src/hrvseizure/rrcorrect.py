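"""RR-series correction to a sinus-only tachogram, and 4 Hz resampling.

Detected RR series contain non-sinus intervals from ectopic beats and
from detector errors (missed or spurious QRS).  Correction runs in two
sequential steps:

1. a finite-state rule pass with a running robust expectation (median of
   the last 7 accepted intervals) that inserts beats into long pauses,
   deletes spurious detections, and averages the short–long signature of
   an ectopic beat with compensatory pause;
2. an adaptive linear predictor (normalized-gradient updates) that
   accepts intervals whose prediction error is small, and otherwise
   replaces them with the prediction nudged a fraction toward the
   observed value.

The corrected series is finally resampled at 4 Hz by linear
interpolation, each interval anchored at the time of its terminating
beat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .records import FLAG_FILTER, FLAG_NONE, FLAG_RULE, RRSeries, UniformRRSeries

__all__ = [
    "RuleConfig",
    "PredictiveConfig",
    "rule_correction",
    "predictive_correction",
    "correct_rr",
    "resample_rr",
]


@dataclass
class RuleConfig:
    long_factor: float = 1.8     # insert beats above this multiple of ê
    short_factor: float = 0.6    # spurious-detection bound
    ectopic_short: float = 0.75
    ectopic_long: float = 1.25
    sum_tolerance: float = 0.2   # relative tolerance on pair sums
    memory: int = 7              # accepted intervals in the running median


@dataclass
class PredictiveConfig:
    order: int = 8
    err_thresh: float = 0.3      # relative prediction-error acceptance bound
    mu: float = 0.05             # normalized-gradient gain
    beta: float = 0.25           # pull of the replacement toward the data
    init_span: int = 30          # intervals used for least-squares start


def rule_correction(rr: RRSeries, config: RuleConfig | None = None) -> RRSeries:
    """Finite-state rule pass: insert, delete or average outlier intervals."""
    cfg = config or RuleConfig()
    x = rr.rr_ms
    if x.size < 3:
        warnings.warn("fewer than 3 intervals; rule correction skipped")
        return rr.copy()

    out: list[float] = []
    flags: list[int] = []
    accepted: list[float] = list(x[:min(cfg.memory, x.size)])

    def expect() -> float:
        return float(np.median(accepted[-cfg.memory:]))

    i = 0
    n = x.size
    while i < n:
        r = x[i]
        e = expect()
        nxt = x[i + 1] if i + 1 < n else None
        if (nxt is not None and r <= cfg.ectopic_short * e
                and nxt >= cfg.ectopic_long * e
                and abs(r + nxt - 2 * e) <= cfg.sum_tolerance * 2 * e):
            # ectopic short-long pair: average
            m = 0.5 * (r + nxt)
            out.extend((m, m))
            flags.extend((FLAG_RULE, FLAG_RULE))
            accepted.append(m)
            accepted.append(m)
            i += 2
        elif (nxt is not None and r < cfg.short_factor * e
                and abs(r + nxt - e) <= cfg.sum_tolerance * e):
            # spurious detection split one interval in two: merge
            out.append(r + nxt)
            flags.append(FLAG_RULE)
            accepted.append(r + nxt)
            i += 2
        elif r > cfg.long_factor * e:
            # long pause from missed detections: insert beats
            n_sub = max(int(round(r / e)), 2)
            sub = r / n_sub
            out.extend([sub] * n_sub)
            flags.extend([FLAG_RULE] * n_sub)
            accepted.extend([sub] * n_sub)
            i += 1
        else:
            out.append(r)
            flags.append(FLAG_NONE)
            accepted.append(r)
            i += 1

    return RRSeries(rr_ms=np.asarray(out), t0_s=rr.t0_s,
                    corrected_flags=np.asarray(flags), source=rr.source)


def predictive_correction(rr: RRSeries,
                          config: PredictiveConfig | None = None) -> RRSeries:
    """Adaptive linear-predictor pass.

    Coefficients start from least squares on the initial span; each
    interval is accepted if its relative prediction error is within
    ``err_thresh`` (with a normalized-gradient coefficient update), else
    replaced by the prediction moved ``beta`` of the way toward the
    observation (and a reduced update is applied).
    """
    cfg = config or PredictiveConfig()
    x = rr.rr_ms.astype(float)
    n = x.size
    if n <= cfg.order:
        warnings.warn("series no longer than predictor order; pass skipped")
        return rr.copy()

    p = cfg.order
    init = min(max(cfg.init_span, p + 2), n)
    # least-squares initialization on the first `init` intervals
    rows = init - p
    coeffs = None
    if rows >= p:
        X = np.stack([x[i:i + p][::-1] for i in range(rows)])
        y = x[p:init]
        if np.ptp(x[:init]) > 1e-9:
            coeffs, *_ = np.linalg.lstsq(X, y, rcond=None)
    if coeffs is None:
        coeffs = np.full(p, 1.0 / p)  # running-mean fallback

    out = x.copy()
    flags = rr.corrected_flags.copy()
    for i in range(init, n):
        hist = out[i - p:i][::-1]
        pred = float(coeffs @ hist)
        if pred <= 0:
            pred = float(np.mean(hist))
        err = out[i] - pred
        denom = float(hist @ hist) + 1e-12
        if abs(err) <= cfg.err_thresh * pred:
            coeffs = coeffs + cfg.mu * err * hist / denom
        else:
            corrected = pred + cfg.beta * err
            out[i] = corrected
            flags[i] = FLAG_FILTER
            coeffs = coeffs + (cfg.mu / 4.0) * (corrected - pred) * hist / denom

    return RRSeries(rr_ms=out, t0_s=rr.t0_s, corrected_flags=flags,
                    source=rr.source)


def correct_rr(rr: RRSeries, rule_config: RuleConfig | None = None,
               predictive_config: PredictiveConfig | None = None) -> RRSeries:
    """Full two-step correction: rules, then the predictive filter."""
    return predictive_correction(rule_correction(rr, rule_config),
                                 predictive_config)


def resample_rr(rr: RRSeries, rate_hz: float = 4.0) -> UniformRRSeries:
    """Resample the tachogram on a uniform grid by linear interpolation.

    The RR value is treated as a function of the time of its terminating
    beat; the grid runs from the series origin ``t0_s`` to the last beat
    time in steps of ``1/rate_hz`` (values before the first beat hold the
    first interval).
    """
    if len(rr) < 1:
        raise ValueError("need at least one interval (two beats)")
    beats = rr.beat_times_s
    span = beats[-1] - rr.t0_s
    n = int(np.floor(span * rate_hz)) + 1
    grid = rr.t0_s + np.arange(n) / rate_hz
    vals = np.interp(grid, beats, rr.rr_ms)
    return UniformRRSeries(values_ms=vals, rate_hz=rate_hz, t0_s=rr.t0_s)
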