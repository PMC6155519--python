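"""Recurrence quantification analysis of short RR windows.

A window of the tachogram is delay-embedded into an m-dimensional phase
space; two states recur when their Euclidean distance falls below a
cutoff eps.  The binary recurrence matrix R[i, j] = 1{||x_i - x_j|| <= eps}
is then summarized by six measures:

%REC   recurrence rate, the density of recurrent points;
%DET   determinism, the share of recurrent points on diagonal lines of
       length >= 2 (excluding the line of identity, LOI);
LMAX   length of the longest off-LOI diagonal line;
LAM    laminarity, the share of recurrent points on vertical lines of
       length >= 2;
TT     trapping time, the mean vertical-line length;
ENT    Shannon entropy (natural log) of the diagonal line-length
       distribution.

Conventions: diagonal lines are counted on every off-LOI diagonal with
the denominator of %DET excluding the LOI (which keeps %DET <= 100);
vertical lines are counted on the full matrix with LAM normalized by all
recurrent points.  More regular dynamics give longer diagonals (higher
DET, LMAX) and, for laminar intermittent dynamics, longer verticals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "EmbeddedTrajectory",
    "RecurrenceMatrix",
    "LineHistograms",
    "EpsilonRule",
    "embed",
    "recurrence_matrix",
    "line_histograms",
    "rqa_measures",
    "rqa_features",
    "RQA_NAMES",
]

RQA_NAMES = ("REC", "DET", "LMAX", "LAM", "TT", "ENT")


@dataclass
class EmbeddedTrajectory:
    states: np.ndarray      # (N, m)
    m: int
    tau: int

    @property
    def N(self) -> int:
        return self.states.shape[0]


@dataclass
class RecurrenceMatrix:
    R: np.ndarray           # (N, N) bool
    epsilon: float
    norm: str = "euclidean"
    loi_included: bool = True

    @property
    def N(self) -> int:
        return self.R.shape[0]


@dataclass
class LineHistograms:
    """Counts of maximal diagonal / vertical runs by exact length.

    ``P_l[l]`` counts off-LOI diagonal lines of length exactly ``l``;
    ``P_v[v]`` counts vertical lines (full matrix).  Measures use the
    minimum lengths ``l_min = v_min = 2``.
    """

    P_l: dict[int, int] = field(default_factory=dict)
    P_v: dict[int, int] = field(default_factory=dict)
    l_min: int = 2
    v_min: int = 2


@dataclass
class EpsilonRule:
    """How the recurrence cutoff is resolved.

    Exactly one of: a fixed value, a fraction of the SD of the window's
    values, or a target recurrence rate (bisected to within 0.5 %REC).
    """

    fixed: float | None = None
    sd_fraction: float | None = 0.2
    target_rec: float | None = None


def embed(series: np.ndarray, m: int = 3, tau: int = 1) -> EmbeddedTrajectory:
    """Delay embedding x_i = (s_i, s_{i+tau}, ..., s_{i+(m-1)tau})."""
    s = np.asarray(series, dtype=float)
    n = s.size - (m - 1) * tau
    if n < 10:
        raise ValueError("series too short for this embedding")
    states = np.stack([s[i * tau:i * tau + n] for i in range(m)], axis=1)
    return EmbeddedTrajectory(states=states, m=m, tau=tau)


def recurrence_matrix(traj: EmbeddedTrajectory,
                      rule: EpsilonRule | float | None = None,
                      series_sd: float | None = None) -> RecurrenceMatrix:
    """Threshold pairwise Euclidean distances into a binary matrix.

    ``series_sd`` optionally supplies the scale for the SD-fraction rule
    (defaults to the SD of the embedded coordinate values).
    """
    if isinstance(rule, (int, float)):
        rule = EpsilonRule(fixed=float(rule), sd_fraction=None)
    rule = rule or EpsilonRule()
    d = squareform(pdist(traj.states, metric="euclidean"))
    if rule.fixed is not None:
        eps = float(rule.fixed)
    elif rule.target_rec is not None:
        eps = float(np.quantile(d[np.triu_indices(traj.N, 1)],
                                rule.target_rec / 100.0))
    else:
        sd = series_sd if series_sd is not None else float(traj.states.std())
        eps = rule.sd_fraction * sd
    if eps <= 0:
        raise ValueError("recurrence threshold must be positive")
    return RecurrenceMatrix(R=d <= eps, epsilon=eps)


def _run_lengths(line: np.ndarray) -> np.ndarray:
    """Lengths of maximal runs of ones in a 1-D binary array."""
    if line.size == 0:
        return np.array([], dtype=int)
    padded = np.concatenate(([0], line.view(np.uint8), [0]))
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return ends - starts


def line_histograms(R: np.ndarray | RecurrenceMatrix) -> LineHistograms:
    """Histogram maximal diagonal (off-LOI) and vertical (full) runs."""
    M = R.R if isinstance(R, RecurrenceMatrix) else np.asarray(R, dtype=bool)
    n = M.shape[0]
    hists = LineHistograms()
    for off in range(-(n - 1), n):
        if off == 0:
            continue  # line of identity
        for ln in _run_lengths(np.diagonal(M, offset=off).copy()):
            hists.P_l[int(ln)] = hists.P_l.get(int(ln), 0) + 1
    for col in range(n):
        for ln in _run_lengths(M[:, col].copy()):
            hists.P_v[int(ln)] = hists.P_v.get(int(ln), 0) + 1
    return hists


def rqa_measures(R: np.ndarray | RecurrenceMatrix,
                 hists: LineHistograms | None = None) -> dict[str, float]:
    """The six recurrence measures; TT/ENT are NaN when no line qualifies."""
    M = R.R if isinstance(R, RecurrenceMatrix) else np.asarray(R, dtype=bool)
    n = M.shape[0]
    if hists is None:
        hists = line_histograms(M)
    total = int(M.sum())
    off_loi = total - int(np.diagonal(M).sum())

    rec = 100.0 * total / (n * n)

    diag_pts = sum(l * c for l, c in hists.P_l.items() if l >= hists.l_min)
    det = 100.0 * diag_pts / off_loi if off_loi else 0.0
    lmax = max(hists.P_l) if hists.P_l else 0

    vert_pts = sum(v * c for v, c in hists.P_v.items() if v >= hists.v_min)
    lam = 100.0 * vert_pts / total if total else 0.0
    vert_lines = sum(c for v, c in hists.P_v.items() if v >= hists.v_min)
    tt = vert_pts / vert_lines if vert_lines else float("nan")

    diag_lines = sum(c for l, c in hists.P_l.items() if l >= hists.l_min)
    if diag_lines:
        p = np.array([c for l, c in hists.P_l.items()
                      if l >= hists.l_min], dtype=float) / diag_lines
        ent = float(-(p * np.log(p)).sum())
    else:
        ent = float("nan")

    return {"REC": rec, "DET": det, "LMAX": float(lmax),
            "LAM": lam, "TT": tt, "ENT": ent}


def rqa_features(series: np.ndarray, m: int = 3, tau: int = 1,
                 rule: EpsilonRule | float | None = None) -> dict[str, float]:
    """Embed a window, build its recurrence matrix and return the measures."""
    s = np.asarray(series, dtype=float)
    traj = embed(s, m=m, tau=tau)
    sd = float(s.std())
    if sd == 0:
        # constant window: every state recurs
        n = traj.N
        return rqa_measures(np.ones((n, n), dtype=bool))
    rm = recurrence_matrix(traj, rule, series_sd=sd)
    return rqa_measures(rm)
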