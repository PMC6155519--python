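"""Reading and writing the pipeline's file formats.

ECG travels as CSV (one column per channel, a ``# fs=<Hz>`` header line)
or EDF (read via :mod:`mne` when installed; EDF writing needs an EDF
backend and is not provided).  Annotations are CSV with
``onset_s,offset_s,label`` columns, ground truth is JSON, beats and RR
series are CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .records import (BeatSequence, ECGRecord, GroundTruth, RRSeries,
                      SeizureAnnotation)

__all__ = [
    "write_ecg_csv", "read_ecg_csv", "read_ecg_edf", "read_ecg",
    "write_annotations_csv", "read_annotations_csv",
    "write_ground_truth_json", "read_ground_truth_json",
    "write_beats_csv", "read_beats_csv",
    "write_rr_csv", "read_rr_csv",
]


def write_ecg_csv(record: ECGRecord, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# fs={record.fs}\n")
        fh.write(",".join(record.channel_names) + "\n")
        np.savetxt(fh, record.samples.T, delimiter=",", fmt="%.6g")


def read_ecg_csv(path: str | Path) -> ECGRecord:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().strip()
        if not header.startswith("# fs="):
            raise ValueError("missing '# fs=' header line")
        fs = float(header.split("=", 1)[1])
        names = fh.readline().strip().split(",")
        data = np.loadtxt(fh, delimiter=",", ndmin=2)
    return ECGRecord(samples=data.T, fs=fs, channel_names=names)


def read_ecg_edf(path: str | Path) -> ECGRecord:
    """Read an EDF recording (requires the optional mne dependency)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading EDF requires mne") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return ECGRecord(samples=raw.get_data() * 1000.0,  # V -> mV
                     fs=float(raw.info["sfreq"]),
                     channel_names=list(raw.ch_names))


def read_ecg(path: str | Path) -> ECGRecord:
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return read_ecg_edf(path)
    return read_ecg_csv(path)


def write_annotations_csv(annotations: list[SeizureAnnotation],
                          path: str | Path) -> None:
    pd.DataFrame([{"onset_s": a.onset_s, "offset_s": a.offset_s,
                   "label": a.label} for a in annotations]).to_csv(
        path, index=False)


def read_annotations_csv(path: str | Path) -> list[SeizureAnnotation]:
    df = pd.read_csv(path)
    return [SeizureAnnotation(onset_s=float(r.onset_s),
                              offset_s=float(r.offset_s),
                              label=str(r.label))
            for r in df.itertuples()]


def write_ground_truth_json(gt: GroundTruth, path: str | Path) -> None:
    payload = {
        "beat_times_s": gt.beat_times_s.tolist(),
        "corrupted_beat_indices": gt.corrupted_beat_indices.tolist(),
        "artifact_spans": [list(s) for s in gt.artifact_spans],
    }
    Path(path).write_text(json.dumps(payload))


def read_ground_truth_json(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        beat_times_s=np.asarray(payload["beat_times_s"]),
        corrupted_beat_indices=np.asarray(payload["corrupted_beat_indices"],
                                          dtype=int),
        artifact_spans=[tuple(s) for s in payload["artifact_spans"]],
    )


def write_beats_csv(beats: BeatSequence, path: str | Path) -> None:
    pd.DataFrame({"time_s": beats.fiducial_times_s,
                  "polarity": beats.polarities}).to_csv(path, index=False)


def read_beats_csv(path: str | Path) -> BeatSequence:
    df = pd.read_csv(path)
    return BeatSequence(fiducial_times_s=df["time_s"].to_numpy(),
                        polarities=df["polarity"].to_numpy())


def write_rr_csv(rr: RRSeries, path: str | Path) -> None:
    pd.DataFrame({"time_s": rr.beat_times_s, "rr_ms": rr.rr_ms,
                  "flag": rr.corrected_flags}).to_csv(path, index=False)


def read_rr_csv(path: str | Path) -> RRSeries:
    df = pd.read_csv(path)
    rr = df["rr_ms"].to_numpy()
    t_end = df["time_s"].to_numpy()
    t0 = float(t_end[0] - rr[0] / 1000.0)
    flags = df["flag"].to_numpy() if "flag" in df else None
    return RRSeries(rr_ms=rr, t0_s=t0, corrected_flags=flags)
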