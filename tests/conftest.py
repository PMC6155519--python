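"""Shared fixtures: synthetic recordings generated once per session."""

import numpy as np
import pytest

import hrvseizure as hs
from hrvseizure.features import extract_features
from hrvseizure.pipeline import label_windows
from hrvseizure.records import RRSeries


@pytest.fixture(scope="session")
def clean_rr():
    """10-minute stationary modulated RR series with ground truth."""
    cfg = hs.SimulationConfig(duration_s=600, seed=3)
    rr, gt = hs.simulate_rr(cfg)
    return rr, gt, cfg


@pytest.fixture(scope="session")
def synthetic_ecg_10min():
    """10-min, 512 Hz, two-channel ECG at 20 dB SNR with tall T waves."""
    cfg = hs.SimulationConfig(duration_s=600, seed=3, t_wave_amp=0.6)
    rr, gt = hs.simulate_rr(cfg)
    record = hs.synthesize_ecg(rr, cfg)
    noisy = hs.add_white_noise(record, snr_db=20.0, seed=11)
    return noisy, gt, cfg


@pytest.fixture(scope="session")
def preictal_dataset():
    """3-seizure recording with strong configured preictal shifts."""
    cfg = hs.SimulationConfig(seed=5)
    rr, anns, gt = hs.simulate_preictal_dataset(cfg, n_seizures=3)
    return rr, anns, gt, cfg


@pytest.fixture(scope="session")
def labeled_windows(preictal_dataset):
    rr, anns, gt, cfg = preictal_dataset
    mat = extract_features(RRSeries(rr))
    return label_windows(mat, anns), anns
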