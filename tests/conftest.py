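import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vds import io as vio, scoring, synth, waves

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def nrem_study():
    """Half-hour NREM-only study (seed 42): the default bundle for
    slow-wave and OFF-period validation."""
    cfg = synth.SynthConfig(
        seed=42, duration_h=0.5, transitions={"NREM": {"NREM": 1.0}}, ma_rate_per_h=0.0
    )
    labels = synth.generate_hypnogram(cfg)
    rec, gt = synth.synthesize_signals(labels, cfg)
    return cfg, rec, gt


@pytest.fixture(scope="session")
def nrem_detection(nrem_study):
    """Filtered LFP, detected events and high-amplitude subset for the
    NREM study."""
    _, rec, gt = nrem_study
    lfp = rec.channels["lfp"]
    filt = waves.filter_swa(lfp.data, lfp.fs)
    events = waves.detect_waves(filt, lfp.fs)
    return filt, events, waves.select_high_amplitude(events)


@pytest.fixture(scope="session")
def mixed_study():
    """One-hour study with the standard three-state architecture."""
    cfg = synth.SynthConfig(seed=7, duration_h=1.0)
    labels = synth.generate_hypnogram(cfg)
    rec, gt = synth.synthesize_signals(labels, cfg)
    return cfg, rec, gt


@pytest.fixture(scope="session")
def scored_mixed(mixed_study):
    cfg, rec, gt = mixed_study
    pre = vio.preprocess(rec)
    return pre, scoring.score_recording(pre), gt


@pytest.fixture(scope="session")
def study_bundle(tmp_path_factory):
    """On-disk drug/vehicle bundle (12 min) for I/O and CLI tests."""
    cfg = synth.SynthConfig(seed=9, duration_h=0.2, drug_window=(120.0, 600.0))
    outdir = tmp_path_factory.mktemp("bundle")
    paths = synth.generate_study(cfg, outdir)
    return cfg, paths
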