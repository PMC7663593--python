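import numpy as np
import pytest

import rgstress as rg


@pytest.fixture(scope="session")
def protocol():
    return rg.ProtocolSpec()


@pytest.fixture(scope="session")
def profile(protocol):
    return rg.StressProfile(protocol=protocol)


@pytest.fixture(scope="session")
def short_protocol():
    """Shrunken session (170 s) for I/O round trips: full structure, less data."""
    return rg.ProtocolSpec(
        block_durations={
            "RS1": 60, "MIST_TRAIN": 10, "MIST_TASK": 20, "RELAX": 20, "RS2": 60,
        }
    )


@pytest.fixture(scope="session")
def clean_subject():
    """No artifacts, no line noise: every sample stays well below 100 uV."""
    return rg.SubjectSpec(
        "S_clean", "control", responder_polarity="direct",
        modulation_depth=0.4, artifact_rate=0.0, line_noise_amplitude=0.0, seed=101,
    )


@pytest.fixture(scope="session")
def clean_session(protocol, clean_subject, profile):
    return rg.generate_session(protocol, clean_subject, profile)


@pytest.fixture(scope="session")
def default_config():
    return rg.validate_config("")


@pytest.fixture(scope="session")
def processed_clean(clean_session, default_config):
    """Smoothed, resampled RG series of the clean direct responder."""
    from rgstress.pipeline import process_session

    rg_series, stats = process_session(clean_session, default_config)
    return rg_series, stats


def make_analysis_signal(data, rate, boundaries=None):
    """Wrap a raw array as an AnalysisSignal for unit tests."""
    return rg.AnalysisSignal(
        data=np.atleast_2d(np.asarray(data, dtype=float)),
        sampling_rate=rate,
        boundaries=boundaries or {},
    )
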