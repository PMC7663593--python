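"""Synthetic EEG cohorts with a band-structured stress response.

Each channel is a sum of band-limited Gaussian noise components, one per
classical band, realised by zero-phase 4th-order Butterworth filtering of
white noise.  The gamma component's amplitude is scaled by
``1 + depth * s(t)`` and the alpha/theta components by ``1 - depth * s(t)``
for a direct responder (sign-flipped for an inverse responder), where
``s(t)`` is the latent stress trajectory of the protocol.  Optional 50 Hz
mains interference and Poisson-placed high-amplitude transients (raised
cosine, 200 ms, 150-300 uV on 1-3 channels) emulate line coupling and
movement artifacts; the transients are guaranteed to trip the 100 uV
epoch-channel zeroing rule downstream.

The generator reproduces only the statistical structure the biomarker
pipeline consumes, not physiological EEG microstructure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .preprocess import EEGSession
from .protocol import ProtocolSpec, StressProfile
from .spectral import DEFAULT_BANDS, BandDefinition

__all__ = [
    "SubjectSpec",
    "DEFAULT_BAND_AMPLITUDES",
    "generate_session",
    "generate_spsl",
    "default_cohort",
]

#: Baseline amplitude spectral densities, uV/sqrt(Hz), per band.  Conventional
#: resting-EEG-like values (alpha-dominant, weak gamma); the study reports no
#: amplitude or SNR figures, so these are a realistic choice, not data-derived.
DEFAULT_BAND_AMPLITUDES: dict[str, float] = {
    "delta": 2.0,
    "theta": 1.5,
    "alpha": 2.0,
    "beta": 0.8,
    "gamma": 0.5,
}

#: Bands whose amplitude rises with stress (direct responder).
_STRESS_UP = ("gamma",)
#: Bands whose amplitude falls with stress (direct responder).
_STRESS_DOWN = ("alpha", "theta")


@dataclass(frozen=True)
class SubjectSpec:
    """Ground truth for one simulated participant."""

    subject_id: str
    group: str  # 'control' | 'test'
    responder_polarity: str = "direct"  # 'direct' | 'inverse'
    band_amplitudes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BAND_AMPLITUDES)
    )
    modulation_depth: float = 0.4
    artifact_rate: float = 2.0  # events / minute
    line_noise_amplitude: float = 2.0  # uV at 50 Hz
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group not in ("control", "test"):
            raise ValueError(f"unknown group {self.group!r}")
        if self.responder_polarity not in ("direct", "inverse"):
            raise ValueError(f"unknown polarity {self.responder_polarity!r}")
        if any(a < 0 for a in self.band_amplitudes.values()):
            raise ValueError("band amplitudes must be >= 0")
        if not (0.0 <= self.modulation_depth < 1.0):
            raise ValueError("modulation_depth must lie in [0, 1)")
        if self.artifact_rate < 0:
            raise ValueError("artifact_rate must be >= 0")
        if self.line_noise_amplitude < 0:
            raise ValueError("line_noise_amplitude must be >= 0")


def _band_noise(
    rng: np.random.Generator, shape: tuple[int, ...], band: BandDefinition, rate: float
) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to ``band`` (zero-phase filter).

    ``shape`` is (channels, samples); each channel is filtered and
    renormalised independently.
    """
    sos = sps.butter(4, [band.low, band.high], btype="bandpass", fs=rate, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(shape), axis=-1)
    return x / x.std(axis=-1, keepdims=True)


def generate_session(
    protocol: ProtocolSpec,
    subject: SubjectSpec,
    profile: StressProfile | None = None,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
) -> EEGSession:
    """Simulate one subject's full annotated session; bit-reproducible per seed."""
    gamma_high = max(b.high for b in bands)
    if protocol.sampling_rate < 2 * gamma_high:
        raise ValueError(
            f"sampling rate {protocol.sampling_rate} Hz cannot represent the "
            f"gamma band (need >= {2 * gamma_high} Hz)"
        )
    if profile is None:
        profile = StressProfile(protocol=protocol)

    rng = np.random.default_rng(subject.seed)
    rate = protocol.sampling_rate
    n_total = sum(protocol.n_samples(b) for b in protocol.block_order)
    t = np.arange(n_total) / rate
    s = profile.level(np.minimum(t, protocol.total_duration))
    sign = 1.0 if subject.responder_polarity == "direct" else -1.0

    n_ch = len(protocol.channel_labels)
    data = np.zeros((n_ch, n_total))
    for band in bands:
        sigma = subject.band_amplitudes.get(band.name, 0.0) * math.sqrt(
            band.high - band.low
        )
        if sigma == 0.0:
            continue
        x = _band_noise(rng, (n_ch, n_total), band, rate)
        if band.name in _STRESS_UP:
            gain = sigma * (1.0 + sign * subject.modulation_depth * s)
        elif band.name in _STRESS_DOWN:
            gain = sigma * (1.0 - sign * subject.modulation_depth * s)
        else:
            gain = sigma
        data += gain * x
    if subject.line_noise_amplitude > 0:
        phases = rng.uniform(0, 2 * np.pi, size=(n_ch, 1))
        data += subject.line_noise_amplitude * np.sin(
            2 * np.pi * 50.0 * t[None, :] + phases
        )

    _add_artifacts(rng, data, rate, subject.artifact_rate)

    blocks = []
    pos = 0
    for label in protocol.block_order:
        n = protocol.n_samples(label)
        blocks.append((label, data[:, pos : pos + n]))
        pos += n
    return EEGSession(
        subject_id=subject.subject_id,
        group=subject.group,
        sampling_rate=rate,
        blocks=blocks,
        channel_labels=protocol.channel_labels,
    )


def _add_artifacts(
    rng: np.random.Generator, data: np.ndarray, rate: float, rate_per_min: float
) -> None:
    """Add Poisson-placed 200 ms raised-cosine transients of 150-300 uV in place."""
    if rate_per_min <= 0:
        return
    n_ch, n = data.shape
    duration_min = n / rate / 60.0
    n_events = rng.poisson(rate_per_min * duration_min)
    width = min(int(round(0.2 * rate)), n)
    pulse = 0.5 * (1.0 - np.cos(2 * np.pi * np.arange(width) / width))
    for _ in range(n_events):
        start = int(rng.integers(0, max(1, n - width)))
        amp = rng.uniform(150.0, 300.0) * rng.choice([-1.0, 1.0])
        chans = rng.choice(n_ch, size=int(rng.integers(1, 4)), replace=False)
        data[np.ix_(chans, np.arange(start, start + width))] += amp * pulse


def generate_spsl(
    cohort: list[SubjectSpec],
    effect_means: tuple[float, float, float, float] = (2.0, 4.0, 2.0, 2.0),
    noise_sd: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Integer 1-5 self-perceived stress responses at T1..T4 for each subject.

    Responses are Gaussian around the per-instant means, rounded and clipped
    to the 1-5 scale.  The default means encode the intended protocol effect:
    stress rises after the MIST (T2) and falls again during relaxation
    (T3, T4).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if any(not (1.0 <= m <= 5.0) for m in effect_means):
        raise ValueError("effect means must lie within the 1-5 scale")
    rng = np.random.default_rng(seed)
    rows = []
    for subj in cohort:
        raw = np.asarray(effect_means) + noise_sd * rng.standard_normal(4)
        resp = np.clip(np.rint(raw), 1, 5).astype(int)
        rows.append(
            {
                "subject_id": subj.subject_id,
                "group": subj.group,
                "T1": resp[0],
                "T2": resp[1],
                "T3": resp[2],
                "T4": resp[3],
            }
        )
    return pd.DataFrame(rows)


def default_cohort(
    n_subjects: int = 20,
    seed: int = 0,
    p_direct: float = 7.0 / 17.0,
    modulation_depth: float = 0.4,
    artifact_rate: float = 2.0,
    line_noise_amplitude: float = 2.0,
) -> list[SubjectSpec]:
    """Study-like cohort: half control, half test, mixed responder polarity.

    Polarity is drawn per subject with P(direct) defaulting to the observed
    7-in-17 proportion; per-subject generator seeds derive from ``seed``.
    """
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n_subjects):
        polarity = "direct" if rng.uniform() < p_direct else "inverse"
        cohort.append(
            SubjectSpec(
                subject_id=f"S{i + 1:02d}",
                group="control" if i < n_subjects / 2 else "test",
                responder_polarity=polarity,
                modulation_depth=modulation_depth,
                artifact_rate=artifact_rate,
                line_noise_amplitude=line_noise_amplitude,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return cohort
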