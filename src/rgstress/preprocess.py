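"""Session assembly and the zero-phase filtering chain.

The analysis window keeps only the central minute of each resting-state
block and the full MIST and relaxation blocks, concatenated in protocol
order (16 min for the standard session).  The concatenated signal is then
band-limited with a zero-phase Butterworth bandpass (1-50 Hz, prototype
order 2, applied forward-backward) and mains interference is removed with a
zero-phase 50 Hz IIR notch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .protocol import BLOCK_ORDER, RESTING_BLOCKS

logger = logging.getLogger(__name__)

__all__ = [
    "EEGSession",
    "AnalysisSignal",
    "FormatError",
    "select_central_minute",
    "concatenate_blocks",
    "bandpass_filter",
    "notch_filter",
]


class FormatError(ValueError):
    """A session file or container violates the protocol structure."""


@dataclass
class EEGSession:
    """One subject's recording: ordered annotated blocks of channels x samples (uV)."""

    subject_id: str
    group: str
    sampling_rate: float
    blocks: list[tuple[str, np.ndarray]]
    channel_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        n_ch = {arr.shape[0] for _, arr in self.blocks}
        if len(n_ch) > 1:
            raise FormatError(f"blocks disagree on channel count: {sorted(n_ch)}")

    @property
    def n_channels(self) -> int:
        return self.blocks[0][1].shape[0]

    def block(self, label: str) -> np.ndarray:
        for name, arr in self.blocks:
            if name == label:
                return arr
        raise KeyError(label)

    @property
    def block_labels(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.blocks)


@dataclass
class AnalysisSignal:
    """Concatenated analysis window with a block boundary map.

    ``boundaries`` maps block label -> [start, end) sample indices (0-based,
    half-open); the boundaries partition the signal exactly.
    """

    data: np.ndarray  # channels x samples, uV
    sampling_rate: float
    boundaries: dict[str, tuple[int, int]]
    subject_id: str = ""
    group: str = ""

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def epoch_boundaries(self, epoch_seconds: float = 2.0) -> dict[str, tuple[int, int]]:
        """Boundary map converted from samples to epoch units."""
        el = int(round(epoch_seconds * self.sampling_rate))
        return {k: (s // el, e // el) for k, (s, e) in self.boundaries.items()}


def select_central_minute(block: np.ndarray, rate: float) -> np.ndarray:
    """Return the 60 s of samples centred on the block midpoint.

    For a 120 s block at 250 Hz this is samples [7500, 22500).
    """
    n_keep = int(round(60.0 * rate))
    n = block.shape[-1]
    if n < n_keep:
        raise ValueError(f"block of {n / rate:.1f} s is shorter than 60 s")
    start = (n - n_keep) // 2
    return block[..., start : start + n_keep]


def concatenate_blocks(session: EEGSession) -> AnalysisSignal:
    """Assemble the analysis window: RS1 central minute | MIST | Relax | RS2 central minute."""
    present = set(session.block_labels)
    missing = [b for b in BLOCK_ORDER if b not in present]
    if missing:
        raise FormatError(f"session is missing block(s): {', '.join(missing)}")

    parts: list[np.ndarray] = []
    boundaries: dict[str, tuple[int, int]] = {}
    pos = 0
    for label in BLOCK_ORDER:
        arr = session.block(label)
        if label in RESTING_BLOCKS:
            arr = select_central_minute(arr, session.sampling_rate)
        boundaries[label] = (pos, pos + arr.shape[1])
        parts.append(arr)
        pos += arr.shape[1]
    data = np.concatenate(parts, axis=1)
    return AnalysisSignal(
        data=data,
        sampling_rate=session.sampling_rate,
        boundaries=boundaries,
        subject_id=session.subject_id,
        group=session.group,
    )


def bandpass_filter(
    x: np.ndarray,
    rate: float,
    low: float = 1.0,
    high: float = 50.0,
    order: int = 2,
) -> np.ndarray:
    """Zero-phase Butterworth bandpass (prototype ``order``, forward-backward).

    The forward-backward pass doubles the effective magnitude order and
    cancels the phase response, so narrowband components inside the passband
    emerge with zero group delay.
    """
    nyq = rate / 2.0
    if high >= nyq:
        raise ValueError(f"high cutoff {high} Hz must be below Nyquist {nyq} Hz")
    if not (0 < low < high):
        raise ValueError("need 0 < low < high")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=rate, output="sos")
    padlen = min(3 * 2 * order * 3, x.shape[-1] - 1)
    return sps.sosfiltfilt(sos, x, axis=-1, padtype="odd", padlen=padlen)


def notch_filter(x: np.ndarray, rate: float, freq: float = 50.0, q: float = 30.0) -> np.ndarray:
    """Zero-phase IIR notch at ``freq`` Hz (quality factor ``q``)."""
    nyq = rate / 2.0
    if freq >= nyq:
        raise ValueError(f"notch frequency {freq} Hz must be below Nyquist {nyq} Hz")
    b, a = sps.iirnotch(freq, q, fs=rate)
    padlen = min(3 * max(len(a), len(b)), x.shape[-1] - 1)
    return sps.filtfilt(b, a, x, axis=-1, padtype="odd", padlen=padlen)
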