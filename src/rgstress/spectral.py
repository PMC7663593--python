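"""Epoching, amplitude artifact zeroing, normalisation and band power.

The analysis signal is cut into non-overlapping 2 s epochs (480 for the
standard 16 min window).  Any epoch-channel whose peak absolute amplitude
exceeds 100 uV is zeroed and masked; an epoch with every channel masked is
rejected outright.  Surviving epoch-channels are linearly detrended and
z-scored, a per-epoch periodogram is integrated over the classical bands
(delta 1-4, theta 4-8, alpha 8-13, beta 13-25, gamma 25-45 Hz) and averaged
across unmasked channels.  The stress biomarker is the relative gamma

    RG = P_gamma / (P_alpha + P_theta)

computed per epoch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .preprocess import AnalysisSignal

logger = logging.getLogger(__name__)

__all__ = [
    "BandDefinition",
    "DEFAULT_BANDS",
    "EpochMatrix",
    "BandPowerSeries",
    "RGSeries",
    "epoch_signal",
    "reject_artifacts",
    "detrend_zscore",
    "band_power",
    "relative_gamma",
]


@dataclass(frozen=True)
class BandDefinition:
    """Frequency band ``[low, high)`` Hz; half-open so adjacent bands partition."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high <= 50):
            raise ValueError(f"band {self.name}: need 0 < low < high <= 50")


DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 25.0),
    BandDefinition("gamma", 25.0, 45.0),
)


@dataclass
class EpochMatrix:
    """Non-overlapping fixed-length epochs: epochs x channels x samples."""

    data: np.ndarray
    sampling_rate: float
    mask: np.ndarray  # epochs x channels, True where zeroed
    rejected: np.ndarray  # epochs, True where all channels masked
    epoch_boundaries: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def masked_fraction(self) -> float:
        """Fraction of epoch-channels zeroed by the amplitude rule."""
        return float(self.mask.mean())

    @property
    def rejected_fraction(self) -> float:
        """Fraction of epochs with every channel masked."""
        return float(self.rejected.mean())


@dataclass
class BandPowerSeries:
    """Channel-averaged per-epoch power in each band (NaN where rejected)."""

    powers: pd.DataFrame  # index: epoch, columns: band names
    epoch_boundaries: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def n_epochs(self) -> int:
        return len(self.powers)

    def __getitem__(self, band: str) -> np.ndarray:
        return self.powers[band].to_numpy()


@dataclass
class RGSeries:
    """Per-epoch relative gamma with its processing state.

    ``values`` may contain NaN for rejected epochs until
    :meth:`interpolate_missing` is applied; downstream smoothing requires a
    gap-free series.
    """

    values: np.ndarray
    epoch_boundaries: dict[str, tuple[int, int]] = field(default_factory=dict)
    subject_id: str = ""
    group: str = ""
    smoothing_span: int | None = None
    resampled_length: int | None = None
    polarity: str | None = None

    def __len__(self) -> int:
        return len(self.values)

    def interpolate_missing(self) -> "RGSeries":
        """Fill NaN epochs by linear interpolation from valid neighbours."""
        v = np.asarray(self.values, dtype=float)
        bad = ~np.isfinite(v)
        if not bad.any():
            return self
        if bad.all():
            raise ValueError("relative gamma series has no valid epochs")
        idx = np.arange(len(v))
        filled = v.copy()
        filled[bad] = np.interp(idx[bad], idx[~bad], v[~bad])
        logger.info("interpolated %d missing RG epochs", int(bad.sum()))
        return replace(self, values=filled)


def epoch_signal(signal: AnalysisSignal, epoch_seconds: float = 2.0) -> EpochMatrix:
    """Cut the analysis signal into non-overlapping epochs.

    Epoch i covers samples ``[i*L, (i+1)*L)`` with ``L = epoch_seconds*rate``;
    a trailing remainder shorter than one epoch is dropped with a warning.
    The standard 16 min window at any rate yields 480 two-second epochs.
    """
    el = int(round(epoch_seconds * signal.sampling_rate))
    n = signal.n_samples
    n_ep = n // el
    if n_ep == 0:
        raise ValueError(
            f"signal of {n} samples is shorter than one {epoch_seconds} s epoch"
        )
    if n % el:
        logger.warning(
            "dropping %.2f s trailing remainder (not a whole epoch)",
            (n % el) / signal.sampling_rate,
        )
    data = signal.data[:, : n_ep * el].reshape(signal.data.shape[0], n_ep, el)
    data = np.ascontiguousarray(np.swapaxes(data, 0, 1))
    return EpochMatrix(
        data=data,
        sampling_rate=signal.sampling_rate,
        mask=np.zeros((n_ep, data.shape[1]), dtype=bool),
        rejected=np.zeros(n_ep, dtype=bool),
        epoch_boundaries=signal.epoch_boundaries(epoch_seconds),
    )


def reject_artifacts(epochs: EpochMatrix, threshold: float = 100.0) -> EpochMatrix:
    """Zero every epoch-channel whose peak |amplitude| exceeds ``threshold`` uV.

    Applied before any normalisation (normalisation would destroy the
    amplitude scale the rule is defined on).  An epoch whose channels are
    all zeroed is flagged rejected and yields missing band powers.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    peak = np.abs(epochs.data).max(axis=2)
    mask = peak > threshold
    data = epochs.data.copy()
    data[mask] = 0.0
    rejected = mask.all(axis=1)
    if mask.any():
        logger.info(
            "amplitude rule zeroed %d/%d epoch-channels (%d epochs fully rejected)",
            int(mask.sum()), mask.size, int(rejected.sum()),
        )
    return replace(epochs, data=data, mask=mask, rejected=rejected)


def detrend_zscore(epochs: EpochMatrix) -> EpochMatrix:
    """Remove the linear trend and z-score each epoch-channel.

    Masked (zeroed) epoch-channels are left exactly zero.  An unmasked
    channel with zero variance after detrending is also left at zero and
    logged.  The output is dimensionless; relative gamma is unaffected
    because it is a ratio of same-epoch powers.
    """
    scale = np.abs(epochs.data).max(axis=2, keepdims=True)
    data = sps.detrend(epochs.data, axis=2, type="linear")
    sd = data.std(axis=2, keepdims=True)
    # residuals at float-noise level relative to the raw amplitude count as
    # zero variance (e.g. an exactly linear epoch)
    ok = sd > 1e-10 * np.maximum(scale, 1e-30)
    degenerate = ~ok[..., 0] & ~epochs.mask
    if degenerate.any():
        logger.warning("%d zero-variance epoch-channels left at zero", int(degenerate.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        data = np.where(ok, data / sd, 0.0)
    data[epochs.mask] = 0.0
    return replace(epochs, data=data)


def band_power(
    epochs: EpochMatrix, bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
) -> BandPowerSeries:
    """Per-epoch band power, averaged across unmasked channels.

    Each 2 s epoch-channel gets a raw rectangular-window periodogram
    (``scaling='spectrum'``, so the bins sum to the mean square); band power
    is the sum of bins with ``low <= f < high``.  Masked channels are
    excluded from the average; fully rejected epochs yield NaN.
    """
    nyq = epochs.sampling_rate / 2.0
    for b in bands:
        if b.high > nyq:
            raise ValueError(f"band {b.name} exceeds Nyquist {nyq} Hz")
    freqs, pxx = sps.periodogram(
        epochs.data, fs=epochs.sampling_rate, window="boxcar",
        detrend=False, scaling="spectrum", axis=2,
    )
    valid = ~epochs.mask
    counts = valid.sum(axis=1)
    out = {}
    for b in bands:
        sel = (freqs >= b.low) & (freqs < b.high)
        bp = pxx[:, :, sel].sum(axis=2)  # epochs x channels
        total = np.where(valid, bp, 0.0).sum(axis=1)
        mean = np.divide(
            total, counts, out=np.full(len(counts), np.nan), where=counts > 0
        )
        out[b.name] = mean
    return BandPowerSeries(
        powers=pd.DataFrame(out), epoch_boundaries=dict(epochs.epoch_boundaries)
    )


def relative_gamma(bp: BandPowerSeries) -> RGSeries:
    """RG = P_gamma / (P_alpha + P_theta) per epoch; NaN where undefined."""
    for band in ("gamma", "alpha", "theta"):
        if band not in bp.powers.columns:
            raise ValueError(f"band power series lacks {band!r}")
    gamma = bp["gamma"]
    denom = bp["alpha"] + bp["theta"]
    with np.errstate(invalid="ignore", divide="ignore"):
        rg = np.where(denom > 0, gamma / denom, np.nan)
    n_bad = int((~np.isfinite(rg)).sum())
    if n_bad:
        logger.info("%d epochs have undefined relative gamma", n_bad)
    return RGSeries(values=rg, epoch_boundaries=dict(bp.epoch_boundaries))
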