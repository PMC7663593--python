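"""Experimental protocol structure and the latent stress trajectory.

The protocol is a fixed sequence of annotated blocks: an eyes-closed resting
state (RS1), a psychosocial stressor (MIST: a timed mental-arithmetic task
with a training period), a relaxation session, and a closing resting state
(RS2).  The latent stress level s(t) in [0, 1] drives the synthetic EEG
generator: gamma-band amplitude rises with s(t) while alpha/theta amplitude
falls (direct responders; the dependence is sign-flipped for inverse
responders).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BLOCK_ORDER",
    "ProtocolSpec",
    "StressProfile",
    "stress_profile_eval",
]

#: Canonical block order for the standard session.
BLOCK_ORDER = ("RS1", "MIST_TRAIN", "MIST_TASK", "RELAX", "RS2")

#: Blocks from which only the central minute enters the analysis window.
RESTING_BLOCKS = ("RS1", "RS2")

_DEFAULT_DURATIONS = {
    "RS1": 120.0,
    "MIST_TRAIN": 180.0,
    "MIST_TASK": 360.0,
    "RELAX": 300.0,
    "RS2": 120.0,
}

_DEFAULT_CHANNELS = ("Fp1", "Fp2", "F7", "F8", "Fz", "Cz", "O1", "O2")


@dataclass(frozen=True)
class ProtocolSpec:
    """Block names/durations, sampling rate and montage of one session.

    The default 18-minute session: 2 min RS1, 3 min MIST training, 6 min
    MIST task, 5 min relaxation, 2 min RS2, recorded from eight 10-20
    electrodes at 250 Hz.
    """

    block_durations: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_DURATIONS)
    )
    sampling_rate: float = 250.0
    channel_labels: tuple[str, ...] = _DEFAULT_CHANNELS

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not self.channel_labels:
            raise ValueError("channel_labels must be non-empty")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel_labels must be unique")
        for name, dur in self.block_durations.items():
            if dur <= 0:
                raise ValueError(f"block {name!r} duration must be positive")
        for name in RESTING_BLOCKS:
            if name in self.block_durations and self.block_durations[name] < 60.0:
                raise ValueError(
                    f"resting block {name!r} must last >= 60 s "
                    "(a central minute must exist)"
                )

    @property
    def block_order(self) -> tuple[str, ...]:
        return tuple(b for b in BLOCK_ORDER if b in self.block_durations)

    @property
    def total_duration(self) -> float:
        """Session length in seconds (18 min for the standard protocol)."""
        return float(sum(self.block_durations.values()))

    def block_onsets(self) -> dict[str, float]:
        """Onset time in seconds of each block, in protocol order."""
        onsets: dict[str, float] = {}
        t = 0.0
        for name in self.block_order:
            onsets[name] = t
            t += self.block_durations[name]
        return onsets

    def n_samples(self, block: str) -> int:
        return int(round(self.block_durations[block] * self.sampling_rate))


@dataclass(frozen=True)
class StressProfile:
    """Piecewise-smooth latent stress trajectory s(t) over one session.

    Shape: flat at a small resting baseline during RS1; exponential rise
    toward a moderate level during MIST training (onset time constant
    ``onset_tau``); continued monotone rise over the MIST task, normalised
    so that s(end of task) = 1; exponential decay during the first
    ``relax_dip_s`` seconds of the relaxation block (time constant
    ``relax_tau``), placing the trajectory minimum about two minutes into
    relaxation; then a slow linear drift back up (boredom / residual
    cognitive activity) and a return toward baseline in RS2.

    The resting baseline is strictly above the relaxation minimum: deep
    relaxation drives arousal below the ordinary eyes-closed resting level,
    which is what lets the group biomarker curve bottom out inside the
    relaxation block rather than in RS1.
    """

    protocol: ProtocolSpec = field(default_factory=ProtocolSpec)
    rest_level: float = 0.15
    train_target: float = 0.6
    onset_tau: float = 30.0
    task_tau: float = 120.0
    relax_tau: float = 45.0
    relax_dip_s: float = 120.0
    relax_end_level: float = 0.12

    def __post_init__(self) -> None:
        if not (0.0 <= self.rest_level < 1.0):
            raise ValueError("rest_level must lie in [0, 1)")
        if not (self.rest_level < self.train_target <= 1.0):
            raise ValueError("train_target must lie in (rest_level, 1]")
        for tau in (self.onset_tau, self.task_tau, self.relax_tau):
            if tau <= 0:
                raise ValueError("time constants must be positive")
        if not (0.0 <= self.relax_end_level <= 1.0):
            raise ValueError("relax_end_level must lie in [0, 1]")

    # -- closed-form pieces -------------------------------------------------

    def _train_end_level(self) -> float:
        d = self.protocol.block_durations["MIST_TRAIN"]
        return self.train_target + (self.rest_level - self.train_target) * math.exp(
            -d / self.onset_tau
        )

    def _task_asymptote(self) -> float:
        # chosen so the task piece ends exactly at 1
        d = self.protocol.block_durations["MIST_TASK"]
        s0 = self._train_end_level()
        e = math.exp(-d / self.task_tau)
        return (1.0 - s0 * e) / (1.0 - e)

    def _relax_end_level_actual(self) -> float:
        d = self.protocol.block_durations["RELAX"]
        dip = min(self.relax_dip_s, d)
        s_dip = math.exp(-dip / self.relax_tau)
        if d <= dip:
            return s_dip
        return self.relax_end_level

    def level(self, t):
        """Evaluate s(t) for scalar or array ``t`` (seconds from session start)."""
        t = np.asarray(t, dtype=float)
        total = self.protocol.total_duration
        if np.any(t < 0) or np.any(t > total):
            raise ValueError(f"t outside session [0, {total}] s")

        onsets = self.protocol.block_onsets()
        durs = self.protocol.block_durations
        out = np.full(t.shape, self.rest_level)

        # MIST training: exponential approach to train_target
        t0 = onsets["MIST_TRAIN"]
        m = (t >= t0) & (t < t0 + durs["MIST_TRAIN"])
        out[m] = self.train_target + (self.rest_level - self.train_target) * np.exp(
            -(t[m] - t0) / self.onset_tau
        )

        # MIST task: monotone rise, normalised to end exactly at 1
        t0 = onsets["MIST_TASK"]
        s0 = self._train_end_level()
        a = self._task_asymptote()
        m = (t >= t0) & (t < t0 + durs["MIST_TASK"])
        out[m] = a + (s0 - a) * np.exp(-(t[m] - t0) / self.task_tau)

        # Relaxation: exponential dip for the first relax_dip_s seconds,
        # then a slow linear drift up toward relax_end_level
        t0 = onsets["RELAX"]
        d = durs["RELAX"]
        dip = min(self.relax_dip_s, d)
        s_dip = math.exp(-dip / self.relax_tau)
        tr = t - t0
        m = (t >= t0) & (tr <= dip)
        out[m] = np.exp(-tr[m] / self.relax_tau)
        m = (t >= t0) & (tr > dip) & (t < t0 + d)
        if d > dip:
            slope = (self._relax_end_level_actual() - s_dip) / (d - dip)
            out[m] = s_dip + slope * (tr[m] - dip)

        # RS2: exponential return to the resting baseline
        t0 = onsets["RS2"]
        s0 = self._relax_end_level_actual()
        m = t >= t0
        out[m] = self.rest_level + (s0 - self.rest_level) * np.exp(
            -(t[m] - t0) / self.onset_tau
        )

        out = np.clip(out, 0.0, 1.0)
        return float(out) if out.ndim == 0 else out


def stress_profile_eval(profile: StressProfile, t) -> float:
    """Latent stress level at time ``t`` seconds; errors outside the session."""
    return profile.level(t)
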