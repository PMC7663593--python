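"""Reading and writing sessions, surveys and fixture sets.

Two session formats are supported: EDF+ with one annotation per protocol
block (read through MNE), and a long-format CSV with columns
``time_s, channel, value_uV, block``.  Survey responses travel as a CSV
with columns ``subject_id, group, T1..T4``; generator ground truth as JSON.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .edf import write_edf
from .preprocess import EEGSession, FormatError
from .protocol import BLOCK_ORDER, ProtocolSpec, StressProfile
from .synth import SubjectSpec, generate_session, generate_spsl

logger = logging.getLogger(__name__)

__all__ = [
    "load_session",
    "save_session_csv",
    "save_session_edf",
    "load_surveys",
    "write_fixture_set",
]

CSV_COLUMNS = ("time_s", "channel", "value_uV", "block")


def save_session_csv(session: EEGSession, path: str | Path) -> None:
    """Write a session as long-format CSV (one row per sample per channel)."""
    labels = session.channel_labels or tuple(
        f"ch{i}" for i in range(session.n_channels)
    )
    frames = []
    offset = 0.0
    for block, arr in session.blocks:
        n = arr.shape[1]
        t = offset + np.arange(n) / session.sampling_rate
        for ci, ch in enumerate(labels):
            frames.append(
                pd.DataFrame(
                    {"time_s": t, "channel": ch, "value_uV": arr[ci], "block": block}
                )
            )
        offset += n / session.sampling_rate
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.4f")


def save_session_edf(session: EEGSession, path: str | Path) -> None:
    """Write a session as EDF+ with one annotation per block."""
    data = np.concatenate([arr for _, arr in session.blocks], axis=1)
    annotations = []
    onset = 0.0
    for block, arr in session.blocks:
        dur = arr.shape[1] / session.sampling_rate
        annotations.append((onset, dur, block))
        onset += dur
    labels = session.channel_labels or tuple(
        f"ch{i}" for i in range(session.n_channels)
    )
    write_edf(
        path, data, session.sampling_rate, labels, annotations,
        patient_id=session.subject_id or "X",
    )


def _session_from_blocks(
    blocks: dict[str, np.ndarray],
    rate: float,
    subject_id: str,
    group: str,
    channel_labels: tuple[str, ...],
) -> EEGSession:
    missing = [b for b in BLOCK_ORDER if b not in blocks]
    if missing:
        raise FormatError(f"session is missing block(s): {', '.join(missing)}")
    unknown = [b for b in blocks if b not in BLOCK_ORDER]
    if unknown:
        logger.warning("ignoring unknown block annotation(s): %s", unknown)
    ordered = [(b, blocks[b]) for b in BLOCK_ORDER]
    return EEGSession(
        subject_id=subject_id, group=group, sampling_rate=rate,
        blocks=ordered, channel_labels=channel_labels,
    )


def _load_session_csv(path: Path, subject_id: str, group: str) -> EEGSession:
    df = pd.read_csv(path)
    missing_cols = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FormatError(f"CSV lacks column(s): {missing_cols}")
    channels = list(dict.fromkeys(df["channel"]))
    known = set(ProtocolSpec().channel_labels)
    for ch in channels:
        if ch not in known:
            logger.warning("unknown channel label %r retained", ch)
    times = np.sort(df["time_s"].unique())
    if len(times) < 2:
        raise FormatError("CSV holds fewer than two time points")
    rate = 1.0 / float(np.median(np.diff(times)))
    blocks: dict[str, np.ndarray] = {}
    for block, sub in df.groupby("block", sort=False):
        wide = sub.pivot_table(
            index="time_s", columns="channel", values="value_uV", sort=True
        )[channels]
        blocks[str(block)] = wide.to_numpy().T
    return _session_from_blocks(blocks, rate, subject_id, group, tuple(channels))


def _load_session_edf(path: Path, subject_id: str, group: str) -> EEGSession:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    rate = float(raw.info["sfreq"])
    data = raw.get_data() * 1e6  # volts -> uV
    channels = tuple(raw.ch_names)
    known = set(ProtocolSpec().channel_labels)
    for ch in channels:
        if ch not in known:
            logger.warning("unknown channel label %r retained", ch)
    blocks: dict[str, np.ndarray] = {}
    for ann in raw.annotations:
        label = ann["description"]
        if label not in BLOCK_ORDER:
            logger.warning("ignoring unknown annotation %r", label)
            continue
        start = int(round(ann["onset"] * rate))
        stop = start + int(round(ann["duration"] * rate))
        blocks[label] = data[:, start:stop]
    return _session_from_blocks(blocks, rate, subject_id, group, channels)


def load_session(
    path: str | Path,
    fmt: str | None = None,
    subject_id: str = "",
    group: str = "",
) -> EEGSession:
    """Load one annotated session from EDF or long CSV.

    ``fmt`` is inferred from the suffix when not given.  A file lacking any
    protocol block raises :class:`FormatError` naming the absent block(s).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "edf" if path.suffix.lower() == ".edf" else "csv"
    if not subject_id:
        subject_id = path.stem
    if fmt == "csv":
        return _load_session_csv(path, subject_id, group)
    if fmt == "edf":
        return _load_session_edf(path, subject_id, group)
    raise ValueError(f"unknown format {fmt!r}")


def load_surveys(path: str | Path) -> pd.DataFrame:
    """Read the surveys CSV (subject_id, group, T1..T4)."""
    df = pd.read_csv(path)
    required = ["subject_id", "group", "T1", "T2", "T3", "T4"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"surveys CSV lacks column(s): {missing}")
    return df


def write_fixture_set(
    cohort: list[SubjectSpec],
    out_dir: str | Path,
    protocol: ProtocolSpec | None = None,
    profile: StressProfile | None = None,
    fmt: str = "csv",
    spsl_means: tuple[float, float, float, float] = (2.0, 4.0, 2.0, 2.0),
    spsl_sd: float = 0.5,
    spsl_seed: int = 0,
) -> dict:
    """Generate and write a full fixture set; returns a manifest.

    One signal file per subject (CSV or EDF), a ``surveys.csv``, and a
    ``truth.json`` echoing each subject's ground-truth specification.
    """
    if fmt not in ("csv", "edf"):
        raise ValueError(f"unknown fixture format {fmt!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    protocol = protocol or ProtocolSpec()

    manifest: dict = {"sessions": [], "surveys": None, "truth": None}
    for subj in cohort:
        session = generate_session(protocol, subj, profile)
        p = out / f"{subj.subject_id}.{fmt}"
        if fmt == "csv":
            save_session_csv(session, p)
        else:
            save_session_edf(session, p)
        manifest["sessions"].append(str(p))

    if cohort:
        surveys = generate_spsl(cohort, spsl_means, spsl_sd, seed=spsl_seed)
        sp = out / "surveys.csv"
        surveys.to_csv(sp, index=False)
        manifest["surveys"] = str(sp)

        truth = {
            s.subject_id: {
                "group": s.group,
                "responder_polarity": s.responder_polarity,
                "modulation_depth": s.modulation_depth,
                "artifact_rate": s.artifact_rate,
                "line_noise_amplitude": s.line_noise_amplitude,
                "band_amplitudes": s.band_amplitudes,
                "seed": s.seed,
            }
            for s in cohort
        }
        tp = out / "truth.json"
        tp.write_text(json.dumps(truth, indent=2, sort_keys=True))
        manifest["truth"] = str(tp)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
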