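"""Minimal EDF+C writer for annotated multi-channel sessions.

Writes 16-bit European Data Format files with one data record per second
and an EDF Annotations channel carrying one annotation per protocol block
(onset + duration + label).  Only the subset of EDF+ needed for the
fixtures produced here is implemented: continuous recording, identical
sampling rate on every signal, integer record count.  Readers such as MNE
recover the samples to within the 16-bit quantisation step.
"""

from __future__ import annotations

import datetime
import math
from pathlib import Path

import numpy as np

__all__ = ["write_edf"]

_DIG_MIN, _DIG_MAX = -32768, 32767


def _ascii(value: str, width: int) -> bytes:
    b = value.encode("ascii")
    if len(b) > width:
        raise ValueError(f"field {value!r} exceeds {width} bytes")
    return b.ljust(width)


def write_edf(
    path: str | Path,
    data: np.ndarray,
    rate: float,
    channel_labels: list[str] | tuple[str, ...],
    annotations: list[tuple[float, float, str]],
    patient_id: str = "X",
) -> None:
    """Write ``data`` (channels x samples, uV) with block annotations.

    ``annotations`` is a list of (onset_s, duration_s, label).  The total
    duration and the sampling rate must both be whole numbers of
    seconds/samples so that one-second records tile the signal exactly.
    """
    path = Path(path)
    n_ch, n_samp = data.shape
    if len(channel_labels) != n_ch:
        raise ValueError("one label per channel required")
    spr = rate
    if abs(spr - round(spr)) > 1e-9:
        raise ValueError("sampling rate must be an integer for EDF output")
    spr = int(round(spr))
    n_records = math.ceil(n_samp / spr)
    padded = np.zeros((n_ch, n_records * spr), dtype=float)
    padded[:, :n_samp] = data

    # physical range: symmetric per-file so quantisation is uniform
    lim = float(np.abs(padded).max())
    lim = max(lim, 1.0) * 1.0001
    lim = float(f"{lim:.6g}")  # what the header will actually carry
    scale = (_DIG_MAX - _DIG_MIN) / (2 * lim)
    digital = np.rint((padded - (-lim)) * scale + _DIG_MIN).astype("<i2")

    # annotation TALs: record-keeping timestamp per record, block labels in
    # the record containing their onset
    tals: list[bytearray] = []
    for rec in range(n_records):
        tal = bytearray(f"+{rec}\x14\x14\x00".encode("ascii"))
        for onset, dur, label in annotations:
            if rec <= onset < rec + 1:
                tal += (
                    f"+{onset:g}\x15{dur:g}\x14{label}\x14\x00".encode("ascii")
                )
        tals.append(tal)
    ann_bytes = max(len(t) for t in tals)
    ann_spr = math.ceil(ann_bytes / 2) + 1  # 2-byte "samples", spare room

    n_signals = n_ch + 1
    header_bytes = 256 * (1 + n_signals)
    start = datetime.datetime(2020, 1, 1, 0, 0, 0)

    with open(path, "wb") as f:
        f.write(_ascii("0", 8))
        f.write(_ascii(patient_id, 80))
        f.write(_ascii("Startdate 01-JAN-2020 X X X", 80))
        f.write(_ascii(start.strftime("%d.%m.%y"), 8))
        f.write(_ascii(start.strftime("%H.%M.%S"), 8))
        f.write(_ascii(str(header_bytes), 8))
        f.write(_ascii("EDF+C", 44))
        f.write(_ascii(str(n_records), 8))
        f.write(_ascii("1", 8))
        f.write(_ascii(str(n_signals), 4))

        labels = [str(lab) for lab in channel_labels] + ["EDF Annotations"]
        for lab in labels:
            f.write(_ascii(lab, 16))
        for _ in labels:
            f.write(_ascii("", 80))  # transducer
        for i in range(n_signals):
            f.write(_ascii("uV" if i < n_ch else "", 8))
        for i in range(n_signals):
            f.write(_ascii(f"{-lim:.6g}" if i < n_ch else "-1", 8))
        for i in range(n_signals):
            f.write(_ascii(f"{lim:.6g}" if i < n_ch else "1", 8))
        for _ in range(n_signals):
            f.write(_ascii(str(_DIG_MIN), 8))
        for _ in range(n_signals):
            f.write(_ascii(str(_DIG_MAX), 8))
        for _ in labels:
            f.write(_ascii("", 80))  # prefiltering
        for i in range(n_signals):
            f.write(_ascii(str(spr if i < n_ch else ann_spr), 8))
        for _ in labels:
            f.write(_ascii("", 32))

        for rec in range(n_records):
            f.write(digital[:, rec * spr : (rec + 1) * spr].tobytes())
            tal = bytes(tals[rec]).ljust(2 * ann_spr, b"\x00")
            f.write(tal)
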