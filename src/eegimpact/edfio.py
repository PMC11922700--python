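"""Minimal European Data Format (EDF) reader/writer.

Implements the plain EDF profile used for continuous multichannel EEG: an
ASCII fixed-field header and 16-bit little-endian samples, physical
dimension microvolts. Enough to round-trip this package's recordings and
to ingest standard exports; EDF+ annotations and discontinuous files are
out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(text: str, width: int) -> bytes:
    s = str(text)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path, data: np.ndarray, fs: float, channel_names,
              record_duration_s: float = 1.0, patient_id: str = "X",
              recording_id: str = "synthetic") -> None:
    """Write (n_channels, n_samples) microvolt data as a standard EDF file.

    Samples are quantized to 16 bits over each channel's own physical
    range. The last data record is zero-padded if the signal length is not
    a whole number of records.
    """
    data = np.asarray(data, dtype=float)
    n_ch, n_samp = data.shape
    if len(channel_names) != n_ch:
        raise ValueError("channel_names must match data rows")
    spr = fs * record_duration_s
    if abs(spr - round(spr)) > 1e-9:
        raise ValueError("record duration must hold a whole number of samples")
    spr = int(round(spr))
    n_rec = math.ceil(n_samp / spr)

    phys_min = data.min(axis=1)
    phys_max = data.max(axis=1)
    flat = phys_max - phys_min == 0
    phys_max[flat] = phys_min[flat] + 1.0

    header = b"".join([
        _field("0", 8), _field(patient_id, 80), _field(recording_id, 80),
        _field("01.01.00", 8), _field("00.00.00", 8),
        _field(str(256 * (1 + n_ch)), 8), _field("", 44),
        _field(str(n_rec), 8),
        _field(f"{record_duration_s:g}", 8), _field(str(n_ch), 4),
    ])
    sig = b"".join(_field(nm, 16) for nm in channel_names)
    sig += b"".join(_field("AgAgCl electrode", 80) for _ in range(n_ch))
    sig += b"".join(_field("uV", 8) for _ in range(n_ch))
    sig += b"".join(_field(f"{v:.6g}", 8) for v in phys_min)
    sig += b"".join(_field(f"{v:.6g}", 8) for v in phys_max)
    sig += b"".join(_field(str(_DIG_MIN), 8) for _ in range(n_ch))
    sig += b"".join(_field(str(_DIG_MAX), 8) for _ in range(n_ch))
    sig += b"".join(_field("", 80) for _ in range(n_ch))
    sig += b"".join(_field(str(spr), 8) for _ in range(n_ch))
    sig += b"".join(_field("", 32) for _ in range(n_ch))

    scale = (_DIG_MAX - _DIG_MIN) / (phys_max - phys_min)
    padded = np.zeros((n_ch, n_rec * spr))
    padded[:, :n_samp] = data
    dig = np.rint((padded - phys_min[:, None]) * scale[:, None] + _DIG_MIN)
    dig = np.clip(dig, _DIG_MIN, _DIG_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header + sig)
        for r in range(n_rec):
            fh.write(dig[:, r * spr:(r + 1) * spr].tobytes())


@dataclass
class EdfFile:
    data: np.ndarray                 # (n_channels, n_samples) physical units
    fs: float
    channel_names: tuple[str, ...]
    record_duration_s: float


def read_edf(path) -> EdfFile:
    """Read a plain EDF file back into microvolt samples."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise ValueError("truncated EDF header")
        n_rec = int(head[236:244])
        rec_dur = float(head[244:252])
        n_ch = int(head[252:256])

        sig = fh.read(256 * n_ch)

        def col(offset: int, width: int) -> list[str]:
            start = offset * n_ch
            return [sig[start + i * width:start + (i + 1) * width]
                    .decode("ascii").strip() for i in range(n_ch)]

        names = tuple(col(0, 16))
        phys_min = np.array([float(v) for v in col(16 + 80 + 8, 8)])
        phys_max = np.array([float(v) for v in col(16 + 80 + 8 + 8, 8)])
        dig_min = np.array([float(v) for v in col(16 + 80 + 8 + 16, 8)])
        dig_max = np.array([float(v) for v in col(16 + 80 + 8 + 24, 8)])
        spr = [int(v) for v in col(16 + 80 + 8 + 32 + 80, 8)]
        if len(set(spr)) != 1:
            raise ValueError("mixed sampling rates are not supported")
        spr = spr[0]

        raw = np.frombuffer(fh.read(), dtype="<i2")
    raw = raw[:n_rec * n_ch * spr].reshape(n_rec, n_ch, spr)
    dig = raw.transpose(1, 0, 2).reshape(n_ch, n_rec * spr).astype(float)
    scale = (phys_max - phys_min) / (dig_max - dig_min)
    data = (dig - dig_min[:, None]) * scale[:, None] + phys_min[:, None]
    return EdfFile(data=data, fs=spr / rec_dur, channel_names=names,
                   record_duration_s=rec_dur)
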