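"""Minimal EDF (European Data Format) reading and writing.

Covers the plain EDF subset needed to ingest epoched recordings: an ASCII
header, equal samples-per-record across signals, 16-bit little-endian
samples scaled by the per-signal physical/digital calibration. Each data
record is exposed as one trial. EDF+ annotation channels and GDF dialects
are out of scope.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["read_edf", "write_edf"]

_HDR = 256  # fixed part of the header, bytes


def read_edf(path: str | Path) -> tuple[np.ndarray, float, list[str]]:
    """Read an EDF file.

    Returns
    -------
    data : (n_records, n_signals, n_samples_per_record) float array
        Samples in physical units (one record = one trial).
    fs : float
        Sampling rate in Hz.
    labels : list of str
        Signal (channel) names.
    """
    raw = Path(path).read_bytes()
    if len(raw) < _HDR:
        raise ValueError("not an EDF file: truncated header")

    def fx(lo: int, hi: int) -> str:
        return raw[lo:hi].decode("ascii", errors="replace").strip()

    n_records = int(fx(236, 244))
    record_dur = float(fx(244, 252))
    ns = int(fx(252, 256))
    off = _HDR

    def sig_field(width: int) -> list[str]:
        nonlocal off
        out = [raw[off + i * width: off + (i + 1) * width].decode("ascii").strip() for i in range(ns)]
        off += ns * width
        return out

    labels = sig_field(16)
    sig_field(80)  # transducer
    sig_field(8)  # physical dimension
    phys_min = np.array([float(v) for v in sig_field(8)])
    phys_max = np.array([float(v) for v in sig_field(8)])
    dig_min = np.array([float(v) for v in sig_field(8)])
    dig_max = np.array([float(v) for v in sig_field(8)])
    sig_field(80)  # prefiltering
    spr = [int(v) for v in sig_field(8)]
    sig_field(32)  # reserved
    if len(set(spr)) != 1:
        raise ValueError("mixed samples-per-record EDF not supported")
    nspr = spr[0]
    if record_dur <= 0:
        raise ValueError("invalid record duration")
    fs = nspr / record_dur

    payload = np.frombuffer(raw, dtype="<i2", offset=off)
    expected = n_records * ns * nspr
    if payload.size < expected:
        raise ValueError("EDF data shorter than header declares")
    data = payload[:expected].reshape(n_records, ns, nspr).astype(float)
    gain = (phys_max - phys_min) / (dig_max - dig_min)
    offset = phys_min - gain * dig_min
    data = data * gain[None, :, None] + offset[None, :, None]
    return data, fs, labels


def write_edf(path: str | Path, data: np.ndarray, fs: float, channel_names: list[str] | None = None) -> None:
    """Write (n_records, n_signals, n_samples_per_record) data as plain EDF.

    Quantizes to 16 bits over each signal's observed range; intended for
    round-trip tests and small exports, not clinical archiving.
    """
    data = np.asarray(data, dtype=float)
    n_records, ns, nspr = data.shape
    if channel_names is None:
        channel_names = [f"ch{i + 1:02d}" for i in range(ns)]
    phys_min = data.min(axis=(0, 2))
    phys_max = data.max(axis=(0, 2))
    span = np.where(phys_max > phys_min, phys_max - phys_min, 1.0)
    phys_max = phys_min + span
    dig_min, dig_max = -32768.0, 32767.0
    scaled = (data - phys_min[None, :, None]) / span[None, :, None]
    digital = np.round(scaled * (dig_max - dig_min) + dig_min).astype("<i2")

    def pad(s: str, width: int) -> bytes:
        b = s.encode("ascii")[:width]
        return b + b" " * (width - len(b))

    hdr = b"".join([
        pad("0", 8), pad("X", 80), pad("mibrainnet export", 80),
        pad("01.01.00", 8), pad("00.00.00", 8),
        pad(str(_HDR + ns * 256), 8), pad("", 44),
        pad(str(n_records), 8), pad(f"{nspr / fs:.6g}", 8), pad(str(ns), 4),
    ])
    cols: list[bytes] = []
    for width, values in [
        (16, channel_names), (80, [""] * ns), (8, ["uV"] * ns),
        (8, [f"{v:.6g}" for v in phys_min]), (8, [f"{v:.6g}" for v in phys_max]),
        (8, [f"{dig_min:.0f}"] * ns), (8, [f"{dig_max:.0f}"] * ns),
        (80, [""] * ns), (8, [str(nspr)] * ns), (32, [""] * ns),
    ]:
        cols.append(b"".join(pad(v, width) for v in values))
    Path(path).write_bytes(hdr + b"".join(cols) + digital.tobytes())
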