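"""Minimal WFDB reader/writer: format-16 signals, .hea headers, MIT-format
annotation files with rhythm aux strings.

Covers exactly what this package needs from the PhysioNet waveform-database
layout — multi-channel format-16 .dat files, gain/baseline conversion to
physical units, and rhythm-change ('+') annotations carrying aux strings
such as "(AFIB" — plus a writer for round-trip tests and synthetic corpora.
"""
from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

RHYTHM_CODE = 28  # '+' rhythm change annotation type
_AUX_CODE = 63
_SKIP_CODE = 59
_NUM_CODE, _SUB_CODE, _CHN_CODE = 60, 61, 62


class HeaderError(ValueError):
    """Malformed or inconsistent .hea header."""


@dataclass
class SignalInfo:
    filename: str
    fmt: int
    gain: float  # ADC units per physical unit
    baseline: int
    units: str
    description: str = ""


@dataclass
class WfdbRecord:
    name: str
    fs: float
    n_samples: int
    signals: List[SignalInfo]
    data: np.ndarray  # (n_samples, n_sig) raw ADC ints

    def physical(self, channel: int) -> np.ndarray:
        if not 0 <= channel < len(self.signals):
            raise IndexError(
                f"channel {channel} out of range for {len(self.signals)}-channel record"
            )
        info = self.signals[channel]
        return (self.data[:, channel].astype(float) - info.baseline) / info.gain


def _parse_gain_field(token: str) -> Tuple[float, Optional[int], str]:
    """Parse 'gain(baseline)/units'; any part may be absent."""
    units = "mV"
    baseline = None
    if "/" in token:
        token, units = token.split("/", 1)
    if "(" in token:
        token, rest = token.split("(", 1)
        baseline = int(rest.rstrip(")"))
    gain = float(token) if token else 200.0
    if gain == 0:
        gain = 200.0
    return gain, baseline, units


def read_header(hea_path) -> Tuple[str, float, int, List[SignalInfo]]:
    hea_path = Path(hea_path)
    lines = [
        ln.strip() for ln in hea_path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise HeaderError(f"{hea_path}: empty header")
    head = lines[0].split()
    if len(head) < 2:
        raise HeaderError(f"{hea_path}: malformed record line {lines[0]!r}")
    try:
        name = head[0].split("/")[0]
        n_sig = int(head[1])
        fs = float(head[2]) if len(head) > 2 else 250.0
        n_samples = int(head[3]) if len(head) > 3 else 0
    except ValueError as exc:
        raise HeaderError(f"{hea_path}: malformed record line {lines[0]!r}") from exc
    if n_sig < 1 or len(lines) < 1 + n_sig:
        raise HeaderError(f"{hea_path}: expected {n_sig} signal lines")
    signals = []
    for ln in lines[1:1 + n_sig]:
        parts = ln.split()
        if len(parts) < 2:
            raise HeaderError(f"{hea_path}: malformed signal line {ln!r}")
        try:
            fmt = int(parts[1].split("x")[0].split(":")[0].split("+")[0])
            gain, baseline, units = _parse_gain_field(parts[2]) if len(parts) > 2 \
                else (200.0, None, "mV")
            adc_zero = int(parts[4]) if len(parts) > 4 else 0
        except ValueError as exc:
            raise HeaderError(f"{hea_path}: malformed signal line {ln!r}") from exc
        signals.append(
            SignalInfo(
                filename=parts[0], fmt=fmt, gain=gain,
                baseline=baseline if baseline is not None else adc_zero,
                units=units,
                description=" ".join(parts[9:]) if len(parts) > 9 else "",
            )
        )
    return name, fs, n_samples, signals


def read_record(path) -> WfdbRecord:
    """Read a WFDB record given the path to its .hea file (or its stem)."""
    path = Path(path)
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(f"header not found: {hea}")
    name, fs, n_samples, signals = read_header(hea)
    fmts = {s.fmt for s in signals}
    if fmts - {16}:
        raise HeaderError(f"unsupported signal format(s) {sorted(fmts - {16})}; "
                          "only format 16 is supported")
    # all this package writes/reads share one .dat per record
    dat = hea.parent / signals[0].filename
    if not dat.exists():
        raise FileNotFoundError(f"signal file not found: {dat}")
    raw = np.fromfile(dat, dtype="<i2")
    n_sig = len(signals)
    if n_samples and raw.size < n_samples * n_sig:
        raise HeaderError(
            f"{dat}: signal file holds {raw.size} samples, header promises "
            f"{n_samples * n_sig}"
        )
    if not n_samples:
        n_samples = raw.size // n_sig
    data = raw[: n_samples * n_sig].reshape(n_samples, n_sig)
    return WfdbRecord(name=name, fs=fs, n_samples=n_samples, signals=signals,
                      data=data)


def write_record(
    directory,
    name: str,
    fs: float,
    physical: np.ndarray,
    gain: float = 200.0,
    units: str = "mV",
) -> Path:
    """Write a (n_samples, n_sig) physical-unit array as a format-16 record."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    physical = np.atleast_2d(np.asarray(physical, dtype=float))
    if physical.shape[0] < physical.shape[1]:
        physical = physical.T
    n_samples, n_sig = physical.shape
    digital = np.clip(np.round(physical * gain), -32768, 32767).astype("<i2")
    dat_name = f"{name}.dat"
    digital.reshape(-1).tofile(directory / dat_name)
    lines = [f"{name} {n_sig} {fs:g} {n_samples}"]
    for ch in range(n_sig):
        lines.append(f"{dat_name} 16 {gain:g}(0)/{units} 16 0 0 0 0 ch{ch}")
    (directory / f"{name}.hea").write_text("\n".join(lines) + "\n")
    return directory / f"{name}.hea"


# --------------------------------------------------------------------------
# MIT-format annotations
# --------------------------------------------------------------------------

def read_annotations(atr_path) -> List[Tuple[int, int, str]]:
    """Read (sample, type_code, aux_string) triples from a .atr file."""
    atr_path = Path(atr_path)
    if not atr_path.exists():
        raise FileNotFoundError(f"annotation file not found: {atr_path}")
    buf = atr_path.read_bytes()
    out: List[Tuple[int, int, str]] = []
    t = 0
    i = 0
    pending_aux = ""
    while i + 1 < len(buf):
        word = buf[i] | (buf[i + 1] << 8)
        i += 2
        code = word >> 10
        delta = word & 0x3FF
        if word == 0:  # EOF
            break
        if code == _SKIP_CODE:
            if i + 3 >= len(buf):
                break
            hi = buf[i] | (buf[i + 1] << 8)
            lo = buf[i + 2] | (buf[i + 3] << 8)
            i += 4
            interval = (hi << 16) | lo
            if interval >= 1 << 31:
                interval -= 1 << 32
            t += interval
            continue
        if code in (_NUM_CODE, _SUB_CODE, _CHN_CODE):
            continue
        if code == _AUX_CODE:
            n = delta
            aux = buf[i:i + n].rstrip(b"\x00").decode("ascii", errors="replace")
            i += n + (n % 2)
            if out:
                samp, c, _ = out[-1]
                out[-1] = (samp, c, aux)
            continue
        t += delta
        out.append((t, code, ""))
    return out


def write_annotations(
    atr_path, annotations: Sequence[Tuple[int, int, str]]
) -> None:
    """Write (sample, type_code, aux_string) triples as a .atr file."""
    parts = bytearray()
    prev = 0
    for samp, code, aux in annotations:
        delta = int(samp) - prev
        if delta < 0:
            raise ValueError("annotation samples must be non-decreasing")
        if delta >= 1024:
            parts += struct.pack("<H", _SKIP_CODE << 10)
            parts += struct.pack("<HH", (delta >> 16) & 0xFFFF, delta & 0xFFFF)
            delta = 0
        parts += struct.pack("<H", (code << 10) | delta)
        if aux:
            raw = aux.encode("ascii")
            parts += struct.pack("<H", (_AUX_CODE << 10) | len(raw))
            parts += raw
            if len(raw) % 2:
                parts += b"\x00"
        prev = int(samp)
    parts += struct.pack("<H", 0)  # EOF
    Path(atr_path).write_bytes(bytes(parts))
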