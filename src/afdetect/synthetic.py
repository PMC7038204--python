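"""Seeded synthetic single-lead ECG generator.

Produces normal sinus rhythm (NSR), atrial fibrillation (AF) and
noise-dominated recordings with ground-truth R positions, standing in for a
hardware ECG bench simulator so that every pipeline stage can be verified
without external data.

The beat template is a sum of Gaussian bumps: a P wave, a Q/R/S complex and a
T wave.  NSR draws RR intervals from a truncated normal with a small
coefficient of variation; AF omits the P wave, draws highly variable RR
intervals i.i.d. and adds a low-amplitude fibrillatory baseline oscillation
with a drifting 4-9 Hz frequency; the noise class contains no coherent beats,
only a white + mains + baseline-wander mixture.
"""
from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Tuple

import numpy as np

from .containers import EcgRecording, RhythmLabel


class Rhythm(str, enum.Enum):
    NSR = "nsr"
    AF = "af"
    NOISE = "noise"


#: Minimum admissible RR interval in seconds (truncation floor).
RR_FLOOR_S = 0.3

# Template geometry (seconds relative to the R peak) and relative amplitudes.
_P_CENTER, _P_SIGMA = -0.16, 0.025
_Q_CENTER, _Q_SIGMA, _Q_REL = -0.022, 0.008, -0.10
_R_SIGMA = 0.010
_S_CENTER, _S_SIGMA, _S_REL = 0.022, 0.008, -0.15
_T_CENTER, _T_SIGMA, _T_REL = 0.26, 0.045, 0.25

_FIB_AMPLITUDE_MV = 0.05  # fibrillatory baseline oscillation


class SpecValidationError(ValueError):
    """A SyntheticSpec field violates its invariant; names the field."""

    def __init__(self, fieldname: str, message: str) -> None:
        self.fieldname = fieldname
        super().__init__(f"{fieldname}: {message}")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic recording.

    ``rr_cv`` is the coefficient of variation of the RR intervals
    (dimensionless); AF requires ``rr_cv >= 0.15`` and ``p_amplitude_mV = 0``.
    ``p_amplitude_mV=None`` resolves to the rhythm default (0.15 for NSR,
    0 otherwise), and ``rr_cv=None`` to 0.03 for NSR / 0.25 for AF.
    """

    rhythm: Rhythm
    duration_s: float = 30.0
    fs: float = 250.0
    heart_rate_bpm: float = 80.0
    r_amplitude_mV: float = 1.0
    p_amplitude_mV: Optional[float] = None
    rr_cv: Optional[float] = None
    noise_sd_mV: float = 0.02
    seed: int = 0

    def resolved(self) -> "SyntheticSpec":
        """Fill rhythm-dependent defaults and validate all invariants."""
        rhythm = Rhythm(self.rhythm)
        p = self.p_amplitude_mV
        if p is None:
            p = 0.15 if rhythm is Rhythm.NSR else 0.0
        cv = self.rr_cv
        if cv is None:
            cv = {Rhythm.NSR: 0.03, Rhythm.AF: 0.25, Rhythm.NOISE: 0.0}[rhythm]
        spec = replace(self, rhythm=rhythm, p_amplitude_mV=p, rr_cv=cv)
        spec._validate()
        return spec

    def _validate(self) -> None:
        if self.duration_s <= 0:
            raise SpecValidationError("duration_s", "must be > 0")
        if self.fs <= 0:
            raise SpecValidationError("fs", "must be > 0")
        if not 20 <= self.heart_rate_bpm <= 300:
            raise SpecValidationError("heart_rate_bpm", "must lie in [20, 300]")
        if self.noise_sd_mV < 0:
            raise SpecValidationError("noise_sd_mV", "must be >= 0")
        if self.rhythm is Rhythm.AF:
            if self.p_amplitude_mV != 0:
                raise SpecValidationError(
                    "p_amplitude_mV", "must be 0 for AF (no P waves)"
                )
            if self.rr_cv is not None and self.rr_cv < 0.15:
                raise SpecValidationError("rr_cv", "must be >= 0.15 for AF")
        if self.rr_cv is not None and self.rr_cv < 0:
            raise SpecValidationError("rr_cv", "must be >= 0")


@dataclass
class GroundTruth:
    """True beat locations and label for a synthetic recording."""

    r_positions: np.ndarray  # sample indices, strictly increasing
    rr_s: np.ndarray  # true RR intervals in seconds
    p_amplitudes_mV: np.ndarray  # per-beat P amplitude
    label: RhythmLabel

    def to_json(self) -> str:
        return json.dumps(
            {
                "r_positions": [int(i) for i in self.r_positions],
                "rr_s": [float(v) for v in self.rr_s],
                "p_amplitudes_mV": [float(v) for v in self.p_amplitudes_mV],
                "label": self.label.value,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            r_positions=np.asarray(d["r_positions"], dtype=int),
            rr_s=np.asarray(d["rr_s"], dtype=float),
            p_amplitudes_mV=np.asarray(d["p_amplitudes_mV"], dtype=float),
            label=RhythmLabel(d["label"]),
        )


_RHYTHM_TO_LABEL = {
    Rhythm.NSR: RhythmLabel.NORMAL,
    Rhythm.AF: RhythmLabel.AF,
    Rhythm.NOISE: RhythmLabel.NOISY,
}


def _gauss(t: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / sigma) ** 2)


def _draw_rr(rng: np.random.Generator, mean_rr: float, cv: float, n: int) -> np.ndarray:
    """Truncated-normal RR intervals with floor RR_FLOOR_S."""
    if cv == 0:
        return np.full(n, mean_rr)
    sd = cv * mean_rr
    rr = rng.normal(mean_rr, sd, size=n)
    # redraw below the floor rather than clipping, to avoid a point mass
    bad = rr < RR_FLOOR_S
    while np.any(bad):
        rr[bad] = rng.normal(mean_rr, sd, size=int(bad.sum()))
        bad = rr < RR_FLOOR_S
    return rr


def generate(spec: SyntheticSpec) -> Tuple[EcgRecording, GroundTruth]:
    """Generate one synthetic recording plus its ground truth.

    The output is bit-identical for identical specs (including seed).
    """
    spec = spec.resolved()
    rng = np.random.default_rng(spec.seed)
    n = int(math.floor(spec.duration_s * spec.fs))
    t = np.arange(n) / spec.fs
    x = np.zeros(n)

    if spec.rhythm is Rhythm.NOISE:
        x += rng.normal(0.0, max(spec.noise_sd_mV, 0.3), size=n)
        x += 0.2 * np.sin(2 * np.pi * 50.0 * t + rng.uniform(0, 2 * np.pi))
        x += 0.4 * np.sin(2 * np.pi * rng.uniform(0.2, 0.6) * t + rng.uniform(0, 2 * np.pi))
        gt = GroundTruth(
            r_positions=np.empty(0, dtype=int),
            rr_s=np.empty(0),
            p_amplitudes_mV=np.empty(0),
            label=RhythmLabel.NOISY,
        )
        rec = EcgRecording(x, spec.fs, record_id=f"syn-noise-{spec.seed}",
                           label=RhythmLabel.NOISY)
        return rec, gt

    mean_rr = 60.0 / spec.heart_rate_bpm
    # draw generously more beats than fit, then keep those inside the trace
    n_draw = int(spec.duration_s / RR_FLOOR_S) + 2
    rr = _draw_rr(rng, mean_rr, float(spec.rr_cv), n_draw)
    beat_times = 0.6 + np.cumsum(np.concatenate(([0.0], rr)))
    keep = beat_times < spec.duration_s - 1.0 / spec.fs
    beat_times = beat_times[keep]
    r_positions = np.round(beat_times * spec.fs).astype(int)
    r_positions = r_positions[r_positions < n]

    amp = spec.r_amplitude_mV
    p_amp = float(spec.p_amplitude_mV)
    for bt in r_positions / spec.fs:
        lo = max(0, int((bt - 0.45) * spec.fs))
        hi = min(n, int((bt + 0.55) * spec.fs))
        tl = t[lo:hi] - bt
        beat = amp * _gauss(tl, 0.0, _R_SIGMA)
        beat += amp * _Q_REL * _gauss(tl, _Q_CENTER, _Q_SIGMA)
        beat += amp * _S_REL * _gauss(tl, _S_CENTER, _S_SIGMA)
        beat += amp * _T_REL * _gauss(tl, _T_CENTER, _T_SIGMA)
        if p_amp:
            beat += p_amp * _gauss(tl, _P_CENTER, _P_SIGMA)
        x[lo:hi] += beat

    if spec.rhythm is Rhythm.AF:
        # fibrillatory baseline: sinusoid with slowly drifting 4-9 Hz frequency
        freq = np.clip(
            6.5 + np.cumsum(rng.normal(0, 0.05, size=n)), 4.0, 9.0
        )
        phase = 2 * np.pi * np.cumsum(freq) / spec.fs
        x += _FIB_AMPLITUDE_MV * np.sin(phase + rng.uniform(0, 2 * np.pi))

    if spec.noise_sd_mV > 0:
        x += rng.normal(0.0, spec.noise_sd_mV, size=n)

    true_rr = np.diff(r_positions) / spec.fs
    gt = GroundTruth(
        r_positions=r_positions,
        rr_s=true_rr,
        p_amplitudes_mV=np.full(r_positions.size, p_amp),
        label=_RHYTHM_TO_LABEL[spec.rhythm],
    )
    rec = EcgRecording(
        x, spec.fs,
        record_id=f"syn-{spec.rhythm.value}-{spec.seed}",
        label=gt.label,
    )
    return rec, gt


def verification_preset(seed: int = 2020) -> SyntheticSpec:
    """Bench-verification preset: 30 s NSR, 80 BPM, 1.0 mV R amplitude, 250 Hz.

    Mirrors the signal-generator settings used to verify the acquisition
    chain on hardware.
    """
    return SyntheticSpec(
        rhythm=Rhythm.NSR,
        duration_s=30.0,
        fs=250.0,
        heart_rate_bpm=80.0,
        r_amplitude_mV=1.0,
        seed=seed,
    )


def write_csv(rec: EcgRecording, gt: Optional[GroundTruth], path) -> None:
    """Write a recording as CSV (time_s, voltage_mV) with a JSON ground-truth
    sidecar at ``<path>.gt.json`` when ground truth is given."""
    path = Path(path)
    times = rec.times()
    with open(path, "w") as fh:
        fh.write("time_s,voltage_mV\n")
        for ts, v in zip(times, rec.samples):
            fh.write(f"{ts:.6f},{v:.6f}\n")
    if gt is not None:
        Path(str(path) + ".gt.json").write_text(gt.to_json())


def make_benchmark(
    n_segments: int,
    seed: int = 0,
    class_weights: Tuple[float, float, float] = (0.4, 0.4, 0.2),
    duration_s: float = 30.0,
):
    """Generate a labeled corpus of NSR / AF / noise segments.

    Heart rate, amplitudes, RR variability and noise level vary per segment
    within realistic ambulatory ranges so the corpus is not a single template
    repeated.  Returns ``(recordings, ground_truths)``.
    """
    rng = np.random.default_rng(seed)
    choices = (Rhythm.NSR, Rhythm.AF, Rhythm.NOISE)
    rhythms = [choices[i] for i in rng.choice(3, size=n_segments, p=class_weights)]
    recs, gts = [], []
    for i, rhythm in enumerate(rhythms):
        sub = int(rng.integers(0, 2**31 - 1))
        if rhythm is Rhythm.NSR:
            spec = SyntheticSpec(
                rhythm=Rhythm.NSR,
                duration_s=duration_s,
                heart_rate_bpm=float(rng.uniform(55, 100)),
                r_amplitude_mV=float(rng.uniform(0.6, 1.4)),
                p_amplitude_mV=float(rng.uniform(0.1, 0.2)),
                rr_cv=float(rng.uniform(0.01, 0.06)),
                noise_sd_mV=float(rng.uniform(0.005, 0.04)),
                seed=sub,
            )
        elif rhythm is Rhythm.AF:
            spec = SyntheticSpec(
                rhythm=Rhythm.AF,
                duration_s=duration_s,
                heart_rate_bpm=float(rng.uniform(60, 140)),
                r_amplitude_mV=float(rng.uniform(0.6, 1.4)),
                p_amplitude_mV=0.0,
                rr_cv=float(rng.uniform(0.18, 0.35)),
                noise_sd_mV=float(rng.uniform(0.005, 0.04)),
                seed=sub,
            )
        else:
            spec = SyntheticSpec(
                rhythm=Rhythm.NOISE,
                duration_s=duration_s,
                noise_sd_mV=float(rng.uniform(0.3, 0.6)),
                seed=sub,
            )
        rec, gt = generate(spec)
        rec.record_id = f"bench-{i:04d}-{rhythm.value}"
        recs.append(rec)
        gts.append(gt)
    return recs, gts
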