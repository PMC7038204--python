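"""The 31-dimensional hand-crafted feature vector for 30 s ECG segments.

Four groups:

* AF features (3) — RR-irregularity statistics: a Lorenz-histogram evidence
  score, the Shannon entropy of the dRR histogram, and a two-sample
  Kolmogorov-Smirnov statistic against a reference AF dRR distribution.
* Morphology features (20) — ten interval/amplitude kinds, each estimated two
  ways: variant E from the average beat, variant O as the per-beat median.
* RR-interval features (5) — median RR, a knowledge-based arrhythmia index,
  plus mean RR, RMSSD and pNN50 (flagged ``gap_fill`` in metadata).
* Noise features (3) — mean pairwise QRS correlation, the fraction of beats
  with a quiet isoelectric window, and the Q-R upstroke smoothness count.

Every code path yields exactly 31 finite values: operations that cannot be
computed (too few beats, failed delineation) fall back to documented
noise-leaning imputation defaults instead of propagating NaN.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sstats
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import EcgRecording, RhythmLabel
from .preprocess import (
    BeatSeries,
    FilterSpec,
    InsufficientBeatsError,
    bandpass_filter,
    build_beat_series,
    detect_r_peaks,
)

# --------------------------------------------------------------------------
# canonical feature manifest
# --------------------------------------------------------------------------

_MORPH_KINDS = (
    "qrs_duration_s",
    "pr_interval_s",
    "qt_interval_s",
    "qs_interval_s",
    "st_amplitude_mV",
    "p_amplitude_mV",
    "q_amplitude_mV",
    "r_amplitude_mV",
    "s_amplitude_mV",
    "t_amplitude_mV",
)

FEATURE_NAMES: Tuple[str, ...] = (
    ("af_evidence", "shannon_entropy_drr", "ks_statistic")
    + tuple(f"{k}_E" for k in _MORPH_KINDS)
    + tuple(f"{k}_O" for k in _MORPH_KINDS)
    + ("median_rr_s", "index_of_arrhythmia", "mean_rr_s", "rmssd_s", "pnn50")
    + ("qrs_similarity", "signal_quality_index", "qr_smoothness_index")
)
assert len(FEATURE_NAMES) == 31

#: RR statistics added to reach the full 31-feature dimensionality.
GAP_FILL_FEATURES = frozenset({"mean_rr_s", "rmssd_s", "pnn50"})

#: Values substituted when a feature cannot be computed.  Failure modes are
#: noise-like, so the defaults push toward the Noisy class rather than
#: fabricating physiology (KS distance maximal, similarity/quality zero).
IMPUTATION_DEFAULTS: Dict[str, float] = {name: 0.0 for name in FEATURE_NAMES}
IMPUTATION_DEFAULTS["ks_statistic"] = 1.0


class DelineationError(ValueError):
    """Wave delineation failed for a beat or average beat."""


# --------------------------------------------------------------------------
# AF features
# --------------------------------------------------------------------------

LORENZ_BIN_WIDTH_S = 0.040
LORENZ_EXTENT_S = 0.600
_ORIGIN_HALF_S = 0.080  # origin box half-width
_INNER_OUTER_S = 0.240  # inner/outer split of the axis arms


@dataclass
class LorenzHistogram:
    """2D histogram of consecutive dRR pairs with a 13-region partition.

    Region codes: 0 origin box; 1-4 quadrant zones (++, -+, --, +-);
    5-12 axis arms split into inner and outer halves.
    """

    counts: np.ndarray  # (nbins, nbins) ints, x = dRR[i-1], y = dRR[i]
    bin_width_s: float
    extent_s: float
    region_map: np.ndarray  # (nbins, nbins) ints in 0..12

    @property
    def point_count(self) -> int:
        return int(self.counts.sum())


def _lorenz_region_map(nbins: int, bin_width: float, extent: float) -> np.ndarray:
    centers = -extent + (np.arange(nbins) + 0.5) * bin_width
    cx, cy = np.meshgrid(centers, centers, indexing="ij")
    region = np.zeros((nbins, nbins), dtype=int)
    in_x = np.abs(cx) < _ORIGIN_HALF_S
    in_y = np.abs(cy) < _ORIGIN_HALF_S
    quad = ~in_x & ~in_y
    region[quad & (cx > 0) & (cy > 0)] = 1
    region[quad & (cx < 0) & (cy > 0)] = 2
    region[quad & (cx < 0) & (cy < 0)] = 3
    region[quad & (cx > 0) & (cy < 0)] = 4
    # axis arms: right, top, left, bottom; inner then outer
    arm = ~in_x & in_y & (cx > 0)
    region[arm & (np.abs(cx) < _INNER_OUTER_S)] = 5
    region[arm & (np.abs(cx) >= _INNER_OUTER_S)] = 6
    arm = in_x & ~in_y & (cy > 0)
    region[arm & (np.abs(cy) < _INNER_OUTER_S)] = 7
    region[arm & (np.abs(cy) >= _INNER_OUTER_S)] = 8
    arm = ~in_x & in_y & (cx < 0)
    region[arm & (np.abs(cx) < _INNER_OUTER_S)] = 9
    region[arm & (np.abs(cx) >= _INNER_OUTER_S)] = 10
    arm = in_x & ~in_y & (cy < 0)
    region[arm & (np.abs(cy) < _INNER_OUTER_S)] = 11
    region[arm & (np.abs(cy) >= _INNER_OUTER_S)] = 12
    return region


def lorenz_histogram(drr_s: np.ndarray) -> LorenzHistogram:
    """Histogram of (dRR[i-1], dRR[i]) pairs; out-of-range points are clipped
    to the edge bins so the total count is conserved."""
    drr_s = np.asarray(drr_s, dtype=float)
    if drr_s.size < 2:
        raise InsufficientBeatsError("need >= 2 dRR values for a Lorenz histogram")
    nbins = int(round(2 * LORENZ_EXTENT_S / LORENZ_BIN_WIDTH_S))
    x, y = drr_s[:-1], drr_s[1:]

    def to_bin(v: np.ndarray) -> np.ndarray:
        idx = np.floor((v + LORENZ_EXTENT_S) / LORENZ_BIN_WIDTH_S).astype(int)
        return np.clip(idx, 0, nbins - 1)

    counts = np.zeros((nbins, nbins), dtype=int)
    np.add.at(counts, (to_bin(x), to_bin(y)), 1)
    return LorenzHistogram(
        counts=counts,
        bin_width_s=LORENZ_BIN_WIDTH_S,
        extent_s=LORENZ_EXTENT_S,
        region_map=_lorenz_region_map(nbins, LORENZ_BIN_WIDTH_S, LORENZ_EXTENT_S),
    )


def af_evidence(beat_series: BeatSeries) -> int:
    """Lorenz-histogram AF evidence score.

    ``IrregularityEvidence - OriginCount - 2 * PACEvidence`` where
    IrregularityEvidence is the number of occupied bins outside the origin
    box, OriginCount the number of points inside it, and PACEvidence the
    excess of points in the short-long alternation quadrants (2 and 4) over
    the symmetric quadrants (1 and 3) — the signature of ectopy patterns
    (bigeminy/trigeminy) rather than sustained irregularity.
    """
    hist = lorenz_histogram(beat_series.drr_s)
    region = hist.region_map
    counts = hist.counts
    origin_count = int(counts[region == 0].sum())
    irregularity = int(np.count_nonzero(counts[region != 0]))
    n24 = int(counts[(region == 2) | (region == 4)].sum())
    n13 = int(counts[(region == 1) | (region == 3)].sum())
    pac = max(0, n24 - n13)
    return irregularity - origin_count - 2 * pac


ENTROPY_BINS = 16
ENTROPY_RANGE_S = (-0.5, 0.5)


def shannon_entropy_drr(beat_series: BeatSeries) -> float:
    """Shannon entropy (natural log) of a fixed 16-bin dRR histogram.

    dRR values are clipped to [-0.5, 0.5] s so extreme intervals land in the
    edge bins; empty bins contribute zero.
    """
    drr = np.asarray(beat_series.drr_s, dtype=float)
    if drr.size < 2:
        raise InsufficientBeatsError("need >= 2 dRR values for entropy")
    clipped = np.clip(drr, *ENTROPY_RANGE_S)
    counts, _ = np.histogram(clipped, bins=ENTROPY_BINS, range=ENTROPY_RANGE_S)
    p = counts[counts > 0] / counts.sum()
    return float(-np.sum(p * np.log(p)))


@dataclass
class KsReference:
    """Sorted reference sample of normalized dRR values characterizing AF."""

    values: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.sort(np.asarray(self.values, dtype=float))
        if self.values.size == 0:
            raise ValueError("KS reference must be non-empty")


def normalized_drr(beat_series: BeatSeries) -> np.ndarray:
    """dRR divided by the median RR interval (rate normalization)."""
    med = float(np.median(beat_series.rr_s))
    if med <= 0:
        raise ValueError("median RR must be positive")
    return np.asarray(beat_series.drr_s, dtype=float) / med


def ks_statistic(beat_series: BeatSeries, reference: KsReference) -> float:
    """Two-sample Kolmogorov-Smirnov statistic sup|F_rec - F_ref| between the
    recording's normalized dRR sample and the AF reference."""
    sample = normalized_drr(beat_series)
    if sample.size < 2:
        raise InsufficientBeatsError("need >= 2 dRR values for the KS statistic")
    return float(sstats.ks_2samp(sample, reference.values).statistic)


def build_ks_reference(
    af_beat_series: Iterable[BeatSeries], provenance: str = "pooled-AF-training"
) -> KsReference:
    """Pool normalized dRR values from AF-labeled training series."""
    pooled: List[np.ndarray] = [normalized_drr(bs) for bs in af_beat_series]
    if not pooled:
        raise ValueError("cannot build a KS reference from an empty collection")
    return KsReference(np.concatenate(pooled), provenance=provenance)


def default_ks_reference() -> KsReference:
    """Synthetic fallback reference built from seeded AF generator output.

    Used when a feature extractor is fitted on data containing no AF
    recordings (labelled ``synthetic`` in its provenance).
    """
    from . import synthetic  # deferred: avoid import cycle

    series = []
    for seed in range(8):
        rec, gt = synthetic.generate(
            synthetic.SyntheticSpec(
                rhythm=synthetic.Rhythm.AF, duration_s=60.0, seed=9000 + seed
            )
        )
        series.append(build_beat_series(gt.r_positions, rec.fs))
    return build_ks_reference(series, provenance="synthetic-af-generator")


# --------------------------------------------------------------------------
# morphology features
# --------------------------------------------------------------------------

BEAT_WINDOW_S = (-0.3, 0.5)  # delineation window around R


@dataclass
class AverageBeat:
    """R-aligned mean beat waveform with delineated fiducial offsets.

    ``fiducials`` maps {p, qrs_onset, q, r, s, qrs_offset, t} to sample
    offsets inside ``waveform``; ``iso_level_mV`` is the isoelectric baseline
    (mean of the [-90, -70] ms window before R).
    """

    waveform: np.ndarray
    fs: float
    fiducials: Dict[str, int]
    iso_level_mV: float
    n_beats: int


def _delineate(window: np.ndarray, fs: float, center: int) -> Tuple[Dict[str, int], float]:
    """Locate fiducials in an R-aligned beat window.

    Q = minimum in [-60, 0] ms before R; S = minimum in [0, 80] ms after;
    QRS onset/offset = where |slope| falls below 10% of the max |slope|
    scanning outward from Q/S; P = maximum in [-250, -80] ms; T = extremum of
    larger magnitude in [+120, +400] ms.  Raises DelineationError when the
    fiducial ordering P < onset <= Q < R < S <= offset < T cannot be met.
    """
    ms = lambda v: int(round(v * fs / 1000.0))
    n = window.size
    # R: extremum near the alignment point
    lo, hi = max(0, center - ms(20)), min(n, center + ms(20) + 1)
    r = lo + int(np.argmax(window[lo:hi]))
    q_lo = max(0, r - ms(60))
    q = q_lo + int(np.argmin(window[q_lo:r])) if r > q_lo else r - 1
    s_hi = min(n, r + ms(80) + 1)
    s = r + 1 + int(np.argmin(window[r + 1:s_hi])) if s_hi > r + 1 else r + 1
    if not q < r < s:
        raise DelineationError("Q/R/S ordering failed")

    slope = np.diff(window)
    max_slope = float(np.max(np.abs(slope[max(q - 1, 0):s]))) if s > q else 0.0
    if max_slope <= 0:
        raise DelineationError("flat QRS segment")
    thr = 0.10 * max_slope
    onset = q
    while onset > 0 and abs(slope[onset - 1]) >= thr:
        onset -= 1
    offset = s
    while offset < n - 1 and abs(slope[offset]) >= thr:
        offset += 1

    p_lo, p_hi = r - ms(250), r - ms(80)
    if p_lo < 0:
        raise DelineationError("window too short before R for P search")
    p = p_lo + int(np.argmax(window[p_lo:p_hi]))
    iso_lo, iso_hi = r - ms(90), r - ms(70)
    iso = float(np.mean(window[iso_lo:iso_hi]))
    t_lo, t_hi = r + ms(120), r + ms(400)
    if t_hi > n:
        raise DelineationError("window too short after R for T search")
    seg = window[t_lo:t_hi]
    t_idx = t_lo + int(np.argmax(np.abs(seg - iso)))

    fid = {"p": p, "qrs_onset": onset, "q": q, "r": r, "s": s,
           "qrs_offset": offset, "t": t_idx}
    if not (fid["p"] < fid["qrs_onset"] <= fid["q"] < fid["r"] < fid["s"]
            <= fid["qrs_offset"] < fid["t"]):
        raise DelineationError(f"fiducial ordering violated: {fid}")
    return fid, iso


def _beat_windows(recording: EcgRecording, r_indices: np.ndarray) -> Tuple[np.ndarray, int]:
    """Stack of full R-aligned windows [-0.3, +0.5] s; returns (windows, center)."""
    fs = recording.fs
    before = int(round(-BEAT_WINDOW_S[0] * fs))
    after = int(round(BEAT_WINDOW_S[1] * fs))
    rows = []
    for r in np.asarray(r_indices, dtype=int):
        if r - before >= 0 and r + after <= recording.n_samples:
            rows.append(recording.samples[r - before:r + after])
    if not rows:
        return np.empty((0, before + after)), before
    return np.vstack(rows), before


def average_beat(recording: EcgRecording, r_indices: np.ndarray) -> AverageBeat:
    """Mean R-aligned beat with delineated fiducials (needs >= 3 full beats)."""
    windows, center = _beat_windows(recording, r_indices)
    if windows.shape[0] < 3:
        raise InsufficientBeatsError(
            f"need >= 3 beats with full windows, got {windows.shape[0]}"
        )
    mean_beat = windows.mean(axis=0)
    fid, iso = _delineate(mean_beat, recording.fs, center)
    return AverageBeat(
        waveform=mean_beat, fs=recording.fs, fiducials=fid,
        iso_level_mV=iso, n_beats=windows.shape[0],
    )


def _morph_from_delineation(
    window: np.ndarray, fs: float, fid: Dict[str, int], iso: float
) -> Dict[str, float]:
    ms = lambda v: int(round(v * fs / 1000.0))
    t_end = min(window.size - 1, fid["t"] + ms(80))
    st_at = min(window.size - 1, fid["qrs_offset"] + ms(60))
    return {
        "qrs_duration_s": (fid["qrs_offset"] - fid["qrs_onset"]) / fs,
        "pr_interval_s": (fid["qrs_onset"] - fid["p"]) / fs,
        "qt_interval_s": (t_end - fid["qrs_onset"]) / fs,
        "qs_interval_s": (fid["s"] - fid["q"]) / fs,
        "st_amplitude_mV": float(window[st_at] - iso),
        "p_amplitude_mV": float(window[fid["p"]] - iso),
        "q_amplitude_mV": float(window[fid["q"]] - iso),
        "r_amplitude_mV": float(window[fid["r"]] - iso),
        "s_amplitude_mV": float(window[fid["s"]] - iso),
        "t_amplitude_mV": float(window[fid["t"]] - iso),
    }


def morphology_features(
    recording: EcgRecording, r_indices: np.ndarray
) -> Dict[str, float]:
    """Ten interval/amplitude kinds, two estimation variants.

    Variant E delineates the average beat.  Variant O delineates each beat
    individually, forms consensus fiducials as the per-fiducial median offset
    across beats (which suppresses incoherent noise peaks — e.g. fibrillatory
    crests masquerading as P waves on single beats), then evaluates the ten
    kinds per beat at the consensus offsets and takes the median across
    beats.  A variant that fails entirely is imputed with zeros.
    """
    out: Dict[str, float] = {}
    try:
        avg = average_beat(recording, r_indices)
        e_vals = _morph_from_delineation(avg.waveform, avg.fs, avg.fiducials,
                                         avg.iso_level_mV)
    except (InsufficientBeatsError, DelineationError):
        e_vals = {k: 0.0 for k in _MORPH_KINDS}
    for k in _MORPH_KINDS:
        out[f"{k}_E"] = e_vals[k]

    windows, center = _beat_windows(recording, r_indices)
    fids: List[Dict[str, int]] = []
    isos: List[float] = []
    kept_rows: List[np.ndarray] = []
    for row in windows:
        try:
            fid, iso = _delineate(row, recording.fs, center)
        except DelineationError:
            continue
        fids.append(fid)
        isos.append(iso)
        kept_rows.append(row)
    if not fids:
        for k in _MORPH_KINDS:
            out[f"{k}_O"] = 0.0
        return out
    consensus = {
        key: int(np.median([f[key] for f in fids])) for key in fids[0]
    }
    per_beat: Dict[str, List[float]] = {k: [] for k in _MORPH_KINDS}
    for row, iso in zip(kept_rows, isos):
        vals = _morph_from_delineation(row, recording.fs, consensus, iso)
        for k in _MORPH_KINDS:
            per_beat[k].append(vals[k])
    for k in _MORPH_KINDS:
        out[f"{k}_O"] = float(np.median(per_beat[k]))
    return out


# --------------------------------------------------------------------------
# RR-interval features
# --------------------------------------------------------------------------

def median_rr(beat_series: BeatSeries) -> float:
    """Median of all RR intervals, seconds."""
    rr = np.asarray(beat_series.rr_s, dtype=float)
    if rr.size < 1:
        raise InsufficientBeatsError("need >= 1 RR interval")
    return float(np.median(rr))


def index_of_arrhythmia(beat_series: BeatSeries) -> int:
    """Count of abnormal beats by four knowledge-based RR conditions.

    For each interior position i with m = mean(rr[i-1], rr[i], rr[i+1]),
    beat i is abnormal if any of: (C1) rr[i] < 0.85 m and rr[i+1] > 1.15 m
    (premature beat plus compensatory pause); (C2) rr[i] > 1.5 m (dropped
    beat); (C3) rr[i] < 0.4 s (ectopic burst); (C4) |rr[i] - rr[i-1]| > 0.3 m
    (abrupt change).
    """
    rr = np.asarray(beat_series.rr_s, dtype=float)
    if rr.size < 3:
        raise InsufficientBeatsError("need >= 3 RR intervals")
    count = 0
    for i in range(1, rr.size - 1):
        m = (rr[i - 1] + rr[i] + rr[i + 1]) / 3.0
        c1 = rr[i] < 0.85 * m and rr[i + 1] > 1.15 * m
        c2 = rr[i] > 1.5 * m
        c3 = rr[i] < 0.4
        c4 = abs(rr[i] - rr[i - 1]) > 0.3 * m
        if c1 or c2 or c3 or c4:
            count += 1
    return count


def _rr_gap_fill(beat_series: BeatSeries) -> Dict[str, float]:
    rr = np.asarray(beat_series.rr_s, dtype=float)
    drr = np.asarray(beat_series.drr_s, dtype=float)
    return {
        "mean_rr_s": float(np.mean(rr)),
        "rmssd_s": float(np.sqrt(np.mean(drr ** 2))) if drr.size else 0.0,
        "pnn50": float(np.mean(np.abs(drr) > 0.050)) if drr.size else 0.0,
    }


# --------------------------------------------------------------------------
# noise features
# --------------------------------------------------------------------------

QRS_WINDOW_S = (-0.060, 0.080)  # correlation window around R


def qrs_similarity(recording: EcgRecording, r_indices: np.ndarray) -> float:
    """Mean Pearson correlation over all unordered pairs of QRS windows."""
    fs = recording.fs
    before = int(round(-QRS_WINDOW_S[0] * fs))
    after = int(round(QRS_WINDOW_S[1] * fs))
    rows = [
        recording.samples[r - before:r + after]
        for r in np.asarray(r_indices, dtype=int)
        if r - before >= 0 and r + after <= recording.n_samples
    ]
    rows = [w for w in rows if np.std(w) > 0]
    if len(rows) < 2:
        raise InsufficientBeatsError("need >= 2 usable QRS windows")
    c = np.corrcoef(np.vstack(rows))
    iu = np.triu_indices_from(c, k=1)
    return float(np.mean(c[iu]))


def signal_quality_index(recording: EcgRecording, r_indices: np.ndarray) -> float:
    """Fraction of beats whose isoelectric window is quiet.

    A beat is high-quality when the peak-to-peak amplitude of its isoelectric
    window ([-90, -70] ms before R) is below 20% of its R amplitude.
    """
    fs = recording.fs
    ms = lambda v: int(round(v * fs / 1000.0))
    total = 0
    good = 0
    for r in np.asarray(r_indices, dtype=int):
        lo, hi = r - ms(90), r - ms(70)
        if lo < 0 or hi <= lo or r >= recording.n_samples:
            continue
        iso_win = recording.samples[lo:hi]
        total += 1
        pkpk = float(np.ptp(iso_win))
        r_amp = abs(float(recording.samples[r]) - float(np.mean(iso_win)))
        if r_amp > 0 and pkpk < 0.20 * r_amp:
            good += 1
    if total == 0:
        raise InsufficientBeatsError("no beats with a full isoelectric window")
    return good / total


def qr_smoothness_index(avg: AverageBeat) -> int:
    """Number of peaks in the first-difference of the QRS-onset-to-R upstroke.

    A smooth monotone upstroke yields 1; high-frequency contamination adds
    extra difference-sequence peaks.  Endpoints are eligible as peaks.
    """
    seg = avg.waveform[avg.fiducials["qrs_onset"]:avg.fiducials["r"] + 1]
    if seg.size < 3:
        return 0
    d = np.diff(seg)
    count = 0
    for i in range(d.size):
        left_ok = i == 0 or d[i] > d[i - 1]
        right_ok = i == d.size - 1 or d[i] > d[i + 1]
        if left_ok and right_ok:
            count += 1
    return count


# --------------------------------------------------------------------------
# assembly
# --------------------------------------------------------------------------

def extract_features(
    recording: EcgRecording,
    ks_reference: KsReference,
    filter_spec: Optional[FilterSpec] = None,
) -> Dict[str, float]:
    """Full 31-feature vector for one recording (a 30 s segment or a whole
    short recording).  Never raises for valid recordings: failed operations
    fall back to ``IMPUTATION_DEFAULTS``."""
    values = dict(IMPUTATION_DEFAULTS)
    filtered = bandpass_filter(recording, filter_spec)
    try:
        r_idx = detect_r_peaks(filtered)
    except ValueError:
        r_idx = np.empty(0, dtype=int)

    beat_series: Optional[BeatSeries] = None
    if r_idx.size >= 3:
        beat_series = build_beat_series(r_idx, filtered.fs)

    if beat_series is not None:
        for name, fn in (
            ("af_evidence", af_evidence),
            ("shannon_entropy_drr", shannon_entropy_drr),
            ("median_rr_s", median_rr),
            ("index_of_arrhythmia", index_of_arrhythmia),
        ):
            try:
                values[name] = float(fn(beat_series))
            except (InsufficientBeatsError, ValueError):
                pass
        try:
            values["ks_statistic"] = ks_statistic(beat_series, ks_reference)
        except (InsufficientBeatsError, ValueError):
            pass
        values.update(_rr_gap_fill(beat_series))

    if r_idx.size:
        values.update(morphology_features(filtered, r_idx))
        try:
            values["qrs_similarity"] = qrs_similarity(filtered, r_idx)
        except (InsufficientBeatsError, ValueError):
            pass
        try:
            values["signal_quality_index"] = signal_quality_index(filtered, r_idx)
        except (InsufficientBeatsError, ValueError):
            pass
        try:
            avg = average_beat(filtered, r_idx)
            values["qr_smoothness_index"] = float(qr_smoothness_index(avg))
        except (InsufficientBeatsError, DelineationError):
            pass

    out = {name: float(values[name]) for name in FEATURE_NAMES}
    assert all(math.isfinite(v) for v in out.values())
    return out


class EcgFeatureExtractor(BaseEstimator, TransformerMixin):
    """Scikit-learn transformer: recordings -> 31-feature DataFrame.

    ``fit`` learns the Kolmogorov-Smirnov AF reference distribution by
    pooling the normalized dRR values of AF-labeled training recordings; if
    the training data contain no AF, a seeded synthetic fallback reference is
    used.  ``transform`` maps a sequence of :class:`EcgRecording` to a
    :class:`pandas.DataFrame` with the canonical 31 columns.

    Parameters
    ----------
    low_hz, high_hz, filter_order : band-pass settings (see FilterSpec).
    """

    def __init__(self, low_hz: float = 0.5, high_hz: float = 40.0,
                 filter_order: int = 3):
        self.low_hz = low_hz
        self.high_hz = high_hz
        self.filter_order = filter_order

    def _filter_spec(self) -> FilterSpec:
        return FilterSpec(low_hz=self.low_hz, high_hz=self.high_hz,
                          order=self.filter_order)

    def fit(self, X: Sequence[EcgRecording], y=None) -> "EcgFeatureExtractor":
        labels = list(y) if y is not None else [rec.label for rec in X]
        spec = self._filter_spec()
        series = []
        for rec, lab in zip(X, labels):
            if lab is None:
                continue
            if RhythmLabel(lab) is not RhythmLabel.AF:
                continue
            try:
                idx = detect_r_peaks(bandpass_filter(rec, spec))
                series.append(build_beat_series(idx, rec.fs))
            except (InsufficientBeatsError, ValueError):
                continue
        if series:
            self.ks_reference_ = build_ks_reference(series)
        else:
            self.ks_reference_ = default_ks_reference()
        self.feature_names_ = list(FEATURE_NAMES)
        return self

    def transform(self, X: Sequence[EcgRecording]):
        import pandas as pd

        if not hasattr(self, "ks_reference_"):
            raise RuntimeError("EcgFeatureExtractor is not fitted")
        spec = self._filter_spec()
        rows = [extract_features(rec, self.ks_reference_, spec) for rec in X]
        return pd.DataFrame(rows, columns=list(FEATURE_NAMES))

    def get_feature_names_out(self, input_features=None):
        return np.asarray(FEATURE_NAMES, dtype=object)
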