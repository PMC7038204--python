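"""Reading ECG sources, 30 s segmentation, labeling and dataset splitting.

Supported sources: WFDB records with rhythm annotations (e.g. the MIT-BIH
Atrial Fibrillation Database layout: .hea/.dat/.atr, first channel, 250 Hz),
PhysioNet/CinC Challenge 2017 recordings (.mat with a REFERENCE label table,
300 Hz), and plain two-column CSV traces.

Long annotated records are cut into consecutive non-overlapping 30 s
windows; each window takes the rhythm class covering the majority of its
duration under the code map AFIB -> AF, AFL/J -> Other, N -> Normal, and
windows whose majority code is unmapped are dropped.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import _wfdb
from .containers import CLASS_ORDER, EcgRecording, LabeledDataset, RhythmLabel

#: Rhythm-annotation code -> class map.
CODE_TO_CLASS: Dict[str, RhythmLabel] = {
    "AFIB": RhythmLabel.AF,
    "AFL": RhythmLabel.OTHER,
    "J": RhythmLabel.OTHER,
    "N": RhythmLabel.NORMAL,
}

#: Challenge 2017 reference-table letter -> class map.
CHALLENGE_LABELS: Dict[str, RhythmLabel] = {
    "N": RhythmLabel.NORMAL,
    "A": RhythmLabel.AF,
    "O": RhythmLabel.OTHER,
    "~": RhythmLabel.NOISY,
}


@dataclass
class RhythmAnnotationTrack:
    """Rhythm codes, each applying from its change point to the next."""

    change_points: np.ndarray  # sample indices, strictly increasing
    rhythm_codes: List[str]

    def __post_init__(self) -> None:
        self.change_points = np.asarray(self.change_points, dtype=int)
        if len(self.rhythm_codes) != self.change_points.size:
            raise ValueError("change_points and rhythm_codes must have equal length")
        if self.change_points.size and np.any(np.diff(self.change_points) <= 0):
            raise ValueError("change_points must be strictly increasing")


def read_wfdb_record(path, channel: int = 0) -> Tuple[EcgRecording, RhythmAnnotationTrack]:
    """Read one WFDB record plus its rhythm annotation track.

    Returns the selected channel converted to physical units (mV) using the
    header's gain/baseline.  Raises FileNotFoundError for missing files,
    IndexError for a channel out of range and HeaderError for a corrupt
    header.
    """
    path = Path(path)
    rec = _wfdb.read_record(path)
    samples = rec.physical(channel)
    stem = path.with_suffix("") if path.suffix else path
    atr = stem.with_suffix(".atr")
    anns = _wfdb.read_annotations(atr) if atr.exists() else []
    points, codes = [], []
    for samp, code, aux in anns:
        if code == _wfdb.RHYTHM_CODE and aux:
            points.append(samp)
            codes.append(aux.lstrip("("))
    track = RhythmAnnotationTrack(np.asarray(points, dtype=int), codes)
    recording = EcgRecording(samples, rec.fs, record_id=rec.name, channel=channel)
    return recording, track


def write_wfdb_record(
    directory,
    recording: EcgRecording,
    track: Optional[RhythmAnnotationTrack] = None,
    extra_channels: Optional[np.ndarray] = None,
    gain: float = 200.0,
) -> Path:
    """Write a recording (plus optional rhythm track) in WFDB layout."""
    sig = recording.samples[:, None]
    if extra_channels is not None:
        sig = np.column_stack([recording.samples, extra_channels])
    hea = _wfdb.write_record(directory, recording.record_id or "record",
                             recording.fs, sig, gain=gain)
    if track is not None:
        anns = [
            (int(s), _wfdb.RHYTHM_CODE, "(" + code)
            for s, code in zip(track.change_points, track.rhythm_codes)
        ]
        _wfdb.write_annotations(hea.with_suffix(".atr"), anns)
    return hea


def read_reference_table(path) -> Dict[str, RhythmLabel]:
    """Read a Challenge-2017 REFERENCE.csv (record_id, letter) label table."""
    table: Dict[str, RhythmLabel] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if len(row) < 2:
                continue
            rid, letter = row[0].strip(), row[1].strip()
            if letter in CHALLENGE_LABELS:
                table[rid] = CHALLENGE_LABELS[letter]
    return table


def read_challenge2017(path, reference: Optional[Dict[str, RhythmLabel]] = None) -> EcgRecording:
    """Read one Challenge-2017 recording (.mat with a 'val' array at 300 Hz,
    ADC units/1000 -> mV) and attach its label from the REFERENCE table in
    the same directory (or one passed in).  Raises if the record is absent
    from the table."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"recording not found: {path}")
    record_id = path.stem
    if reference is None:
        ref_path = path.parent / "REFERENCE.csv"
        if not ref_path.exists():
            raise FileNotFoundError(f"label table not found: {ref_path}")
        reference = read_reference_table(ref_path)
    if record_id not in reference:
        raise KeyError(f"record {record_id!r} absent from the label table")
    if path.suffix == ".mat":
        from scipy.io import loadmat

        val = np.asarray(loadmat(str(path))["val"], dtype=float).ravel()
        samples = val / 1000.0  # ADC units at gain 1000/mV
        fs = 300.0
    else:
        samples, fs = _read_csv_samples(path)
    return EcgRecording(samples, fs, record_id=record_id,
                        label=reference[record_id])


def _read_csv_samples(path) -> Tuple[np.ndarray, float]:
    arr = np.genfromtxt(path, delimiter=",", names=True)
    t = np.asarray(arr["time_s"], dtype=float)
    v = np.asarray(arr["voltage_mV"], dtype=float)
    if t.size < 2:
        raise ValueError(f"{path}: need at least 2 samples")
    fs = 1.0 / float(np.median(np.diff(t)))
    return v, fs


def read_csv_recording(path, label: Optional[RhythmLabel] = None) -> EcgRecording:
    """Read a two-column (time_s, voltage_mV) CSV trace."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"recording not found: {path}")
    samples, fs = _read_csv_samples(path)
    return EcgRecording(samples, round(fs, 6), record_id=path.stem, label=label)


def segment_and_label(
    recording: EcgRecording,
    track: RhythmAnnotationTrack,
    segment_s: float = 30.0,
) -> List[Tuple[EcgRecording, RhythmLabel]]:
    """Cut a long annotated record into labeled, non-overlapping windows.

    Windows are exactly ``segment_s * fs`` samples, half-open
    ``[start, start + w)``; the trailing partial window is discarded.  Each
    window takes the class covering the majority of its duration; samples
    before the first change point are unmapped, and windows with an unmapped
    majority are dropped.  Ties prefer a mapped class, then canonical class
    order.
    """
    if track.change_points.size == 0:
        raise ValueError("empty annotation track")
    w = int(segment_s * recording.fs)
    n_windows = recording.n_samples // w
    cps = track.change_points
    out: List[Tuple[EcgRecording, RhythmLabel]] = []
    for wi in range(n_windows):
        start, stop = wi * w, (wi + 1) * w
        # duration covered by each class within [start, stop)
        durations: Dict[Optional[RhythmLabel], int] = {}
        bounds = np.concatenate(([start], cps[(cps > start) & (cps < stop)], [stop]))
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            j = int(np.searchsorted(cps, lo, side="right")) - 1
            cls = CODE_TO_CLASS.get(track.rhythm_codes[j]) if j >= 0 else None
            durations[cls] = durations.get(cls, 0) + int(hi - lo)
        order = {lab: i for i, lab in enumerate(CLASS_ORDER)}
        best = max(
            durations.items(),
            key=lambda kv: (kv[1], kv[0] is not None, -order.get(kv[0], 99)),
        )[0]
        if best is None:
            continue
        seg = EcgRecording(
            recording.samples[start:stop], recording.fs,
            record_id=f"{recording.record_id}-seg{wi:04d}",
            channel=recording.channel, label=best,
        )
        out.append((seg, best))
    return out


def count_segments(recording: EcgRecording, segment_s: float = 30.0) -> int:
    """Number of full windows before label filtering."""
    return recording.n_samples // int(segment_s * recording.fs)


def split_dataset(
    items: Sequence[Tuple[EcgRecording, RhythmLabel]],
    test_fraction: float = 0.2,
    seed: int = 0,
    provenance: str = "",
) -> Tuple[LabeledDataset, LabeledDataset]:
    """Label-stratified random split into disjoint, exhaustive train/test sets.

    Deterministic for a fixed seed; each class contributes
    ``round(test_fraction * n_class)`` items to the test set.
    """
    if not items:
        raise ValueError("cannot split an empty dataset")
    if not 0 < test_fraction < 1:
        raise ValueError(f"test_fraction must lie in (0, 1), got {test_fraction}")
    rng = np.random.default_rng(seed)
    by_class: Dict[RhythmLabel, List[int]] = {}
    for i, (_, lab) in enumerate(items):
        by_class.setdefault(RhythmLabel(lab), []).append(i)
    test_idx: List[int] = []
    for lab in sorted(by_class, key=lambda l: l.value):
        idx = np.asarray(by_class[lab])
        perm = rng.permutation(idx.size)
        n_test = int(round(test_fraction * idx.size))
        test_idx.extend(int(i) for i in idx[perm[:n_test]])
    test_set = set(test_idx)
    train = [items[i] for i in range(len(items)) if i not in test_set]
    test = [items[i] for i in sorted(test_set)]
    return (
        LabeledDataset(train, provenance=provenance, split_tag="train"),
        LabeledDataset(test, provenance=provenance, split_tag="test"),
    )
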