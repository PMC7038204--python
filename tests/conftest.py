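import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import afdetect as af
from afdetect import synthetic as syn
from afdetect.features import default_ks_reference

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def preset_recording():
    """Verification-preset NSR recording (30 s, 80 BPM, 1.0 mV) + ground truth."""
    rec, gt = syn.generate(syn.verification_preset())
    return rec, gt


@pytest.fixture(scope="session")
def preset_peaks(preset_recording):
    rec, _ = preset_recording
    filt = af.bandpass_filter(rec)
    return filt, af.detect_r_peaks(filt)


@pytest.fixture(scope="session")
def ks_ref():
    return default_ks_reference()


@pytest.fixture(scope="session")
def benchmark_fit():
    """Shared end-to-end benchmark: 800 train / 200 held-out synthetic
    segments, fitted extractor and classifier, held-out predictions.

    Session-scoped because feature extraction on 1000 segments dominates the
    suite's runtime.
    """
    recs, _ = syn.make_benchmark(1000, seed=42)
    labels = [r.label for r in recs]
    tr_recs, te_recs = recs[:800], recs[800:]
    tr_y, te_y = labels[:800], labels[800:]
    ext = af.EcgFeatureExtractor().fit(tr_recs, tr_y)
    Xtr, Xte = ext.transform(tr_recs), ext.transform(te_recs)
    clf = af.BoostedRhythmClassifier(random_seed=7).fit(
        Xtr, tr_y, ks_reference=ext.ks_reference_
    )
    pred = list(clf.predict(Xte))
    return {
        "extractor": ext, "clf": clf,
        "Xtr": Xtr, "Xte": Xte, "tr_y": tr_y, "te_y": te_y, "pred": pred,
    }
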