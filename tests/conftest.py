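import logging

import numpy as np
import pytest

import ecgwave as ew

# the band-clamp warning for short T segments fires per segment and is
# contract behaviour; keep test output readable
logging.getLogger("ecgwave.tfr").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def template() -> ew.BeatTemplateSpec:
    return ew.BeatTemplateSpec()


@pytest.fixture(scope="session")
def clean_record_72():
    """Noise-free 10-s record at 72 bpm with ground truth."""
    return ew.synthesize_record(72, 10.0, seed=1)


@pytest.fixture(scope="session")
def clean_records_by_rate():
    """Noise-free 10-s records at 40/72/140 bpm, keyed by bpm."""
    return {bpm: ew.synthesize_record(bpm, 10.0, seed=1) for bpm in (40, 72, 140)}


def match_fiducials(annotations, truth, fs, r_tol_s=0.025):
    """Pair each annotation with the ground-truth beat of nearest R.

    Returns a list of (annotation, truth_beat) pairs; unmatched
    annotations (no truth R within r_tol_s) are excluded.
    """
    tol = int(round(r_tol_s * fs))
    pairs = []
    for ann in annotations:
        best = min(truth.beats, key=lambda b: abs(b.R - ann.R))
        if abs(best.R - ann.R) <= tol:
            pairs.append((ann, best))
    return pairs


def fiducial_errors(annotations, truth, fs):
    """Absolute per-fiducial errors (samples) over matched beats."""
    errs = []
    for ann, beat in match_fiducials(annotations, truth, fs):
        for name in ew.synthetic.FIDUCIAL_NAMES:
            errs.append(abs(getattr(ann, name) - getattr(beat, name)))
    return np.asarray(errs)
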