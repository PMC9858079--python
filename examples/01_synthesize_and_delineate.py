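"""Synthesize a 10-s ECG and delineate every beat.

Generates a clean 72-bpm record with exact ground-truth fiducials, runs
the delineator (Pan–Tompkins R detection + windowed P/T search +
zero-crossing bounds), and reports how close the detected fiducials are
to the truth.
"""

import numpy as np

import ecgwave as ew

record, truth = ew.synthesize_record(bpm=72, duration_s=10.0, seed=1)
annotations = ew.delineate_beats(record)

print(f"record: {record.record_id}, {record.duration_s:.0f} s at {record.fs:.0f} Hz, "
      f"class={record.label}")
print(f"ground-truth beats: {len(truth.beats)}, delineated: {len(annotations)}")

errors = []
for ann in annotations:
    beat = min(truth.beats, key=lambda b: abs(b.R - ann.R))
    for name in ew.synthetic.FIDUCIAL_NAMES:
        errors.append(abs(getattr(ann, name) - getattr(beat, name)))
errors_ms = 1000.0 * np.asarray(errors) / record.fs
print(f"fiducial error vs truth: max {errors_ms.max():.2f} ms, "
      f"mean {errors_ms.mean():.2f} ms over {errors_ms.size} fiducials")
# max error ~3 ms (one sample) means every onset/peak/offset is
# recovered essentially exactly on a noise-free zero-baseline signal
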