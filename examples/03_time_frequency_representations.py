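"""Image one heartbeat's waves as spectrogram, irisgram and scalogram.

Cuts the P, QRS and T segments of a delineated beat and computes all
three time-frequency surfaces, printing their shapes and ranges.  The
irisgram's geometry (pupil radius max(f)/3, θ over [−π, π]) and the
±120 dB clipping are visible directly in the numbers.
"""

import numpy as np

import ecgwave as ew

record, _ = ew.synthesize_record(bpm=72, duration_s=10.0, seed=1)
annotations = ew.delineate_beats(record)

for wave in ("P", "QRS", "T"):
    seg = ew.extract_wave_segments(record, annotations, wave)[5]
    grid = ew.stft_spectrogram(seg)
    iris = ew.irisgram(seg)
    sg = ew.cwt_scalogram(seg)
    print(f"{wave}-wave segment: {len(seg)} samples "
          f"({1000 * len(seg) / seg.fs:.0f} ms)")
    print(f"  spectrogram: {grid.psd.shape[0]} freq x {grid.psd.shape[1]} time, "
          f"f up to {grid.f.max():.0f} Hz")
    print(f"  irisgram: pupil radius {iris.inner_radius:.1f} = max(f)/3, "
          f"Z in [{iris.Z.min():.0f}, {iris.Z.max():.0f}] dB, "
          f"theta [{iris.theta[0]:.3f}, {iris.theta[-1]:.3f}] rad")
    print(f"  scalogram: 64 scales, pseudo-frequencies "
          f"{sg.frequencies.min():.1f}-{sg.frequencies.max():.1f} Hz, "
          f"peak |W| {sg.coefficients.max():.3f}")
    img = ew.segment_image(seg, "scalogram")
    print(f"  rendered image: {img.pixels.shape}, dtype {img.pixels.dtype}")
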