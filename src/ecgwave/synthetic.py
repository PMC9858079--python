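"""Synthetic single-lead ECG with exact ground-truth fiducials.

Each heartbeat is modelled as a sum of five Gaussian deflections — P, Q,
R, S, T — whose amplitudes follow the textbook scale for lead-II ECG
(P ≈ 0.25 mV, R ≈ 1.6 mV, T ≈ 0.3 mV).  Because the deflections are
analytic, every fiducial point (onset, peak, offset of each wave) is
known exactly: the onset/offset of a deflection is defined as the first/
last sample at which its absolute value reaches 1% of its peak
amplitude, and each deflection is exactly zero outside that support.
This makes the generated signal an exact target for zero-crossing
delineation: between waves the baseline is identically zero, so the
zero-crossing detectors land within one sample of the stored truth.

Records are built by tiling beats at a fixed RR interval (60/bpm s,
optionally jittered), and labelled by the standard rate rule: below
60 bpm bradycardia, 60–100 bpm normal sinus rhythm, above 100 bpm
tachycardia.  Beat timing intervals are shrunk/stretched with RR
(bounded), emulating the physiological shortening of the QT interval at
high rates, so that fast rhythms remain morphologically valid.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .records import EcgRecord

logger = logging.getLogger(__name__)

#: fraction of peak amplitude at which a deflection's support ends
SUPPORT_FRACTION = 0.01

#: reference RR interval (s) at which the default template is defined (72 bpm)
RR_REFERENCE = 60.0 / 72.0

#: bounds on the rate-scaling factor applied to beat timing intervals
RATE_SCALE_BOUNDS = (0.35, 1.25)

FIDUCIAL_NAMES = (
    "P_on", "P_peak", "P_off",
    "QRS_on", "Q", "R", "S", "QRS_off",
    "T_on", "T_peak", "T_off",
)


@dataclass(frozen=True)
class Deflection:
    """One Gaussian deflection: amplitude (mV), center (s, relative to R),
    width (s, the Gaussian standard deviation)."""

    amplitude: float
    center: float
    width: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"deflection width must be > 0, got {self.width}")

    @property
    def half_support(self) -> float:
        """Half-width (s) of the region where |g(t)| >= 1% of the peak."""
        return self.width * math.sqrt(2.0 * math.log(1.0 / SUPPORT_FRACTION))


@dataclass(frozen=True)
class BeatTemplateSpec:
    """Morphology of one heartbeat as five Gaussian deflections.

    Default amplitudes follow the standard lead-II scale (P-wave
    0.25 mV, R-wave 1.6 mV as the largest deflection, T-wave 0.3 mV);
    Q and S are small negative deflections flanking R.
    """

    p: Deflection = Deflection(0.25, -0.22, 0.020)
    q: Deflection = Deflection(-0.15, -0.040, 0.008)
    r: Deflection = Deflection(1.6, 0.0, 0.012)
    s: Deflection = Deflection(-0.15, 0.040, 0.008)
    t: Deflection = Deflection(0.30, 0.28, 0.040)
    fs: float = 360.0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.r.center != 0.0:
            raise ValueError("R deflection must be centered at 0")
        centers = [self.p.center, self.q.center, self.r.center,
                   self.s.center, self.t.center]
        if not all(a < b for a, b in zip(centers, centers[1:])):
            raise ValueError("deflection centers must be ordered P < Q < R < S < T")
        if any(d.amplitude != 0 for d in (self.p, self.q, self.r, self.s, self.t)):
            if not (abs(self.r.amplitude) > abs(self.p.amplitude)
                    and abs(self.r.amplitude) > abs(self.t.amplitude)):
                raise ValueError("R amplitude must exceed |P| and |T| amplitudes")
        # waves must not collide: P support before Q support, S before T
        if self.p.center + self.p.half_support > self.q.center - self.q.half_support:
            raise ValueError("P and Q deflections overlap")
        if self.s.center + self.s.half_support > self.t.center - self.t.half_support:
            raise ValueError("S and T deflections overlap")

    @property
    def deflections(self) -> dict[str, Deflection]:
        return {"P": self.p, "Q": self.q, "R": self.r, "S": self.s, "T": self.t}

    def scaled(self, factor: float) -> "BeatTemplateSpec":
        """Template with all centers and widths multiplied by ``factor``.

        Amplitudes are unchanged; used to compress/stretch beat timing
        with heart rate.
        """
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        kw = {
            name.lower(): Deflection(d.amplitude, d.center * factor, d.width * factor)
            for name, d in self.deflections.items()
        }
        return BeatTemplateSpec(fs=self.fs, **kw)

    @property
    def onset_offset_span(self) -> tuple[float, float]:
        """(P-wave onset, T-wave offset) in seconds relative to R."""
        return (self.p.center - self.p.half_support,
                self.t.center + self.t.half_support)


@dataclass(frozen=True)
class NoiseSpec:
    """Additive noise model: baseline-wander and power-line sinusoids plus
    seeded white (broadband) noise.  All amplitudes in mV."""

    baseline_amplitude: float = 0.0
    baseline_hz: float = 0.3
    powerline_amplitude: float = 0.0
    powerline_hz: float = 50.0
    broadband_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("baseline_amplitude", "powerline_amplitude", "broadband_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def broadband_for_snr(cls, record: EcgRecord, snr_db: float,
                          seed: int = 0) -> "NoiseSpec":
        """White-noise spec whose power sets the given SNR (dB) vs the record."""
        rms = float(np.sqrt(np.mean(record.samples**2)))
        return cls(broadband_sd=rms * 10.0 ** (-snr_db / 20.0), seed=seed)


@dataclass(frozen=True)
class BeatFiducials:
    """Ground-truth sample indices of the 11 fiducials of one beat."""

    P_on: int
    P_peak: int
    P_off: int
    QRS_on: int
    Q: int
    R: int
    S: int
    QRS_off: int
    T_on: int
    T_peak: int
    T_off: int

    def as_dict(self) -> dict[str, int]:
        return {name: getattr(self, name) for name in FIDUCIAL_NAMES}

    def is_ordered(self) -> bool:
        v = [getattr(self, n) for n in FIDUCIAL_NAMES]
        strict = all(a < b for a, b in zip(v[:3], v[1:3]))          # P_on<P_peak<P_off
        strict &= v[2] <= v[3]                                      # P_off <= QRS_on
        strict &= all(a < b for a, b in zip(v[3:7], v[4:8]))        # QRS_on<Q<R<S<QRS_off
        strict &= v[7] <= v[8]                                      # QRS_off <= T_on
        strict &= all(a < b for a, b in zip(v[8:10], v[9:11]))      # T_on<T_peak<T_off
        return strict

    def shifted(self, k: int) -> "BeatFiducials":
        return BeatFiducials(**{n: getattr(self, n) + k for n in FIDUCIAL_NAMES})


@dataclass
class GroundTruth:
    """Per-beat fiducials plus record-level rate and rhythm class."""

    beats: list[BeatFiducials]
    mean_bpm: float
    rhythm: str

    @property
    def r_peaks(self) -> np.ndarray:
        return np.array([b.R for b in self.beats], dtype=int)

    def fiducial(self, name: str) -> np.ndarray:
        return np.array([getattr(b, name) for b in self.beats], dtype=int)

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {"beat": i, "fiducial": name, "sample_index": getattr(b, name)}
            for i, b in enumerate(self.beats)
            for name in FIDUCIAL_NAMES
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.as_frame().to_csv(path, index=False)
        return path


# ----------------------------------------------------------------------
# rhythm labelling
# ----------------------------------------------------------------------
def label_rhythm(bpm: float) -> str:
    """Classify a heart rate: <60 bradycardia, 60–100 normal (inclusive),
    >100 tachycardia."""
    if bpm <= 0:
        raise ValueError(f"bpm must be positive, got {bpm}")
    if bpm < 60:
        return "bradycardia"
    if bpm <= 100:
        return "normal"
    return "tachycardia"


# ----------------------------------------------------------------------
# beat synthesis
# ----------------------------------------------------------------------
def _deflection_bounds(d: Deflection, r_index: int, fs: float) -> tuple[int, int, int]:
    """Integer (onset, peak, offset) sample indices of one deflection for a
    beat whose R peak sits at ``r_index``.

    Onset is the first sample inside the 1% support, offset the last; the
    generated waveform is exactly zero outside [onset, offset].
    """
    on = math.ceil(r_index + (d.center - d.half_support) * fs - 1e-9)
    off = math.floor(r_index + (d.center + d.half_support) * fs + 1e-9)
    peak = round(r_index + d.center * fs)
    return on, peak, off


def _add_beat(samples: np.ndarray, template: BeatTemplateSpec,
              r_index: int) -> BeatFiducials:
    """Add one beat to ``samples`` in place; return its ground truth."""
    fs = template.fs
    n = samples.size
    bounds = {name: _deflection_bounds(d, r_index, fs)
              for name, d in template.deflections.items()}
    for name, d in template.deflections.items():
        on, _, off = bounds[name]
        lo, hi = max(on, 0), min(off, n - 1)
        if lo > hi:
            continue
        k = np.arange(lo, hi + 1)
        t = k / fs - r_index / fs
        samples[k] += d.amplitude * np.exp(-((t - d.center) ** 2) / (2 * d.width**2))
    return BeatFiducials(
        P_on=bounds["P"][0], P_peak=bounds["P"][1], P_off=bounds["P"][2],
        QRS_on=bounds["Q"][0], Q=bounds["Q"][1],
        R=bounds["R"][1],
        S=bounds["S"][1], QRS_off=bounds["S"][2],
        T_on=bounds["T"][0], T_peak=bounds["T"][1], T_off=bounds["T"][2],
    )


def make_beat(template: BeatTemplateSpec | None = None) -> tuple[np.ndarray, BeatFiducials]:
    """Synthesize a single beat and its ground-truth fiducials.

    The returned waveform spans the beat's [P onset, T offset] support
    with a two-sample zero margin on each side; fiducials are indices
    into that array.
    """
    template = template or BeatTemplateSpec()
    fs = template.fs
    span_lo, span_hi = template.onset_offset_span
    margin = 2
    r_index = math.ceil(-span_lo * fs) + margin
    n = r_index + math.floor(span_hi * fs) + margin + 1
    samples = np.zeros(n)
    fid = _add_beat(samples, template, r_index)
    if not fid.is_ordered():
        raise ValueError("template deflections overlap: fiducials not ordered")
    return samples, fid


def synthesize_record(
    bpm: float,
    duration_s: float,
    template: BeatTemplateSpec | None = None,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    rr_jitter_s: float = 0.0,
    rate_scaling: bool = True,
    record_id: str | None = None,
) -> tuple[EcgRecord, GroundTruth]:
    """Generate a record of beats at the given rate with exact ground truth.

    Beats are placed at RR = 60/bpm s (Gaussian-jittered by
    ``rr_jitter_s`` if nonzero, seeded); the number of beats is
    floor(duration/RR) and all beats fit completely inside the record.
    With ``rate_scaling`` the template's timing intervals are multiplied
    by RR/RR_ref (bounded) so fast rhythms stay non-overlapping.

    Returns the (optionally noisy) record, labelled by
    :func:`label_rhythm`, and its :class:`GroundTruth`.
    """
    if bpm <= 0 or duration_s <= 0:
        raise ValueError("bpm and duration_s must be positive")
    template = template or BeatTemplateSpec()
    fs = template.fs
    rr = 60.0 / bpm
    if rate_scaling:
        factor = float(np.clip(rr / RR_REFERENCE, *RATE_SCALE_BOUNDS))
        if factor != 1.0:
            template = template.scaled(factor)
    span_lo, span_hi = template.onset_offset_span
    beat_extent = -span_lo + span_hi
    if beat_extent >= rr:
        raise ValueError(
            f"bpm={bpm} too high for this template: beat extent "
            f"{beat_extent:.3f} s exceeds RR {rr:.3f} s (beats would overlap)"
        )
    n_beats = int(duration_s / rr)
    if n_beats < 1:
        raise ValueError("duration too short for a single beat at this rate")

    gap = rr - beat_extent
    t0 = -span_lo + gap / 2.0  # time of first R peak
    rng = np.random.default_rng(seed)
    r_times = t0 + np.arange(n_beats) * rr
    if rr_jitter_s > 0:
        r_times = r_times + rng.normal(0.0, rr_jitter_s, size=n_beats)

    n = round(duration_s * fs)
    samples = np.zeros(n)
    beats: list[BeatFiducials] = []
    for rt in r_times:
        fid = _add_beat(samples, template, round(rt * fs))
        beats.append(fid)
    for prev, cur in zip(beats, beats[1:]):
        if prev.T_off >= cur.P_on:
            raise ValueError("beats overlap after jitter; reduce rr_jitter_s or bpm")
    for fid in beats:
        if not fid.is_ordered() or fid.P_on < 0 or fid.T_off >= n:
            raise ValueError("generated beat violates fiducial ordering/bounds")

    rid = record_id or f"synth_{int(round(bpm))}bpm_seed{seed}"
    record = EcgRecord(samples=samples, fs=fs, record_id=rid,
                       label=label_rhythm(bpm))
    truth = GroundTruth(beats=beats, mean_bpm=bpm, rhythm=record.label)
    if noise is not None:
        record = add_noise(record, noise)
    return record, truth


def add_noise(record: EcgRecord, noise: NoiseSpec) -> EcgRecord:
    """Add baseline-wander + power-line sinusoids and seeded white noise.

    The two sinusoids have zero initial phase; the broadband component is
    drawn from a generator seeded with ``noise.seed``, so a fixed spec
    yields a bit-identical realization.
    """
    t = record.time
    out = record.samples.copy()
    if noise.baseline_amplitude > 0:
        out += noise.baseline_amplitude * np.sin(2 * np.pi * noise.baseline_hz * t)
    if noise.powerline_amplitude > 0:
        out += noise.powerline_amplitude * np.sin(2 * np.pi * noise.powerline_hz * t)
    if noise.broadband_sd > 0:
        rng = np.random.default_rng(noise.seed)
        out += rng.normal(0.0, noise.broadband_sd, size=out.size)
    return record.with_samples(out)
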