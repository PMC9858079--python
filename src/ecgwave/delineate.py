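"""Beat delineation: R-peak detection and P/QRS/T fiducial location.

R peaks are found with a Pan–Tompkins-style chain (5–15 Hz bandpass →
five-point derivative → squaring → 150 ms moving-window integration →
adaptive dual threshold with a 200 ms refractory period), then refined
to the local maximum of the input signal.  Around each R peak:

* the P and T peaks are the signal maxima in rate-adaptive windows to
  the left and right of R;
* P/T onsets and offsets are found by scanning outward from each peak to
  the nearest zero crossing (the signal is assumed baseline-corrected,
  so waves sit on a zero baseline);
* Q and S are the local minima within 80 ms on either side of R;
* the QRS onset is the last zero crossing between the P offset and Q,
  and the QRS offset the first zero crossing between S and the T onset.

Beats whose search windows collapse or whose fiducials violate the
canonical ordering P_on < P_peak < P_off ≤ QRS_on < Q < R < S < QRS_off
≤ T_on < T_peak < T_off are dropped with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.ndimage import uniform_filter1d

from .records import EcgRecord
from .synthetic import FIDUCIAL_NAMES

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BeatAnnotation:
    """Fiducial sample indices of one delineated beat."""

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
    beat: int = 0
    record_id: str = ""

    def as_dict(self) -> dict[str, int]:
        return {name: getattr(self, name) for name in FIDUCIAL_NAMES}

    def is_ordered(self) -> bool:
        v = [getattr(self, n) for n in FIDUCIAL_NAMES]
        return (v[0] < v[1] < v[2] <= v[3] < v[4] < v[5] < v[6] < v[7]
                <= v[8] < v[9] < v[10])


@dataclass(frozen=True)
class WaveSegment:
    """One extracted P-, QRS- or T-wave snippet with provenance."""

    samples: np.ndarray
    fs: float
    wave: str                     # "P" | "QRS" | "T"
    label: str | None = None      # rhythm class of the source record
    record_id: str = ""
    beat: int = 0

    def __post_init__(self) -> None:
        if self.wave not in ("P", "QRS", "T"):
            raise ValueError(f"unknown wave kind {self.wave!r}")
        if np.asarray(self.samples).size == 0:
            raise ValueError("empty wave segment")

    def __len__(self) -> int:
        return np.asarray(self.samples).size


# ----------------------------------------------------------------------
# R-peak detection (Pan–Tompkins style)
# ----------------------------------------------------------------------
def detect_r_peaks(record: EcgRecord, refractory_s: float = 0.2) -> np.ndarray:
    """Detect R peaks; returns strictly increasing sample indices.

    Empty or flat signals yield an empty array.  Detections are refined
    to the argmax of the raw signal within ±100 ms of the integrator
    peak, so reported indices land on the R apex.
    """
    x = record.samples
    fs = record.fs
    if x.size < 4 or np.all(x == x[0]):
        return np.array([], dtype=int)

    # 5-15 Hz QRS passband
    high = min(15.0, 0.45 * fs)
    sos = signal.butter(3, [5.0, high], btype="bandpass", fs=fs, output="sos")
    f = signal.sosfiltfilt(sos, x)
    # five-point derivative, squaring, 150 ms integration window
    kernel = np.array([1.0, 2.0, 0.0, -2.0, -1.0]) * fs / 8.0
    d = np.convolve(f, kernel, mode="same")
    sq = d * d
    win = max(1, int(round(0.150 * fs)))
    mwi = uniform_filter1d(sq, size=win, mode="nearest")

    refractory = max(1, int(round(refractory_s * fs)))
    cand, _ = signal.find_peaks(mwi, distance=refractory)
    if cand.size == 0:
        return np.array([], dtype=int)

    # adaptive dual threshold (running signal/noise peak estimates)
    head = mwi[: min(mwi.size, int(2 * fs))]
    spki = 0.25 * float(head.max())
    npki = 0.5 * float(head.mean())
    accepted: list[int] = []
    for p in cand:
        thr = npki + 0.25 * (spki - npki)
        if mwi[p] > thr:
            spki = 0.125 * mwi[p] + 0.875 * spki
            accepted.append(int(p))
        else:
            npki = 0.125 * mwi[p] + 0.875 * npki
    if not accepted:
        return np.array([], dtype=int)

    # refine to the apex of the raw signal near each integrator peak
    half = int(round(0.100 * fs))
    peaks: list[int] = []
    for p in accepted:
        lo, hi = max(0, p - half), min(x.size, p + half + 1)
        r = lo + int(np.argmax(x[lo:hi]))
        if not peaks or r - peaks[-1] >= refractory:
            peaks.append(r)
        elif x[r] > x[peaks[-1]]:
            peaks[-1] = r
    return np.array(sorted(set(peaks)), dtype=int)


# ----------------------------------------------------------------------
# windowed P/T peak search
# ----------------------------------------------------------------------
def locate_p_t_peaks(
    record: EcgRecord,
    r_peaks: np.ndarray,
    p_window: tuple[float, float] = (0.35, 0.060),
    t_window: tuple[float, float] = (0.080, 0.6),
) -> list[tuple[int, int] | None]:
    """Find (P_peak, T_peak) for each beat as windowed maxima around R.

    The P window spans [R − p_window[0]·RR, R − p_window[1] s) and the T
    window (R + t_window[0] s, R + t_window[1]·RR], clamped to the
    record; RR is the median R-R interval (1 s default for a single
    beat).  A beat whose window collapses to nothing is reported as
    ``None`` and logged.
    """
    x = record.samples
    fs = record.fs
    r = np.asarray(r_peaks, dtype=int)
    if r.size == 0:
        return []
    rr = float(np.median(np.diff(r))) if r.size >= 2 else fs  # samples

    out: list[tuple[int, int] | None] = []
    for k, rk in enumerate(r):
        p_lo = max(0, rk - int(round(p_window[0] * rr)))
        p_hi = rk - int(round(p_window[1] * fs))
        t_lo = rk + int(round(t_window[0] * fs)) + 1
        t_hi = min(x.size, rk + int(round(t_window[1] * rr)) + 1)
        if p_lo >= p_hi or t_lo >= t_hi:
            logger.warning("beat %d at sample %d: empty P/T search window; dropped",
                           k, rk)
            out.append(None)
            continue
        p_peak = p_lo + int(np.argmax(x[p_lo:p_hi]))
        t_peak = t_lo + int(np.argmax(x[t_lo:t_hi]))
        out.append((p_peak, t_peak))
    return out


# ----------------------------------------------------------------------
# zero-crossing bound searches
# ----------------------------------------------------------------------
def find_wave_bounds(samples: np.ndarray, peak_index: int) -> tuple[int, int]:
    """Onset/offset of the wave at ``peak_index`` by zero-crossing scans.

    Scanning backward (forward) from the peak, the onset (offset) is the
    first sample whose value is zero or of opposite sign to the peak —
    i.e. the far-side sample of the crossing.  If no crossing exists
    before the record edge the boundary index is returned and a warning
    logged.
    """
    x = np.asarray(samples, dtype=float)
    v = x[peak_index]
    if v == 0:
        raise ValueError("signal value at peak_index must be nonzero")
    s = np.sign(v)

    onset = 0
    for i in range(peak_index - 1, -1, -1):
        if x[i] == 0 or np.sign(x[i]) != s:
            onset = i
            break
    else:
        logger.warning("no zero crossing before sample %d; clamped to 0", peak_index)

    offset = x.size - 1
    for i in range(peak_index + 1, x.size):
        if x[i] == 0 or np.sign(x[i]) != s:
            offset = i
            break
    else:
        logger.warning("no zero crossing after sample %d; clamped to end", peak_index)
    return onset, offset


def _crossings(x: np.ndarray, lo: int, hi: int) -> list[int]:
    """Zero-crossing indices inside [lo, hi): exact zeros, plus the far
    index of each sign change between consecutive in-window samples."""
    idx = [i for i in range(lo, hi) if x[i] == 0.0]
    idx += [i + 1 for i in range(lo, hi - 1) if x[i] * x[i + 1] < 0.0]
    return sorted(set(idx))


def find_qrs_bounds(samples: np.ndarray, p_off: int, q: int, s: int,
                    t_on: int) -> tuple[int, int]:
    """QRS onset/offset by zero-crossing search in the flanking windows.

    Onset: last zero crossing in [P_off, Q); offset: first zero crossing
    in (S, T_on].  A window with no crossing falls back to the inner
    boundary (Q−1 resp. S+1) with a logged warning.
    """
    if not p_off < q < s < t_on:
        raise ValueError("need P_off < Q < S < T_on")
    x = np.asarray(samples, dtype=float)
    on_c = _crossings(x, p_off, q)
    off_c = _crossings(x, s + 1, t_on + 1)
    if on_c:
        qrs_on = on_c[-1]
    else:
        qrs_on = q - 1
        logger.warning("no zero crossing in [P_off=%d, Q=%d); using Q-1", p_off, q)
    if off_c:
        qrs_off = off_c[0]
    else:
        qrs_off = s + 1
        logger.warning("no zero crossing in (S=%d, T_on=%d]; using S+1", s, t_on)
    return qrs_on, qrs_off


# ----------------------------------------------------------------------
# full delineation
# ----------------------------------------------------------------------
def delineate_beats(record: EcgRecord,
                    r_peaks: np.ndarray | None = None,
                    qs_window_s: float = 0.080) -> list[BeatAnnotation]:
    """Delineate every beat of a (baseline-corrected) record.

    Composes R detection, windowed P/T peak search, zero-crossing bound
    searches and local-minimum Q/S location.  Beats with degenerate
    windows or an invalid fiducial ordering are dropped and logged.
    """
    x = record.samples
    fs = record.fs
    if r_peaks is None:
        r_peaks = detect_r_peaks(record)
    r_peaks = np.asarray(r_peaks, dtype=int)
    if r_peaks.size == 0:
        return []
    pt = locate_p_t_peaks(record, r_peaks)
    qs = max(1, int(round(qs_window_s * fs)))

    annotations: list[BeatAnnotation] = []
    for k, rk in enumerate(r_peaks):
        if pt[k] is None:
            continue
        p_peak, t_peak = pt[k]
        if x[p_peak] == 0 or x[t_peak] == 0:
            logger.warning("beat %d: zero-amplitude P or T peak; dropped", k)
            continue
        p_on, p_off = find_wave_bounds(x, p_peak)
        t_on, t_off = find_wave_bounds(x, t_peak)
        q_lo = max(p_off + 1, rk - qs)
        s_hi = min(t_on, rk + qs + 1)
        if q_lo >= rk or rk + 1 >= s_hi:
            logger.warning("beat %d: empty Q/S window; dropped", k)
            continue
        q = q_lo + int(np.argmin(x[q_lo:rk]))
        s = rk + 1 + int(np.argmin(x[rk + 1:s_hi]))
        if not p_off < q < s < t_on:
            logger.warning("beat %d: Q/S search violated ordering; dropped", k)
            continue
        qrs_on, qrs_off = find_qrs_bounds(x, p_off, q, s, t_on)
        ann = BeatAnnotation(
            P_on=p_on, P_peak=p_peak, P_off=p_off,
            QRS_on=qrs_on, Q=q, R=int(rk), S=s, QRS_off=qrs_off,
            T_on=t_on, T_peak=t_peak, T_off=t_off,
            beat=k, record_id=record.record_id,
        )
        if not ann.is_ordered():
            logger.warning("beat %d: fiducial ordering violated; dropped", k)
            continue
        annotations.append(ann)
    return annotations


_WAVE_BOUNDS = {"P": ("P_on", "P_off"), "QRS": ("QRS_on", "QRS_off"),
                "T": ("T_on", "T_off")}


def extract_wave_segments(record: EcgRecord,
                          annotations: list[BeatAnnotation],
                          wave: str,
                          min_samples: int = 3) -> list[WaveSegment]:
    """Cut [onset, offset) snippets of one wave kind from a record.

    Each segment carries the record's rhythm label; segments shorter
    than ``min_samples`` are dropped with a warning.
    """
    if wave not in _WAVE_BOUNDS:
        raise ValueError(f"wave must be one of {sorted(_WAVE_BOUNDS)}, got {wave!r}")
    on_name, off_name = _WAVE_BOUNDS[wave]
    segments: list[WaveSegment] = []
    for ann in annotations:
        on, off = getattr(ann, on_name), getattr(ann, off_name)
        if off - on < min_samples:
            logger.warning("beat %d: %s segment of %d samples dropped",
                           ann.beat, wave, off - on)
            continue
        segments.append(WaveSegment(
            samples=record.samples[on:off].copy(), fs=record.fs, wave=wave,
            label=record.label, record_id=record.record_id, beat=ann.beat,
        ))
    return segments


def annotations_to_frame(annotations: list[BeatAnnotation]):
    """Long-format table (record_id, beat, fiducial, sample_index)."""
    import pandas as pd

    rows = [
        {"record_id": a.record_id, "beat": a.beat, "fiducial": name,
         "sample_index": getattr(a, name)}
        for a in annotations for name in FIDUCIAL_NAMES
    ]
    return pd.DataFrame(rows, columns=["record_id", "beat", "fiducial",
                                       "sample_index"])
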