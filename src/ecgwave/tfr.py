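"""Time-frequency representations: spectrogram, irisgram, scalogram.

Three views of a wave segment:

* **Spectrogram** — one-sided power spectral density of the short-time
  Fourier transform over a sliding window (Hann by default).
* **Irisgram** — the spectrogram in decibels, remapped to polar
  coordinates: time runs circumferentially over θ ∈ [−π, π], frequency
  runs radially as ρ = max(f)/3 + f (the constant offset opens a
  central "pupil"), and amplitude is clipped to [−120, 120] dB.
* **Scalogram** — the magnitude surface |W(a, b)| of the continuous
  wavelet transform (Morlet mother wavelet), with the scale vector
  chosen so the pseudo-frequencies f = fc·fs/a cover the physiological
  band of the wave being imaged (P: 5–30 Hz, QRS: 8–50 Hz, T-wave band
  clamped to 0.5–10 Hz, since the scale diverges at 0 Hz).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pywt
from scipy.signal import ShortTimeFFT, get_window

from .delineate import WaveSegment

logger = logging.getLogger(__name__)

DB_CLIP = 120.0
DB_POWER_FLOOR = 1e-12

#: physiological frequency band (Hz) of each wave kind
WAVE_BANDS: dict[str, tuple[float, float]] = {
    "P": (5.0, 30.0),
    "QRS": (8.0, 50.0),
    "T": (0.5, 10.0),   # nominal 0-10 Hz band, clamped away from DC
}


@dataclass(frozen=True)
class WindowSpec:
    """STFT window parameters: window name, length in samples (``None``
    = auto: min(64, ceil(segment/4)) rounded up to even), fractional
    overlap, and DFT length (zero-padded)."""

    name: str = "hann"
    length: int | None = None
    overlap: float = 0.75
    nfft: int = 256

    def resolve_length(self, n_samples: int) -> int:
        if self.length is not None:
            L = self.length
        else:
            L = min(64, -(-n_samples // 4))
            L += L % 2
        if L < 4:
            L = 4
        return L


@dataclass
class TimeFrequencyGrid:
    """STFT spectrogram: one-sided PSD over a time × frequency grid."""

    t: np.ndarray            # segment-center times (s)
    f: np.ndarray            # non-negative ascending frequencies (Hz)
    psd: np.ndarray          # shape (|f|, |t|), >= 0
    window: WindowSpec
    hop: int                 # samples between segment positions

    def __post_init__(self) -> None:
        if self.psd.shape != (self.f.size, self.t.size):
            raise ValueError("psd shape must be |f| x |t|")


@dataclass
class Irisgram:
    """Polar spectrogram surface.

    θ has one point per time column, spanning [−π, π]; ρ = max(f)/3 + f,
    so the annulus has inner radius max(f)/3; Z is the dB amplitude
    clipped to [−120, 120], bound to the (X, Y) grid.
    """

    theta: np.ndarray        # (T,)
    rho: np.ndarray          # (|f|,)
    X: np.ndarray            # (|f|, T)
    Y: np.ndarray            # (|f|, T)
    Z: np.ndarray            # (|f|, T) dB
    t: np.ndarray
    f: np.ndarray

    @property
    def inner_radius(self) -> float:
        return float(self.rho[0])


@dataclass
class Scalogram:
    """CWT magnitude surface |W| over (translation, scale)."""

    scales: np.ndarray           # ascending, > 0
    times: np.ndarray            # translation axis (s)
    coefficients: np.ndarray     # |W|, shape (|scales|, |times|)
    wavelet: str
    frequencies: np.ndarray      # pseudo-frequency of each scale (Hz)

    @property
    def energy(self) -> float:
        return float(np.sum(self.coefficients**2))


def _segment_array(segment: WaveSegment | np.ndarray,
                   fs: float | None) -> tuple[np.ndarray, float]:
    if isinstance(segment, WaveSegment):
        return np.asarray(segment.samples, dtype=float), float(segment.fs)
    if fs is None:
        raise ValueError("fs is required when passing a raw array")
    return np.asarray(segment, dtype=float), float(fs)


# ----------------------------------------------------------------------
# STFT spectrogram
# ----------------------------------------------------------------------
def stft_spectrogram(segment: WaveSegment | np.ndarray,
                     window_spec: WindowSpec | None = None,
                     fs: float | None = None) -> TimeFrequencyGrid:
    """One-sided PSD spectrogram of a wave segment.

    Uses the one-sided density convention (non-DC/non-Nyquist bins
    doubled), so ``sum(psd) * Δf * Δt`` approximates the signal energy
    ``sum(x²)/fs`` for well-behaved windows.
    """
    x, fs = _segment_array(segment, fs)
    spec = window_spec or WindowSpec()
    L = spec.resolve_length(x.size)
    if x.size < L:
        raise ValueError(
            f"segment of {x.size} samples is shorter than the {L}-sample window")
    win = get_window(spec.name, L)
    hop = max(1, int(round(L * (1.0 - spec.overlap))))
    mfft = max(spec.nfft, L)
    sft = ShortTimeFFT(win, hop=hop, fs=fs, mfft=mfft, scale_to="psd")
    psd = sft.spectrogram(x)
    # one-sided density: double everything except DC (and Nyquist if present)
    psd = psd.copy()
    last = psd.shape[0] - 1 if mfft % 2 == 0 else psd.shape[0]
    psd[1:last, :] *= 2.0
    t = sft.t(x.size)
    return TimeFrequencyGrid(t=t, f=sft.f, psd=psd, window=spec, hop=hop)


def psd_to_db(psd: np.ndarray, floor: float = DB_POWER_FLOOR,
              clip_db: float = DB_CLIP) -> np.ndarray:
    """Power → dB with an ε floor, clipped to [−clip_db, +clip_db]."""
    psd = np.asarray(psd, dtype=float)
    if np.any(psd < 0):
        raise ValueError("psd must be non-negative")
    return np.clip(10.0 * np.log10(psd + floor), -clip_db, clip_db)


# ----------------------------------------------------------------------
# irisgram
# ----------------------------------------------------------------------
def polar_map(T: int, f: np.ndarray) -> tuple[np.ndarray, np.ndarray,
                                              np.ndarray, np.ndarray]:
    """Map a time index axis and frequency vector to polar coordinates.

    θ = −π : 2π/(T−1) : π (T points); ρ = max(f)/3 + f; X = ρ cos θ and
    Y = ρ sin θ on the outer-product grid (shape |f| × T).
    """
    if T < 2:
        raise ValueError("need at least two time points")
    f = np.asarray(f, dtype=float)
    if f.size == 0 or f.max() <= 0:
        raise ValueError("frequency vector must be non-empty with max(f) > 0")
    theta = np.linspace(-np.pi, np.pi, T)
    rho = f.max() / 3.0 + f
    X = np.outer(rho, np.cos(theta))
    Y = np.outer(rho, np.sin(theta))
    return theta, rho, X, Y


def irisgram(segment: WaveSegment | np.ndarray,
             window_spec: WindowSpec | None = None,
             fs: float | None = None) -> Irisgram:
    """Polar spectrogram: STFT → dB clipping → polar remap.

    The annulus inner radius (the "pupil") equals max(f)/3; time
    increases with θ over one full turn.
    """
    grid = stft_spectrogram(segment, window_spec, fs=fs)
    Z = psd_to_db(grid.psd)
    theta, rho, X, Y = polar_map(grid.t.size, grid.f)
    return Irisgram(theta=theta, rho=rho, X=X, Y=Y, Z=Z, t=grid.t, f=grid.f)


# ----------------------------------------------------------------------
# CWT scalogram
# ----------------------------------------------------------------------
def cwt_scalogram(segment: WaveSegment | np.ndarray,
                  wave: str | None = None,
                  band_hz: tuple[float, float] | None = None,
                  n_scales: int = 64,
                  wavelet: str = "morl",
                  fs: float | None = None) -> Scalogram:
    """CWT magnitude scalogram over a wave-specific frequency band.

    The scale vector has ``n_scales`` logarithmically spaced scales
    whose pseudo-frequencies (f = fc·fs/a) span ``band_hz``; the band
    defaults to the wave kind's physiological band (:data:`WAVE_BANDS`).
    Bands infeasible for the segment are clamped with a warning: the
    upper edge to the Nyquist frequency, the lower edge so at least one
    wavelet period fits the segment.
    """
    x, fs = _segment_array(segment, fs)
    if x.size < 8:
        raise ValueError("segment must have at least 8 samples")
    if band_hz is None:
        kind = wave or (segment.wave if isinstance(segment, WaveSegment) else None)
        if kind is None:
            raise ValueError("give either wave kind or an explicit band_hz")
        band_hz = WAVE_BANDS[kind]
    f_lo, f_hi = float(band_hz[0]), float(band_hz[1])
    if not 0 < f_lo < f_hi:
        raise ValueError("band must satisfy 0 < low < high")
    fc = pywt.central_frequency(wavelet)
    nyq = fs / 2.0
    min_f = 2.0 * fc * fs / x.size  # at least ~one wavelet period in segment
    if f_hi > nyq:
        logger.warning("band upper edge %.3g Hz clamped to Nyquist %.3g Hz", f_hi, nyq)
        f_hi = nyq
    if f_lo < min_f:
        logger.warning("band lower edge %.3g Hz clamped to %.3g Hz for a "
                       "%d-sample segment", f_lo, min_f, x.size)
        f_lo = min(min_f, f_hi / 1.5)
    freqs = np.geomspace(f_hi, f_lo, n_scales)   # descending => scales ascending
    scales = fc * fs / freqs
    coef, _ = pywt.cwt(x, scales, wavelet, sampling_period=1.0 / fs)
    return Scalogram(scales=scales, times=np.arange(x.size) / fs,
                     coefficients=np.abs(coef), wavelet=wavelet,
                     frequencies=freqs)


# ----------------------------------------------------------------------
# serialization
# ----------------------------------------------------------------------
def save_representation(rep, path: str | Path) -> Path:
    """Save any representation to an ``.npz`` with named arrays."""
    path = Path(path)
    if isinstance(rep, TimeFrequencyGrid):
        np.savez(path, kind="spectrogram", t=rep.t, f=rep.f, psd=rep.psd)
    elif isinstance(rep, Irisgram):
        np.savez(path, kind="irisgram", theta=rep.theta, rho=rep.rho,
                 X=rep.X, Y=rep.Y, Z=rep.Z, t=rep.t, f=rep.f)
    elif isinstance(rep, Scalogram):
        np.savez(path, kind="scalogram", scales=rep.scales, times=rep.times,
                 W=rep.coefficients, frequencies=rep.frequencies)
    else:
        raise TypeError(f"cannot serialize {type(rep).__name__}")
    return path
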