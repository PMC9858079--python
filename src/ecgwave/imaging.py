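"""Rendering representations to images and assembling labeled datasets.

Each time-frequency representation is rendered deterministically to a
224 × 224 × 3 RGB image (the input size of the standard ImageNet-family
classifiers): rectangular surfaces (spectrogram, scalogram) are
color-mapped and bilinearly resized; the irisgram is rasterized top-down
onto its polar (X, Y) annulus with nearest-neighbour sampling, pixels
outside the annulus taking the colormap's floor color.

Datasets are laid out as one PNG per wave segment under class-named
subdirectories plus a CSV manifest, and split either 70/30 (stratified
by rhythm class) or into stratified k folds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd
from PIL import Image
from sklearn.model_selection import StratifiedKFold

from .delineate import WaveSegment, delineate_beats, extract_wave_segments
from .records import RHYTHM_CLASSES, EcgRecord
from .tfr import (DB_CLIP, Irisgram, Scalogram, TimeFrequencyGrid, WindowSpec,
                  cwt_scalogram, irisgram, psd_to_db, stft_spectrogram)

logger = logging.getLogger(__name__)

IMAGE_SIZE = 224
DEFAULT_COLORMAP = "viridis"

REPRESENTATIONS = ("spectrogram", "irisgram", "scalogram")

MANIFEST_COLUMNS = ("path", "class", "wave", "representation",
                    "record_id", "beat")


@dataclass
class RepresentationImage:
    """A rendered 224×224×3 8-bit image with its provenance."""

    pixels: np.ndarray
    label: str | None
    wave: str
    representation: str
    record_id: str = ""
    beat: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)
        if self.pixels.shape != (IMAGE_SIZE, IMAGE_SIZE, 3):
            raise ValueError(
                f"expected {IMAGE_SIZE}x{IMAGE_SIZE}x3 pixels, got {self.pixels.shape}")

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        Image.fromarray(self.pixels).save(path, format="PNG")
        return path


def _colormap_rgb(values01: np.ndarray, colormap: str) -> np.ndarray:
    """Map values in [0, 1] through a named colormap to uint8 RGB."""
    cmap = matplotlib.colormaps[colormap]
    rgba = cmap(np.clip(values01, 0.0, 1.0), bytes=True)
    return np.asarray(rgba[..., :3], dtype=np.uint8)


def _render_matrix(values: np.ndarray, colormap: str, size: int,
                   vmin: float | None, vmax: float | None) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    lo = values.min() if vmin is None else vmin
    hi = values.max() if vmax is None else vmax
    if hi > lo:
        norm = (values - lo) / (hi - lo)
    else:
        norm = np.full_like(values, 0.5)  # degenerate surface -> uniform image
    rgb = _colormap_rgb(norm[::-1, :], colormap)  # low freq/scale at the bottom
    img = Image.fromarray(rgb).resize((size, size), Image.BILINEAR)
    return np.asarray(img, dtype=np.uint8)


def _render_irisgram(rep: Irisgram, colormap: str, size: int) -> np.ndarray:
    """Top-down orthographic rasterization of the polar (X, Y, Z) surface."""
    r0 = rep.inner_radius
    r1 = float(rep.rho[-1])
    half = size / 2.0
    # pixel-center coordinates in data units
    coords = (np.arange(size) + 0.5) / size * 2 * r1 - r1
    u, v = np.meshgrid(coords, -coords)  # v axis points up
    radius = np.hypot(u, v)
    angle = np.arctan2(v, u)
    drho = rep.rho[1] - rep.rho[0] if rep.rho.size > 1 else 1.0
    dtheta = rep.theta[1] - rep.theta[0]
    f_idx = np.clip(np.round((radius - r0) / drho).astype(int), 0, rep.rho.size - 1)
    t_idx = np.clip(np.round((angle + np.pi) / dtheta).astype(int), 0,
                    rep.theta.size - 1)
    z01 = (rep.Z[f_idx, t_idx] + DB_CLIP) / (2 * DB_CLIP)
    z01[(radius < r0) | (radius > r1)] = 0.0  # outside the annulus: floor color
    return _colormap_rgb(z01, colormap)


def render_image(rep, colormap: str = DEFAULT_COLORMAP,
                 size: int = IMAGE_SIZE, label: str | None = None,
                 record_id: str = "", beat: int = 0) -> RepresentationImage:
    """Render a representation to a fixed-size RGB image, deterministically.

    dB surfaces (spectrogram, irisgram) are mapped over the fixed clip
    range [−120, 120] dB so identical values always yield identical
    colors; scalograms are mapped over their own [0, max |W|] range.
    """
    if isinstance(rep, TimeFrequencyGrid):
        pixels = _render_matrix(psd_to_db(rep.psd), colormap, size,
                                vmin=-DB_CLIP, vmax=DB_CLIP)
        kind, wave = "spectrogram", ""
    elif isinstance(rep, Irisgram):
        if size != IMAGE_SIZE:
            raise ValueError("irisgram rendering is fixed at the native size")
        pixels = _render_irisgram(rep, colormap, size)
        kind, wave = "irisgram", ""
    elif isinstance(rep, Scalogram):
        pixels = _render_matrix(rep.coefficients, colormap, size,
                                vmin=0.0, vmax=None)
        kind, wave = "scalogram", ""
    else:
        raise TypeError(f"cannot render {type(rep).__name__}")
    return RepresentationImage(pixels=pixels, label=label, wave=wave,
                               representation=kind, record_id=record_id,
                               beat=beat)


# ----------------------------------------------------------------------
# dataset assembly
# ----------------------------------------------------------------------
def represent_segment(segment: WaveSegment, representation: str,
                      window_spec: WindowSpec | None = None):
    """Compute the named representation of one wave segment."""
    if representation == "spectrogram":
        return stft_spectrogram(segment, window_spec)
    if representation == "irisgram":
        return irisgram(segment, window_spec)
    if representation == "scalogram":
        return cwt_scalogram(segment)
    raise ValueError(f"representation must be one of {REPRESENTATIONS}, "
                     f"got {representation!r}")


def segment_image(segment: WaveSegment, representation: str,
                  colormap: str = DEFAULT_COLORMAP,
                  window_spec: WindowSpec | None = None) -> RepresentationImage:
    """Representation image of one segment (compute + render)."""
    rep = represent_segment(segment, representation, window_spec)
    img = render_image(rep, colormap=colormap, label=segment.label,
                       record_id=segment.record_id, beat=segment.beat)
    img.wave = segment.wave
    return img


def build_dataset(records: list[EcgRecord], wave: str, representation: str,
                  out_dir: str | Path,
                  colormap: str = DEFAULT_COLORMAP,
                  window_spec: WindowSpec | None = None) -> pd.DataFrame:
    """Delineate records, image one wave kind, store a labeled dataset.

    Writes one PNG per surviving segment under
    ``out_dir/<class>/<record>_beat<k>_<wave>_<rep>.png`` and returns
    (and writes) the manifest.  Records with no delineable beats or no
    rhythm label are skipped with a log entry.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for record in records:
        if record.label is None:
            logger.warning("record %s has no rhythm label; skipped", record.record_id)
            continue
        annotations = delineate_beats(record)
        if not annotations:
            logger.warning("record %s: no delineable beats; skipped",
                           record.record_id)
            continue
        segments = extract_wave_segments(record, annotations, wave)
        for seg in segments:
            try:
                img = segment_image(seg, representation, colormap, window_spec)
            except ValueError as exc:
                logger.warning("record %s beat %d: %s; segment skipped",
                               seg.record_id, seg.beat, exc)
                continue
            cls_dir = out_dir / record.label
            cls_dir.mkdir(exist_ok=True)
            name = f"{seg.record_id}_beat{seg.beat}_{wave}_{representation}.png"
            path = img.save(cls_dir / name)
            rows.append({"path": str(path), "class": record.label,
                         "wave": wave, "representation": representation,
                         "record_id": seg.record_id, "beat": seg.beat})
    manifest = pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS))
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


# ----------------------------------------------------------------------
# splits
# ----------------------------------------------------------------------
def split_dataset(manifest: pd.DataFrame, train_fraction: float = 0.7,
                  seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified train/test split by rhythm class.

    Within each class, round(train_fraction · n) rows go to training
    after a seeded shuffle; a single-row class goes entirely to training
    with a warning.  The two manifests are disjoint and exhaustive.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_parts, test_parts = [], []
    for cls, group in manifest.groupby("class", sort=True):
        idx = rng.permutation(group.index.to_numpy())
        n_train = int(round(train_fraction * idx.size))
        if idx.size == 1:
            logger.warning("class %r has a single row; assigned to training", cls)
            n_train = 1
        n_train = min(max(n_train, 1), idx.size)
        train_parts.append(manifest.loc[idx[:n_train]])
        test_parts.append(manifest.loc[idx[n_train:]])
    train = pd.concat(train_parts).sort_index()
    test = (pd.concat(test_parts).sort_index() if any(len(p) for p in test_parts)
            else manifest.iloc[0:0])
    return train, test


def kfold_split(manifest: pd.DataFrame, k: int = 5,
                seed: int = 0) -> list[tuple[pd.DataFrame, pd.DataFrame]]:
    """Stratified k-fold partition; every row tests exactly once."""
    counts = manifest["class"].value_counts()
    if (counts < k).any():
        small = counts[counts < k].index.tolist()
        raise ValueError(f"classes {small} have fewer than k={k} rows")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    y = manifest["class"].to_numpy()
    folds = []
    for train_idx, test_idx in skf.split(np.zeros(len(manifest)), y):
        folds.append((manifest.iloc[train_idx], manifest.iloc[test_idx]))
    return folds
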