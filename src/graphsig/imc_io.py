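"""Multichannel image IO, preprocessing and ROI extraction.

Imaging mass cytometry yields one intensity image per protein marker at
~1 um^2 per pixel.  Analysis works on b x b patches ("ROIs") anchored on
the channel of a tumor-indicator marker (Cytokeratin by default): patches
are picked greedily by maximal window mean of that channel, previously
selected regions are zeroed and excluded, and the m channel patches at
each selected position form one :class:`~graphsig.signatures.ObservationBundle`.

Preprocessing per channel is a z-score whose mean/std are computed over
the *nonzero* pixels only (IMC backgrounds are structurally zero), with an
optional 3x3 median filter beforehand for dense-expression datasets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .signatures import ObservationBundle

__all__ = [
    "MultiplexImage",
    "ROISet",
    "ExtractionConfig",
    "znorm_nonzero",
    "median_filter_3x3",
    "select_rois",
    "preprocess_and_extract",
    "read_multiplex",
]

logger = logging.getLogger(__name__)


@dataclass
class MultiplexImage:
    """An m-channel image stack with marker names."""

    channels: np.ndarray
    marker_names: Sequence[str]
    indicator_channel: str = "Cytokeratin"
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.ndim != 3:
            raise ValueError("channels must be an (m, height, width) array")
        if len(self.marker_names) != self.channels.shape[0]:
            raise ValueError("marker_names length must equal the channel count")
        if not np.all(np.isfinite(self.channels)):
            raise ValueError("channel intensities must be finite")

    @property
    def n_channels(self) -> int:
        return self.channels.shape[0]

    def indicator_index(self) -> int:
        try:
            return list(self.marker_names).index(self.indicator_channel)
        except ValueError:
            raise KeyError(
                f"indicator channel {self.indicator_channel!r} not among markers"
            ) from None


@dataclass
class ROISet:
    """Selected patch positions (top-left corners) and their bundles."""

    positions: np.ndarray
    patch_size: int
    bundles: list[ObservationBundle]
    subject_id: str | None = None
    scores: np.ndarray | None = None


@dataclass
class ExtractionConfig:
    """Settings for :func:`preprocess_and_extract`."""

    n_rois: int = 10
    patch_size: int = 35
    median_filter: bool = False
    select_on_raw: bool = False
    exclusion: str = "hard"  # "hard" excludes overlaps; "zeroing" relies on zeroed scores


def znorm_nonzero(channel: np.ndarray) -> np.ndarray:
    """Z-score a channel with statistics from its nonzero pixels only.

    Every pixel (zeros included) passes through the same affine transform.
    An all-zero channel is returned unchanged; a zero standard deviation is
    clamped to 1.  Both degenerate cases log a warning.
    """
    channel = np.asarray(channel, dtype=float)
    nonzero = channel[channel != 0]
    if nonzero.size == 0:
        logger.warning("channel has no nonzero pixels; left unnormalized")
        return channel.copy()
    mean = nonzero.mean()
    std = nonzero.std()
    if std == 0:
        logger.warning("nonzero pixels have zero spread; std clamped to 1")
        std = 1.0
    return (channel - mean) / std


def median_filter_3x3(channel: np.ndarray) -> np.ndarray:
    """3x3 median filter with reflected borders (constants pass through)."""
    return ndimage.median_filter(np.asarray(channel, dtype=float), size=3,
                                 mode="reflect")


def _window_means(image: np.ndarray, b: int) -> np.ndarray:
    """Mean over every valid b x b window (shape (H-b+1, W-b+1))."""
    padded = np.zeros((image.shape[0] + 1, image.shape[1] + 1))
    padded[1:, 1:] = np.cumsum(np.cumsum(image, axis=0), axis=1)
    sums = (padded[b:, b:] - padded[:-b, b:] - padded[b:, :-b] + padded[:-b, :-b])
    return sums / (b * b)


def select_rois(image: MultiplexImage, n_rois: int, patch_size: int,
                exclusion: str = "hard") -> ROISet:
    """Greedy selection of the n_rois brightest indicator windows.

    Each round scores all fully-inside b x b windows of a working copy of
    the indicator channel by their mean, takes the row-major-first argmax,
    records it and zeroes the selected region.  With ``exclusion="hard"``
    (default) any window intersecting a previously selected one is also
    removed from contention, guaranteeing pairwise-disjoint patches; with
    ``"zeroing"`` only the zeroed scores discourage overlap.
    """
    if n_rois < 1 or patch_size < 1:
        raise ValueError("n_rois and patch_size must be >= 1")
    b = int(patch_size)
    m, height, width = image.channels.shape
    if b > min(height, width):
        raise ValueError("patch_size exceeds image dimensions")
    if exclusion not in ("hard", "zeroing"):
        raise ValueError("exclusion must be 'hard' or 'zeroing'")

    work = image.channels[image.indicator_index()].copy()
    blocked = np.zeros((height - b + 1, width - b + 1), dtype=bool)
    positions: list[tuple[int, int]] = []
    scores: list[float] = []
    for _ in range(n_rois):
        means = _window_means(work, b)
        if exclusion == "hard":
            means = np.where(blocked, -np.inf, means)
            if not np.any(np.isfinite(means)):
                raise ValueError(
                    f"image too small for {n_rois} non-overlapping {b}x{b} patches"
                )
        flat = int(np.argmax(means))  # row-major first on ties
        r, c = divmod(flat, means.shape[1])
        positions.append((r, c))
        scores.append(float(means[r, c]))
        work[r : r + b, c : c + b] = 0.0
        r_lo, r_hi = max(0, r - b + 1), min(blocked.shape[0], r + b)
        c_lo, c_hi = max(0, c - b + 1), min(blocked.shape[1], c + b)
        blocked[r_lo:r_hi, c_lo:c_hi] = True

    # a bundle needs at least two features; a bare indicator image still
    # yields positions and scores
    bundles = ([_bundle_at(image, r, c, b) for r, c in positions]
               if m >= 2 else [])
    return ROISet(positions=np.asarray(positions, dtype=int), patch_size=b,
                  bundles=bundles, subject_id=image.subject_id,
                  scores=np.asarray(scores))


def _bundle_at(image: MultiplexImage, r: int, c: int, b: int) -> ObservationBundle:
    patch = image.channels[:, r : r + b, c : c + b]
    features = patch.reshape(image.n_channels, b * b)  # row-major flattening
    return ObservationBundle(
        features=features,
        feature_names=list(image.marker_names),
        point_id=f"{image.subject_id or 'img'}:{r},{c}",
    )


def preprocess_and_extract(raw: MultiplexImage,
                           config: ExtractionConfig) -> list[ObservationBundle]:
    """Normalize channels, pick indicator-anchored ROIs, return bundles.

    Per channel: optional 3x3 median filter, then the nonzero-pixel
    z-score.  ROI positions are computed on the preprocessed indicator
    channel unless ``select_on_raw`` is set.
    """
    raw.indicator_index()  # validates the configuration early
    processed = np.empty_like(raw.channels)
    for k in range(raw.n_channels):
        channel = raw.channels[k]
        if config.median_filter:
            channel = median_filter_3x3(channel)
        processed[k] = znorm_nonzero(channel)
    prepped = MultiplexImage(channels=processed, marker_names=raw.marker_names,
                             indicator_channel=raw.indicator_channel,
                             subject_id=raw.subject_id)
    source = raw if config.select_on_raw else prepped
    rois = select_rois(source, config.n_rois, config.patch_size,
                       exclusion=config.exclusion)
    return [_bundle_at(prepped, r, c, rois.patch_size)
            for r, c in rois.positions]


def read_multiplex(image_path: str | Path, markers_path: str | Path | None = None,
                   indicator: str = "Cytokeratin",
                   subject_id: str | None = None) -> MultiplexImage:
    """Read a multipage TIFF stack (one page per channel) or a directory of
    per-channel TIFFs, with marker names from a CSV/TSV table
    (columns: channel_index, marker_name)."""
    import tifffile

    image_path = Path(image_path)
    if image_path.is_dir():
        files = sorted(image_path.glob("*.tif*"))
        if not files:
            raise FileNotFoundError(f"no TIFF files in {image_path}")
        channels = np.stack([tifffile.imread(f) for f in files])
        names = [f.stem for f in files]
    else:
        channels = np.asarray(tifffile.imread(image_path))
        if channels.ndim == 2:
            channels = channels[None]
        names = [f"ch{i}" for i in range(channels.shape[0])]
    if markers_path is not None:
        sep = "\t" if str(markers_path).endswith((".tsv", ".txt")) else ","
        table = pd.read_csv(markers_path, sep=sep)
        table = table.sort_values("channel_index")
        names = table["marker_name"].tolist()
        if len(names) != channels.shape[0]:
            raise ValueError("marker table length does not match channel count")
    return MultiplexImage(channels=channels.astype(float), marker_names=names,
                          indicator_channel=indicator,
                          subject_id=subject_id or Path(image_path).stem)
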