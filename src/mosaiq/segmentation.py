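"""Watershed segmentation of nuclei and per-nucleus intensity measurement.

The nuclear-stain channel is smoothed, contrast-equalized (CLAHE) and Otsu
thresholded to obtain a foreground mask.  Seeds for watershed segmentation
are the local maxima of the Euclidean distance transform of that mask, so
touching nuclei split along the ridge between their distance-transform
basins.  Mean pixel intensity inside each segment, in every channel, yields
the per-nucleus fluorescence measurements consumed downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.exposure import equalize_adapthist
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import relabel_sequential, watershed

from .data import MeasurementTable, channel_column
from .errors import DegenerateThresholdError, DimensionError


@dataclass
class SegmentationParams:
    """Tunable knobs of the watershed pipeline (pixel units throughout)."""

    smoothing_sigma: float = 2.0   # Gaussian pre-smoothing
    clahe_clip: float = 0.01       # CLAHE clip limit (fraction)
    clahe_tile: int = 64           # CLAHE tile size
    min_seed_distance: int = 5     # min separation between watershed seeds
    min_area: int = 10             # discard speckle segments below this area


def build_foreground_mask(
    stain_image: np.ndarray,
    smoothing_sigma: float = 2.0,
    clahe_clip: float = 0.01,
    clahe_tile: int = 64,
) -> np.ndarray:
    """Binary foreground mask via smoothing + CLAHE + Otsu thresholding.

    The image is first normalized by its maximum, which makes the mask
    invariant to a global intensity rescaling (e.g. 8- vs 16-bit range).

    Raises
    ------
    DegenerateThresholdError
        If the image is constant, so no threshold separates foreground.
    """
    img = np.asarray(stain_image, dtype=float)
    if img.ndim != 2:
        raise DimensionError("stain image must be 2-D")
    if not np.all(np.isfinite(img)) or np.any(img < 0):
        raise ValueError("stain image must be finite and non-negative")
    if img.max() == img.min():
        raise DegenerateThresholdError("constant image: no foreground")
    img = img / img.max()
    tile = max(2, min(clahe_tile, min(img.shape)))
    img = equalize_adapthist(img, kernel_size=tile, clip_limit=clahe_clip)
    img = gaussian(img, sigma=smoothing_sigma, preserve_range=True)
    if img.max() == img.min():
        raise DegenerateThresholdError("image constant after preprocessing")
    return img >= threshold_otsu(img)


def segment_nuclei(
    stain_image: np.ndarray, params: SegmentationParams | None = None
) -> np.ndarray:
    """Label matrix of nuclei (0 = background, k >= 1 = segment k).

    Watershed of the negated Euclidean distance transform, seeded at the
    distance-transform local maxima and restricted to the foreground mask.
    Segments smaller than ``params.min_area`` pixels are discarded; surviving
    labels are renumbered consecutively from 1.
    """
    if params is None:
        params = SegmentationParams()
    mask = build_foreground_mask(
        stain_image, params.smoothing_sigma, params.clahe_clip, params.clahe_tile
    )
    distance = ndimage.distance_transform_edt(mask)
    peaks = peak_local_max(
        distance,
        min_distance=params.min_seed_distance,
        labels=mask,
        exclude_border=False,
    )
    markers = np.zeros(mask.shape, dtype=int)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    # merge seeds that fall on the same distance plateau of one nucleus
    plateau, _ = ndimage.label(markers > 0)
    if plateau.max() and plateau.max() < len(peaks):
        markers = plateau
    labels = watershed(-distance, markers, mask=mask, connectivity=1)
    if params.min_area > 1:
        sizes = np.bincount(labels.ravel())
        small = np.flatnonzero(sizes < params.min_area)
        labels[np.isin(labels, small[small > 0])] = 0
    labels, _, _ = relabel_sequential(labels)
    return labels


def measure_segments(
    labels: np.ndarray, channels: list[np.ndarray]
) -> MeasurementTable:
    """One measurement record per segment.

    ``raw_level[c]`` is the arithmetic mean of channel ``c`` over the
    segment's pixels; (x, y) is the pixel centroid (x = column, y = row).
    Invariant to any renumbering of the positive labels.
    """
    labels = np.asarray(labels)
    for c, ch in enumerate(channels):
        if np.asarray(ch).shape != labels.shape:
            raise DimensionError(
                f"channel {c} shape {np.asarray(ch).shape} != labels {labels.shape}"
            )
    props = regionprops(labels)
    records = []
    for i, p in enumerate(props):
        row, col = p.centroid
        rec = {"cell_id": i + 1, "x": col, "y": row, "segment_label": p.label}
        coords = tuple(p.coords.T)
        for c, ch in enumerate(channels):
            rec[channel_column(c)] = float(np.asarray(ch, dtype=float)[coords].mean())
        records.append(rec)
    cols = ["cell_id", "x", "y"] + [channel_column(c) for c in range(len(channels))]
    df = pd.DataFrame(records, columns=cols + ["segment_label"])
    return MeasurementTable(df)
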