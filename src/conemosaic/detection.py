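"""Cone outer-segment detection in single-opsin fluorescence channels.

The pipeline mirrors a standard ImageJ-style counting routine: rolling-ball
background subtraction, a fractional threshold (default 15.7% of the
post-subtraction channel maximum), binary median despeckling, splitting of
touching cones by a distance-transform watershed, and size/shape filtering
of the resulting objects.  Centroids are reported in μm in the image frame
(x right, y down, origin at the top-left pixel corner).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.measure import label as sk_label
from skimage.measure import regionprops_table
from skimage.morphology import disk as disk_footprint
from skimage.morphology import h_maxima, white_tophat
from skimage.segmentation import watershed


@dataclass(frozen=True)
class DetectionConfig:
    """Tunable parameters of the counting routine.

    threshold_fraction defaults to 0.157, applied to the maximum of the
    background-subtracted channel.  The size/shape filter bounds (min_area
    2 μm², max_area 30 μm², circularity ≥ 0.3) are set at cone
    outer-segment scale and are all overridable.
    """

    background_radius_um: float = 10.0
    threshold_fraction: float = 0.157
    despeckle_kernel_px: int = 3
    min_area_um2: float = 2.0
    max_area_um2: float = 30.0
    min_circularity: float = 0.3
    # marker suppression depth for the watershed, as a fraction of the
    # post-subtraction channel maximum: shallower intensity dips between
    # neighbouring maxima are not split (avoids noise over-segmentation)
    marker_h_fraction: float = 0.05
    smoothing_sigma_px: float = 1.0

    def __post_init__(self):
        if not 0.0 < self.threshold_fraction < 1.0:
            raise ValueError("threshold_fraction must be in (0, 1)")
        if self.min_area_um2 >= self.max_area_um2:
            raise ValueError("min_area_um2 must be smaller than max_area_um2")


@dataclass
class DetectionResult:
    """Per-object centroids (image-frame μm), sizes and shapes for one channel."""

    table: pd.DataFrame  # columns: x_um, y_um, area_um2, circularity
    channel: str
    pixel_size_um: float

    @property
    def count(self) -> int:
        return len(self.table)

    @property
    def centroids(self) -> np.ndarray:
        return self.table[["x_um", "y_um"]].to_numpy()


def subtract_background(image: np.ndarray, radius_px: float) -> np.ndarray:
    """Rolling-ball-style background removal via a white top-hat with a
    disk structuring element of the given radius."""
    return white_tophat(image.astype(float), footprint=disk_footprint(int(round(radius_px))))


def binary_mask(image_bs: np.ndarray, threshold_fraction: float) -> np.ndarray:
    peak = float(image_bs.max())
    if peak <= 0:
        return np.zeros(image_bs.shape, dtype=bool)
    return image_bs > threshold_fraction * peak


def despeckle(mask: np.ndarray, kernel_px: int = 3) -> np.ndarray:
    """Binary median filter; idempotent on an already-filtered mask."""
    return ndi.median_filter(mask.astype(np.uint8), size=kernel_px).astype(bool)


def split_touching(
    mask: np.ndarray, intensity: np.ndarray, h: float, smoothing_sigma_px: float = 1.0
) -> np.ndarray:
    """Split merged cones by a marker-controlled watershed.

    Markers are h-maxima of the lightly smoothed intensity (two cones
    merged at threshold still show two intensity peaks); h suppresses
    shallow, noise-induced maxima that would over-segment single cones.
    The watershed floods the negated intensity within the mask.  Because
    the markers do not depend on the threshold, lowering the threshold can
    only add objects, never remove them.
    """
    if not mask.any():
        return np.zeros(mask.shape, dtype=np.int32)
    smooth = ndi.gaussian_filter(intensity.astype(float), smoothing_sigma_px)
    peaks = h_maxima(smooth, max(h, 1e-9)) & mask
    markers = sk_label(peaks)
    if markers.max() == 0:
        return sk_label(mask)
    return watershed(-smooth, markers=markers, mask=mask)


def detect_cones(
    image: np.ndarray,
    cfg: DetectionConfig,
    pixel_size_um: float,
    channel: str = "s",
    apply_filters: bool = True,
) -> DetectionResult:
    """Run the full counting pipeline on one channel.

    Deterministic for a fixed input.  A blank or saturated-flat image
    yields zero objects without raising.  ``apply_filters=False`` skips the
    size/shape filter (used for threshold-monotonicity diagnostics).
    """
    if pixel_size_um is None or pixel_size_um <= 0:
        raise ValueError("pixel size must be known and positive")
    if image.ndim != 2:
        raise ValueError("detect_cones expects a single-channel 2-D image")

    img = image.astype(float)
    img_bs = subtract_background(img, cfg.background_radius_um / pixel_size_um)
    mask = binary_mask(img_bs, cfg.threshold_fraction)
    mask = despeckle(mask, cfg.despeckle_kernel_px)
    labels = split_touching(
        mask, img_bs, cfg.marker_h_fraction * float(img_bs.max()), cfg.smoothing_sigma_px
    )

    if labels.max() == 0:
        empty = pd.DataFrame(columns=["x_um", "y_um", "area_um2", "circularity"])
        return DetectionResult(empty, channel, pixel_size_um)

    props = regionprops_table(
        labels, intensity_image=img_bs, properties=("label", "area", "perimeter", "centroid_weighted")
    )
    area_um2 = props["area"] * pixel_size_um**2
    perim = props["perimeter"]
    with np.errstate(divide="ignore", invalid="ignore"):
        circularity = np.where(perim > 0, 4 * np.pi * props["area"] / perim**2, 1.0)
    circularity = np.minimum(circularity, 1.0)

    # intensity-weighted centroids; +0.5 px puts coordinates at pixel centres
    x_um = (props["centroid_weighted-1"] + 0.5) * pixel_size_um
    y_um = (props["centroid_weighted-0"] + 0.5) * pixel_size_um

    table = pd.DataFrame(
        {"x_um": x_um, "y_um": y_um, "area_um2": area_um2, "circularity": circularity}
    )
    if apply_filters:
        keep = (
            (table["area_um2"] >= cfg.min_area_um2)
            & (table["area_um2"] <= cfg.max_area_um2)
            & (table["circularity"] >= cfg.min_circularity)
        )
        table = table[keep].reset_index(drop=True)
    return DetectionResult(table, channel, pixel_size_um)


def validate_counts(auto_counts, reference_counts) -> float:
    """Squared Pearson correlation between automated and reference per-field
    counts.  Returns NaN (flagged undefined) when either vector has zero
    variance."""
    a = np.asarray(auto_counts, dtype=float)
    b = np.asarray(reference_counts, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need ≥ 3 paired fields of equal length")
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)
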