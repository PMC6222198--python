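"""Phase-contrast segmentation and fluorescence quantification.

The imaging pipeline: correct the fluorescence image for uneven excitation
illumination, suppress high-frequency noise, segment dark cells (or small
clusters) from the phase-contrast image by global thresholding, measure a
background-subtracted mean pixel intensity per segmented object, and link
manually-placed survival markers to segmented cells by nearest centroid.

All kernel sizes and thresholds live in :class:`SegmentationConfig`; the
defaults are a large-kernel Gaussian illumination estimate, a small median
denoising kernel, an Otsu threshold on phase contrast, and an area window
that rejects debris and merged clumps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, median_filter
from skimage.filters import threshold_otsu
from skimage.measure import label as label_regions
from skimage.measure import regionprops

__all__ = [
    "SegmentationConfig",
    "SegmentedObject",
    "Marker",
    "correct_illumination",
    "denoise",
    "segment_phase",
    "measure_cells",
    "link_markers",
    "objects_to_frame",
]


@dataclass(frozen=True)
class SegmentationConfig:
    illumination_sigma_px: float = 60.0  # large-kernel blur for flat-field estimate
    denoise_size_px: int = 3  # median filter footprint
    min_area_um2: float = 0.5  # area window for plausible single cells/clusters
    max_area_um2: float = 50.0
    marker_cutoff_px: float = 20.0  # linkage distances beyond this are flagged


@dataclass(frozen=True)
class SegmentedObject:
    """One segmented cell (or small cluster) with intensity statistics."""

    label: int
    centroid: tuple[float, float]  # (row, col), 0-based pixels
    area_um2: float
    mean_intensity: float  # background-subtracted a.u./pixel
    total_intensity: float  # background-subtracted a.u.


@dataclass(frozen=True)
class Marker:
    """A manual survival/death click: position and assigned value."""

    position: tuple[float, float]  # (row, col) pixels
    value: float  # 1.0 survival, 0.0 death

    def __post_init__(self):
        if self.value not in (0.0, 1.0):
            raise ValueError("marker value must be 0.0 (death) or 1.0 (survival)")


def _check_image(image) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D image")
    return img


def correct_illumination(
    fluor_image,
    flat_field=None,
    config: SegmentationConfig = SegmentationConfig(),
) -> np.ndarray:
    """Divide out a smooth illumination profile, preserving the global mean.

    When a ``flat_field`` (an image of a uniformly fluorescent sample) is
    supplied it is used directly as the profile; otherwise the profile is
    a large-kernel Gaussian blur of the image itself. Rejects negative
    pixels and all-zero images.
    """
    img = _check_image(fluor_image)
    if np.any(img < 0):
        raise ValueError("fluorescence image must be non-negative")
    if not np.any(img > 0):
        raise ValueError("cannot correct an all-zero image")
    if flat_field is not None:
        profile = _check_image(flat_field)
    else:
        profile = gaussian_filter(img, config.illumination_sigma_px, mode="nearest")
    profile = np.maximum(profile, 1e-12 * profile.max())
    corrected = img / profile
    return corrected * (img.mean() / corrected.mean())


def denoise(image, config: SegmentationConfig = SegmentationConfig()) -> np.ndarray:
    """Small-kernel median filter against shot/impulse noise.

    The median is unbiased for symmetric noise, so smooth images keep
    their mean intensity to well under 0.1%; impulse outliers are
    deliberately discarded (that is the point of the filter).
    """
    img = _check_image(image)
    if img.size == 0:
        return img
    return median_filter(img, size=config.denoise_size_px, mode="nearest")


def segment_phase(
    phase_image,
    pixel_size_um: float,
    config: SegmentationConfig = SegmentationConfig(),
) -> np.ndarray:
    """Label dark (below-Otsu) connected regions within the area window.

    Returns an int32 label mask; blank fields (no contrast) give an empty
    mask rather than an error.
    """
    img = _check_image(phase_image)
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    if np.ptp(img) == 0:
        return np.zeros(img.shape, dtype=np.int32)
    thresh = threshold_otsu(img)
    mask = label_regions(img < thresh, connectivity=2)
    min_px = config.min_area_um2 / pixel_size_um**2
    max_px = config.max_area_um2 / pixel_size_um**2
    out = np.zeros_like(mask, dtype=np.int32)
    next_label = 1
    for region in regionprops(mask):
        if min_px <= region.area <= max_px:
            out[mask == region.label] = next_label
            next_label += 1
    return out


def measure_cells(mask, fluor_image, pixel_size_um: float) -> list[SegmentedObject]:
    """Per-object area and background-subtracted intensity statistics.

    The background is the median fluorescence over unmasked pixels,
    subtracted from every cell pixel before computing the mean and total.
    """
    mask = np.asarray(mask)
    img = _check_image(fluor_image)
    if mask.shape != img.shape:
        raise ValueError("mask and image must have the same shape")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    outside = img[mask == 0]
    background = float(np.median(outside)) if outside.size else 0.0
    objects = []
    for region in regionprops(mask.astype(np.int32), intensity_image=img):
        mean = float(region.intensity_mean) - background
        objects.append(SegmentedObject(
            label=int(region.label),
            centroid=(float(region.centroid[0]), float(region.centroid[1])),
            area_um2=float(region.area) * pixel_size_um**2,
            mean_intensity=mean,
            total_intensity=mean * float(region.area),
        ))
    return objects


def link_markers(
    markers: list[Marker],
    objects: list[SegmentedObject],
    cutoff_px: float | None = None,
):
    """Pair each manual marker with the nearest segmented-cell centroid.

    Assignment is one-to-one and greedy by ascending (distance, marker
    index): the globally closest remaining pair is linked first, so ties
    resolve deterministically in marker order. Pairs farther apart than
    ``cutoff_px`` are still linked but flagged for manual review.

    Returns ``(pairs, unmatched_markers)`` where ``pairs`` is a list of
    ``(marker_index, object_label, distance_px, flagged)`` tuples and
    ``unmatched_markers`` the marker indices left over when markers
    outnumber objects.
    """
    if cutoff_px is None:
        cutoff_px = SegmentationConfig().marker_cutoff_px
    if not markers or not objects:
        return [], list(range(len(markers)))
    pos = np.array([m.position for m in markers], dtype=float)
    cen = np.array([o.centroid for o in objects], dtype=float)
    dist = np.sqrt(((pos[:, None, :] - cen[None, :, :]) ** 2).sum(axis=2))

    order = sorted(
        ((dist[i, j], i, j) for i in range(len(markers)) for j in range(len(objects))),
        key=lambda t: (t[0], t[1], t[2]),
    )
    used_m: set[int] = set()
    used_o: set[int] = set()
    pairs = []
    for d, i, j in order:
        if i in used_m or j in used_o:
            continue
        # ambiguous pairings (another marker exactly as close) are flagged
        tie = int(np.sum(np.isclose(dist[:, j], d))) > 1
        pairs.append((i, objects[j].label, float(d), bool(d > cutoff_px or tie)))
        used_m.add(i)
        used_o.add(j)
        if len(used_m) == len(markers) or len(used_o) == len(objects):
            break
    pairs.sort(key=lambda p: p[0])
    unmatched = [i for i in range(len(markers)) if i not in used_m]
    return pairs, unmatched


def objects_to_frame(objects: list[SegmentedObject]) -> pd.DataFrame:
    """Tabulate measurements in the per-cell CSV schema."""
    return pd.DataFrame([
        {
            "label": o.label,
            "centroid_row": o.centroid[0],
            "centroid_col": o.centroid[1],
            "area_um2": o.area_um2,
            "mean_intensity": o.mean_intensity,
            "total_intensity": o.total_intensity,
        }
        for o in objects
    ])
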