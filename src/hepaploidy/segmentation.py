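"""Watershed segmentation of fluorescence-like patches.

The calibration path mirrors how ground-truth cell boundaries are obtained
from immunofluorescence: a nuclear marker highlights hepatocyte nuclei and a
membrane marker outlines each cell.  Nuclei are segmented by watershed on
the inverted distance transform of the thresholded nuclear channel; cell
regions by watershed flooding of the membrane ridge landscape.  Each nucleus
is then assigned to the cell region containing its centroid, and only cells
whose centroid falls in the central region of the patch are kept, so that
cells truncated by the patch edge cannot bias the statistics.
"""

from __future__ import annotations

import math
from typing import Callable, List, Optional, Sequence, Tuple, TypeVar

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .records import CellAssignment, NucleusRecord

# minimum foreground/background contrast (on a [0,1] scale) for an Otsu
# split to be considered real signal rather than noise
_MIN_CONTRAST = 0.15


def _validate_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D single-channel image, got shape {image.shape}")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    return image


def _otsu_foreground(smoothed: np.ndarray) -> Optional[np.ndarray]:
    """Foreground mask by Otsu, or None when there is no real contrast."""
    if smoothed.max() - smoothed.min() < 1e-6:
        return None
    threshold = threshold_otsu(smoothed)
    mask = smoothed > threshold
    if not mask.any() or mask.all():
        return None
    if smoothed[mask].mean() - smoothed[~mask].mean() < _MIN_CONTRAST:
        return None
    return mask


def segment_nuclei(
    nuclear_channel: np.ndarray,
    min_area: float = 30.0,
    smoothing_sigma: float = 1.0,
    min_seed_distance: int = 5,
    patch_id: str = "",
) -> List[NucleusRecord]:
    """Segment nuclei from the nuclear-marker channel.

    Gaussian smoothing, Otsu foreground, seeds from local maxima of the
    distance transform (minimum separation ``min_seed_distance``), then
    watershed on the inverted distance transform.  Regions smaller than
    ``min_area`` px^2 are discarded as noise specks.  A blank or contrast-free
    image yields an empty list.  Nuclei touching the patch border are kept;
    edge effects are handled later by the central-region filter on cells.
    """
    image = _validate_image(nuclear_channel)
    smoothed = gaussian(image, sigma=smoothing_sigma, preserve_range=True)
    foreground = _otsu_foreground(smoothed)
    if foreground is None:
        return []
    distance = ndi.distance_transform_edt(foreground)
    peaks = peak_local_max(distance, min_distance=min_seed_distance,
                           labels=foreground, exclude_border=False)
    if len(peaks) == 0:
        return []
    seeds = np.zeros(image.shape, dtype=np.int32)
    seeds[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-distance, seeds, mask=foreground)
    records = []
    for region in regionprops(labels):
        if region.area < min_area:
            continue
        row, col = region.centroid
        records.append(NucleusRecord(
            nucleus_id=int(region.label),
            centroid_row=float(row),
            centroid_col=float(col),
            area=float(region.area),
            equivalent_radius=math.sqrt(float(region.area) / math.pi),
            class_label="hepatocyte",
            patch_id=patch_id,
        ))
    return records


def segment_membranes(
    membrane_channel: np.ndarray,
    smoothing_sigma: float = 1.0,
) -> np.ndarray:
    """Partition the patch into cell regions bounded by membrane ridges.

    Membrane ridges are thresholded by Otsu on the smoothed channel; the
    connected components between ridges seed a watershed on the ridge
    landscape, which allocates the ridge pixels and returns a full label
    image.  A contrast-free (e.g. uniform) image yields a single region.
    """
    image = _validate_image(membrane_channel)
    smoothed = gaussian(image, sigma=smoothing_sigma, preserve_range=True)
    ridges = _otsu_foreground(smoothed)
    if ridges is None:
        return np.ones(image.shape, dtype=np.int32)
    interior, n_regions = ndi.label(~ridges)
    if n_regions == 0:
        return np.ones(image.shape, dtype=np.int32)
    return watershed(smoothed, interior.astype(np.int32))


def assign_nuclei_to_cells(
    nuclei: Sequence[NucleusRecord],
    cell_labels: np.ndarray,
) -> Tuple[List[CellAssignment], List[int]]:
    """Assign each nucleus to the cell region containing its centroid.

    The centroid is rounded to the nearest pixel and the region label at that
    pixel decides the cell; nuclei landing on background (label 0) are
    returned separately as unassigned.  Returns ``(assignments,
    unassigned_nucleus_ids)``; the assignments partition the assigned nuclei.
    """
    cell_labels = np.asarray(cell_labels)
    if cell_labels.ndim != 2:
        raise ValueError("cell label image must be 2-D")
    members: dict = {}
    unassigned: List[int] = []
    for nucleus in nuclei:
        row = min(max(int(round(nucleus.centroid_row)), 0), cell_labels.shape[0] - 1)
        col = min(max(int(round(nucleus.centroid_col)), 0), cell_labels.shape[1] - 1)
        label = int(cell_labels[row, col])
        if label == 0:
            unassigned.append(nucleus.nucleus_id)
        else:
            members.setdefault(label, []).append(nucleus)
    assignments = []
    for label in sorted(members):
        group = members[label]
        assignments.append(CellAssignment(
            cell_id=label,
            nucleus_ids=tuple(n.nucleus_id for n in group),
            cell_centroid_row=float(np.mean([n.centroid_row for n in group])),
            cell_centroid_col=float(np.mean([n.centroid_col for n in group])),
        ))
    return assignments, unassigned


T = TypeVar("T")


def _default_centroid(item) -> Tuple[float, float]:
    for row_attr, col_attr in (("cell_centroid_row", "cell_centroid_col"),
                               ("centroid_row", "centroid_col")):
        if hasattr(item, row_attr):
            return float(getattr(item, row_attr)), float(getattr(item, col_attr))
    row, col = item
    return float(row), float(col)


def filter_central(
    items: Sequence[T],
    patch_size: int | Tuple[int, int],
    padding: float,
    centroid: Callable[[T], Tuple[float, float]] = _default_centroid,
) -> List[T]:
    """Keep items whose centroid lies in the central region of the patch.

    The rule is half-open on both axes: ``padding <= coordinate <
    size - padding``.  With a 360 px patch and padding 30 the central region
    is 300x300; with a 500 px patch and padding 85 it is 330x330.  Order is
    preserved and the filter is idempotent.
    """
    if isinstance(patch_size, (tuple, list)):
        height, width = patch_size
    else:
        height = width = patch_size
    if padding < 0:
        raise ValueError("padding must be >= 0")
    if 2 * padding >= min(height, width):
        raise ValueError(
            f"padding {padding} leaves no central region in a "
            f"{height}x{width} patch")
    kept = []
    for item in items:
        row, col = centroid(item)
        if padding <= row < height - padding and padding <= col < width - padding:
            kept.append(item)
    return kept
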