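"""Seeded synthetic liver-tissue fixtures.

Two generators share one geometric layout engine:

* :func:`generate_if_patch` — a two-channel fluorescence-like patch (nuclear
  marker + membrane marker) with exact ground truth, emulating
  immunofluorescence slides where a nuclear stain marks hepatocyte nuclei and
  a membrane stain marks cell boundaries.
* :func:`generate_labelled_mask` — an integer instance-label image with a
  per-label class table, emulating the output of an upstream H&E nucleus
  segmenter that distinguishes hepatocyte nuclei from five other classes.

Cells are mono- or binuclear; binuclear cells are allocated by deterministic
quota ``round(fraction * n_cells)`` so tests can assert exact counts.  Nuclei
are ellipses (axis ratio drawn in [0.8, 1.0]) whose *equivalent radius*
(circle of equal area) follows the per-ploidy-class size model.  Sibling
nuclei are placed so that their relative distance (centroid distance minus
both radii) stays below ``intra_cell_nucleus_gap``, and nuclei of different
cells keep a relative distance of at least ``min_inter_cell_gap`` — the
separability downstream threshold calibration relies on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation
from skimage.draw import ellipse
from skimage.segmentation import find_boundaries

from .records import NUCLEUS_CLASSES, PLOIDY_LABELS

PLACEMENT_ATTEMPTS = 10_000
_FOREGROUND = 0.8
_BACKGROUND = 0.1
_NOISE_SD = 0.05

NON_HEPATOCYTE_CLASSES = tuple(c for c in NUCLEUS_CLASSES if c != "hepatocyte")


class PlacementError(RuntimeError):
    """Raised when rejection sampling cannot satisfy the layout constraints."""


@dataclass(frozen=True)
class SyntheticPatchSpec:
    """Layout parameters for one synthetic patch.

    Defaults describe the fluorescence-like regime: 360x360 px patches,
    nucleus equivalent radius around 9 px, a quarter of hepatocytes
    binuclear, and 2n/4n/8n class fractions matching the normal-liver
    proportions used by the sphere-slicing simulation.  ``area_multiplier``
    scales the mean radius per ploidy step.
    """

    height: int = 360
    width: int = 360
    n_cells: int = 40
    binuclear_fraction: float = 0.25
    nucleus_radius_mean: float = 9.0
    nucleus_radius_sd: float = 0.9
    intra_cell_nucleus_gap: float = 3.0
    min_inter_cell_gap: float = 12.0
    ploidy_class_fractions: Tuple[float, float, float] = (0.6605, 0.2248, 0.1147)
    area_multiplier: float = 1.18
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("patch dimensions must be positive")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if not 0.0 <= self.binuclear_fraction <= 1.0:
            raise ValueError("binuclear_fraction must lie in [0, 1]")
        for name in ("nucleus_radius_mean", "nucleus_radius_sd",
                     "intra_cell_nucleus_gap", "min_inter_cell_gap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        fr = self.ploidy_class_fractions
        if len(fr) != 3 or any(f < 0 or f > 1 for f in fr):
            raise ValueError("ploidy_class_fractions must be three fractions in [0, 1]")
        if abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError("ploidy_class_fractions must sum to 1")
        if self.intra_cell_nucleus_gap >= self.min_inter_cell_gap:
            raise ValueError("intra_cell_nucleus_gap must be < min_inter_cell_gap")


@dataclass(frozen=True)
class TrueNucleus:
    nucleus_id: int
    cell_id: Optional[int]
    centroid_row: float
    centroid_col: float
    radius: float
    area: float
    ploidy: Optional[str]
    class_label: str


@dataclass(frozen=True)
class TrueCell:
    cell_id: int
    nucleus_ids: Tuple[int, ...]
    centroid_row: float
    centroid_col: float


@dataclass(frozen=True)
class PatchTruth:
    """Exact geometry of a generated patch (hepatocyte cells + all nuclei)."""

    cells: Tuple[TrueCell, ...]
    nuclei: Tuple[TrueNucleus, ...]

    def nuclei_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "nucleus_id": n.nucleus_id,
                    "cell_id": n.cell_id if n.cell_id is not None else -1,
                    "row": n.centroid_row,
                    "col": n.centroid_col,
                    "radius_px": n.radius,
                    "area_px2": n.area,
                    "class": n.class_label,
                    "ploidy": n.ploidy if n.ploidy is not None else "",
                }
                for n in self.nuclei
            ],
            columns=["nucleus_id", "cell_id", "row", "col",
                     "radius_px", "area_px2", "class", "ploidy"],
        )

    def class_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"label": [n.nucleus_id for n in self.nuclei],
             "class": [n.class_label for n in self.nuclei]}
        )


# ---------------------------------------------------------------------------
# layout engine


def _quota_counts(fractions: Sequence[float], n: int) -> List[int]:
    """Largest-remainder apportionment of n items over fractions."""
    raw = [f * n for f in fractions]
    counts = [int(math.floor(x)) for x in raw]
    remainder = n - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: (raw[i] - counts[i], -i), reverse=True)
    for i in order[:remainder]:
        counts[i] += 1
    return counts


@dataclass
class _PlacedNucleus:
    row: float
    col: float
    target_radius: float
    axis_ratio: float
    orientation: float
    cell_index: Optional[int]
    ploidy: Optional[str]
    class_label: str


def _footprint(nuc: _PlacedNucleus, shape: Tuple[int, int]) -> Tuple[np.ndarray, np.ndarray]:
    # semi-axes a >= b with geometric mean equal to the target equivalent radius
    q = nuc.axis_ratio
    a = nuc.target_radius / math.sqrt(q)
    b = nuc.target_radius * math.sqrt(q)
    return ellipse(nuc.row, nuc.col, a, b, shape=shape, rotation=nuc.orientation)


def _semi_major(radius: float, axis_ratio: float) -> float:
    return radius / math.sqrt(axis_ratio)


def _fits(candidate: Sequence[_PlacedNucleus], placed: Sequence[_PlacedNucleus],
          gap: float) -> bool:
    # gap is enforced on equivalent radii; the semi-major extents additionally
    # guarantee that footprints cannot touch
    for c in candidate:
        for p in placed:
            d = math.hypot(c.row - p.row, c.col - p.col)
            if d - c.target_radius - p.target_radius < gap:
                return False
            if d < _semi_major(c.target_radius, c.axis_ratio) + \
                    _semi_major(p.target_radius, p.axis_ratio) + 1.0:
                return False
    return True


def _place_cells(spec: SyntheticPatchSpec, rng: np.random.Generator,
                 extra_nuclei: int = 0,
                 extra_radius: Optional[float] = None) -> List[_PlacedNucleus]:
    """Place hepatocyte cells (and optional non-hepatocyte singleton nuclei)."""
    n_bi = round(spec.binuclear_fraction * spec.n_cells)
    n_nuclei = spec.n_cells + n_bi
    class_counts = _quota_counts(spec.ploidy_class_fractions, n_nuclei)
    ploidy_pool = np.repeat(np.arange(3), class_counts)
    rng.shuffle(ploidy_pool)

    placed: List[_PlacedNucleus] = []
    pool_pos = 0
    # inter-cell margin above the stated minimum absorbs rasterisation jitter
    inter_gap = spec.min_inter_cell_gap + 1.5
    for cell_index in range(spec.n_cells):
        binuclear = cell_index < n_bi
        k = 2 if binuclear else 1
        classes = ploidy_pool[pool_pos:pool_pos + k]
        pool_pos += k
        radii = []
        for cls in classes:
            mean = spec.nucleus_radius_mean * spec.area_multiplier ** int(cls)
            sd = spec.nucleus_radius_sd * spec.area_multiplier ** int(cls)
            r = float(rng.normal(mean, sd))
            radii.append(max(r, 1.5))
        for attempt in range(PLACEMENT_ATTEMPTS):
            candidate: List[_PlacedNucleus] = []
            if binuclear:
                r1, r2 = radii
                q1, q2 = rng.uniform(0.8, 1.0), rng.uniform(0.8, 1.0)
                # siblings sit well inside the intra-cell gap so the truth
                # relative distance stays <= the stated gap after rasterisation
                sep = r1 + r2 + 0.7 * spec.intra_cell_nucleus_gap
                theta = rng.uniform(0, 2 * math.pi)
                half = sep / 2.0
                # major axes perpendicular to the separation axis: footprint
                # support along the axis is the semi-minor, so siblings at
                # sep >= r1 + r2 cannot overlap
                orient = theta + math.pi / 2.0
                ext = half + max(_semi_major(r1, q1), _semi_major(r2, q2)) + 1
                if spec.height - 2 * ext <= 0 or spec.width - 2 * ext <= 0:
                    raise PlacementError(
                        "cannot place: binuclear cell footprint exceeds patch size")
                mr = rng.uniform(ext, spec.height - ext)
                mc = rng.uniform(ext, spec.width - ext)
                dr, dc = half * math.sin(theta), half * math.cos(theta)
                for (r, q, rr, cc) in ((r1, q1, mr - dr, mc - dc),
                                       (r2, q2, mr + dr, mc + dc)):
                    candidate.append(_PlacedNucleus(
                        rr, cc, r, q, orient, cell_index,
                        PLOIDY_LABELS[int(classes[len(candidate)])], "hepatocyte"))
            else:
                r = radii[0]
                q = rng.uniform(0.8, 1.0)
                ext = _semi_major(r, q) + 1
                if spec.height - 2 * ext <= 0 or spec.width - 2 * ext <= 0:
                    raise PlacementError("cannot place: nucleus larger than patch")
                rr = rng.uniform(ext, spec.height - ext)
                cc = rng.uniform(ext, spec.width - ext)
                candidate.append(_PlacedNucleus(
                    rr, cc, r, q, rng.uniform(0, math.pi),
                    cell_index, PLOIDY_LABELS[int(classes[0])], "hepatocyte"))
            if binuclear:
                # exact footprint-disjointness check for the sibling pair
                shape = (spec.height, spec.width)
                rr1, cc1 = _footprint(candidate[0], shape)
                rr2, cc2 = _footprint(candidate[1], shape)
                keys1 = rr1.astype(np.int64) * spec.width + cc1
                keys2 = rr2.astype(np.int64) * spec.width + cc2
                if np.intersect1d(keys1, keys2).size:
                    continue
            if _fits(candidate, placed, inter_gap):
                placed.extend(candidate)
                break
        else:
            raise PlacementError(
                f"cannot place cell {cell_index}: min_inter_cell_gap="
                f"{spec.min_inter_cell_gap} unsatisfiable after "
                f"{PLACEMENT_ATTEMPTS} attempts")

    for j in range(extra_nuclei):
        r_mean = extra_radius if extra_radius is not None else 0.5 * spec.nucleus_radius_mean
        cls = NON_HEPATOCYTE_CLASSES[int(rng.integers(len(NON_HEPATOCYTE_CLASSES)))]
        for attempt in range(PLACEMENT_ATTEMPTS):
            r = max(float(rng.normal(r_mean, 0.1 * r_mean)), 1.5)
            q = rng.uniform(0.8, 1.0)
            ext = _semi_major(r, q) + 1
            rr = rng.uniform(ext, spec.height - ext)
            cc = rng.uniform(ext, spec.width - ext)
            candidate = [_PlacedNucleus(rr, cc, r, q,
                                        rng.uniform(0, math.pi), None, None, cls)]
            if _fits(candidate, placed, inter_gap):
                placed.extend(candidate)
                break
        else:
            raise PlacementError(
                f"cannot place non-hepatocyte nucleus {j}: gap constraint "
                f"unsatisfiable after {PLACEMENT_ATTEMPTS} attempts")
    return placed


def _rasterize(placed: Sequence[_PlacedNucleus],
               shape: Tuple[int, int]) -> Tuple[np.ndarray, PatchTruth]:
    """Draw the label image and build truth from the rasterised footprints."""
    labels = np.zeros(shape, dtype=np.uint16)
    nuclei: List[TrueNucleus] = []
    for i, nuc in enumerate(placed, start=1):
        rr, cc = _footprint(nuc, shape)
        if rr.size == 0:
            raise PlacementError("cannot place: nucleus footprint rasterised to zero pixels")
        labels[rr, cc] = i
        area = float(rr.size)
        nuclei.append(TrueNucleus(
            nucleus_id=i,
            cell_id=(nuc.cell_index + 1) if nuc.cell_index is not None else None,
            centroid_row=float(rr.mean()),
            centroid_col=float(cc.mean()),
            radius=math.sqrt(area / math.pi),
            area=area,
            ploidy=nuc.ploidy,
            class_label=nuc.class_label,
        ))
    cells: List[TrueCell] = []
    by_cell: dict = {}
    for n in nuclei:
        if n.cell_id is not None:
            by_cell.setdefault(n.cell_id, []).append(n)
    for cid in sorted(by_cell):
        members = by_cell[cid]
        cells.append(TrueCell(
            cell_id=cid,
            nucleus_ids=tuple(m.nucleus_id for m in members),
            centroid_row=float(np.mean([m.centroid_row for m in members])),
            centroid_col=float(np.mean([m.centroid_col for m in members])),
        ))
    return labels, PatchTruth(cells=tuple(cells), nuclei=tuple(nuclei))


# ---------------------------------------------------------------------------
# public generators


def generate_if_patch(spec: SyntheticPatchSpec) -> Tuple[np.ndarray, np.ndarray, PatchTruth]:
    """Generate a two-channel fluorescence-like patch with ground truth.

    Returns ``(nuclear_channel, membrane_channel, truth)``.  Channels are
    float images on [0, 1]: foreground 0.8, background 0.1, additive Gaussian
    noise (sd 0.05).  Membrane ridges are the boundaries of the Voronoi
    partition induced by the true cell centroids, the stand-in for a
    membrane marker outlining each hepatocyte.
    """
    rng = np.random.default_rng(spec.seed)
    shape = (spec.height, spec.width)
    placed = _place_cells(spec, rng)
    labels, truth = _rasterize(placed, shape)

    nuclear = np.full(shape, _BACKGROUND, dtype=np.float64)
    nuclear[labels > 0] = _FOREGROUND

    membrane = np.full(shape, _BACKGROUND, dtype=np.float64)
    if truth.cells:
        centroids = np.array([[c.centroid_row, c.centroid_col] for c in truth.cells])
        rows, cols = np.mgrid[0:spec.height, 0:spec.width]
        d2 = ((rows[..., None] - centroids[:, 0]) ** 2
              + (cols[..., None] - centroids[:, 1]) ** 2)
        region = np.argmin(d2, axis=-1) + 1
        ridges = find_boundaries(region, mode="thick")
        ridges = binary_dilation(ridges)
        membrane[ridges] = _FOREGROUND

    nuclear = nuclear + rng.normal(0.0, _NOISE_SD, shape)
    membrane = membrane + rng.normal(0.0, _NOISE_SD, shape)
    return np.clip(nuclear, 0.0, 1.0), np.clip(membrane, 0.0, 1.0), truth


def generate_labelled_mask(
    spec: SyntheticPatchSpec,
    non_hepatocyte_fraction: float = 0.0,
) -> Tuple[np.ndarray, pd.DataFrame, PatchTruth]:
    """Generate an instance-label image plus class table, mimicking the output
    of an H&E nucleus segmenter.

    ``non_hepatocyte_fraction`` of all nuclei carry one of the five
    non-hepatocyte classes (stroma, lymphocyte, macrophage, red blood cell,
    karyorrhexis); these extra nuclei are smaller singletons with no ploidy
    label.  Returns ``(label_image, class_table, truth)`` where the class
    table maps each positive label to its class.
    """
    if not 0.0 <= non_hepatocyte_fraction < 1.0:
        raise ValueError("non_hepatocyte_fraction must lie in [0, 1)")
    rng = np.random.default_rng(spec.seed)
    n_hep = spec.n_cells + round(spec.binuclear_fraction * spec.n_cells)
    n_extra = round(non_hepatocyte_fraction * n_hep / (1.0 - non_hepatocyte_fraction))
    placed = _place_cells(spec, rng, extra_nuclei=n_extra)
    labels, truth = _rasterize(placed, (spec.height, spec.width))
    return labels, truth.class_table(), truth
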