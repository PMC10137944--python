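"""Core record types shared across the pipeline.

A hepatocyte's ploidy has two layers: cellular ploidy (how many nuclei the
cell holds) and nuclear ploidy (the DNA content class of each nucleus,
inferred downstream from cross-sectional area).  The records here carry a
segmented nucleus instance, its assignment to a cell, and the grouped cell.
Coordinates are 0-based ``(row, col)`` with pixel centres at integer
coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

NUCLEUS_CLASSES = (
    "hepatocyte",
    "stroma",
    "lymphocyte",
    "macrophage",
    "red_blood_cell",
    "karyorrhexis",
)

PLOIDY_LABELS = ("2n", "4n", "8n")


def equivalent_radius(area: float) -> float:
    """Radius of the circle with the same area as the region."""
    return math.sqrt(area / math.pi)


@dataclass(frozen=True)
class NucleusRecord:
    """One segmented nucleus instance.

    ``equivalent_radius`` is derived from the area (circle of equal area);
    it is the radius used in the relative-distance formula.
    """

    nucleus_id: int
    centroid_row: float
    centroid_col: float
    area: float
    equivalent_radius: float = field(default=None)  # type: ignore[assignment]
    class_label: str = "hepatocyte"
    patch_id: str = ""

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError(f"nucleus {self.nucleus_id}: area must be > 0, got {self.area}")
        if self.equivalent_radius is None:
            object.__setattr__(self, "equivalent_radius", equivalent_radius(self.area))
        if self.class_label not in NUCLEUS_CLASSES:
            raise ValueError(
                f"nucleus {self.nucleus_id}: unknown class {self.class_label!r}; "
                f"expected one of {NUCLEUS_CLASSES}"
            )


@dataclass(frozen=True)
class CellAssignment:
    """A nucleus group assigned to one membrane-bounded cell region."""

    cell_id: int
    nucleus_ids: Tuple[int, ...]
    cell_centroid_row: float
    cell_centroid_col: float
    in_central_region: bool = True

    def __post_init__(self) -> None:
        if len(self.nucleus_ids) < 1:
            raise ValueError(f"cell {self.cell_id}: must contain at least one nucleus")

    @property
    def centroid_row(self) -> float:
        return self.cell_centroid_row

    @property
    def centroid_col(self) -> float:
        return self.cell_centroid_col


@dataclass(frozen=True)
class CellRecord:
    """A hepatocyte reconstructed by relative-distance grouping.

    ``cellular_ploidy`` is the nucleus count (mononuclear = 1, binuclear = 2,
    larger components signal a misconfigured threshold and are flagged in
    summaries rather than rejected).
    """

    cell_id: int
    nucleus_ids: Tuple[int, ...]
    cell_centroid_row: float
    cell_centroid_col: float
    in_central_region: bool = True

    @property
    def cellular_ploidy(self) -> int:
        return len(self.nucleus_ids)

    @property
    def centroid_row(self) -> float:
        return self.cell_centroid_row

    @property
    def centroid_col(self) -> float:
        return self.cell_centroid_col


@dataclass(frozen=True)
class NucleusPair:
    """A sampled pair of nuclei with their relative distance.

    relative distance = d - r1 - r2, the gap between the two equivalent
    circles; negative when footprints overlap.  ``same_cell`` is True for
    RDNSC samples (nuclei of one cell), False for RDNDC samples (nuclei of
    different cells), None when unknown.
    """

    nucleus_id_a: int
    nucleus_id_b: int
    absolute_distance: float
    radius_a: float
    radius_b: float
    same_cell: Optional[bool] = None

    @property
    def relative_distance(self) -> float:
        return self.absolute_distance - self.radius_a - self.radius_b


@dataclass(frozen=True)
class NuclearPloidyCall:
    """Per-nucleus ploidy call with mixture posterior (orders as 2n, 4n, 8n)."""

    nucleus_id: int
    area: float
    ploidy: str
    posterior: Tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.ploidy not in PLOIDY_LABELS:
            raise ValueError(f"ploidy must be one of {PLOIDY_LABELS}, got {self.ploidy!r}")
        if abs(sum(self.posterior) - 1.0) > 1e-6:
            raise ValueError("posterior probabilities must sum to 1")
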