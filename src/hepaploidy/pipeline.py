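"""End-to-end orchestration: masks in, per-cell ploidy report out.

``load_instances`` ingests the output format of an upstream nucleus
segmenter (an integer instance-label image plus a label-to-class table);
``run_patch`` filters to hepatocyte nuclei, groups them into cells by
thresholded relative distance, drops cells outside the central region,
calls nuclear ploidy with the mixture model and emits one report row per
nucleus.  ``run_calibration`` reproduces the threshold calibration from
fluorescence-like patches and converts it to the target resolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from skimage.measure import regionprops

from . import synthetic
from .distance import (CalibrationResult, ResolutionSpec,
                       collect_calibration_pairs, convert_threshold,
                       select_threshold)
from .gmm import NuclearPloidyGMM, classify_nuclei, fit_gmm, summarize_total_ploidy
from .grouping import group_nuclei
from .records import NUCLEUS_CLASSES, CellRecord, NucleusRecord, equivalent_radius
from .segmentation import (assign_nuclei_to_cells, filter_central,
                           segment_membranes, segment_nuclei)

logger = logging.getLogger(__name__)

REPORT_COLUMNS = [
    "patch_id", "cell_id", "cell_row", "cell_col", "cellular_ploidy",
    "nucleus_id", "nuclear_area_px2", "nuclear_ploidy",
    "p_2n", "p_4n", "p_8n", "cell_total_ploidy",
]


@dataclass
class PipelineConfig:
    """Tunables of the quantification pipeline.

    ``threshold_he`` and ``padding_he`` are the two user-facing knobs: the
    relative-distance threshold (default 15.54 px, the converted
    fluorescence calibration) and the edge margin that defines the central
    region (default 85 px, leaving 330x330 of a 500 px patch).
    """

    threshold_he: float = 15.54
    padding_he: float = 85.0
    patch_size: int = 500
    resolution_he: float = 0.23
    gmm_model_path: Optional[str] = None  # None -> fit from the input areas
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.threshold_he <= 0:
            raise ValueError("threshold_he must be positive")
        if 2 * self.padding_he >= self.patch_size:
            raise ValueError("2 * padding_he must be smaller than patch_size")
        if self.resolution_he <= 0:
            raise ValueError("resolution_he must be positive")


def load_instances(label_image: np.ndarray, class_table: pd.DataFrame,
                   patch_id: str = "") -> List[NucleusRecord]:
    """Build nucleus records from an instance-label image and class table.

    The table must have ``label`` and ``class`` columns covering exactly the
    positive labels present in the image; centroid, area and equivalent
    radius are measured from the mask.
    """
    label_image = np.asarray(label_image)
    if label_image.ndim != 2:
        raise ValueError("label image must be 2-D")
    for column in ("label", "class"):
        if column not in class_table.columns:
            raise ValueError(f"class table is missing the {column!r} column")
    classes = {int(r.label): str(r["class"]) for _, r in class_table.iterrows()}
    unknown = sorted(set(classes.values()) - set(NUCLEUS_CLASSES))
    if unknown:
        raise ValueError(f"unknown nucleus classes in table: {unknown}")

    regions = regionprops(label_image.astype(np.int64))
    present = {region.label for region in regions}
    missing_class = sorted(present - classes.keys())
    missing_pixels = sorted(classes.keys() - present)
    if missing_class or missing_pixels:
        raise ValueError(
            f"label/class table mismatch: labels without class row "
            f"{missing_class}; class rows without pixels {missing_pixels}")

    records = []
    for region in regions:
        row, col = region.centroid
        records.append(NucleusRecord(
            nucleus_id=int(region.label),
            centroid_row=float(row),
            centroid_col=float(col),
            area=float(region.area),
            equivalent_radius=equivalent_radius(float(region.area)),
            class_label=classes[int(region.label)],
            patch_id=patch_id,
        ))
    return records


def _resolve_gmm(config: PipelineConfig, nuclei: Sequence[NucleusRecord],
                 gmm: Optional[NuclearPloidyGMM]) -> NuclearPloidyGMM:
    if gmm is not None:
        return gmm
    if config.gmm_model_path is not None:
        return NuclearPloidyGMM.from_json(config.gmm_model_path)
    areas = [n.area for n in nuclei]
    return fit_gmm(areas, training_resolution=config.resolution_he)


def run_patch(config: PipelineConfig, nuclei: Sequence[NucleusRecord],
              gmm: Optional[NuclearPloidyGMM] = None) -> pd.DataFrame:
    """Quantify ploidy on one patch; returns the long-format report.

    One row per nucleus of every cell whose centroid passes the central-
    region filter, with the cell fields repeated: patch and cell identity,
    cell centroid, cellular ploidy, nuclear area, nuclear ploidy with its
    three posterior probabilities, and the cell's total ploidy.
    """
    hepatocytes = [n for n in nuclei if n.class_label == "hepatocyte"]
    logger.info("patch: %d nuclei in, %d hepatocyte-class",
                len(nuclei), len(hepatocytes))
    if not hepatocytes:
        logger.warning("no hepatocyte nuclei on this patch; empty report")
        return pd.DataFrame(columns=REPORT_COLUMNS)

    cells = group_nuclei(hepatocytes, config.threshold_he)
    kept = filter_central(cells, config.patch_size, config.padding_he)
    kept = [CellRecord(c.cell_id, c.nucleus_ids, c.cell_centroid_row,
                       c.cell_centroid_col, in_central_region=True)
            for c in kept]
    logger.info("%d cells, %d inside the central region", len(cells), len(kept))
    if not kept:
        return pd.DataFrame(columns=REPORT_COLUMNS)

    model = _resolve_gmm(config, hepatocytes, gmm)
    calls = classify_nuclei(model, hepatocytes, resolution=config.resolution_he)
    call_of = {c.nucleus_id: c for c in calls}
    nucleus_of = {n.nucleus_id: n for n in hepatocytes}
    totals = summarize_total_ploidy(kept, calls).set_index("cell_id")

    rows = []
    for cell in kept:
        for nid in cell.nucleus_ids:
            call = call_of[nid]
            rows.append({
                "patch_id": nucleus_of[nid].patch_id,
                "cell_id": cell.cell_id,
                "cell_row": cell.cell_centroid_row,
                "cell_col": cell.cell_centroid_col,
                "cellular_ploidy": cell.cellular_ploidy,
                "nucleus_id": nid,
                "nuclear_area_px2": nucleus_of[nid].area,
                "nuclear_ploidy": call.ploidy,
                "p_2n": call.posterior[0],
                "p_4n": call.posterior[1],
                "p_8n": call.posterior[2],
                "cell_total_ploidy": int(totals.loc[cell.cell_id, "total_ploidy"]),
            })
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


PatchInput = Union[synthetic.SyntheticPatchSpec, Tuple[np.ndarray, np.ndarray]]


def run_calibration(
    patches: Sequence[PatchInput],
    resolution: ResolutionSpec = ResolutionSpec(),
    padding_if: float = 30.0,
    min_nucleus_area: float = 30.0,
) -> Tuple[CalibrationResult, float]:
    """Calibrate the relative-distance threshold from fluorescence-like data.

    Each patch is either a ``(nuclear_channel, membrane_channel)`` image
    pair or a :class:`~hepaploidy.synthetic.SyntheticPatchSpec` to generate
    one.  Nuclei and membranes are watershed-segmented, nuclei assigned to
    cells, cells filtered to the central region, and the pooled RDNSC/RDNDC
    samples drive threshold selection.  Returns the calibration plus the
    threshold converted to the target resolution.
    """
    if not patches:
        raise ValueError("at least one patch is required")
    pooled = []
    for patch in patches:
        if isinstance(patch, synthetic.SyntheticPatchSpec):
            nuclear, membrane, _ = synthetic.generate_if_patch(patch)
        else:
            nuclear, membrane = patch
        nuclei = segment_nuclei(nuclear, min_area=min_nucleus_area)
        cell_labels = segment_membranes(membrane)
        assignments, unassigned = assign_nuclei_to_cells(nuclei, cell_labels)
        if unassigned:
            logger.warning("%d nuclei fell on background and were dropped",
                           len(unassigned))
        assignments = filter_central(assignments, nuclear.shape, padding_if)
        kept_ids = {nid for a in assignments for nid in a.nucleus_ids}
        kept_nuclei = [n for n in nuclei if n.nucleus_id in kept_ids]
        pooled.extend(collect_calibration_pairs(kept_nuclei, assignments))
    result = select_threshold(pooled)
    threshold_he = convert_threshold(result.threshold_if, resolution)
    logger.info("calibrated threshold %.3f px -> %.2f px at %.2f um/px",
                result.threshold_if, threshold_he, resolution.resolution_he)
    return result, threshold_he
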