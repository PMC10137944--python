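"""Nuclear relative distance: computation, calibration and resolution transfer.

The relative distance between two nuclei is the centroid distance minus both
equivalent radii — the gap between the two equal-area circles.  Nuclei of
one cell sit much closer (RDNSC, relative distance between nuclei within the
same cell) than nuclei of neighbouring cells (RDNDC, relative distance
between nuclei within different cells), so a single threshold on relative
distance separates the two populations.  The threshold is calibrated on
membrane-resolved fluorescence data by maximising F1 over a sweep of
candidate thresholds and is transferred between image sources by the ratio
of their pixel resolutions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .records import CellAssignment, NucleusPair, NucleusRecord

logger = logging.getLogger(__name__)


def relative_distance(d: float, r1: float, r2: float) -> float:
    """Gap between two equal-area circles: ``d - r1 - r2``.

    ``d`` is the Euclidean distance between the nuclear centroids and ``r1``,
    ``r2`` the equivalent radii.  Negative values mean overlapping
    footprints.
    """
    if d < 0:
        raise ValueError(f"absolute distance must be >= 0, got {d}")
    if r1 <= 0 or r2 <= 0:
        raise ValueError(f"radii must be > 0, got {r1}, {r2}")
    return d - r1 - r2


@dataclass(frozen=True)
class ResolutionSpec:
    """Pixel resolutions of the two image sources, in micrometres per pixel."""

    resolution_if: float = 0.65
    resolution_he: float = 0.23

    def __post_init__(self) -> None:
        if self.resolution_if <= 0 or self.resolution_he <= 0:
            raise ValueError("resolutions must be positive")


def convert_threshold(threshold_if: float, res: ResolutionSpec) -> float:
    """Transfer a pixel threshold between resolutions.

    A physical distance of ``threshold_if`` pixels at ``resolution_if``
    micrometres/pixel spans ``threshold_if * resolution_if / resolution_he``
    pixels at the target resolution.  Full precision is returned; round to
    two decimals for reporting.
    """
    if threshold_if <= 0:
        raise ValueError("threshold must be positive")
    return threshold_if * res.resolution_if / res.resolution_he


def collect_calibration_pairs(
    nuclei: Sequence[NucleusRecord],
    assignments: Sequence[CellAssignment],
) -> List[NucleusPair]:
    """Collect per-nucleus RDNDC and RDNSC calibration samples.

    For every nucleus, one RDNDC pair: its nearest nucleus in a different
    cell, nearest by *relative* distance (the quantity the classifier
    thresholds).  For every nucleus of a polynuclear cell, additionally one
    RDNSC pair: its nearest nucleus within the same cell.  Sampling is per
    nucleus, so an unordered pair can legitimately appear twice.  Ties are
    broken toward the smaller nucleus_id.
    """
    cell_of = {}
    for assignment in assignments:
        for nid in assignment.nucleus_ids:
            cell_of[nid] = assignment.cell_id
    missing = [n.nucleus_id for n in nuclei if n.nucleus_id not in cell_of]
    if missing:
        raise ValueError(f"nuclei without a cell assignment: {missing}")

    ordered = sorted(nuclei, key=lambda n: n.nucleus_id)
    n = len(ordered)
    if n < 2:
        return []
    coords = np.array([[x.centroid_row, x.centroid_col] for x in ordered])
    radii = np.array([x.equivalent_radius for x in ordered])
    cells = np.array([cell_of[x.nucleus_id] for x in ordered])
    dist = cdist(coords, coords)
    rel = dist - radii[:, None] - radii[None, :]

    if len(set(cells.tolist())) < 2:
        logger.warning("only one cell present: no RDNDC pairs can be collected")

    pairs: List[NucleusPair] = []
    for i in range(n):
        same = (cells == cells[i])
        same[i] = False
        diff = ~(cells == cells[i])
        for mask, same_cell in ((diff, False), (same, True)):
            if not mask.any():
                continue
            # argmin over ascending nucleus_id order breaks ties deterministically
            masked = np.where(mask, rel[i], np.inf)
            j = int(np.argmin(masked))
            pairs.append(NucleusPair(
                nucleus_id_a=ordered[i].nucleus_id,
                nucleus_id_b=ordered[j].nucleus_id,
                absolute_distance=float(dist[i, j]),
                radius_a=float(radii[i]),
                radius_b=float(radii[j]),
                same_cell=same_cell,
            ))
    return pairs


@dataclass
class CalibrationResult:
    """Selected relative-distance threshold with its supporting evidence."""

    threshold_if: float
    f1_at_threshold: float
    precision_recall: pd.DataFrame  # columns: threshold, precision, recall, f1
    roc: pd.DataFrame  # columns: threshold, fpr, tpr
    auc: float
    n_rdnsc: int
    n_rdndc: int

    def to_json(self) -> str:
        return json.dumps({
            "threshold_if": self.threshold_if,
            "f1_at_threshold": self.f1_at_threshold,
            "auc": self.auc,
            "n_rdnsc": self.n_rdnsc,
            "n_rdndc": self.n_rdndc,
        }, indent=2)


def _sweep(distances: np.ndarray, same_cell: np.ndarray) -> CalibrationResult:
    """Threshold sweep over midpoint candidates; positive class = same cell,
    predicted positive iff relative distance < threshold."""
    distances = np.asarray(distances, dtype=np.float64)
    same_cell = np.asarray(same_cell, dtype=bool)
    if same_cell.all():
        raise ValueError("calibration requires different-cell (RDNDC) pairs; none present")
    if not same_cell.any():
        raise ValueError("calibration requires same-cell (RDNSC) pairs; none present")

    unique = np.unique(distances)
    candidates = np.concatenate((
        [unique[0] - 1.0],
        (unique[:-1] + unique[1:]) / 2.0,
        [unique[-1] + 1.0],
    ))
    n_pos = int(same_cell.sum())
    n_neg = int((~same_cell).sum())

    order = np.argsort(distances, kind="stable")
    sorted_d = distances[order]
    sorted_pos = same_cell[order].astype(np.int64)
    cum_pos = np.concatenate(([0], np.cumsum(sorted_pos)))
    cum_all = np.arange(len(sorted_d) + 1)

    # predictions below each candidate threshold, via binary search
    idx = np.searchsorted(sorted_d, candidates, side="left")
    tp = cum_pos[idx].astype(np.float64)
    fp = (cum_all[idx] - cum_pos[idx]).astype(np.float64)
    fn = n_pos - tp
    denom = 2 * tp + fp + fn
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = np.where(denom > 0, 2 * tp / denom, 0.0)
        precision = np.where(tp + fp > 0, tp / (tp + fp), 1.0)
    recall = tp / n_pos
    tpr = tp / n_pos
    fpr = fp / n_neg

    best = int(np.argmax(f1))  # first (smallest) maximiser on ascending candidates
    auc = float(np.trapezoid(tpr, fpr))
    return CalibrationResult(
        threshold_if=float(candidates[best]),
        f1_at_threshold=float(f1[best]),
        precision_recall=pd.DataFrame({
            "threshold": candidates, "precision": precision,
            "recall": recall, "f1": f1}),
        roc=pd.DataFrame({"threshold": candidates, "fpr": fpr, "tpr": tpr}),
        auc=auc,
        n_rdnsc=n_pos,
        n_rdndc=n_neg,
    )


class ThresholdCalibrator(ClassifierMixin, BaseEstimator):
    """F1-maximising threshold classifier on nuclear relative distance.

    A pair of nuclei is predicted to share a cell iff its relative distance
    is strictly below the fitted threshold.  Candidate thresholds are the
    midpoints between consecutive distinct distances plus sentinels beyond
    the range; the smallest candidate maximising F1 is chosen, which makes
    the fit deterministic.

    Attributes (after ``fit``)
    --------------------------
    threshold_ : float
        Selected relative-distance threshold (pixels).
    f1_ : float
        F1 score at the threshold.
    auc_ : float
        Area under the ROC sweep (trapezoidal rule).
    calibration_ : CalibrationResult
        Full curves and sample counts.
    """

    classes_ = np.array([False, True])

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("X must be 1-D relative distances or shape (n, 1)")
            X = X[:, 0]
        result = _sweep(X, np.asarray(y, dtype=bool))
        self.calibration_ = result
        self.threshold_ = result.threshold_if
        self.f1_ = result.f1_at_threshold
        self.auc_ = result.auc
        return self

    def predict(self, X):
        check_is_fitted(self, "threshold_")
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 2:
            X = X[:, 0]
        return X < self.threshold_


def select_threshold(pairs: Sequence[NucleusPair]) -> CalibrationResult:
    """Select the F1-maximising relative-distance threshold from labelled pairs."""
    labelled = [p for p in pairs if p.same_cell is not None]
    if not labelled:
        raise ValueError("no labelled pairs provided")
    distances = np.array([p.relative_distance for p in labelled])
    same = np.array([p.same_cell for p in labelled])
    return ThresholdCalibrator().fit(distances, same).calibration_


def pairs_to_frame(pairs: Sequence[NucleusPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [{
            "nucleus_id_a": p.nucleus_id_a,
            "nucleus_id_b": p.nucleus_id_b,
            "absolute_distance": p.absolute_distance,
            "radius_a": p.radius_a,
            "radius_b": p.radius_b,
            "relative_distance": p.relative_distance,
            "same_cell": p.same_cell,
        } for p in pairs],
        columns=["nucleus_id_a", "nucleus_id_b", "absolute_distance",
                 "radius_a", "radius_b", "relative_distance", "same_cell"],
    )
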