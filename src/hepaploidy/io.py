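"""Reading and writing images, label masks and record tables.

Images are exchanged as single-channel 16-bit TIFF or PNG.  Float images on
[0, 1] are scaled to the full 16-bit range on write and scaled back on read;
integer label masks are stored verbatim.  Tables go through CSV with fixed,
documented headers.
"""

from __future__ import annotations

import os
from typing import Iterable, List, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .records import CellAssignment, CellRecord, NucleusRecord

_U16_MAX = np.iinfo(np.uint16).max


def _is_tiff(path: str) -> bool:
    return os.path.splitext(str(path))[1].lower() in (".tif", ".tiff")


def write_image(path: str, image: np.ndarray) -> None:
    """Write a single-channel image as 16-bit TIFF/PNG.

    Float input must lie in [0, 1] and is scaled to uint16.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D single-channel image, got shape {image.shape}")
    if np.issubdtype(image.dtype, np.floating):
        if image.min() < 0 or image.max() > 1:
            raise ValueError("float images must lie in [0, 1]")
        data = np.round(image * _U16_MAX).astype(np.uint16)
    else:
        data = image.astype(np.uint16)
    if _is_tiff(path):
        tifffile.imwrite(path, data)
    else:
        iio.imwrite(path, data)


def read_image(path: str) -> np.ndarray:
    """Read a single-channel image; integer data is rescaled to float [0, 1]."""
    data = tifffile.imread(path) if _is_tiff(path) else iio.imread(path)
    if data.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel image, got shape {data.shape}")
    if np.issubdtype(data.dtype, np.integer):
        return data.astype(np.float64) / np.iinfo(data.dtype).max
    return data.astype(np.float64)


def write_label_mask(path: str, labels: np.ndarray) -> None:
    """Write an integer instance-label image (background 0) as 16-bit."""
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise ValueError("label mask must be 2-D")
    if labels.min() < 0 or labels.max() > _U16_MAX:
        raise ValueError("labels must fit in uint16")
    data = labels.astype(np.uint16)
    if _is_tiff(path):
        tifffile.imwrite(path, data)
    else:
        iio.imwrite(path, data)


def read_label_mask(path: str) -> np.ndarray:
    data = tifffile.imread(path) if _is_tiff(path) else iio.imread(path)
    if data.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D label mask, got shape {data.shape}")
    return data.astype(np.int64)


NUCLEUS_COLUMNS = ["nucleus_id", "centroid_row", "centroid_col", "area",
                   "equivalent_radius", "class_label", "patch_id"]


def nuclei_to_frame(nuclei: Iterable[NucleusRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{c: getattr(n, c) for c in NUCLEUS_COLUMNS} for n in nuclei],
        columns=NUCLEUS_COLUMNS,
    )


def nuclei_from_frame(frame: pd.DataFrame) -> List[NucleusRecord]:
    return [
        NucleusRecord(
            nucleus_id=int(row.nucleus_id),
            centroid_row=float(row.centroid_row),
            centroid_col=float(row.centroid_col),
            area=float(row.area),
            equivalent_radius=float(row.equivalent_radius),
            class_label=str(row.class_label),
            patch_id=str(row.patch_id) if not pd.isna(row.patch_id) else "",
        )
        for row in frame.itertuples(index=False)
    ]


def write_nuclei_csv(path: str, nuclei: Iterable[NucleusRecord]) -> None:
    nuclei_to_frame(nuclei).to_csv(path, index=False)


def read_nuclei_csv(path: str) -> List[NucleusRecord]:
    return nuclei_from_frame(pd.read_csv(path, keep_default_na=False))


def cells_to_frame(cells: Sequence[CellRecord | CellAssignment]) -> pd.DataFrame:
    rows = [
        {
            "cell_id": c.cell_id,
            "row": c.cell_centroid_row,
            "col": c.cell_centroid_col,
            "cellular_ploidy": len(c.nucleus_ids),
            "nucleus_ids": ";".join(str(i) for i in c.nucleus_ids),
            "in_central_region": c.in_central_region,
        }
        for c in cells
    ]
    return pd.DataFrame(rows, columns=["cell_id", "row", "col", "cellular_ploidy",
                                       "nucleus_ids", "in_central_region"])


def write_cells_csv(path: str, cells: Sequence[CellRecord | CellAssignment]) -> None:
    cells_to_frame(cells).to_csv(path, index=False)
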