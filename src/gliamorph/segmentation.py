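"""Fixed-threshold identification of immunopositive microglia.

Mirrors the classical densitometry workflow for DAB micrographs: the image
is converted to 8-bit grayscale and immunostained cells are identified by a
fixed threshold-level mask, with the threshold held constant (within the
band 160-180) across all sections of the same batch.  Synthetic images are
rendered signal-bright on a dark background, so the mask is ``value >=
threshold``.

Connected components of the mask are labelled with 8-connectivity (thin
diagonal processes stay connected), small specks are removed, and a soma
centroid is located per cell at the maximum of the distance transform —
robust for asymmetric arbors, and the analogue of counting only cells with
a visible cell body.  Fragmented cells (disconnected process segments of
one cell, as rendered by the dystrophic preset) are regrouped by closing
gaps up to ``join_gaps_um`` before labelling; labels are then transferred
back to the original mask pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.util import img_as_ubyte

from .errors import FormatError, ParameterError

__all__ = [
    "SegmentationParams",
    "BinaryMask",
    "LabeledCells",
    "to_gray8",
    "threshold_mask",
    "label_cells",
]

THRESHOLD_BAND = (160, 180)


@dataclass
class SegmentationParams:
    """Parameters of the fixed-threshold segmentation stage.

    ``threshold`` must lie in the band 160-180 (the range used for DAB
    densitometry) unless ``allow_threshold_override`` is set.  The default
    170 is the midpoint of the band.  ``join_gaps_um`` is the largest
    fragmentation gap bridged when grouping disconnected segments of one
    dystrophic cell into a single label (rendered gaps are 2-4 um; the
    default comfortably exceeds them while staying far below the soma
    exclusion distance between neighbouring cells).
    """

    threshold: int = 170
    min_object_area_um2: float = 20.0
    soma_min_radius_um: float = 2.0
    join_gaps_um: float = 5.0
    allow_threshold_override: bool = False

    def __post_init__(self) -> None:
        lo, hi = THRESHOLD_BAND
        if not self.allow_threshold_override and not lo <= self.threshold <= hi:
            raise ParameterError(
                f"threshold {self.threshold} outside the fixed band [{lo}, {hi}]; "
                "set allow_threshold_override=True to bypass"
            )
        if not 0 <= self.threshold <= 255:
            raise ParameterError("threshold must be an 8-bit value")
        if self.min_object_area_um2 <= 0:
            raise ParameterError("min_object_area_um2 must be > 0")
        if self.soma_min_radius_um <= 0:
            raise ParameterError("soma_min_radius_um must be > 0")
        if self.join_gaps_um < 0:
            raise ParameterError("join_gaps_um must be >= 0")


@dataclass
class BinaryMask:
    """A thresholded (immunopositive) mask with physical pixel size."""

    grid: np.ndarray  # bool (H, W)
    px_size_um: float

    @property
    def positive_area_um2(self) -> float:
        return float(self.grid.sum()) * self.px_size_um**2


@dataclass
class LabeledCells:
    """Labelled microglial cells.

    ``label_grid`` assigns every positive pixel a consecutive positive
    integer label (0 = background).  ``cells`` has one row per cell with
    columns ``label, area_um2, soma_x_um, soma_y_um, soma_radius_um,
    min_row, min_col, max_row, max_col``.
    """

    label_grid: np.ndarray  # int32 (H, W)
    cells: pd.DataFrame
    px_size_um: float

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def cell_mask(self, label: int) -> np.ndarray:
        """Boolean patch of one cell, cropped to its bounding box."""
        row = self.cells.loc[self.cells["label"] == label]
        if row.empty:
            raise KeyError(f"no cell with label {label}")
        r = row.iloc[0]
        sub = self.label_grid[
            int(r.min_row) : int(r.max_row) + 1, int(r.min_col) : int(r.max_col) + 1
        ]
        return sub == label


def to_gray8(raster: np.ndarray) -> np.ndarray:
    """Convert a single-channel raster of any bit depth to 8-bit grayscale.

    Linear rescale over the dtype range (so a full-range 16-bit ramp maps
    onto the full 8-bit ramp); idempotent on 8-bit input.  Multichannel
    input is rejected — stain-to-gray conversion is out of scope.
    """
    arr = np.asarray(raster)
    if arr.ndim != 2:
        raise FormatError(f"expected a single-channel 2-D raster, got shape {arr.shape}")
    if arr.dtype == np.uint8:
        return arr
    return img_as_ubyte(arr)


def threshold_mask(raster: np.ndarray, params: SegmentationParams, px_size_um: float = 1.0) -> BinaryMask:
    """Threshold-level mask: true exactly where ``raster >= threshold``."""
    arr = np.asarray(raster)
    if arr.dtype != np.uint8:
        raise FormatError("threshold_mask expects an 8-bit raster; use to_gray8 first")
    return BinaryMask(grid=arr >= params.threshold, px_size_um=px_size_um)


def label_cells(mask: BinaryMask, params: SegmentationParams) -> LabeledCells:
    """Label connected microglial cells and locate their somata.

    8-connected components; components smaller than ``min_object_area_um2``
    are removed; when ``join_gaps_um > 0``, disconnected fragments closer
    than that distance are merged into one cell label (labels are computed
    on a morphologically closed copy and transferred to the original mask
    pixels, so every labelled pixel is positive in the parent mask).
    The soma of each cell is placed at the maximum of the Euclidean
    distance transform within the cell, and its value is reported as
    ``soma_radius_um``.
    """
    px = mask.px_size_um
    grid = mask.grid
    if params.join_gaps_um > 0 and grid.any():
        # Square dilation by half the join distance (separable, fast): any
        # two fragments closer than join_gaps_um become one component for
        # labelling.  Chebyshev rather than Euclidean joining is slightly
        # more permissive diagonally, which is harmless at cell spacings
        # well above the join distance.
        r_px = max(1, int(np.ceil(0.5 * params.join_gaps_um / px)))
        closed = ndi.maximum_filter(grid.view(np.uint8), size=2 * r_px + 1) > 0
    else:
        closed = grid
    structure = np.ones((3, 3), dtype=bool)  # 8-connectivity
    labels, n = ndi.label(closed, structure=structure)
    labels = np.where(grid, labels, 0).astype(np.int32)

    if n == 0:
        return LabeledCells(
            label_grid=labels,
            cells=_empty_cells_frame(),
            px_size_um=px,
        )

    # area filter on true mask pixels per label
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    min_px = params.min_object_area_um2 / px**2
    keep = np.flatnonzero(counts[1:] >= min_px) + 1

    # relabel consecutively
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[keep] = np.arange(1, len(keep) + 1, dtype=np.int32)
    labels = remap[labels]

    rows = []
    objects = ndi.find_objects(labels)
    for new_label, slc in enumerate(objects, start=1):
        if slc is None:  # pragma: no cover - consecutive labels
            continue
        sub = labels[slc] == new_label
        # per-cell distance transform on the padded bounding box: the soma
        # is the point of the cell farthest from its own boundary
        d = ndi.distance_transform_edt(np.pad(sub, 1))[1:-1, 1:-1]
        flat = int(np.argmax(d))
        r, c = divmod(flat, d.shape[1])
        soma_r_px = float(d[r, c])
        rows.append(
            {
                "label": new_label,
                "area_um2": float(sub.sum()) * px**2,
                "soma_x_um": (slc[1].start + c + 0.5) * px,
                "soma_y_um": (slc[0].start + r + 0.5) * px,
                "soma_radius_um": soma_r_px * px,
                "min_row": slc[0].start,
                "min_col": slc[1].start,
                "max_row": slc[0].stop - 1,
                "max_col": slc[1].stop - 1,
            }
        )
    cells = pd.DataFrame(rows) if rows else _empty_cells_frame()
    return LabeledCells(label_grid=labels, cells=cells, px_size_um=px)


def _empty_cells_frame() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "label",
            "area_um2",
            "soma_x_um",
            "soma_y_um",
            "soma_radius_um",
            "min_row",
            "min_col",
            "max_row",
            "max_col",
        ]
    )
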