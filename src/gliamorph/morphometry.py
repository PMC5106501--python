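"""Microglial morphometry: loading, grid spatial coverage, and cell domains.

Three measurements characterise the microglial population of a region:

* **Microglial loading** — the fraction (reported as %) of the region's
  area occupied by immunopositive signal.
* **Grid spatial distribution** — the region is tiled with a grid of
  354 x 354 um squares (30-50 squares over a typical hilar field) and the
  immunopositive coverage of each square is recorded; its frequency
  distribution captures how evenly the parenchyma is surveyed.
* **Microglial domain** — the surveillance territory of a single cell,
  measured as the area of a polygon over the distal ends of its processes
  (implemented as the convex hull of topological-skeleton endpoints).

Cells for the domain measurement are selected by design-based systematic
sampling: square frames of 7118.3 um^2 placed on a lattice of pitch
238.64 um with a uniform random offset, applying the unbiased counting
rule (somata on the forbidden left/bottom lines are excluded).  A per-cell
dystrophy score (skeleton fragments, total process length, endpoint count,
spheroid count) operationalises deramification, shortening and
fragmentation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from shapely.geometry import MultiPoint
from skimage.morphology import skeletonize

from .errors import MeasurementError, ParameterError, SamplingError, UndefinedMeasureError
from .segmentation import BinaryMask, LabeledCells

__all__ = [
    "LoadingResult",
    "GridCoverageResult",
    "DomainMeasurement",
    "SamplingDesign2D",
    "DystrophyScore",
    "microglial_loading",
    "grid_coverage",
    "coverage_distribution",
    "skeleton_endpoints",
    "microglial_domain",
    "sample_cells_systematic",
    "dystrophy_metrics",
]

GRID_SQUARE_SIDE_UM = 354.0


@dataclass
class LoadingResult:
    """Area fraction of immunopositive signal within the analysed region."""

    positive_area_um2: float
    region_area_um2: float
    loading: float  # fraction in [0, 1]

    @property
    def percent(self) -> float:
        return 100.0 * self.loading


@dataclass
class GridCoverageResult:
    """Per-square immunopositive coverage over the region.

    ``squares`` has one row per included square with columns
    ``square_index, center_x_um, center_y_um, region_overlap_fraction,
    covered_area_um2, covered_fraction``.
    """

    square_side_um: float
    squares: pd.DataFrame
    n_squares: int


@dataclass
class DomainMeasurement:
    """Territory of one cell: convex-polygon area over its process tips."""

    cell_id: int
    n_endpoints: int
    domain_um2: float  # nan when excluded
    excluded_reason: str | None = None


@dataclass
class SamplingDesign2D:
    """Systematic area-sampling design for cell selection.

    Square frames of ``frame_area_um2`` on a lattice of pitch ``step_um``
    with a seeded uniform random offset; each cell's inclusion probability
    is ``frame_area / step^2`` (0.125 for the defaults).
    """

    frame_area_um2: float = 7118.3
    step_um: float = 238.64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_area_um2 <= 0 or self.step_um <= 0:
            raise ParameterError("frame area and step must be > 0")
        if np.sqrt(self.frame_area_um2) > self.step_um:
            raise ParameterError("frame side must not exceed the step length")

    @property
    def frame_side_um(self) -> float:
        return float(np.sqrt(self.frame_area_um2))


@dataclass
class DystrophyScore:
    """Quantitative dystrophy descriptors for one cell."""

    cell_id: int
    n_skeleton_fragments: int
    total_branch_length_um: float
    n_endpoints: int
    spheroid_count: int


# ---------------------------------------------------------------------------
# loading


def microglial_loading(mask: BinaryMask, region: np.ndarray) -> LoadingResult:
    """Fraction of the region's area that is immunopositive."""
    region = np.asarray(region, dtype=bool)
    if region.shape != mask.grid.shape:
        raise MeasurementError("mask and region must have the same geometry")
    region_px = int(region.sum())
    if region_px == 0:
        raise UndefinedMeasureError("empty region: loading is undefined")
    pos_px = int((mask.grid & region).sum())
    a = mask.px_size_um**2
    return LoadingResult(
        positive_area_um2=pos_px * a,
        region_area_um2=region_px * a,
        loading=pos_px / region_px,
    )


# ---------------------------------------------------------------------------
# grid coverage


def grid_coverage(
    mask: BinaryMask,
    region: np.ndarray,
    side_um: float = GRID_SQUARE_SIDE_UM,
    inclusion_cutoff: float = 0.5,
) -> GridCoverageResult:
    """Per-square immunopositive coverage on a regular grid over the region.

    The grid is anchored at the top-left corner of the region's bounding
    box (deterministic, no random offset).  A square enters the analysis
    iff at least ``inclusion_cutoff`` of its area overlaps the region;
    its covered area is the positive area within square-and-region.
    """
    if side_um <= 0:
        raise ParameterError("side_um must be > 0")
    region = np.asarray(region, dtype=bool)
    if region.shape != mask.grid.shape:
        raise MeasurementError("mask and region must have the same geometry")
    if not region.any():
        raise UndefinedMeasureError("empty region")
    px = mask.px_size_um
    side_px = int(round(side_um / px))
    rows = np.any(region, axis=1).nonzero()[0]
    cols = np.any(region, axis=0).nonzero()[0]
    r0, r1 = rows[0], rows[-1]
    c0, c1 = cols[0], cols[-1]
    if (r1 - r0 + 1) < side_px or (c1 - c0 + 1) < side_px:
        warnings.warn(
            "region is smaller than one grid square; returning a single-square result",
            stacklevel=2,
        )
    pos = mask.grid & region
    records = []
    sq_area_px = side_px * side_px

    def _square_record(index: int, gr: int, gc: int, overlap: float) -> dict:
        covered_px = int(pos[gr : gr + side_px, gc : gc + side_px].sum())
        return {
            "square_index": index,
            "center_x_um": (gc + side_px / 2.0) * px,
            "center_y_um": (gr + side_px / 2.0) * px,
            "region_overlap_fraction": float(overlap),
            "covered_area_um2": covered_px * px**2,
            "covered_fraction": covered_px / sq_area_px,
        }

    for gr in range(r0, r1 + 1, side_px):
        for gc in range(c0, c1 + 1, side_px):
            overlap = region[gr : gr + side_px, gc : gc + side_px].sum() / sq_area_px
            if overlap < inclusion_cutoff:
                continue
            records.append(_square_record(len(records), gr, gc, overlap))
    if not records:
        # degenerate region: keep the origin square so callers still get a
        # (single-square) result rather than an empty table
        overlap = region[r0 : r0 + side_px, c0 : c0 + side_px].sum() / sq_area_px
        records.append(_square_record(0, r0, c0, overlap))
    squares = pd.DataFrame(
        records,
        columns=[
            "square_index",
            "center_x_um",
            "center_y_um",
            "region_overlap_fraction",
            "covered_area_um2",
            "covered_fraction",
        ],
    )
    return GridCoverageResult(
        square_side_um=side_px * px, squares=squares, n_squares=len(squares)
    )


def coverage_distribution(
    grid: GridCoverageResult, bin_width_um2: float = 5000.0
) -> pd.DataFrame:
    """Relative frequency distribution of per-square covered area.

    Returns a DataFrame with ``bin_left_um2, bin_right_um2, frequency``;
    frequencies sum to 1.
    """
    if grid.n_squares < 1:
        raise MeasurementError("need at least one grid square")
    if bin_width_um2 <= 0:
        raise ParameterError("bin_width_um2 must be > 0")
    values = grid.squares["covered_area_um2"].to_numpy()
    n_bins = int(np.floor(values.max() / bin_width_um2)) + 1
    edges = np.arange(n_bins + 1) * bin_width_um2
    counts, _ = np.histogram(values, bins=edges)
    return pd.DataFrame(
        {
            "bin_left_um2": edges[:-1],
            "bin_right_um2": edges[1:],
            "frequency": counts / counts.sum(),
        }
    )


# ---------------------------------------------------------------------------
# skeleton, endpoints, domain

_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])


def _skeleton(cell_mask: np.ndarray) -> np.ndarray:
    return skeletonize(np.asarray(cell_mask, dtype=bool))


def _endpoint_pixels(skel: np.ndarray) -> np.ndarray:
    """(n, 2) array of (row, col) skeleton pixels with exactly one neighbour."""
    nb = ndi.convolve(skel.astype(np.uint8), _NEIGHBOR_KERNEL, mode="constant")
    return np.argwhere(skel & (nb == 1))


def skeleton_endpoints(cell_mask: np.ndarray) -> np.ndarray:
    """Branch-tip pixel coordinates of a single-cell mask.

    The topological skeleton is computed and its endpoints — skeleton
    pixels with exactly one 8-connected skeleton neighbour — are returned
    as an (n, 2) array of (x, y) pixel coordinates.  For fragmented cells
    the mask should contain all fragments of the cell; endpoints are
    pooled over them.
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if not cell_mask.any():
        raise MeasurementError("empty cell mask")
    eps = _endpoint_pixels(_skeleton(cell_mask))
    return eps[:, ::-1].astype(float)  # (row, col) -> (x, y)


def microglial_domain(
    endpoints: np.ndarray,
    px_size_um: float,
    cell_id: int = 0,
    method: str = "hull",
) -> DomainMeasurement:
    """Territory area (um^2) of one cell from its process-tip coordinates.

    ``method="hull"`` (default) takes the convex hull of the endpoints —
    the reproducible formalisation of drawing a polygon that connects the
    distal ends of all processes.  ``method="angular"`` instead joins the
    endpoints in angular order around their centroid, allowing a concave
    territory outline.  With fewer than 3 non-collinear endpoints the
    domain is undefined and an excluded record (not an exception) is
    returned.
    """
    pts = np.asarray(endpoints, dtype=float)
    n = len(pts)
    if n < 3:
        return DomainMeasurement(cell_id, n, float("nan"), "fewer than 3 endpoints")
    pts_um = pts * px_size_um
    if method == "hull":
        geom = MultiPoint(pts_um.tolist()).convex_hull
        area = float(geom.area)
    elif method == "angular":
        c = pts_um.mean(axis=0)
        order = np.argsort(np.arctan2(pts_um[:, 1] - c[1], pts_um[:, 0] - c[0]))
        v = pts_um[order]
        x, y = v[:, 0], v[:, 1]
        area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))
    else:
        raise ParameterError(f"unknown domain method {method!r}")
    if area <= 0.0:
        return DomainMeasurement(cell_id, n, float("nan"), "collinear endpoints")
    return DomainMeasurement(cell_id, n, area)


# ---------------------------------------------------------------------------
# systematic sampling of cells


def sample_cells_systematic(
    cells: LabeledCells,
    region: np.ndarray,
    design: SamplingDesign2D,
    n_target: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[int]:
    """Select cell labels by systematic uniform random area sampling.

    Square frames of ``design.frame_area_um2`` are laid on a lattice of
    pitch ``design.step_um`` with a uniformly random offset (seeded by
    ``design.seed`` unless an ``rng`` is supplied).  A cell is sampled iff
    its soma lies strictly inside a frame or on its acceptance (top/right)
    edges and does not touch the forbidden (left/bottom, extended) lines —
    the planar unbiased counting rule.  Frames whose centre falls outside
    the region are discarded.  Sampling stops after ``n_target`` cells;
    ``None`` keeps every sampled cell.
    """
    region = np.asarray(region, dtype=bool)
    if not region.any():
        raise SamplingError("empty region")
    if cells.n_cells == 0:
        return []
    if rng is None:
        rng = np.random.default_rng(design.seed)
    px = cells.px_size_um
    h, w = region.shape
    step = design.step_um
    side = design.frame_side_um
    offset = rng.uniform(0.0, step, size=2)

    xs = cells.cells["soma_x_um"].to_numpy()
    ys = cells.cells["soma_y_um"].to_numpy()
    labels = cells.cells["label"].to_numpy()

    max_x, max_y = w * px, h * px
    frames = []
    x0 = offset[0] - step  # start one pitch early so the offset tiles the plane
    while x0 < max_x:
        y0 = offset[1] - step
        while y0 < max_y:
            cx = (x0 + side / 2.0) / px
            cy = (y0 + side / 2.0) / px
            ci, cj = int(cy), int(cx)
            if 0 <= ci < h and 0 <= cj < w and region[ci, cj]:
                frames.append((x0, y0))
            y0 += step
        x0 += step

    if not frames:
        raise SamplingError("no sampling frame intersects the region")

    sampled: list[int] = []
    for x0, y0 in frames:
        # forbidden left/bottom (y0) lines: strict lower bounds; acceptance
        # top/right edges: inclusive upper bounds
        inside = (xs > x0) & (xs <= x0 + side) & (ys > y0) & (ys <= y0 + side)
        for lab in labels[inside]:
            sampled.append(int(lab))
            if n_target is not None and len(sampled) >= n_target:
                return sampled
    return sampled


# ---------------------------------------------------------------------------
# dystrophy metrics

_ORTHO = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
_DIAG = np.array([[1, 0, 1], [0, 0, 0], [1, 0, 1]])


def _skeleton_length_px(skel: np.ndarray) -> float:
    """Diagonal-corrected skeleton length in pixel units.

    Each orthogonal pixel adjacency contributes 1 and each diagonal one
    sqrt(2); edge lengths are split between the two pixels.
    """
    s = skel.astype(np.uint8)
    n_ortho = ndi.convolve(s, _ORTHO, mode="constant")[skel].sum()
    n_diag = ndi.convolve(s, _DIAG, mode="constant")[skel].sum()
    return 0.5 * (float(n_ortho) + np.sqrt(2.0) * float(n_diag))


def dystrophy_metrics(
    cell_mask: np.ndarray,
    px_size_um: float,
    branch_width_um: float = 2.0,
    cell_id: int = 0,
) -> DystrophyScore:
    """Fragmentation / shortening / beading descriptors for one cell.

    Fragments are connected components of the skeleton; total branch
    length is the diagonal-corrected skeleton length; spheroids are
    counted as connected skeleton regions whose local mask width (twice
    the distance transform) reaches at least ``2 * branch_width_um``,
    excluding the region containing the global width maximum (the soma).
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if not cell_mask.any():
        raise MeasurementError("empty cell mask")
    skel = _skeleton(cell_mask)
    structure = np.ones((3, 3), dtype=bool)
    _, n_fragments = ndi.label(skel, structure=structure)
    n_fragments = max(int(n_fragments), 1)
    length_um = _skeleton_length_px(skel) * px_size_um
    n_endpoints = len(_endpoint_pixels(skel))

    dt = ndi.distance_transform_edt(cell_mask) * px_size_um
    wide = skel & (2.0 * dt >= 2.0 * branch_width_um)
    spheroid_count = 0
    if wide.any():
        lab, n_wide = ndi.label(wide, structure=structure)
        # drop the blob holding the global thickness maximum: that is the soma
        dt_on_skel = np.where(skel, dt, -1.0)
        soma_pix = np.unravel_index(int(np.argmax(dt_on_skel)), dt.shape)
        soma_blob = lab[soma_pix]
        spheroid_count = int(n_wide - (1 if soma_blob > 0 else 0))
    return DystrophyScore(
        cell_id=cell_id,
        n_skeleton_fragments=n_fragments,
        total_branch_length_um=float(length_um),
        n_endpoints=int(n_endpoints),
        spheroid_count=spheroid_count,
    )
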