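"""Seeded synthetic micrographs of immunostained microglia with ground truth.

The generator emulates single-channel 8-bit micrographs of Iba1/P2ry12-
immunostained dentate-gyrus hilus fields: bright ramified cells on a dark,
noisy background at a known micrometre-per-pixel scale.  Every image carries
full per-cell ground truth (soma position, branch-tip coordinates, exact
territory area, rendered area) so that the measurement pipeline can be
validated end to end without human tissue data.

Cell model
----------
Each cell is a soma disc plus a radial arbor of ``k >= 3`` processes.  The
process tips are placed at jittered angles around the soma at a common
radius ``R`` chosen in closed form so that the polygon over the tips has
*exactly* the territory area drawn from the preset's domain distribution:
for tips at angles ``theta_i`` on a circle of radius ``R`` the shoelace
formula gives ``area = R^2/2 * sum_i sin(delta_i)`` with ``delta_i`` the
consecutive angular gaps, hence ``R = sqrt(2*area / sum_i sin(delta_i))``.
Any error in the measured domain is therefore attributable to the
measurement pipeline, not the generator.

Processes are rendered at the preset width but taper to one pixel over the
final ~2 um so that the topological skeleton terminates at the true tip.
Dystrophic cells are additionally fragmented (branches broken into
disconnected segments with 2-4 um gaps) and decorated with spheroidal
swellings, mimicking cytorrhexis and beading.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import disk as disk_footprint

from .errors import CalibrationError, GenerationError, ParameterError
from .presets import PhenotypePreset

__all__ = [
    "SyntheticSpec",
    "CellGroundTruth",
    "MicrogliaImage",
    "default_region",
    "generate_image",
    "calibrate_density",
    "polygon_area",
]

#: 8-bit value used for rendered cell pixels.
FOREGROUND_LEVEL = 230

#: Rejected lower bound for drawn territory areas (um^2); keeps the
#: truncated-normal draw numerically sane without noticeably biasing the
#: preset distributions (the floor sits >2.7 SD below both preset means).
_MIN_DOMAIN_UM2 = 100.0


def default_region(width_px: int, height_px: int, margin_px: int = 0) -> np.ndarray:
    """Rectangular region polygon inset by ``margin_px``, as (x, y) vertices."""
    m = margin_px
    return np.array(
        [
            [m, m],
            [width_px - 1 - m, m],
            [width_px - 1 - m, height_px - 1 - m],
            [m, height_px - 1 - m],
        ],
        dtype=float,
    )


def rasterize_polygon(shape: tuple[int, int], vertices_xy: np.ndarray) -> np.ndarray:
    """Even-odd scanline fill of a polygon given as (x, y) vertices.

    A pixel (row r, col c) is inside iff the point (c, r) is inside the
    polygon.  Horizontal edges are skipped; each edge contributes its
    lower endpoint and excludes its upper one, the standard half-open
    crossing rule.
    """
    h, w = shape
    v = np.asarray(vertices_xy, dtype=float)
    x1, y1 = v[:, 0], v[:, 1]
    x2, y2 = np.roll(x1, -1), np.roll(y1, -1)
    mask = np.zeros((h, w), dtype=bool)
    rows = np.arange(h, dtype=float)
    crossings: list[np.ndarray] = []
    for ex1, ey1, ex2, ey2 in zip(x1, y1, x2, y2):
        if ey1 == ey2:
            continue
        ylo, yhi = (ey1, ey2) if ey1 < ey2 else (ey2, ey1)
        active = (rows >= ylo) & (rows < yhi)
        xs = np.full(h, np.nan)
        xs[active] = ex1 + (rows[active] - ey1) * (ex2 - ex1) / (ey2 - ey1)
        crossings.append(xs)
    if not crossings:
        return mask
    xs_all = np.sort(np.stack(crossings, axis=1), axis=1)
    for r in range(h):
        row = xs_all[r]
        row = row[np.isfinite(row)]
        for a, b in zip(row[0::2], row[1::2]):
            c0 = max(0, int(np.ceil(a)))
            c1 = min(w - 1, int(np.floor(b)))
            if c1 >= c0:
                mask[r, c0 : c1 + 1] = True
    return mask


def polygon_area(vertices_xy: np.ndarray) -> float:
    """Shoelace area of a simple polygon given as (n, 2) (x, y) vertices."""
    v = np.asarray(vertices_xy, dtype=float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


@dataclass
class SyntheticSpec:
    """Full description of one synthetic micrograph.

    ``region`` is a polygon of (x, y) vertices in pixel coordinates — the
    analog of the manually outlined hilar region.  Cell number is given
    either directly (``n_cells``) or as an areal intensity in cells/mm^2
    (``cell_intensity``), in which case the count is Poisson-drawn from
    intensity x region area.  ``min_separation_um`` enforces a soma
    exclusion distance (used for territory-measurement fields where cells
    must not touch); ``None`` places somata uniformly at random.
    """

    preset: PhenotypePreset
    width_px: int = 2048
    height_px: int = 2048
    px_size_um: float = 0.5
    region: np.ndarray | None = None
    n_cells: int | None = None
    cell_intensity: float | None = None  # cells per mm^2
    background_level: int = 40
    noise_sd: float = 10.0
    foreground_level: int = FOREGROUND_LEVEL
    min_separation_um: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.px_size_um <= 0:
            raise ParameterError("px_size_um must be > 0")
        if self.width_px <= 0 or self.height_px <= 0:
            raise ParameterError("image dimensions must be positive")
        if self.region is None:
            self.region = default_region(self.width_px, self.height_px)
        self.region = np.asarray(self.region, dtype=float)
        if self.region.ndim != 2 or self.region.shape[1] != 2 or len(self.region) < 3:
            raise ParameterError("region must be an (n>=3, 2) polygon")
        if (
            self.region[:, 0].min() < 0
            or self.region[:, 1].min() < 0
            or self.region[:, 0].max() > self.width_px - 1
            or self.region[:, 1].max() > self.height_px - 1
        ):
            raise ParameterError("region polygon must lie within image bounds")
        if self.n_cells is None and self.cell_intensity is None:
            raise ParameterError("one of n_cells / cell_intensity is required")
        if self.n_cells is not None and self.n_cells < 0:
            raise ParameterError("n_cells must be >= 0")
        if self.cell_intensity is not None and self.cell_intensity < 0:
            raise ParameterError("cell_intensity must be >= 0")
        if not 0 <= self.background_level <= 255:
            raise ParameterError("background_level must be an 8-bit value")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        # Signal separability: rendered cells must sit clear of the noise floor.
        if self.foreground_level <= self.background_level + 3 * self.noise_sd:
            raise ParameterError(
                "foreground_level must exceed background_level + 3*noise_sd"
            )

    def region_mask(self) -> np.ndarray:
        """Boolean raster of the region polygon (cached)."""
        cached = getattr(self, "_region_mask", None)
        if cached is None:
            cached = rasterize_polygon(
                (self.height_px, self.width_px), self.region
            )
            object.__setattr__(self, "_region_mask", cached)
        return cached


@dataclass
class CellGroundTruth:
    """Ground truth for one rendered cell (all coordinates in micrometres)."""

    cell_id: int
    soma_xy_um: tuple[float, float]
    endpoints_um: np.ndarray  # (k, 2) branch-tip coordinates
    true_domain_um2: float  # polygon area over endpoints (exact)
    rendered_area_um2: float  # pixels painted for this cell alone
    fragmented: bool


@dataclass
class MicrogliaImage:
    """A synthetic micrograph plus its ground truth."""

    raster: np.ndarray  # uint8 (H, W)
    px_size_um: float
    region_mask: np.ndarray  # bool (H, W)
    ground_truth: list[CellGroundTruth]
    true_coverage: float  # union of cell pixels within region / region area
    cell_mask: np.ndarray | None = None  # bool union of rendered cell pixels

    def to_dataframe(self):
        """Ground truth as a pandas DataFrame (one row per cell)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "cell_id": [c.cell_id for c in self.ground_truth],
                "soma_x_um": [c.soma_xy_um[0] for c in self.ground_truth],
                "soma_y_um": [c.soma_xy_um[1] for c in self.ground_truth],
                "n_endpoints": [len(c.endpoints_um) for c in self.ground_truth],
                "true_domain_um2": [c.true_domain_um2 for c in self.ground_truth],
                "rendered_area_um2": [c.rendered_area_um2 for c in self.ground_truth],
                "fragmented": [c.fragmented for c in self.ground_truth],
            }
        )


# ---------------------------------------------------------------------------
# cell geometry


def _draw_cell_geometry(preset: PhenotypePreset, rng: np.random.Generator):
    """Draw (k, tip angles, tip radius, target area, soma radius) for one cell."""
    mean_k, disp_k = preset.n_primary_branches
    k = max(3, int(round(rng.normal(mean_k, disp_k))))
    mean_a, sd_a = preset.domain_area_um2
    area = rng.normal(mean_a, sd_a)
    while area < _MIN_DOMAIN_UM2:
        area = rng.normal(mean_a, sd_a)
    soma_r = max(1.5, rng.normal(*preset.soma_radius_um))
    # Jittered-regular tip angles: guarantees angular separation so distinct
    # branches stay resolvable near the soma.
    for _ in range(100):
        jitter = rng.uniform(-0.3, 0.3, size=k)
        theta = 2.0 * np.pi * (np.arange(k) + jitter) / k + rng.uniform(0, 2 * np.pi)
        theta = np.sort(theta % (2.0 * np.pi))
        gaps = np.diff(np.concatenate([theta, [theta[0] + 2 * np.pi]]))
        s = np.sin(gaps).sum()
        if s > 0.4 * k * np.sin(2 * np.pi / k):
            break
    radius = np.sqrt(2.0 * area / s)
    return k, theta, radius, area, soma_r


def _branch_path(
    soma_xy_px: np.ndarray,
    tip_xy_px: np.ndarray,
    tortuosity: float,
    rng: np.random.Generator,
):
    """Parametric centreline from soma to tip with lateral wobble.

    Returns ``pos(t)`` mapping an array of t in [0, 1] to (x, y) pixel
    coordinates.  The wobble is a half-sine bow of amplitude proportional
    to ``tortuosity * length`` with zero displacement at both ends, so the
    tip position is exact.
    """
    vec = tip_xy_px - soma_xy_px
    length = float(np.hypot(*vec))
    if tortuosity > 0 and length > 0:
        perp = np.array([-vec[1], vec[0]]) / length
        amp = tortuosity * length * rng.uniform(-1.0, 1.0) * 0.5
    else:
        perp = np.zeros(2)
        amp = 0.0

    def pos(t: np.ndarray) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        base = soma_xy_px[None, :] + t[:, None] * vec[None, :]
        return base + (amp * np.sin(np.pi * t))[:, None] * perp[None, :]

    return pos, length


def _polyline_pixels(pos, a: float, b: float, length_px: float) -> np.ndarray:
    """1-px-wide 8-connected pixel chain along pos(t) for t in [a, b].

    Vertices are sampled every ~3 px and joined with Bresenham lines, so
    the chain never doubles up laterally — a genuine digital curve whose
    topological skeleton is itself (endpoints preserved exactly).
    """
    from skimage.draw import line as draw_line

    span = max(b - a, 0.0)
    n = max(2, int(np.ceil(span * length_px / 3.0)) + 1)
    verts = np.round(pos(np.linspace(a, b, n))).astype(int)
    chains = []
    for (x0, y0), (x1, y1) in zip(verts[:-1], verts[1:]):
        rr, cc = draw_line(y0, x0, y1, x1)
        chains.append(np.stack([cc, rr], axis=1))
    return np.concatenate(chains) if chains else verts


def _fragment_intervals(rng: np.random.Generator, length_um: float):
    """Return kept t-intervals after cutting 1-2 gaps of 2-4 um into a branch.

    Gap half-widths are capped at 20% of the branch so short dystrophic
    processes are never obliterated, two gaps are drawn in disjoint bands
    so they cannot merge into one oversized break, and a distal piece of
    at least ~2.5 um is always preserved so fragmented cells keep their
    territory-defining tip.
    """
    kept = [(0.0, 1.0)]
    two = rng.random() < 0.35
    bands = [(0.28, 0.45), (0.62, 0.82)] if two else [(0.30, 0.80)]
    distal_keep = max(0.05, 2.5 / max(length_um, 1e-9))
    for lo_band, hi_band in bands:
        gap_um = rng.uniform(2.0, 4.0)
        half = min(0.5 * gap_um / max(length_um, 1e-9), 0.10)
        center = rng.uniform(lo_band, hi_band)
        lo, hi = center - half, min(center + half, 1.0 - distal_keep)
        new = []
        for a, b in kept:
            if hi <= a or lo >= b:
                new.append((a, b))
                continue
            if lo > a:
                new.append((a, lo))
            if hi < b:
                new.append((hi, b))
        kept = new or kept
    return kept


def _render_cell(
    preset: PhenotypePreset,
    soma_xy_um: np.ndarray,
    px: float,
    shape: tuple[int, int],
    rng: np.random.Generator,
):
    """Render one cell into a local patch; returns (patch, offset, truth dict)."""
    k, theta, radius_um, area_um2, soma_r_um = _draw_cell_geometry(preset, rng)
    tips_um = soma_xy_um[None, :] + radius_um * np.stack(
        [np.cos(theta), np.sin(theta)], axis=1
    )

    spheroid_r_max = 2.0  # um; diameter 2-4 um
    pad_um = radius_um + preset.branch_width_um + spheroid_r_max + 2.0
    pad_px = int(np.ceil(pad_um / px)) + 2
    soma_px = soma_xy_um / px
    cx, cy = int(round(soma_px[0])), int(round(soma_px[1]))
    x0, y0 = cx - pad_px, cy - pad_px
    side = 2 * pad_px + 1
    thin = np.zeros((side, side), dtype=bool)
    thick_src = np.zeros_like(thin)

    width_r_px = max(1, int(round(preset.branch_width_um / (2.0 * px))))
    # the taper must outlast the dilation radius so the distal end of every
    # process is a genuine 1-px spur whose skeleton endpoint is the true tip
    taper_um = max(2.5, preset.branch_width_um) + width_r_px * px
    fragmented = False
    total_len_um = 0.0
    branch_paths = []
    for tip_um in tips_um:
        pos, length_px = _branch_path(soma_px, tip_um / px, preset.tortuosity, rng)
        branch_len_um = radius_um  # chord length; wobble correction negligible
        total_len_um += branch_len_um
        if preset.fragmentation_prob > 0 and rng.random() < preset.fragmentation_prob:
            intervals = _fragment_intervals(rng, branch_len_um)
            fragmented = True
        else:
            intervals = [(0.0, 1.0)]
        taper_frac = min(0.9, taper_um / max(branch_len_um, 1e-9))
        branch_paths.append((pos, length_px, branch_len_um))
        for a, b in intervals:
            pts = _polyline_pixels(pos, a, b, length_px)
            thick_b = min(b, 1.0 - taper_frac)
            pts_thick = (
                _polyline_pixels(pos, a, thick_b, length_px)
                if thick_b > a
                else np.empty((0, 2), int)
            )
            for arr, target in ((pts, thin), (pts_thick, thick_src)):
                if len(arr) == 0:
                    continue
                ix = arr[:, 0] - x0
                iy = arr[:, 1] - y0
                ok = (ix >= 0) & (ix < side) & (iy >= 0) & (iy < side)
                target[iy[ok], ix[ok]] = True
    patch = thin | ndi.binary_dilation(thick_src, structure=disk_footprint(width_r_px))

    # soma disc
    _paint_disk(patch, soma_px[1] - y0, soma_px[0] - x0, soma_r_um / px)

    # spheroidal swellings along branches
    if preset.spheroid_rate > 0:
        n_sph = rng.poisson(preset.spheroid_rate * total_len_um / 100.0)
        for _ in range(n_sph):
            pos, _length_px, _len = branch_paths[rng.integers(len(branch_paths))]
            p = pos(rng.uniform(0.15, 0.95))[0]
            _paint_disk(patch, p[1] - y0, p[0] - x0, rng.uniform(1.0, 2.0) / px)

    truth = {
        "endpoints_um": tips_um,
        "true_domain_um2": polygon_area(tips_um),
        "fragmented": fragmented,
        "radius_um": radius_um,
    }
    return patch, (x0, y0), truth


def _paint_disk(arr: np.ndarray, cy: float, cx: float, r: float) -> None:
    """Set pixels within radius ``r`` of (cy, cx) to True (clipped in place)."""
    y0 = max(0, int(np.floor(cy - r)))
    y1 = min(arr.shape[0] - 1, int(np.ceil(cy + r)))
    x0 = max(0, int(np.floor(cx - r)))
    x1 = min(arr.shape[1] - 1, int(np.ceil(cx + r)))
    if y1 < y0 or x1 < x0:
        return
    yy = np.arange(y0, y1 + 1)[:, None] - cy
    xx = np.arange(x0, x1 + 1)[None, :] - cx
    arr[y0 : y1 + 1, x0 : x1 + 1] |= yy**2 + xx**2 <= r**2


def _paste(union: np.ndarray, patch: np.ndarray, offset: tuple[int, int]) -> int:
    """OR a patch into the union mask with clipping; return patch pixel count."""
    x0, y0 = offset
    h, w = union.shape
    ph, pw = patch.shape
    sy, sx = max(0, -y0), max(0, -x0)
    ey, ex = min(ph, h - y0), min(pw, w - x0)
    if ey <= sy or ex <= sx:
        return 0
    sub = patch[sy:ey, sx:ex]
    union[y0 + sy : y0 + ey, x0 + sx : x0 + ex] |= sub
    return int(patch.sum())


def _place_somata(
    spec: SyntheticSpec, region: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform soma positions (um) inside the region, honouring separation."""
    idx = np.flatnonzero(region.ravel())
    if idx.size == 0:
        raise GenerationError("region mask is empty; nowhere to place somata")
    if n == 0:
        return np.empty((0, 2))
    min_sep = spec.min_separation_um
    placed: list[np.ndarray] = []
    attempts = 0
    max_attempts = 400 * n
    while len(placed) < n:
        attempts += 1
        if attempts > max_attempts:
            raise GenerationError(
                f"placed only {len(placed)}/{n} somata at "
                f"min_separation_um={min_sep}; region too small or too crowded"
            )
        flat = idx[rng.integers(idx.size)]
        row, col = divmod(flat, region.shape[1])
        pt = (np.array([col, row]) + rng.random(2)) * spec.px_size_um
        if min_sep is not None and placed:
            d2 = np.sum((np.asarray(placed) - pt) ** 2, axis=1)
            if d2.min() < min_sep**2:
                continue
        placed.append(pt)
    return np.asarray(placed)


def _render_cells(spec: SyntheticSpec, rng: np.random.Generator):
    """Render all cells; returns (union cell mask, ground-truth list)."""
    region = spec.region_mask()
    region_px = int(region.sum())
    if spec.n_cells is not None:
        n = spec.n_cells
    else:
        area_mm2 = region_px * spec.px_size_um**2 / 1e6
        n = int(rng.poisson(spec.cell_intensity * area_mm2))
    somata = _place_somata(spec, region, n, rng)

    shape = (spec.height_px, spec.width_px)
    union = np.zeros(shape, dtype=bool)
    truths: list[CellGroundTruth] = []
    for i, soma_um in enumerate(somata):
        patch, offset, t = _render_cell(spec.preset, soma_um, spec.px_size_um, shape, rng)
        n_px = _paste(union, patch, offset)
        truths.append(
            CellGroundTruth(
                cell_id=i + 1,
                soma_xy_um=(float(soma_um[0]), float(soma_um[1])),
                endpoints_um=t["endpoints_um"],
                true_domain_um2=float(t["true_domain_um2"]),
                rendered_area_um2=n_px * spec.px_size_um**2,
                fragmented=bool(t["fragmented"]),
            )
        )
    coverage = float((union & region).sum() / region_px)
    return union, region, truths, coverage


def generate_image(spec: SyntheticSpec) -> MicrogliaImage:
    """Generate one seeded synthetic micrograph with full ground truth.

    The output is deterministic given ``spec`` (including its seed): two
    calls with identical specs return bitwise-identical rasters and ground
    truth.  ``n_cells = 0`` yields a pure background-noise field.
    """
    rng = np.random.default_rng(spec.seed)
    union, region, truths, coverage = _render_cells(spec, rng)

    shape = (spec.height_px, spec.width_px)
    if spec.noise_sd > 0:
        raster = rng.standard_normal(shape, dtype=np.float32)
        raster *= spec.noise_sd
        raster += spec.background_level
        np.rint(raster, out=raster)
        np.clip(raster, 0, 255, out=raster)
        raster = raster.astype(np.uint8)
    else:
        raster = np.full(shape, spec.background_level, dtype=np.uint8)
    raster[union] = spec.foreground_level
    return MicrogliaImage(
        raster=raster,
        px_size_um=spec.px_size_um,
        region_mask=region,
        ground_truth=truths,
        true_coverage=coverage,
        cell_mask=union,
    )


def _mean_coverage(
    spec_template: SyntheticSpec, intensity: float, seeds: np.ndarray
) -> float:
    cov = []
    for s in seeds:
        spec = dataclasses.replace(
            spec_template, n_cells=None, cell_intensity=float(intensity), seed=int(s)
        )
        rng = np.random.default_rng(spec.seed)
        *_, c = _render_cells(spec, rng)
        cov.append(c)
    return float(np.mean(cov))


def calibrate_density(
    preset: PhenotypePreset,
    spec_template: SyntheticSpec,
    tol: float = 0.01,
    n_replicates: int = 20,
    max_intensity: float = 5000.0,
    max_iter: int = 18,
) -> float:
    """Cell intensity (cells/mm^2) whose mean coverage hits the preset target.

    Bisects on areal cell intensity, evaluating the replicate-mean
    ``true_coverage`` of ``n_replicates`` seeded generator runs at each
    step (common random numbers across intensities keep the evaluation
    monotone up to Monte-Carlo noise; the Boolean-model monotonicity of
    coverage in intensity is asserted on the initial bracket).

    Raises
    ------
    CalibrationError
        If the coverage target is unreachable at ``max_intensity``.
    """
    if tol <= 0:
        raise ParameterError("tol must be > 0")
    target = preset.target_coverage
    if not 0.0 <= target < 1.0:
        raise ParameterError("target_coverage must lie in [0, 1)")
    if target == 0.0:
        return 0.0

    template = dataclasses.replace(spec_template, preset=preset)
    ss = np.random.SeedSequence([int(spec_template.seed) % (2**31), 0xCA11])
    seeds = np.array(
        [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n_replicates)]
    )

    # Boolean-model initial bracket: coverage ~ 1 - exp(-lambda * a) with a
    # the mean rendered area per cell, estimated from one small render.
    probe = dataclasses.replace(template, n_cells=40, cell_intensity=None, seed=int(seeds[0]))
    rng = np.random.default_rng(probe.seed)
    _, _, probe_truth, _ = _render_cells(probe, rng)
    a_um2 = float(np.mean([c.rendered_area_um2 for c in probe_truth]))
    lam0 = -np.log(1.0 - target) / a_um2 * 1e6  # cells per mm^2

    # Model-accelerated bisection: each evaluation refits the effective
    # per-cell area a_eff from cov = 1 - exp(-lambda * a_eff) and jumps to
    # the predicted root, clipped to the current monotone bracket.
    lo, f_lo = 0.0, 0.0
    hi, f_hi = float(max_intensity), None
    lam = min(lam0, hi)
    for _ in range(max_iter):
        f = _mean_coverage(template, lam, seeds)
        if abs(f - target) <= tol:
            return lam
        if f < target:
            if f < f_lo - 5.0 * tol:
                raise CalibrationError("coverage is not nondecreasing in intensity")
            lo, f_lo = lam, f
            if lam >= max_intensity:
                raise CalibrationError(
                    f"coverage target {target} unreachable: max intensity "
                    f"{max_intensity} cells/mm^2 yields mean coverage {f:.4f}"
                )
        else:
            hi, f_hi = lam, f
        if 0 < f < 1:
            a_eff = -np.log(1.0 - f) / lam
            lam_model = -np.log(1.0 - target) / a_eff
        else:
            lam_model = 0.5 * (lo + hi)
        if not lo < lam_model < hi:
            lam_model = 0.5 * (lo + hi) if f_hi is not None else min(2.0 * lam, hi)
        lam = min(lam_model, float(max_intensity))
    raise CalibrationError(
        f"calibration did not reach coverage {target} +/- {tol} in {max_iter} steps"
    )
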