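"""Optical-fractionator estimation of microglial numerical density.

Somata are counted in systematically placed unbiased counting frames
(frame area 1722 um^2, step length 131.23 um by default) over every
sampled section, and the numerical density in cells/mm^3 is estimated
with the fractionator formula

    ND = Q / (sum(A) * h)

where ``Q`` is the number of disector-counted somatic profiles,
``sum(A)`` the accumulated counting-frame area and ``h`` the section
thickness (30 um).  Counting uses the planar unbiased counting-frame
rule: a soma counts iff it lies strictly inside a frame or on its
acceptance (top/right) edges and does not touch the forbidden
(left/bottom, extended) lines, so each soma is counted at most once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DesignError, ParameterError

__all__ = [
    "FractionatorDesign",
    "DensityEstimate",
    "place_frames",
    "count_Q",
    "numerical_density",
    "estimate_density",
]

UM3_PER_MM3 = 1e9


@dataclass
class FractionatorDesign:
    """Sampling design of the optical fractionator.

    Frames are squares of ``frame_area_um2`` on a lattice of pitch
    ``step_um``; sections are sampled with period ``section_period``
    (every 6th section, 180 um apart, 5-6 sections per subject by
    default) and have thickness ``section_thickness_um``.
    """

    frame_area_um2: float = 1722.0
    step_um: float = 131.23
    section_thickness_um: float = 30.0
    section_period: int = 6
    section_spacing_um: float = 180.0
    n_sections: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_area_um2 <= 0 or self.step_um <= 0:
            raise ParameterError("frame area and step must be > 0")
        if np.sqrt(self.frame_area_um2) > self.step_um:
            raise DesignError("frame side must not exceed the step (frames overlap)")
        if self.section_thickness_um <= 0:
            raise ParameterError("section thickness h must be > 0")
        if self.n_sections <= 0 or self.section_period <= 0:
            raise ParameterError("section counts must be positive")

    @property
    def frame_side_um(self) -> float:
        return float(np.sqrt(self.frame_area_um2))


@dataclass
class DensityEstimate:
    """Fractionator inputs and the resulting numerical density."""

    Q: int
    n_frames: int
    sum_A_um2: float
    h_um: float
    nd_cells_per_mm3: float


def place_frames(
    region: np.ndarray,
    design: FractionatorDesign,
    px_size_um: float,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Systematic uniform random frame positions over a region mask.

    Returns an (n, 2) array of frame lower-left corners (x0, y0) in um.
    The lattice has pitch ``design.step_um`` and a seeded uniform random
    offset; a frame is retained iff its centre falls inside the region.
    May return an empty array.
    """
    region = np.asarray(region, dtype=bool)
    if not region.any():
        return np.empty((0, 2))
    if rng is None:
        rng = np.random.default_rng(design.seed)
    h, w = region.shape
    step = design.step_um
    side = design.frame_side_um
    offset = rng.uniform(0.0, step, size=2)
    max_x, max_y = w * px_size_um, h * px_size_um
    frames = []
    x0 = offset[0] - step
    while x0 < max_x:
        y0 = offset[1] - step
        while y0 < max_y:
            ci = int((y0 + side / 2.0) / px_size_um)
            cj = int((x0 + side / 2.0) / px_size_um)
            if 0 <= ci < h and 0 <= cj < w and region[ci, cj]:
                frames.append((x0, y0))
            y0 += step
        x0 += step
    return np.asarray(frames, dtype=float).reshape(-1, 2)


def count_Q(
    somata_um: np.ndarray, frames: np.ndarray, frame_side_um: float, step_um: float | None = None
) -> int:
    """Disector count of somata over a set of counting frames.

    ``somata_um`` is an (n, 2) array of (x, y) positions in um.  A soma
    counts iff it lies strictly inside a frame or on the acceptance
    (top/right) edges, and not on the forbidden (left/bottom, extended)
    lines; with disjoint frames each soma is counted at most once.
    """
    if step_um is not None and frame_side_um > step_um:
        raise DesignError("overlapping frames: frame side exceeds the step")
    somata = np.asarray(somata_um, dtype=float).reshape(-1, 2)
    frames = np.asarray(frames, dtype=float).reshape(-1, 2)
    if len(somata) == 0 or len(frames) == 0:
        return 0
    x, y = somata[:, 0], somata[:, 1]
    q = 0
    for x0, y0 in frames:
        q += int(
            np.sum((x > x0) & (x <= x0 + frame_side_um) & (y > y0) & (y <= y0 + frame_side_um))
        )
    return q


def numerical_density(Q: int, sum_A_um2: float, h_um: float, n_frames: int = 0) -> DensityEstimate:
    """Apply the fractionator formula ND = Q / (sum(A) * h) in cells/mm^3.

    All inputs are stored in the returned estimate for audit.
    """
    if sum_A_um2 <= 0:
        raise ParameterError("sum_A_um2 must be > 0")
    if h_um <= 0:
        raise ParameterError("h_um must be > 0")
    if Q < 0 or int(Q) != Q:
        raise ParameterError("Q must be a nonnegative integer")
    nd = Q / (sum_A_um2 * h_um) * UM3_PER_MM3
    return DensityEstimate(
        Q=int(Q), n_frames=n_frames, sum_A_um2=float(sum_A_um2), h_um=float(h_um),
        nd_cells_per_mm3=float(nd),
    )


def estimate_density(
    somata_by_section: list[np.ndarray],
    region_masks: list[np.ndarray],
    design: FractionatorDesign,
    px_size_um: float,
    rng: np.random.Generator | None = None,
) -> DensityEstimate:
    """Run the full fractionator over a subject's sampled sections.

    Each section contributes its own systematically placed frames (fresh
    random offset per section) and disector counts; Q and the sampled
    area accumulate across sections.
    """
    if len(somata_by_section) != len(region_masks):
        raise ParameterError("need one region mask per section")
    if rng is None:
        rng = np.random.default_rng(design.seed)
    side = design.frame_side_um
    Q = 0
    n_frames = 0
    for somata, region in zip(somata_by_section, region_masks):
        frames = place_frames(region, design, px_size_um, rng=rng)
        n_frames += len(frames)
        Q += count_Q(somata, frames, side, design.step_um)
    sum_A = n_frames * design.frame_area_um2
    if sum_A <= 0:
        raise ParameterError("no counting frames landed in any section region")
    return numerical_density(Q, sum_A, design.section_thickness_um, n_frames=n_frames)
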