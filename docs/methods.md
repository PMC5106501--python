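# Methods

`gliamorph` quantifies microglial morphology in single-channel micrographs
the way classical neuropathology image analysis does, and ships a synthetic
micrograph generator with exact per-cell ground truth so that every
measurement stage can be validated end to end. This note documents the
models, the numerical choices, and what validation on synthetic data does
and does not establish.

## The synthetic micrograph model

Images emulate Iba1/P2ry12-immunostained hippocampal (dentate-gyrus hilus)
fields: bright cells on a dark noisy background, 8-bit grayscale, default
0.5 µm/px and 2048×2048 px (≈1×1 mm). The region of interest (the "hilus")
is a polygon rasterised by even-odd scanline fill.

Each cell is a soma disc plus `k ≥ 3` radial processes. Tip angles are
jittered-regular (`θ_i = 2π(i + U(−0.3, 0.3))/k`, random global rotation),
which guarantees angular separation so neighbouring processes remain
resolvable near the soma. The per-cell territory `A` is drawn from the
preset's normal distribution (rejected below 100 µm², a floor > 2.7 SD
under both preset means), and the common tip radius solves the shoelace
identity for points on a circle,

    A = R²/2 · Σ_i sin(Δθ_i)   ⇒   R = sqrt(2A / Σ_i sin(Δθ_i)),

so the polygon over the tips has *exactly* the drawn area. Angle sets whose
`Σ sin(Δθ)` falls below 40% of the regular-polygon value are redrawn to keep
`R` bounded. Any discrepancy between measured and true territory is
therefore attributable to the measurement pipeline, not the generator.

Process centrelines are straight chords with a half-sine lateral bow of
amplitude ∝ `tortuosity × length` (zero at both ends, so the tip is exact).
They are rendered as genuine 1-px Bresenham polylines (vertices every
~3 px), dilated to the preset's width over the proximal part only: the
distal `max(2.5 µm, width) + dilation radius` stays 1 px wide. This taper
mimics the distal thinning of real processes and — crucially for
validation — makes the topological skeleton of the rendered cell terminate
at the true tip pixel instead of retracting by half the process width.

Dystrophic features follow the minimal parameterisation of the qualitative
pathology (deramification, shortening, beading, cytorrhexis):

- *fragmentation*: with probability `fragmentation_prob` a process is cut
  by one gap (65%) or two gaps in disjoint bands (35%), each 2–4 µm long,
  capped at 20% of the process length; a distal piece of ≥ 2.5 µm is always
  preserved so the territory-defining tip survives;
- *spheroids*: discs of 2–4 µm diameter placed on processes at
  `spheroid_rate` per 100 µm of process length.

Noise is additive Gaussian on the background only (default sd 10 at
background level 40), clipped to [0, 255]; cell pixels are painted at 230.
The construction guarantees foreground > background + 3·noise sd, so a
fixed threshold in the 160–180 band recovers the rendered mask exactly.
This idealisation deliberately isolates the *geometric* measurement error;
it does not model stain variability (see Limitations).

### Phenotype presets

| parameter | ramified_braak2 | dystrophic_braak56 |
|---|---|---|
| territory mean ± SD (µm²) | 2012.12 ± 453.44 | 1119.39 ± 376.86 |
| target coverage (µm²/µm²) | 0.24 | 0.08 |
| processes (mean ± disp.) | 10 ± 2 | 5 ± 1.2 |
| soma radius (µm) | 4.5 ± 0.5 | 4.0 ± 0.5 |
| process width (µm) | 2.0 | 2.0 |
| tortuosity | 0.12 | 0.20 |
| fragmentation prob. | 0 | 0.35 |
| spheroids / 100 µm | 0 | 1.5 |

Territory and coverage anchors are the published morphometry of the two
phenotypes; process counts, soma radii, widths and tortuosity are declared
values chosen to look like the respective phenotypes at 0.5 µm/px (no
published values exist for them at this rendering model's level of
abstraction). Pixel size itself is a declared default: the source imaging
protocol reports objectives (4×/40×), not µm/px.

### Density calibration

`calibrate_density` finds the areal cell intensity (cells/mm²) whose mean
`true_coverage` over ≥ 20 seeded replicates hits the preset target within
`tol` (default 0.01). The search is a safeguarded bisection accelerated by
the Boolean model: coverage ≈ 1 − exp(−λ·a_eff), each evaluation refits
a_eff and jumps to the predicted root, clipped to the bracket. Replicates
use common random numbers across intensities, and non-monotone coverage
(beyond Monte-Carlo slack) aborts the calibration. Coverage fields place
somata without an exclusion distance (Poisson-like), so cells overlap as
they do in densely covered tissue.

## Segmentation

- 8-bit conversion rescales over the dtype range (a full-range 16-bit ramp
  maps onto the full 8-bit ramp); already-8-bit input passes through.
- The mask is `value ≥ threshold` with a fixed per-batch threshold,
  default 170, constrained to [160, 180] unless explicitly overridden
  (`≥` vs `>` and the absence of pre-smoothing are declared choices; the
  original densitometry software's semantics are not recoverable).
- Components use 8-connectivity so 1-px diagonal processes stay connected.
- Fragment grouping: components closer than `join_gaps_um` (default 5 µm,
  comfortably above the rendered 2–4 µm gaps and far below inter-cell
  spacing) are merged into one cell label. Implemented as labelling on a
  square (Chebyshev) dilation by half the join distance — separable and
  fast — with labels transferred back to original mask pixels, so every
  labelled pixel is mask-positive.
- Objects below `min_object_area_um2` (default 20 µm²) are removed after
  grouping.
- The soma is the maximum of the per-cell Euclidean distance transform
  (computed on the cell's padded bounding box); its value is the soma
  radius. Cells whose radius falls below `soma_min_radius_um` (default
  2 µm) have no visible cell body and are excluded from territory
  sampling and disector counting.

## Morphometry

**Loading** is positive area / region area, reported as a fraction and as
percent.

**Grid coverage** tiles the region with 354 × 354 µm squares anchored at
the region bounding-box origin (deterministic; no random offset is used
because none is specified for the reference procedure). A square enters
the analysis iff ≥ 50% of its area overlaps the region; covered area is
measured over square ∩ region. The nominal square area at this side length
is 125,316 µm² (the commonly quoted "125,000 µm²" is a rounding). A region
smaller than one square still yields a single-square result, with a
warning. Note that at the default 2048-px field (1024 µm side) a region
holds ~9 such squares; the 30–50 squares of a full hilar outline
correspond to a ~2×2 mm field, which the generator supports via
`width_px`/`height_px`.

**Territory (domain)**: skeleton endpoints are skeleton pixels with
exactly one 8-connected skeleton neighbour, pooled over all fragments of a
cell; the territory is the area of the convex hull of the endpoints — the
reproducible formalisation of "a polygon connecting the distal ends of all
processes". Whether a manually traced polygon is convex is ambiguous, so
the angular-order (possibly concave) polygon is available via
`method="angular"`; the hull is the default and is what all reported
numbers use. Fewer than 3 non-collinear endpoints yields an excluded
record, not an exception.

**Systematic cell sampling** uses square frames of 7118.3 µm² on a lattice
of pitch 238.64 µm with a seeded uniform random offset (inclusion
probability 7118.3/238.64² = 0.125 per cell). A cell is sampled iff its
soma lies strictly inside a frame or on the acceptance (top/right) edges
and not on the forbidden (left/bottom, extended) lines. Frames whose
centre falls outside the region are discarded. Sections are consumed
round-robin across subjects until the target cell count is reached.

**Dystrophy descriptors** per cell: skeleton fragment count, diagonal-
corrected skeleton length (orthogonal adjacency 1, diagonal √2, half per
pixel), endpoint count, and spheroid count — connected skeleton regions
whose local width (2 × distance transform) reaches 2 × the nominal process
width, minus the region containing the global width maximum (the soma).
The 2× width threshold is a declared constant.

## Optical fractionator

Counting frames of 1722 µm² on a 131.23 µm lattice with seeded uniform
random offset, a fresh offset per section; frames retained iff their
centre lies in the region. Somata are counted with the planar unbiased
counting-frame rule (strict inside or acceptance edges; forbidden
left/bottom extended lines excluded; frame side ≤ step guarantees each
soma counts at most once). Density is the printed estimator applied
verbatim,

    ND = Q / (ΣA · h) · 10⁹  cells/mm³,

with `h` the full section thickness (30 µm) and ΣA the accumulated frame
area. No guard zones are applied and somata are treated as projected
points — fidelity to the printed formula over textbook guard-zone
practice, as none are specified for the reference procedure. Worked
arithmetic: Q = 50 over 30 frames (ΣA = 51,660 µm²), h = 30 µm gives
32,262 cells/mm³. For homogeneous Poisson somata of known 3D density the
estimator is unbiased provided the point field extends beyond the region
(edge frames protrude by up to half a frame side; simulations that
truncate the point field at the region boundary show the expected ~2.5%
edge deficit, which is a property of the bounded simulation, not the
estimator).

## Statistics

`compare_groups` reproduces the standard decision tree: per-group
normality via a Kolmogorov–Smirnov test with estimated mean/SD
(Lilliefors situation), whose null distribution is simulated by a seeded
parametric bootstrap (default 2000 resamples, each re-standardised by its
own estimates; p = (1 + #{D* ≥ D})/(B+1)). If every group passes at
α = 0.05 the parametric branch runs (two-tailed t test, or one-way ANOVA
with Tukey HSD); otherwise the nonparametric branch (Mann–Whitney U, or
Kruskal–Wallis with Dunn's post hoc). All tests are two-sided.

- Mann–Whitney: for combined n ≤ 12 the permutation null of U is
  enumerated exhaustively over all C(n₁+n₂, n₁) labelings of the pooled
  midranks (ties handled naturally; two-sided p = P(|U−μ| ≥ |U_obs−μ|));
  otherwise the normal approximation with tie and continuity correction.
- Dunn's z uses pooled mean ranks with tie correction; the family-wise
  adjustment is Bonferroni by default (configurable: holm, none) since the
  reference procedure names no adjustment.
- Kendall τ-b is tie-corrected; for n ≤ 8 the two-sided p enumerates all
  n! pairings (valid under ties), otherwise the normal approximation.
  All-tied input is an error (undefined correlation).
- 2^−ΔΔCt expression: ΔCt = Ct_target − Ct_housekeeper; ΔΔCt references
  the arithmetic-mean ΔCt of the reference group (per gene when a gene
  column is present), making the reference group's geometric-mean fold
  exactly 1. Mean-referencing is a declared choice; per-sample pairing is
  the alternative the source leaves unspecified.

Under a two-group Gaussian null the full tree's type-I error at α = 0.05
is calibrated (checked at 2000 replicates in the test suite).

## Problem sizes used in validation

The test suite and `scripts/acceptance.py` validate at the cohort sizes of
the reference morphometry: 5 subjects / 200 sampled cells (ramified) and
7 / 300 (dystrophic) for territories on 2048-px fields; 4 and 9 subjects ×
2 sections for calibrated-coverage loading; 200 seeded designs for
fractionator recovery at ρ = 30,000 cells/mm³; 2000 replicates for type-I
calibration. Unit tests use 1024-px fields and smaller cohorts.

Territory fields place somata with an exclusion distance of twice a
high-quantile tip radius plus 12 µm, at ~60% of the random-sequential-
packing limit (≈ 49 cells per 2048-px field for the ramified preset) —
the synthetic analogue of imaging isolated cells at high magnification.
Coverage fields use the calibrated Poisson intensity (≈ 500 and ≈ 300
cells/mm² for the two presets) with overlap allowed.

## Limitations

- 2D only: no confocal stacks, no optical sectioning, no Cavalieri
  volumes, no CE estimation.
- The generator's arbor is single-level (radial processes without
  secondary branching); endpoint counts, not branch-order statistics, are
  the meaningful dystrophy readout.
- No amyloid plaques and no plaque-associated activated-microglia
  clustering are simulated, so the "areas distant from plaques" inclusion
  rule of real-tissue territory measurement never triggers.
- Noise-free foreground and exact threshold separability mean the
  validation exercises geometry recovery, not stain-intensity robustness:
  passing tests show the measurement pipeline is correct on images whose
  signal model is known, not that the threshold band is optimal for any
  particular real stain.
- Fractionator counting treats somata as points in projected sections; no
  guard zones, nucleus-vs-soma-top conventions, or z-axis shrinkage.
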