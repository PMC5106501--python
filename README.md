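# gliamorph

Quantitative microglial morphometry for immunostained micrographs, with a
ground-truthed synthetic image generator that makes every measurement
stage verifiable.

Microglia tile the brain parenchyma with non-overlapping surveillance
territories. In Alzheimer's-disease hippocampus they degenerate —
shortened, fragmented, beaded processes; shrunken territories; patchy
parenchymal coverage — and quantifying that degeneration from
Iba1/P2ry12-immunostained sections requires a handful of classical
measurements that are rarely available as tested, reusable code:

- **microglial loading** — the fraction of a region's area occupied by
  immunopositive signal;
- **grid spatial coverage** — the per-square stained area on a
  354 × 354 µm grid over the region, and its frequency distribution;
- **microglial domain** — the territory of a single cell, the area of the
  polygon over the distal endpoints of its processes (computed here as
  the convex hull of topological-skeleton endpoints), with cells selected
  by systematic uniform random sampling (7118.3 µm² frames, 238.64 µm
  steps, unbiased counting rule);
- **numerical density** via the optical fractionator,
  `ND = Q / (ΣA · h)` in cells/mm³, with Q the somata counted in unbiased
  frames (1722 µm², 131.23 µm steps) and h the section thickness (30 µm);
- the accompanying **group statistics**: a Kolmogorov–Smirnov normality
  gate (parametric-bootstrap null) routing to t test / ANOVA + Tukey or
  Mann–Whitney U / Kruskal–Wallis + Dunn, Kendall τ-b correlations, and
  2^−ΔΔCt relative qPCR expression.

No public raw images exist for the human-tissue studies this serves, so
the package ships a seeded generator of synthetic hilus fields — bright
ramified cells on dark noisy background at known µm/px — with two
phenotype presets calibrated to published Braak II vs Braak V–VI
morphometry (territories 2012.12 ± 453.44 vs 1119.39 ± 376.86 µm²;
coverage 0.24 vs 0.08 µm²/µm²) and exact per-cell ground truth: tip
polygons realise each cell's drawn territory *exactly*, so any
measurement error is attributable to the pipeline. See
`docs/methods.md` for the model and its limitations.

Intended users: neuropathology/neuroimmunology groups quantifying
microglial pathology in sections, and method developers who need a
ground-truthed benchmark for skeleton/territory/stereology code.

## Worked example

```python
import numpy as np
from gliamorph import (
    SegmentationParams, SyntheticSpec, default_region, generate_image,
    label_cells, make_preset, microglial_domain, microglial_loading,
    skeleton_endpoints, threshold_mask, to_gray8,
)

preset = make_preset("ramified_braak2")
# inset the region so every arbor stays inside the field
spec = SyntheticSpec(preset=preset, width_px=1024, height_px=1024,
                     region=default_region(1024, 1024, margin_px=100),
                     n_cells=12, min_separation_um=80.0, seed=7)
img = generate_image(spec)

params = SegmentationParams()          # fixed threshold 170, band 160-180
mask = threshold_mask(to_gray8(img.raster), params, px_size_um=img.px_size_um)
cells = label_cells(mask, params)

loading = microglial_loading(mask, img.region_mask)
domains = []
for lab in cells.cells["label"]:
    eps = skeleton_endpoints(cells.cell_mask(lab))
    m = microglial_domain(eps, img.px_size_um)
    if np.isfinite(m.domain_um2):
        domains.append(m.domain_um2)

print(f"cells: {cells.n_cells}  loading: {loading.loading:.4f}")
print(f"measured domain {np.mean(domains):.1f} um^2 "
      f"vs true {np.mean([c.true_domain_um2 for c in img.ground_truth]):.1f}")
```

Output:

```
cells: 12  loading: 0.0343
measured domain 2143.1 um^2 vs true 2141.0
```

Twelve well-separated ramified cells occupy ~3.4% of the inset region;
the pipeline recovers every cell and measures a mean territory within
0.1% of the generator's ground truth for this field (cohort-level
agreement with the preset anchors is validated in the test suite).
The same stages are available from the shell:

```sh
gliamorph synth --preset dystrophic_braak56 --seed 42 --out field/
gliamorph segment field/image.tif field/region.png --out seg/
gliamorph measure seg/labels.tif field/region.png --out measures/
gliamorph run config.yaml --out results/   # full two-cohort experiment
```

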