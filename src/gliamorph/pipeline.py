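"""End-to-end experiments: generate -> segment -> measure -> estimate -> compare.

The central use case is the Braak II vs Braak V-VI morphometric contrast:
cohorts of synthetic subjects are generated from the two phenotype
presets, every image is pushed through the measurement pipeline, and the
group statistics are computed on the recovered quantities.  Because the
generator records exact per-cell ground truth, the same machinery doubles
as a validation harness for the measurement stages.

Reproducibility: a single global seed fans out to per-stage child seeds
through a stated derivation (``SeedSequence([global_seed, crc32(stage)])``),
so each stage can be re-run independently with identical results, and the
experiment summary carries a hash of its full configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .morphometry import (
    SamplingDesign2D,
    dystrophy_metrics,
    grid_coverage,
    microglial_domain,
    microglial_loading,
    sample_cells_systematic,
    skeleton_endpoints,
)
from .presets import PhenotypePreset, make_preset
from .segmentation import SegmentationParams, label_cells, threshold_mask, to_gray8
from .stereology import FractionatorDesign, estimate_density
from .stats import compare_groups
from .synth import SyntheticSpec, calibrate_density, default_region, generate_image

__all__ = [
    "ExperimentConfig",
    "stage_seed",
    "domain_field_layout",
    "run_domain_recovery",
    "run_coverage_recovery",
    "run_experiment",
]


def stage_seed(global_seed: int, stage: str, index: int = 0) -> int:
    """Deterministic child seed for a named stage (< 2**31)."""
    ss = np.random.SeedSequence(
        [int(global_seed) % (2**31), zlib.crc32(stage.encode()), int(index)]
    )
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# domain-measurement fields


def domain_field_layout(
    preset: PhenotypePreset, width_px: int, height_px: int, px_size_um: float
) -> tuple[float, int, int]:
    """Soma separation, cell count and region margin for territory fields.

    Territory measurement requires cells that do not touch, so somata are
    placed with an exclusion distance of twice a high-quantile tip radius
    (mean + 2 SD of the territory area at the preset's typical branch
    count) plus a safety gap.  The cell count is set to ~60% of the
    random-sequential-packing limit at that separation, which places
    reliably; the region is inset so arbors stay inside the image.
    """
    k = max(3.0, preset.n_primary_branches[0])
    s_typ = 0.9 * k * np.sin(2 * np.pi / k)
    a_hi = preset.domain_area_um2[0] + 2.0 * preset.domain_area_um2[1]
    r_hi = np.sqrt(2.0 * a_hi / s_typ)
    sep_um = 2.0 * r_hi + 12.0
    margin_px = int(np.ceil((r_hi + 10.0) / px_size_um))
    region_area_um2 = (
        (width_px - 2 * margin_px) * (height_px - 2 * margin_px) * px_size_um**2
    )
    jam = 0.547 * region_area_um2 / (np.pi * (sep_um / 2.0) ** 2)
    n_cells = max(1, int(0.6 * jam))
    return sep_um, n_cells, margin_px


def _measure_image_domains(
    img,
    seg: SegmentationParams,
    design: SamplingDesign2D,
    sample_seed: int,
    domain_method: str = "hull",
    with_dystrophy: bool = False,
    branch_width_um: float = 2.0,
):
    """Segment one image, systematically sample cells, measure territories."""
    mask = threshold_mask(to_gray8(img.raster), seg, px_size_um=img.px_size_um)
    cells = label_cells(mask, seg)
    # only cells with a visible cell body enter the territory measurement:
    # stray fragments have no soma-scale distance-transform maximum
    visible = cells.cells[cells.cells["soma_radius_um"] >= seg.soma_min_radius_um]
    cells = dataclasses.replace(cells, cells=visible.reset_index(drop=True))
    design_i = dataclasses.replace(design, seed=sample_seed)
    sampled = sample_cells_systematic(cells, img.region_mask, design_i)
    rows = []
    for lab in sampled:
        patch = cells.cell_mask(lab)
        eps = skeleton_endpoints(patch)
        meas = microglial_domain(eps, img.px_size_um, cell_id=lab, method=domain_method)
        row = {
            "label": lab,
            "n_endpoints": meas.n_endpoints,
            "domain_um2": meas.domain_um2,
            "excluded_reason": meas.excluded_reason,
        }
        if with_dystrophy:
            d = dystrophy_metrics(
                patch, img.px_size_um, branch_width_um=branch_width_um, cell_id=lab
            )
            row.update(
                n_skeleton_fragments=d.n_skeleton_fragments,
                total_branch_length_um=d.total_branch_length_um,
                spheroid_count=d.spheroid_count,
            )
        rows.append(row)
    return rows


def run_domain_recovery(
    preset_name: str,
    n_subjects: int,
    n_cells_target: int,
    seed: int,
    *,
    width_px: int = 2048,
    height_px: int = 2048,
    px_size_um: float = 0.5,
    seg: SegmentationParams | None = None,
    design: SamplingDesign2D | None = None,
    max_sections_per_subject: int = 12,
    domain_method: str = "hull",
    with_dystrophy: bool = False,
) -> dict:
    """Measure microglial territories over a cohort of synthetic subjects.

    Subjects contribute sections round-robin (each section is one
    generated field, segmented and systematically sampled with the
    7118.3 um^2 / 238.64 um design) until ``n_cells_target`` cells have
    been measured.  Returns per-cell measurements, the cohort mean, and
    the matching generator ground truth.
    """
    preset = make_preset(preset_name)
    seg = seg or SegmentationParams()
    design = design or SamplingDesign2D()
    sep_um, n_cells, margin_px = domain_field_layout(
        preset, width_px, height_px, px_size_um
    )
    region = default_region(width_px, height_px, margin_px)

    rows: list[dict] = []
    truth_domains: list[float] = []
    done = False
    for section in range(max_sections_per_subject):
        for subject in range(n_subjects):
            img_seed = stage_seed(seed, f"domain/{preset_name}/s{subject}", section)
            spec = SyntheticSpec(
                preset=preset,
                width_px=width_px,
                height_px=height_px,
                px_size_um=px_size_um,
                region=region,
                n_cells=n_cells,
                min_separation_um=sep_um,
                seed=img_seed,
            )
            img = generate_image(spec)
            truth_domains.extend(c.true_domain_um2 for c in img.ground_truth)
            samp_seed = stage_seed(seed, f"domain-sample/{preset_name}/s{subject}", section)
            for r in _measure_image_domains(
                img,
                seg,
                design,
                samp_seed,
                domain_method=domain_method,
                with_dystrophy=with_dystrophy,
                branch_width_um=preset.branch_width_um,
            ):
                r.update(subject=subject, section=section)
                rows.append(r)
            n_ok = sum(1 for r in rows if np.isfinite(r["domain_um2"]))
            if n_ok >= n_cells_target:
                done = True
                break
        if done:
            break
    df = pd.DataFrame(rows)
    measured = df[np.isfinite(df["domain_um2"])].head(n_cells_target)
    return {
        "preset": preset_name,
        "cells": df,
        "domains_um2": measured["domain_um2"].to_numpy(),
        "mean_domain_um2": float(measured["domain_um2"].mean()),
        "sd_domain_um2": float(measured["domain_um2"].std(ddof=1)),
        "n_cells": int(len(measured)),
        "truth_mean_domain_um2": float(np.mean(truth_domains)),
        "subjects": measured["subject"].to_numpy(),
    }


# ---------------------------------------------------------------------------
# coverage / loading fields


def run_coverage_recovery(
    preset_name: str,
    n_subjects: int,
    seed: int,
    *,
    images_per_subject: int = 2,
    tol: float = 0.01,
    width_px: int = 2048,
    height_px: int = 2048,
    px_size_um: float = 0.5,
    seg: SegmentationParams | None = None,
    calibration_replicates: int = 20,
    with_grid: bool = False,
    grid_side_um: float = 354.0,
) -> dict:
    """Calibrated-coverage cohort: generate, segment, measure loading.

    The cell intensity is first calibrated so the generator's mean
    coverage matches the preset target within ``tol``; subject images are
    then generated at that intensity and their microglial loading (and
    optionally per-square grid coverage) measured.
    """
    preset = make_preset(preset_name)
    seg = seg or SegmentationParams()
    template = SyntheticSpec(
        preset=preset,
        width_px=width_px,
        height_px=height_px,
        px_size_um=px_size_um,
        cell_intensity=0.0,
        seed=stage_seed(seed, f"calibrate/{preset_name}"),
    )
    intensity = calibrate_density(
        preset, template, tol=tol, n_replicates=calibration_replicates
    )
    rows = []
    grid_rows = []
    for subject in range(n_subjects):
        for section in range(images_per_subject):
            img_seed = stage_seed(seed, f"coverage/{preset_name}/s{subject}", section)
            spec = dataclasses.replace(template, cell_intensity=intensity, seed=img_seed)
            img = generate_image(spec)
            mask = threshold_mask(to_gray8(img.raster), seg, px_size_um=px_size_um)
            loading = microglial_loading(mask, img.region_mask)
            rows.append(
                {
                    "subject": subject,
                    "section": section,
                    "loading": loading.loading,
                    "positive_area_um2": loading.positive_area_um2,
                    "region_area_um2": loading.region_area_um2,
                    "true_coverage": img.true_coverage,
                }
            )
            if with_grid:
                g = grid_coverage(mask, img.region_mask, side_um=grid_side_um)
                gdf = g.squares.assign(subject=subject, section=section)
                grid_rows.append(gdf)
    loadings = pd.DataFrame(rows)
    per_subject = loadings.groupby("subject")["loading"].mean()
    out = {
        "preset": preset_name,
        "intensity_cells_per_mm2": float(intensity),
        "images": loadings,
        "mean_loading": float(per_subject.mean()),
        "per_subject_loading": per_subject.to_numpy(),
        "mean_true_coverage": float(loadings["true_coverage"].mean()),
    }
    if with_grid:
        out["grid_squares"] = (
            pd.concat(grid_rows, ignore_index=True) if grid_rows else pd.DataFrame()
        )
    return out


# ---------------------------------------------------------------------------
# the full experiment


@dataclass
class GroupSpec:
    """Cohort definition for one experimental group."""

    preset: str
    n_subjects: int
    domain_cells_target: int


@dataclass
class ExperimentConfig:
    """Configuration of the full two-group morphometry experiment.

    Defaults mirror the reference cohort shape: 5 control-like subjects
    vs 7 dystrophic subjects, 2 coverage sections per subject, and
    territory targets of 200 vs 300 systematically sampled cells.
    """

    groups: dict[str, GroupSpec] = field(
        default_factory=lambda: {
            "BraakII": GroupSpec("ramified_braak2", 5, 200),
            "BraakV_VI": GroupSpec("dystrophic_braak56", 7, 300),
        }
    )
    width_px: int = 2048
    height_px: int = 2048
    px_size_um: float = 0.5
    images_per_subject: int = 2
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    sampling: SamplingDesign2D = field(default_factory=SamplingDesign2D)
    fractionator: FractionatorDesign = field(default_factory=FractionatorDesign)
    grid_side_um: float = 354.0
    calibration_tol: float = 0.01
    calibration_replicates: int = 20
    domain_method: str = "hull"
    seed: int = 0
    out_dir: str | None = None

    def validate(self) -> None:
        for name, g in self.groups.items():
            make_preset(g.preset)  # raises ConfigurationError for unknown names
            if g.n_subjects < 1 or g.domain_cells_target < 1:
                raise ConfigurationError(f"group {name!r} has an empty cohort")

    def config_hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return {k: enc(v) for k, v in dataclasses.asdict(o).items()}
            if isinstance(o, dict):
                return {k: enc(v) for k, v in o.items()}
            if isinstance(o, np.ndarray):
                return o.tolist()
            return o

        payload = json.dumps(enc(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_experiment(config: ExperimentConfig) -> dict:
    """Run the full generate -> measure -> estimate -> compare experiment.

    Deterministic given the config seed.  Returns a summary dict with
    per-group means/SDs and group-comparison p-values for loading,
    territory, per-square grid coverage, and numerical density; when
    ``config.out_dir`` is set the per-image/per-cell tables and the
    summary JSON are also written there.
    """
    config.validate()
    chash = config.config_hash()
    summary: dict = {"config_hash": chash, "seed": config.seed, "groups": {}}
    tables: dict[str, pd.DataFrame] = {}

    loading_tbl, domain_tbl, grid_tbl, nd_tbl = [], [], [], []
    for gname, gspec in config.groups.items():
        cov = run_coverage_recovery(
            gspec.preset,
            gspec.n_subjects,
            stage_seed(config.seed, f"coverage-stage/{gname}"),
            images_per_subject=config.images_per_subject,
            tol=config.calibration_tol,
            width_px=config.width_px,
            height_px=config.height_px,
            px_size_um=config.px_size_um,
            seg=config.segmentation,
            calibration_replicates=config.calibration_replicates,
            with_grid=True,
            grid_side_um=config.grid_side_um,
        )
        dom = run_domain_recovery(
            gspec.preset,
            gspec.n_subjects,
            gspec.domain_cells_target,
            stage_seed(config.seed, f"domain-stage/{gname}"),
            width_px=config.width_px,
            height_px=config.height_px,
            px_size_um=config.px_size_um,
            seg=config.segmentation,
            design=config.sampling,
            domain_method=config.domain_method,
            with_dystrophy=True,
        )
        # numerical density per subject from the segmented coverage images:
        # each image is one sampled section, somata from the labelled cells.
        nd_rows = []
        for subject in range(gspec.n_subjects):
            somata, regions = [], []
            for section in range(config.images_per_subject):
                img_seed = stage_seed(
                    stage_seed(config.seed, f"coverage-stage/{gname}"),
                    f"coverage/{gspec.preset}/s{subject}",
                    section,
                )
                spec = SyntheticSpec(
                    preset=make_preset(gspec.preset),
                    width_px=config.width_px,
                    height_px=config.height_px,
                    px_size_um=config.px_size_um,
                    cell_intensity=cov["intensity_cells_per_mm2"],
                    seed=img_seed,
                )
                img = generate_image(spec)
                mask = threshold_mask(
                    to_gray8(img.raster), config.segmentation, px_size_um=config.px_size_um
                )
                cells = label_cells(mask, config.segmentation)
                ok = cells.cells["soma_radius_um"] >= config.segmentation.soma_min_radius_um
                somata.append(
                    cells.cells.loc[ok, ["soma_x_um", "soma_y_um"]].to_numpy()
                )
                regions.append(img.region_mask)
            est = estimate_density(
                somata,
                regions,
                config.fractionator,
                config.px_size_um,
                rng=np.random.default_rng(
                    stage_seed(config.seed, f"density/{gname}", subject)
                ),
            )
            nd_rows.append(
                {
                    "group": gname,
                    "subject": subject,
                    "Q": est.Q,
                    "n_frames": est.n_frames,
                    "sum_A_um2": est.sum_A_um2,
                    "nd_cells_per_mm3": est.nd_cells_per_mm3,
                }
            )

        loading_tbl.append(cov["images"].assign(group=gname))
        domain_tbl.append(dom["cells"].assign(group=gname))
        grid_tbl.append(cov["grid_squares"].assign(group=gname))
        nd_tbl.extend(nd_rows)
        summary["groups"][gname] = {
            "preset": gspec.preset,
            "intensity_cells_per_mm2": cov["intensity_cells_per_mm2"],
            "mean_loading": cov["mean_loading"],
            "sd_loading": float(np.std(cov["per_subject_loading"], ddof=1)),
            "mean_domain_um2": dom["mean_domain_um2"],
            "sd_domain_um2": dom["sd_domain_um2"],
            "n_domain_cells": dom["n_cells"],
            "mean_nd_cells_per_mm3": float(
                np.mean([r["nd_cells_per_mm3"] for r in nd_rows])
            ),
        }

    tables["loading"] = pd.concat(loading_tbl, ignore_index=True)
    tables["domains"] = pd.concat(domain_tbl, ignore_index=True)
    tables["grid"] = pd.concat(grid_tbl, ignore_index=True)
    tables["density"] = pd.DataFrame(nd_tbl)

    rng = np.random.default_rng(stage_seed(config.seed, "stats"))
    comparisons = {}
    per_subject_loading = (
        tables["loading"].groupby(["group", "subject"])["loading"].mean().reset_index()
    )
    comparisons["loading"] = compare_groups(
        {
            g: sub["loading"].to_numpy()
            for g, sub in per_subject_loading.groupby("group")
        },
        rng=rng,
    )
    dom_ok = tables["domains"][np.isfinite(tables["domains"]["domain_um2"])]
    comparisons["domain"] = compare_groups(
        {g: sub["domain_um2"].to_numpy() for g, sub in dom_ok.groupby("group")},
        rng=rng,
    )
    comparisons["grid_coverage"] = compare_groups(
        {
            g: sub["covered_area_um2"].to_numpy()
            for g, sub in tables["grid"].groupby("group")
        },
        rng=rng,
    )
    comparisons["density"] = compare_groups(
        {
            g: sub["nd_cells_per_mm3"].to_numpy()
            for g, sub in tables["density"].groupby("group")
        },
        rng=rng,
    )
    summary["comparisons"] = {
        k: {"method": c.method, "statistic": c.statistic, "p_value": c.p_value}
        for k, c in comparisons.items()
    }

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(out / f"{name}.csv", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        # provenance sidecar: everything needed to re-run this experiment
        import scipy

        from . import __version__

        meta = {
            "config_hash": chash,
            "seed": config.seed,
            "segmentation": dataclasses.asdict(config.segmentation),
            "sampling": dataclasses.asdict(config.sampling),
            "fractionator": dataclasses.asdict(config.fractionator),
            "versions": {
                "gliamorph": __version__,
                "numpy": np.__version__,
                "scipy": scipy.__version__,
                "pandas": pd.__version__,
            },
        }
        with open(out / "run_metadata.json", "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
    summary["tables"] = tables
    summary["comparison_objects"] = comparisons
    return summary
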