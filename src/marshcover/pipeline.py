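"""End-to-end orchestration of the synthetic drone-vs-ground study.

``run_pipeline`` reproduces the whole assessment on a seeded synthetic
landscape: simulate the scene per flight altitude, classify each plot's
mosaic separately, clean the classified maps, estimate per-cell cover by
ground transects, drone pixel counts and drone transects, run the accuracy
assessment, and fit the beta GLMM comparisons.  All randomness fans out
from one master seed through named substreams so single stages re-run
reproducibly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import accuracy as acc
from . import betastats
from . import classify as clf
from . import estimators as est
from . import ground
from . import postprocess as post
from .geometry import GsdModel, SurveyDesign, default_design
from .raster import CLASS_IDS, ClassRaster, write_raster
from .synthetic import SceneSpec, SyntheticScene, simulate_study

logger = logging.getLogger(__name__)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed (< 2^31)."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


@dataclass
class PipelineConfig:
    master_seed: int = 0
    altitudes_m: tuple[float, ...] = (75.0, 100.0, 120.0)
    gsd_k: float = 0.0016          # synthetic default: 16 cm at 100 m
    target_props: tuple[float, float, float] = (0.755, 0.035, 0.210)
    spatial_corr_length_m: float = 6.0
    confusability: float = 0.5
    shadow_fraction: float = 0.15
    dark_soil_fraction: float = 0.25
    noise_sd: float | None = None  # None -> generator's default spectral covariances
    plot_cell_counts: tuple[int, ...] = (24, 20, 20, 16, 12)
    plot_rows: int = 4
    n_clusters: int = 30
    kmeans_sample_size: int | None = 200_000
    ground_spacing_m: float = 1.0
    misclass_rate: float = 0.0
    mmu_m2: float = 0.25
    n_accuracy_points: int = 100
    quadrature_nodes: int = 15
    run_stats: bool = True
    output_dir: str | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @staticmethod
    def from_json(text: str) -> "PipelineConfig":
        d = json.loads(text)
        for k in ("altitudes_m", "target_props", "plot_cell_counts"):
            if k in d and d[k] is not None:
                d[k] = tuple(d[k])
        return PipelineConfig(**d)

    def design(self) -> SurveyDesign:
        counts = tuple(self.plot_cell_counts)
        return default_design(counts, self.plot_rows, scaled=sum(counts) != 92)

    def scene_spec(self) -> SceneSpec:
        native_gsd = self.gsd_k * min(self.altitudes_m)
        return SceneSpec(
            seed=stage_seed(self.master_seed, "scene"),
            gsd_m=native_gsd,
            target_props=self.target_props,
            spatial_corr_length_m=self.spatial_corr_length_m,
            confusability=self.confusability,
            shadow_fraction=self.shadow_fraction,
            dark_soil_fraction=self.dark_soil_fraction,
            noise_sd=self.noise_sd,
        )


@dataclass
class PipelineResult:
    config: PipelineConfig
    scenes: dict[float, SyntheticScene]
    classified: dict[float, ClassRaster]
    cover_table: pd.DataFrame
    study_proportions: dict[float, np.ndarray]
    confusion: dict[float, list[acc.ConfusionMatrix]]
    accuracy_summary: pd.DataFrame
    stats_report: dict[str, pd.DataFrame] | None
    manifest: dict


def classify_scene(
    scene: SyntheticScene, design: SurveyDesign, config: PipelineConfig, seed: int
) -> ClassRaster:
    """Per-plot clustering + plurality reclassification + clean-up chain.

    Each plot is clustered separately (light conditions vary between
    mosaics in the field workflow), then the per-plot maps are mosaicked
    back and post-processed as one raster.
    """
    rgb, truth = scene.rgb, scene.truth
    from .raster import NODATA

    out = np.full(rgb.shape, NODATA, dtype=np.uint8)  # margin outside plots stays nodata
    rows, cols = rgb.shape
    for i, plot in enumerate(design.plots):
        # outward-rounded pixel bounds: every pixel is classified by some
        # plot's model; pixels straddling a plot edge take the later plot's
        g = rgb.gsd_m
        c0 = int(np.floor(plot.x_min / g + 1e-9))
        c1 = min(int(np.ceil((plot.x_min + plot.width_m) / g - 1e-9)), cols)
        r1 = min(rows - int(np.floor(plot.y_min / g + 1e-9)), rows)
        r0 = max(rows - int(np.ceil((plot.y_min + plot.height_m) / g - 1e-9)), 0)
        if plot.y_min + plot.height_m >= rows * g - g - 1e-9:  # absorb the ceil margin strip
            r0 = 0
        if plot.x_min + plot.width_m >= cols * g - g - 1e-9:
            c1 = cols
        sub_rgb = type(rgb)(rgb.data[r0:r1, c0:c1].copy(), rgb.gsd_m)
        sub_truth = ClassRaster(truth.data[r0:r1, c0:c1].copy(), truth.gsd_m)
        model = clf.fit_clusters(
            sub_rgb, K=config.n_clusters, seed=seed + i,
            sample_size=config.kmeans_sample_size,
        )
        mapped = clf.reclassify_clusters(model, sub_rgb, reference=sub_truth)
        out[r0:r1, c0:c1] = mapped.data
    raw = ClassRaster(out, rgb.gsd_m, rgb.origin)
    return post.postprocess_chain(raw, min_area_m2=config.mmu_m2)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    t0 = time.time()
    design = config.design()
    spec = config.scene_spec()
    gsd_model = GsdModel(k=config.gsd_k)
    logger.info("simulating %d-cell study at %d altitudes", design.n_cells, len(config.altitudes_m))
    scenes = simulate_study(spec, design, list(config.altitudes_m), gsd_model)

    # ground truth sampling happens once, on the native-resolution truth
    native_truth = scenes[min(config.altitudes_m, key=lambda a: gsd_model.gsd_m(a))].truth
    records = ground.walk_transects(
        native_truth, design, spacing_m=config.ground_spacing_m,
        misclass_rate=config.misclass_rate, seed=stage_seed(config.master_seed, "ground"),
    )
    tables = [ground.cell_proportions_from_points(records)]

    classified: dict[float, ClassRaster] = {}
    study_props: dict[float, np.ndarray] = {}
    confusion: dict[float, list[acc.ConfusionMatrix]] = {}
    per_alt_metrics: dict[float, list[dict]] = {}
    for alt, scene in scenes.items():
        logger.info("altitude %.0f m: classifying %s px", alt, scene.rgb.data.shape[:2])
        cls = classify_scene(scene, design, config, seed=stage_seed(config.master_seed, f"classify:{alt}"))
        classified[alt] = cls
        tables.append(est.pixel_count_proportions(cls, design, altitude_m=alt))
        tables.append(est.virtual_transect_proportions(cls, design, spacing_m=config.ground_spacing_m, altitude_m=alt))
        study_props[alt] = est.study_area_proportions(cls, design)
        cms, metrics = [], []
        for plot in design.plots:
            pts = acc.stratified_points(
                cls, plot, n_points=config.n_accuracy_points,
                seed=stage_seed(config.master_seed, f"assess:{alt}:{plot.plot_id}"),
            )
            cm = acc.confusion_matrix(pts, cls, scene.truth, plot_id=plot.plot_id, altitude_m=alt)
            cms.append(cm)
            metrics.append(acc.accuracy_metrics(cm))
        confusion[alt] = cms
        per_alt_metrics[alt] = metrics

    cover_table = pd.concat(tables, ignore_index=True)
    est.validate_cover_table(cover_table)

    summaries = []
    for alt, metrics in per_alt_metrics.items():
        s = acc.summarize_accuracy(metrics)
        s.insert(0, "altitude_m", alt)
        summaries.append(s)
    accuracy_summary = pd.concat(summaries, ignore_index=True)

    stats_report = None
    if config.run_stats:
        if len(config.altitudes_m) >= 2:
            stats_report = betastats.method_comparison_report(
                cover_table, altitudes=tuple(config.altitudes_m),
                reference_altitude=min(config.altitudes_m),
                quadrature_nodes=config.quadrature_nodes,
            )
        else:
            logger.info("single altitude: altitude models skipped, method family only")
            stats_report = betastats.method_comparison_report(
                cover_table, altitudes=tuple(config.altitudes_m),
                reference_altitude=config.altitudes_m[0],
                quadrature_nodes=config.quadrature_nodes,
            )

    manifest = {
        "config": json.loads(config.to_json()),
        "n_cells": design.n_cells,
        "wall_time_s": round(time.time() - t0, 2),
        "hashes": {
            f"truth@{alt:g}": hashlib.sha256(s.truth.data.tobytes()).hexdigest()[:16]
            for alt, s in scenes.items()
        }
        | {
            f"classified@{alt:g}": hashlib.sha256(c.data.tobytes()).hexdigest()[:16]
            for alt, c in classified.items()
        }
        | {"cover_table": hashlib.sha256(cover_table.round(12).to_csv(index=False).encode()).hexdigest()[:16]},
    }

    result = PipelineResult(
        config=config, scenes=scenes, classified=classified, cover_table=cover_table,
        study_proportions=study_props, confusion=confusion,
        accuracy_summary=accuracy_summary, stats_report=stats_report, manifest=manifest,
    )
    if config.output_dir:
        _write_outputs(result, Path(config.output_dir))
    return result


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for alt, scene in result.scenes.items():
        write_raster(scene.truth, outdir / f"truth_{alt:g}m.tif")
        write_raster(scene.rgb, outdir / f"rgb_{alt:g}m.tif")
        write_raster(result.classified[alt], outdir / f"classified_{alt:g}m.tif")
    est.write_cover_table(result.cover_table, outdir / "cell_cover.csv")
    result.accuracy_summary.to_csv(outdir / "accuracy_summary.csv", index=False)
    rows = []
    for alt, cms in result.confusion.items():
        for cm in cms:
            for i in CLASS_IDS:
                for j in CLASS_IDS:
                    rows.append({"altitude_m": alt, "plot_id": cm.plot_id,
                                 "mapped": i, "reference": j, "count": int(cm.counts[i, j])})
    pd.DataFrame(rows).to_csv(outdir / "confusion_matrices.csv", index=False)
    if result.stats_report:
        for name, df in result.stats_report.items():
            df.to_csv(outdir / f"stats_{name}.csv", index=False)
    (outdir / "manifest.json").write_text(json.dumps(result.manifest, indent=2, sort_keys=True))
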