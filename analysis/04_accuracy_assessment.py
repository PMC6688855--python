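#!/usr/bin/env python
"""Accuracy assessment of the cleaned classifications.

100 stratified random points per plot per altitude (500 per altitude),
scored against the truth raster: per-plot confusion matrices, overall
accuracy, kappa, omission/commission, and the across-plot summary
(mean +/- SD, range).  Writes results/accuracy_summary.csv and
results/confusion_matrices.csv.
"""

from pathlib import Path

import pandas as pd

from marshcover import accuracy as acc
from marshcover.pipeline import PipelineConfig, stage_seed
from marshcover.raster import CLASS_IDS, CLASS_NAMES, read_raster

ROOT = Path(__file__).resolve().parents[1]
RASTERS = ROOT / "scratch" / "rasters"
RESULTS = ROOT / "results"


def main() -> None:
    cfg = PipelineConfig.from_json((RESULTS / "study_config.json").read_text())
    design = cfg.design()
    summaries, cm_rows = [], []
    for alt in cfg.altitudes_m:
        cls = read_raster(RASTERS / f"classified_{alt:g}m.tif")
        truth = read_raster(RASTERS / f"truth_{alt:g}m.tif")
        metrics = []
        for plot in design.plots:
            pts = acc.stratified_points(cls, plot, cfg.n_accuracy_points,
                                        seed=stage_seed(cfg.master_seed, f"assess:{alt}:{plot.plot_id}"))
            cm = acc.confusion_matrix(pts, cls, truth, plot_id=plot.plot_id, altitude_m=alt)
            metrics.append(acc.accuracy_metrics(cm))
            for i in CLASS_IDS:
                for j in CLASS_IDS:
                    cm_rows.append({"altitude_m": alt, "plot_id": plot.plot_id,
                                    "mapped": CLASS_NAMES[i], "reference": CLASS_NAMES[j],
                                    "count": int(cm.counts[i, j])})
        s = acc.summarize_accuracy(metrics)
        s.insert(0, "altitude_m", alt)
        summaries.append(s)
        oa = s[s["metric"] == "overall_accuracy"].iloc[0]
        print(f"{alt:g} m AGL: OA {100*oa['mean']:.1f}% +/- {oa['sd']:.3f} "
              f"(range {oa['min']:.2f}-{oa['max']:.2f})")
    pd.concat(summaries, ignore_index=True).to_csv(RESULTS / "accuracy_summary.csv", index=False)
    pd.DataFrame(cm_rows).to_csv(RESULTS / "confusion_matrices.csv", index=False)


if __name__ == "__main__":
    main()
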