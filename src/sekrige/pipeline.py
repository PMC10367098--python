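"""End-to-end survey-to-maps pipeline.

Per stratum (district x demographic group): GPS exclusions -> summary
statistics + octile-skew normality gate + inflammation-correlation check ->
empirical variograms (Matheron and Cressie–Hawkins) -> REML fits for each
candidate family -> leave-one-out cross-validation and model selection by
median SSPE -> kriging prediction, variance, and threshold-probability
surfaces on the polygon-clipped grid -> prevalence tables.  Every stage's
outputs land in the run directory, together with a machine-readable
manifest that suffices to re-run the pipeline identically.

A stage failure aborts the stratum, not the run; the manifest records it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import Polygon

from . import __version__
from .exploratory import (
    exclude_bad_gps,
    inflammation_check,
    normality_gate,
    quantile_post_classes,
    summarize,
)
from .io import read_polygon, read_survey, records_xyz, polygon_is_geographic
from .kriging import loo_cross_validate, select_model
from .mapping import (
    ThresholdSet,
    average_district_probability,
    build_grid,
    predict_surface,
    prevalence_table,
    probability_surface,
    verbal_classify,
)
from .variogram import empirical_variogram, reml_fit

log = logging.getLogger("sekrige")


@dataclass
class PipelineConfig:
    survey_csv: str
    polygon_geojson: str
    output_dir: str
    districts: Sequence[str] | None = None       # None -> all present
    groups: Sequence[str] | None = None
    families: Sequence[str] = ("exponential", "spherical")
    estimators: Sequence[str] = ("matheron", "cressie_hawkins")
    grid_spacing_m: float = 250.0
    thresholds: ThresholdSet = dc_field(default_factory=ThresholdSet)
    alpha: float = 0.05
    gps_buffer_km: float = 1.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        thr = raw.pop("thresholds", None)
        cfg = cls(**raw)
        if thr:
            cfg.thresholds = ThresholdSet(**thr)
        return cfg

    def to_dict(self) -> dict:
        d = {
            "survey_csv": self.survey_csv,
            "polygon_geojson": self.polygon_geojson,
            "output_dir": self.output_dir,
            "districts": list(self.districts) if self.districts else None,
            "groups": list(self.groups) if self.groups else None,
            "families": list(self.families),
            "estimators": list(self.estimators),
            "grid_spacing_m": self.grid_spacing_m,
            "thresholds": self.thresholds.as_dict(),
            "alpha": self.alpha,
            "gps_buffer_km": self.gps_buffer_km,
            "seed": self.seed,
        }
        return d


#: group -> the threshold used for its conditional probability map
#: (GPX3 for women of reproductive age, IDI for young children)
GROUP_THRESHOLD = {"wra": "gpx3", "child": "idi"}


def _run_stratum(
    records,
    polygon: Polygon,
    district: str,
    group: str,
    cfg: PipelineConfig,
    outdir: Path,
) -> dict:
    """One district x group stratum; returns its manifest entry."""
    entry: dict = {"district": district, "group": group}
    tag = f"{district}_{group}"

    retained, excl = exclude_bad_gps(records, polygon, cfg.gps_buffer_km)
    entry["exclusions"] = excl.to_dict()
    (outdir / f"{tag}_exclusions.json").write_text(
        json.dumps(excl.to_dict(), indent=2)
    )
    coords, values = records_xyz(retained)

    stats = summarize(values)
    verdict, rationale = normality_gate(stats)
    entry["summary"] = stats.to_dict()
    entry["normality_gate"] = {"verdict": verdict, "rationale": rationale}
    pd.DataFrame([stats.to_dict()]).to_csv(
        outdir / f"{tag}_summary.csv", index=False
    )

    decision, table = inflammation_check(retained, alpha=cfg.alpha)
    entry["inflammation"] = {"decision": decision, "correlations": table}
    pd.DataFrame(table).to_csv(outdir / f"{tag}_inflammation.csv", index=False)

    bins = quantile_post_classes(values)
    pd.DataFrame(
        {
            "id": [r.id for r in retained],
            "x_km": coords[:, 0],
            "y_km": coords[:, 1],
            "se_ugL": values,
            "quartile_bin": bins,
        }
    ).to_csv(outdir / f"{tag}_postplot.csv", index=False)

    if verdict == "fail":
        entry["status"] = "needs_transformation"
        log.warning("%s: octile-skew gate failed; kriging skipped", tag)
        return entry

    for est in cfg.estimators:
        ev = empirical_variogram(coords, values, estimator=est)
        ev.to_frame().to_csv(outdir / f"{tag}_variogram_{est}.csv", index=False)

    reports = []
    fits = {}
    for family in cfg.families:
        model = reml_fit(coords, values, family)
        fits[family] = model.to_dict()
        reports.append(loo_cross_validate(model, coords, values))
    chosen, selection = select_model(reports)
    entry["fits"] = fits
    entry["selection"] = selection
    (outdir / f"{tag}_selection.json").write_text(json.dumps(selection, indent=2))
    pd.DataFrame(
        {"sspe": chosen.sspe}
    ).to_csv(outdir / f"{tag}_loocv_sspe.csv", index=False)

    grid = build_grid(polygon, cfg.grid_spacing_m)
    pred, var = predict_surface(chosen.model, coords, values, grid)
    thr_name = GROUP_THRESHOLD.get(group, "generic")
    threshold = getattr(cfg.thresholds, thr_name)
    prob = probability_surface(pred, var, threshold)

    surf = pred.to_frame().rename(columns={"value": "prediction_ugL"})
    surf["variance"] = var.values
    surf["p_below_threshold"] = prob.values
    surf["verbal_class"] = verbal_classify(prob.values)
    surf.to_csv(outdir / f"{tag}_surfaces.csv", index=False, float_format="%.6g")

    entry["chosen_model"] = chosen.model.to_dict()
    entry["median_sspe"] = chosen.median_sspe
    entry["grid_nodes"] = int(len(grid.nodes))
    entry["mean_kriging_variance"] = float(np.mean(var.values))
    entry["conditional_threshold"] = {"name": thr_name, "value": threshold}
    entry["average_probability_below"] = average_district_probability(prob)
    entry["status"] = "ok"
    log.info(
        "%s: n=%d, chose %s, median SSPE %.3f, avg P(<%.1f)=%.3f",
        tag, len(retained), chosen.model.family, chosen.median_sspe,
        threshold, entry["average_probability_below"],
    )
    return entry


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every requested stratum; returns (and writes) the run manifest."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    records, parse_report, transform = read_survey(cfg.survey_csv)
    polygon = read_polygon(cfg.polygon_geojson)
    if transform is not None and polygon_is_geographic(polygon):
        polygon = transform.project_polygon(polygon)

    districts = cfg.districts or sorted({r.district for r in records})
    groups = cfg.groups or sorted({r.group for r in records})

    manifest: dict = {
        "version": __version__,
        "config": cfg.to_dict(),
        "parse_report": parse_report,
        "strata": [],
    }
    for district in districts:
        for group in groups:
            sub = [r for r in records
                   if r.district == district and r.group == group]
            if not sub:
                manifest["strata"].append(
                    {"district": district, "group": group, "status": "empty"}
                )
                continue
            try:
                entry = _run_stratum(sub, polygon, district, group, cfg, outdir)
            except Exception as exc:  # stage failure aborts stratum, not run
                log.exception("stratum %s/%s failed", district, group)
                entry = {
                    "district": district,
                    "group": group,
                    "status": "failed",
                    "error": f"{type(exc).__name__}: {exc}",
                }
            manifest["strata"].append(entry)

    prev = prevalence_table(records, cfg.thresholds)
    prev.to_csv(outdir / "prevalence.csv", index=False, float_format="%.4g")
    manifest["prevalence_rows"] = len(prev)

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
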