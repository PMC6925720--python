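"""End-to-end pipeline: simulate -> screen -> fit -> appraise -> export.

A single resolved configuration drives every stage; each run writes its
artifacts (dataset snapshot, screening report, fit JSON, odds-ratio table,
smooth grid, spatial surface, district league table, GeoJSON exports and a
structured log) plus the resolved configuration itself into one directory, so
any output can be regenerated identically from the archived config.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import appraisal as appraisal_mod
from . import cohort, gamm, synthetic_data

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "summarize_cohort"]


@dataclass
class PipelineConfig:
    """Resolved configuration of a full pipeline run.

    In synthetic mode the geography / truth blocks drive the generator; in
    file mode ``data_path`` points at a child table CSV.  The config
    round-trips through YAML unchanged and is archived next to the outputs.
    """

    out_dir: str = "run"
    seed: int = 0
    mode: str = "synthetic"                   # "synthetic" | "file"
    data_path: str | None = None
    n_children: int = 8000
    geography: dict = field(default_factory=dict)      # GeographyConfig overrides
    truth: dict = field(default_factory=dict)          # TrueModel overrides
    model_spec: dict | None = None
    screening_alpha: float = 0.10
    interaction_alpha: float = 0.05
    run_screening: bool = False
    tolerances: dict = field(default_factory=dict)
    appraisal_k: int = 3
    appraisal_mode: str = "se"
    appraisal_within: str = "country"

    def validate(self) -> None:
        if self.mode not in ("synthetic", "file"):
            raise ValueError("mode must be 'synthetic' or 'file'")
        if self.mode == "file" and not self.data_path:
            raise ValueError("file mode needs data_path")
        if self.model_spec is None:
            raise ValueError("config missing model_spec")
        cohort.ModelSpec.from_dict(self.model_spec)  # fail fast on bad keys

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def _round_share(x: float) -> float:
    """Percentage share rounded half-up to one decimal."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"),
                                                  rounding=ROUND_HALF_UP))


def summarize_cohort(records: pd.DataFrame) -> pd.DataFrame:
    """Per-country counts, percentage shares and observed anaemia prevalence."""
    if len(records) == 0:
        raise ValueError("empty dataset")
    n_total = len(records)
    rows = []
    for country, g in records.groupby("country", sort=True):
        rows.append({
            "country": country,
            "n": len(g),
            "share_pct": _round_share(100.0 * len(g) / n_total),
            "prevalence_pct": _round_share(100.0 * g["y"].mean())
            if "y" in g else float("nan"),
        })
    rows.append({
        "country": "ALL", "n": n_total, "share_pct": 100.0,
        "prevalence_pct": _round_share(100.0 * records["y"].mean())
        if "y" in records else float("nan"),
    })
    return pd.DataFrame(rows)


def _districts_geojson(clusters: pd.DataFrame, league: pd.DataFrame) -> dict:
    """Point-per-district GeoJSON (district centroid of its clusters) carrying
    the appraisal properties, for quick choropleth-style joins."""
    cent = clusters.groupby("district_id")[["lon", "lat"]].mean()
    feats = []
    for _, row in league.iterrows():
        d = row["district_id"]
        if d not in cent.index:
            continue
        props = {k: (None if isinstance(v, float) and np.isnan(v) else v)
                 for k, v in row.items()}
        feats.append({
            "type": "Feature",
            "geometry": {"type": "Point",
                         "coordinates": [float(cent.loc[d, "lon"]),
                                         float(cent.loc[d, "lat"])]},
            "properties": props,
        })
    return {"type": "FeatureCollection", "features": feats}


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage under the given configuration; returns the run directory.

    Stage failures raise with the failing stage named; partial outputs remain
    for inspection.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    run_log: list[dict] = []

    def stage(name):
        t0 = time.time()
        run_log.append({"stage": name, "t_start": t0})
        log.info("stage %s", name)
        return t0

    try:
        stage("data")
        if config.mode == "synthetic":
            geo_cfg = synthetic_data.GeographyConfig(**config.geography) \
                if config.geography else synthetic_data.GeographyConfig()
            truth = synthetic_data.default_true_model(**config.truth)
            ds = synthetic_data.generate_dataset(
                geo_cfg, n_children=config.n_children, truth=truth,
                seed=config.seed)
            records = ds.records
            clusters = ds.geography.clusters
            ds.to_csv(out / "dataset.csv")
            with open(out / "clusters.geojson", "w") as fh:
                json.dump(ds.clusters_geojson(), fh)
            with open(out / "truth.json", "w") as fh:
                json.dump(ds.truth_sidecar(), fh, indent=2)
        else:
            records = cohort.load_records(config.data_path,
                                          report_path=out / "validation.json")
            clusters = records.drop_duplicates("cluster_id")[
                ["cluster_id", "district_id", "country", "lon", "lat"]]
        report = cohort.validate_records(records)
        summarize_cohort(records).to_csv(out / "cohort_summary.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'data' failed: {exc}") from exc

    spec = cohort.ModelSpec.from_dict(config.model_spec)

    try:
        stage("screen")
        if config.run_screening:
            screen = cohort.screen_covariates(
                records, [v for v in spec.linear], alpha=config.screening_alpha)
            screen.to_csv(out / "screening.csv", index=False)
            spec.linear = [v for v, keep in
                           zip(screen["variable"], screen["keep"]) if keep]
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'screen' failed: {exc}") from exc

    try:
        stage("fit")
        tols = gamm.Tolerances(**config.tolerances)
        fit = gamm.fit(records, spec, tolerances=tols)
        with open(out / "fit.json", "w") as fh:
            json.dump(fit.to_json_dict(), fh, indent=2)
        fit.aor_table().to_csv(out / "aor_table.csv", index=False)
        for term in spec.smooth:
            info = fit.state.terms[term]
            lo, hi = info.spline.domain
            grid = np.linspace(lo, hi, 101)
            fit.smooth_curve(term, grid).to_csv(
                out / f"smooth_{term}.csv", index=False)
        if spec.spatial:
            surf = fit.spatial_surface(clusters["lon"].to_numpy(),
                                       clusters["lat"].to_numpy())
            surf.insert(0, "cluster_id", clusters["cluster_id"].to_numpy())
            surf.to_csv(out / "spatial_surface.csv", index=False)
        if spec.interactions:
            fit.total_residence_country_effects().to_csv(
                out / "residence_country_totals.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'fit' failed: {exc}") from exc

    try:
        stage("appraise")
        if spec.district_effect:
            dmeta = records.drop_duplicates("district_id")[
                ["district_id", "country"]]
            league = appraisal_mod.appraise(
                fit, dmeta, k=config.appraisal_k, mode=config.appraisal_mode,
                within=config.appraisal_within)
            league.to_csv(out / "district_league.csv", index=False)
            with open(out / "districts.geojson", "w") as fh:
                json.dump(_districts_geojson(clusters, league), fh)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'appraise' failed: {exc}") from exc

    run_log.append({"stage": "done", "converged": bool(fit.converged),
                    "n_records": report["n_records"]})
    with open(out / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=2)
    return out
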