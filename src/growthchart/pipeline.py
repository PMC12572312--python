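"""Pipeline orchestration: simulate -> quantify -> flatmap -> fda -> mlm -> report.

Every stage reads its inputs from the output directory of the previous
stage and writes plain-text artifacts (CSV / JSON / YAML; NIfTI for the
label volume), each stamped with the config hash and study seed so any
reported number traces back to a stage artifact.  Rerunning a completed
stage without ``force`` is a no-op.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pathlib
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import fda as fda_mod
from . import flatmap as flatmap_mod
from . import multilevel as mlm_mod
from . import quantify, synthetic
from .atlas import LabelVolume, Ontology

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "write_growthchart_tables",
    "summarize_trajectories",
    "STAGES",
]

log = logging.getLogger(__name__)

STAGES = ("simulate", "quantify", "flatmap", "fda", "mlm", "report")


@dataclass
class PipelineConfig:
    outdir: str = "results/pipeline"
    seed: int = 0
    n_per_age: int = 4
    stages: tuple[str, ...] = STAGES
    detection_mode: str = "stochastic"
    factors: dict = field(default_factory=lambda: {"cytoplasmic": 1.4, "nuclear": 1.5})
    fda: dict = field(default_factory=dict)  # FdaConfig overrides
    mlm: dict = field(default_factory=dict)  # MultilevelSpec overrides
    reference_age: str | None = None  # flatmap normalization reference (default: oldest)
    ages: tuple[str, ...] = synthetic.DEFAULT_AGES
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.stages = tuple(cfg.stages)
        cfg.ages = tuple(cfg.ages)
        return cfg

    def config_hash(self) -> str:
        canon = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def conversion_factors(self) -> quantify.ConversionFactors:
        return quantify.ConversionFactors(**self.factors)

    def fda_config(self) -> fda_mod.FdaConfig:
        kwargs = dict(self.fda)
        kwargs.setdefault("seed", self.seed)
        if "n_basis" in kwargs:
            kwargs["n_basis"] = tuple(kwargs["n_basis"])
        return fda_mod.FdaConfig(**kwargs)

    def mlm_spec(self) -> mlm_mod.MultilevelSpec:
        kwargs = dict(self.mlm)
        kwargs.setdefault("seed", self.seed)
        return mlm_mod.MultilevelSpec(**kwargs)


def _stamp(config: PipelineConfig) -> dict:
    return {"config_hash": config.config_hash(), "seed": config.seed}


def _stage_dir(config: PipelineConfig, stage: str) -> pathlib.Path:
    d = pathlib.Path(config.outdir) / stage
    d.mkdir(parents=True, exist_ok=True)
    return d


def _done_marker(config: PipelineConfig, stage: str) -> pathlib.Path:
    return _stage_dir(config, stage) / "stage.json"

def _require(config: PipelineConfig, stage: str) -> None:
    if not _done_marker(config, stage).exists():
        raise FileNotFoundError(
            f"missing artifacts of upstream stage {stage!r}; run that stage first"
        )


def _finish(config: PipelineConfig, stage: str, artifacts: dict[str, str]) -> None:
    payload = {**_stamp(config), "stage": stage, "artifacts": artifacts}
    with open(_done_marker(config, stage), "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# stages


def stage_simulate(config: PipelineConfig, force: bool = False) -> dict[str, str]:
    out = _stage_dir(config, "simulate")
    if _done_marker(config, "simulate").exists() and not force:
        log.info("simulate: up to date")
        with open(_done_marker(config, "simulate")) as fh:
            return json.load(fh)["artifacts"]
    det = synthetic.DetectionSimSpec(mode=config.detection_mode)
    bundle = synthetic.generate_study(
        detection=det, n_per_age=config.n_per_age, seed=config.seed
    )
    paths = synthetic.write_study(bundle, out)
    log.info("simulate: %d truth cells, %d detections, %d samples",
             len(bundle.truth_cells), len(bundle.detected_cells), len(bundle.sample_ids()))
    _finish(config, "simulate", paths)
    return paths


def _load_simulated(config: PipelineConfig):
    out = _stage_dir(config, "simulate")
    volume = LabelVolume.from_nifti(str(out / "labels.nii.gz"))
    ontology = Ontology.from_csv(str(out / "ontology.csv"))
    detected = pd.read_csv(out / "cells_detected.csv")
    truth = pd.read_csv(out / "cells_truth.csv")
    lookup_table = pd.read_csv(out / "flatmap_lookup.csv")
    lookup = flatmap_mod.FlatmapLookup(
        table=lookup_table,
        n_ap=int(lookup_table["ap_bin"].max()) + 1,
        n_az=int(lookup_table["az_bin"].max()) + 1,
        voxel_volume_mm3=volume.voxel_volume_mm3,
    )
    with open(out / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    return volume, ontology, truth, detected, lookup, manifest


def stage_quantify(config: PipelineConfig, force: bool = False) -> dict[str, str]:
    _require(config, "simulate")
    out = _stage_dir(config, "quantify")
    if _done_marker(config, "quantify").exists() and not force:
        log.info("quantify: up to date")
        with open(_done_marker(config, "quantify")) as fh:
            return json.load(fh)["artifacts"]
    volume, ontology, _truth, detected, _lookup, _manifest = _load_simulated(config)
    stats = quantify.build_region_stats(
        detected, volume, ontology, config.conversion_factors()
    )
    artifacts = write_growthchart_tables(stats, ontology, out, ages=config.ages)
    stats_path = str(out / "region_stats.csv")
    stats.to_csv(stats_path, index=False)
    artifacts["region_stats"] = stats_path
    log.info("quantify: %d stat rows over %d samples",
             len(stats), stats["sample_id"].nunique())
    _finish(config, "quantify", artifacts)
    return artifacts


def stage_flatmap(config: PipelineConfig, force: bool = False) -> dict[str, str]:
    _require(config, "simulate")
    out = _stage_dir(config, "flatmap")
    if _done_marker(config, "flatmap").exists() and not force:
        log.info("flatmap: up to date")
        with open(_done_marker(config, "flatmap")) as fh:
            return json.load(fh)["artifacts"]
    volume, ontology, _truth, detected, lookup, manifest = _load_simulated(config)
    factors = config.conversion_factors()
    cortical_vol = lookup.bin_volumes().sum()
    ref_age = config.reference_age or config.ages[-1]
    artifacts: dict[str, str] = {}
    for cell_type, grp_ct in detected.groupby("cell_type"):
        for age in config.ages:
            grp = grp_ct[grp_ct["age"] == age]
            if grp.empty:
                continue
            images = [
                flatmap_mod.project_to_flatmap(g, lookup, volume, factors)
                for _, g in grp.groupby("sample_id")
            ]
            avg = flatmap_mod.average_flatmaps(images)
            # toy study has one fixed geometry, so the age/reference cortical
            # volumes coincide; the factor is recorded in the sidecar anyway
            norm = flatmap_mod.normalize_flatmap(avg, cortical_vol, cortical_vol)
            base = out / f"flatmap_{cell_type}_{age}"
            norm.meta.update(_stamp(config))
            norm.write(str(base) + ".csv", str(base) + ".json")
            artifacts[f"{cell_type}_{age}"] = str(base) + ".csv"
    log.info("flatmap: wrote %d averaged maps (reference age %s)", len(artifacts), ref_age)
    _finish(config, "flatmap", artifacts)
    return artifacts


def _cortical_density_matrix(
    stats: pd.DataFrame, ontology: Ontology, cell_type: str, cortical_parent: int
):
    """(samples x cortical leaf regions) density pivot for one cell type."""
    cortical = set(ontology.descendants(cortical_parent))
    rows = stats[
        (stats["cell_type"] == cell_type)
        & stats["region_id"].isin(cortical)
        & ~stats["invalid"]
    ]
    pivot = rows.pivot_table(
        index=["sample_id", "age"], columns="region_id",
        values="density_cells_per_mm3",
    ).sort_index()
    if pivot.isna().any().any():
        raise ValueError("missing region densities in pivot")
    return pivot


def stage_fda(config: PipelineConfig, force: bool = False) -> dict[str, str]:
    _require(config, "quantify")
    out = _stage_dir(config, "fda")
    if _done_marker(config, "fda").exists() and not force:
        log.info("fda: up to date")
        with open(_done_marker(config, "fda")) as fh:
            return json.load(fh)["artifacts"]
    volume, ontology, *_ = _load_simulated(config)
    stats = pd.read_csv(_stage_dir(config, "quantify") / "region_stats.csv")
    fda_cfg = config.fda_config()
    artifacts: dict[str, str] = {}
    for cell_type in sorted(stats["cell_type"].unique()):
        pivot = _cortical_density_matrix(stats, ontology, cell_type, synthetic.CORTEX_ID)
        region_ids = list(pivot.columns)
        cents = fda_mod.compute_region_centroids(volume, region_ids)
        result = fda_mod.topography_test(
            pivot.to_numpy(),
            [age for _sid, age in pivot.index],
            cents[["x_um", "y_um", "z_um"]].to_numpy(),
            fda_cfg,
            sample_ids=[sid for sid, _age in pivot.index],
        )
        payload = {**_stamp(config), **result.to_dict()}
        jpath = out / f"fda_{cell_type}.json"
        with open(jpath, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
        cpath = out / f"fda_pairwise_{cell_type}.csv"
        result.pairwise.to_csv(cpath, index=False)
        artifacts[cell_type] = str(jpath)
        log.info("fda[%s]: F = %.3f, permuted p = %.4f", cell_type,
                 result.f_statistic, result.p_value)
    _finish(config, "fda", artifacts)
    return artifacts


def stage_mlm(config: PipelineConfig, force: bool = False) -> dict[str, str]:
    _require(config, "quantify")
    out = _stage_dir(config, "mlm")
    if _done_marker(config, "mlm").exists() and not force:
        log.info("mlm: up to date")
        with open(_done_marker(config, "mlm")) as fh:
            return json.load(fh)["artifacts"]
    _volume, ontology, *_ = _load_simulated(config)
    stats = pd.read_csv(_stage_dir(config, "quantify") / "region_stats.csv")
    spec = config.mlm_spec()
    artifacts: dict[str, str] = {}
    cortical = set(ontology.descendants(synthetic.CORTEX_ID))
    for cell_type in sorted(stats["cell_type"].unique()):
        rows = stats[
            (stats["cell_type"] == cell_type)
            & stats["region_id"].isin(cortical)
            & ~stats["invalid"]
        ][["density_cells_per_mm3", "age", "region_id", "sample_id"]].rename(
            columns={"density_cells_per_mm3": "density"}
        )
        draws = mlm_mod.fit_multilevel(rows, spec, age_order=list(config.ages))
        glob = mlm_mod.global_age_test(draws)
        pairs = mlm_mod.pairwise_contrasts(draws)
        payload = {
            **_stamp(config),
            "global": glob,
            "rhat": draws.rhat,
            "converged": draws.converged,
            "pairwise": pairs.to_dict("records"),
        }
        jpath = out / f"mlm_{cell_type}.json"
        with open(jpath, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
        pairs.to_csv(out / f"mlm_pairwise_{cell_type}.csv", index=False)
        artifacts[cell_type] = str(jpath)
        log.info("mlm[%s]: trend Est. = %.2f, CI [%.2f, %.2f]%s", cell_type,
                 glob["estimate"], glob["ci_lower"], glob["ci_upper"],
                 "" if draws.converged else " (NOT converged)")
    _finish(config, "mlm", artifacts)
    return artifacts


def stage_report(config: PipelineConfig, force: bool = False) -> dict[str, str]:
    _require(config, "quantify")
    out = _stage_dir(config, "report")
    if _done_marker(config, "report").exists() and not force:
        log.info("report: up to date")
        with open(_done_marker(config, "report")) as fh:
            return json.load(fh)["artifacts"]
    stats = pd.read_csv(_stage_dir(config, "quantify") / "region_stats.csv")
    summary = summarize_trajectories(stats, ages=list(config.ages))
    artifacts: dict[str, str] = {}
    tpath = out / "trajectory_summary.csv"
    summary["per_region"].to_csv(tpath, index=False)
    artifacts["trajectories"] = str(tpath)
    cpath = out / "cross_type_correlations.json"
    with open(cpath, "w") as fh:
        json.dump({**_stamp(config), "correlations": summary["correlations"]},
                  fh, indent=2, sort_keys=True)
    artifacts["correlations"] = str(cpath)
    log.info("report: %d region trajectories, %d cross-type correlations",
             len(summary["per_region"]), len(summary["correlations"]))
    _finish(config, "report", artifacts)
    return artifacts


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "quantify": stage_quantify,
    "flatmap": stage_flatmap,
    "fda": stage_fda,
    "mlm": stage_mlm,
    "report": stage_report,
}


def run_pipeline(config: PipelineConfig, force: bool = False) -> dict:
    """Execute the enabled stages in dependency order; returns the manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO),
                        format="%(asctime)s %(levelname)s %(name)s: %(message)s")
    manifest = {**_stamp(config), "stages": {}}
    for stage in STAGES:
        if stage in config.stages:
            manifest["stages"][stage] = _STAGE_FUNCS[stage](config, force=force)
    mpath = pathlib.Path(config.outdir) / "manifest.json"
    mpath.parent.mkdir(parents=True, exist_ok=True)
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# report helpers


def write_growthchart_tables(
    stats: pd.DataFrame, ontology: Ontology, out_dir, ages=None
) -> dict[str, str]:
    """One growth-chart CSV per cell type (leaf + rolled-up rows) plus a
    per-age mean +/- s.d. companion table (s.d. across samples)."""
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    age_order = list(ages) if ages is not None else sorted(stats["age"].unique())
    for cell_type, grp in stats.groupby("cell_type"):
        if grp.empty:
            continue
        rolled = [grp]
        max_depth = max(ontology.depth(r) for r in ontology.ids())
        for level in range(max_depth):
            r = quantify.rollup_ontology(grp, ontology, level)
            if len(r):
                rolled.append(r)
        full = pd.concat(rolled, ignore_index=True)[
            quantify.REGION_STATS_COLUMNS + ["invalid"]
        ]
        path = out / f"growthchart_{cell_type}.csv"
        full.sort_values(["region_id", "sample_id"]).to_csv(path, index=False)
        artifacts[f"growthchart_{cell_type}"] = str(path)

        valid = full[~full["invalid"]]
        comp = (
            valid.groupby(["region_id", "age"])
            .agg(
                density_mean=("density_cells_per_mm3", "mean"),
                density_sd=("density_cells_per_mm3", lambda x: x.std(ddof=1)),
                volume_mm3=("volume_mm3", "mean"),
                n_samples=("sample_id", "nunique"),
            )
            .reset_index()
        )
        comp["age"] = pd.Categorical(comp["age"], categories=age_order, ordered=True)
        comp = comp.sort_values(["region_id", "age"])
        cpath = out / f"growthchart_{cell_type}_mean_sd.csv"
        comp.to_csv(cpath, index=False)
        artifacts[f"mean_sd_{cell_type}"] = str(cpath)
    if not artifacts:
        log.warning("no stats rows; writing header-only growth chart")
        path = out / "growthchart_empty.csv"
        pd.DataFrame(columns=quantify.REGION_STATS_COLUMNS).to_csv(path, index=False)
        artifacts["growthchart_empty"] = str(path)
    return artifacts


def summarize_trajectories(
    stats: pd.DataFrame, ages: list[str], type_pairs: list[tuple[str, str]] | None = None
) -> dict:
    """Per-region net change between first and last age, plus Pearson r / p
    of the cortex-mean density trajectories for cell-type pairs."""
    if len(ages) < 3:
        raise ValueError("need at least 3 ages to summarize trajectories")
    valid = stats[~stats["invalid"]] if "invalid" in stats.columns else stats
    mean_per_age = (
        valid.groupby(["cell_type", "region_id", "age"])["density_cells_per_mm3"]
        .mean()
        .reset_index()
    )
    first, last = ages[0], ages[-1]
    rows = []
    for (ct, rid), grp in mean_per_age.groupby(["cell_type", "region_id"]):
        by_age = dict(zip(grp["age"], grp["density_cells_per_mm3"]))
        if first not in by_age or last not in by_age:
            continue
        d0, d1 = by_age[first], by_age[last]
        direction = "increase" if d1 > d0 * 1.05 else ("decrease" if d1 < d0 * 0.95 else "stable")
        rows.append(
            {"cell_type": ct, "region_id": rid, f"density_{first}": d0,
             f"density_{last}": d1, "net_change": d1 - d0, "direction": direction}
        )
    per_region = pd.DataFrame(rows)

    cell_types = sorted(valid["cell_type"].unique())
    if type_pairs is None:
        type_pairs = [
            (a, b) for i, a in enumerate(cell_types) for b in cell_types[i + 1:]
        ]
    mean_traj = {}
    for ct in cell_types:
        sub = mean_per_age[mean_per_age["cell_type"] == ct]
        mean_traj[ct] = np.array(
            [sub.loc[sub["age"] == age, "density_cells_per_mm3"].mean() for age in ages]
        )
    correlations = []
    for a, b in type_pairs:
        r, p = quantify.trajectory_correlation(mean_traj[a], mean_traj[b])
        correlations.append({"cell_type_a": a, "cell_type_b": b, "pearson_r": r, "p_value": p})
    return {"per_region": per_region, "correlations": correlations}
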