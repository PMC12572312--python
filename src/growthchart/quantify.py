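"""Region-wise quantification: counts, volumes, densities, roll-ups, F-scores.

Turns a label volume plus per-sample centroid tables into growth-chart rows:
per (region, sample, cell type) the 2D centroid count, the 3D count obtained
with compartment-specific conversion factors (1.4 cytoplasmic, 1.5 nuclear),
the region volume from voxel counting, and the density in cells/mm^3.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import LabelVolume, Ontology

__all__ = [
    "ConversionFactors",
    "DetectionEvaluation",
    "compute_region_volumes",
    "assign_cells_to_regions",
    "convert_counts",
    "compute_densities",
    "build_region_stats",
    "rollup_ontology",
    "evaluate_detection",
    "trajectory_correlation",
]

log = logging.getLogger(__name__)

REGION_STATS_COLUMNS = [
    "region_id", "sample_id", "age", "cell_type",
    "count_2d", "count_3d", "volume_mm3", "density_cells_per_mm3",
]


@dataclass(frozen=True)
class ConversionFactors:
    """2D -> 3D multiplicative count conversion per signal compartment."""

    cytoplasmic: float = 1.4
    nuclear: float = 1.5

    def __post_init__(self) -> None:
        if self.cytoplasmic <= 0 or self.nuclear <= 0:
            raise ValueError("conversion factors must be > 0")

    def get(self, compartment: str) -> float:
        if compartment == "cytoplasmic":
            return self.cytoplasmic
        if compartment == "nuclear":
            return self.nuclear
        raise ValueError(
            f"unknown compartment {compartment!r}; expected 'cytoplasmic' or 'nuclear'"
        )


@dataclass(frozen=True)
class DetectionEvaluation:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f_score: float


def compute_region_volumes(volume: LabelVolume, ontology: Ontology) -> pd.Series:
    """Volume in mm^3 per ontology node (leaves and parent roll-ups).

    A leaf's volume is its voxel count times the voxel volume; a parent's
    volume is the sum over its descendants plus any voxels carrying the
    parent id itself.
    """
    ontology.validate_labels(volume)
    vox = volume.voxel_counts()
    vols = {}
    for rid in ontology.ids():
        own = int(vox.get(rid, 0))
        desc = sum(int(vox.get(d, 0)) for d in ontology.descendants(rid))
        vols[rid] = (own + desc) * volume.voxel_volume_mm3
    return pd.Series(vols, name="volume_mm3").rename_axis("region_id")


def assign_cells_to_regions(
    cells: pd.DataFrame, volume: LabelVolume
) -> tuple[pd.DataFrame, int]:
    """Map each centroid to its voxel label; returns (table, out-of-grid tally).

    Voxels are half-open boxes ``[k*s, (k+1)*s)`` so the voxel index is the
    floor of (coordinate - origin) / size; cells outside the grid (including
    exactly on the upper boundary) get background id 0 and are tallied.
    """
    cells = cells.copy()
    if len(cells) == 0:
        cells["region_id"] = pd.Series(dtype=np.int64)
        return cells, 0
    xyz = cells[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    if not np.isfinite(xyz).all():
        raise ValueError("cell coordinates must be finite")
    idx = np.floor((xyz - np.asarray(volume.origin_um)) / np.asarray(volume.voxel_size_um)).astype(np.int64)
    in_grid = np.all((idx >= 0) & (idx < np.asarray(volume.shape)), axis=1)
    labels = np.zeros(len(cells), dtype=np.int64)
    labels[in_grid] = volume.grid[idx[in_grid, 0], idx[in_grid, 1], idx[in_grid, 2]]
    cells["region_id"] = labels
    n_out = int((~in_grid).sum())
    if n_out:
        log.warning("%d cells fall outside the label grid (assigned background)", n_out)
    return cells, n_out


def convert_counts(
    count_2d: float, compartment: str, factors: ConversionFactors | None = None
) -> float:
    """2D centroid count -> 3D count estimate (kept fractional)."""
    if count_2d < 0:
        raise ValueError("count_2d must be >= 0")
    factors = factors or ConversionFactors()
    return float(count_2d) * factors.get(compartment)


def compute_densities(stats: pd.DataFrame) -> pd.DataFrame:
    """Add ``density_cells_per_mm3`` (count_3d / volume) and an invalid flag.

    Zero volume with zero count gives density 0; zero volume with a positive
    count is flagged invalid (and excluded by downstream consumers).
    """
    if (stats["count_3d"] < 0).any() or (stats["volume_mm3"] < 0).any():
        raise ValueError("counts and volumes must be >= 0")
    out = stats.copy()
    vol = out["volume_mm3"].to_numpy(dtype=float)
    cnt = out["count_3d"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        dens = np.where(vol > 0, cnt / np.where(vol > 0, vol, 1.0), 0.0)
    out["density_cells_per_mm3"] = dens
    out["invalid"] = (vol == 0) & (cnt > 0)
    if out["invalid"].any():
        log.warning("%d rows have cells in zero-volume regions", int(out["invalid"].sum()))
    return out


def build_region_stats(
    cells: pd.DataFrame,
    volume: LabelVolume,
    ontology: Ontology,
    factors: ConversionFactors | None = None,
) -> pd.DataFrame:
    """Leaf-level growth-chart rows for every (sample, region) combination.

    ``cells`` are detected (or truth) centroids of possibly several samples
    and cell types.  Background (region 0) rows are retained and flagged
    invalid; every labeled region present in the volume appears for every
    sample, with zero counts where no cell landed.
    """
    factors = factors or ConversionFactors()
    assigned, _ = assign_cells_to_regions(cells, volume)
    vols = compute_region_volumes(volume, ontology)
    leaf_ids = [rid for rid in ontology.ids() if rid in set(volume.region_ids().tolist())]

    samples = (
        assigned[["sample_id", "age", "cell_type", "compartment"]].drop_duplicates()
        if len(assigned)
        else pd.DataFrame(columns=["sample_id", "age", "cell_type", "compartment"])
    )
    counts = (
        assigned.groupby(["sample_id", "cell_type", "region_id"], sort=True)
        .size()
        .rename("count_2d")
        .reset_index()
    )
    rows = []
    for s in samples.itertuples():
        base = counts.query("sample_id == @s.sample_id and cell_type == @s.cell_type")
        by_region = dict(zip(base["region_id"], base["count_2d"]))
        factor = factors.get(s.compartment)
        for rid in leaf_ids + [0]:
            c2d = int(by_region.get(rid, 0))
            rows.append(
                {
                    "region_id": rid, "sample_id": s.sample_id, "age": s.age,
                    "cell_type": s.cell_type,
                    "count_2d": c2d, "count_3d": c2d * factor,
                    "volume_mm3": float(vols.get(rid, 0.0)) if rid else 0.0,
                }
            )
    stats = pd.DataFrame(rows, columns=[c for c in REGION_STATS_COLUMNS if c != "density_cells_per_mm3"])
    stats = compute_densities(stats)
    stats.loc[stats["region_id"] == 0, "invalid"] = True  # background rows excluded from densities
    return stats


def rollup_ontology(
    stats: pd.DataFrame, ontology: Ontology, level: int | str = "leaf"
) -> pd.DataFrame:
    """Aggregate leaf rows to ancestors at the given ontology depth.

    Counts and volumes sum over descendants; density is recomputed from the
    summed counts and volumes (never averaged).  ``level='leaf'`` is the
    identity; an integer keeps nodes at that depth (root = 0).
    """
    if level == "leaf":
        return stats.copy()
    targets = [rid for rid in ontology.ids() if ontology.depth(rid) == int(level)]
    invalid = stats["invalid"] if "invalid" in stats.columns else pd.Series(False, index=stats.index)
    leaf_rows = stats[(~invalid) & (stats["region_id"] != 0)]
    rows = []
    for tid in targets:
        members = set(ontology.descendants(tid)) | {tid}
        grp = leaf_rows[leaf_rows["region_id"].isin(members)]
        if grp.empty:
            continue
        agg = (
            grp.groupby(["sample_id", "age", "cell_type"], sort=True)
            .agg(count_2d=("count_2d", "sum"), count_3d=("count_3d", "sum"),
                 volume_mm3=("volume_mm3", "sum"))
            .reset_index()
        )
        agg.insert(0, "region_id", tid)
        rows.append(agg)
    if not rows:
        return pd.DataFrame(columns=REGION_STATS_COLUMNS)
    return compute_densities(pd.concat(rows, ignore_index=True))


def evaluate_detection(tp: int, fp: int, fn: int) -> DetectionEvaluation:
    """Precision, recall and F-score (harmonic mean) from match counts.

    The degenerate all-zero case is defined as F = 0 with a warning (the
    harmonic-mean formula is 0/0 there).
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("TP, FP, FN must be >= 0")
    if tp == 0 and fp == 0 and fn == 0:
        warnings.warn("F-score undefined for TP=FP=FN=0; reporting 0 by convention")
        return DetectionEvaluation(0, 0, 0, 0.0, 0.0, 0.0)
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    return DetectionEvaluation(tp, fp, fn, precision, recall, f)


def trajectory_correlation(
    series_a: np.ndarray, series_b: np.ndarray
) -> tuple[float, float]:
    """Pearson r and two-tailed p (t transform, n-2 df) between trajectories."""
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("series must be equal-length 1D with at least 3 points")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("series must have nonzero variance")
    res = stats.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)
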