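"""Synthetic miniature study generator with known ground truth.

Emulates, at desk scale, a developmental cell-type mapping study: a
parcellated cortex-like slab plus subcortical blobs in a 20 um labeled
volume, per-region density trajectories following three developmental
archetypes (continual increase, initial decline followed by stabilization,
relative stability), homogeneous-Poisson cell placement with between-sample
lognormal noise, simulated 2D detections with compartment-specific
conversion factors, and a column-projection cortical flatmap lookup.

Every output is deterministic given the study seed; the manifest records the
per-sample child seeds and the ground-truth density table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .atlas import LabelVolume, Ontology
from .flatmap import FlatmapLookup
from .quantify import ConversionFactors, assign_cells_to_regions

__all__ = [
    "RegionDef",
    "AtlasSpec",
    "TrajectorySpec",
    "DetectionSimSpec",
    "DetectionResult",
    "StudyBundle",
    "default_atlas_spec",
    "default_trajectories",
    "default_compartments",
    "generate_label_volume",
    "build_ontology",
    "make_density_table",
    "sample_cells",
    "sample_region_densities",
    "simulate_detection",
    "make_flatmap_lookup",
    "generate_study",
    "write_study",
]

CELL_COLUMNS = ["sample_id", "age", "x_um", "y_um", "z_um", "cell_type", "compartment", "truth_flag"]

PATTERNS = ("increase", "decline_then_stable", "stable")


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class RegionDef:
    """Axis-aligned voxel box [lo, hi) assigned to one leaf region."""

    region_id: int
    parent_id: int
    lo: tuple[int, int, int]
    hi: tuple[int, int, int]
    acronym: str = ""

    def n_voxels(self) -> int:
        return int(np.prod([h - l for l, h in zip(self.lo, self.hi)]))


@dataclass(frozen=True)
class AtlasSpec:
    grid_shape: tuple[int, int, int]
    voxel_size_um: tuple[float, float, float]
    regions: tuple[RegionDef, ...]
    cortical_ids: tuple[int, ...]
    ages: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(int(n) < 1 for n in self.grid_shape):
            raise ValueError(f"grid_shape must be 3 positive ints, got {self.grid_shape}")
        if any(s <= 0 for s in self.voxel_size_um):
            raise ValueError("voxel sizes must be positive")
        ids = [r.region_id for r in self.regions]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate region ids in layout")
        if any(i <= 0 for i in ids):
            raise ValueError("region ids must be > 0 (0 is background)")
        unknown = set(self.cortical_ids) - set(ids)
        if unknown:
            raise ValueError(f"cortical_ids not in region layout: {sorted(unknown)}")
        nums = [age_number(a) for a in self.ages]
        if any(b <= a for a, b in zip(nums, nums[1:])):
            raise ValueError(f"ages must be strictly ordered, got {self.ages}")


@dataclass(frozen=True)
class TrajectorySpec:
    """Density trajectory archetype for one (region, cell type)."""

    region_id: int
    cell_type: str
    pattern: str
    baseline_density: float  # cells/mm^3 at the first age
    effect_magnitude: float = 1.0  # multiplicative change by the last age
    stabilization_age: str | None = None  # plateau onset for decline patterns
    sample_cv: float = 0.1

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}; expected one of {PATTERNS}")
        if self.baseline_density < 0:
            raise ValueError("baseline_density must be >= 0")
        if self.effect_magnitude <= 0:
            raise ValueError("effect_magnitude must be > 0")
        if self.sample_cv < 0:
            raise ValueError("sample_cv must be >= 0")
        if self.pattern == "increase" and self.effect_magnitude < 1:
            raise ValueError("increase pattern requires effect_magnitude >= 1")
        if self.pattern == "decline_then_stable" and self.effect_magnitude > 1:
            raise ValueError("decline_then_stable pattern requires effect_magnitude <= 1")


@dataclass(frozen=True)
class DetectionSimSpec:
    """Detection-error model for F-score evaluation.

    ``ideal`` mode reproduces section-based 2D counting exactly: per region
    the detected 2D count is the true count divided by the compartment's
    conversion factor, rounded half-up, with no false positives.
    ``stochastic`` mode thins cells with probability
    ``detection_probability / factor`` and adds uniform false positives at
    ``false_positive_rate`` per mm^3 of labeled tissue.
    """

    mode: str = "stochastic"
    section_spacing_um: float = 50.0
    detection_probability: float = 0.95
    false_positive_rate: float = 50.0  # spurious detections per mm^3
    match_radius_um: float = 15.0

    def __post_init__(self) -> None:
        if self.mode not in ("ideal", "stochastic"):
            raise ValueError(f"mode must be 'ideal' or 'stochastic', got {self.mode!r}")
        if not 0.0 <= self.detection_probability <= 1.0:
            raise ValueError("detection_probability must be in [0, 1]")
        if self.false_positive_rate < 0 or self.match_radius_um < 0:
            raise ValueError("rates and radii must be >= 0")
        if self.section_spacing_um <= 0:
            raise ValueError("section spacing must be > 0")


def age_number(age: str) -> int:
    """Numeric postnatal day from an age label like 'P12'."""
    if not age.startswith("P"):
        raise ValueError(f"age labels look like 'P4'..'P14', got {age!r}")
    return int(age[1:])


# ---------------------------------------------------------------------------
# default miniature study (the study conditions)

#: ages of the emulated atlas, postnatal days 4-14 in 2-day steps
DEFAULT_AGES = ("P4", "P6", "P8", "P10", "P12", "P14")

ROOT_ID, CORTEX_ID, SUBCORTEX_ID = 1, 2, 3


def default_atlas_spec() -> AtlasSpec:
    """64 x 64 x 32 voxel miniature atlas at 20 um isotropic.

    The cortex is a 6 x 6 parcellation of 10-voxel-square columns (36 leaf
    regions, close to the 37 cortical regions of a real mouse isocortical
    parcellation).  Column depth follows a shallow dome plus a small
    deterministic stagger so region centroids are not coplanar, which keeps
    the 3x3x3 tensor-spline design full column rank.  Four subcortical
    blocks sit beneath the slab.
    """
    regions: list[RegionDef] = []
    for a in range(6):
        for b in range(6):
            d2 = (a - 2.5) ** 2 + (b - 2.5) ** 2
            dome = round(6.0 * d2 / 12.5)
            stagger = (3 * a + 5 * b) % 2
            k_lo = 14 + dome + stagger
            rid = 100 + 6 * a + b
            regions.append(
                RegionDef(
                    region_id=rid,
                    parent_id=CORTEX_ID,
                    lo=(2 + 10 * a, 2 + 10 * b, k_lo),
                    hi=(12 + 10 * a, 12 + 10 * b, k_lo + 10),
                    acronym=f"CTX-{a}{b}",
                )
            )
    for n, (a, b) in enumerate([(0, 0), (0, 1), (1, 0), (1, 1)]):
        regions.append(
            RegionDef(
                region_id=200 + n,
                parent_id=SUBCORTEX_ID,
                lo=(8 + 32 * a, 8 + 32 * b, 2),
                hi=(24 + 32 * a, 24 + 32 * b, 10),
                acronym=f"SUB-{n}",
            )
        )
    return AtlasSpec(
        grid_shape=(64, 64, 32),
        voxel_size_um=(20.0, 20.0, 20.0),
        regions=tuple(regions),
        cortical_ids=tuple(r.region_id for r in regions if r.parent_id == CORTEX_ID),
        ages=DEFAULT_AGES,
    )


def default_compartments() -> dict[str, str]:
    """Signal compartment per cell type (sets the 2D->3D conversion factor)."""
    return {"gabaergic": "cytoplasmic", "microglia": "nuclear"}


def default_trajectories(spec: AtlasSpec | None = None) -> list[TrajectorySpec]:
    """Ground-truth trajectories of the default study.

    Cortical GABAergic density starts high with a mild spatial gradient
    (sensory-like enrichment toward one corner), declines roughly two-fold
    and stabilizes at P12; subcortical (striatum-like) GABAergic density
    doubles.  Microglial density triples in cortex (continual increase) and
    stays stable subcortically.  Magnitudes are in the 10^3-10^4 cells/mm^3
    range typical of interneuron and microglia densities.
    """
    spec = spec or default_atlas_spec()
    trajs: list[TrajectorySpec] = []
    cortical = [r for r in spec.regions if r.region_id in spec.cortical_ids]
    for r in cortical:
        a, b = (r.region_id - 100) // 6, (r.region_id - 100) % 6
        grad = 1.0 + 0.3 * ((a + b) / 10.0 - 0.5)  # +/-15% regional enrichment
        trajs.append(
            TrajectorySpec(r.region_id, "gabaergic", "decline_then_stable",
                           baseline_density=12000.0 * grad, effect_magnitude=0.5,
                           stabilization_age="P12")
        )
        trajs.append(
            TrajectorySpec(r.region_id, "microglia", "increase",
                           baseline_density=3000.0 / grad, effect_magnitude=3.0)
        )
    for r in spec.regions:
        if r.region_id in spec.cortical_ids:
            continue
        trajs.append(
            TrajectorySpec(r.region_id, "gabaergic", "increase",
                           baseline_density=6000.0, effect_magnitude=2.0)
        )
        trajs.append(
            TrajectorySpec(r.region_id, "microglia", "stable", baseline_density=4000.0)
        )
    return trajs


# ---------------------------------------------------------------------------
# label volume + ontology


def generate_label_volume(spec: AtlasSpec) -> LabelVolume:
    """Paint each region's voxel box; error on overlap or out-of-bounds."""
    grid = np.zeros(spec.grid_shape, dtype=np.int32)
    shape = np.asarray(spec.grid_shape)
    for r in spec.regions:
        lo, hi = np.asarray(r.lo), np.asarray(r.hi)
        if (lo < 0).any() or (hi > shape).any() or (hi <= lo).any():
            raise ValueError(
                f"region {r.region_id} extent {r.lo}..{r.hi} outside grid {spec.grid_shape}"
            )
        block = grid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        if (block != 0).any():
            colliding = sorted(set(block[block != 0].tolist()))
            raise ValueError(
                f"region extents overlap: {r.region_id} collides with {colliding}"
            )
        block[...] = r.region_id
    return LabelVolume(grid=grid, voxel_size_um=spec.voxel_size_um)


def build_ontology(spec: AtlasSpec) -> Ontology:
    """Three-level hierarchy: root -> {cortex, subcortex} -> leaf regions."""
    rows = [
        {"id": ROOT_ID, "acronym": "BRAIN", "name": "whole brain", "parent_id": None},
        {"id": CORTEX_ID, "acronym": "CTX", "name": "cortical plate", "parent_id": ROOT_ID},
        {"id": SUBCORTEX_ID, "acronym": "SUB", "name": "subcortical", "parent_id": ROOT_ID},
    ]
    used_parents = {r.parent_id for r in spec.regions}
    rows = [row for row in rows if row["id"] in used_parents | {ROOT_ID}]
    for r in spec.regions:
        rows.append(
            {
                "id": r.region_id,
                "acronym": r.acronym or f"R{r.region_id}",
                "name": r.acronym or f"region {r.region_id}",
                "parent_id": r.parent_id,
            }
        )
    return Ontology(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# density trajectories


def _trajectory_values(traj: TrajectorySpec, ages: tuple[str, ...]) -> np.ndarray:
    n = len(ages)
    base, final = traj.baseline_density, traj.baseline_density * traj.effect_magnitude
    if traj.pattern == "stable":
        return np.full(n, base)
    if traj.pattern == "increase":
        t = np.arange(n) / max(n - 1, 1)
        return base + (final - base) * t
    # decline_then_stable: linear decline to the plateau value, constant after
    stab = traj.stabilization_age or ages[-1]
    if stab not in ages:
        raise ValueError(f"stabilization_age {stab!r} not in study ages {ages}")
    s = ages.index(stab)
    vals = np.full(n, final)
    if s > 0:
        t = np.arange(s + 1) / s
        vals[: s + 1] = base + (final - base) * t
    return vals


def make_density_table(trajectories: list[TrajectorySpec], ages: tuple[str, ...]) -> pd.DataFrame:
    """Expected density per (region_id, cell_type, age): the ground truth."""
    records = []
    for traj in trajectories:
        vals = _trajectory_values(traj, tuple(ages))
        for age, d in zip(ages, vals):
            records.append(
                {"region_id": traj.region_id, "cell_type": traj.cell_type,
                 "age": age, "density": float(d)}
            )
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# cell sampling


def _lognormal_factor(cv: float, rng: np.random.Generator) -> float:
    """Unit-mean multiplicative lognormal factor with the given CV."""
    if cv == 0:
        return 1.0
    s2 = math.log(1.0 + cv * cv)
    return float(rng.lognormal(mean=-0.5 * s2, sigma=math.sqrt(s2)))


def _region_voxel_index(volume: LabelVolume) -> dict[int, np.ndarray]:
    """region_id -> (n, 3) array of voxel indices, in C scan order."""
    flat = volume.grid.ravel()
    order = np.argsort(flat, kind="stable")
    sorted_vals = flat[order]
    out: dict[int, np.ndarray] = {}
    ids = np.unique(sorted_vals[sorted_vals > 0])
    for rid in ids:
        lo = np.searchsorted(sorted_vals, rid, side="left")
        hi = np.searchsorted(sorted_vals, rid, side="right")
        out[int(rid)] = np.stack(np.unravel_index(order[lo:hi], volume.shape), axis=1)
    return out


def sample_cells(
    volume: LabelVolume,
    densities: pd.DataFrame,
    sample_id: str,
    age: str,
    seed: int,
    compartments: dict[str, str] | None = None,
    sample_cv: float = 0.1,
) -> pd.DataFrame:
    """Draw a homogeneous-Poisson cell cloud for one biological sample.

    Per region and cell type the count is Poisson(density x region volume x
    sample factor), where the sample factor is a unit-mean lognormal with
    coefficient of variation ``sample_cv`` shared across regions of the
    sample.  Positions are uniform within the region: a voxel is chosen
    uniformly among the region's voxels, then the position uniformly within
    the voxel.
    """
    if (densities["density"] < 0).any():
        bad = densities.loc[densities["density"] < 0]
        raise ValueError(f"negative densities for regions {bad['region_id'].tolist()}")
    compartments = compartments or default_compartments()
    rng = np.random.default_rng(seed)
    factor = _lognormal_factor(sample_cv, rng)
    vox_index = _region_voxel_index(volume)
    vox_vol = volume.voxel_volume_mm3
    size = np.asarray(volume.voxel_size_um)
    origin = np.asarray(volume.origin_um)

    frames: list[pd.DataFrame] = []
    for row in densities.itertuples():
        rid = int(row.region_id)
        if rid not in vox_index:
            raise ValueError(f"region {rid} has no voxels in the label volume")
        voxels = vox_index[rid]
        lam = row.density * len(voxels) * vox_vol * factor
        n = int(rng.poisson(lam))
        if n == 0:
            continue
        picks = voxels[rng.integers(0, len(voxels), size=n)]
        pos = (picks + rng.random((n, 3))) * size + origin
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": sample_id,
                    "age": age,
                    "x_um": pos[:, 0],
                    "y_um": pos[:, 1],
                    "z_um": pos[:, 2],
                    "cell_type": row.cell_type,
                    "compartment": compartments[row.cell_type],
                    "truth_flag": True,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=CELL_COLUMNS)
    return pd.concat(frames, ignore_index=True)[CELL_COLUMNS]


def sample_region_densities(
    region_volumes_mm3: np.ndarray,
    true_densities: np.ndarray,
    sample_cv: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Observed per-region density for one sample, without cell placement.

    Same count model as :func:`sample_cells` (shared lognormal sample factor,
    Poisson counts), returned directly as counts / volume.  Used for
    replicated statistical experiments where individual positions are not
    needed.
    """
    factor = _lognormal_factor(sample_cv, rng)
    lam = np.asarray(true_densities) * np.asarray(region_volumes_mm3) * factor
    counts = rng.poisson(lam)
    return counts / np.asarray(region_volumes_mm3)


# ---------------------------------------------------------------------------
# detection simulation


@dataclass
class DetectionResult:
    """Detections plus truth-match annotations for one sample."""

    detected: pd.DataFrame  # CELL_COLUMNS + status ('TP'/'FP'), truth_index
    n_truth: int

    @property
    def tp(self) -> int:
        return int((self.detected["status"] == "TP").sum())

    @property
    def fp(self) -> int:
        return int((self.detected["status"] == "FP").sum())

    @property
    def fn(self) -> int:
        return self.n_truth - self.tp


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _greedy_match(
    detected_xyz: np.ndarray, truth_xyz: np.ndarray, radius: float
) -> np.ndarray:
    """Greedy nearest-neighbour matching; each truth cell used at most once.

    Returns the matched truth index per detection (-1 = unmatched).
    Detections are processed in order of their nearest-truth distance so
    exact hits claim their truth cell first.
    """
    match = np.full(len(detected_xyz), -1, dtype=np.int64)
    if len(truth_xyz) == 0 or len(detected_xyz) == 0:
        return match
    tree = cKDTree(truth_xyz)
    k = min(len(truth_xyz), 8)
    dists, idxs = tree.query(detected_xyz, k=k)
    dists = np.atleast_2d(dists.reshape(len(detected_xyz), -1))
    idxs = np.atleast_2d(idxs.reshape(len(detected_xyz), -1))
    taken = np.zeros(len(truth_xyz), dtype=bool)
    for det in np.argsort(dists[:, 0], kind="stable"):
        for j in range(dists.shape[1]):
            d, t = dists[det, j], idxs[det, j]
            if d > radius:
                break
            if not taken[t]:
                taken[t] = True
                match[det] = t
                break
    return match


def simulate_detection(
    cells: pd.DataFrame,
    volume: LabelVolume,
    spec: DetectionSimSpec,
    seed: int,
    factors: ConversionFactors | None = None,
) -> DetectionResult:
    """Emulate section-based 2D detection of a truth cell cloud.

    See :class:`DetectionSimSpec` for the two modes.  Every detection is
    annotated TP or FP by greedy nearest-neighbour matching against the
    truth within ``match_radius_um``.
    """
    factors = factors or ConversionFactors()
    rng = np.random.default_rng(seed)
    cells = cells.reset_index(drop=True)

    if spec.mode == "ideal":
        cells_assigned, _ = assign_cells_to_regions(cells, volume)
        keep_idx: list[np.ndarray] = []
        for (_rid, comp), grp in cells_assigned.groupby(["region_id", "compartment"], sort=True):
            n2d = _round_half_up(len(grp) / factors.get(comp))
            keep_idx.append(grp.index.to_numpy()[: min(n2d, len(grp))])
        keep = np.sort(np.concatenate(keep_idx)) if keep_idx else np.array([], dtype=int)
        detected = cells.loc[keep].copy()
        detected["status"] = "TP"
        detected["truth_index"] = keep
        return DetectionResult(detected.reset_index(drop=True), n_truth=len(cells))

    # stochastic: binomial thinning + uniform false positives over labeled tissue
    thin_p = {
        comp: min(1.0, spec.detection_probability / factors.get(comp))
        for comp in cells["compartment"].unique()
    } if len(cells) else {}
    keep_mask = np.zeros(len(cells), dtype=bool)
    for comp, p in thin_p.items():
        m = (cells["compartment"] == comp).to_numpy()
        keep_mask[m] = rng.random(m.sum()) < p
    detected = cells.loc[keep_mask].copy()

    labeled = np.argwhere(volume.grid > 0)
    labeled_vol = len(labeled) * volume.voxel_volume_mm3
    n_fp = int(rng.poisson(spec.false_positive_rate * labeled_vol))
    if n_fp > 0:
        picks = labeled[rng.integers(0, len(labeled), size=n_fp)]
        pos = (picks + rng.random((n_fp, 3))) * np.asarray(volume.voxel_size_um) + np.asarray(
            volume.origin_um
        )
        ct = cells["cell_type"].iloc[0] if len(cells) else "unknown"
        comp = cells["compartment"].iloc[0] if len(cells) else "cytoplasmic"
        sid = cells["sample_id"].iloc[0] if len(cells) else ""
        age = cells["age"].iloc[0] if len(cells) else ""
        fp_df = pd.DataFrame(
            {
                "sample_id": sid, "age": age,
                "x_um": pos[:, 0], "y_um": pos[:, 1], "z_um": pos[:, 2],
                "cell_type": ct, "compartment": comp, "truth_flag": False,
            }
        )
        detected = pd.concat([detected, fp_df], ignore_index=True)
    detected = detected.reset_index(drop=True)

    truth_xyz = cells[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    det_xyz = detected[["x_um", "y_um", "z_um"]].to_numpy(dtype=float) if len(detected) else np.empty((0, 3))
    match = _greedy_match(det_xyz, truth_xyz, spec.match_radius_um)
    detected["truth_index"] = match
    detected["status"] = np.where(match >= 0, "TP", "FP")
    return DetectionResult(detected, n_truth=len(cells))


# ---------------------------------------------------------------------------
# flatmap lookup


def make_flatmap_lookup(volume: LabelVolume, cortical_ids: tuple[int, ...]) -> FlatmapLookup:
    """Column projection of the cortical slab onto an (AP, azimuth) grid.

    Each cortical voxel (i, j, k) maps to bin (i - i_min, j - j_min): voxels
    sharing an (i, j) column share a bin.  The per-bin volume is the mapped
    voxel count times the voxel volume.
    """
    if not cortical_ids:
        raise ValueError("cortical id set is empty")
    mask = np.isin(volume.grid, list(cortical_ids))
    voxels = np.argwhere(mask)
    if len(voxels) == 0:
        raise ValueError(f"no voxels carry cortical ids {sorted(cortical_ids)}")
    i_min, j_min = voxels[:, 0].min(), voxels[:, 1].min()
    n_ap = int(voxels[:, 0].max() - i_min + 1)
    n_az = int(voxels[:, 1].max() - j_min + 1)
    table = pd.DataFrame(
        {
            "i": voxels[:, 0], "j": voxels[:, 1], "k": voxels[:, 2],
            "ap_bin": voxels[:, 0] - i_min, "az_bin": voxels[:, 1] - j_min,
        }
    )
    return FlatmapLookup(table=table, n_ap=n_ap, n_az=n_az,
                         voxel_volume_mm3=volume.voxel_volume_mm3)


# ---------------------------------------------------------------------------
# whole-study bundle


@dataclass
class StudyBundle:
    spec: AtlasSpec
    volume: LabelVolume
    ontology: Ontology
    density_table: pd.DataFrame
    truth_cells: pd.DataFrame          # all samples concatenated
    detected_cells: pd.DataFrame       # all samples concatenated, with status
    detections: dict[str, DetectionResult]
    lookup: FlatmapLookup
    manifest: dict

    def sample_ids(self) -> list[str]:
        return [s["sample_id"] for s in self.manifest["samples"]]


def generate_study(
    atlas: AtlasSpec | None = None,
    trajectories: list[TrajectorySpec] | None = None,
    detection: DetectionSimSpec | None = None,
    n_per_age: dict[str, int] | int = 4,
    seed: int = 0,
    compartments: dict[str, str] | None = None,
) -> StudyBundle:
    """Generate the full miniature study deterministically from one seed.

    Samples emulate per-animal datasets: each (cell type, age, replicate)
    triple is one biological sample with its own child seed
    ``seed + sample_index`` (recorded in the manifest).
    """
    atlas = atlas or default_atlas_spec()
    trajectories = trajectories if trajectories is not None else default_trajectories(atlas)
    detection = detection or DetectionSimSpec()
    compartments = compartments or default_compartments()

    volume = generate_label_volume(atlas)
    ontology = build_ontology(atlas)
    density = make_density_table(trajectories, atlas.ages)
    lookup = make_flatmap_lookup(volume, atlas.cortical_ids)
    cell_types = sorted(density["cell_type"].unique())
    if isinstance(n_per_age, int):
        n_per_age = {age: n_per_age for age in atlas.ages}
    if any(n < 1 for n in n_per_age.values()):
        raise ValueError("n_per_age must be >= 1 for every age")

    sample_cv = trajectories[0].sample_cv if trajectories else 0.1
    truth_frames, det_frames = [], []
    detections: dict[str, DetectionResult] = {}
    manifest_samples = []
    sample_index = 0
    for cell_type in cell_types:
        for age in atlas.ages:
            d_age = density.query("cell_type == @cell_type and age == @age")
            for rep in range(1, n_per_age.get(age, 0) + 1):
                sid = f"{cell_type}_{age}_s{rep}"
                child_seed = seed + sample_index
                cells = sample_cells(volume, d_age, sid, age, seed=child_seed,
                                     compartments=compartments, sample_cv=sample_cv)
                res = simulate_detection(cells, volume, detection, seed=child_seed + 1_000_000)
                truth_frames.append(cells)
                det_frames.append(res.detected)
                detections[sid] = res
                manifest_samples.append(
                    {"sample_id": sid, "cell_type": cell_type, "age": age,
                     "replicate": rep, "seed": int(child_seed)}
                )
                sample_index += 1

    manifest = {
        "study_seed": int(seed),
        "ages": list(atlas.ages),
        "cell_types": cell_types,
        "compartments": compartments,
        "detection": {
            "mode": detection.mode,
            "section_spacing_um": detection.section_spacing_um,
            "detection_probability": detection.detection_probability,
            "false_positive_rate": detection.false_positive_rate,
            "match_radius_um": detection.match_radius_um,
        },
        "sample_cv": sample_cv,
        "samples": manifest_samples,
        "densities": density.to_dict("records"),
    }
    truth = pd.concat(truth_frames, ignore_index=True) if truth_frames else pd.DataFrame(columns=CELL_COLUMNS)
    det = pd.concat(det_frames, ignore_index=True) if det_frames else pd.DataFrame(columns=CELL_COLUMNS + ["status", "truth_index"])
    return StudyBundle(atlas, volume, ontology, density, truth, det, detections, lookup, manifest)


def write_study(bundle: StudyBundle, outdir) -> dict[str, str]:
    """Write the study as text-first artifacts; returns path map."""
    import pathlib

    import yaml

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "volume": str(out / "labels.nii.gz"),
        "ontology": str(out / "ontology.csv"),
        "truth_cells": str(out / "cells_truth.csv"),
        "detected_cells": str(out / "cells_detected.csv"),
        "lookup": str(out / "flatmap_lookup.csv"),
        "densities": str(out / "true_densities.csv"),
        "manifest": str(out / "manifest.yaml"),
    }
    bundle.volume.to_nifti(paths["volume"])
    bundle.ontology.to_csv(paths["ontology"])
    bundle.truth_cells.to_csv(paths["truth_cells"], index=False)
    bundle.detected_cells.to_csv(paths["detected_cells"], index=False)
    bundle.lookup.table.to_csv(paths["lookup"], index=False)
    bundle.density_table.to_csv(paths["densities"], index=False)
    manifest = dict(bundle.manifest)
    manifest["densities"] = paths["densities"]
    with open(paths["manifest"], "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return paths
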