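"""Cortical flatmap projection, averaging, and age-volume normalization.

A flatmap lookup maps each cortical voxel to one (AP bin, azimuth bin); a
flatmap image holds per-bin densities in cells/mm^3 (the bin's denominator
is its true mapped tissue volume, keeping units consistent with the
region-wise growth chart).  Bins with no mapped tissue are masked, never
zero-filled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .quantify import ConversionFactors

__all__ = ["FlatmapLookup", "FlatmapImage", "project_to_flatmap", "average_flatmaps", "normalize_flatmap"]


@dataclass
class FlatmapLookup:
    """Voxel -> (ap_bin, az_bin) mapping over a rectangular bin grid."""

    table: pd.DataFrame  # columns i, j, k, ap_bin, az_bin
    n_ap: int
    n_az: int
    voxel_volume_mm3: float

    def __post_init__(self) -> None:
        required = {"i", "j", "k", "ap_bin", "az_bin"}
        if missing := required - set(self.table.columns):
            raise ValueError(f"lookup table missing columns {sorted(missing)}")
        if ((self.table["ap_bin"] < 0) | (self.table["ap_bin"] >= self.n_ap)).any():
            raise ValueError("ap_bin outside bin grid")
        if ((self.table["az_bin"] < 0) | (self.table["az_bin"] >= self.n_az)).any():
            raise ValueError("az_bin outside bin grid")

    def bin_volumes(self) -> np.ndarray:
        """(n_ap, n_az) mapped tissue volume per bin in mm^3."""
        counts = np.zeros((self.n_ap, self.n_az))
        np.add.at(counts, (self.table["ap_bin"].to_numpy(), self.table["az_bin"].to_numpy()), 1.0)
        return counts * self.voxel_volume_mm3

    def voxel_to_bin(self) -> dict[tuple[int, int, int], tuple[int, int]]:
        return {
            (int(r.i), int(r.j), int(r.k)): (int(r.ap_bin), int(r.az_bin))
            for r in self.table.itertuples()
        }

    def to_csv(self, path: str) -> None:
        self.table.to_csv(path, index=False)


@dataclass
class FlatmapImage:
    """Per-bin density grid with companion 2D-count grid and mask."""

    density: np.ndarray  # cells/mm^3, (n_ap, n_az)
    counts: np.ndarray  # summed 2D counts per bin
    mask: np.ndarray  # True where the bin has no mapped tissue
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.density.shape != self.counts.shape or self.density.shape != self.mask.shape:
            raise ValueError("density, counts and mask must share a shape")
        if np.nanmin(np.where(self.mask, 0.0, self.density)) < 0:
            raise ValueError("densities must be >= 0")

    def write(self, csv_path: str, sidecar_path: str | None = None) -> None:
        """CSV matrix (masked bins empty) plus a JSON sidecar."""
        dens = np.where(self.mask, np.nan, self.density)
        pd.DataFrame(dens).to_csv(csv_path, index=False, header=False)
        if sidecar_path:
            meta = {
                "shape": list(self.density.shape),
                "n_masked_bins": int(self.mask.sum()),
                **{k: v for k, v in self.meta.items()},
            }
            with open(sidecar_path, "w") as fh:
                json.dump(meta, fh, indent=2, sort_keys=True, default=str)

    def render_png(self, path: str, title: str = "") -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, 4))
        shown = np.where(self.mask, np.nan, self.density)
        im = ax.imshow(shown.T, origin="lower", cmap="viridis")
        ax.set_xlabel("AP bin")
        ax.set_ylabel("azimuth bin")
        if title:
            ax.set_title(title)
        fig.colorbar(im, ax=ax, label="cells/mm$^3$")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def project_to_flatmap(
    cells: pd.DataFrame,
    lookup: FlatmapLookup,
    volume,
    factors: ConversionFactors | None = None,
) -> FlatmapImage:
    """Project one sample's detected cells onto the flatmap.

    Per bin: density = (sum of 2D counts of cells in mapped voxels x the
    compartment's conversion factor) / bin volume.  Cells whose voxel is not
    in the lookup (non-cortical or out of grid) are excluded and tallied in
    the metadata.
    """
    from .quantify import assign_cells_to_regions  # local to avoid cycle at import

    factors = factors or ConversionFactors()
    bin_vol = lookup.bin_volumes()
    mask = bin_vol == 0
    counts = np.zeros_like(bin_vol)
    excluded = 0
    if len(cells):
        xyz = cells[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
        idx = np.floor(
            (xyz - np.asarray(volume.origin_um)) / np.asarray(volume.voxel_size_um)
        ).astype(np.int64)
        # map voxel triples to bins via a flat-key join against the lookup table
        shape = np.asarray(volume.shape)
        in_grid = np.all((idx >= 0) & (idx < shape), axis=1)
        flat = idx[:, 0] * shape[1] * shape[2] + idx[:, 1] * shape[2] + idx[:, 2]
        lut = lookup.table
        lut_flat = (
            lut["i"].to_numpy() * shape[1] * shape[2]
            + lut["j"].to_numpy() * shape[2]
            + lut["k"].to_numpy()
        )
        order = np.argsort(lut_flat)
        pos = np.searchsorted(lut_flat[order], flat)
        pos_clipped = np.clip(pos, 0, len(lut_flat) - 1)
        hit = in_grid & (lut_flat[order][pos_clipped] == flat)
        excluded = int((~hit).sum())
        comp_factor = cells["compartment"].map(factors.get).to_numpy(dtype=float)
        ap = lut["ap_bin"].to_numpy()[order][pos_clipped[hit]]
        az = lut["az_bin"].to_numpy()[order][pos_clipped[hit]]
        np.add.at(counts, (ap, az), 1.0)
        weighted = np.zeros_like(bin_vol)
        np.add.at(weighted, (ap, az), comp_factor[hit])
    else:
        weighted = np.zeros_like(bin_vol)
    assert not np.any((bin_vol == 0) & (counts > 0)), "cells mapped to a zero-volume bin"
    density = np.where(mask, 0.0, weighted / np.where(mask, 1.0, bin_vol))
    meta = {"excluded_cells": excluded, "n_cells": int(len(cells))}
    if len(cells):
        meta["sample_id"] = str(cells["sample_id"].iloc[0])
        meta["age"] = str(cells["age"].iloc[0])
        meta["cell_type"] = str(cells["cell_type"].iloc[0])
    return FlatmapImage(density=density, counts=counts, mask=mask, meta=meta)


def average_flatmaps(images: list[FlatmapImage]) -> FlatmapImage:
    """Element-wise mean over samples; the mask is the union of masks."""
    if not images:
        raise ValueError("need at least one flatmap image")
    shape = images[0].density.shape
    if any(im.density.shape != shape for im in images):
        raise ValueError("flatmap bin grids differ between samples")
    mask = np.logical_or.reduce([im.mask for im in images])
    density = np.mean([im.density for im in images], axis=0)
    counts = np.mean([im.counts for im in images], axis=0)
    density = np.where(mask, 0.0, density)
    meta = {"n_averaged": len(images),
            "samples": [im.meta.get("sample_id") for im in images]}
    for key in ("age", "cell_type"):
        vals = {im.meta.get(key) for im in images if key in im.meta}
        if len(vals) == 1:
            meta[key] = vals.pop()
    return FlatmapImage(density=density, counts=counts, mask=mask, meta=meta)


def normalize_flatmap(
    image: FlatmapImage, age_volume_mm3: float, reference_volume_mm3: float
) -> FlatmapImage:
    """Scale every bin by V_age / V_reference (factor stored in metadata).

    The direction (multiplying native-age data by the ratio of the age's
    cortical volume to the adult reference volume) follows the published
    convention; the factor is recorded so it can be inverted.
    """
    if age_volume_mm3 <= 0 or reference_volume_mm3 <= 0:
        raise ValueError("volumes must be > 0")
    factor = age_volume_mm3 / reference_volume_mm3
    meta = dict(image.meta)
    meta["normalization_factor"] = factor * meta.get("normalization_factor", 1.0)
    return FlatmapImage(
        density=image.density * factor,
        counts=image.counts.copy(),
        mask=image.mask.copy(),
        meta=meta,
    )
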