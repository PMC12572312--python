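"""Functional-data-analysis test for age differences in density topography.

Each sample's per-region densities are treated as noisy evaluations of a
smooth 3D function of space at the region centroids.  The function is
represented in a tensor-product B-spline basis (one 1D clamped basis per
spatial axis), fitted by (optionally ridge-penalized) least squares.
Functional PCA under the true function-space inner product (Gram-matrix
weighted) retains the fewest components explaining a target share of the
variance (default 99%); each sample's L2 reconstruction error at the region
evaluation points is then the raw material of a one-way permutation ANOVA on
age labels, followed by pairwise permutation tests with Benjamini-Hochberg
adjustment.  Samples whose spatial pattern sits inside the common
low-dimensional topography reconstruct well; an age whose topography
deviates inflates its group's errors.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from statsmodels.stats.multitest import multipletests

from .atlas import LabelVolume

__all__ = [
    "FdaConfig",
    "TensorBSplineBasis",
    "FPCAModel",
    "TopographyTestResult",
    "compute_region_centroids",
    "make_tensor_basis",
    "build_design_matrix",
    "basis_gram",
    "fit_function_samples",
    "fit_fpca",
    "reconstruction_errors",
    "permutation_anova",
    "pairwise_permutation_tests",
    "bh_adjust",
    "topography_test",
]


@dataclass(frozen=True)
class FdaConfig:
    n_basis: tuple[int, int, int] = (3, 3, 3)
    degree: int = 2
    ridge: float = 0.0  # lambda; 0 = plain least squares
    variance_target: float = 0.99
    outlier_percentile: float = 99.0
    n_perm: int = 10_000
    seed: int = 0
    permutation_mode: str = "monte_carlo"  # or "exhaustive"
    domain_expand: float = 0.05  # bounding-box expansion per side

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not 0 < self.outlier_percentile < 100:
            raise ValueError("outlier percentile must be in (0, 100)")
        if not 0 < self.variance_target <= 1:
            raise ValueError("variance target must be in (0, 1]")
        if self.permutation_mode not in ("monte_carlo", "exhaustive"):
            raise ValueError(f"unknown permutation mode {self.permutation_mode!r}")
        if any(n < self.degree + 1 for n in self.n_basis):
            raise ValueError(
                f"need n_basis >= degree+1 per axis (clamped basis); got {self.n_basis} at degree {self.degree}"
            )
        if self.ridge < 0:
            raise ValueError("ridge penalty must be >= 0")


# ---------------------------------------------------------------------------
# centroids


def compute_region_centroids(volume: LabelVolume, region_ids) -> pd.DataFrame:
    """Mean voxel-center world coordinate per region (columns x/y/z _um)."""
    rows = []
    size = np.asarray(volume.voxel_size_um)
    origin = np.asarray(volume.origin_um)
    for rid in region_ids:
        vox = np.argwhere(volume.grid == rid)
        if len(vox) == 0:
            raise ValueError(f"region {rid} has no voxels in the label volume")
        center = (vox + 0.5).mean(axis=0) * size + origin
        rows.append({"region_id": int(rid), "x_um": center[0], "y_um": center[1], "z_um": center[2]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# tensor basis


@dataclass(frozen=True)
class TensorBSplineBasis:
    """Product basis of clamped 1D B-splines per spatial axis.

    Column order of the flattened basis is lexicographic over
    (x-index, y-index, z-index).
    """

    knots: tuple[np.ndarray, np.ndarray, np.ndarray]
    degree: int

    @property
    def n_basis(self) -> tuple[int, int, int]:
        return tuple(len(t) - self.degree - 1 for t in self.knots)  # type: ignore[return-value]

    @property
    def size(self) -> int:
        return int(np.prod(self.n_basis))

    @property
    def domain(self) -> tuple[tuple[float, float], ...]:
        return tuple((float(t[self.degree]), float(t[-self.degree - 1])) for t in self.knots)


def _clamped_knots(lo: float, hi: float, n_basis: int, degree: int) -> np.ndarray:
    if n_basis < degree + 1:
        raise ValueError(f"n_basis must be >= degree+1, got {n_basis} at degree {degree}")
    interior = np.linspace(lo, hi, n_basis - degree + 1)[1:-1]
    return np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])


def make_tensor_basis(
    points: np.ndarray,
    n_basis: tuple[int, int, int] = (3, 3, 3),
    degree: int = 2,
    expand: float = 0.05,
) -> TensorBSplineBasis:
    """Basis with uniform knots over the points' bounding box, expanded
    by ``expand`` per side so no evaluation point sits on the boundary."""
    pts = np.asarray(points, dtype=float)
    knots = []
    for ax in range(3):
        lo, hi = pts[:, ax].min(), pts[:, ax].max()
        pad = max((hi - lo) * expand, 1e-9)
        knots.append(_clamped_knots(lo - pad, hi + pad, n_basis[ax], degree))
    return TensorBSplineBasis(knots=tuple(knots), degree=degree)


def _axis_design(x: np.ndarray, knots: np.ndarray, degree: int) -> np.ndarray:
    lo, hi = knots[degree], knots[-degree - 1]
    if (x < lo).any() or (x > hi).any():
        raise ValueError("evaluation points outside the basis domain")
    return BSpline.design_matrix(x, knots, degree, extrapolate=False).toarray()


def build_design_matrix(points: np.ndarray, basis: TensorBSplineBasis) -> np.ndarray:
    """(n_points, total basis size) tensor design; each entry is the product
    of the three per-axis B-spline values.  Rows sum to 1 (partition of
    unity) on the domain."""
    pts = np.asarray(points, dtype=float)
    bx = _axis_design(pts[:, 0], basis.knots[0], basis.degree)
    by = _axis_design(pts[:, 1], basis.knots[1], basis.degree)
    bz = _axis_design(pts[:, 2], basis.knots[2], basis.degree)
    # row-wise Kronecker with x slowest: lexicographic (ix, iy, iz)
    n = len(pts)
    design = (bx[:, :, None, None] * by[:, None, :, None] * bz[:, None, None, :]).reshape(n, -1)
    return design


def _axis_gram(knots: np.ndarray, degree: int) -> np.ndarray:
    """Exact 1D Gram by Gauss-Legendre per knot span (degree+1 nodes
    integrate the degree-2d product polynomials exactly)."""
    n_basis = len(knots) - degree - 1
    nodes, weights = np.polynomial.legendre.leggauss(degree + 1)
    gram = np.zeros((n_basis, n_basis))
    spans = np.unique(knots)
    for a, b in zip(spans[:-1], spans[1:]):
        mid, half = (a + b) / 2.0, (b - a) / 2.0
        x = mid + half * nodes
        bvals = BSpline.design_matrix(x, knots, degree, extrapolate=False).toarray()
        gram += half * (bvals * weights[:, None]).T @ bvals
    return gram


def basis_gram(basis: TensorBSplineBasis) -> np.ndarray:
    """Function-space inner-product matrix of the tensor basis
    (Kronecker product of per-axis Grams)."""
    gx, gy, gz = (_axis_gram(t, basis.degree) for t in basis.knots)
    return np.kron(gx, np.kron(gy, gz))


# ---------------------------------------------------------------------------
# least-squares fit


def fit_function_samples(
    design: np.ndarray, densities: np.ndarray, ridge: float = 0.0
) -> np.ndarray:
    """Coefficients (n_samples, basis size) minimizing
    ||D c - y||^2 + ridge ||c||^2 per sample."""
    D = np.asarray(design, dtype=float)
    Y = np.atleast_2d(np.asarray(densities, dtype=float))
    if Y.shape[1] != D.shape[0]:
        raise ValueError(
            f"density matrix has {Y.shape[1]} regions but design has {D.shape[0]} rows"
        )
    if ridge == 0.0:
        rank = np.linalg.matrix_rank(D)
        if rank < D.shape[1]:
            raise ValueError(
                f"design rank {rank} < {D.shape[1]} columns; use a smaller basis or ridge > 0"
            )
        coef, *_ = np.linalg.lstsq(D, Y.T, rcond=None)
        return coef.T
    K = D.shape[1]
    A = D.T @ D + ridge * np.eye(K)
    return np.linalg.solve(A, D.T @ Y.T).T


# ---------------------------------------------------------------------------
# FPCA


@dataclass(frozen=True)
class FPCAModel:
    mean_coef: np.ndarray  # (K,)
    components: np.ndarray  # (K, m) coefficient representations, G-orthonormal
    explained_variance_ratio: np.ndarray  # (n_kept_eigs,) all ratios, nonincreasing
    n_components: int
    variance_target: float
    gram: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]


def fit_fpca(
    coefficients: np.ndarray, gram: np.ndarray, target: float = 0.99
) -> FPCAModel:
    """Functional PCA of fitted functions under the Gram inner product.

    Components are returned as coefficient vectors, orthonormal under the
    Gram matrix; the component count is the smallest m whose cumulative
    explained-variance ratio reaches the target, capped at
    min(n_samples - 1, basis size).  All-identical samples give a
    0-component model with total variance 0.
    """
    C = np.asarray(coefficients, dtype=float)
    if C.ndim != 2 or C.shape[0] < 2:
        raise ValueError("FPCA needs at least 2 samples of coefficients")
    G = np.asarray(gram, dtype=float)
    mean = C.mean(axis=0)
    A = C - mean
    L = np.linalg.cholesky(G)
    B = A @ L
    U, S, Vt = np.linalg.svd(B, full_matrices=False)
    var = S**2
    total = var.sum()
    if total <= max(1e-12 * (np.abs(C).max() ** 2 + 1.0), 0.0):
        return FPCAModel(mean, np.zeros((C.shape[1], 0)), np.zeros(0), 0, target, G)
    ratios = var / total
    cap = min(C.shape[0] - 1, C.shape[1])
    cum = np.cumsum(ratios)
    m = int(np.searchsorted(cum, target - 1e-12) + 1)
    m = min(m, cap)
    W = np.linalg.solve(L.T, Vt[:m].T)  # G-orthonormal coefficient directions
    return FPCAModel(mean, W, ratios, m, target, G)


def reconstruction_errors(
    densities: np.ndarray,
    design: np.ndarray,
    coefficients: np.ndarray,
    fpca: FPCAModel,
    outlier_percentile: float = 99.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample L2 deviation between observed densities and their
    reconstruction from the retained components, plus outlier flags.

    A sample is an outlier iff its error reaches the empirical
    ``outlier_percentile`` of the errors (linear-interpolation quantile).
    """
    Y = np.atleast_2d(np.asarray(densities, dtype=float))
    C = np.asarray(coefficients, dtype=float)
    A = C - fpca.mean_coef
    if fpca.n_components > 0:
        W = fpca.components[:, : fpca.n_components]
        scores = A @ fpca.gram @ W
        C_hat = fpca.mean_coef + scores @ W.T
    else:
        C_hat = np.broadcast_to(fpca.mean_coef, C.shape)
    Y_hat = C_hat @ np.asarray(design, dtype=float).T
    errors = np.linalg.norm(Y - Y_hat, axis=1)
    threshold = np.percentile(errors, outlier_percentile)
    return errors, errors >= threshold


# ---------------------------------------------------------------------------
# permutation tests


def _round_sig(x: np.ndarray | float, digits: int = 12):
    """Round to significant digits to stabilize >= comparisons between
    analytically equal F values computed along different code paths."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    nz = (x != 0) & np.isfinite(x)
    mag = np.zeros_like(x)
    mag[nz] = np.floor(np.log10(np.abs(x[nz])))
    out[nz] = np.round(x[nz] / 10.0 ** mag[nz], digits - 1) * 10.0 ** mag[nz]
    out[~np.isfinite(x)] = x[~np.isfinite(x)]
    return out


def _group_structure(labels) -> tuple[np.ndarray, np.ndarray, list]:
    labels = np.asarray(labels)
    uniq, idx = np.unique(labels, return_inverse=True)
    sizes = np.bincount(idx)
    if (sizes == 0).any() or len(uniq) < 2:
        raise ValueError("need >= 2 non-empty groups")
    return idx, sizes, list(uniq)


def _f_stat_batch(values: np.ndarray, group_idx: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """One-way between/within F for each row of ``values``."""
    V = np.atleast_2d(values)
    n, k = V.shape[1], len(sizes)
    indicator = np.zeros((n, k))
    indicator[np.arange(n), group_idx] = 1.0
    sums = V @ indicator
    means = sums / sizes
    grand = V.mean(axis=1, keepdims=True)
    ssb = ((means - grand) ** 2 * sizes).sum(axis=1)
    sst = ((V - grand) ** 2).sum(axis=1)
    ssw = np.maximum(sst - ssb, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / (k - 1)) / (ssw / (n - k))
    f = np.where(ssb == 0, 0.0, f)  # all-equal / pure-null degenerate rows
    return f


def _exhaustive_assignments(n: int, sizes: np.ndarray):
    """Yield index tuples per group over all distinct assignments."""
    def rec(remaining: tuple[int, ...], sizes_left: list[int]):
        if len(sizes_left) == 1:
            yield (remaining,)
            return
        s = sizes_left[0]
        for combo in itertools.combinations(remaining, s):
            rest = tuple(i for i in remaining if i not in combo)
            for tail in rec(rest, sizes_left[1:]):
                yield (combo, *tail)

    yield from rec(tuple(range(n)), list(sizes))


def permutation_anova(
    errors: np.ndarray, age_labels, config: FdaConfig | None = None
) -> tuple[float, float]:
    """One-way F on per-sample errors grouped by age, with a permutation p.

    Monte-Carlo mode: p = (1 + #{F* >= F_obs}) / (1 + n_perm) over random
    label permutations (never exactly 0).  Exhaustive mode enumerates every
    distinct assignment (identity included): p = #{F* >= F_obs} / #assignments.
    All-equal errors give F = 0, p = 1.
    """
    config = config or FdaConfig()
    vals = np.asarray(errors, dtype=float)
    group_idx, sizes, _ = _group_structure(age_labels)
    if np.allclose(vals, vals[0]):
        return 0.0, 1.0
    f_obs = float(_f_stat_batch(vals[None, :], group_idx, sizes)[0])
    f_obs_r = _round_sig(f_obs)
    if config.permutation_mode == "exhaustive":
        n_hits = n_total = 0
        for assignment in _exhaustive_assignments(len(vals), sizes):
            perm_idx = np.empty(len(vals), dtype=int)
            for g, members in enumerate(assignment):
                perm_idx[list(members)] = g
            f_star = float(_f_stat_batch(vals[None, :], perm_idx, sizes)[0])
            n_hits += bool(_round_sig(f_star) >= f_obs_r)
            n_total += 1
            if n_total > 500_000:
                raise ValueError("exhaustive enumeration too large; use monte_carlo")
        return f_obs, n_hits / n_total
    rng = np.random.default_rng(config.seed)
    perms = rng.permuted(np.tile(vals, (config.n_perm, 1)), axis=1)
    f_star = _f_stat_batch(perms, group_idx, sizes)
    n_ge = int(np.sum(_round_sig(f_star) >= f_obs_r))
    return f_obs, (1 + n_ge) / (1 + config.n_perm)


def pairwise_permutation_tests(
    errors: np.ndarray, age_labels, config: FdaConfig | None = None
) -> pd.DataFrame:
    """Two-group permutation tests on |mean difference| for every age pair,
    Benjamini-Hochberg adjusted across pairs."""
    config = config or FdaConfig()
    vals = np.asarray(errors, dtype=float)
    labels = np.asarray(age_labels)
    _, _, groups = _group_structure(labels)
    rows = []
    for i, a in enumerate(groups):
        for b in groups[i + 1:]:
            xa, xb = vals[labels == a], vals[labels == b]
            if config.permutation_mode == "monte_carlo" and (len(xa) == 1 or len(xb) == 1):
                warnings.warn(
                    f"singleton group in pair ({a}, {b}); permutation p resolution is limited"
                )
            stat, p = _two_group_perm(xa, xb, config)
            rows.append({"age_a": a, "age_b": b, "statistic": stat, "p_raw": p})
    table = pd.DataFrame(rows)
    if len(table):
        table["p_adj"] = bh_adjust(table["p_raw"].to_numpy())
    return table


def bh_adjust(p_raw: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (adjusted >= raw)."""
    p_raw = np.asarray(p_raw, dtype=float)
    adj = multipletests(p_raw, method="fdr_bh")[1]
    return np.maximum(adj, p_raw)


def _two_group_perm(xa: np.ndarray, xb: np.ndarray, config: FdaConfig) -> tuple[float, float]:
    pooled = np.concatenate([xa, xb])
    na = len(xa)
    obs = abs(xa.mean() - xb.mean())
    obs_r = _round_sig(obs)
    if config.permutation_mode == "exhaustive":
        hits = total = 0
        for combo in itertools.combinations(range(len(pooled)), na):
            sel = np.zeros(len(pooled), dtype=bool)
            sel[list(combo)] = True
            stat = abs(pooled[sel].mean() - pooled[~sel].mean())
            hits += bool(_round_sig(stat) >= obs_r)
            total += 1
        return float(obs), hits / total
    rng = np.random.default_rng(config.seed)
    perms = rng.permuted(np.tile(pooled, (config.n_perm, 1)), axis=1)
    stats = np.abs(perms[:, :na].mean(axis=1) - perms[:, na:].mean(axis=1))
    n_ge = int(np.sum(_round_sig(stats) >= obs_r))
    return float(obs), (1 + n_ge) / (1 + config.n_perm)


# ---------------------------------------------------------------------------
# full procedure


@dataclass
class TopographyTestResult:
    f_statistic: float
    p_value: float
    errors: np.ndarray
    outliers: np.ndarray
    pairwise: pd.DataFrame
    fpca: FPCAModel
    sample_ids: list | None = None
    age_labels: list | None = None

    def to_dict(self) -> dict:
        return {
            "F": self.f_statistic,
            "permuted_p": self.p_value,
            "n_components": self.fpca.n_components,
            "errors": self.errors.tolist(),
            "outliers": self.outliers.tolist(),
            "sample_ids": self.sample_ids,
            "age_labels": list(self.age_labels) if self.age_labels is not None else None,
            "pairwise": self.pairwise.to_dict("records"),
        }


def topography_test(
    density_matrix: np.ndarray,
    age_labels,
    centroids: np.ndarray,
    config: FdaConfig | None = None,
    sample_ids=None,
) -> TopographyTestResult:
    """Run the full FDA topography procedure on a (samples x regions)
    density matrix evaluated at the region centroids."""
    config = config or FdaConfig()
    pts = np.asarray(centroids, dtype=float)
    basis = make_tensor_basis(pts, config.n_basis, config.degree, config.domain_expand)
    design = build_design_matrix(pts, basis)
    coefs = fit_function_samples(design, density_matrix, config.ridge)
    fpca = fit_fpca(coefs, basis_gram(basis), config.variance_target)
    errors, outliers = reconstruction_errors(
        density_matrix, design, coefs, fpca, config.outlier_percentile
    )
    f, p = permutation_anova(errors, age_labels, config)
    pairwise = pairwise_permutation_tests(errors, age_labels, config)
    return TopographyTestResult(f, p, errors, outliers, pairwise, fpca,
                                sample_ids=sample_ids, age_labels=list(age_labels))
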