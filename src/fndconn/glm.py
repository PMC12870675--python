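"""Mass-univariate brain-behavior GLMs with Monte-Carlo cluster-extent
correction.

At every voxel the symptom-change score is regressed on the voxel's
connectivity metric plus the nuisance covariates (age, sex, SSRI/SNRI use,
mean framewise displacement, inter-session interval, baseline symptom
score).  The metric term's t statistic is converted to a z statistic by
tail-probability matching, thresholded two-sidedly at |z| > 1.96, and
suprathreshold clusters are retained only if their extent exceeds a
threshold derived from Monte-Carlo simulation of smoothness-matched
Gaussian null fields.

Implementation notes
--------------------
The voxel loop is vectorized with the Frisch-Waugh-Lovell identity: the
outcome and every metric column are residualized against the shared
nuisance design once (via QR), after which each voxel reduces to a simple
regression.  This is numerically identical to per-voxel full OLS.

The smoothness of the null fields is estimated from the GLM residual maps
with the classical gradient-variance estimator.  The per-axis Gaussian
kernel used to build null fields is sqrt(max(FWHM^2 - 1, 0)) / 2.3548
voxels: FWHM is interpreted as the total smoothness including the
intrinsic one-voxel floor of a discrete grid, so spatially white residuals
reproduce unsmoothed white null fields.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "GLMResult",
    "ClusterNull",
    "fit_brain_behavior_glm",
    "t_to_z",
    "estimate_map_smoothness",
    "cluster_null_distribution",
    "apply_cluster_correction",
    "posthoc_covariate_sensitivity",
    "BASE_COVARIATES",
    "Z_CAP",
]

Z_CAP = 8.2
GAUSS_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548 sigma per FWHM

#: primary-model nuisance set (baseline symptom score appended per outcome)
BASE_COVARIATES = ["age", "sex", "ssri_snri", "mean_fd", "interval", "baseline_score"]

_BINARY = {"sex", "ssri_snri", "fnd_seizure"}


class ModelError(ValueError):
    pass


@dataclass
class GLMResult:
    """Per-voxel results for the metric-of-interest term."""

    beta: np.ndarray
    t: np.ndarray
    z: np.ndarray
    df: int
    residuals: np.ndarray  # (n_subjects, n_voxels)
    voxel_index: np.ndarray
    design_columns: list[str]
    outcome_name: str = ""
    zero_variance: np.ndarray = field(default=None)  # masked-out voxels
    saturated: np.ndarray = field(default=None)  # |z| capped voxels


@dataclass
class ClusterNull:
    """Monte-Carlo null distribution of maximum cluster extents."""

    z_thresh: float
    fwhm: np.ndarray  # per-axis, voxels
    n_iterations: int
    max_extents: np.ndarray
    alpha: float
    extent_threshold: int  # smallest surviving extent
    seed: int | None
    connectivity: int = 26
    degenerate: bool = False


def _design_matrix(
    covariates: pd.DataFrame, columns: list[str], return_names: bool = False
):
    """Intercept + covariates; continuous columns mean-centered.

    Covariates with no variance across subjects (e.g. an all-female
    sample's sex indicator) carry no information and are dropped with a
    warning rather than rendering the design singular.
    """
    cols = [np.ones(len(covariates))]
    kept = []
    for name in columns:
        if name not in covariates:
            raise ModelError(f"missing covariate column {name!r}")
        v = covariates[name].to_numpy(dtype=float)
        if np.isnan(v).any():
            raise ModelError(f"covariate {name!r} has missing values")
        if v.std() == 0:
            warnings.warn(f"covariate {name!r} is constant; dropped",
                          RuntimeWarning, stacklevel=3)
            continue
        if name not in _BINARY:
            v = v - v.mean()
        cols.append(v)
        kept.append(name)
    X = np.column_stack(cols)
    return (X, kept) if return_names else X


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    r = np.linalg.qr(X, mode="r")
    scale = np.abs(np.diag(r)).max()
    bad = np.abs(np.diag(r)) < 1e-10 * max(scale, 1.0)
    if bad.any():
        culprits = [(["intercept"] + names)[i] for i in np.flatnonzero(bad)]
        raise ModelError(f"rank-deficient design; collinear columns: {culprits}")


def _as_metric_matrix(metric_maps) -> tuple[np.ndarray, np.ndarray]:
    """Stack MetricMaps (or accept an (n, V) array with voxel_index)."""
    if isinstance(metric_maps, np.ndarray):
        raise TypeError("pass a list of MetricMap or (matrix, voxel_index) tuple")
    if isinstance(metric_maps, tuple):
        return np.asarray(metric_maps[0], float), np.asarray(metric_maps[1])
    idx0 = metric_maps[0].voxel_index
    for m in metric_maps[1:]:
        if not np.array_equal(m.voxel_index, idx0):
            raise ModelError("metric maps are not on a common mask")
    return np.stack([m.values for m in metric_maps]), idx0


def fit_brain_behavior_glm(
    metric_maps,
    outcome: np.ndarray,
    covariates: pd.DataFrame,
    covariate_columns: list[str] | None = None,
    outcome_name: str = "",
) -> GLMResult:
    """Fit ``outcome ~ metric + covariates`` at every voxel.

    Parameters
    ----------
    metric_maps : list of MetricMap, or (matrix, voxel_index) tuple
        One map per subject on a shared mask; matrix shape (n_subjects, V).
    outcome : (n_subjects,) symptom-change scores.
    covariates : DataFrame with the covariate columns.
    covariate_columns : defaults to :data:`BASE_COVARIATES`.
    """
    M, voxel_index = _as_metric_matrix(metric_maps)
    y = np.asarray(outcome, dtype=float)
    n = len(y)
    if M.shape[0] != n or len(covariates) != n:
        raise ModelError("subject dimension mismatch")
    if n < 8:
        raise ModelError("need >= 8 subjects")
    columns = list(BASE_COVARIATES if covariate_columns is None else covariate_columns)
    Z, columns = _design_matrix(covariates, columns, return_names=True)
    _check_rank(Z, columns)
    p = Z.shape[1]
    df = n - p - 1
    if df <= 0:
        raise ModelError("non-positive residual degrees of freedom")

    # Frisch-Waugh: residualize y and every metric column against Z
    Q, _ = np.linalg.qr(Z)
    y_res = y - Q @ (Q.T @ y)
    M_res = M - Q @ (Q.T @ M)

    mm = np.einsum("ij,ij->j", M_res, M_res)
    zero_var = mm < 1e-12 * max(float(np.abs(M).max()) ** 2, 1.0) * n
    mm_safe = np.where(zero_var, 1.0, mm)

    my = M_res.T @ y_res
    beta = my / mm_safe
    resid = y_res[:, None] - M_res * beta[None, :]
    rss = np.einsum("ij,ij->j", resid, resid)
    sigma2 = rss / df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / np.sqrt(sigma2 / mm_safe)
    t[zero_var] = 0.0
    t[np.isnan(t)] = 0.0  # 0/0: outcome fully explained with beta = 0

    z, saturated = t_to_z(t, df, return_saturated=True)
    z[zero_var] = 0.0
    beta = np.where(zero_var, 0.0, beta)
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} voxel(s) with zero metric variance masked out",
            RuntimeWarning,
            stacklevel=2,
        )
    return GLMResult(
        beta=beta, t=t, z=z, df=df, residuals=resid, voxel_index=voxel_index,
        design_columns=["intercept", "metric"] + columns,
        outcome_name=outcome_name, zero_variance=zero_var, saturated=saturated,
    )


def t_to_z(t, df: int, return_saturated: bool = False):
    """Tail-probability-matching t -> z conversion, sign-preserving.

    z is the standard-normal quantile of the Student-t CDF of t; values
    beyond ±Z_CAP (numerically perfect fits) are capped and flagged.
    Non-finite t propagates as a capped, flagged value (NaN stays NaN).
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    z = np.empty_like(t)
    finite = np.isfinite(t)
    # work on |t| in the upper tail for numerical stability
    sf = stats.t.sf(np.abs(t[finite]), df)
    z[finite] = np.sign(t[finite]) * stats.norm.isf(sf)
    z[~finite] = np.sign(t[~finite]) * np.inf
    z[np.isnan(t)] = np.nan
    saturated = np.abs(z) > Z_CAP
    z[saturated] = np.sign(z[saturated]) * Z_CAP
    if scalar:
        z, saturated = z[0], saturated[0]
    return (z, saturated) if return_saturated else z


def _to_volumes(values: np.ndarray, voxel_index: np.ndarray, shape) -> np.ndarray:
    vols = np.zeros((values.shape[0],) + tuple(shape))
    vols[:, voxel_index[:, 0], voxel_index[:, 1], voxel_index[:, 2]] = values
    return vols


def estimate_map_smoothness(
    residual_maps: np.ndarray, mask: np.ndarray, voxel_index: np.ndarray | None = None
) -> np.ndarray:
    """Per-axis FWHM (voxels) from the gradient-variance estimator.

    For each axis a, with e the residual field restricted to the mask and
    ∂e its forward difference along a (both ends in-mask),

        FWHM_a = sqrt(-2 ln 2 / ln(1 - var(∂e) / (2 var(e)))),

    pooled over maps and floored at 1 voxel (the intrinsic resolution of
    the grid).  ``residual_maps`` is (n_maps, V) aligned with
    ``voxel_index`` (default: lexicographic order of ``mask``).

    Raises
    ------
    ValueError
        If fewer than 2 maps, fewer than 2 mask voxels, or all maps are
        spatially constant.
    """
    maps = np.asarray(residual_maps, dtype=float)
    if maps.ndim != 2 or maps.shape[0] < 2:
        raise ValueError("need >= 2 residual maps")
    if mask.sum() < 2:
        raise ValueError("mask too small to estimate smoothness")
    if voxel_index is None:
        voxel_index = np.argwhere(mask)
    vols = _to_volumes(maps, voxel_index, mask.shape)

    var_e = maps.var(axis=1)
    keep = var_e > 0
    if not keep.any():
        raise ValueError("all residual maps are constant; smoothness undefined")
    vols, var_e = vols[keep], var_e[keep]

    fwhm = np.empty(3)
    for ax in range(3):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[ax] = slice(0, -1)
        sl_hi[ax] = slice(1, None)
        pair = mask[tuple(sl_lo)] & mask[tuple(sl_hi)]
        if pair.sum() < 2:
            fwhm[ax] = 1.0
            continue
        diffs = (vols[(slice(None),) + tuple(sl_hi)] -
                 vols[(slice(None),) + tuple(sl_lo)])[:, pair]
        # pooled over maps, each normalized by its own field variance
        ratio = np.mean(diffs.var(axis=1) / (2.0 * var_e))
        s = 1.0 - ratio
        if s <= 0:
            fwhm[ax] = 1.0
        else:
            fwhm[ax] = max(1.0, np.sqrt(-2.0 * np.log(2.0) / np.log(s)))
    return fwhm


def _structure(connectivity: int) -> np.ndarray:
    order = {6: 1, 18: 2, 26: 3}
    if connectivity not in order:
        raise ValueError("connectivity must be 6, 18 or 26")
    return ndimage.generate_binary_structure(3, order[connectivity])


def _null_field(rng, mask: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """One smoothness-matched standardized Gaussian field on the mask."""
    noise = rng.standard_normal(mask.shape)
    if np.any(sigma > 0):
        noise = ndimage.gaussian_filter(noise, sigma=sigma, mode="constant")
    vals = noise[mask]
    return (vals - vals.mean()) / vals.std()


def _max_cluster_extent(
    field_vals: np.ndarray, mask: np.ndarray, z_thresh: float, structure: np.ndarray
) -> int:
    vol = np.zeros(mask.shape)
    vol[mask] = field_vals
    best = 0
    for sgn in (1.0, -1.0):
        lab, n_lab = ndimage.label((sgn * vol > z_thresh) & mask, structure=structure)
        if n_lab:
            best = max(best, int(np.bincount(lab.ravel())[1:].max()))
    return best


def cluster_null_distribution(
    mask: np.ndarray,
    fwhm,
    z_thresh: float = 1.96,
    n_iter: int = 10_000,
    seed: int | None = 0,
    alpha: float = 0.05,
    connectivity: int = 26,
) -> ClusterNull:
    """Monte-Carlo null of maximum cluster extents.

    Each iteration draws white Gaussian noise on the grid, smooths it to
    the target per-axis FWHM, re-standardizes within the mask so the voxel
    threshold keeps its nominal two-sided rate, thresholds at |z| >
    ``z_thresh`` and records the maximum connected-component extent over
    both signs.  The surviving-extent threshold is the smallest integer
    strictly above the empirical (1 - alpha) quantile, so clusters at
    least that large have family-wise error <= alpha on fresh null fields.
    """
    if z_thresh <= 0:
        raise ValueError("z_thresh must be > 0")
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100")
    fwhm = np.broadcast_to(np.asarray(fwhm, dtype=float), (3,)).copy()
    sigma = np.sqrt(np.maximum(fwhm**2 - 1.0, 0.0)) / GAUSS_FWHM
    structure = _structure(connectivity)
    rng = np.random.default_rng(seed)
    extents = np.empty(n_iter, dtype=int)
    for i in range(n_iter):
        vals = _null_field(rng, mask, sigma)
        extents[i] = _max_cluster_extent(vals, mask, z_thresh, structure)
    q = float(np.quantile(extents, 1.0 - alpha))
    threshold = int(np.floor(q)) + 1
    degenerate = q == 0
    if degenerate:
        warnings.warn(
            "degenerate cluster null: (1-alpha) quantile of max extents is 0 "
            "(voxel threshold beyond field range?)",
            RuntimeWarning,
            stacklevel=2,
        )
    return ClusterNull(
        z_thresh=float(z_thresh), fwhm=fwhm, n_iterations=n_iter,
        max_extents=extents, alpha=alpha, extent_threshold=threshold,
        seed=seed if isinstance(seed, int) else None,
        connectivity=connectivity, degenerate=degenerate,
    )


def apply_cluster_correction(
    z_values: np.ndarray,
    mask: np.ndarray,
    null: ClusterNull,
    voxel_index: np.ndarray | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Retain suprathreshold clusters larger than the null extent threshold.

    Positive and negative clusters are labeled separately.  Returns a
    cluster table (id, sign, extent, peak |z|, peak coordinate) and a
    boolean significance volume.
    """
    if voxel_index is None:
        voxel_index = np.argwhere(mask)
    if len(voxel_index) != int(mask.sum()):
        raise ValueError("z map and mask sizes do not match")
    vol = np.zeros(mask.shape)
    vol[voxel_index[:, 0], voxel_index[:, 1], voxel_index[:, 2]] = z_values
    structure = _structure(null.connectivity)

    rows = []
    sig = np.zeros(mask.shape, dtype=bool)
    cid = 0
    for sgn, name in ((1.0, "positive"), (-1.0, "negative")):
        lab, n_lab = ndimage.label((sgn * vol > null.z_thresh) & mask,
                                   structure=structure)
        for k in range(1, n_lab + 1):
            members = lab == k
            extent = int(members.sum())
            if extent < null.extent_threshold:
                continue
            cid += 1
            zs = vol[members]
            peak_local = np.argmax(np.abs(zs))
            coords = np.argwhere(members)
            rows.append({
                "cluster_id": cid,
                "sign": name,
                "extent": extent,
                "peak_abs_z": float(np.abs(zs[peak_local])),
                "peak_x": int(coords[peak_local, 0]),
                "peak_y": int(coords[peak_local, 1]),
                "peak_z": int(coords[peak_local, 2]),
            })
            sig |= members
    table = pd.DataFrame(
        rows, columns=["cluster_id", "sign", "extent", "peak_abs_z",
                       "peak_x", "peak_y", "peak_z"],
    )
    return table, sig


def cluster_subject_means(
    sig_or_cluster_mask: np.ndarray,
    metric_matrix: np.ndarray,
    voxel_index: np.ndarray,
) -> np.ndarray:
    """Per-subject mean metric value over a cluster/significance mask."""
    inside = sig_or_cluster_mask[
        voxel_index[:, 0], voxel_index[:, 1], voxel_index[:, 2]
    ]
    if not inside.any():
        raise ValueError("mask selects no voxels")
    return np.asarray(metric_matrix, float)[:, inside].mean(axis=1)


def posthoc_covariate_sensitivity(
    metric_maps,
    outcome: np.ndarray,
    covariates: pd.DataFrame,
    extra_sets: dict[str, list[str]],
    primary_table: pd.DataFrame,
    primary_sig: np.ndarray,
    mask: np.ndarray,
    base_columns: list[str] | None = None,
    z_thresh: float = 1.96,
    alpha: float = 0.05,
    n_iter: int = 2000,
    connectivity: int = 26,
    seed: int = 0,
) -> pd.DataFrame:
    """Re-fit the voxel-wise GLM with each extra covariate set and report,
    per primary cluster, whether it is held (>= 1 surviving voxel overlaps).

    Smoothness and the Monte-Carlo null are re-derived from each re-fit's
    residuals.
    """
    M, voxel_index = _as_metric_matrix(metric_maps)
    base = list(BASE_COVARIATES if base_columns is None else base_columns)
    rows = []
    for name, extras in extra_sets.items():
        res = fit_brain_behavior_glm(
            (M, voxel_index), outcome, covariates, base + list(extras)
        )
        fwhm = estimate_map_smoothness(res.residuals, mask, voxel_index)
        null = cluster_null_distribution(
            mask, fwhm, z_thresh=z_thresh, n_iter=n_iter, seed=seed,
            alpha=alpha, connectivity=connectivity,
        )
        _, sig = apply_cluster_correction(res.z, mask, null, voxel_index)
        for _, cl in primary_table.iterrows():
            members = _cluster_members(primary_sig, cl, connectivity)
            overlap = int((members & sig).sum())
            rows.append({
                "covariate_set": name,
                "cluster_id": int(cl["cluster_id"]),
                "n_overlap": overlap,
                "held": overlap >= 1,
            })
    return pd.DataFrame(rows, columns=["covariate_set", "cluster_id",
                                       "n_overlap", "held"])


def _cluster_members(primary_sig: np.ndarray, cluster_row, connectivity: int):
    """Recover one primary cluster's voxels from the significance mask."""
    lab, _ = ndimage.label(primary_sig, structure=_structure(connectivity))
    k = lab[int(cluster_row["peak_x"]), int(cluster_row["peak_y"]),
            int(cluster_row["peak_z"])]
    return lab == k
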