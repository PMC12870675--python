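"""Seed-based post-hoc characterization of integration findings.

Significant integration voxels are assigned to their functional networks;
for the top networks a seed ROI averages the time series of its
significant voxels, seed-to-voxel Pearson maps are Fisher r-to-z
transformed, tested against zero at the group level with nuisance
covariates, and the surviving voxels are counted per *other* network
(within-network links are excluded — they do not measure integration).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .glm import (
    GLMResult,
    apply_cluster_correction,
    cluster_null_distribution,
    estimate_map_smoothness,
    t_to_z,
)

__all__ = [
    "SeedDefinition",
    "NetworkConnectionCounts",
    "assign_cluster_voxels_to_networks",
    "select_top_networks",
    "seed_to_voxel_zmap",
    "group_seed_glm",
    "count_between_network_connections",
    "compare_timepoint_connection_counts",
]

R_CLIP = 1.0 - 1e-7

#: covariates for the seed group model (no interval / baseline score)
SEED_COVARIATES = ["age", "sex", "ssri_snri", "mean_fd"]


@dataclass(frozen=True)
class SeedDefinition:
    """Seed ROI: the significant voxels of one network."""

    network: int
    member_voxels: np.ndarray  # (m, 3) coordinates
    source_analysis: str = ""  # "baseline_predictor" | "longitudinal_change"

    def __post_init__(self):
        if len(self.member_voxels) == 0:
            raise ValueError("seed has no member voxels")


@dataclass(frozen=True)
class NetworkConnectionCounts:
    """Significant-voxel counts from one seed network to each other network."""

    seed_network: int
    counts: dict[int, int]  # target network -> count (seed network absent)
    timepoint: str = "baseline"


def assign_cluster_voxels_to_networks(
    significance_mask: np.ndarray, labels: np.ndarray, n_networks: int = 7
) -> dict[int, int]:
    """Histogram of network labels over significant voxels.

    Significant voxels outside the labeled (isocortical) region are
    excluded with a warning.
    """
    sig_labels = labels[significance_mask]
    outside = sig_labels <= 0
    if outside.any():
        warnings.warn(
            f"{int(outside.sum())} significant voxel(s) outside the labeled "
            "region excluded from network assignment",
            RuntimeWarning,
            stacklevel=2,
        )
    sig_labels = sig_labels[~outside]
    return {k: int((sig_labels == k).sum()) for k in range(1, n_networks + 1)}


def select_top_networks(counts: dict[int, int], k: int = 3) -> list[int]:
    """The k networks with most significant voxels.

    Ties break by ascending network index; zero-count networks are never
    selected (a warning is issued if fewer than k remain).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    nonzero = sorted(
        (net for net, c in counts.items() if c > 0),
        key=lambda net: (-counts[net], net),
    )
    if len(nonzero) < k:
        warnings.warn(
            f"only {len(nonzero)} network(s) with significant voxels "
            f"(requested {k})",
            RuntimeWarning,
            stacklevel=2,
        )
    return nonzero[:k]


def make_seed(
    significance_mask: np.ndarray, labels: np.ndarray, network: int,
    source_analysis: str = "",
) -> SeedDefinition:
    """Seed ROI from the significant voxels carrying one network's label."""
    voxels = np.argwhere(significance_mask & (labels == network))
    return SeedDefinition(network, voxels, source_analysis)


def seed_to_voxel_zmap(
    subject_timeseries: np.ndarray,
    seed: SeedDefinition,
    grey_index: np.ndarray,
    iso_selector: np.ndarray,
) -> np.ndarray:
    """Fisher r-to-z map of the seed-average series with every isocortical
    voxel.

    Parameters
    ----------
    subject_timeseries : (T, n_grey) session array in grey-voxel order.
    grey_index : (n_grey, 3) coordinates of the columns.
    iso_selector : boolean (n_grey,) marking isocortical columns.

    Correlations are clipped to ±(1 - 1e-7) before atanh, so a voxel equal
    to the seed average yields a large finite z.  A zero-variance seed
    average yields an all-NaN map.
    """
    flat = np.ravel_multi_index(grey_index.T, grey_index.max(axis=0) + 1)
    seed_flat = np.ravel_multi_index(
        np.asarray(seed.member_voxels).T, grey_index.max(axis=0) + 1
    )
    in_seed = np.isin(flat, seed_flat)
    if not in_seed.any():
        raise ValueError("seed voxels not present in the time series")
    seed_ts = subject_timeseries[:, in_seed].mean(axis=1)
    if seed_ts.std() == 0:
        warnings.warn("zero-variance seed average; map flagged NaN",
                      RuntimeWarning, stacklevel=2)
        return np.full(int(iso_selector.sum()), np.nan)

    ts = subject_timeseries[:, iso_selector]
    s = (seed_ts - seed_ts.mean()) / seed_ts.std()
    v = ts - ts.mean(axis=0)
    sd = v.std(axis=0)
    sd[sd == 0] = np.inf  # dead voxel -> r = 0
    r = (s @ v) / (len(s) * sd)
    return np.arctanh(np.clip(r, -R_CLIP, R_CLIP))


def group_seed_glm(
    z_maps: np.ndarray,
    covariates: pd.DataFrame,
    mask: np.ndarray,
    voxel_index: np.ndarray,
    covariate_columns: list[str] | None = None,
    z_thresh: float = 1.96,
    alpha: float = 0.05,
    n_iter: int = 10_000,
    connectivity: int = 26,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray, object]:
    """Test whether seed connectivity differs from zero across subjects.

    Per voxel fits ``z ~ intercept + centered covariates`` and tests the
    intercept against zero, then applies the same Monte-Carlo cluster
    correction as the brain-behavior models.  Because the covariates are
    mean-centered, the intercept is the covariate-adjusted group mean.

    Returns (cluster table, significance volume, GLMResult).
    """
    cols = list(SEED_COVARIATES if covariate_columns is None else covariate_columns)
    Z = np.column_stack(
        [covariates[c].to_numpy(float) - covariates[c].to_numpy(float).mean()
         for c in cols]
    ) if cols else np.empty((len(covariates), 0))

    n = z_maps.shape[0]
    if Z.shape[1]:
        Q, _ = np.linalg.qr(Z)
        Y_res = z_maps - Q @ (Q.T @ z_maps)
        p = Z.shape[1]
    else:
        Y_res, p = z_maps.copy(), 0
    df = n - p - 1
    mean = Y_res.mean(axis=0)
    resid = Y_res - mean
    se = np.sqrt(np.einsum("ij,ij->j", resid, resid) / df / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / se
    t[np.isnan(t)] = 0.0
    z, saturated = t_to_z(t, df, return_saturated=True)
    res = GLMResult(
        beta=mean, t=t, z=z, df=df, residuals=resid, voxel_index=voxel_index,
        design_columns=["intercept"] + cols, outcome_name="seed_fc",
        zero_variance=np.zeros_like(t, dtype=bool), saturated=saturated,
    )
    fwhm = estimate_map_smoothness(resid, mask, voxel_index)
    null = cluster_null_distribution(
        mask, fwhm, z_thresh=z_thresh, n_iter=n_iter, seed=seed,
        alpha=alpha, connectivity=connectivity,
    )
    table, sig = apply_cluster_correction(z, mask, null, voxel_index)
    return table, sig, res


def count_between_network_connections(
    significance_mask: np.ndarray,
    labels: np.ndarray,
    seed_network: int,
    n_networks: int = 7,
    timepoint: str = "baseline",
) -> NetworkConnectionCounts:
    """Count significant voxels per target network, excluding the seed's own
    network (within-network links do not measure integration)."""
    sig_labels = labels[significance_mask]
    counts = {
        k: int((sig_labels == k).sum())
        for k in range(1, n_networks + 1)
        if k != seed_network
    }
    return NetworkConnectionCounts(seed_network, counts, timepoint)


def compare_timepoint_connection_counts(
    base: NetworkConnectionCounts,
    follow: NetworkConnectionCounts,
    network_sizes: dict[int, int],
) -> pd.DataFrame:
    """Baseline vs follow-up percent-connected tables per target network.

    Percents use each target network's isocortical voxel count as the
    denominator; networks whose follow-up connectivity decreased are
    flagged.
    """
    if base.seed_network != follow.seed_network:
        raise ValueError("counts come from different seed networks")
    targets = sorted(set(base.counts) | set(follow.counts))
    rows = []
    for net in targets:
        size = network_sizes[net]
        b = 100.0 * base.counts.get(net, 0) / size
        f = 100.0 * follow.counts.get(net, 0) / size
        rows.append({
            "seed_network": base.seed_network,
            "target_network": net,
            "baseline_pct": b,
            "followup_pct": f,
            "delta_pct": f - b,
            "decreased": f < b,
        })
    return pd.DataFrame(rows)
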