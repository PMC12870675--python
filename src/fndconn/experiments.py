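"""Calibration and parameter-recovery studies over synthetic cohorts.

These are the package's evidence that the inferential machinery behaves:

* :func:`fwe_calibration` — does the Monte-Carlo extent threshold control
  family-wise error at the nominal alpha on fresh null fields?
* :func:`null_pipeline_calibration` — does the *whole* pipeline (time
  series -> metrics -> GLM -> correction) flag anything on cohorts with no
  planted effect at roughly the alpha rate?
* :func:`recovery_experiment` — is a planted baseline integration-symptom
  effect recovered, and only where it was planted?

Problem sizes default to a ~800-grey-voxel phantom, 32-subject cohorts and
reduced Monte-Carlo iteration counts so a full study runs in minutes.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy import ndimage

from .glm import _max_cluster_extent, _null_field, _structure, cluster_null_distribution
from .phantom import make_phantom_space
from .pipeline import analyze
from .simulate import SimulationConfig, simulate_longitudinal_cohort, simulate_null_cohort

__all__ = [
    "fwe_calibration",
    "null_pipeline_calibration",
    "recovery_experiment",
]


def fwe_calibration(
    seed: int = 0,
    dims=(12, 12, 10),
    fwhm: float = 2.0,
    z_thresh: float = 1.96,
    n_iter: int = 2000,
    n_fresh: int = 200,
    alpha: float = 0.05,
    connectivity: int = 26,
) -> dict:
    """Self-calibration of the cluster-extent threshold.

    Derives the extent threshold from ``n_iter`` null iterations, then
    measures the family-wise error (any surviving cluster) on ``n_fresh``
    independent null fields from the same generator.
    """
    space = make_phantom_space(dims, seed=seed)
    mask = space.grey_mask
    null = cluster_null_distribution(
        mask, fwhm, z_thresh=z_thresh, n_iter=n_iter, seed=seed,
        alpha=alpha, connectivity=connectivity,
    )
    sigma = np.sqrt(np.maximum(np.broadcast_to(np.asarray(fwhm, float), (3,)) ** 2 - 1.0, 0.0))
    sigma = sigma / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    structure = _structure(connectivity)
    rng = np.random.default_rng([seed, 77])
    hits = 0
    for _ in range(n_fresh):
        vals = _null_field(rng, mask, sigma)
        if _max_cluster_extent(vals, mask, z_thresh, structure) >= null.extent_threshold:
            hits += 1
    rate = hits / n_fresh
    return {
        "extent_threshold": null.extent_threshold,
        "observed_fwe": rate,
        "n_fresh": n_fresh,
        "alpha": alpha,
        "n_mask_voxels": int(mask.sum()),
    }


def _base_config(seed: int, **overrides) -> SimulationConfig:
    """Study conditions without healthy controls (not needed for GLMs)."""
    return SimulationConfig(seed=seed, n_hc=0, **overrides)


def null_pipeline_calibration(
    seed: int = 0,
    n_cohorts: int = 100,
    n_iter: int = 600,
    dims=(12, 12, 10),
) -> dict:
    """Fraction of no-effect cohorts in which the full pipeline reports at
    least one significant cluster (baseline integration analysis)."""
    space = make_phantom_space(dims, seed=seed)
    hits = 0
    for rep in range(n_cohorts):
        cfg = _base_config(int(np.random.default_rng([seed, 5, rep]).integers(2**31)))
        cohort = simulate_null_cohort(space, cfg)
        r = analyze(cohort, "integration", "baseline_predictor", "soms_cd",
                    n_iter=n_iter, seed=cfg.seed)
        if len(r["cluster_table"]) > 0:
            hits += 1
    return {
        "n_cohorts": n_cohorts,
        "n_with_cluster": hits,
        "rate": hits / n_cohorts,
    }


def recovery_experiment(
    seed: int = 0,
    n_replicates: int = 25,
    n_iter: int = 1000,
    dims=(12, 12, 10),
    recovery_fraction: float = 0.5,
) -> dict:
    """Recovery of a planted baseline integration-symptom association.

    A replicate counts as recovered when >= ``recovery_fraction`` of the
    planted effect-region voxels fall inside a surviving cluster; it
    counts as a false flag when a surviving cluster is disjoint from the
    region dilated by the estimated smoothness margin (a false region).
    The true-positive cluster's chance suprathreshold fringe is not a
    false region: a strong anchor cluster accretes 26-connected noise
    voxels in a sizeable share of replicates whatever the threshold, so
    voxel-level exactness is not a meaningful error criterion here.
    """
    space = make_phantom_space(dims, seed=seed)
    recovered = 0
    false_flags = 0
    partial_rs = []
    for rep in range(n_replicates):
        cfg = _base_config(
            int(np.random.default_rng([seed, 9, rep]).integers(2**31)),
            longitudinal_effect_size=0.0,
        )
        cohort = simulate_longitudinal_cohort(space, cfg)
        r = analyze(cohort, "integration", "baseline_predictor", "soms_cd",
                    n_iter=n_iter, seed=cfg.seed)
        region = cohort.truth["effect_region"]
        region_mask = np.zeros(space.dims, dtype=bool)
        region_mask[region[:, 0], region[:, 1], region[:, 2]] = True
        sig = r["sig_mask"]
        frac = (sig & region_mask).sum() / region_mask.sum()
        if frac >= recovery_fraction:
            recovered += 1
        margin = int(np.ceil(float(np.max(r["fwhm"]))))
        dilated = ndimage.binary_dilation(
            region_mask, structure=_structure(26), iterations=max(1, margin)
        )
        lab, n_lab = ndimage.label(sig, structure=_structure(26))
        if any(not dilated[lab == k].any() for k in range(1, n_lab + 1)):
            false_flags += 1
        partial_rs.append(_region_partial_r(r, region_mask))
    return {
        "n_replicates": n_replicates,
        "recovery_rate": recovered / n_replicates,
        "false_flag_rate": false_flags / n_replicates,
        "mean_planted_partial_r": float(np.mean(partial_rs)),
    }


def _region_partial_r(analysis_result: dict, region_mask: np.ndarray) -> float:
    """Realized partial correlation of mean effect-region metric with the
    outcome, given the nuisance covariates."""
    vi = analysis_result["voxel_index"]
    inside = region_mask[vi[:, 0], vi[:, 1], vi[:, 2]]
    m = analysis_result["metric_matrix"][:, inside].mean(axis=1)
    y = analysis_result["outcome"]
    cov = analysis_result["covariates"]
    from .glm import BASE_COVARIATES, _design_matrix

    Z = _design_matrix(cov, BASE_COVARIATES)
    Q, _ = np.linalg.qr(Z)
    m_res = m - Q @ (Q.T @ m)
    y_res = y - Q @ (Q.T @ y)
    denom = np.linalg.norm(m_res) * np.linalg.norm(y_res)
    return float(m_res @ y_res / denom) if denom else 0.0
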