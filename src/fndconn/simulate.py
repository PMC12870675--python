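"""Synthetic longitudinal FND + healthy-control cohorts with known,
configurable brain-behavior effects.

The generative model for one scanning session is a latent-factor block
covariance.  Each voxel v with network label L(v) observes

    x_v(t) = sqrt(rb) g(t) + sqrt(rw - rb) f_L(v)(t) + beta_v c_v(t)
             + sqrt(1 - rw) e_v(t),

rescaled to unit variance, where g is a global factor, f_k a per-network
factor, e_v voxel noise (all iid standard normal across time), rw / rb the
target within- and between-network Pearson correlations, and beta_v a
cross-network loading that is nonzero only inside the planted effect
region.  The cross signal c_v is either one target network's factor
(``target_network`` set) or the unit-variance average of all other
networks' factors (default), which elevates the region's correlation with
every other network uniformly.  The expected correlation of two voxels is
rw within a network and rb across networks; effect-region voxels gain
cross-network correlation monotone in their boost, which elevates their
integration metric.

Per-subject symptom change is generated from the planted boosts:

    change = baseline_slope * (-(boost - boost_mean))
             + longitudinal_slope * (-(boost_followup - boost))
             + N(0, noise_sd),

so higher baseline integration, and integration *decreases* over time, map
to more negative (improved) change scores.  Each subject draws from an RNG
stream derived from the master seed by a fixed offset, so adding subjects
never perturbs earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace

import numpy as np
import pandas as pd

from .phantom import PhantomSpace, default_effect_region

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "simulate_subject_timeseries",
    "simulate_longitudinal_cohort",
    "simulate_null_cohort",
]


class ParameterizationError(ValueError):
    """Requested correlation structure is not realizable."""


CGI_CATEGORIES = ["much improved", "improved", "unchanged", "worse", "much worse"]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the modelled study: 32 FND participants (28 with a
    follow-up scan), 50 healthy controls, ~6.8-month inter-session
    interval, 28F:4M, SSRI/SNRI 13/32, FND-seizure 10/32, and Table-1-level
    questionnaire distributions.  ``baseline_effect_size`` and
    ``longitudinal_effect_size`` are slopes (score points per unit boost)
    linking the planted coupling boosts to the symptom-change score; the
    defaults place the latent brain-behavior correlation near 0.65 for
    each pathway alone (slope * boost_sd = 0.855 * noise_sd).
    """

    n_fnd: int = 32
    n_followup: int = 28
    n_hc: int = 50
    n_timepoints: int = 200
    base_within_r: float = 0.35
    base_between_r: float = 0.10
    effect_network: int = 3
    target_network: int | None = None  # None = spread over all other networks
    effect_region_size: int = 12
    boost_mean: float = 0.4
    boost_sd: float = 0.2
    longitudinal_boost_sd: float = 0.2
    baseline_effect_size: float = 12.5
    longitudinal_effect_size: float = 12.5
    noise_sd: float = 3.0
    voxel_snr_jitter: float = 0.15
    outcome: str = "soms_cd"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.base_between_r <= self.base_within_r < 1.0):
            raise ParameterizationError(
                "need 0 <= base_between_r <= base_within_r < 1, got "
                f"between={self.base_between_r}, within={self.base_within_r}"
            )
        if self.n_timepoints < 20:
            raise ValueError("n_timepoints must be >= 20")
        if self.n_followup > self.n_fnd:
            raise ValueError("n_followup cannot exceed n_fnd")
        if self.outcome not in ("soms_cd", "phq15"):
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.target_network is not None and self.effect_network == self.target_network:
            raise ValueError("effect_network and target_network must differ")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(**d)


@dataclass
class SyntheticCohort:
    """One realized cohort: scans, covariate table, and ground truth."""

    space: PhantomSpace
    config: SimulationConfig
    # scans[(subject_id, timepoint)] -> (n_timepoints, n_grey) array;
    # timepoint in {"baseline", "followup"}
    scans: dict[tuple[str, str], np.ndarray]
    covariates: pd.DataFrame
    truth: dict

    @property
    def fnd_ids(self) -> list[str]:
        tab = self.covariates
        return list(tab.loc[tab["group"] == "FND", "subject_id"])

    @property
    def hc_ids(self) -> list[str]:
        tab = self.covariates
        return list(tab.loc[tab["group"] == "HC", "subject_id"])

    @property
    def followup_ids(self) -> list[str]:
        tab = self.covariates
        return list(
            tab.loc[(tab["group"] == "FND") & tab["has_followup_scan"], "subject_id"]
        )


def simulate_subject_timeseries(
    space: PhantomSpace,
    within_r: float,
    between_r: float,
    region_boost: float,
    n_timepoints: int,
    seed,
    effect_region: np.ndarray | None = None,
    target_network: int | None = None,
    voxel_snr_jitter: float = 0.0,
) -> np.ndarray:
    """One session of grey-matter time series, shape (T, n_grey).

    Columns follow the lexicographic grey-voxel order of ``space``.
    Unlabeled grey voxels (subcortex) form their own latent block.  A
    positive ``region_boost`` adds a cross-network loading to
    ``effect_region`` voxels only: on ``target_network``'s factor if given,
    otherwise spread uniformly over every other network's factor.
    """
    if not (0.0 <= between_r <= within_r < 1.0):
        raise ParameterizationError(
            f"need 0 <= between_r <= within_r < 1, got {between_r}, {within_r}"
        )
    if n_timepoints < 20:
        raise ValueError("n_timepoints must be >= 20")
    if region_boost < 0:
        raise ParameterizationError("region_boost must be >= 0")
    if region_boost > 0 and effect_region is None:
        raise ValueError("region_boost > 0 requires effect_region")

    rng = np.random.default_rng(seed)
    grey_idx = space.grey_index
    n_grey = len(grey_idx)
    # block id per grey voxel: network label, with 0 = unlabeled subcortex
    block = space.labels[grey_idx[:, 0], grey_idx[:, 1], grey_idx[:, 2]]
    n_blocks = space.n_networks + 1

    a = np.sqrt(between_r)
    b = np.sqrt(within_r - between_r)
    c = np.sqrt(1.0 - within_r)

    # Latent factors are orthonormalized within the session (zero mean,
    # unit variance, exactly uncorrelated), so the factor-level correlation
    # targets hold exactly in-sample.  This emulates nuisance-cleaned data:
    # without it, finite-T empirical correlations among factors act as a
    # global connectivity confound shared by every voxel pair.
    raw = rng.standard_normal((n_timepoints, 1 + n_blocks))
    basis = np.column_stack([np.ones(n_timepoints), raw])
    q, _ = np.linalg.qr(basis)
    factors = q[:, 1:] * np.sqrt(n_timepoints)  # g + per-block factors
    g = factors[:, :1]
    f = factors[:, 1 : 1 + n_blocks]

    e = rng.standard_normal((n_timepoints, n_grey))
    e -= q @ (q.T @ e)  # voxel noise orthogonal to mean and factors
    e /= e.std(axis=0)

    signal = a * g + b * f[:, block]
    signal_var = np.full(n_grey, within_r)

    if region_boost > 0:
        beta = np.zeros(n_grey)
        flat = np.ravel_multi_index(grey_idx.T, space.dims)
        region_flat = np.ravel_multi_index(np.asarray(effect_region).T, space.dims)
        beta[np.isin(flat, region_flat)] = region_boost
        if target_network is not None:
            cross = np.broadcast_to(f[:, [target_network]], (n_timepoints, n_grey))
        else:
            # unit-variance average of all *other* networks' factors
            k = space.n_networks
            nets = f[:, 1 : k + 1]
            cross = (nets.sum(axis=1, keepdims=True) - nets[:, block - 1]) / np.sqrt(
                k - 1
            )
        signal = signal + beta * cross
        signal_var = signal_var + beta**2

    # per-voxel signal-amplitude jitter: between-subject (and
    # between-session) variation in voxel-level SNR, the dominant realistic
    # source of metric-map noise across subjects
    if voxel_snr_jitter > 0:
        kappa = 1.0 + rng.normal(0.0, voxel_snr_jitter, n_grey)
        kappa = np.clip(kappa, 0.5, None)
    else:
        kappa = np.ones(n_grey)
    kappa = np.minimum(kappa, 0.995 / np.sqrt(signal_var))

    return kappa * signal + np.sqrt(1.0 - kappa**2 * signal_var) * e


def _clip_round(v, lo, hi):
    return float(np.clip(np.round(v), lo, hi))


def _cgi_category(change: float, rng: np.random.Generator) -> str:
    """Patient-reported global impression from the true change + perception noise."""
    perceived = change + rng.normal(0.0, 2.0)
    if perceived <= -6.0:
        return "much improved"
    if perceived <= -0.75:
        return "improved"
    if perceived < 2.0:
        return "unchanged"
    if perceived < 8.0:
        return "worse"
    return "much worse"


def simulate_longitudinal_cohort(
    space: PhantomSpace, config: SimulationConfig
) -> SyntheticCohort:
    """Generate a full cohort: FND scans at two timepoints, HC scans at one,
    covariate/symptom table, and the ground-truth record."""
    effect_region = default_effect_region(
        space, config.effect_network, config.effect_region_size
    )

    scans: dict[tuple[str, str], np.ndarray] = {}
    rows = []
    boosts = np.zeros(config.n_fnd)
    boost_change = np.zeros(config.n_fnd)
    planted_change = np.zeros(config.n_fnd)

    for i in range(config.n_fnd):
        sid = f"fnd{i:03d}"
        rng = np.random.default_rng([config.seed, 1, i])
        b0 = max(0.0, rng.normal(config.boost_mean, config.boost_sd))
        b1 = max(0.0, b0 + rng.normal(0.0, config.longitudinal_boost_sd))
        planted = (
            config.baseline_effect_size * (-(b0 - config.boost_mean))
            + config.longitudinal_effect_size * (-(b1 - b0))
        )
        change = planted + rng.normal(0.0, config.noise_sd)
        boosts[i], boost_change[i] = b0, b1 - b0
        planted_change[i] = planted

        has_followup = i < config.n_followup
        scans[(sid, "baseline")] = simulate_subject_timeseries(
            space, config.base_within_r, config.base_between_r, b0,
            config.n_timepoints, [config.seed, 2, i, 0],
            effect_region, config.target_network, config.voxel_snr_jitter,
        )
        if has_followup:
            scans[(sid, "followup")] = simulate_subject_timeseries(
                space, config.base_within_r, config.base_between_r, b1,
                config.n_timepoints, [config.seed, 2, i, 1],
                effect_region, config.target_network, config.voxel_snr_jitter,
            )

        soms0 = _clip_round(rng.normal(6.6, 6.3), 0, 28)
        phq0 = _clip_round(rng.normal(11.8, 5.7), 0, 30)
        if config.outcome == "soms_cd":
            soms1 = _clip_round(soms0 + change, 0, 28)
            phq1 = _clip_round(phq0 + rng.normal(0.4, 3.0), 0, 30)
            realized = soms1 - soms0
        else:
            phq1 = _clip_round(phq0 + change, 0, 30)
            soms1 = _clip_round(soms0 + rng.normal(-0.9, 4.0), 0, 28)
            realized = phq1 - phq0
        bdi0 = _clip_round(rng.normal(15.3, 11.4), 0, 63)
        stai0 = _clip_round(rng.normal(82.5, 23.2), 40, 160)
        rows.append({
            "subject_id": sid,
            "group": "FND",
            "age": float(np.clip(rng.normal(42.4, 13.3), 18, 80)),
            "sex": int(rng.random() < 28 / 32),  # female=1
            "ssri_snri": int(rng.random() < 13 / 32),
            "fnd_seizure": int(rng.random() < 10 / 32),
            "interval_months": float(np.clip(rng.normal(6.8, 0.8), 4.5, 9.5)),
            "mean_fd_baseline": float(max(0.02, rng.normal(0.073, 0.041))),
            "mean_fd_followup": float(max(0.02, rng.normal(0.076, 0.032))),
            "has_followup_scan": has_followup,
            "soms_cd_baseline": soms0,
            "soms_cd_followup": soms1,
            "phq15_baseline": phq0,
            "phq15_followup": phq1,
            "bdi_baseline": bdi0,
            "bdi_followup": _clip_round(bdi0 + rng.normal(-3.2, 7.0), 0, 63),
            "stai_baseline": stai0,
            "stai_followup": _clip_round(stai0 + rng.normal(-5.2, 12.0), 40, 160),
            "pcl5_baseline": _clip_round(rng.normal(23.4, 17.9), 0, 80),
            "ctq_abuse": _clip_round(rng.normal(31.0, 14.7), 15, 75),
            "ctq_neglect": _clip_round(rng.normal(21.6, 8.5), 10, 50),
            "cgi_i": _cgi_category(realized, rng),
        })

    for i in range(config.n_hc):
        sid = f"hc{i:03d}"
        rng = np.random.default_rng([config.seed, 3, i])
        scans[(sid, "baseline")] = simulate_subject_timeseries(
            space, config.base_within_r, config.base_between_r, 0.0,
            config.n_timepoints, [config.seed, 4, i],
            voxel_snr_jitter=config.voxel_snr_jitter,
        )
        rows.append({
            "subject_id": sid,
            "group": "HC",
            "age": float(np.clip(rng.normal(42.4, 13.3), 18, 80)),
            "sex": int(rng.random() < 28 / 32),
            "ssri_snri": 0,
            "fnd_seizure": np.nan,
            "interval_months": np.nan,
            "mean_fd_baseline": float(max(0.02, rng.normal(0.073, 0.041))),
            "mean_fd_followup": np.nan,
            "has_followup_scan": False,
            "soms_cd_baseline": np.nan, "soms_cd_followup": np.nan,
            "phq15_baseline": np.nan, "phq15_followup": np.nan,
            "bdi_baseline": np.nan, "bdi_followup": np.nan,
            "stai_baseline": np.nan, "stai_followup": np.nan,
            "pcl5_baseline": np.nan, "ctq_abuse": np.nan, "ctq_neglect": np.nan,
            "cgi_i": np.nan,
        })

    covariates = pd.DataFrame(rows)
    truth = {
        "boosts": boosts,
        "boost_change": boost_change,
        "planted_change": planted_change,
        "effect_region": effect_region,
        "effect_network": config.effect_network,
        "target_network": config.target_network,
    }
    return SyntheticCohort(space, config, scans, covariates, truth)


def simulate_null_cohort(space: PhantomSpace, config: SimulationConfig) -> SyntheticCohort:
    """Cohort with no planted effect anywhere: zero boosts, zero slopes.

    Used to calibrate the type-I error of the downstream pipeline.
    """
    null_cfg = replace(
        config,
        baseline_effect_size=0.0,
        longitudinal_effect_size=0.0,
        boost_mean=0.0,
        boost_sd=0.0,
        longitudinal_boost_sd=0.0,
    )
    return simulate_longitudinal_cohort(space, null_cfg)
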