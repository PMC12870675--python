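"""End-to-end pipeline: simulate -> metrics -> GLM -> cluster correction ->
seed post-hocs -> cohort statistics -> healthy-control contextualization.

The driver consumes a :class:`PipelineConfig`, runs the baseline-predictor
and longitudinal-change analyses for the configured metric and outcome,
and emits a JSON-serializable report plus (optionally) NIfTI maps and TSV
tables under an output directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort_stats as cs
from . import seeds as sd
from .glm import (
    apply_cluster_correction,
    cluster_null_distribution,
    cluster_subject_means,
    estimate_map_smoothness,
    fit_brain_behavior_glm,
)
from .metrics import (
    ConnectivityMatrix,
    compute_fc_matrix,
    flag_outlier_subjects,
    weighted_degree_map,
)
from .phantom import make_phantom_space
from .simulate import SimulationConfig, SyntheticCohort, simulate_longitudinal_cohort

log = logging.getLogger("fndconn")

__all__ = ["PipelineConfig", "run_pipeline", "metric_matrix", "subject_metrics"]


@dataclass
class PipelineConfig:
    """Everything one run needs; every field lands in the report."""

    dims: tuple[int, int, int] = (12, 12, 10)
    n_networks: int = 7
    outcome: str = "soms_cd"
    metric: str = "integration"
    z_thresh: float = 1.96
    alpha: float = 0.05
    n_iter: int = 10_000
    connectivity: int = 26
    seed: int = 0
    synthetic: SimulationConfig = field(default_factory=SimulationConfig)
    output_dir: str | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["dims"] = list(self.dims)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        d["dims"] = tuple(d.get("dims", (12, 12, 10)))
        if isinstance(d.get("synthetic"), dict):
            d["synthetic"] = SimulationConfig(**d["synthetic"])
        return cls(**d)


def _session_fc(cohort: SyntheticCohort, sid: str, timepoint: str):
    """Whole-grey FC matrix plus its isocortical submatrix.

    Pearson correlations are unaffected by which other voxels are present,
    so the isocortical matrix is taken as a submatrix of the grey one.
    """
    space = cohort.space
    ts = cohort.scans[(sid, timepoint)]
    grey_fc = compute_fc_matrix(ts, space.grey_index, "grey")
    sel = space.iso_in_grey
    iso_fc = ConnectivityMatrix(
        grey_fc.weights[np.ix_(sel, sel)], space.iso_index, "iso"
    )
    return grey_fc, iso_fc


def subject_metrics(cohort: SyntheticCohort, sid: str, timepoint: str) -> dict:
    """All three metric maps for one subject session."""
    from .metrics import integration_map, segregation_map

    space = cohort.space
    grey_fc, iso_fc = _session_fc(cohort, sid, timepoint)
    return {
        "weighted_degree": weighted_degree_map(grey_fc, sid, timepoint),
        "integration": integration_map(iso_fc, space.labels, sid, timepoint),
        "segregation": segregation_map(iso_fc, space.labels, sid, timepoint),
    }


def metric_matrix(
    cohort: SyntheticCohort, metric: str, analysis: str, subjects: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """(n_subjects, V) metric matrix for one analysis.

    ``analysis``: "baseline_predictor" uses baseline maps;
    "longitudinal_change" uses follow-up minus baseline maps;
    "followup_session" uses the follow-up maps themselves.
    Returns (matrix, voxel_index).
    """
    from .metrics import integration_map, metric_change_map, segregation_map

    space = cohort.space
    rows = []
    for sid in subjects:
        def one(timepoint):
            grey_fc, iso_fc = _session_fc(cohort, sid, timepoint)
            if metric == "weighted_degree":
                return weighted_degree_map(grey_fc, sid, timepoint)
            if metric == "integration":
                return integration_map(iso_fc, space.labels, sid, timepoint)
            if metric == "segregation":
                return segregation_map(iso_fc, space.labels, sid, timepoint)
            raise ValueError(f"unknown metric {metric!r}")

        if analysis == "baseline_predictor":
            m = one("baseline")
        elif analysis == "followup_session":
            m = one("followup")
        elif analysis == "longitudinal_change":
            m = metric_change_map(one("followup"), one("baseline"))
        else:
            raise ValueError(f"unknown analysis {analysis!r}")
        rows.append(m.values)
    voxel_index = space.grey_index if metric == "weighted_degree" else space.iso_index
    return np.stack(rows), voxel_index


def _covariate_frame(
    cohort: SyntheticCohort, subjects: list[str], outcome: str, analysis: str
) -> pd.DataFrame:
    tab = cohort.covariates.set_index("subject_id").loc[subjects]
    fd = (
        tab["mean_fd_baseline"]
        if analysis == "baseline_predictor"
        else (tab["mean_fd_baseline"] + tab["mean_fd_followup"]) / 2.0
    )
    return pd.DataFrame({
        "age": tab["age"].to_numpy(float),
        "sex": tab["sex"].to_numpy(float),
        "ssri_snri": tab["ssri_snri"].to_numpy(float),
        "mean_fd": fd.to_numpy(float),
        "interval": tab["interval_months"].to_numpy(float),
        "baseline_score": tab[f"{outcome}_baseline"].to_numpy(float),
        "fnd_seizure": tab["fnd_seizure"].to_numpy(float),
        "bdi_baseline": tab["bdi_baseline"].to_numpy(float),
        "stai_baseline": tab["stai_baseline"].to_numpy(float),
        "pcl5_baseline": tab["pcl5_baseline"].to_numpy(float),
        "ctq_abuse": tab["ctq_abuse"].to_numpy(float),
        "ctq_neglect": tab["ctq_neglect"].to_numpy(float),
        "delta_bdi": (tab["bdi_followup"] - tab["bdi_baseline"]).to_numpy(float),
        "delta_stai": (tab["stai_followup"] - tab["stai_baseline"]).to_numpy(float),
    }, index=subjects)


def analyze(
    cohort: SyntheticCohort,
    metric: str,
    analysis: str,
    outcome: str,
    n_iter: int = 10_000,
    z_thresh: float = 1.96,
    alpha: float = 0.05,
    connectivity: int = 26,
    seed: int = 0,
) -> dict:
    """One brain-behavior analysis: GLM, smoothness, Monte-Carlo null,
    cluster correction.  Returns a dict of intermediate objects."""
    space = cohort.space
    subjects = (
        cohort.fnd_ids if analysis == "baseline_predictor" else cohort.followup_ids
    )
    M, voxel_index = metric_matrix(cohort, metric, analysis, subjects)
    cov = _covariate_frame(cohort, subjects, outcome, analysis)
    tab = cohort.covariates.set_index("subject_id").loc[subjects]
    y = (tab[f"{outcome}_followup"] - tab[f"{outcome}_baseline"]).to_numpy(float)

    res = fit_brain_behavior_glm((M, voxel_index), y, cov, outcome_name=outcome)
    mask = space.grey_mask if metric == "weighted_degree" else space.iso_mask
    fwhm = estimate_map_smoothness(res.residuals, mask, voxel_index)
    null = cluster_null_distribution(
        mask, fwhm, z_thresh=z_thresh, n_iter=n_iter, seed=seed,
        alpha=alpha, connectivity=connectivity,
    )
    table, sig = apply_cluster_correction(res.z, mask, null, voxel_index)
    return {
        "subjects": subjects, "metric_matrix": M, "voxel_index": voxel_index,
        "covariates": cov, "outcome": y, "glm": res, "fwhm": fwhm,
        "null": null, "cluster_table": table, "sig_mask": sig, "mask": mask,
    }


#: post-hoc covariate sensitivity sets for the primary models
SENSITIVITY_SETS = {
    "phenotype": ["fnd_seizure"],
    "affective_baseline": ["bdi_baseline", "stai_baseline", "pcl5_baseline"],
    "childhood_trauma": ["ctq_abuse", "ctq_neglect"],
}
SENSITIVITY_SETS_LONGITUDINAL = {
    **SENSITIVITY_SETS,
    "bdi_change": ["delta_bdi"],
    "stai_change": ["delta_stai"],
}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full synthetic study and return the report bundle.

    Stages: simulate -> weighted-degree outlier screen -> baseline and
    longitudinal brain-behavior analyses -> integration seed post-hocs ->
    cohort statistics -> overlap-voxel HC contextualization.  Re-running
    with the same config reproduces every number.
    """
    t0 = time.time()
    space = make_phantom_space(config.dims, config.n_networks, config.seed)
    cohort = simulate_longitudinal_cohort(space, config.synthetic)
    log.info("simulated cohort: %d FND / %d HC on %d grey voxels",
             config.synthetic.n_fnd, config.synthetic.n_hc, space.n)

    report: dict = {
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps({k: v for k, v in config.to_dict().items()
                        if k != "output_dir"}, sort_keys=True).encode()
        ).hexdigest()[:16],
        "n_grey_voxels": space.n,
        "n_iso_voxels": space.n_iso,
    }

    # outlier screen on grey-mean weighted-degree at baseline
    wd_means = {}
    for sid in cohort.fnd_ids:
        grey_fc, _ = _session_fc(cohort, sid, "baseline")
        wd_means[sid] = float(grey_fc.weights.sum(axis=1).mean())
    outliers = flag_outlier_subjects(wd_means)
    report["wd_outliers"] = sorted(outliers)

    results = {}
    for analysis in ("baseline_predictor", "longitudinal_change"):
        r = analyze(
            cohort, config.metric, analysis, config.outcome,
            n_iter=config.n_iter, z_thresh=config.z_thresh,
            alpha=config.alpha, connectivity=config.connectivity,
            seed=config.seed,
        )
        results[analysis] = r
        report[analysis] = {
            "n_subjects": len(r["subjects"]),
            "df": r["glm"].df,
            "fwhm": list(np.round(r["fwhm"], 3)),
            "extent_threshold": r["null"].extent_threshold,
            "n_clusters": int(len(r["cluster_table"])),
            "n_sig_voxels": int(r["sig_mask"].sum()),
            "clusters": r["cluster_table"].to_dict("records"),
        }
        log.info("%s: %d cluster(s), %d significant voxel(s)",
                 analysis, len(r["cluster_table"]), int(r["sig_mask"].sum()))

    # seed post-hoc on the integration findings (baseline analysis)
    report["seed_posthoc"] = {}
    if config.metric == "integration":
        sig = results["baseline_predictor"]["sig_mask"]
        counts = sd.assign_cluster_voxels_to_networks(
            sig, space.labels, space.n_networks
        )
        top = sd.select_top_networks(counts, k=3)
        report["seed_posthoc"] = {"network_counts": counts, "top_networks": top}

    # cohort statistics
    tab = cohort.covariates
    fnd = tab[tab["group"] == "FND"]
    cgi_counts = [int((fnd["cgi_i"] == c).sum())
                  for c in ("much improved", "improved", "unchanged",
                            "worse", "much worse")]
    stats_block = {
        "cgi_counts": cgi_counts,
        "cgi_summary": cs.summarize_cgi(cgi_counts),
    }
    paired = {}
    for score, method in (("soms_cd", "wilcoxon_signed_rank"),
                          ("phq15", "paired_t"),
                          ("bdi", "wilcoxon_signed_rank"),
                          ("stai", "paired_t")):
        r = cs.paired_test(fnd[f"{score}_baseline"], fnd[f"{score}_followup"],
                           method)
        paired[score] = {"test": r.test, "statistic": r.statistic, "p": r.p}
    rej, p_adj = cs.bh_fdr([paired[s]["p"] for s in paired])
    for (s, block), pa, rj in zip(paired.items(), p_adj, rej):
        block["p_fdr"] = float(pa)
        block["reject_fdr"] = bool(rj)
    stats_block["paired_tests"] = paired
    followers = fnd[fnd["has_followup_scan"]]
    fd_t = cs.paired_test(followers["mean_fd_baseline"],
                          followers["mean_fd_followup"], "paired_t")
    stats_block["fd_paired_t"] = {"t": fd_t.statistic, "df": fd_t.df, "p": fd_t.p}
    report["cohort_stats"] = stats_block

    # overlap-voxel HC contextualization (integration analyses only make
    # sense here, but the machinery is metric-agnostic)
    overlap = cs.overlap_mask(results["baseline_predictor"]["sig_mask"],
                              results["longitudinal_change"]["sig_mask"])
    report["overlap_n_voxels"] = int(overlap.sum())
    if overlap.any():
        fu = cohort.followup_ids
        M_base, vi = metric_matrix(cohort, config.metric, "baseline_predictor", fu)
        M_fol, _ = metric_matrix(cohort, config.metric, "followup_session", fu)
        hc_M = (
            metric_matrix(cohort, config.metric, "baseline_predictor",
                          cohort.hc_ids)[0]
            if cohort.hc_ids else np.empty((0, M_base.shape[1]))
        )
        base_means = cluster_subject_means(overlap, M_base, vi)
        fol_means = cluster_subject_means(overlap, M_fol, vi)
        hc_means = (cluster_subject_means(overlap, hc_M, vi)
                    if len(hc_M) else np.array([]))
        t2 = tab.set_index("subject_id").loc[fu]
        change = (t2[f"{config.outcome}_followup"]
                  - t2[f"{config.outcome}_baseline"]).to_numpy(float)
        improved, worsened = cs.stratify_extremes(change, list(range(len(fu))))
        if len(hc_means):
            ctx = cs.hc_contextualize(base_means, fol_means, hc_means,
                                      improved, worsened)
            report["hc_contextualization"] = ctx.to_dict("records")

    report["runtime_s"] = round(time.time() - t0, 2)

    if config.output_dir:
        _write_bundle(config, space, cohort, results, report)
    return report


def _write_bundle(config, space, cohort, results, report) -> None:
    from . import io as fio

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    fio.write_volume(space.grey_mask.astype(np.uint8), out / "grey_mask.nii.gz")
    fio.write_volume(space.iso_mask.astype(np.uint8), out / "iso_mask.nii.gz")
    fio.write_volume(space.labels.astype(np.int16), out / "network_labels.nii.gz")
    fio.write_cohort_table(cohort.covariates, out / "cohort.tsv")
    fio.save_config(config, out / "config.yaml")
    fio.save_truth(cohort.truth, out / "truth.json")
    for analysis, r in results.items():
        vol = np.zeros(space.dims)
        vi = r["voxel_index"]
        vol[vi[:, 0], vi[:, 1], vi[:, 2]] = r["glm"].z
        fio.write_volume(vol, out / f"{analysis}_zmap.nii.gz")
        fio.write_volume(r["sig_mask"].astype(np.uint8),
                         out / f"{analysis}_sig_mask.nii.gz")
        r["cluster_table"].to_csv(out / f"{analysis}_clusters.tsv",
                                  sep="\t", index=False)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=str)
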