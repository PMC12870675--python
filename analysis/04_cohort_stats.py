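#!/usr/bin/env python
"""Clinical characterization of the synthetic cohort and healthy-control
contextualization of the overlap voxels.

Reproduces the clinical-table statistics (CGI-I summary, paired pre-post
tests with BH-FDR, framewise-displacement paired t), then intersects the
baseline-predictor and longitudinal-change integration masks and compares
mean integration in FND vs HC subjects, full-cohort and stratified by the
extreme responders.  Writes results/cohort_stats/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from fndconn import cohort_stats as cs
from fndconn.glm import cluster_subject_means
from fndconn.phantom import make_phantom_space
from fndconn.pipeline import analyze, metric_matrix
from fndconn.simulate import SimulationConfig, simulate_longitudinal_cohort

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort_stats"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    space = make_phantom_space((12, 12, 10), n_networks=7, seed=SEED)
    cohort = simulate_longitudinal_cohort(space, SimulationConfig(seed=SEED))
    tab = cohort.covariates
    fnd = tab[tab["group"] == "FND"]

    report: dict = {}

    cgi_counts = [int((fnd["cgi_i"] == c).sum())
                  for c in ("much improved", "improved", "unchanged",
                            "worse", "much worse")]
    report["cgi_counts"] = cgi_counts
    report["cgi_summary"] = cs.summarize_cgi(cgi_counts)
    print(f"CGI-I: counts {cgi_counts} -> {report['cgi_summary']}")

    paired = {}
    for score, method in (("soms_cd", "wilcoxon_signed_rank"),
                          ("phq15", "paired_t"),
                          ("bdi", "wilcoxon_signed_rank"),
                          ("stai", "paired_t")):
        r = cs.paired_test(fnd[f"{score}_baseline"],
                           fnd[f"{score}_followup"], method)
        paired[score] = {"test": r.test, "statistic": round(r.statistic, 3),
                         "p": round(r.p, 4)}
    _, p_adj = cs.bh_fdr([paired[s]["p"] for s in paired])
    for (s, blk), pa in zip(paired.items(), p_adj):
        blk["p_fdr"] = round(float(pa), 4)
    report["paired_tests"] = paired
    for s, blk in paired.items():
        print(f"  {s}: {blk['test']} statistic={blk['statistic']} "
              f"p={blk['p']} (FDR {blk['p_fdr']})")

    followers = fnd[fnd["has_followup_scan"]]
    fd = cs.paired_test(followers["mean_fd_baseline"],
                        followers["mean_fd_followup"], "paired_t")
    report["fd_paired_t"] = {"t": round(fd.statistic, 3), "df": fd.df,
                             "p": round(fd.p, 3)}
    print(f"  head motion: t({fd.df})={fd.statistic:.2f}, p={fd.p:.2f}")

    # overlap voxels across baseline and longitudinal integration analyses
    base = analyze(cohort, "integration", "baseline_predictor", "soms_cd",
                   n_iter=2000, seed=SEED)
    longi = analyze(cohort, "integration", "longitudinal_change", "soms_cd",
                    n_iter=2000, seed=SEED)
    overlap = cs.overlap_mask(base["sig_mask"], longi["sig_mask"])
    report["overlap_n_voxels"] = int(overlap.sum())
    print(f"overlap voxels across baseline and longitudinal analyses: "
          f"{int(overlap.sum())}")

    if overlap.any():
        fu = cohort.followup_ids
        M_base, vi = metric_matrix(cohort, "integration",
                                   "baseline_predictor", fu)
        M_fol, _ = metric_matrix(cohort, "integration", "followup_session", fu)
        M_hc, _ = metric_matrix(cohort, "integration", "baseline_predictor",
                                cohort.hc_ids)
        base_means = cluster_subject_means(overlap, M_base, vi)
        fol_means = cluster_subject_means(overlap, M_fol, vi)
        hc_means = cluster_subject_means(overlap, M_hc, vi)
        t2 = tab.set_index("subject_id").loc[fu]
        change = (t2["soms_cd_followup"] - t2["soms_cd_baseline"]).to_numpy()
        improved, worsened = cs.stratify_extremes(change, list(range(len(fu))))
        ctx = cs.hc_contextualize(base_means, fol_means, hc_means,
                                  improved, worsened)
        ctx.to_csv(OUT / "hc_contextualization.tsv", sep="\t", index=False)
        report["hc_contextualization"] = ctx.to_dict("records")
        for _, row in ctx.iterrows():
            star = " *" if row["p"] < 0.05 else ""
            print(f"  {row['stratum']:>13s} {row['timepoint']:>9s}: "
                  f"U={row['U']:.0f}, p={row['p']:.3f}{star}")

    with open(OUT / "report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    print(f"wrote cohort statistics to {OUT}")


if __name__ == "__main__":
    main()
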