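#!/usr/bin/env python
"""Seed-based characterization of the integration findings.

Takes the significant voxels of the baseline integration analysis, labels
them by network, builds seed ROIs for the top networks, computes
seed-to-voxel Fisher-z maps per subject at both timepoints, tests them
against zero at the group level, counts significant between-network
voxels, and compares baseline vs follow-up percentages.  Writes tidy
tables under results/seed_posthoc/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from fndconn.phantom import make_phantom_space
from fndconn.pipeline import analyze
from fndconn.seeds import (
    assign_cluster_voxels_to_networks,
    compare_timepoint_connection_counts,
    count_between_network_connections,
    group_seed_glm,
    make_seed,
    seed_to_voxel_zmap,
    select_top_networks,
)
from fndconn.simulate import SimulationConfig, simulate_longitudinal_cohort

OUT = Path(__file__).resolve().parent.parent / "results" / "seed_posthoc"
SEED = 1
N_ITER = 1000


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    space = make_phantom_space((12, 12, 10), n_networks=7, seed=SEED)
    cohort = simulate_longitudinal_cohort(
        space, SimulationConfig(seed=SEED, n_hc=0))

    primary = analyze(cohort, "integration", "baseline_predictor", "soms_cd",
                      n_iter=2000, seed=SEED)
    counts = assign_cluster_voxels_to_networks(primary["sig_mask"],
                                               space.labels)
    top = select_top_networks(counts, k=3)
    pd.DataFrame([
        {"network": k, "n_significant_voxels": v} for k, v in counts.items()
    ]).to_csv(OUT / "network_assignment.tsv", sep="\t", index=False)
    print(f"significant integration voxels per network: "
          f"{ {k: v for k, v in counts.items() if v} }; top: {top}")

    tab = cohort.covariates.set_index("subject_id")
    sizes = {k: int((space.labels == k).sum()) for k in range(1, 8)}
    comparisons = []
    for net in top:
        seed_roi = make_seed(primary["sig_mask"], space.labels, net,
                             "baseline_predictor")
        per_tp_counts = {}
        for tp, subjects in (("baseline", cohort.fnd_ids),
                             ("followup", cohort.followup_ids)):
            z_maps = np.stack([
                seed_to_voxel_zmap(cohort.scans[(sid, tp)], seed_roi,
                                   space.grey_index, space.iso_in_grey)
                for sid in subjects
            ])
            sub = tab.loc[subjects]
            cov = pd.DataFrame({
                "age": sub["age"].to_numpy(float),
                "sex": sub["sex"].to_numpy(float),
                "ssri_snri": sub["ssri_snri"].to_numpy(float),
                "mean_fd": sub[f"mean_fd_{tp}"].to_numpy(float),
            })
            _, sig, _ = group_seed_glm(z_maps, cov, space.iso_mask,
                                       space.iso_index, n_iter=N_ITER,
                                       seed=SEED)
            per_tp_counts[tp] = count_between_network_connections(
                sig, space.labels, net, timepoint=tp)
        cmp_tab = compare_timepoint_connection_counts(
            per_tp_counts["baseline"], per_tp_counts["followup"], sizes)
        comparisons.append(cmp_tab)
        decreased = cmp_tab.loc[cmp_tab["decreased"], "target_network"]
        print(f"seed network {net}: decreased follow-up connectivity to "
              f"networks {sorted(decreased.tolist()) or 'none'}")
    if comparisons:
        pd.concat(comparisons).to_csv(OUT / "timepoint_comparison.tsv",
                                      sep="\t", index=False)
        print(f"wrote seed post-hoc tables to {OUT}")


if __name__ == "__main__":
    main()
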