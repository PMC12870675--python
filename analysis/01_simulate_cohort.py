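#!/usr/bin/env python
"""Generate the synthetic study: a phantom brain space and a longitudinal
FND + healthy-control cohort with a planted baseline integration effect.

Writes masks, network labels, the cohort table, the simulation config and
the ground-truth record under results/cohort/.  Scans stay in memory for
the downstream scripts, which regenerate them deterministically from the
same seed; only the compact artifacts are persisted.
"""

from pathlib import Path

import numpy as np

from fndconn import io as fio
from fndconn.phantom import make_phantom_space
from fndconn.simulate import SimulationConfig, simulate_longitudinal_cohort

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    space = make_phantom_space((12, 12, 10), n_networks=7, seed=SEED)
    config = SimulationConfig(seed=SEED)
    cohort = simulate_longitudinal_cohort(space, config)

    fio.write_volume(space.grey_mask.astype(np.uint8), OUT / "grey_mask.nii.gz")
    fio.write_volume(space.iso_mask.astype(np.uint8), OUT / "iso_mask.nii.gz")
    fio.write_volume(space.labels.astype(np.int16), OUT / "network_labels.nii.gz")
    fio.write_cohort_table(cohort.covariates, OUT / "cohort.tsv")
    fio.save_config(config, OUT / "simulation.yaml")
    fio.save_truth(cohort.truth, OUT / "truth.json")

    tab = cohort.covariates
    fnd = tab[tab["group"] == "FND"]
    change = fnd["soms_cd_followup"] - fnd["soms_cd_baseline"]
    print(f"phantom: {space.n} grey voxels, {space.n_iso} isocortical, "
          f"7 networks")
    print(f"cohort: {len(fnd)} FND ({int(fnd['has_followup_scan'].sum())} "
          f"with follow-up scan), {(tab['group'] == 'HC').sum()} HC")
    print(f"core symptom change (SOMS:CD): mean {change.mean():+.1f}, "
          f"sd {change.std():.1f}, range [{change.min():+.0f}, "
          f"{change.max():+.0f}]")
    print(f"planted effect: {len(cohort.truth['effect_region'])} voxels in "
          f"network {cohort.truth['effect_network']}")
    print(f"wrote cohort artifacts to {OUT}")


if __name__ == "__main__":
    main()
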