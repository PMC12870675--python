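import numpy as np
import pandas as pd
import pytest

from fndconn.phantom import default_effect_region
from fndconn.seeds import (
    NetworkConnectionCounts,
    SeedDefinition,
    assign_cluster_voxels_to_networks,
    compare_timepoint_connection_counts,
    count_between_network_connections,
    group_seed_glm,
    make_seed,
    seed_to_voxel_zmap,
    select_top_networks,
)
from fndconn.simulate import SimulationConfig, simulate_longitudinal_cohort


class TestNetworkAssignment:
    def test_histogram_over_significant_voxels(self, space):
        mask = np.zeros(space.dims, dtype=bool)
        picked = {5: 3, 6: 2, 7: 1}
        for net, k in picked.items():
            vox = np.argwhere(space.labels == net)[:k]
            mask[vox[:, 0], vox[:, 1], vox[:, 2]] = True
        counts = assign_cluster_voxels_to_networks(mask, space.labels)
        assert {k: v for k, v in counts.items() if v} == picked

    def test_empty_mask_gives_zero_counts(self, space):
        counts = assign_cluster_voxels_to_networks(
            np.zeros(space.dims, dtype=bool), space.labels)
        assert sum(counts.values()) == 0

    def test_counts_conserve_mask_size(self, space, rng):
        mask = np.zeros(space.dims, dtype=bool)
        iso = np.argwhere(space.iso_mask)
        sel = iso[rng.choice(len(iso), 40, replace=False)]
        mask[sel[:, 0], sel[:, 1], sel[:, 2]] = True
        counts = assign_cluster_voxels_to_networks(mask, space.labels)
        assert sum(counts.values()) == 40

    def test_voxels_outside_labels_excluded_with_warning(self, space):
        mask = np.zeros(space.dims, dtype=bool)
        sub = np.argwhere(space.grey_mask & ~space.iso_mask)[:3]
        mask[sub[:, 0], sub[:, 1], sub[:, 2]] = True
        with pytest.warns(RuntimeWarning, match="outside the labeled"):
            counts = assign_cluster_voxels_to_networks(mask, space.labels)
        assert sum(counts.values()) == 0


class TestTopNetworks:
    def test_ties_break_by_ascending_index(self):
        assert select_top_networks({1: 10, 4: 7, 5: 7, 7: 1}, k=3) == [1, 4, 5]

    def test_fewer_nonzero_than_k_warns(self):
        with pytest.warns(RuntimeWarning):
            assert select_top_networks({2: 5, 3: 0}, k=3) == [2]

    def test_all_zero_returns_empty(self):
        with pytest.warns(RuntimeWarning):
            assert select_top_networks({1: 0, 2: 0}, k=3) == []


class TestSeedToVoxelMap:
    def test_fisher_transform_properties(self):
        r = np.linspace(-0.99, 0.99, 41)
        z = np.arctanh(r)
        assert np.all(np.diff(z) > 0)
        assert np.allclose(z, -np.arctanh(-r))
        assert np.arctanh(0.0) == 0.0
        # closed form: z = 0.5 ln((1+r)/(1-r))
        assert np.allclose(z, 0.5 * np.log((1 + r) / (1 - r)))

    def test_known_correlation_maps_to_atanh(self, space, small_cohort):
        ts = small_cohort.scans[("fnd000", "baseline")]
        region = default_effect_region(space, 2, 5)
        seed = SeedDefinition(2, region)
        zmap = seed_to_voxel_zmap(ts, seed, space.grey_index, space.iso_in_grey)
        # oracle at one voxel
        in_seed = np.zeros(space.dims, dtype=bool)
        in_seed[region[:, 0], region[:, 1], region[:, 2]] = True
        sel = in_seed[space.grey_index[:, 0], space.grey_index[:, 1],
                      space.grey_index[:, 2]]
        seed_ts = ts[:, sel].mean(axis=1)
        iso_cols = np.flatnonzero(space.iso_in_grey)
        v = 123
        r = np.corrcoef(seed_ts, ts[:, iso_cols[v]])[0, 1]
        assert zmap[v] == pytest.approx(np.arctanh(r), abs=1e-10)

    def test_voxel_equal_to_seed_average_clipped_finite(self, space):
        rng = np.random.default_rng(0)
        T, n = 50, space.n
        ts = rng.standard_normal((T, n))
        region = default_effect_region(space, 1, 1)
        seed = SeedDefinition(1, region)
        # make one iso voxel identical to the (single-voxel) seed series
        sel = np.zeros(space.dims, dtype=bool)
        sel[region[0, 0], region[0, 1], region[0, 2]] = True
        seed_col = np.flatnonzero(
            sel[space.grey_index[:, 0], space.grey_index[:, 1],
                space.grey_index[:, 2]])[0]
        iso_cols = np.flatnonzero(space.iso_in_grey)
        ts[:, iso_cols[7]] = ts[:, seed_col]
        zmap = seed_to_voxel_zmap(ts, seed, space.grey_index, space.iso_in_grey)
        assert np.isfinite(zmap[7]) and zmap[7] > 8.0

    def test_zero_variance_seed_flagged(self, space):
        ts = np.ones((30, space.n))
        region = default_effect_region(space, 1, 3)
        seed = SeedDefinition(1, region)
        with pytest.warns(RuntimeWarning, match="zero-variance seed"):
            zmap = seed_to_voxel_zmap(ts, seed, space.grey_index,
                                      space.iso_in_grey)
        assert np.isnan(zmap).all()


class TestConnectionCounts:
    def test_seed_network_voxels_excluded(self, space):
        mask = np.zeros(space.dims, dtype=bool)
        vox1 = np.argwhere(space.labels == 1)[:2]
        vox2 = np.argwhere(space.labels == 2)[:1]
        vox3 = np.argwhere(space.labels == 3)[:2]
        for v in (vox1, vox2, vox3):
            mask[v[:, 0], v[:, 1], v[:, 2]] = True
        counts = count_between_network_connections(mask, space.labels, 1)
        assert 1 not in counts.counts
        assert counts.counts[2] == 1 and counts.counts[3] == 2
        assert sum(counts.counts.values()) == mask.sum() - 2

    def test_all_within_seed_gives_zero(self, space):
        mask = np.zeros(space.dims, dtype=bool)
        vox = np.argwhere(space.labels == 4)[:5]
        mask[vox[:, 0], vox[:, 1], vox[:, 2]] = True
        counts = count_between_network_connections(mask, space.labels, 4)
        assert sum(counts.counts.values()) == 0


class TestTimepointComparison:
    sizes = {2: 100, 3: 50}

    def test_identical_counts_zero_delta(self):
        a = NetworkConnectionCounts(1, {2: 10, 3: 5}, "baseline")
        b = NetworkConnectionCounts(1, {2: 10, 3: 5}, "followup")
        tab = compare_timepoint_connection_counts(a, b, self.sizes)
        assert (tab["delta_pct"] == 0).all()
        assert not tab["decreased"].any()

    def test_decrease_flagged_with_percent_arithmetic(self):
        a = NetworkConnectionCounts(1, {2: 10}, "baseline")
        b = NetworkConnectionCounts(1, {2: 4}, "followup")
        tab = compare_timepoint_connection_counts(a, b, self.sizes)
        row = tab.iloc[0]
        assert row["baseline_pct"] == 10.0
        assert row["followup_pct"] == 4.0
        assert row["delta_pct"] == -6.0
        assert row["decreased"]

    def test_empty_baseline_counts(self):
        a = NetworkConnectionCounts(1, {}, "baseline")
        b = NetworkConnectionCounts(1, {3: 5}, "followup")
        tab = compare_timepoint_connection_counts(a, b, self.sizes)
        assert tab.iloc[0]["delta_pct"] == tab.iloc[0]["followup_pct"]

    def test_mismatched_seed_rejected(self):
        a = NetworkConnectionCounts(1, {2: 1}, "baseline")
        b = NetworkConnectionCounts(2, {3: 1}, "followup")
        with pytest.raises(ValueError):
            compare_timepoint_connection_counts(a, b, self.sizes)


class TestGroupSeedGlm:
    def test_all_zero_maps_give_empty_mask(self, space):
        n = 14
        z_maps = np.zeros((n, space.n_iso))
        rng = np.random.default_rng(0)
        z_maps += rng.standard_normal(z_maps.shape) * 1e-6
        cov = pd.DataFrame({
            "age": rng.uniform(20, 60, n), "sex": rng.integers(0, 2, n),
            "ssri_snri": rng.integers(0, 2, n), "mean_fd": rng.uniform(0.02, 0.1, n),
        })
        table, sig, _ = group_seed_glm(z_maps, cov, space.iso_mask,
                                       space.iso_index, n_iter=150, seed=0)
        assert not sig.any()

    def test_planted_positive_mean_region_recovered(self, space):
        rng = np.random.default_rng(1)
        n = 20
        z_maps = rng.standard_normal((n, space.n_iso)) * 0.2
        region = default_effect_region(space, 5, 25)
        inside = np.zeros(space.dims, dtype=bool)
        inside[region[:, 0], region[:, 1], region[:, 2]] = True
        sel = inside[space.iso_index[:, 0], space.iso_index[:, 1],
                     space.iso_index[:, 2]]
        z_maps[:, sel] += 0.5
        cov = pd.DataFrame({
            "age": rng.uniform(20, 60, n), "sex": rng.integers(0, 2, n),
            "ssri_snri": rng.integers(0, 2, n), "mean_fd": rng.uniform(0.02, 0.1, n),
        })
        table, sig, res = group_seed_glm(z_maps, cov, space.iso_mask,
                                         space.iso_index, n_iter=300, seed=1)
        recovered = (sig & inside).sum() / inside.sum()
        assert recovered >= 0.8
        # spurious coverage stays small
        assert (sig & ~inside).sum() <= 0.02 * space.n_iso


def test_planted_target_network_dominates_between_network_counts(space):
    """End to end: with cross-network coupling planted from the effect
    region (seed) to one target network, that network receives the largest
    significant-voxel count, across replicates."""
    wins = 0
    for rep in range(10):
        cfg = SimulationConfig(
            n_fnd=16, n_followup=0, n_hc=0, n_timepoints=150,
            base_within_r=0.35, base_between_r=0.0,
            effect_network=3, target_network=6,
            boost_mean=0.5, boost_sd=0.05, effect_region_size=12,
            seed=1000 + rep,
        )
        cohort = simulate_longitudinal_cohort(space, cfg)
        region = cohort.truth["effect_region"]
        seed_mask = np.zeros(space.dims, dtype=bool)
        seed_mask[region[:, 0], region[:, 1], region[:, 2]] = True
        seed = make_seed(seed_mask, space.labels, 3, "baseline_predictor")
        z_maps = np.stack([
            seed_to_voxel_zmap(cohort.scans[(sid, "baseline")], seed,
                               space.grey_index, space.iso_in_grey)
            for sid in cohort.fnd_ids
        ])
        tab = cohort.covariates
        cov = pd.DataFrame({
            "age": tab["age"], "sex": tab["sex"],
            "ssri_snri": tab["ssri_snri"], "mean_fd": tab["mean_fd_baseline"],
        })
        _, sig, _ = group_seed_glm(z_maps, cov, space.iso_mask,
                                   space.iso_index, n_iter=300,
                                   seed=1000 + rep)
        counts = count_between_network_connections(sig, space.labels, 3)
        if counts.counts and max(counts.counts.values()) > 0:
            best = max(counts.counts, key=lambda k: (counts.counts[k], -k))
            wins += best == 6
    assert wins >= 8
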