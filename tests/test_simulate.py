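import numpy as np
import pytest

from fcdens.fcd import FcdParams, compute_fcd
from fcdens.simulate import (
    ClinicalSpec,
    ConfigurationError,
    EffectSpec,
    HubSpec,
    SimulationConfig,
    default_mask,
    generate_dataset,
    ground_truth_region,
    reference_config,
)


def _short_hub(rho, at=(3, 3, 3)):
    x, y, z = at
    return HubSpec(
        member_voxels=((x, y, z), (x + 1, y, z), (x, y + 1, z), (x, y, z + 1)),
        coupling_rho=rho,
        range_class="short",
    )


def _pair_corr(series, cols):
    r = np.corrcoef(series[:, cols].T)
    iu = np.triu_indices(len(cols), k=1)
    return r[iu]


class TestMixingModel:
    def test_within_hub_correlation_matches_design_rho(self):
        # long record, no jitter / AR / spatial smoothing: the empirical
        # within-hub correlation must equal the design rho = 0.49
        cfg = SimulationConfig(
            n_per_group=1, grid_dims=(8, 8, 8), n_volumes=5000,
            hubs=[_short_hub(0.49)], temporal_ar1=0.0,
            spatial_noise_fwhm_mm=0.0, coupling_jitter_sd=0.0, seed=7,
        )
        bold_list, _, hub_masks = generate_dataset(cfg)
        mask = default_mask(cfg)
        mat = mask.extract(bold_list[0])
        cols = np.where(hub_masks[0][mask.membership])[0]
        rs = _pair_corr(mat, cols)
        assert np.all(np.abs(rs - 0.49) < 0.03)

    def test_patient_multiplier_raises_within_hub_correlation(self):
        cfg = SimulationConfig(
            n_per_group=1, grid_dims=(8, 8, 8), n_volumes=5000,
            hubs=[_short_hub(0.2)],
            group_effects=[EffectSpec(hub_index=0, group_multiplier=2.0)],
            temporal_ar1=0.0, spatial_noise_fwhm_mm=0.0,
            coupling_jitter_sd=0.0, seed=7,
        )
        assert cfg.patient_rho(0) == pytest.approx(0.8)
        bold_list, _, hub_masks = generate_dataset(cfg)
        mask = default_mask(cfg)
        cols = np.where(hub_masks[0][mask.membership])[0]
        r_ctrl = _pair_corr(mask.extract(bold_list[0]), cols).mean()
        r_pat = _pair_corr(mask.extract(bold_list[1]), cols).mean()
        assert abs(r_ctrl - 0.2) < 0.04
        assert abs(r_pat - 0.8) < 0.04

    def test_near_unit_coupling_saturates_hub_degree(self):
        cfg = SimulationConfig(
            n_per_group=1, grid_dims=(8, 8, 8), n_volumes=200,
            hubs=[_short_hub(0.999)], temporal_ar1=0.0,
            spatial_noise_fwhm_mm=0.0, coupling_jitter_sd=0.0, seed=3,
        )
        bold_list, _, hub_masks = generate_dataset(cfg)
        mask = default_mask(cfg)
        mat = mask.extract(bold_list[0])
        maps = compute_fcd(mat, mask.world_coords(), FcdParams(r_threshold=0.45))
        cols = np.where(hub_masks[0][mask.membership])[0]
        n_members = len(cols)
        assert np.all(maps.global_map[cols] >= n_members - 1)


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        cfg = reference_config(seed=11)
        a_bold, a_tab, a_hubs = generate_dataset(cfg)
        b_bold, b_tab, b_hubs = generate_dataset(reference_config(seed=11))
        for a, b in zip(a_bold, b_bold):
            assert np.array_equal(a.data, b.data)
        assert a_tab.equals(b_tab)
        for a, b in zip(a_hubs, b_hubs):
            assert np.array_equal(a, b)

    def test_different_seed_differs(self):
        a, _, _ = generate_dataset(reference_config(seed=11))
        b, _, _ = generate_dataset(reference_config(seed=12))
        assert not np.array_equal(a[0].data, b[0].data)


class TestValidation:
    def test_short_hub_with_distant_members_rejected(self):
        hub = HubSpec(member_voxels=((0, 0, 0), (5, 0, 0)),
                      coupling_rho=0.3, range_class="short")
        cfg = SimulationConfig(n_per_group=1, grid_dims=(8, 8, 8),
                               n_volumes=30, hubs=[hub])
        with pytest.raises(ConfigurationError, match="short hub"):
            generate_dataset(cfg)

    def test_long_hub_with_adjacent_members_rejected(self):
        hub = HubSpec(member_voxels=((2, 2, 2), (3, 2, 2)),
                      coupling_rho=0.3, range_class="long")
        cfg = SimulationConfig(n_per_group=1, grid_dims=(8, 8, 8),
                               n_volumes=30, hubs=[hub])
        with pytest.raises(ConfigurationError, match="long hub"):
            generate_dataset(cfg)

    def test_hub_outside_mask_rejected(self):
        # corner voxels fall outside the centered-cuboid default mask
        hub = HubSpec(member_voxels=((0, 0, 0), (1, 0, 0)),
                      coupling_rho=0.3, range_class="short")
        cfg = SimulationConfig(n_per_group=1, grid_dims=(10, 10, 10),
                               n_volumes=30, mask_fraction=0.5, hubs=[hub])
        with pytest.raises(ConfigurationError, match="outside the mask"):
            generate_dataset(cfg)

    def test_patient_rho_at_or_above_one_rejected(self):
        with pytest.raises(ConfigurationError, match="outside"):
            SimulationConfig(
                n_per_group=1, grid_dims=(8, 8, 8), n_volumes=30,
                hubs=[_short_hub(0.3)],
                group_effects=[EffectSpec(hub_index=0, group_multiplier=2.0)],
            )

    def test_overlapping_hubs_rejected(self):
        h1 = _short_hub(0.3, at=(3, 3, 3))
        h2 = _short_hub(0.3, at=(3, 3, 3))
        cfg = SimulationConfig(n_per_group=1, grid_dims=(10, 10, 10),
                               n_volumes=30, hubs=[h1, h2])
        with pytest.raises(ConfigurationError, match="share"):
            generate_dataset(cfg)

    def test_invalid_rho_rejected(self):
        with pytest.raises(ConfigurationError):
            HubSpec(member_voxels=((0, 0, 0), (1, 0, 0)),
                    coupling_rho=1.5, range_class="short")

    def test_invalid_target_r_rejected(self):
        with pytest.raises(ConfigurationError):
            ClinicalSpec(name="x", hub_index=0, target_r=1.5)


class TestClinicalTable:
    def _table_and_couplings(self, target_r, seed):
        cfg = SimulationConfig(
            n_per_group=24, grid_dims=(8, 8, 8), n_volumes=30,
            hubs=[_short_hub(0.3)],
            clinical_specs=[ClinicalSpec(name="score", hub_index=0,
                                         target_r=target_r, mean=20.0, sd=5.0)],
            coupling_jitter_sd=0.03, seed=seed,
        )
        _, table, _ = generate_dataset(cfg)
        return cfg, table

    def test_perfect_coupling_gives_exact_sample_correlation(self):
        # two target_r = 1 variables on the same hub must be exact affine
        # maps of the same coupling, hence perfectly correlated
        cfg2 = SimulationConfig(
            n_per_group=24, grid_dims=(8, 8, 8), n_volumes=30,
            hubs=[_short_hub(0.3)],
            clinical_specs=[
                ClinicalSpec(name="a", hub_index=0, target_r=1.0),
                ClinicalSpec(name="b", hub_index=0, target_r=1.0,
                             mean=100.0, sd=9.0),
            ],
            seed=5,
        )
        _, t2, _ = generate_dataset(cfg2)
        pat2 = t2[t2.group == "patient"]
        r = np.corrcoef(pat2["a"], pat2["b"])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-10)

    def test_strong_negative_design_yields_negative_sample_r(self):
        # with target r = -0.9 and n = 24 per group, the sample correlation
        # is overwhelmingly likely below -0.6 (checked across 10 seeds
        # against couplings reconstructed through a paired r = 1 variable)
        hits = 0
        for seed in range(10):
            cfg = SimulationConfig(
                n_per_group=24, grid_dims=(8, 8, 8), n_volumes=30,
                hubs=[_short_hub(0.3)],
                clinical_specs=[
                    ClinicalSpec(name="proxy", hub_index=0, target_r=1.0),
                    ClinicalSpec(name="score", hub_index=0, target_r=-0.9),
                ],
                seed=seed,
            )
            _, table, _ = generate_dataset(cfg)
            pat = table[table.group == "patient"]
            r = np.corrcoef(pat["proxy"], pat["score"])[0, 1]
            if r < -0.6:
                hits += 1
        assert hits >= 9

    def test_mean_and_sd_scale_applied(self):
        _, table = self._table_and_couplings(target_r=0.0, seed=2)
        assert abs(table["score"].mean() - 20.0) < 3.0
        assert abs(table["score"].std() - 5.0) < 2.0

    def test_required_columns_present(self):
        cfg = reference_config(seed=1)
        _, table, _ = generate_dataset(cfg)
        for col in ("subject_id", "group", "age", "education"):
            assert col in table.columns
        assert (table.group.value_counts() == cfg.n_per_group).all()


class TestGroundTruthRegion:
    def test_zero_dilation_returns_hub_mask(self):
        cfg = reference_config(seed=0)
        _, _, hub_masks = generate_dataset(cfg)
        out = ground_truth_region(hub_masks[0], cfg.grid, dilate_mm=0.0)
        assert np.array_equal(out, hub_masks[0])

    def test_dilation_strictly_grows_and_contains_hub(self):
        cfg = reference_config(seed=0)
        _, _, hub_masks = generate_dataset(cfg)
        out = ground_truth_region(hub_masks[0], cfg.grid, dilate_mm=6.0)
        assert np.all(out[hub_masks[0]])
        assert out.sum() > hub_masks[0].sum()
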