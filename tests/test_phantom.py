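"""Phantom generation: geometry, signal model, PET simulation, series."""

import numpy as np
import pytest
from scipy import ndimage

from fibroquant import GridSpec, TissueClass, TissueProperties, TrajectorySpec
from fibroquant.phantom import (
    TE_LONG_MS,
    TE_SHORT_MS,
    lung_region_mask,
    make_label_map,
    make_series,
    sigma_for_snr,
    simulate_echo,
    simulate_echo_pair,
    simulate_pet,
)

LESIONS = (TissueClass.EDEMA, TissueClass.FIBROTIC_TISSUE)


class TestTrajectorySpec:
    def test_defaults_encode_disease_course(self, trajectory):
        assert trajectory.days == (0, 7, 14, 21, 28)
        assert trajectory.days[np.argmax(trajectory.edema_volume_curve)] == 7
        assert trajectory.days[np.argmax(trajectory.tissue_volume_curve)] == 28

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(edema_volume_curve=(0, 100, 800, 100, 100)),  # peak at 14
            dict(tissue_volume_curve=(0, 900, 100, 100, 100)),  # peak at 7
            dict(edema_volume_curve=(50, 800, 100, 100, 100)),  # day-0 nonzero
            dict(days=(7, 14, 21, 28), edema_volume_curve=(800, 1, 1, 1),
                 tissue_volume_curve=(1, 1, 1, 500),
                 border_uptake_curve=(1, 1, 1, 1)),  # no baseline
        ],
    )
    def test_invalid_trajectories_rejected(self, kwargs):
        with pytest.raises(ValueError):
            TrajectorySpec(**kwargs)

    def test_control_trajectory_is_lesion_free(self):
        t = TrajectorySpec.control()
        assert set(t.edema_volume_curve) == {0.0}
        assert set(t.tissue_volume_curve) == {0.0}


class TestMakeLabelMap:
    def test_day_zero_has_no_lesions(self, grid48, label_map_factory):
        lm = label_map_factory(grid48, day=0, seed=1)
        for cls in (*LESIONS, TissueClass.ACTIVE_BORDER):
            assert lm.volume_mm3(cls) == 0.0

    def test_edema_volume_peaks_at_day_seven(self, grid48, label_map_factory):
        vols = {
            day: label_map_factory(grid48, day, seed=2).volume_mm3(TissueClass.EDEMA)
            for day in (0, 7, 14, 21, 28)
        }
        assert max(vols, key=vols.get) == 7

    def test_volume_targets_met_within_one_voxel(self, grid48, trajectory,
                                                 label_map_factory):
        voxvol = grid48.voxel_volume
        for day in trajectory.days:
            lm = label_map_factory(grid48, day, seed=3)
            e_target, t_target, _ = trajectory.at(day)
            assert abs(lm.volume_mm3(TissueClass.EDEMA) - e_target) <= voxvol
            assert abs(lm.volume_mm3(TissueClass.FIBROTIC_TISSUE) - t_target) <= voxvol

    def test_determinism_same_seed_identical(self, grid48, trajectory):
        a = make_label_map(grid48, trajectory, 7, seed=42)
        b = make_label_map(grid48, trajectory, 7, seed=42)
        np.testing.assert_array_equal(a.labels, b.labels)
        c = make_label_map(grid48, trajectory, 7, seed=43)
        assert (a.labels != c.labels).any()

    def test_disease_lives_inside_the_lung(self, grid48, label_map_factory):
        lm = label_map_factory(grid48, day=28, seed=4)
        inside = lung_region_mask(lm.labels)
        for cls in (TissueClass.VESSEL, *LESIONS, TissueClass.ACTIVE_BORDER):
            assert not np.any((lm.labels == cls) & ~inside)

    def test_border_is_one_voxel_shell_adjacent_to_lesions(self, grid48,
                                                           label_map_factory):
        lm = label_map_factory(grid48, day=14, seed=5)
        lesion = np.isin(lm.labels, LESIONS)
        border = lm.labels == TissueClass.ACTIVE_BORDER
        six = ndimage.generate_binary_structure(3, 1)
        touching = ndimage.binary_dilation(lesion, structure=six) & ~lesion
        assert not np.any(border & ~touching)  # every border voxel touches a lesion
        assert not np.any(touching & (lm.labels == TissueClass.LUNG_PARENCHYMA))

    def test_unknown_day_error_names_valid_days(self, grid48, trajectory):
        with pytest.raises(ValueError, match=r"valid days.*0, 7, 14, 21, 28"):
            make_label_map(grid48, trajectory, 9, seed=0)

    def test_oversized_lesion_target_rejected(self, grid48):
        t = TrajectorySpec(edema_volume_curve=(0, 5e5, 1, 1, 1))
        with pytest.raises(ValueError, match="exceeds"):
            make_label_map(grid48, t, 7, seed=0)


class TestSimulateEcho:
    def test_closed_form_monoexponential(self, grid48, props):
        # PD 100, T2* 10 ms, TE 1 ms -> 100 * exp(-0.1)
        lm = make_label_map(grid48, TrajectorySpec.control(), 0, seed=0)
        custom = TissueProperties(
            proton_density={c: 100.0 for c in TissueClass},
            t2_star={c: 10.0 for c in TissueClass},
        )
        sig = simulate_echo(lm, custom, te_ms=1.0, noise_sigma=0.0)
        np.testing.assert_allclose(sig, 100.0 * np.exp(-0.1))

    def test_noise_free_long_echo_never_brighter(self, grid48, props,
                                                 label_map_factory):
        lm = label_map_factory(grid48, day=14, seed=6)
        short = simulate_echo(lm, props, TE_SHORT_MS, 0.0)
        long_ = simulate_echo(lm, props, TE_LONG_MS, 0.0)
        assert np.all(long_ <= short + 1e-12)

    def test_fibrotic_fades_between_echoes_but_fluid_does_not(self, props):
        # evaluate the decay ratio from the default property table
        dt = TE_LONG_MS - TE_SHORT_MS
        ratio_fib = np.exp(-dt / props.t2_star[TissueClass.FIBROTIC_TISSUE])
        ratio_edema = np.exp(-dt / props.t2_star[TissueClass.EDEMA])
        assert ratio_fib == pytest.approx(0.381, abs=0.005)
        assert ratio_edema > 0.9

    def test_unknown_class_id_rejected(self, grid48, props, trajectory):
        lm = make_label_map(grid48, trajectory, 0, seed=0)
        bad = lm.labels.copy()
        bad[0, 0, 0] = 99
        from fibroquant.phantom import TissueLabelMap

        with pytest.raises(ValueError, match="unknown class"):
            simulate_echo(TissueLabelMap(grid=grid48, labels=bad), props, 1.0)

    def test_rician_noise_is_seeded_and_nonnegative(self, grid48, props,
                                                    label_map_factory):
        lm = label_map_factory(grid48, day=7, seed=7)
        a = simulate_echo(lm, props, TE_SHORT_MS, 5.0, seed=1)
        b = simulate_echo(lm, props, TE_SHORT_MS, 5.0, seed=1)
        c = simulate_echo(lm, props, TE_SHORT_MS, 5.0, seed=2)
        np.testing.assert_array_equal(a, b)
        assert (a != c).any()
        assert (a >= 0).all()


class TestSimulatePet:
    def test_uniform_activity_conserved_exactly(self, grid48, props):
        lm = make_label_map(grid48, TrajectorySpec.control(), 0, seed=1)
        uniform = TissueProperties(
            pet_uptake_density={c: 1.0 for c in TissueClass}
        )
        pet = simulate_pet(
            lm, uniform, grid48, psf_fwhm_mm=0.0, count_scale=np.inf,
            injected_dose_mbq=35.0, lung_fraction=0.005,
        )
        # total activity = %ID-implied MBq = sum(conc) * voxvol
        total_mbq = pet.activity_concentration.sum() * grid48.voxel_volume * 1e-9
        scale = pet.meta["activity_scale_mbq_per_unit"]
        expected = scale * 1.0 * lm.labels.size * grid48.voxel_volume
        assert total_mbq == pytest.approx(expected, rel=1e-9)

    def test_noiseless_per_class_means_recover_densities(self, grid48, props,
                                                         label_map_factory):
        lm = label_map_factory(grid48, day=28, seed=8)
        pet = simulate_pet(lm, props, grid48, psf_fwhm_mm=0.0, count_scale=np.inf)
        scale = pet.meta["activity_scale_mbq_per_unit"] * 1e9
        for cls in (TissueClass.LUNG_PARENCHYMA, TissueClass.EDEMA,
                    TissueClass.ACTIVE_BORDER):
            mean = pet.activity_concentration[lm.labels == cls].mean()
            assert mean == pytest.approx(
                props.pet_uptake_density[cls] * scale, rel=1e-9
            )

    def test_border_hotter_than_distant_parenchyma(self, grid48, props,
                                                   label_map_factory):
        lm = label_map_factory(grid48, day=28, seed=8)
        pet = simulate_pet(lm, props, grid48, psf_fwhm_mm=0.8, count_scale=1e7,
                           seed=3)
        lesion = np.isin(lm.labels, LESIONS)
        dist = ndimage.distance_transform_edt(~lesion, sampling=grid48.spacing)
        far_lung = (lm.labels == TissueClass.LUNG_PARENCHYMA) & (dist > 2.0)
        border = lm.labels == TissueClass.ACTIVE_BORDER
        assert (
            pet.activity_concentration[border].mean()
            > pet.activity_concentration[far_lung].mean()
        )

    def test_pet_grid_must_cover_phantom(self, grid48, props, label_map_factory):
        lm = label_map_factory(grid48, day=7, seed=9)
        small = GridSpec(shape=(10, 10, 10), spacing=(1.0, 1.0, 1.0))
        with pytest.raises(ValueError, match="cover"):
            simulate_pet(lm, props, small)


class TestMakeSeries:
    @pytest.fixture(scope="class")
    def series(self, grid48, trajectory, props):
        pet_grid = GridSpec(shape=(36, 36, 36), spacing=(1.6, 1.6, 1.6))
        return make_series(trajectory, grid48, pet_grid, props=props,
                           noise_sigma=sigma_for_snr(20), count_scale=1e7, seed=11)

    def test_five_time_points(self, series):
        assert [r.day for r in series.records] == [0, 7, 14, 21, 28]

    def test_truth_tissue_volume_peaks_at_day_28(self, series):
        t = series.truth.set_index("day")
        assert t["tissue_volume_mm3"].idxmax() == 28
        assert t["edema_volume_mm3"].idxmax() == 7

    def test_doses_within_advertised_range(self, series):
        assert series.truth["injected_dose_mbq"].between(30, 40).all()
        assert series.truth["delay_minutes"].between(55, 65).all()

    def test_same_seed_reproduces_bitwise(self, grid48, trajectory, props, series):
        pet_grid = GridSpec(shape=(36, 36, 36), spacing=(1.6, 1.6, 1.6))
        again = make_series(trajectory, grid48, pet_grid, props=props,
                            noise_sigma=sigma_for_snr(20), count_scale=1e7, seed=11)
        for a, b in zip(series.records, again.records):
            np.testing.assert_array_equal(a.label_map.labels, b.label_map.labels)
            np.testing.assert_array_equal(a.echoes.te_short_image, b.echoes.te_short_image)
            np.testing.assert_array_equal(
                a.pet.activity_concentration, b.pet.activity_concentration
            )
        assert series.truth.equals(again.truth)

    def test_disease_raises_lung_activity_over_baseline(self, series):
        t = series.truth.set_index("day")
        assert (t.loc[[7, 14, 21, 28], "true_lung_percent_id"]
                > t.loc[0, "true_lung_percent_id"]).all()
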