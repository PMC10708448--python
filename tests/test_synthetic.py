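"""Generator properties: endmember shape, effects, scene forward model, study design."""

import warnings

import numpy as np
import pytest

from hsisoa.evaluate import loo_experiment
from hsisoa.io import calibrate
from hsisoa.segmentation import make_window, rededge_slope_map
from hsisoa.synthetic import (
    CONTROL,
    EffectBand,
    SceneConfig,
    StudyConfig,
    TreatmentSpec,
    apply_treatment_effect,
    canonical_order,
    damage_weight,
    damaged_endmember,
    default_treatments,
    generate_study,
    leaf_endmember,
    render_scene,
)

WL = np.arange(380.0, 1030.0, 1.2)


def _at(values, wl, target):
    return values[np.argmin(np.abs(wl - target))]


class TestLeafEndmember:
    def test_vegetation_shape(self):
        r = leaf_endmember(WL)
        assert np.all((r > 0) & (r < 1))
        assert _at(r, WL, 550) > _at(r, WL, 670)
        assert _at(r, WL, 800) > _at(r, WL, 680)

    def test_red_edge_slope_positive_by_regression_oracle(self):
        r = leaf_endmember(WL)
        sel = (WL >= 680) & (WL <= 732)
        slope = np.polyfit(WL[sel], r[sel], 1)[0]
        assert slope > 0

    def test_deterministic(self):
        np.testing.assert_array_equal(leaf_endmember(WL), leaf_endmember(WL))

    def test_empty_grid_raises(self):
        with pytest.raises(ValueError, match="empty"):
            leaf_endmember(np.array([]))

    def test_damaged_endmember_has_weaker_red_edge(self):
        healthy, damaged = leaf_endmember(WL), damaged_endmember(WL)
        sel = (WL >= 680) & (WL <= 732)
        assert np.polyfit(WL[sel], damaged[sel], 1)[0] < np.polyfit(WL[sel], healthy[sel], 1)[0]
        assert _at(damaged, WL, 800) < _at(healthy, WL, 800)


class TestTreatmentEffect:
    def test_control_unchanged_any_day(self):
        base = leaf_endmember(WL)
        control = default_treatments()[0]
        for day in (0, 1, 5):
            np.testing.assert_array_equal(apply_treatment_effect(base, WL, control, day), base)

    def test_single_effect_peaks_at_center(self):
        # flat base isolates the Gaussian: for multiplicative effects the
        # absolute change is base * |a| * gaussian, maximal at the center
        base = np.full(WL.size, 0.5)
        spec = TreatmentSpec(
            "Atrazine", "Photosynthesis inhibition", "PS II inhibition", 62.5,
            (EffectBand(700.0, 10.0, 0.2, onset_day=1),),
        )
        out = apply_treatment_effect(base, WL, spec, day=1)
        diff = np.abs(out - base)
        assert abs(WL[np.argmax(diff)] - 700.0) < 1.3
        # outside the active band the spectrum is untouched
        far = np.abs(WL - 700.0) > 80.0
        np.testing.assert_allclose(out[far], base[far], atol=1e-9)

    def test_inactive_before_onset(self):
        base = leaf_endmember(WL)
        spec = TreatmentSpec(
            "Paraquat", "Cell membrane disrupter", "PS I electron diversion", 3.9,
            (EffectBand(860.0, 20.0, -0.2, onset_day=3),),
        )
        np.testing.assert_array_equal(apply_treatment_effect(base, WL, spec, day=2), base)
        assert not np.allclose(apply_treatment_effect(base, WL, spec, day=3), base)

    def test_magnitude_follows_severity_growth(self):
        base = np.full(WL.size, 0.5)
        spec = TreatmentSpec(
            "Atrazine", "Photosynthesis inhibition", "PS II inhibition", 62.5,
            (EffectBand(700.0, 10.0, 0.1, onset_day=1),), severity_growth=1.5,
        )
        d1 = apply_treatment_effect(base, WL, spec, 1)
        d2 = apply_treatment_effect(base, WL, spec, 2)
        peak = np.argmin(np.abs(WL - 700.0))
        assert (d2[peak] - 0.5) == pytest.approx(1.5 * (d1[peak] - 0.5), rel=1e-9)

    def test_output_clipped_to_unit_interval(self):
        base = np.full(WL.size, 0.9)
        spec = TreatmentSpec(
            "Dinoseb", "Photosynthesis inhibition", "Uncoupler", 125.0,
            (EffectBand(700.0, 50.0, 5.0, onset_day=0),),
        )
        out = apply_treatment_effect(base, WL, spec, day=6)
        assert np.all(out > 0) and np.all(out < 1)

    def test_negative_day_raises(self):
        with pytest.raises(ValueError):
            apply_treatment_effect(np.full(WL.size, 0.5), WL, default_treatments()[1], -1)

    def test_control_spec_rejects_effect_bands(self):
        with pytest.raises(ValueError, match="control"):
            TreatmentSpec(CONTROL, "control", "untreated", 0.0, (EffectBand(700, 10, 0.1),))


class TestDamageWeight:
    def test_zero_on_first_day_and_for_control(self):
        treated = default_treatments()[4]  # paraquat, fastest
        assert damage_weight(treated, 1) == 0.0
        assert damage_weight(default_treatments()[0], 5) == 0.0

    def test_increases_and_saturates(self):
        spec = default_treatments()[4]
        w = [damage_weight(spec, d) for d in range(1, 8)]
        assert all(b > a for a, b in zip(w, w[1:]))
        assert w[-1] < 1.0


class TestRenderScene:
    def test_noiseless_round_trip_recovers_endmember(self):
        cfg = SceneConfig(height=24, width=32, noise_sd=0.0, seed=5)
        em = leaf_endmember(cfg.wavelengths)
        scene = render_scene(em, cfg)
        refl = calibrate(scene.raw, scene.refs)
        assert scene.truth_mask.any()
        plant = refl.data[scene.truth_mask]
        np.testing.assert_allclose(plant, np.broadcast_to(em, plant.shape), atol=1e-10)
        background = refl.data[~scene.truth_mask]
        np.testing.assert_allclose(background, cfg.background_reflectance, atol=1e-10)

    def test_zero_plant_fraction_gives_empty_mask(self):
        cfg = SceneConfig(height=24, width=32, plant_fraction=0.0, seed=1)
        scene = render_scene(leaf_endmember(cfg.wavelengths), cfg)
        assert not scene.truth_mask.any()

    def test_fixed_seed_reproducible(self):
        cfg = SceneConfig(height=16, width=20, seed=9)
        em = leaf_endmember(cfg.wavelengths)
        a, b = render_scene(em, cfg), render_scene(em, cfg)
        np.testing.assert_array_equal(a.raw.data, b.raw.data)
        np.testing.assert_array_equal(a.truth_mask, b.truth_mask)

    def test_grid_mismatch_raises(self):
        cfg = SceneConfig(height=16, width=20)
        with pytest.raises(ValueError, match="does not match grid"):
            render_scene(np.ones(10), cfg)

    def test_reference_frames_span_dn_range(self):
        cfg = SceneConfig(height=16, width=20, seed=2)
        scene = render_scene(leaf_endmember(cfg.wavelengths), cfg)
        assert scene.refs.white.max() > 3000.0  # near the top of a 12-bit range
        assert scene.refs.dark.max() < 200.0
        assert np.all(scene.refs.white - scene.refs.dark > 0)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SceneConfig(wl_step=0.0)
        with pytest.raises(ValueError):
            SceneConfig(noise_sd=-1.0)
        with pytest.raises(ValueError):
            SceneConfig(plant_fraction=1.2)


class TestGenerateStudy:
    def test_default_design_yields_320_samples(self, default_study):
        table = default_study.table
        assert table.meta["sample_id"].nunique() == 320
        assert len(table) == 320 * 7
        counts = table.filter(dat=1).meta["treatment"].value_counts()
        assert counts[CONTROL] == 64
        assert all(counts[t.name] == 32 for t in default_treatments()[1:])

    def test_minimal_design(self):
        cfg = StudyConfig(
            treatments=default_treatments()[:2],
            samples_per_herbicide=1,
            control_samples=2,
            rounds=1,
            days=(1,),
            outlier_count=0,
        )
        table = generate_study(cfg).table
        assert len(table) == 3

    def test_exactly_five_outlier_plants_flagged(self, default_study):
        assert len(default_study.outlier_ids) == 5
        flagged = default_study.table.meta.loc[
            default_study.table.meta["outlier"], "sample_id"
        ].unique()
        assert sorted(flagged) == default_study.outlier_ids

    def test_outliers_necrotic_from_injection_day(self, default_study):
        table = default_study.table
        sid = default_study.outlier_ids[0]
        rows = table.meta["sample_id"] == sid
        day2 = table.X[(rows & (table.meta["dat"] == 2)).to_numpy()][0]
        day1 = table.X[(rows & (table.meta["dat"] == 1)).to_numpy()][0]
        assert day2.mean() < 0.05 < day1.mean()

    def test_unknown_treatment_name_rejected(self):
        bad = TreatmentSpec("Roundup", "x", "y", 1.0, ())
        with pytest.raises(ValueError, match="unknown treatment"):
            StudyConfig(treatments=[bad])

    def test_days_must_increase(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            StudyConfig(days=(1, 3, 2))

    def test_same_seed_bit_identical(self):
        cfg = dict(
            treatments=default_treatments()[:3],
            samples_per_herbicide=2,
            control_samples=2,
            rounds=1,
            days=(1, 2),
            outlier_count=1,
        )
        a = generate_study(StudyConfig(seed=42, **cfg))
        b = generate_study(StudyConfig(seed=42, **cfg))
        np.testing.assert_array_equal(a.table.X, b.table.X)
        assert a.outlier_ids == b.outlier_ids

    def test_yaml_round_trip(self, tmp_path):
        cfg = StudyConfig(rounds=1, days=(1, 2, 3), seed=17)
        path = str(tmp_path / "study.yaml")
        cfg.to_yaml(path)
        back = StudyConfig.from_yaml(path)
        assert back == cfg

    def test_canonical_order_puts_control_first(self):
        assert canonical_order(["Paraquat", "UTC", "Atrazine"]) == ["UTC", "Atrazine", "Paraquat"]


def test_separability_monotone_in_effect_amplitude():
    """Leave-one-out accuracy does not decrease as effect amplitude grows."""
    oas = []
    for scale in (0.02, 0.3, 1.0):
        cfg = StudyConfig(
            treatments=default_treatments(amplitude_scale=scale)[:4],
            samples_per_herbicide=6,
            control_samples=6,
            rounds=1,
            days=(1,),
            outlier_count=0,
            seed=23,
        )
        table = generate_study(cfg).table
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            oas.append(loo_experiment(table, learner="plsda").overall_accuracy)
    assert oas[0] <= oas[1] <= oas[2]
    assert oas[2] > 0.9
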