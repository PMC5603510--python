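"""The synthetic screen must be structurally faithful and reproducible."""

import numpy as np
import pytest

from kinotox import synth
from kinotox.errors import InvalidArgumentError


class TestRegistry:
    def test_default_screen_dimensions(self, default_registry):
        assert default_registry.n_compounds == 80
        assert len(default_registry.targets) == 23

    def test_every_target_covered(self, default_registry):
        covered = {c.kinase_target for c in default_registry.compounds}
        assert covered == set(range(23))

    @pytest.mark.parametrize(
        "n_comp,n_targ,seed",
        [(1, 1, 0), (5, 5, 3), (80, 23, 7), (10, 3, 1)],
    )
    def test_counts_and_coverage(self, n_comp, n_targ, seed):
        reg = synth.make_registry(n_comp, n_targ, seed)
        assert reg.n_compounds == n_comp
        assert len(reg.targets) == n_targ
        if n_comp == n_targ:
            # forced bijection when counts are equal
            assert len({c.kinase_target for c in reg.compounds}) == n_comp

    def test_deterministic_under_seed(self):
        a = synth.make_registry(40, 11, seed=5)
        b = synth.make_registry(40, 11, seed=5)
        assert a == b
        c = synth.make_registry(40, 11, seed=6)
        assert a != c

    def test_more_targets_than_compounds_rejected(self):
        with pytest.raises(InvalidArgumentError):
            synth.make_registry(3, 5, 0)


class TestPlateMaps:
    def test_default_screen_test_well_count(self, default_registry):
        plates = synth.make_plate_maps(default_registry)
        test_wells = [w for p in plates for w in p.wells_by_role("test")]
        assert len(test_wells) == 720  # 80 compounds x 3 concentrations x 3 replicates

    def test_each_plate_has_reference_roles_and_blanks(self, default_registry):
        for plate in synth.make_plate_maps(default_registry):
            for role in synth.REFERENCE_ROLES:
                assert plate.wells_by_role(role), f"{plate.plate_id} missing {role}"
            assert len(plate.wells_by_role("blank")) >= 3

    def test_each_compound_occupies_expected_wells(self, default_registry):
        plates = synth.make_plate_maps(default_registry)
        seen = {}
        for p in plates:
            for w in p.wells_by_role("test"):
                seen.setdefault(w.compound_id, []).append((w.concentration_uM, w.replicate))
        assert set(seen) == {c.compound_id for c in default_registry.compounds}
        for pairs in seen.values():
            assert sorted(pairs) == sorted(
                (c, r) for c in (0.1, 1.0, 10.0) for r in (1, 2, 3)
            )

    def test_capacity_overflow_splits_plates(self, default_registry):
        plates = synth.make_plate_maps(default_registry)
        assert len(plates) == 3  # 720 test wells / 352 per plate
        for plate in plates:
            assert len(plate.wells) <= 384

    def test_single_condition_layout(self):
        reg = synth.make_registry(1, 1, 0)
        plates = synth.make_plate_maps(reg, concentrations=[1.0], replicates=1)
        assert len(plates) == 1
        assert len(plates[0].wells_by_role("test")) == 1

    def test_empty_concentrations_rejected(self, default_registry):
        with pytest.raises(InvalidArgumentError):
            synth.make_plate_maps(default_registry, concentrations=[])

    def test_zero_replicates_rejected(self, default_registry):
        with pytest.raises(InvalidArgumentError):
            synth.make_plate_maps(default_registry, replicates=0)


class TestCalciumTraces:
    def test_zero_noise_peak_count_and_amplitude(self, zero_noise_params):
        tr = synth.synthesize_trace(None, None, None, zero_noise_params, seed=0)
        assert len(tr.samples) == 401
        assert tr.truth["peak_count"] == 40
        assert tr.truth["amplitude"] == 25.0
        # at zero noise the bumps sit exactly on the flat baseline
        assert np.min(tr.samples) == zero_noise_params.baseline
        assert np.max(tr.samples) == pytest.approx(
            zero_noise_params.baseline + zero_noise_params.amplitude
        )

    def test_zero_frequency_gives_flat_trace(self):
        p = synth.TraceParams(frequency_hz=0.0, noise_sd=0.0)
        tr = synth.synthesize_trace(None, None, None, p)
        assert np.all(tr.samples == p.baseline)

    def test_lethal_control_has_zero_amplitude(self, neutral_model, zero_noise_params):
        well = synth.Well("A1", "lethal_control", None, None, None)
        tr = synth.well_trace(neutral_model, well, zero_noise_params)
        assert np.all(tr.samples == zero_noise_params.baseline)

    def test_effect_multipliers_scale_amplitude_and_frequency(self, zero_noise_params):
        reg = synth.make_registry(1, 1, 0)
        effects = {(1, 1.0): synth.EndpointEffects(1.0, 1.0, 2.0, 0.5)}
        model = synth.EffectModel(effects=effects, seed=0)
        tr = synth.synthesize_trace(model, 1, 1.0, zero_noise_params)
        assert tr.truth["amplitude"] == 50.0
        assert tr.truth["peak_count"] == 20  # floor(40 s x 0.5 Hz)

    def test_negative_noise_rejected(self):
        with pytest.raises(InvalidArgumentError):
            synth.synthesize_trace(None, None, None, synth.TraceParams(noise_sd=-1.0))

    def test_dt_must_divide_duration(self, zero_noise_params):
        with pytest.raises(InvalidArgumentError):
            synth.synthesize_trace(None, None, None, zero_noise_params, dt=0.3, duration=40.0)

    def test_bit_identical_under_seed(self):
        p = synth.TraceParams(noise_sd=1.0)
        a = synth.synthesize_trace(None, None, None, p, seed=42)
        b = synth.synthesize_trace(None, None, None, p, seed=42)
        assert np.array_equal(a.samples, b.samples)
        c = synth.synthesize_trace(None, None, None, p, seed=43)
        assert not np.array_equal(a.samples, c.samples)


class TestCellCounts:
    def test_zero_noise_closed_form(self, neutral_model):
        c = synth.synthesize_counts(neutral_model, 1, 1.0, baseline_total=8000)
        assert (c.total_cells, c.dead_cells) == (8000, 800)  # viability 0.9

    def test_zero_viability_kills_all(self, neutral_model):
        effects = {(1, 1.0): synth.EndpointEffects(0.0, 1.0, 1.0, 1.0)}
        model = synth.EffectModel(effects=effects, noise_cv=neutral_model.noise_cv, seed=0)
        c = synth.synthesize_counts(model, 1, 1.0, baseline_total=5000)
        assert c.dead_cells == c.total_cells

    def test_lethal_flag_overrides(self, neutral_model):
        c = synth.synthesize_counts(neutral_model, None, None, baseline_total=5000, lethal=True)
        assert c.dead_cells == c.total_cells

    def test_zero_baseline_rejected(self, neutral_model):
        with pytest.raises(InvalidArgumentError):
            synth.synthesize_counts(neutral_model, None, None, baseline_total=0)

    def test_dead_never_exceeds_total(self, neutral_model):
        for seed in range(20):
            c = synth.synthesize_counts(neutral_model, 1, 1.0, 1000, seed=seed)
            assert 0 <= c.dead_cells <= c.total_cells


class TestForceTraces:
    def test_beat_geometry(self):
        tr = synth.synthesize_force_trace(
            amplitude=10.0, contraction_slope=100.0, relaxation_slope=50.0
        )
        # rise 0.1 s + fall 0.2 s
        assert tr.truth["beat_duration"] == pytest.approx(0.9 * 0.3)
        assert np.max(tr.samples) == pytest.approx(10.0)
        assert np.min(tr.samples) == 0.0

    def test_zero_amplitude_flat(self):
        tr = synth.synthesize_force_trace(amplitude=0.0)
        assert np.all(tr.samples == 0.0)

    def test_beat_count(self):
        tr = synth.synthesize_force_trace(pacing_hz=1.0, duration=10.0)
        assert tr.truth["n_beats"] == 10

    def test_beat_longer_than_period_rejected(self):
        with pytest.raises(InvalidArgumentError):
            synth.synthesize_force_trace(
                amplitude=10.0, contraction_slope=15.0, relaxation_slope=15.0, pacing_hz=1.0
            )


class TestEffectModel:
    def test_default_model_is_deterministic(self, default_registry):
        a = synth.sample_effect_model(default_registry, seed=3)
        b = synth.sample_effect_model(default_registry, seed=3)
        assert a.effects == b.effects

    def test_all_multipliers_positive(self, default_registry):
        model = synth.sample_effect_model(default_registry, seed=3)
        for e in model.effects.values():
            assert e.viability > 0 and e.live_cells > 0
            assert e.magnitude > 0 and e.frequency > 0

    def test_every_condition_in_registry(self, default_registry):
        model = synth.sample_effect_model(default_registry, seed=3)
        ids = {c.compound_id for c in default_registry.compounds}
        for cid, conc in model.effects:
            assert cid in ids
            assert conc in synth.DEFAULT_CONCENTRATIONS

    def test_planted_score_is_mean_effect(self):
        reg = synth.make_registry(1, 1, 0)
        effects = {
            (1, 0.1): synth.EndpointEffects(1, 1, 1.0, 1),
            (1, 1.0): synth.EndpointEffects(1, 1, 2.0, 1),
            (1, 10.0): synth.EndpointEffects(1, 1, 3.0, 1),
        }
        model = synth.EffectModel(effects=effects, seed=0)
        assert model.planted_magnitude_score(1) == pytest.approx(1.0)  # mean of 0, 1, 2
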