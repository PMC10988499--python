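"""Synthetic generators: determinism, parameter recovery, planted truth."""

import numpy as np
import pytest

from capdomain import (
    ValidationError,
    compute_global_indices,
    compute_local_indices,
    generate_cross_section,
    generate_flow_trace,
    generate_metabolome,
    generate_tension_trace,
    tessellate,
)
from capdomain.synth import (
    CORE_PRESET,
    CORTEX_PRESET,
    EffectSpec,
    PhenotypeSpec,
    phenotype_for_group,
)


class TestCrossSection:
    def test_bit_reproducible_given_seed(self):
        a = generate_cross_section(CORE_PRESET, 99)
        b = generate_cross_section(CORE_PRESET, 99)
        np.testing.assert_array_equal(a.capillaries, b.capillaries)
        assert len(a.fibres) == len(b.fibres)

    def test_different_seeds_differ(self):
        a = generate_cross_section(CORE_PRESET, 1)
        b = generate_cross_section(CORE_PRESET, 2)
        assert a.n_capillaries != b.n_capillaries or not np.array_equal(
            a.capillaries, b.capillaries
        )

    def test_perfect_lattice_has_negligible_logsd(self):
        spec = PhenotypeSpec(target_CD=None, fibre_CSA_mean=1870.0,
                             jitter=0.0, frame_area_mm2=0.145)
        tess = tessellate(generate_cross_section(spec, 0))
        interior = tess.interior()
        assert interior.size > 50
        assert np.std(np.log(interior), ddof=1) < 1e-3

    def test_capillary_count_expectation(self):
        """Mean observed count over seeds matches CD * frame_area."""
        expected = CORE_PRESET.target_CD * CORE_PRESET.frame_area_mm2  # 142.68
        counts = [
            generate_cross_section(CORE_PRESET, s).n_capillaries
            for s in range(40)
        ]
        # binomial thinning: SE of the mean ~ sqrt(n p (1-p) / 40) < 2
        assert np.mean(counts) == pytest.approx(expected, abs=6.0)

    def test_measured_cd_recovers_target(self):
        cds = [
            compute_global_indices(generate_cross_section(CORTEX_PRESET, s)).CD
            for s in range(30)
        ]
        assert np.mean(cds) == pytest.approx(CORTEX_PRESET.target_CD, rel=0.05)

    def test_unreachable_cd_is_error(self):
        spec = PhenotypeSpec(target_CD=5000.0, fibre_CSA_mean=5000.0,
                             frame_area_mm2=0.145)
        with pytest.raises(ValidationError, match="edge midpoints"):
            generate_cross_section(spec, 0)

    def test_group_multiplier_raises_cd(self):
        eff = EffectSpec()
        spec10 = phenotype_for_group(CORTEX_PRESET, "10Hz", eff)
        assert spec10.target_CD == pytest.approx(1120.0, rel=1e-6)
        core10 = phenotype_for_group(CORE_PRESET, "10Hz", eff)
        assert core10.target_CD == pytest.approx(1360.0, rel=1e-6)
        cds = [
            compute_global_indices(generate_cross_section(spec10, s)).CD
            for s in range(15)
        ]
        assert np.mean(cds) == pytest.approx(1120.0, rel=0.07)

    def test_higher_cd_gives_higher_mean_po2(self):
        from capdomain.oxygen import EXERCISE_PARAMS
        from capdomain import solve_frame

        lo_spec = PhenotypeSpec(target_CD=500.0, fibre_CSA_mean=2758.0,
                                frame_area_mm2=0.04)
        hi_spec = PhenotypeSpec(target_CD=1000.0, fibre_CSA_mean=1870.0,
                                frame_area_mm2=0.04)
        diffs = []
        for s in range(3):
            lo = generate_cross_section(lo_spec, s)
            hi = generate_cross_section(hi_spec, 100 + s)
            f_lo = solve_frame(tessellate(lo), lo, EXERCISE_PARAMS, h=2.0)
            f_hi = solve_frame(tessellate(hi), hi, EXERCISE_PARAMS, h=2.0)
            diffs.append(f_hi.mean_PO2 - f_lo.mean_PO2)
        assert all(d > 0 for d in diffs)


class TestTensionGenerator:
    def test_no_fatigue_target_gives_unit_fi(self):
        from capdomain import fatigue_index

        tr = generate_tension_trace(FI_target=1.0, noise_sd=0.0, seed=0)
        assert fatigue_index(tr, min_separation=0.05).FI == pytest.approx(
            1.0, abs=1e-6
        )

    def test_noiseless_half_target_recovered_closely(self):
        from capdomain import fatigue_index

        tr = generate_tension_trace(FI_target=0.5, noise_sd=0.0, seed=0)
        fi = fatigue_index(tr, min_separation=0.05).FI
        # exact up to the geometric decay across the five-twitch windows
        assert fi == pytest.approx(0.5, abs=0.002)

    def test_deterministic_given_seed(self):
        a = generate_tension_trace(seed=5)
        b = generate_tension_trace(seed=5)
        np.testing.assert_array_equal(a.tension, b.tension)

    def test_invalid_fi_target_rejected(self):
        with pytest.raises(ValidationError):
            generate_tension_trace(FI_target=0.0)


class TestFlowGenerator:
    def test_unit_peak_ratio_gives_flat_trace(self):
        tr = generate_flow_trace(peak_ratio=1.0, noise_sd=0.0, seed=0)
        np.testing.assert_allclose(tr.flow, tr.flow[0])

    def test_40hz_peak_occurs_after_stimulation_end(self):
        tr = generate_flow_trace(peak_ratio=3.0, kinetics="40Hz",
                                 noise_sd=0.0, seed=0)
        t_peak = tr.time[np.argmax(tr.flow)]
        assert t_peak > tr.stimulation_window[1]

    def test_10hz_peak_occurs_mid_window(self):
        tr = generate_flow_trace(peak_ratio=3.0, kinetics="10Hz",
                                 noise_sd=0.0, seed=0)
        t_peak = tr.time[np.argmax(tr.flow)]
        a, b = tr.stimulation_window
        assert a < t_peak < b

    def test_bad_kinetics_rejected(self):
        with pytest.raises(ValidationError):
            generate_flow_trace(kinetics="100Hz")


class TestMetabolomeGenerator:
    def test_planted_fold_recovered_in_group_mean_ratio(self):
        effects = EffectSpec(metabolite_folds={"10Hz": {"kynurenic acid": 2.0}})
        ratios = []
        for seed in range(40):
            m = generate_metabolome(
                n_per_group=5, compounds=["kynurenic acid", "filler"],
                effects=effects, sigma_log=0.2, seed=seed,
                groups=("CT", "10Hz"),
            )
            j = m.compound_ids.index("kynurenic acid")
            ct = m.intensities[m.group_mask("CT"), j].mean()
            hz = m.intensities[m.group_mask("10Hz"), j].mean()
            ratios.append(hz / ct)
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.05)

    def test_deterministic_given_seed(self):
        a = generate_metabolome(seed=3)
        b = generate_metabolome(seed=3)
        np.testing.assert_array_equal(a.intensities, b.intensities)

    def test_intensities_positive(self):
        m = generate_metabolome(seed=0)
        assert np.all(m.intensities > 0)

    def test_n_per_group_lower_bound(self):
        with pytest.raises(ValidationError):
            generate_metabolome(n_per_group=1)
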