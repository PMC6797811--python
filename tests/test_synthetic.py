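"""Generator tests: waveform shape, bookkeeping, noise calibration, cohorts."""

import numpy as np
import pytest

from pulsecnn.synthetic import (
    CLASS_SPECS,
    DATASET1_SPECS,
    Jitter,
    PulseClassSpec,
    PulseComponentSpec,
    SubjectProfile,
    generate_cohort,
    generate_cycle,
    generate_record,
    snr_db_to_noise_sd,
)


class TestGenerateCycle:
    def test_zero_amplitude_gives_zero_sequence(self, rng):
        spec = PulseClassSpec("z", (PulseComponentSpec(0.0, 0.2, 0.05),))
        assert np.all(generate_cycle(spec, 64, rng) == 0)

    def test_single_bump_peaks_at_center(self, single_bump_spec, rng):
        # dense-grid argmax of the closed-form component: center 0.2 of 200
        t = np.linspace(0, 1, 20001)
        oracle = t[np.argmax(np.exp(-0.5 * ((t - 0.2) / 0.05) ** 2))]
        cyc = generate_cycle(single_bump_spec, 200, rng)
        assert abs(int(np.argmax(cyc)) - round(oracle * 200)) <= 1

    def test_seeded_determinism(self, h1_spec):
        a = generate_cycle(h1_spec, 200, np.random.default_rng(3))
        b = generate_cycle(h1_spec, 200, np.random.default_rng(3))
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("n", [0, -5, 15])
    def test_rejects_undersized_grid(self, h1_spec, rng, n):
        with pytest.raises(ValueError, match="n_points"):
            generate_cycle(h1_spec, n, rng)


class TestGenerateRecord:
    def test_single_clean_cycle(self, h1_spec):
        rec = generate_record(h1_spec, 1, rng=np.random.default_rng(0))
        np.testing.assert_array_equal(rec.true_boundaries, [0])
        np.testing.assert_allclose(rec.samples, rec.clean)

    def test_cycle_bookkeeping(self, h1_spec):
        rec = generate_record(h1_spec, 10, rng=np.random.default_rng(1))
        assert len(rec.true_boundaries) == 10
        lengths = np.diff(np.concatenate((rec.true_boundaries, [len(rec.samples)])))
        assert np.all(lengths >= 16)
        assert lengths.sum() == len(rec.samples)

    def test_requested_snr_achieved(self, h1_spec):
        rec = generate_record(h1_spec, 20, noise_sd=snr_db_to_noise_sd(20.0),
                              rng=np.random.default_rng(2))
        noise = rec.samples - rec.clean
        snr = 10 * np.log10(np.mean(rec.clean**2) / np.mean(noise**2))
        assert snr == pytest.approx(20.0, abs=1.0)

    def test_rejects_zero_cycles(self, h1_spec):
        with pytest.raises(ValueError, match="n_cycles"):
            generate_record(h1_spec, 0)

    @pytest.mark.parametrize("label", list(CLASS_SPECS))
    def test_each_segment_has_one_early_percussion_maximum(self, label):
        rec = generate_record(CLASS_SPECS[label], 8, rng=np.random.default_rng(5))
        bounds = np.concatenate((rec.true_boundaries, [len(rec.clean)]))
        for i in range(len(rec.true_boundaries)):
            seg = rec.clean[bounds[i]: bounds[i + 1]]
            peak = int(np.argmax(seg))
            # the percussion maximum sits in the systolic (first) half
            assert 0.02 < peak / len(seg) < 0.5
            # and it is the unique global maximum
            assert np.sum(seg == seg.max()) == 1


class TestClassStructure:
    def test_zero_jitter_yields_fixed_curves(self):
        spec = PulseClassSpec("f", DATASET1_SPECS["Hn"].components, Jitter())
        a = generate_cycle(spec, 200, np.random.default_rng(0))
        b = generate_cycle(spec, 200, np.random.default_rng(99))
        np.testing.assert_array_equal(a, b)

    def test_within_class_tighter_than_between_class(self):
        """With default jitter, mean squared distance within a class stays
        below the distance between any two class means (data set 1)."""
        rng = np.random.default_rng(42)
        draws = {
            label: np.stack([generate_cycle(spec, 200, rng) for _ in range(12)])
            for label, spec in DATASET1_SPECS.items()
        }
        means = {label: d.mean(axis=0) for label, d in draws.items()}
        within = max(
            np.mean((d - means[label]) ** 2)
            for label, d in draws.items()
        )
        between = min(
            np.mean((means[a] - means[b]) ** 2)
            for a in means for b in means if a < b
        )
        assert within < between


class TestCohort:
    def test_empty_mix_gives_empty_cohort(self, rng):
        assert generate_cohort({}, {}, rng=rng) == []

    def test_class_mix_counts_and_diseases(self, rng):
        cohort = generate_cohort({"Hn": 25}, rng=rng, n_cycles_per_subject=1)
        assert len(cohort) == 25
        assert all(s.diseases == frozenset({"hypertension"}) for s in cohort)
        assert all(s.record is not None and s.record.true_label == "Hn" for s in cohort)

    def test_comorbidity_mix_emits_expected_subjects(self, rng):
        mix = {"Td+Hn": 4, "Td+At": 3, "Td+HF": 5, "diabetic foot": 8}
        cohort = generate_cohort({}, mix, rng=rng, n_cycles_per_subject=1)
        assert len(cohort) == 20
        by_label = {}
        for s in cohort:
            by_label.setdefault(s.label, []).append(s)
        assert len(by_label["Td+Hn"]) == 4
        assert by_label["Td+Hn"][0].diseases == {"type 2 diabetes", "hypertension"}
        assert len(by_label["diabetic foot"]) == 8
        assert by_label["diabetic foot"][0].diseases == {"diabetic foot disease"}

    def test_pattern_subjects_have_consistent_parameters(self, rng):
        cohort = generate_cohort({"BP": 5, "H2": 5}, rng=rng, n_cycles_per_subject=1)
        for s in cohort:
            if s.label == "BP":
                assert s.systolic > 140 and s.diastolic > 90
                assert s.cavi <= 9.0 and s.bapwv <= 1400 and s.viscosity <= 5.0
            else:
                assert s.systolic <= 140 and s.diastolic <= 90

    def test_seeded_cohorts_are_identical(self):
        a = generate_cohort({"H1": 3}, rng=np.random.default_rng(6), n_cycles_per_subject=2)
        b = generate_cohort({"H1": 3}, rng=np.random.default_rng(6), n_cycles_per_subject=2)
        for s, t in zip(a, b):
            assert s.subject_id == t.subject_id
            assert s.systolic == t.systolic
            np.testing.assert_array_equal(s.record.samples, t.record.samples)


class TestInvariants:
    def test_subject_profile_rejects_inverted_pressures(self):
        with pytest.raises(ValueError):
            SubjectProfile("x", frozenset(), systolic=80.0, diastolic=90.0,
                           cavi=8.0, bapwv=1200.0, viscosity=4.0)

    def test_component_spec_bounds(self):
        with pytest.raises(ValueError):
            PulseComponentSpec(1.0, 1.5, 0.05)
        with pytest.raises(ValueError):
            PulseComponentSpec(1.0, 0.5, 0.6)
        with pytest.raises(ValueError):
            PulseComponentSpec(-0.1, 0.5, 0.05)

    def test_percussion_must_dominate(self):
        with pytest.raises(ValueError, match="percussion"):
            PulseClassSpec("bad", (
                PulseComponentSpec(0.5, 0.2, 0.05),
                PulseComponentSpec(1.0, 0.4, 0.1),
            ))
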