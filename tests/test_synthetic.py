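"""Synthetic EMR generator: calibration, determinism, planted confounding."""

import dataclasses

import numpy as np
import pytest

import textconfound as tc

NULL_CONFIG = tc.SimulationConfig(
    n_patients=10000,
    confounder_terms={},
    structured_effects={},
    treatment_intercept=0.0,
    true_treatment_loghr=0.0,
    censoring_rate=0.0,
    seed=123,
)


class TestConfigInvariants:
    def test_confounder_terms_must_be_in_vocab(self):
        with pytest.raises(ValueError, match="vocab"):
            tc.SimulationConfig(
                vocab=("a",), confounder_terms={"b": tc.TermEffect(1, 1)}
            )

    def test_censoring_rate_bounds(self):
        with pytest.raises(ValueError, match="censoring_rate"):
            tc.SimulationConfig(censoring_rate=1.5)

    def test_positive_baseline_hazard(self):
        with pytest.raises(ValueError, match="baseline_hazard_rate"):
            tc.SimulationConfig(baseline_hazard_rate=0.0)


class TestGenerateCohort:
    def test_null_treatment_fraction_is_half(self):
        _, manifest = tc.generate_cohort(NULL_CONFIG)
        n = NULL_CONFIG.n_patients
        se = np.sqrt(0.25 / n)
        assert abs(manifest.W.mean() - 0.5) < 3 * se

    def test_determinism_byte_identical(self):
        cfg = dataclasses.replace(tc.SimulationConfig(n_patients=50), seed=7)
        rec_a, man_a = tc.generate_cohort(cfg)
        rec_b, man_b = tc.generate_cohort(cfg)
        assert rec_a == rec_b
        np.testing.assert_array_equal(man_a.term_indicators, man_b.term_indicators)
        np.testing.assert_array_equal(man_a.W, man_b.W)
        np.testing.assert_array_equal(man_a.survival_days, man_b.survival_days)

    def test_treatment_hr_consistency_large_n(self):
        """With b_w = ln 2, no confounding, the Cox HR for W must approach 2."""
        cfg = tc.SimulationConfig(
            n_patients=20000,
            confounder_terms={},
            structured_effects={},
            true_treatment_loghr=np.log(2.0),
            censoring_rate=0.0,
            seed=99,
        )
        _, manifest = tc.generate_cohort(cfg)
        hr = tc.oracle_marginal_hr(manifest, [])
        assert 1.9 <= hr <= 2.1

    def test_censoring_rate_calibrated(self):
        cfg = dataclasses.replace(tc.SimulationConfig(n_patients=8000), seed=5)
        _, manifest = tc.generate_cohort(cfg)
        censored = 1.0 - manifest.event.mean()
        se = np.sqrt(0.2 * 0.8 / cfg.n_patients)
        assert abs(censored - cfg.censoring_rate) < 4 * se

    def test_notes_written_into_records(self, confounded_cohort):
        _, records, manifest = confounded_cohort
        idx = manifest.patient_ids.index(records[0].patient_id)
        active = [
            name
            for k, name in enumerate(manifest.confounder_names)
            if manifest.term_indicators[idx, k] == 1
        ]
        for term in active:
            assert any(term in n.text for n in records[0].notes)


class TestRenderNote:
    def test_active_term_in_affirmative_sentence(self):
        cfg = tc.SimulationConfig(negated_mention_rate=0.0)
        rng = np.random.default_rng(0)
        text = tc.render_note(["bladder"], cfg, rng)
        sentences = tc.segment_sentences(text)
        hits = [s for s in sentences if "bladder" in s]
        assert hits and all("no " not in s.lower() for s in hits)

    def test_zero_negation_rate_means_no_negations(self):
        cfg = tc.SimulationConfig(negated_mention_rate=0.0, noise_term_rate=0.0)
        rng = np.random.default_rng(1)
        text_cfg = tc.TextFeatureConfig(entity_dictionary=frozenset(cfg.vocab))
        for _ in range(20):
            text = tc.render_note(["copd"], cfg, rng, inactive_terms=["smoking"])
            sentences = tc.segment_sentences(text)
            assert tc.filter_negated(sentences, text_cfg) == sentences

    def test_certain_negation_adds_filterable_sentence(self):
        cfg = tc.SimulationConfig(negated_mention_rate=1.0, noise_term_rate=0.0)
        rng = np.random.default_rng(2)
        text = tc.render_note(["copd"], cfg, rng, inactive_terms=["smoking"])
        assert "No history of smoking." in text
        text_cfg = tc.TextFeatureConfig(entity_dictionary=frozenset(cfg.vocab))
        sentences = tc.filter_negated(tc.segment_sentences(text), text_cfg)
        assert not any("smoking" in s for s in sentences)


class TestOracleMarginalHR:
    def test_full_adjustment_recovers_truth(self):
        # confounding flows only through the planted terms here, so the
        # term-adjusted conditional HR is exactly exp(b_w)
        cfg = tc.SimulationConfig(
            n_patients=20000, seed=31, true_treatment_loghr=np.log(1.5),
            structured_effects={},
        )
        _, manifest = tc.generate_cohort(cfg)
        hr = tc.oracle_marginal_hr(manifest, manifest.confounder_names)
        assert abs(hr - 1.5) / 1.5 < 0.05

    def test_unadjusted_is_more_biased(self, confounded_cohort):
        _, _, manifest = confounded_cohort
        truth = np.exp(manifest.true_treatment_loghr)
        adjusted = tc.oracle_marginal_hr(manifest, manifest.confounder_names)
        unadjusted = tc.oracle_marginal_hr(manifest, [])
        assert abs(unadjusted - truth) > abs(adjusted - truth)
        assert unadjusted > truth  # positive gamma_t, gamma_y inflate the HR

    def test_deterministic(self, confounded_cohort):
        _, _, manifest = confounded_cohort
        a = tc.oracle_marginal_hr(manifest, ["bladder"])
        b = tc.oracle_marginal_hr(manifest, ["bladder"])
        assert a == b

    def test_empty_cohort_rejected(self):
        manifest = tc.GroundTruthManifest(
            patient_ids=[], confounder_names=[],
            term_indicators=np.zeros((0, 0)), true_propensity=np.zeros(0),
            W=np.zeros(0, int), survival_days=np.zeros(0), event=np.zeros(0, int),
        )
        with pytest.raises(ValueError, match="empty"):
            tc.oracle_marginal_hr(manifest, [])


class TestCohortRoundTrip:
    def test_write_then_read(self, tmp_path):
        cfg = dataclasses.replace(tc.SimulationConfig(n_patients=20), seed=13)
        records, manifest = tc.generate_cohort(cfg)
        tc.write_cohort(records, manifest, tmp_path)
        back = tc.read_cohort(tmp_path)
        assert len(back) == len(records)
        for orig, rt in zip(records, back):
            assert rt.patient_id == orig.patient_id
            assert rt.survival_days == orig.survival_days
            assert rt.treatment_records == orig.treatment_records
            assert [n.text for n in rt.notes] == [n.text for n in orig.notes]
        manifest_rt = tc.GroundTruthManifest.from_json(tmp_path / "manifest.json")
        np.testing.assert_array_equal(manifest_rt.W, manifest.W)
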