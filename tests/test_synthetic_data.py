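import numpy as np
import pytest
from scipy import stats

from microdcm.synthetic_data import (
    BehavioralRecord,
    CohortSpec,
    generate_behavior,
    generate_cohort,
    read_cohort,
    sample_subject_parameters,
    simulate_subject,
    write_cohort,
)

REDUCED = ("L",)


class TestCohortSpec:
    def test_group_defaults(self):
        older = CohortSpec(group="older")
        assert older.generative_model_id == 2
        assert older.effects.forward_delay_ms == pytest.approx(9.18)
        assert older.effects.frontal_input_mean is not None
        assert older.base_rt == (815.9, 727.0)
        younger = CohortSpec(group="younger")
        assert younger.generative_model_id == 3
        assert younger.effects.forward_delay_ms == pytest.approx(7.98)
        assert younger.effects.frontal_input_mean is None
        assert younger.base_rt == (679.1, 608.8)

    def test_repetition_effect_means(self):
        """Generative defaults reproduce the target novel/repeated means."""
        eff = CohortSpec(group="older").effects
        assert eff.novel_forward_strengths == (1.21, 0.81)
        assert 1.21 * np.exp(eff.repetition_forward_b[0]) == pytest.approx(0.99)
        assert 0.81 * np.exp(eff.repetition_forward_b[1]) == pytest.approx(0.67)
        effy = CohortSpec(group="younger").effects
        assert effy.novel_gain == pytest.approx(1.16)
        assert 1.16 * np.exp(effy.repetition_gain_b) == pytest.approx(0.98)

    def test_validation(self):
        with pytest.raises(ValueError):
            CohortSpec(group="middle")
        with pytest.raises(ValueError):
            CohortSpec(group="older", n_subjects=1)
        with pytest.raises(ValueError):
            CohortSpec(group="older", snr=0.0)


class TestSampleSubjectParameters:
    def test_zero_sd_hits_group_means(self):
        import dataclasses

        base = CohortSpec(group="older", n_subjects=3, hemispheres=REDUCED)
        spec = CohortSpec(
            group="older", n_subjects=3, subject_sd=0.0, hemispheres=REDUCED,
            effects=dataclasses.replace(
                base.effects, forward_delay_sd=0.0,
                forward_delay_edge_jitter_sd=0.0,
            ),
        )
        p = sample_subject_parameters(spec, 0)
        # novel EV->aVT (->ss) physical strength equals the printed 1.21
        z = p.value("Af:EV.L->aVT.L:ss")
        assert np.exp(z) * 1.0 == pytest.approx(1.21)
        # forward delays at the group mean
        zd = p.value("D:f:EV.L->aVT.L")
        assert 8.0 * np.exp(zd) == pytest.approx(9.18)

    def test_younger_gain_defaults(self):
        spec = CohortSpec(group="younger", n_subjects=3, subject_sd=0.0,
                          hemispheres=REDUCED)
        p = sample_subject_parameters(spec, 0)
        novel_gain = np.exp(p.value("G:aVT.L"))
        rep_gain = novel_gain * np.exp(p.value("B:G:aVT.L"))
        assert novel_gain == pytest.approx(1.16, abs=1e-9)
        assert rep_gain == pytest.approx(0.98, abs=1e-9)

    def test_subjects_differ(self):
        spec = CohortSpec(group="older", n_subjects=3, hemispheres=REDUCED)
        p0 = sample_subject_parameters(spec, 0)
        p1 = sample_subject_parameters(spec, 1)
        assert not np.allclose(p0.theta, p1.theta)

    def test_out_of_range_index(self):
        spec = CohortSpec(group="older", n_subjects=2, hemispheres=REDUCED)
        with pytest.raises(ValueError):
            sample_subject_parameters(spec, 5)

    def test_younger_has_no_frontal_input(self):
        spec = CohortSpec(group="younger", n_subjects=2, hemispheres=REDUCED)
        assert sample_subject_parameters(spec, 0).input_strength == 0.0


class TestSimulateSubject:
    def test_noise_free_matches_clean(self, grid):
        spec = CohortSpec(group="older", n_subjects=2, hemispheres=REDUCED, seed=4)
        p = sample_subject_parameters(spec, 0)
        ds, clean = simulate_subject(p, spec, add_noise=False)
        assert np.allclose(ds.stacked(), clean)

    def test_empirical_snr(self):
        """Measured SNR within 10% of the requested value over subjects."""
        spec = CohortSpec(group="older", n_subjects=20, hemispheres=REDUCED,
                          seed=8, snr=5.0)
        ratios = []
        for i in range(spec.n_subjects):
            p = sample_subject_parameters(spec, i)
            ds, clean = simulate_subject(p, spec, subject_index=i)
            noise = ds.stacked() - clean
            ratios.append(np.sqrt((clean**2).mean()) / noise.std())
        assert np.mean(ratios) == pytest.approx(5.0, rel=0.1)

    def test_identical_pre_onset_baseline(self):
        """Condition effects propagate only once the input arrives."""
        spec = CohortSpec(group="older", n_subjects=2, hemispheres=REDUCED, seed=5)
        p = sample_subject_parameters(spec, 0)
        ds, clean = simulate_subject(p, spec, add_noise=False)
        pre = ds.times < 20  # Gaussian-bump tail only
        pre_diff = np.abs(clean[0][:, pre] - clean[1][:, pre]).max()
        post_diff = np.abs(clean[0] - clean[1]).max()
        assert pre_diff < 0.05 * post_diff

    def test_conditions_differ_post_onset(self):
        spec = CohortSpec(group="older", n_subjects=2, hemispheres=REDUCED, seed=5)
        p = sample_subject_parameters(spec, 0)
        _, clean = simulate_subject(p, spec, add_noise=False)
        assert not np.allclose(clean[0], clean[1])


class TestGenerateBehavior:
    def test_noise_free_coupling_is_perfectly_anticorrelated(self):
        spec = CohortSpec(
            group="older", n_subjects=30, hemispheres=REDUCED, seed=6,
            rt_coupling_r=-1.0, rt_condition_jitter_sd=0.0,
        )
        subs = [sample_subject_parameters(spec, i) for i in range(30)]
        beh = generate_behavior(subs, spec)
        x = [b.input_strength for b in beh]
        y = [(b.rt_novel + b.rt_repeated) / 2 for b in beh]
        r, _ = stats.pearsonr(x, y)
        assert r == pytest.approx(-1.0, abs=1e-9)

    def test_older_base_rts_give_printed_priming(self):
        spec = CohortSpec(group="older", n_subjects=3, hemispheres=REDUCED)
        assert spec.base_rt[0] - spec.base_rt[1] == pytest.approx(88.9)

    def test_calibrated_correlation_large_n(self):
        spec = CohortSpec(group="older", n_subjects=200, hemispheres=REDUCED, seed=3)
        subs = [sample_subject_parameters(spec, i) for i in range(200)]
        beh = generate_behavior(subs, spec)
        x = [b.input_strength for b in beh]
        y = [(b.rt_novel + b.rt_repeated) / 2 for b in beh]
        r, _ = stats.pearsonr(x, y)
        assert r == pytest.approx(-0.39, abs=0.1)

    def test_younger_uncoupled(self):
        spec = CohortSpec(group="younger", n_subjects=50, hemispheres=REDUCED, seed=3)
        subs = [sample_subject_parameters(spec, i) for i in range(50)]
        beh = generate_behavior(subs, spec)
        assert all(b.input_strength == 0.0 for b in beh)

    def test_too_few_subjects(self):
        spec = CohortSpec(group="older", n_subjects=2, hemispheres=REDUCED)
        subs = [sample_subject_parameters(spec, i) for i in range(2)]
        with pytest.raises(ValueError, match="3 subjects"):
            generate_behavior(subs, spec)

    def test_positive_rt_validation(self):
        with pytest.raises(ValueError):
            BehavioralRecord("s", -1.0, 700.0, 1.0)


class TestCohort:
    def test_reproducibility(self):
        spec = CohortSpec(group="older", n_subjects=3, hemispheres=REDUCED, seed=11)
        c1 = generate_cohort(spec)
        c2 = generate_cohort(spec)
        for d1, d2 in zip(c1.datasets, c2.datasets):
            for cond in d1.conditions:
                assert np.array_equal(d1.conditions[cond], d2.conditions[cond])
        for b1, b2 in zip(c1.behavior, c2.behavior):
            assert b1 == b2

    def test_write_read_round_trip(self, tmp_path):
        spec = CohortSpec(group="younger", n_subjects=2, hemispheres=REDUCED, seed=12)
        cohort = generate_cohort(spec)
        out = write_cohort(cohort, tmp_path / "cohort")
        manifest, datasets, behavior = read_cohort(out)
        assert manifest["group"] == "younger"
        assert len(datasets) == 2
        for orig, back in zip(cohort.datasets, datasets):
            for cond in orig.conditions:
                assert np.allclose(
                    back.conditions[cond], orig.conditions[cond], atol=1e-8
                )
        assert [b.subject for b in behavior] == [b.subject for b in cohort.behavior]

    def test_byte_identical_writes(self, tmp_path):
        spec = CohortSpec(group="older", n_subjects=3, hemispheres=REDUCED, seed=13)
        p1 = write_cohort(generate_cohort(spec), tmp_path / "a")
        p2 = write_cohort(generate_cohort(spec), tmp_path / "b")
        for f1 in sorted(p1.rglob("*")):
            f2 = p2 / f1.relative_to(p1)
            if f1.is_file():
                assert f1.read_bytes() == f2.read_bytes()

    def test_generative_delay_group_separation(self):
        """Older-like forward delays exceed younger-like across seeds."""
        seeds = range(20)
        ordered = 0
        significant = 0
        for seed in seeds:
            means = {}
            for group in ("older", "younger"):
                spec = CohortSpec(group=group, n_subjects=15,
                                  hemispheres=REDUCED, seed=1000 + seed)
                delays = []
                for i in range(15):
                    p = sample_subject_parameters(spec, i)
                    zf = [p.value(n) for n in p.names if n.startswith("D:f:")]
                    delays.append(np.mean(8.0 * np.exp(zf)))
                means[group] = np.array(delays)
            ordered += means["older"].mean() > means["younger"].mean()
            t, p = stats.ttest_ind(means["older"], means["younger"])
            significant += (t > 0) and (p < 0.05)
        assert ordered >= 19  # >= 95% of seeds
        assert significant >= 16
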