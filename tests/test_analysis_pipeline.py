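import json

import numpy as np
import pytest
from scipy import stats

from microdcm.analysis_pipeline import (
    HARVEST_COLUMNS,
    HarvestTable,
    StudyManifest,
    StudyOptions,
    compare_group_delays,
    correlate_input_behavior,
    harvest_parameters,
    priming_effect,
    run_study,
    test_repetition_effects,
)
from microdcm.inversion import Posterior, pack_parameters
from microdcm.model_space import build_model
from microdcm.synthetic_data import BehavioralRecord, CohortSpec, generate_cohort

REDUCED = ("L",)


def make_posterior(model, ep=None, subject="sub-01", fit=0.9):
    index = pack_parameters(model)
    vec = np.zeros(len(index))
    for name, val in (ep or {}).items():
        vec[index.pos[name]] = val
    return Posterior(
        names=index.names, Ep_vec=vec, Cp=np.eye(len(index)), F=0.0,
        fit=fit, n_iter=1, log_precision=4.0, model_id=model.model_id,
        subject=subject,
    )


class TestPrimingEffect:
    def test_printed_older_means(self):
        assert priming_effect(815.9, 727.0) == pytest.approx(88.9, abs=1e-9)

    def test_equal_rts(self):
        assert priming_effect(700.0, 700.0) == 0.0

    def test_printed_younger_means_exact_arithmetic(self):
        # exact arithmetic gives 70.3 (the rounded summary prints 70.2)
        assert priming_effect(679.1, 608.8) == pytest.approx(70.3, abs=1e-9)

    def test_positive_rts_required(self):
        with pytest.raises(ValueError):
            priming_effect(-1.0, 700.0)


class TestHarvestParameters:
    def test_c_rows_only_for_input_sources(self):
        model = build_model(1, ("L",))
        post = make_posterior(model)
        table = harvest_parameters({"sub-01": post}, model, classes=("C",))
        assert set(table["name"]) == {"C:EV.L"}
        assert (table["condition"] == "-").all()

    def test_zero_b_gives_equal_conditions(self):
        model = build_model(1, ("L",))
        post = make_posterior(model)
        table = harvest_parameters({"sub-01": post}, model, classes=("B",))
        wide = table.pivot_table(index="name", columns="condition", values="value")
        assert np.allclose(wide["novel"], wide["repeated"])

    def test_d_rows_cover_edges_and_self(self):
        model = build_model(2, ("L",))
        post = make_posterior(model)
        table = harvest_parameters({"sub-01": post}, model, classes=("D",))
        n_edges = len(model.forward) + len(model.backward)
        assert len(table) == n_edges + model.n_sources
        # physical scale: default delays in ms
        fwd = table[table["name"].str.startswith("D:f:")]
        assert np.allclose(fwd["value"], 8.0)

    def test_b_rows_resolve_conditions_physically(self):
        model = build_model(1, ("L",))
        post = make_posterior(
            model,
            ep={"Af:EV.L->aVT.L:ss": np.log(1.21), "B:Af:EV.L->aVT.L:ss": -0.2},
        )
        table = harvest_parameters({"sub-01": post}, model, classes=("B",))
        rows = table[table["name"] == "Af:EV.L->aVT.L:ss"]
        novel = rows[rows["condition"] == "novel"]["value"].item()
        rep = rows[rows["condition"] == "repeated"]["value"].item()
        assert novel == pytest.approx(1.21)
        assert rep == pytest.approx(1.21 * np.exp(-0.2))

    def test_absent_class_errors(self):
        model = build_model(1, ("L",))
        for s in model.c:
            model.c[s] = 0.0  # no input sources -> no C parameters
        post = make_posterior(model)
        with pytest.raises(ValueError, match="classes"):
            harvest_parameters({"sub-01": post}, model, classes=("C",))

    def test_mixed_models_rejected(self):
        m1, m2 = build_model(1, ("L",)), build_model(2, ("L",))
        with pytest.raises(ValueError, match="multiple models"):
            harvest_parameters(
                {"a": make_posterior(m1), "b": make_posterior(m2)}, m1
            )

    def test_harvest_conservation(self):
        """Each parameter appears exactly once per subject and condition."""
        model = build_model(2, ("L",))
        index = pack_parameters(model)
        posts = {
            s: make_posterior(model, subject=s) for s in ("sub-01", "sub-02")
        }
        table = harvest_parameters(posts, model)
        counts = table.groupby(["subject", "name", "condition"]).size()
        assert (counts == 1).all()
        n_c = len(index.by_class("C"))
        n_b_targets = sum(
            1 for e in index.by_class("B") if not e.name.startswith("B:G:")
        )
        n_g = len(index.by_class("G"))
        n_d = len(index.by_class("D"))
        expected = n_c + 2 * n_b_targets + 2 * n_g + n_d
        assert len(table) == 2 * expected


class TestCorrelateInputBehavior:
    @staticmethod
    def _harvest(strengths):
        rows = [
            (f"sub-{i:02d}", "older", 2, "C", "C:IFG.L", "-", v)
            for i, v in enumerate(strengths)
        ]
        return HarvestTable(rows, columns=HARVEST_COLUMNS)

    def test_perfect_anticorrelation(self):
        strengths = [1.0, 2.0, 3.0, 4.0]
        beh = [
            BehavioralRecord(f"sub-{i:02d}", 900 - 50 * v, 800 - 50 * v, v)
            for i, v in enumerate(strengths)
        ]
        r, p = correlate_input_behavior(self._harvest(strengths), beh)
        assert r == pytest.approx(-1.0)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        strengths = rng.uniform(0.5, 2.0, 8)
        beh = [
            BehavioralRecord(f"sub-{i:02d}", 800 + rng.normal(0, 30),
                             700 + rng.normal(0, 30), v)
            for i, v in enumerate(strengths)
        ]
        r1, _ = correlate_input_behavior(self._harvest(strengths), beh)
        r2, _ = correlate_input_behavior(self._harvest(strengths), beh[::-1])
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_too_few_pairs(self):
        beh = [BehavioralRecord("sub-00", 800, 700, 1.0)]
        with pytest.raises(ValueError, match="3 paired"):
            correlate_input_behavior(self._harvest([1.0]), beh)

    def test_zero_variance_errors(self):
        beh = [BehavioralRecord(f"sub-{i:02d}", 800, 700, 1.0) for i in range(4)]
        with pytest.raises(ValueError, match="variance"):
            correlate_input_behavior(self._harvest([1.0] * 4), beh)


def _rep_harvest(values_by_subject):
    """values_by_subject: subject -> {(name, condition): value}"""
    rows = []
    for subj, d in values_by_subject.items():
        for (name, cond), v in d.items():
            rows.append((subj, "g", 2, "B", name, cond, v))
    return HarvestTable(rows, columns=HARVEST_COLUMNS)


class TestRepetitionEffects:
    def test_all_zero_contrasts(self):
        data = {
            f"s{i}": {
                ("Af:EV.L->aVT.L:ss", "novel"): 1.2,
                ("Af:EV.L->aVT.L:ss", "repeated"): 1.2,
            }
            for i in range(4)
        }
        res = test_repetition_effects(_rep_harvest(data))
        assert (res["t"] == 0).all()
        assert (res["p_corrected"] == 1.0).all()

    def test_bonferroni_matches_direct_arithmetic(self):
        rng = np.random.default_rng(1)
        names = ["Af:EV.L->aVT.L:ss", "Af:EV.L->aVT.L:dp", "G:aVT.L"]
        data = {}
        for i in range(8):
            d = {}
            for name in names:
                base = rng.uniform(0.8, 1.4)
                d[(name, "novel")] = base
                d[(name, "repeated")] = base - rng.normal(0.1, 0.05)
            data[f"s{i}"] = d
        res = test_repetition_effects(_rep_harvest(data), correction="bonferroni")
        m = len(res)
        assert np.allclose(
            res["p_corrected"], np.minimum(1.0, m * res["p"]), atol=1e-12
        )

    def test_reference_t_oracle(self):
        """Hand-rolled one-sample t against the pipeline output, 50 tables."""
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = rng.integers(3, 9)
            contrasts = rng.normal(0.05, 0.1, int(n))
            data = {
                f"s{i}": {
                    ("Af:EV.L->aVT.L:ss", "novel"): 1.0 + contrasts[i],
                    ("Af:EV.L->aVT.L:ss", "repeated"): 1.0,
                }
                for i in range(int(n))
            }
            res = test_repetition_effects(_rep_harvest(data))
            mean = contrasts.mean()
            se = contrasts.std(ddof=1) / np.sqrt(n)
            t_ref = mean / se
            p_ref = 2 * stats.t.sf(abs(t_ref), n - 1)
            assert res["t"].item() == pytest.approx(t_ref, abs=1e-10)
            assert res["p"].item() == pytest.approx(p_ref, abs=1e-10)

    def test_ventral_filter_excludes_dorsal(self):
        data = {
            f"s{i}": {
                ("Af:EV.L->AG.L:ss", "novel"): 1.0,
                ("Af:EV.L->AG.L:ss", "repeated"): 0.9,
                ("Af:EV.L->aVT.L:ss", "novel"): 1.2,
                ("Af:EV.L->aVT.L:ss", "repeated"): 1.0,
            }
            for i in range(3)
        }
        res = test_repetition_effects(_rep_harvest(data), ventral_only=True)
        assert list(res["name"]) == ["Af:EV.L->aVT.L:ss"]

    def test_single_subject_errors(self):
        data = {"s0": {("Af:EV.L->aVT.L:ss", "novel"): 1.0,
                       ("Af:EV.L->aVT.L:ss", "repeated"): 0.9}}
        with pytest.raises(ValueError, match="2 subjects"):
            test_repetition_effects(_rep_harvest(data))

    def test_unknown_correction(self):
        with pytest.raises(ValueError, match="correction"):
            test_repetition_effects(_rep_harvest({}), correction="sidak")


def _delay_harvest(group, per_subject):
    rows = []
    for subj, delays in per_subject.items():
        for name, v in delays.items():
            rows.append((subj, group, 2, "D", name, "-", v))
    return HarvestTable(rows, columns=HARVEST_COLUMNS)


class TestCompareGroupDelays:
    names = ["D:f:EV.L->aVT.L", "D:b:aVT.L->EV.L", "D:self:EV.L"]

    def _group(self, rng, fwd_mean, n=5):
        return {
            f"s{i}": {
                "D:f:EV.L->aVT.L": rng.normal(fwd_mean, 0.5),
                "D:b:aVT.L->EV.L": rng.normal(8.0, 0.5),
                "D:self:EV.L": rng.normal(1.0, 0.05),
            }
            for i in range(n)
        }

    def test_identical_groups_t_zero(self):
        fixed = {f"s{i}": {n: 8.0 for n in self.names} for i in range(4)}
        res = compare_group_delays(
            _delay_harvest("a", fixed), _delay_harvest("b", fixed), ("a", "b")
        )
        assert (res["t"] == 0).all()

    def test_forward_difference_detected(self):
        rng = np.random.default_rng(3)
        a = _delay_harvest("older", self._group(rng, 10.5, n=10))
        b = _delay_harvest("younger", self._group(rng, 8.0, n=10))
        res = compare_group_delays(a, b, ("older", "younger")).set_index(
            "delay_class"
        )
        assert res.loc["forward", "t"] > 0
        assert res.loc["forward", "p"] < 0.01
        assert res.loc["backward", "p"] > 0.05

    def test_reference_two_sample_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            na, nb = rng.integers(3, 8, 2)
            xa = rng.normal(9.0, 1.0, int(na))
            xb = rng.normal(8.0, 1.0, int(nb))
            ha = _delay_harvest("a", {
                f"s{i}": {"D:f:X": v, "D:b:X": 8.0, "D:self:X": 1.0}
                for i, v in enumerate(xa)
            })
            hb = _delay_harvest("b", {
                f"s{i}": {"D:f:X": v, "D:b:X": 8.0, "D:self:X": 1.0}
                for i, v in enumerate(xb)
            })
            res = compare_group_delays(ha, hb, ("a", "b")).set_index("delay_class")
            # pooled-variance two-sample t computed from first principles
            sa2 = xa.var(ddof=1)
            sb2 = xb.var(ddof=1)
            sp2 = ((na - 1) * sa2 + (nb - 1) * sb2) / (na + nb - 2)
            t_ref = (xa.mean() - xb.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
            assert res.loc["forward", "t"] == pytest.approx(t_ref, abs=1e-10)

    def test_missing_class_errors(self):
        ha = _delay_harvest("a", {"s0": {"D:f:X": 8.0}, "s1": {"D:f:X": 8.5}})
        with pytest.raises(ValueError, match="prefix"):
            compare_group_delays(ha, ha, ("a", "b"))

    def test_singleton_group_errors(self):
        full = {f"s{i}": {n: 8.0 for n in self.names} for i in range(3)}
        single = {"s0": {n: 8.0 for n in self.names}}
        with pytest.raises(ValueError, match="2 subjects"):
            compare_group_delays(
                _delay_harvest("a", full), _delay_harvest("b", single), ("a", "b")
            )


@pytest.fixture(scope="module")
def tiny_study():
    data, beh = {}, {}
    for group in ("older", "younger"):
        c = generate_cohort(
            CohortSpec(group=group, n_subjects=3, hemispheres=REDUCED, seed=21)
        )
        data[group] = c.datasets
        beh[group] = c.behavior
    options = StudyOptions(
        hemispheres=REDUCED, max_iter=8, n_bms_samples=50_000, seed=2,
        model_ids=(1, 2),
    )
    return data, beh, options


class TestRunStudy:
    def test_report_structure(self, tiny_study, tmp_path):
        data, beh, options = tiny_study
        report = run_study(data, beh, options, out_dir=tmp_path / "out")
        for group in ("older", "younger"):
            g = report["groups"][group]
            assert "family_bms" in g and "model_bms" in g
            assert g["winning_family"] in (1, 2)
            assert g["winning_model"] in (1, 2)
            assert "behavior" in g
        assert "delay_comparison" in report
        assert "behavior_comparison" in report
        assert (tmp_path / "out" / "report.json").exists()
        assert (tmp_path / "out" / "harvest_older.tsv").exists()

    def test_determinism(self, tiny_study):
        data, beh, options = tiny_study
        r1 = run_study(data, beh, options)
        r2 = run_study(data, beh, options)
        assert json.dumps(r1, sort_keys=True) == json.dumps(r2, sort_keys=True)

    def test_empty_study_rejected(self):
        with pytest.raises(ValueError):
            run_study({}, {}, StudyOptions())


class TestStudyManifest:
    def test_json_manifest(self, tmp_path):
        path = tmp_path / "study.json"
        path.write_text(json.dumps({
            "groups": {"older": "cohort_old"},
            "options": {"max_iter": 8, "hemispheres": ["L"]},
        }))
        m = StudyManifest.from_file(path)
        assert m.groups == {"older": "cohort_old"}
        assert m.options.max_iter == 8
        assert m.options.hemispheres == ("L",)

    def test_yaml_manifest(self, tmp_path):
        path = tmp_path / "study.yaml"
        path.write_text(
            "groups:\n  older: cohort_old\noptions:\n  correction: holm\n"
        )
        m = StudyManifest.from_file(path)
        assert m.options.correction == "holm"

    def test_empty_groups_rejected(self, tmp_path):
        path = tmp_path / "study.json"
        path.write_text(json.dumps({"groups": {}}))
        with pytest.raises(ValueError):
            StudyManifest.from_file(path)

    def test_bad_correction_rejected(self):
        with pytest.raises(ValueError, match="correction"):
            StudyOptions(correction="sidak")
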