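"""End-to-end study orchestration and downstream parameter statistics.

``run_study`` inverts every model for every subject, applies the low-fit
re-initialization pass, runs family-level then within-family random-effects
model selection per group, harvests posterior parameters from each group's
winning model, and computes the behavioral and parameter statistics
(priming effects, input-strength/RT correlation, repetition-effect t-tests,
group conduction-delay comparison).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import ERPDataset
from .inversion import (
    InversionError,
    Posterior,
    PriorSpec,
    pack_parameters,
    reinitialize_low_fit,
    variational_laplace,
)
from .model_selection import EvidenceTable, family_bms, rfx_bms
from .model_space import CONDITIONS, NetworkModel, build_model, family_partition
from .neural_dynamics import CMCParameters, SimulationGrid, StimulusInput
from .observation_model import ObservationSpec
from .synthetic_data import BehavioralRecord, read_cohort

logger = logging.getLogger(__name__)

__all__ = [
    "StudyOptions",
    "StudyManifest",
    "HarvestTable",
    "harvest_parameters",
    "priming_effect",
    "correlate_input_behavior",
    "test_repetition_effects",
    "compare_group_delays",
    "invert_group",
    "run_study",
    "run_study_from_manifest",
]

_CORRECTIONS = {"bonferroni": "bonferroni", "holm": "holm", "fdr-bh": "fdr_bh"}

#: columns of the long-format harvest table
HARVEST_COLUMNS = [
    "subject", "group", "model_id", "class", "name", "condition", "value",
]


class HarvestTable(pd.DataFrame):
    """Long-format table of harvested physical-scale parameter values."""

    @property
    def _constructor(self):
        return HarvestTable


@dataclass
class StudyOptions:
    """Analysis options shared by the whole run."""

    fit_threshold: float = 0.75
    correction: str = "bonferroni"
    alpha: float = 0.05
    seed: int = 0
    n_bms_samples: int = 1_000_000
    max_iter: int = 64
    model_ids: tuple[int, ...] = (1, 2, 3)
    hemispheres: tuple[str, ...] = ("L", "R")
    rt_summary: str = "mean"  # 'mean' | 'novel' | 'repeated'

    def __post_init__(self) -> None:
        if self.correction not in _CORRECTIONS:
            raise ValueError(
                f"unknown correction {self.correction!r}; "
                f"choose from {sorted(_CORRECTIONS)}"
            )
        if self.rt_summary not in ("mean", "novel", "repeated"):
            raise ValueError("rt_summary must be 'mean', 'novel' or 'repeated'")


@dataclass
class StudyManifest:
    """File-based description of a study: groups of cohort directories."""

    groups: dict[str, str]  # group label -> cohort directory
    options: StudyOptions = field(default_factory=StudyOptions)

    @classmethod
    def from_file(cls, path) -> "StudyManifest":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            d = yaml.safe_load(text)
        else:
            d = json.loads(text)
        opts = StudyOptions(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in d.get("options", {}).items()
        })
        groups = d["groups"]
        if not groups:
            raise ValueError("manifest must declare at least one group")
        return cls(groups=groups, options=opts)


# ----------------------------------------------------------------------
# parameter harvesting
# ----------------------------------------------------------------------


def harvest_parameters(
    posteriors: Mapping[str, Posterior],
    model: NetworkModel,
    classes: Sequence[str] = ("C", "B", "G", "D"),
    group: str | None = None,
) -> HarvestTable:
    """Physical-scale posterior parameter values in long format.

    For B-modulated parameters both the novel and repeated effective
    strengths are emitted (class ``B``); gains (class ``G``) are likewise
    condition-resolved.  Input gains (``C``) and conduction delays (``D``)
    are condition-independent.
    """
    classes = list(classes)
    index = pack_parameters(model)
    available = {e.cls for e in index.entries}
    missing = set(classes) - available
    if missing:
        raise ValueError(
            f"classes {sorted(missing)} not present in model {model.model_id}"
        )
    model_ids = {p.model_id for p in posteriors.values()}
    if len(model_ids) > 1:
        raise ValueError(f"posteriors span multiple models: {sorted(model_ids)}")

    defaults = {e.name: e.default for e in index.entries}
    rows = []
    for subject, post in posteriors.items():
        ep = post.Ep
        if "C" in classes:
            for e in index.by_class("C"):
                rows.append(
                    (subject, group, model.model_id, "C", e.name, "-",
                     e.default * np.exp(ep[e.name]))
                )
        if "B" in classes:
            for e in index.by_class("B"):
                target = e.name[2:]  # strip the 'B:' prefix
                if target.startswith("G:"):
                    continue  # gains are reported under class G
                base = defaults[target] * np.exp(ep[target])
                rows.append(
                    (subject, group, model.model_id, "B", target, "novel", base)
                )
                rows.append(
                    (subject, group, model.model_id, "B", target, "repeated",
                     base * np.exp(ep[e.name]))
                )
        if "G" in classes:
            for e in index.by_class("G"):
                base = np.exp(ep[e.name])
                rows.append(
                    (subject, group, model.model_id, "G", e.name, "novel", base)
                )
                bname = f"B:{e.name}"
                if bname in ep:
                    rows.append(
                        (subject, group, model.model_id, "G", e.name, "repeated",
                         base * np.exp(ep[bname]))
                    )
        if "D" in classes:
            for e in index.by_class("D"):
                rows.append(
                    (subject, group, model.model_id, "D", e.name, "-",
                     e.default * np.exp(ep[e.name]))
                )
    return HarvestTable(rows, columns=HARVEST_COLUMNS)


# ----------------------------------------------------------------------
# statistics
# ----------------------------------------------------------------------


def priming_effect(rt_novel: float, rt_repeated: float) -> float:
    """Priming in ms: novel RT minus repeated RT."""
    if rt_novel <= 0 or rt_repeated <= 0:
        raise ValueError("reaction times must be positive")
    return rt_novel - rt_repeated


def correlate_input_behavior(
    harvest: HarvestTable,
    behavior: Sequence[BehavioralRecord],
    rt_summary: str = "mean",
) -> tuple[float, float]:
    """Pearson correlation between frontal input strength and naming speed.

    Input strength is the harvested exogenous gain at left IFG (falling
    back to any IFG input source for single-hemisphere networks); RT is
    summarized per subject according to ``rt_summary``.
    """
    c_rows = harvest[(harvest["class"] == "C")
                     & harvest["name"].str.contains("IFG")]
    left = c_rows[c_rows["name"].str.endswith(".L")]
    if len(left):
        c_rows = left
    if not len(c_rows):
        raise ValueError("no IFG input gain in harvest table")
    strength = c_rows.set_index("subject")["value"]

    rts = {}
    for rec in behavior:
        if rt_summary == "novel":
            rts[rec.subject] = rec.rt_novel
        elif rt_summary == "repeated":
            rts[rec.subject] = rec.rt_repeated
        else:
            rts[rec.subject] = 0.5 * (rec.rt_novel + rec.rt_repeated)

    common = [s for s in strength.index if s in rts]
    if len(common) < 3:
        raise ValueError("need >= 3 paired observations")
    x = strength.loc[common].to_numpy(dtype=float)
    y = np.array([rts[s] for s in common])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in input strength or RT")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def _ventral_stream_mask(names: pd.Series) -> pd.Series:
    """Edges/gains on the EV -> aVT -> IFG route."""
    def on_route(name: str) -> bool:
        if name.startswith(("Af:", "Ab:")):
            edge = name.split(":")[1]
            src, dst = edge.split("->")
            regions = {src.split(".")[0], dst.split(".")[0]}
            return regions in ({"EV", "aVT"}, {"aVT", "IFG"}, {"EV", "IFG"})
        if name.startswith("G:"):
            return name.split(":")[1].split(".")[0] in ("EV", "aVT", "IFG")
        return False

    return names.map(on_route)


def test_repetition_effects(
    harvest: HarvestTable,
    correction: str = "bonferroni",
    ventral_only: bool = True,
) -> pd.DataFrame:
    """One-sample t-tests of the novel-repeated contrast per parameter.

    Works on the condition-resolved rows (classes B and G) of a harvest
    table; returns a frame with the mean contrast, t, raw and corrected p
    per parameter.
    """
    if correction not in _CORRECTIONS:
        raise ValueError(f"unknown correction {correction!r}")
    resolved = harvest[harvest["condition"].isin(CONDITIONS)]
    if ventral_only:
        resolved = resolved[_ventral_stream_mask(resolved["name"])]
    if not len(resolved):
        raise ValueError("no condition-resolved parameters to test")

    wide = resolved.pivot_table(
        index=["name", "subject"], columns="condition", values="value"
    )
    if wide.isna().any().any():
        raise ValueError("unbalanced conditions in harvest table")
    wide["contrast"] = wide["novel"] - wide["repeated"]

    out = []
    for name, sub in wide.groupby(level="name"):
        contrasts = sub["contrast"].to_numpy()
        if len(contrasts) < 2:
            raise ValueError(f"fewer than 2 subjects for parameter {name!r}")
        if np.allclose(contrasts, 0.0):
            t, p = 0.0, 1.0
        elif np.ptp(contrasts) == 0:
            # nonzero constant contrast: infinite t, p -> 0
            t = np.inf if contrasts[0] > 0 else -np.inf
            p = 0.0
        else:
            t, p = stats.ttest_1samp(contrasts, 0.0)
        out.append((name, len(contrasts), float(np.mean(contrasts)), float(t), float(p)))
    res = pd.DataFrame(out, columns=["name", "n", "mean_contrast", "t", "p"])
    _, p_corr, _, _ = multipletests(res["p"], method=_CORRECTIONS[correction])
    res["p_corrected"] = np.minimum(p_corr, 1.0)
    return res


# the name follows the operation it implements; tell pytest it is not a test
test_repetition_effects.__test__ = False  # type: ignore[attr-defined]


_DELAY_CLASSES = {"forward": "D:f:", "backward": "D:b:", "self": "D:self:"}


def _subject_mean_delays(harvest: HarvestTable, prefix: str) -> pd.Series:
    d = harvest[(harvest["class"] == "D") & harvest["name"].str.startswith(prefix)]
    if not len(d):
        raise ValueError(f"no delay parameters with prefix {prefix!r}")
    return d.groupby("subject")["value"].mean()


def compare_group_delays(
    harvest_a: HarvestTable,
    harvest_b: HarvestTable,
    labels: tuple[str, str] = ("older", "younger"),
) -> pd.DataFrame:
    """Two-sample t-tests on subject-mean conduction delays per class."""
    rows = []
    for cls, prefix in _DELAY_CLASSES.items():
        a = _subject_mean_delays(harvest_a, prefix).to_numpy()
        b = _subject_mean_delays(harvest_b, prefix).to_numpy()
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"need >= 2 subjects per group for class {cls!r}")
        if np.ptp(a) == 0 and np.ptp(b) == 0 and np.isclose(a.mean(), b.mean()):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(a, b)
        rows.append(
            (cls, len(a), len(b), float(a.mean()), float(b.mean()),
             float(t), float(p))
        )
    return pd.DataFrame(
        rows,
        columns=["delay_class", f"n_{labels[0]}", f"n_{labels[1]}",
                 f"mean_{labels[0]}", f"mean_{labels[1]}", "t", "p"],
    )


# ----------------------------------------------------------------------
# orchestration
# ----------------------------------------------------------------------


def invert_group(
    datasets: Sequence[ERPDataset],
    models: Sequence[NetworkModel],
    priors: PriorSpec,
    options: StudyOptions,
    *,
    grid: SimulationGrid | None = None,
    stimulus: StimulusInput | None = None,
    obs_spec: ObservationSpec | None = None,
    cmc: CMCParameters | None = None,
    fit_threshold: float | None = None,
) -> dict[int, dict[str, Posterior]]:
    """Invert every model for every subject, with the low-fit refit pass.

    After the first pass, subjects whose fit fell below the threshold are
    re-inverted starting from the mean posterior of the above-threshold
    subjects (per model).  Refits replace originals only when they improve
    the free energy.
    """
    threshold = options.fit_threshold if fit_threshold is None else fit_threshold
    out: dict[int, dict[str, Posterior]] = {}
    for model in models:
        index = pack_parameters(model)
        posteriors: dict[str, Posterior] = {}
        for ds in datasets:
            t0 = time.perf_counter()
            post = variational_laplace(
                ds, model, priors,
                grid=grid, stimulus=stimulus, obs_spec=obs_spec, cmc=cmc,
                index=index, max_iter=options.max_iter,
            )
            posteriors[ds.subject] = post
            logger.info(
                "model %d subject %s: F=%.1f fit=%.3f (%.1fs)",
                model.model_id, ds.subject, post.F, post.fit,
                time.perf_counter() - t0,
            )
        try:
            inits = reinitialize_low_fit(posteriors, threshold)
        except InversionError:
            logger.warning(
                "model %d: no subject above fit threshold %.2f; skipping refits",
                model.model_id, threshold,
            )
            inits = {}
        for subject, init in inits.items():
            ds = next(d for d in datasets if d.subject == subject)
            refit = variational_laplace(
                ds, model, priors, init=init,
                grid=grid, stimulus=stimulus, obs_spec=obs_spec, cmc=cmc,
                index=index, max_iter=options.max_iter,
            )
            if refit.F > posteriors[subject].F:
                posteriors[subject] = refit
        out[model.model_id] = posteriors
    return out


def _evidence_table(
    posteriors: dict[int, dict[str, Posterior]],
    subjects: Sequence[str],
    group: str,
) -> EvidenceTable:
    model_ids = sorted(posteriors)
    L = np.array(
        [[posteriors[m][s].F for m in model_ids] for s in subjects]
    )
    return EvidenceTable(L, model_ids=model_ids, subjects=list(subjects), group=group)


def run_study(
    datasets_by_group: Mapping[str, Sequence[ERPDataset]],
    behavior_by_group: Mapping[str, Sequence[BehavioralRecord]] | None = None,
    options: StudyOptions | None = None,
    *,
    priors: PriorSpec | None = None,
    grid: SimulationGrid | None = None,
    stimulus: StimulusInput | None = None,
    obs_spec: ObservationSpec | None = None,
    cmc: CMCParameters | None = None,
    out_dir=None,
    return_details: bool = False,
):
    """Run the full analysis and return a JSON-serializable report.

    Deterministic given the data and ``options.seed``.  If ``out_dir`` is
    given, the report, evidence tables and harvest tables are written there
    and each stage is checkpointed as it completes.  With
    ``return_details=True`` a ``(report, details)`` tuple is returned, where
    ``details`` holds the per-group posteriors and harvest tables.
    """
    options = options or StudyOptions()
    priors = priors or PriorSpec()
    behavior_by_group = behavior_by_group or {}
    if not datasets_by_group:
        raise ValueError("at least one group is required")

    models = [build_model(m, options.hemispheres) for m in options.model_ids]
    partition = family_partition(models)
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    report: dict = {
        "options": {
            "fit_threshold": options.fit_threshold,
            "correction": options.correction,
            "alpha": options.alpha,
            "seed": options.seed,
            "model_ids": list(options.model_ids),
            "hemispheres": list(options.hemispheres),
            "rt_summary": options.rt_summary,
        },
        "families": {str(k): v for k, v in partition.items()},
        "groups": {},
        "stages": [],
    }

    def checkpoint(stage: str) -> None:
        report["stages"].append(stage)
        if out_path is not None:
            with open(out_path / "report.json", "w") as fh:
                json.dump(_to_jsonable(report), fh, indent=2, sort_keys=True)
                fh.write("\n")

    harvests: dict[str, HarvestTable] = {}
    details: dict[str, dict] = {}
    for group in sorted(datasets_by_group):
        datasets = list(datasets_by_group[group])
        subjects = [d.subject for d in datasets]
        posteriors = invert_group(
            datasets, models, priors, options,
            grid=grid, stimulus=stimulus, obs_spec=obs_spec, cmc=cmc,
        )
        checkpoint(f"invert:{group}")

        table = _evidence_table(posteriors, subjects, group)
        fam_res = family_bms(
            table, partition,
            n_samples=options.n_bms_samples, seed=options.seed,
        )
        model_res = rfx_bms(
            table, n_samples=options.n_bms_samples, seed=options.seed + 1
        )
        fam23 = [m for m in table.model_ids if m in partition.get(2, [])]
        within = None
        if len(fam23) >= 2:
            within = rfx_bms(
                table.select(fam23),
                n_samples=options.n_bms_samples, seed=options.seed + 2,
            )

        win_family = int(fam_res.labels[int(np.argmax(fam_res.exceedance_prob))])
        members = partition[win_family]
        if len(members) == 1:
            win_model = members[0]
        else:
            sub = table.select(members)
            sub_res = rfx_bms(
                sub, n_samples=options.n_bms_samples, seed=options.seed + 3
            )
            win_model = members[int(np.argmax(sub_res.exceedance_prob))]
        checkpoint(f"bms:{group}")

        win_model_obj = next(m for m in models if m.model_id == win_model)
        harvest = harvest_parameters(
            posteriors[win_model], win_model_obj, ("C", "B", "G", "D"), group
        )
        harvests[group] = harvest
        if out_path is not None:
            harvest.to_csv(out_path / f"harvest_{group}.tsv", sep="\t", index=False)
        checkpoint(f"harvest:{group}")

        group_report = {
            "subjects": subjects,
            "fits": {
                str(m): {s: posteriors[m][s].fit for s in subjects}
                for m in sorted(posteriors)
            },
            "evidence": {
                "model_ids": table.model_ids,
                "log_evidence": table.log_evidence.tolist(),
            },
            "family_bms": fam_res.to_dict(),
            "model_bms": model_res.to_dict(),
            "model2_vs_3": within.to_dict() if within is not None else None,
            "winning_family": win_family,
            "winning_model": win_model,
        }

        behavior = list(behavior_by_group.get(group, []))
        if behavior:
            priming = [priming_effect(b.rt_novel, b.rt_repeated) for b in behavior]
            group_report["behavior"] = {
                "mean_rt_novel": float(np.mean([b.rt_novel for b in behavior])),
                "mean_rt_repeated": float(
                    np.mean([b.rt_repeated for b in behavior])
                ),
                "mean_priming_ms": float(np.mean(priming)),
            }
            has_ifg_input = bool(
                ((harvest["class"] == "C")
                 & harvest["name"].str.contains("IFG")).any()
            )
            if has_ifg_input:
                r, p = correlate_input_behavior(
                    harvest, behavior, options.rt_summary
                )
                group_report["input_rt_correlation"] = {"r": r, "p": p}

        try:
            rep = test_repetition_effects(harvest, options.correction)
            group_report["repetition_effects"] = rep.to_dict(orient="records")
        except ValueError as err:
            group_report["repetition_effects"] = {"error": str(err)}

        report["groups"][group] = group_report
        details[group] = {
            "posteriors": posteriors,
            "harvest": harvest,
            "evidence": table,
            "winning_model": win_model,
        }
        checkpoint(f"stats:{group}")

    group_names = sorted(datasets_by_group)
    if len(group_names) == 2:
        a, b = group_names
        delays = compare_group_delays(harvests[a], harvests[b], (a, b))
        report["delay_comparison"] = {
            "groups": [a, b],
            "table": delays.to_dict(orient="records"),
        }
        beh_a = behavior_by_group.get(a)
        beh_b = behavior_by_group.get(b)
        if beh_a and beh_b:
            pa = [priming_effect(x.rt_novel, x.rt_repeated) for x in beh_a]
            pb = [priming_effect(x.rt_novel, x.rt_repeated) for x in beh_b]
            t_n, p_n = stats.ttest_ind(
                [x.rt_novel for x in beh_a], [x.rt_novel for x in beh_b]
            )
            t_r, p_r = stats.ttest_ind(
                [x.rt_repeated for x in beh_a], [x.rt_repeated for x in beh_b]
            )
            t_p, p_p = stats.ttest_ind(pa, pb)
            report["behavior_comparison"] = {
                "groups": [a, b],
                "novel_rt": {"t": float(t_n), "p": float(p_n)},
                "repeated_rt": {"t": float(t_r), "p": float(p_r)},
                "priming": {"t": float(t_p), "p": float(p_p)},
            }
    checkpoint("group_comparison")

    report = _to_jsonable(report)
    if out_path is not None:
        with open(out_path / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
    if return_details:
        return report, details
    return report


def run_study_from_manifest(manifest: StudyManifest, out_dir=None) -> dict:
    """Load written cohorts per the manifest and run the study."""
    datasets_by_group = {}
    behavior_by_group = {}
    for group, cohort_dir in manifest.groups.items():
        _, datasets, behavior = read_cohort(cohort_dir)
        datasets_by_group[group] = datasets
        behavior_by_group[group] = behavior
    return run_study(
        datasets_by_group, behavior_by_group, manifest.options, out_dir=out_dir
    )


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return str(obj)
    return obj
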