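"""Ground-truth cohort generation: evoked datasets plus behavior.

Two cohort archetypes are provided.  The *older-like* cohort is generated
from the dual-input architecture (model 2): positive exogenous input gain
at inferior frontal gyrus, repetition effects on the EV->aVT forward
connection strengths, longer forward conduction delays, and reaction times
negatively coupled to the frontal input strength.  The *younger-like*
cohort is generated from model 3 (visual input plus a direct EV->IFG
feedforward edge): repetition effects on anterior ventral temporal
superficial-pyramidal gain, shorter forward delays, and reaction times
uncoupled from input strength.

The generative forward model is exactly the one the inversion fits, so
parameter-recovery benchmarks are well posed by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .data import ERPDataset, read_dataset, write_dataset
from .inversion import ParameterIndex, build_condition_arrays, pack_parameters
from .model_space import CONDITIONS, NetworkModel, build_model
from .neural_dynamics import (
    CMCParameters,
    SimulationGrid,
    StimulusInput,
    compile_network,
    simulate_batch,
)
from .observation_model import ObservationSpec, observe

__all__ = [
    "Effects",
    "CohortSpec",
    "SubjectParameters",
    "BehavioralRecord",
    "CohortData",
    "sample_subject_parameters",
    "simulate_subject",
    "generate_behavior",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]


@dataclass(frozen=True)
class Effects:
    """Group-level generative effects (means on the physical scale)."""

    #: baseline ('novel') EV->aVT forward strengths, (->ss, ->dp) components
    novel_forward_strengths: tuple[float, float] | None = None
    #: log drop applied to those strengths for repeated stimuli
    repetition_forward_b: tuple[float, float] | None = None
    #: baseline aVT superficial-pyramidal gain and its repetition log drop
    novel_gain: float | None = None
    repetition_gain_b: float | None = None
    #: group mean / between-subject SD of the subject-level forward delay (ms)
    forward_delay_ms: float = 8.0
    forward_delay_sd: float = 0.8
    #: within-subject per-edge jitter around the subject-level delay (ms)
    forward_delay_edge_jitter_sd: float = 0.3
    #: mean exogenous input gain at IFG (None = no frontal input)
    frontal_input_mean: float | None = None
    #: between-subject SD (log scale) of the frontal input gain
    frontal_input_sd: float = 0.3


_OLDER_EFFECTS = Effects(
    novel_forward_strengths=(1.21, 0.81),
    repetition_forward_b=(float(np.log(0.99 / 1.21)), float(np.log(0.67 / 0.81))),
    novel_gain=None,
    repetition_gain_b=None,
    forward_delay_ms=9.18,
    forward_delay_sd=1.04,
    frontal_input_mean=1.0,
)
_YOUNGER_EFFECTS = Effects(
    novel_forward_strengths=None,
    repetition_forward_b=None,
    novel_gain=1.16,
    repetition_gain_b=float(np.log(0.98 / 1.16)),
    forward_delay_ms=7.98,
    forward_delay_sd=0.64,
    frontal_input_mean=None,
)
_GROUP_DEFAULTS = {
    "older": dict(
        generative_model_id=2,
        effects=_OLDER_EFFECTS,
        base_rt=(815.9, 727.0),
        rt_coupling_r=-0.39,
    ),
    "younger": dict(
        generative_model_id=3,
        effects=_YOUNGER_EFFECTS,
        base_rt=(679.1, 608.8),
        rt_coupling_r=0.0,
    ),
}


@dataclass(frozen=True)
class CohortSpec:
    """Specification of one synthetic cohort."""

    group: str
    n_subjects: int = 15
    generative_model_id: int | None = None
    subject_sd: float = 0.15
    snr: float = 5.0
    effects: Effects | None = None
    base_rt: tuple[float, float] | None = None  # (novel, repeated) group means, ms
    rt_sd: float = 50.0            # SD of mean RT across subjects
    rt_condition_jitter_sd: float = 27.0
    rt_coupling_r: float | None = None
    hemispheres: tuple[str, ...] = ("L", "R")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group not in _GROUP_DEFAULTS:
            raise ValueError(f"unknown group {self.group!r}; use 'older'/'younger'")
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if not self.snr > 0:
            raise ValueError("snr must be > 0")
        defaults = _GROUP_DEFAULTS[self.group]
        if self.generative_model_id is None:
            object.__setattr__(
                self, "generative_model_id", defaults["generative_model_id"]
            )
        if self.generative_model_id not in (1, 2, 3):
            raise ValueError("generative_model_id must be 1, 2 or 3")
        if self.effects is None:
            object.__setattr__(self, "effects", defaults["effects"])
        if self.base_rt is None:
            object.__setattr__(self, "base_rt", defaults["base_rt"])
        if self.rt_coupling_r is None:
            object.__setattr__(self, "rt_coupling_r", defaults["rt_coupling_r"])


@dataclass
class SubjectParameters:
    """One subject's generative log-scaling vector and metadata."""

    subject: str
    theta: np.ndarray
    names: list[str]
    input_strength: float  # physical exogenous gain at left IFG (0 if none)

    def value(self, name: str) -> float:
        return float(self.theta[self.names.index(name)])


@dataclass
class BehavioralRecord:
    subject: str
    rt_novel: float
    rt_repeated: float
    input_strength: float

    def __post_init__(self) -> None:
        if self.rt_novel <= 0 or self.rt_repeated <= 0:
            raise ValueError("reaction times must be positive")


@dataclass
class CohortData:
    """A fully generated cohort with its ground truth."""

    spec: CohortSpec
    model: NetworkModel
    index: ParameterIndex
    subjects: list[SubjectParameters]
    datasets: list[ERPDataset]
    behavior: list[BehavioralRecord]
    clean: dict[str, np.ndarray] = field(default_factory=dict, repr=False)


def _group_mean_vector(spec: CohortSpec, model: NetworkModel,
                       index: ParameterIndex) -> np.ndarray:
    """Group-level mean log-scaling vector implied by the cohort effects."""
    eff = spec.effects
    mean = np.zeros(len(index))
    # EV->aVT forward strengths and their modulations
    for e in model.forward:
        src_region = e.src.split(".")[0]
        dst_region = e.dst.split(".")[0]
        if src_region == "EV" and dst_region == "aVT":
            if eff.novel_forward_strengths is not None:
                for comp, target in zip(("ss", "dp"), eff.novel_forward_strengths):
                    nm = f"Af:{e.key}:{comp}"
                    default = dict(zip(("ss", "dp"), model.a_forward[e.key]))[comp]
                    mean[index.pos[nm]] = np.log(target / default)
            if eff.repetition_forward_b is not None:
                for comp, b in zip(("ss", "dp"), eff.repetition_forward_b):
                    nm = f"B:Af:{e.key}:{comp}"
                    if nm in index.pos:
                        mean[index.pos[nm]] = b
    # aVT gain and its modulation
    for s in model.source_names:
        if s.split(".")[0] == "aVT":
            if eff.novel_gain is not None:
                mean[index.pos[f"G:{s}"]] = np.log(eff.novel_gain)
            if eff.repetition_gain_b is not None:
                nm = f"B:G:{s}"
                if nm in index.pos:
                    mean[index.pos[nm]] = eff.repetition_gain_b
    # frontal input strength
    if eff.frontal_input_mean is not None:
        for s in model.input_sources:
            if s.split(".")[0] == "IFG":
                mean[index.pos[f"C:{s}"]] = np.log(
                    eff.frontal_input_mean / model.c[s]
                )
    return mean


def sample_subject_parameters(
    spec: CohortSpec,
    subject_index: int,
    model: NetworkModel | None = None,
    index: ParameterIndex | None = None,
) -> SubjectParameters:
    """Draw one subject's generative log-scaling parameter vector.

    Log-scaling parameters vary log-normally around the group means with
    ``spec.subject_sd``; forward conduction delays are drawn in physical ms
    around the group delay mean with the group delay SD; observation gains
    are held at baseline.  Each subject gets an independent seeded stream.
    """
    if not 0 <= subject_index < spec.n_subjects:
        raise ValueError("subject_index out of range")
    model = model or build_model(spec.generative_model_id, spec.hemispheres)
    index = index or pack_parameters(model)
    rng = np.random.default_rng(
        np.random.SeedSequence((int(spec.seed), int(subject_index), 11))
    )
    eff = spec.effects

    theta = _group_mean_vector(spec, model, index)
    # one subject-level forward delay, shared by all forward edges (the
    # printed group SDs describe subject-average forward delays)
    subject_delay = rng.normal(eff.forward_delay_ms, eff.forward_delay_sd)
    for k, entry in enumerate(index.entries):
        if entry.cls == "L":
            continue  # observation gains stay at baseline
        if entry.name.startswith("D:f:"):
            draw = subject_delay + rng.normal(
                0.0, eff.forward_delay_edge_jitter_sd
            )
            draw = max(draw, 1.0)  # delays must stay positive
            theta[k] = np.log(draw / entry.default)
        elif entry.cls == "C" and entry.name.split(":")[1].startswith("IFG"):
            theta[k] += rng.normal(0.0, eff.frontal_input_sd)
        elif spec.subject_sd > 0:
            theta[k] += rng.normal(0.0, spec.subject_sd)

    input_strength = 0.0
    for s in model.input_sources:
        if s.split(".")[0] == "IFG" and s.endswith(".L"):
            input_strength = model.c[s] * float(
                np.exp(theta[index.pos[f"C:{s}"]])
            )
    # single-hemisphere right-only networks fall back to any IFG input
    if input_strength == 0.0:
        for s in model.input_sources:
            if s.split(".")[0] == "IFG":
                input_strength = model.c[s] * float(
                    np.exp(theta[index.pos[f"C:{s}"]])
                )
                break

    return SubjectParameters(
        subject=f"sub-{subject_index + 1:02d}",
        theta=theta,
        names=index.names,
        input_strength=input_strength,
    )


def simulate_subject(
    params: SubjectParameters,
    spec: CohortSpec,
    model: NetworkModel | None = None,
    index: ParameterIndex | None = None,
    *,
    grid: SimulationGrid | None = None,
    stimulus: StimulusInput | None = None,
    obs_spec: ObservationSpec | None = None,
    cmc: CMCParameters | None = None,
    subject_index: int | None = None,
    add_noise: bool = True,
) -> tuple[ERPDataset, np.ndarray]:
    """Simulate one subject's two-condition evoked dataset.

    Returns ``(dataset, clean)`` where ``clean`` is the noise-free
    ``(n_cond, S, T)`` signal.  Additive Gaussian noise has standard
    deviation ``rms(clean) / spec.snr``, drawn from the subject's stream.
    """
    model = model or build_model(spec.generative_model_id, spec.hemispheres)
    index = index or pack_parameters(model)
    grid = grid or SimulationGrid()
    stimulus = stimulus or StimulusInput()
    obs_spec = obs_spec or ObservationSpec()
    cmc = cmc or CMCParameters()
    static = compile_network(model)

    clean = []
    for cond in CONDITIONS:
        arrs, obs_gain = build_condition_arrays(
            model, index, params.theta[None, :], cond, cmc
        )
        volt = simulate_batch(static, arrs, stimulus, grid)
        sig = observe(volt, obs_spec)[0] * obs_gain[0][:, None]
        clean.append(sig)
    clean = np.stack(clean)  # (n_cond, S, T)

    if add_noise:
        if subject_index is None:
            subject_index = int(params.subject.split("-")[-1]) - 1
        rng = np.random.default_rng(
            np.random.SeedSequence((int(spec.seed), int(subject_index), 23))
        )
        sd = float(np.sqrt(np.mean(clean**2))) / spec.snr
        noisy = clean + rng.normal(0.0, sd, size=clean.shape)
    else:
        noisy = clean.copy()

    dataset = ERPDataset(
        subject=params.subject,
        sources=model.source_names,
        times=grid.times,
        fs=grid.output_rate,
        conditions={c: noisy[i] for i, c in enumerate(CONDITIONS)},
    )
    return dataset, clean


def generate_behavior(
    subjects: Sequence[SubjectParameters],
    spec: CohortSpec,
    rng: np.random.Generator | None = None,
) -> list[BehavioralRecord]:
    """Reaction times coupled (or not) to frontal input strength.

    ``rt_cond = base_cond - beta (c - mean_c) + shared noise + condition
    jitter``; ``beta`` and the noise SD are calibrated analytically so the
    population correlation between input strength and mean RT equals
    ``spec.rt_coupling_r`` (for coupled cohorts).
    """
    r_target = spec.rt_coupling_r or 0.0
    if r_target != 0.0 and len(subjects) < 3:
        raise ValueError("need >= 3 subjects to calibrate the RT correlation")
    rng = rng or np.random.default_rng(np.random.SeedSequence((int(spec.seed), 37)))
    strengths = np.array([s.input_strength for s in subjects])

    # population SD of input strength: lognormal around the frontal mean
    eff = spec.effects
    if eff.frontal_input_mean is not None and eff.frontal_input_sd > 0:
        sd2 = eff.frontal_input_sd**2
        sigma_c = eff.frontal_input_mean * float(
            np.sqrt(np.exp(sd2) - 1.0) * np.exp(sd2 / 2.0)
        )
    else:
        sigma_c = 0.0

    if r_target != 0.0 and sigma_c > 0:
        beta = abs(r_target) * spec.rt_sd / sigma_c
        if r_target > 0:
            beta = -beta
        var_noise = spec.rt_sd**2 * (1.0 - r_target**2)
    else:
        beta = 0.0
        var_noise = spec.rt_sd**2
    var_shared = var_noise - spec.rt_condition_jitter_sd**2 / 2.0
    if var_shared < 0:
        raise ValueError(
            "rt_condition_jitter_sd too large for the requested rt_sd/correlation"
        )

    base_novel, base_repeated = spec.base_rt
    mean_c = (
        eff.frontal_input_mean if eff.frontal_input_mean is not None else 0.0
    )
    records = []
    for subj, c in zip(subjects, strengths):
        shared = rng.normal(0.0, np.sqrt(var_shared))
        jitter = rng.normal(0.0, spec.rt_condition_jitter_sd, size=2)
        shift = -beta * (c - mean_c) + shared
        records.append(
            BehavioralRecord(
                subject=subj.subject,
                rt_novel=float(base_novel + shift + jitter[0]),
                rt_repeated=float(base_repeated + shift + jitter[1]),
                input_strength=float(c),
            )
        )
    return records


def generate_cohort(
    spec: CohortSpec,
    *,
    grid: SimulationGrid | None = None,
    stimulus: StimulusInput | None = None,
    obs_spec: ObservationSpec | None = None,
    cmc: CMCParameters | None = None,
) -> CohortData:
    """Generate a full cohort: parameters, datasets and behavior."""
    model = build_model(spec.generative_model_id, spec.hemispheres)
    index = pack_parameters(model)
    subjects = []
    datasets = []
    clean = {}
    seen_streams = set()
    for i in range(spec.n_subjects):
        key = (int(spec.seed), i)
        if key in seen_streams:
            raise ValueError(f"seed collision for subject {i}")
        seen_streams.add(key)
        params = sample_subject_parameters(spec, i, model, index)
        ds, cl = simulate_subject(
            params, spec, model, index,
            grid=grid, stimulus=stimulus, obs_spec=obs_spec, cmc=cmc,
            subject_index=i,
        )
        subjects.append(params)
        datasets.append(ds)
        clean[params.subject] = cl
    behavior = generate_behavior(subjects, spec)
    return CohortData(
        spec=spec,
        model=model,
        index=index,
        subjects=subjects,
        datasets=datasets,
        behavior=behavior,
        clean=clean,
    )


def write_cohort(cohort: CohortData, out_dir) -> Path:
    """Write a cohort as per-subject TSV directories plus behavior/manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for ds in cohort.datasets:
        write_dataset(ds, out / ds.subject)
    with open(out / "behavior.tsv", "w") as fh:
        fh.write("subject\trt_novel_ms\trt_repeated_ms\tinput_strength\n")
        for rec in cohort.behavior:
            fh.write(
                f"{rec.subject}\t{rec.rt_novel:.6g}\t{rec.rt_repeated:.6g}"
                f"\t{rec.input_strength:.10g}\n"
            )
    manifest = {
        "group": cohort.spec.group,
        "n_subjects": cohort.spec.n_subjects,
        "generative_model_id": cohort.spec.generative_model_id,
        "snr": cohort.spec.snr,
        "subject_sd": cohort.spec.subject_sd,
        "seed": cohort.spec.seed,
        "hemispheres": list(cohort.spec.hemispheres),
        "subjects": [s.subject for s in cohort.subjects],
        "sources": cohort.model.source_names,
        "sampling_rate_hz": cohort.datasets[0].fs,
        "conditions": list(CONDITIONS),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out


def read_cohort(cohort_dir):
    """Load the datasets and behavior of a written cohort.

    Returns ``(manifest, datasets, behavior)``; the generative ground truth
    is not persisted (it lives in the :class:`CohortData` that wrote it).
    """
    cohort_dir = Path(cohort_dir)
    with open(cohort_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    datasets = [read_dataset(cohort_dir / s) for s in manifest["subjects"]]
    behavior = []
    with open(cohort_dir / "behavior.tsv") as fh:
        fh.readline()
        for line in fh:
            parts = line.strip().split("\t")
            if len(parts) < 4:
                continue
            behavior.append(
                BehavioralRecord(
                    subject=parts[0],
                    rt_novel=float(parts[1]),
                    rt_repeated=float(parts[2]),
                    input_strength=float(parts[3]),
                )
            )
    return manifest, datasets, behavior
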