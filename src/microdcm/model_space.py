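"""Network architectures for the eight-source object-naming model.

A :class:`NetworkModel` describes the extrinsic wiring of a multi-source
network: directed forward/backward connections with per-component baseline
strengths, exogenous input gains ``C``, conduction delays ``D`` and the set
of parameters eligible for condition modulation (``B``).

Three canonical architectures are provided by :func:`build_model`:

* model 1 — input to early visual cortex only (family 1),
* model 2 — input to early visual cortex and inferior frontal gyrus (family 2),
* model 3 — input to early visual cortex plus a direct feedforward
  edge from early visual cortex to inferior frontal gyrus (family 2).

Forward connections originate in superficial pyramidal cells and target
spiny stellate and deep pyramidal cells; backward connections originate in
deep pyramidal cells and target superficial pyramidal cells and inhibitory
interneurons.  Each extrinsic edge therefore carries two separately
parameterised component strengths.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Source",
    "Edge",
    "NetworkModel",
    "ConditionModulation",
    "build_model",
    "apply_modulation",
    "family_partition",
    "CONDITIONS",
    "FORWARD_COMPONENTS",
    "BACKWARD_COMPONENTS",
]

CONDITIONS = ("novel", "repeated")

#: forward edges excite spiny stellate and deep pyramidal cells
FORWARD_COMPONENTS = ("ss", "dp")
#: backward edges drive superficial pyramidal cells and inhibitory interneurons
BACKWARD_COMPONENTS = ("sp", "ii")

# Region coordinates (MNI) for the bilateral object-naming network.
_ROIS = {
    "EV": {"L": (-34, -94, -6), "R": (34, -92, 2)},
    "AG": {"L": (-60, -31, 20), "R": (56, -36, 18)},
    "aVT": {"L": (-46, -6, -32), "R": (46, -8, -32)},
    "IFG": {"L": (-50, 30, -2), "R": (48, 36, 6)},
}

# Per-hemisphere hierarchy: EV at the bottom, AG/aVT intermediate, IFG on top.
_FORWARD_ROUTE = (("EV", "AG"), ("EV", "aVT"), ("AG", "IFG"), ("aVT", "IFG"))

DEFAULT_FORWARD_STRENGTHS = (1.0, 0.8)   # (->ss, ->dp)
DEFAULT_BACKWARD_STRENGTHS = (0.2, 0.1)  # (->sp, ->ii)
DEFAULT_EXTRINSIC_DELAY_MS = 8.0
DEFAULT_SELF_DELAY_MS = 1.0
DEFAULT_INPUT_GAIN = 1.0


@dataclass(frozen=True)
class Source:
    """A network node: name, hemisphere and coordinate (metadata only)."""

    name: str
    region: str
    hemisphere: str
    mni: tuple[float, float, float]


@dataclass(frozen=True)
class Edge:
    """A directed extrinsic connection between two sources."""

    src: str
    dst: str

    @property
    def key(self) -> str:
        return f"{self.src}->{self.dst}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.key


@dataclass
class NetworkModel:
    """Directed multi-source architecture with baseline physical parameters.

    Strengths, input gains and delays stored here are baseline *physical*
    values; inversion estimates log-scaling deviations around them.
    """

    model_id: int
    family_id: int
    sources: list[Source]
    forward: list[Edge]
    backward: list[Edge]
    a_forward: dict[str, tuple[float, float]]
    a_backward: dict[str, tuple[float, float]]
    c: dict[str, float]
    d_forward: dict[str, float]
    d_backward: dict[str, float]
    d_self: dict[str, float]
    b_mask: tuple[str, ...] = field(default_factory=tuple)

    # -- validation ---------------------------------------------------
    def __post_init__(self) -> None:
        names = [s.name for s in self.sources]
        if len(set(names)) != len(names):
            raise ValueError("duplicate source names")
        fkeys = {e.key for e in self.forward}
        bkeys = {e.key for e in self.backward}
        if fkeys & bkeys:
            raise ValueError("forward and backward edge sets must be disjoint")
        for e in self.forward + self.backward:
            if e.src not in names or e.dst not in names:
                raise ValueError(f"edge {e.key} references unknown source")
        for key, d in {**self.d_forward, **self.d_backward, **self.d_self}.items():
            if not d > 0:
                raise ValueError(f"delay on {key} must be > 0 (got {d})")
        for s, gain in self.c.items():
            if gain < 0:
                raise ValueError(f"input gain at {s} must be >= 0")

    # -- convenience --------------------------------------------------
    @property
    def source_names(self) -> list[str]:
        return [s.name for s in self.sources]

    @property
    def input_sources(self) -> list[str]:
        return [s for s in self.source_names if self.c.get(s, 0.0) > 0]

    @property
    def n_sources(self) -> int:
        return len(self.sources)

    def parameter_names(self) -> list[str]:
        """Names of all baseline extrinsic parameters (excluding B)."""
        names: list[str] = []
        for e in self.forward:
            names += [f"Af:{e.key}:{c}" for c in FORWARD_COMPONENTS]
        for e in self.backward:
            names += [f"Ab:{e.key}:{c}" for c in BACKWARD_COMPONENTS]
        names += [f"C:{s}" for s in self.input_sources]
        names += [f"G:{s}" for s in self.source_names]
        names += [f"D:f:{e.key}" for e in self.forward]
        names += [f"D:b:{e.key}" for e in self.backward]
        names += [f"D:self:{s}" for s in self.source_names]
        return names

    # -- serialization ------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "family_id": self.family_id,
            "sources": [
                {"name": s.name, "region": s.region, "hemisphere": s.hemisphere,
                 "mni": list(s.mni)}
                for s in self.sources
            ],
            "forward": [e.key for e in self.forward],
            "backward": [e.key for e in self.backward],
            "a_forward": {k: list(v) for k, v in self.a_forward.items()},
            "a_backward": {k: list(v) for k, v in self.a_backward.items()},
            "c": dict(self.c),
            "d_forward": dict(self.d_forward),
            "d_backward": dict(self.d_backward),
            "d_self": dict(self.d_self),
            "b_mask": list(self.b_mask),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "NetworkModel":
        def edge(key: str) -> Edge:
            src, dst = key.split("->")
            return Edge(src, dst)

        return cls(
            model_id=int(d["model_id"]),
            family_id=int(d["family_id"]),
            sources=[
                Source(s["name"], s["region"], s["hemisphere"], tuple(s["mni"]))
                for s in d["sources"]
            ],
            forward=[edge(k) for k in d["forward"]],
            backward=[edge(k) for k in d["backward"]],
            a_forward={k: tuple(v) for k, v in d["a_forward"].items()},
            a_backward={k: tuple(v) for k, v in d["a_backward"].items()},
            c={k: float(v) for k, v in d["c"].items()},
            d_forward={k: float(v) for k, v in d["d_forward"].items()},
            d_backward={k: float(v) for k, v in d["d_backward"].items()},
            d_self={k: float(v) for k, v in d["d_self"].items()},
            b_mask=tuple(d["b_mask"]),
        )

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, path_or_text) -> "NetworkModel":
        try:
            d = json.loads(path_or_text)
        except (ValueError, TypeError):
            with open(path_or_text) as fh:
                d = json.load(fh)
        return cls.from_dict(d)


@dataclass
class ConditionModulation:
    """Condition-specific log-scaling deviations (B parameters).

    ``b`` maps a modulated parameter name (a member of the model's
    ``b_mask``) to its log-scaling deviation: the 'repeated' condition
    multiplies that parameter by ``exp(b)``; 'novel' is baseline.
    """

    b: dict[str, float] = field(default_factory=dict)
    condition_labels: tuple[str, str] = CONDITIONS


def build_model(model_id: int, hemispheres: Sequence[str] = ("L", "R")) -> NetworkModel:
    """Construct one of the three canonical input architectures.

    Parameters
    ----------
    model_id : int
        1 — visual input only; 2 — visual and frontal input; 3 — visual
        input plus a direct feedforward EV->IFG edge.
    hemispheres : sequence of {"L", "R"}
        Which hemispheres to instantiate.  The default builds the full
        bilateral 8-source network; ``("L",)`` gives the reduced 4-source
        test network.
    """
    if model_id not in (1, 2, 3):
        raise ValueError(f"unknown model_id {model_id!r}; expected 1, 2 or 3")
    for h in hemispheres:
        if h not in ("L", "R"):
            raise ValueError(f"unknown hemisphere {h!r}")

    sources = [
        Source(f"{region}.{h}", region, h, _ROIS[region][h])
        for h in hemispheres
        for region in ("EV", "AG", "aVT", "IFG")
    ]

    forward: list[Edge] = []
    backward: list[Edge] = []
    for h in hemispheres:
        for lo, hi in _FORWARD_ROUTE:
            forward.append(Edge(f"{lo}.{h}", f"{hi}.{h}"))
            backward.append(Edge(f"{hi}.{h}", f"{lo}.{h}"))
    if model_id == 3:
        # direct feedforward visual->frontal shortcut, no backward partner
        for h in hemispheres:
            forward.append(Edge(f"EV.{h}", f"IFG.{h}"))

    input_regions = ("EV", "IFG") if model_id == 2 else ("EV",)
    c = {
        s.name: (DEFAULT_INPUT_GAIN if s.region in input_regions else 0.0)
        for s in sources
    }

    a_forward = {e.key: DEFAULT_FORWARD_STRENGTHS for e in forward}
    a_backward = {e.key: DEFAULT_BACKWARD_STRENGTHS for e in backward}
    d_forward = {e.key: DEFAULT_EXTRINSIC_DELAY_MS for e in forward}
    d_backward = {e.key: DEFAULT_EXTRINSIC_DELAY_MS for e in backward}
    d_self = {s.name: DEFAULT_SELF_DELAY_MS for s in sources}

    b_mask: list[str] = []
    for e in forward:
        b_mask += [f"Af:{e.key}:{comp}" for comp in FORWARD_COMPONENTS]
    for e in backward:
        b_mask += [f"Ab:{e.key}:{comp}" for comp in BACKWARD_COMPONENTS]
    b_mask += [f"G:{s.name}" for s in sources]

    return NetworkModel(
        model_id=model_id,
        family_id=1 if model_id == 1 else 2,
        sources=sources,
        forward=forward,
        backward=backward,
        a_forward=a_forward,
        a_backward=a_backward,
        c=c,
        d_forward=d_forward,
        d_backward=d_backward,
        d_self=d_self,
        b_mask=tuple(b_mask),
    )


def apply_modulation(
    model: NetworkModel,
    mod: ConditionModulation | None,
    condition: str,
) -> dict[str, float]:
    """Effective physical strengths for one condition.

    'novel' returns baseline values; 'repeated' multiplies every modulated
    parameter by ``exp(b)``.  Returns a flat name -> value mapping over all
    extrinsic component strengths and per-source gains.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    b = dict(mod.b) if mod is not None else {}
    mask = set(model.b_mask)
    outside = set(b) - mask
    if outside:
        raise ValueError(
            f"modulation requested outside B mask: {sorted(outside)}"
        )

    values: dict[str, float] = {}
    for e in model.forward:
        for comp, w in zip(FORWARD_COMPONENTS, model.a_forward[e.key]):
            values[f"Af:{e.key}:{comp}"] = w
    for e in model.backward:
        for comp, w in zip(BACKWARD_COMPONENTS, model.a_backward[e.key]):
            values[f"Ab:{e.key}:{comp}"] = w
    for s in model.source_names:
        values[f"G:{s}"] = 1.0

    if condition == "repeated":
        import math

        for name, dev in b.items():
            values[name] *= math.exp(dev)
    return values


def family_partition(models: Iterable[NetworkModel]) -> dict[int, list[int]]:
    """Group models into families by their ``family_id``.

    Returns a mapping family_id -> sorted list of model_ids.  The partition
    is exhaustive and disjoint by construction; duplicate model ids or a
    missing family id are errors.
    """
    models = list(models)
    if not models:
        raise ValueError("empty model list")
    seen: set[int] = set()
    out: dict[int, list[int]] = {}
    for m in models:
        if m.family_id is None:
            raise ValueError(f"model {m.model_id} has no family_id")
        if m.model_id in seen:
            raise ValueError(f"duplicate model_id {m.model_id}")
        seen.add(m.model_id)
        out.setdefault(m.family_id, []).append(m.model_id)
    return {fam: sorted(ids) for fam, ids in sorted(out.items())}
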