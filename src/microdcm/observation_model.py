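"""Mapping from population states to measured evoked signals, and model fit.

The observation model is a local-field-potential style projection: each
source's signal is a fixed linear mixture of its population membrane
potentials, scaled by a per-source channel gain.  Noise is never added here;
synthetic-data generation owns the noise process.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .neural_dynamics import POPULATIONS, SimulationResult

__all__ = ["ObservationSpec", "observe", "fit_score"]

DEFAULT_CONTRIBUTION = {"ss": 0.0, "sp": 0.8, "ii": 0.0, "dp": 0.2}


@dataclass(frozen=True)
class ObservationSpec:
    """Per-population contribution weights and per-source channel gains."""

    contribution: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONTRIBUTION)
    )
    channel_gain: float | np.ndarray = 1.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        extra = set(self.contribution) - set(POPULATIONS)
        if extra:
            raise ValueError(f"unknown populations in contribution: {sorted(extra)}")
        w = self.weights()
        if not np.all(np.isfinite(w)):
            raise ValueError("contribution weights must be finite")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def weights(self) -> np.ndarray:
        return np.array(
            [self.contribution.get(p, 0.0) for p in POPULATIONS], dtype=float
        )


def observe(states, spec: ObservationSpec | None = None) -> np.ndarray:
    """Project population voltages to the measured signal per source.

    ``states`` is either a :class:`SimulationResult` or an array of shape
    ``(..., n_sources, 4, n_times)``.  Returns ``(..., n_sources, n_times)``:
    ``gain_s * sum_p w_p v_{s,p}(t)``.  Deterministic — no noise.
    """
    spec = spec or ObservationSpec()
    if isinstance(states, SimulationResult):
        states = states.voltages
    states = np.asarray(states, dtype=float)
    if states.shape[-2] != len(POPULATIONS):
        raise ValueError(
            f"expected {len(POPULATIONS)} populations on axis -2, "
            f"got {states.shape[-2]}"
        )
    if not np.all(np.isfinite(states)):
        raise ValueError("non-finite states")
    w = spec.weights()
    sig = np.einsum("...spt,p->...st", states, w)
    gain = np.asarray(spec.channel_gain, dtype=float)
    if gain.ndim == 1:
        sig = sig * gain[:, None]
    else:
        sig = sig * gain
    return sig


def fit_score(predicted, observed) -> float:
    """Proportion of variance explained, pooled over everything.

    ``1 - SS_res / SS_tot`` with ``SS_tot`` taken about the observed grand
    mean, pooled across all sources, time points and conditions.  Identical
    arrays score 1; predicting the observed mean scores 0; values may be
    arbitrarily negative for bad predictions.
    """
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {o.shape}")
    ss_tot = float(np.sum((o - o.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("observed data are constant; fit score undefined")
    ss_res = float(np.sum((o - p) ** 2))
    return 1.0 - ss_res / ss_tot
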