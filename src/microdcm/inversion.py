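"""Variational-Laplace estimation of network parameters from evoked data.

Free parameters are log-scaling deviations around the model's baseline
physical values (so the prior mean 0 corresponds to the defaults), except
condition-modulation (B) parameters which are themselves log deviations
applied to the 'repeated' condition.  The scheme is a Gauss-Newton /
Levenberg-Marquardt ascent on the free energy

    F = accuracy - KL(posterior || prior)

with a single log-precision noise hyperparameter updated analytically each
iteration.  Steps are only accepted if they increase F, so the accepted-F
trajectory is non-decreasing by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .data import ERPDataset
from .model_space import (
    BACKWARD_COMPONENTS,
    CONDITIONS,
    FORWARD_COMPONENTS,
    NetworkModel,
)
from .neural_dynamics import (
    SP_SELF_EDGE as _SP_SELF,
    CMCParameters,
    NetworkStatic,
    SimArrays,
    SimulationGrid,
    StimulusInput,
    compile_network,
    simulate_batch,
)
from .observation_model import ObservationSpec, fit_score, observe

logger = logging.getLogger(__name__)

__all__ = [
    "PriorSpec",
    "ParamEntry",
    "ParameterIndex",
    "Posterior",
    "InversionError",
    "pack_parameters",
    "build_condition_arrays",
    "variational_laplace",
    "reinitialize_low_fit",
]

DEFAULT_PRIOR_VARIANCES = {
    "A": 1.0 / 8.0,
    "B": 1.0 / 8.0,
    "C": 1.0 / 8.0,
    "G": 1.0 / 16.0,
    "D": 1.0 / 16.0,
    "tau": 1.0 / 32.0,
    # observation gains are nuisance amplitude parameters; a loose prior
    # here trades off against the input gains C, so keep them shrunk
    "L": 1.0 / 32.0,
}


class InversionError(RuntimeError):
    """Inversion failure; carries the last stable posterior if available."""

    def __init__(self, message: str, posterior: "Posterior | None" = None):
        super().__init__(message)
        self.posterior = posterior


@dataclass(frozen=True)
class PriorSpec:
    """Gaussian shrinkage priors on log-scaling parameters, by class."""

    variances: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PRIOR_VARIANCES)
    )
    mean: float = 0.0
    hyper_mean: float = 4.0
    hyper_variance: float = 1.0

    def __post_init__(self) -> None:
        for cls, v in self.variances.items():
            if not v > 0:
                raise ValueError(f"prior variance for class {cls!r} must be > 0")
        if not self.hyper_variance > 0:
            raise ValueError("hyper_variance must be > 0")

    def variance_vector(self, index: "ParameterIndex") -> np.ndarray:
        return np.array([self.variances[e.cls] for e in index.entries])


@dataclass(frozen=True)
class ParamEntry:
    name: str
    cls: str            # one of A, B, C, G, D, L
    default: float      # baseline physical value
    addr: tuple         # where the value lands in SimArrays / obs gains


class ParameterIndex:
    """Bijective map between named parameters and vector positions."""

    def __init__(self, entries: Sequence[ParamEntry]):
        self.entries = list(entries)
        self.pos: dict[str, int] = {}
        for k, e in enumerate(self.entries):
            if e.name in self.pos:
                raise ValueError(f"parameter name collision: {e.name!r}")
            self.pos[e.name] = k

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def by_class(self, cls: str) -> list[ParamEntry]:
        return [e for e in self.entries if e.cls == cls]

    def vector_to_dict(self, theta: np.ndarray) -> dict[str, float]:
        return {e.name: float(theta[k]) for k, e in enumerate(self.entries)}

    def dict_to_vector(self, values: Mapping[str, float]) -> np.ndarray:
        theta = np.zeros(len(self.entries))
        for name, v in values.items():
            theta[self.pos[name]] = v
        return theta


def pack_parameters(
    model: NetworkModel,
    obs_spec: ObservationSpec | None = None,
    modulated: Sequence[str] | None = None,
) -> ParameterIndex:
    """Build the free-parameter index for a model.

    ``modulated`` restricts the B parameters to a subset of the model's
    ``b_mask``; by default every masked parameter gets a B term.  The
    physical value of a positive-constrained parameter is
    ``default * exp(log-scaling)``.
    """
    del obs_spec  # shape of the observation map is fixed; gains are per source
    names = model.source_names
    src_pos = {n: k for k, n in enumerate(names)}
    entries: list[ParamEntry] = []

    addr_of: dict[str, tuple] = {}
    for ei, e in enumerate(model.forward):
        for ci, comp in enumerate(FORWARD_COMPONENTS):
            name = f"Af:{e.key}:{comp}"
            addr = ("wf", ei, ci)
            addr_of[name] = addr
            entries.append(ParamEntry(name, "A", model.a_forward[e.key][ci], addr))
    for ei, e in enumerate(model.backward):
        for ci, comp in enumerate(BACKWARD_COMPONENTS):
            name = f"Ab:{e.key}:{comp}"
            addr = ("wb", ei, ci)
            addr_of[name] = addr
            entries.append(ParamEntry(name, "A", model.a_backward[e.key][ci], addr))
    for s in model.input_sources:
        entries.append(ParamEntry(f"C:{s}", "C", model.c[s], ("c", src_pos[s])))
    for s in names:
        name = f"G:{s}"
        addr = ("g", src_pos[s])
        addr_of[name] = addr
        entries.append(ParamEntry(name, "G", 1.0, addr))

    if modulated is None:
        modulated = model.b_mask
    unknown = set(modulated) - set(model.b_mask)
    if unknown:
        raise ValueError(f"modulated parameters outside B mask: {sorted(unknown)}")
    for target in modulated:
        entries.append(ParamEntry(f"B:{target}", "B", 0.0, ("b", addr_of[target])))

    for ei, e in enumerate(model.forward):
        entries.append(
            ParamEntry(f"D:f:{e.key}", "D", model.d_forward[e.key], ("df", ei))
        )
    for ei, e in enumerate(model.backward):
        entries.append(
            ParamEntry(f"D:b:{e.key}", "D", model.d_backward[e.key], ("db", ei))
        )
    for s in names:
        entries.append(
            ParamEntry(f"D:self:{s}", "D", model.d_self[s], ("dself", src_pos[s]))
        )
    for s in names:
        entries.append(ParamEntry(f"L:{s}", "L", 1.0, ("obs", src_pos[s])))

    return ParameterIndex(entries)


def _apply_addr(arrs: dict[str, np.ndarray], addr: tuple, factor: np.ndarray) -> None:
    kind = addr[0]
    if kind == "wf":
        arrs["wf"][:, addr[1], addr[2]] *= factor
    elif kind == "wb":
        arrs["wb"][:, addr[1], addr[2]] *= factor
    elif kind == "c":
        arrs["c"][:, addr[1]] *= factor
    elif kind == "g":
        arrs["g"][:, addr[1], _SP_SELF] *= factor
    elif kind == "df":
        arrs["df"][:, addr[1]] *= factor
    elif kind == "db":
        arrs["db"][:, addr[1]] *= factor
    elif kind == "dself":
        arrs["dself"][:, addr[1]] *= factor
    elif kind == "obs":
        arrs["obs"][:, addr[1]] *= factor
    else:  # pragma: no cover - guarded by pack_parameters
        raise ValueError(f"unknown address kind {kind!r}")


def build_condition_arrays(
    model: NetworkModel,
    index: ParameterIndex,
    theta: np.ndarray,
    condition: str,
    cmc: CMCParameters | None = None,
) -> tuple[SimArrays, np.ndarray]:
    """Turn a batch of log-scaling vectors into physical simulation arrays.

    Returns ``(SimArrays, obs_gain (B, S))`` for the requested condition.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    cmc = cmc or CMCParameters()
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    B = theta.shape[0]
    if theta.shape[1] != len(index):
        raise ValueError(
            f"theta has {theta.shape[1]} columns; index expects {len(index)}"
        )
    names = model.source_names
    S = len(names)
    Ef, Eb = len(model.forward), len(model.backward)

    wf = np.array([model.a_forward[e.key] for e in model.forward], dtype=float)
    wb = np.array([model.a_backward[e.key] for e in model.backward], dtype=float)
    arrs = {
        "g": np.tile(cmc.g_array()[None, None, :], (B, S, 1)),
        "wf": np.tile(wf.reshape(1, Ef, 2), (B, 1, 1)),
        "wb": np.tile(wb.reshape(1, Eb, 2), (B, 1, 1)),
        "c": np.tile(
            np.array([model.c.get(n, 0.0) for n in names])[None, :], (B, 1)
        ),
        "df": np.tile(
            np.array([model.d_forward[e.key] for e in model.forward])[None, :],
            (B, 1),
        ),
        "db": np.tile(
            np.array([model.d_backward[e.key] for e in model.backward])[None, :],
            (B, 1),
        ),
        "dself": np.tile(
            np.array([model.d_self[n] for n in names])[None, :], (B, 1)
        ),
        "obs": np.ones((B, S)),
    }

    for k, entry in enumerate(index.entries):
        if entry.cls == "B":
            continue
        _apply_addr(arrs, entry.addr, np.exp(theta[:, k]))
    if condition == "repeated":
        for k, entry in enumerate(index.entries):
            if entry.cls == "B":
                _apply_addr(arrs, entry.addr[1], np.exp(theta[:, k]))

    sim = SimArrays(
        g=arrs["g"],
        tau=cmc.tau_array()[None, :].repeat(S, axis=0),
        slope=cmc.sigmoid_slope,
        wf=arrs["wf"],
        wb=arrs["wb"],
        c=arrs["c"],
        df=arrs["df"],
        db=arrs["db"],
        dself=arrs["dself"],
    )
    return sim, arrs["obs"]


@dataclass
class Posterior:
    """Posterior density over log-scaling parameters plus diagnostics."""

    names: list[str]
    Ep_vec: np.ndarray
    Cp: np.ndarray
    F: float
    fit: float
    n_iter: int
    log_precision: float
    F_trace: list[float] = field(default_factory=list)
    model_id: int | None = None
    subject: str | None = None

    @property
    def Ep(self) -> dict[str, float]:
        return {n: float(v) for n, v in zip(self.names, self.Ep_vec)}

    def by_class(self, cls: str) -> dict[str, float]:
        prefix = f"{cls}:"
        return {n: v for n, v in self.Ep.items() if n.startswith(prefix)}

    def credible_interval(self, name: str, level: float = 0.9) -> tuple[float, float]:
        from scipy.stats import norm

        k = self.names.index(name)
        sd = float(np.sqrt(self.Cp[k, k]))
        z = norm.ppf(0.5 + level / 2.0)
        mu = float(self.Ep_vec[k])
        return mu - z * sd, mu + z * sd

    def to_dict(self) -> dict:
        return {
            "Ep": self.Ep,
            "F": self.F,
            "fit": self.fit,
            "n_iter": self.n_iter,
            "log_precision": self.log_precision,
            "model_id": self.model_id,
            "subject": self.subject,
        }


class _ForwardMap:
    """Caches the compiled network and evaluates batched predictions."""

    def __init__(self, model, index, grid, stimulus, obs_spec, cmc, bound):
        self.model = model
        self.index = index
        self.grid = grid
        self.stimulus = stimulus
        self.obs_spec = obs_spec
        self.cmc = cmc
        self.bound = bound
        self.static: NetworkStatic = compile_network(model)

    def predict(self, theta_batch: np.ndarray) -> np.ndarray:
        """(B, P) -> (B, n_cond, S, T) predicted signals."""
        theta_batch = np.atleast_2d(theta_batch)
        B = theta_batch.shape[0]
        sims = []
        gains = []
        for cond in CONDITIONS:
            arrs, obs_gain = build_condition_arrays(
                self.model, self.index, theta_batch, cond, self.cmc
            )
            sims.append(arrs)
            gains.append(obs_gain)
        merged = SimArrays(
            g=np.concatenate([a.g for a in sims]),
            tau=sims[0].tau,
            slope=sims[0].slope,
            wf=np.concatenate([a.wf for a in sims]),
            wb=np.concatenate([a.wb for a in sims]),
            c=np.concatenate([a.c for a in sims]),
            df=np.concatenate([a.df for a in sims]),
            db=np.concatenate([a.db for a in sims]),
            dself=np.concatenate([a.dself for a in sims]),
        )
        volt = simulate_batch(
            self.static, merged, self.stimulus, self.grid, bound=self.bound
        )
        sig = observe(volt, self.obs_spec)  # (2B, S, T)
        out = np.empty((B, len(CONDITIONS), sig.shape[1], sig.shape[2]))
        for ci in range(len(CONDITIONS)):
            out[:, ci] = sig[ci * B : (ci + 1) * B] * gains[ci][:, :, None]
        return out


def _free_energy(r2, n, lam, dtheta, P0_diag, logdet_H, logdet_P0, priors):
    acc = -0.5 * np.exp(lam) * r2 + 0.5 * n * lam - 0.5 * n * np.log(2 * np.pi)
    kl_theta = 0.5 * float(dtheta @ (P0_diag * dtheta)) + 0.5 * (logdet_H - logdet_P0)
    kl_lam = 0.5 * (lam - priors.hyper_mean) ** 2 / priors.hyper_variance
    return acc - kl_theta - kl_lam


def _update_lambda(lam, s, n, priors, lo=-8.0, hi=32.0):
    """Newton solve of dF/dlam = n/2 - exp(lam) s/2 - (lam - mu)/v = 0."""
    mu, v = priors.hyper_mean, priors.hyper_variance
    for _ in range(12):
        f = 0.5 * n - 0.5 * np.exp(lam) * s - (lam - mu) / v
        fp = -0.5 * np.exp(lam) * s - 1.0 / v
        step = f / fp
        lam = float(np.clip(lam - step, lo, hi))
        if abs(step) < 1e-6:
            break
    return lam


def variational_laplace(
    data: ERPDataset,
    model: NetworkModel,
    priors: PriorSpec | None = None,
    init: np.ndarray | Mapping[str, float] | None = None,
    *,
    grid: SimulationGrid | None = None,
    stimulus: StimulusInput | None = None,
    obs_spec: ObservationSpec | None = None,
    cmc: CMCParameters | None = None,
    index: ParameterIndex | None = None,
    max_iter: int = 64,
    tol: float = 0.01,
    tol_streak: int = 4,
    fd_step: float = 1e-3,
    max_lm: int = 8,
    bound: float = 1e3,
) -> Posterior:
    """Estimate the posterior over a model's parameters for one subject.

    Gauss-Newton / Levenberg-Marquardt ascent on the variational free
    energy, with central finite-difference sensitivities and an analytic
    update of the shared log noise precision.  Accepted steps never
    decrease F; convergence is declared after ``tol_streak`` consecutive
    iterations with ``|dF| < tol``.
    """
    priors = priors or PriorSpec()
    grid = grid or SimulationGrid()
    stimulus = stimulus or StimulusInput()
    obs_spec = obs_spec or ObservationSpec()
    cmc = cmc or CMCParameters()
    index = index or pack_parameters(model, obs_spec)

    if list(data.sources) != model.source_names:
        raise ValueError(
            "data sources do not match model sources: "
            f"{data.sources} vs {model.source_names}"
        )
    if len(data.times) != len(grid.times) or not np.allclose(
        data.times, grid.times, atol=1e-6
    ):
        raise ValueError("data time axis does not match the simulation grid")

    y = np.stack([data.conditions[c] for c in CONDITIONS]).ravel()
    n = y.size
    P = len(index)

    v0 = priors.variance_vector(index)
    P0_diag = 1.0 / v0
    logdet_P0 = float(np.sum(np.log(P0_diag)))
    m0 = np.full(P, priors.mean)

    if init is None:
        theta = m0.copy()
    elif isinstance(init, Mapping):
        theta = index.dict_to_vector(init)
    else:
        theta = np.asarray(init, dtype=float).copy()
        if theta.shape != (P,):
            raise ValueError(f"init has shape {theta.shape}, expected {(P,)}")

    fwd = _ForwardMap(model, index, grid, stimulus, obs_spec, cmc, bound)
    lam = priors.hyper_mean

    def predict_flat(th_batch):
        return fwd.predict(th_batch).reshape(np.atleast_2d(th_batch).shape[0], -1)

    h = predict_flat(theta)[0]
    r = y - h
    r2 = float(r @ r)
    lam = _update_lambda(lam, r2, n, priors)

    Cp = np.diag(v0)
    dtheta = theta - m0
    # before curvature is known, take H = P0 (zero KL logdet term)
    F = _free_energy(r2, n, lam, dtheta, P0_diag, logdet_P0, logdet_P0, priors)
    F_trace = [F]

    nu = 1.0 / 128.0
    streak = 0
    n_iter = 0
    J = None

    for it in range(max_iter):
        n_iter = it + 1
        # central finite-difference Jacobian, batched in one simulation call
        steps = np.eye(P) * fd_step
        batch = np.vstack([theta + steps, theta - steps])
        preds = predict_flat(batch)
        J = (preds[:P] - preds[P:]).T / (2.0 * fd_step)  # (n, P)

        JtJ = J.T @ J
        Jtr = J.T @ r

        # hyperparameter update uses the expected squared residual
        s = r2 + float(np.sum(JtJ * Cp))
        lam = _update_lambda(lam, s, n, priors)
        prec = np.exp(lam)

        H = prec * JtJ + np.diag(P0_diag)
        sign, logdet_H = np.linalg.slogdet(H)
        if sign <= 0 or not np.isfinite(logdet_H):
            raise InversionError(
                "indefinite curvature in free-energy ascent",
                _make_posterior(index, theta, Cp, F, y, h, n_iter, lam, F_trace,
                                model, data),
            )
        grad = prec * Jtr - P0_diag * (theta - m0)

        accepted = False
        nu_local = nu
        for _ in range(max_lm):
            Hreg = H + nu_local * np.diag(np.diag(H))
            try:
                cf = cho_factor(Hreg, lower=True)
            except np.linalg.LinAlgError:
                nu_local *= 8.0
                continue
            step = cho_solve(cf, grad)
            theta_new = theta + step
            try:
                h_new = predict_flat(theta_new)[0]
            except Exception:
                nu_local *= 8.0
                continue
            r_new = y - h_new
            r2_new = float(r_new @ r_new)
            dtheta_new = theta_new - m0
            F_new = _free_energy(
                r2_new, n, lam, dtheta_new, P0_diag, logdet_H, logdet_P0, priors
            )
            if not np.isfinite(F_new):
                raise InversionError(
                    "non-finite free energy",
                    _make_posterior(index, theta, Cp, F, y, h, n_iter, lam,
                                    F_trace, model, data),
                )
            if F_new > F:
                theta, h, r, r2 = theta_new, h_new, r_new, r2_new
                F = F_new
                nu = max(nu_local / 2.0, 1.0 / 1024.0)
                accepted = True
                break
            nu_local *= 8.0

        Cp = np.linalg.inv(H)
        Cp = 0.5 * (Cp + Cp.T)

        dF = F - F_trace[-1]
        F_trace.append(F)
        logger.debug(
            "iter %d: F=%.4f dF=%.4f lam=%.2f accepted=%s", it, F, dF, lam, accepted
        )
        if accepted and dF < tol:
            streak += 1
        elif not accepted:
            streak += 1  # no admissible uphill step: effectively converged
        else:
            streak = 0
        if streak >= tol_streak:
            break

    return _make_posterior(index, theta, Cp, F, y, h, n_iter, lam, F_trace, model, data)


def _make_posterior(index, theta, Cp, F, y, h, n_iter, lam, F_trace, model, data):
    n_cond = len(CONDITIONS)
    shape = (n_cond, len(data.sources), len(data.times))
    fit = fit_score(h.reshape(shape), y.reshape(shape))
    return Posterior(
        names=index.names,
        Ep_vec=theta.copy(),
        Cp=Cp.copy(),
        F=float(F),
        fit=float(fit),
        n_iter=n_iter,
        log_precision=float(lam),
        F_trace=list(F_trace),
        model_id=model.model_id,
        subject=data.subject,
    )


def reinitialize_low_fit(
    posteriors: Mapping[str, Posterior], threshold: float = 0.75
) -> dict[str, np.ndarray]:
    """Starting means for refitting subjects whose fit fell below threshold.

    Subjects with ``fit >= threshold`` act as donors; each low-fit subject
    receives the elementwise mean of the donors' posterior means as a new
    starting point.  Returns an empty mapping when nobody needs a refit;
    raises if there is no donor (the procedure is then undefined).
    """
    if not posteriors:
        raise ValueError("no posteriors supplied")
    donors = {s: p for s, p in posteriors.items() if p.fit >= threshold}
    if not donors:
        raise InversionError(
            f"no subject reached fit >= {threshold}; re-initialization undefined"
        )
    low = {s: p for s, p in posteriors.items() if p.fit < threshold}
    if not low:
        return {}
    mean_ep = np.mean([p.Ep_vec for p in donors.values()], axis=0)
    return {s: mean_ep.copy() for s in low}
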