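"""Canonical-microcircuit neural-mass dynamics with conduction delays.

Each source holds four populations — spiny stellate (ss), superficial
pyramidal (sp), inhibitory interneuron (ii) and deep pyramidal (dp) — with
second-order synaptic kernels::

    v'_p = i_p
    i'_p = kappa_p * afferent_p - 2 kappa_p * i_p - kappa_p^2 * v_p

where ``kappa_p = 1/tau_p`` and ``afferent_p`` sums signed intrinsic drive
(firing of the same source, lagged by its self delay), extrinsic drive
(presynaptic firing lagged by the edge delay) and the exogenous Gaussian
bump input on spiny stellate cells.

Firing is a centred logistic of membrane potential, bounded in (-1/2, 1/2).

Integration is fixed-step (Heun / RK2) with a ring buffer of past firing
rates and cubic Hermite interpolation at ``t - D``.  A batched kernel
(:func:`simulate_batch`) integrates many parameter sets simultaneously,
which is what makes finite-difference inversion affordable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .model_space import NetworkModel

__all__ = [
    "POPULATIONS",
    "INTRINSIC_EDGES",
    "SP_SELF_EDGE",
    "CMCParameters",
    "StimulusInput",
    "SimulationGrid",
    "SimulationResult",
    "NetworkInstabilityError",
    "sigmoid_firing",
    "gaussian_bump",
    "source_derivative",
    "integrate_network",
    "compile_network",
    "simulate_batch",
    "SimArrays",
]

POPULATIONS = ("ss", "sp", "ii", "dp")
SS, SP, II, DP = 0, 1, 2, 3

#: the ten canonical within-source edges as (presynaptic, postsynaptic, sign)
INTRINSIC_EDGES = (
    ("ss", "ss", -1),
    ("sp", "ss", -1),
    ("ii", "ss", -1),
    ("ii", "ii", -1),
    ("ss", "ii", +1),
    ("dp", "ii", +1),
    ("sp", "sp", -1),
    ("ss", "sp", +1),
    ("ii", "dp", -1),
    ("dp", "dp", -1),
)
#: index of the superficial-pyramidal self connection (the gain edge)
SP_SELF_EDGE = 6

DEFAULT_TAU = {"ss": 2.0, "sp": 2.0, "ii": 16.0, "dp": 28.0}
# magnitudes chosen so the resting state is linearly stable (with margin)
# under the default self delay, while evoked responses still propagate
DEFAULT_INTRINSIC = {
    "ss->ss": 2.0,
    "sp->ss": 2.0,
    "ii->ss": 4.0,
    "ii->ii": 2.0,
    "ss->ii": 2.0,
    "dp->ii": 1.0,
    "sp->sp": 2.0,
    "ss->sp": 4.0,
    "ii->dp": 1.0,
    "dp->dp": 1.0,
}
DEFAULT_SIGMOID_SLOPE = 2.0 / 3.0
#: fixed multiplier converting extrinsic strength parameters to afferent drive
EXTRINSIC_SCALE = 3.0


class NetworkInstabilityError(RuntimeError):
    """Raised when a simulated membrane potential exceeds the stability bound."""

    def __init__(self, source: str, value: float, bound: float):
        self.source = source
        self.value = value
        self.bound = bound
        super().__init__(
            f"simulation diverged at source {source!r}: |v| = {value:.3g} "
            f"exceeds bound {bound:.3g}"
        )


@dataclass(frozen=True)
class CMCParameters:
    """Intrinsic (within-source) parameters of one canonical microcircuit."""

    tau: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_TAU))
    g: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_INTRINSIC))
    sigmoid_slope: float = DEFAULT_SIGMOID_SLOPE
    gain_sp: float = 1.0

    def __post_init__(self) -> None:
        for p in POPULATIONS:
            if not self.tau.get(p, 0.0) > 0:
                raise ValueError(f"tau[{p}] must be > 0")
        for pre, post, _sign in INTRINSIC_EDGES:
            if self.g.get(f"{pre}->{post}", -1.0) < 0:
                raise ValueError(f"intrinsic magnitude {pre}->{post} must be >= 0")
        if not self.sigmoid_slope > 0:
            raise ValueError("sigmoid_slope must be > 0")
        if not self.gain_sp > 0:
            raise ValueError("gain_sp must be > 0")

    def tau_array(self) -> np.ndarray:
        return np.array([self.tau[p] for p in POPULATIONS], dtype=float)

    def g_array(self) -> np.ndarray:
        """Signed magnitudes in canonical edge order, gain applied to sp->sp."""
        g = np.array(
            [self.g[f"{pre}->{post}"] for pre, post, _ in INTRINSIC_EDGES],
            dtype=float,
        )
        g[SP_SELF_EDGE] *= self.gain_sp
        return g


@dataclass(frozen=True)
class StimulusInput:
    """Gaussian-bump exogenous drive."""

    onset: float = 64.0
    dispersion: float = 16.0
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if not self.dispersion > 0:
            raise ValueError("dispersion must be > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


@dataclass(frozen=True)
class SimulationGrid:
    """Integration window, step and output sampling rate."""

    t_start: float = 1.0
    t_end: float = 450.0
    dt: float = 0.5
    output_rate: float = 250.0

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ValueError("t_start must be < t_end")
        if not self.dt > 0:
            raise ValueError("dt must be > 0")
        if self.dt > 1000.0 / self.output_rate + 1e-12:
            raise ValueError("dt must not exceed the output sampling interval")
        step = 1000.0 / self.output_rate
        for t in (self.t_start, step):
            if abs(t / self.dt - round(t / self.dt)) > 1e-9:
                raise ValueError(
                    "output sample times must fall on integration steps "
                    f"(dt={self.dt}, sample interval={step}, t_start={self.t_start})"
                )

    @property
    def times(self) -> np.ndarray:
        step = 1000.0 / self.output_rate
        n = int(np.floor((self.t_end - self.t_start) / step + 1e-9)) + 1
        return self.t_start + step * np.arange(n)

    @property
    def n_steps(self) -> int:
        return int(round(self.t_end / self.dt))


@dataclass
class SimulationResult:
    """Population voltages on the output grid."""

    times: np.ndarray
    voltages: np.ndarray  # (n_sources, 4, n_times)
    sources: list[str]


def sigmoid_firing(v, slope: float = DEFAULT_SIGMOID_SLOPE):
    """Centred logistic transfer ``S(v) = 1/(1+exp(-r v)) - 1/2``.

    Odd, strictly increasing, bounded in (-1/2, 1/2).
    """
    if not slope > 0:
        raise ValueError("slope must be > 0")
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite membrane potential")
    out = 1.0 / (1.0 + np.exp(-slope * v)) - 0.5
    return out if out.ndim else float(out)


def gaussian_bump(t, stimulus: StimulusInput):
    """Exogenous drive ``u(t) = a exp(-(t-onset)^2 / (2 sigma^2))``."""
    t = np.asarray(t, dtype=float)
    u = stimulus.amplitude * np.exp(
        -((t - stimulus.onset) ** 2) / (2.0 * stimulus.dispersion**2)
    )
    return u if u.ndim else float(u)


def source_derivative(
    state: np.ndarray, afferent: np.ndarray, params: CMCParameters
) -> np.ndarray:
    """Time derivative of one source's state given summed afferent drive.

    ``state`` is ``[v_ss, v_sp, v_ii, v_dp, i_ss, i_sp, i_ii, i_dp]``;
    ``afferent`` is the per-population presynaptic drive (already combining
    intrinsic, extrinsic and stimulus terms).
    """
    state = np.asarray(state, dtype=float)
    afferent = np.asarray(afferent, dtype=float)
    if state.shape != (8,):
        raise ValueError("state must have length 8 (4 populations x 2)")
    if afferent.shape != (4,):
        raise ValueError("afferent must have length 4")
    if not np.all(np.isfinite(state)):
        raise ValueError("non-finite state")
    if not np.all(np.isfinite(afferent)):
        raise ValueError("non-finite afferent drive")
    v, i = state[:4], state[4:]
    kappa = 1.0 / params.tau_array()
    dv = i
    di = kappa * afferent - 2.0 * kappa * i - kappa**2 * v
    return np.concatenate([dv, di])


# ----------------------------------------------------------------------
# batched delayed integration
# ----------------------------------------------------------------------


@dataclass
class NetworkStatic:
    """Topology of a network compiled to index arrays (parameter-free)."""

    sources: list[str]
    f_src: np.ndarray  # (Ef,) presynaptic source index per forward edge
    f_dst: np.ndarray
    b_src: np.ndarray  # (Eb,)
    b_dst: np.ndarray
    scatter_f: np.ndarray  # (Ef, S) one-hot destination matrix
    scatter_b: np.ndarray  # (Eb, S)
    forward_keys: list[str]
    backward_keys: list[str]

    @property
    def n_sources(self) -> int:
        return len(self.sources)


def compile_network(model: NetworkModel) -> NetworkStatic:
    names = model.source_names
    idx = {n: k for k, n in enumerate(names)}
    f_src = np.array([idx[e.src] for e in model.forward], dtype=np.intp)
    f_dst = np.array([idx[e.dst] for e in model.forward], dtype=np.intp)
    b_src = np.array([idx[e.src] for e in model.backward], dtype=np.intp)
    b_dst = np.array([idx[e.dst] for e in model.backward], dtype=np.intp)
    S = len(names)
    scatter_f = np.zeros((len(f_dst), S))
    scatter_f[np.arange(len(f_dst)), f_dst] = 1.0
    scatter_b = np.zeros((len(b_dst), S))
    scatter_b[np.arange(len(b_dst)), b_dst] = 1.0
    return NetworkStatic(
        sources=names,
        f_src=f_src,
        f_dst=f_dst,
        b_src=b_src,
        b_dst=b_dst,
        scatter_f=scatter_f,
        scatter_b=scatter_b,
        forward_keys=[e.key for e in model.forward],
        backward_keys=[e.key for e in model.backward],
    )


@dataclass
class SimArrays:
    """One batch of physical parameter sets ready for integration.

    Shapes use B = batch, S = sources, Ef/Eb = forward/backward edges.
    """

    g: np.ndarray       # (B, S, 10) signed-magnitude intrinsic strengths (gain applied)
    tau: np.ndarray     # (B, S, 4) or (S, 4)
    slope: float
    wf: np.ndarray      # (B, Ef, 2) forward strengths (->ss, ->dp)
    wb: np.ndarray      # (B, Eb, 2) backward strengths (->sp, ->ii)
    c: np.ndarray       # (B, S) input gains
    df: np.ndarray      # (B, Ef) forward delays (ms)
    db: np.ndarray      # (B, Eb)
    dself: np.ndarray   # (B, S)

    @property
    def batch(self) -> int:
        return self.g.shape[0]


# signed intrinsic connection matrix template: rows = postsynaptic population
_PRE = np.array([POPULATIONS.index(e[0]) for e in INTRINSIC_EDGES])
_POST = np.array([POPULATIONS.index(e[1]) for e in INTRINSIC_EDGES])
_SIGN = np.array([e[2] for e in INTRINSIC_EDGES], dtype=float)


def _intrinsic_matrices(g: np.ndarray) -> np.ndarray:
    """(B, S, 10) signed magnitudes -> (B, S, 4, 4) connection matrices."""
    B, S, _ = g.shape
    M = np.zeros((B, S, 4, 4))
    for k in range(len(INTRINSIC_EDGES)):
        M[:, :, _POST[k], _PRE[k]] += _SIGN[k] * g[:, :, k]
    return M


def simulate_batch(
    static: NetworkStatic,
    arrs: SimArrays,
    stimulus: StimulusInput,
    grid: SimulationGrid,
    *,
    bound: float = 1e3,
    check_every: int = 25,
    engine: str = "auto",
) -> np.ndarray:
    """Integrate a batch of delayed CMC networks from the origin state.

    Returns voltages of shape ``(B, S, 4, n_out)`` sampled on ``grid.times``.
    Heun (explicit trapezoid) steps; delayed firing is interpolated from a
    cubic-Hermite history buffer, with zero history before ``t = 0``.

    ``engine`` is 'auto' (numba when available), 'numba' or 'numpy'; both
    implementations compute the same scheme.
    """
    from . import _kernels

    if engine == "auto":
        engine = "numba" if _kernels.HAVE_NUMBA else "numpy"
    if engine == "numpy":
        return _simulate_numpy(
            static, arrs, stimulus, grid, bound=bound, check_every=check_every
        )
    if engine != "numba":
        raise ValueError(f"unknown engine {engine!r}")
    if not _kernels.HAVE_NUMBA:
        raise RuntimeError("numba is not available; use engine='numpy'")

    B, S = arrs.c.shape
    dt = grid.dt
    tau = np.ascontiguousarray(np.broadcast_to(arrs.tau, (B, S, 4)))
    dself_s = arrs.dself / dt
    df_s = arrs.df / dt
    db_s = arrs.db / dt
    max_delay = 0.0
    for d in (dself_s, df_s, db_s):
        if d.size:
            if not np.all(d > 0):
                raise ValueError("all delays must be > 0")
            max_delay = max(max_delay, float(d.max()))
    pad = int(np.ceil(max_delay)) + 2
    step_u = np.asarray(
        gaussian_bump(dt * np.arange(grid.n_steps + 1), stimulus), dtype=float
    )
    out_steps = np.round(grid.times / dt).astype(np.int64)

    out, bad_src, bad_val = _kernels.integrate_heun(
        _intrinsic_matrices(arrs.g),
        1.0 / tau,
        np.ascontiguousarray(arrs.c),
        float(arrs.slope),
        np.ascontiguousarray(EXTRINSIC_SCALE * arrs.wf[:, :, 0]),
        np.ascontiguousarray(EXTRINSIC_SCALE * arrs.wf[:, :, 1]),
        static.f_src.astype(np.int64),
        static.f_dst.astype(np.int64),
        np.ascontiguousarray(EXTRINSIC_SCALE * arrs.wb[:, :, 0]),
        np.ascontiguousarray(EXTRINSIC_SCALE * arrs.wb[:, :, 1]),
        static.b_src.astype(np.int64),
        static.b_dst.astype(np.int64),
        np.ascontiguousarray(dself_s),
        np.ascontiguousarray(df_s),
        np.ascontiguousarray(db_s),
        step_u,
        float(dt),
        int(grid.n_steps),
        pad,
        out_steps,
        float(bound),
        int(check_every),
    )
    if bad_src >= 0:
        raise NetworkInstabilityError(
            static.sources[int(bad_src)], float(bad_val), bound
        )
    return out


def _simulate_numpy(
    static: NetworkStatic,
    arrs: SimArrays,
    stimulus: StimulusInput,
    grid: SimulationGrid,
    *,
    bound: float = 1e3,
    check_every: int = 25,
) -> np.ndarray:
    """Pure-numpy reference implementation of :func:`simulate_batch`."""
    B, S = arrs.c.shape
    dt = grid.dt
    n_steps = grid.n_steps
    r = arrs.slope

    tau = np.broadcast_to(arrs.tau, (B, S, 4))
    kappa = 1.0 / tau
    kap2 = kappa**2
    Mint = _intrinsic_matrices(arrs.g)

    # delays in fractional steps
    dself_s = arrs.dself / dt
    df_s = arrs.df / dt
    db_s = arrs.db / dt
    max_delay = 0.0
    for d in (dself_s, df_s, db_s):
        if d.size:
            if not np.all(d > 0):
                raise ValueError("all delays must be > 0")
            max_delay = max(max_delay, float(d.max()))
    pad = int(np.ceil(max_delay)) + 2

    n_hist = pad + n_steps + 1
    # firing-rate history and its time derivative (for cubic Hermite lookups)
    hist = np.zeros((n_hist, B, S, 4))
    dhist = np.zeros((n_hist, B, S, 4))

    wf_ss = EXTRINSIC_SCALE * arrs.wf[:, :, 0]
    wf_dp = EXTRINSIC_SCALE * arrs.wf[:, :, 1]
    wb_sp = EXTRINSIC_SCALE * arrs.wb[:, :, 0]
    wb_ii = EXTRINSIC_SCALE * arrs.wb[:, :, 1]
    have_f = arrs.wf.shape[1] > 0
    have_b = arrs.wb.shape[1] > 0

    bb = np.arange(B)[:, None]
    cols = np.arange(B * S)

    out_times = grid.times
    out_steps = np.round(out_times / dt).astype(int)
    out_pos = {step: j for j, step in enumerate(out_steps)}
    out = np.zeros((B, S, 4, len(out_times)))

    # precompute stimulus at step and half-step times used by Heun stages
    step_u = gaussian_bump(dt * np.arange(n_steps + 1), stimulus)

    v = np.zeros((B, S, 4))
    i = np.zeros((B, S, 4))

    def _hermite(u, F0, F1, d0, d1):
        """Cubic Hermite in index units (derivatives pre-scaled by dt)."""
        u2 = u * u
        u3 = u2 * u
        return (
            (2 * u3 - 3 * u2 + 1) * F0
            + (u3 - 2 * u2 + u) * d0
            + (-2 * u3 + 3 * u2) * F1
            + (u3 - u2) * d1
        )

    def rhs(k_float: float, u_k: float, v, i, latest: int):
        """Derivative at stage time ``k_float * dt``; ``latest`` = newest hist row."""
        # intrinsic drive from self-delayed firing of all populations
        idx = np.clip(pad + k_float - dself_s, 0.0, float(latest))
        lo = np.minimum(idx.astype(int), latest - 1)
        frac = idx - lo
        Hf = hist.reshape(n_hist, B * S, 4)
        Df = dhist.reshape(n_hist, B * S, 4)
        lo_f = lo.reshape(B * S)
        fr = frac.reshape(B * S, 1)
        Fs = _hermite(
            fr,
            Hf[lo_f, cols, :], Hf[lo_f + 1, cols, :],
            Df[lo_f, cols, :], Df[lo_f + 1, cols, :],
        ).reshape(B, S, 4)
        aff = np.einsum("bspq,bsq->bsp", Mint, Fs)

        if have_f:
            idx = np.clip(pad + k_float - df_s, 0.0, float(latest))
            lo = np.minimum(idx.astype(int), latest - 1)
            frac = idx - lo
            Hsp = hist[:, :, :, SP]
            Dsp = dhist[:, :, :, SP]
            vf = _hermite(
                frac,
                Hsp[lo, bb, static.f_src], Hsp[lo + 1, bb, static.f_src],
                Dsp[lo, bb, static.f_src], Dsp[lo + 1, bb, static.f_src],
            )
            aff[:, :, SS] += (wf_ss * vf) @ static.scatter_f
            aff[:, :, DP] += (wf_dp * vf) @ static.scatter_f
        if have_b:
            idx = np.clip(pad + k_float - db_s, 0.0, float(latest))
            lo = np.minimum(idx.astype(int), latest - 1)
            frac = idx - lo
            Hdp = hist[:, :, :, DP]
            Ddp = dhist[:, :, :, DP]
            vb = _hermite(
                frac,
                Hdp[lo, bb, static.b_src], Hdp[lo + 1, bb, static.b_src],
                Ddp[lo, bb, static.b_src], Ddp[lo + 1, bb, static.b_src],
            )
            aff[:, :, SP] += (wb_sp * vb) @ static.scatter_b
            aff[:, :, II] += (wb_ii * vb) @ static.scatter_b

        aff[:, :, SS] += arrs.c * u_k

        dv = i
        di = kappa * aff - 2.0 * kappa * i - kap2 * v
        return dv, di

    if 0 in out_pos:
        out[:, :, :, out_pos[0]] = v

    for k in range(n_steps):
        latest = pad + k
        d1v, d1i = rhs(float(k), step_u[k], v, i, latest)
        vp = v + dt * d1v
        ip = i + dt * d1i
        d2v, d2i = rhs(float(k + 1), step_u[k + 1], vp, ip, latest)
        v = v + 0.5 * dt * (d1v + d2v)
        i = i + 0.5 * dt * (d1i + d2i)
        s_logit = 1.0 / (1.0 + np.exp(-r * v))
        hist[pad + k + 1] = s_logit - 0.5
        # d/d(index) of firing = dt * S'(v) * v' for Hermite lookups
        dhist[pad + k + 1] = dt * r * s_logit * (1.0 - s_logit) * i

        j = out_pos.get(k + 1)
        if j is not None:
            out[:, :, :, j] = v

        if (k + 1) % check_every == 0 or k == n_steps - 1:
            amax = np.abs(v).max()
            if not np.isfinite(amax) or amax > bound:
                flat = np.abs(v).reshape(B, S, 4)
                with np.errstate(invalid="ignore"):
                    bad = np.nanargmax(np.nan_to_num(flat, nan=np.inf).max(axis=(0, 2)))
                raise NetworkInstabilityError(
                    static.sources[int(bad)], float(amax), bound
                )

    return out


def _arrays_from_model(
    model: NetworkModel,
    params: CMCParameters | Mapping[str, CMCParameters],
) -> SimArrays:
    names = model.source_names
    if isinstance(params, CMCParameters):
        per_source = {n: params for n in names}
    else:
        per_source = dict(params)
        missing = set(names) - set(per_source)
        if missing:
            raise ValueError(f"missing CMCParameters for sources {sorted(missing)}")
    slope = {per_source[n].sigmoid_slope for n in names}
    if len(slope) != 1:
        raise ValueError("all sources must share a sigmoid slope")
    g = np.stack([per_source[n].g_array() for n in names])[None]
    tau = np.stack([per_source[n].tau_array() for n in names])
    wf = np.array([model.a_forward[e.key] for e in model.forward], dtype=float)
    wb = np.array([model.a_backward[e.key] for e in model.backward], dtype=float)
    return SimArrays(
        g=g,
        tau=tau,
        slope=slope.pop(),
        wf=wf.reshape(1, -1, 2) if wf.size else np.zeros((1, 0, 2)),
        wb=wb.reshape(1, -1, 2) if wb.size else np.zeros((1, 0, 2)),
        c=np.array([[model.c.get(n, 0.0) for n in names]]),
        df=np.array([[model.d_forward[e.key] for e in model.forward]]).reshape(1, -1),
        db=np.array([[model.d_backward[e.key] for e in model.backward]]).reshape(1, -1),
        dself=np.array([[model.d_self[n] for n in names]]),
    )


def integrate_network(
    model: NetworkModel,
    params: CMCParameters | Mapping[str, CMCParameters],
    stimulus: StimulusInput | None = None,
    grid: SimulationGrid | None = None,
    *,
    bound: float = 1e3,
) -> SimulationResult:
    """Simulate a network's evoked response from the origin state.

    ``params`` may be a single :class:`CMCParameters` shared by all sources
    or a mapping source name -> parameters.  Extrinsic strengths, input
    gains and delays are taken from the model's baseline values.
    """
    stimulus = stimulus or StimulusInput()
    grid = grid or SimulationGrid()
    static = compile_network(model)
    arrs = _arrays_from_model(model, params)
    volt = simulate_batch(static, arrs, stimulus, grid, bound=bound)
    return SimulationResult(times=grid.times, voltages=volt[0], sources=static.sources)
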