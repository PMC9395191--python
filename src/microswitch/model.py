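"""Stochastic Wilson-Cowan dynamics of the eight-population microcircuit.

Each population is a single rate unit.  The coupled dynamics are

    tau_i dr_i/dt = -r_i + phi(sum_j W_ij r_j + I_ext,i) + eta_i

with the transfer function ``phi(x) = a*x / (1 - exp(-x/b))`` shared by all
populations and ``eta`` additive Gaussian noise of standard deviation
``sigma``.  Integration is forward Euler with the noise term added inside the
``dt/tau`` update (per-step i.i.d., no sqrt(dt) rescaling), matching the
discrete scheme the dynamics are defined by at ``dt = 0.1 ms``; an optional
flag switches to Euler-Maruyama sqrt(dt) scaling for users who want
dt-invariant noise statistics.  Conduction delays are not modeled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import optimize

from .connectivity import ConnectivityMatrix
from .populations import N_POP, POPULATIONS, index_of, pyr_index

__all__ = [
    "ModelParams",
    "StimulusProtocol",
    "RateTrace",
    "SteadyState",
    "DivergenceError",
    "transfer",
    "transfer_deriv",
    "simulate",
    "steady_state",
    "linearized_frequency",
]

#: Literature-motivated population time constants (ms): fast pyramidal and PV
#: decay, slower SST, intermediate VIP.  Placeholders standing in for measured
#: per-type values; override per population for any specific dataset.
DEFAULT_TAU: dict[str, float] = {"PYR": 4.0, "PV": 5.0, "SST": 25.0, "VIP": 12.0}


class DivergenceError(RuntimeError):
    """Simulation blew up (non-finite or astronomically large rates)."""

    def __init__(self, time_ms: float):
        self.time_ms = time_ms
        super().__init__(f"rates diverged at t = {time_ms:.3f} ms")


def _default_tau_vector() -> np.ndarray:
    return np.array([DEFAULT_TAU[lbl.split("_")[0]] for lbl in POPULATIONS])


@dataclass
class ModelParams:
    """Dynamical parameters of the rate model.

    tau : per-population time constants (ms); a : transfer slope; b :
    transfer threshold (Hz); sigma : noise SD (Hz, 0.01 by default); dt :
    Euler step (ms, 0.1 by default).
    """

    tau: np.ndarray = field(default_factory=_default_tau_vector)
    a: float = 1.0
    b: float = 1.0
    sigma: float = 0.01
    dt: float = 0.1
    sqrt_dt_noise: bool = False   # Euler-Maruyama noise scaling, off by default
    clip_rates: bool = False      # clamp rates at 0 after each step, off by default

    def __post_init__(self) -> None:
        self.tau = np.broadcast_to(np.asarray(self.tau, dtype=float),
                                   (N_POP,)).copy()
        if (self.tau <= 0).any():
            raise ValueError("all time constants must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.a <= 0 or self.b <= 0:
            raise ValueError("transfer parameters a and b must be positive")

    def with_(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)

    def with_tau(self, per_class: dict[str, float]) -> "ModelParams":
        """New params with time constants overridden per cell class or label."""
        tau = self.tau.copy()
        for key, val in per_class.items():
            if key in POPULATIONS:
                tau[index_of(key)] = val
            else:
                for i, lbl in enumerate(POPULATIONS):
                    if lbl.split("_")[0] == key:
                        tau[i] = val
        return replace(self, tau=tau)


@dataclass
class StimulusProtocol:
    """External drive per population: constant baseline plus timed steps.

    ``baseline`` is a length-8 constant drive (Hz).  ``steps`` is an ordered
    list of ``(t_start_ms, t_end_ms, drive_vector)`` added within the window;
    windows must not overlap.  ``input_weights`` (with ``amplitude``)
    expresses a scaled per-population drive, e.g. feedforward/feedback weight
    vectors normalized to PYR; it is added to the baseline.
    """

    baseline: np.ndarray = field(default_factory=lambda: np.zeros(N_POP))
    steps: list[tuple[float, float, np.ndarray]] = field(default_factory=list)
    input_weights: np.ndarray | None = None
    amplitude: float = 0.0

    def __post_init__(self) -> None:
        self.baseline = np.broadcast_to(
            np.asarray(self.baseline, dtype=float), (N_POP,)).copy()
        self.steps = [
            (float(t0), float(t1),
             np.broadcast_to(np.asarray(d, dtype=float), (N_POP,)).copy())
            for t0, t1, d in self.steps
        ]
        if self.input_weights is not None:
            self.input_weights = np.broadcast_to(
                np.asarray(self.input_weights, dtype=float), (N_POP,)).copy()

    @classmethod
    def from_dict(cls, drives: dict[str, float], **kwargs) -> "StimulusProtocol":
        """Baseline drive from a ``{population or cell class: Hz}`` mapping."""
        baseline = np.zeros(N_POP)
        for key, val in drives.items():
            if key in POPULATIONS:
                baseline[index_of(key)] += val
            else:
                hit = False
                for i, lbl in enumerate(POPULATIONS):
                    if lbl.split("_")[0] == key:
                        baseline[i] += val
                        hit = True
                if not hit:
                    raise KeyError(f"unknown population or cell class {key!r}")
        return cls(baseline=baseline, **kwargs)

    def constant_drive(self) -> np.ndarray:
        """Baseline plus weighted component (the time-invariant part)."""
        drive = self.baseline.copy()
        if self.input_weights is not None:
            drive += self.input_weights * self.amplitude
        return drive

    def added(self, extra: np.ndarray | dict[str, float]) -> "StimulusProtocol":
        """New protocol with ``extra`` added to the baseline."""
        if isinstance(extra, dict):
            extra = StimulusProtocol.from_dict(extra).baseline
        return StimulusProtocol(
            baseline=self.baseline + np.asarray(extra, dtype=float),
            steps=list(self.steps),
            input_weights=None if self.input_weights is None
            else self.input_weights.copy(),
            amplitude=self.amplitude,
        )

    def validate_windows(self, duration_ms: float) -> None:
        windows = sorted((t0, t1) for t0, t1, _ in self.steps)
        for (a0, a1), (b0, b1) in zip(windows, windows[1:]):
            if b0 < a1:
                raise ValueError(f"overlapping stimulus windows {a0, a1} and {b0, b1}")
        for t0, t1 in windows:
            if t0 < 0 or t1 > duration_ms or t1 <= t0:
                raise ValueError(f"stimulus window ({t0}, {t1}) outside simulation")


def background_drive(pyr_hz: float = 5.0) -> StimulusProtocol:
    """Canonical background: constant drive to both PYR populations.

    Pyramidal cells need a small external drive (5 Hz unless stated
    otherwise) for their rate — the oscillation readout — to stay above zero
    under strong inhibition.
    """
    return StimulusProtocol.from_dict({"PYR": pyr_hz})


# ----------------------------------------------------------------------
# Transfer function
# ----------------------------------------------------------------------

def transfer(x, a: float = 1.0, b: float = 1.0):
    """Rate transfer ``phi(x) = a*x / (1 - exp(-x/b))``.

    Positive, strictly increasing, with the removable singularity at
    ``x = 0`` evaluated by its limit ``a*b``.  Overflow-safe for any real
    input: for large negative ``x`` the value decays like ``-a*x*exp(x/b)``.
    """
    x = np.asarray(x, dtype=float)
    u = x / b
    out = np.empty_like(u)
    small = np.abs(u) < 1e-9
    pos = (u >= 0) & ~small
    neg = (u < 0) & ~small
    # u >= 0: 1 - exp(-u) = -expm1(-u), no overflow
    out[pos] = u[pos] / (-np.expm1(-u[pos]))
    # u < 0: multiply through by exp(u) (in (0,1)): u*exp(u) / (exp(u) - 1)
    eu = np.exp(u[neg])
    out[neg] = u[neg] * eu / (eu - 1.0)
    out[small] = 1.0 + u[small] / 2.0
    result = a * b * out
    return float(result) if result.ndim == 0 else result


def transfer_deriv(x, a: float = 1.0, b: float = 1.0):
    """Derivative ``d phi / d x``; equals ``a/2`` at the origin."""
    x = np.asarray(x, dtype=float)
    u = x / b
    out = np.empty_like(u)
    small = np.abs(u) < 1e-6
    pos = (u >= 0) & ~small
    neg = (u < 0) & ~small
    d_pos = -np.expm1(-u[pos])            # 1 - exp(-u)
    out[pos] = 1.0 / d_pos - u[pos] * np.exp(-u[pos]) / d_pos ** 2
    eu = np.exp(u[neg])                   # in (0, 1)
    den = eu - 1.0
    out[neg] = eu / den - u[neg] * eu / den ** 2
    out[small] = 0.5 + u[small] / 6.0
    result = a * out
    return float(result) if result.ndim == 0 else result


# ----------------------------------------------------------------------
# Euler integration kernel (numba-jitted when available)
# ----------------------------------------------------------------------

def _euler_loop(W, dt_over_tau, a, b, r0, drive, drive_2d, noise, has_noise,
                n_steps, stride, out):
    n = r0.shape[0]
    r = r0.copy()
    out[0, :] = r
    k = 1
    for t in range(n_steps):
        d_row = t if drive_2d else 0
        s = np.empty(n)
        for i in range(n):
            acc = drive[d_row, i]
            for j in range(n):
                acc += W[i, j] * r[j]
            s[i] = acc
        for i in range(n):
            u = s[i] / b
            if u > 1e-9:
                phi = a * b * u / (1.0 - math.exp(-u))
            elif u < -1e-9:
                eu = math.exp(u)
                phi = a * b * u * eu / (eu - 1.0)
            else:
                phi = a * b * (1.0 + 0.5 * u)
            eta = noise[t, i] if has_noise else 0.0
            r[i] = r[i] + dt_over_tau[i] * (-r[i] + phi + eta)
            if not (-1e9 < r[i] < 1e9):
                return t
        if (t + 1) % stride == 0:
            out[k, :] = r
            k += 1
    return -1


try:  # pragma: no cover - exercised indirectly
    from numba import njit

    _euler_jit = njit(cache=True, fastmath=False)(_euler_loop)
except Exception:  # pragma: no cover
    _euler_jit = _euler_loop


# ----------------------------------------------------------------------
# Simulation contracts
# ----------------------------------------------------------------------

@dataclass
class RateTrace:
    """Population rate time series from one simulation run."""

    time: np.ndarray          # sample times (ms)
    rates: np.ndarray         # (n_samples, 8) rates (Hz)
    params: ModelParams
    G: float
    seed: int | None

    def population(self, label: str) -> np.ndarray:
        return self.rates[:, index_of(label)]

    def layer_lfp(self, layer: str) -> np.ndarray:
        """LFP proxy of a layer: its pyramidal-population rate."""
        return self.rates[:, pyr_index(layer)]

    def mean_rates(self, discard_ms: float = 0.0) -> np.ndarray:
        keep = self.time >= discard_ms
        return self.rates[keep].mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long format: time, population, rate."""
        n = len(self.time)
        return pd.DataFrame({
            "time": np.repeat(self.time, N_POP),
            "population": np.tile(np.array(POPULATIONS), n),
            "rate": self.rates.ravel(),
        })

    def save(self, path) -> None:
        """Compact binary cache (compressed npz) of the trace and provenance."""
        np.savez_compressed(
            path, time=self.time, rates=self.rates, tau=self.params.tau,
            scalars=np.array([self.params.a, self.params.b, self.params.sigma,
                              self.params.dt, self.G,
                              np.nan if self.seed is None else self.seed]))

    @classmethod
    def load(cls, path) -> "RateTrace":
        with np.load(path) as data:
            a, b, sigma, dt, G, seed = data["scalars"]
            params = ModelParams(tau=data["tau"], a=a, b=b, sigma=sigma, dt=dt)
            return cls(time=data["time"], rates=data["rates"], params=params,
                       G=float(G), seed=None if np.isnan(seed) else int(seed))


def simulate(
    C: ConnectivityMatrix,
    params: ModelParams,
    stim: StimulusProtocol,
    duration: float,
    seed: int | None = None,
    initial_rates: np.ndarray | None = None,
    record_stride: int = 1,
) -> RateTrace:
    """Integrate the stochastic rate dynamics for ``duration`` ms.

    Noise is drawn i.i.d. Gaussian(0, sigma) per population per step from a
    generator seeded with ``seed``; identical arguments give bit-identical
    traces.  ``record_stride`` subsamples the stored trace (the integration
    step itself is always ``params.dt``).

    Raises :class:`DivergenceError` if rates become non-finite, which happens
    for example under very strong recurrent excitation.
    """
    if duration < params.dt:
        raise ValueError("duration must be at least one integration step")
    stim.validate_windows(duration)
    n_steps = int(round(duration / params.dt))
    const = stim.constant_drive()
    if stim.steps:
        drive = np.tile(const, (n_steps, 1))
        t_axis = np.arange(n_steps) * params.dt
        for t0, t1, extra in stim.steps:
            mask = (t_axis >= t0) & (t_axis < t1)
            drive[mask] += extra
    else:
        drive = const.reshape(1, N_POP)

    if params.sigma > 0:
        rng = np.random.default_rng(seed)
        noise = rng.standard_normal((n_steps, N_POP)) * params.sigma
        if params.sqrt_dt_noise:
            noise /= math.sqrt(params.dt)
    else:
        noise = np.zeros((1, N_POP))

    r0 = (np.zeros(N_POP) if initial_rates is None
          else np.asarray(initial_rates, dtype=float).copy())
    n_rec = n_steps // record_stride + 1
    out = np.empty((n_rec, N_POP))
    dt_over_tau = params.dt / params.tau

    status = _euler_jit(
        np.ascontiguousarray(C.W), dt_over_tau, params.a, params.b,
        r0, np.ascontiguousarray(drive), drive.shape[0] > 1,
        np.ascontiguousarray(noise), params.sigma > 0,
        n_steps, record_stride, out,
    )
    if status >= 0:
        raise DivergenceError((status + 1) * params.dt)
    if params.clip_rates:
        np.clip(out, 0.0, None, out=out)
    time = np.arange(n_rec) * (record_stride * params.dt)
    return RateTrace(time=time, rates=out, params=params, G=C.G, seed=seed)


class SteadyState(NamedTuple):
    """Terminal rates of a noise-free relaxation plus a convergence flag."""

    rates: np.ndarray
    converged: bool


def steady_state(
    C: ConnectivityMatrix,
    params: ModelParams,
    stim: StimulusProtocol,
    duration: float = 2000.0,
    initial_rates: np.ndarray | None = None,
    tol: float = 1e-7,
) -> SteadyState:
    """Noise-free (sigma = 0) relaxation for 2 s; returns terminal rates.

    ``converged`` is False when the terminal time-derivative still exceeds
    ``tol`` Hz/ms (e.g. on a sustained limit cycle); no exception is raised
    in that case.
    """
    p0 = params.with_(sigma=0.0)
    trace = simulate(C, p0, stim, duration, seed=None,
                     initial_rates=initial_rates,
                     record_stride=max(1, int(round(duration / params.dt)) // 2))
    r = trace.rates[-1]
    drive = stim.constant_drive()
    dr = (-r + transfer(C.W @ r + drive, params.a, params.b)) / params.tau
    return SteadyState(rates=r, converged=bool(np.max(np.abs(dr)) < tol))


class FixedPointError(RuntimeError):
    """No stable fixed point could be located."""


def linearized_frequency(
    C: ConnectivityMatrix,
    params: ModelParams,
    stim: StimulusProtocol,
) -> float | None:
    """Resonance frequency (Hz) from the Jacobian at the fixed point.

    Relaxes to the noise-free steady state, polishes it with a root solver on
    ``r = phi(W r + I_ext)``, forms the Jacobian
    ``J = diag(1/tau) (-I + diag(phi') W)`` and returns ``Im(lambda)/2pi`` of
    the least-damped complex eigenpair — the frequency at which noise-driven
    fluctuations resonate.  Returns ``None`` when all eigenvalues are real.
    """
    ss = steady_state(C, params, stim)
    drive = stim.constant_drive()

    def residual(r):
        return r - transfer(C.W @ r + drive, params.a, params.b)

    sol = optimize.root(residual, ss.rates, method="hybr", tol=1e-12)
    if not sol.success or np.max(np.abs(residual(sol.x))) > 1e-6:
        raise FixedPointError("root polish of the steady state failed")
    r_star = sol.x
    slope = transfer_deriv(C.W @ r_star + drive, params.a, params.b)
    J = (1.0 / params.tau)[:, None] * (-np.eye(N_POP) + slope[:, None] * C.W)
    lam = np.linalg.eigvals(J)
    complex_pairs = lam[np.abs(lam.imag) > 1e-9]
    if complex_pairs.size == 0:
        return None
    lead = complex_pairs[np.argmax(complex_pairs.real)]
    # J is in 1/ms, so Im(lambda)/(2 pi) is in kHz
    return float(abs(lead.imag) / (2.0 * math.pi) * 1000.0)
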