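"""Ultrasensitivity and bistability metrics of input-response sweeps.

A sweep drives selected populations over a grid of input values and records
the noise-free steady state at each grid point, warm-starting each point from
the previous one — the protocol that exposes hysteresis when the circuit is
bistable.  The SST response curve is summarized by a Hill-equation fit

    y(x) = c + d * x^n / (k^n + x^n)

whose exponent ``n`` (the Hill coefficient ``n_H``) measures ultrasensitivity;
``d`` may be negative for decreasing (SST-suppression) curves.  Hysteresis is
the summed absolute difference between ascending and descending SST curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lmfit import Model as LmModel

from .connectivity import ConnectivityMatrix
from .model import ModelParams, StimulusProtocol, steady_state
from .populations import N_POP, POPULATIONS, index_of

__all__ = [
    "ResponseCurve",
    "SweepResult",
    "HillFit",
    "HysteresisResult",
    "sweep_response",
    "fit_hill",
    "hysteresis_area",
]


@dataclass
class ResponseCurve:
    """Steady-state rate of one population along an input sweep."""

    input_grid: np.ndarray
    rates: np.ndarray
    population: str
    direction: str              # "ascending" or "descending"
    warm_started: bool

    def __post_init__(self) -> None:
        diffs = np.diff(self.input_grid)
        if self.direction == "ascending" and not (diffs > 0).all():
            raise ValueError("ascending sweep requires a strictly increasing grid")
        if self.direction == "descending" and not (diffs < 0).all():
            raise ValueError("descending sweep requires a strictly decreasing grid")


@dataclass
class SweepResult:
    """All-population response curves of one warm-started sweep."""

    input_grid: np.ndarray      # in sweep order
    rates: np.ndarray           # (n_grid, 8)
    direction: str
    warm_started: bool
    target_populations: tuple[str, ...]

    def curve(self, population: str) -> ResponseCurve:
        return ResponseCurve(
            input_grid=self.input_grid.copy(),
            rates=self.rates[:, index_of(population)].copy(),
            population=population,
            direction=self.direction,
            warm_started=self.warm_started,
        )

    def to_frame(self) -> pd.DataFrame:
        n = len(self.input_grid)
        return pd.DataFrame({
            "input": np.repeat(self.input_grid, N_POP),
            "population": np.tile(np.array(POPULATIONS), n),
            "rate": self.rates.ravel(),
            "direction": self.direction,
        })


def sweep_response(
    C: ConnectivityMatrix,
    params: ModelParams,
    stim_template: StimulusProtocol,
    target_populations: tuple[str, ...] | list[str],
    input_grid: np.ndarray,
    direction: str = "ascending",
    warm_start: bool = True,
    settle_ms: float = 2000.0,
) -> SweepResult:
    """Noise-free steady-state response along an input grid.

    Each grid value is added to the template baseline of every population in
    ``target_populations``.  With ``warm_start`` the steady state at grid
    point ``i`` initializes point ``i + 1`` (the hysteresis protocol);
    otherwise every point starts from zero rates.  Divergence at any grid
    point raises with the offending input value named.
    """
    grid = np.asarray(input_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("input grid must be non-empty")
    if direction not in ("ascending", "descending"):
        raise ValueError(f"unknown direction {direction!r}")
    targets = [index_of(p) for p in target_populations]
    extra = np.zeros(N_POP)
    rates = np.empty((grid.size, N_POP))
    r_prev: np.ndarray | None = None
    for i, value in enumerate(grid):
        extra[:] = 0.0
        extra[targets] = value
        stim = stim_template.added(extra)
        try:
            ss = steady_state(C, params, stim, duration=settle_ms,
                              initial_rates=r_prev if warm_start else None)
        except Exception as exc:
            raise RuntimeError(f"sweep diverged at input {value}") from exc
        rates[i] = ss.rates
        r_prev = ss.rates
    return SweepResult(input_grid=grid, rates=rates, direction=direction,
                       warm_started=warm_start,
                       target_populations=tuple(target_populations))


# ----------------------------------------------------------------------
# Hill fit
# ----------------------------------------------------------------------

@dataclass
class HillFit:
    """Hill-equation parameters fitted to a response curve."""

    c: float
    d: float
    k: float
    n: float
    residual_norm: float
    quality_warning: str | None = None

    @property
    def n_H(self) -> float:
        return self.n

    def predict(self, x: np.ndarray) -> np.ndarray:
        return hill(np.asarray(x, dtype=float), self.c, self.d, self.k, self.n)


def hill(x, c, d, k, n):
    """Hill curve ``c + d x^n / (k^n + x^n)`` (hyperbolic for n = 1)."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        xn = np.where(x > 0, np.power(x, n), 0.0)
        out = c + d * xn / (k ** n + xn)
    return out


_N_STARTS = (0.5, 1.0, 2.0, 4.0, 8.0, 16.0)


def fit_hill(curve: ResponseCurve) -> HillFit:
    """Least-squares Hill fit with multi-start over the exponent.

    ``d`` is free to be negative so decreasing (SST-suppression) curves are
    fitted directly.  Bounds: ``|d|`` at most 10x the data range, ``k``
    within 0.01-100x the swept input range, ``n`` in (0, 50].  A flat or
    strongly non-monotone curve yields a ``quality_warning`` in the returned
    fit instead of an exception.
    """
    x = np.asarray(curve.input_grid, dtype=float)
    y = np.asarray(curve.rates, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 input values for a Hill fit")
    order = np.argsort(x)
    x, y = x[order], y[order]

    y_range = float(y.max() - y.min())
    x_span = float(max(x.max(), 1e-6))
    quality = None
    if y_range < 1e-9:
        quality = "flat response curve; Hill parameters are not identifiable"
        return HillFit(c=float(y.mean()), d=0.0, k=x_span / 2, n=1.0,
                       residual_norm=0.0, quality_warning=quality)
    dy = np.diff(y)
    if (dy > 1e-9).any() and (dy < -1e-9).any():
        frac = min((dy > 1e-9).sum(), (dy < -1e-9).sum()) / dy.size
        if frac > 0.2:
            quality = "response curve is strongly non-monotone; fit may be poor"

    model = LmModel(hill)
    d0 = y[-1] - y[0]
    best = None
    for n0 in _N_STARTS:
        pars = model.make_params(
            c=dict(value=float(y[0])),
            d=dict(value=float(d0) if d0 != 0 else y_range,
                   min=-10 * y_range, max=10 * y_range),
            k=dict(value=float(np.median(x[x > 0])) if (x > 0).any() else 1.0,
                   min=0.01 * x_span, max=100.0 * x_span),
            n=dict(value=n0, min=1e-3, max=50.0),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = model.fit(y, pars, x=x)
            except Exception:
                continue
        rnorm = float(np.sqrt(np.sum(res.residual ** 2)))
        if best is None or rnorm < best[0]:
            best = (rnorm, res)
    if best is None:
        return HillFit(c=float(y.mean()), d=0.0, k=x_span / 2, n=1.0,
                       residual_norm=float(np.sqrt(np.sum((y - y.mean()) ** 2))),
                       quality_warning="Hill fit failed to converge")
    rnorm, res = best
    p = res.params
    return HillFit(c=float(p["c"].value), d=float(p["d"].value),
                   k=float(p["k"].value), n=float(p["n"].value),
                   residual_norm=rnorm, quality_warning=quality)


# ----------------------------------------------------------------------
# Hysteresis
# ----------------------------------------------------------------------

@dataclass
class HysteresisResult:
    """Summed up/down SST response differences per layer."""

    h_superficial: float
    h_deep: float
    up: SweepResult | None = field(default=None, repr=False)
    down: SweepResult | None = field(default=None, repr=False)

    @property
    def h_total(self) -> float:
        return self.h_superficial + self.h_deep


def hysteresis_area(up: SweepResult, down: SweepResult) -> HysteresisResult:
    """Hysteresis ``h`` per layer from ascending and descending sweeps.

    ``h`` is the sum over the grid of |ascending - descending| SST rates of
    each layer; it is zero exactly when the curves coincide on the grid.
    The two sweeps must cover the same grid (one reversed).
    """
    if not np.allclose(up.input_grid, down.input_grid[::-1]):
        raise ValueError("up and down sweeps must share the same input grid")
    rev = down.rates[::-1]
    h = {}
    for layer, lbl in (("superficial", "SST_sup"), ("deep", "SST_deep")):
        j = index_of(lbl)
        h[layer] = float(np.abs(up.rates[:, j] - rev[:, j]).sum())
    return HysteresisResult(h_superficial=h["superficial"], h_deep=h["deep"],
                            up=up, down=down)
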