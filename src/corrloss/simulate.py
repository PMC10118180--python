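"""Synthetic Cauchy-type (Lorentzian) band series with controllable
amplitude nonlinearity, perturbation-coupled peak shift, and
multiplicative/additive corruption."""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Literal

import numpy as np

from .corr2d import Curve, CurveGrid, CurveSeries

__all__ = [
    "CauchyParams",
    "ErrorModel",
    "cauchy_curve",
    "generate_series",
    "apply_error",
    "mixture_pair",
    "default_grid",
    "DEFAULT_T_VALUES",
]

#: perturbation values of the reference rejection experiment
DEFAULT_T_VALUES = (1.0, 2.0, 3.0, 4.0, 5.0)


def default_grid() -> CurveGrid:
    """Unit-step integer grid on the open interval (900, 1100)."""
    return CurveGrid(np.arange(901.0, 1100.0))


@dataclass(frozen=True)
class CauchyParams:
    """Parameters of the band model

        f(x, t) = t (1 + a t) gamma / ((x - x0 +/- b t)^2 + gamma^2)

    ``a`` makes the amplitude grow nonlinearly with t; ``b`` couples the
    peak position to t.  In the default ``downshift`` mode the peak sits at
    ``x0 - b t`` (it moves to smaller x as t grows); ``as-printed`` places
    it at ``x0 + b t``.
    """

    x0: float = 1000.0
    gamma: float = 30.0
    a: float = 0.0
    b: float = 0.0
    shift_sign: Literal["downshift", "as-printed"] = "downshift"

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")

    @property
    def peak_sign(self) -> float:
        return -1.0 if self.shift_sign == "downshift" else 1.0

    def peak_position(self, t: float) -> float:
        return self.x0 + self.peak_sign * self.b * t


@dataclass(frozen=True)
class ErrorModel:
    """Systematic corruption: entrywise multiplication by ``factor``
    (a constant or a function of x), then addition of ``offset``."""

    factor: float | Callable[[np.ndarray], np.ndarray] = 1.0
    offset: float = 0.0

    def factor_on(self, x: np.ndarray) -> np.ndarray:
        f = self.factor(x) if callable(self.factor) else np.full_like(x, self.factor)
        f = np.asarray(f, dtype=float)
        if np.any(f <= 0):
            raise ValueError("multiplicative factor must be positive everywhere")
        return f


def cauchy_curve(params: CauchyParams, grid: CurveGrid, t: float) -> Curve:
    """Evaluate the band model at perturbation t.  Peak height is
    ``t (1 + a t) / gamma`` at the peak position."""
    x = grid.x_values
    peak = params.peak_position(t)
    y = t * (1.0 + params.a * t) * params.gamma / ((x - peak) ** 2 + params.gamma**2)
    return Curve(grid, y, role="simulated")


def generate_series(
    params: CauchyParams, grid: CurveGrid, t_values
) -> CurveSeries:
    """Stack one band curve per t value (row order follows ``t_values``;
    neither ordering nor equidistance is required, duplicates allowed)."""
    t = np.atleast_1d(np.asarray(t_values, dtype=float))
    if t.size == 0:
        raise ValueError("t_values must be nonempty")
    rows = np.vstack([cauchy_curve(params, grid, tj).intensities for tj in t])
    return CurveSeries(grid, t, rows)


def apply_error(series: CurveSeries, model: ErrorModel) -> CurveSeries:
    """Corrupt a series: scale each column by the (possibly x-dependent)
    factor, then add the offset."""
    f = model.factor_on(series.grid.x_values)
    y = series.intensities * f[np.newaxis, :] + model.offset
    return CurveSeries(series.grid, series.t_values, y)


def mixture_pair(
    params1: CauchyParams,
    params2: CauchyParams,
    grid: CurveGrid,
    t_values,
) -> tuple[CurveSeries, CurveSeries]:
    """Two series sharing grid, t, x0 and gamma but differing in (a, b) —
    the setting in which hybrid asynchronous maps lose their antisymmetry
    and a fit must be rejected."""
    if (params1.x0, params1.gamma) != (params2.x0, params2.gamma):
        raise ValueError("mixture_pair varies only a and b; x0/gamma must match")
    return (
        generate_series(params1, grid, t_values),
        generate_series(params2, grid, t_values),
    )
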