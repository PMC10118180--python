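"""Two-dimensional correlation maps for curve series and curve pairs.

A *curve series* is a stack of sampled curves sharing an x-grid, one curve
per value of an external perturbation variable ``t``.  From such a series
(or from a single pair of curves) synchronous and asynchronous correlation
maps are built; their symmetry structure is what the loss functions in
:mod:`corrloss.losses` exploit.

Conventions
-----------
* The intensity block of a series is ``(m, n)``: row ``j`` is the curve at
  ``t_j``, column ``i`` the intensity at ``x_i``.
* Maps are ``(n, n)`` with entry ``[j, k]`` correlating grid positions
  ``x_j`` and ``x_k``.
* Series maps are normalized by ``m - 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "CurveGrid",
    "Curve",
    "CurveSeries",
    "CorrelationMaps",
    "PhaseAngleMap",
    "build_dynamic_matrix",
    "noda_matrix",
    "synchronous_map",
    "asynchronous_map",
    "correlation_maps",
    "two_trace_maps",
    "phase_angle_map",
    "export_map",
]

MapKind = Literal["conventional", "hybrid-series", "two-trace"]


@dataclass(frozen=True)
class CurveGrid:
    """Strictly increasing sampling grid of the shaping variable x."""

    x_values: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x_values, dtype=float)
        if x.ndim != 1 or x.size < 2:
            raise ValueError("grid must be a 1-D array of length >= 2")
        if not np.all(np.isfinite(x)):
            raise ValueError("grid values must be finite")
        if not np.all(np.diff(x) > 0):
            raise ValueError("grid values must be strictly increasing")
        object.__setattr__(self, "x_values", x)

    def __len__(self) -> int:
        return self.x_values.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CurveGrid):
            return NotImplemented
        return np.array_equal(self.x_values, other.x_values)


@dataclass(frozen=True)
class Curve:
    """A single sampled curve on a grid."""

    grid: CurveGrid
    intensities: np.ndarray
    role: Literal["measured", "simulated"] = "measured"

    def __post_init__(self) -> None:
        y = np.asarray(self.intensities, dtype=float)
        if y.ndim != 1 or y.size != len(self.grid):
            raise ValueError("intensities must be 1-D and match the grid length")
        if not np.all(np.isfinite(y)):
            raise ValueError("intensities must be finite")
        object.__setattr__(self, "intensities", y)


@dataclass(frozen=True)
class CurveSeries:
    """A stack of curves over perturbation values t (row j = curve at t_j)."""

    grid: CurveGrid
    t_values: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        t = np.atleast_1d(np.asarray(self.t_values, dtype=float))
        y = np.asarray(self.intensities, dtype=float)
        if y.ndim != 2:
            raise ValueError("intensity block must be 2-D (rows = curves)")
        if y.shape != (t.size, len(self.grid)):
            raise ValueError(
                f"intensity block {y.shape} does not match "
                f"(m={t.size}, n={len(self.grid)})"
            )
        if not np.all(np.isfinite(y)):
            raise ValueError("intensities must be finite")
        object.__setattr__(self, "t_values", t)
        object.__setattr__(self, "intensities", y)

    @property
    def m(self) -> int:
        return self.t_values.size

    @property
    def n(self) -> int:
        return len(self.grid)

    def curve(self, j: int) -> Curve:
        """Extract row ``j`` as a standalone :class:`Curve`."""
        return Curve(self.grid, self.intensities[j])


@dataclass(frozen=True)
class CorrelationMaps:
    """Paired synchronous (symmetric-structured) and asynchronous maps."""

    synchronous: np.ndarray
    asynchronous: np.ndarray
    kind: MapKind
    m_used: int | None = None

    def __post_init__(self) -> None:
        phi = np.asarray(self.synchronous, dtype=float)
        psi = np.asarray(self.asynchronous, dtype=float)
        if phi.shape != psi.shape or phi.ndim != 2 or phi.shape[0] != phi.shape[1]:
            raise ValueError("maps must be square and share a shape")
        object.__setattr__(self, "synchronous", phi)
        object.__setattr__(self, "asynchronous", psi)


@dataclass(frozen=True)
class PhaseAngleMap:
    """Quadrant-adjusted phase angles, confined to (-pi/4, 3*pi/4]."""

    theta: np.ndarray
    epsilon_used: float
    branch_adjusted_count: int = 0


def build_dynamic_matrix(
    series: CurveSeries, remove_common_offset: bool = False
) -> CurveSeries:
    """Prepare a series for correlation analysis.

    With ``remove_common_offset`` the single scalar offset shared by all
    curves is subtracted from every entry; the offset is estimated as the
    global minimum of the intensity block (documented choice — the
    methodology requires removal but prescribes no estimator).
    """
    if not remove_common_offset:
        return series
    offset = float(series.intensities.min())
    return CurveSeries(series.grid, series.t_values, series.intensities - offset)


def noda_matrix(m: int) -> np.ndarray:
    """Discrete Hilbert-Noda transform matrix: 0 on the diagonal,
    ``1 / (pi * (j - i))`` off it.  Antisymmetric by construction."""
    if m < 2:
        raise ValueError("noda_matrix requires m >= 2")
    idx = np.arange(m)
    diff = idx[np.newaxis, :] - idx[:, np.newaxis]
    with np.errstate(divide="ignore"):
        n = np.where(diff == 0, 0.0, 1.0 / (np.pi * diff))
    return n


def _check_conformable(y1: CurveSeries, y2: CurveSeries) -> None:
    if y1.grid != y2.grid:
        raise ValueError("series do not share a grid")
    if y1.m != y2.m:
        raise ValueError("series do not share the number of curves")
    if y1.m < 2:
        raise ValueError("series maps require at least two curves (m >= 2)")


def _series_kind(y1: CurveSeries, y2: CurveSeries) -> MapKind:
    same = y1 is y2 or np.array_equal(y1.intensities, y2.intensities)
    return "conventional" if same else "hybrid-series"


def synchronous_map(y1: CurveSeries, y2: CurveSeries) -> np.ndarray:
    """Synchronous map ``(1/(m-1)) Y1^T Y2`` — the variance-covariance
    block between intensity variations at pairs of grid positions."""
    _check_conformable(y1, y2)
    return y1.intensities.T @ y2.intensities / (y1.m - 1)


def asynchronous_map(y1: CurveSeries, y2: CurveSeries) -> np.ndarray:
    """Asynchronous map ``(1/(m-1)) Y1^T N Y2`` with N the Hilbert-Noda
    matrix; captures disproportionate (out-of-phase) intensity changes."""
    _check_conformable(y1, y2)
    n = noda_matrix(y1.m)
    return y1.intensities.T @ n @ y2.intensities / (y1.m - 1)


def correlation_maps(y1: CurveSeries, y2: CurveSeries | None = None) -> CorrelationMaps:
    """Both series maps bundled with provenance.

    ``correlation_maps(y)`` gives the conventional (single-series) maps;
    two distinct series give hybrid maps for which the usual symmetry
    relations need not hold.
    """
    if y2 is None:
        y2 = y1
    return CorrelationMaps(
        synchronous=synchronous_map(y1, y2),
        asynchronous=asynchronous_map(y1, y2),
        kind=_series_kind(y1, y2),
        m_used=y1.m,
    )


def two_trace_maps(s_curve: Curve, m_curve: Curve) -> CorrelationMaps:
    """Correlation maps from exactly two curves.

    ``Phi[j, k] = (s_j s_k + m_j m_k) / 2`` (symmetric) and
    ``Psi[j, k] = (s_j m_k - m_j s_k) / 2`` (antisymmetric).  Psi vanishes
    identically iff the two curves are linearly dependent, which is the
    property the two-trace losses minimize.
    """
    if s_curve.grid != m_curve.grid:
        raise ValueError("curves do not share a grid")
    s = s_curve.intensities
    m = m_curve.intensities
    phi = 0.5 * (np.outer(s, s) + np.outer(m, m))
    psi = 0.5 * (np.outer(s, m) - np.outer(m, s))
    return CorrelationMaps(synchronous=phi, asynchronous=psi, kind="two-trace")


def phase_angle_map(maps: CorrelationMaps, epsilon: float = 1e-10) -> PhaseAngleMap:
    """Phase angles ``arctan(Psi / Phi)`` with a sign-matched regularizer.

    The denominator is ``Phi + sign(Phi) * epsilon`` (with ``+epsilon``
    where ``Phi == 0``), so a 0/0 entry resolves to angle 0.  Raw angles in
    ``(-pi/2, -pi/4]`` are shifted by ``+pi``, confining the result to
    ``(-pi/4, 3*pi/4]``.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    phi = maps.synchronous
    psi = maps.asynchronous
    denom = phi + np.where(phi >= 0, epsilon, -epsilon)
    raw = np.arctan(psi / denom)
    adjust = raw <= -np.pi / 4
    theta = np.where(adjust, raw + np.pi, raw)
    return PhaseAngleMap(
        theta=theta,
        epsilon_used=epsilon,
        branch_adjusted_count=int(adjust.sum()),
    )


def export_map(values: np.ndarray, grid: CurveGrid, path) -> None:
    """Write a square map as CSV labelled by grid values on both axes,
    at 17 significant digits."""
    values = np.asarray(values, dtype=float)
    n = len(grid)
    if values.shape != (n, n):
        raise ValueError("map shape does not match the grid")
    fmt = "%.17g"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("x," + ",".join(fmt % v for v in grid.x_values) + "\n")
        for xj, row in zip(grid.x_values, values):
            fh.write(fmt % xj + "," + ",".join(fmt % v for v in row) + "\n")
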