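"""Loss functions built on 2D correlation structure.

Besides the conventional residual sum of squares (RSS), every loss here is
invariant under multiplication of the measured data by a positive scalar,
so a fit driven by one of them is undisturbed by a uniform multiplicative
systematic error.  Families:

============== ===============================================================
``RSS``          pointwise residual sum of squares (baseline, not invariant)
``SES_SERIES``   ln(SRSS + eps) + ln(ARSS + eps) from hybrid series maps
``ASYNC_2T2D``   upper-triangle sum of squared two-trace asynchronous entries
``ASYNC_2T2D_FAST`` closed form of the full-matrix two-trace asynchronous sum,
                 O(N); equals exactly 2x ``ASYNC_2T2D``
``PHASE_2T2D``   upper-triangle sum of squared two-trace phase angles
``PHASE_SERIES`` upper-triangle sum of squared phase-angle differences between
                 the conventional maps of the two series
``NEG_NCC``      negated normalized cross-correlation
``NEG_ZNCC``     negated zero-mean normalized cross-correlation
============== ===============================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corr2d import (
    Curve,
    CurveSeries,
    CorrelationMaps,
    correlation_maps,
    phase_angle_map,
    two_trace_maps,
)

__all__ = [
    "FAMILIES",
    "SERIES_FAMILIES",
    "LossSpec",
    "LossValue",
    "rss",
    "srss",
    "arss",
    "ses_series",
    "async_2t2d",
    "async_2t2d_fast",
    "phase_2t2d",
    "phase_series_ses",
    "ncc",
    "zncc",
    "evaluate",
]

FAMILIES = (
    "RSS",
    "SES_SERIES",
    "ASYNC_2T2D",
    "ASYNC_2T2D_FAST",
    "PHASE_2T2D",
    "PHASE_SERIES",
    "NEG_NCC",
    "NEG_ZNCC",
)

#: families that consume whole series (fitted jointly over all t)
SERIES_FAMILIES = ("SES_SERIES", "PHASE_SERIES")


@dataclass(frozen=True)
class LossSpec:
    """Configuration of a loss evaluation.

    ``p`` must be a positive even integer (only ``p = 2`` is exercised by
    the test suite); ``epsilon`` regularizes logarithms and phase-angle
    denominators; the preprocessing flags are opt-in and default off.
    """

    family: str = "RSS"
    p: int = 2
    epsilon: float = 1e-10
    remove_common_offset: bool = False
    mean_center: bool = False
    exp_transform: bool = False
    strict_zncc: bool = False

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown loss family {self.family!r}")
        if self.p < 2 or self.p % 2 != 0:
            raise ValueError("exponent p must be a positive even integer")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass(frozen=True)
class LossValue:
    value: float
    components: tuple[float, float] | None = None  # (SRSS, ARSS) for SES_SERIES

    def __float__(self) -> float:
        return self.value


def _triu_sum_pow(a: np.ndarray, p: int) -> float:
    # upper triangle including the diagonal; diagonal terms vanish for all
    # symmetry/antisymmetry residuals so including it is harmless
    return float(np.sum(np.triu(a) ** p))


def _as_array(obj: Curve | CurveSeries) -> np.ndarray:
    return obj.intensities


def rss(measured: Curve | CurveSeries, simulated: Curve | CurveSeries) -> LossValue:
    """Conventional residual sum of squares over all points (and curves)."""
    a, b = _as_array(measured), _as_array(simulated)
    if a.shape != b.shape:
        raise ValueError("shape mismatch between measured and simulated data")
    return LossValue(float(np.sum((a - b) ** 2)))


def srss(maps: CorrelationMaps, p: int = 2) -> LossValue:
    """Synchronous residual sum: upper-triangle sum of
    ``[Phi(j,k) - Phi(k,j)]**p`` — symmetry violations of a hybrid map."""
    phi = maps.synchronous
    return LossValue(_triu_sum_pow(phi - phi.T, p))


def arss(maps: CorrelationMaps, p: int = 2) -> LossValue:
    """Asynchronous residual sum: upper-triangle sum of
    ``[Psi(j,k) + Psi(k,j)]**p`` — antisymmetry violations."""
    psi = maps.asynchronous
    return LossValue(_triu_sum_pow(psi + psi.T, p))


def ses_series(
    y1: CurveSeries, y2: CurveSeries, spec: LossSpec | None = None
) -> LossValue:
    """Series loss ``ln(SRSS + eps) + ln(ARSS + eps)`` from the hybrid maps
    of the two series.  Bounded below by ``2 ln(eps)`` when both residual
    sums vanish (the two series then differ by at most a scalar factor)."""
    spec = spec or LossSpec(family="SES_SERIES")
    maps = correlation_maps(y1, y2)
    s = srss(maps, spec.p).value
    a = arss(maps, spec.p).value
    eps = spec.epsilon
    return LossValue(float(np.log(s + eps) + np.log(a + eps)), components=(s, a))


def async_2t2d(s_curve: Curve, m_curve: Curve, p: int = 2) -> LossValue:
    """Upper-triangle sum of ``Psi**p`` of the two-trace maps; zero iff the
    curves are proportional."""
    if p % 2 != 0:
        raise ValueError("odd exponents cancel antisymmetric terms; p must be even")
    maps = two_trace_maps(s_curve, m_curve)
    return LossValue(_triu_sum_pow(maps.asynchronous, p))


def async_2t2d_fast(s_curve: Curve, m_curve: Curve) -> LossValue:
    """O(N) closed form of the full-matrix two-trace asynchronous sum:

        0.5 * [ (sum s^2)(sum m^2) - (sum s*m)^2 ]

    Exactly twice :func:`async_2t2d` (the full matrix double-counts the
    strict upper triangle; the diagonal is zero)."""
    if s_curve.grid != m_curve.grid:
        raise ValueError("curves do not share a grid")
    s = s_curve.intensities
    m = m_curve.intensities
    val = 0.5 * (np.dot(s, s) * np.dot(m, m) - np.dot(s, m) ** 2)
    return LossValue(float(val))


def phase_2t2d(
    s_curve: Curve, m_curve: Curve, spec: LossSpec | None = None
) -> LossValue:
    """Upper-triangle sum of squared two-trace phase angles."""
    spec = spec or LossSpec(family="PHASE_2T2D")
    maps = two_trace_maps(s_curve, m_curve)
    theta = phase_angle_map(maps, spec.epsilon).theta
    return LossValue(_triu_sum_pow(theta, spec.p))


def phase_series_ses(
    y1: CurveSeries, y2: CurveSeries, spec: LossSpec | None = None
) -> LossValue:
    """Upper-triangle sum of squared differences between the phase-angle
    maps of the conventional (single-series) maps of ``y1`` and ``y2``.
    Insensitive to scalar rescaling of either series, since scaling leaves
    phase angles unchanged."""
    spec = spec or LossSpec(family="PHASE_SERIES")
    th1 = phase_angle_map(correlation_maps(y1), spec.epsilon).theta
    th2 = phase_angle_map(correlation_maps(y2), spec.epsilon).theta
    return LossValue(_triu_sum_pow(th1 - th2, spec.p))


def ncc(s_curve: Curve, m_curve: Curve) -> LossValue:
    """Normalized cross-correlation; 1 iff ``m = C*s`` with ``C > 0``.
    Use the negation as a loss."""
    s = s_curve.intensities
    m = m_curve.intensities
    ss, mm = np.dot(s, s), np.dot(m, m)
    if ss == 0.0 or mm == 0.0:
        raise ValueError("NCC undefined for an all-zero curve")
    return LossValue(float(np.dot(s, m) / np.sqrt(ss * mm)))


def zncc(s_curve: Curve, m_curve: Curve, strict: bool = False) -> LossValue:
    """Zero-mean normalized cross-correlation; 1 iff ``m = C*s + O`` with
    ``C > 0``.  Population standard deviations (divisor l) paired with a
    matching 1/l prefactor keep the value in [-1, 1]; ``strict`` switches
    the prefactor to 1/(l+1) as sometimes printed, sacrificing boundedness.
    """
    s = s_curve.intensities
    m = m_curve.intensities
    l = s.size
    sd_s = s.std()
    sd_m = m.std()
    if sd_s == 0.0 or sd_m == 0.0:
        raise ValueError("ZNCC undefined for a constant curve")
    prefactor = 1.0 / (l + 1) if strict else 1.0 / l
    val = prefactor * np.sum((m - m.mean()) * (s - s.mean())) / (sd_m * sd_s)
    return LossValue(float(val))


def _preprocess_curve(c: Curve, spec: LossSpec) -> Curve:
    y = c.intensities
    if spec.exp_transform:
        y = np.exp(y)
    if spec.mean_center:
        y = y - y.mean()
    return Curve(c.grid, y, c.role) if y is not c.intensities else c


def _preprocess_series(s: CurveSeries, spec: LossSpec) -> CurveSeries:
    y = s.intensities
    if spec.exp_transform:
        y = np.exp(y)
    if spec.remove_common_offset:
        y = y - y.min()
    if spec.mean_center:
        y = y - y.mean(axis=0, keepdims=True)
    return CurveSeries(s.grid, s.t_values, y) if y is not s.intensities else s


def evaluate(
    spec: LossSpec,
    measured: Curve | CurveSeries,
    simulated: Curve | CurveSeries,
) -> LossValue:
    """Dispatch to the configured loss family, applying the preprocessing
    flags first.  Correlation families are returned in loss orientation
    (NCC/ZNCC negated), so lower is always better."""
    if spec.family in SERIES_FAMILIES:
        if not isinstance(measured, CurveSeries) or not isinstance(
            simulated, CurveSeries
        ):
            raise TypeError(f"{spec.family} requires CurveSeries inputs")
        y1 = _preprocess_series(measured, spec)
        y2 = _preprocess_series(simulated, spec)
        if spec.family == "SES_SERIES":
            return ses_series(y1, y2, spec)
        return phase_series_ses(y1, y2, spec)

    if isinstance(measured, CurveSeries) or isinstance(simulated, CurveSeries):
        if spec.family == "RSS":
            return rss(
                _preprocess_series(measured, spec), _preprocess_series(simulated, spec)
            )
        raise TypeError(f"{spec.family} operates on single curves")

    s = _preprocess_curve(measured, spec)
    m = _preprocess_curve(simulated, spec)
    if spec.family == "RSS":
        return rss(s, m)
    if spec.family == "ASYNC_2T2D":
        return async_2t2d(s, m, spec.p)
    if spec.family == "ASYNC_2T2D_FAST":
        return async_2t2d_fast(s, m)
    if spec.family == "PHASE_2T2D":
        return phase_2t2d(s, m, spec)
    if spec.family == "NEG_NCC":
        return LossValue(-ncc(s, m).value)
    if spec.family == "NEG_ZNCC":
        return LossValue(-zncc(s, m, strict=spec.strict_zncc).value)
    raise ValueError(f"unknown loss family {spec.family!r}")
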