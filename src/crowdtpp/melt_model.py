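"""Sigmoid melting-curve model, nonlinear fitting, and stringency QC.

Thermal proteome profiling (TPP) measures, per protein, the fraction that
remains soluble after heating aliquots of a lysate to a gradient of
temperatures. After normalizing reporter intensities to the lowest
(reference) temperature, the resulting fold-change curve is modelled with a
three-parameter sigmoid

    f(T) = (1 - p) / (1 + exp(b - a/T)) + p

with temperature T in degrees Celsius, a shape parameter ``a`` (> 0, units
of °C), a dimensionless offset ``b`` (> 0), and a post-transition plateau
``p`` in [0, 1) — the asymptotic soluble fraction remaining at high
temperature, reflecting incomplete aggregation.

The melting temperature is the point where half the protein is still
soluble.  Setting f(Tm) = 1/2 gives the closed form

    Tm = a / (b + ln(1 - 2p)),

defined whenever p < 1/2 and b + ln(1 - 2p) > 0.  The slope reported for a
fit is the analytic derivative df/dT evaluated at Tm,

    df/dT |_Tm = -(1/2) (1/2 - p) a / ((1 - p) Tm^2),

which is negative for any a > 0 (melting curves always descend).
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import expit

log = logging.getLogger(__name__)

__all__ = [
    "MeltModelError",
    "UndefinedMeltingPointError",
    "NormalizationError",
    "MeltParams",
    "MeltFit",
    "FitOptions",
    "QCCriteria",
    "DEFAULT_FIT_OPTIONS",
    "DEFAULT_QC",
    "melt_eval",
    "melt_derivative",
    "melting_point",
    "melt_slope",
    "normalize_to_reference",
    "fit_melt_curve",
    "passes_qc",
    "fit_condition",
    "FIT_COLUMNS",
]


class MeltModelError(ValueError):
    """Invalid melting-model parameters or evaluation domain."""


class UndefinedMeltingPointError(MeltModelError):
    """The melting curve never reaches a soluble fraction of one half."""


class NormalizationError(MeltModelError):
    """Reference-temperature normalization is impossible for this protein."""

    def __init__(self, reason: str):
        super().__init__(f"normalization failed: {reason}")
        self.reason = reason


@dataclasses.dataclass(frozen=True)
class MeltParams:
    """Parameters (a, b, plateau) of the three-parameter melting sigmoid."""

    a: float
    b: float
    plateau: float

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise MeltModelError(f"shape parameter a must be > 0, got {self.a}")
        if not self.b > 0:
            raise MeltModelError(f"offset b must be > 0, got {self.b}")
        if not 0.0 <= self.plateau < 1.0:
            raise MeltModelError(
                f"plateau must lie in [0, 1), got {self.plateau}"
            )


@dataclasses.dataclass(frozen=True)
class MeltFit:
    """Summary of one fitted melting curve.

    ``tm`` satisfies melt_eval(params, tm) = 1/2 when it is finite; ``slope``
    is df/dT at Tm (≤ 0); ``r2`` is 1 - SSres/SStot on the fold changes.
    ``qc_pass`` records the per-curve stringency checks (convergence, r2,
    slope); the control-plateau check is applied at pairing time by
    :func:`passes_qc`.
    """

    params: MeltParams | None
    tm: float
    slope: float
    r2: float
    converged: bool
    qc_pass: bool
    qc_reasons: tuple[str, ...] = ()

    @property
    def plateau(self) -> float:
        return self.params.plateau if self.params is not None else math.nan


@dataclasses.dataclass(frozen=True)
class FitOptions:
    """Optimizer settings for :func:`fit_melt_curve`.

    ``tol`` is the relative convergence tolerance passed to the trust-region
    least-squares solver; ``min_points`` is the minimum number of finite
    fold changes required to attempt a fit.  When the single deterministic
    start fails to converge, or converges with r2 below ``refit_r2``, a
    fallback multi-start (a logit-linear data-driven estimate plus a 3x3
    grid over b0 and p0) is tried and the best residual kept.
    """

    tol: float = 1e-8
    max_nfev: int = 5000
    min_points: int = 5
    plateau_bound: float = 0.49
    b0: float = 10.0
    fallback_b0: tuple[float, ...] = (5.0, 10.0, 15.0)
    fallback_p0: tuple[float, ...] = (0.0, 0.1, 0.2)
    refit_r2: float = 0.8


@dataclasses.dataclass(frozen=True)
class QCCriteria:
    """'Highest stringency' quality thresholds for melting-curve pairs.

    Both fits need r2 ≥ ``r2_min`` and a slope at Tm of at most
    ``slope_max`` (i.e. at least as steep); the control curve's plateau must
    stay below ``plateau_max``.
    """

    r2_min: float = 0.8
    plateau_max: float = 0.3
    slope_max: float = -0.06


DEFAULT_FIT_OPTIONS = FitOptions()
DEFAULT_QC = QCCriteria()


# ---------------------------------------------------------------------------
# model evaluation


def melt_eval(params: MeltParams, temperature):
    """Soluble fraction f(T) of the melting sigmoid at temperature(s) T (°C).

    Strictly decreasing in T for a > 0, with range (plateau, 1).
    """
    t = np.asarray(temperature, dtype=float)
    if np.any(t <= 0):
        raise MeltModelError("temperature must be > 0 °C")
    # 1 / (1 + exp(b - a/T)) written via expit to avoid overflow
    f = (1.0 - params.plateau) * expit(params.a / t - params.b) + params.plateau
    if np.ndim(temperature) == 0:
        return float(f)
    return f


def melt_derivative(params: MeltParams, temperature):
    """Analytic df/dT of the melting sigmoid (per °C); negative for a > 0."""
    t = np.asarray(temperature, dtype=float)
    if np.any(t <= 0):
        raise MeltModelError("temperature must be > 0 °C")
    s = expit(params.a / t - params.b)
    d = -(1.0 - params.plateau) * s * (1.0 - s) * params.a / (t * t)
    if np.ndim(temperature) == 0:
        return float(d)
    return d


def melting_point(params: MeltParams) -> float:
    """Closed-form Tm = a / (b + ln(1 - 2p)); the temperature where f = 1/2."""
    if params.plateau >= 0.5:
        raise UndefinedMeltingPointError(
            "plateau ≥ 0.5: the curve never drops to a soluble fraction of 0.5"
        )
    denom = params.b + math.log1p(-2.0 * params.plateau)
    if denom <= 0:
        raise UndefinedMeltingPointError(
            "b + ln(1 - 2p) ≤ 0: the curve stays above 0.5 for every T > 0"
        )
    return params.a / denom


def melt_slope(params: MeltParams) -> float:
    """df/dT evaluated at the melting point (per °C, always negative)."""
    tm = melting_point(params)
    p = params.plateau
    return -0.5 * (0.5 - p) * params.a / ((1.0 - p) * tm * tm)


# ---------------------------------------------------------------------------
# normalization


def normalize_to_reference(
    intensities: Sequence[float], temperatures: Sequence[float]
) -> np.ndarray:
    """Fold changes FC(T) = I(T) / I(T_min) relative to the lowest temperature.

    The reference channel is the one with the minimum temperature; its fold
    change is exactly 1.  Missing intensities propagate as NaN.  Raises
    :class:`NormalizationError` (reason ``"no_reference"``) when the
    reference intensity is missing or non-positive.
    """
    i = np.asarray(intensities, dtype=float)
    t = np.asarray(temperatures, dtype=float)
    if i.shape != t.shape:
        raise ValueError("intensities and temperatures must have equal length")
    ref = i[int(np.argmin(t))]
    if not np.isfinite(ref) or ref <= 0:
        raise NormalizationError("no_reference")
    return i / ref


# ---------------------------------------------------------------------------
# fitting


def _residuals(theta: np.ndarray, t: np.ndarray, y: np.ndarray) -> np.ndarray:
    a, b, p = theta
    return (1.0 - p) * expit(a / t - b) + p - y


def _logit_linear_start(
    t: np.ndarray, y: np.ndarray, plateau_bound: float
) -> tuple[float, float, float] | None:
    """Closed-form start: regress logit(1 - y') on 1/T for mid-range points.

    With p ≈ 0 the model gives ln(1/y - 1) = b - a/T, linear in 1/T, so a
    weighted two-point line through the transition yields (a, b) directly.
    """
    yy = np.clip(y, 1e-6, 1.0 - 1e-6)
    mask = (yy > 0.05) & (yy < 0.95)
    if mask.sum() < 2:
        return None
    z = np.log(1.0 / yy[mask] - 1.0)
    x = 1.0 / t[mask]
    slope, intercept = np.polyfit(x, z, 1)
    a0, b0 = -slope, intercept
    if not (a0 > 0 and b0 > 0):
        return None
    p0 = float(np.clip(np.min(y) - 0.01, 0.0, min(0.3, plateau_bound)))
    return (a0, b0, p0)


def fit_melt_curve(
    fold_changes: Sequence[float],
    temperatures: Sequence[float],
    options: FitOptions = DEFAULT_FIT_OPTIONS,
    criteria: QCCriteria = DEFAULT_QC,
) -> MeltFit:
    """Bounded least-squares fit of the melting sigmoid to one fold-change curve.

    Deterministic given identical inputs and options.  Curves with fewer
    than ``options.min_points`` finite points, or that defeat the optimizer,
    come back as a non-converged fit with NaN summaries rather than raising,
    so a pipeline over thousands of proteins never aborts mid-way.
    """
    y_all = np.asarray(fold_changes, dtype=float)
    t_all = np.asarray(temperatures, dtype=float)
    if y_all.shape != t_all.shape:
        raise ValueError("fold_changes and temperatures must have equal length")
    mask = np.isfinite(y_all) & np.isfinite(t_all)
    if int(mask.sum()) < options.min_points:
        return MeltFit(
            params=None,
            tm=math.nan,
            slope=math.nan,
            r2=math.nan,
            converged=False,
            qc_pass=False,
            qc_reasons=("too_few_points",),
        )
    t = t_all[mask]
    y = y_all[mask]

    # deterministic start: plateau from the curve floor, Tm from the point
    # nearest FC = 0.5, a tied to b0 so the start's Tm is about tm0
    p0 = float(np.clip(np.min(y) - 0.01, 0.0, min(0.3, options.plateau_bound)))
    tm0 = float(t[int(np.argmin(np.abs(y - 0.5)))])
    if not tm0 > 0:
        tm0 = float(np.median(t))
    b0 = options.b0
    starts: list[tuple[float, float, float]] = [(b0 * tm0, b0, p0)]

    lower = np.array([1e-8, 1e-8, 0.0])
    upper = np.array([1e7, 500.0, options.plateau_bound])

    def run(start: tuple[float, float, float]):
        x0 = np.clip(np.asarray(start, dtype=float), lower, upper)
        return least_squares(
            _residuals,
            x0,
            args=(t, y),
            bounds=(lower, upper),
            xtol=options.tol,
            ftol=options.tol,
            gtol=None,
            max_nfev=options.max_nfev,
        )

    sstot = float(np.sum((y - y.mean()) ** 2))

    def r2_of(res) -> float:
        ssres = float(np.sum(res.fun**2))
        if sstot == 0:
            return math.nan
        return 1.0 - ssres / sstot

    best = run(starts[0])
    if not best.success or r2_of(best) < options.refit_r2:
        fallback = []
        est = _logit_linear_start(t, y, options.plateau_bound)
        if est is not None:
            fallback.append(est)
        fallback += [
            (bg * tm0, bg, pg)
            for bg in options.fallback_b0
            for pg in options.fallback_p0
        ]
        for start in fallback:
            res = run(start)
            if res.success and (
                not best.success or float(np.sum(res.fun**2)) < float(np.sum(best.fun**2))
            ):
                best = res

    a, b, p = (float(v) for v in best.x)
    converged = bool(best.success)
    r2 = r2_of(best)
    try:
        params = MeltParams(a=a, b=b, plateau=p)
    except MeltModelError:
        params = None
    tm = math.nan
    slope = math.nan
    reasons: list[str] = []
    if params is not None:
        try:
            tm = melting_point(params)
            slope = melt_slope(params)
        except UndefinedMeltingPointError:
            reasons.append("no_tm")
    else:
        reasons.append("invalid_params")

    if not converged:
        reasons.append("not_converged")
    if not (r2 >= criteria.r2_min):  # NaN-safe: NaN comparison is False
        reasons.append("r2")
    if not (slope <= criteria.slope_max):
        reasons.append("slope")
    qc_pass = converged and math.isfinite(tm) and not reasons
    return MeltFit(
        params=params,
        tm=tm,
        slope=slope,
        r2=r2,
        converged=converged,
        qc_pass=qc_pass,
        qc_reasons=tuple(reasons),
    )


def passes_qc(
    fit_control: MeltFit,
    fit_treatment: MeltFit,
    criteria: QCCriteria = DEFAULT_QC,
) -> tuple[bool, tuple[str, ...]]:
    """Pairwise stringency check for a (control, treatment) fit pair.

    Passes iff both fits converged with a defined Tm, both r2 ≥ r2_min, the
    control plateau is below plateau_max, and both slopes are at most
    slope_max.  The reasons tuple enumerates every failed criterion:
    ``converged``, ``r2``, ``plateau``, ``slope``.
    """
    reasons: list[str] = []
    if not (
        fit_control.converged
        and fit_treatment.converged
        and math.isfinite(fit_control.tm)
        and math.isfinite(fit_treatment.tm)
    ):
        reasons.append("converged")
    if not (fit_control.r2 >= criteria.r2_min and fit_treatment.r2 >= criteria.r2_min):
        reasons.append("r2")
    if not (fit_control.plateau < criteria.plateau_max):
        reasons.append("plateau")
    if not (
        fit_control.slope <= criteria.slope_max
        and fit_treatment.slope <= criteria.slope_max
    ):
        reasons.append("slope")
    return (not reasons, tuple(reasons))


# ---------------------------------------------------------------------------
# condition-level driver

FIT_COLUMNS = [
    "protein",
    "condition",
    "a",
    "b",
    "plateau",
    "tm",
    "slope",
    "r2",
    "converged",
    "qc_pass",
    "qc_reasons",
]


def fit_condition(
    quant,
    options: FitOptions = DEFAULT_FIT_OPTIONS,
    criteria: QCCriteria = DEFAULT_QC,
) -> pd.DataFrame:
    """Normalize and fit every protein of one condition's quantification.

    ``quant`` is a :class:`crowdtpp.quant_io.ProteomeQuant` (duck-typed:
    needs protein_ids, intensities, temperatures, condition).  Proteins that
    cannot be normalized are retained with NaN parameters and the reason in
    ``qc_reasons`` rather than dropped, so the output always has one row per
    input protein.
    """
    rows = []
    temps = np.asarray(quant.temperatures, dtype=float)
    for idx, protein in enumerate(quant.protein_ids):
        intens = np.asarray(quant.intensities[idx], dtype=float)
        try:
            fc = normalize_to_reference(intens, temps)
        except NormalizationError as err:
            rows.append(
                {
                    "protein": protein,
                    "condition": quant.condition,
                    "a": math.nan,
                    "b": math.nan,
                    "plateau": math.nan,
                    "tm": math.nan,
                    "slope": math.nan,
                    "r2": math.nan,
                    "converged": False,
                    "qc_pass": False,
                    "qc_reasons": err.reason,
                }
            )
            continue
        fit = fit_melt_curve(fc, temps, options=options, criteria=criteria)
        rows.append(
            {
                "protein": protein,
                "condition": quant.condition,
                "a": fit.params.a if fit.params else math.nan,
                "b": fit.params.b if fit.params else math.nan,
                "plateau": fit.plateau,
                "tm": fit.tm,
                "slope": fit.slope,
                "r2": fit.r2,
                "converged": fit.converged,
                "qc_pass": fit.qc_pass,
                "qc_reasons": ";".join(fit.qc_reasons),
            }
        )
    return pd.DataFrame(rows, columns=FIT_COLUMNS)


def fit_from_row(row: pd.Series) -> MeltFit:
    """Rehydrate a MeltFit from one row of a fits table (inverse of fit_condition)."""
    params = None
    if np.isfinite(row["a"]) and np.isfinite(row["b"]) and np.isfinite(row["plateau"]):
        params = MeltParams(a=float(row["a"]), b=float(row["b"]), plateau=float(row["plateau"]))
    reasons = tuple(str(row.get("qc_reasons", "")).split(";")) if row.get("qc_reasons") else ()
    return MeltFit(
        params=params,
        tm=float(row["tm"]),
        slope=float(row["slope"]),
        r2=float(row["r2"]),
        converged=bool(row["converged"]),
        qc_pass=bool(row["qc_pass"]),
        qc_reasons=reasons,
    )
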