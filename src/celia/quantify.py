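"""Endpoint calibration and inverse quantification statistics.

Calibration fits a five-parameter sigmoid to endpoint signal versus
log10(concentration in M),

    f(x) = L + H / (1 + b * exp(-k * (x - x0))),

with L the lower asymptote, L+H the upper asymptote, k the steepness per
decade, x0 the mid-point and b a horizontal-offset parameter (redundant
with x0, b = exp(k*delta); both are kept to match the conventional
parameterisation, and the redundancy is reported as an identifiability
caveat in the fit diagnostics).  The limit of detection is the
concentration whose expected signal equals the blank mean plus three blank
standard deviations.  Unknowns are inverted through the closed-form inverse
of f; panel accuracy is summarised by the symmetric fold difference
max(estimate/truth, truth/estimate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .network import ValidationError

__all__ = [
    "CalibrationModel",
    "QuantResult",
    "PanelEvaluation",
    "FitError",
    "sigmoid_eval",
    "fit_sigmoid",
    "invert_sigmoid",
    "lod",
    "quantify_endpoint",
    "fold_difference",
]


class FitError(RuntimeError):
    """Calibration fit failure (non-convergence or unusable data)."""


@dataclass
class CalibrationModel:
    L: float  # lower asymptote, signal units
    H: float  # span; upper asymptote = L + H
    b: float  # dimensionless horizontal offset
    k: float  # steepness per log10-M decade
    x0: float  # log10 molar concentration at mid-point
    residual_sd: float = 0.0
    lod_molar: float | None = None
    lod_censored: bool = False
    x_min: float | None = None  # lowest calibrated log10 M
    x_max: float | None = None  # highest calibrated log10 M
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.H > 0:
            raise ValidationError("H", "sigmoid span H must be > 0")
        if not self.k > 0:
            raise ValidationError("k", "steepness k must be > 0 for a positive assay")
        if not self.b > 0:
            raise ValidationError("b", "b must be > 0")

    @property
    def invert_eps(self) -> float:
        return max(self.residual_sd, 1e-6 * self.H)

    def to_dict(self) -> dict:
        return {
            "L": self.L,
            "H": self.H,
            "b": self.b,
            "k": self.k,
            "x0": self.x0,
            "residual_sd": self.residual_sd,
            "lod_molar": self.lod_molar,
            "lod_censored": self.lod_censored,
            "x_min": self.x_min,
            "x_max": self.x_max,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        return cls(**{k: d.get(k) for k in
                      ("L", "H", "b", "k", "x0", "residual_sd", "lod_molar",
                       "lod_censored", "x_min", "x_max")})


@dataclass(frozen=True)
class QuantResult:
    estimate_molar: float | None
    flag: str  # ok | below_lod | below_range | above_range
    endpoint_used: float

    def __post_init__(self):
        if self.flag not in ("ok", "below_lod", "below_range", "above_range"):
            raise ValidationError("flag", f"unknown flag {self.flag!r}")


@dataclass(frozen=True)
class PanelEvaluation:
    fold_differences: tuple[float, ...]
    mean_fd: float
    sd_fd: float
    n_censored: int = 0


def sigmoid_eval(m: CalibrationModel, x) -> float | np.ndarray:
    """f(x) = L + H/(1 + b*exp(-k*(x - x0)))."""
    x = np.asarray(x, dtype=float)
    out = m.L + m.H / (1.0 + m.b * np.exp(-m.k * (x - m.x0)))
    return float(out) if out.ndim == 0 else out


def _sigmoid(x, L, H, b, k, x0):
    return L + H / (1.0 + b * np.exp(-k * (x - x0)))


def fit_sigmoid(points: Sequence[tuple[float, float]]) -> CalibrationModel:
    """Nonlinear least squares sigmoid fit (multi-start, deterministic).

    ``points`` are (log10 molar concentration, endpoint signal); replicates
    may share x.  Requires at least 5 distinct x values spanning at least 3
    decades.  Eight deterministic data-driven starts (k in {0.5,1,2,4},
    x0 at the half-range crossing and at the median x, b=1); the best SSE
    wins, ties broken by the smallest k.
    """
    pts = [(float(x), float(y)) for x, y in points]
    if any(not (math.isfinite(x) and math.isfinite(y)) for x, y in pts):
        raise ValidationError("points", "calibration points must be finite")
    xs = np.array([x for x, _ in pts])
    ys = np.array([y for _, y in pts])
    distinct = np.unique(xs)
    if len(distinct) < 5:
        raise FitError(f"need >= 5 distinct concentrations, got {len(distinct)}")
    if distinct.max() - distinct.min() < 3.0:
        raise FitError(
            f"calibration span {distinct.max() - distinct.min():.2f} decades < 3 decades"
        )
    y_lo, y_hi = float(ys.min()), float(ys.max())
    span = max(y_hi - y_lo, 1e-12)
    half = y_lo + 0.5 * span
    # x where the mean response first exceeds half range
    means = np.array([ys[xs == x].mean() for x in distinct])
    above = means >= half
    x_half = float(distinct[int(np.argmax(above))]) if above.any() else float(np.median(distinct))
    starts = []
    for k0 in (0.5, 1.0, 2.0, 4.0):
        for x00 in (x_half, float(np.median(distinct))):
            starts.append((y_lo, span, 1.0, k0, x00))
    lower = [-np.inf, 1e-9 * span, 1e-9, 1e-6, -np.inf]
    upper = [np.inf, np.inf, np.inf, np.inf, np.inf]

    def resid(theta):
        return _sigmoid(xs, *theta) - ys

    best = None
    for theta0 in starts:
        try:
            sol = least_squares(resid, theta0, bounds=(lower, upper), method="trf",
                                xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=5000)
        except Exception:
            continue
        if not sol.success:
            continue
        sse = float(np.sum(sol.fun**2))
        k_val = float(sol.x[3])
        key = (round(sse, 12), k_val)
        if best is None or key < best[0]:
            best = (key, sol)
    if best is None:
        raise FitError("sigmoid fit did not converge from any start")
    sol = best[1]
    L, H, b, k, x0 = (float(v) for v in sol.x)
    # b and x0 are only jointly identified (b*exp(-k(x-x0)) = exp(-k(x-x0'))
    # with x0' = x0 + ln(b)/k); report the canonical b=1 parameterisation
    x0 += math.log(b) / k
    b = 1.0
    dof = max(len(ys) - 5, 1)
    residual_sd = float(np.sqrt(np.sum(sol.fun**2) / dof))
    return CalibrationModel(
        L=L, H=H, b=b, k=k, x0=x0, residual_sd=residual_sd,
        x_min=float(distinct.min()), x_max=float(distinct.max()),
        diagnostics={
            "sse": float(np.sum(sol.fun**2)),
            "n_points": len(ys),
            "n_starts": len(starts),
            "identifiability": "b is redundant with x0 (b = exp(k*delta)); "
                               "only the product parameterisation is identified",
        },
    )


def invert_sigmoid(m: CalibrationModel, y: float) -> float:
    """Closed-form inverse x = x0 - (1/k)*ln((H/(y-L) - 1)/b).

    Only defined on the open band (L+eps, L+H-eps) with
    eps = max(residual_sd, 1e-6*H); outside, raises ValueError with the
    censoring side in the message (use :func:`quantify_endpoint` for flagged
    results).
    """
    eps = m.invert_eps
    if y <= m.L + eps:
        raise ValueError("below_range")
    if y >= m.L + m.H - eps:
        raise ValueError("above_range")
    return m.x0 - (1.0 / m.k) * math.log((m.H / (y - m.L) - 1.0) / m.b)


def lod(m: CalibrationModel, blank_endpoints: Sequence[float]) -> CalibrationModel:
    """Attach the limit of detection: signal = blank mean + 3*blank SD.

    Returns a copy of the model with ``lod_molar`` set.  When the LoD signal
    falls below the invertible band the LoD is censored at the lowest
    calibrated concentration (``lod_censored`` True, meaning "< that
    concentration").  Requires >= 2 blanks (sample SD, n-1 denominator).
    """
    blanks = np.asarray(list(blank_endpoints), dtype=float)
    if blanks.size < 2:
        raise ValidationError("blank_endpoints", "need >= 2 blank measurements")
    y_star = float(blanks.mean() + 3.0 * blanks.std(ddof=1))
    if y_star >= m.L + m.H:
        raise FitError(
            f"blank-derived LoD signal {y_star:.3g} is above the upper asymptote "
            f"{m.L + m.H:.3g} (assay failure)"
        )
    try:
        x = invert_sigmoid(m, y_star)
    except ValueError as err:
        if "below" in str(err):
            if m.x_min is None:
                raise FitError("LoD below band and calibration range unknown") from err
            return replace(m, lod_molar=10.0**m.x_min, lod_censored=True)
        raise FitError(f"LoD signal {y_star:.3g} not invertible: {err}") from err
    value = 10.0**x
    if m.x_min is not None and x < m.x_min:
        return replace(m, lod_molar=10.0**m.x_min, lod_censored=True)
    return replace(m, lod_molar=value, lod_censored=False)


def quantify_endpoint(m: CalibrationModel, y: float) -> QuantResult:
    """Invert one endpoint signal through the calibration, with censoring flags."""
    try:
        x = invert_sigmoid(m, float(y))
    except ValueError as err:
        flag = "below_range" if "below" in str(err) else "above_range"
        return QuantResult(estimate_molar=None, flag=flag, endpoint_used=float(y))
    est = 10.0**x
    if m.lod_molar is not None and est < m.lod_molar:
        return QuantResult(estimate_molar=est, flag="below_lod", endpoint_used=float(y))
    return QuantResult(estimate_molar=est, flag="ok", endpoint_used=float(y))


def fold_difference(estimates: Sequence[tuple[float | None, float]]) -> PanelEvaluation:
    """Symmetric fold difference max(est/true, true/est) per sample.

    Censored or invalid estimates (None or <= 0) are excluded and counted in
    ``n_censored``.  True concentrations must be positive.
    """
    fds = []
    n_censored = 0
    for est, true in estimates:
        if not true > 0:
            raise ValidationError("estimates", f"true concentration must be > 0, got {true}")
        if est is None or not est > 0:
            n_censored += 1
            continue
        r = est / true
        fds.append(max(r, 1.0 / r))
    arr = np.asarray(fds)
    mean_fd = float(arr.mean()) if arr.size else float("nan")
    sd_fd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return PanelEvaluation(
        fold_differences=tuple(fds), mean_fd=mean_fd, sd_fd=sd_fd, n_censored=n_censored
    )
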