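"""Observable extraction from fluorescence traces.

Implements the assay's four observables: the amplification time At (first
threshold crossing of the exponential-channel signal, the isothermal
analogue of a qPCR Cq), the linear-phase gain / saturation / window of the
linear-channel signal, the endpoint signal at a fixed time, and the
endpoint-versus-At ordinary least squares regression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .network import ValidationError

__all__ = [
    "Trace",
    "AtResult",
    "LinearPhaseFit",
    "RegressionResult",
    "amplification_time",
    "linear_phase_fit",
    "endpoint_signal",
    "endpoint_vs_at_regression",
    "observables_table",
]


@dataclass
class Trace:
    """A single-channel fluorescence time series (times in min)."""

    times: np.ndarray
    values: np.ndarray
    channel: str = ""
    well_id: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValidationError("times", "times and values must be 1-D and equally long")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("values", "trace values must be finite")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class AtResult:
    at: float | None  # min; None when never crossed
    threshold_used: float  # signal units
    crossed: bool

    def __post_init__(self):
        if self.crossed != (self.at is not None):
            raise ValidationError("crossed", "crossed must match at being defined")


@dataclass(frozen=True)
class LinearPhaseFit:
    gain: float  # signal units per min
    intercept: float  # signal units
    saturation: float  # signal units
    window: float  # min (censored at t_end when the plateau is not reached)
    r2_fit: float
    censored: bool = False  # True when the trace never plateaus


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r2: float


def _check_times(times: np.ndarray) -> None:
    if np.any(np.diff(times) <= 0):
        raise ValidationError("times", "time axis must be strictly increasing")


def amplification_time(
    tr: Trace,
    threshold: dict | float,
    baseline_correct: bool = False,
) -> AtResult:
    """First crossing time of the trace above a threshold (linear interpolation).

    ``threshold`` is either ``{"absolute": value}`` (signal units, fixed
    across wells as when a common threshold line is drawn over a plate) or
    ``{"fraction_of_max": f}`` with f in (0, 1), relative to this well's
    maximum.  A bare float means absolute.  With ``baseline_correct`` the
    mean of the first three samples is subtracted first (useful when the
    noise model adds per-well baseline offsets).
    """
    if len(tr) < 2:
        raise ValidationError("trace", "need at least 2 points")
    _check_times(tr.times)
    values = tr.values.astype(float)
    if baseline_correct:
        values = values - values[: min(3, len(values))].mean()
    if isinstance(threshold, dict):
        if "absolute" in threshold:
            thr = float(threshold["absolute"])
        elif "fraction_of_max" in threshold:
            f = float(threshold["fraction_of_max"])
            if not 0.0 < f < 1.0:
                raise ValidationError("fraction_of_max", "must be in (0, 1)")
            thr = f * float(values.max())
        else:
            raise ValidationError("threshold", f"unknown threshold spec {threshold!r}")
    else:
        thr = float(threshold)
    if thr <= values[0]:
        raise ValidationError("threshold", f"threshold {thr} not above the initial signal")
    above = values >= thr
    if not above.any():
        return AtResult(at=None, threshold_used=thr, crossed=False)
    i = int(np.argmax(above))
    t0, t1 = tr.times[i - 1], tr.times[i]
    v0, v1 = values[i - 1], values[i]
    at = t0 + (t1 - t0) * (thr - v0) / (v1 - v0)
    return AtResult(at=float(at), threshold_used=thr, crossed=True)


def linear_phase_fit(
    tr: Trace,
    sat_fraction: float = 0.99,
    fit_span: float = 0.8,
) -> LinearPhaseFit:
    """Gain, saturation and linear window of a linear-amplification trace.

    The plateau is the mean of the final 5% of samples when the local slope
    there has fallen below 1% of the peak slope; otherwise the trace is
    still rising and the maximum is reported with the window censored at the
    last time point.  The window is the first time the signal reaches
    ``sat_fraction`` of the saturation (interpolated).  The gain is the
    least-squares slope over the central ``fit_span`` band of the rise
    (samples between the symmetric quantiles of the signal range, e.g.
    10%–90% of saturation for fit_span=0.8), which is robust to an onset
    delay before the ramp.
    """
    if len(tr) < 4:
        raise ValidationError("trace", "need at least 4 points")
    _check_times(tr.times)
    if not 0.0 < fit_span <= 1.0:
        raise ValidationError("fit_span", "must be in (0, 1]")
    t, v = tr.times, tr.values
    slopes = np.gradient(v, t)
    peak_slope = float(np.max(np.abs(slopes)))
    n_tail = max(2, int(np.ceil(0.05 * len(v))))
    tail_slope = float(np.mean(np.abs(slopes[-n_tail:])))
    if peak_slope > 0 and tail_slope < 0.01 * peak_slope:
        saturation = float(np.mean(v[-n_tail:]))
        censored = False
    else:
        saturation = float(np.max(v))
        censored = True
    target = sat_fraction * saturation
    reached = v >= target
    if (not censored) and reached.any():
        i = int(np.argmax(reached))
        if i == 0:
            window = float(t[0])
        else:
            window = float(
                t[i - 1] + (t[i] - t[i - 1]) * (target - v[i - 1]) / (v[i] - v[i - 1])
            )
    else:
        window = float(t[-1])
        censored = True
    base = float(v[0])
    span = saturation - base
    lo = base + 0.5 * (1.0 - fit_span) * span
    hi = base + (1.0 - 0.5 * (1.0 - fit_span)) * span
    mask = (v >= lo) & (v <= hi) & (t <= window)
    if mask.sum() < 4:
        mask = (v >= lo) & (v <= hi)
    if mask.sum() < 4:
        raise ValidationError("trace", "fewer than 4 rising-phase points")
    res = stats.linregress(t[mask], v[mask])
    r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else 0.0
    return LinearPhaseFit(
        gain=max(float(res.slope), 0.0),
        intercept=float(res.intercept),
        saturation=saturation,
        window=window,
        r2_fit=r2,
        censored=censored,
    )


def endpoint_signal(tr: Trace, t_end: float) -> float:
    """Signal at ``t_end``, linearly interpolated between samples."""
    _check_times(tr.times)
    if not (tr.times[0] <= t_end <= tr.times[-1]):
        raise ValidationError(
            "t_end", f"{t_end} outside trace span [{tr.times[0]}, {tr.times[-1]}]"
        )
    return float(np.interp(t_end, tr.times, tr.values))


def endpoint_vs_at_regression(pairs: Sequence[tuple[float, float]]) -> RegressionResult:
    """OLS of endpoint signal on amplification time."""
    pairs = [(float(a), float(e)) for a, e in pairs]
    if len(pairs) < 3:
        raise ValidationError("pairs", "need at least 3 (At, endpoint) pairs")
    at = np.array([a for a, _ in pairs])
    ep = np.array([e for _, e in pairs])
    if np.ptp(at) == 0:
        raise ValidationError("pairs", "all At values are equal (degenerate regression)")
    res = stats.linregress(at, ep)
    return RegressionResult(
        slope=float(res.slope), intercept=float(res.intercept), r2=float(res.rvalue**2)
    )


def observables_table(
    traces: Iterable[Trace],
    at_channel: str = "alpha",
    endpoint_channel: str = "omega",
    at_threshold: dict | float | None = None,
    t_end: float | None = None,
    baseline_correct: bool = True,
) -> pd.DataFrame:
    """Per-well observables from a collection of traces.

    Groups traces by well; extracts At from ``at_channel`` (default
    threshold: 20% of that well's plateau) and gain/saturation/window/
    endpoint from ``endpoint_channel``.  Returns one row per well with
    columns well_id, channel, at_min, gain, saturation, window_min, endpoint.
    """
    at_threshold = at_threshold if at_threshold is not None else {"fraction_of_max": 0.2}
    by_well: dict[str, dict[str, Trace]] = {}
    for tr in traces:
        by_well.setdefault(tr.well_id, {})[tr.channel] = tr
    rows = []
    for well_id, chans in by_well.items():
        row: dict = {"well_id": well_id, "channel": endpoint_channel}
        row["at_min"] = np.nan
        if at_channel in chans:
            try:
                res = amplification_time(chans[at_channel], at_threshold, baseline_correct)
                if res.crossed:
                    row["at_min"] = res.at
            except ValidationError:
                pass
        row.update(gain=np.nan, saturation=np.nan, window_min=np.nan, endpoint=np.nan)
        if endpoint_channel in chans:
            tr = chans[endpoint_channel]
            te = t_end if t_end is not None else float(tr.times[-1])
            row["endpoint"] = endpoint_signal(tr, te)
            try:
                fit = linear_phase_fit(tr)
                row.update(gain=fit.gain, saturation=fit.saturation, window_min=fit.window)
            except ValidationError:
                pass
        rows.append(row)
    return pd.DataFrame(
        rows, columns=["well_id", "channel", "at_min", "gain", "saturation", "window_min", "endpoint"]
    )
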