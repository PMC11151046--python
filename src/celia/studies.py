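"""Headline in-silico studies of the exponential-to-linear circuit family.

Each function reproduces one quantitative behaviour end to end from the
package's own simulations: the tunable linear window, the six-decade
endpoint dynamic range, the endpoint-versus-At correlations of the coupled
and inverter circuits, the gain-constancy check, and the throughput
arithmetic.  These are shared by the analysis drivers, the test suite and
the acceptance script.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .circuits import build_linear_module, coupled_circuit, inverter_circuit
from .network import KineticParams
from .pipeline import plate_endpoints
from .simulate import simulate_ode
from .synthetic import NoiseModel, apply_noise, calibration_series, generate_plate
from .throughput import (
    endpoint_samples_per_day,
    realtime_samples_per_day,
    throughput_improvement,
)
from .traces import (
    amplification_time,
    endpoint_signal,
    endpoint_vs_at_regression,
    linear_phase_fit,
)

__all__ = [
    "default_at_threshold",
    "initiators_for_at_span",
    "linear_window_at_reference",
    "endpoint_dynamic_range",
    "endpoint_at_study",
    "gain_constancy_study",
    "throughput_summary",
]


def default_at_threshold(params: KineticParams, rT_alpha_conc: float = 50.0) -> float:
    """Fixed cross-well At threshold: 20% of the theoretical rT_alpha plateau."""
    plateau = params.s_F * rT_alpha_conc * params.alpha_max / (params.K_r + params.alpha_max)
    return 0.2 * plateau


def initiators_for_at_span(
    params: KineticParams, at_min: float = 10.0, at_max: float = 985.0, n: int = 12
) -> np.ndarray:
    """Initiator (alpha0) grid giving amplification times spanning
    [at_min, at_max]: At = ln(alpha_thr/alpha0)/r_exp in the pre-saturation
    regime, with alpha_thr ~ 2.2 nM at the default threshold."""
    alpha_thr = 2.2
    return alpha_thr * np.exp(-params.r_exp * np.linspace(at_min, at_max, n))


def linear_window_at_reference(
    alpha_to_omega: float = 2.0,
    rT_omega: float = 200.0,
    params: KineticParams | None = None,
) -> float:
    """Linear window (min) of the isolated linear module, pre-activated, at
    the reference 2 nM / 200 nM template setting: time for the omega channel
    to reach 99% of its saturation."""
    p = params or KineticParams()
    net = build_linear_module(alpha_to_omega, rT_omega, p, activated_fraction=1.0)
    ts = simulate_ode(net, 4000.0, 2.0)
    return linear_phase_fit(ts.trace("omega"), sat_fraction=0.99).window


def endpoint_dynamic_range(params: KineticParams | None = None, t_end: float = 1000.0):
    """Noise-free calibration endpoints across the tenfold series (1 fM-1 nM).

    Returns (concentrations_molar, endpoints, n_increasing_decades) where
    n_increasing_decades counts consecutive tenfold steps with strictly
    increasing endpoint.
    """
    p = params or KineticParams()
    samples = calibration_series(replicates=1, include_blank=False)
    plate = generate_plate(samples, t_end=t_end, noise=NoiseModel(0.0, 0.0, 0.0), seed=0, params=p)
    df = plate_endpoints(plate, baseline_correct=False).sort_values("true_molar")
    concs = df["true_molar"].to_numpy()
    eps = df["endpoint"].to_numpy()
    n_increasing = int(np.sum(np.diff(eps) > 0))
    return concs, eps, n_increasing


@dataclass(frozen=True)
class EndpointAtResult:
    at: np.ndarray
    endpoint: np.ndarray
    slope: float
    intercept: float
    r2: float


def endpoint_at_study(
    circuit: str = "coupled",
    n_conditions: int = 12,
    t_end: float = 1000.0,
    params: KineticParams | None = None,
) -> EndpointAtResult:
    """Endpoint-versus-At regression over noise-free conditions spanning
    At ~10-1000 min (modulated through the initiator concentration).

    circuit "coupled": the linear stage follows amplification, endpoint
    negatively correlated with At.  circuit "inverter": constitutive
    production killed by amplification, positive correlation.
    """
    p = params or KineticParams()
    factory = {"coupled": coupled_circuit, "inverter": inverter_circuit}[circuit]
    thr = default_at_threshold(p)
    ats, eps = [], []
    for a0 in initiators_for_at_span(p, n=n_conditions):
        ts = simulate_ode(factory(alpha0=float(a0), params=p), t_end, 2.0)
        res = amplification_time(ts.trace("alpha"), {"absolute": thr})
        ats.append(res.at)
        eps.append(endpoint_signal(ts.trace("omega"), t_end))
    reg = endpoint_vs_at_regression(list(zip(ats, eps)))
    return EndpointAtResult(
        at=np.array(ats), endpoint=np.array(eps),
        slope=reg.slope, intercept=reg.intercept, r2=reg.r2,
    )


def gain_constancy_study(
    n_conditions: int = 8,
    noise: NoiseModel | None = None,
    seed: int = 0,
    replicates: int = 3,
    params: KineticParams | None = None,
):
    """Gain CV across coupled-circuit conditions spanning At ~10-900 min.

    Traces are integrated to reporter saturation (3500 min) so every
    condition exhibits its full linear phase; the noise-free CV isolates the
    estimator (expected ~0) and the noisy CV reflects the optical noise
    model.  Returns (cv_noise_free, cv_noisy, gains_noise_free).
    """
    p = params or KineticParams()
    noise = noise if noise is not None else NoiseModel()
    traces = [
        simulate_ode(coupled_circuit(alpha0=float(a0), params=p), 3500.0, 5.0).trace(
            "omega", well_id=f"W{i:03d}"
        )
        for i, a0 in enumerate(initiators_for_at_span(p, at_max=900.0, n=n_conditions))
    ]
    gains = np.array([linear_phase_fit(tr).gain for tr in traces])
    cv_free = float(gains.std(ddof=1) / gains.mean())
    noisy = []
    for rep in range(replicates):
        for i, tr in enumerate(traces):
            ntr = apply_noise(tr, noise, well_index=rep * 100 + i, seed=seed)
            noisy.append(linear_phase_fit(ntr).gain)
    noisy = np.array(noisy)
    cv_noisy = float(noisy.std(ddof=1) / noisy.mean())
    return cv_free, cv_noisy, gains


def throughput_summary() -> dict[str, float]:
    """Daily sample capacities of real-time vs endpoint readout (96-well
    instrument, 2 h assay occupancy, 2 min endpoint turnover)."""
    return {
        "realtime_samples_per_day": realtime_samples_per_day(96, 2.0),
        "endpoint_samples_per_day": endpoint_samples_per_day(96, 2.0),
        "improvement_factor": throughput_improvement(96, 2.0, 2.0),
    }
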