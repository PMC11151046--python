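"""Deterministic (ODE) and stochastic (Gillespie) integration of reaction networks.

The ODE path is the workhorse: LSODA with tight tolerances, sampled on a
uniform output grid (default cadence 2 min, mimicking a plate reader).  The
stochastic path is an exact-sampling oracle used to validate the mean-field
behaviour of small instances; saturating rate laws are evaluated on
instantaneous concentrations (mean-field hybrid), which is documented as
oracle-only, not small-copy realism.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .network import ReactionNetwork, Reporter, ValidationError

__all__ = ["SolverOptions", "TraceSet", "SimulationError", "simulate_ode", "simulate_ssa"]

AVOGADRO = 6.02214076e23


class SimulationError(RuntimeError):
    """Integration failure; carries the failing time and state when known."""

    def __init__(self, message: str, t: float | None = None, state=None):
        self.t = t
        self.state = state
        super().__init__(message)


@dataclass(frozen=True)
class SolverOptions:
    rel_tol: float = 1e-8
    abs_tol: float = 1e-12  # nM
    max_step: float = math.inf  # min
    method_hint: str = "stiff"  # "stiff" | "nonstiff"

    def __post_init__(self):
        if not (self.rel_tol > 0 and self.abs_tol > 0):
            raise ValidationError("rel_tol", "solver tolerances must be > 0")
        if self.method_hint not in ("stiff", "nonstiff"):
            raise ValidationError("method_hint", f"unknown hint {self.method_hint!r}")


@dataclass
class TraceSet:
    """Time grid (min) with per-species concentrations and per-channel signals."""

    times: np.ndarray
    concentrations: dict[str, np.ndarray]
    channels: dict[str, np.ndarray]
    provenance: dict = field(default_factory=dict)

    def species(self, name: str) -> np.ndarray:
        return self.concentrations[name]

    def channel(self, name: str) -> np.ndarray:
        return self.channels[name]

    def trace(self, channel: str, well_id: str = "well"):
        from .traces import Trace

        return Trace(times=self.times.copy(), values=self.channels[channel].copy(),
                     channel=channel, well_id=well_id)


def network_hash(net: ReactionNetwork) -> str:
    """Stable digest of the network structure, rates and initial state."""
    payload = {
        "species": [(s.name, s.role, net.initial[s.name]) for s in net.species.values()],
        "reactions": [
            (
                rx.name,
                rx.reactants,
                rx.products,
                rx.modifiers,
                (rx.law.form, rx.law.rate_constant, rx.law.half_saturation, rx.law.driver),
            )
            for rx in net.reactions
        ],
        "reporters": [
            (r.channel, r.mode, r.species, r.scale, r.total, r.k_half)
            for r in net.reporters.values()
        ],
    }
    blob = json.dumps(payload, sort_keys=True, default=float).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


class _CompiledNetwork:
    """Index-based representation for fast rate evaluation."""

    def __init__(self, net: ReactionNetwork):
        net.validate()
        self.names = list(net.species)
        self.index = {n: i for i, n in enumerate(self.names)}
        self.y0 = np.array([net.initial[n] for n in self.names], dtype=float)
        self.n_rx = len(net.reactions)
        self.stoich = np.zeros((len(self.names), self.n_rx))
        self.rx_factors: list[list[tuple[int, int]]] = []  # (species index, power)
        self.rx_k = np.zeros(self.n_rx)
        self.rx_sat: list[tuple[int, float] | None] = []  # (driver index, K)
        self.reactant_counts: list[list[tuple[int, int]]] = []  # for SSA propensities
        for j, rx in enumerate(net.reactions):
            for sp, st in rx.reactants:
                self.stoich[self.index[sp], j] -= st
            for sp, st in rx.products:
                self.stoich[self.index[sp], j] += st
            self.rx_k[j] = rx.law.rate_constant
            sat = None
            if rx.law.form == "saturating":
                sat = (self.index[rx.law.driver], rx.law.half_saturation)
            self.rx_sat.append(sat)
            factors: list[tuple[int, int]] = []
            for sp, st in rx.reactants:
                idx = self.index[sp]
                if sat is not None and idx == sat[0]:
                    continue
                factors.append((idx, st))
            for sp in rx.modifiers:
                idx = self.index[sp]
                if sat is not None and idx == sat[0]:
                    continue
                factors.append((idx, 1))
            self.rx_factors.append(factors)
            self.reactant_counts.append([(self.index[sp], st) for sp, st in rx.reactants])
        # per-reaction SSA metadata: (idx, power, falling-factorial?) and order
        self.ssa_factors: list[list[tuple[int, int, bool]]] = []
        self.ssa_order: list[int] = []
        for j in range(self.n_rx):
            consumed = dict(self.reactant_counts[j])
            fs = []
            order = 0
            for idx, power in self.rx_factors[j]:
                fs.append((idx, power, consumed.get(idx, 0) >= power))
                order += power
            self.ssa_factors.append(fs)
            self.ssa_order.append(order)

    def rates(self, y: np.ndarray) -> np.ndarray:
        """Concentration-space reaction rates (nM/min) at state ``y``."""
        v = self.rx_k.copy()
        for j in range(self.n_rx):
            for idx, power in self.rx_factors[j]:
                yi = y[idx]
                v[j] *= yi if power == 1 else yi**power
            sat = self.rx_sat[j]
            if sat is not None:
                d = max(y[sat[0]], 0.0)
                v[j] *= d / (sat[1] + d)
        return v

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        return self.stoich @ self.rates(np.maximum(y, 0.0))


def _channels_from(net: ReactionNetwork, names: list[str], conc: np.ndarray) -> dict[str, np.ndarray]:
    index = {n: i for i, n in enumerate(names)}
    out = {}
    for chan, rep in net.reporters.items():
        x = conc[index[rep.species]]
        if rep.mode == "species":
            out[chan] = rep.scale * x
        else:
            out[chan] = rep.scale * rep.total * x / (rep.k_half + x)
    return out


def simulate_ode(
    net: ReactionNetwork,
    t_end: float,
    dt_out: float = 2.0,
    opts: SolverOptions | None = None,
) -> TraceSet:
    """Integrate the network ODEs and sample on the grid {0, dt_out, ..., t_end}.

    Raises :class:`SimulationError` on integrator failure or non-finite
    state.  Output concentrations are clipped to zero; the clip magnitude is
    bounded by the solver's absolute tolerance (checked).
    """
    if not t_end > 0:
        raise ValidationError("t_end", "must be > 0")
    if not dt_out > 0:
        raise ValidationError("dt_out", "must be > 0")
    opts = opts or SolverOptions()
    comp = _CompiledNetwork(net)
    n_steps = int(round(t_end / dt_out))
    t_eval = np.linspace(0.0, n_steps * dt_out, n_steps + 1)
    if t_eval[-1] > t_end + 1e-12:
        t_eval = np.arange(0.0, t_end + 0.5 * dt_out, dt_out)
    method = "LSODA" if opts.method_hint == "stiff" else "RK45"
    sol = solve_ivp(
        comp.rhs,
        (0.0, float(t_eval[-1])),
        comp.y0,
        method=method,
        t_eval=t_eval,
        rtol=opts.rel_tol,
        atol=opts.abs_tol,
        max_step=opts.max_step,
    )
    if not sol.success:
        t_fail = sol.t[-1] if sol.t.size else 0.0
        raise SimulationError(f"ODE integration failed: {sol.message}", t=t_fail)
    if not np.all(np.isfinite(sol.y)):
        bad = np.argwhere(~np.isfinite(sol.y))
        t_fail = float(sol.t[bad[0][1]])
        raise SimulationError("non-finite state encountered", t=t_fail)
    # negative excursions beyond ~solver accuracy indicate real failure
    clip_floor = -max(opts.abs_tol, opts.rel_tol * float(np.max(np.abs(sol.y))))
    if float(sol.y.min(initial=0.0)) < 100 * clip_floor:
        raise SimulationError(
            f"concentration undershoot {sol.y.min():.3e} nM exceeds solver tolerance"
        )
    y = np.clip(sol.y, 0.0, None)
    conc = {name: y[i] for i, name in enumerate(comp.names)}
    channels = _channels_from(net, comp.names, y)
    prov = {
        "network_hash": network_hash(net),
        "solver": {
            "method": method,
            "rel_tol": opts.rel_tol,
            "abs_tol": opts.abs_tol,
            "dt_out": dt_out,
            "t_end": float(t_eval[-1]),
        },
    }
    return TraceSet(times=sol.t.copy(), concentrations=conc, channels=channels, provenance=prov)


def simulate_ssa(
    net: ReactionNetwork,
    volume: float,
    t_end: float,
    seed: int,
    dt_out: float = 2.0,
) -> TraceSet:
    """Exact stochastic trajectory (Gillespie direct method) at ``volume`` litres.

    Mass-action propensities use falling factorials of copy numbers;
    saturating laws are evaluated on instantaneous concentrations
    (mean-field hybrid) — a validation oracle, not a small-copy model.
    Deterministic given ``seed``.
    """
    if not (volume > 0 and t_end > 0):
        raise ValidationError("volume", "volume and t_end must be > 0")
    comp = _CompiledNetwork(net)
    conv = 1e-9 * AVOGADRO * volume  # copies per nM
    counts = np.rint(comp.y0 * conv).astype(np.int64)
    if counts.max(initial=0) > 1_000_000:
        raise SimulationError(
            "initial copy number exceeds 1e6; use a smaller volume or the ODE solver"
        )
    rng = np.random.default_rng(seed)
    n_steps = int(round(t_end / dt_out))
    grid = np.linspace(0.0, n_steps * dt_out, n_steps + 1)
    rec = np.zeros((len(counts), len(grid)))
    stoich_cols = comp.stoich.T.astype(np.int64)  # reaction -> species delta

    def propensities(n: np.ndarray) -> np.ndarray:
        a = np.empty(comp.n_rx)
        for j in range(comp.n_rx):
            v = comp.rx_k[j]
            for idx, power, falling in comp.ssa_factors[j]:
                ni = n[idx]
                if falling:  # reactant: falling factorial n(n-1)...(n-power+1)
                    for m in range(power):
                        v *= max(ni - m, 0)
                else:  # modifier: plain power
                    v *= float(ni) ** power
            sat = comp.rx_sat[j]
            if sat is not None:
                d = n[sat[0]] / conv
                v *= d / (sat[1] + d)
            # concentration-space constant -> copy-number propensity:
            # k [nM^(1-order) min^-1] * conv^(1-order)
            a[j] = v * conv ** (1 - comp.ssa_order[j])
        return np.maximum(a, 0.0)

    t = 0.0
    gi = 0
    while True:
        a = propensities(counts)
        a0 = float(a.sum())
        if a0 <= 0.0:
            t_next = math.inf
        else:
            t_next = t + rng.exponential(1.0 / a0)
        while gi < len(grid) and grid[gi] <= t_next:
            rec[:, gi] = counts
            gi += 1
        if gi >= len(grid) or t_next > t_end:
            break
        t = t_next
        j = int(np.searchsorted(np.cumsum(a), rng.random() * a0, side="right"))
        j = min(j, comp.n_rx - 1)
        counts = counts + stoich_cols[j]
        if counts.max(initial=0) > 1_000_000:
            raise SimulationError(
                f"copy number overflow at t={t:.1f} min; use a smaller volume or the ODE solver",
                t=t,
            )
    while gi < len(grid):
        rec[:, gi] = counts
        gi += 1

    y = rec / conv
    conc = {name: y[i] for i, name in enumerate(comp.names)}
    channels = _channels_from(net, comp.names, y)
    prov = {
        "network_hash": network_hash(net),
        "solver": {"method": "gillespie-direct", "volume_L": volume, "dt_out": dt_out},
        "seed": int(seed),
    }
    return TraceSet(times=grid, concentrations=conc, channels=channels, provenance=prov)
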