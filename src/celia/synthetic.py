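"""Synthetic plate experiments: circuits + target spikes + optical noise.

Emulates the assay's data-generating process: each well runs the full
endpoint-quantification circuit at its spiked target concentration, is read
on two fluorescence channels every 2 min, and carries plate-reader optical
noise — a per-well multiplicative scale (lognormal, CV ~5%), a per-well
baseline offset, and i.i.d. additive noise per time point.  Noise acts on
the optical channels only, never on the chemistry; kinetic stochasticity is
the job of the Gillespie oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .circuits import quantification_circuit
from .network import KineticParams, ValidationError
from .simulate import SolverOptions, simulate_ode
from .traces import Trace

__all__ = [
    "NoiseModel",
    "Sample",
    "Well",
    "PlateExperiment",
    "random_panel",
    "calibration_series",
    "apply_noise",
    "generate_plate",
    "DEFAULT_PANEL_RANGE",
    "CALIBRATION_DECADES",
]

#: log-uniform spike range of the random panel, mol/L (5 fM – 100 pM)
DEFAULT_PANEL_RANGE = (5e-15, 1e-10)
#: tenfold calibration series, mol/L (1 fM – 1 nM)
CALIBRATION_DECADES = tuple(10.0**e for e in range(-15, -8))


@dataclass(frozen=True)
class NoiseModel:
    """Optical noise of the plate reader (all parameters may be zero)."""

    well_scale_cv: float = 0.05  # lognormal sigma of the per-well scale factor
    additive_sd: float = 0.01  # signal units, i.i.d. per time point
    baseline_offset_sd: float = 0.02  # signal units, per well
    seed: int = 0

    def __post_init__(self):
        for name in ("well_scale_cv", "additive_sd", "baseline_offset_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(name, "noise SDs must be >= 0")

    @property
    def silent(self) -> bool:
        return self.well_scale_cv == 0 and self.additive_sd == 0 and self.baseline_offset_sd == 0


@dataclass(frozen=True)
class Sample:
    sample_id: str
    target: str
    conc_molar: float  # true spiked concentration, mol/L (0 for blanks)
    kind: str = "unknown"  # unknown | standard | blank


@dataclass(frozen=True)
class Well:
    well_id: str
    sample: Sample


@dataclass
class PlateExperiment:
    """Wells x channels x time synthetic dataset with ground truth and seed."""

    wells: list[Well]
    traces: dict[tuple[str, str], Trace]  # (well_id, channel) -> Trace
    seed: int
    config: dict = field(default_factory=dict)

    def trace(self, well_id: str, channel: str) -> Trace:
        return self.traces[(well_id, channel)]

    def channels(self) -> list[str]:
        return sorted({chan for _, chan in self.traces})

    def well_traces(self, well_id: str) -> list[Trace]:
        return [tr for (wid, _), tr in self.traces.items() if wid == well_id]

    def all_traces(self) -> list[Trace]:
        return list(self.traces.values())

    def truth(self) -> dict[str, tuple[str, float]]:
        return {w.well_id: (w.sample.target, w.sample.conc_molar) for w in self.wells}


def random_panel(
    n: int,
    c_min: float,
    c_max: float,
    targets: Sequence[str],
    seed: int,
) -> list[Sample]:
    """n samples, each spiked with every target at a log-uniform concentration.

    Concentrations are drawn independently per (sample, target) from a
    uniform distribution on [log10 c_min, log10 c_max]; deterministic given
    ``seed``.
    """
    if n <= 0:
        raise ValidationError("n", "panel size must be > 0")
    if not (0 < c_min <= c_max):
        raise ValidationError("c_min", "need 0 < c_min <= c_max")
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0x70A1)))
    lo, hi = math.log10(c_min), math.log10(c_max)
    samples = []
    for i in range(n):
        for target in targets:
            conc = 10.0 ** rng.uniform(lo, hi)
            samples.append(Sample(f"S{i:03d}", target, float(conc), kind="unknown"))
    return samples


def calibration_series(
    concentrations_molar: Sequence[float] = CALIBRATION_DECADES,
    replicates: int = 3,
    include_blank: bool = True,
    target: str = "miR",
) -> list[Sample]:
    """Tenfold standard series with replicates, plus no-target blanks."""
    if replicates <= 0:
        raise ValidationError("replicates", "must be > 0")
    samples = []
    for conc in concentrations_molar:
        for r in range(replicates):
            samples.append(Sample(f"std_{conc:.0e}_r{r}", target, float(conc), kind="standard"))
    if include_blank:
        for r in range(replicates):
            samples.append(Sample(f"blank_r{r}", target, 0.0, kind="blank"))
    return samples


def apply_noise(tr: Trace, noise: NoiseModel, well_index: int, seed: int | None = None) -> Trace:
    """Optical noise: value' = scale_w * value + offset_w + eps_t.

    scale_w ~ lognormal(0, well_scale_cv) and offset_w ~ N(0,
    baseline_offset_sd) are drawn once per well; eps_t ~ N(0, additive_sd)
    per time point.  The RNG stream is derived from (seed, well_index), so a
    plate is reproducible under well reordering.
    """
    seed = noise.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), int(well_index))))
    scale = rng.lognormal(0.0, noise.well_scale_cv) if noise.well_scale_cv > 0 else 1.0
    offset = rng.normal(0.0, noise.baseline_offset_sd) if noise.baseline_offset_sd > 0 else 0.0
    eps = (
        rng.normal(0.0, noise.additive_sd, size=len(tr))
        if noise.additive_sd > 0
        else np.zeros(len(tr))
    )
    return Trace(
        times=tr.times.copy(),
        values=scale * tr.values + offset + eps,
        channel=tr.channel,
        well_id=tr.well_id,
    )


def generate_plate(
    samples: Sequence[Sample],
    t_end: float = 1000.0,
    dt_out: float = 2.0,
    noise: NoiseModel | None = None,
    seed: int = 0,
    params: KineticParams | None = None,
    circuit_factory: Callable | None = None,
    solver: SolverOptions | None = None,
) -> PlateExperiment:
    """Simulate one well per sample and apply optical noise.

    ``circuit_factory(conc_molar, target_name, params)`` builds the per-well
    network; the default is the full endpoint-quantification circuit
    (converter -> exponential switch -> linear amplifier).  Channel noise
    streams are keyed by (seed, well_index, channel_index); identical
    (samples, seed, config) give an identical plate.
    """
    noise = noise if noise is not None else NoiseModel()
    params = params or KineticParams()
    factory = circuit_factory or (
        lambda conc, target, p: quantification_circuit(conc, target_name=target, params=p)
    )
    wells: list[Well] = []
    traces: dict[tuple[str, str], Trace] = {}
    # cache simulations: wells sharing (target, conc) differ only in noise
    sim_cache: dict[tuple[str, float], dict[str, Trace]] = {}
    for idx, sample in enumerate(samples):
        well_id = f"W{idx:03d}"
        wells.append(Well(well_id, sample))
        key = (sample.target, sample.conc_molar)
        if key not in sim_cache:
            net = factory(sample.conc_molar, sample.target, params)
            ts = simulate_ode(net, t_end=t_end, dt_out=dt_out, opts=solver)
            sim_cache[key] = {
                chan: Trace(ts.times, ts.channels[chan], channel=chan, well_id="")
                for chan in ts.channels
            }
        for ci, (chan, clean) in enumerate(sorted(sim_cache[key].items())):
            tr = Trace(clean.times.copy(), clean.values.copy(), channel=chan, well_id=well_id)
            if not noise.silent:
                tr = apply_noise(tr, noise, well_index=idx * 16 + ci, seed=seed)
            traces[(well_id, chan)] = tr
    config = {
        "t_end": t_end,
        "dt_out": dt_out,
        "noise": {
            "well_scale_cv": noise.well_scale_cv,
            "additive_sd": noise.additive_sd,
            "baseline_offset_sd": noise.baseline_offset_sd,
        },
        "params": params.to_dict(),
    }
    return PlateExperiment(wells=wells, traces=traces, seed=int(seed), config=config)
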