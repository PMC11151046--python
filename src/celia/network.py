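"""Reaction-network primitives for PEN-toolbox amplification circuits.

The circuits modelled here are DNA/enzyme reaction networks built from the
polymerase–exonuclease–nickase (PEN) toolbox: short signal strands (alpha,
beta, omega) are produced, deactivated and degraded under the control of DNA
templates.  Enzymes are not explicit species; each template's
polymerisation/nicking cycle is lumped into a single phenomenological
production term, first-order in the template and (where relevant) saturating
in the strand that loads it.

Concentration unit is nM throughout, time unit is minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ValidationError",
    "Species",
    "TemplateSpec",
    "RateLaw",
    "Reaction",
    "Reporter",
    "ReactionNetwork",
    "KineticParams",
]

SPECIES_ROLES = ("signal-strand", "template-state", "reporter-state", "inert")
TEMPLATE_KINDS = (
    "aT_alpha",
    "pT_alpha",
    "rT_alpha",
    "alpha_to_omega",
    "rT_omega",
    "beta_to_omega",
    "alpha_k_beta",
    "miR_to_alpha",
)
ACTIVATION_MODES = ("irreversible", "reversible", "constitutive", "n/a")

#: template kinds whose activation mode is fixed by the template chemistry:
#: alpha_to_omega is nicked by a type-IIS enzyme (cut outside the recognition
#: site, activation irreversible); beta_to_omega by a type-IIP enzyme (cut at
#: the site, input can unbind, activation reversible).
_FIXED_ACTIVATION = {"alpha_to_omega": "irreversible", "beta_to_omega": "reversible"}


class ValidationError(ValueError):
    """Raised when a network ingredient violates its contract.

    Carries the offending field name in ``field`` so callers (and the CLI)
    can point the user at the bad key.
    """

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


def _require_nonneg(name: str, value: float) -> float:
    value = float(value)
    if not value >= 0.0:  # also catches NaN
        raise ValidationError(name, f"must be >= 0, got {value!r}")
    return value


def _require_pos(name: str, value: float) -> float:
    value = float(value)
    if not value > 0.0:
        raise ValidationError(name, f"must be > 0, got {value!r}")
    return value


@dataclass(frozen=True)
class Species:
    """A named chemical species with a structural role."""

    name: str
    role: str = "signal-strand"

    def __post_init__(self):
        if self.role not in SPECIES_ROLES:
            raise ValidationError("role", f"unknown role {self.role!r} for {self.name!r}")


@dataclass(frozen=True)
class TemplateSpec:
    """A DNA template, its total concentration and its activation chemistry.

    ``state_species`` lists the network species that partition the template
    pool (e.g. inactive/active forms, intact/reacted reporter); their
    concentrations must sum to ``total_conc`` at all times.
    """

    kind: str
    total_conc: float
    activation_mode: str = "n/a"
    state_species: tuple[str, ...] = ()

    def __post_init__(self):
        if self.kind not in TEMPLATE_KINDS:
            raise ValidationError("kind", f"unknown template kind {self.kind!r}")
        if self.activation_mode not in ACTIVATION_MODES:
            raise ValidationError("activation_mode", f"unknown mode {self.activation_mode!r}")
        fixed = _FIXED_ACTIVATION.get(self.kind)
        if fixed is not None and self.activation_mode != fixed:
            raise ValidationError(
                "activation_mode",
                f"{self.kind} must be {fixed} (template nicking chemistry), got {self.activation_mode!r}",
            )
        _require_nonneg(f"{self.kind}.total_conc", self.total_conc)


@dataclass(frozen=True)
class RateLaw:
    """Phenomenological rate law: plain mass action or saturating.

    mass-action:  rate = k * prod(reactants^stoich) * prod(modifiers)
    saturating:   rate = k * [same product, driver excluded] * D/(K + D)
                  where D is the concentration of ``driver``.

    ``rate_constant`` is per-min for unimolecular terms and per-nM-per-min
    for bimolecular ones.
    """

    form: str
    rate_constant: float
    half_saturation: float | None = None
    driver: str | None = None

    def __post_init__(self):
        if self.form not in ("mass-action", "saturating"):
            raise ValidationError("form", f"unknown rate-law form {self.form!r}")
        _require_pos("rate_constant", self.rate_constant)
        if self.form == "saturating":
            if self.half_saturation is None or self.driver is None:
                raise ValidationError(
                    "half_saturation", "saturating law needs half_saturation and driver"
                )
            _require_pos("half_saturation", self.half_saturation)
        elif self.half_saturation is not None or self.driver is not None:
            raise ValidationError("half_saturation", "only valid for the saturating form")


@dataclass(frozen=True)
class Reaction:
    """One reaction channel.

    Modifiers are catalytic: they enter the rate but are not consumed.
    """

    name: str
    reactants: tuple[tuple[str, int], ...] = ()
    products: tuple[tuple[str, int], ...] = ()
    modifiers: tuple[str, ...] = ()
    law: RateLaw = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.law is None:
            raise ValidationError("law", f"reaction {self.name!r} has no rate law")
        for sp, st in (*self.reactants, *self.products):
            if not (isinstance(st, int) and st > 0):
                raise ValidationError(
                    "stoichiometry", f"{self.name}: {sp} stoichiometry must be a positive int"
                )
        reactant_names = {sp for sp, _ in self.reactants}
        overlap = reactant_names.intersection(self.modifiers)
        if overlap:
            raise ValidationError(
                "modifiers",
                f"{self.name}: {sorted(overlap)} appear as both reactant and modifier",
            )
        if self.law.form == "saturating":
            names = reactant_names.union(self.modifiers)
            if self.law.driver not in names:
                raise ValidationError(
                    "driver", f"{self.name}: saturating driver {self.law.driver!r} not in reaction"
                )

    def species_names(self) -> set[str]:
        return (
            {sp for sp, _ in self.reactants}
            | {sp for sp, _ in self.products}
            | set(self.modifiers)
        )


@dataclass(frozen=True)
class Reporter:
    """Maps a fluorescence channel to the network state.

    mode "species": signal = scale * [species]  (species is the reacted
    reporter; irreversible, signal is non-decreasing).

    mode "equilibrium": signal = scale * total * D/(k_half + D) with D the
    concentration of ``species`` (fast reversible hybridisation of the probe
    to the signal strand; the probe pool is not an explicit species).
    """

    channel: str
    mode: str
    species: str
    scale: float = 1.0
    total: float | None = None
    k_half: float | None = None

    def __post_init__(self):
        if self.mode not in ("species", "equilibrium"):
            raise ValidationError("mode", f"unknown reporter mode {self.mode!r}")
        _require_pos(f"reporter[{self.channel}].scale", self.scale)
        if self.mode == "equilibrium":
            if self.total is None or self.k_half is None:
                raise ValidationError(
                    "total", f"reporter[{self.channel}]: equilibrium mode needs total and k_half"
                )
            _require_nonneg(f"reporter[{self.channel}].total", self.total)
            _require_pos(f"reporter[{self.channel}].k_half", self.k_half)

    @property
    def irreversible(self) -> bool:
        return self.mode == "species"


@dataclass
class ReactionNetwork:
    """Species, initial concentrations (nM), reactions and reporter channels."""

    species: dict[str, Species] = field(default_factory=dict)
    initial: dict[str, float] = field(default_factory=dict)
    reactions: list[Reaction] = field(default_factory=list)
    reporters: dict[str, Reporter] = field(default_factory=dict)
    templates: list[TemplateSpec] = field(default_factory=list)

    def add_species(self, sp: Species, conc: float = 0.0) -> None:
        conc = _require_nonneg(f"initial[{sp.name}]", conc)
        if sp.name in self.species:
            if self.species[sp.name].role != sp.role:
                raise ValidationError(
                    "role",
                    f"species {sp.name!r} redefined with role {sp.role!r} "
                    f"(was {self.species[sp.name].role!r})",
                )
            self.initial[sp.name] += conc
        else:
            self.species[sp.name] = sp
            self.initial[sp.name] = conc

    def add_reaction(self, rx: Reaction) -> None:
        missing = rx.species_names() - self.species.keys()
        if missing:
            raise ValidationError(
                "reactants", f"reaction {rx.name!r} references unknown species {sorted(missing)}"
            )
        self.reactions.append(rx)

    def add_reporter(self, rep: Reporter) -> None:
        if rep.channel in self.reporters:
            raise ValidationError("channel", f"duplicate reporter channel {rep.channel!r}")
        if rep.species not in self.species:
            raise ValidationError(
                "species", f"reporter {rep.channel!r} references unknown species {rep.species!r}"
            )
        self.reporters[rep.channel] = rep

    def validate(self) -> None:
        """Check structural invariants; raises ValidationError on failure."""
        for rx in self.reactions:
            missing = rx.species_names() - self.species.keys()
            if missing:
                raise ValidationError(
                    "reactions", f"{rx.name!r} references unknown species {sorted(missing)}"
                )
        for name, conc in self.initial.items():
            _require_nonneg(f"initial[{name}]", conc)
        for tmpl in self.templates:
            if not tmpl.state_species:
                continue
            tot = sum(self.initial.get(s, 0.0) for s in tmpl.state_species)
            if abs(tot - tmpl.total_conc) > 1e-9 * max(1.0, tmpl.total_conc):
                raise ValidationError(
                    "templates",
                    f"{tmpl.kind}: state species sum to {tot} nM, expected {tmpl.total_conc} nM",
                )

    @property
    def species_names(self) -> list[str]:
        return list(self.species)

    def copy(self) -> "ReactionNetwork":
        return ReactionNetwork(
            species=dict(self.species),
            initial=dict(self.initial),
            reactions=list(self.reactions),
            reporters=dict(self.reporters),
            templates=list(self.templates),
        )


@dataclass(frozen=True)
class KineticParams:
    """Lumped kinetic constants of the amplification circuits.

    These are phenomenological calibration constants, not measured enzyme
    kinetics; defaults are chosen so that the shipped circuits reproduce the
    characteristic behaviours of the assay family (amplification times of
    ~50–900 min over a 10 fM–10 nM input span, a >1000 min linear window at
    the 2 nM / 200 nM template setting, endpoint dynamic range of six
    decades).  All are overridable from configuration.

    Units: first-order constants min^-1; bimolecular constants nM^-1 min^-1;
    half-saturation constants nM.
    """

    r_exp: float = 0.017  #: net exponential growth rate of alpha, min^-1
    alpha_max: float = 100.0  #: logistic ceiling of alpha (template/enzyme saturation proxy), nM
    K_exp: float = 10.0  #: half-saturation of aT_alpha (and alpha_k_beta) occupancy by alpha, nM
    k_deact: float = 0.01  #: pseudotemplate-mediated strand deactivation, nM^-1 min^-1
    k_deg: float = 0.01  #: exonuclease degradation of unprotected strands, min^-1
    k_act: float = 0.002  #: alpha loading rate onto alpha_to_omega, nM^-1 min^-1
    k_lin: float = 0.05  #: omega throughput per activated linear template, min^-1
    k_rep: float = 0.1  #: omega + rT_omega reporting rate, nM^-1 min^-1
    K_r: float = 10.0  #: rT_alpha quasi-equilibrium half-saturation, nM
    K_beta: float = 5.0  #: beta_to_omega occupancy half-constant, nM
    k_kill: float = 0.2  #: pT_beta production per alpha_k_beta at saturating alpha, min^-1
    leak_kill: float = 1e-3  #: alpha-independent pT_beta production per alpha_k_beta, min^-1
    k_degP: float = 0.02  #: degradation of pT_beta, min^-1
    k_conv: float = 1e-3  #: alpha production per miR_to_alpha at saturating miRNA, min^-1
    K_conv: float = 1.0  #: converter half-saturation, nM
    s_F: float = 1.0  #: fluorescence scale, signal units per nM of reacted reporter

    def __post_init__(self):
        for name in self.__dataclass_fields__:
            _require_pos(name, getattr(self, name))

    def replace(self, **kw) -> "KineticParams":
        return replace(self, **kw)

    def to_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}
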