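"""Builders for the exponential, linear, inverter and converter sub-circuits.

Each builder returns a :class:`~celia.network.ReactionNetwork` for one
sub-circuit; :func:`compose` merges them into a single simulatable network
(shared species pooled, reporter channels merged).

Circuit inventory
-----------------
exponential  aT_alpha autocatalysis of the signal strand alpha, pT_alpha
             thresholding (alpha -> alpha_i), exonuclease degradation, and a
             reversible rT_alpha reporter on channel "alpha".
linear       alpha_to_omega is irreversibly activated by alpha and then
             constitutively produces omega, which irreversibly reacts with
             the rT_omega reporter (channel "omega"; plateau = s_F*[rT_omega]).
inverter     beta_to_omega constitutively produces omega under reversible
             occupancy by beta; the killer template alpha_k_beta converts
             amplified alpha into the degradable pseudotemplate pT_beta,
             which deactivates beta (beta -> beta_i) and shuts omega
             production down.
converter    miR_to_alpha transduces an input microRNA (recycled, not
             consumed) into a constitutive alpha source.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

from .network import (
    KineticParams,
    RateLaw,
    Reaction,
    ReactionNetwork,
    Reporter,
    Species,
    TemplateSpec,
    ValidationError,
    _require_nonneg,
)

__all__ = [
    "build_exponential_module",
    "build_linear_module",
    "build_inverter_module",
    "build_converter",
    "compose",
    "coupled_circuit",
    "inverter_circuit",
    "quantification_circuit",
    "MOLAR_TO_NM",
]

MOLAR_TO_NM = 1e9  # mol/L -> nM


def build_exponential_module(
    aT_alpha_conc: float,
    pT_alpha_conc: float,
    rT_alpha_conc: float,
    alpha0: float,
    params: KineticParams | None = None,
) -> ReactionNetwork:
    """Exponential amplification switch (aT_alpha / pT_alpha / rT_alpha).

    alpha self-replicates on the dual-repeat template aT_alpha with net
    low-copy growth rate ``r_exp`` and a logistic ceiling ``alpha_max``
    (the production constant is r_exp + k_deg, so production minus
    first-order degradation gives exactly r_exp at low alpha and zero
    pT_alpha).  pT_alpha deactivates alpha to alpha_i at ``k_deact`` per nM
    of pseudotemplate.  The rT_alpha probe is modelled as fast reversible
    hybridisation: channel "alpha" = s_F*rT_tot*alpha/(K_r+alpha).
    """
    p = params or KineticParams()
    aT = _require_nonneg("aT_alpha_conc", aT_alpha_conc)
    pT = _require_nonneg("pT_alpha_conc", pT_alpha_conc)
    rT = _require_nonneg("rT_alpha_conc", rT_alpha_conc)
    a0 = _require_nonneg("alpha0", alpha0)

    net = ReactionNetwork()
    net.add_species(Species("alpha", "signal-strand"), a0)
    net.add_species(Species("alpha_i", "inert"), 0.0)
    net.add_species(Species("aT_alpha", "template-state"), aT)
    net.add_species(Species("pT_alpha", "template-state"), pT)

    if aT > 0:
        k_grow = p.r_exp + p.k_deg
        net.add_reaction(
            Reaction(
                "alpha_autocatalysis",
                reactants=(("alpha", 1),),
                products=(("alpha", 2),),
                law=RateLaw("mass-action", k_grow),
            )
        )
        # logistic crowding term: 2 alpha -> alpha at k_grow/alpha_max gives
        # net growth k_grow*alpha*(1 - alpha/alpha_max)
        net.add_reaction(
            Reaction(
                "alpha_crowding",
                reactants=(("alpha", 2),),
                products=(("alpha", 1),),
                law=RateLaw("mass-action", k_grow / p.alpha_max),
            )
        )
    net.add_reaction(
        Reaction(
            "alpha_deactivation",
            reactants=(("alpha", 1),),
            products=(("alpha_i", 1),),
            modifiers=("pT_alpha",),
            law=RateLaw("mass-action", p.k_deact),
        )
    )
    net.add_reaction(
        Reaction(
            "alpha_degradation",
            reactants=(("alpha", 1),),
            law=RateLaw("mass-action", p.k_deg),
        )
    )
    net.add_reporter(
        Reporter("alpha", "equilibrium", "alpha", scale=p.s_F, total=rT, k_half=p.K_r)
    )
    net.templates += [
        TemplateSpec("aT_alpha", aT, "n/a", ("aT_alpha",)),
        TemplateSpec("pT_alpha", pT, "n/a", ("pT_alpha",)),
        TemplateSpec("rT_alpha", rT, "n/a", ()),
    ]
    net.validate()
    return net


def build_linear_module(
    alpha_to_omega_conc: float,
    rT_omega_conc: float,
    params: KineticParams | None = None,
    activated_fraction: float = 0.0,
) -> ReactionNetwork:
    """Tunable linear amplifier (alpha_to_omega / rT_omega).

    Activation of alpha_to_omega by alpha is irreversible (type-IIS nicking);
    the activated template produces omega at ``k_lin`` per nM; omega reacts
    irreversibly with the intact rT_omega probe (channel "omega").  Gain is
    s_F*k_lin*[alpha_to_omega], saturation s_F*[rT_omega], and the linear
    window their ratio [rT_omega]/(k_lin*[alpha_to_omega]).

    ``activated_fraction`` pre-activates that fraction of the template
    (e.g. 1.0 emulates pre-loading with a saturating excess of alpha).
    """
    p = params or KineticParams()
    ato = _require_nonneg("alpha_to_omega_conc", alpha_to_omega_conc)
    rT = _require_nonneg("rT_omega_conc", rT_omega_conc)
    if not 0.0 <= activated_fraction <= 1.0:
        raise ValidationError("activated_fraction", "must be in [0, 1]")

    net = ReactionNetwork()
    net.add_species(Species("alpha", "signal-strand"), 0.0)
    net.add_species(Species("alpha_to_omega_inactive", "template-state"), ato * (1 - activated_fraction))
    net.add_species(Species("alpha_to_omega_active", "template-state"), ato * activated_fraction)
    net.add_species(Species("omega", "signal-strand"), 0.0)
    net.add_species(Species("rT_omega_intact", "reporter-state"), rT)
    net.add_species(Species("rT_omega_reacted", "reporter-state"), 0.0)

    # alpha acts catalytically: hybridisation uses only the 9 3' bases of
    # alpha, so loading does not sequester it from the exponential module.
    net.add_reaction(
        Reaction(
            "alpha_to_omega_activation",
            reactants=(("alpha_to_omega_inactive", 1),),
            products=(("alpha_to_omega_active", 1),),
            modifiers=("alpha",),
            law=RateLaw("mass-action", p.k_act),
        )
    )
    net.add_reaction(
        Reaction(
            "omega_production",
            products=(("omega", 1),),
            modifiers=("alpha_to_omega_active",),
            law=RateLaw("mass-action", p.k_lin),
        )
    )
    net.add_reaction(
        Reaction(
            "omega_reporting",
            reactants=(("omega", 1), ("rT_omega_intact", 1)),
            products=(("rT_omega_reacted", 1),),
            law=RateLaw("mass-action", p.k_rep),
        )
    )
    net.add_reporter(Reporter("omega", "species", "rT_omega_reacted", scale=p.s_F))
    net.templates += [
        TemplateSpec(
            "alpha_to_omega", ato, "irreversible",
            ("alpha_to_omega_inactive", "alpha_to_omega_active"),
        ),
        TemplateSpec("rT_omega", rT, "n/a", ("rT_omega_intact", "rT_omega_reacted")),
    ]
    net.validate()
    return net


def build_inverter_module(
    beta_to_omega_conc: float,
    beta0: float,
    alpha_k_beta_conc: float,
    rT_omega_conc: float,
    params: KineticParams | None = None,
) -> ReactionNetwork:
    """Inverter (NOT-gate) branch: constitutive omega production killed by alpha.

    beta occupies beta_to_omega reversibly (quasi-equilibrium fraction
    beta/(K_beta+beta)); omega is produced at k_lin per nM of template times
    that occupancy.  alpha_k_beta produces the degradable pseudotemplate
    pT_beta at k_kill*[akb]*alpha/(K_exp+alpha) plus an alpha-independent
    leak; pT_beta deactivates beta to beta_i and is itself degraded at
    k_degP.  The 3'-C-extended beta released by nicking is deactivated the
    same way, so a single beta pool suffices.
    """
    p = params or KineticParams()
    bto = _require_nonneg("beta_to_omega_conc", beta_to_omega_conc)
    b0 = _require_nonneg("beta0", beta0)
    akb = _require_nonneg("alpha_k_beta_conc", alpha_k_beta_conc)
    rT = _require_nonneg("rT_omega_conc", rT_omega_conc)

    net = ReactionNetwork()
    net.add_species(Species("alpha", "signal-strand"), 0.0)
    net.add_species(Species("beta", "signal-strand"), b0)
    net.add_species(Species("beta_i", "inert"), 0.0)
    net.add_species(Species("pT_beta", "template-state"), 0.0)
    net.add_species(Species("beta_to_omega", "template-state"), bto)
    net.add_species(Species("alpha_k_beta", "template-state"), akb)
    net.add_species(Species("omega", "signal-strand"), 0.0)
    net.add_species(Species("rT_omega_intact", "reporter-state"), rT)
    net.add_species(Species("rT_omega_reacted", "reporter-state"), 0.0)

    net.add_reaction(
        Reaction(
            "omega_constitutive_production",
            products=(("omega", 1),),
            modifiers=("beta_to_omega", "beta"),
            law=RateLaw("saturating", p.k_lin, half_saturation=p.K_beta, driver="beta"),
        )
    )
    net.add_reaction(
        Reaction(
            "pT_beta_production",
            products=(("pT_beta", 1),),
            modifiers=("alpha_k_beta", "alpha"),
            law=RateLaw("saturating", p.k_kill, half_saturation=p.K_exp, driver="alpha"),
        )
    )
    net.add_reaction(
        Reaction(
            "pT_beta_leak",
            products=(("pT_beta", 1),),
            modifiers=("alpha_k_beta",),
            law=RateLaw("mass-action", p.leak_kill),
        )
    )
    net.add_reaction(
        Reaction(
            "beta_deactivation",
            reactants=(("beta", 1),),
            products=(("beta_i", 1),),
            modifiers=("pT_beta",),
            law=RateLaw("mass-action", p.k_deact),
        )
    )
    net.add_reaction(
        Reaction(
            "pT_beta_degradation",
            reactants=(("pT_beta", 1),),
            law=RateLaw("mass-action", p.k_degP),
        )
    )
    net.add_reaction(
        Reaction(
            "omega_reporting",
            reactants=(("omega", 1), ("rT_omega_intact", 1)),
            products=(("rT_omega_reacted", 1),),
            law=RateLaw("mass-action", p.k_rep),
        )
    )
    net.add_reporter(Reporter("omega", "species", "rT_omega_reacted", scale=p.s_F))
    net.templates += [
        TemplateSpec("beta_to_omega", bto, "reversible", ("beta_to_omega",)),
        TemplateSpec("alpha_k_beta", akb, "n/a", ("alpha_k_beta",)),
        TemplateSpec("rT_omega", rT, "n/a", ("rT_omega_intact", "rT_omega_reacted")),
    ]
    net.validate()
    return net


def build_converter(
    miR_to_alpha_conc: float,
    miR_conc_molar: float,
    params: KineticParams | None = None,
    target_name: str = "miR",
) -> ReactionNetwork:
    """microRNA converter: a constitutive alpha source gated by the target.

    The miRNA is a catalytic modifier (recycled, never consumed); the alpha
    source rate is k_conv*[miR_to_alpha]*miR/(K_conv+miR).  ``miR_conc_molar``
    is in mol/L; internally converted to nM.  ``target_name`` only labels the
    species: converters for different miRNAs (e.g. let-7a, miR-203a) are
    interchangeable at this abstraction.
    """
    p = params or KineticParams()
    conv = _require_nonneg("miR_to_alpha_conc", miR_to_alpha_conc)
    miR_nM = _require_nonneg("miR_conc", miR_conc_molar) * MOLAR_TO_NM

    net = ReactionNetwork()
    net.add_species(Species("alpha", "signal-strand"), 0.0)
    net.add_species(Species(target_name, "signal-strand"), miR_nM)
    net.add_species(Species("miR_to_alpha", "template-state"), conv)
    net.add_reaction(
        Reaction(
            "alpha_conversion",
            products=(("alpha", 1),),
            modifiers=("miR_to_alpha", target_name),
            law=RateLaw("saturating", p.k_conv, half_saturation=p.K_conv, driver=target_name),
        )
    )
    net.templates.append(TemplateSpec("miR_to_alpha", conv, "n/a", ("miR_to_alpha",)))
    net.validate()
    return net


def compose(modules: Sequence[ReactionNetwork]) -> ReactionNetwork:
    """Merge sub-circuits into one network.

    Shared species must agree in role; their initial concentrations are
    summed.  Reporter channels are merged; a duplicate channel name is an
    error unless the definitions are identical (the shared "omega" reporter
    of the linear and inverter branches).
    """
    if not modules:
        raise ValidationError("modules", "compose needs at least one module")
    out = ReactionNetwork()
    for mod in modules:
        for name, sp in mod.species.items():
            out.add_species(sp, mod.initial[name])
        for rx in mod.reactions:
            out.add_reaction(rx)
        for chan, rep in mod.reporters.items():
            if chan in out.reporters:
                if out.reporters[chan] != rep:
                    raise ValidationError("channel", f"duplicate reporter channel {chan!r}")
            else:
                out.add_reporter(rep)
        out.templates += mod.templates
    out.validate()
    return out


# ---------------------------------------------------------------------------
# canonical assembled circuits


def coupled_circuit(
    alpha0: float = 0.0,
    pT_alpha_conc: float = 0.0,
    aT_alpha_conc: float = 20.0,
    rT_alpha_conc: float = 50.0,
    alpha_to_omega_conc: float = 2.0,
    rT_omega_conc: float = 200.0,
    params: KineticParams | None = None,
) -> ReactionNetwork:
    """Exponential switch feeding the linear amplifier (two channels).

    Defaults use the 2 nM alpha_to_omega / 200 nM rT_omega setting, whose
    linear window exceeds the 1000 min assay horizon.
    """
    return compose(
        [
            build_exponential_module(aT_alpha_conc, pT_alpha_conc, rT_alpha_conc, alpha0, params),
            build_linear_module(alpha_to_omega_conc, rT_omega_conc, params),
        ]
    )


def inverter_circuit(
    alpha0: float = 0.0,
    pT_alpha_conc: float = 0.0,
    aT_alpha_conc: float = 20.0,
    rT_alpha_conc: float = 50.0,
    beta_to_omega_conc: float = 10.0,
    beta0: float = 2.0,
    alpha_k_beta_conc: float = 1.0,
    rT_omega_conc: float = 200.0,
    params: KineticParams | None = None,
) -> ReactionNetwork:
    """Exponential switch wired to the inverter branch (NOT gate)."""
    return compose(
        [
            build_exponential_module(aT_alpha_conc, pT_alpha_conc, rT_alpha_conc, alpha0, params),
            build_inverter_module(
                beta_to_omega_conc, beta0, alpha_k_beta_conc, rT_omega_conc, params
            ),
        ]
    )


def quantification_circuit(
    miR_conc_molar: float,
    miR_to_alpha_conc: float = 10.0,
    target_name: str = "miR",
    alpha0: float = 0.0,
    pT_alpha_conc: float = 0.0,
    aT_alpha_conc: float = 20.0,
    rT_alpha_conc: float = 50.0,
    alpha_to_omega_conc: float = 2.0,
    rT_omega_conc: float = 200.0,
    params: KineticParams | None = None,
) -> ReactionNetwork:
    """Full endpoint-quantification circuit: converter -> exponential -> linear."""
    return compose(
        [
            build_converter(miR_to_alpha_conc, miR_conc_molar, params, target_name=target_name),
            build_exponential_module(aT_alpha_conc, pT_alpha_conc, rT_alpha_conc, alpha0, params),
            build_linear_module(alpha_to_omega_conc, rT_omega_conc, params),
        ]
    )
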