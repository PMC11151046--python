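# Methods

## The circuit family

The package models a family of isothermal DNA/enzyme amplification circuits
built from the PEN toolbox (polymerase, nicking endonuclease, exonuclease),
in which short signal strands are produced and destroyed under the control
of DNA templates:

- **Exponential switch.** The signal strand α replicates autocatalytically on
  the dual-repeat amplification template aTα; the pseudotemplate pTα
  deactivates α (α → α_i) by directing a short polymerase extension; the
  exonuclease degrades unprotected strands. The reversible reporter probe
  rTα reads α out on the green channel. The time at which this channel
  crosses a threshold — the amplification time At, the isothermal analogue
  of a qPCR Cq — is linear in −log10 of the initial trigger concentration.
- **Linear amplifier.** The template αtoω is irreversibly activated by α
  (its type-IIS nicking chemistry releases the product without letting the
  input unbind) and then produces ω at a constant rate; ω reacts
  irreversibly with the rTω probe (red channel). Gain, saturation and
  linear window are independently tunable: gain = s_F·k_lin·[αtoω],
  saturation = s_F·[rTω], window = [rTω]/(k_lin·[αtoω]).
- **Inverter (NOT gate).** βtoω constitutively produces ω under reversible
  occupancy by β; the killer template αkβ converts amplified α into the
  degradable pseudotemplate pTβ, which deactivates β and halts production.
  Early amplification ⇒ low plateau: the endpoint–At correlation flips sign.
- **Converter.** miRtoα transduces an input microRNA (recycled, not
  consumed) into a constitutive α source, so the whole chain maps target
  concentration → At → endpoint signal, enabling quantification from a
  single endpoint read.

## Kinetic model

Enzymes are not explicit species. Each template's polymerisation/nicking
cycle is lumped into one phenomenological production term, first-order in
the template and saturating (Michaelis form) in the strand that loads it —
the standard desk-scale reduction for PEN circuits. Networks are built from
two rate-law forms only (mass action, saturating); the logistic ceiling of
the exponential switch is expressed as the mass-action pair α → 2α and
2α → α so that the whole network stays within those forms (which the
Gillespie oracle can sample).

Net α growth at low copy and zero pTα is exactly `r_exp` (the production
constant is `r_exp + k_deg`, so production minus first-order degradation
leaves `r_exp`); this makes the closed forms used by the tests exact in the
pre-saturation regime: doubling the trigger advances At by ln2/r_exp, a
tenfold change by ln10/r_exp.

Reporter semantics follow the template chemistry: rTω reporting is
irreversible and consumes ω (extension along the probe), so the red plateau
equals s_F·[rTω]; rTα reporting is fast reversible hybridisation, modelled
as a quasi-equilibrium channel signal s_F·[rTα]·α/(K_r+α) without explicit
probe species (only the threshold crossing matters for At). βtoω occupancy
by β is likewise a quasi-equilibrium fraction β/(K_beta+β) — reversibility
is the design point of that template, and one constant captures it. pTα is
treated as protected (non-degradable) over the run, pTβ as degradable
(first order, `k_degP`). The 3′-C-extended β variant released by nicking is
not a separate species: it is deactivated by the same pseudotemplate, so a
single β pool is equivalent at this abstraction. α loading onto αtoω uses
only the 9 3′-terminal bases, so activation is modelled as catalytic in α
(no sequestration from the autocatalytic template).

### Parameters

All constants are phenomenological calibration targets, not measured enzyme
kinetics; they live in `KineticParams` and are overridable from YAML.
Units: min⁻¹ (first order), nM⁻¹ min⁻¹ (bimolecular), nM (half-saturation).

| parameter | default | role / why this value |
|---|---|---|
| r_exp | 0.017 | net α growth; ln10/r_exp ≈ 135 min per decade, giving At spans of ~10–1000 min over six decades of input |
| alpha_max | 100 | logistic ceiling of α (template/enzyme saturation proxy) |
| K_exp | 10 | α half-saturation of aTα and αkβ occupancy |
| k_deact | 0.01 | pseudotemplate-mediated deactivation; a few nM of pTα outruns r_exp |
| k_deg | 0.01 | exonuclease degradation of unprotected strands |
| k_act | 0.002 | α loading on αtoω; calibrated (once, before any test was frozen) so the activation midpoint α ≈ r_exp/k_act ≈ 2 nM coincides with the At threshold crossing — the linear stage then kicks in quasi-instantaneously (ω < 1% of saturation before At). Larger values start the ramp long before the threshold |
| k_lin | 0.05 | ω throughput per active template; at the 2 nM/200 nM reference setting the window is 200/(0.05·2) = 2000 min > the 1000 min horizon |
| k_rep | 0.1 | ω + rTω reporting |
| K_r | 10 | rTα quasi-equilibrium half-saturation |
| K_beta | 5 | βtoω occupancy half-constant |
| k_kill / leak_kill | 0.2 / 1e-3 | pTβ production per αkβ at saturating α / α-independent leak (the leak causes the gradual late-time sag of the inverter ramp) |
| k_degP | 0.02 | pTβ degradation |
| k_conv / K_conv | 1e-3 / 1 | converter source per template at saturating target / half-constant |
| s_F | 1 | signal units per nM of reacted reporter; arbitrary fluorescence scaling belongs to the noise model, not the kinetics |

Default template concentrations: aTα 20 nM, rTα 50 nM, αtoω 2 nM, rTω
200 nM (the reference coupled setting), miRtoα 10 nM, βtoω 10 nM, β 2 nM,
αkβ 1 nM, pTα 0 in the quantification circuit (net growth must stay at
r_exp for the six-decade At span).

## Numerics

Deterministic integration uses LSODA (stiff-capable; the networks mix fast
reporting with slow production) at rtol 1e-8 / atol 1e-12 nM, sampled on a
uniform output grid (default 2 min, a plate-reader cadence). Output
concentrations are clipped to zero; an undershoot beyond ~100× the solver
tolerance raises instead of being hidden. Template-state and reporter
totals are conserved to 1e-6 relative at every output time (tested).

The Gillespie direct-method sampler is a validation oracle for small
instances: mass-action propensities use falling factorials of copy numbers;
saturating laws are evaluated on instantaneous concentrations (mean-field
hybrid) — documented as oracle-only, not small-copy realism. Volumes must
be large enough that initial copy numbers are not distorted by integer
rounding (≥ ~1e-13 L at nM concentrations); tests use 200 seeded runs and
compare ensemble means to the ODE (or to closed forms) within 3 SE.

Observable extraction is linear-interpolation everywhere (At crossing,
endpoint); no smoothing is applied by default. The default At threshold is
20% of the well's own plateau; a fixed absolute threshold (20% of the
theoretical rTα plateau) is used when comparing wells, as when a common
threshold line is drawn across a plate. Baseline correction (subtracting
the mean of the first three samples) is off by default and enabled by the
pipeline, whose noise model adds per-well offsets. The linear-phase gain is
fitted over the central 80% band of the signal range (10–90% of
saturation), which is robust to the onset delay before the ramp; the
plateau requires the local tail slope to fall below 1% of the peak slope,
otherwise the window is censored at the end of the trace.

Gain constancy is measured on traces integrated to reporter saturation
(3500 min) rather than truncated at the 1000-min endpoint: noise-free, the
conditions are exact time-translates of one another, so the fitted gain CV
is ~0 by construction, and any CV measured with noise on is attributable to
the optical model. On 1000-min traces, late-At wells only exhibit the
accelerating start of the ramp and a slope fit there measures the onset
transient, not the gain.

The sigmoid calibration f(x) = L + H/(1 + b·e^(−k(x−x0))) (x = log10 of
molar concentration) is fitted by bounded nonlinear least squares from 8
deterministic data-driven starts (k ∈ {0.5, 1, 2, 4} × two x0 heuristics,
b = 1); the best SSE wins, ties broken by the smallest k. b and x0 are only
jointly identified (b·e^(−k(x−x0)) = e^(−k(x−x0−ln b/k))), so fits are
reported in the canonical b = 1 parameterisation and the redundancy is
noted in the fit diagnostics. Blanks are excluded from the fit (log of zero
is undefined) and used only for the LoD = blank mean + 3·SD mapped through
the inverse calibration; an LoD signal below the invertible band is
censored at the lowest calibrated concentration and reported as "< 1 fM".
Estimates outside the invertible band are flagged below_range/above_range;
in-range estimates below the LoD are flagged below_lod and excluded from
fold-difference means (counted separately). The fold difference is the
symmetric max(ĉ/c, c/ĉ) — the only form under which a mean ≥ 1 with the
reported spread is interpretable.

## Synthetic data

The generator emulates the assay's data-generating process: one well per
(sample, target), each running the converter → exponential → linear circuit
at the spiked concentration, read every 2 min for 1000 min on two channels.
Optical noise is applied to channels only (never to the chemistry):
value′ = scale_w·value + offset_w + ε_t with scale_w lognormal(0, 0.05) and
offset_w N(0, 0.02) per well and ε_t N(0, 0.01) per time point. Per-well
RNG streams are derived from (seed, well index), so plates are reproducible
under well reordering. Defaults: calibration standards 1 fM–1 nM tenfold
in triplicate plus triplicate blanks; random panels of 54 samples × 2
targets, log-uniform on 5 fM–100 pM.

What the generator does **not** emulate: pipetting-volume error, carry-over
contamination, cross-target converter interference, enzyme batch effects or
activity decay over the run, and temperature excursions. Passing tests
therefore demonstrate the internal consistency of the circuit model and the
statistics pipeline under the stated noise model, not the performance of
the wet assay; the experimentally reported detection limits and fold
differences depend on unreleased raw data and are used here only as
property-level bounds (LoD in the femtomolar range, ≥ 90% of in-range
panel samples within 3-fold, gain CV bracketing 5%).

## Problem sizes

The shipped studies use desk-scale sizes chosen to characterise each claim:
12 conditions for each endpoint–At regression, 8 conditions × 3 noise
replicates for gain constancy, 7 decades × 3 replicates (+3 blanks) per
calibration, 54×2 wells per panel, 200 seeded Gillespie runs per
stochastic comparison.

## Known limitations

- Rate constants are calibrated, not measured; only behaviours the tests
  assert (spacing of At, window/gain/saturation identities, correlation
  signs and strengths) are meaningful, not absolute time constants.
- The logistic ceiling makes the post-threshold rise of α slower than
  typical experimental curves; consequently the linear stage reaches full
  gain ~150–200 min after At, visible as the onset delay δ in the
  endpoint ≈ gain·(t_end − At − δ) relation.
- The SSA treats saturating laws in mean field and is not a small-copy
  model of enzyme kinetics.
- Calibration confidence bands are limited to the residual SD; no
  bootstrap intervals.
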