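# Methods and modeling conventions

## The system

The Calvin–Benson cycle is treated as a deterministic reaction network
integrated as `dX/dt = N·v(X)`: `N` is the species-by-reaction
stoichiometry matrix (real-valued coefficients are first-class; the lumped
carboxylation/oxygenation reaction needs them) and `v(X)` evaluates one
rate law per reaction. Units are mM for concentrations, seconds for time,
mM·s⁻¹ for rates; fluxes quoted in mmol·s⁻¹ convert through the declared
compartment volume (default 1 l), recorded in model metadata. Clamped
(boundary) species keep their rows in `N` for flux accounting but have their
time derivatives forced to zero.

## Rate-law families

* **Mass action** `k·Π[reactants]`, optionally reversible via
  `− (k/Keq)·Π[products]`.
* **Michaelis–Menten** (irreversible, multi-substrate as a product of
  saturation factors); competitive inhibitors scale the first substrate's
  Michaelis constant by `1 + Σ I/K_i`.
* **Reversible MM** `Vm(ΠS − ΠP/Keq)/D` with a saturating denominator.
* **Transketolase** `v = Vm(kE·S1·S2 − P1·P2)/D`. The equilibrium constant
  multiplies the *forward* term: this is the only placement under which
  mis-setting kE7 to 10 instead of 0.076 overdrives the forward rate by the
  observed two orders of magnitude while detailed balance
  (`P1·P2 = kE·S1·S2 ⇒ v = 0`) still holds. The modifier factor carries the
  erythrose-4-phosphate and ribose-5-phosphate saturation terms, combined
  additively (the dimensionally consistent convention) or multiplicatively
  (the encoding found in the appendix-form model); both are selectable and
  the multiplicative form draws a validation warning. kM103 is the
  Michaelis constant of the Ri5P modifier term; values below 0.06 mM warn
  on multiplicative-modifier networks.
* **Phosphate translocator (V_PGAout)** with stromal and cytosolic
  saturation sums `T_s`, `T_c` and rate
  `Vm11(T_c·PGA/KmPGA − T_s·PGAc/KmPGAc)/(T_s + T_c + T_s·T_c)`. No
  idle-carrier "+1" term is added; a consequence worth knowing is that a
  completely empty opposite compartment gives zero exchange (an antiporter
  without counter-substrate), while any cytosolic phosphate supports export.
* **RuBisCO oxygenase** with competitive CO₂ inhibition and the
  sugar-phosphate/NADPH inhibition ring in the RuBP saturation term.
* **Starch phosphorylase** in two variants: `corrected` uses starch in the
  substrate position (zero rate at zero starch); `original` reproduces the
  documented defect of using stromal phosphate there, which degrades
  non-existent starch and drives its concentration negative. Models that
  deliberately exhibit this are flagged `diagnostic_mode`, the only mode in
  which negative concentrations are representable; otherwise rates are
  evaluated on concentrations floored at zero and excursions are recorded
  as events.
* **Generic expressions** — imported SBML kinetic laws that match no named
  family are kept as arithmetic expression trees (operators, powers,
  min/max) and evaluated by a tree walk.

## Photorespiration

Two encodings are supported and are exactly interconvertible by patches:

* **Lumped:** `RuBP + CO2 → A·PGA + B·PGCA` with `B = 2f`, `A = 2 − 2f` for
  oxygenation fraction `f`. Each RuBP turnover yields two three-carbon
  product slots; `f = 0.042` diverts 8.4 % of them, giving the coefficient
  pair (1.916, 0.084). The alternative reading `B = f` (one PGCA per
  oxygenation event) is selectable. The lump is intentionally not
  carbon-closed (−0.084 C per event); element bookkeeping reports this
  rather than hiding it.
* **Split:** carboxylation plus an explicit oxygenase reaction
  `RuBP + O2 → PGA + PGCA`. `split_oxygenation` parameterises the oxygenase
  at the model's computed steady state so that the steady state itself is
  preserved exactly; the reverse patch restores the lump.

Folding minor sinks into the PGA sink multiplies each flux fraction by a
carbon-equivalent factor q. The default table uses the conventional printed
values q(Ri5P) = 5/3, q(DHAP) = 1, q(E4P) = 4/3 and q(PGCA) = 1.66 (the
source counts the phosphoglycolate drain in RuBP carbon equivalents); a
strict carbon-ratio rule (q = carbons/3, giving 2/3 for PGCA) is available
by flag. Display of such factors truncates to two decimals (5/3 → 1.66) to
match the conventional printed form; computation always carries full
precision.

## The cyanobacterial template and its parameterisation

The library's variants share a one-compartment network: 13 cycle reactions
(CC_1–CC_13), 3 starch-synthesis reactions (SS_1–SS_3) and export sinks
(SR_*), with CO₂, O₂, Pi and the adenylate/pyridine cofactors held constant
and every hexose, pentose, GAP and DHAP as its own species. Quantitative
parameterisations of the historical models are not published in reusable
form, so the template uses a designed fixture parameterisation, tagged
`non-archival` in the lineage:

* A design steady state (concentrations in the low-mM range, PGA at 5 mM
  inside the reported 2.15–11.7 mM window) and a reference RuBP-synthesis
  flux of 0.1 mM·s⁻¹ are fixed first.
* The internal flux distribution is solved from the species balances given
  the sink fractions (flux-balance shares of RuBP synthesis: F6P 2.4 %,
  Ri5P 0.7 %, DHAP 0.32 %, E4P 0.31 %, PGCA 4.2 %; a 2 % starch-synthesis
  share; the PGA sink takes the remainder, which closes the carbon balance
  identically).
* Michaelis constants anchor at the design concentrations, equilibrium
  constants at three times the design mass-action ratio (forward-driven),
  and maximal rates are solved so every reaction carries its design flux —
  the design state is therefore an *exact* steady state of every variant.
* Two stabilising choices keep the autocatalytic network off the
  collapse/blow-up knife edge: RuBisCO carries competitive product
  inhibition by PGA, FBP and SBP (Ki = twice the design concentration, the
  same inhibition ring the oxygenase law carries), and MM sinks run at a
  third of saturation (Km = 3× design, Vmax = 4× design flux) so they
  respond near-linearly with capacity headroom. Under these conditions all
  six variants hold stable steady states across kE7 ∈ [0.076, 10] and
  kM103 ∈ [0.015, 0.46] and return from perturbed starts.

`zhu_A`/`zhu_S` carry the uncorrected constants (kE7 = 10, kM103 = 0.46)
with multiplicative vs. additive modifier encodings; the `cyano_*` variants
carry the corrected kE7 = 0.076 and kM103 = 0.06. C variants have no
oxygenase chemistry and fold the PGCA drain into the PGA sink; D variants
use the lumped oxygenation. The `*1` variants fold the minor sinks, the
`*2` variants declare them explicitly.

A known limitation follows from self-consistency: the steady state of the
template is provably independent of the carboxylation law (the RuBP
concentration absorbs it), and every transketolase modifier is itself a
product of the transketolase branch, so slowing that branch relieves its own
inhibition. As a result the kE7 correction reproduces the published
direction and approximate magnitude (F6P ×5.6, S7P ×2.5 on correction,
monotone), but the kM103 = 0.015 "blocked cycle with F6P/S7P accumulation"
mode does not exist in this parameterisation — the network re-equilibrates
instead. The stability threshold (kM103 ≥ 0.06 for the
multiplicative-modifier form) is carried as a validation warning. Table-like
sink comparisons are likewise generated from a standardized
out-of-steady-state start (a fixed multiplicative perturbation of the design
state), because flux-matched sink implementations share the operating point
and only differ transiently; their published raw cells depend on the
original, unpublished sink parameters.

## Simulation and steady-state conventions

* Integration: SciPy's LSODA with relative tolerance 1e−8 and absolute
  tolerance 1e−12 mM; dense output on a grid that is linear below 1 s and
  log-spaced above (≈1000 points per decade, capped).
* Steady-state criterion: `max_i |dX_i/dt| / max(|X_i|, 1e−9 mM) < ε` with
  ε = 1e−6 s⁻¹, over *balanced* species only — unclamped species that are
  not open product pools. Starch and the sink accumulators grow at constant
  rate in the steady regime and are excluded by construction. Because ε is
  a convention, times-to-steady-state are reported with an ε-band
  (1e−5…1e−7).
* `find_steady_state` integrates on a geometrically growing horizon (cap
  1e5 s), then refines by damped root-finding restricted to balanced
  species, accepting the refinement only when it reduces the residual and
  stays non-negative. Any species crossing 1e6 mM raises an "unbounded
  accumulation" diagnosis naming the species — the designed outcome when
  the PGA outlet is missing.
* Energy-charge clamping removes ATP/ADP from the ODE state and pins
  `ATP = ec·total`, `ADP = (1−ec)·total`; this reproduces the scan axis
  exactly and avoids adding stiff buffering reactions.
* Flux matching between variants scales the requested knob parameters by
  bisection until the reference steady fluxes agree within the stated
  Δflux; the adjustment is recorded in the lineage.

## Analyses

* **Stability test:** all state variables start at the computed steady
  state with one species (default RuBP) zeroed. "Suspension" means the
  RuBP-synthesis flux ends below 1 % of its steady value; "ATP collapse" is
  the first time the energy charge falls below 0.01. Both thresholds are
  package definitions and are reported with every run.
* **Mass conventions:** "total mass production" is the carbon-weighted
  accumulation in the open pools (export sinks plus starch) — the only
  convention consistent with carbon-equivalent folding factors; a molar sum
  is selectable. The "Calvin–Benson pool" is the carbon-weighted sum of
  unclamped, non-accumulator species; cofactors carry zero cycle carbons by
  construction.
* **Sink comparison table:** six (variant × {MA, MM, MMcb}) configurations,
  each re-parameterised to carry the same export flux at the design point,
  integrated 3 h from the standardized perturbed start and normalized to
  the supplement-form + MM cell = 100.
* **Paired ratios:** both models start from the shared initial
  concentrations; ratios guard denominators below 1e−12 mM and flag those
  points.

## Synthetic fixtures

Fixtures claim known answers, not biological realism. The toy cycle is a
five-intermediate autocatalytic analogue whose rate constants are solved
from a designed steady state. Three of its design features were forced by
analysis rather than taste: all-bilinear versions of the cycle possess
flux-preserving degeneracy manifolds (ATP trades against its co-substrates
with the phosphate balance enslaved to the energy fluxes), so a first-order
PGA drain and ATP upkeep reaction pin the steady state to an isolated
point; and the biosynthetic steps run substrate-saturated while drains stay
near-linear, which puts the low-concentration autocatalytic gain above one
so the cycle recovers from an acceptor knockout whenever the phosphate
supply holds. With a small unclamped external phosphate pool the exports
sequester phosphate, ATP synthesis stalls and the cycle suspends — the
phosphate-depletion behavior class. The starch-branch fixture adds the
defective/corrected starch-phosphorylase pair; the linear chain provides
closed-form steady states `x_i* = J/k_i`; the translocator fixture shows
unbounded stromal PGA without a relay sink and Vm11-independent export with
one.

What passing fixture tests do **not** show: agreement with the published
chloroplast parameterisations (import their SBML for that), behavior under
light/temperature dynamics, or enzyme activation kinetics (RuBisCO
activation on the 120–600 s scale is deliberately out of scope).

## SBML exchange

Export writes SBML L2V4 with content-MathML kinetic laws plus a small
annotation namespace carrying the structured rate-law description, element
counts, accumulator flags and lineage, making read(write(m)) structurally
identical to m. Import accepts Level 2 versions 1–4 from any source:
boundary/constant species become clamped, reaction-local parameters are
namespaced `<reaction>_<parameter>`, plain mass-action products are
recognised structurally and everything else stays a generic expression.
Events, rules and constraints are rejected with a report. Documents without
unit definitions import under the mM/s convention with a warning note.
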