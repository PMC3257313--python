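# cbckit

A kinetic-modeling toolkit for the Calvin–Benson cycle, built around the
corrections that published models of the cycle have turned out to need.

The Calvin–Benson cycle fixes CO₂ onto ribulose-1,5-bisphosphate (RuBP) and
regenerates its own acceptor, which makes it autocatalytic: a kinetic model
of it lives or dies by its rate laws, its export ("sink") reactions and its
conserved phosphate/adenylate pools. Several widely reused models carry
documented defects — a starch-degradation law that runs without starch and
drives its concentration negative, a transketolase equilibrium constant two
orders of magnitude off (kE7 = 10 instead of 0.076), transketolase modifier
terms multiplied where they should be added, and phosphate-translocator sink
implementations whose behavior differs far more inside the cycle than at the
export flux. cbckit implements these rate-law families and their corrected
forms as first-class, testable objects, together with the simulation and
diagnostic machinery needed to see each defect and its repair.

## What is in the box

* **`model_core`** — species/reaction/parameter data model with carbon and
  phosphate bookkeeping, real-valued stoichiometry, and the lumped
  carboxylation/oxygenation reaction
  `RuBP + CO2 → A·PGA + B·PGCA` with `A = 2 − 2f`, `B = 2f` for an
  oxygenation fraction `f` (f = 4.2 % gives the pair 1.916 / 0.084).
* **`rate_laws`** — mass action, (reversible) Michaelis–Menten, the
  transketolase form `v = Vm(kE·S1·S2 − P1·P2)/D` with selectable
  additive/multiplied modifier terms, the phosphate-translocator PGA export
  law (V_PGAout), the RuBisCO oxygenase law, and both variants of the
  starch-phosphorylase law (defective and corrected).
* **`simulate`** — stiff ODE integration of `dX/dt = N·v(X)` with clamped
  species, energy-charge clamping (ATP·(ADP+ATP)⁻¹), steady-state detection
  with a declared criterion, divergence diagnosis ("unbounded accumulation"
  when a sink is missing), and flux matching between model variants.
* **`model_library`** — buildable variants: the two transketolase encodings
  of the C₃ model (`zhu_A`, `zhu_S`), the cyanobacterial variants
  `cyano_C1/C2` (photorespiration folded into the PGA sink) and
  `cyano_D1/D2` (photorespiration as explicit O₂ fixation), plus recorded,
  reversible patches (`set_kE7`, `set_kM103`, `starch_fix`,
  `tk_modifier_mode`, `lump_oxygenation`/`split_oxygenation`, sink
  reconfiguration) with full lineage tracking.
* **`analyses`** — stability test (knockout at steady state, suspension and
  ATP-collapse flags), energy-charge scan, sink-output analysis,
  model × sink-kinetics comparison table, paired-variant ratio series.
* **`sbml_io`** — SBML Level 2 (V1–V4) read/write with content-MathML
  kinetic laws; foreign documents import as generic expression trees.
* **`fixtures`** — synthetic networks with known analytic answers (linear
  chain, an autocatalytic toy cycle with designed steady state, a starch-bug
  fixture, a translocator fixture); these drive the test suite with no
  downloads.

## Worked example

```python
from cbckit import build_model, find_steady_state, apply_patch
from cbckit.model_library import PatchDescriptor

m = build_model("cyano_D2")          # 13 cycle + 3 starch + 6 export reactions
ss = find_steady_state(m)
print(f"RuBP-synthesis flux: {ss.fluxes['CC_13']:.4f} mM/s")
print(f"PGA sink flux:       {ss.fluxes['SR_PGA']:.4f} mM/s "
      f"({100*ss.fluxes['SR_PGA']/ss.fluxes['CC_13']:.1f}% of RuBP synthesis)")
print(f"PGCA drain:          {ss.fluxes['SR_PGCA']:.4f} mM/s")
print(f"steady PGA:          {ss.state['PGA']:.2f} mM")

c2 = build_model("cyano_C2")
wrong = apply_patch(c2, PatchDescriptor("set_kE7", {"value": 10.0}))
bad = find_steady_state(wrong)
good = find_steady_state(c2)
print(f"F6P with kE7=10: {bad.state['F6P']:.3f} mM  (corrected: {good.state['F6P']:.3f} mM)")
print(f"S7P with kE7=10: {bad.state['S7P']:.3f} mM  (corrected: {good.state['S7P']:.3f} mM)")
```

prints

```
RuBP-synthesis flux: 0.1000 mM/s
PGA sink flux:       0.0142 mM/s (14.2% of RuBP synthesis)
PGCA drain:          0.0084 mM/s
steady PGA:          5.00 mM
F6P with kE7=10: 0.355 mM  (corrected: 2.000 mM)
S7P with kE7=10: 0.596 mM  (corrected: 1.500 mM)
```

The D2 model exports 2-phosphoglycolate at exactly `B = 0.084` of the RuBP
consumption, and the steady PGA sits inside the reported physiological range
(2.15–11.7 mM). The kE7 demonstration shows the defect class: with the
mis-set equilibrium constant the transketolase forward rate is overdriven
~130-fold and the steady F6P and S7P pools are several-fold too low;
correcting kE7 to 0.076 restores them.

A command-line surface mirrors the library
(`cbckit steady-state --model cyano_D2 --out run/`,
`cbckit stability-test …`, `cbckit energy-scan …`, `cbckit sink-table`,
`cbckit export-sbml …`; see `cbckit --help`).

## Layout

```
src/cbckit/        model_core, rate_laws, simulate, model_library,
                   analyses, sbml_io, fixtures, serialize, expr, cli
tests/             pytest suite (fixtures generated programmatically)
scripts/           acceptance.py
docs/methods.md    modeling conventions, design choices, limitations
```
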