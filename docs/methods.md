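# Methods

## Dynamical model

`squadron` implements the standard continuous relaxation of a Boolean
signaling network. Node activities live in `[0, 1]` and follow
`dx/dt = f_h(ω) − γx` with the normalized input weight ω and sigmoid
response `f_h` given in the README. The formulation has three properties
the rest of the package leans on:

- **Corner consistency.** ω reproduces the inhibitor-dominant Boolean rule
  `OR(activators) AND NOT OR(inhibitors)` at the corners of the input
  hypercube: any single inhibitor at activity 1 forces ω = 0; a node with
  inhibitors but no activators is constitutively driven (ω = 1 − I); a node
  with no inputs has ω = 0 and decays. With γ = 1 and steep gain
  (h ≳ 50) every synchronous Boolean fixed point therefore has a continuous
  steady state within 0.1 per node of its corner. This is the
  discrete–continuous correspondence the test suite checks exhaustively on
  random-network ensembles against `squadron.boolean`, which enumerates all
  fixed points by brute-force 2^n sweep (refused above 20 free nodes).
- **Anchored midpoint.** `f_h(1/2) = 1/2` for every gain, so at γ = 1 a
  node whose aggregate drive is half-maximal settles at exactly 0.5 —
  convenient for calibrating graded, semi-quantitative activation levels.
- **Exact clamping.** Clamped nodes (mutations, drugs, measured activation
  levels) are removed from the integrated state vector and substituted
  algebraically. Clamp fidelity is exact by construction, not enforced by a
  stiff penalty.

Integration uses `scipy.integrate.solve_ivp` (LSODA, rtol 1e-8, atol
1e-10) over a default horizon of 100 dimensionless time units with 400
equally spaced output points; output activities are hard-projected onto
`[0, 1]` to absorb roundoff. Convergence is declared when
`max |dx/dt| < 1e-6` at the final time; non-convergent runs keep their
trajectory, emit a warning (possible oscillation) and are flagged — never
silently treated as steady states. All of these knobs sit in
`SimulationConfig`. Time is dimensionless throughout; only steady-state
levels, not trajectory shapes, are treated as quantitative outputs.

Defaults are gain h = 10, decay γ = 1, edge weight 1. The packaged CRC
model overrides a handful of parameters (below); synthetic networks draw
theirs from configurable ranges.

## The HROC87 colorectal-cancer model

The fixture (`src/squadron/data/hroc87.json`, 29 nodes, 38 edges) encodes
the MAPK / PI3K–AKT / intrinsic-apoptosis crosstalk of a BRAF(V600E) and
p53 co-mutated, microsatellite-instable colorectal cancer background:

- Receptor arms: total EGFR and HGFR drive their activated forms
  `(EGFR)*` and `(HGFR)*`; both feed RAS → RAF (wild-type) and PI3K → AKT.
- Mutant BRAF: the clamp input `BRAF(V600)-Act` drives a BRAF node that
  vemurafenib inhibits; wild-type RAF is vemurafenib-insensitive and
  carries a raised weight onto MEK (1.544), which is why BRAF blockade
  alone barely dents MEK–ERK output — receptor flux through RAF sustains
  it. Gefitinib inhibits `(EGFR)*`; dedicated `MEK-Inhibitor` and
  `Bcl2-Inhibitor` nodes inhibit their targets.
- p53 arm: `p53-Mut` suppresses functional p53, which otherwise activates
  PTEN (⊣ AKT) and BAX.
- Apoptotic balance: Bcl2 integrates ERK and AKT survival input and is
  suppressed by BAD and the Bcl2 inhibitor; MEK and AKT jointly silence
  BAD; Bcl2 inhibits BAX (weight 3.63, switch-like BAX gain h = 19.8 —
  mitochondrial commitment behaves like a threshold, which is what makes
  MEK or Bcl2 blockade flip apoptosis from ~0.2 to ~0.99 while the milder
  receptor-level drugs only nudge it). Casp3/7 integrates BAX, BAD and
  c-Myc (apoptotic priming) against weak survival inhibition by ERK, AKT
  and Bcl2, and drives the `apoptosis` phenotype node.
- Proliferation: ERK → c-Myc → proliferation, modulated by the auxiliary
  calibration inputs `ERK-Inh`, `c-Myc-Inh`, `c-Myc-Act` that carry the
  scenario-specific pre-stimulation levels.
- Phenotype nodes (`apoptosis`, `proliferation`) are sinks.

Because AKT is clamped in every packaged scenario and the remaining free
subnetwork is acyclic, each scenario has a unique steady state reached from
any initial condition; the test suite cross-checks the integrator endpoint
against closed-form propagation in topological order.

### Scenarios

The six treatment scenarios (`data/treatment_scenarios.tsv`) clamp, per
condition, the mutation inputs, total receptors, measured activation
levels of AKT and the starred receptors, the auxiliary calibration nodes,
and the drug nodes at 1.0 when given. Blank cells leave a node free; free
undeclared nodes start at activity 0. Clamps persist for the whole horizon
(the clamped readout rows of the reference table echo the pre-stimulation
values exactly, which is only consistent with persistent clamps).

### Calibration

The fixture's constants were obtained by manual iterative refinement:
starting from defaults (h = 10, γ = 1, weight 1), a small set of weights,
gains and decays was adjusted until the six scenarios reproduce the
reference steady-state readout table within 0.05 per cell (0.01 for the
clamped pass-throughs, the 0.0/0.99 extremes and the unchanged
proliferation under Bcl2 blockade). All non-default values are recorded in
the fixture metadata (`calibration.overrides`); the load-bearing ones are
the RAF→MEK weight (vemurafenib resistance), the Bcl2⊣BAX weight and BAX
gain (apoptotic switch), the weak survival inhibitions of Casp3/7
(0.06–0.18 — they set the graded 0.21 → 0.35 apoptosis response to
receptor-level therapy), and the phenotype decays (γ = 1.769 for
proliferation, 1.01 for apoptosis) that place the untreated phenotype at
0.50 / 0.21. The `(EGFR)*` decay 1.6915 puts the free ligand-driven level
at 0.50. Calibration is curated: the package deliberately ships no fitting
routine.

## Synthetic networks

`squadron.synth` draws simple directed Erdős–Rényi topologies with
configurable size, edge probability, inhibition fraction, weight/gain/decay
ranges and seed (identical config + seed ⇒ identical model). Defaults
(n = 10, p = 0.25, 30% inhibitory edges) give sparse networks with mean
in-degree ≈ 2, comparable to curated signaling maps. The ensembles drive
the property suites: boundedness, exact clamp fidelity, round-trip
serialization, and the high-gain Boolean correspondence (checked at n = 8,
h = 50 and 80, with two randomly clamped nodes per instance — sizes chosen
so the exhaustive 2^n oracle stays cheap and the full suite runs in a few
minutes on one CPU). What these ensembles do *not* emulate: scale-free
degree structure, autoregulation, multi-level logic, or biologically
plausible motif composition — so passing properties certify the engine's
mathematics, not the realism of any particular biological topology.

## Numerical choices and degenerate inputs

- Screen ranking key: apoptosis delta descending, proliferation delta
  ascending, lexicographic node-name tiebreak; non-convergent perturbations
  rank last and stay flagged. A screen clamp on a node the base scenario
  already clamps replaces the base clamp (a perturbation supersedes a
  pre-stimulation); explicit user subsets may not contain base-clamped or
  phenotype nodes.
- Inhibition in the screen is a clamp to 0 (complete block); activation a
  clamp to 1.
- "Unchanged" band for qualitative direction calls: |Δ| ≤ 0.05 versus the
  untreated column.
- Fully clamped models integrate a zero-dimensional system and return the
  clamps unchanged; empty activator/inhibitor sets follow the ω
  conventions above; duplicate edges, dangling endpoints, non-positive
  gains/decays/weights and out-of-range activities are rejected at
  construction with named errors.
- BoolNet export writes the default logic only and refuses models with
  non-unit weights rather than silently discarding them; non-word
  characters in node names are mangled deterministically.

## Limitations

- The model is a curated subnetwork of one cell background; it does not
  cover the Wnt/β-catenin progression arm (APC, DCC, TGFβR, SMAD4) needed
  for other colorectal genotypes, and no quantitative scenario set exists
  here for an APC-mutant line.
- Steady-state levels are semi-quantitative activation degrees, not
  concentrations; trajectory shapes and the dimensionless time axis carry
  no calibrated meaning.
- Wet-lab observables (staining-based proliferation indices, immunoblot
  densitometry, apoptosis ELISA fold changes) are outside the model's
  vocabulary; the readout table is the only quantitative surface.
- Synchronous update is the only discrete semantics; asynchronous
  attractors, trap spaces and model checking are out of scope, as are
  stochastic dynamics, bifurcation analysis and dose–response sweeps.
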