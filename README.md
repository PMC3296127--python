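# thermoefm

Thermodynamic feasibility analysis of elementary flux modes (EFMs) in
compartmentalized metabolic networks.

## The problem

Steady-state flux analysis of a stoichiometric network answers *what flows
are balanced*, but not *what flows are thermodynamically possible*.  In
eukaryotes the question is sharpened by compartmentation: metabolite
concentrations are usually measured as cell averages, while the Gibbs
energies that decide reaction directions depend on compartment-specific
concentrations, pH, ionic strength and membrane potentials.

`thermoefm` characterizes the whole flux solution space instead of a single
optimal flux vector.  It enumerates the elementary flux modes of a network
— the minimal balanced routes from which every steady-state flux
distribution is a non-negative combination — and tests each mode's set of
reaction directions against quantitative metabolite concentration ranges.
The key theorem the package operationalizes: **a thermodynamically feasible
flux distribution is a non-negative combination of the thermodynamically
feasible EFMs alone**, so discarding infeasible modes provably loses no
feasible flux distribution.

It is intended for systems biologists who have a medium-size stoichiometric
model (SBML), measured exchange rates, and metabolome data, and who want
condition-specific reaction directions, flux bounds per unit substrate, and
the minimal combinations of reaction activities that thermodynamics forbids.

## The method

For a network with stoichiometric matrix S, a flux distribution v satisfies
S·v = 0 with bounds from reversibilities and measured exchange rates.  The
pipeline is:

1. **Flux variability analysis (FVA).**  Per reaction r, minimize and
   maximize v_r over the constrained flux space.  The range classifies the
   reaction: spanning zero → reversible; one-signed → unidirectional;
   bounded away from zero → *always active* with that sign.
2. **Thermodynamic direction derivation (NET analysis).**  A reaction
   carrying flux with sign σ needs σ·ΔG′ < 0, where
   ΔG′ = ΔG°′ + RT·Σⱼ s_j ln c_j (+ membrane transport terms).  Against the
   backdrop of the always-active reactions, each remaining reversible
   reaction is tested in both directions; directions with no consistent
   concentration assignment are eliminated.  FVA and NET iterate to a
   fixpoint.
3. **EFM enumeration** of the direction-constrained network (double
   description with exact rational arithmetic), removal of internal cycles
   (modes with zero substrate uptake).
4. **Per-mode classification.**  Each mode's activity sign pattern is
   tested by NET analysis against the concentration ranges; metabolites
   present in several compartments are constrained only through the
   volume-weighted sum Σₖ fₖ·cₖ of their compartment concentrations, so the
   compartmental split stays free.
5. **Insight extraction.**  Reaction activities used by the feasible vs.
   the full set; per-reaction flux ranges in mol per mol substrate; and
   minimal infeasible *patterns*: subsets of reaction activities that are
   impossible only jointly, mined by iterative constraint removal and
   verified minimal.

Infeasibility verdicts are always certified through a linear outer
relaxation of the (partly nonconvex) constraint system, so no feasible mode
is ever discarded; undecided cases are conservatively kept.

## Worked example

The built-in five-reaction network `toy6` (uptake T_A; an exergonic route
R1: A→B with ΔG°′ = −10 kJ/mol; a parallel two-step route R2: A→C,
R3: C→B with ΔG°′ = +5 kJ/mol each; secretion T_B; bounds A ∈ [0.001, 1],
B ∈ [1, 10], C ∈ [0.001, 10] mM):

```
$ thermoefm run --config config.yaml
{
  "feasible": 1,
  "feasible_fraction": 0.5,
  "infeasible": 1,
  "infeasible_fraction": 0.5,
  "n_after_cycle_removal": 2,
  "n_efms": 3,
  "n_patterns": 1,
  "total": 2,
  "unclassified": 0,
  "undetermined": 0
}
```

Three EFMs exist: the R1 route, the R2/R3 route, and an internal cycle
(R1 backward against R2, R3) that is removed because it carries no
substrate.  The R2/R3 route is classified infeasible: running both steps
forward needs c_B < c_A·exp(−10/RT), i.e. c_B/c_A < 0.018, while the bounds
force c_B/c_A ≥ 1.  The mined pattern names exactly that pair
(`patterns.json`):

```
[{"activities": {"R2": 1, "R3": 1}, "efm_count": 1, "infeasible_fraction": 1.0}]
```

Feasibility of a single activity, with attainable ranges:

```
$ thermoefm net-check --config config.yaml --activity R2=+1 --ranges
{
  "dg_ranges_kJ_mol": {"R2": [-12.124029, -1e-06]},
  "species_ranges_mM": {"A": [0.007515576, 1.0], "C": [0.001, 0.133056999]},
  "verdict": "feasible",
  "witness_mM": {"A": 1.0, "C": 0.001}
}
```

Forward R2 alone is fine, but it caps the product at
c_C < c_A·exp(−5/RT) ≈ 0.133 mM — a quantitative concentration prediction
from a direction assumption.

The same functions are available as a library (`thermoefm.enumerate_efms`,
`net_feasibility`, `classify_efm_set`, `aggregate_patterns`, ...); the CLI
is a thin layer over them.  Models are read from SBML
(`thermoefm.read_sbml`), condition data from TSV; see `docs/methods.md` for
formats and parameter conventions.

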