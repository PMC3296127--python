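# Methods

This note records the models, conventions, numerical choices and known
limitations behind `thermoefm`, in the order the pipeline runs them.

## Model container and units

A model is a set of compartments (volume fraction of total cell volume, pH,
ionic strength), species assigned to compartments (with an SBML-style
boundary flag excluding them from mass balance), and reactions as signed
stoichiometry maps — negative coefficients for substrates, positive for
products; the forward flux direction is the written direction.  Fluxes are
mmol·gDW⁻¹·h⁻¹, concentrations mM, energies kJ/mol.

Reactions carry a flux cap (default **1000 mmol·gDW⁻¹·h⁻¹** when the SBML
provides none) so that flux variability analysis is always a bounded LP.
Condition-specific narrowing (forward-only, backward-only, inactive) is
expressed through bound overrides `[0, cap]`, `[−cap, 0]`, `[0, 0]` and
never by rewriting stoichiometry — this keeps the sign convention of the
standard reaction energies intact.  Exchange reactions are detected as
those touching a boundary species or having one-sided stoichiometry,
covering both common SBML dialects.  Measured exchange rates enter as
intervals; an exact measurement is a zero-width interval.

## FVA and direction classes

Per reaction, min and max flux over {S·v = 0, bounds, measured exchange
intervals} via `scipy.optimize.linprog` (HiGHS).  Classification tolerance
**tol = 10⁻⁶ mmol·gDW⁻¹·h⁻¹**: a range spanning beyond ±tol on both sides
is reversible; within ±tol of zero, inactive; one-signed ranges give
forward-/backward-only, upgraded to *always-forward/-backward* when the
range is bounded away from zero by more than tol ("cannot be inactive" is
read literally as |min| > tol with both extremes of one sign).  On an
infeasible constraint system the error names the measured exchanges whose
individual removal restores feasibility (single-constraint relaxation; an
irreducible-infeasible-set computation would be stronger but this
diagnosis is cheap and usually sufficient).

FVA and the thermodynamic direction derivation below alternate until no
new constraint appears, with an iteration cap of 10; in practice the
fixpoint is reached after one or two rounds.

## NET analysis

### Constraint system

A reaction i carrying flux with sign σᵢ must satisfy σᵢ·ΔG′ᵢ < 0 with

ΔG′ᵢ = ΔG°′ᵢ + ΔG_transport,i + RT·Σⱼ sᵢⱼ·xⱼ,  xⱼ = ln(cⱼ/c_ref).

ΔG°′ is the standard transformed Gibbs energy valid at the compartment's
pH and ionic strength; reactions without a ΔG°′ and without a transport
model (typically transporters of unknown mechanism) are thermodynamically
unconstrained and contribute nothing.  The reference concentration c_ref
is 1 mM; for mass-balanced reactions only concentration ratios enter, so
the choice is a bookkeeping convention that must merely match the standard
state of the supplied ΔG°′ values.  The strict inequality is implemented
as σ·ΔG′ ≤ −ε with **ε = 10⁻⁶ kJ/mol**, and the LP additionally maximizes
a margin variable so feasible verdicts return an interior witness.

Protons and water are excluded as free variables (the transformed-energy
convention fixes them via compartment pH), consistent with models that are
deliberately not proton-balanced; the exclusion set is configurable.
Temperature defaults to **298.15 K** (RT = 2.479 kJ/mol), configurable.

### Transport

The concentration-independent membrane contribution per transported
species: z·F·Δψ per translocated charge (F = 96.485 kJ·mol⁻¹·V⁻¹) plus
RT·ln 10·(pH_source − pH_dest) per translocated proton — the chemical part
of the proton gradient; the RT·ln(c_dest/c_source) part rides on the
ordinary stoichiometric term.  Membrane potentials default to **Δψ = 0**
unless configured; this is a documented assumption, not a claim that
membranes are unpolarized, and matters mainly for charged transporters.

A helper builds ΔG°′ inputs from formation energies via the Legendre
transform (Alberty convention): +nH·RT·ln 10·pH and the extended
Debye–Hückel correction −RT·α·(z² − nH)·√I/(1 + B√I) with
α = 1.17582 kg^½·mol^−½, B = 1.6 kg^½·mol^−½.

### Compartment pooling

A metabolite measured as a cell average but present in several
compartments is constrained only through Σₖ fₖ·cₖ ∈ [c_min, c_max], with
fₖ the compartment volume fractions of *total* cell volume (yeast
reference values: cytosol 0.35, mitochondrion 0.1); the compartmental
split remains free.  Normalizing by Σfₖ instead is a one-line change kept
out of the default because the volume-weighted sum is the direct reading
of a whole-cell measurement.

In x = ln c the sign constraints are linear and the pooled upper bound is
convex, but the pooled lower bound is not.  Feasibility is decided by
branch-and-bound over the pooled variables with linear outer
approximations — tangents under exp for upper bounds, chords over exp for
lower bounds — branching at box midpoints, depth cap **20**.  Three
outcomes:

* **infeasible** — every node's linear relaxation is empty.  Since each
  relaxation contains the true feasible set, this verdict is a
  certificate: no feasible pattern is ever labeled infeasible.
* **feasible** — a relaxation solution satisfies the exact pool
  constraints (tolerance 10⁻⁹); the witness concentration vector is
  returned.
* **undetermined** — depth cap reached.  Classification pools this with
  feasible, preserving the guarantee that discarding infeasible modes
  loses no feasible flux distribution.

### Range estimation

Attainable concentration and ΔG′ ranges are computed per variable as
min/max over the root linear relaxation.  They are therefore *outer*
envelopes: every feasible point (in particular the witness) lies inside,
and they never extend past the input bounds.  For systems without pools
the relaxation is exact and so are the ranges.

### Direction derivation

Each reversible, thermodynamically constrained reaction is tested in both
directions jointly with the signs of the always-active reactions; if
exactly one direction is feasible the corresponding constraint is emitted
(provenance `NET`).  Both directions infeasible raises a model/data
inconsistency rather than silently picking one.

## EFM enumeration

Double description over exact `Fraction` arithmetic: reactions with
two-sided capacity are split into forward/backward columns, making the
cone {w ≥ 0, S·w = 0} pointed; mass-balance hyperplanes are intersected
one at a time, keeping at each step the extreme rays.  A candidate from a
(positive, negative) ray pair is admitted only if the pair is adjacent —
no third ray's support is contained in their combined support (the
combinatorial adjacency test).  Rows are processed greedily by fewest
positive×negative pairs, which keeps intermediate ray counts small and
fixes a deterministic output order.  Split artifacts (forward+backward of
one reaction) map to the zero vector and are dropped; modes supported
entirely on two-way reactions appear once per sign and are canonicalized
to a positive leading coefficient.  Exact arithmetic makes S·e = 0 hold
exactly and elementarity (nullity one on the support) verifiable without
tolerances.

The splitting formulation was chosen over keeping reversible reactions as
free-sign columns: with two-cycle removal and sign canonicalization it
returns exactly the elementary modes, and its correctness is much easier
to audit against the brute-force oracle.  The enumerator targets
fixture-scale networks (≲20 reactions; the ray cap defaults to 10⁷ and
aborts with a capacity error rather than thrash).  Genome-scale runs with
10⁷–10⁸ modes need the specialized compiled enumerators and cluster
memory; this implementation favors exactness and testability at small
scale, which is also the scale at which the oracle cross-checks are
possible.

Internal cycles — modes with zero substrate flux — are removed before
classification; they are physiologically meaningless at steady state.
Normalization divides a mode by its substrate flux, giving rates in mol
per mol substrate.

## Classification, usage, ranges

Feasibility depends only on a mode's sign pattern restricted to
constrained reactions, so verdicts are memoized on that restriction and
optionally journaled to an append-only TSV keyed by pattern hash — long
runs are restartable and order-independent.  Summary fractions count
undetermined with feasible.  Activity-usage tables flag reactions whose
feasible-set directions are a strict subset of their full-set directions
(condition-specific direction or inactivity predictions).  Per-reaction
normalized flux ranges are computed over any label filter; on cycle-free
networks the full-set ranges coincide with LP optima over
{S·v = 0, bounds, v_substrate = 1}, which the tests verify.

## Pattern mining

For an infeasible mode, activities are removed one at a time in a fixed
order (default: model reaction order; optional seeded random orders):
if removal makes the remainder feasible the activity is part of the
pattern and is kept, otherwise it stays removed.  The result is verified —
the pattern infeasible as a whole, every single-activity removal feasible —
and a verification failure raises instead of returning a wrong pattern.
Which minimal pattern is found depends on the removal order; the
multi-order option unions the alternatives.  Mining runs per distinct sign
pattern, not per mode, and occurrence counts are mapped back.  Every
infeasible mode contains at least one reported pattern.

## Decomposition and FBA cross-checks

Cone membership (is v a non-negative combination of a mode set?) is an
elastic feasibility LP minimizing L1 slack; membership requires slack
≤ 10⁻⁸ (scaled), non-membership is certified by a separating hyperplane
y with yᵀE ≤ 0 and yᵀv > 0 from a second LP.  Decompositions are not
unique and no uniqueness is claimed.  Linear FBA (single-reaction
objectives) is provided to test optimizer outputs for the mined patterns:
a flux vector whose active signs (|v| > 10⁻⁶) contain a pattern is
thermodynamically suspect.  Nonlinear objectives (e.g. ratios with
quadratic denominators) are out of scope.

## Fixtures and oracles

Two independent oracles back every guarantee:

* **Brute-force enumeration** — a support T carries an EFM iff S
  restricted to T has nullity one and the kernel vector covers T with
  signs compatible with the bounds (exact rational linear algebra;
  exponential, fixtures only).
* **Grid search** — exhaustive scan of a log-concentration grid at **50
  points per log10 decade per species** (the oracle's documented
  precision), intended for ≤6 free species; memory grows as
  points^n_species, so random-network labels are only precomputed where
  that stays near 10⁸ cells.

`toy6` plants the essential structure in five reactions: two parallel
routes of which one is blocked because two +5 kJ/mol steps cannot both be
downhill within the concentration bounds (c_B < c_A·e^(−10/RT) vs.
c_B/c_A ≥ 1), plus the internal cycle formed by reversing the other route.
Expected modes, labels and the minimal pattern are recomputed from the
oracles at fixture construction, never hard-coded.

Random fixtures are connected chain-plus-shortcut networks with one
uptake and one secretion, unit coefficients, ~40% reversible shortcuts,
random ΔG°′ in ±15 kJ/mol and species bounds [0.1, 10] mM — sizes and
ranges chosen so the oracles stay exact and fast.  An acyclic variant
orients all reactions along the chain (a DAG, hence no internal cycles)
for the LP-tightness checks.  What the fixtures do *not* emulate: real
stoichiometric coupling (cofactor pairs, biomass equations), realistic
ΔG°′ correlations, multi-compartment pooling at scale, or networks big
enough that enumeration order and memory management dominate.  Passing
tests therefore demonstrate correctness of the algorithms, not
performance or biological calibration on a genome-scale model.

## Known limitations

* Enumeration and classification are exact but not engineered for
  genome-scale mode counts; the mode cap aborts early by design.
* The infeasibility diagnosis for over-constrained FVA uses single-
  constraint relaxation, which can miss jointly-implicated sets.
* Range estimation over pooled systems returns outer envelopes, not tight
  bounds.
* ΔG°′ uncertainty is not propagated; the intended use is wide
  concentration ranges that dominate formation-energy errors.
* Membrane potential and transported-species annotations must be supplied;
  there is no inference of transport mechanisms.
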