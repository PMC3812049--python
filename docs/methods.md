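# Methods

## The screening method

`pepscreen` implements multisequence Monte Carlo screening of
protein-peptide binding specificity.  A peptide with a set of *variable*
positions interacts with a receptor; the sampler simulates the joint
distribution

    P(x, s)  ∝  exp( -E(x, s)/T + g_s ),

where `x` is the chain conformation (all torsional and rigid-body
degrees of freedom), `s` the amino acid sequence at the variable
positions, `E` the potential energy and `g_s` a per-sequence weight.
Conformational moves and mutational moves are both ordinary Metropolis
updates on this weight: a move is accepted with probability
`min(1, exp(-ΔE/T + Δg))`, with `Δg = 0` for conformational moves.

The sequence marginal of the joint distribution is
`P(s) ∝ Z_s exp(g_s)`, with `Z_s` the canonical partition function of
sequence `s`.  Splitting conformation space into a bound class B
(peptide Cα RMSD to the native pose below 6 Å, strict) and its
complement U gives the central identity: the ratio
`P_B(s)/P_U(s) = exp(-ΔF_bind(s)/T)` is independent of the `g_s`.

The two-step protocol:

1. **Unbound-state flattening.**  The unbound state is approximated by
   a free peptide (no receptor).  `g_s` takes the linear form
   `g_s = Σ_i γ(s_i)` over variable positions, with one γ parameter per
   amino acid type.  Iterative free-peptide simulations measure the
   aggregated type probabilities `P_U(a)` and apply the
   expanded-ensemble correction

       γ'(a) = γ(a) − ln(20 · P_U(a)),

   re-centered to zero mean, whose fixed point is the flat
   distribution.  At convergence `g_s ≈ F_U(s)/T`.
2. **Bound-state screening.**  With the flattened γ, a joint run of the
   receptor-peptide system generates bound-state sequences with
   Boltzmann weights `exp(-ΔF_bind(s)/T)`.  The conditional
   distribution `P(s|B)`, estimated from bound samples, yields
   per-position specificity profiles `p_i(a)`, their entropies
   `S_i = −Σ_a p_i ln p_i` (ln 20 ≈ 3.00 for a fully promiscuous
   position), and relative binding free energies
   `ΔF(s) = −T ln P(s|B)`, reported relative to the weakest
   well-observed binder.

Any residual error δ_s of the linear unbound-state model shifts
`ln P(s|B)` by exactly δ_s; the observable proxy is the residual
deviation of `P_U(a)` from 1/20, which the flattening diagnostics
record (defaults target ≤ 10%).

## Chain representation

Chains use a reduced representation: an N–Cα–C backbone built from phi
and psi with the peptide bond fixed at trans, plus 0–3 side-chain
pseudo-atoms per residue (the count of side-chain heavy atoms, capped
at three) placed by fixed geometry (CB) and the torsions chi1/chi2.
All bond lengths and angles are fixed at the values of the shipped
ideal-geometry table (`data/ideal_geometry.txt`; standard backbone
values, pseudo-bonds of 1.8 Å for side-chain sites).  Glycine carries
no side-chain site — a deliberate deviation from a strict "one to
three sites" rule, because glycine has no side chain.

Every residue formally carries 7 internal degrees of freedom (phi, psi,
chi1–chi5) regardless of type.  Angles a type does not use are
*phantom*: they are carried in the state, sampled by rotamer moves (and
therefore relax to a uniform distribution), and have no effect on
geometry or energy.  On a mutational move the new type inherits all 7
angles unchanged, which makes the move exactly symmetric between types
with different numbers of real degrees of freedom; the round trip
a→b→a restores coordinates and energy bitwise.

## Energy model

The production potential is a coarse-grained surrogate with the five
physical ingredients of implicit-solvent peptide force fields —
excluded volume, local torsional energy, backbone hydrogen bonding,
side-chain contact interactions, and a backbone desolvation penalty —
plus a harmonic restraint of receptor sites to their native positions
and the piecewise-linear pocket constraint.  All parameters are
dimensionless (k_B = 1) and live in one dataclass
(`CoarseGrainedModel`).  Functional forms:

- excluded volume: truncated quadratic `ε(1 − r/σ)²` below the summed
  radii (backbone 1.5 Å, side sites 1.7 Å, receptor sites per-site);
- local: `w(1 + cos 3θ)` over used backbone and chi torsions;
- hydrogen bonding: a distance window (plateau 3.2–4.6 Å) between
  backbone N and C sites of residues ≥ 3 apart, and between peptide
  backbone and polar/amide receptor sites scaled by site strength;
- side-chain contacts: a symmetric 5×5 residue-class matrix
  (hydrophobic, polar, amide, basic, acidic) weighted by a linear
  contact switch between 4.5 and 6.5 Å, evaluated at the outermost
  side-chain site, scaled by receptor-site strength;
- desolvation: a per-contact penalty for peptide backbone burial
  against *bare* (strength-0) receptor sites; interaction sites
  represent solvated functional groups and carry no penalty.

The receptor is a set of typed interaction sites rather than a second
full chain: one site per receptor residue when loaded from a PDB file,
engineered sites in the synthetic fixture.  Sites are restrained
harmonically to their native coordinates (default k = 5 per Å²) and
jiggled by a dedicated move type, realising the "restrained receptor"
protocol at desk scale and anchoring the frame in which RMSD is
computed without superposition.

These functional forms are intentionally simple surrogates: they honor
the five-term decomposition of published all-atom interaction
potentials for protein-peptide binding but do not reproduce any
specific published parameterization.

## Temperatures, box, constraint

The default temperature is T = 0.60 (dimensionless), chosen once for
the surrogate model such that binding and unbinding events both occur
in the shipped systems — the same operational criterion used for
published midpoint temperatures (≈ 0.51–0.58 in the all-atom model this
method was developed with).  Discovery-mode runs (no pocket
constraint) use T = 0.85: with the constraint removed the same
criterion — substantial time both bound and freely diffusing — demands
a weaker-binding regime; the flattening step is redone at the
discovery temperature, since gamma tables are temperature-specific.  The simulation box is cubic, L = 50 Å,
periodic.  The pocket constraint is `k·max(0, d − d0)` on the peptide
C-terminal Cα displacement from its native position, with defaults
k = 1 (per Å) and d0 = 10 Å; it keeps screening runs near the pocket
without disturbing bound-state statistics (it vanishes identically on
B, which lies well inside the onset).

## The toy model: exact verification

`ToyEnumerableModel` is a finite catalogue of discrete "conformations"
with labelled bound/unbound subsets and per-(state, position, type)
energy couplings, small enough (≤ 10⁷ states × sequences) for exact
partition sums.  Because B/U labels are catalogue facts, no geometry
enters: sampler correctness (stationary distributions, the
g-independence of P_B/P_U, flattening fixed points, error-injection
identities) is verified against exact enumeration, with an independent
brute-force loop in the tests guarding the enumeration itself.

## The synthetic receptor fixture

The fixture emulates a PDZ-like peptide-binding site at desk scale,
with preferences that are recoverable by construction:

- a **groove**: polar sites under the native peptide line that reward
  backbone alignment (type-independent affinity), flanked by two
  layers of sterically repulsive ridge sites and closed by a
  cul-de-sac wall past the C-terminus, so docking means lying along
  the groove;
- **anchor** sites: amide-class sites at hydrogen-bond distance from
  the C-terminal backbone (the carboxylate-binding-loop analogue);
- a **pocket**: recognition sites of configurable class and strength
  placed beside the first side-chain site (CB) of chosen peptide
  positions.  Anchoring at CB — which every non-glycine type places
  identically — makes the engineered discrimination class-based
  rather than reach-based.  The default prefers hydrophobic types and
  contains an acidic sub-site (attracting basic, repelling acidic
  residues);
- **decoy** surface sites: a plane of weak polar sites below the
  groove.

The default peptide is a tripeptide with all positions variable and
the preference at the C-terminal position.  A short peptide is a
deliberate choice: with 3 Cα sites, any conformation with the
C-terminus docked lies within the 6 Å RMSD cutoff, so the B/U
classification tracks a single docking coordinate and fixed-sequence
runs show many bound/unbound transitions at desk-scale run lengths.
Longer peptides (the package handles any length) exhibit
partially-docked states that are slow to exchange — physically
realistic, but needing orders of magnitude more sampling.

What the fixture does *not* emulate: real rotamer packing,
directional hydrogen bonds, electrostatics beyond class contacts,
solvent structure, receptor conformational change.  Tests passing on
the fixture demonstrate that the *sampling machinery and estimators*
are correct and that engineered preferences are recovered; they do not
validate the surrogate energy function against real binding data.

## Numerical choices

- Angles in radians, wrapped to (−π, π]; degrees only at I/O
  boundaries.
- Move schedule defaults: pivot 0.25 / rotamer 0.25 / rigid rotation
  0.10 / rigid translation 0.15 / mutation 0.20 / receptor jiggle
  0.05, with amplitudes 0.8 / 1.2 / 0.35 / 0.8 (Å) / 0.25 (Å).  The
  translation amplitude matters for bound-unbound exchange; 0.8 Å
  maximizes transition rates on the shipped fixture.
- Mutation proposals are uniform over all 20 types (self-proposals
  allowed; trivially symmetric); a config switch selects
  uniform-over-19 instead, also symmetric.
- One elementary MC step is one attempted move of any type; every
  proposal re-evaluates the full energy (systems are small enough that
  incremental bookkeeping is not worth its failure modes), so reported
  deltas are exact by construction.
- Flattening: start from γ = 0 and all-alanine variable positions;
  burn-in 10% of each iteration; pseudo-probability 1e-4 for unseen
  types before the log; tol 0.10 on max |20·P_U(a) − 1|; max 30
  iterations, warning (not an error) on non-convergence.
- Relative ΔF tables anchor the zero at the weakest binder observed at
  least `min_count` (default 10) times, to avoid anchoring on noise.
- RMSD-conditioned profiles use 1 Å bins from 0 to the box diagonal;
  empty bins are omitted.
- Acceptance guards against overflow by accepting outright whenever
  `−ΔE/T + Δg ≥ 0`.

## Problem sizes

Shipped defaults are desk-scale by design: tests and the acceptance
script use free peptides of 3–6 residues, receptors of ~40–70 sites,
runs of 10⁵–2×10⁶ steps, and 2–3 replicates per estimate.  These sizes
give flattening residuals of ~3–7%, total-variation distances below
0.01 against exact enumeration on the toy model, and standard errors
of ~0.1–0.3 (units of T) on fixed-sequence binding free energies.

## Known limitations

- The surrogate energy model is not the published all-atom force
  field; absolute ΔF values are not comparable to experimental
  affinities (relative values within a system are the method's
  output).
- The linear (position-independent) γ model is the default; a
  position-dependent table is a straightforward extension but not
  implemented.
- Screening assumes the unbound state is well approximated by the free
  peptide.  Receptors whose surface interacts strongly and
  type-dependently with the *unconstrained* peptide violate this
  approximation; the fixture was designed so that it holds (weak,
  backbone-mediated nonspecific interactions).
- Exact degeneracies exist in the coarse-grained alphabet: types with
  the same class and side-chain site count (e.g. L/I/F) have identical
  energetics, so their relative rankings in any estimate are ties
  broken by noise.
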