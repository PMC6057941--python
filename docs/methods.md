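# Methods

## Model

`contactsieve` treats contact filtering as a structural consistency
problem.  A polypeptide is represented in torsion space: per-residue
(φ, ψ, ω) with ω fixed at 180° and a reduced backbone of N, CA, C and a
CB side-chain proxy (absent for glycine) built sequentially from ideal
internal coordinates (N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å; angles
N–CA–C 111.2°, CA–C–N 116.2°, C–N–CA 121.7°; CB at 1.521 Å in an ideal
tetrahedral frame).  Residues covered by predicted helix or strand
segments are locked at canonical dihedrals; loops start extended
(−135°, 135°) and are the only degrees of freedom.

The energy is a soft-core clash term plus switchable flat-bottom
distance restraints on the selected contacts:

* clash: k (r_min − r)² for every N/CA/C/CB pair closer than
  r_min = 3 Å, excluding pairs within the same or adjacent residues
  (k = 1);
* restraint i: λ_i (d_i − d⁰)² + D² (1 − λ_i²) when the CB–CB (CA for
  Gly) distance d_i exceeds d⁰ = 7 Å, zero otherwise, with weight
  λ_i ∈ [0, 1].

The restraint energy is concave in λ_i, so each weight is bistable:
E(λ=1) = (d−d⁰)² against E(λ=0) = D².  Switching a restraint off is
favorable when its squared violation exceeds D², and noiseless gradient
descent from λ = 1 reaches zero once (d−d⁰)² > 2D².  Because the λ
energy is *flat* when a restraint is satisfied (the switching cost term
only applies for d > d⁰, exactly as the energy is defined), the weight
of a satisfied contact diffuses freely under the thermal noise term and
ends up roughly uniform on [0, 1].  This is a property of the energy,
not a defect: per-run on/off calls for good contacts behave like fair
coin flips, which is precisely why the consensus threshold is the
rather low "on in more than 30% of runs".  Violated contacts, by
contrast, are driven deterministically to λ = 0 once D has annealed
below their violation, and this asymmetry is the entire filtering
signal.

## Protocol

1. Parse sequence, secondary structure and the ranked contact list;
   build the fixed-segment chain.
2. Select the top ⌊1.2 · N_AA⌋ contacts whose two residues are not
   inside one predicted segment (duplicates collapse to the
   highest-scoring orientation; if the list runs out a warning is
   raised and the shorter set used).
3. For each of n_repeats = 64 seeds: (a) simulated annealing with
   Metropolis moves on free dihedrals while D anneals 150 → 3 Å and T
   cools geometrically, with one Brownian λ update per schedule step
   (γ = 0.00025, δ = 0.6666, Δt = 1, clamp to [0, 1]); (b) the refined
   list is read off as λ ≥ 0.5 (the midpoint of the enforced range —
   how the refined list is derived from the annealed weights is
   otherwise unspecified); (c) a second annealing with only the refined
   contacts, weights fixed at 1; (d) a contact is "on" if it is in the
   refined list and its final distance is at most d⁰ + D_end = 10 Å.
4. Consensus: keep contacts on in strictly more than 30% of runs.

Runs are independent; seeds are base_seed + k, and a thread pool may
execute them concurrently with bit-identical results.

## Sampling engine

The integrator is Metropolis Monte Carlo in torsion space rather than
torsion-angle dynamics: one uniformly chosen free φ/ψ is perturbed by
uniform(−30°, 30°), which rigidly rotates the downstream suffix of the
chain.  Proposals are evaluated through cross-block energy deltas (the
rotated block is internally rigid), implemented in compiled (numba)
kernels; a full-precision identity between the incremental rotations
and the sequential rebuild is asserted in the tests.  Schedule sizes
default to 150 steps with 8 moves per free dihedral per step and
T: 10 → 0.1 (geometric).  These sampler sizes are calibration choices
of this package — they are large enough that the 60-residue synthetic
benchmark folds reproducibly, and small enough to keep a full 64-repeat
protocol in the tens of seconds on one core.  All randomness flows from
explicit integer seeds through numpy Generators.

## Synthetic data

`make_toy_sheet` builds idealized antiparallel β-meanders directly in
torsion space (strands at canonical dihedrals, loops at curated turn
angles, numerically refined for the 19-residue 3×5 and 60-residue 3×18
topologies so that adjacent strands pair at ~5 Å ladders with no
backbone contact below ~3 Å).  Because the ground truth is constructed
from exactly the degrees of freedom the sampler moves, every true
contact is reachable by the protocol.  True contacts are all long-range
pairs at ≤ 9 Å; decoys are drawn from pairs beyond 12 Å (configurable
down to the 9–12 Å borderline regime), and `make_prediction` enforces
an exact input precision with scores shuffled so rank carries no
signal.  `make_toy_msa` constructs gapless alignments whose effective
sequence count equals the number of clusters by giving cluster members
disjoint mutation blocks.

What the toys do not emulate: real side-chain sterics, hydrogen-bond
geometry, bent/curved secondary-structure elements, alignment-derived
contact-score correlations, and gapped MSAs.  Passing tests therefore
demonstrate the mechanics and internal consistency of the protocol, not
its published accuracy on crystallographic benchmarks.

## Known limitations

* **Reduced backbone under-constrains tiny systems.**  With only
  N/CA/C/CB atoms and a 3 Å soft core, three short strands can pack
  into a clash-free triangular bundle that satisfies essentially any
  five restraints on a ~20-residue chain — including a deliberately
  wrong outer-strand contact.  The filter then (correctly, by its own
  criterion) finds the whole set self-consistent and keeps it.
  Detecting such an error requires the steric bulk of a fuller atom
  representation.  The behavior is exercised by a dedicated acceptance
  test on the five-contact toy, which documents this limit; on the
  60-residue fold with ~72 restraints, where false contacts must fight
  a large self-consistent majority, filtering works as intended
  (precision typically rises from 0.6–0.8 to > 0.9 at recall ≥ 0.9).
* Borderline false positives (true distance just above 9 Å) are
  retained by design: the final on/off cutoff tolerates violations up
  to d⁰ + D_end = 10 Å.
* GDT uses a seeded, iteratively trimmed Kabsch search rather than the
  exhaustive LGA enumeration; it is deterministic and can only
  underestimate the optimum.
* Precision/recall denominators exclude contacts touching unresolved
  reference residues.
* mmCIF, multi-model ensembles beyond the first model, and ligands are
  out of scope; PSIPRED and the coevolution predictors themselves are
  inputs, not components.
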