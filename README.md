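# contactsieve

Coevolution-based contact predictors rank residue pairs by coupling
strength, but the ranked list gives no natural cutoff and, especially for
shallow alignments, contains many false positives.  `contactsieve`
filters such a list by **structural self-consistency**: it repeatedly
folds the protein in torsion space under the predicted contacts as
distance restraints, lets each restraint carry a sampled on/off weight,
and keeps only the contacts that the ensemble of structure calculations
can actually accommodate.

## Method

The input is a ranked contact list, a per-residue secondary-structure
prediction and the sequence.  Residues inside predicted helix/strand
segments are fixed at canonical dihedrals (φ_α = −60°, ψ_α = −45°;
φ_β = −135°, ψ_β = 135°); only loop dihedrals move.  The top
⌊1.2 · N_AA⌋ contacts whose residues do not fall inside a single
segment are used as restraints with the energy

    E = E_clash + Σ_i { λ_i (d_i − d⁰)² + D² (1 − λ_i²)   if d_i > d⁰
                      { 0                                  otherwise

where d_i is the Cβ–Cβ (Cα for Gly) distance, d⁰ = 7 Å, λ_i ∈ [0, 1] a
per-restraint weight and D the cost of switching a restraint off
(λ_i = 0 costs D²).  Simulated annealing cools the temperature while D
anneals from 150 Å to 3 Å; λ_i follows a Brownian update
λ_i ← λ_i − γ (∂E/∂λ_i) Δt + δ √(TΔt) ζ with γ = 0.00025, δ = 0.6666.
Switching a restraint off becomes favorable exactly when
(d_i − d⁰)² > D², so systematically violated restraints are shed as D
falls.  Each of 64 independent runs reports which contacts ended up
"on" (λ_i ≥ ½ and final violation ≤ d⁰ + D); contacts on in more than
30% of runs form the consensus output.

Evaluation utilities are included: TP/FP classification against a
reference structure (Cβ–Cβ ≤ 9 Å), precision/recall, mean squared
distance violations beyond 9 Å, Kabsch superposition, GDT(5)/GDT-TS,
and the effective sequence count N_eff (80%-identity clustering
weights).  A synthetic module generates toy β-sheet folds, noisy
predictions with controlled precision, and toy MSAs so the whole
pipeline runs without any external data.

## Worked example

Generate a synthetic fixture (a 19-residue three-stranded antiparallel
sheet with a noisy 12-contact prediction at 75% precision), filter it,
and evaluate against the known toy structure:

```bash
contactsieve toy --out-dir fix --n-contacts 12 --precision 0.75 --seed 3
contactsieve filter --fasta fix/toy.fasta --ss fix/toy.ss2 \
    --contacts fix/toy.contacts --repeats 16 --seed 11 --out-prefix run/toy
contactsieve evaluate --contacts run/toy.contacts.tsv \
    --reference fix/toy.pdb --fasta fix/toy.fasta
```

The filter step prints

```
kept 10 of 12 contacts -> run/toy.contacts.tsv
```

and the evaluation report (precision/recall of the kept set against the
reference, plus the violation energy of the kept contacts) reads

```
n_input	12
n_kept	10
tp	9
fp	1
fn	0
precision	0.9
recall	1
violation_energy	1.47792
input_precision	0.75
input_violation_energy	19.9017
```

meaning the consensus dropped two of the three false contacts, kept all
nine true ones (recall 1.0), raised precision from 0.75 to 0.90 and cut
the mean squared distance violation of the retained set from 19.9 Å² to
1.5 Å².  On larger synthetic folds (60 residues, 72 input contacts at
60–80% precision) the same protocol typically lifts precision above
0.9 at recall ≥ 0.9.

`contactsieve neff fix/toy.msa.fasta` prints the effective sequence
count of an alignment (here `3.0000`, the number of constructed
clusters).

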