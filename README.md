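# rnatopo

Topology-independent rigid-body superposition of RNA (and DNA) 3D structures,
with structure-based sequence alignments scored by the RNA TM-score.

Structurally similar non-coding RNAs do not always share the same backbone
topology: tRNA-mimicking viral RNAs and bacterial Y RNAs superimpose onto
tRNAs only through circularly or non-circularly permuted residue
correspondences, which conventional (sequentially-ordered) structure
alignment cannot express. `rnatopo` solves the pairwise RNA 3D structure
alignment problem in both regimes: given two coordinate files it reports the
optimal sequentially-ordered alignment *and* the optimal topology-independent
alignment, classifies the permutation (none / circular / non-circular), and
flags backbone-permuted similarity. It is aimed at structural
bioinformaticians comparing non-coding RNA folds, motifs, and conformational
states.

## Method

Let *X* and *Y* be the two structures with *N* ≥ *M* nucleotides. The
algorithm assumes the ideal superposition contains at least one
residue–residue match of near-zero RMSD:

1. **Seed superpositions.** For every residue pair (*X*ᵢ, *Y*ⱼ), superimpose
   *Y* on *X* by the Kabsch algorithm on a 3-pseudo-atom residue
   representation: the phosphate point (OP1/O5′ midpoint), the ribose point
   (C2′/C4′ midpoint), and the glycosidic base nitrogen (N9 for purines, N1
   for pyrimidines).
2. **Hits.** Each seed yields a *hit*: the mutually closest residue pairs
   whose C3′–C3′ distance is below MATCHRANGE1 = 3.5 Å.
3. **Extension.** The TOPLARGEST = *M* largest hits are re-superimposed on
   their matched residues' pseudo-atoms, and the adjusted superposition is
   extended to the mutually closest set under MATCHRANGE2 = 8 Å — a candidate
   topology-independent alignment.
4. **Sequential alignment.** From the same adjusted superposition, a scoring
   matrix S = −D + SHIFT1 + SHIFT2 is built from the C3′ distance matrix D
   (SHIFT1 = largest matched distance, SHIFT2 = 3 Å) and a zero-gap-penalty
   Needleman–Wunsch alignment maximizes the score. At SHIFT2 = 0 the
   sequential alignment is a subset of the topology-independent matching;
   larger SHIFT2 increases coverage.
5. **TM refinement.** For each candidate alignment of length L_ali, fragments
   of lengths L_ali, L_ali/2, L_ali/4, …, 3 are superimposed, pairs below
   d₀(M) are iteratively re-selected and re-fit, and the transform maximizing
   TM1 + TM2 over all pairs wins, where

   TM-score = (1/L) Σᵢ 1 / (1 + (dᵢ/d₀(L))²),  d₀(L) = max(0.3, 0.6·√(L−0.5) − 2.5)

   TM1 normalizes by *N* (longer chain), TM2 by *M* (shorter).

For *M* > 500 an accelerated mode seeds from every (1 + M // 100)-th
reference residue, extends only 2 × CPUs hits, and raises SHIFT2 to 20 Å.
Non-default modes: `--superonly` scores the trivial 1:1 alignment of
equal-length inputs (conformational changes between states), and
`--addhits T` reports all sub-optimal matchings with TM2 > T (multiple
instances of a small structure inside a large one).

## Worked example

Generate an idealized 10-bp double helix and a circularly permuted copy
(same coordinates, residue order rotated by half), then align them:

```bash
python - <<'EOF'
from rnatopo.fixtures import HelixParams, generate_a_form_helix, circular_permute
from rnatopo.geometry import RigidTransform
from rnatopo.structure_model import write_superposed
m = generate_a_form_helix(HelixParams(n_bp=10))
p, _ = circular_permute(m, 11)
write_superposed(m, RigidTransform.identity(), 'helix.pdb')
write_superposed(p, RigidTransform.identity(), 'permuted.pdb')
EOF
rnatopo helix.pdb permuted.pdb
```

```
Reference: helix.pdb  (20 nucleic residues)
Query    : permuted.pdb  (20 nucleic residues)

=== Sequentially-ordered alignment ===
----------GGGGGGGGGGCCCCCCCCCC
CCCCCCCCCCGGGGGGGGGG----------

TM1-score : 0.500   (normalized by the longer chain)
TM2-score : 0.500   (normalized by the shorter chain)
RMSD      : 0.00 A over 10 aligned C3' pairs
L_ali     : 10   coverage 0.500 / 0.500
Permutation: none

=== Topology-independent alignment ===
A/G1=A/G11 A/G2=A/G12 ... B/C10=A/C10

TM1-score : 1.000   (normalized by the longer chain)
TM2-score : 1.000   (normalized by the shorter chain)
RMSD      : 0.00 A over 20 aligned C3' pairs
L_ali     : 20   coverage 1.000 / 1.000
Permutation: circular

Backbone-permuted similarity detected (topology-independent TM1 > 0.45 and +0.1 over sequential).
```

The sequential alignment can only pick up half the residues (TM 0.500)
because the permuted copy's residue order is rotated; the
topology-independent alignment recovers the full correspondence (TM 1.000),
classifies it as circular, and the permuted-similarity rule
(topology-independent TM1 > 0.45 and ≥ 0.1 above sequential TM1) fires.

Useful flags: `--superonly`, `--addhits 0.3`, `--selection-ref "A:5-70"`,
`--save-superposed out.pdb`, `--save-pairs pairs.tsv`, `--json`,
`--residue-config repr.cfg` (modified-residue pseudo-atom recipes).

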