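# Methods

## Problem and model

`rnatopo` addresses pairwise rigid-body alignment of nucleic-acid 3D
structures. An alignment between structures *X* (N residues) and *Y*
(M ≤ N residues) is a one-to-one set of residue pairs; if two pairs
(i, j) and (k, l) exist with i < k and j > l, the alignment is
*topology-independent* (it cannot be expressed as a conventional sequence
alignment), otherwise it is *sequentially-ordered*. The goal is the
alignment maximizing TM1 + TM2, where

    TM(L) = (1/L) * sum_i 1 / (1 + (d_i / d0(L))^2)

over the aligned C3′–C3′ distances d_i; TM1 uses L = N, TM2 uses L = M,
so TM1 ≤ TM2 and both lie in (0, 1]. The search heuristic assumes the
ideal superposition contains at least one residue pair with near-zero
RMSD — a mild assumption for RNA given its recurrent local geometries —
and is polynomial: all N·M single-residue seed superpositions are
enumerated, and only single-residue seeds are used (no multi-residue seed
generalization).

## Pipeline and parameters

| parameter | default | meaning |
|---|---|---|
| MATCHRANGE1 | 3.5 Å | C3′ cutoff for mutually-closest *hit* pairs under a seed superposition |
| MATCHRANGE2 | 8 Å | C3′ cutoff for the extended matching under the adjusted superposition |
| SHIFT2 | 3 Å | additive margin in the Needleman–Wunsch scoring matrix; higher = more coverage |
| TOPLARGEST | M | number of largest hits extended to candidates |
| STEPDIV | 100 | accelerated-mode stride divisor: STEP = 1 + M // STEPDIV |
| acceleration trigger | M > 500 | switches to STEP-strided seeding, TOPLARGEST = 2×CPUs, SHIFT2 = 20 Å |
| d0 floor | 0.3 Å | lower clamp of d0(L) = 0.6·sqrt(L − 0.5) − 2.5 |
| topo display margin | 10% | topology-independent section shown when its TM2 ≥ 1.1 × sequential TM2 |
| addhits threshold | TM2 > 0.3 | sub-optimal matchings reported in additional-hits mode |

Residues are represented by three pseudo-atoms — phosphate (unweighted
OP1/O5′ midpoint), ribose (C2′/C4′ midpoint), and the glycosidic base
nitrogen (N9 for purines, N1 for pyrimidines) — stored in an editable
configuration so modified residues can be mapped to parents or given
explicit recipes. "Center of mass" of two near-equal-mass atoms is
implemented as the unweighted midpoint. Residues lacking a complete triple
(e.g. 5′-terminal residues without OP1/O5′) cannot seed or re-fit a
superposition but still participate as C3′ match targets; residues without
a C3′ atom are excluded from alignment entirely.

Each candidate topology-independent alignment is the extended matching of
one top hit. The corresponding sequential candidate is the zero-gap-cost
Needleman–Wunsch alignment over S = −D + SHIFT1 + SHIFT2, with SHIFT1 the
largest matched distance; with gap cost 0 a negative-score cell is never
matched, which makes the SHIFT2 = 0 sequential alignment a subset of the
matching, and L_ali monotone non-decreasing in SHIFT2 (both properties are
asserted as tests). Every candidate is refined (below) and the best per
mode by TM1 + TM2 is reported. If the first input is the shorter
structure, roles swap internally and reported pairs follow the caller's
order.

## TM refinement

The minimum-RMSD (Kabsch) fit of all aligned pairs does not generally
maximize the TM score, so the refinement generates candidate transforms
from fragment fits: for each fragment length ℓ in {L_ali, ⌈L_ali/2⌉, …, 3},
every window of ℓ consecutive pairs (pairs ordered by reference index,
window stride ℓ/2) is Kabsch-fit and then iterated — select pairs with
C3′ distance < d0(M), re-fit on the selection — until the selection is
stable, at most 20 iterations, stopping if fewer than 3 pairs qualify.
Sliding windows were chosen over a disjoint partition because every
partition block is also a window, so the maximized score can only improve;
the selection threshold always uses d0(M) while scoring uses d0 of each
score's own normalization length. Reported RMSD is computed over all
aligned pairs under the TM-maximizing transform, not a separate
minimum-RMSD fit. Alignments of fewer than 3 pairs fall back to the plain
all-pair Kabsch fit.

## Numerical choices

- Kabsch via SVD with sign correction of the smallest singular value, so
  the rotation determinant is always +1 (orthonormality tolerance 1e-8);
  collinear point sets still yield a proper rotation and are not
  special-cased — unproductive seeds are filtered by hit size downstream.
- Mutual-closest matching breaks argmin ties to the lower index; hits are
  deduplicated by pair-set equality keeping the first in seed order; the
  minimum hit size kept is 2 (a 1-pair hit cannot be re-superimposed).
- Hit ranking: pair count descending, ties by ascending seed indices;
  Needleman–Wunsch traceback prefers match over skipping a reference
  residue over skipping a query residue. Together these make the whole
  pipeline deterministic; seed enumeration is embarrassingly parallel over
  residue pairs but a deterministic ordering is imposed before ranking, so
  results are identical for any worker count (the current implementation
  executes serially).
- "Circular" permutation is operationalized as: the ranks of the query
  indices, taken in reference order, become strictly increasing after some
  cyclic rotation; monotone = no permutation; otherwise non-circular.
- The permuted-similarity rule (topology-independent TM1 > 0.45 and
  ≥ 0.1 above sequential TM1) and the 10% topo-display margin are applied
  to the final refined scores; the display margin is read as relative
  (TM2_topo ≥ 1.1 × TM2_seq, boundary inclusive) since TM scores are
  ratios. The acceleration trigger follows the strict reading "M exceeds
  500" and is configurable.
- Alternate locations resolve to the highest occupancy (ties by file
  order); only the first model of a file is read; legacy `*` primes in
  atom names are normalized to `'`.
- In additional-hits mode, two matchings sharing more than 50% of the
  smaller one's reference residues are deduplicated keeping the higher
  TM2.

## Synthetic fixtures: what they do and do not show

The fixture generator builds idealized double helices on a cylinder
(defaults: 32.7°/step twist, 2.81 Å rise, 9.4 Å backbone radius —
approximate A-form step parameters), with all pseudo-atom source atoms
placed at fixed local offsets so triples are well separated and
consecutive C3′ spacing falls in a realistic 5–7 Å window. Derived
fixtures renumber residues (circular permutation with exact ground
truth), add per-atom Gaussian noise, apply rigid motions, or duplicate
the helix at 40 Å separation (multi-instance search). The geometry is
schematic: it reproduces the *topological* and *metric* structure the
algorithm consumes (chain connectivity, spacing, rigid sub-units) but not
crystallographic detail, tertiary motifs, non-uniform flexibility, or
missing/modified residues as they occur in real data. Passing tests
therefore demonstrate algorithmic correctness (optimality properties,
permutation recovery, invariances, mode behavior), not benchmark-level
accuracy on experimental structures; the tRNA-like comparison script
(`scripts/trna_benchmark.py`) covers the latter when coordinate files are
supplied.

At 1 Å per-atom noise the extended matching may re-pair neighbours that
the single-seed hit mispaired — correct behavior, but it means strict
hit-containment is only asserted at 0.5 Å noise (98% of 50 replicates),
with matching-size non-shrinkage asserted at 1 Å.

## Problem sizes and defaults used in checks

The automated checks use 5–16 bp helices (10–32 residues), 100-replicate
property loops for the subset and alignment-oracle properties, 10⁴ random
rigid placements per Kabsch optimality case, and 50 replicates for noise
recovery — sizes at which the exhaustive oracles are exact and the full
pipeline runs in seconds.

## Known limitations

- Single-residue seeds only; no multi-residue or clique seeding.
- Rigid-body superposition only; no flexible alignment.
- No protein residue support; proteins in input files are carried through
  to superposed output but never aligned.
- Multi-model files use model 1 only; no ensemble handling.
- The fragment enumeration schedule (sliding windows, stride ℓ/2) is one
  of several defensible readings of "splitting into fragments"; third-
  decimal TM differences against other implementations are possible.
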