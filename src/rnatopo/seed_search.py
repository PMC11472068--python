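"""Seed superpositions and mutually-closest-residue matching.

The query structure is superimposed on the reference from every single
residue pair, using 3-pseudo-atom representations.  Each seed superposition
yields a *hit*: the set of mutually closest residue pairs whose C3'-C3'
distance falls below the tight match range (3.5 A by default).  The largest
hits are re-superimposed on their matched residues and extended into
candidate topology-independent matchings under the loose match range (8 A).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import RigidTransform, kabsch, pairwise_distance_matrix
from .structure_model import ResidueTriple

__all__ = [
    "SeedParams",
    "Hit",
    "Matching",
    "mutual_closest_matching",
    "enumerate_seed_hits",
    "top_hits",
    "extend_hit",
]


@dataclass(frozen=True)
class SeedParams:
    matchrange1: float = 3.5   # tight C3' cutoff for hits, Angstroms
    matchrange2: float = 8.0   # loose C3' cutoff for extended matchings
    toplargest: int | None = None   # None -> M (smaller structure length)
    step: int = 1              # stride over reference residues when seeding

    def __post_init__(self) -> None:
        if self.matchrange1 >= self.matchrange2:
            raise ValueError("matchrange1 must be < matchrange2")
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if self.toplargest is not None and self.toplargest < 1:
            raise ValueError("toplargest must be >= 1")


@dataclass(frozen=True)
class Hit:
    pairs: frozenset[tuple[int, int]]
    seed: tuple[int, int]
    transform: RigidTransform

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class Matching:
    pairs: frozenset[tuple[int, int]]
    transform: RigidTransform

    def __len__(self) -> int:
        return len(self.pairs)


def mutual_closest_matching(
    ref_c3: np.ndarray, qry_c3_transformed: np.ndarray, cutoff: float
) -> set[tuple[int, int]]:
    """Pairs (i, j) where i and j are each other's nearest neighbour and
    their distance is below the cutoff.  Argmin ties break to the lower
    index.  The result is one-to-one by construction."""
    D = pairwise_distance_matrix(ref_c3, qry_c3_transformed)
    nearest_j = D.argmin(axis=1)   # first (lowest) index on ties
    nearest_i = D.argmin(axis=0)
    i_idx = np.arange(D.shape[0])
    mutual = nearest_i[nearest_j[i_idx]] == i_idx
    below = D[i_idx, nearest_j] < cutoff
    return {(int(i), int(nearest_j[i])) for i in i_idx[mutual & below]}


def enumerate_seed_hits(
    x_triples: list[ResidueTriple | None],
    y_triples: list[ResidueTriple | None],
    x_c3: np.ndarray,
    y_c3: np.ndarray,
    params: SeedParams,
) -> list[Hit]:
    """All single-residue seed superpositions and their hits.

    Reference residues are traversed with the configured stride; residues
    lacking a complete pseudo-atom triple cannot define a superposition and
    are skipped as seeds (they still participate as C3' match targets).
    Hits with fewer than 2 pairs are discarded; duplicate hits (identical
    pair sets from different seeds) keep the first in (i, j) seed order.
    """
    hits: list[Hit] = []
    seen: set[frozenset[tuple[int, int]]] = set()
    seedable_j = [j for j, t in enumerate(y_triples) if t is not None]
    any_seed = False
    for i in range(0, len(x_triples), params.step):
        ti = x_triples[i]
        if ti is None:
            continue
        for j in seedable_j:
            any_seed = True
            tj = y_triples[j]
            transform, _ = kabsch(ti.points, tj.points)  # type: ignore[union-attr]
            pairs = mutual_closest_matching(
                x_c3, transform.apply(y_c3), params.matchrange1
            )
            if len(pairs) < 2:
                continue
            key = frozenset(pairs)
            if key in seen:
                continue
            seen.add(key)
            hits.append(Hit(pairs=key, seed=(i, j), transform=transform))
    if not any_seed:
        raise ValueError("no seedable residue pairs (no complete pseudo-atom triples)")
    return hits


def top_hits(hits: list[Hit], toplargest: int) -> list[Hit]:
    """Largest hits first; ties by ascending seed indices; truncated."""
    ordered = sorted(hits, key=lambda h: (-len(h.pairs), h.seed))
    return ordered[:toplargest]


def extend_hit(
    hit: Hit,
    x_triples: list[ResidueTriple | None],
    y_triples: list[ResidueTriple | None],
    x_c3: np.ndarray,
    y_c3: np.ndarray,
    params: SeedParams,
) -> Matching:
    """Re-superimpose on the hit's matched residues and extend the matching.

    The adjusted transform is the Kabsch fit over the concatenated
    3-pseudo-atom triples of all matched residue pairs that carry triples on
    both sides; the extended matching is the mutually-closest set under the
    loose match range.
    """
    ref_pts, mob_pts = [], []
    for i, j in sorted(hit.pairs):
        ti, tj = x_triples[i], y_triples[j]
        if ti is None or tj is None:
            continue
        ref_pts.append(ti.points)
        mob_pts.append(tj.points)
    if not ref_pts:
        raise ValueError("no hit residues carry complete pseudo-atom triples")
    transform, _ = kabsch(np.vstack(ref_pts), np.vstack(mob_pts))
    pairs = mutual_closest_matching(x_c3, transform.apply(y_c3), params.matchrange2)
    return Matching(pairs=frozenset(pairs), transform=transform)
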