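"""Length-normalized structure similarity scoring and TM-maximizing refinement.

For an alignment of L_ali residue pairs with C3'-C3' distances d_i under a
superposition, the score is

    TM = (1 / L_norm) * sum_i 1 / (1 + (d_i / d0(L_norm))^2)

with d0(L) = 0.6 * sqrt(L - 0.5) - 2.5, floored at 0.3 A.  TM1 normalizes by
the longer chain length N, TM2 by the shorter length M, so TM1 <= TM2.

The minimum-RMSD (Kabsch) superposition of all aligned pairs does not in
general maximize the TM score, so the refinement splits the aligned pairs
into fragments of lengths L_ali, L_ali/2, L_ali/4, ... down to 3, fits each
fragment, iteratively re-fits on the pairs falling below d0(M) under the
current transform, and keeps the transform maximizing TM1 + TM2 over all
pairs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .geometry import RigidTransform, kabsch

logger = logging.getLogger(__name__)

__all__ = ["ScoreReport", "d0_rna", "tm_score", "refine_superposition"]

D0_FLOOR = 0.3  # Angstroms; lower clamp of the distance scale
_MAX_REFIT_ITER = 20


@dataclass(frozen=True)
class ScoreReport:
    tm1: float                 # normalized by the longer chain length N
    tm2: float                 # normalized by the shorter chain length M
    rmsd: float                # over all aligned C3' pairs, winning transform
    l_ali: int
    transform: RigidTransform
    per_pair_d: np.ndarray     # aligned C3' distances under the transform


def d0_rna(l_norm: int) -> float:
    """Distance scale of the TM-score denominator for a chain of given length."""
    if l_norm < 1:
        raise ValueError("normalization length must be >= 1")
    return max(D0_FLOOR, 0.6 * math.sqrt(l_norm - 0.5) - 2.5)


def tm_score(per_pair_d: np.ndarray, l_norm: int) -> float:
    """Sum of 1/(1+(d_i/d0)^2) contributions over aligned pairs, over L_norm."""
    d = np.asarray(per_pair_d, dtype=float)
    if l_norm < len(d):
        raise ValueError("normalization length shorter than the alignment")
    if len(d) == 0:
        return 0.0
    d0 = d0_rna(l_norm)
    return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / l_norm)


def _fragment_lengths(l_ali: int) -> list[int]:
    """l_ali, ceil(l/2), ceil(l/4), ... down to (and including) 3."""
    lengths = []
    l = l_ali
    while l > 3:
        lengths.append(l)
        l = math.ceil(l / 2)
    lengths.append(max(l, 3) if l_ali >= 3 else l_ali)
    return lengths


def _refit_on_close_pairs(
    ref: np.ndarray, mob: np.ndarray, transform: RigidTransform, d_cut: float
) -> RigidTransform:
    """Iterate {select pairs with distance < d_cut; Kabsch on selection}
    until the selected set stabilizes (or the iteration cap)."""
    selected: frozenset[int] | None = None
    for _ in range(_MAX_REFIT_ITER):
        d = np.linalg.norm(transform.apply(mob) - ref, axis=1)
        new = frozenset(np.flatnonzero(d < d_cut).tolist())
        if len(new) < 3 or new == selected:
            break
        selected = new
        idx = sorted(new)
        transform, _ = kabsch(ref[idx], mob[idx])
    return transform


def refine_superposition(
    x_c3: np.ndarray,
    y_c3: np.ndarray,
    pairs,
    n: int,
    m: int,
) -> ScoreReport:
    """TM-maximizing superposition of an alignment's C3' pairs.

    ``x_c3``/``y_c3`` are the full C3' coordinate arrays of the reference
    and query; ``pairs`` the aligned (i, j) index pairs; ``n``/``m`` the
    chain lengths used for TM1/TM2 normalization (n >= m).  The candidate
    transforms are the all-pair Kabsch fit plus, for every fragment window
    (stride half the window length), the converged close-pair refit; the
    selection threshold is d0(m).  Scores are evaluated over ALL pairs.
    """
    ordered = sorted(pairs)
    if not ordered:
        raise ValueError("empty alignment")
    ref = np.asarray(x_c3, dtype=float)[[i for i, _ in ordered]]
    mob = np.asarray(y_c3, dtype=float)[[j for _, j in ordered]]
    l_ali = len(ordered)

    candidates: list[RigidTransform] = []
    all_fit, _ = kabsch(ref, mob)
    candidates.append(all_fit)

    if l_ali < 3:
        logger.info("alignment of %d pairs: plain Kabsch only", l_ali)
    else:
        d_cut = d0_rna(m)
        for frag_len in _fragment_lengths(l_ali):
            stride = max(1, frag_len // 2)
            for start in range(0, l_ali - frag_len + 1, stride):
                window = slice(start, start + frag_len)
                t, _ = kabsch(ref[window], mob[window])
                candidates.append(_refit_on_close_pairs(ref, mob, t, d_cut))

    best: tuple[float, int] | None = None
    best_d: np.ndarray | None = None
    for idx, t in enumerate(candidates):
        d = np.linalg.norm(t.apply(mob) - ref, axis=1)
        total = tm_score(d, n) + tm_score(d, m)
        if best is None or total > best[0] + 1e-12:
            best = (total, idx)
            best_d = d
    assert best is not None and best_d is not None
    winner = candidates[best[1]]
    return ScoreReport(
        tm1=tm_score(best_d, n),
        tm2=tm_score(best_d, m),
        rmsd=float(np.sqrt(np.mean(best_d**2))),
        l_ali=l_ali,
        transform=winner,
        per_pair_d=best_d,
    )
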