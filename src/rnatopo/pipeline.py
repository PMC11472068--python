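"""End-to-end orchestration: seed search, hit extension, candidate alignment
construction, TM refinement, mode selection, and the accelerated-parameter
heuristic for long chains.

The pipeline assigns reference/query roles so the reference is the longer
structure (N >= M); if the caller's first input is shorter the roles swap
internally and swap back in the reported pairs.  All stages are
deterministic given inputs and configuration.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace

import numpy as np

from .alignment import (
    AlignmentResult,
    Permutation,
    build_scoring_matrix,
    needleman_wunsch,
    sequential_alignment,
    topology_independent_alignment,
)
from .geometry import pairwise_distance_matrix
from .seed_search import (
    Hit,
    Matching,
    SeedParams,
    enumerate_seed_hits,
    extend_hit,
    top_hits,
)
from .structure_model import Residue, ResidueRepresentation, residue_triple
from .tmscore import ScoreReport, refine_superposition

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunResult", "accelerated_config", "align_pair",
           "superonly", "addhits"]


@dataclass(frozen=True)
class RunConfig:
    matchrange1: float = 3.5
    matchrange2: float = 8.0
    shift2: float = 3.0           # Angstroms, NW scoring-matrix margin
    stepdiv: int = 100
    step: int = 1
    toplargest: int | None = None  # None -> M
    accel_threshold: int = 500     # accelerate when M exceeds this
    topo_display_margin: float = 0.10
    addhits_threshold: float = 0.3  # TM2 cutoff for additional hits
    cpu_count: int | None = None    # None -> os.cpu_count()
    representation: ResidueRepresentation = field(
        default_factory=ResidueRepresentation
    )

    @property
    def cpus(self) -> int:
        return self.cpu_count or os.cpu_count() or 1


@dataclass(frozen=True)
class RunResult:
    sequential: tuple[AlignmentResult, ScoreReport] | None
    topology_independent: tuple[AlignmentResult, ScoreReport] | None
    show_topo: bool
    n: int                       # longer selection length
    m: int                       # shorter selection length
    swapped: bool                # True if the user's first input was shorter

    @property
    def permuted_similarity(self) -> bool:
        from .alignment import permuted_similarity_flag

        if self.sequential is None or self.topology_independent is None:
            return False
        return permuted_similarity_flag(
            self.topology_independent[1].tm1, self.sequential[1].tm1
        )


def accelerated_config(m: int, cpu: int, base: RunConfig) -> RunConfig:
    """Fast-mode parameter adjustment for long chains.

    When the shorter structure exceeds the acceleration threshold (500
    residues by default): seed from every STEP-th reference residue with
    STEP = 1 + M // STEPDIV, extend only the 2 x CPUs largest hits, and
    raise SHIFT2 to 20 A to capture flexible regions of long chains.
    Below the threshold the configuration is returned unchanged.
    """
    if m <= base.accel_threshold:
        return base
    return replace(
        base,
        step=1 + m // base.stepdiv,
        toplargest=2 * cpu,
        shift2=20.0,
    )


def _prepare(residues: list[Residue], cfg: RunConfig):
    """Residues with a C3' atom, their original indices, triples and C3'
    coordinates.  Pair indices reported by the pipeline refer to the
    caller's residue lists via the returned index map."""
    kept_idx, triples, c3 = [], [], []
    for orig, r in enumerate(residues):
        t = residue_triple(r, cfg.representation)
        a = r.atom("C3'")
        if a is None:
            logger.debug("residue %r lacks C3'; excluded", r)
            continue
        kept_idx.append(orig)
        triples.append(t)
        c3.append(a.coord)
    return kept_idx, triples, np.asarray(c3, dtype=float).reshape(-1, 3)


def _empty_result(n: int, m: int, swapped: bool) -> RunResult:
    logger.warning("no alignment found")
    return RunResult(sequential=None, topology_independent=None,
                     show_topo=False, n=n, m=m, swapped=swapped)


def align_pair(
    x_residues: list[Residue],
    y_residues: list[Residue],
    cfg: RunConfig | None = None,
) -> RunResult:
    """Full pairwise alignment: optimal sequentially-ordered and optimal
    topology-independent alignment, each with its TM-maximizing superposition.

    Every extended matching from the top hits yields two candidates — the
    matching itself (topology-independent) and the Needleman-Wunsch
    alignment over its adjusted superposition (sequentially-ordered) — and
    every candidate is refined; the best candidate per mode by TM1 + TM2 is
    reported.
    """
    cfg = cfg or RunConfig()
    if not x_residues or not y_residues:
        raise ValueError("both residue selections must be non-empty")

    swapped = len(x_residues) < len(y_residues)
    ref_res, qry_res = (y_residues, x_residues) if swapped else (x_residues, y_residues)

    ref_idx, ref_triples, ref_c3 = _prepare(ref_res, cfg)
    qry_idx, qry_triples, qry_c3 = _prepare(qry_res, cfg)
    n, m = len(ref_idx), len(qry_idx)
    if n == 0 or m == 0:
        raise ValueError("no residues with C3' atoms in one of the selections")

    cfg = accelerated_config(m, cfg.cpus, cfg)
    params = SeedParams(
        matchrange1=cfg.matchrange1,
        matchrange2=cfg.matchrange2,
        step=cfg.step,
        toplargest=cfg.toplargest,
    )
    hits = enumerate_seed_hits(ref_triples, qry_triples, ref_c3, qry_c3, params)
    if not hits:
        return _empty_result(n, m, swapped)
    selected = top_hits(hits, params.toplargest or m)

    best_seq: tuple[AlignmentResult, ScoreReport] | None = None
    best_topo: tuple[AlignmentResult, ScoreReport] | None = None
    for hit in selected:
        try:
            matching = extend_hit(hit, ref_triples, qry_triples, ref_c3, qry_c3,
                                  params)
        except ValueError:
            continue
        if not matching.pairs:
            continue
        # topology-independent candidate: the extended matching itself
        topo_aln = topology_independent_alignment(matching, n, m)
        topo_rep = refine_superposition(ref_c3, qry_c3, topo_aln.pairs, n, m)
        if best_topo is None or topo_rep.tm1 + topo_rep.tm2 > (
            best_topo[1].tm1 + best_topo[1].tm2 + 1e-12
        ):
            best_topo = (topo_aln, topo_rep)
        # sequential candidate: NW over the adjusted superposition
        dist = pairwise_distance_matrix(ref_c3, matching.transform.apply(qry_c3))
        S = build_scoring_matrix(dist, set(matching.pairs), cfg.shift2)
        nw_pairs, _ = needleman_wunsch(S)
        if not nw_pairs:
            continue
        seq_aln = sequential_alignment(nw_pairs, n, m)
        seq_rep = refine_superposition(ref_c3, qry_c3, seq_aln.pairs, n, m)
        if best_seq is None or seq_rep.tm1 + seq_rep.tm2 > (
            best_seq[1].tm1 + best_seq[1].tm2 + 1e-12
        ):
            best_seq = (seq_aln, seq_rep)

    if best_seq is None and best_topo is None:
        return _empty_result(n, m, swapped)

    show_topo = False
    if best_seq is not None and best_topo is not None:
        show_topo = best_topo[1].tm2 >= (1.0 + cfg.topo_display_margin) * best_seq[1].tm2

    def remap(entry):
        if entry is None:
            return None
        aln, rep = entry
        pairs = [(ref_idx[i], qry_idx[j]) for i, j in aln.pairs]
        if swapped:
            pairs = [(j, i) for i, j in pairs]
        return replace(aln, pairs=tuple(sorted(pairs))), rep

    best_seq = remap(best_seq)
    best_topo = remap(best_topo)
    return RunResult(
        sequential=best_seq,
        topology_independent=best_topo,
        show_topo=show_topo,
        n=n,
        m=m,
        swapped=swapped,
    )


def superonly(
    x_residues: list[Residue],
    y_residues: list[Residue],
    cfg: RunConfig | None = None,
) -> ScoreReport:
    """Score the trivial positional alignment between equal-length inputs.

    No seed search: residue i of the first input pairs with residue i of
    the second, and the TM-maximizing refinement is applied.  Intended for
    conformational-change assessment between states of the same molecule.
    """
    cfg = cfg or RunConfig()
    _, _, x_c3 = _prepare(x_residues, cfg)
    _, _, y_c3 = _prepare(y_residues, cfg)
    if len(x_c3) != len(y_c3):
        raise ValueError(
            f"superposition-only mode needs equal lengths, got {len(x_c3)} "
            f"and {len(y_c3)} residues with C3' atoms"
        )
    if len(x_c3) == 0:
        raise ValueError("no residues with C3' atoms")
    pairs = [(i, i) for i in range(len(x_c3))]
    l = len(pairs)
    return refine_superposition(x_c3, y_c3, pairs, l, l)


def addhits(
    x_residues: list[Residue],
    y_residues: list[Residue],
    cfg: RunConfig | None = None,
) -> list[tuple[Matching, ScoreReport]]:
    """All refined sub-optimal matchings with TM2 above the threshold.

    Used to find multiple instances of the smaller structure within the
    larger one.  Matchings sharing more than half of their reference
    residues are deduplicated, keeping the higher TM2; results are sorted
    by TM2 descending.
    """
    cfg = cfg or RunConfig()
    swapped = len(x_residues) < len(y_residues)
    ref_res, qry_res = (y_residues, x_residues) if swapped else (x_residues, y_residues)
    ref_idx, ref_triples, ref_c3 = _prepare(ref_res, cfg)
    qry_idx, qry_triples, qry_c3 = _prepare(qry_res, cfg)
    n, m = len(ref_idx), len(qry_idx)
    if n == 0 or m == 0:
        raise ValueError("no residues with C3' atoms in one of the selections")

    cfg = accelerated_config(m, cfg.cpus, cfg)
    params = SeedParams(
        matchrange1=cfg.matchrange1,
        matchrange2=cfg.matchrange2,
        step=cfg.step,
        toplargest=cfg.toplargest,
    )
    hits = enumerate_seed_hits(ref_triples, qry_triples, ref_c3, qry_c3, params)
    scored: list[tuple[Matching, ScoreReport]] = []
    for hit in top_hits(hits, params.toplargest or m):
        try:
            matching = extend_hit(hit, ref_triples, qry_triples, ref_c3, qry_c3,
                                  params)
        except ValueError:
            continue
        if not matching.pairs:
            continue
        rep = refine_superposition(ref_c3, qry_c3, matching.pairs, n, m)
        if rep.tm2 > cfg.addhits_threshold:
            scored.append((matching, rep))

    scored.sort(key=lambda t: (-t[1].tm2, sorted(t[0].pairs)))
    kept: list[tuple[Matching, ScoreReport]] = []
    for matching, rep in scored:
        refs = {i for i, _ in matching.pairs}
        dominated = False
        for km, _ in kept:
            krefs = {i for i, _ in km.pairs}
            if len(refs & krefs) > 0.5 * min(len(refs), len(krefs)):
                dominated = True
                break
        if not dominated:
            kept.append((matching, rep))

    def remap(matching: Matching) -> Matching:
        pairs = [(ref_idx[i], qry_idx[j]) for i, j in matching.pairs]
        if swapped:
            pairs = [(j, i) for i, j in pairs]
        return Matching(pairs=frozenset(pairs), transform=matching.transform)

    return [(remap(m_), rep) for m_, rep in kept]
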