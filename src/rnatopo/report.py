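"""Text report rendering: structure summaries, gapped sequence alignments,
score blocks, and the matched-residue table."""

from __future__ import annotations

import numpy as np

from .alignment import AlignmentResult
from .pipeline import RunResult
from .structure_model import MODIFIED_PARENTS, Residue
from .tmscore import ScoreReport

__all__ = ["one_letter", "render_alignment_rows", "render_report",
           "matched_residue_table", "result_to_dict"]

_ONE_LETTER = {"A": "A", "G": "G", "C": "C", "U": "U", "T": "T",
               "DA": "A", "DG": "G", "DC": "C", "DT": "T"}


def one_letter(res_name: str) -> str:
    """One-letter code; modified residues lower-case their parent, unknown 'n'."""
    name = res_name.strip().upper()
    if name in _ONE_LETTER:
        return _ONE_LETTER[name]
    parent = MODIFIED_PARENTS.get(name)
    if parent in _ONE_LETTER:
        return _ONE_LETTER[parent].lower()
    return "n"


def render_alignment_rows(
    ref: list[Residue], qry: list[Residue], pairs, width: int = 60
) -> str:
    """Gapped two-row rendering of a sequentially-ordered alignment."""
    top, bottom = [], []
    pi, pj = -1, -1
    for i, j in sorted(pairs):
        for k in range(pi + 1, i):
            top.append(one_letter(ref[k].res_name))
            bottom.append("-")
        for l in range(pj + 1, j):
            top.append("-")
            bottom.append(one_letter(qry[l].res_name))
        top.append(one_letter(ref[i].res_name))
        bottom.append(one_letter(qry[j].res_name))
        pi, pj = i, j
    for k in range(pi + 1, len(ref)):
        top.append(one_letter(ref[k].res_name))
        bottom.append("-")
    for l in range(pj + 1, len(qry)):
        top.append("-")
        bottom.append(one_letter(qry[l].res_name))
    lines = []
    for start in range(0, len(top), width):
        lines.append("".join(top[start:start + width]))
        lines.append("".join(bottom[start:start + width]))
        lines.append("")
    return "\n".join(lines).rstrip()


def _score_block(aln: AlignmentResult, rep: ScoreReport) -> str:
    return "\n".join([
        f"TM1-score : {rep.tm1:.3f}   (normalized by the longer chain)",
        f"TM2-score : {rep.tm2:.3f}   (normalized by the shorter chain)",
        f"RMSD      : {rep.rmsd:.2f} A over {rep.l_ali} aligned C3' pairs",
        f"L_ali     : {aln.l_ali}   coverage {aln.coverage1:.3f} / "
        f"{aln.coverage2:.3f}",
        f"Permutation: {aln.permutation.value}",
    ])


def matched_residue_table(
    ref: list[Residue], qry: list[Residue], pairs, per_pair_d: np.ndarray
) -> str:
    """Tab-separated matched-residue list: reference id, query id, C3'
    distance in Angstroms to 3 decimals, one row per aligned pair."""
    rows = ["ref\tqry\tdist_A"]
    for (i, j), d in zip(sorted(pairs), per_pair_d):
        rows.append(f"{ref[i]!r}\t{qry[j]!r}\t{d:.3f}")
    return "\n".join(rows) + "\n"


def render_report(
    result: RunResult,
    ref_name: str,
    qry_name: str,
    ref: list[Residue],
    qry: list[Residue],
    show_topo: bool | None = None,
) -> str:
    """Full text report; the topology-independent section appears when
    requested or when its TM2 beats the sequential TM2 by the display margin."""
    lines = [
        f"Reference: {ref_name}  ({len(ref)} nucleic residues)",
        f"Query    : {qry_name}  ({len(qry)} nucleic residues)",
        "",
    ]
    if result.sequential is None and result.topology_independent is None:
        lines.append("No alignment found (no seed hits); all scores zero.")
        return "\n".join(lines)

    if result.sequential is not None:
        aln, rep = result.sequential
        lines += ["=== Sequentially-ordered alignment ===",
                  render_alignment_rows(ref, qry, aln.pairs), "",
                  _score_block(aln, rep), ""]
    display_topo = result.show_topo if show_topo is None else show_topo
    if display_topo and result.topology_independent is not None:
        aln, rep = result.topology_independent
        pair_text = " ".join(f"{ref[i]!r}={qry[j]!r}" for i, j in aln.pairs)
        lines += ["=== Topology-independent alignment ===",
                  pair_text, "", _score_block(aln, rep), ""]
    if result.permuted_similarity:
        lines.append("Backbone-permuted similarity detected "
                     "(topology-independent TM1 > 0.45 and +0.1 over sequential).")
    return "\n".join(lines).rstrip() + "\n"


def result_to_dict(result: RunResult) -> dict:
    """Machine-readable summary of a run."""
    def pack(entry):
        if entry is None:
            return None
        aln, rep = entry
        return {
            "pairs": [list(p) for p in aln.pairs],
            "mode": aln.mode,
            "permutation": aln.permutation.value,
            "l_ali": aln.l_ali,
            "coverage1": aln.coverage1,
            "coverage2": aln.coverage2,
            "tm1": rep.tm1,
            "tm2": rep.tm2,
            "rmsd": rep.rmsd,
        }

    return {
        "n": result.n,
        "m": result.m,
        "sequential": pack(result.sequential),
        "topology_independent": pack(result.topology_independent),
        "show_topo": result.show_topo,
        "permuted_similarity": result.permuted_similarity,
    }
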