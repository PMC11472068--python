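#!/usr/bin/env python
"""Topology-independent superposition of a tRNA against five tRNA-like RNAs,
plus superposition-only conformational-change scores between states of the
BMV tRNA-like RNA.

Requires locally downloaded coordinate files (e.g. from the PDB archive:
1IVS, 2CZJ, 3ADD, 4P5J, 6CU1, 7SAM, 7SC6, 7SCQ) in one directory as
``<pdbid>.cif`` or ``<pdbid>.pdb`` (lower-case ids).

Usage:
    python scripts/trna_benchmark.py --data-dir path/to/structures
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

from rnatopo.pipeline import align_pair, superonly
from rnatopo.structure_model import parse_structure, select_residues

PAIRS = [("2czj", "B"), ("3add", "C"), ("4p5j", "A"), ("6cu1", "A"), ("7sam", "A")]
STATES = [("7sc6", "C", "7scq", "C"), ("7sam", "A", "7sc6", "C"),
          ("7sam", "A", "7scq", "C")]


def load_chain(data_dir: Path, pdb_id: str, chain: str):
    for suffix in (".cif", ".pdb"):
        path = data_dir / f"{pdb_id}{suffix}"
        if path.exists():
            return select_residues(parse_structure(path), chain)
    raise FileNotFoundError(f"{pdb_id}.cif / {pdb_id}.pdb not in {data_dir}")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data-dir", type=Path, required=True)
    parser.add_argument("--out", type=Path, default=None)
    args = parser.parse_args()

    out: dict[str, dict] = {}
    ref = load_chain(args.data_dir, "1ivs", "C")
    for pdb_id, chain in PAIRS:
        qry = load_chain(args.data_dir, pdb_id, chain)
        result = align_pair(ref, qry)
        aln, rep = result.topology_independent
        out[f"topo_{pdb_id}{chain}"] = {
            "tm1": round(rep.tm1, 3), "tm2": round(rep.tm2, 3),
            "rmsd": round(rep.rmsd, 2), "l_ali": rep.l_ali,
            "permutation": aln.permutation.value,
        }
    for id1, ch1, id2, ch2 in STATES:
        rep = superonly(load_chain(args.data_dir, id1, ch1),
                        load_chain(args.data_dir, id2, ch2))
        out[f"superonly_{id1}{ch1}_{id2}{ch2}"] = {
            "tm": round(rep.tm2, 3), "rmsd": round(rep.rmsd, 2),
        }

    text = json.dumps(out, indent=2)
    print(text)
    if args.out:
        args.out.write_text(text + "\n")


if __name__ == "__main__":
    main()
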