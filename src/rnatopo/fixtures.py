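"""Synthetic nucleic-acid structures with known ground truth.

The generators build idealized double helices on a cylinder with
approximately A-form step parameters.  The geometry is schematic — tests
assert topology and recovery properties, never absolute coordinates — but
every residue carries the atoms the alignment pipeline consumes (OP1, O5',
C2', C4', C3', and the glycosidic nitrogen), and the writer emits standard
PDB so fixtures also exercise the parser.
"""

from __future__ import annotations

from dataclasses import dataclass

import gemmi
import numpy as np

from .structure_model import (
    Residue,
    ResidueRepresentation,
    StructureModel,
    _model_from_gemmi,
)

__all__ = [
    "HelixParams",
    "generate_a_form_helix",
    "circular_permute",
    "perturb",
    "rigid_copy",
    "two_instance_reference",
]


@dataclass(frozen=True)
class HelixParams:
    n_bp: int = 10
    twist: float = 32.7       # degrees per step
    rise: float = 2.81        # Angstroms per step
    radius: float = 9.4       # backbone radius, Angstroms
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bp < 1:
            raise ValueError("n_bp must be >= 1")
        if self.rise <= 0:
            raise ValueError("rise must be positive")


# Local atom offsets (radial, tangential, axial) from the residue's backbone
# anchor; chosen so the 3 pseudo-atoms are well separated and non-collinear.
_ATOM_OFFSETS = {
    "P":   (0.8, -0.9, -1.2),
    "OP1": (1.9, -1.1, -1.6),
    "O5'": (0.3, -0.5, -1.9),
    "C5'": (0.1, -0.2, -1.1),
    "C4'": (0.0, 0.0, 0.0),
    "C3'": (0.6, 0.9, 0.6),
    "C2'": (-0.9, 1.0, 0.2),
    "C1'": (-1.6, 0.3, -0.4),
    "O2'": (-1.2, 2.2, 0.7),
}
_GLYCO_OFFSET = (-3.0, 0.4, -0.6)  # N9/N1, pointing toward the helix axis


def _place_chain(
    n: int, twist: float, rise: float, radius: float,
    phase_deg: float, direction: int, handed: int,
) -> list[dict[str, np.ndarray]]:
    residues = []
    for k in range(n):
        theta = np.deg2rad(handed * k * twist + phase_deg)
        z = direction * k * rise
        # local frame at the backbone anchor: radial (outward), tangential, axial
        radial = np.array([np.cos(theta), np.sin(theta), 0.0])
        tangential = np.array([-np.sin(theta), np.cos(theta), 0.0]) * handed
        axial = np.array([0.0, 0.0, float(direction)])
        anchor = radius * radial + np.array([0.0, 0.0, z])
        atoms = {}
        for name, (dr, dt, dz) in _ATOM_OFFSETS.items():
            atoms[name] = anchor + dr * radial + dt * tangential + dz * axial
        atoms["_glyco"] = (
            anchor
            + _GLYCO_OFFSET[0] * radial
            + _GLYCO_OFFSET[1] * tangential
            + _GLYCO_OFFSET[2] * axial
        )
        residues.append(atoms)
    return residues


def _build_structure(
    chains: dict[str, list[tuple[str, int, dict[str, np.ndarray]]]],
    entry_id: str,
) -> StructureModel:
    st = gemmi.Structure()
    st.name = entry_id
    model = gemmi.Model(1)
    for chain_id, residues in chains.items():
        chain = gemmi.Chain(chain_id)
        for res_name, seq_num, atom_map in residues:
            res = gemmi.Residue()
            res.name = res_name
            res.seqid = gemmi.SeqId(seq_num, " ")
            res.het_flag = "A"
            glyco_name = "N9" if res_name in ("A", "G") else "N1"
            for atom_name, coord in atom_map.items():
                atom = gemmi.Atom()
                atom.name = glyco_name if atom_name == "_glyco" else atom_name
                atom.element = gemmi.Element(
                    (glyco_name if atom_name == "_glyco" else atom_name)[0]
                )
                atom.pos = gemmi.Position(*coord)
                atom.occ = 1.0
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return _model_from_gemmi(st, "pdb", ResidueRepresentation(), entry_id)


def generate_a_form_helix(p: HelixParams) -> StructureModel:
    """Build a two-chain antiparallel idealized helix of ``n_bp`` base pairs.

    Chain A runs 5'->3' up the axis with G residues; chain B runs back down
    with C residues, rotated half a turn so the strands interleave.
    Deterministic given the parameters.
    """
    strand_a = _place_chain(p.n_bp, p.twist, p.rise, p.radius,
                            phase_deg=0.0, direction=+1, handed=+1)
    strand_b = _place_chain(p.n_bp, p.twist, p.rise, p.radius,
                            phase_deg=160.0, direction=+1, handed=+1)
    # antiparallel: chain B residues listed 3'->5' along +z, so reverse order
    strand_b = strand_b[::-1]
    chains = {
        "A": [("G", i + 1, atoms) for i, atoms in enumerate(strand_a)],
        "B": [("C", i + 1, atoms) for i, atoms in enumerate(strand_b)],
    }
    return _build_structure(chains, f"helix{p.n_bp}")


def circular_permute(
    model: StructureModel, k: int
) -> tuple[StructureModel, dict[int, int]]:
    """Renumber the model's residues so file order becomes k.., then 1..k-1.

    Residue order is taken over the whole model (file order across chains);
    the permuted copy is a single chain renumbered 1..n with coordinates
    bit-identical to the input.  Returns the copy and the ground-truth
    mapping from original flat index to permuted flat index (0-based).
    """
    residues = model.residues()
    n = len(residues)
    if not (1 <= k <= n):
        raise ValueError(f"break index k={k} outside 1..{n}")
    order = list(range(k - 1, n)) + list(range(k - 1))
    truth = {orig: new for new, orig in enumerate(order)}
    permuted = [
        (residues[o].res_name, new + 1, {a.name: a.coord for a in residues[o].atoms})
        for new, o in enumerate(order)
    ]
    return _build_structure({"A": permuted}, f"{model.entry_id}_cp{k}"), truth


def perturb(model: StructureModel, sigma: float, seed: int) -> StructureModel:
    """Apply independent Gaussian displacement (std ``sigma`` per axis) to
    every atom.  Deterministic given the seed."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    chains: dict[str, list[tuple[str, int, dict[str, np.ndarray]]]] = {}
    for chain_id, residues in model.chains.items():
        out = []
        for r in residues:
            atoms = {
                a.name: a.coord + rng.normal(0.0, sigma, size=3) for a in r.atoms
            }
            out.append((r.res_name, r.seq_number, atoms))
        chains[chain_id] = out
    return _build_structure(chains, f"{model.entry_id}_s{sigma}")


def rigid_copy(
    model: StructureModel, rotation: np.ndarray, translation: np.ndarray
) -> StructureModel:
    """Apply a rigid motion to every atom; useful for invariance tests."""
    R = np.asarray(rotation, dtype=float)
    t = np.asarray(translation, dtype=float)
    chains: dict[str, list[tuple[str, int, dict[str, np.ndarray]]]] = {}
    for chain_id, residues in model.chains.items():
        chains[chain_id] = [
            (r.res_name, r.seq_number, {a.name: R @ a.coord + t for a in r.atoms})
            for r in residues
        ]
    return _build_structure(chains, f"{model.entry_id}_rt")


def two_instance_reference(p: HelixParams, separation: float = 40.0) -> StructureModel:
    """A reference containing two rigid copies of the helix ``separation``
    Angstroms apart along x, as distinct chains; used for multi-instance
    search fixtures.  The separation must exceed twice the extended match
    range so the two copies cannot share a matching."""
    base = generate_a_form_helix(p)
    offset = np.array([separation, 0.0, 0.0])
    chains: dict[str, list[tuple[str, int, dict[str, np.ndarray]]]] = {}
    for suffix, shift in (("", np.zeros(3)), ("2", offset)):
        for chain_id, residues in base.chains.items():
            chains[chain_id + suffix if suffix else chain_id] = [
                (r.res_name, r.seq_number, {a.name: a.coord + shift for a in r.atoms})
                for r in residues
            ]
    # gemmi chain ids: A, B, A2, B2 -> rename to single letters
    renamed = dict(zip(["A", "B", "C", "D"], chains.values()))
    return _build_structure(renamed, f"helix2x{p.n_bp}")
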