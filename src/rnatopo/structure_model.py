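"""Nucleic-acid structure model: PDB/mmCIF parsing, residue selection,
3-pseudo-atom residue representations, and writing of superposed coordinates.

Only the first model of a coordinate file is retained.  Non-nucleic residues
(amino acids, waters, ions, ligands) are excluded from the default residue
list but kept in the underlying file object so superposed output can include
them.  Alternate locations are resolved to the highest-occupancy conformer
(ties broken by file order).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .geometry import RigidTransform

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "Residue",
    "StructureModel",
    "ResidueRepresentation",
    "ResidueTriple",
    "parse_structure",
    "select_residues",
    "residue_triple",
    "write_superposed",
    "load_representation_config",
]


@dataclass(frozen=True)
class AtomRecord:
    name: str
    element: str
    coord: np.ndarray  # (3,) Angstroms
    altloc: str = ""
    occupancy: float = 1.0


@dataclass
class Residue:
    chain_id: str
    seq_number: int
    insertion_code: str
    res_name: str
    atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def ident(self) -> tuple[str, int, str]:
        """Author identity used in reports: (chain, number, insertion code)."""
        return (self.chain_id, self.seq_number, self.insertion_code)

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def __repr__(self) -> str:  # compact: A/G15
        ic = self.insertion_code or ""
        return f"{self.chain_id}/{self.res_name}{self.seq_number}{ic}"


@dataclass
class StructureModel:
    entry_id: str
    chains: dict[str, list[Residue]]  # insertion-ordered, file order
    source_format: str  # "pdb" | "mmcif"
    raw: gemmi.Structure | None = None  # full first-model structure for output

    def residues(self) -> list[Residue]:
        """All nucleic residues in file order."""
        return [r for ch in self.chains.values() for r in ch]

    def __len__(self) -> int:
        return sum(len(ch) for ch in self.chains.values())


# --- residue representation -------------------------------------------------

# One-letter parents for common modified nucleotides; user configs extend this.
MODIFIED_PARENTS: dict[str, str] = {
    "PSU": "U", "H2U": "U", "4SU": "U", "5MU": "U", "OMU": "U", "UR3": "U",
    "1MA": "A", "2MA": "A", "MA6": "A", "6MZ": "A", "A2M": "A",
    "5MC": "C", "OMC": "C", "4OC": "C",
    "1MG": "G", "2MG": "G", "M2G": "G", "7MG": "G", "OMG": "G", "G7M": "G",
    "YG": "G", "QUO": "G", "I": "G", "T6A": "A", "MIA": "A",
}

_PURINE_PARENTS = {"A", "G", "DA", "DG"}

_STANDARD_RECIPES: dict[str, tuple[list[str], list[str], list[str]]] = {}
for _name in ("A", "G", "C", "U", "T", "DA", "DG", "DC", "DT"):
    _glyco = "N9" if _name in _PURINE_PARENTS else "N1"
    _STANDARD_RECIPES[_name] = (["OP1", "O5'"], ["C2'", "C4'"], [_glyco])


@dataclass
class ResidueRepresentation:
    """Mapping of residue names to 3-pseudo-atom recipes.

    Each recipe defines the phosphate, ribose, and base points as the
    unweighted centroid of named atoms: by default the OP1/O5' midpoint,
    the C2'/C4' midpoint, and the glycosidic base nitrogen (N9 for purines,
    N1 for pyrimidines).  Unknown residue names fall back through the
    modified-residue parent table.
    """

    recipes: dict[str, tuple[list[str], list[str], list[str]]] = field(
        default_factory=lambda: dict(_STANDARD_RECIPES)
    )
    parents: dict[str, str] = field(default_factory=lambda: dict(MODIFIED_PARENTS))

    def recipe_for(self, res_name: str) -> tuple[list[str], list[str], list[str]] | None:
        name = res_name.strip().upper()
        if name in self.recipes:
            return self.recipes[name]
        parent = self.parents.get(name)
        if parent is not None and parent in self.recipes:
            return self.recipes[parent]
        return None

    def is_nucleic(self, res_name: str) -> bool:
        return self.recipe_for(res_name) is not None


def load_representation_config(path: str | Path) -> ResidueRepresentation:
    """Load a residue-representation config from a structured text file.

    Two line forms are accepted (``#`` comments, blank lines ignored)::

        RES = parent PARENT            # map a modified residue to a parent
        RES = P_ATOMS | R_ATOMS | B_ATOMS   # explicit recipe, atoms comma-split

    e.g. ``PSU = parent U`` or ``XYZ = OP1,O5' | C2',C4' | N1``.
    """
    repr_ = ResidueRepresentation()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'NAME = ...'")
        name, rhs = (s.strip() for s in line.split("=", 1))
        name = name.upper()
        if rhs.lower().startswith("parent "):
            repr_.parents[name] = rhs.split(None, 1)[1].strip().upper()
            continue
        groups = [g.strip() for g in rhs.split("|")]
        if len(groups) != 3:
            raise ValueError(f"{path}:{lineno}: recipe needs 3 '|'-separated groups")
        recipe = tuple([a.strip() for a in g.split(",") if a.strip()] for g in groups)
        if any(not g for g in recipe):
            raise ValueError(f"{path}:{lineno}: empty pseudo-atom group")
        repr_.recipes[name] = recipe  # type: ignore[assignment]
    return repr_


@dataclass(frozen=True)
class ResidueTriple:
    """3-pseudo-atom representation of one residue plus its C3' coordinate."""

    p_point: np.ndarray
    r_point: np.ndarray
    b_point: np.ndarray
    c3: np.ndarray
    owner: Residue

    @property
    def points(self) -> np.ndarray:
        return np.vstack([self.p_point, self.r_point, self.b_point])


# --- parsing ----------------------------------------------------------------

def _normalize_atom_name(name: str) -> str:
    # legacy PDB files use * for the prime mark
    return name.strip().replace("*", "'")


def _sniff_format(path: Path) -> str:
    if path.suffix.lower() in {".cif", ".mmcif"}:
        return "mmcif"
    if path.suffix.lower() in {".pdb", ".ent"}:
        return "pdb"
    head = path.read_text(errors="ignore")[:2048]
    if head.lstrip().startswith("data_") or "_atom_site." in head:
        return "mmcif"
    return "pdb"


def _resolve_altlocs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Keep one conformer per atom name: highest occupancy, ties to file order."""
    best: dict[str, AtomRecord] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in best:
            best[a.name] = a
            order.append(a.name)
        elif a.occupancy > best[a.name].occupancy:
            best[a.name] = a
    return [best[n] for n in order]


def parse_structure(
    path: str | Path,
    format: str | None = None,
    representation: ResidueRepresentation | None = None,
) -> StructureModel:
    """Read a PDB or mmCIF file into a nucleic-acid structure model.

    Only the first model is retained.  Residues whose name has no
    3-pseudo-atom recipe (proteins, waters, ions, unconfigured ligands) are
    excluded from the model's residue lists; the full first model is kept in
    ``raw`` for writing superposed output.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _sniff_format(path)
    if fmt not in {"pdb", "mmcif"}:
        raise ValueError(f"unknown format {fmt!r}")
    repr_ = representation or ResidueRepresentation()

    if fmt == "mmcif":
        st = gemmi.make_structure_from_block(gemmi.cif.read(str(path)).sole_block())
    else:
        st = gemmi.read_pdb(str(path))
    st.setup_entities()
    while len(st) > 1:  # first model only
        del st[1]

    return _model_from_gemmi(st, fmt, repr_, entry_id=st.name or path.stem)


def _model_from_gemmi(
    st: gemmi.Structure,
    fmt: str,
    repr_: ResidueRepresentation,
    entry_id: str,
) -> StructureModel:
    chains: dict[str, list[Residue]] = {}
    skipped: set[str] = set()
    for chain in st[0]:
        residues: list[Residue] = []
        for res in chain:
            if not repr_.is_nucleic(res.name):
                if res.name not in {"HOH", "H2O"} and not gemmi.find_tabulated_residue(
                    res.name
                ):
                    skipped.add(res.name)
                continue
            atoms = [
                AtomRecord(
                    name=_normalize_atom_name(a.name),
                    element=a.element.name,
                    coord=np.array([a.pos.x, a.pos.y, a.pos.z]),
                    altloc=a.altloc or "",
                    occupancy=a.occ,
                )
                for a in res
            ]
            residues.append(
                Residue(
                    chain_id=chain.name,
                    seq_number=res.seqid.num,
                    insertion_code=(res.seqid.icode or "").strip(),
                    res_name=res.name.strip(),
                    atoms=_resolve_altlocs(atoms),
                )
            )
        if residues:
            chains.setdefault(chain.name, []).extend(residues)
    if skipped:
        logger.warning("skipped residues with no pseudo-atom recipe: %s",
                       ", ".join(sorted(skipped)))
    if not chains:
        raise ValueError(f"no nucleic acid residues found in {entry_id!r}")
    return StructureModel(entry_id=entry_id, chains=chains, source_format=fmt, raw=st)


# --- selection --------------------------------------------------------------

def _parse_number_token(tok: str) -> tuple[int, str]:
    """Split '10A' into (10, 'A'); plain '10' into (10, '')."""
    i = len(tok)
    while i > 0 and not (tok[i - 1].isdigit() or tok[i - 1] == "-"):
        i -= 1
    if i == 0:
        raise ValueError(f"bad residue number {tok!r}")
    return int(tok[:i]), tok[i:]


def select_residues(model: StructureModel, spec: str | None = None) -> list[Residue]:
    """Apply a residue-selection expression; ``None`` selects everything.

    Grammar: comma-separated union of ``CHAIN`` or ``CHAIN:a-b`` terms;
    insertion codes are appended to the number (``A:10A``, ``A:5-10B``).
    File order is preserved.
    """
    if spec is None or not spec.strip():
        out = model.residues()
        if not out:
            raise ValueError("empty selection")
        return out

    keep: set[int] = set()
    all_res = model.residues()
    index = {id(r): i for i, r in enumerate(all_res)}
    for term in spec.split(","):
        term = term.strip()
        if not term:
            continue
        chain, _, rng = term.partition(":")
        chain = chain.strip()
        if chain not in model.chains:
            raise KeyError(f"chain {chain!r} not in structure "
                           f"(has {sorted(model.chains)})")
        chain_res = model.chains[chain]
        if not rng:
            keep.update(index[id(r)] for r in chain_res)
            continue
        lo_s, dash, hi_s = rng.partition("-")
        if dash:
            lo, lo_ic = _parse_number_token(lo_s.strip())
            hi, hi_ic = _parse_number_token(hi_s.strip())
        else:
            lo, lo_ic = _parse_number_token(lo_s.strip())
            hi, hi_ic = lo, lo_ic
        for r in chain_res:
            key = (r.seq_number, r.insertion_code)
            if (lo, lo_ic) <= key <= (hi, hi_ic):
                keep.update([index[id(r)]])
    if not keep:
        raise ValueError(f"selection {spec!r} matched no residues")
    return [all_res[i] for i in sorted(keep)]


# --- pseudo-atoms -----------------------------------------------------------

def residue_triple(
    res: Residue, representation: ResidueRepresentation | None = None
) -> ResidueTriple | None:
    """Compute the 3-pseudo-atom representation of a residue.

    Each point is the unweighted centroid of the recipe atoms that are
    present.  A residue whose recipe group is entirely missing (e.g. a
    5'-terminal residue lacking OP1 and O5') or lacking a C3' atom yields
    ``None``; it cannot seed a superposition but still participates in
    C3'-based matching if its C3' exists.
    """
    repr_ = representation or ResidueRepresentation()
    recipe = repr_.recipe_for(res.res_name)
    if recipe is None:
        return None
    c3 = res.atom("C3'")
    if c3 is None:
        return None
    points = []
    for group in recipe:
        coords = [a.coord for name in group if (a := res.atom(name)) is not None]
        if not coords:
            return None
        points.append(np.mean(coords, axis=0))
    return ResidueTriple(points[0], points[1], points[2], c3.coord, res)


# --- output -----------------------------------------------------------------

def write_superposed(
    model: StructureModel,
    transform: RigidTransform,
    path: str | Path,
    format: str | None = None,
    save_selection: str | None = None,
) -> None:
    """Write the model's coordinates transformed into the reference frame.

    By default every atom of the underlying file's first model is
    transformed and written (including non-nucleic chains); a selection
    expression restricts output to the named nucleic residues.
    """
    if model.raw is None:
        raise ValueError("model has no underlying coordinate file to write")
    fmt = format or model.source_format
    st = model.raw.clone()

    keep: set[tuple[str, int, str, str]] | None = None
    if save_selection is not None:
        keep = {
            (r.chain_id, r.seq_number, r.insertion_code, r.res_name)
            for r in select_residues(model, save_selection)
        }

    for chain in st[0]:
        drop = []
        for idx, res in enumerate(chain):
            key = (chain.name, res.seqid.num, (res.seqid.icode or "").strip(),
                   res.name.strip())
            if keep is not None and key not in keep:
                drop.append(idx)
                continue
            for atom in res:
                new = transform.apply(np.array([atom.pos.x, atom.pos.y, atom.pos.z]))
                atom.pos = gemmi.Position(*new)
        for idx in reversed(drop):
            del chain[idx]

    path = Path(path)
    if fmt == "pdb":
        st.write_pdb(str(path))
    elif fmt == "mmcif":
        st.make_mmcif_document().write_file(str(path))
    else:
        raise ValueError(f"unknown format {fmt!r}")
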