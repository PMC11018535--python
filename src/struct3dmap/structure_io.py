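"""Parse PDB and mmCIF files into a uniform structure model.

Structures arrive as ``.pdb`` or ``.cif`` files (experimental or predicted;
AlphaFold-style models carry per-residue pLDDT in the B-factor column). This
module reduces each file to a single deterministic coordinate set:

* one model (the first) for multi-model files;
* alternate locations resolved to the highest-occupancy conformer
  (ties broken by the alphabetically first altloc identifier);
* hydrogens and waters retained but flagged so downstream distance
  computations can exclude them.

Author chains are split into *entities*: one polymer chain model
(protein or nucleic) plus one chain model per non-polymer ligand instance
and one per-chain water group. Each ligand instance is its own entity so
that contacts with two copies of the same compound count as two distinct
interfaces.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, NamedTuple, Optional, Tuple

import gemmi

__all__ = [
    "ResidueKey",
    "Atom",
    "Residue",
    "ChainModel",
    "StructureModel",
    "StructureParseError",
    "parse_structure",
    "classify_chain",
    "extract_sequence",
]

_WATER_NAMES = {"HOH", "DOD", "WAT", "H2O"}
_HYDROGEN_ELEMENTS = {"H", "D", "T"}


class StructureParseError(Exception):
    """Raised when a structure file cannot be read or is malformed."""


class ResidueKey(NamedTuple):
    """Author-assigned identity of a residue: chain, number, insertion code.

    The insertion code is normalized to the empty string when absent.
    """

    chain_id: str
    resnum: int
    icode: str


class Atom(NamedTuple):
    name: str
    element: str
    x: float
    y: float
    z: float


@dataclass
class Residue:
    key: ResidueKey
    name: str  # 3-letter chemical component code
    one_letter: str  # translated 1-letter code, 'X' if unknown
    atoms: List[Atom]
    bfactor: float  # mean over atoms; equals pLDDT in AlphaFold models
    is_hetero: bool

    def heavy_atoms(self) -> List[Atom]:
        return [a for a in self.atoms if a.element not in _HYDROGEN_ELEMENTS]


@dataclass
class ChainModel:
    """One entity of a structure: a polymer chain, a ligand instance or waters.

    ``chain_id`` is the author chain identifier for polymers; ligand and
    water entities get synthetic instance IDs (``A:HEM:201``) that are unique
    within the structure.
    """

    chain_id: str
    kind: str  # protein | nucleic | ligand | water
    residues: List[Residue]
    author_chain_id: str = ""
    seq: str = ""
    seq_to_key: Dict[int, ResidueKey] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.author_chain_id:
            self.author_chain_id = self.chain_id
        if self.kind in ("protein", "nucleic") and not self.seq:
            self.seq, self.seq_to_key = extract_sequence(self)


@dataclass
class StructureModel:
    structure_id: str
    chains: List[ChainModel]
    source_format: str  # 'pdb' | 'cif'
    model_number: int = 1

    def polymer_chains(self) -> List[ChainModel]:
        return [c for c in self.chains if c.kind in ("protein", "nucleic")]

    def get_chain(self, chain_id: str) -> ChainModel:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(chain_id)


def _residue_info(name: str) -> gemmi.ResidueInfo:
    return gemmi.find_tabulated_residue(name)


def _one_letter(name: str) -> str:
    info = _residue_info(name)
    if info and (info.is_amino_acid() or info.is_nucleic_acid()):
        code = info.one_letter_code.upper()
        if code.isalpha():
            return code
    return "X"


def _is_water(name: str) -> bool:
    info = _residue_info(name)
    if info and info.is_water():
        return True
    return name.upper() in _WATER_NAMES


def _is_polymer_component(name: str) -> bool:
    """Amino-acid or nucleotide components belong to the polymer, even when
    flagged HETATM (MSE and friends); everything else is a ligand or water."""
    info = _residue_info(name)
    return bool(info) and (info.is_amino_acid() or info.is_nucleic_acid())


def _resolve_altlocs(res: gemmi.Residue) -> List[gemmi.Atom]:
    """Keep one conformer per atom name: highest occupancy, ties broken by
    the alphabetically first altloc identifier."""
    by_name: Dict[str, gemmi.Atom] = {}
    for atom in res:
        prev = by_name.get(atom.name)
        if prev is None:
            by_name[atom.name] = atom
            continue
        if atom.occ > prev.occ or (atom.occ == prev.occ and atom.altloc < prev.altloc):
            by_name[atom.name] = atom
    return list(by_name.values())


def _convert_residue(chain_id: str, res: gemmi.Residue) -> Optional[Residue]:
    atoms = []
    bsum = 0.0
    for atom in _resolve_altlocs(res):
        pos = atom.pos
        if not all(math.isfinite(v) for v in (pos.x, pos.y, pos.z)):
            continue
        atoms.append(Atom(atom.name, atom.element.name.upper(), pos.x, pos.y, pos.z))
        bsum += atom.b_iso
    if not atoms:
        return None
    icode = res.seqid.icode.strip()
    return Residue(
        key=ResidueKey(chain_id, res.seqid.num, icode),
        name=res.name.strip().upper(),
        one_letter=_one_letter(res.name),
        atoms=atoms,
        bfactor=bsum / len(atoms),
        is_hetero=(res.het_flag == "H"),
    )


def classify_chain(residues: List[Residue]) -> str:
    """Classify raw chain content into protein / nucleic / ligand / water.

    A chain is protein if more than half of its polymer residues are amino
    acids, nucleic if more than half are nucleotides, water if it consists
    only of water molecules, and ligand otherwise.
    """
    if not residues:
        raise StructureParseError("cannot classify an empty chain")
    if all(_is_water(r.name) for r in residues):
        return "water"
    polymer = [r for r in residues if _is_polymer_component(r.name)]
    if polymer:
        n_aa = sum(1 for r in polymer if _residue_info(r.name).is_amino_acid())
        n_nt = sum(1 for r in polymer if _residue_info(r.name).is_nucleic_acid())
        if n_aa * 2 > len(polymer):
            return "protein"
        if n_nt * 2 > len(polymer):
            return "nucleic"
    return "ligand"


def extract_sequence(chain: ChainModel) -> Tuple[str, Dict[int, ResidueKey]]:
    """Build the 1-letter sequence of observed polymer residues, in author
    order, together with the exact 1-based sequence-index -> residue-key map.

    A residue counts as observed if it has at least one heavy atom, so
    CA-only models remain mappable. Nonstandard residues with a known parent
    translate to the parent's letter; unknown components become 'X'. Gaps in
    author numbering produce no gap characters — the map carries the true
    numbering, insertion codes included.
    """
    letters: List[str] = []
    seq_to_key: Dict[int, ResidueKey] = {}
    for res in chain.residues:
        if not res.heavy_atoms():
            continue
        letters.append(res.one_letter)
        seq_to_key[len(letters)] = res.key
    return "".join(letters), seq_to_key


def _split_entities(chain_id: str, residues: List[Residue]) -> List[ChainModel]:
    """Split one author chain into polymer / ligand-instance / water entities."""
    polymer: List[Residue] = []
    waters: List[Residue] = []
    ligands: List[Residue] = []
    for res in residues:
        if _is_water(res.name):
            waters.append(res)
        elif _is_polymer_component(res.name):
            polymer.append(res)
        else:
            ligands.append(res)
    entities: List[ChainModel] = []
    if polymer:
        kind = classify_chain(polymer)
        entities.append(
            ChainModel(chain_id=chain_id, kind=kind, residues=polymer,
                       author_chain_id=chain_id)
        )
    for res in ligands:
        inst_id = f"{chain_id}:{res.name}:{res.key.resnum}{res.key.icode}"
        entities.append(
            ChainModel(chain_id=inst_id, kind="ligand", residues=[res],
                       author_chain_id=chain_id)
        )
    if waters:
        entities.append(
            ChainModel(chain_id=f"{chain_id}:water", kind="water",
                       residues=waters, author_chain_id=chain_id)
        )
    return entities


def parse_structure(
    path: str | Path,
    model_select: str = "first",
    fmt: Optional[str] = None,
) -> StructureModel:
    """Parse a PDB or mmCIF file into a :class:`StructureModel`.

    Format is inferred from the extension (``.pdb``/``.ent`` vs ``.cif``)
    unless ``fmt`` overrides it. Multi-model files are reduced to the first
    model; altlocs are resolved to the highest-occupancy conformer.

    Raises :class:`StructureParseError` (naming the path) if the file is
    unreadable; a file with zero polymer chains parses with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"structure file not found: {path}")
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = "cif" if suffix in (".cif", ".mmcif") else "pdb"
    try:
        if fmt == "cif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse structure file {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureParseError(f"no models in structure file {path}")
    if model_select != "first":
        raise ValueError(f"unknown model_select policy: {model_select}")
    model = st[0]

    chains: List[ChainModel] = []
    for chain in model:
        residues = []
        for res in chain:
            converted = _convert_residue(chain.name, res)
            if converted is not None:
                residues.append(converted)
        if residues:
            chains.extend(_split_entities(chain.name, residues))

    structure = StructureModel(
        structure_id=path.stem,
        chains=chains,
        source_format=fmt,
        model_number=1,
    )
    if not structure.polymer_chains():
        warnings.warn(f"structure {path} contains no polymer chains", stacklevel=2)
    return structure
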