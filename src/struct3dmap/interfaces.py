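"""Inter-chain interface detection and redundancy removal.

A residue of a protein chain is an interface residue toward a partner entity
(another protein chain, a nucleic-acid chain, or an individual ligand
instance) when the minimum heavy-atom--heavy-atom Euclidean distance between
the residue and any residue of the partner is within the cutoff (default
5.0 A, the standard contact threshold). Hydrogens and waters are excluded
from the distance computation; intra-chain contacts are never reported.

Each ligand instance is a distinct interface: a structure with two copies of
the same compound near a chain yields two interface IDs.

Redundancy removal mirrors how interface sets are consolidated when many
structures cover the same protein: interfaces mapped through alignments
below 80% Pident are discarded (strictly below — 80.0 survives), and per
(query protein, partner type) only the structure with the highest Pident is
kept, ties going to the lexicographically smallest structure ID. Ligand
instances within the winning structure are all retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import ChainModel, ResidueKey, StructureModel

__all__ = [
    "InterfaceRecord",
    "ScoredInterface",
    "compute_interfaces",
    "deduplicate_interfaces",
    "DEFAULT_CUTOFF",
    "DEFAULT_PIDENT_FLOOR",
]

DEFAULT_CUTOFF = 5.0
DEFAULT_PIDENT_FLOOR = 80.0


@dataclass(frozen=True)
class InterfaceRecord:
    """One protein residue in contact with one partner entity."""

    structure_id: str
    chain_id: str
    residue: ResidueKey
    partner_entity: str
    partner_type: str  # protein | ligand | nucleic
    min_distance: float

    @property
    def interface_id(self) -> Tuple[str, str, str]:
        return (self.structure_id, self.chain_id, self.partner_entity)


@dataclass(frozen=True)
class ScoredInterface:
    """An interface record joined to the alignment that mapped its protein."""

    record: InterfaceRecord
    query_id: str
    pident: float


def _entity_atoms(chain: ChainModel) -> Tuple[np.ndarray, List[int]]:
    """Heavy-atom coordinates of an entity plus per-atom residue indices."""
    coords: List[Tuple[float, float, float]] = []
    res_idx: List[int] = []
    for i, res in enumerate(chain.residues):
        for atom in res.heavy_atoms():
            coords.append((atom.x, atom.y, atom.z))
            res_idx.append(i)
    if not coords:
        return np.empty((0, 3)), []
    return np.asarray(coords, dtype=float), res_idx


def compute_interfaces(
    structure: StructureModel, cutoff: float = DEFAULT_CUTOFF
) -> List[InterfaceRecord]:
    """All interface residues of the protein chains of a structure.

    Returns one record per (protein residue, partner entity) whose minimum
    heavy-atom distance is <= cutoff. Results are ordered by chain, residue,
    then partner entity, and are identical to an all-pairs distance scan
    (the KD-tree is an implementation detail).
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    protein_chains = [c for c in structure.chains if c.kind == "protein"]
    if not protein_chains:
        warnings.warn(
            f"structure {structure.structure_id} has no protein chains; "
            "no interfaces computed",
            stacklevel=2,
        )
        return []

    partners = [c for c in structure.chains if c.kind != "water"]
    atoms_cache = {c.chain_id: _entity_atoms(c) for c in structure.chains}
    trees = {
        cid: cKDTree(xyz) for cid, (xyz, _) in atoms_cache.items() if len(xyz)
    }

    records: List[InterfaceRecord] = []
    for chain in protein_chains:
        xyz, res_idx = atoms_cache[chain.chain_id]
        if not len(xyz):
            continue
        for partner in partners:
            if partner.chain_id == chain.chain_id:
                continue
            tree = trees.get(partner.chain_id)
            if tree is None:
                continue
            # the KD-tree bound is exclusive at equality; the contact
            # definition is inclusive (d <= cutoff), so inflate then filter
            dists, _ = tree.query(xyz, k=1, distance_upper_bound=cutoff * (1 + 1e-9))
            per_res: Dict[int, float] = {}
            for atom_i, d in enumerate(dists):
                if not np.isfinite(d) or d > cutoff:
                    continue
                ri = res_idx[atom_i]
                if d < per_res.get(ri, np.inf):
                    per_res[ri] = float(d)
            for ri in sorted(per_res):
                records.append(
                    InterfaceRecord(
                        structure_id=structure.structure_id,
                        chain_id=chain.chain_id,
                        residue=chain.residues[ri].key,
                        partner_entity=partner.chain_id,
                        partner_type=partner.kind,
                        min_distance=per_res[ri],
                    )
                )
    records.sort(key=lambda r: (r.chain_id, r.residue.resnum, r.residue.icode,
                                r.partner_entity))
    return records


def deduplicate_interfaces(
    scored: Sequence[ScoredInterface],
    pident_floor: float = DEFAULT_PIDENT_FLOOR,
) -> List[ScoredInterface]:
    """Apply the interface redundancy policy; idempotent.

    Drops records below the Pident floor (strict: exactly 80.0 is kept with
    the default), then per (query protein, partner type) keeps only records
    from the structure whose best alignment has the highest Pident, breaking
    ties by the lexicographically smallest structure ID.
    """
    surviving = [s for s in scored if s.pident >= pident_floor]

    # best pident per (query, partner_type, structure)
    best: Dict[Tuple[str, str], Dict[str, float]] = {}
    for s in surviving:
        group = best.setdefault((s.query_id, s.record.partner_type), {})
        sid = s.record.structure_id
        group[sid] = max(group.get(sid, -np.inf), s.pident)

    winners: Dict[Tuple[str, str], str] = {}
    for key, per_structure in best.items():
        winners[key] = min(
            per_structure, key=lambda sid: (-per_structure[sid], sid)
        )

    return [
        s
        for s in surviving
        if winners[(s.query_id, s.record.partner_type)] == s.record.structure_id
    ]
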