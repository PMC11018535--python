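"""Independent brute-force oracles used to check the production code.

These deliberately avoid the algorithmic shortcuts of the implementation:
the alignment oracle uses the original quadratic-gap-scan dynamic program
(no affine-gap state machine), and the interface oracle is a plain all-pairs
distance scan (no spatial index).
"""

from __future__ import annotations

import math
from typing import Dict, List, Tuple

from struct3dmap.structure_io import StructureModel


def sw_score_bruteforce(
    query: str,
    subject: str,
    matrix: Dict[Tuple[str, str], float],
    gap_open: float,
    gap_extend: float,
) -> float:
    """Smith–Waterman local score with a general gap function w(L) =
    gap_open + L * gap_extend, computed by scanning all gap lengths at each
    cell (O(mn(m+n)))."""
    m, n = len(query), len(subject)
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            score = H[i - 1][j - 1] + matrix[(query[i - 1], subject[j - 1])]
            for k in range(1, i + 1):
                score = max(score, H[i - k][j] - (gap_open + k * gap_extend))
            for l in range(1, j + 1):
                score = max(score, H[i][j - l] - (gap_open + l * gap_extend))
            H[i][j] = max(0.0, score)
            best = max(best, H[i][j])
    return best


def interfaces_bruteforce(
    structure: StructureModel, cutoff: float
) -> List[Tuple[str, int, str, str, str]]:
    """All (chain, resnum, icode, partner_entity, partner_type) contacts of
    protein-chain residues, by exhaustive heavy-atom pair scan."""
    out = []
    for chain in structure.chains:
        if chain.kind != "protein":
            continue
        for partner in structure.chains:
            if partner.chain_id == chain.chain_id or partner.kind == "water":
                continue
            partner_atoms = [
                a for res in partner.residues for a in res.heavy_atoms()
            ]
            for res in chain.residues:
                dmin = math.inf
                for a in res.heavy_atoms():
                    for b in partner_atoms:
                        d = math.dist((a.x, a.y, a.z), (b.x, b.y, b.z))
                        dmin = min(dmin, d)
                if dmin <= cutoff:
                    out.append(
                        (chain.chain_id, res.key.resnum, res.key.icode,
                         partner.chain_id, partner.kind)
                    )
    return sorted(out)
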