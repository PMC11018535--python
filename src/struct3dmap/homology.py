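"""Sequence-to-structure homology transfer.

Proteome sequences are aligned locally to structure-chain sequences; the
resulting per-column map is what carries a protein position onto an author
residue number. Alignments are scored with BLOSUM62 under affine gaps
(open 11, extend 1 — standard protein-search defaults) and assigned
bit scores and e-values with Karlin–Altschul statistics, so that an external
BLAST+ backend can substitute the internal aligner while populating the same
record. Alignments are then filtered by percent identity (Pident) and
e-value; defaults are Pident >= 50% and e-value <= 1e-5, thresholds chosen
to keep structural templates reliable.

Conventions:

* Pident = 100 * identical columns / alignment length *including* gap
  columns (the BLAST tabular convention, so backends are interchangeable).
* 'X' never counts as an identity, not even against another 'X' — wildcards
  must not inflate Pident.
* One alignment is retained per (query, structure, chain): the
  highest-scoring local alignment.
"""

from __future__ import annotations

import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from Bio.Align import substitution_matrices

from .structure_io import ChainModel, ResidueKey

__all__ = [
    "ChainAlignment",
    "PositionMap",
    "local_align",
    "filter_alignments",
    "build_position_map",
    "blast_align",
    "DEFAULT_PIDENT_MIN",
    "DEFAULT_EVALUE_MAX",
    "DEFAULT_GAP_OPEN",
    "DEFAULT_GAP_EXTEND",
]

DEFAULT_PIDENT_MIN = 50.0
DEFAULT_EVALUE_MAX = 1e-5
DEFAULT_GAP_OPEN = 11
DEFAULT_GAP_EXTEND = 1

# Karlin–Altschul parameters (lambda, K) for BLOSUM62. The gapped values are
# the published estimates for gap open 11 / extend 1; the ungapped pair is
# the analytic solution for the matrix itself.
_KA_GAPPED = {("BLOSUM62", 11, 1): (0.267, 0.041)}
_KA_UNGAPPED = {"BLOSUM62": (0.3176, 0.134)}


def _load_matrix(name: str = "BLOSUM62") -> Dict[Tuple[str, str], float]:
    arr = substitution_matrices.load(name)
    alpha = arr.alphabet
    return {(a, b): float(arr[a, b]) for a in alpha for b in alpha}


_BLOSUM62 = _load_matrix("BLOSUM62")
_BLOSUM62_ALPHABET = frozenset(a for a, _ in _BLOSUM62) - {"*"}


@dataclass
class ChainAlignment:
    """A local alignment of one proteome sequence to one structure chain.

    ``colmap`` holds one ``(query_pos, subject_pos)`` pair per alignment
    column, 1-based, with ``None`` on the gapped side.
    """

    query_id: str
    structure_id: str
    chain_id: str
    qstart: int
    qend: int
    sstart: int
    send: int
    n_identical: int
    aln_len: int
    pident: float
    evalue: float
    bitscore: float
    score: float = 0.0
    colmap: List[Tuple[Optional[int], Optional[int]]] = field(default_factory=list)


@dataclass
class PositionMap:
    """Query protein position -> structural residue, for one chain alignment.

    ``entries`` maps each aligned (both-sides-non-gap) query position to
    ``(ResidueKey, structure_aa, is_identity, pident)``. Positions outside
    the aligned span, or opposite a gap, are absent.
    """

    query_id: str
    structure_id: str
    chain_id: str
    entries: Dict[int, Tuple[ResidueKey, str, bool, float]]


def _validate(seq: str, label: str, alphabet=_BLOSUM62_ALPHABET) -> None:
    if not seq:
        raise ValueError(f"{label} sequence is empty")
    for ch in seq:
        if ch not in alphabet:
            raise ValueError(f"invalid character {ch!r} in {label} sequence")


def _ka_params(matrix_name: str, gap_open: int, gap_extend: int) -> Tuple[float, float]:
    key = (matrix_name, gap_open, gap_extend)
    if key in _KA_GAPPED:
        return _KA_GAPPED[key]
    return _KA_UNGAPPED.get(matrix_name, _KA_UNGAPPED["BLOSUM62"])


def karlin_altschul(
    score: float, m: int, n: int,
    matrix_name: str = "BLOSUM62",
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
) -> Tuple[float, float]:
    """Bit score and e-value for a raw alignment score over an m x n search
    space (pairwise mode: no database-length correction)."""
    lam, k = _ka_params(matrix_name, gap_open, gap_extend)
    bitscore = (lam * score - math.log(k)) / math.log(2.0)
    evalue = m * n * 2.0 ** (-bitscore)
    return bitscore, evalue


# Traceback states / pointers.
_M, _UP, _LEFT = 0, 1, 2  # diagonal, gap-in-subject, gap-in-query
_START = 3


def local_align(
    query_seq: str,
    subject_seq: str,
    substitution_matrix: Optional[Dict[Tuple[str, str], float]] = None,
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
    query_id: str = "query",
    structure_id: str = "",
    chain_id: str = "",
    matrix_name: str = "BLOSUM62",
) -> ChainAlignment:
    """Optimal Smith–Waterman local alignment under affine gap costs.

    A gap of length L costs ``gap_open + L * gap_extend``. Traceback is
    deterministic: on ties the diagonal move is preferred over a gap in the
    subject ("up"), which is preferred over a gap in the query ("left");
    among equally scoring end cells the smallest (query, subject) coordinate
    wins.
    """
    mat = substitution_matrix if substitution_matrix is not None else _BLOSUM62
    if substitution_matrix is None:
        _validate(query_seq, "query")
        _validate(subject_seq, "subject")
    m, n = len(query_seq), len(subject_seq)
    neg = -math.inf
    open_cost = gap_open + gap_extend

    # Gotoh: H = best score of alignment ending at (i, j) in a match column;
    # E/F = ending with a gap in query / subject respectively.
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[neg] * (n + 1) for _ in range(m + 1)]  # gap in subject (consumes query)
    F = [[neg] * (n + 1) for _ in range(m + 1)]  # gap in query (consumes subject)
    ptr_h = [[_START] * (n + 1) for _ in range(m + 1)]
    ptr_e = [[_M] * (n + 1) for _ in range(m + 1)]
    ptr_f = [[_M] * (n + 1) for _ in range(m + 1)]

    best, bi, bj = 0.0, 0, 0
    for i in range(1, m + 1):
        qc = query_seq[i - 1]
        Hi, Hi1 = H[i], H[i - 1]
        Ei, Ei1 = E[i], E[i - 1]
        Fi = F[i]
        for j in range(1, n + 1):
            sub = mat.get((qc, subject_seq[j - 1]), min(mat.values()))

            e_open = Hi1[j] - open_cost
            e_ext = Ei1[j] - gap_extend
            if e_open >= e_ext:  # tie -> open from match (shorter gap)
                Ei[j], ptr_e[i][j] = e_open, _M
            else:
                Ei[j], ptr_e[i][j] = e_ext, _UP

            f_open = Hi[j - 1] - open_cost
            f_ext = Fi[j - 1] - gap_extend
            if f_open >= f_ext:
                Fi[j], ptr_f[i][j] = f_open, _M
            else:
                Fi[j], ptr_f[i][j] = f_ext, _LEFT

            diag = Hi1[j - 1]
            e_prev, f_prev = Ei1[j - 1], F[i - 1][j - 1]
            # best predecessor for a match column; diagonal-from-match first
            prev_score = diag
            prev_state = _M
            if e_prev > prev_score:
                prev_score, prev_state = e_prev, _UP
            if f_prev > prev_score:
                prev_score, prev_state = f_prev, _LEFT
            h = prev_score + sub
            if h <= 0.0:
                if sub > 0.0:
                    Hi[j], ptr_h[i][j] = sub, _START
                    h = sub
                else:
                    Hi[j], ptr_h[i][j] = 0.0, _START
                    h = 0.0
            elif prev_score == 0.0 and prev_state == _M:
                Hi[j], ptr_h[i][j] = h, _START
            else:
                Hi[j], ptr_h[i][j] = h, prev_state
            if h > best:
                best, bi, bj = h, i, j

    colmap: List[Tuple[Optional[int], Optional[int]]] = []
    n_identical = 0
    if best > 0.0:
        i, j, state = bi, bj, _M
        while True:
            if state == _M:
                qc, sc = query_seq[i - 1], subject_seq[j - 1]
                colmap.append((i, j))
                if qc == sc and qc != "X":
                    n_identical += 1
                nxt = ptr_h[i][j]
                i, j = i - 1, j - 1
                if nxt == _START:
                    break
                state = nxt
            elif state == _UP:
                colmap.append((i, None))
                nxt = ptr_e[i][j]
                i -= 1
                state = _M if nxt == _M else _UP
            else:
                colmap.append((None, j))
                nxt = ptr_f[i][j]
                j -= 1
                state = _M if nxt == _M else _LEFT
        colmap.reverse()

    aln_len = len(colmap)
    q_positions = [q for q, _ in colmap if q is not None]
    s_positions = [s for _, s in colmap if s is not None]
    qstart, qend = (q_positions[0], q_positions[-1]) if q_positions else (0, 0)
    sstart, send = (s_positions[0], s_positions[-1]) if s_positions else (0, 0)
    pident = 100.0 * n_identical / aln_len if aln_len else 0.0
    bitscore, evalue = karlin_altschul(best, m, n, matrix_name, gap_open, gap_extend)
    return ChainAlignment(
        query_id=query_id,
        structure_id=structure_id,
        chain_id=chain_id,
        qstart=qstart,
        qend=qend,
        sstart=sstart,
        send=send,
        n_identical=n_identical,
        aln_len=aln_len,
        pident=pident,
        evalue=evalue,
        bitscore=bitscore,
        score=best,
        colmap=colmap,
    )


def filter_alignments(
    alns: Sequence[ChainAlignment],
    pident_min: float = DEFAULT_PIDENT_MIN,
    evalue_max: float = DEFAULT_EVALUE_MAX,
) -> List[ChainAlignment]:
    """Keep alignments with pident >= pident_min AND evalue <= evalue_max.

    Both comparisons are inclusive: a template at exactly Pident 50.0 with
    e-value exactly 1e-5 survives the default thresholds. Order is preserved.
    """
    return [a for a in alns if a.pident >= pident_min and a.evalue <= evalue_max]


def build_position_map(
    aln: ChainAlignment, chain: ChainModel, query_seq: Optional[str] = None
) -> PositionMap:
    """Turn an alignment into the query-position -> residue-key map.

    Gap columns have no structural image and produce no entry. A subject
    position outside the chain sequence signals an aligner/parser mismatch
    and is a fatal consistency error. When ``query_seq`` is given, each entry
    carries a per-column identity flag ('X' never counts as identical).
    """
    entries: Dict[int, Tuple[ResidueKey, str, bool, float]] = {}
    for qpos, spos in aln.colmap:
        if qpos is None or spos is None:
            continue
        if spos < 1 or spos > len(chain.seq):
            raise RuntimeError(
                f"alignment subject position {spos} outside chain "
                f"{aln.structure_id}/{chain.chain_id} of length {len(chain.seq)}"
            )
        s_aa = chain.seq[spos - 1]
        is_identity = (
            query_seq is not None
            and s_aa != "X"
            and query_seq[qpos - 1] == s_aa
        )
        entries[qpos] = (chain.seq_to_key[spos], s_aa, is_identity, aln.pident)
    return PositionMap(
        query_id=aln.query_id,
        structure_id=aln.structure_id,
        chain_id=aln.chain_id,
        entries=entries,
    )


def blast_align(
    query_id: str,
    query_seq: str,
    subject_id: str,
    subject_seq: str,
    structure_id: str = "",
    chain_id: str = "",
) -> Optional[ChainAlignment]:
    """Align one pair with the external ``blastp`` binary (optional backend).

    Parses tabular output (qstart/qend/sstart/send plus the aligned strings)
    into the same :class:`ChainAlignment` record as the internal aligner.
    Returns ``None`` when BLAST reports no hit. Requires BLAST+ on PATH.
    """
    if shutil.which("blastp") is None:
        raise RuntimeError("blastp not found on PATH; use the internal backend")
    with tempfile.TemporaryDirectory() as tmp:
        qf = Path(tmp) / "q.fa"
        sf = Path(tmp) / "s.fa"
        qf.write_text(f">q\n{query_seq}\n")
        sf.write_text(f">s\n{subject_seq}\n")
        out = subprocess.run(
            [
                "blastp", "-query", str(qf), "-subject", str(sf),
                "-outfmt", "6 pident length nident evalue bitscore qstart qend sstart send qseq sseq",
            ],
            capture_output=True, text=True, check=True,
        ).stdout.strip()
    if not out:
        return None
    fields = out.splitlines()[0].split("\t")
    (pident, length, nident, evalue, bitscore,
     qstart, qend, sstart, send, qseq, sseq) = fields
    colmap: List[Tuple[Optional[int], Optional[int]]] = []
    qi, si = int(qstart), int(sstart)
    n_identical = 0
    for qa, sa in zip(qseq, sseq):
        qpos = qi if qa != "-" else None
        spos = si if sa != "-" else None
        colmap.append((qpos, spos))
        if qa == sa and qa not in ("-", "X"):
            n_identical += 1
        if qa != "-":
            qi += 1
        if sa != "-":
            si += 1
    aln_len = len(colmap)
    return ChainAlignment(
        query_id=query_id,
        structure_id=structure_id,
        chain_id=chain_id,
        qstart=int(qstart),
        qend=int(qend),
        sstart=int(sstart),
        send=int(send),
        n_identical=n_identical,
        aln_len=aln_len,
        pident=100.0 * n_identical / aln_len if aln_len else 0.0,
        evalue=float(evalue),
        bitscore=float(bitscore),
        score=float(bitscore),
        colmap=colmap,
    )
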