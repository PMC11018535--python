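"""Build the structurally annotated protein database (``makestructuraldb``).

For every proteome sequence, every structure chain it aligns to above the
Pident/e-value thresholds contributes one block of per-position rows: the
query position, the author residue key it lands on, the structure amino
acid, alignment identity and quality, the residue B-factor (pLDDT for
predicted models), and any interface contacts of that residue. Interface
flags are passed through the redundancy-removal policy (Pident floor,
best structure per partner type) before being joined to rows; plain
structural coverage rows are not deduplicated.

Output is one tab-separated file per protein ID (sanitized for filenames,
original ID kept in the rows) plus a JSON run manifest. Files are written
in a fixed order (protein, structure, chain, position), so repeated runs —
serial or parallel — are byte-identical.
"""

from __future__ import annotations

import json
import multiprocessing
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd
from Bio import SeqIO

from ._util import sanitize_id
from .homology import (
    DEFAULT_EVALUE_MAX,
    DEFAULT_PIDENT_MIN,
    ChainAlignment,
    blast_align,
    build_position_map,
    filter_alignments,
    local_align,
)
from .interfaces import (
    DEFAULT_CUTOFF,
    DEFAULT_PIDENT_FLOOR,
    InterfaceRecord,
    ScoredInterface,
    compute_interfaces,
    deduplicate_interfaces,
)
from .structure_io import StructureModel, StructureParseError, parse_structure

__all__ = [
    "make_structural_db",
    "coverage_summary",
    "read_annotation_file",
    "ANNOTATION_COLUMNS",
    "DB_FORMAT_TAG",
]

DB_FORMAT_TAG = "#struct3dmap_structdb_v1"

ANNOTATION_COLUMNS = [
    "protein_id", "protein_pos", "protein_aa", "structure_id", "chain_id",
    "resnum", "icode", "structure_aa", "is_identity", "pident", "evalue",
    "bfactor", "interfaces",
]

_STRUCT_SUFFIXES = (".pdb", ".ent", ".cif", ".mmcif")


def _load_proteome(path: Path) -> List[Tuple[str, str]]:
    seqs = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    return sorted(seqs)


def _structure_files(directory: Path) -> List[Path]:
    return sorted(
        p for p in directory.iterdir()
        if p.suffix.lower() in _STRUCT_SUFFIXES and p.is_file()
    )


@dataclass
class _ProteinResult:
    protein_id: str
    filename: Optional[str]
    n_rows: int
    n_alignments_kept: int
    n_alignments_filtered: int
    lines: List[str]


# Shared state for forked workers: structures and parameters are read-only.
_SHARED: dict = {}


def _align_protein(
    query_id: str,
    query_seq: str,
    structures: Sequence[StructureModel],
    pident_min: float,
    evalue_max: float,
    backend: str,
) -> Tuple[List[ChainAlignment], int]:
    """Best alignment per (structure, chain) passing the thresholds, plus the
    count of alignments that were computed but filtered out."""
    raw: List[ChainAlignment] = []
    for st in structures:
        for chain in st.polymer_chains():
            if chain.kind != "protein" or not chain.seq:
                continue
            if backend == "blast":
                aln = blast_align(query_id, query_seq, chain.chain_id, chain.seq,
                                  structure_id=st.structure_id, chain_id=chain.chain_id)
                if aln is None:
                    continue
            else:
                aln = local_align(
                    query_seq, chain.seq, query_id=query_id,
                    structure_id=st.structure_id, chain_id=chain.chain_id,
                )
            if aln.aln_len == 0:
                continue
            raw.append(aln)
    kept = filter_alignments(raw, pident_min, evalue_max)
    return kept, len(raw) - len(kept)


def _format_row(
    protein_id: str, qpos: int, q_aa: str, aln: ChainAlignment,
    key, s_aa: str, is_identity: bool, bfactor: float,
    flags: Sequence[Tuple[str, str, float]],
) -> str:
    flag_str = (
        ";".join(f"{pe}|{pt}|{d:.3f}" for pe, pt, d in flags) if flags else "."
    )
    return "\t".join([
        protein_id, str(qpos), q_aa, aln.structure_id, aln.chain_id,
        str(key.resnum), key.icode or ".", s_aa,
        "1" if is_identity else "0",
        f"{aln.pident:.4f}", f"{aln.evalue:.6e}", f"{bfactor:.2f}", flag_str,
    ])


def _process_protein(item: Tuple[str, str]) -> _ProteinResult:
    query_id, query_seq = item
    structures: List[StructureModel] = _SHARED["structures"]
    interfaces: Dict[str, List[InterfaceRecord]] = _SHARED["interfaces"]
    p = _SHARED["params"]

    kept, n_filtered = _align_protein(
        query_id, query_seq, structures, p["pident_min"], p["evalue_max"],
        p["backend"],
    )
    kept.sort(key=lambda a: (a.structure_id, a.chain_id))

    structures_by_id = {st.structure_id: st for st in structures}

    # Interface flags go through redundancy removal across structures.
    scored: List[ScoredInterface] = []
    maps = {}
    for aln in kept:
        chain = structures_by_id[aln.structure_id].get_chain(aln.chain_id)
        pm = build_position_map(aln, chain, query_seq)
        maps[(aln.structure_id, aln.chain_id)] = (aln, chain, pm)
        mapped_keys = {entry[0] for entry in pm.entries.values()}
        for rec in interfaces.get(aln.structure_id, []):
            if rec.chain_id == aln.chain_id and rec.residue in mapped_keys:
                scored.append(ScoredInterface(rec, query_id, aln.pident))
    surviving = deduplicate_interfaces(scored, p["pident_floor"])
    flags_by_residue: Dict[Tuple[str, str, object], List[Tuple[str, str, float]]] = {}
    for s in surviving:
        keyed = (s.record.structure_id, s.record.chain_id, s.record.residue)
        flags_by_residue.setdefault(keyed, []).append(
            (s.record.partner_entity, s.record.partner_type, s.record.min_distance)
        )
    for v in flags_by_residue.values():
        v.sort()

    lines: List[str] = []
    n_rows = 0
    for aln in kept:
        _, chain, pm = maps[(aln.structure_id, aln.chain_id)]
        residues_by_key = {r.key: r for r in chain.residues}
        for qpos in sorted(pm.entries):
            key, s_aa, is_identity, _pident = pm.entries[qpos]
            res = residues_by_key[key]
            flags = flags_by_residue.get((aln.structure_id, aln.chain_id, key), [])
            lines.append(
                _format_row(
                    query_id, qpos, query_seq[qpos - 1], aln, key, s_aa,
                    is_identity, res.bfactor, flags,
                )
            )
            n_rows += 1

    filename = f"{sanitize_id(query_id)}.tsv" if lines else None
    return _ProteinResult(
        protein_id=query_id,
        filename=filename,
        n_rows=n_rows,
        n_alignments_kept=len(kept),
        n_alignments_filtered=n_filtered,
        lines=lines,
    )


def make_structural_db(
    proteome: str | Path,
    structures: str | Path,
    outdir: str | Path,
    pident_min: float = DEFAULT_PIDENT_MIN,
    evalue_max: float = DEFAULT_EVALUE_MAX,
    cutoff: float = DEFAULT_CUTOFF,
    pident_floor: float = DEFAULT_PIDENT_FLOOR,
    backend: str = "internal",
    jobs: int = 1,
) -> dict:
    """Build the structural database; returns the run manifest.

    Per-protein work is independent: with ``jobs > 1`` proteins are processed
    in a fork-based pool, and outputs are byte-identical to a serial run
    because files are written in sorted protein order from collected results.
    A single corrupt structure file is skipped with a warning; an empty
    proteome or structure directory is fatal.
    """
    proteome = Path(proteome)
    structures_dir = Path(structures)
    outdir = Path(outdir)
    seqs = _load_proteome(proteome)
    if not seqs:
        raise ValueError(f"no sequences in proteome {proteome}")
    files = _structure_files(structures_dir)
    if not files:
        raise ValueError(f"no structure files in {structures_dir}")

    parsed: List[StructureModel] = []
    seen_ids = set()
    n_failed = 0
    for f in files:
        try:
            st = parse_structure(f)
        except StructureParseError as exc:
            warnings.warn(f"skipping corrupt structure file: {exc}", stacklevel=2)
            n_failed += 1
            continue
        if st.structure_id in seen_ids:
            # same entry in both .pdb and .cif form: one model per structure
            warnings.warn(
                f"duplicate structure id {st.structure_id!r} from {f.name}; "
                "keeping the first file", stacklevel=2,
            )
            continue
        seen_ids.add(st.structure_id)
        parsed.append(st)
    if not parsed:
        raise ValueError(f"no parseable structure files in {structures_dir}")
    parsed.sort(key=lambda st: st.structure_id)

    interface_map = {
        st.structure_id: compute_interfaces(st, cutoff) for st in parsed
    }

    _SHARED.clear()
    _SHARED.update(
        structures=parsed,
        interfaces=interface_map,
        params=dict(
            pident_min=pident_min, evalue_max=evalue_max,
            pident_floor=pident_floor, backend=backend,
        ),
    )
    try:
        if jobs > 1:
            ctx = multiprocessing.get_context("fork")
            with ctx.Pool(jobs) as pool:
                results = pool.map(_process_protein, seqs)
        else:
            results = [_process_protein(item) for item in seqs]
    finally:
        _SHARED.clear()

    outdir.mkdir(parents=True, exist_ok=True)
    manifest_proteins: Dict[str, dict] = {}
    n_covered = 0
    total_kept = total_filtered = 0
    for res in sorted(results, key=lambda r: r.protein_id):
        if res.filename:
            with open(outdir / res.filename, "w") as fh:
                fh.write(DB_FORMAT_TAG + "\n")
                fh.write("\t".join(ANNOTATION_COLUMNS) + "\n")
                for line in res.lines:
                    fh.write(line + "\n")
            n_covered += 1
        manifest_proteins[res.protein_id] = {
            "file": res.filename,
            "n_rows": res.n_rows,
            "n_alignments": res.n_alignments_kept,
        }
        total_kept += res.n_alignments_kept
        total_filtered += res.n_alignments_filtered

    manifest = {
        "proteins_total": len(seqs),
        "proteins_covered": n_covered,
        "structures_used": [st.structure_id for st in parsed],
        "structures_failed": n_failed,
        "alignments_kept": total_kept,
        "alignments_filtered_out": total_filtered,
        "parameters": {
            "pident_min": pident_min,
            "evalue_max": evalue_max,
            "distance_cutoff": cutoff,
            "interface_pident_floor": pident_floor,
            "backend": backend,
        },
        "proteins": manifest_proteins,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def read_annotation_file(path: str | Path) -> pd.DataFrame:
    """Read one per-protein annotation TSV back into a DataFrame."""
    with open(path) as fh:
        tag = fh.readline().strip()
        if tag != DB_FORMAT_TAG:
            raise ValueError(f"{path}: unexpected format tag {tag!r}")
        df = pd.read_csv(
            fh, sep="\t", dtype={"icode": str, "interfaces": str},
            keep_default_na=False, na_values=[],
        )
    df["icode"] = df["icode"].replace(".", "")
    return df


def coverage_summary(
    db_dir: str | Path,
    proteome: str | Path,
    thresholds: Iterable[float] = (100.0, 90.0, 80.0, 70.0, 60.0, 50.0),
) -> pd.DataFrame:
    """Residue- and protein-level structural coverage per Pident threshold.

    For each threshold t: the fraction of proteome residues carrying at
    least one annotation row with pident >= t, and the fraction of proteins
    with at least one such row. Both are non-decreasing as t drops.
    """
    db_dir = Path(db_dir)
    seqs = _load_proteome(Path(proteome))
    total_residues = sum(len(s) for _, s in seqs)
    manifest = json.loads((db_dir / "manifest.json").read_text())
    per_protein: Dict[str, pd.DataFrame] = {}
    for pid, info in manifest["proteins"].items():
        if info["file"]:
            per_protein[pid] = read_annotation_file(db_dir / info["file"])

    rows = []
    for t in thresholds:
        res_covered = 0
        prot_covered = 0
        for pid, _seq in seqs:
            df = per_protein.get(pid)
            if df is None:
                continue
            hit = df[df["pident"] >= t]
            if len(hit):
                prot_covered += 1
                res_covered += hit["protein_pos"].nunique()
        rows.append(
            {
                "pident_min": t,
                "residue_coverage": res_covered / total_residues if total_residues else 0.0,
                "protein_coverage": prot_covered / len(seqs) if seqs else 0.0,
            }
        )
    return pd.DataFrame(rows)
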