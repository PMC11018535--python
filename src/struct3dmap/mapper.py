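"""Join variants to structural annotations and classify them (``mapper``).

Each variant position is looked up in the per-protein structural annotation
files and classified:

* **interface** — a covering annotation row carries at least one interface
  contact flag;
* **structure** — covered by a row without interface flags;
* **unmapped** — a protein position exists but no annotation row covers it
  (or all covering rows were removed by quality filters);
* **non-coding** — the record has no protein position at all.

A variant covered by several structures yields several rows (long format);
a per-variant summary keeps the best class under the ordering
interface > structure > unmapped > non-coding. Interval protein positions
(in-frame indels) expand to one row per covered position. By default no
consequence-type filtering is applied; optional filters restrict by
consequence terms, minimum Pident, minimum pLDDT (B-factor) and — when a
per-model score table is supplied — minimum pDockQ (default 0.23; models at
or below the threshold are excluded, reflecting the quality level found
acceptable for predicted complexes).

The reference-allele sanity check compares the variant's reference amino
acid with the query residue in the annotation row and sets a mismatch flag
instead of dropping the row: discrepancies between database sequences and
the constructs used for structures are common, and visibility beats silent
loss.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from ._util import sanitize_id
from .structdb import read_annotation_file
from .variantdb import (
    VariantRecord,
    read_transcript_file,
    strip_transcript_version,
)

__all__ = [
    "map_variants",
    "write_outputs",
    "summarize_by_variant",
    "build_setid",
    "load_id_map",
    "MAPPED_COLUMNS",
    "CLASS_ORDER",
]

CLASS_ORDER = ["interface", "structure", "unmapped", "non-coding"]

MAPPED_COLUMNS = [
    "variant_id", "transcript_id", "gene_id", "consequence", "protein_id",
    "protein_pos", "variant_span", "aa_ref", "aa_alt", "source_format",
    "structure_id", "chain_id", "resnum", "icode", "structure_aa",
    "is_identity", "pident", "evalue", "bfactor", "pdockq", "interfaces",
    "class", "ref_mismatch", "reason",
]


def load_id_map(path: str | Path) -> Dict[str, str]:
    """Read a transcript -> protein TSV (header optional, 2 columns)."""
    mapping: Dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cells = line.split("\t")
            if len(cells) < 2:
                continue
            if cells[0].lower() in ("transcript_id", "transcript"):
                continue
            mapping[strip_transcript_version(cells[0])] = cells[1]
    return mapping


def _consequence_matches(consequence: str, allowed: Sequence[str]) -> bool:
    terms = {t.strip() for t in consequence.replace("&", ",").split(",") if t.strip()}
    return bool(terms & set(allowed))


def _base_row(rec: VariantRecord, protein_id: str) -> dict:
    span = None
    if rec.protein_pos is not None:
        lo, hi = rec.protein_pos
        span = f"{lo}-{hi}" if hi != lo else str(lo)
    return {
        "variant_id": rec.variant_id,
        "transcript_id": rec.transcript_id,
        "gene_id": rec.gene_id,
        "consequence": rec.consequence,
        "protein_id": protein_id,
        "protein_pos": pd.NA,
        "variant_span": span,
        "aa_ref": rec.aa_ref,
        "aa_alt": rec.aa_alt,
        "source_format": rec.source_format,
        "structure_id": None,
        "chain_id": None,
        "resnum": pd.NA,
        "icode": None,
        "structure_aa": None,
        "is_identity": pd.NA,
        "pident": pd.NA,
        "evalue": pd.NA,
        "bfactor": pd.NA,
        "pdockq": pd.NA,
        "interfaces": None,
        "class": None,
        "ref_mismatch": pd.NA,
        "reason": None,
    }


def map_variants(
    protdb_dir: str | Path,
    vardb_dir: str | Path,
    id_map: Optional[Dict[str, str] | str | Path] = None,
    consequences: Optional[Sequence[str]] = None,
    min_pident: Optional[float] = None,
    min_plddt: Optional[float] = None,
    pdockq_table: Optional[Dict[str, float] | str | Path] = None,
    min_pdockq: float = 0.23,
) -> pd.DataFrame:
    """Map every variant in the variant database onto the structural database.

    ``id_map`` maps version-stripped transcript IDs to protein IDs; ``None``
    uses the transcript ID itself (identity map). ``pdockq_table`` maps
    structure IDs to per-model pDockQ scores; when supplied, structural hits
    from models with pDockQ <= ``min_pdockq`` are excluded before
    classification (strictly greater scores survive). Variants on
    transcripts absent from the id map are emitted as unmapped with a reason
    code. Returns the long-format mapped table.
    """
    protdb_dir = Path(protdb_dir)
    vardb_dir = Path(vardb_dir)
    if isinstance(id_map, (str, Path)):
        id_map = load_id_map(id_map)
    if isinstance(pdockq_table, (str, Path)):
        pdockq_table = _load_pdockq(pdockq_table)

    manifest = json.loads((protdb_dir / "manifest.json").read_text())
    annotation_cache: Dict[str, Optional[pd.DataFrame]] = {}

    def annotations_for(protein_id: str) -> Optional[pd.DataFrame]:
        if protein_id not in annotation_cache:
            info = manifest["proteins"].get(protein_id)
            if info and info["file"]:
                annotation_cache[protein_id] = read_annotation_file(
                    protdb_dir / info["file"]
                )
            else:
                annotation_cache[protein_id] = None
        return annotation_cache[protein_id]

    index = json.loads((vardb_dir / "index.json").read_text())
    rows: List[dict] = []
    for transcript_key in sorted(index):
        records = read_transcript_file(vardb_dir / index[transcript_key]["path"])
        if id_map is None:
            protein_id = transcript_key
            known_transcript = True
        else:
            protein_id = id_map.get(transcript_key, "")
            known_transcript = transcript_key in id_map
        for rec in records:
            if consequences and not _consequence_matches(rec.consequence, consequences):
                continue
            rows.extend(
                _map_one(
                    rec, protein_id, known_transcript, annotations_for,
                    min_pident, min_plddt, pdockq_table, min_pdockq,
                )
            )
    df = pd.DataFrame(rows, columns=MAPPED_COLUMNS)
    return df


def _load_pdockq(path: str | Path) -> Dict[str, float]:
    table: Dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cells = line.split("\t")
            if len(cells) < 2 or cells[0].lower() in ("structure_id", "model"):
                continue
            table[cells[0]] = float(cells[1])
    return table


def _map_one(
    rec: VariantRecord,
    protein_id: str,
    known_transcript: bool,
    annotations_for,
    min_pident: Optional[float],
    min_plddt: Optional[float],
    pdockq_table: Optional[Dict[str, float]],
    min_pdockq: float,
) -> List[dict]:
    base = _base_row(rec, protein_id)
    if rec.protein_pos is None:
        row = dict(base)
        row["class"] = "non-coding"
        return [row]
    if not known_transcript:
        row = dict(base)
        row["protein_pos"] = rec.protein_pos[0]
        row["class"] = "unmapped"
        row["reason"] = "transcript_not_in_idmap"
        return [row]

    df = annotations_for(protein_id)
    out: List[dict] = []
    for pos in rec.positions:
        hits = None
        if df is not None:
            hits = df[df["protein_pos"] == pos]
            if min_pident is not None:
                hits = hits[hits["pident"] >= min_pident]
            if min_plddt is not None:
                hits = hits[hits["bfactor"] >= min_plddt]
            if pdockq_table is not None:
                hits = hits[
                    hits["structure_id"].map(
                        lambda sid: pdockq_table.get(str(sid), float("-inf"))
                    )
                    > min_pdockq
                ]
        if hits is None or hits.empty:
            row = dict(base)
            row["protein_pos"] = pos
            row["class"] = "unmapped"
            row["reason"] = (
                "no_structural_coverage" if df is not None else "protein_not_in_structdb"
            )
            out.append(row)
            continue
        for _, hit in hits.iterrows():
            row = dict(base)
            row["protein_pos"] = pos
            row["structure_id"] = hit["structure_id"]
            row["chain_id"] = hit["chain_id"]
            row["resnum"] = hit["resnum"]
            row["icode"] = hit["icode"]
            row["structure_aa"] = hit["structure_aa"]
            row["is_identity"] = hit["is_identity"]
            row["pident"] = hit["pident"]
            row["evalue"] = hit["evalue"]
            row["bfactor"] = hit["bfactor"]
            if pdockq_table is not None:
                row["pdockq"] = pdockq_table.get(str(hit["structure_id"]), pd.NA)
            flags = hit["interfaces"]
            has_flags = isinstance(flags, str) and flags not in ("", ".")
            row["interfaces"] = flags if has_flags else None
            row["class"] = "interface" if has_flags else "structure"
            if rec.aa_ref and len(rec.aa_ref) == len(rec.positions):
                expected = rec.aa_ref[pos - rec.positions[0]]
                row["ref_mismatch"] = expected != hit["protein_aa"]
            out.append(row)
    return out


def summarize_by_variant(mapped: pd.DataFrame) -> pd.DataFrame:
    """One row per variant with its best class (interface > structure >
    unmapped > non-coding) and the number of structural hits."""
    rank = {c: i for i, c in enumerate(CLASS_ORDER)}
    rows = []
    for vid, grp in mapped.groupby("variant_id", sort=True):
        best = min(grp["class"], key=lambda c: rank[c])
        n_hits = int(grp["structure_id"].notna().sum())
        rows.append(
            {
                "variant_id": vid,
                "best_class": best,
                "n_structural_hits": n_hits,
                "protein_id": grp["protein_id"].iloc[0],
            }
        )
    return pd.DataFrame(rows, columns=["variant_id", "best_class",
                                       "n_structural_hits", "protein_id"])


def _interface_partners(flags: Optional[str]) -> List[str]:
    if not flags or flags == ".":
        return []
    return [part.split("|")[0] for part in flags.split(";") if part]


def build_setid(mapped: pd.DataFrame, grouping: str = "per-interface") -> List[Tuple[str, str]]:
    """Build (set_id, variant_id) pairs for rare-variant association tests.

    Groupings: ``per-protein`` (one set per protein, mapped variants),
    ``per-interface`` (one set per (protein, partner entity)), or
    ``per-structure-class`` (one set per (protein, class) over interface and
    structure classes). Pairs are unique and sorted.
    """
    pairs = set()
    for _, row in mapped.iterrows():
        cls = row["class"]
        if cls not in ("interface", "structure"):
            continue
        pid = sanitize_id(str(row["protein_id"]))
        if grouping == "per-protein":
            pairs.add((pid, row["variant_id"]))
        elif grouping == "per-structure-class":
            pairs.add((f"{pid}_{cls}", row["variant_id"]))
        elif grouping == "per-interface":
            for partner in _interface_partners(row["interfaces"]):
                pairs.add((f"{pid}_interface_{sanitize_id(partner)}", row["variant_id"]))
        else:
            raise ValueError(f"unknown SetID grouping: {grouping}")
    return sorted(pairs)


def write_outputs(
    mapped: pd.DataFrame,
    outdir: str | Path,
    fmt: str = "csv",
    setid_grouping: str = "per-interface",
    basename: str = "mapped",
) -> Dict[str, Path]:
    """Write the mapped table (CSV or HDF5), the per-variant summary and the
    SetID file. The CSV is RFC-4180 with a header row and stable column
    order; the HDF5 file holds one table dataset with identical rows."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out: Dict[str, Path] = {}
    table = mapped[MAPPED_COLUMNS]
    if fmt == "csv":
        path = outdir / f"{basename}.csv"
        table.to_csv(path, index=False)
    elif fmt == "hdf5":
        path = outdir / f"{basename}.h5"
        store = table.copy()
        # pytables cannot store mixed NA/object columns natively; normalize
        for col in store.columns:
            if store[col].dtype == object:
                store[col] = store[col].astype("string")
        store.to_hdf(path, key="mapped", mode="w", format="table")
    else:
        raise ValueError(f"unknown output format: {fmt}")
    out["table"] = path

    summary_path = outdir / f"{basename}.summary.csv"
    summarize_by_variant(mapped).to_csv(summary_path, index=False)
    out["summary"] = summary_path

    setid_path = outdir / f"{basename}.setid"
    with open(setid_path, "w") as fh:
        for set_id, variant_id in build_setid(mapped, setid_grouping):
            fh.write(f"{set_id} {variant_id}\n")
    out["setid"] = setid_path
    return out


def read_mapped(path: str | Path) -> pd.DataFrame:
    """Read a mapped table back from CSV or HDF5."""
    path = Path(path)
    if path.suffix == ".csv":
        return pd.read_csv(path, keep_default_na=False, na_values=[""])
    return pd.read_hdf(path, key="mapped")
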