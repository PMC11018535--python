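"""Normalize variant/position files and split them by transcript.

Accepted dialects:

* **VEP** tabular output — columns located by header name
  (``#Uploaded_variation``, ``Feature``, ``Consequence``,
  ``Protein_position``, ``Amino_acids``).
* **VEP-like** — the same, tolerating extra or missing optional columns.
* **MAF** — Mutation Annotation Format, using ``Transcript_ID`` and
  ``HGVSp_Short``-style protein-change fields.
* **VCF** — requires a VEP/CSQ-style annotation field in INFO; each
  transcript consequence becomes one record. Plain VCFs without consequence
  annotation are rejected with a pointer to run VEP first — consequence
  prediction is outside this tool.

Records lacking a protein position (non-coding consequences) are retained
with the position absent; they classify as non-coding downstream.
Protein-position intervals ("86-88", in-frame indels) are stored as
intervals and expanded to per-position queries by the mapper. Transcript
version suffixes are stripped for matching but preserved in output.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

import pysam

from ._util import sanitize_id

__all__ = [
    "VariantRecord",
    "VariantParseError",
    "parse_variants",
    "split_by_transcript",
    "strip_transcript_version",
]


class VariantParseError(Exception):
    pass


@dataclass
class VariantRecord:
    """One normalized variant (or annotated position) on one transcript."""

    variant_id: str
    transcript_id: str
    gene_id: Optional[str] = None
    consequence: str = ""
    protein_pos: Optional[Tuple[int, int]] = None  # 1-based inclusive interval
    aa_ref: Optional[str] = None
    aa_alt: Optional[str] = None
    source_format: str = "vep"
    extras: Dict[str, str] = field(default_factory=dict)

    @property
    def positions(self) -> List[int]:
        if self.protein_pos is None:
            return []
        lo, hi = self.protein_pos
        return list(range(lo, hi + 1))


def strip_transcript_version(transcript_id: str) -> str:
    return re.sub(r"\.\d+$", "", transcript_id)


_POS_RE = re.compile(r"^(\d+)(?:-(\d+))?$")
# p.H86N / p.His86Asn / H86N
_HGVSP_RE = re.compile(r"^(?:p\.)?\(?([A-Za-z]{1,3})(\d+)([A-Za-z*=]{1,3})\)?$")

_AA3_TO_1 = {
    "Ala": "A", "Cys": "C", "Asp": "D", "Glu": "E", "Phe": "F", "Gly": "G",
    "His": "H", "Ile": "I", "Lys": "K", "Leu": "L", "Met": "M", "Asn": "N",
    "Pro": "P", "Gln": "Q", "Arg": "R", "Ser": "S", "Thr": "T", "Val": "V",
    "Trp": "W", "Tyr": "Y", "Ter": "*", "Sec": "U",
}


def _parse_protein_pos(text: str) -> Optional[Tuple[int, int]]:
    text = text.strip()
    if not text or text in ("-", "?", "."):
        return None
    m = _POS_RE.match(text)
    if not m:
        return None
    lo = int(m.group(1))
    hi = int(m.group(2)) if m.group(2) else lo
    if lo < 1 or hi < lo:
        return None
    return (lo, hi)


def _parse_amino_acids(text: str) -> Tuple[Optional[str], Optional[str], bool]:
    """VEP Amino_acids field: 'H/N', or 'H' for synonymous. Returns
    (ref, alt, ok); ok=False marks an unparseable string (kept, counted)."""
    text = text.strip()
    if not text or text in ("-", "."):
        return None, None, True
    parts = text.split("/")
    if len(parts) == 1 and len(parts[0]) >= 1:
        aa = parts[0]
        return aa, aa, True
    if len(parts) == 2 and parts[0] and parts[1]:
        return parts[0], parts[1], True
    return None, None, False


def _aa_to_one(token: str) -> Optional[str]:
    if len(token) == 1:
        return token.upper() if token != "=" else None
    return _AA3_TO_1.get(token.capitalize())


def _parse_hgvsp(text: str) -> Tuple[Optional[Tuple[int, int]], Optional[str], Optional[str], bool]:
    """MAF HGVSp_Short, e.g. 'p.H86N' -> ((86, 86), 'H', 'N', True)."""
    text = text.strip()
    if not text or text in ("-", "."):
        return None, None, None, True
    m = _HGVSP_RE.match(text)
    if not m:
        return None, None, None, False
    ref = _aa_to_one(m.group(1))
    pos = int(m.group(2))
    alt_tok = m.group(3)
    alt = ref if alt_tok == "=" else _aa_to_one(alt_tok)
    if ref is None or pos < 1:
        return None, None, None, False
    return (pos, pos), ref, alt, True


def _sniff_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".vcf":
        return "vcf"
    if suffix == ".maf":
        return "maf"
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            if line.startswith("##fileformat=VCF"):
                return "vcf"
            low = line.lower()
            if "hugo_symbol" in low or "hgvsp_short" in low:
                return "maf"
            if "uploaded_variation" in low or "\tfeature\t" in low or low.startswith("#uploaded"):
                return "vep"
            return "vep"
    raise VariantParseError(f"cannot infer variant format of {path}")


def _read_table_header(line: str) -> List[str]:
    return [c.strip() for c in line.rstrip("\n").split("\t")]


def _norm_col(name: str) -> str:
    return name.lstrip("#").strip().lower()


def _parse_vep_tabular(path: Path, source_format: str) -> Iterator[VariantRecord]:
    with open(path) as fh:
        header: Optional[List[str]] = None
        for line in fh:
            if line.startswith("##") or not line.strip():
                continue
            header = _read_table_header(line)
            break
        if header is None:
            return
        idx = {_norm_col(c): i for i, c in enumerate(header)}
        for required in ("uploaded_variation", "feature", "consequence"):
            if required not in idx:
                raise VariantParseError(
                    f"{path}: required column '{required}' missing from header"
                )
        has_ppos = "protein_position" in idx
        has_aa = "amino_acids" in idx
        n_bad_aa = 0
        for lineno, line in enumerate(fh, start=2):
            if not line.strip() or line.startswith("#"):
                continue
            cells = line.rstrip("\n").split("\t")

            def get(col: str) -> str:
                i = idx.get(col)
                return cells[i].strip() if i is not None and i < len(cells) else ""

            ppos = _parse_protein_pos(get("protein_position")) if has_ppos else None
            aa_ref = aa_alt = None
            if has_aa and ppos is not None:
                aa_ref, aa_alt, ok = _parse_amino_acids(get("amino_acids"))
                if not ok:
                    n_bad_aa += 1
            extras = {
                header[i]: cells[i]
                for i in range(len(header))
                if i < len(cells)
                and _norm_col(header[i])
                not in ("uploaded_variation", "feature", "consequence",
                        "protein_position", "amino_acids")
                and cells[i] not in ("", "-")
            }
            yield VariantRecord(
                variant_id=get("uploaded_variation"),
                transcript_id=get("feature"),
                gene_id=get("gene") or None,
                consequence=get("consequence"),
                protein_pos=ppos,
                aa_ref=aa_ref,
                aa_alt=aa_alt,
                source_format=source_format,
                extras=extras,
            )


def _parse_maf(path: Path) -> Iterator[VariantRecord]:
    with open(path) as fh:
        header: Optional[List[str]] = None
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            header = _read_table_header(line)
            break
        if header is None:
            return
        idx = {_norm_col(c): i for i, c in enumerate(header)}
        if "transcript_id" not in idx:
            raise VariantParseError(
                f"{path}: required column 'Transcript_ID' missing from MAF header"
            )
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cells = line.rstrip("\n").split("\t")

            def get(col: str) -> str:
                i = idx.get(col)
                return cells[i].strip() if i is not None and i < len(cells) else ""

            chrom, start = get("chromosome"), get("start_position")
            ref, alt = get("reference_allele"), get("tumor_seq_allele2")
            if chrom and start:
                variant_id = f"{chrom}_{start}_{ref or '.'}_{alt or '.'}"
            else:
                variant_id = get("hugo_symbol") or "maf_variant"
            ppos, aa_ref, aa_alt, _ok = _parse_hgvsp(get("hgvsp_short"))
            yield VariantRecord(
                variant_id=variant_id,
                transcript_id=get("transcript_id"),
                gene_id=get("hugo_symbol") or None,
                consequence=get("variant_classification"),
                protein_pos=ppos,
                aa_ref=aa_ref,
                aa_alt=aa_alt,
                source_format="maf",
            )


def _parse_vcf(path: Path) -> Iterator[VariantRecord]:
    vcf = pysam.VariantFile(str(path))
    csq_key = None
    for key in ("CSQ", "ANN", "vep"):
        if key in vcf.header.info:
            csq_key = key
            break
    if csq_key is None:
        raise VariantParseError(
            f"{path}: no CSQ/ANN consequence annotation in VCF header; "
            "run VEP on the file first — consequence prediction is not "
            "performed by this tool"
        )
    desc = vcf.header.info[csq_key].description
    m = re.search(r"Format:\s*(\S+)", desc)
    if not m:
        raise VariantParseError(f"{path}: cannot locate Format in {csq_key} description")
    fields = [f.strip() for f in m.group(1).split("|")]
    fidx = {_norm_col(f): i for i, f in enumerate(fields)}
    for rec in vcf:
        alts = rec.alts or ("?",)
        vid = rec.id or f"{rec.chrom}_{rec.pos}_{rec.ref}_{alts[0]}"
        for ann in rec.info.get(csq_key, ()):  # type: ignore[union-attr]
            cells = ann.split("|")

            def get(col: str) -> str:
                i = fidx.get(col)
                return cells[i].strip() if i is not None and i < len(cells) else ""

            ppos = _parse_protein_pos(get("protein_position"))
            aa_ref = aa_alt = None
            if ppos is not None:
                aa_ref, aa_alt, _ok = _parse_amino_acids(get("amino_acids"))
            yield VariantRecord(
                variant_id=vid,
                transcript_id=get("feature") or get("transcript_id"),
                gene_id=get("gene") or None,
                consequence=get("consequence"),
                protein_pos=ppos,
                aa_ref=aa_ref,
                aa_alt=aa_alt,
                source_format="vcf",
            )


def parse_variants(
    path: str | Path, format_hint: Optional[str] = None
) -> Iterator[VariantRecord]:
    """Parse a variant/position file into normalized records.

    ``format_hint`` may be one of vcf | vep | veplike | maf; when absent the
    format is inferred from the extension and header.
    """
    path = Path(path)
    if not path.exists():
        raise VariantParseError(f"variant file not found: {path}")
    fmt = (format_hint or _sniff_format(path)).lower()
    if fmt in ("vep", "veplike", "vep-like", "auto"):
        yield from _parse_vep_tabular(path, "veplike" if "like" in fmt else "vep")
    elif fmt == "maf":
        yield from _parse_maf(path)
    elif fmt == "vcf":
        yield from _parse_vcf(path)
    else:
        raise VariantParseError(f"unknown variant format: {fmt}")


_SPLIT_COLUMNS = [
    "variant_id", "transcript_id", "gene_id", "consequence", "protein_pos",
    "aa_ref", "aa_alt", "source_format", "extras",
]


def record_to_row(rec: VariantRecord) -> List[str]:
    if rec.protein_pos is None:
        ppos = "."
    elif rec.protein_pos[0] == rec.protein_pos[1]:
        ppos = str(rec.protein_pos[0])
    else:
        ppos = f"{rec.protein_pos[0]}-{rec.protein_pos[1]}"
    return [
        rec.variant_id,
        rec.transcript_id,
        rec.gene_id or ".",
        rec.consequence or ".",
        ppos,
        rec.aa_ref or ".",
        rec.aa_alt or ".",
        rec.source_format,
        json.dumps(rec.extras, sort_keys=True) if rec.extras else ".",
    ]


def row_to_record(cells: List[str]) -> VariantRecord:
    return VariantRecord(
        variant_id=cells[0],
        transcript_id=cells[1],
        gene_id=None if cells[2] == "." else cells[2],
        consequence="" if cells[3] == "." else cells[3],
        protein_pos=_parse_protein_pos(cells[4]),
        aa_ref=None if cells[5] == "." else cells[5],
        aa_alt=None if cells[6] == "." else cells[6],
        source_format=cells[7],
        extras={} if cells[8] == "." else json.loads(cells[8]),
    )


def split_by_transcript(
    records: Iterable[VariantRecord], outdir: str | Path
) -> Dict[str, dict]:
    """Write one TSV per transcript plus a JSON index.

    Each record lands in exactly one file per (record, transcript) — a
    variant annotated on two transcripts arrives as two records and appears
    in both files. Within-file order equals input order. The index maps the
    version-stripped transcript ID to its path and record count.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    buffers: Dict[str, List[List[str]]] = {}
    for rec in records:
        key = strip_transcript_version(rec.transcript_id)
        if not key:
            key = "_no_transcript"
        buffers.setdefault(key, []).append(record_to_row(rec))

    index: Dict[str, dict] = {}
    for key in sorted(buffers):
        fname = f"{sanitize_id(key)}.tsv"
        fpath = outdir / fname
        with open(fpath, "w") as fh:
            fh.write("\t".join(_SPLIT_COLUMNS) + "\n")
            for row in buffers[key]:
                fh.write("\t".join(row) + "\n")
        index[key] = {"path": fname, "n_records": len(buffers[key])}
    (outdir / "index.json").write_text(json.dumps(index, indent=1, sort_keys=True))
    return index


def read_transcript_file(path: str | Path) -> List[VariantRecord]:
    """Read back one per-transcript TSV written by :func:`split_by_transcript`."""
    out: List[VariantRecord] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("variant_id\t"):
            raise VariantParseError(f"{path}: not a per-transcript variant file")
        for line in fh:
            if line.strip():
                out.append(row_to_record(line.rstrip("\n").split("\t")))
    return out


def make_variants_db(
    input_path: str | Path, outdir: str | Path, format_hint: Optional[str] = None
) -> Dict[str, dict]:
    """The ``makevariantsdb`` command: parse then split by transcript."""
    return split_by_transcript(parse_variants(input_path, format_hint), outdir)
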