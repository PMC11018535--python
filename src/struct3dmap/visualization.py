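"""Emit ChimeraX command scripts highlighting mapped variant positions.

One ``.cxc`` script per structure: an ``open`` command, a grey-cartoon base
representation, then one coloring command per variant class over a residue
selector built from chain + author residue number + insertion code
(``/A:3-4,7A``). Interface and structure classes get distinct, configurable
colors (defaults: interface red, structure-only blue). A legend comment
header lists the variant IDs per residue. Scripts are deterministic given
the same mapped table; structures with only unmapped/non-coding rows
produce no script.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from ._util import sanitize_id

__all__ = [
    "make_visualization",
    "build_selector",
    "parse_selector",
    "DEFAULT_PALETTE",
]

logger = logging.getLogger(__name__)

DEFAULT_PALETTE = {
    "interface": "red",
    "structure": "blue",
    "base": "gray",
}

ResidueSpec = Tuple[str, int, str]  # (chain_id, resnum, icode)


def build_selector(residues: Sequence[ResidueSpec]) -> str:
    """ChimeraX atom-spec for a residue set: ``/A:1,3-4,7A/B:2``.

    Consecutive insertion-code-free residue numbers collapse into ranges;
    residues with insertion codes render as ``:7A`` singletons.
    """
    by_chain: Dict[str, List[Tuple[int, str]]] = {}
    for chain_id, resnum, icode in residues:
        by_chain.setdefault(chain_id, []).append((resnum, icode))
    parts: List[str] = []
    for chain_id in sorted(by_chain):
        items = sorted(set(by_chain[chain_id]))
        specs: List[str] = []
        run_start: Optional[int] = None
        run_end: Optional[int] = None

        def flush() -> None:
            nonlocal run_start, run_end
            if run_start is None:
                return
            if run_end == run_start:
                specs.append(str(run_start))
            else:
                specs.append(f"{run_start}-{run_end}")
            run_start = run_end = None

        for resnum, icode in items:
            if icode:
                flush()
                specs.append(f"{resnum}{icode}")
                continue
            if run_start is not None and resnum == run_end + 1:
                run_end = resnum
            else:
                flush()
                run_start = run_end = resnum
        flush()
        parts.append(f"/{chain_id}:{','.join(specs)}")
    return "".join(parts)


def parse_selector(selector: str) -> List[ResidueSpec]:
    """Inverse of :func:`build_selector`: expand a selector back into
    (chain, resnum, icode) triples."""
    out: List[ResidueSpec] = []
    for chunk in selector.split("/"):
        chunk = chunk.strip()
        if not chunk:
            continue
        chain_id, _, spec = chunk.partition(":")
        for item in spec.split(","):
            item = item.strip()
            if not item:
                continue
            if "-" in item:
                lo, hi = item.split("-")
                for num in range(int(lo), int(hi) + 1):
                    out.append((chain_id, num, ""))
            else:
                digits = item
                icode = ""
                while digits and digits[-1].isalpha():
                    icode = digits[-1] + icode
                    digits = digits[:-1]
                out.append((chain_id, int(digits), icode))
    return out


def _residues_of(rows: pd.DataFrame) -> List[ResidueSpec]:
    specs = set()
    for _, r in rows.iterrows():
        icode = r["icode"]
        specs.add((str(r["chain_id"]), int(r["resnum"]),
                   "" if icode in (None, "", ".") or pd.isna(icode) else str(icode)))
    return sorted(specs)


def make_visualization(
    mapped: pd.DataFrame,
    outdir: str | Path,
    palette: Optional[Dict[str, str]] = None,
    structure_paths: Optional[Dict[str, str]] = None,
) -> Dict[str, Path]:
    """Write one ChimeraX ``.cxc`` script per structure with mapped variants.

    ``structure_paths`` optionally maps structure IDs to file paths for the
    ``open`` command; the bare structure ID is used otherwise. Returns the
    mapping of structure ID to script path.
    """
    colors = dict(DEFAULT_PALETTE)
    if palette:
        colors.update(palette)
    outdir = Path(outdir)
    scripts: Dict[str, Path] = {}
    visible = mapped[mapped["class"].isin(["interface", "structure"])]
    structure_ids = sorted(visible["structure_id"].dropna().unique())
    skipped = sorted(
        set(mapped["structure_id"].dropna().unique()) - set(structure_ids)
    )
    for sid in skipped:
        logger.info("structure %s has only unmapped/non-coding rows; no script", sid)
    if not structure_ids:
        return scripts
    outdir.mkdir(parents=True, exist_ok=True)
    for sid in structure_ids:
        rows = visible[visible["structure_id"] == sid]
        lines: List[str] = ["# struct3dmap visualization script"]
        legend: Dict[ResidueSpec, List[str]] = {}
        for _, r in rows.iterrows():
            icode = r["icode"]
            spec = (str(r["chain_id"]), int(r["resnum"]),
                    "" if icode in (None, "", ".") or pd.isna(icode) else str(icode))
            legend.setdefault(spec, []).append(str(r["variant_id"]))
        for spec in sorted(legend):
            sel = build_selector([spec])
            lines.append(f"# {sel} {','.join(sorted(set(legend[spec])))}")
        open_target = (structure_paths or {}).get(sid, sid)
        lines.append(f"open {open_target}")
        lines.append("hide atoms")
        lines.append("show cartoon")
        lines.append(f"color {colors['base']}")
        for cls in ("structure", "interface"):
            cls_rows = rows[rows["class"] == cls]
            if cls_rows.empty:
                continue
            sel = build_selector(_residues_of(cls_rows))
            lines.append(f"color {sel} {colors[cls]}")
            lines.append(f"show {sel} atoms")
        path = outdir / f"{sanitize_id(str(sid))}.cxc"
        path.write_text("\n".join(lines) + "\n")
        scripts[str(sid)] = path
    return scripts
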