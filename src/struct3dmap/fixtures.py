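"""Synthetic structures, proteomes and variant files with known ground truth.

Everything the pipeline consumes can be generated here deterministically, so
every stage is testable without downloading a single real structure. Chains
are laid out as ideal extended C-alpha traces (3.8 A spacing along x) at
controlled y-offsets, which makes inter-chain contact sets exactly
predictable: two parallel strands d apart have aligned-residue distances of
exactly d and next-neighbour distances of sqrt(d^2 + 3.8^2). Ground-truth
interface sets are computed by an independent all-pairs distance scan over
the generated coordinates — never by the production interface code.

Physical realism is a non-goal; exact control of contacts, numbering quirks
(insertion codes, author-numbering gaps), mutations and pLDDT-style
B-factors is the point.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import gemmi

__all__ = [
    "ChainSpec",
    "FixtureSpec",
    "VariantSpec",
    "make_structure_fixture",
    "make_variant_fixture",
    "demo_fixture_tree",
]

CA_SPACING = 3.8  # A between consecutive C-alphas in an extended trace

_AA1 = "ACDEFGHIKLMNPQRSTVWY"
_ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}
_NT_TO_NAME = {"A": "DA", "C": "DC", "G": "DG", "T": "DT"}


@dataclass
class ChainSpec:
    """Recipe for one chain (or ligand/water entity) of a fixture structure.

    ``mutations`` are applied to the generated reference sequence, so the
    written chain differs from the reference by exactly those substitutions;
    the reference acts as the unmutated query for Pident ground truth.
    """

    chain_id: str
    kind: str = "protein"  # protein | nucleic | ligand | water
    length: int = 10
    sequence: Optional[str] = None  # reference sequence; random when None
    component: str = "HEM"  # ligand/water component code
    y_offset: float = 0.0
    z_offset: float = 0.0
    x_shift: int = 0  # placement offset in residue units along x
    start_resnum: int = 1
    numbering_gaps: Dict[int, int] = field(default_factory=dict)  # pos -> extra jump
    insertion_positions: List[int] = field(default_factory=list)  # reuse prev resnum + icode
    mutations: List[Tuple[int, str]] = field(default_factory=list)  # (pos, new_aa)
    bfactors: Optional[List[float]] = None  # per-residue; default 90 + i * 0.1
    extra_atoms: List[Tuple[int, str, str, float, float, float]] = field(
        default_factory=list
    )  # (pos, atom_name, element, dx, dy, dz)


@dataclass
class FixtureSpec:
    structure_id: str
    chains: List[ChainSpec]
    cutoff: float = 5.0
    seed: int = 0
    spacing: float = CA_SPACING


@dataclass
class VariantSpec:
    """One designed variant row with its expected mapped class."""

    variant_id: str
    transcript_id: str
    protein_pos: Optional[int]
    aa_ref: Optional[str] = None
    aa_alt: Optional[str] = None
    consequence: str = "missense_variant"
    expected_class: str = "structure"
    gene_id: str = "GENE1"


def _random_seq(rng: random.Random, n: int, alphabet: str = _AA1) -> str:
    return "".join(rng.choice(alphabet) for _ in range(n))


def _chain_numbering(spec: ChainSpec) -> List[Tuple[int, str]]:
    """Author (resnum, icode) for each 1-based sequence position."""
    keys: List[Tuple[int, str]] = []
    num = spec.start_resnum - 1
    for pos in range(1, spec.length + 1):
        if pos in spec.insertion_positions and keys:
            keys.append((keys[-1][0], "A"))
            continue
        num += 1 + spec.numbering_gaps.get(pos, 0)
        keys.append((num, ""))
    return keys


def _build_chain_atoms(
    spec: ChainSpec, rng: random.Random, spacing: float
) -> Tuple[str, str, List[Tuple[int, str]], List[dict]]:
    """Returns (reference_seq, observed_seq, keys, residue dicts with atoms)."""
    if spec.kind in ("ligand", "water"):
        name = spec.component if spec.kind == "ligand" else "HOH"
        element = "FE" if spec.kind == "ligand" and spec.component == "HEM" else (
            "O" if spec.kind == "water" else "C"
        )
        x = spec.x_shift * spacing
        res = {
            "name": name,
            "resnum": spec.start_resnum,
            "icode": "",
            "het": True,
            "bfactor": 30.0,
            "atoms": [(element, element, x, spec.y_offset, spec.z_offset)],
        }
        return "", "", [(spec.start_resnum, "")], [res]

    alphabet = _AA1 if spec.kind == "protein" else "ACGT"
    ref = spec.sequence if spec.sequence is not None else _random_seq(
        rng, spec.length, alphabet
    )
    if len(ref) != spec.length:
        raise ValueError("sequence length does not match spec length")
    observed = list(ref)
    for pos, new_aa in spec.mutations:
        if not 1 <= pos <= spec.length:
            raise ValueError(f"mutation position {pos} outside chain")
        observed[pos - 1] = new_aa
    observed_seq = "".join(observed)
    keys = _chain_numbering(spec)
    bfs = spec.bfactors or [90.0 + 0.1 * i for i in range(spec.length)]
    residues: List[dict] = []
    extra_by_pos: Dict[int, List[Tuple[str, str, float, float, float]]] = {}
    for pos, aname, elem, dx, dy, dz in spec.extra_atoms:
        extra_by_pos.setdefault(pos, []).append((aname, elem, dx, dy, dz))
    for i, aa in enumerate(observed_seq, start=1):
        x = (spec.x_shift + i - 1) * spacing
        if spec.kind == "protein":
            name = _ONE_TO_THREE[aa]
            atoms = [("CA", "C", x, spec.y_offset, spec.z_offset)]
        else:
            name = _NT_TO_NAME[aa]
            atoms = [("C1'", "C", x, spec.y_offset, spec.z_offset)]
        for aname, elem, dx, dy, dz in extra_by_pos.get(i, []):
            atoms.append((aname, elem, x + dx, spec.y_offset + dy, spec.z_offset + dz))
        resnum, icode = keys[i - 1]
        residues.append(
            {
                "name": name,
                "resnum": resnum,
                "icode": icode,
                "het": False,
                "bfactor": bfs[i - 1],
                "atoms": atoms,
            }
        )
    return ref, observed_seq, keys, residues


def _ground_truth_interfaces(
    chain_data: Dict[str, dict], cutoff: float
) -> List[dict]:
    """Independent O(n^2) heavy-atom distance scan over generated coordinates."""
    out: List[dict] = []
    ids = sorted(chain_data)
    for cid in ids:
        me = chain_data[cid]
        if me["kind"] != "protein":
            continue
        for pid in ids:
            other = chain_data[pid]
            if pid == cid or other["kind"] == "water":
                continue
            for res in me["residues"]:
                dmin = math.inf
                for _, el, x, y, z in res["atoms"]:
                    if el in ("H", "D"):
                        continue
                    for ores in other["residues"]:
                        for _, oel, ox, oy, oz in ores["atoms"]:
                            if oel in ("H", "D"):
                                continue
                            d = math.dist((x, y, z), (ox, oy, oz))
                            dmin = min(dmin, d)
                if dmin <= cutoff:
                    out.append(
                        {
                            "chain_id": cid,
                            "resnum": res["resnum"],
                            "icode": res["icode"],
                            "partner_entity": other["entity_id"],
                            "partner_type": other["kind"],
                            "min_distance": round(dmin, 6),
                        }
                    )
    return out


def _write_gemmi(
    structure_id: str, chain_data: Dict[str, dict], outdir: Path
) -> Dict[str, Path]:
    st = gemmi.Structure()
    st.name = structure_id
    model = gemmi.Model(1)
    # group entities back by author chain for writing
    by_author: Dict[str, List[dict]] = {}
    for cid in sorted(chain_data):
        data = chain_data[cid]
        by_author.setdefault(data["author_chain"], []).extend(data["residues"])
    for author_chain in sorted(by_author):
        chain = gemmi.Chain(author_chain)
        for res in by_author[author_chain]:
            r = gemmi.Residue()
            r.name = res["name"]
            r.seqid = gemmi.SeqId(res["resnum"], res["icode"] or " ")
            r.het_flag = "H" if res["het"] else "A"
            for aname, elem, x, y, z in res["atoms"]:
                a = gemmi.Atom()
                a.name = aname
                a.element = gemmi.Element(elem)
                a.pos = gemmi.Position(x, y, z)
                a.occ = 1.0
                a.b_iso = res["bfactor"]
                r.add_atom(a)
            chain.add_residue(r)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    outdir.mkdir(parents=True, exist_ok=True)
    pdb_path = outdir / f"{structure_id}.pdb"
    cif_path = outdir / f"{structure_id}.cif"
    st.write_pdb(str(pdb_path))
    st.make_mmcif_document().write_file(str(cif_path))
    return {"pdb": pdb_path, "cif": cif_path}


def make_structure_fixture(
    spec: FixtureSpec, outdir: str | Path, write_cif: bool = True
) -> dict:
    """Write a fixture structure as .pdb and .cif plus a ground-truth JSON.

    The ground truth records, per chain: the reference (unmutated) sequence,
    the observed sequence, author residue keys, the expected Pident of the
    reference aligned to the observed chain, and the expected interface set
    at the spec's cutoff (verified by the internal brute-force scan, not by
    the production interface code).
    """
    outdir = Path(outdir)
    rng = random.Random(spec.seed)
    chain_data: Dict[str, dict] = {}
    for cs in spec.chains:
        if cs.y_offset < 0 and cs.kind == "protein":
            pass  # negative offsets are fine; only validate separations below
        ref, observed, keys, residues = _build_chain_atoms(cs, rng, spec.spacing)
        if cs.kind == "ligand":
            entity_id = f"{cs.chain_id}:{cs.component}:{cs.start_resnum}"
        elif cs.kind == "water":
            entity_id = f"{cs.chain_id}:water"
        else:
            entity_id = cs.chain_id
        if entity_id in chain_data:
            raise ValueError(f"duplicate entity {entity_id}")
        # only effective substitutions reduce identity
        n_mut = sum(1 for a, b in zip(ref, observed) if a != b)
        chain_data[entity_id] = {
            "author_chain": cs.chain_id,
            "entity_id": entity_id,
            "kind": cs.kind,
            "reference_seq": ref,
            "observed_seq": observed,
            "keys": keys,
            "residues": residues,
            "expected_pident": (
                100.0 * (cs.length - n_mut) / cs.length
                if cs.kind in ("protein", "nucleic")
                else None
            ),
        }
    paths = _write_gemmi(spec.structure_id, chain_data, outdir)
    truth = {
        "structure_id": spec.structure_id,
        "cutoff": spec.cutoff,
        "seed": spec.seed,
        "chains": {
            cid: {
                "kind": d["kind"],
                "reference_seq": d["reference_seq"],
                "observed_seq": d["observed_seq"],
                "keys": d["keys"],
                "expected_pident": d["expected_pident"],
            }
            for cid, d in sorted(chain_data.items())
        },
        "interfaces": _ground_truth_interfaces(chain_data, spec.cutoff),
    }
    truth_path = outdir / f"{spec.structure_id}.truth.json"
    truth_path.write_text(json.dumps(truth, indent=1, sort_keys=True))
    result = {"structure_id": spec.structure_id, "truth": truth, **paths,
              "truth_path": truth_path}
    if not write_cif:
        paths["cif"].unlink()
        del result["cif"]
    return result


_VEP_COLUMNS = [
    "#Uploaded_variation", "Location", "Allele", "Gene", "Feature",
    "Feature_type", "Consequence", "cDNA_position", "CDS_position",
    "Protein_position", "Amino_acids", "Codons", "Existing_variation", "Extra",
]


def make_variant_fixture(
    variants: Sequence[VariantSpec], out_path: str | Path,
    truth_path: Optional[str | Path] = None,
) -> dict:
    """Write a minimal valid VEP tabular file for the designed variants.

    The ground truth records the expected class of every variant and the
    expected class histogram after mapping against the companion structure
    fixture.
    """
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    lines = ["\t".join(_VEP_COLUMNS)]
    for i, v in enumerate(variants, start=1):
        if v.protein_pos is not None:
            ppos = str(v.protein_pos)
            aas = (
                f"{v.aa_ref}/{v.aa_alt}"
                if v.aa_ref and v.aa_alt
                else (v.aa_ref or "-")
            )
        else:
            ppos, aas = "-", "-"
        lines.append(
            "\t".join(
                [
                    v.variant_id, f"1:{1000 + 3 * i}", "A", v.gene_id,
                    v.transcript_id, "Transcript", v.consequence, "-", "-",
                    ppos, aas, "-", "-", "-",
                ]
            )
        )
    out_path.write_text("\n".join(lines) + "\n")
    histogram: Dict[str, int] = {}
    for v in variants:
        histogram[v.expected_class] = histogram.get(v.expected_class, 0) + 1
    truth = {
        "expected_classes": {v.variant_id: v.expected_class for v in variants},
        "expected_histogram": histogram,
    }
    if truth_path is not None:
        Path(truth_path).write_text(json.dumps(truth, indent=1, sort_keys=True))
    return {"path": out_path, "truth": truth}


def demo_fixture_tree(outdir: str | Path, seed: int = 0) -> dict:
    """The canonical end-to-end scenario used by tests and the worked example.

    One 12-residue query protein whose first 10 residues exactly match chain A
    of the fixture structure; a 2-residue chain B sits 4.5 A away opposite
    positions 3-4, so at the 5.0 A cutoff exactly positions 3 and 4 of the
    query are interface residues. Five designed variants then map to
    2 interface, 1 structure, 1 unmapped and 1 non-coding.
    """
    outdir = Path(outdir)
    rng = random.Random(seed)
    chain_a_seq = _random_seq(rng, 10)
    tail = _random_seq(rng, 2)
    query_seq = chain_a_seq + tail

    spec = FixtureSpec(
        structure_id="demo1",
        seed=seed,
        cutoff=5.0,
        chains=[
            ChainSpec(chain_id="A", length=10, sequence=chain_a_seq),
            ChainSpec(chain_id="B", length=2, sequence=_random_seq(rng, 2),
                      y_offset=4.5, x_shift=2),
        ],
    )
    structures_dir = outdir / "structures"
    fixture = make_structure_fixture(spec, structures_dir)

    proteome = outdir / "proteome.fasta"
    proteome.write_text(f">PROT1\n{query_seq}\n")

    def aa(pos: int) -> str:
        return query_seq[pos - 1]

    variants = [
        VariantSpec("var_if_1", "TX1.2", 3, aa(3), "W" if aa(3) != "W" else "F",
                    expected_class="interface"),
        VariantSpec("var_if_2", "TX1.2", 4, aa(4), "W" if aa(4) != "W" else "F",
                    expected_class="interface"),
        VariantSpec("var_st_1", "TX1.2", 1, aa(1), "W" if aa(1) != "W" else "F",
                    expected_class="structure"),
        VariantSpec("var_un_1", "TX1.2", 11, aa(11), "W" if aa(11) != "W" else "F",
                    expected_class="unmapped"),
        VariantSpec("var_nc_1", "TX1.2", None, consequence="intron_variant",
                    expected_class="non-coding"),
    ]
    variant_fixture = make_variant_fixture(
        variants, outdir / "variants.vep", outdir / "variants.truth.json"
    )

    idmap = outdir / "idmap.tsv"
    idmap.write_text("transcript_id\tprotein_id\nTX1\tPROT1\n")

    return {
        "outdir": outdir,
        "structures_dir": structures_dir,
        "structure": fixture,
        "proteome": proteome,
        "query_seq": query_seq,
        "chain_a_seq": chain_a_seq,
        "variants": variant_fixture,
        "variant_specs": variants,
        "idmap": idmap,
        "expected_histogram": variant_fixture["truth"]["expected_histogram"],
    }
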