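# struct3dmap

Map annotated protein positions and genetic variants onto protein
structures — at any scale, for any organism.

Interpreting coding variants is far easier with structural context: whether
a mutated residue sits at a protein–protein, protein–ligand or
protein–nucleic interface, and how reliable the model underneath it is.
Getting there is tedious because residue numbering in structure files
(author numbers, insertion codes, gaps, engineered constructs) rarely lines
up with protein database coordinates, and most existing mapping services
are web-based and unsuited to biobank-scale input. `struct3dmap` is a
stand-alone library + CLI that does the whole mapping locally and
reproducibly.

## The method

Four composable commands:

1. **makestructuraldb** — aligns every proteome sequence (FASTA) to the
   observed chain sequences of a directory of `.pdb`/`.cif` files with
   Smith–Waterman local alignment (BLOSUM62, affine gaps 11/1,
   Karlin–Altschul bit scores and e-values; optional external BLAST+
   backend). Alignments are kept when **Pident ≥ 50 %** and
   **e-value ≤ 1e-5** (both configurable). For every structure it computes
   inter-chain interfaces: residue *r* contacts entity *E* iff
   min heavy-atom distance(r, E) ≤ *d* (default **5.0 Å**), with every
   ligand instance a distinct interface and waters/hydrogens excluded.
   Interface annotations then pass a redundancy filter: alignments below
   **80 % Pident** are dropped and, per (protein, partner type), only the
   structure with the highest Pident survives. Output: one TSV of
   per-position structural annotations per protein ID (pipe characters in
   IDs are sanitized in filenames only), plus a JSON manifest.
2. **makevariantsdb** — normalizes VEP tabular, VEP-like, MAF or
   VEP-annotated VCF input into per-transcript variant files (protein
   position intervals preserved; transcript versions stripped for matching).
3. **mapper** — joins the two databases through a transcript→protein ID map
   and classifies every variant row as **interface**, **structure**,
   **unmapped** or **non-coding**. Optional filters: consequence terms,
   minimum Pident, minimum pLDDT (B-factor), and minimum pDockQ (> 0.23 by
   default) when a per-model score table is supplied. Output: a long-format
   table (CSV or HDF5), a per-variant best-class summary, and a SetID file
   for rare-variant association testing.
4. **makevisualization** — ChimeraX `.cxc` scripts coloring the mapped
   residues by class.

B-factors travel with every mapped residue, so AlphaFold-style models carry
their per-residue pLDDT into the final table.

## Worked example

Everything below runs offline on generated toy data:

```bash
struct3dmap fixtures --out demo --seed 1
struct3dmap makestructuraldb --proteome demo/proteome.fasta \
    --structures demo/structures --out demo/protdb
# proteins covered: 1/1  structures: 1  alignments kept: 1
struct3dmap makevariantsdb --input demo/variants.vep --out demo/vardb
# 5 records over 1 transcripts -> demo/vardb
struct3dmap mapper --protdb demo/protdb --vardb demo/vardb \
    --idmap demo/idmap.tsv --out demo/mapped
# mapped rows: 5  classes: {'interface': 2, 'structure': 1, 'unmapped': 1, 'non-coding': 1}
struct3dmap makevisualization --mapped demo/mapped/mapped.csv --out demo/viz
# 1 scripts -> demo/viz
```

The fixture is a 12-residue query protein whose first 10 residues match
chain A of a two-chain toy structure; chain B sits 4.5 Å away opposite
positions 3–4. The five designed variants therefore classify as exactly
2 interface (positions 3, 4), 1 structure (position 1), 1 unmapped
(position 11, beyond the template) and 1 non-coding (an intron consequence
with no protein position). The SetID file groups the two interface variants
into the set `PROT1_interface_B`, and `demo/viz/demo1.cxc` colors `/A:3-4`
red and `/A:1` blue.

## Layout

- `src/struct3dmap/structure_io.py` — PDB/mmCIF parsing into a uniform model
- `src/struct3dmap/homology.py` — local alignment, Pident/e-value filtering,
  position maps
- `src/struct3dmap/interfaces.py` — distance-based interfaces + redundancy
  removal
- `src/struct3dmap/structdb.py`, `variantdb.py`, `mapper.py`,
  `visualization.py` — the four pipeline commands
- `src/struct3dmap/fixtures.py` — deterministic synthetic structures,
  proteomes and variant files with known ground truth
- `docs/methods.md` — model, parameters, numerical choices, limitations
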