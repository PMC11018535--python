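# Methods

## The mapping model

The pipeline transfers annotations between two coordinate systems: protein
database coordinates (1-based positions in a proteome FASTA sequence) and
structure coordinates (author chain ID, author residue number, insertion
code). The bridge is a local sequence alignment between the query protein
and the *observed* chain sequence — the one-letter translation of the
residues that actually have coordinates, in author order. SEQRES-derived
sequences are deliberately not used: a residue without coordinates cannot
carry a variant spatially, and aligning against unobserved residues would
manufacture mappings to nothing. The `seq_to_key` table built during
parsing is exact (insertion codes included, numbering gaps skipped, no gap
characters), so alignment columns translate directly into author residue
keys.

A variant maps through transcript → protein → alignment column → residue
key, and is classified by what it lands on:

| class | condition |
|---|---|
| interface | covering annotation row has ≥ 1 interface contact |
| structure | covered, no contact flags |
| unmapped | protein position exists, no row covers it |
| non-coding | no protein position at all |

A variant covered by several structures yields several rows; the
per-variant summary keeps the best class under
interface > structure > unmapped > non-coding.

## Structure parsing

gemmi parses both PDB and mmCIF. One deterministic coordinate set is kept
per file: model 1 of multi-model entries, and per atom name the
highest-occupancy altloc (ties → alphabetically first altloc ID). Author
chains are split into entities: one polymer chain model (protein if > 50 %
of polymer residues are amino acids, nucleic if > 50 % are nucleotides),
one entity per non-polymer ligand instance (`A:HEM:201`), and a per-chain
water group. Modified polymer residues (MSE and similar) stay in their
chain and translate to the parent letter; unknown components become `X`. A
residue is "observed" with ≥ 1 heavy atom, so Cα-only models remain
mappable. Mean per-residue B-factor is carried through to output — for
AlphaFold-style models this is the pLDDT.

## Alignment and statistics

The internal aligner is Smith–Waterman with affine gaps (Gotoh three-state
recursion): BLOSUM62, gap open 11, extend 1 — the standard protein-search
defaults, chosen so that the optional external BLAST+ backend is
drop-in-comparable. A gap of length L costs 11 + L. Traceback is
deterministic: diagonal beats a gap in the subject beats a gap in the
query; among equal-scoring end cells the smallest (query, subject)
coordinate wins. Raw scores convert to bit scores and e-values with
Karlin–Altschul statistics (gapped BLOSUM62 parameters λ = 0.267,
K = 0.041) over an m·n pairwise search space; there is no database-length
correction in pairwise mode, so e-values from the BLAST backend can differ
slightly.

Pident is 100 · identities / alignment length *including gap columns* (the
BLAST tabular convention), and `X` never counts as an identity — even
against another `X` — so wildcards cannot inflate identity. Default
retention thresholds are Pident ≥ 50 % and e-value ≤ 1e-5, both inclusive.
One alignment (the best-scoring) is retained per (query, structure, chain).

Note that when two different local alignments share the optimal score, the
identity count of the reported one depends on tie-breaking; score is
invariant under swapping query and subject, identity count is guaranteed
invariant only when the optimum is unique.

## Interfaces

Residue r of a protein chain is an interface residue toward entity E iff
the minimum heavy-atom–heavy-atom Euclidean distance between r and any
residue of E is ≤ the cutoff. The default cutoff is 5.0 Å — the common
contact convention — and is fully user-configurable. Hydrogens and waters
are excluded; intra-chain contacts are not reported; each ligand instance
is its own interface. The production scan uses a per-entity KD-tree but is
specified (and tested) to be set-identical to the O(n²) all-pairs scan; the
tree query bound is inflated by 1e-9 relatively and re-filtered because the
contact definition is inclusive at the cutoff.

Redundancy removal applies to interface annotations only (plain coverage
rows are untouched): records mapped through alignments below 80 % Pident
are dropped (exactly 80.0 survives), then per (query protein, partner type
∈ {protein, ligand, nucleic}) only the records of the structure with the
highest Pident are kept, ties to the lexicographically smallest structure
ID. The operation is idempotent. The 80 % floor is interpreted against the
local-alignment Pident already computed for the mapping alignment.

## Variant input dialects

VEP tabular columns are located by header name; the VEP-like dialect is the
same parser tolerating extra or missing optional columns. Required columns
are `#Uploaded_variation`, `Feature`, `Consequence`; `Protein_position` and
`Amino_acids` are optional and their absence yields records without protein
positions. Interval positions ("86-88") are preserved and expanded to
per-position queries at mapping time, so in-frame indels are not silently
dropped. MAF input uses `Transcript_ID` and `HGVSp_Short` (`p.H86N`,
three-letter codes and `=` for synonymous accepted). VCF input requires a
CSQ/ANN annotation whose sub-field layout is read from the header
`Format:` description; one record is emitted per transcript consequence. A
VCF without consequence annotation is rejected with a message to run VEP
first — consequence prediction is out of scope. Unparseable amino-acid
strings keep the record, drop the amino-acid fields and count a warning.
Transcript versions are stripped for matching, preserved in output.

## Quality filters at mapping time

Minimum Pident and minimum pLDDT filters restrict which annotation rows can
cover a position. When a per-model pDockQ table is supplied, rows from
models with pDockQ ≤ 0.23 (configurable; comparison strict) are excluded
before classification — 0.23 is the published acceptability threshold for
predicted complexes. Positions whose every covering row is filtered away
classify as unmapped. The reference-allele check (variant `aa_ref` vs the
query residue) sets a `ref_mismatch` flag rather than dropping the row.

## Determinism and parallelism

All outputs are written in fixed order (protein, structure, chain,
position) with fixed numeric formatting, so two runs are byte-identical.
Per-protein work in the database build is independent; with `--jobs N` it
runs in a fork-based pool and the parent writes collected results in sorted
order, so parallel output equals serial output bytewise.

## Synthetic data

The fixture generator lays chains out as ideal extended Cα traces (3.8 Å
spacing) at controlled offsets, which makes contact sets exactly
predictable (aligned residues of two parallel strands d Å apart are at
exactly d; next neighbours at √(d² + 3.8²)). It writes each structure in
both PDB and mmCIF form, supports insertion codes, author-numbering gaps,
point mutations, per-residue B-factors, ligand/water/nucleic entities and
extra atoms (e.g. hydrogens), and emits a ground-truth JSON whose interface
set comes from its own all-pairs scan — never from the production code
path. The canonical end-to-end scenario is a 12-residue query over a
10-residue template with a 2-residue partner chain at 4.5 Å opposite
positions 3–4, plus five designed variants (2 interface / 1 structure /
1 unmapped / 1 non-coding).

What the fixtures do *not* emulate: realistic side-chain geometry, packing
density, crystallographic artifacts, large multi-domain proteins,
alternative splicing and genuinely ambiguous homology. Passing tests
demonstrate coordinate bookkeeping, threshold semantics and algorithmic
correctness at desk scale; they do not measure biological accuracy of
interface calls on real complexes, nor proteome-scale coverage statistics.
Test and acceptance problem sizes (sequences ≤ 40 residues, 50-structure
oracle sweeps, a 3-protein coverage scenario) were chosen as the smallest
sizes that exercise every code path with exact expected values.

## Known limitations

- No biological-assembly expansion: interfaces are computed within the
  deposited asymmetric unit, so crystal-contact and symmetry-mate
  interfaces are invisible.
- No ΔSASA-based interface definition; the distance criterion is the only
  one offered.
- The internal aligner is quadratic per pair; for large proteomes against
  many structures the BLAST+ backend is the practical choice.
- e-values assume pairwise search-space statistics and one published λ/K
  pair per matrix; unusual matrix/gap combinations fall back to ungapped
  parameters.
- SetID grouping policies cover per-protein, per-interface and
  per-structure-class sets; finer region definitions (e.g. per-domain)
  require post-processing.
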