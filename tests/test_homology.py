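"""Alignment correctness against an exhaustive oracle; thresholds; maps."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import sw_score_bruteforce
from struct3dmap.fixtures import ChainSpec, FixtureSpec, make_structure_fixture
from struct3dmap.homology import (
    _BLOSUM62,
    ChainAlignment,
    blast_align,
    build_position_map,
    filter_alignments,
    local_align,
)
from struct3dmap.structure_io import ResidueKey, parse_structure

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def _rand_seq(rng, n):
    return "".join(rng.choice(AA20) for _ in range(n))


class TestLocalAlign:
    def test_identity_self_alignment(self):
        rng = random.Random(0)
        seq = _rand_seq(rng, 30)
        aln = local_align(seq, seq)
        assert aln.pident == 100.0
        assert aln.n_identical == 30
        assert aln.colmap == [(i, i) for i in range(1, 31)]
        assert aln.qstart == aln.sstart == 1 and aln.qend == aln.send == 30

    @pytest.mark.parametrize("seed", range(25))
    def test_score_matches_bruteforce_oracle(self, seed):
        rng = random.Random(seed)
        q = _rand_seq(rng, rng.randint(4, 12))
        s = _rand_seq(rng, rng.randint(4, 12))
        expected = sw_score_bruteforce(q, s, _BLOSUM62, 11, 1)
        assert local_align(q, s).score == pytest.approx(expected)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_score_is_symmetric(self, seed):
        rng = random.Random(seed)
        q = _rand_seq(rng, rng.randint(3, 15))
        s = _rand_seq(rng, rng.randint(3, 15))
        assert local_align(q, s).score == local_align(s, q).score

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_identity_count_symmetric_for_unique_optimum(self, seed):
        # a planted shared 8-mer makes the optimal local alignment unique,
        # so the identity count cannot depend on argument order
        rng = random.Random(seed)
        core = _rand_seq(rng, 8)
        q = _rand_seq(rng, 4) + core + _rand_seq(rng, 3)
        s = _rand_seq(rng, 2) + core + _rand_seq(rng, 5)
        assert local_align(q, s).n_identical == local_align(s, q).n_identical

    def test_x_never_counts_as_identity(self):
        aln = local_align("AXAXA", "AXAXA")
        assert aln.n_identical == 3  # only the three A columns
        assert aln.pident == pytest.approx(60.0)

    def test_invalid_character_is_named(self):
        with pytest.raises(ValueError, match="'J'"):
            local_align("AJA", "AAA")

    def test_gap_costs_are_affine(self):
        # deleting the WW block in one 2-gap (48 - 13 = 35) must beat both
        # the 2-mismatch path (34) and the ungapped sub-alignment (24)
        aln = local_align("AAAAAAWWAAAAAA", "AAAAAAAAAAAA")
        assert aln.score == pytest.approx(35.0)
        gap_idx = [i for i, (_, s) in enumerate(aln.colmap) if s is None]
        assert len(gap_idx) == 2
        assert gap_idx[1] == gap_idx[0] + 1  # single gap opening


class TestAgainstBiopython:
    @pytest.mark.parametrize("seed", range(10))
    def test_scores_match_pairwise_aligner(self, seed):
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = Align.substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -12.0  # open 11 + first extension 1
        aligner.extend_gap_score = -1.0
        rng = random.Random(seed)
        q = _rand_seq(rng, rng.randint(10, 40))
        s = _rand_seq(rng, rng.randint(10, 40))
        assert local_align(q, s).score == pytest.approx(aligner.score(q, s))


class TestFilterAlignments:
    def _aln(self, pident, evalue):
        return ChainAlignment(
            query_id="q", structure_id="s", chain_id="A", qstart=1, qend=10,
            sstart=1, send=10, n_identical=10, aln_len=10, pident=pident,
            evalue=evalue, bitscore=50.0,
        )

    def test_boundaries_are_inclusive(self):
        kept = filter_alignments(
            [self._aln(100.0, 0.0), self._aln(50.0, 1e-5),
             self._aln(49.9, 1e-9), self._aln(80.0, 1e-3)],
            pident_min=50.0, evalue_max=1e-5,
        )
        assert [(a.pident, a.evalue) for a in kept] == [(100.0, 0.0), (50.0, 1e-5)]

    def test_raising_pident_never_adds_alignments(self):
        rng = random.Random(1)
        alns = [self._aln(rng.uniform(0, 100), 10 ** -rng.uniform(0, 10))
                for _ in range(40)]
        sizes = [len(filter_alignments(alns, pident_min=t)) for t in range(0, 101, 5)]
        assert sizes == sorted(sizes, reverse=True)


class TestPositionMap:
    def test_identity_map_onto_offset_numbering(self, tmp_path):
        spec = FixtureSpec(
            structure_id="off1",
            chains=[ChainSpec(chain_id="A", length=8, start_resnum=5)],
        )
        fx = make_structure_fixture(spec, tmp_path)
        chain = parse_structure(fx["pdb"]).get_chain("A")
        aln = local_align(chain.seq, chain.seq, query_id="q",
                          structure_id="off1", chain_id="A")
        pm = build_position_map(aln, chain, chain.seq)
        assert pm.entries[1][0] == ResidueKey("A", 5, "")
        assert pm.entries[8][0] == ResidueKey("A", 12, "")
        assert all(entry[2] for entry in pm.entries.values())  # all identities

    def test_query_insertion_positions_absent_from_map(self, tmp_path):
        spec = FixtureSpec(
            structure_id="ins2", seed=0, chains=[ChainSpec(chain_id="A", length=12)],
        )
        fx = make_structure_fixture(spec, tmp_path)
        chain = parse_structure(fx["pdb"]).get_chain("A")
        # query = chain sequence with 2 residues inserted in the middle
        query = chain.seq[:6] + "WW" + chain.seq[6:]
        aln = local_align(query, chain.seq, query_id="q",
                          structure_id="ins2", chain_id="A")
        pm = build_position_map(aln, chain, query)
        inserted = {7, 8}
        if any(q in pm.entries for q in inserted):
            # insertion aligned as mismatch columns instead of a gap is only
            # acceptable if the alignment says so
            gap_q = {q for q, s in aln.colmap if s is None}
            assert not (inserted & gap_q & set(pm.entries))
        gap_positions = {q for q, s in aln.colmap if q is not None and s is None}
        assert gap_positions.isdisjoint(pm.entries)

    def test_every_map_entry_resolves_in_structure(self, two_strand_fixture):
        st = parse_structure(two_strand_fixture["pdb"])
        for chain in st.polymer_chains():
            aln = local_align(chain.seq, chain.seq, structure_id=st.structure_id,
                              chain_id=chain.chain_id)
            pm = build_position_map(aln, chain, chain.seq)
            keys = {r.key for r in chain.residues}
            assert {e[0] for e in pm.entries.values()} <= keys

    def test_subject_position_outside_chain_is_fatal(self, two_strand_fixture):
        st = parse_structure(two_strand_fixture["pdb"])
        chain = st.get_chain("A")
        bad = ChainAlignment(
            query_id="q", structure_id=st.structure_id, chain_id="A",
            qstart=1, qend=2, sstart=1, send=99, n_identical=2, aln_len=2,
            pident=100.0, evalue=0.0, bitscore=10.0,
            colmap=[(1, 1), (2, 99)],
        )
        with pytest.raises(RuntimeError, match="outside chain"):
            build_position_map(bad, chain)


class TestBlastBackend:
    def test_blast_agrees_with_internal_on_identity(self):
        rng = random.Random(5)
        seq = _rand_seq(rng, 40)
        aln = blast_align("q", seq, "s", seq)
        assert aln is not None
        assert aln.pident == pytest.approx(100.0)
        internal = local_align(seq, seq)
        assert aln.n_identical == internal.n_identical
        assert aln.colmap == internal.colmap
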