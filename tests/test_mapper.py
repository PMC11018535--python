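"""Variant-to-structure joining, classification, outputs and SetID files."""

import random

import pandas as pd
import pytest

from struct3dmap.fixtures import VariantSpec, make_variant_fixture
from struct3dmap.mapper import (
    build_setid,
    map_variants,
    read_mapped,
    summarize_by_variant,
    write_outputs,
)
from struct3dmap.structdb import make_structural_db
from struct3dmap.variantdb import make_variants_db


@pytest.fixture(scope="module")
def built_dbs(demo_tree, tmp_path_factory):
    base = tmp_path_factory.mktemp("dbs")
    protdb = base / "protdb"
    vardb = base / "vardb"
    make_structural_db(demo_tree["proteome"], demo_tree["structures_dir"], protdb)
    make_variants_db(demo_tree["variants"]["path"], vardb)
    return {"protdb": protdb, "vardb": vardb, "idmap": demo_tree["idmap"],
            "tree": demo_tree}


@pytest.fixture(scope="module")
def mapped(built_dbs):
    return map_variants(built_dbs["protdb"], built_dbs["vardb"],
                        id_map=built_dbs["idmap"])


class TestClassification:
    def test_designed_class_histogram(self, built_dbs, mapped):
        expected = built_dbs["tree"]["expected_histogram"]
        got = mapped["class"].value_counts().to_dict()
        assert got == expected

    def test_per_variant_classes_match_design(self, built_dbs, mapped):
        truth = built_dbs["tree"]["variants"]["truth"]["expected_classes"]
        summary = summarize_by_variant(mapped).set_index("variant_id")
        for vid, cls in truth.items():
            assert summary.loc[vid, "best_class"] == cls

    def test_every_variant_appears(self, built_dbs, mapped):
        truth = built_dbs["tree"]["variants"]["truth"]["expected_classes"]
        assert set(mapped["variant_id"]) == set(truth)

    def test_non_coding_iff_no_protein_position(self, mapped):
        nc = mapped[mapped["class"] == "non-coding"]
        assert nc["protein_pos"].isna().all()
        other = mapped[mapped["class"] != "non-coding"]
        assert other["protein_pos"].notna().all()

    def test_class_counts_invariant_to_input_order(self, built_dbs, tmp_path):
        vep = built_dbs["tree"]["variants"]["path"]
        lines = vep.read_text().rstrip("\n").split("\n")
        header, rows = lines[0], lines[1:]
        random.Random(3).shuffle(rows)
        shuffled = tmp_path / "shuffled.vep"
        shuffled.write_text("\n".join([header] + rows) + "\n")
        vardb2 = tmp_path / "vardb2"
        make_variants_db(shuffled, vardb2)
        mapped2 = map_variants(built_dbs["protdb"], vardb2,
                               id_map=built_dbs["idmap"])
        base = map_variants(built_dbs["protdb"], built_dbs["vardb"],
                            id_map=built_dbs["idmap"])
        assert (mapped2["class"].value_counts().to_dict()
                == base["class"].value_counts().to_dict())

    def test_unknown_transcript_gets_reason_code(self, built_dbs, tmp_path):
        empty_map = tmp_path / "empty_idmap.tsv"
        empty_map.write_text("transcript_id\tprotein_id\nOTHER\tX1\n")
        m = map_variants(built_dbs["protdb"], built_dbs["vardb"], id_map=empty_map)
        coding = m[m["class"] != "non-coding"]
        assert (coding["class"] == "unmapped").all()
        assert (coding["reason"] == "transcript_not_in_idmap").all()

    def test_identity_id_map(self, built_dbs, tmp_path):
        # identity map: transcript key itself is the protein id -> no protein
        # in structdb, everything coding becomes unmapped
        m = map_variants(built_dbs["protdb"], built_dbs["vardb"], id_map=None)
        coding = m[m["class"] != "non-coding"]
        assert (coding["class"] == "unmapped").all()
        assert (coding["reason"] == "protein_not_in_structdb").all()

    def test_ref_mismatch_flagged_not_dropped(self, built_dbs, tmp_path):
        tree = built_dbs["tree"]
        wrong_ref = "W" if tree["query_seq"][0] != "W" else "F"
        specs = [VariantSpec("vbad", "TX1.2", 1, wrong_ref, "A",
                             expected_class="structure")]
        fx = make_variant_fixture(specs, tmp_path / "bad.vep")
        vardb = tmp_path / "vardb_bad"
        make_variants_db(fx["path"], vardb)
        m = map_variants(built_dbs["protdb"], vardb, id_map=built_dbs["idmap"])
        assert len(m) == 1
        assert m.iloc[0]["class"] == "structure"
        assert bool(m.iloc[0]["ref_mismatch"]) is True


class TestFilters:
    def test_pdockq_threshold(self, built_dbs, tmp_path):
        for score, expect_structural in [(0.20, False), (0.30, True)]:
            table = tmp_path / f"pdockq_{score}.tsv"
            table.write_text(f"structure_id\tpdockq\ndemo1\t{score}\n")
            m = map_variants(built_dbs["protdb"], built_dbs["vardb"],
                             id_map=built_dbs["idmap"], pdockq_table=table)
            structural = m[m["class"].isin(["interface", "structure"])]
            if expect_structural:
                assert len(structural) == 3
                assert (structural["pdockq"] == score).all()
            else:
                assert structural.empty
                coding = m[m["class"] != "non-coding"]
                assert (coding["class"] == "unmapped").all()

    def test_min_plddt_filter(self, built_dbs):
        # fixture pLDDT runs 90.0..90.9; an impossible floor unmaps everything
        m = map_variants(built_dbs["protdb"], built_dbs["vardb"],
                         id_map=built_dbs["idmap"], min_plddt=99.0)
        assert m[m["class"].isin(["interface", "structure"])].empty

    def test_consequence_restriction(self, built_dbs):
        m = map_variants(built_dbs["protdb"], built_dbs["vardb"],
                         id_map=built_dbs["idmap"],
                         consequences=["missense_variant"])
        assert set(m["consequence"]) == {"missense_variant"}
        assert len(m) == 4  # the intron row is excluded

    def test_interval_positions_expand(self, built_dbs, tmp_path):
        specs = [VariantSpec("vint", "TX1.2", 3, "AAA", "A",
                             expected_class="interface")]
        fx = make_variant_fixture(specs, tmp_path / "int.vep")
        # rewrite the Protein_position column as an interval 3-5
        text = fx["path"].read_text().replace("\t3\t", "\t3-5\t")
        fx["path"].write_text(text)
        vardb = tmp_path / "vardb_int"
        make_variants_db(fx["path"], vardb)
        m = map_variants(built_dbs["protdb"], vardb, id_map=built_dbs["idmap"])
        assert sorted(m["protein_pos"]) == [3, 4, 5]
        assert m.set_index("protein_pos")["class"].to_dict() == {
            3: "interface", 4: "interface", 5: "structure",
        }


class TestOutputs:
    def test_csv_and_hdf5_round_trip_identically(self, mapped, tmp_path):
        p_csv = write_outputs(mapped, tmp_path / "csv", fmt="csv")
        p_h5 = write_outputs(mapped, tmp_path / "h5", fmt="hdf5")
        df_csv = read_mapped(p_csv["table"])
        df_h5 = read_mapped(p_h5["table"])
        assert len(df_csv) == len(df_h5) == len(mapped)
        key = ["variant_id", "protein_pos", "structure_id", "class"]

        def norm(df):
            out = df[key].copy()
            out["protein_pos"] = pd.to_numeric(out["protein_pos"], errors="coerce")
            out = out.astype({"variant_id": str, "structure_id": str, "class": str})
            return out.sort_values(key).reset_index(drop=True)

        pd.testing.assert_frame_equal(norm(df_csv), norm(df_h5))

    def test_unknown_format_fatal(self, mapped, tmp_path):
        with pytest.raises(ValueError, match="format"):
            write_outputs(mapped, tmp_path, fmt="parquet")

    def test_empty_table_writes_header_only(self, mapped, tmp_path):
        empty = mapped.iloc[0:0]
        paths = write_outputs(empty, tmp_path / "empty", fmt="csv")
        lines = paths["table"].read_text().strip().split("\n")
        assert len(lines) == 1  # header only
        assert paths["setid"].read_text() == ""

    def test_setid_groupings(self, mapped):
        per_iface = build_setid(mapped, "per-interface")
        assert per_iface == [
            ("PROT1_interface_B", "var_if_1"),
            ("PROT1_interface_B", "var_if_2"),
        ]
        per_protein = build_setid(mapped, "per-protein")
        assert {v for _, v in per_protein} == {"var_if_1", "var_if_2", "var_st_1"}
        per_class = build_setid(mapped, "per-structure-class")
        assert ("PROT1_interface", "var_if_1") in per_class
        assert ("PROT1_structure", "var_st_1") in per_class

    def test_setid_pairs_unique(self, mapped):
        pairs = build_setid(mapped, "per-interface")
        assert len(pairs) == len(set(pairs))
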