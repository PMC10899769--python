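import numpy as np
import pandas as pd
import pytest

from teprofile.catalog import (
    AnnotationError,
    CladeTable,
    DEFAULT_CLADES,
    GenomeLayout,
    apply_exclusions,
    assign_clades,
    occupancy,
    partition_repetitive,
    read_repeat_annotation,
    write_catalog_bed,
)

from conftest import make_catalog
from oracles import partition_per_base, union_bp


class TestReadAnnotation:
    def test_gtf_coordinates_converted_to_half_open(self, tmp_path, toy_genome):
        gtf = tmp_path / "r.gtf"
        gtf.write_text(
            'chr1\trm\texon\t101\t200\t.\t+\t.\tgene_id "AluY"; transcript_id "AluY"; '
            'family_id "Alu"; class_id "SINE";\n'
        )
        cat = read_repeat_annotation(gtf, "gtf", toy_genome)
        assert len(cat) == 1
        row = cat.copies.iloc[0]
        assert (row["start"], row["end"]) == (100, 200)
        assert row["copy_id"] == "chr1:100-200:AluY"

    def test_empty_file_gives_empty_catalog(self, tmp_path, toy_genome):
        path = tmp_path / "empty.bed"
        path.write_text("")
        cat = read_repeat_annotation(path, "bed", toy_genome)
        assert len(cat) == 0
        assert cat.hierarchy == {}

    def test_conflicting_family_labels_rejected(self, tmp_path, toy_genome):
        bed = tmp_path / "r.bed"
        bed.write_text(
            "chr1\t0\t100\tSINE/Alu/AluY\t0\t+\n"
            "chr1\t200\t300\tSINE/Alu/AluY\t0\t+\n"
            "chr1\t400\t500\tSINE/MIR/AluY\t0\t+\n"
        )
        with pytest.raises(AnnotationError, match="AluY"):
            read_repeat_annotation(bed, "bed", toy_genome)

    def test_out_of_bounds_copy_rejected(self, tmp_path, toy_genome):
        bed = tmp_path / "r.bed"
        bed.write_text("chr1\t9000\t12000\tSINE/Alu/AluY\t0\t+\n")
        with pytest.raises(AnnotationError, match="outside"):
            read_repeat_annotation(bed, "bed", toy_genome)

    def test_bed_roundtrip_preserves_copies(self, tmp_path, toy_catalog, toy_genome):
        out = tmp_path / "out.bed"
        write_catalog_bed(toy_catalog, out)
        back = read_repeat_annotation(out, "bed", toy_genome)
        a = toy_catalog.copies.sort_values("copy_id").reset_index(drop=True)
        b = back.copies.sort_values("copy_id").reset_index(drop=True)
        pd.testing.assert_frame_equal(a[b.columns], b)


class TestExclusions:
    def test_uncertain_class_removed(self, toy_genome):
        cat = make_catalog(
            [
                ("chr1", 0, 100, "+", "X1", "Alu", "SINE?"),
                ("chr1", 200, 300, "+", "X2", "Alu?", "SINE"),
                ("chr1", 400, 500, "+", "AluY", "Alu", "SINE"),
            ],
            toy_genome,
        )
        out = apply_exclusions(cat)
        assert out.copies["repeat_name"].tolist() == ["AluY"]
        assert out.exclusion_counts["uncertain"] == 2

    @pytest.mark.parametrize(
        "blacklist,expect_kept",
        [
            ([("chr1", 199, 300)], False),  # 1 bp overlap -> removed
            ([("chr1", 200, 300)], True),  # half-open adjacency -> retained
        ],
    )
    def test_blacklist_overlap_boundary(self, toy_genome, blacklist, expect_kept):
        cat = make_catalog([("chr1", 100, 200, "+", "AluY", "Alu", "SINE")], toy_genome)
        out = apply_exclusions(cat, blacklist)
        assert (len(out) == 1) == expect_kept

    def test_idempotent(self, toy_genome):
        cat = make_catalog(
            [
                ("chr1", 0, 100, "+", "X1", "Alu", "SINE?"),
                ("chr1", 400, 500, "+", "AluY", "Alu", "SINE"),
            ],
            toy_genome,
        )
        bl = [("chr1", 450, 460)]
        once = apply_exclusions(cat, bl)
        twice = apply_exclusions(once, bl)
        assert once.copies["copy_id"].tolist() == twice.copies["copy_id"].tolist()


class TestOccupancy:
    def test_overlapping_copies_not_double_counted(self):
        genome = GenomeLayout({"chr1": 1000})
        cat = make_catalog(
            [
                ("chr1", 0, 100, "+", "A", "F", "C"),
                ("chr1", 50, 150, "+", "A", "F", "C"),
            ],
            genome,
        )
        occ = occupancy(cat, genome, level="class")
        assert occ.iloc[0]["bp"] == 150
        assert occ.iloc[0]["percent"] == pytest.approx(15.0)

    def test_disjoint_copies_sum(self):
        genome = GenomeLayout({"chr1": 1000})
        cat = make_catalog(
            [
                ("chr1", 0, 100, "+", "A", "F", "C"),
                ("chr1", 200, 300, "+", "A", "F", "C"),
            ],
            genome,
        )
        occ = occupancy(cat, genome, level="all")
        assert occ.iloc[0]["bp"] == 200
        assert occ.iloc[0]["percent"] == pytest.approx(20.0)

    def test_empty_catalog_zero(self, toy_genome):
        cat = make_catalog([], toy_genome)
        occ = occupancy(cat, toy_genome, level="all")
        assert len(occ) == 0 or (occ["bp"] == 0).all()

    def test_matches_per_base_union_on_random_catalogs(self, toy_genome):
        rng = np.random.default_rng(42)
        for _ in range(25):
            rows = []
            for _ in range(rng.integers(1, 30)):
                chrom = "chr1" if rng.random() < 0.5 else "chr2"
                s = int(rng.integers(0, toy_genome[chrom] - 500))
                e = s + int(rng.integers(1, 500))
                rows.append((chrom, s, e, "+", "A", "F", "C"))
            cat = make_catalog(rows, toy_genome)
            expected = sum(
                union_bp([(s, e) for c, s, e, *_ in rows if c == chrom])
                for chrom in ("chr1", "chr2")
            )
            occ = occupancy(cat, toy_genome, level="all")
            assert occ.iloc[0]["bp"] == expected


class TestPartition:
    def test_single_repeat_inside_segment(self, toy_genome):
        cat = make_catalog([("chr1", 200, 400, "+", "A", "F", "C")], toy_genome)
        segs = pd.DataFrame([("chr1", 0, 1000, "A")], columns=["chrom", "start", "end", "label"])
        out = partition_repetitive(segs, cat)
        assert [tuple(r) for r in out[["start", "end", "repeat_status"]].to_numpy()] == [
            (0, 200, "NR"),
            (200, 400, "R"),
            (400, 1000, "NR"),
        ]

    def test_no_overlap_single_nr(self, toy_genome):
        cat = make_catalog([("chr2", 0, 100, "+", "A", "F", "C")], toy_genome)
        segs = pd.DataFrame([("chr1", 100, 500, "B")], columns=["chrom", "start", "end", "label"])
        out = partition_repetitive(segs, cat)
        assert len(out) == 1
        assert out.iloc[0]["repeat_status"] == "NR"
        assert (out.iloc[0]["start"], out.iloc[0]["end"]) == (100, 500)

    def test_fully_covered_single_r(self, toy_genome):
        cat = make_catalog([("chr1", 0, 1000, "+", "A", "F", "C")], toy_genome)
        segs = pd.DataFrame([("chr1", 100, 500, "A")], columns=["chrom", "start", "end", "label"])
        out = partition_repetitive(segs, cat)
        assert len(out) == 1
        assert out.iloc[0]["repeat_status"] == "R"

    def test_tiles_input_exactly_on_random_cases(self, toy_genome):
        rng = np.random.default_rng(7)
        for _ in range(25):
            rows = []
            for _ in range(rng.integers(0, 20)):
                s = int(rng.integers(0, 9000))
                rows.append(("chr1", s, s + int(rng.integers(1, 800)), "+", "A", "F", "C"))
            cat = make_catalog(rows, toy_genome)
            seg = (int(rng.integers(0, 5000)), int(rng.integers(5001, 10000)))
            segs = pd.DataFrame(
                [("chr1", seg[0], seg[1], "A")], columns=["chrom", "start", "end", "label"]
            )
            out = partition_repetitive(segs, cat)
            expected = partition_per_base(seg[0], seg[1], [(s, e) for _, s, e, *_ in rows])
            got = [tuple(r) for r in out[["start", "end", "repeat_status"]].to_numpy()]
            assert got == expected
            assert (out["end"] - out["start"]).sum() == seg[1] - seg[0]


class TestClades:
    def make_table(self):
        return CladeTable(
            {"SVA_F": "Homo sapiens", "AluY": "Hominoidea", "L1ME": "Non-Primates",
             "AluSx": "Simiiformes"},
            tuple(DEFAULT_CLADES),
        )

    def test_youngest_clade_gets_max_rank(self, toy_genome):
        cat = make_catalog([("chr1", 0, 100, "+", "SVA_F", "SVA", "Other")], toy_genome)
        out = assign_clades(cat, self.make_table())
        assert out.copies["clade_rank"].iloc[0] == len(DEFAULT_CLADES) - 1

    def test_missing_name_flagged(self, toy_genome):
        cat = make_catalog([("chr1", 0, 100, "+", "Unknown1", "F", "C")], toy_genome)
        out = assign_clades(cat, self.make_table(), on_missing="label_unknown")
        assert out.copies["clade_rank"].isna().all()
        assert out.copies["clade_unknown"].all()
        with pytest.raises(KeyError, match="Unknown1"):
            assign_clades(cat, self.make_table(), on_missing="error")

    def test_ranks_per_name_not_per_family(self, toy_genome):
        cat = make_catalog(
            [
                ("chr1", 0, 100, "+", "AluY", "Alu", "SINE"),
                ("chr1", 200, 300, "+", "AluSx", "Alu", "SINE"),
            ],
            toy_genome,
        )
        out = assign_clades(cat, self.make_table())
        ranks = out.copies.set_index("repeat_name")["clade_rank"]
        assert ranks["AluY"] == DEFAULT_CLADES.index("Hominoidea")
        assert ranks["AluSx"] == DEFAULT_CLADES.index("Simiiformes")

    def test_clade_table_rejects_unknown_label(self):
        with pytest.raises(ValueError, match="not in ordered list"):
            CladeTable({"X": "Martians"}, tuple(DEFAULT_CLADES))
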