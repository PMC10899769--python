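import numpy as np
import pandas as pd
import pytest

from teprofile.catalog import GenomeLayout
from teprofile.expression import (
    SampleSheet,
    classify_from_table,
    count_reads,
    differential_classification,
    expressed_split,
    group_proportions,
    read_change_categories,
)

from conftest import make_catalog
from oracles import count_read_bruteforce


def sheet_3v3():
    samples = [f"control_{i}" for i in range(1, 4)] + [f"kd_{i}" for i in range(1, 4)]
    return SampleSheet(
        pd.DataFrame(
            {
                "sample": samples,
                "condition": ["control"] * 3 + ["kd"] * 3,
                "replicate": [1, 2, 3, 1, 2, 3],
            }
        )
    )


def nb_counts(rng, n, mu, dispersion, cols):
    npar = 1.0 / dispersion
    return rng.negative_binomial(npar, npar / (npar + mu), size=(n, cols)).astype(float)


class TestCountReads:
    def test_read_inside_one_copy(self, toy_genome, toy_catalog):
        counts = count_reads([("chr1", 150, 250, 1)], toy_catalog)
        assert counts["chr1:100-400:AluY"] == 1.0
        assert counts.sum() == 1.0

    def test_largest_overlap_wins(self, toy_genome):
        cat = make_catalog(
            [
                ("chr1", 100, 130, "+", "A", "F", "C"),  # 30 bp overlap
                ("chr1", 140, 400, "+", "B", "F", "C"),  # 60 bp overlap
            ],
            toy_genome,
        )
        counts = count_reads([("chr1", 100, 200, 1)], cat)
        by_name = counts.groupby(cat.copies.set_index("copy_id")["repeat_name"]).sum()
        assert by_name["B"] == 1.0 and by_name["A"] == 0.0

    def test_fractional_conservation(self, toy_genome):
        cat = make_catalog(
            [
                ("chr1", 100, 400, "+", "A", "F", "C"),
                ("chr2", 100, 400, "+", "B", "F", "C"),
            ],
            toy_genome,
        )
        counts = count_reads(
            [("chr1", 150, 250, 2), ("chr2", 150, 250, 2)], cat, policy="fractional"
        )
        assert counts.sum() == pytest.approx(1.0)
        assert (counts == 0.5).all()

    def test_matches_bruteforce(self, toy_genome):
        rng = np.random.default_rng(90)
        rows = []
        for i in range(40):
            s = int(rng.integers(0, 9000))
            rows.append(("chr1", s, s + int(rng.integers(50, 600)), "+", f"R{i}", "F", "C"))
        cat = make_catalog(rows, toy_genome)
        copies = list(cat.copies[["start", "end", "copy_id"]].itertuples(index=False))
        reads = [
            ("chr1", int(s), int(s) + 100, 1) for s in rng.integers(0, 9800, 200)
        ]
        counts = count_reads(reads, cat)
        expected = dict.fromkeys(cat.copies["copy_id"], 0.0)
        for _, s, e, _h in reads:
            cid = count_read_bruteforce((s, e), copies)
            if cid is not None:
                expected[cid] += 1.0
        assert counts.to_dict() == expected


class TestExpressedSplit:
    @pytest.mark.parametrize("mean,expected", [(3.0, "E"), (2.9, "Ne")])
    def test_inclusive_threshold(self, mean, expected):
        counts = pd.DataFrame(
            {s: [mean] for s in ["control_1", "control_2", "control_3"]}, index=["c1"]
        )
        counts[["kd_1", "kd_2", "kd_3"]] = 0.0
        out = expressed_split(counts, sheet_3v3(), "control")
        assert out["c1"] == expected

    def test_unknown_condition_rejected(self):
        counts = pd.DataFrame({"control_1": [1.0]}, index=["c1"])
        with pytest.raises(KeyError):
            expressed_split(counts, sheet_3v3(), "mock")

    def test_split_fractions_match_bruteforce(self):
        rng = np.random.default_rng(91)
        counts = pd.DataFrame(
            nb_counts(rng, 500, 4.0, 0.3, 6),
            index=[f"c{i}" for i in range(500)],
            columns=sheet_3v3().table["sample"],
        )
        out = expressed_split(counts, sheet_3v3(), "kd")
        expected = counts[["kd_1", "kd_2", "kd_3"]].mean(axis=1) >= 3.0
        assert ((out == "E") == expected).all()


class TestDifferentialClassification:
    def test_identical_conditions_all_ns(self):
        rng = np.random.default_rng(92)
        counts = pd.DataFrame(
            nb_counts(rng, 800, 50.0, 0.1, 6),
            index=[f"c{i}" for i in range(800)],
            columns=sheet_3v3().table["sample"],
        )
        de = differential_classification(counts, sheet_3v3())
        assert (de["status"] == "ns").mean() > 0.99
        pv = de["pvalue"].dropna()
        assert 0.02 < (pv < 0.05).mean() < 0.10  # roughly uniform null p

    def test_threshold_arithmetic(self):
        table = pd.DataFrame(
            {"log2FoldChange": [0.70, 0.50, -0.70], "padj": [0.01, 0.01, 0.01]},
            index=["a", "b", "c"],
        )
        out = classify_from_table(table)
        assert out.loc["a", "status"] == "up"  # 0.70 > log2(1.5) = 0.585
        assert out.loc["b", "status"] == "ns"
        assert out.loc["c", "status"] == "down"

    def test_planted_fold_change_detected(self):
        rng = np.random.default_rng(93)
        n_null, n_alt = 900, 100
        control = nb_counts(rng, n_null + n_alt, 50.0, 0.1, 3)
        kd = np.vstack(
            [
                nb_counts(rng, n_null, 50.0, 0.1, 3),
                nb_counts(rng, n_alt, 200.0, 0.1, 3),
            ]
        )
        counts = pd.DataFrame(
            np.hstack([control, kd]),
            index=[f"c{i}" for i in range(n_null + n_alt)],
            columns=sheet_3v3().table["sample"],
        )
        de = differential_classification(counts, sheet_3v3())
        planted = de.iloc[n_null:]
        assert (planted["status"] == "up").mean() >= 0.8
        assert (de.iloc[:n_null]["status"] != "ns").mean() < 0.05

    def test_padj_at_least_p(self):
        rng = np.random.default_rng(94)
        counts = pd.DataFrame(
            nb_counts(rng, 300, 30.0, 0.1, 6),
            index=[f"c{i}" for i in range(300)],
            columns=sheet_3v3().table["sample"],
        )
        de = differential_classification(counts, sheet_3v3())
        tested = de[de["tested"]]
        assert (tested["padj"] >= tested["pvalue"] - 1e-12).all()

    def test_low_count_copies_not_tested(self):
        counts = pd.DataFrame(
            [[1, 0, 1, 0, 1, 0], [50, 60, 55, 52, 48, 61]],
            index=["low", "high"],
            columns=sheet_3v3().table["sample"],
            dtype=float,
        )
        de = differential_classification(counts, sheet_3v3(), min_total=10)
        assert not de.loc["low", "tested"]
        assert np.isnan(de.loc["low", "pvalue"])
        assert de.loc["high", "tested"]

    def test_single_replicate_rejected(self):
        sheet = SampleSheet(
            pd.DataFrame(
                {"sample": ["a", "b", "c"], "condition": ["control", "kd", "kd"],
                 "replicate": [1, 1, 2]}
            )
        )
        counts = pd.DataFrame({"a": [1.0], "b": [1.0], "c": [1.0]}, index=["x"])
        with pytest.raises(ValueError, match="replicates"):
            differential_classification(counts, sheet)


class TestGroupProportions:
    def make_de(self, n_up, n_tested):
        status = ["up"] * n_up + ["ns"] * (n_tested - n_up)
        return pd.DataFrame(
            {"status": status, "tested": True}, index=[f"c{i}" for i in range(n_tested)]
        )

    def test_observed_vs_expected_arithmetic(self):
        de = self.make_de(100, 1000)
        groups = pd.Series("other", index=de.index)
        up_in_g = de.index[:34]
        tested_in_g = list(up_in_g) + [f"c{i}" for i in range(100, 263)]  # 197 total
        groups[tested_in_g] = "G"
        out = group_proportions(de, groups).set_index("group")
        assert out.loc["G", "observed_pct"] == pytest.approx(34.0)
        assert out.loc["G", "expected_pct"] == pytest.approx(19.7)
        assert out.loc["G", "enriched"]

    def test_uniform_labels_observed_near_expected(self):
        rng = np.random.default_rng(95)
        n = 2000
        status = np.where(rng.random(n) < 0.1, "up", "ns")
        de = pd.DataFrame({"status": status, "tested": True},
                          index=[f"c{i}" for i in range(n)])
        groups = pd.Series(rng.choice(["g1", "g2", "g3"], size=n), index=de.index)
        out = group_proportions(de, groups)
        for _, row in out.iterrows():
            se = 100 * np.sqrt(row["expected_pct"] / 100 * (1 - row["expected_pct"] / 100)
                               / max((de["status"] == "up").sum(), 1))
            assert abs(row["observed_pct"] - row["expected_pct"]) < 4 * se

    def test_single_group_hundred_percent(self):
        de = self.make_de(10, 50)
        groups = pd.Series("only", index=de.index)
        out = group_proportions(de, groups)
        assert out.iloc[0]["observed_pct"] == 100.0
        assert out.iloc[0]["expected_pct"] == 100.0


class TestReadChangeCategories:
    def frame(self, control_mean, kd_mean):
        return pd.DataFrame(
            {
                "control_1": [control_mean], "control_2": [control_mean],
                "control_3": [control_mean],
                "kd_1": [kd_mean], "kd_2": [kd_mean], "kd_3": [kd_mean],
            },
            index=["c1"], dtype=float,
        )

    @pytest.mark.parametrize(
        "cm,km,expected",
        [
            (0.0, 0.0, "never_expressed"),
            (0.0, 5.0, "became_expressed"),
            (5.0, 0.0, "became_silent"),
            (10.0, 25.0, "increased"),  # (25.5/10.5) = 2.43 >= 1.5
            (25.0, 10.0, "decreased"),
            (10.0, 12.0, "unchanged"),
        ],
    )
    def test_category_rules(self, cm, km, expected):
        cats, fractions = read_change_categories(self.frame(cm, km), sheet_3v3())
        assert cats["category"].iloc[0] == expected
        assert fractions.sum() == pytest.approx(100.0)

    def test_fractions_sum_to_100_on_random(self):
        rng = np.random.default_rng(96)
        counts = pd.DataFrame(
            nb_counts(rng, 400, 5.0, 0.5, 6),
            index=[f"c{i}" for i in range(400)],
            columns=sheet_3v3().table["sample"],
        )
        _, fractions = read_change_categories(counts, sheet_3v3())
        assert fractions.sum() == pytest.approx(100.0)

    def test_requires_two_conditions(self):
        sheet = SampleSheet(
            pd.DataFrame({"sample": ["a", "b"], "condition": ["x", "x"], "replicate": [1, 2]})
        )
        counts = pd.DataFrame({"a": [1.0], "b": [2.0]}, index=["c1"])
        with pytest.raises(ValueError, match="2 conditions"):
            read_change_categories(counts, sheet)
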