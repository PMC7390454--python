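import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact

from ppicore.errors import EmptyInputError, FormatError
from ppicore.enrichment import (
    AnnotationGeneSet,
    DegreeBinSpec,
    class_overlap_enrichment,
    degree_stratified_enrichment,
    fisher_one_sided,
    load_annotation_sets,
    load_clinvar_pathogenic,
    load_gene_list,
    overlap_row,
    pathway_enrichment,
    rank_fraction_analysis,
    read_gmt,
)
from ppicore.gwas_catalog import GwasStudy, Hit

from oracles import bh_adjust_bruteforce


class TestFisherOneSided:
    def test_hand_worked_table(self):
        # [[3,1],[1,3]]: P(X>=3) drawing 4 from 4 in / 4 out = 17/70
        assert fisher_one_sided(3, 1, 1, 3) == pytest.approx(17 / 70, rel=1e-12)

    def test_perfect_split(self):
        # all 5 annotated genes in A, none in B: p = 1 / C(10,5) = 1/252
        assert fisher_one_sided(5, 0, 0, 5) == pytest.approx(1 / 252, rel=1e-12)

    def test_matches_scipy_greater_alternative(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            a_in, a_out, b_in, b_out = rng.integers(0, 12, size=4)
            ours = fisher_one_sided(int(a_in), int(a_out), int(b_in), int(b_out))
            _, scipy_p = fisher_exact(
                [[a_in, a_out], [b_in, b_out]], alternative="greater"
            )
            assert ours == pytest.approx(scipy_p, rel=1e-9)

    def test_no_annotation_anywhere_is_one(self):
        assert fisher_one_sided(0, 5, 0, 5) == pytest.approx(1.0)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            fisher_one_sided(-1, 2, 3, 4)


CLINVAR_HEADER = """\
##fileformat=VCFv4.1
##INFO=<ID=CLNSIG,Number=.,Type=String,Description="Clinical significance">
##INFO=<ID=GENEINFO,Number=1,Type=String,Description="Gene(s): symbol:id">
##contig=<ID=1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


@pytest.fixture
def clinvar_vcf(tmp_path):
    rows = [
        "1\t100\trs1\tA\tG\t.\t.\tCLNSIG=Pathogenic;GENEINFO=GENEA:1",
        "1\t200\trs2\tA\tG\t.\t.\tCLNSIG=Pathogenic/Likely_pathogenic;GENEINFO=GENEB:2",
        "1\t300\trs3\tA\tG\t.\t.\tCLNSIG=Benign;GENEINFO=GENEC:3",
        "1\t400\trs4\tA\tG\t.\t.\tCLNSIG=Pathogenic;GENEINFO=OUTSIDE:4",
        "1\t500\trs5\tA\tG\t.\t.\tGENEINFO=GENED:5",
        "1\t600\trs6\tA\tG\t.\t.\tCLNSIG=Pathogenic;GENEINFO=GENED:5|GENEE:6",
    ]
    path = tmp_path / "clinvar.vcf"
    path.write_text(CLINVAR_HEADER + "\n".join(rows) + "\n")
    return path


class TestLoaders:
    def test_clinvar_single_annotation_pathogenic_only(self, clinvar_vcf):
        universe = {"GENEA", "GENEB", "GENEC", "GENED", "GENEE"}
        genes = load_clinvar_pathogenic(clinvar_vcf, universe)
        # GENEB dropped (compound significance), GENEC benign, OUTSIDE not in
        # universe, rs5 has no CLNSIG; rs6 contributes both GENED and GENEE
        assert genes == {"GENEA", "GENED", "GENEE"}

    def test_clinvar_empty_result_raises(self, clinvar_vcf):
        with pytest.raises(EmptyInputError):
            load_clinvar_pathogenic(clinvar_vcf, {"NOPE"})

    def test_gene_list_intersected_with_universe(self, tmp_path):
        p = tmp_path / "genes.tsv"
        p.write_text("GENEA\nGENEX\nGENEB\n")
        assert load_gene_list(p, {"GENEA", "GENEB", "GENEC"}) == {"GENEA", "GENEB"}

    def test_load_annotation_sets(self, tmp_path, clinvar_vcf):
        p = tmp_path / "census.tsv"
        p.write_text("GENEA\nGENEC\n")
        sets = load_annotation_sets(
            {"GENEA", "GENEC", "GENED"}, clinvar_vcf=clinvar_vcf, cosmic=p
        )
        assert sets["clinvar_pathogenic"].genes == {"GENEA", "GENED"}
        assert sets["cosmic"].genes == {"GENEA", "GENEC"}

    def test_empty_annotation_set_rejected(self):
        with pytest.raises(EmptyInputError):
            AnnotationGeneSet("empty", frozenset())


class TestOverlapRow:
    ANN = AnnotationGeneSet("ann", frozenset({"A", "B", "C"}))

    def test_counts_and_proportions(self):
        row = overlap_row("X", {"A", "B", "Z"}, "Y", {"C", "W", "V", "U"}, self.ANN)
        assert (row["a_in"], row["a_out"], row["b_in"], row["b_out"]) == (2, 1, 1, 3)
        assert row["proportion_a"] == pytest.approx(2 / 3)
        assert row["proportion_b"] == pytest.approx(1 / 4)
        assert row["odds_ratio"] == pytest.approx(6 / 1)
        assert not row["empty_class"]

    def test_infinite_odds(self):
        row = overlap_row("X", {"A", "B"}, "Y", {"W", "V"}, self.ANN)
        assert row["odds_ratio"] == np.inf

    def test_undefined_odds_is_nan(self):
        # no annotated genes on either side
        row = overlap_row("X", {"Z"}, "Y", {"W"}, self.ANN)
        assert np.isnan(row["odds_ratio"])

    def test_empty_class_flag(self):
        row = overlap_row("X", set(), "Y", {"A"}, self.ANN)
        assert row["empty_class"] and np.isnan(row["fisher_p"])


class TestClassOverlapEnrichment:
    def test_all_pseudo_class_and_default_comparisons(self):
        classes = {"PPI_ONLY": {"A", "Z"}, "GWAS_ONLY": {"C", "W"}}
        df = class_overlap_enrichment(
            classes, TestOverlapRow.ANN, universe={"A", "B", "C", "Z", "W", "V"}
        )
        pairs = set(zip(df["class_a"], df["class_b"]))
        assert pairs == {("PPI_ONLY", "GWAS_ONLY"), ("PPI_ONLY", "ALL")}

    def test_annotation_equal_to_universe_gives_p_one(self):
        uni = {"A", "B", "C", "D"}
        ann = AnnotationGeneSet("all", frozenset(uni))
        df = class_overlap_enrichment(
            {"PPI_ONLY": {"A", "B"}, "GWAS_ONLY": {"C", "D"}}, ann, uni
        )
        assert np.allclose(df["fisher_p"], 1.0)

    def test_explicit_comparisons_honored(self):
        classes = {"X": {"A"}, "Y": {"C"}}
        df = class_overlap_enrichment(
            classes, TestOverlapRow.ANN, {"A", "C"}, comparisons=[("Y", "X")]
        )
        assert list(zip(df["class_a"], df["class_b"])) == [("Y", "X")]


class TestDegreeStratified:
    def test_quartile_edges_and_assignment(self):
        degrees = {f"g{i}": d for i, d in enumerate([1, 1, 2, 2, 3, 3, 4, 4])}
        bins = DegreeBinSpec.quartiles(degrees)
        assert bins.edges[0] == 1 and bins.edges[-1] == 4
        # max degree falls in the last (closed) bin
        assert bins.assign(4) == len(bins.edges) - 2
        assert bins.assign(1) == 0

    def test_single_bin_equals_unstratified(self):
        degrees = {g: 3 for g in "ABCDWZ"}
        bins = DegreeBinSpec(edges=(0, 10))
        classes = {"PPI_ONLY": {"A", "Z"}, "GWAS_ONLY": {"C", "W"}}
        strat = degree_stratified_enrichment(classes, TestOverlapRow.ANN, bins, degrees)
        flat = class_overlap_enrichment(classes, TestOverlapRow.ANN, set(degrees))
        assert len(strat) == len(flat)
        for col in ("a_in", "b_in", "fisher_p"):
            assert list(strat[col]) == list(flat[col])

    def test_degree_confounding_resolved_within_bins(self):
        """Annotation tracks degree, detected class tracks degree: pooled
        comparison looks enriched, but within bins there is no signal."""
        rng = np.random.default_rng(6)
        high = [f"H{i}" for i in range(40)]
        low = [f"L{i}" for i in range(40)]
        degrees = {**{g: 50 for g in high}, **{g: 2 for g in low}}
        # annotation hits 50% of high-degree, 5% of low-degree genes
        ann_genes = set(rng.choice(high, 20, replace=False)) | set(
            rng.choice(low, 2, replace=False)
        )
        ann = AnnotationGeneSet("deg_tracking", frozenset(ann_genes))
        # "detections" are simply the high-degree genes (pure degree artifact)
        classes = {"PPI_ONLY": set(high[:30]), "GWAS_ONLY": set(low[:30])}
        pooled = class_overlap_enrichment(classes, ann, set(degrees),
                                          comparisons=[("PPI_ONLY", "GWAS_ONLY")])
        assert pooled["fisher_p"].iloc[0] < 0.01  # confounded signal
        bins = DegreeBinSpec(edges=(0, 10, 100))
        strat = degree_stratified_enrichment(classes, ann, bins, degrees,
                                             comparisons=[("PPI_ONLY", "GWAS_ONLY")])
        # within each bin only one class is non-empty -> no valid comparison
        assert strat["empty_class"].all()


def _study(acc, gene_ps):
    return GwasStudy(acc, "t", "P", "European",
                     {g: Hit(p, "1", 1000, "rs1") for g, p in gene_ps.items()})


class TestRankFraction:
    def test_fractions_for_three_distinct_ps(self):
        s = _study("S1", {"A": 1e-10, "B": 1e-9, "C": 1e-8})
        rec, _ = rank_fraction_analysis([(s, {"A"})])
        fr = rec.set_index("gene")["rank_fraction"]
        assert fr["A"] == pytest.approx(1 / 3)
        assert fr["B"] == pytest.approx(2 / 3)
        assert fr["C"] == pytest.approx(1.0)

    def test_ties_get_average_rank(self):
        s = _study("S1", {"A": 1e-9, "B": 1e-9, "C": 1e-8})
        rec, _ = rank_fraction_analysis([(s, {"A"})])
        fr = rec.set_index("gene")["rank_fraction"]
        assert fr["A"] == fr["B"] == pytest.approx(1.5 / 3)

    def test_studies_without_detections_excluded(self):
        s1 = _study("S1", {"A": 1e-10, "B": 1e-9})
        s2 = _study("S2", {"C": 1e-10})
        rec, tests = rank_fraction_analysis([(s1, {"A"}), (s2, set())])
        assert set(rec["study_accession"]) == {"S1"}
        assert set(tests["threshold"]) == {"top_10pct", "top_25pct"}

    def test_empty_input_gives_nan_tests(self):
        rec, tests = rank_fraction_analysis([])
        assert rec.empty and tests["fisher_p"].isna().all()

    def test_low_p_detections_enriched_in_top_quartile(self):
        """Generative check: when PPI-GWAS genes are exactly the smallest-p
        hits of a 40-hit study, the top-25% Fisher test is significant."""
        genes = {f"G{i:02d}": 10.0 ** -(30 - i) for i in range(40)}
        s = _study("S1", genes)
        ppi_gwas = {f"G{i:02d}" for i in range(8)}  # the 8 smallest p-values
        _, tests = rank_fraction_analysis([(s, ppi_gwas)])
        top25 = tests.set_index("threshold").loc["top_25pct"]
        assert top25["ppi_gwas_in_top"] == 8
        assert top25["fisher_p"] < 1e-4


class TestGmtAndPathways:
    def test_round_trip_parse(self, tmp_path):
        p = tmp_path / "c.gmt"
        p.write_text("pathA\tdesc\tG1\tG2\npathB\tdesc\tG2\tG3\tG4\n")
        coll = read_gmt(p)
        assert coll == {"pathA": {"G1", "G2"}, "pathB": {"G2", "G3", "G4"}}

    def test_duplicate_names_first_wins(self, tmp_path, caplog):
        p = tmp_path / "c.gmt"
        p.write_text("pathA\td\tG1\npathA\td\tG9\n")
        with caplog.at_level("WARNING"):
            coll = read_gmt(p)
        assert coll["pathA"] == {"G1"} and "deduplicated" in caplog.text

    def test_malformed_line_raises(self, tmp_path):
        p = tmp_path / "c.gmt"
        p.write_text("pathA\tonly-two-fields\n")
        with pytest.raises(FormatError):
            read_gmt(p)

    def test_blank_lines_skipped_and_empty_raises(self, tmp_path):
        p = tmp_path / "c.gmt"
        p.write_text("\n\n")
        with pytest.raises(EmptyInputError):
            read_gmt(p)

    def test_pathway_identity_case_ranks_first(self):
        uni = {f"G{i}" for i in range(50)}
        gene_set = {"G0", "G1", "G2", "G3"}
        coll = {"exact": frozenset(gene_set),
                "disjoint": frozenset({"G10", "G11", "G12", "G13"})}
        df = pathway_enrichment(gene_set, coll, uni)
        assert df.iloc[0]["pathway"] == "exact"
        assert df.iloc[0]["overlap"] == 4
        assert df.set_index("pathway").loc["disjoint", "fisher_p"] == pytest.approx(1.0)

    def test_bh_column_matches_bruteforce(self):
        uni = {f"G{i}" for i in range(30)}
        rng = np.random.default_rng(9)
        coll = {
            f"p{j}": frozenset(rng.choice(sorted(uni), 6, replace=False))
            for j in range(8)
        }
        df = pathway_enrichment({"G0", "G1", "G2", "G3", "G4"}, coll, uni)
        assert np.allclose(
            df["bh_adjusted_p"], bh_adjust_bruteforce(df["fisher_p"]), atol=1e-12
        )

    def test_sorted_by_raw_p(self):
        uni = {f"G{i}" for i in range(30)}
        coll = {"a": frozenset({"G0", "G1"}), "b": frozenset({"G20", "G21"})}
        df = pathway_enrichment({"G0", "G1"}, coll, uni)
        assert list(df["fisher_p"]) == sorted(df["fisher_p"])
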