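import numpy as np
import pandas as pd
import pytest

from stressdeg.datasets import REFERENCE_MOTIF_COUNTS
from stressdeg.io import AnalysisConfig, FormatError
from stressdeg.motifs import (
    DEFAULT_MOTIFS,
    MotifCountTable,
    MotifDefinition,
    aggregate_motif_table,
    count_motifs_by_region,
    expand_iupac,
    extract_windows,
    scan_sequence,
    scan_upstream_region,
)

from _oracles import brute_scan

SKN1, DBE, DAE = DEFAULT_MOTIFS


def _match_set(seq, motif):
    return {(m.start, m.end, m.strand) for m in scan_sequence(seq, motif)}


class TestExpand:
    @pytest.mark.parametrize(
        "pattern,expected",
        [
            ("RTCAT", {"ATCAT", "GTCAT"}),
            ("TRTTTAC", {"TATTTAC", "TGTTTAC"}),
            ("CTTATCA", {"CTTATCA"}),
        ],
    )
    def test_paper_motifs(self, pattern, expected):
        assert expand_iupac(pattern) == expected

    def test_illegal_letter_rejected(self):
        with pytest.raises(FormatError):
            expand_iupac("RTXAT")
        with pytest.raises(FormatError):
            MotifDefinition("bad", "QQ", "SKN1")


class TestScan:
    def test_forward_matches(self):
        starts = [m.start for m in scan_sequence("ATCATGTCAT", SKN1, both_strands=False)]
        assert starts == [0, 5]

    def test_minus_strand_match(self):
        matches = scan_sequence("ATGAT", SKN1, both_strands=True)
        assert [(m.start, m.strand) for m in matches] == [(0, "-")]

    def test_overlapping_matches_all_counted(self):
        motif = MotifDefinition("aa", "AA", "SKN1")
        matches = scan_sequence("AAA", motif, both_strands=False)
        assert [m.start for m in matches] == [0, 1]

    def test_palindromic_pattern_reported_once_per_interval(self):
        motif = MotifDefinition("pal", "AT", "SKN1")
        assert motif.is_palindromic
        matches = scan_sequence("GATG", motif, both_strands=True)
        assert [(m.start, m.strand) for m in matches] == [(1, "+")]

    def test_lowercase_uppercased_and_n_matches_only_pattern_n(self):
        assert len(scan_sequence("atcat", SKN1, both_strands=False)) == 1
        assert len(scan_sequence("NTCAT", SKN1, both_strands=False)) == 0
        any_n = MotifDefinition("n", "NT", "SKN1")
        assert [m.start for m in scan_sequence("NTG", any_n, both_strands=False)] == [0]

    def test_empty_sequence(self):
        assert scan_sequence("", SKN1) == []

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=5000))
            for motif in DEFAULT_MOTIFS:
                assert _match_set(seq, motif) == brute_scan(seq, motif.pattern)

    def test_reverse_complement_scan_symmetry(self):
        from Bio.Seq import Seq

        rng = np.random.default_rng(31)
        seq = "".join(rng.choice(list("ACGT"), size=3000))
        rc = str(Seq(seq).reverse_complement())
        L = len(seq)
        for motif in DEFAULT_MOTIFS:
            fwd = _match_set(seq, motif)
            mirrored = {
                (L - end, L - start, "+" if strand == "-" else "-")
                for start, end, strand in _match_set(rc, motif)
            }
            assert fwd == mirrored

    def test_translation_invariance(self):
        rng = np.random.default_rng(41)
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        k = 37
        padded = "N" * k + seq  # N prefix can create no new matches
        for motif in DEFAULT_MOTIFS:
            shifted = {(s + k, e + k, st) for s, e, st in _match_set(seq, motif)}
            assert _match_set(padded, motif) == shifted


class TestWindows:
    def _gene(self, strand="+", start_codon=3000, stop_codon=4999):
        return pd.Series(
            {
                "chrom": "c1",
                "strand": strand,
                "gene_start": min(start_codon, stop_codon),
                "gene_end": max(start_codon, stop_codon) + 1,
                "start_codon_pos": start_codon,
                "stop_codon_pos": stop_codon,
            },
            name="gX",
        )

    def test_plus_strand_coordinates(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), size=10_000))
        genome = {"c1": seq}
        windows = extract_windows(self._gene(), genome, 2000, 2000)
        assert windows["upstream"] == seq[1000:3000]
        assert windows["intragenic"] == seq[3000:5000]
        assert windows["downstream"] == seq[5000:7000]

    def test_minus_strand_upstream_lies_at_higher_coordinates(self):
        from Bio.Seq import Seq

        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), size=10_000))
        genome = {"c1": seq}
        gene = self._gene(strand="-", start_codon=4999, stop_codon=3000)
        windows = extract_windows(gene, genome, 2000, 2000)
        assert windows["upstream"] == str(Seq(seq[5000:7000]).reverse_complement())
        assert windows["intragenic"] == str(Seq(seq[3000:5000]).reverse_complement())
        assert windows["downstream"] == str(Seq(seq[1000:3000]).reverse_complement())

    def test_clipping_at_contig_start_warns(self, caplog):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), size=4000))
        gene = self._gene(start_codon=500, stop_codon=999)
        with caplog.at_level("WARNING"):
            windows = extract_windows(gene, {"c1": seq}, 2000, 2000)
        assert windows["upstream"] == seq[0:500]
        assert "clipped" in caplog.text

    def test_gene_off_contig_is_an_error(self):
        gene = self._gene(start_codon=5000, stop_codon=5999)
        with pytest.raises(ValueError, match="gX"):
            extract_windows(gene, {"c1": "ACGT" * 100})
        with pytest.raises(KeyError, match="c9"):
            gene = self._gene()
            gene["chrom"] = "c9"
            extract_windows(gene, {"c1": "ACGT" * 100})


class TestCounting:
    def test_planted_counts_reproduced_exactly(self, planted_sim):
        genes = planted_sim.annotation.loc[planted_sim.genes_bed["name"]]
        table = count_motifs_by_region(genes, planted_sim.genome, config=AnalysisConfig())
        truth = planted_sim.motif_truth
        for gene_id, row in table.rows.iterrows():
            mine = truth[truth["gene_id"] == gene_id]
            for window in ("upstream", "intragenic", "downstream"):
                in_window = mine[mine["window"] == window]
                assert row[f"skn1_{window}"] == (in_window["motif"] == "SKN-1").sum()
                assert row[f"daf16_{window}"] == in_window["motif"].isin(
                    ["DBE", "DAE"]
                ).sum()

    def test_all_zero_row_for_motif_free_gene(self):
        # all-C sequence cannot host any of the built-in motifs
        genome = {"c1": "C" * 9000}
        genes = pd.DataFrame(
            {
                "chrom": ["c1"], "strand": ["+"], "gene_start": [3000],
                "gene_end": [5000], "start_codon_pos": [3000],
                "stop_codon_pos": [4999],
            },
            index=pd.Index(["g1"], name="gene_id"),
        )
        table = count_motifs_by_region(genes, genome, config=AnalysisConfig())
        assert (table.rows.loc["g1"] == 0).all()

    def test_row_and_column_sum_invariants(self, planted_sim):
        genes = planted_sim.annotation.loc[planted_sim.genes_bed["name"]]
        table = count_motifs_by_region(genes, planted_sim.genome, config=AnalysisConfig())
        for group in ("skn1", "daf16"):
            windows = [f"{group}_upstream", f"{group}_intragenic", f"{group}_downstream"]
            assert (
                table.rows[windows].sum(axis=1) == table.rows[f"{group}_total"]
            ).all()
        assert (table.totals == table.rows.sum(axis=0)).all()


class TestAggregate:
    def test_reference_rows_reproduce_reported_totals(self):
        totals = aggregate_motif_table(REFERENCE_MOTIF_COUNTS)
        assert totals["skn1_upstream"] == 26
        assert totals["skn1_intragenic"] == 0
        assert totals["skn1_downstream"] == 22
        assert totals["skn1_total"] == 48
        assert totals["daf16_upstream"] == 14
        assert totals["daf16_intragenic"] == 2
        assert totals["daf16_downstream"] == 11
        assert totals["daf16_total"] == 27

    def test_empty_and_single_row(self):
        empty = aggregate_motif_table(REFERENCE_MOTIF_COUNTS.iloc[:0])
        assert (empty == 0).all()
        single = aggregate_motif_table(REFERENCE_MOTIF_COUNTS.iloc[:1])
        assert (single == REFERENCE_MOTIF_COUNTS.iloc[0]).all()

    def test_inconsistent_row_total_rejected(self):
        bad = REFERENCE_MOTIF_COUNTS.copy()
        bad.loc["nit-1", "skn1_total"] = 99
        with pytest.raises(ValueError, match="nit-1"):
            aggregate_motif_table(bad)


class TestUpstreamScan:
    def _promoter_genome(self, window=4000):
        # all-C background provably hosts no built-in motif on either
        # strand; planted instances use only A/C/T so no cross-matches
        # or junction artefacts can arise
        upstream = ["C"] * window
        for pos in (100, 900):
            upstream[pos : pos + 7] = "TATTTAC"  # DBE instance
        for pos in (1500, 2000, 2500, 3000, 3500):
            upstream[pos : pos + 7] = "CTTATCA"  # DAE instance
        seq = "".join(upstream) + "C" * 2000
        genes = pd.Series(
            {
                "chrom": "c1", "strand": "+", "gene_start": window,
                "gene_end": window + 1500, "start_codon_pos": window,
                "stop_codon_pos": window + 1499,
            },
            name="mrp-like",
        )
        return {"c1": seq}, genes

    def test_planted_promoter_counts(self):
        genome, gene = self._promoter_genome()
        counts = scan_upstream_region(gene, genome, window_bp=4000)
        assert counts.loc["DBE", "both"] == 2
        assert counts.loc["DAE", "both"] == 5
        assert counts.loc["SKN-1", "both"] == 0

    def test_window_monotonicity(self):
        genome, gene = self._promoter_genome()
        wide = scan_upstream_region(gene, genome, window_bp=4000)
        narrow = scan_upstream_region(gene, genome, window_bp=2000)
        assert (narrow["both"] <= wide["both"]).all()
        # the plants at 100/900/1500 lie outside the trailing 2 kb
        assert narrow["both"].sum() < wide["both"].sum()

    def test_strand_resolved_counts_sum_to_both(self, planted_sim):
        genes = planted_sim.annotation.loc[planted_sim.genes_bed["name"]]
        gene = genes.iloc[0]
        counts = scan_upstream_region(gene, planted_sim.genome, window_bp=2000)
        assert (counts["plus"] + counts["minus"] == counts["both"]).all()
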