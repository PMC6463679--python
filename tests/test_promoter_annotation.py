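import numpy as np
import pandas as pd
import pytest

from cagesel import io_cage, promoter_annotation as pa

from conftest import make_cluster


class TestRepresentativeTss:
    def test_unique_argmax(self):
        tc = make_cluster({100: 3, 105: 9, 110: 2})
        assert pa.representative_tss(tc) == 105

    def test_tie_breaks_five_prime_most_plus(self):
        tc = make_cluster({100: 5, 110: 5}, "+")
        assert pa.representative_tss(tc) == 100

    def test_tie_breaks_five_prime_most_minus(self):
        tc = make_cluster({100: 5, 110: 5}, "-")
        assert pa.representative_tss(tc) == 110


@pytest.fixture
def two_gene_index(tmp_path):
    """Gene A: intron 2001-3000 overlapping gene B's 5'UTR on + strand."""
    gtf = (
        'chr1\tx\texon\t1001\t2000\t.\t+\t.\tgene_id "gA"; transcript_id "tA";\n'
        'chr1\tx\texon\t3001\t4000\t.\t+\t.\tgene_id "gA"; transcript_id "tA";\n'
        'chr1\tx\tCDS\t1001\t1500\t.\t+\t.\tgene_id "gA"; transcript_id "tA";\n'
        'chr1\tx\texon\t2101\t2900\t.\t+\t.\tgene_id "gB"; transcript_id "tB";\n'
        'chr1\tx\tCDS\t2601\t2900\t.\t+\t.\tgene_id "gB"; transcript_id "tB";\n'
    )
    path = tmp_path / "two.gtf"
    path.write_text(gtf)
    return io_cage.read_annotation(path)


class TestAssignFeature:
    def test_priority_5utr_beats_intron(self, two_gene_index):
        # 2500 is inside gA's intron (2001-3000) and inside gB's 5'UTR
        tc = make_cluster({2500: 10})
        ann = pa.assign_feature(tc, two_gene_index)
        assert (ann.feature, ann.gene) == ("5utr", "gB")

    def test_upstream_extension_counts_as_5utr(self, two_gene_index):
        # 40 nt upstream of gB's annotated 5'UTR start at 2101
        tc = make_cluster({2061: 10})
        ann = pa.assign_feature(tc, two_gene_index)
        assert (ann.feature, ann.gene) == ("5utr", "gB")

    def test_intergenic(self, two_gene_index):
        ann = pa.assign_feature(make_cluster({9000: 4}), two_gene_index)
        assert ann.feature == "intergenic" and ann.gene is None

    def test_cds_and_intron(self, two_gene_index):
        assert pa.assign_feature(make_cluster({1200: 4}), two_gene_index).feature == "cds"
        assert pa.assign_feature(make_cluster({2950: 4}), two_gene_index).feature == "intron"

    def test_priority_monotone(self, two_gene_index, tmp_path):
        """Adding a lower-priority (intron) interval never changes a 5utr call."""
        before = pa.assign_feature(make_cluster({2500: 10}), two_gene_index)
        two_gene_index._add("intron", "chr1", "+", 2000, 3500, "tA")
        after = pa.assign_feature(make_cluster({2500: 10}), two_gene_index)
        assert (before.feature, before.gene) == (after.feature, after.gene)


class TestUtrLength:
    @pytest.fixture
    def index(self, tmp_path):
        gtf = (
            'chr1\tx\texon\t1001\t2000\t.\t+\t.\tgene_id "g"; transcript_id "t1";\n'
            'chr1\tx\tCDS\t1201\t1800\t.\t+\t.\tgene_id "g"; transcript_id "t1";\n'
            'chr2\tx\texon\t1001\t2000\t.\t-\t.\tgene_id "h"; transcript_id "t2";\n'
            'chr2\tx\tCDS\t1201\t1800\t.\t-\t.\tgene_id "h"; transcript_id "t2";\n'
        )
        path = tmp_path / "u.gtf"
        path.write_text(gtf)
        return io_cage.read_annotation(path)

    def ann(self, index, ctss, strand="+", chrom="chr1"):
        return pa.assign_feature(make_cluster(ctss, strand, chrom), index)

    def test_same_length_status(self, index):
        a = self.ann(index, {1171: 20})   # 30 nt 5' of start codon 1201
        b = self.ann(index, {1171: 20})
        assert pa.five_prime_utr_length(a, index) == 30
        assert pa.utr_length_difference(a, b, index) == (0, "same")

    def test_downstream_shift_shortens(self, index):
        a = self.ann(index, {1181: 20})   # 10 nt downstream of b's rep TSS
        b = self.ann(index, {1171: 20})
        assert pa.utr_length_difference(a, b, index) == (-10, "shorter")

    def test_minus_strand_mirrors(self, index):
        # start codon first base at 1800 on chr2 minus strand
        a = self.ann(index, {1830: 20}, "-", "chr2")
        b = self.ann(index, {1840: 20}, "-", "chr2")
        assert pa.five_prime_utr_length(a, index) == 30
        assert pa.utr_length_difference(a, b, index) == (-10, "shorter")

    def test_no_downstream_start_codon_flagged(self, index):
        # rep TSS downstream of the start codon: length undefined
        a = self.ann(index, {1950: 20})
        assert a.feature == "3utr"
        assert pa.five_prime_utr_length(a, index) is None


class TestFirstNt:
    def test_planted_bases_recovered_exactly(self, tmp_path):
        io_cage.write_fasta({"chr1": "ACGTC" * 20}, tmp_path / "g.fa")
        genome = io_cage.read_fasta(tmp_path / "g.fa")
        anns = [pa.AnnotatedCluster(make_cluster({p: 10}), "5utr", "g", "t", p, 10)
                for p in (1, 6, 11, 2)]   # A, A, A, C
        freqs = pa.first_nt_frequency(anns, genome)
        assert freqs["A"] == 0.75 and freqs["C"] == 0.25
        assert freqs[list("ACGT")].sum() == pytest.approx(1.0, abs=1e-12)

    def test_minus_strand_base_is_complemented(self, tmp_path):
        io_cage.write_fasta({"chr1": "AAAA"}, tmp_path / "g.fa")
        genome = io_cage.read_fasta(tmp_path / "g.fa")
        ann = pa.AnnotatedCluster(make_cluster({2: 10}, "-"), "5utr", "g", "t", 2, 10)
        assert pa.first_nt_frequency([ann], genome)["T"] == 1.0


class TestGCorrection:
    @pytest.fixture
    def genome(self, tmp_path):
        io_cage.write_fasta({"chr1": "GATTACAGGA"}, tmp_path / "g.fa")
        return io_cage.read_fasta(tmp_path / "g.fa")

    def test_templated_g_unchanged(self, genome):
        df = pd.DataFrame([("chr1", 1, "+", 5, "G")],
                          columns=["chrom", "pos", "strand", "count", "first_nt"])
        out = pa.g_correction(df, genome)
        assert out.loc[0, "pos"] == 1 and out.loc[0, "count"] == 5

    def test_untemplated_g_shifts_downstream(self, genome):
        # genomic base at pos 2 is A; read starts with an added G
        df = pd.DataFrame([("chr1", 2, "+", 5, "G"), ("chr1", 3, "+", 2, "T")],
                          columns=["chrom", "pos", "strand", "count", "first_nt"])
        out = pa.g_correction(df, genome)
        assert out.to_dict("records") == [
            {"chrom": "chr1", "pos": 3, "strand": "+", "count": 7}]

    def test_count_conserved(self, genome):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "chrom": "chr1",
            "pos": rng.integers(2, 9, 20),
            "strand": rng.choice(["+", "-"], 20),
            "count": rng.integers(1, 10, 20),
            "first_nt": rng.choice(list("ACGT"), 20),
        }).drop_duplicates(subset=["chrom", "pos", "strand"])
        out = pa.g_correction(df, genome)
        assert out["count"].sum() == df["count"].sum()

    def test_missing_first_nt_column_is_error(self, genome):
        df = pd.DataFrame([("chr1", 2, "+", 5)],
                          columns=["chrom", "pos", "strand", "count"])
        with pytest.raises(ValueError, match="first_nt"):
            pa.g_correction(df, genome)


class TestExpressedFlags:
    def test_definitions(self, two_gene_index):
        # one TC in gB's extended 5'UTR, one in gA's CDS
        anns = [pa.assign_feature(make_cluster({2500: 10}), two_gene_index),
                pa.assign_feature(make_cluster({1200: 10}), two_gene_index)]
        tx, gene = pa.expressed_flags(anns, two_gene_index)
        assert tx["tB"] and not tx["tA"]
        assert gene["gB"] and not gene["gA"]
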