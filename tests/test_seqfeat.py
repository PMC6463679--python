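import numpy as np
import pandas as pd
import pytest

from cagesel import io_cage, seqfeat

from oracles import count_aug_oracle


def ws(label, seqs, width=None):
    width = width if width is not None else len(seqs[0])
    return seqfeat.WindowSet(label, list(seqs), width=width)


class TestWindowSet:
    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            seqfeat.WindowSet("x", ["ACGT"], width=100)


class TestExtractWindows:
    @pytest.fixture
    def genome(self, tmp_path):
        io_cage.write_fasta({"chr1": "".join("ACGT"[i % 4] for i in range(60))},
                            tmp_path / "g.fa")
        return io_cage.read_fasta(tmp_path / "g.fa")

    def test_downstream_starts_at_rep_tss(self, genome):
        got = seqfeat.extract_windows("x", [("chr1", 5, "+")], genome,
                                      "downstream", width=4)
        assert got.sequences == ["ACGT"]       # positions 5-8

    def test_minus_strand_reads_transcript_orientation(self, genome):
        plus = seqfeat.extract_windows("x", [("chr1", 8, "+")], genome,
                                       "downstream", width=4).sequences[0]
        minus = seqfeat.extract_windows("x", [("chr1", 11, "-")], genome,
                                        "downstream", width=4).sequences[0]
        assert minus == io_cage.revcomp(genome.fetch("chr1", 8, 11, "+"))
        assert plus == genome.fetch("chr1", 8, 11, "+")

    def test_upstream_is_five_prime_of_tss(self, genome):
        got = seqfeat.extract_windows("x", [("chr1", 5, "+")], genome,
                                      "upstream", width=4)
        assert got.sequences == [genome.fetch("chr1", 1, 4, "+")]

    def test_contig_edge_excluded_and_counted(self, genome):
        got = seqfeat.extract_windows("x", [("chr1", 2, "+")], genome,
                                      "upstream", width=4)
        assert got.sequences == [] and got.n_excluded == 1


class TestPickGroups:
    def build(self):
        rows = []
        for i in range(30):
            status = ["enriched", "depleted", "unchanged"][i % 3]
            fc = {"enriched": 4.0, "depleted": 0.2, "unchanged": 1.0}[status]
            rows.append((f"p{i:02d}", fc, 1e-5 * (i + 1), status))
        return pd.DataFrame(rows, columns=["pair_id", "fc", "p_value", "status"])

    def test_toy_selection(self):
        groups = seqfeat.pick_groups(self.build(), k=2, seed=0)
        assert list(groups["enriched"]["pair_id"]) == ["p00", "p03"]
        assert list(groups["depleted"]["pair_id"]) == ["p01", "p04"]
        assert len(groups["control"]) == 2
        assert (groups["control"]["status"] == "unchanged").all()

    def test_control_deterministic_under_seed(self):
        a = seqfeat.pick_groups(self.build(), k=3, seed=42)
        b = seqfeat.pick_groups(self.build(), k=3, seed=42)
        assert list(a["control"]["pair_id"]) == list(b["control"]["pair_id"])

    def test_small_band_warns_and_returns_all(self):
        small = self.build()[lambda d: (d["status"] != "unchanged")
                             | (d["pair_id"] == "p02")]
        with pytest.warns(UserWarning, match="band holds only"):
            groups = seqfeat.pick_groups(small, k=5, seed=0)
        assert list(groups["control"]["pair_id"]) == ["p02"]

    def test_groups_disjoint(self):
        groups = seqfeat.pick_groups(self.build(), k=4, seed=1)
        ids = [set(g["pair_id"]) for g in groups.values()]
        assert not (ids[0] & ids[1] or ids[0] & ids[2] or ids[1] & ids[2])


class TestGcProfile:
    def test_extremes(self):
        gc, _ = seqfeat.gc_profile(ws("g", ["GC" * 50] * 3))
        assert gc == 1.0
        at, _ = seqfeat.gc_profile(ws("a", ["AT" * 50] * 3))
        assert at == 0.0

    def test_per_position_frequencies_sum_to_one(self):
        rng = np.random.default_rng(11)
        seqs = ["".join(rng.choice(list("ACGT"), 100)) for _ in range(20)]
        _, freqs = seqfeat.gc_profile(ws("r", seqs))
        assert np.allclose(freqs[list("ACGT")].sum(axis=1), 1.0)

    def test_non_acgt_excluded_from_denominator(self):
        _, freqs = seqfeat.gc_profile(ws("n", ["NA", "CA"], width=2))
        assert freqs.loc[1, "other_count"] == 1
        assert freqs.loc[1, "C"] == 1.0     # only the C counts at position 1

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            seqfeat.gc_profile(seqfeat.WindowSet("e", [], width=100))

    def test_planted_gc_gradient_recovered(self):
        rng = np.random.default_rng(12)
        for target in (0.3, 0.6):
            seqs = ["".join(rng.choice(list("ACGT"), 100,
                                       p=[(1 - target) / 2, target / 2,
                                          target / 2, (1 - target) / 2]))
                    for _ in range(50)]
            gc, _ = seqfeat.gc_profile(ws("p", seqs))
            assert gc == pytest.approx(target, abs=0.03)


class TestCountAug:
    def test_examples(self):
        base = "C" * 94
        assert seqfeat.count_aug(ws("x", ["ATGATG" + base]))[0] == 2
        assert seqfeat.count_aug(ws("y", ["ATATGG" + base]))[0] == 1
        assert seqfeat.count_aug(seqfeat.WindowSet("e", [], width=100))[0] == 0

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(13)
        seqs = ["".join(rng.choice(list("ACGT"), 100, p=[0.4, 0.1, 0.2, 0.3]))
                for _ in range(40)]
        total, per = seqfeat.count_aug(ws("r", seqs))
        assert total == count_aug_oracle(seqs)
        assert sum(per) == total


class TestTataEnrichment:
    def test_identical_groups_fold_one(self):
        seqs = ["TATAAAA" + "C" * 93] * 10
        res = seqfeat.tata_enrichment(ws("a", seqs), ws("b", list(seqs)))
        assert res["fold"] == 1.0

    def test_planted_ratio_recovered(self):
        rng = np.random.default_rng(14)

        def group(rate, n=300):
            seqs = []
            for _ in range(n):
                s = "".join(rng.choice(list("CG"), 100))
                if rng.random() < rate:
                    i = rng.integers(0, 93)
                    s = s[:i] + "TATATAA" + s[i + 7:]
                seqs.append(s)
            return ws("g", seqs)

        res = seqfeat.tata_enrichment(group(0.6), group(0.1))
        assert res["fold"] == pytest.approx(6.0, rel=0.35)
        assert res["p_value"] < 1e-6

    def test_zero_denominator_is_infinity(self):
        a = ws("a", ["TATAAAA" + "C" * 93] * 5)
        b = ws("b", ["C" * 100] * 5)
        assert seqfeat.tata_enrichment(a, b)["fold"] == np.inf

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            seqfeat.tata_enrichment(ws("a", ["C" * 100]),
                                    seqfeat.WindowSet("b", [], width=100))
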