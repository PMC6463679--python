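import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cagesel import differential as diff

from oracles import binom_two_sided_oracle, hypergeom_tail_oracle


class TestTcDiff:
    def test_balanced_pair_unchanged(self):
        res = diff.tc_diff((50, 50), (10**6, 10**6))
        assert res.fc == 1.0 and res.p == pytest.approx(1.0) and res.status == "unchanged"

    def test_one_sided_zero_is_condition_only(self):
        res = diff.tc_diff((100, 0), (10**6, 10**6))
        assert res.status == "translatome_only" and np.isnan(res.fc)
        res = diff.tc_diff((0, 100), (10**6, 10**6))
        assert res.status == "transcriptome_only"

    def test_binomial_tail_matches_oracle(self):
        res = diff.tc_diff((80, 20), (10**6, 10**6))
        assert res.log2fc == pytest.approx(2.0)
        assert res.p == pytest.approx(binom_two_sided_oracle(80, 100, 0.5), rel=1e-9)
        assert res.status == "enriched"

    def test_unequal_libraries_shift_null(self):
        # 2:1 library ratio makes 80:40 the null expectation
        res = diff.tc_diff((80, 40), (2 * 10**6, 10**6))
        assert res.fc == pytest.approx(1.0)
        assert res.p == pytest.approx(binom_two_sided_oracle(80, 120, 2 / 3), rel=1e-9)

    def test_both_zero_excluded(self):
        with pytest.raises(ValueError, match="zero counts"):
            diff.tc_diff((0, 0), (10**6, 10**6))

    def test_table_applies_bh(self):
        table = diff.tc_diff_table(
            [("a", 80, 20), ("b", 50, 50), ("c", 200, 10)], (10**6, 10**6))
        assert (table["q_value"] >= table["p_value"]).all()
        assert set(table["status"]) == {"enriched", "unchanged"}


class TestSdu:
    def test_disjoint_support_is_one(self):
        assert diff.s_du([100, 0], [0, 50]) == 1.0

    def test_equal_proportions_zero(self):
        assert diff.s_du([50, 50], [200, 200]) == 0.0

    def test_half(self):
        assert diff.s_du([50, 50], [100, 0]) == 0.5

    def test_single_promoter_zero(self):
        assert diff.s_du([70], [30]) == 0.0

    def test_zero_side_undefined(self):
        assert np.isnan(diff.s_du([0, 0], [1, 2]))

    @given(st.integers(2, 8), st.integers(0, 2**31 - 1))
    @settings(max_examples=200, deadline=None)
    def test_bounds_on_random_vectors(self, n, seed):
        rng = np.random.default_rng(seed)
        p = rng.gamma(1.0, 10.0, size=n)
        t = rng.gamma(1.0, 10.0, size=n)
        val = diff.s_du(p, t)
        assert 0.0 <= val <= 1.0
        assert diff.s_du(p, p) == pytest.approx(0.0, abs=1e-12)


class TestGeneScores:
    def test_conservation_and_values(self):
        promoters = {"g1": [(10.0, 5.0, 100, 50), (30.0, 5.0, 300, 50)],
                     "g2": [(2.0, 8.0, 20, 80)]}
        scores = diff.gene_scores(promoters, (10**7, 10**7))
        by = {s.gene: s for s in scores}
        assert by["g1"].E_p == pytest.approx(40.0)     # sum of promoter RPMs
        assert by["g1"].E_t == pytest.approx(10.0)
        assert by["g1"].S_fc == pytest.approx(4.0)
        assert by["g2"].S_du == 0.0
        assert (by["g1"].q >= by["g1"].p)

    def test_zero_transcriptome_flagged(self):
        scores = diff.gene_scores({"g": [(10.0, 0.0, 100, 0)]}, (10**7, 10**7))
        assert np.isnan(scores[0].S_fc) and np.isnan(scores[0].S_du)


class TestSelectMatchedGroups:
    def build(self):
        rng = np.random.default_rng(8)
        rows = []
        for i in range(300):
            sfc = [4.0, 1.0, 0.25][i % 3]
            sig = i % 3 != 1
            rows.append((f"g{i:03d}", sfc, np.log2(sfc), 1e-6 * (i + 1),
                         float(rng.uniform(10, 500)), sig))
        return pd.DataFrame(rows, columns=["gene", "S_fc", "log2_S_fc",
                                           "p_value", "E_t", "significant"])

    def test_rule_recovery_and_disjoint(self):
        df = self.build()
        groups = diff.select_matched_groups(df, group_size=20)
        # enriched: smallest p among S_fc>2 & significant -> first 20 i%3==0
        assert list(groups["enriched"]["gene"])[:3] == ["g000", "g003", "g006"]
        # depleted: ranks 21-40 by p among S_fc<0.5
        dep_sorted = df[(df["S_fc"] < 0.5)].sort_values("p_value")
        assert list(groups["depleted"]["gene"]) == list(dep_sorted["gene"][20:40])
        # unchanged ranked by transcriptome abundance, descending
        assert groups["unchanged"]["E_t"].is_monotonic_decreasing
        ids = [set(g["gene"]) for g in groups.values()]
        assert not (ids[0] & ids[1] or ids[0] & ids[2] or ids[1] & ids[2])

    def test_short_pool_warns(self):
        df = self.build().head(9)
        with pytest.warns(UserWarning, match="only"):
            groups = diff.select_matched_groups(df, group_size=20)
        assert len(groups["enriched"]) == 3


class TestEnrichment:
    def test_full_family_overlap_matches_hypergeometric(self):
        universe = {f"g{i}" for i in range(40)}
        fam = {f"g{i}" for i in range(10)}
        res = diff.enrichment_test(fam, {"F": fam}, universe)
        row = res.iloc[0]
        assert np.isinf(row["odds_ratio"])
        assert row["p_value"] == pytest.approx(
            hypergeom_tail_oracle(10, 10, 10, 40), rel=1e-9)

    def test_disjoint_query_not_enriched(self):
        universe = {f"g{i}" for i in range(40)}
        fam = {f"g{i}" for i in range(10)}
        query = {f"g{i}" for i in range(10, 20)}
        res = diff.enrichment_test(query, {"F": fam}, universe)
        assert res.iloc[0]["odds_ratio"] <= 1.0
        assert res.iloc[0]["p_value"] > 0.5

    def test_random_queries_calibrated(self):
        rng = np.random.default_rng(9)
        universe = {f"g{i}" for i in range(60)}
        fam = {f"g{i}" for i in range(15)}
        names = sorted(universe)
        ps = []
        for _ in range(400):
            query = set(rng.choice(names, size=12, replace=False))
            ps.append(diff.enrichment_test(query, {"F": fam}, universe)
                      .iloc[0]["p_value"])
        # discrete one-sided p-values are super-uniform under the null
        assert np.mean(np.array(ps) < 0.05) <= 0.07

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            diff.enrichment_test({"a"}, {"F": {"a"}}, set())


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        assert diff.bh_adjust([0.01, 0.02, 0.03]) == pytest.approx(
            [0.03, 0.03, 0.03])

    def test_identity_cases(self):
        assert diff.bh_adjust([0.2]) == pytest.approx([0.2])
        assert diff.bh_adjust([1.0, 1.0]) == pytest.approx([1.0, 1.0])

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(10)
        p = rng.uniform(size=50)
        q = diff.bh_adjust(p)
        assert (q >= p).all() and (q <= 1).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            diff.bh_adjust([0.5, 1.5])
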