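"""Decile extraction, joint detection, bootstrap nulls, subsample bias."""

import math

import numpy as np
import pandas as pd
import pytest

from luadcohort import (
    RankingTable,
    SimConfig,
    cross_cohort_overlap_test,
    generate_cohort,
    joint_detection,
    multi_tool_coincidence_test,
    pick_planted_drivers,
    rank_from_scores,
    read_ranking_tsv,
    recurrence_ranker,
    subsample_bias_test,
    top_decile,
    write_ranking_tsv,
)
from oracles import overlap_null_distribution_oracle, poisson_upper_tail_oracle


def _ranking(genes, tool="t", scores=None):
    if scores is None:
        scores = {g: float(len(genes) - i) for i, g in enumerate(genes)}
    return rank_from_scores(pd.Series(scores), tool)


class TestTopDecile:
    def test_sizes_use_ceiling(self):
        genes = [f"g{i:03d}" for i in range(100)]
        assert len(top_decile(_ranking(genes))) == 10
        assert len(top_decile(_ranking(genes[:25]))) == 3   # ceil(2.5)

    def test_tie_at_cutoff_breaks_lexicographically(self):
        scores = {"bb": 3.0, "aa": 2.0, "cc": 2.0, "dd": 1.0, "ee": 0.5,
                  "ff": 0.4, "gg": 0.3, "hh": 0.2, "ii": 0.1, "jj": 0.05}
        decile = top_decile(_ranking(None, scores=scores), 0.2)
        assert decile == {"bb", "aa"}   # aa beats cc on the tie

    def test_validation(self):
        with pytest.raises(ValueError):
            top_decile(_ranking(["a", "b"]), 0.0)
        with pytest.raises(ValueError):
            RankingTable("t", pd.DataFrame(
                {"gene": ["a", "b"], "score": [1, 2], "rank": [1, 3]}))


class TestJointDetection:
    def test_identical_sets(self):
        s = {"a", "b", "c"}
        assert joint_detection([s, s, s], 2) == s

    def test_disjoint_sets(self):
        assert joint_detection([{"a"}, {"b"}, {"c"}], 2) == frozenset()

    def test_pairwise_overlaps(self):
        assert joint_detection([{"a", "b"}, {"b", "c"}, {"c", "d"}], 2) == \
            {"b", "c"}

    def test_min_tools_bounds(self):
        with pytest.raises(ValueError):
            joint_detection([{"a"}], 2)


class TestCoincidenceTest:
    def test_identical_rankings_floor_p(self):
        genes = [f"g{i:03d}" for i in range(200)]
        rks = [_ranking(genes, t) for t in "abc"]
        res = multi_tool_coincidence_test(rks, B=999, seed=0)
        assert res.observed_stat == 20
        assert res.p_empirical == 1 / 1000
        assert not np.any(res.null_stats >= 20)

    def test_zero_observed_gives_p_one(self):
        # 30 genes, decile of 3 per tool, constructed pairwise disjoint
        genes = [f"g{i:02d}" for i in range(30)]
        rks = []
        for t in range(3):
            rolled = genes[10 * t:] + genes[:10 * t]
            rks.append(_ranking(rolled, f"t{t}"))
        res = multi_tool_coincidence_test(rks, B=199, seed=1)
        assert res.observed_stat == 0
        assert res.p_empirical == 1.0

    def test_seed_reproducibility(self):
        genes = [f"g{i:03d}" for i in range(100)]
        rks = [_ranking(genes, t) for t in "abc"]
        a = multi_tool_coincidence_test(rks, B=500, seed=3)
        b = multi_tool_coincidence_test(rks, B=500, seed=3)
        assert np.array_equal(a.null_stats, b.null_stats)

    def test_universe_mismatch_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            multi_tool_coincidence_test(
                [_ranking(["a", "b"]), _ranking(["a", "c"]),
                 _ranking(["a", "b"])], B=10)

    def test_p_bounds(self):
        genes = [f"g{i:03d}" for i in range(100)]
        rks = [_ranking(genes, t) for t in "abc"]
        res = multi_tool_coincidence_test(rks, B=100, seed=0)
        assert 1 / 101 <= res.p_empirical <= 1


class TestOverlapTest:
    def test_analytic_expectation(self):
        u = [f"g{i}" for i in range(630)]
        res = cross_cohort_overlap_test(u[:63], u[:63], u, B=100, seed=0)
        assert res.expected_overlap == pytest.approx(6.3)

    def test_equal_sets_floor_p(self):
        u = [f"g{i}" for i in range(500)]
        a = u[:40]
        res = cross_cohort_overlap_test(a, a, u, B=2000, seed=0)
        assert res.observed_overlap == 40
        assert res.p_empirical == 1 / 2001

    def test_disjoint_partition_gives_p_one(self):
        u = [f"g{i}" for i in range(20)]
        res = cross_cohort_overlap_test(u[:8], u[8:], u, B=500, seed=0)
        assert res.observed_overlap == 0
        assert res.p_empirical == 1.0

    def test_containment_enforced(self):
        with pytest.raises(ValueError):
            cross_cohort_overlap_test({"x"}, {"a"}, {"a", "b"}, B=10)

    def test_null_matches_enumeration_small_universe(self):
        exact = overlap_null_distribution_oracle(10, 3, 4)
        u = [f"g{i}" for i in range(10)]
        res = cross_cohort_overlap_test(u[:3], u[3:7], u, B=40000, seed=5)
        for k, frac in exact.items():
            mc = np.mean(res.null_stats == k)
            se = math.sqrt(float(frac) * (1 - float(frac)) / 40000)
            assert abs(mc - float(frac)) < 5 * se + 1e-12

    def test_larger_intersection_never_raises_p(self):
        u = [f"g{i}" for i in range(100)]
        ps = []
        for k in (0, 5, 10):
            a = u[:10]
            b = u[10 - k:20 - k]
            res = cross_cohort_overlap_test(a, b, u, B=3000, seed=7)
            assert res.observed_overlap == k
            ps.append(res.p_empirical)
        assert ps[0] >= ps[1] >= ps[2]


class TestRecurrenceRanker:
    def _somatic(self, rows):
        return pd.DataFrame(rows, columns=["patient_id", "gene",
                                           "variant_class"])

    def test_poisson_tail_score(self):
        # ten genes of equal length, one carrying 10 of the 19 mutations:
        # cohort rate gives that gene expectation ~1.9, the rest share it
        rows = [("P1", "hot", "missense")] * 10
        rows += [("P1", f"g{i}", "missense") for i in range(9)]
        lengths = {f"g{i}": 1000.0 for i in range(9)}
        lengths["hot"] = 1000.0
        rk = recurrence_ranker(self._somatic(rows), lengths)
        t = rk.table.set_index("gene")
        assert t.loc["hot", "rank"] == 1
        mu = 19 / 10
        assert t.loc["hot", "score"] == pytest.approx(
            poisson_upper_tail_oracle(10, mu), rel=1e-9)

    def test_tail_value_at_unit_expectation(self):
        # 10 genes of 1 kb, 10 mutations all in one gene: cohort rate puts
        # each gene's expectation at exactly 1; tail P(X >= 10) ~ 1.1e-7
        rows = [("P1", "hot", "missense")] * 10
        lengths = {"hot": 1000.0, **{f"g{i}": 1000.0 for i in range(9)}}
        rk = recurrence_ranker(self._somatic(rows), lengths)
        score = rk.table.set_index("gene").loc["hot", "score"]
        assert score == pytest.approx(poisson_upper_tail_oracle(10, 1.0),
                                      rel=1e-9)
        assert score == pytest.approx(1.1142e-7, rel=1e-3)

    def test_all_tied_ranking_is_lexicographic(self):
        rows = [("P1", g, "missense") for g in ("b", "a", "c")]
        lengths = {g: 500.0 for g in "abc"}
        rk = recurrence_ranker(self._somatic(rows), lengths)
        assert rk.table.sort_values("rank")["gene"].tolist() == ["a", "b", "c"]

    def test_silent_mutations_ignored(self):
        rows = [("P1", "a", "silent")] * 5 + [("P1", "b", "missense")]
        lengths = {"a": 500.0, "b": 500.0}
        rk = recurrence_ranker(self._somatic(rows), lengths)
        assert rk.table.sort_values("rank")["gene"].iloc[0] == "b"

    def test_missing_length_rejected(self):
        rows = [("P1", "a", "missense")]
        with pytest.raises(ValueError, match="length"):
            recurrence_ranker(self._somatic(rows), {"b": 100.0})

    @pytest.mark.parametrize("seed", range(5))
    def test_planted_drivers_reach_top_decile(self, catalog, seed):
        drivers = pick_planted_drivers(500, 10, 10.0)
        cfg = SimConfig(seed=seed, n_patients=200, n_genes=500,
                        mutation_rate=60, planted_drivers=drivers)
        cohort = generate_cohort(cfg, catalog)
        rk = recurrence_ranker(cohort.somatic, cfg.lengths_series())
        assert set(drivers) <= top_decile(rk)


class TestSubsampleBias:
    def test_subsample_must_be_smaller_than_cohort(self, catalog):
        cfg = SimConfig(seed=0, n_patients=10, n_genes=50, mutation_rate=20)
        cohort = generate_cohort(cfg, catalog)
        with pytest.raises(ValueError):
            subsample_bias_test(cohort.somatic, set(), cfg.lengths_series(),
                                m=10, B=5)

    def test_reproducible_and_bounded(self, catalog):
        drivers = pick_planted_drivers(200, 10, 3.0)
        cfg = SimConfig(seed=1, n_patients=60, n_genes=200, mutation_rate=50,
                        planted_drivers=drivers)
        cohort = generate_cohort(cfg, catalog)
        args = (cohort.somatic, frozenset(drivers), cfg.lengths_series())
        a = subsample_bias_test(*args, m=20, B=30, seed=4)
        b = subsample_bias_test(*args, m=20, B=30, seed=4)
        assert np.array_equal(a.intersections, b.intersections)
        assert (a.intersections <= min(20, len(drivers))).all()
        assert ((a.proportion_nonreference >= 0)
                & (a.proportion_nonreference <= 1)).all()

    def test_observed_quantile_placement(self, catalog):
        drivers = pick_planted_drivers(200, 10, 3.0)
        cfg = SimConfig(seed=2, n_patients=60, n_genes=200, mutation_rate=50,
                        planted_drivers=drivers)
        cohort = generate_cohort(cfg, catalog)
        res = subsample_bias_test(
            cohort.somatic, frozenset(drivers), cfg.lengths_series(),
            m=20, B=30, seed=4, observed_nonreference_fraction=1.0)
        assert res.observed_quantile == 1.0


class TestRankingIO:
    def test_roundtrip(self, tmp_path):
        rk = _ranking([f"g{i}" for i in range(10)], tool="mytool")
        p = tmp_path / "rk.tsv"
        write_ranking_tsv(rk, p)
        back = read_ranking_tsv(p)
        assert back.tool == "mytool"
        pd.testing.assert_frame_equal(back.table, rk.table)

    def test_permutation_validated_on_read(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("tool\tgene\tscore\trank\nt\ta\t1.0\t1\nt\tb\t0.5\t3\n")
        with pytest.raises(ValueError, match="permutation"):
            read_ranking_tsv(p)
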