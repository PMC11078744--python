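"""IBD-network filters, node statistics and group tests."""

import numpy as np
import pytest
from scipy import stats as sps

from steppekin.datamodel import Individual, IBDSegment, PairRelatedness
from steppekin.network import (build_network, cumulative_degree_distribution,
                               filter_edges, group_means, ks_permutation_test,
                               node_stats, welch_t_test)


def _pair(a, b, lengths, density=250.0):
    segs = [IBDSegment("chr1", 10.0 * i, 10.0 * i + ln,
                       n_snps=int(ln * density))
            for i, ln in enumerate(lengths, start=1)]
    return PairRelatedness(id_a=a, id_b=b, segments=segs)


def _ind(iid, site="s", sex="male", adult=True, snps=600_000):
    return Individual(id=iid, site=site, sex=sex,
                      age_class="adult" if adult else "subadult",
                      snp_count=snps)


class TestFilterRules:
    def test_single_14cm_segment_is_no_edge(self):
        assert filter_edges([_pair("A", "B", [14.0])]) == []

    def test_two_13cm_segments_make_an_edge(self):
        out = filter_edges([_pair("A", "B", [13.0, 13.0])])
        assert len(out) == 1 and out[0].max_ibd_cM == pytest.approx(13.0)

    def test_single_20cm_segment_is_an_edge(self):
        out = filter_edges([_pair("A", "B", [20.0])])
        assert len(out) == 1 and out[0].max_ibd_cM == pytest.approx(20.0)

    def test_low_density_segments_are_screened(self):
        out = filter_edges([_pair("A", "B", [20.0], density=200.0)])
        assert out == []

    def test_low_coverage_individual_dropped(self):
        inds = [_ind("A", snps=400_000), _ind("B")]
        assert filter_edges([_pair("A", "B", [20.0])], inds) == []

    def test_brute_force_rule_oracle(self, rng):
        """Re-apply the three filter rules independently on random segment sets."""
        for _ in range(300):
            lengths = rng.uniform(2.0, 30.0, size=rng.integers(1, 6))
            pr = _pair("A", "B", list(lengths))
            got = filter_edges([pr])
            kept = [ln for ln in lengths if ln > 8.0]        # density is 250/cM
            long = [ln for ln in kept if ln > 12.0]
            expect_edge = bool(long) and (max(long, default=0.0) >= 16.0
                                          or len(long) >= 2)
            assert bool(got) == expect_edge
            if got:
                assert got[0].max_ibd_cM == pytest.approx(max(long))

    def test_idempotent(self, rng):
        prs = [_pair(f"A{i}", f"B{i}", list(rng.uniform(2.0, 30.0, size=4)))
               for i in range(50)]
        once = filter_edges(prs)
        twice = filter_edges(once)
        assert [(p.key, p.max_ibd_cM, p.n_segments) for p in once] == \
            [(p.key, p.max_ibd_cM, p.n_segments) for p in twice]


class TestNetworkStats:
    def test_empty_edge_list_empty_network(self):
        net = build_network([], [])
        assert net.n_nodes == 0 and net.n_edges == 0

    def test_triangle_within_one_site(self):
        inds = [_ind(x) for x in "ABC"]
        edges = filter_edges([_pair(a, b, [20.0])
                              for a, b in [("A", "B"), ("B", "C"), ("A", "C")]])
        stats = node_stats(build_network(edges, inds))
        assert (stats["k"] == 2).all()
        assert (stats["k_B"] == 0).all()
        assert (stats["kB_over_k"] == 0.0).all()

    def test_single_cross_site_edge_ratio_one(self):
        inds = [_ind("A", site="s1"), _ind("B", site="s2")]
        stats = node_stats(build_network(filter_edges([_pair("A", "B", [20.0])]),
                                         inds))
        assert (stats["kB_over_k"] == 1.0).all()

    def test_two_site_fixture_hand_enumeration(self):
        # sites: s1 = {A, B, C}, s2 = {D, E}; edges with weights:
        # A-B 20, A-C 30, B-C 18, A-D 25, D-E 40
        inds = [_ind(x, site="s1") for x in "ABC"] + \
               [_ind(x, site="s2") for x in "DE"]
        pairs = [_pair("A", "B", [20.0]), _pair("A", "C", [30.0]),
                 _pair("B", "C", [18.0]), _pair("A", "D", [25.0]),
                 _pair("D", "E", [40.0])]
        stats = node_stats(build_network(filter_edges(pairs), inds)).set_index("id")
        assert stats.loc["A", "k"] == 3 and stats.loc["A", "k_B"] == 1
        assert stats.loc["A", "w"] == pytest.approx(75.0)
        assert stats.loc["A", "kB_over_k"] == pytest.approx(1 / 3)
        assert stats.loc["D", "k"] == 2 and stats.loc["D", "k_B"] == 1
        assert stats.loc["E", "k_B"] == 0
        means = group_means(stats.reset_index())
        assert means["all"]["k"] == pytest.approx((3 + 2 + 2 + 2 + 1) / 5)

    def test_adults_only_removes_subadult_endpoints(self):
        inds = [_ind("A"), _ind("B", adult=False), _ind("C")]
        pairs = [_pair("A", "B", [20.0]), _pair("A", "C", [20.0])]
        net = build_network(filter_edges(pairs), inds, adults_only=True)
        assert set(net.graph.nodes) == {"A", "C"}

    def test_degree_and_strength_identities(self, multi_site_bundle):
        b = multi_site_bundle
        edges = filter_edges(b.pairs, b.cemetery.individuals)
        net = build_network(edges, b.cemetery.individuals)
        stats = node_stats(net)
        assert stats["k"].sum() == 2 * net.n_edges
        total_w = sum(d["weight"] for _, _, d in net.graph.edges(data=True))
        assert stats["w"].sum() == pytest.approx(2 * total_w)
        assert (stats["k"] == stats["k_W"] + stats["k_B"]).all()

    def test_cumulative_degree_distribution_is_survival(self):
        inds = [_ind(x) for x in "ABC"]
        edges = filter_edges([_pair("A", "B", [20.0]), _pair("A", "C", [20.0])])
        stats = node_stats(build_network(edges, inds))
        cdd = cumulative_degree_distribution(stats)
        assert cdd["p_k_gt_x"].iloc[-1] == 0.0
        assert (cdd["p_k_gt_x"].diff().dropna() <= 0).all()

    def test_female_between_site_ratio_exceeds_male(self):
        """Directional property of female exogamy across seeds: on the
        adults-only network, women carry a larger share of between-site
        links than men embedded in their local patrilines."""
        from steppekin.scenarios import ScenarioSpec, generate_scenario

        fem, mal = [], []
        for seed in range(8):
            b = generate_scenario(ScenarioSpec(preset="multi_site", seed=seed))
            edges = filter_edges(b.pairs, b.cemetery.individuals)
            stats = node_stats(build_network(edges, b.cemetery.individuals,
                                             adults_only=True))
            fem.extend(stats.loc[stats.sex == "female", "kB_over_k"].dropna())
            mal.extend(stats.loc[stats.sex == "male", "kB_over_k"].dropna())
        assert np.mean(fem) > np.mean(mal)


class TestGroupTests:
    def test_ks_identical_samples(self):
        a = [1.0, 2.0, 3.0]
        d, p = ks_permutation_test(a, a, n_perm=99, seed=0)
        assert d == 0.0 and p == 1.0

    def test_ks_disjoint_support(self):
        d, p = ks_permutation_test([1, 2, 3, 4, 5], [10, 11, 12, 13, 14],
                                   n_perm=999, seed=0)
        assert d == 1.0
        assert p >= 1 / 1000
        assert p < 0.05

    def test_ks_empty_sample_raises(self):
        with pytest.raises(ValueError):
            ks_permutation_test([], [1.0])

    def test_ks_statistic_matches_scipy(self, rng):
        for _ in range(20):
            a = rng.normal(size=rng.integers(5, 30))
            b = rng.normal(size=rng.integers(5, 30))
            d, _ = ks_permutation_test(a, b, n_perm=1, seed=0)
            assert d == pytest.approx(sps.ks_2samp(a, b).statistic)

    def test_welch_equal_samples(self):
        t, df, p = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_welch_matches_reference_implementation(self, rng):
        for _ in range(20):
            a = rng.normal(size=rng.integers(5, 30))
            b = rng.normal(loc=0.5, size=rng.integers(5, 30))
            t, df, p = welch_t_test(a, b)
            ref = sps.ttest_ind(a, b, equal_var=False)
            assert t == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)

    def test_welch_small_sample_raises(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0], [1.0, 2.0])
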