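"""Degree classification, second-degree discrimination and consanguinity."""

import numpy as np
import pytest

from steppekin.datamodel import DEFAULT_MAP, IBDSegment, PairRelatedness
from steppekin.relatedness import (SecondDegreeClassifier,
                                   build_reference_distributions,
                                   classify_degree, classify_second_degree,
                                   consanguinity_from_diplotype,
                                   detect_consanguinity,
                                   inbred_offspring_pedigree, pair_summary,
                                   second_degree_pedigree,
                                   simulate_pair_segments)
from steppekin.transmission import drop_genomes

L = DEFAULT_MAP.total_cM


def _summary(p1, p2):
    pr = PairRelatedness(id_a="A", id_b="B",
                         total_ibd1_cM=p1 * L, total_ibd2_cM=p2 * L,
                         n_segments=1, max_ibd_cM=10.0,
                         kinship=0.25 * p1 + 0.5 * p2)
    classify_degree(pr)
    return pr


class TestPairSummary:
    def test_empty_is_unrelated(self):
        pr = pair_summary("A", "B", [])
        assert pr.kinship == 0.0 and pr.degree == "unrelated"

    def test_full_genome_ibd1_is_parent_child(self):
        segs = [IBDSegment(name, 0.0, ln, state="IBD1")
                for name, ln in DEFAULT_MAP.chromosomes]
        pr = pair_summary("A", "B", segs)
        assert pr.kinship == pytest.approx(0.25)
        assert pr.degree == "parent_child"

    def test_sibling_kinship_averages_quarter(self, rng):
        phis = []
        for _ in range(300):
            segs = simulate_pair_segments("sibling", rng)
            phis.append(pair_summary("A", "B", segs).kinship)
        mean, se = np.mean(phis), np.std(phis) / np.sqrt(len(phis))
        assert abs(mean - 0.25) < 3 * se


class TestDegreeClassifier:
    @pytest.mark.parametrize("p1,p2,expected", [
        (1.0, 0.0, "parent_child"),
        (0.5, 0.25, "sibling"),
        (0.0, 0.0, "unrelated"),
        (0.5, 0.0, "second"),
        (0.25, 0.0, "third"),
        (0.0, 1.0, "identical"),
    ])
    def test_analytic_cases(self, p1, p2, expected):
        assert _summary(p1, p2).degree == expected

    def test_monotone_in_kinship(self):
        order = {"unrelated": 0, "third": 1, "second": 2,
                 "parent_child": 3, "sibling": 3, "first_ambiguous": 3,
                 "identical": 4}
        last = -1
        for p1 in np.linspace(0.0, 1.0, 101):
            rank = order[_summary(p1, 0.0).degree]
            assert rank >= last
            last = rank

    def test_confusion_matrix_on_perfect_observations(self, rng):
        """First/second-degree diagonal accuracy on noiseless simulated pairs."""
        relations = {"parent_child": "parent_child", "sibling": "sibling",
                     "avuncular": "second", "unrelated": "unrelated"}
        n = 150
        for relation, expected in relations.items():
            hits = 0
            for _ in range(n):
                segs = simulate_pair_segments(relation, rng)
                if pair_summary("A", "B", segs).degree == expected:
                    hits += 1
            assert hits / n >= 0.95, relation


class TestSecondDegreeDiscrimination:
    def test_avuncular_more_segments_than_grandparent(self, reference_distributions):
        s = reference_distributions.samples
        assert s["avuncular"][:, 0].mean() > s["grandparent"][:, 0].mean()

    def test_grandparent_longer_segments_than_avuncular(self, reference_distributions):
        s = reference_distributions.samples
        assert s["grandparent"][:, 1].mean() > s["avuncular"][:, 1].mean()

    def test_half_siblings_overlap_both(self, reference_distributions):
        s = reference_distributions.samples
        hs = s["half_sibling"]
        for other in ("avuncular", "grandparent"):
            for axis in (0, 1):  # segment count and mean length
                assert hs[:, axis].min() <= s[other][:, axis].max()
                assert hs[:, axis].max() >= s[other][:, axis].min()

    def test_requires_two_pedigrees(self):
        with pytest.raises(ValueError):
            build_reference_distributions(n_pedigrees=1)

    def test_centroid_classifies_to_own_class(self, reference_distributions):
        clf = SecondDegreeClassifier().fit(reference_distributions)
        for cls in ("avuncular", "grandparent"):
            centroid = reference_distributions.samples[cls][:, :2].mean(axis=0)
            assert clf.predict_one(*centroid)[0] == cls

    def test_high_ambiguity_ratio_yields_ambiguous(self, reference_distributions):
        clf = SecondDegreeClassifier(ambiguity_ratio=1e9).fit(reference_distributions)
        centroid = reference_distributions.samples["avuncular"][:, :2].mean(axis=0)
        assert clf.predict_one(*centroid)[0] == "ambiguous"

    def test_params_round_trip(self):
        clf = SecondDegreeClassifier(ambiguity_ratio=3.0)
        assert clf.get_params() == {"ambiguity_ratio": 3.0}
        clf.set_params(ambiguity_ratio=2.0)
        assert clf.ambiguity_ratio == 2.0

    def test_held_out_accuracy_and_half_sib_overlap(self, reference_distributions):
        """Cross-validated: avuncular/grandparent beat the majority baseline;
        half siblings, overlapping both, are recalled less reliably."""
        clf = SecondDegreeClassifier(ambiguity_ratio=1.0).fit(reference_distributions)
        held_out = build_reference_distributions(n_pedigrees=60, seed=99)
        recall = {}
        for cls, arr in held_out.samples.items():
            hits = sum(clf.predict_one(*row)[0] == cls for row in arr[:, :2])
            recall[cls] = hits / len(arr)
        assert recall["avuncular"] > 0.5
        assert recall["grandparent"] > 0.5
        assert recall["half_sibling"] < max(recall["avuncular"],
                                            recall["grandparent"])

    def test_classify_second_degree_sets_subtype(self, reference_distributions):
        pr = PairRelatedness(id_a="A", id_b="B", n_segments=26,
                             total_ibd1_cM=26 * 68.0, total_ibd2_cM=0.0,
                             max_ibd_cM=100.0, kinship=0.125, degree="second")
        subtype, score = classify_second_degree(pr, reference_distributions,
                                                ambiguity_ratio=1.0)
        assert subtype in ("avuncular", "grandparent", "half_sibling")
        assert score >= 1.0
        assert pr.subtype == subtype


class TestConsanguinity:
    def test_empty_roh_not_flagged(self):
        call = detect_consanguinity("X", [])
        assert call.sum_roh_gt4_cM == 0.0 and not call.flagged

    def test_outbred_false_positive_rate(self, rng):
        from steppekin.relatedness import sibling_pair_pedigree

        ped, _ = sibling_pair_pedigree()
        flags = 0
        for _ in range(200):
            genomes = drop_genomes(ped, DEFAULT_MAP, rng)
            if consanguinity_from_diplotype("A", genomes["A"]).flagged:
                flags += 1
        assert flags / 200 <= 0.05

    def test_first_cousin_offspring_flagged(self, rng):
        ped, child = inbred_offspring_pedigree("first_cousins")
        flags = 0
        for _ in range(200):
            genomes = drop_genomes(ped, DEFAULT_MAP, rng)
            if consanguinity_from_diplotype(child, genomes[child]).flagged:
                flags += 1
        assert flags / 200 >= 0.95

    def test_second_cousin_offspring_sensitivity(self, rng):
        ped, child = inbred_offspring_pedigree("second_cousins")
        flags = 0
        for _ in range(200):
            genomes = drop_genomes(ped, DEFAULT_MAP, rng)
            if consanguinity_from_diplotype(child, genomes[child]).flagged:
                flags += 1
        assert flags / 200 >= 0.80
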