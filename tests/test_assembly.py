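"""Pedigree assembly and social-practice metrics."""

import numpy as np
import pytest

from steppekin.assembly import (AssemblyConstraints, assemble_pedigrees,
                                detect_shared_partner_unions, partner_counts,
                                patriliny_metrics)
from steppekin.datamodel import Individual, PairRelatedness
from steppekin.pedigree import PedigreeGraph
from steppekin.simulate import SimulationConfig, simulate_community


def _pc_pair(a, b):
    return PairRelatedness(id_a=a, id_b=b, total_ibd1_cM=3546.0,
                           total_ibd2_cM=0.0, n_segments=22, max_ibd_cM=280.0,
                           kinship=0.25, degree="parent_child")


class TestAssembly:
    def test_adult_subadult_pair_forces_orientation(self):
        inds = [Individual(id="F", site="s", sex="male", age_class="adult",
                           y_haplogroup="J1a"),
                Individual(id="S", site="s", sex="male", age_class="subadult",
                           y_haplogroup="J1a")]
        out = assemble_pedigrees([_pc_pair("F", "S")], inds)
        assert len(out) == 1
        assert out[0].pedigree.father.get("S") == "F"
        assert not out[0].conflicts

    def test_mt_mismatch_reported_as_conflict(self):
        inds = [Individual(id="M", site="s", sex="female", age_class="adult",
                           mt_haplogroup="H1"),
                Individual(id="C", site="s", sex="male", age_class="subadult",
                           mt_haplogroup="U5")]
        out = assemble_pedigrees([_pc_pair("C", "M")], inds)
        assert any(c.kind == "mt_mismatch" for c in out[0].conflicts)
        assert "C" not in out[0].pedigree.mother

    def test_y_mismatch_reported_as_conflict(self):
        inds = [Individual(id="F", site="s", sex="male", age_class="adult",
                           y_haplogroup="J1a"),
                Individual(id="S", site="s", sex="male", age_class="subadult",
                           y_haplogroup="N1a")]
        out = assemble_pedigrees([_pc_pair("F", "S")], inds)
        assert any(c.kind == "y_mismatch" for c in out[0].conflicts)

    def test_same_phase_adults_left_unresolved(self):
        inds = [Individual(id="A", site="s", sex="male", age_class="adult",
                           phase="middle"),
                Individual(id="B", site="s", sex="male", age_class="adult",
                           phase="middle")]
        out = assemble_pedigrees([_pc_pair("A", "B")], inds)
        assert out[0].unresolved_pairs == [("A", "B")]

    def test_birth_order_anchors_decide(self):
        inds = [Individual(id="A", site="s", sex="male", age_class="adult"),
                Individual(id="B", site="s", sex="male", age_class="adult")]
        out = assemble_pedigrees([_pc_pair("A", "B")], inds,
                                 birth_order={"A": 600.0, "B": 630.0})
        assert out[0].pedigree.father.get("B") == "A"

    def test_sibling_group_shares_parents(self):
        inds = [Individual(id="F", site="s", sex="male", age_class="adult",
                           phase="early"),
                Individual(id="A", site="s", sex="male", phase="late"),
                Individual(id="B", site="s", sex="female", phase="late")]
        sib = PairRelatedness(id_a="A", id_b="B", total_ibd1_cM=1773.0,
                              total_ibd2_cM=886.0, n_segments=60,
                              max_ibd_cM=150.0, kinship=0.25, degree="sibling")
        out = assemble_pedigrees([_pc_pair("F", "A"), sib], inds)
        ped = out[0].pedigree
        assert ped.father.get("A") == "F" and ped.father.get("B") == "F"


class TestSocialMetrics:
    @pytest.fixture()
    def toy(self):
        # founder M, two exogamous wives, two sons, one daughter
        ped = PedigreeGraph()
        for iid, sex in [("M", "male"), ("W1", "female"), ("W2", "female"),
                         ("S1", "male"), ("S2", "male"), ("D1", "female")]:
            ped.add_individual(Individual(id=iid, site="s", sex=sex))
        ped.set_parents("S1", "M", "W1")
        ped.set_parents("S2", "M", "W2")
        ped.set_parents("D1", "M", "W1")
        ped.add_union("M", "W1").children = ["S1", "D1"]
        ped.add_union("M", "W2").children = ["S2"]
        return ped

    def test_hand_enumerated_counts(self, toy):
        m = patriliny_metrics(toy)
        assert m.n_sons == 2 and m.n_daughters == 1
        assert m.n_exogamous_mothers == 2 and m.n_lineage_mothers == 0
        assert m.patriline_purity == 1.0

    def test_broken_patriline_lowers_purity(self, toy):
        # father whose own father is absent but mother present: not a true founder
        toy.add_individual(Individual(id="X", site="s", sex="male"))
        toy.add_individual(Individual(id="C", site="s", sex="male"))
        toy.set_parents("X", None, "W1")
        toy.set_parents("C", "X", None)
        m = patriliny_metrics(toy)
        assert m.patriline_purity is not None and m.patriline_purity < 1.0

    def test_partner_counts(self, toy):
        counts = partner_counts(toy)
        assert counts["M"] == 2 and counts["W1"] == 1 and counts["W2"] == 1

    def test_no_shared_partner_in_monogamy(self, toy):
        assert detect_shared_partner_unions(toy) == []

    def test_constructed_levirate_detected_as_full_brothers(self, toy):
        toy.add_union("S1", "W2")
        recs = detect_shared_partner_unions(toy)
        assert len(recs) == 1
        rec = recs[0]
        assert rec.relation == "father_son"  # M and S1 share W2
        toy.add_union("S2", "W1")
        recs = detect_shared_partner_unions(toy)
        by_female = {r.female: r for r in recs}
        assert by_female["W1"].relation == "father_son"

    def test_brother_levirate_relation(self):
        ped = PedigreeGraph()
        for iid, sex in [("F", "male"), ("Mo", "female"), ("B1", "male"),
                         ("B2", "male"), ("W", "female")]:
            ped.add_individual(Individual(id=iid, site="s", sex=sex))
        ped.set_parents("B1", "F", "Mo")
        ped.set_parents("B2", "F", "Mo")
        ped.add_union("B1", "W")
        ped.add_union("B2", "W", levirate=True)
        recs = detect_shared_partner_unions(ped)
        assert len(recs) == 1 and recs[0].relation == "full_brothers"
        assert recs[0].levirate_consistent


class TestParameterRecovery:
    def test_polygyny_partner_count_matches_closed_form(self):
        """Mean partners per married male under the truncated-geometric
        union model: E = (1 - p^4) / (1 - p)."""
        p = 0.3
        counts = []
        for seed in range(150):
            com = simulate_community(SimulationConfig(
                n_generations=3, n_founder_males=3, polygyny_prob=p,
                levirate_prob=0.0, seed=seed))
            pc = partner_counts(com.pedigree)
            males = {u.male_id for u in com.pedigree.unions}
            counts.extend(pc[m] for m in males)
        expected = (1 - p ** 4) / (1 - p)
        mean = np.mean(counts)
        se = np.std(counts) / np.sqrt(len(counts))
        assert abs(mean - expected) < 3 * se

    def test_exogamy_rate_recovered_without_bias(self):
        rate = 0.8
        ests = []
        for seed in range(100):
            com = simulate_community(SimulationConfig(
                n_generations=4, n_founder_males=6, exogamy_rate=rate,
                mean_daughters_per_union=2.0, consanguinity_min_degree=3,
                levirate_prob=0.0, seed=seed))
            e = patriliny_metrics(com.pedigree).exogamy_fraction_nonfounding
            if e is not None:
                ests.append(e)
        mean = np.mean(ests)
        se = np.std(ests) / np.sqrt(len(ests))
        assert abs(mean - rate) < 3 * se
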