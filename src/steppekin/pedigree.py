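"""Pedigree graph: directed parent->child structure with union (partnership) records.

Genealogical degree follows the standard convention: parent-child = 1,
full siblings = 1 (a couple of shared ancestors at one meiosis each),
half siblings / avuncular / grandparent = 2, first cousins = 3, and so on.
For a shared ancestral *couple* the degree is g_a + g_b - 1; for a single
shared ancestor it is g_a + g_b, where g is the number of meioses from each
individual up to that ancestor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx

from .datamodel import Individual, ValidationError


@dataclass
class UnionRecord:
    """A reproductive partnership and the offspring it produced."""

    male_id: str
    female_id: str
    children: list[str] = field(default_factory=list)
    levirate: bool = False


@dataclass
class PedigreeGraph:
    individuals: dict[str, Individual] = field(default_factory=dict)
    father: dict[str, str] = field(default_factory=dict)
    mother: dict[str, str] = field(default_factory=dict)
    unions: list[UnionRecord] = field(default_factory=list)
    founders: set[str] = field(default_factory=set)
    generation: dict[str, int] = field(default_factory=dict)

    def add_individual(self, ind: Individual, generation: Optional[int] = None,
                       founder: bool = False) -> None:
        if ind.id in self.individuals:
            raise ValidationError(f"duplicate individual id {ind.id}")
        self.individuals[ind.id] = ind
        if generation is not None:
            self.generation[ind.id] = generation
        if founder:
            self.founders.add(ind.id)

    def set_parents(self, child: str, father: Optional[str], mother: Optional[str]) -> None:
        if father is not None:
            self.father[child] = father
        if mother is not None:
            self.mother[child] = mother

    def parents_of(self, iid: str) -> tuple[Optional[str], Optional[str]]:
        return self.father.get(iid), self.mother.get(iid)

    def children_of(self, iid: str) -> list[str]:
        out = [c for c, f in self.father.items() if f == iid]
        out += [c for c, m in self.mother.items() if m == iid]
        return sorted(set(out))

    def add_union(self, male_id: str, female_id: str, levirate: bool = False) -> UnionRecord:
        rec = UnionRecord(male_id, female_id, levirate=levirate)
        self.unions.append(rec)
        return rec

    def union_for(self, male_id: str, female_id: str) -> Optional[UnionRecord]:
        for u in self.unions:
            if u.male_id == male_id and u.female_id == female_id:
                return u
        return None

    # --- queries -------------------------------------------------------

    def ancestor_depths(self, iid: str) -> dict[str, int]:
        """Minimum meiosis count from `iid` up to each ancestor (self at 0)."""
        depths = {iid: 0}
        frontier = [iid]
        while frontier:
            nxt = []
            for x in frontier:
                for p in self.parents_of(x):
                    if p is not None and p in self.individuals:
                        d = depths[x] + 1
                        if p not in depths or d < depths[p]:
                            depths[p] = d
                            nxt.append(p)
            frontier = nxt
        return depths

    def relationship_degree(self, a: str, b: str) -> Optional[int]:
        """Genealogical degree between a and b, or None if unrelated in graph."""
        if a == b:
            return 0
        da = self.ancestor_depths(a)
        db = self.ancestor_depths(b)
        common = set(da) & set(db)
        if not common:
            return None
        best: Optional[int] = None
        couples = {(u.male_id, u.female_id) for u in self.unions}
        # also treat shared (father, mother) assignments as couples
        for child in set(self.father) & set(self.mother):
            couples.add((self.father[child], self.mother[child]))
        for c in common:
            d = da[c] + db[c]
            best = d if best is None else min(best, d)
        for m, f in couples:
            if m in common and f in common and da[m] == da[f] and db[m] == db[f]:
                d = da[m] + db[m] - 1
                best = d if best is None else min(best, d)
        return best

    def is_patrilineal_descendant(self, iid: str, ancestor: str) -> bool:
        x: Optional[str] = iid
        while x is not None:
            if x == ancestor:
                return True
            x = self.father.get(x)
        return False

    def patriline_root(self, iid: str) -> str:
        x = iid
        while x in self.father:
            x = self.father[x]
        return x

    def agnatic_relation(self, m1: str, m2: str) -> str:
        """Label the male-line relation between two males.

        Returns one of father_son, full_brothers, paternal_half_brothers,
        paternal_uncle_nephew, other_agnatic, unrelated.
        """
        if self.father.get(m2) == m1 or self.father.get(m1) == m2:
            return "father_son"
        f1, f2 = self.father.get(m1), self.father.get(m2)
        if f1 is not None and f1 == f2:
            mo1, mo2 = self.mother.get(m1), self.mother.get(m2)
            if mo1 is not None and mo1 == mo2:
                return "full_brothers"
            return "paternal_half_brothers"
        # paternal uncle-nephew: one's father is a (paternal) brother of the other
        for unc, nep in ((m1, m2), (m2, m1)):
            fn = self.father.get(nep)
            if fn is not None and fn != unc:
                if self.father.get(fn) is not None and self.father.get(fn) == self.father.get(unc):
                    return "paternal_uncle_nephew"
        if self.patriline_root(m1) == self.patriline_root(m2):
            return "other_agnatic"
        return "unrelated"

    def topological_order(self) -> list[str]:
        g = self.to_networkx()
        return list(nx.topological_sort(g))

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.individuals)
        for child, f in self.father.items():
            if f in self.individuals:
                g.add_edge(f, child)
        for child, m in self.mother.items():
            if m in self.individuals:
                g.add_edge(m, child)
        return g

    def validate(self) -> None:
        g = self.to_networkx()
        if not nx.is_directed_acyclic_graph(g):
            raise ValidationError("pedigree contains a parent cycle")
        for child, f in self.father.items():
            if f in self.individuals and self.individuals[f].sex == "female":
                raise ValidationError(f"father {f} of {child} recorded as female")
        for child, m in self.mother.items():
            if m in self.individuals and self.individuals[m].sex == "male":
                raise ValidationError(f"mother {m} of {child} recorded as male")

    def subset_ids(self) -> set[str]:
        return set(self.individuals)


def connected_components(ped: PedigreeGraph, ids: Optional[Iterable[str]] = None) -> list[set[str]]:
    """Components of the undirected parent-child graph, restricted to `ids`."""
    g = ped.to_networkx().to_undirected()
    if ids is not None:
        g = g.subgraph(set(ids)).copy()
    return [set(c) for c in nx.connected_components(g)]
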