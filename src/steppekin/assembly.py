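"""Pedigree assembly from pairwise relatedness calls, and social-practice metrics.

Assembly is constraint propagation, not probabilistic search: connected
components over first/second-degree calls become candidate pedigrees;
parent-child edges are oriented by chronology (explicit anchors if available,
otherwise the adult/subadult distinction and chronological phase), parents are
slotted by sex, sibling groups share parents, and uniparental haplogroups
(Y father-son, mtDNA mother-child) veto inconsistent placements.  Where the
data cannot orient an edge the pair is reported unresolved rather than
guessed.  A single unobserved parent connecting two or more observed
siblings is emitted as an inferred ("ghost") individual.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx

from .datamodel import Individual, PairRelatedness
from .pedigree import PedigreeGraph, UnionRecord
from .relatedness import CLOSE_DEGREES, FIRST_DEGREE

PHASE_ORDER = {"early": 0, "middle": 1, "late": 2}


@dataclass
class AssemblyConstraints:
    enforce_mt_mother_child: bool = True
    enforce_y_father_son: bool = True
    allow_missing_individuals: bool = True


@dataclass
class Conflict:
    kind: str
    ids: tuple[str, ...]
    detail: str


@dataclass
class AssembledPedigree:
    pedigree: PedigreeGraph
    members: set[str]
    conflicts: list[Conflict] = field(default_factory=list)
    unresolved_pairs: list[tuple[str, str]] = field(default_factory=list)
    inferred_ids: set[str] = field(default_factory=set)

    @property
    def resolved(self) -> bool:
        return not self.conflicts


def _orient_parent_child(a: Individual, b: Individual,
                         birth_order: Optional[dict[str, float]]) -> Optional[tuple[str, str]]:
    """Return (parent_id, child_id), or None when chronology cannot decide."""
    if birth_order and a.id in birth_order and b.id in birth_order:
        if birth_order[a.id] < birth_order[b.id]:
            return a.id, b.id
        if birth_order[b.id] < birth_order[a.id]:
            return b.id, a.id
        return None
    # a subadult (died before 18) can never be the parent
    if a.is_adult and not b.is_adult and b.age_class == "subadult":
        return a.id, b.id
    if b.is_adult and not a.is_adult and a.age_class == "subadult":
        return b.id, a.id
    pa, pb = PHASE_ORDER.get(a.phase), PHASE_ORDER.get(b.phase)
    if pa is not None and pb is not None and pa != pb:
        return (a.id, b.id) if pa < pb else (b.id, a.id)
    return None


def assemble_pedigrees(
    pairs: Iterable[PairRelatedness],
    individuals: Iterable[Individual],
    constraints: Optional[AssemblyConstraints] = None,
    birth_order: Optional[dict[str, float]] = None,
) -> list[AssembledPedigree]:
    """Assemble candidate pedigrees from classified pairwise calls.

    ``birth_order`` optionally maps individual ids to chronological anchors
    (e.g. calibrated radiocarbon point estimates or known birth offsets);
    smaller means earlier.  Output order is deterministic.
    """
    constraints = constraints or AssemblyConstraints()
    inds = {i.id: i for i in individuals}
    close = [p for p in pairs if p.degree in CLOSE_DEGREES
             and p.id_a in inds and p.id_b in inds]
    g = nx.Graph()
    for p in close:
        g.add_edge(p.id_a, p.id_b, degree=p.degree)
    components = sorted((sorted(c) for c in nx.connected_components(g)),
                        key=lambda c: c[0])
    out = []
    for comp in components:
        out.append(_assemble_component(set(comp), close, inds, constraints, birth_order))
    return out


def _assemble_component(members, pairs, inds, constraints, birth_order) -> AssembledPedigree:
    ped = PedigreeGraph()
    for iid in sorted(members):
        ped.add_individual(inds[iid])
    result = AssembledPedigree(pedigree=ped, members=set(members))
    comp_pairs = [p for p in pairs if p.id_a in members and p.id_b in members]
    pc_pairs = [p for p in comp_pairs if p.degree == "parent_child"]
    sib_pairs = [p for p in comp_pairs if p.degree == "sibling"]
    second_pairs = [p for p in comp_pairs if p.degree == "second"]

    for p in sorted(pc_pairs, key=lambda q: q.key):
        oriented = _orient_parent_child(inds[p.id_a], inds[p.id_b], birth_order)
        if oriented is None:
            result.unresolved_pairs.append(p.key)
            continue
        parent, child = oriented
        _place_parent(ped, parent, child, inds, constraints, result)

    # sibling groups share parents
    sib_graph = nx.Graph()
    sib_graph.add_nodes_from(p.id_a for p in sib_pairs)
    sib_graph.add_edges_from((p.id_a, p.id_b) for p in sib_pairs)
    sib_groups = sorted((sorted(c) for c in nx.connected_components(sib_graph)),
                        key=lambda c: c[0])
    for group in sib_groups:
        _propagate_sibling_parents(ped, group, inds, constraints, result)

    if constraints.allow_missing_individuals:
        _infer_ghost_parents(ped, sib_groups, second_pairs, result)

    _rebuild_unions(ped)
    return result


def _place_parent(ped: PedigreeGraph, parent: str, child: str, inds,
                  constraints: AssemblyConstraints, result: AssembledPedigree) -> None:
    p_ind, c_ind = inds[parent], inds[child]
    if p_ind.sex == "male":
        if (constraints.enforce_y_father_son and c_ind.sex == "male"
                and p_ind.y_haplogroup and c_ind.y_haplogroup
                and p_ind.y_haplogroup != c_ind.y_haplogroup):
            result.conflicts.append(Conflict(
                "y_mismatch", (parent, child),
                f"father {parent} Y={p_ind.y_haplogroup} vs son {child} "
                f"Y={c_ind.y_haplogroup}"))
            return
        existing = ped.father.get(child)
        if existing is not None and existing != parent:
            result.conflicts.append(Conflict(
                "two_fathers", (existing, parent, child),
                f"child {child} assigned two fathers"))
            return
        ped.father[child] = parent
    elif p_ind.sex == "female":
        if (constraints.enforce_mt_mother_child
                and p_ind.mt_haplogroup and c_ind.mt_haplogroup
                and p_ind.mt_haplogroup != c_ind.mt_haplogroup):
            result.conflicts.append(Conflict(
                "mt_mismatch", (parent, child),
                f"mother {parent} mt={p_ind.mt_haplogroup} vs child {child} "
                f"mt={c_ind.mt_haplogroup}"))
            return
        existing = ped.mother.get(child)
        if existing is not None and existing != parent:
            result.conflicts.append(Conflict(
                "two_mothers", (existing, parent, child),
                f"child {child} assigned two mothers"))
            return
        ped.mother[child] = parent
    else:
        result.unresolved_pairs.append((parent, child))


def _propagate_sibling_parents(ped, group, inds, constraints, result) -> None:
    fathers = sorted({ped.father[m] for m in group if m in ped.father})
    mothers = sorted({ped.mother[m] for m in group if m in ped.mother})
    if len(fathers) > 1:
        result.conflicts.append(Conflict(
            "sibling_fathers", tuple(group),
            f"full-sibling group with fathers {fathers}"))
    elif fathers:
        for m in group:
            if m not in ped.father:
                _place_parent(ped, fathers[0], m, _inds_of(ped), constraints, result)
    if len(mothers) > 1:
        result.conflicts.append(Conflict(
            "sibling_mothers", tuple(group),
            f"full-sibling group with mothers {mothers}"))
    elif mothers:
        for m in group:
            if m not in ped.mother:
                _place_parent(ped, mothers[0], m, _inds_of(ped), constraints, result)


def _inds_of(ped: PedigreeGraph) -> dict[str, Individual]:
    return ped.individuals


def _infer_ghost_parents(ped, sib_groups, second_pairs, result) -> None:
    """One unobserved parent connecting >=2 observed siblings becomes a ghost."""
    second = {frozenset(p.key) for p in second_pairs}
    n = 0
    for group in sib_groups:
        if len(group) < 2:
            continue
        for slot, store, sex in (("father", ped.father, "male"),
                                 ("mother", ped.mother, "female")):
            if any(m in store for m in group):
                continue
            # require some second-degree support through the missing parent
            supported = any(frozenset((m, other)) in second
                            for m in group for other in ped.individuals)
            if not supported:
                continue
            n += 1
            gid = f"ghost_{slot}_{n:02d}"
            ghost = Individual(id=gid, site=ped.individuals[group[0]].site, sex=sex)
            ped.add_individual(ghost)
            for m in group:
                store[m] = gid
            result.inferred_ids.add(gid)


def _rebuild_unions(ped: PedigreeGraph) -> None:
    ped.unions = []
    seen: dict[tuple[str, str], UnionRecord] = {}
    for child in sorted(set(ped.father) & set(ped.mother)):
        key = (ped.father[child], ped.mother[child])
        if key not in seen:
            seen[key] = ped.add_union(*key)
        seen[key].children.append(child)


# --------------------------------------------------------------------------
# social-practice metrics


@dataclass
class SharedPartnerRecord:
    male_a: str
    male_b: str
    female: str
    relation: str
    levirate_consistent: bool


@dataclass
class SocialMetrics:
    n_sons: int = 0
    n_daughters: int = 0
    n_exogamous_mothers: int = 0
    n_lineage_mothers: int = 0
    patriline_purity: Optional[float] = None
    shared_partner_unions: list[SharedPartnerRecord] = field(default_factory=list)
    partner_counts: dict[str, int] = field(default_factory=dict)
    n_unrelated_by_sex: dict[str, int] = field(default_factory=dict)
    # restricted to mothers whose partners are themselves lineage sons; wives
    # of founding males are exogamous by necessity, not by choice
    n_exogamous_mothers_nonfounding: int = 0
    n_lineage_mothers_nonfounding: int = 0

    @property
    def exogamy_fraction(self) -> Optional[float]:
        total = self.n_exogamous_mothers + self.n_lineage_mothers
        return self.n_exogamous_mothers / total if total else None

    @property
    def exogamy_fraction_nonfounding(self) -> Optional[float]:
        total = (self.n_exogamous_mothers_nonfounding
                 + self.n_lineage_mothers_nonfounding)
        return self.n_exogamous_mothers_nonfounding / total if total else None


def patriliny_metrics(ped: PedigreeGraph,
                      observed_ids: Optional[set[str]] = None,
                      pairs: Optional[list[PairRelatedness]] = None) -> SocialMetrics:
    """Sons/daughters, exogamous vs lineage mothers, and patriline purity.

    A father is patriline-pure when following father links upward ends at a
    true founder (a male with neither parent present); a chain that dead-ends
    at a male whose mother is present but father is not marks a break in the
    male line.
    """
    ids = observed_ids if observed_ids is not None else set(ped.individuals)
    m = SocialMetrics()
    mothers = {mo for c, mo in ped.mother.items() if c in ids and mo in ids}
    fathers = {fa for c, fa in ped.father.items() if c in ids and fa in ids}
    for iid in sorted(ids):
        ind = ped.individuals.get(iid)
        if ind is None:
            continue
        f, mo = ped.parents_of(iid)
        has_parent = (f in ids) or (mo in ids)
        if has_parent and ind.sex == "male":
            m.n_sons += 1
        elif has_parent and ind.sex == "female":
            m.n_daughters += 1
    children_of_mother: dict[str, list[str]] = {}
    for c, mo in ped.mother.items():
        if c in ids and mo in ids:
            children_of_mother.setdefault(mo, []).append(c)
    for mo in sorted(mothers):
        f, mm = ped.parents_of(mo)
        lineage = (f in ids) or (mm in ids)
        if lineage:
            m.n_lineage_mothers += 1
        else:
            m.n_exogamous_mothers += 1
        husbands = {ped.father[c] for c in children_of_mother.get(mo, [])
                    if c in ped.father}
        nonfounding = any((ped.father.get(h) in ids) or (ped.mother.get(h) in ids)
                          for h in husbands)
        if nonfounding:
            if lineage:
                m.n_lineage_mothers_nonfounding += 1
            else:
                m.n_exogamous_mothers_nonfounding += 1
    if fathers:
        pure = 0
        for fa in sorted(fathers):
            x = fa
            while ped.father.get(x) in ids and ped.father.get(x) is not None:
                x = ped.father[x]
            root_mother = ped.mother.get(x)
            if root_mother is None or root_mother not in ids:
                pure += 1
        m.patriline_purity = pure / len(fathers)
    m.shared_partner_unions = detect_shared_partner_unions(ped)
    m.partner_counts = partner_counts(ped)
    if pairs is not None:
        m.n_unrelated_by_sex = unrelated_sex_counts(ped, ids, pairs)
    return m


def detect_shared_partner_unions(ped: PedigreeGraph) -> list[SharedPartnerRecord]:
    """All pairs of distinct males who share a reproductive partner."""
    partners_of_female: dict[str, set[str]] = {}
    for u in ped.unions:
        partners_of_female.setdefault(u.female_id, set()).add(u.male_id)
    out = []
    for female in sorted(partners_of_female):
        males = sorted(partners_of_female[female])
        for i in range(len(males)):
            for j in range(i + 1, len(males)):
                rel = ped.agnatic_relation(males[i], males[j])
                out.append(SharedPartnerRecord(
                    male_a=males[i], male_b=males[j], female=female,
                    relation=rel,
                    levirate_consistent=rel not in ("unrelated",)))
    return out


def partner_counts(ped: PedigreeGraph) -> dict[str, int]:
    """Distinct reproductive partners per individual (both sexes)."""
    partners: dict[str, set[str]] = {}
    for u in ped.unions:
        partners.setdefault(u.male_id, set()).add(u.female_id)
        partners.setdefault(u.female_id, set()).add(u.male_id)
    return {iid: len(p) for iid, p in sorted(partners.items())}


def unrelated_sex_counts(ped: PedigreeGraph, ids: set[str],
                         pairs: list[PairRelatedness]) -> dict[str, int]:
    """Counts by sex of individuals with no close call to anyone at their site."""
    related: set[str] = set()
    site_of = {iid: ped.individuals[iid].site for iid in ids if iid in ped.individuals}
    for p in pairs:
        if p.degree in CLOSE_DEGREES + ("third",):
            if site_of.get(p.id_a) is not None and site_of.get(p.id_a) == site_of.get(p.id_b):
                related.add(p.id_a)
                related.add(p.id_b)
    counts = {"male": 0, "female": 0, "unknown": 0}
    for iid in ids:
        if iid in related or iid not in ped.individuals:
            continue
        counts[ped.individuals[iid].sex] += 1
    return counts
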