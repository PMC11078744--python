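"""Forward simulation of patrilineal cemetery communities.

The generator encodes the kinship rules inferred for steppe-descent
communities: patrilineal descent from a small set of founding males,
patrilocality with female exogamy (in-marrying wives are unrelated
immigrants, or daughters exchanged between simulated sites), strict
avoidance of consanguineous unions, polygyny, and levirate succession in
which a deceased man's widow is re-partnered to one of his agnates.
Burial sampling then reproduces the observational filters of a real
cemetery: emigrated daughters are missing, immigrant wives' parents are
never present, and some still-childless partners of last-generation men
are buried as unrelated females.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .datamodel import Individual, SimulationError
from .pedigree import PedigreeGraph

MAX_PARTNERS = 4  # observed maximum number of reproductive partners per male


@dataclass
class SimulationConfig:
    """Parameters of the community model.

    Probabilities are per-event; offspring counts per union are Poisson with
    the configured means.  ``consanguinity_min_degree`` forbids unions between
    partners related at a closer genealogical degree.
    """

    n_generations: int = 4
    n_founder_males: int = 3
    mean_sons_per_union: float = 1.5
    mean_daughters_per_union: float = 1.5
    polygyny_prob: float = 0.15
    levirate_prob: float = 0.10
    exogamy_rate: float = 1.0
    daughter_emigration_prob: float = 0.9
    consanguinity_min_degree: int = 6
    n_sites: int = 1
    female_exchange_rate: float = 0.0
    generation_gap_mean: float = 29.0
    generation_gap_sd: float = 6.0
    subadult_prob: float = 0.2
    childless_partner_frac: float = 0.5
    replacement_generation: Optional[int] = None
    replacement_n_founders: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("polygyny_prob", "levirate_prob", "exogamy_rate",
                     "daughter_emigration_prob", "female_exchange_rate",
                     "subadult_prob", "childless_partner_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_generations < 1 or self.n_founder_males < 1 or self.n_sites < 1:
            raise ValueError("n_generations, n_founder_males and n_sites must be >= 1")
        if self.consanguinity_min_degree < 0:
            raise ValueError("consanguinity_min_degree must be >= 0")


@dataclass
class LevirateEvent:
    deceased_male: str
    successor_male: str
    female: str
    relation: str
    generation: int


@dataclass
class SimulatedCommunity:
    """A simulated multi-site community with full truth metadata."""

    pedigree: PedigreeGraph
    config: SimulationConfig
    birth_year: dict[str, float] = field(default_factory=dict)
    death_age: dict[str, int] = field(default_factory=dict)
    levirate_events: list[LevirateEvent] = field(default_factory=list)
    replacement_founders: list[str] = field(default_factory=list)
    in_community_unions: int = 0
    immigrant_fallbacks: int = 0

    def site_of(self, iid: str) -> str:
        return self.pedigree.individuals[iid].site


@dataclass
class ObservedCemetery:
    """Individuals retained by burial sampling, with their metadata."""

    individuals: list[Individual]
    observed_ids: set[str]
    childless_partner_ids: set[str] = field(default_factory=set)

    def by_site(self) -> dict[str, list[Individual]]:
        out: dict[str, list[Individual]] = {}
        for ind in self.individuals:
            out.setdefault(ind.site, []).append(ind)
        return out


class _Simulator:
    def __init__(self, config: SimulationConfig):
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        self.ped = PedigreeGraph()
        self.community = SimulatedCommunity(pedigree=self.ped, config=config)
        self._counter = 0
        self._mt_counter = 0
        self.married_females: set[str] = set()
        self.married_males: set[str] = set()
        self.deceased_males: set[str] = set()
        # per-site pool of unmarried lineage daughters: (id, generation)
        self.daughter_pool: dict[str, list[str]] = {}

    # --- identity helpers ------------------------------------------------

    def _new_id(self, site: str) -> str:
        self._counter += 1
        return f"{site}I{self._counter:04d}"

    def _new_mt(self) -> str:
        self._mt_counter += 1
        return f"mt{self._mt_counter:03d}"

    def _draw_death_age(self) -> int:
        if self.rng.uniform() < self.cfg.subadult_prob:
            return int(self.rng.integers(0, 18))
        return int(self.rng.integers(18, 71))

    def _make_individual(self, site: str, sex: str, generation: int,
                         birth_year: float, y_label: Optional[str],
                         mt_label: str, founder: bool) -> Individual:
        age = self._draw_death_age()
        if age >= 18:
            age_class = "adult"
            age_range = (max(18, age - 2), age + 2)
        else:
            age_class = "subadult"
            age_range = (max(0, age - 2), min(17, age + 2))
        ind = Individual(
            id=self._new_id(site), site=site, sex=sex, age_class=age_class,
            age_range_years=age_range,
            y_haplogroup=y_label if sex == "male" else None,
            mt_haplogroup=mt_label,
        )
        self.ped.add_individual(ind, generation=generation, founder=founder)
        self.community.birth_year[ind.id] = birth_year
        self.community.death_age[ind.id] = age
        return ind

    # --- union formation -------------------------------------------------

    def _immigrant_wife(self, site: str, generation: int, birth_year: float) -> Individual:
        return self._make_individual(site, "female", generation, birth_year,
                                     None, self._new_mt(), founder=True)

    def _degree_ok(self, a: str, b: str) -> bool:
        d = self.ped.relationship_degree(a, b)
        return d is None or d >= self.cfg.consanguinity_min_degree

    def _choose_wife(self, groom: str, site: str, generation: int,
                     sites: list[str]) -> Individual:
        rng = self.rng
        birth = self.community.birth_year[groom] + rng.normal(0.0, 4.0)
        if rng.uniform() < self.cfg.exogamy_rate:
            # exogamous: exchanged daughter from another site, else immigrant
            if len(sites) > 1 and rng.uniform() < self.cfg.female_exchange_rate:
                others = [s for s in sites if s != site]
                rng.shuffle(others)
                for other in others:
                    pool = [f for f in self.daughter_pool.get(other, [])
                            if f not in self.married_females
                            and self.ped.individuals[f].is_adult
                            and self._degree_ok(groom, f)]
                    if pool:
                        bride_id = pool[int(rng.integers(len(pool)))]
                        bride = self.ped.individuals[bride_id]
                        bride.site = site  # patrilocality: buried at husband's site
                        self.married_females.add(bride_id)
                        return bride
            return self._immigrant_wife(site, generation, birth)
        # in-community union, subject to the consanguinity rule
        pool = [f for f in self.daughter_pool.get(site, [])
                if f not in self.married_females
                and self.ped.individuals[f].is_adult
                and self._degree_ok(groom, f)]
        if pool:
            self.community.in_community_unions += 1
            bride_id = pool[int(rng.integers(len(pool)))]
            self.married_females.add(bride_id)
            return self.ped.individuals[bride_id]
        if self.cfg.exogamy_rate == 0.0:
            raise SimulationError(
                "no in-community bride satisfies consanguinity_min_degree="
                f"{self.cfg.consanguinity_min_degree} for {groom}")
        self.community.immigrant_fallbacks += 1
        return self._immigrant_wife(site, generation, birth)

    def _offspring(self, father: str, mother: str, site: str, generation: int) -> None:
        rng = self.rng
        union = self.ped.union_for(father, mother)
        assert union is not None
        n_sons = rng.poisson(self.cfg.mean_sons_per_union)
        n_daughters = rng.poisson(self.cfg.mean_daughters_per_union)
        f_ind = self.ped.individuals[father]
        m_ind = self.ped.individuals[mother]
        child_gen = 1 + max(self.ped.generation[father], self.ped.generation[mother])
        for sex in ["male"] * n_sons + ["female"] * n_daughters:
            birth = (self.community.birth_year[father]
                     + rng.normal(self.cfg.generation_gap_mean,
                                  self.cfg.generation_gap_sd))
            y = f_ind.y_haplogroup if sex == "male" else None
            child = self._make_individual(site, sex, child_gen, birth, y,
                                          m_ind.mt_haplogroup or self._new_mt(),
                                          founder=False)
            self.ped.set_parents(child.id, father, mother)
            union.children.append(child.id)
            if sex == "female":
                self.daughter_pool.setdefault(site, []).append(child.id)

    # --- levirate ---------------------------------------------------------

    _LEVIRATE_PRIORITY = ("full_brothers", "paternal_half_brothers",
                          "paternal_uncle_nephew", "father_son")

    def _levirate_candidates(self, deceased: str, site: str) -> list[tuple[int, str, str]]:
        out = []
        for other, ind in self.ped.individuals.items():
            if other == deceased or ind.sex != "male" or ind.site != site:
                continue
            if not ind.is_adult or other in self.deceased_males:
                continue
            rel = self.ped.agnatic_relation(deceased, other)
            if rel == "father_son" and self.ped.father.get(other) != deceased:
                continue  # only a *son* of the deceased may succeed, not his father
            if rel in self._LEVIRATE_PRIORITY:
                out.append((self._LEVIRATE_PRIORITY.index(rel), other, rel))
        out.sort(key=lambda t: (t[0], t[1]))
        return out

    def _apply_levirate(self, deceased: str, site: str, generation: int) -> None:
        widows = [u.female_id for u in self.ped.unions if u.male_id == deceased]
        candidates = self._levirate_candidates(deceased, site)
        for widow in widows:
            chosen = None
            for _, male, rel in candidates:
                if self.ped.union_for(male, widow) is not None:
                    continue
                if self.ped.mother.get(male) == widow:
                    continue  # a son of the deceased never inherits his own mother
                if self._degree_ok(male, widow):
                    chosen = (male, rel)
                    break
            if chosen is None:
                continue
            male, rel = chosen
            self.ped.add_union(male, widow, levirate=True)
            self.married_males.add(male)
            self.community.levirate_events.append(
                LevirateEvent(deceased, male, widow, rel, generation))
            self._offspring(male, widow, site, generation)

    # --- main loop ---------------------------------------------------------

    def run(self) -> SimulatedCommunity:
        cfg = self.cfg
        sites = [f"S{i + 1}" for i in range(cfg.n_sites)]
        for site in sites:
            for i in range(cfg.n_founder_males):
                self._make_individual(
                    site, "male", 0, float(self.rng.normal(0.0, 5.0)),
                    y_label=f"Y-{site}-{i + 1}", mt_label=self._new_mt(),
                    founder=True)
        replaced_sites: set[str] = set()
        for g in range(cfg.n_generations - 1):
            if cfg.replacement_generation is not None and g == cfg.replacement_generation:
                self._inject_replacement(sites[0], g)
                replaced_sites.add(sites[0])
            for site in sites:
                grooms = self._grooms(site, g, replaced_sites)
                for groom in grooms:
                    wives = [self._choose_wife(groom, site, g, sites)]
                    while (len(wives) < MAX_PARTNERS
                           and self.rng.uniform() < cfg.polygyny_prob):
                        wives.append(self._choose_wife(groom, site, g, sites))
                    self.married_males.add(groom)
                    for wife in wives:
                        self.married_females.add(wife.id)
                        self.ped.add_union(groom, wife.id)
                        self._offspring(groom, wife.id, site, g)
                # levirate succession after this generation's unions
                for groom in grooms:
                    if self.rng.uniform() < cfg.levirate_prob:
                        self.deceased_males.add(groom)
                        self._apply_levirate(groom, site, g)
        self.ped.validate()
        return self.community

    def _grooms(self, site: str, g: int, replaced_sites: set[str]) -> list[str]:
        cfg = self.cfg
        out = []
        for iid, ind in self.ped.individuals.items():
            if ind.sex != "male" or ind.site != site or not ind.is_adult:
                continue
            if self.ped.generation.get(iid) != g:
                continue
            if iid in self.married_males or iid in self.deceased_males:
                continue
            if (site in replaced_sites and cfg.replacement_generation is not None
                    and g >= cfg.replacement_generation
                    and not self._is_replacement_line(iid)):
                continue  # the incoming patriline takes over reproduction
            out.append(iid)
        return sorted(out)

    def _is_replacement_line(self, iid: str) -> bool:
        for root in self.community.replacement_founders:
            if self.ped.is_patrilineal_descendant(iid, root):
                return True
        return False

    def _inject_replacement(self, site: str, g: int) -> None:
        base_year = (self.cfg.generation_gap_mean * g)
        for i in range(self.cfg.replacement_n_founders):
            ind = self._make_individual(
                site, "male", g, float(base_year + self.rng.normal(0.0, 5.0)),
                y_label=f"Y-{site}-NEW", mt_label=self._new_mt(), founder=True)
            self.community.replacement_founders.append(ind.id)


def simulate_community(config: SimulationConfig) -> SimulatedCommunity:
    """Simulate a multi-site community under the configured kinship rules."""
    return _Simulator(config).run()


def assign_phases(community: SimulatedCommunity) -> None:
    """Assign early/middle/late phases from birth-year terciles per site."""
    by_site: dict[str, list[str]] = {}
    for iid, ind in community.pedigree.individuals.items():
        by_site.setdefault(ind.site, []).append(iid)
    for ids in by_site.values():
        years = np.array([community.birth_year[i] for i in ids])
        lo, hi = np.quantile(years, [1 / 3, 2 / 3])
        for iid in ids:
            y = community.birth_year[iid]
            ind = community.pedigree.individuals[iid]
            ind.phase = "early" if y <= lo else ("middle" if y <= hi else "late")


def apply_burial_sampling(community: SimulatedCommunity,
                          rng: Optional[np.random.Generator] = None) -> ObservedCemetery:
    """Subset the simulated community to the individuals a cemetery would hold.

    Unmarried adult lineage daughters emigrate (are absent) with
    ``daughter_emigration_prob``; immigrant mothers' parents are absent by
    construction; a configured fraction of unmarried last-generation adult
    males receive a childless partner buried as an unrelated female.  With
    several sites, such partners are drawn from other sites' emigrated
    daughters at ``female_exchange_rate`` (and relocated to the husband's
    site), otherwise they are fresh immigrants with no genetic ties.
    """
    cfg = community.config
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    ped = community.pedigree
    sim = _Simulator(cfg)          # reused only for id/metadata helpers
    sim.ped = ped
    sim.community = community
    sim._counter = len(ped.individuals) + 1000
    sim._mt_counter = len(ped.individuals) + 1000
    sim.rng = rng
    married_females = {u.female_id for u in ped.unions}
    married_males = {u.male_id for u in ped.unions}
    observed = set(ped.individuals)
    last_gen = max(ped.generation.values()) if ped.generation else 0
    emigrated: list[str] = []
    for iid in sorted(ped.individuals):
        ind = ped.individuals[iid]
        if (ind.sex == "female" and ind.is_adult
                and ped.parents_of(iid) != (None, None)
                and iid not in married_females):
            if rng.uniform() < cfg.daughter_emigration_prob:
                observed.discard(iid)
                emigrated.append(iid)
    childless: set[str] = set()
    for iid in sorted(ped.individuals):
        ind = ped.individuals[iid]
        if (ind.sex == "male" and ind.is_adult
                and ped.generation.get(iid) == last_gen
                and iid not in married_males):
            if rng.uniform() < cfg.childless_partner_frac:
                partner_id = None
                if cfg.n_sites > 1 and rng.uniform() < cfg.female_exchange_rate:
                    pool = [d for d in emigrated
                            if ped.individuals[d].site != ind.site]
                    if pool:
                        partner_id = pool[int(rng.integers(len(pool)))]
                        emigrated.remove(partner_id)
                        ped.individuals[partner_id].site = ind.site
                if partner_id is None:
                    partner_id = sim._make_individual(
                        ind.site, "female", last_gen,
                        community.birth_year[iid] + float(rng.normal(0.0, 4.0)),
                        None, sim._new_mt(), founder=True).id
                observed.add(partner_id)
                childless.add(partner_id)
    individuals = [ped.individuals[i] for i in sorted(observed)]
    return ObservedCemetery(individuals=individuals, observed_ids=observed,
                            childless_partner_ids=childless)
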