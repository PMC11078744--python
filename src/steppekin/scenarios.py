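"""End-to-end synthetic fixture generation.

A scenario bundles everything one cemetery study provides: individual
metadata, the true pedigree with unions, observed (degraded) pairwise IBD
segments, radiocarbon measurements on a synthetic calibration curve, and the
truth logs (levirate events, community-replacement generation, birth years)
needed for oracle tests.  Presets:

* ``rk_like``   - one large site, nine generations, strict female exogamy,
                  levirate on, and a community-replacement event in which a
                  new founder cohort with a distinct Y label takes over
                  reproduction mid-sequence;
* ``multi_site``- three sites exchanging exogamous brides, so between-site
                  IBD edges run through women;
* ``null``      - shallow unstructured community (no polygyny, no levirate).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .datamodel import (CalibrationCurve, DEFAULT_MAP, GeneticMap,
                        PairRelatedness, RadiocarbonDate)
from .io import (write_calibration_curve, write_dates, write_ibd_pairs,
                 write_individuals, write_pedigree)
from .relatedness import pair_summary
from .simulate import (ObservedCemetery, SimulatedCommunity, SimulationConfig,
                       apply_burial_sampling, assign_phases, simulate_community)
from .transmission import (Diplotype, ObservationModel, degrade_segments,
                           drop_genomes, pairwise_ibd)

EPOCH_AD = 575  # calendar anchor for simulated birth years (year 0 of the sim)
DATE_SIGMA = 25.0
CURVE_SIGMA = 8.0


def preset_config(name: str, seed: int = 0) -> SimulationConfig:
    if name == "rk_like":
        return SimulationConfig(
            n_generations=9, n_founder_males=3,
            mean_sons_per_union=1.3, mean_daughters_per_union=1.3,
            polygyny_prob=0.15, levirate_prob=0.15, exogamy_rate=1.0,
            daughter_emigration_prob=0.9, consanguinity_min_degree=6,
            n_sites=1, replacement_generation=4, replacement_n_founders=2,
            seed=seed)
    if name == "multi_site":
        return SimulationConfig(
            n_generations=5, n_founder_males=3,
            mean_sons_per_union=1.4, mean_daughters_per_union=1.4,
            polygyny_prob=0.15, levirate_prob=0.1, exogamy_rate=1.0,
            daughter_emigration_prob=0.9, consanguinity_min_degree=6,
            n_sites=3, female_exchange_rate=0.15, seed=seed)
    if name == "null":
        return SimulationConfig(
            n_generations=2, n_founder_males=8,
            mean_sons_per_union=1.0, mean_daughters_per_union=1.0,
            polygyny_prob=0.0, levirate_prob=0.0, exogamy_rate=1.0,
            daughter_emigration_prob=0.0, consanguinity_min_degree=0,
            n_sites=1, seed=seed)
    raise ValueError(f"unknown preset {name!r}")


@dataclass
class ScenarioSpec:
    preset: str = "rk_like"
    seed: int = 0
    overrides: dict = field(default_factory=dict)
    observation: Optional[ObservationModel] = None
    n_dates: int = 40

    def resolve(self) -> SimulationConfig:
        cfg = preset_config(self.preset, seed=self.seed)
        return replace(cfg, **self.overrides) if self.overrides else cfg


@dataclass
class ScenarioBundle:
    spec: ScenarioSpec
    config: SimulationConfig
    community: SimulatedCommunity
    cemetery: ObservedCemetery
    genomes: dict[str, Diplotype]
    pairs: list[PairRelatedness]
    dates: list[RadiocarbonDate]
    curve: CalibrationCurve
    gmap: GeneticMap = DEFAULT_MAP

    @property
    def birth_year_ad(self) -> dict[str, float]:
        return {iid: EPOCH_AD + y for iid, y in self.community.birth_year.items()}

    def events(self) -> dict:
        return {
            "levirate": [
                {"deceased": e.deceased_male, "successor": e.successor_male,
                 "female": e.female, "relation": e.relation,
                 "generation": e.generation}
                for e in self.community.levirate_events],
            "replacement_generation": self.config.replacement_generation,
            "replacement_founders": list(self.community.replacement_founders),
            "exogamy_rate": self.config.exogamy_rate,
        }


def synthetic_curve(year_min_ad: float, year_max_ad: float,
                    step: float = 5.0) -> CalibrationCurve:
    """A wiggly calibration curve covering [year_min, year_max] AD with margin."""
    lo_bp = np.floor(1950 - (year_max_ad + 250))
    hi_bp = np.ceil(1950 - (year_min_ad - 250))
    cal_bp = np.arange(lo_bp, hi_bp + step, step)
    c14 = (cal_bp
           + 20.0 * np.sin(2 * np.pi * cal_bp / 80.0)
           + 10.0 * np.sin(2 * np.pi * cal_bp / 33.0))
    sigma = np.full_like(cal_bp, CURVE_SIGMA, dtype=float)
    return CalibrationCurve(cal_bp, c14, sigma)


def observed_pairs(genomes: dict[str, Diplotype], ids: list[str],
                   model: ObservationModel, gmap: GeneticMap = DEFAULT_MAP,
                   rng: Optional[np.random.Generator] = None) -> list[PairRelatedness]:
    """Pairwise IBD among `ids`, degraded by the observation model."""
    rng = rng if rng is not None else model.rng()
    ids = sorted(ids)
    out = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            segs = pairwise_ibd(genomes[ids[i]], genomes[ids[j]], gmap)
            segs = degrade_segments(segs, model, gmap, rng)
            if segs:
                out.append(pair_summary(ids[i], ids[j], segs, gmap))
    return out


def generate_scenario(spec: ScenarioSpec) -> ScenarioBundle:
    """Simulate a full scenario bundle; deterministic given the spec seed."""
    cfg = spec.resolve()
    community = simulate_community(cfg)
    assign_phases(community)
    cemetery = apply_burial_sampling(
        community, np.random.default_rng(spec.seed + 1))
    genomes = drop_genomes(community.pedigree, DEFAULT_MAP,
                           np.random.default_rng(spec.seed + 2))
    model = spec.observation or ObservationModel()
    pairs = observed_pairs(genomes, sorted(cemetery.observed_ids), model,
                           DEFAULT_MAP, np.random.default_rng(spec.seed + 3))
    # radiocarbon dates on a synthetic curve, anchored to true birth cohorts
    years = {iid: EPOCH_AD + community.birth_year[iid]
             for iid in sorted(cemetery.observed_ids)}
    curve = synthetic_curve(min(years.values()), max(years.values()))
    rng = np.random.default_rng(spec.seed + 4)
    dated_ids = sorted(years)
    if len(dated_ids) > spec.n_dates:
        dated_ids = sorted(rng.choice(dated_ids, size=spec.n_dates, replace=False))
    dates = []
    for iid in dated_ids:
        true_bp = 1950.0 - years[iid]
        mean = float(curve.mean_at(true_bp))
        meas = mean + float(rng.normal(0.0, DATE_SIGMA))
        dates.append(RadiocarbonDate(iid, meas, DATE_SIGMA))
    return ScenarioBundle(spec=spec, config=cfg, community=community,
                          cemetery=cemetery, genomes=genomes, pairs=pairs,
                          dates=dates, curve=curve)


def write_bundle(bundle: ScenarioBundle, out_dir: str | Path) -> None:
    """Write the bundle as the pipeline's text dialects plus truth files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_individuals(bundle.cemetery.individuals, out / "individuals.tsv")
    write_pedigree(bundle.community.pedigree, out / "pedigree.fam",
                   out / "unions.tsv")
    write_ibd_pairs(bundle.pairs, out / "ibd_pairs.tsv")
    write_dates(bundle.dates, out / "dates.tsv")
    write_calibration_curve(bundle.curve, out / "curve.14c")
    (out / "events.json").write_text(json.dumps(bundle.events(), indent=2))
    with open(out / "birth_years.tsv", "w") as fh:
        fh.write("id\tbirth_year_ad\n")
        for iid, y in sorted(bundle.birth_year_ad.items()):
            fh.write(f"{iid}\t{y:.1f}\n")
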