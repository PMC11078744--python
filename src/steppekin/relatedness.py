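"""Pairwise relatedness inference from IBD segment summaries.

The degree classifier bins the kinship coefficient phi = p1/4 + p2/2 (p1, p2
the genome fractions in IBD1 / IBD2) at the standard log2 midpoints, and
separates parent-child from full siblings by the presence of IBD2.  Within
the second degree, avuncular / grandparent-grandchild / half-sibling calls use
reference distributions of (segment count, mean segment length) built from
simulated pedigrees passed through the same observation model as the data:
grandparent-grandchild sharing concentrates in fewer, longer segments than
avuncular sharing, while half siblings overlap both.

Consanguinity of an individual's parents is flagged from the summed length of
long (>4 cM) runs of homozygosity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.stats import gaussian_kde

from .datamodel import (DEFAULT_MAP, GeneticMap, IBDSegment, Individual,
                        PairRelatedness)
from .pedigree import PedigreeGraph
from .transmission import (Diplotype, ObservationModel, degrade_segments,
                           drop_genomes, pairwise_ibd, roh_segments)

# kinship bin edges: log2 midpoints between expected phi of adjacent degrees
PHI_IDENTICAL = 0.354
PHI_FIRST = 0.177
PHI_SECOND = 0.088
PHI_THIRD = 0.044

# first-degree subtype rules on genome fractions
PC_MAX_P2 = 0.02
PC_MIN_P1 = 0.90
SIB_MIN_P2 = 0.10

ROH_LONG_CM = 4.0                  # "long ROH" threshold
CONSANGUINITY_SUM_CM = 10.0        # flag when summed long ROH exceeds this

SECOND_DEGREE_CLASSES = ("avuncular", "grandparent", "half_sibling")


def pair_summary(id_a: str, id_b: str, segments: list[IBDSegment],
                 gmap: Optional[GeneticMap] = None) -> PairRelatedness:
    """Summarise observed segments into a PairRelatedness record."""
    gmap = gmap or DEFAULT_MAP
    total1 = sum(s.length_cM for s in segments if s.state == "IBD1")
    total2 = sum(s.length_cM for s in segments if s.state == "IBD2")
    p1 = total1 / gmap.total_cM
    p2 = total2 / gmap.total_cM
    pr = PairRelatedness(
        id_a=id_a, id_b=id_b, segments=list(segments),
        total_ibd1_cM=total1, total_ibd2_cM=total2,
        n_segments=len(segments),
        max_ibd_cM=max((s.length_cM for s in segments), default=0.0),
        kinship=0.25 * p1 + 0.5 * p2,
    )
    pr.degree = classify_degree(pr, gmap)
    return pr


def classify_degree(pr: PairRelatedness, gmap: Optional[GeneticMap] = None) -> str:
    """Kinship-bin classification; sets and returns the degree label."""
    gmap = gmap or DEFAULT_MAP
    phi = pr.kinship
    if phi > PHI_IDENTICAL:
        pr.degree = "identical"
    elif phi >= PHI_FIRST:
        p1 = pr.total_ibd1_cM / gmap.total_cM
        p2 = pr.total_ibd2_cM / gmap.total_cM
        if p2 < PC_MAX_P2 and p1 > PC_MIN_P1:
            pr.degree = "parent_child"
        elif p2 >= SIB_MIN_P2:
            pr.degree = "sibling"
        else:
            pr.degree = "first_ambiguous"
    elif phi >= PHI_SECOND:
        pr.degree = "second"
    elif phi >= PHI_THIRD:
        pr.degree = "third"
    else:
        pr.degree = "unrelated"
    return pr.degree


FIRST_DEGREE = ("parent_child", "sibling", "first_ambiguous", "identical")
CLOSE_DEGREES = FIRST_DEGREE + ("second",)


# --------------------------------------------------------------------------
# small reference pedigrees


def _ind(iid: str, sex: str) -> Individual:
    return Individual(id=iid, site="ref", sex=sex)


def second_degree_pedigree() -> PedigreeGraph:
    """Eight-member pedigree holding all three second-degree pair types.

    GF+GM -> U (uncle) and F; F+W1 -> C; F+W2 -> D.
    (U, C) avuncular; (GF, C) and (GM, C) grandparent; (C, D) half siblings.
    """
    ped = PedigreeGraph()
    for iid, sex in [("GF", "male"), ("GM", "female"), ("U", "male"),
                     ("F", "male"), ("W1", "female"), ("W2", "female"),
                     ("C", "male"), ("D", "female")]:
        ped.add_individual(_ind(iid, sex))
    ped.set_parents("U", "GF", "GM")
    ped.set_parents("F", "GF", "GM")
    ped.set_parents("C", "F", "W1")
    ped.set_parents("D", "F", "W2")
    ped.add_union("GF", "GM").children = ["U", "F"]
    ped.add_union("F", "W1").children = ["C"]
    ped.add_union("F", "W2").children = ["D"]
    return ped


SECOND_DEGREE_PAIRS = {"avuncular": ("U", "C"), "grandparent": ("GF", "C"),
                       "half_sibling": ("C", "D")}


def inbred_offspring_pedigree(loop: str) -> tuple[PedigreeGraph, str]:
    """Pedigree whose last member is the offspring of related parents.

    loop: 'siblings' (F=1/4), 'first_cousins' (F=1/16) or
    'second_cousins' (F=1/64).  Returns (pedigree, child id).
    """
    ped = PedigreeGraph()
    if loop == "siblings":
        for iid, sex in [("A", "male"), ("B", "female"),
                         ("S1", "male"), ("S2", "female"), ("X", "male")]:
            ped.add_individual(_ind(iid, sex))
        ped.set_parents("S1", "A", "B")
        ped.set_parents("S2", "A", "B")
        ped.set_parents("X", "S1", "S2")
        return ped, "X"
    if loop == "first_cousins":
        for iid, sex in [("A", "male"), ("B", "female"),
                         ("S1", "male"), ("S2", "female"),
                         ("W1", "female"), ("W2", "male"),
                         ("P1", "male"), ("P2", "female"), ("X", "male")]:
            ped.add_individual(_ind(iid, sex))
        ped.set_parents("S1", "A", "B")
        ped.set_parents("S2", "A", "B")
        ped.set_parents("P1", "S1", "W1")
        ped.set_parents("P2", "W2", "S2")
        ped.set_parents("X", "P1", "P2")
        return ped, "X"
    if loop == "second_cousins":
        for iid, sex in [("A", "male"), ("B", "female"),
                         ("S1", "male"), ("S2", "female"),
                         ("W1", "female"), ("W2", "male"),
                         ("C1", "male"), ("C2", "female"),
                         ("V1", "female"), ("V2", "male"),
                         ("P1", "male"), ("P2", "female"), ("X", "male")]:
            ped.add_individual(_ind(iid, sex))
        ped.set_parents("S1", "A", "B")
        ped.set_parents("S2", "A", "B")
        ped.set_parents("C1", "S1", "W1")
        ped.set_parents("C2", "W2", "S2")
        ped.set_parents("P1", "C1", "V1")
        ped.set_parents("P2", "V2", "C2")
        ped.set_parents("X", "P1", "P2")
        return ped, "X"
    raise ValueError(f"unknown consanguinity loop {loop!r}")


def sibling_pair_pedigree() -> tuple[PedigreeGraph, tuple[str, str]]:
    ped = PedigreeGraph()
    for iid, sex in [("F", "male"), ("M", "female"), ("A", "male"), ("B", "female")]:
        ped.add_individual(_ind(iid, sex))
    ped.set_parents("A", "F", "M")
    ped.set_parents("B", "F", "M")
    return ped, ("A", "B")


def simulate_pair_segments(relation: str, rng: np.random.Generator,
                           gmap: GeneticMap = DEFAULT_MAP,
                           model: Optional[ObservationModel] = None) -> list[IBDSegment]:
    """True (or observed, if a model is given) IBD segments for one simulated pair."""
    if relation == "parent_child":
        ped, pair = sibling_pair_pedigree(), ("F", "A")
        ped = ped[0]
    elif relation == "sibling":
        ped, pair = sibling_pair_pedigree()
    elif relation in SECOND_DEGREE_PAIRS:
        ped = second_degree_pedigree()
        pair = SECOND_DEGREE_PAIRS[relation]
    elif relation == "unrelated":
        ped, _ = sibling_pair_pedigree()
        pair = ("F", "M")
    else:
        raise ValueError(f"unknown relation {relation!r}")
    genomes = drop_genomes(ped, gmap, rng)
    segs = pairwise_ibd(genomes[pair[0]], genomes[pair[1]], gmap)
    if model is not None:
        segs = degrade_segments(segs, model, gmap, rng)
    return segs


# --------------------------------------------------------------------------
# second-degree reference distributions and classifier


@dataclass
class ReferenceDistributions:
    """Empirical (n_segments, mean_length_cM, total_cM) samples per class."""

    samples: dict[str, np.ndarray]
    n_pedigrees: int = 0
    seed: int = 0
    model: Optional[ObservationModel] = None

    def __post_init__(self) -> None:
        for cls, arr in self.samples.items():
            if arr.size == 0:
                raise ValueError(f"empty reference sample for class {cls!r}")


def build_reference_distributions(
    n_pedigrees: int = 60,
    seed: int = 0,
    model: Optional[ObservationModel] = None,
    gmap: GeneticMap = DEFAULT_MAP,
) -> ReferenceDistributions:
    """Simulate pedigrees holding all three second-degree pair types.

    Each replicate gene-drops the eight-member reference pedigree, extracts
    the avuncular, grandparent-grandchild and half-sibling pair segments,
    applies the observation model and records (n_segments, mean_length,
    total) per class.
    """
    if n_pedigrees < 2:
        raise ValueError("need at least 2 reference pedigrees")
    model = model or ObservationModel()
    rng = np.random.default_rng(seed)
    samples: dict[str, list[list[float]]] = {c: [] for c in SECOND_DEGREE_CLASSES}
    ped = second_degree_pedigree()
    for _ in range(n_pedigrees):
        genomes = drop_genomes(ped, gmap, rng)
        for cls, (a, b) in SECOND_DEGREE_PAIRS.items():
            segs = pairwise_ibd(genomes[a], genomes[b], gmap)
            segs = degrade_segments(segs, model, gmap, rng)
            n = len(segs)
            total = sum(s.length_cM for s in segs)
            mean = total / n if n else 0.0
            samples[cls].append([n, mean, total])
    return ReferenceDistributions(
        samples={c: np.asarray(v, dtype=float) for c, v in samples.items()},
        n_pedigrees=n_pedigrees, seed=seed, model=model)


class SecondDegreeClassifier:
    """Kernel-density classifier for second-degree subtypes.

    Fits one 2-D Gaussian KDE per class on (n_segments, mean_length_cM) from
    simulated reference distributions; predicts the class maximising the
    density, with a likelihood-ratio ambiguity rule.

    Parameters
    ----------
    ambiguity_ratio : float
        Calls with best/second-best likelihood ratio below this value are
        returned as "ambiguous".
    """

    def __init__(self, ambiguity_ratio: float = 2.0):
        self.ambiguity_ratio = ambiguity_ratio

    def get_params(self, deep: bool = True) -> dict:
        return {"ambiguity_ratio": self.ambiguity_ratio}

    def set_params(self, **params) -> "SecondDegreeClassifier":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, refs: ReferenceDistributions) -> "SecondDegreeClassifier":
        if not refs.samples:
            raise ValueError("reference distributions are empty")
        pooled = np.vstack([arr[:, :2] for arr in refs.samples.values()])
        self.scale_ = pooled.std(axis=0)
        self.scale_[self.scale_ == 0] = 1.0
        self.kdes_ = {}
        for cls, arr in refs.samples.items():
            self.kdes_[cls] = gaussian_kde((arr[:, :2] / self.scale_).T)
        self.classes_ = sorted(self.kdes_)
        return self

    def predict_one(self, n_segments: float, mean_length_cM: float) -> tuple[str, float]:
        """Return (subtype, likelihood ratio of best vs second-best)."""
        x = (np.array([n_segments, mean_length_cM]) / self.scale_).reshape(2, 1)
        dens = {cls: float(kde(x)[0]) for cls, kde in self.kdes_.items()}
        ranked = sorted(dens.items(), key=lambda kv: (-kv[1], kv[0]))
        best, second = ranked[0], ranked[1]
        ratio = best[1] / second[1] if second[1] > 0 else np.inf
        label = best[0] if ratio >= self.ambiguity_ratio else "ambiguous"
        return label, float(ratio)

    def predict(self, summaries) -> list[str]:
        out = []
        for pr in summaries:
            n = pr.n_segments
            mean = (pr.total_ibd1_cM + pr.total_ibd2_cM) / n if n else 0.0
            out.append(self.predict_one(n, mean)[0])
        return out


def classify_second_degree(pr: PairRelatedness, refs: ReferenceDistributions,
                           ambiguity_ratio: float = 2.0) -> tuple[str, float]:
    """Subtype call for a pair already classified as second degree."""
    clf = SecondDegreeClassifier(ambiguity_ratio=ambiguity_ratio).fit(refs)
    n = pr.n_segments
    mean = (pr.total_ibd1_cM + pr.total_ibd2_cM) / n if n else 0.0
    subtype, score = clf.predict_one(n, mean)
    pr.subtype = subtype
    return subtype, score


# --------------------------------------------------------------------------
# consanguinity


@dataclass
class ConsanguinityCall:
    individual_id: str
    sum_roh_gt4_cM: float
    n_roh_gt4: int
    flagged: bool
    f_estimate: float


def detect_consanguinity(individual_id: str, roh: list[IBDSegment],
                         gmap: GeneticMap = DEFAULT_MAP) -> ConsanguinityCall:
    """Flag parental consanguinity from long (>4 cM) ROH.

    The threshold on the summed long-ROH length is set so that offspring of
    second cousins (F = 1/64, expected ~55 cM of long ROH on a ~3,540 cM map)
    are detected with high sensitivity while outbred individuals, which carry
    no ROH loops at all, are never flagged.
    """
    long_roh = [s for s in roh if s.length_cM > ROH_LONG_CM]
    total = sum(s.length_cM for s in long_roh)
    return ConsanguinityCall(
        individual_id=individual_id,
        sum_roh_gt4_cM=total,
        n_roh_gt4=len(long_roh),
        flagged=total > CONSANGUINITY_SUM_CM,
        f_estimate=total / gmap.total_cM,
    )


def consanguinity_from_diplotype(individual_id: str, diplo: Diplotype,
                                 gmap: GeneticMap = DEFAULT_MAP) -> ConsanguinityCall:
    return detect_consanguinity(individual_id, roh_segments(diplo, gmap), gmap)
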