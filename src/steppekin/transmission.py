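"""Gene dropping through a pedigree and label-based IBD / ROH extraction.

Founders carry two uniquely labelled whole-chromosome haplotypes; each meiosis
draws a Poisson(L/100) number of crossovers placed uniformly on the chromosome
(no interference) and a random starting haplotype.  IBD between two
individuals is then exact identity of founder-haplotype labels, so segment
truth requires no genotypes.  An observation model degrades true segments to
ancient-DNA-like detections (minimum length, boundary jitter, length-dependent
dropout, SNP counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .datamodel import DEFAULT_MAP, GeneticMap, IBDSegment
from .pedigree import PedigreeGraph

# A haplotype is a list of (start_cM, end_cM, founder_label) tiles that
# partition [0, L); a diplotype maps chromosome name -> (hapA, hapB).
Haplotype = list[tuple[float, float, str]]
Diplotype = dict[str, tuple[Haplotype, Haplotype]]


def founder_diplotype(iid: str, gmap: GeneticMap) -> Diplotype:
    return {name: ([(0.0, length, f"{iid}.0")], [(0.0, length, f"{iid}.1")])
            for name, length in gmap.chromosomes}


def _gamete(hap_a: Haplotype, hap_b: Haplotype, length: float,
            rng: np.random.Generator) -> Haplotype:
    n_x = rng.poisson(length / 100.0)
    cuts = np.sort(rng.uniform(0.0, length, size=n_x)) if n_x else np.empty(0)
    current = int(rng.integers(2))
    haps = (hap_a, hap_b)
    bounds = np.concatenate(([0.0], cuts, [length]))
    out: Haplotype = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if hi <= lo:
            continue
        for start, end, label in haps[current]:
            s, e = max(start, lo), min(end, hi)
            if e > s:
                if out and out[-1][2] == label and abs(out[-1][1] - s) < 1e-12:
                    out[-1] = (out[-1][0], e, label)
                else:
                    out.append((s, e, label))
        current = 1 - current
    return out


def meiosis(diplo: Diplotype, gmap: GeneticMap, rng: np.random.Generator) -> Diplotype:
    """One full gamete (returned as a single-haplotype-per-chrom mapping)."""
    gam: dict[str, Haplotype] = {}
    for name, length in gmap.chromosomes:
        hap_a, hap_b = diplo[name]
        gam[name] = _gamete(hap_a, hap_b, length, rng)
    return gam  # type: ignore[return-value]


def drop_genomes(ped: PedigreeGraph, gmap: GeneticMap = DEFAULT_MAP,
                 seed: int | np.random.Generator = 0) -> dict[str, Diplotype]:
    """Transmit founder-labelled genomes through the pedigree.

    Individuals with no parents in the graph are founders and receive two
    uniquely labelled whole-chromosome haplotypes.  An individual with exactly
    one recorded parent cannot be dropped and raises an error naming it.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    genomes: dict[str, Diplotype] = {}
    for iid in ped.topological_order():
        f, m = ped.parents_of(iid)
        if f is None and m is None:
            genomes[iid] = founder_diplotype(iid, gmap)
            continue
        if f is None or m is None or f not in genomes or m not in genomes:
            raise ValueError(f"individual {iid} has a missing parent; cannot drop genome")
        pat = meiosis(genomes[f], gmap, rng)
        mat = meiosis(genomes[m], gmap, rng)
        genomes[iid] = {name: (pat[name], mat[name]) for name in gmap.names}
    return genomes


# --------------------------------------------------------------------------
# label sweeps


def _boundaries(haps: list[Haplotype]) -> np.ndarray:
    pts = {tile[0] for hap in haps for tile in hap}
    pts |= {tile[1] for hap in haps for tile in hap}
    return np.array(sorted(pts))


def _labels_at(hap: Haplotype, positions: np.ndarray) -> list[str]:
    """Label of the tile covering each interval midpoint (positions sorted)."""
    out = []
    i = 0
    for pos in positions:
        while i < len(hap) and hap[i][1] <= pos:
            i += 1
        out.append(hap[i][2])
    return out


def pairwise_ibd(a: Diplotype, b: Diplotype, gmap: GeneticMap = DEFAULT_MAP) -> list[IBDSegment]:
    """Exact IBD segments between two diplotypes, with IBD1/IBD2 state.

    At each map position the state is IBD2 when the two label multisets are
    equal, IBD1 when exactly one pair of labels matches, and non-IBD
    otherwise; maximal constant-state runs are emitted.
    """
    if set(a) != set(b):
        raise ValueError("diplotypes are on different genetic maps")
    segments: list[IBDSegment] = []
    for chrom in gmap.names:
        a1, a2 = a[chrom]
        b1, b2 = b[chrom]
        bounds = _boundaries([a1, a2, b1, b2])
        mids = (bounds[:-1] + bounds[1:]) / 2.0
        la1, la2 = _labels_at(a1, mids), _labels_at(a2, mids)
        lb1, lb2 = _labels_at(b1, mids), _labels_at(b2, mids)
        states = []
        for x1, x2, y1, y2 in zip(la1, la2, lb1, lb2):
            sa = sorted((x1, x2))
            sb = sorted((y1, y2))
            if sa == sb:
                states.append("IBD2")
            else:
                matches = _multiset_overlap(sa, sb)
                states.append("IBD1" if matches >= 1 else None)
        segments.extend(_runs_to_segments(chrom, bounds, states))
    return segments


def _multiset_overlap(sa: list[str], sb: list[str]) -> int:
    sb = list(sb)
    n = 0
    for x in sa:
        if x in sb:
            sb.remove(x)
            n += 1
    return n


def _runs_to_segments(chrom: str, bounds: np.ndarray, states: list) -> list[IBDSegment]:
    segs = []
    run_start = None
    run_state = None
    for i, st in enumerate(states):
        if st != run_state:
            if run_state is not None:
                segs.append(IBDSegment(chrom, float(run_start), float(bounds[i]),
                                       state=run_state))
            run_state = st
            run_start = bounds[i]
    if run_state is not None:
        segs.append(IBDSegment(chrom, float(run_start), float(bounds[-1]),
                               state=run_state))
    return segs


def roh_segments(a: Diplotype, gmap: GeneticMap = DEFAULT_MAP) -> list[IBDSegment]:
    """Maximal runs where the two haplotype labels of one individual coincide."""
    segs: list[IBDSegment] = []
    for chrom in gmap.names:
        h1, h2 = a[chrom]
        bounds = _boundaries([h1, h2])
        mids = (bounds[:-1] + bounds[1:]) / 2.0
        l1, l2 = _labels_at(h1, mids), _labels_at(h2, mids)
        states = ["IBD2" if x == y else None for x, y in zip(l1, l2)]
        segs.extend(_runs_to_segments(chrom, bounds, states))
    return segs


def roh_fraction(a: Diplotype, gmap: GeneticMap = DEFAULT_MAP) -> float:
    total = sum(s.length_cM for s in roh_segments(a, gmap))
    return total / gmap.total_cM


# --------------------------------------------------------------------------
# observation model


@dataclass
class ObservationModel:
    """Degradation of true segments to ancient-DNA-like detections.

    min_detect_cM: detection floor (cM); segments below it are never seen.
    snps_per_cM: marker density used to assign per-segment SNP counts; the
        default sits above the 220 SNPs/cM quality screen applied downstream.
    boundary_jitter_cM: uniform +/- jitter applied to each endpoint.
    dropout_prob: optional length -> probability of losing the segment.
    """

    min_detect_cM: float = 8.0
    snps_per_cM: float = 250.0
    boundary_jitter_cM: float = 0.0
    dropout_prob: Optional[Callable[[float], float]] = None
    seed: int = 0

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


PERFECT_OBSERVATION = ObservationModel(min_detect_cM=0.0, boundary_jitter_cM=0.0)


def degrade_segments(segments: list[IBDSegment], model: ObservationModel,
                     gmap: GeneticMap = DEFAULT_MAP,
                     rng: Optional[np.random.Generator] = None) -> list[IBDSegment]:
    rng = rng if rng is not None else model.rng()
    out: list[IBDSegment] = []
    for seg in segments:
        if seg.length_cM < model.min_detect_cM:
            continue
        if model.dropout_prob is not None:
            p = float(model.dropout_prob(seg.length_cM))
            if rng.uniform() < p:
                continue
        start, end = seg.start_cM, seg.end_cM
        if model.boundary_jitter_cM > 0:
            j = model.boundary_jitter_cM
            length = gmap.length_of(seg.chrom)
            start = float(np.clip(start + rng.uniform(-j, j), 0.0, length))
            end = float(np.clip(end + rng.uniform(-j, j), 0.0, length))
            if end <= start:
                continue
        n_snps = int(round((end - start) * model.snps_per_cM))
        out.append(IBDSegment(seg.chrom, start, end, n_snps=n_snps, state=seg.state))
    return out
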