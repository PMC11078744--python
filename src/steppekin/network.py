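"""Weighted undirected IBD-sharing networks and their node statistics.

Edges carry the pair's maximum shared-segment length (cM) after the quality
filters used for ancient-DNA IBD detection: segments count only when longer
than 8 cM at more than 220 SNPs/cM; a pair becomes an edge only with at least
one segment over 12 cM, and pairs whose longest retained segment is under
16 cM need at least two such segments.  Individuals below the SNP-coverage
floor (450,000) are excluded.  Node degree k splits into within-module k_W
and between-module k_B with the burial site as the module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .datamodel import Individual, PairRelatedness, as_sequence
from .relatedness import pair_summary

MIN_SEGMENT_CM = 8.0
MIN_SNPS_PER_CM = 220.0
MIN_EDGE_SEGMENT_CM = 12.0
SINGLE_SEGMENT_MIN_CM = 16.0
MIN_SNP_COUNT = 450_000


def filter_edges(pairs: Iterable[PairRelatedness],
                 individuals: Optional[Iterable[Individual]] = None,
                 min_snp_count: int = MIN_SNP_COUNT) -> list[PairRelatedness]:
    """Apply the IBD quality filters; keep only pairs that qualify as edges.

    Returns new PairRelatedness records holding only the retained segments;
    the edge weight is the longest retained segment (``max_ibd_cM``).  The
    operation is idempotent.
    """
    snp_ok: Optional[dict[str, bool]] = None
    if individuals is not None:
        snp_ok = {i.id: (i.snp_count is None or i.snp_count > min_snp_count)
                  for i in individuals}
    out = []
    for pr in pairs:
        if snp_ok is not None:
            if not snp_ok.get(pr.id_a, True) or not snp_ok.get(pr.id_b, True):
                continue
        kept = [s for s in pr.segments
                if s.length_cM > MIN_SEGMENT_CM
                and (s.snp_density is None or s.snp_density > MIN_SNPS_PER_CM)]
        long = [s for s in kept if s.length_cM > MIN_EDGE_SEGMENT_CM]
        if not long:
            continue
        longest = max(s.length_cM for s in long)
        if longest < SINGLE_SEGMENT_MIN_CM and len(long) < 2:
            continue
        summary = pair_summary(pr.id_a, pr.id_b, kept)
        summary.max_ibd_cM = longest
        out.append(summary)
    return out


@dataclass
class KinNetwork:
    """Undirected simple graph over individuals with site modules."""

    graph: nx.Graph
    adults_only: bool = False

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_network(edges: Iterable[PairRelatedness],
                  individuals: Iterable[Individual],
                  adults_only: bool = False) -> KinNetwork:
    """Build the IBD network; nodes are individuals appearing in >=1 edge."""
    inds = {i.id: i for i in individuals}
    g = nx.Graph()
    for pr in edges:
        a, b = pr.id_a, pr.id_b
        if a not in inds or b not in inds:
            continue
        if adults_only and not (inds[a].is_adult and inds[b].is_adult):
            continue
        g.add_edge(a, b, weight=pr.max_ibd_cM)
    for iid in g.nodes:
        g.nodes[iid]["site"] = inds[iid].site
        g.nodes[iid]["sex"] = inds[iid].sex
    return KinNetwork(graph=g, adults_only=adults_only)


def node_stats(network: KinNetwork) -> pd.DataFrame:
    """Per-node k, w, k_W, k_B and k_B/k (modules = sites)."""
    g = network.graph
    rows = []
    for iid in sorted(g.nodes):
        site = g.nodes[iid]["site"]
        k = g.degree[iid]
        w = sum(g.edges[iid, nb]["weight"] for nb in g.neighbors(iid))
        k_b = sum(1 for nb in g.neighbors(iid) if g.nodes[nb]["site"] != site)
        rows.append({
            "id": iid, "site": site, "sex": g.nodes[iid]["sex"],
            "k": k, "w": w, "k_W": k - k_b, "k_B": k_b,
            "kB_over_k": (k_b / k) if k else np.nan,
        })
    return pd.DataFrame(rows, columns=["id", "site", "sex", "k", "w", "k_W",
                                       "k_B", "kB_over_k"])


def group_means(stats: pd.DataFrame) -> dict[str, dict[str, float]]:
    """Mean degree <k> and strength <w>, overall and by sex (unknown excluded)."""
    out = {"all": {"k": float(stats["k"].mean()) if len(stats) else np.nan,
                   "w": float(stats["w"].mean()) if len(stats) else np.nan}}
    for sex in ("male", "female"):
        sub = stats[stats["sex"] == sex]
        out[sex] = {"k": float(sub["k"].mean()) if len(sub) else np.nan,
                    "w": float(sub["w"].mean()) if len(sub) else np.nan}
    return out


def cumulative_degree_distribution(stats: pd.DataFrame) -> pd.DataFrame:
    """P(k > x) on the observed degree support, for survival-function plots."""
    k = np.sort(stats["k"].to_numpy())
    xs = np.unique(k)
    p = [(k > x).mean() for x in xs]
    return pd.DataFrame({"x": xs, "p_k_gt_x": p})


# --------------------------------------------------------------------------
# group tests


def _ks_statistic(a: np.ndarray, b: np.ndarray) -> float:
    pooled = np.concatenate([a, b])
    grid = np.sort(pooled)
    fa = np.searchsorted(np.sort(a), grid, side="right") / a.size
    fb = np.searchsorted(np.sort(b), grid, side="right") / b.size
    return float(np.max(np.abs(fa - fb)))


def ks_permutation_test(values_a: Sequence[float], values_b: Sequence[float],
                        n_perm: int = 1000, seed: int = 0) -> tuple[float, float]:
    """Two-sample KS test with a pooled-relabelling permutation null.

    p = (1 + #{D* >= D}) / (1 + n_perm), so the smallest attainable p is
    1/(1 + n_perm).
    """
    a = as_sequence(values_a)
    b = as_sequence(values_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("KS permutation test requires nonempty samples")
    d_obs = _ks_statistic(a, b)
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if _ks_statistic(perm[:a.size], perm[a.size:]) >= d_obs - 1e-12:
            count += 1
    return d_obs, (1 + count) / (1 + n_perm)


def welch_t_test(values_a: Sequence[float], values_b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test with Welch-Satterthwaite df; two-sided p."""
    from scipy.stats import t as t_dist

    a = as_sequence(values_a)
    b = as_sequence(values_b)
    if a.size < 2 or b.size < 2:
        raise ValueError("Welch test requires samples of size >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    if se2 == 0:
        return 0.0, float(na + nb - 2), 1.0
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * t_dist.sf(abs(t), df)
    return float(t), float(df), float(p)
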