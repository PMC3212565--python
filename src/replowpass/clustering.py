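"""Repeat-family identification by similarity-graph clustering of long reads.

Reads become graph nodes; an edge joins two reads whose best local alignment
(on either strand) reaches at least 90% identity over at least 55% of the
shorter read.  Connected components are computed first and components with a
modular internal structure are subdivided by greedy modularity maximisation.
Cluster graph shape (circular / linear / globular) and tandem periodicity
provide a first structural characterisation of each family.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from . import align
from ._seq import encode, kmer_set, revcomp_codes
from .records import SequenceRead

MIN_IDENTITY = 0.90
MIN_SHORTER_COVERAGE = 0.55


@dataclass(frozen=True)
class OverlapEdge:
    """A qualifying pairwise overlap between two reads."""

    read_a: str
    read_b: str
    identity: float
    shorter_coverage: float
    score: int
    strand: str  # '+' if b aligned forward, '-' if reverse-complemented


@dataclass
class ReadCluster:
    """A community of mutually similar reads representing one repeat family."""

    id: str
    members: list[str]
    shape_class: str | None = None
    tandem_period: int | None = None
    family_label: str | None = None

    @property
    def size(self) -> int:
        return len(self.members)


def _pair_passes(alignment: align.LocalAlignment, len_a: int, len_b: int,
                 min_identity: float, min_cov: float) -> tuple[bool, float, float]:
    shorter = min(len_a, len_b)
    on_a = alignment.a_end - alignment.a_start
    on_b = alignment.b_end - alignment.b_start
    aligned_shorter = on_a if len_a <= len_b else on_b
    cov = aligned_shorter / shorter if shorter else 0.0
    ident = alignment.identity
    return (ident >= min_identity and cov >= min_cov), ident, cov


def find_overlaps(reads: list[SequenceRead] | list[tuple[str, str]],
                  min_identity: float = MIN_IDENTITY,
                  min_shorter_coverage: float = MIN_SHORTER_COVERAGE,
                  use_seed_filter: bool = True) -> list[OverlapEdge]:
    """All-to-all overlap detection over both strands.

    The accelerated route prescreens pairs with a shared exact k-mer whose
    length is chosen (``align.safe_seed_length``) so that every alignment
    meeting the thresholds must contain one; a score lower bound then skips
    traceback for pairs that cannot qualify.  The result equals exhaustive
    alignment of every pair.
    """
    items = [(r.id, r.bases) if isinstance(r, SequenceRead) else tuple(r) for r in reads]
    if len(items) < 2:
        return []
    ids = [i for i, _ in items]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate read ids")
    fwd = [encode(s) for _, s in items]
    rev = [revcomp_codes(c) for c in fwd]
    lengths = [len(c) for c in fwd]

    seed_k = None
    fwd_kmers = rev_kmers = None
    if use_seed_filter:
        seed_k = align.safe_seed_length(min(lengths), min_identity,
                                        min_shorter_coverage, max_len=2 * max(lengths))
        fwd_kmers = [kmer_set(c, seed_k) for c in fwd]
        rev_kmers = [kmer_set(c, seed_k) for c in rev]

    edges: list[OverlapEdge] = []
    n = len(items)
    for i in range(n):
        for j in range(i + 1, n):
            shorter = min(lengths[i], lengths[j])
            score_floor = align.min_overlap_score(shorter, min_identity,
                                                  min_shorter_coverage)
            best_edge = None
            for strand, b_codes, b_seeds in (
                ("+", fwd[j], fwd_kmers[j] if use_seed_filter else None),
                ("-", rev[j], rev_kmers[j] if use_seed_filter else None),
            ):
                if use_seed_filter and fwd_kmers[i].isdisjoint(b_seeds):
                    continue
                if align.sw_score(fwd[i], b_codes) < score_floor:
                    continue
                aln = align.sw_align(fwd[i], b_codes)
                ok, ident, cov = _pair_passes(aln, lengths[i], lengths[j],
                                              min_identity, min_shorter_coverage)
                if ok and (best_edge is None or aln.score > best_edge.score):
                    best_edge = OverlapEdge(ids[i], ids[j], ident, cov,
                                            aln.score, strand)
            if best_edge is not None:
                edges.append(best_edge)
    return edges


def overlap_graph(read_ids: list[str], edges: list[OverlapEdge]) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(read_ids)
    g.add_edges_from((e.read_a, e.read_b) for e in edges)
    return g


def build_clusters(read_ids: list[str], edges: list[OverlapEdge],
                   community_split: bool = True,
                   min_modularity_gain: float = 0.05,
                   max_bridge_fraction: float = 0.01,
                   min_size: int = 2) -> tuple[list[ReadCluster], list[str]]:
    """Partition reads into clusters (communities) plus unclustered singletons.

    Connected components of the overlap graph are computed first.  A
    component is subdivided by greedy modularity maximisation only when the
    partition (a) improves modularity by more than ``min_modularity_gain``
    over the unsplit component (whose modularity is zero) and (b) leaves at
    most ``max_bridge_fraction`` of the component's edges running between
    communities.  Condition (b) is what separates genuinely distinct
    families joined by a few chimeric or shared-similarity edges (a thin
    bridge: split) from the internal geometry of a single family's overlap
    graph, where modularity is always high but adjacent "communities"
    exchange many edges (keep whole).  Clusters are numbered CL1, CL2, ...
    by decreasing size, ties broken by smallest member id.
    """
    g = overlap_graph(read_ids, edges)
    groups: list[list[str]] = []
    singletons: list[str] = []
    for comp in nx.connected_components(g):
        comp = sorted(comp)
        if len(comp) < max(min_size, 2):
            singletons.extend(comp)
            continue
        sub = g.subgraph(comp)
        parts = [comp]
        if community_split and len(comp) >= 4:
            communities = list(nx.community.greedy_modularity_communities(sub))
            if len(communities) > 1:
                q = nx.community.modularity(sub, communities)
                member = {n: ci for ci, c in enumerate(communities) for n in c}
                bridges = sum(1 for u, v in sub.edges() if member[u] != member[v])
                # chimeric merges hang on a handful of edges; internal
                # geometry of one family exchanges many more
                allowed = max(2 * (len(communities) - 1),
                              max_bridge_fraction * sub.number_of_edges())
                if q > min_modularity_gain and bridges <= allowed:
                    parts = [sorted(c) for c in communities]
        for part in parts:
            if len(part) >= max(min_size, 2):
                groups.append(part)
            else:
                singletons.extend(part)
    groups.sort(key=lambda m: (-len(m), min(m)))
    clusters = [ReadCluster(id=f"CL{i + 1}", members=m) for i, m in enumerate(groups)]
    return clusters, sorted(singletons)


def cluster_summary(clusters: list[ReadCluster], total_reads: int):
    """Size-ranked cluster table with per-cluster and cumulative proportions.

    Also reports (as DataFrame attrs) the clustered read fraction and the
    minimal number of top clusters covering half of all reads.
    """
    import pandas as pd

    if total_reads == 0:
        raise ValueError("total_reads must be positive")
    rows = []
    cum = 0.0
    for cl in sorted(clusters, key=lambda c: (-c.size, c.id)):
        p = cl.size / total_reads
        cum += p
        rows.append({"cluster_id": cl.id, "size": cl.size,
                     "proportion": p, "cumulative_proportion": cum})
    df = pd.DataFrame(rows, columns=["cluster_id", "size", "proportion",
                                     "cumulative_proportion"])
    df.attrs["clustered_fraction"] = float(df["proportion"].sum()) if len(df) else 0.0
    half = df.index[df["cumulative_proportion"] >= 0.5 - 1e-12]
    df.attrs["k_half"] = int(half[0]) + 1 if len(half) else None
    return df


def classify_graph_shape(cluster: ReadCluster, graph: nx.Graph,
                         density_globular: float = 0.2,
                         ecc_ratio_circular: float = 0.75,
                         min_diameter: int = 4,
                         max_bfs_sources: int = 200) -> str:
    """Deterministic graph-shape label for a cluster.

    Near-clique graphs (density >= ``density_globular``) are *globular*, the
    signature of short-monomer satellites where every read overlaps every
    other.  Among sparse graphs, cycle-like layouts (tandem units much longer
    than the read) have nearly constant node eccentricity, while path-like
    layouts (dispersed elements) have a ~2x eccentricity spread between ends
    and middle: min/max eccentricity >= ``ecc_ratio_circular`` -> *circular*,
    otherwise *linear*.  Graphs too small or too compact to call are *other*.
    """
    if cluster.size < 10:
        return "other"
    sub = graph.subgraph(cluster.members)
    if nx.density(sub) >= density_globular:
        return "globular"
    nodes = sorted(sub.nodes())
    if len(nodes) > max_bfs_sources:
        stride = len(nodes) / max_bfs_sources
        nodes = [nodes[int(i * stride)] for i in range(max_bfs_sources)]
    eccs = []
    for source in nodes:
        dist = nx.single_source_shortest_path_length(sub, source)
        eccs.append(max(dist.values()))
    diam = max(eccs)
    if diam < min_diameter:
        return "other"
    ratio = min(eccs) / diam
    return "circular" if ratio >= ecc_ratio_circular else "linear"


def detect_tandem_period(sequence: str, min_identity: float = 0.80,
                         max_period: int | None = None,
                         tie_tolerance: float = 0.02) -> int | None:
    """Smallest self-alignment lag with >= ``min_identity`` matching positions.

    The sequence is compared against itself shifted by each candidate lag
    p <= len/3; among qualifying lags the smallest one within
    ``tie_tolerance`` of the best identity is returned (so the fundamental
    period wins over its multiples), or ``None`` if no lag qualifies.
    """
    codes = encode(sequence)
    n = len(codes)
    limit = max_period if max_period is not None else n // 3
    if limit < 1:
        return None
    identities = np.full(limit + 1, -1.0)
    for p in range(1, limit + 1):
        a = codes[:-p]
        b = codes[p:]
        identities[p] = float(((a == b) & (a < 4)).mean())
    qualifying = np.flatnonzero(identities >= min_identity)
    if len(qualifying) == 0:
        return None
    best = identities[qualifying].max()
    for p in qualifying:
        if identities[p] >= best - tie_tolerance:
            return int(p)
    return None


def cluster_representative(cluster: ReadCluster, seqs: dict[str, str]) -> str:
    """Longest member read (ties by id) as the cluster's representative."""
    return max(cluster.members, key=lambda r: (len(seqs[r]), r))
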