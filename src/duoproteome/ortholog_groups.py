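"""Cross-species similarity graph and Markov clustering into ortholog groups.

Follows the OrthoMCL scheme in simplified form: hits are gated by percent
match length (alignment length over the shorter sequence) and an E-value
exponent cutoff; inter-species edges come from reciprocal best hits;
intra-species (in-paralog) edges are pairs more similar to each other than
either member is to any gene of another species. The resulting weighted
graph is clustered with MCL.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from ._core import InputError, logger
from .pairwise_align import HitRecord

WEIGHT_CAP = 300.0  # -log10(E) cap, avoids infinities at E == 0
SUPPORT_EPS = 1.0e-4  # matrix entries below this do not link clusters


def _neglog10(evalue: float) -> float:
    if evalue <= 0.0:
        return WEIGHT_CAP
    return min(WEIGHT_CAP, -math.log10(evalue))


def build_graph(hits: Sequence[HitRecord],
                species_of: Mapping[str, str],
                seq_lengths: Mapping[str, int],
                percent_match_cutoff: float = 50.0,
                evalue_exponent_cutoff: float = -5.0) -> nx.Graph:
    """Build the similarity graph from all pairwise hit tables.

    Nodes are all genes in ``species_of`` (so genes with no retained hit
    become singletons). A hit is retained when its percent match length
    (alignment columns over the shorter sequence, x100) reaches
    ``percent_match_cutoff`` and E <= 10**evalue_exponent_cutoff.
    Edge weight is the mean of the two directions' -log10(E), capped.
    """
    evalue_max = 10.0 ** evalue_exponent_cutoff
    # best retained hit per ordered (query, subject) pair
    best: dict[tuple[str, str], HitRecord] = {}
    for h in hits:
        if h.query_id == h.subject_id:
            continue
        for gid in (h.query_id, h.subject_id):
            if gid not in species_of:
                raise InputError(f"hit references unknown gene {gid!r}")
            if gid not in seq_lengths:
                raise InputError(f"no sequence length for gene {gid!r}")
        shorter = min(seq_lengths[h.query_id], seq_lengths[h.subject_id])
        if 100.0 * h.alignment_length / shorter < percent_match_cutoff:
            continue
        if h.evalue > evalue_max:
            continue
        key = (h.query_id, h.subject_id)
        prev = best.get(key)
        if prev is None or (h.bitscore, -h.evalue) > (prev.bitscore, -prev.evalue):
            best[key] = h
    # symmetrized pair weights
    pair_weight: dict[tuple[str, str], float] = {}
    for (q, s), h in best.items():
        pair = (q, s) if q < s else (s, q)
        w = _neglog10(h.evalue)
        if pair in pair_weight:
            pair_weight[pair] = (pair_weight[pair] + w) / 2.0
        else:
            pair_weight[pair] = w
    # per-gene best inter-species similarity, and per-(gene, species) best
    # subject for the reciprocal-best-hit rule
    best_inter_sim: dict[str, float] = {}
    best_subject: dict[tuple[str, str], str] = {}
    best_subject_key: dict[tuple[str, str], tuple] = {}
    for (q, s), h in best.items():
        if species_of[q] == species_of[s]:
            continue
        w = pair_weight[(q, s) if q < s else (s, q)]
        best_inter_sim[q] = max(best_inter_sim.get(q, 0.0), w)
        key = (q, species_of[s])
        # ties: higher bitscore, then lower E, then lexicographic subject id
        rank = (h.bitscore, -h.evalue, _rev(s))
        if key not in best_subject_key or rank > best_subject_key[key]:
            best_subject_key[key] = rank
            best_subject[key] = s
    graph = nx.Graph()
    for gid in sorted(species_of):
        graph.add_node(gid, species=species_of[gid])
    for pair, w in sorted(pair_weight.items()):
        q, s = pair
        if (q, s) not in best or (s, q) not in best:
            continue  # edges need hits in both directions
        if species_of[q] != species_of[s]:
            if best_subject.get((q, species_of[s])) == s and \
                    best_subject.get((s, species_of[q])) == q:
                graph.add_edge(q, s, weight=w)
        else:
            if w > best_inter_sim.get(q, 0.0) and w > best_inter_sim.get(s, 0.0):
                graph.add_edge(q, s, weight=w)
    return graph


class _Rev(str):
    """String with reversed ordering, for 'lower id wins' inside max-ranks."""

    def __lt__(self, other):
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def _rev(s: str) -> "_Rev":
    return _Rev(s)


# ---------------------------------------------------------------------------
# Markov clustering


def _mcl_component(nodes: list, adj: np.ndarray, inflation: float,
                   max_iter: int, eps: float, tol: float) -> tuple[list[frozenset], bool]:
    n = len(nodes)
    m = adj.astype(float).copy()
    # self-loops at each node's maximum incident weight (1 for isolated)
    loops = m.max(axis=0)
    loops[loops <= 0] = 1.0
    np.fill_diagonal(m, loops)
    m /= m.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(max_iter):
        new = m @ m
        np.power(new, inflation, out=new)
        if eps > 0:
            new[new < eps] = 0.0
        colsum = new.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        new /= colsum
        if np.abs(new - m).max() < tol:
            m = new
            converged = True
            break
        m = new
    # clusters: connected components of the converged support structure
    support = (m > SUPPORT_EPS) | (m > SUPPORT_EPS).T
    seen = [False] * n
    clusters = []
    for start in range(n):
        if seen[start]:
            continue
        stack = [start]
        seen[start] = True
        comp = []
        while stack:
            u = stack.pop()
            comp.append(nodes[u])
            for v in np.nonzero(support[u])[0]:
                if not seen[v]:
                    seen[v] = True
                    stack.append(int(v))
        clusters.append(frozenset(comp))
    return clusters, converged


def mcl_cluster(graph: nx.Graph, inflation: float = 1.5, max_iter: int = 200,
                eps: float = 1.0e-6, tol: float = 1.0e-8
                ) -> tuple[list[frozenset], dict]:
    """Markov clustering of the similarity graph.

    Runs the expansion/inflation iteration per connected component (the
    matrix is block-diagonal across components, so this is exact).
    Disconnected nodes become singletons. Returns clusters (sorted by
    smallest member id) and an info dict with a convergence flag.
    """
    if inflation <= 1.0:
        raise InputError("inflation must be > 1")
    clusters: list[frozenset] = []
    all_converged = True
    for comp in nx.connected_components(graph):
        nodes = sorted(comp)
        if len(nodes) == 1:
            clusters.append(frozenset(nodes))
            continue
        sub = graph.subgraph(nodes)
        adj = np.zeros((len(nodes), len(nodes)))
        idx = {g: i for i, g in enumerate(nodes)}
        for u, v, data in sub.edges(data=True):
            w = float(data.get("weight", 1.0))
            adj[idx[u], idx[v]] = w
            adj[idx[v], idx[u]] = w
        comp_clusters, converged = _mcl_component(
            nodes, adj, inflation, max_iter, eps, tol)
        clusters.extend(comp_clusters)
        all_converged = all_converged and converged
    if not all_converged:
        logger.warning("MCL did not fully converge within max_iter=%d", max_iter)
    clusters.sort(key=lambda c: min(c))
    return clusters, {"converged": all_converged, "n_clusters": len(clusters)}


# ---------------------------------------------------------------------------
# OG classification


@dataclass(frozen=True)
class OrthoGroup:
    """One cluster of the similarity graph with per-species bookkeeping."""

    og_id: str
    members: tuple[str, ...]
    n_a: int
    n_b: int
    n_out: int
    category: str  # shared | single_species | singleton
    conserved: bool  # same nonzero gene count from both compared species


def classify_ogs(clusters: Sequence[frozenset],
                 species_of: Mapping[str, str],
                 species_a: str = "A", species_b: str = "B",
                 outgroup: str = "OUT"
                 ) -> tuple[list[OrthoGroup], dict]:
    """Categorize clusters and tally the paper-style summary counts.

    ``shared`` requires genes from both compared species; size-1 clusters
    are ``singleton``; anything else is ``single_species``. The
    presumptive species-specific pool of a species is its genes in
    non-shared clusters. Multi-member clusters are counted as OGs proper;
    singletons are tallied separately (both conventions reported).
    """
    seen: set[str] = set()
    ogs: list[OrthoGroup] = []
    ordered = sorted(clusters, key=lambda c: min(c))
    for i, cluster in enumerate(ordered):
        members = tuple(sorted(cluster))
        overlap = seen.intersection(members)
        if overlap:
            raise InputError(f"clusters do not partition genes: {sorted(overlap)[:3]}")
        seen.update(members)
        n_a = sum(1 for g in members if species_of[g] == species_a)
        n_b = sum(1 for g in members if species_of[g] == species_b)
        n_out = sum(1 for g in members if species_of[g] == outgroup)
        if len(members) == 1:
            category = "singleton"
        elif n_a > 0 and n_b > 0:
            category = "shared"
        else:
            category = "single_species"
        conserved = n_a == n_b and n_a > 0
        ogs.append(OrthoGroup(f"OG{i + 1:06d}", members, n_a, n_b, n_out,
                              category, conserved))
    missing = set(species_of) - seen
    if missing:
        raise InputError(f"genes missing from every cluster: {sorted(missing)[:3]}")
    shared = [og for og in ogs if og.category == "shared"]
    multi = [og for og in ogs if len(og.members) > 1]
    singletons = [og for og in ogs if og.category == "singleton"]
    summary = {
        "n_ogs_multi": len(multi),
        "n_singletons": len(singletons),
        "n_ogs_total": len(ogs),
        "n_shared_ogs": len(shared),
        "n_conserved_ogs": sum(1 for og in ogs if og.conserved),
        "shared_genes_a": sum(og.n_a for og in shared),
        "shared_genes_b": sum(og.n_b for og in shared),
        "presumptive_specific_a": sum(
            og.n_a for og in ogs if og.category != "shared"),
        "presumptive_specific_b": sum(
            og.n_b for og in ogs if og.category != "shared"),
        "proteome_size_a": sum(1 for s in species_of.values() if s == species_a),
        "proteome_size_b": sum(1 for s in species_of.values() if s == species_b),
    }
    return ogs, summary


def presumptive_pool(ogs: Sequence[OrthoGroup], species_of: Mapping[str, str],
                     species: str) -> set[str]:
    """Genes of ``species`` in single-species OGs or singletons."""
    pool: set[str] = set()
    for og in ogs:
        if og.category != "shared":
            pool.update(g for g in og.members if species_of[g] == species)
    return pool


def write_ogs(ogs: Sequence[OrthoGroup], species_of: Mapping[str, str],
              path: str | Path) -> None:
    rows = []
    for og in ogs:
        for g in og.members:
            rows.append((g, species_of[g], og.og_id, og.category,
                         int(og.conserved)))
    pd.DataFrame(rows, columns=[
        "gene_id", "species", "og_id", "og_category", "conserved_flag",
    ]).to_csv(path, sep="\t", index=False)
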