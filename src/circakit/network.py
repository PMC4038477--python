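"""Gene-interaction network assembly and enrichment testing.

Builds shell-structured networks from provenance-tagged edge lists,
counts inter-set connections, and tests the connectivity of a query set
against a citation-bin-matched random-set null, reporting empirical,
z-score and Wilcoxon signed-rank significance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "InteractionNetwork",
    "NullDistribution",
    "assemble_network",
    "cross_set_connections",
    "citation_bin_null",
    "wilcoxon_one_sample",
    "overlap_summary",
    "citation_bin",
]

SHELLS = ("core", "first_shell", "outer_shell", "other")


def norm_symbol(s: str) -> str:
    return str(s).strip().upper()


@dataclass
class InteractionNetwork:
    """Undirected provenance-merged gene graph with shell labels."""

    graph: nx.Graph

    @property
    def nodes(self):
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def shell_of(self, node: str) -> str:
        return self.graph.nodes[node].get("shell", "other")

    def shell_counts(self) -> dict:
        counts = {s: 0 for s in SHELLS}
        for n in self.graph.nodes:
            counts[self.shell_of(n)] += 1
        return counts


def _merge_edge(g: nx.Graph, u: str, v: str, attrs: dict):
    if u == v:
        return  # self-loops excluded
    if g.has_edge(u, v):
        old = g.edges[u, v]
        sources = {old.get("source"), attrs.get("source")} - {None}
        old["source"] = "both" if len(sources) > 1 else sources.pop()
        old["pubmed_ids"] = sorted(set(old.get("pubmed_ids", [])) | set(attrs.get("pubmed_ids", [])))
        old["confidence"] = max(old.get("confidence", 0.0), attrs.get("confidence", 0.0))
        if old.get("type") != attrs.get("type"):
            old["type"] = old.get("type") or attrs.get("type") or "other"
    else:
        g.add_edge(u, v, **attrs)


def assemble_network(
    edges: pd.DataFrame,
    core_set: set,
    first_shell: set | None = None,
) -> InteractionNetwork:
    """Assemble core + declared first shell + edge-implied outer shell.

    Outer-shell membership requires at least one edge to a core gene.
    Edges are restricted to placed nodes; duplicate undirected edges are
    merged with provenance union.
    """
    core = {norm_symbol(s) for s in core_set}
    if not core:
        raise ValueError("core set must be non-empty")
    first = {norm_symbol(s) for s in (first_shell or set())} - core

    g_all = nx.Graph()
    for _, row in edges.iterrows():
        u, v = norm_symbol(row["src"]), norm_symbol(row["dst"])
        attrs = {
            "type": row.get("type", "other"),
            "source": row.get("source", "other"),
            "pubmed_ids": _split_ids(row.get("pubmed_ids", "")),
            "confidence": float(row.get("confidence", 1.0) or 1.0),
        }
        _merge_edge(g_all, u, v, attrs)

    outer = {
        n for n in g_all.nodes
        if n not in core and n not in first and any(m in core for m in g_all.neighbors(n))
    }
    placed = core | first | outer
    g = nx.Graph()
    for n in placed:
        shell = "core" if n in core else ("first_shell" if n in first else "outer_shell")
        g.add_node(n, shell=shell)
    for u, v, attrs in g_all.edges(data=True):
        if u in placed and v in placed:
            g.add_edge(u, v, **attrs)
    return InteractionNetwork(g)


def _split_ids(raw) -> list:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return []
    if isinstance(raw, (list, tuple)):
        return [str(x) for x in raw]
    s = str(raw).strip()
    return [x for x in s.replace(";", ",").split(",") if x] if s else []


def cross_set_connections(network: InteractionNetwork | nx.Graph, set_a, set_b) -> int:
    """Edges with one endpoint in each set; within-set edges excluded."""
    g = network.graph if isinstance(network, InteractionNetwork) else network
    a = {norm_symbol(s) for s in set_a}
    b = {norm_symbol(s) for s in set_b}
    shared = a & b
    a, b = a - shared, b  # shared symbols count on the target side only
    if not (a & set(g.nodes)) or not (b & set(g.nodes)):
        warnings.warn("a gene set has no overlap with the network")
    count = 0
    for u, v in g.edges:
        if (u in a and v in b) or (v in a and u in b):
            count += 1
    return count


def citation_bin(citations: int) -> int:
    """Log2-width citation bin: floor(log2(citations + 1))."""
    return int(np.floor(np.log2(citations + 1)))


@dataclass
class NullDistribution:
    observed: int
    counts: np.ndarray
    mean: float
    sd: float
    z: float
    empirical_p: float
    wilcoxon_p: float
    seed: int
    replicate_sets: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "observed": self.observed,
            "counts": [int(c) for c in self.counts],
            "mean": self.mean,
            "sd": self.sd,
            "z": self.z,
            "empirical_p": self.empirical_p,
            "wilcoxon_p": self.wilcoxon_p,
            "seed": self.seed,
        }


def citation_bin_null(
    citations: dict,
    query_set,
    target_sets,
    edges_or_graph,
    B: int = 50,
    seed: int = 0,
    exclude_query_target: bool = True,
    keep_sets: bool = False,
) -> NullDistribution:
    """Citation-matched random-set null for inter-set connectivity.

    Each of ``B`` replicates replaces every query gene by a uniform draw
    (without replacement within the replicate) from the universe genes in
    the same log2 citation bin, excluding query and target genes, then
    recounts connections to the union of target sets.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    cit = {norm_symbol(g): int(c) for g, c in citations.items()}
    query = [norm_symbol(g) for g in query_set]
    targets = set()
    for ts in target_sets:
        targets |= {norm_symbol(g) for g in ts}
    query = [g for g in query if g not in targets]  # common genes count on the target side
    missing = [g for g in query if g not in cit]
    if missing:
        raise KeyError(f"query genes without citation counts: {missing}")
    if len(cit) < 10 * len(query):
        raise ValueError("citation universe must be >= 10x the query set")

    if isinstance(edges_or_graph, InteractionNetwork):
        g = edges_or_graph.graph
    elif isinstance(edges_or_graph, nx.Graph):
        g = edges_or_graph
    else:
        g = nx.Graph()
        for _, row in edges_or_graph.iterrows():
            u, v = norm_symbol(row["src"]), norm_symbol(row["dst"])
            if u != v:
                g.add_edge(u, v)

    observed = cross_set_connections(g, query, targets)

    forbidden = set(query) | targets if exclude_query_target else set()
    bins: dict[int, list] = {}
    for gene, c in cit.items():
        if gene in forbidden:
            continue
        bins.setdefault(citation_bin(c), []).append(gene)
    for b in bins.values():
        b.sort()

    rng = np.random.default_rng(seed)
    counts = np.empty(B, dtype=int)
    sets = []
    query_bins = [citation_bin(cit[q]) for q in query]
    for rep in range(B):
        taken: set = set()
        sampled = []
        for qb in query_bins:
            pool, b = [], qb
            # fall back to the nearest non-empty bin if this one is spent
            for radius in range(0, 64):
                for cand in ({qb - radius, qb + radius} if radius else {qb}):
                    pool = [x for x in bins.get(cand, []) if x not in taken]
                    if pool:
                        b = cand
                        break
                if pool:
                    break
            if not pool:
                raise ValueError("citation universe exhausted while sampling")
            if b != qb:
                warnings.warn(f"empty citation bin {qb}; fell back to bin {b}")
            pick = pool[rng.integers(len(pool))]
            taken.add(pick)
            sampled.append(pick)
        counts[rep] = cross_set_connections(g, sampled, targets)
        if keep_sets:
            sets.append(sampled)

    mean = float(np.mean(counts))
    sd = float(np.std(counts, ddof=1))
    z = (observed - mean) / sd if sd > 0 else float("inf") * np.sign(observed - mean or 1)
    emp = (1 + int(np.sum(counts >= observed))) / (1 + B)
    wil = wilcoxon_one_sample(counts, observed, alternative="greater")
    return NullDistribution(observed, counts, mean, sd, float(z), emp, wil, seed, sets)


def _signed_rank_exact_p(ranks2: np.ndarray, w_plus2: int, alternative: str) -> float:
    """Exact signed-rank tail by DP over doubled (integer) midranks."""
    total = int(ranks2.sum())
    # dist[w] = number of sign assignments with positive-rank sum w (doubled scale)
    dist = np.zeros(total + 1, dtype=float)
    dist[0] = 1.0
    for r in ranks2:
        new = dist.copy()
        new[r:] += dist[: total + 1 - r]
        dist = new
    n_total = dist.sum()
    if alternative == "greater":
        p = dist[w_plus2:].sum() / n_total
    elif alternative == "less":
        p = dist[: w_plus2 + 1].sum() / n_total
    else:
        p_hi = dist[w_plus2:].sum() / n_total
        p_lo = dist[: w_plus2 + 1].sum() / n_total
        p = min(1.0, 2 * min(p_hi, p_lo))
    return float(p)


def wilcoxon_one_sample(values, observed: float, alternative: str = "greater") -> float:
    """One-sample Wilcoxon signed-rank p-value of ``observed`` vs ``values``.

    Tests whether the observed value exceeds the null location: the
    differences ``observed - values`` are signed-ranked (zeros dropped,
    ties midranked). Exact enumeration for n <= 25; otherwise the normal
    approximation with continuity correction.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 5:
        raise ValueError("need at least 5 null values")
    d = observed - values
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all differences are zero; p = 1")
        return 1.0
    absd = np.abs(d)
    order = np.argsort(absd, kind="mergesort")
    ranks = np.empty(d.size)
    sorted_abs = absd[order]
    i = 0
    pos = 1
    while i < d.size:
        j = i
        while j + 1 < d.size and sorted_abs[j + 1] == sorted_abs[i]:
            j += 1
        midrank = (pos + (pos + j - i)) / 2
        for k in range(i, j + 1):
            ranks[order[k]] = midrank
        pos += j - i + 1
        i = j + 1
    w_plus = float(ranks[d > 0].sum())
    n = d.size
    if n <= 25:
        ranks2 = np.rint(ranks * 2).astype(int)
        w2 = int(round(w_plus * 2))
        return _signed_rank_exact_p(ranks2, w2, alternative)
    mu = n * (n + 1) / 4
    tie_term = 0.0
    _, tie_counts = np.unique(absd, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / 48
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24 - tie_term)
    from scipy.special import ndtr
    if alternative == "greater":
        return float(1 - ndtr((w_plus - 0.5 - mu) / sigma))
    if alternative == "less":
        return float(ndtr((w_plus + 0.5 - mu) / sigma))
    z = (w_plus - mu - 0.5 * np.sign(w_plus - mu)) / sigma
    return float(min(1.0, 2 * (1 - ndtr(abs(z)))))


def overlap_summary(network: InteractionNetwork | nx.Graph, query_set, set_a, set_b) -> dict:
    """Per-query-gene incidence to two target sets and the three tallies."""
    g = network.graph if isinstance(network, InteractionNetwork) else network
    a = {norm_symbol(s) for s in set_a}
    b = {norm_symbol(s) for s in set_b}
    flags = {}
    for q in (norm_symbol(s) for s in query_set):
        nbrs = set(g.neighbors(q)) if q in g else set()
        flags[q] = {"to_a": bool(nbrs & (a - {q})), "to_b": bool(nbrs & (b - {q}))}
    n_a = sum(f["to_a"] for f in flags.values())
    n_b = sum(f["to_b"] for f in flags.values())
    n_both = sum(f["to_a"] and f["to_b"] for f in flags.values())
    return {"to_a": n_a, "to_b": n_b, "to_both": n_both, "flags": flags}
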