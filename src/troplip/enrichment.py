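"""Preranked GSEA and the leading-edge overlap graph.

Enrichment uses the weighted Kolmogorov–Smirnov running sum (weight
exponent 1): walking down the ranked list, a set member increments the sum
by |score| / Σ|scores over members| and a non-member decrements it by
1/(N − n).  ES is the deviation of maximal magnitude; NES divides ES by the
mean |ES| of same-sign gene-label permutations, and the permutation p gets
+1 smoothing.  The leading edge is the set members at or before the
running-sum maximum (positive ES) or at or after the minimum (negative ES).

The overlap graph connects significantly enriched sets of one direction by
the fraction of one leading edge contained in another, reported as
"k/n (p%)"; clusters are connected components above an edge threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .diffexp import benjamini_hochberg
from .errors import DataError
from .io_formats import GeneSetCollection


@dataclass
class GseaResult:
    """Per-set enrichment: ES, NES, permutation p, padj, leading edge."""

    table: pd.DataFrame            # set, size, es, nes, p, padj
    leading_edges: dict[str, list[str]]
    skipped: list[str] = field(default_factory=list)


def _rank_scores(ranked: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    df = ranked.sort_values(["score", "gene"], ascending=[False, True],
                            kind="stable")
    return df["score"].to_numpy(dtype=float), list(df["gene"])


def _es_from_hits(scores: np.ndarray, hits: np.ndarray) -> tuple[float, int, int]:
    """ES plus the positions of the running-sum max and min.

    ``hits`` are sorted 0-based positions of the set members in the ranked
    list.  Extremes of the running sum occur right after a hit (candidates
    for the max) or right before one (candidates for the min); between hits
    the sum decays linearly and ends at 0.
    """
    n_total = scores.size
    k = hits.size
    if k == 0 or k == n_total:
        return 0.0, -1, -1
    w = np.abs(scores[hits])
    denom = w.sum()
    if denom == 0:
        w = np.ones(k)
        denom = float(k)
    cum = np.cumsum(w) / denom
    miss = 1.0 / (n_total - k)
    i = np.arange(1, k + 1)
    after = cum - (hits + 1 - i) * miss          # value just after hit i
    before = np.concatenate([[0.0], cum[:-1]]) - (hits - (i - 1)) * miss
    top = float(after.max())
    bottom = float(min(before.min(), 0.0))
    if top >= -bottom:
        return top, int(hits[int(after.argmax())]), int(hits[int(before.argmin())])
    return bottom, int(hits[int(after.argmax())]), int(hits[int(before.argmin())])


def running_sum(scores: np.ndarray, member_mask: np.ndarray) -> np.ndarray:
    """The full running sum, mainly for inspection and plotting."""
    n = scores.size
    k = int(member_mask.sum())
    w = np.abs(scores) * member_mask
    denom = w.sum()
    if denom == 0:
        w = member_mask.astype(float)
        denom = float(k)
    steps = np.where(member_mask, w / denom, -1.0 / (n - k))
    return np.cumsum(steps)


def extract_leading_edge(
    genes: list[str], member_mask: np.ndarray, es: float,
    max_pos: int, min_pos: int,
) -> list[str]:
    """Set members driving the enrichment, in ranking order."""
    idx = np.flatnonzero(member_mask)
    if es > 0:
        keep = idx[idx <= max_pos]
    elif es < 0:
        keep = idx[idx >= min_pos]
    else:
        keep = np.array([], dtype=int)
    return [genes[i] for i in keep]


def preranked_gsea(
    ranked: pd.DataFrame,
    sets: GeneSetCollection,
    n_perm: int = 10_000,
    seed: int = 0,
    min_size: int = 5,
    max_size: int = 500,
) -> GseaResult:
    """Preranked GSEA over every set, with gene-label permutation nulls.

    ``ranked`` needs columns ``gene`` and ``score``; ties are broken by
    gene id so the ranking is deterministic.  Sets are restricted to the
    ranked universe; sets outside the size window, fully covering the
    universe, or absent from it are skipped and listed in ``skipped``.
    """
    scores, genes = _rank_scores(ranked)
    if len(set(genes)) != len(genes):
        raise DataError("ranked list contains duplicate genes")
    pos = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    rng = np.random.default_rng(seed)

    rows, leading, skipped = [], {}, []
    for name, members in sets:
        hit_idx = np.array(sorted(pos[g] for g in members if g in pos),
                           dtype=int)
        k = hit_idx.size
        if k == 0 or k == n or not (min_size <= k <= max_size):
            skipped.append(name)
            continue
        es, max_pos, min_pos = _es_from_hits(scores, hit_idx)
        mask = np.zeros(n, dtype=bool)
        mask[hit_idx] = True
        leading[name] = extract_leading_edge(genes, mask, es, max_pos, min_pos)

        perm_es = np.empty(n_perm)
        for b in range(n_perm):
            ph = np.sort(rng.choice(n, size=k, replace=False))
            perm_es[b] = _es_from_hits(scores, ph)[0]
        same = perm_es >= 0 if es >= 0 else perm_es < 0
        n_same = int(same.sum())
        if n_same == 0:
            nes = np.nan
            p = 1.0 / (n_perm + 1)
        else:
            nes = es / np.abs(perm_es[same]).mean()
            p = (1 + int((np.abs(perm_es[same]) >= abs(es)).sum())) / (1 + n_same)
        rows.append({"set": name, "size": k, "es": es, "nes": nes, "p": p})

    table = pd.DataFrame(rows, columns=["set", "size", "es", "nes", "p"])
    if len(table):
        table["padj"] = benjamini_hochberg(table["p"].to_numpy())
    else:
        table["padj"] = []
    return GseaResult(table, leading, skipped)


# ---------------------------------------------------------------------------
# Leading-edge overlap graph
# ---------------------------------------------------------------------------

def overlap_fraction(le_a: list[str], le_b: list[str]) -> tuple[int, int, int]:
    """Overlap of leading edge A with B as ``(k, n, percent)``.

    ``k`` genes of the ``n`` in A also occur in B; percent is rounded to
    the nearest integer.  Undefined (flagged by :class:`DataError`) when A
    is empty.
    """
    if not le_a:
        raise DataError("overlap fraction undefined for an empty leading edge")
    k = len(set(le_a) & set(le_b))
    n = len(le_a)
    return k, n, int(round(100.0 * k / n))


@dataclass
class OverlapGraph:
    """Directed overlap percentages between leading edges plus components."""

    edges: pd.DataFrame       # source, target, k, n, percent, kept
    clusters: pd.DataFrame    # set, n_leading, cluster


def build_overlap_graph(
    result: GseaResult,
    direction: str = "up",
    weight_threshold: float = 25.0,
    fdr_threshold: float = 0.05,
) -> OverlapGraph:
    """Overlap graph over significant sets of one direction.

    Both directed weights are emitted for every ordered pair; an edge is
    *kept* (and contributes to clustering) when the percentage measured
    from the smaller leading edge reaches ``weight_threshold``.  Clusters
    are connected components of the kept edges; isolated sets form
    singleton clusters.
    """
    if direction not in ("up", "down"):
        raise DataError("direction must be 'up' or 'down'")
    tab = result.table
    sign = 1.0 if direction == "up" else -1.0
    keep = (tab["padj"] < fdr_threshold) & (np.sign(tab["es"]) == sign)
    names = [s for s in tab.loc[keep, "set"] if result.leading_edges.get(s)]

    edge_rows = []
    graph = nx.Graph()
    graph.add_nodes_from(names)
    for a in names:
        for b in names:
            if a == b:
                continue
            k, n, pct = overlap_fraction(
                result.leading_edges[a], result.leading_edges[b]
            )
            smaller_first = len(result.leading_edges[a]) <= len(
                result.leading_edges[b]
            )
            kept = smaller_first and pct >= weight_threshold
            if kept:
                graph.add_edge(a, b)
            edge_rows.append({
                "source": a, "target": b, "k": k, "n": n,
                "percent": pct, "label": f"{k}/{n} ({pct}%)", "kept": kept,
            })

    components = sorted(
        (sorted(c) for c in nx.connected_components(graph)),
        key=lambda c: (-len(c), c),
    )
    cluster_rows = []
    for ci, comp in enumerate(components, start=1):
        for name in comp:
            cluster_rows.append({
                "set": name,
                "n_leading": len(result.leading_edges[name]),
                "cluster": ci,
            })
    edges = pd.DataFrame(
        edge_rows,
        columns=["source", "target", "k", "n", "percent", "label", "kept"],
    )
    clusters = pd.DataFrame(cluster_rows, columns=["set", "n_leading", "cluster"])
    return OverlapGraph(edges, clusters)


def graph_clusters(graph: OverlapGraph) -> dict[str, int]:
    """Set → cluster id mapping from a built overlap graph."""
    return dict(zip(graph.clusters["set"], graph.clusters["cluster"]))
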