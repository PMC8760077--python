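"""Hit-interaction network construction and Fisher's exact over-representation.

In-repo replacement for the web-service steps of the original analysis: the
network is the subgraph induced by the hits on a supplied weighted edge list
at a confidence cutoff (default 0.7) with singletons removed, and gene-set
enrichment is a one-sided Fisher's exact test per set, filtered on
-log10(p) at an inclusive threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import math

import networkx as nx
import pandas as pd
from scipy import stats

from .errors import ValidationError


@dataclass(frozen=True)
class GeneSetResult:
    """Over-representation of one gene set among the hits."""

    set_name: str
    set_size: int
    overlap: int
    universe_size: int
    hit_count: int
    p_value: float

    def __post_init__(self) -> None:
        if self.overlap > min(self.set_size, self.hit_count):
            raise ValidationError(
                f"{self.set_name}: overlap {self.overlap} exceeds "
                f"min(set_size, hit_count)"
            )

    @property
    def neg_log10_p(self) -> float:
        return -math.log10(self.p_value) if self.p_value > 0 else math.inf


def build_network(
    hits: Iterable[str],
    edges: pd.DataFrame,
    cutoff: float = 0.7,
) -> nx.Graph:
    """Subgraph induced on ``hits``, keeping edges scoring at least ``cutoff``
    and dropping the nodes this leaves unconnected.

    ``edges`` is the frame produced by :func:`trapline.tables_io.read_edge_scores`
    (columns ``symbol_a, symbol_b, score`` on [0, 1]).  Node and edge order in
    the returned graph is deterministic (lexicographic) regardless of input
    row order.
    """
    if not (0.0 <= cutoff <= 1.0):
        raise ValidationError(f"cutoff must be in [0, 1], got {cutoff}")
    hit_set = {str(h).upper() for h in hits}
    graph = nx.Graph()
    kept = []
    for row in edges.itertuples(index=False):
        a, b, score = str(row[0]).upper(), str(row[1]).upper(), float(row[2])
        if a in hit_set and b in hit_set and a != b and score >= cutoff:
            key = (a, b) if a < b else (b, a)
            kept.append((*key, score))
    for a, b, score in sorted(kept):
        graph.add_edge(a, b, score=score)
    # adding edges in sorted order makes node insertion order deterministic,
    # and degree-0 nodes never enter the graph
    return graph


def graph_summary(graph: nx.Graph) -> dict:
    """JSON-friendly summary: node/edge counts and connected components."""
    components = sorted(
        (sorted(c) for c in nx.connected_components(graph)),
        key=lambda c: (-len(c), c),
    )
    return {
        "n_nodes": graph.number_of_nodes(),
        "n_edges": graph.number_of_edges(),
        "n_components": len(components),
        "components": components,
    }


def fisher_enrichment(
    hits: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str] | None = None,
) -> list[GeneSetResult]:
    """One-sided (over-representation) Fisher's exact test per gene set.

    The universe defaults to the union of all supplied set members; hits must
    be contained in it.  Sets are intersected with the universe before
    testing.  Results are sorted by p ascending, ties by set name.
    """
    sets = {name: {str(m).upper() for m in members}
            for name, members in gene_sets.items()}
    if universe is None:
        universe_set: set[str] = set()
        for members in sets.values():
            universe_set |= members
    else:
        universe_set = {str(u).upper() for u in universe}
    hit_set = {str(h).upper() for h in hits}
    outside = sorted(hit_set - universe_set)
    if outside:
        raise ValidationError(
            f"hit symbol(s) not in the universe: {', '.join(outside[:5])}"
            + ("..." if len(outside) > 5 else "")
        )

    n_universe = len(universe_set)
    n_hits = len(hit_set)
    results = []
    for name, members in sets.items():
        members = members & universe_set
        overlap = len(members & hit_set)
        table = [
            [overlap, n_hits - overlap],
            [len(members) - overlap, n_universe - n_hits - (len(members) - overlap)],
        ]
        _, p_value = stats.fisher_exact(table, alternative="greater")
        results.append(
            GeneSetResult(
                set_name=name,
                set_size=len(members),
                overlap=overlap,
                universe_size=n_universe,
                hit_count=n_hits,
                p_value=float(min(p_value, 1.0)),
            )
        )
    return sorted(results, key=lambda r: (r.p_value, r.set_name))


def filter_terms(
    results: Iterable[GeneSetResult],
    neg_log10_threshold: float = 1.3,
) -> list[GeneSetResult]:
    """Keep results whose -log10(p) is at least the threshold (inclusive).

    No multiple-testing adjustment is applied here; see
    :func:`benjamini_hochberg` for an optional FDR-based alternative.
    """
    if neg_log10_threshold < 0:
        raise ValidationError("neg_log10_threshold must be >= 0")
    return [r for r in results if r.neg_log10_p >= neg_log10_threshold]


def benjamini_hochberg(
    results: Iterable[GeneSetResult],
    alpha: float = 0.05,
) -> list[GeneSetResult]:
    """Optional FDR filter (off by default in the pipeline)."""
    ordered = sorted(results, key=lambda r: (r.p_value, r.set_name))
    m = len(ordered)
    kept_until = -1
    for i, r in enumerate(ordered):
        if r.p_value <= alpha * (i + 1) / m:
            kept_until = i
    return ordered[: kept_until + 1]


def results_frame(results: Iterable[GeneSetResult]) -> pd.DataFrame:
    rows = [
        (r.set_name, r.set_size, r.overlap, r.universe_size, r.hit_count,
         r.p_value, r.neg_log10_p)
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=["set_name", "set_size", "overlap", "universe_size",
                 "hit_count", "p_value", "neg_log10_p"],
    )
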