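"""Mechanistic causal network reconstruction over a PPI table.

Enriched phosphoproteins at each sampled time point (3, 6, 24 h by
convention) are expanded to their first-level interaction partners in a
STRING-style PPI graph; proteins are partitioned by which time points
they appear in (Venn regions, e.g. "remained enriched across 3, 6 and
24 h"); and a local hypergeometric over-representation test against GMT
gene-set libraries replaces a web enrichment service.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_gct import GeneSetLibrary, PpiGraph

#: "High confidence" STRING combined-score cutoff.
DEFAULT_MIN_CONFIDENCE = 700
DEFAULT_TIMEPOINTS = (3.0, 6.0, 24.0)


def expand_first_level(seeds: set[str], ppi: PpiGraph) -> nx.Graph:
    """First-level PPI neighborhood of the seed proteins.

    Nodes are the seeds plus their direct interaction partners; edges are
    every PPI edge with both endpoints inside that node set (so
    partner-partner links are kept).  Seeds carry ``seed=True``; a seed
    absent from the PPI stays as an isolated node with a warning.
    """
    if not seeds:
        raise ValueError("seed set is empty")
    known = ppi.proteins
    orphans = sorted(s for s in seeds if s not in known)
    if orphans:
        warnings.warn(f"seeds absent from the PPI graph: {orphans}", stacklevel=2)
    nodes = set(seeds)
    for s in seeds:
        nodes |= ppi.neighbors(s)
    g = nx.Graph()
    for n in nodes:
        g.add_node(n, seed=n in seeds)
    for (a, b), score in ppi.edges.items():
        if a in nodes and b in nodes:
            g.add_edge(a, b, combined_score=score)
    return g


@dataclass
class TimepointSets:
    """Per-time-point sets of enriched proteins."""

    sets: dict[float, set[str]]

    def __post_init__(self) -> None:
        if not self.sets:
            raise ValueError("need at least one time point")

    @property
    def timepoints(self) -> list[float]:
        return sorted(self.sets)


def timepoint_partition(
    sets: TimepointSets | dict[float, set[str]],
) -> tuple[dict[str, frozenset[float]], dict[frozenset[float], int]]:
    """Map every protein to its time-point membership signature.

    Returns (protein -> signature, signature -> count); signatures are the
    Venn regions, e.g. frozenset({3, 6, 24}) marks proteins that remained
    enriched across all three time points.  Region counts sum to the size
    of the union.
    """
    if isinstance(sets, TimepointSets):
        sets = sets.sets
    if not sets:
        raise ValueError("need at least one time point")
    signature: dict[str, frozenset[float]] = {}
    union: set[str] = set()
    for members in sets.values():
        union |= members
    for protein in union:
        signature[protein] = frozenset(t for t, members in sets.items() if protein in members)
    counts: dict[frozenset[float], int] = {}
    for sig in signature.values():
        counts[sig] = counts.get(sig, 0) + 1
    return signature, counts


@dataclass(frozen=True)
class EnrichmentResult:
    """One term of an over-representation analysis."""

    term: str
    overlap: int
    query_size: int
    set_size: int
    universe_size: int
    p_value: float
    q_value: float
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if self.overlap > min(self.query_size, self.set_size):
            raise ValueError("overlap exceeds query or set size")
        if not (0 <= self.p_value <= 1 and 0 <= self.q_value <= 1):
            raise ValueError("p and q must lie in [0, 1]")


def hypergeom_pvalue(overlap: int, universe: int, set_size: int, query: int) -> float:
    """Upper-tail hypergeometric P(X >= overlap): the chance of drawing at
    least this much of the term set in a random query of the same size."""
    return float(stats.hypergeom.sf(overlap - 1, universe, set_size, query))


def enrich(
    query: set[str],
    library: GeneSetLibrary,
    universe: set[str],
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of ``query`` in each library term.

    Library sets are intersected with the universe before testing; the
    query must be a subset of the universe (the universe choice dominates
    ORA p-values, so it is explicit).  q-values are Benjamini-Hochberg
    over all tested terms.  Results are sorted by p then term name.
    """
    if not query:
        raise ValueError("query gene set is empty")
    if not universe:
        raise ValueError("universe is empty")
    stray = query - universe
    if stray:
        raise ValueError(f"query genes outside the universe: {sorted(stray)}")
    rows = []
    for term, genes in library.sets.items():
        in_universe = genes & universe
        if not in_universe:
            continue
        hit = query & in_universe
        p = hypergeom_pvalue(len(hit), len(universe), len(in_universe), len(query))
        rows.append((term, hit, in_universe, p))
    if not rows:
        return []
    _, q_values, _, _ = multipletests([r[3] for r in rows], method="fdr_bh")
    results = [
        EnrichmentResult(
            term=term,
            overlap=len(hit),
            query_size=len(query),
            set_size=len(in_universe),
            universe_size=len(universe),
            p_value=float(p),
            q_value=float(max(q, p)),  # BH never reports q below p
            genes=frozenset(hit),
        )
        for (term, hit, in_universe, p), q in zip(rows, q_values)
    ]
    results.sort(key=lambda r: (r.p_value, r.term))
    return results
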