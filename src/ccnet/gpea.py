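"""Gene-pair enrichment analysis (GPEA) and gene-level hypergeometric tests.

GPEA asks whether a gene set contains more *network edges* among its members
than expected by chance.  For a network over ``p`` genes there are
``N = p(p-1)/2`` possible gene pairs; a term of ``p_GO`` genes contributes
``m_GO = p_GO(p_GO-1)/2`` of them.  If the network has ``n`` edges of which
``k`` join two term genes, the enrichment p-value is the upper tail
``P(X >= k)`` of a hypergeometric distribution drawing ``n`` pairs from the
``N`` with ``m_GO`` marked — i.e. edges play the role usually played by genes.

The conventional gene-level hypergeometric test (used for census-gene
enrichment and for annotating subnetworks) is provided alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from ccnet._util import log


class GeneSetCollection:
    """Named gene sets (GO-like terms or a census list).

    ``entries`` maps term id -> (description, set of gene ids).
    """

    def __init__(self, entries: dict[str, tuple[str, set[str]]]):
        for term, (_, genes) in entries.items():
            if not genes:
                raise ValueError(f"term {term!r} has an empty gene set")
        self.entries = {t: (d, set(g)) for t, (d, g) in entries.items()}

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def genes(self, term: str) -> set[str]:
        return self.entries[term][1]

    def description(self, term: str) -> str:
        return self.entries[term][0]

    def universe(self) -> set[str]:
        out: set[str] = set()
        for _, genes in self.entries.values():
            out |= genes
        return out


def _log_hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """log P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn).

    Summed directly over the upper tail in log space (log-gamma binomials +
    logsumexp), which is the shorter tail in every enrichment use.
    """
    upper = min(K, n)
    lower = max(0, K + n - N)
    if k <= lower:
        return 0.0
    i = np.arange(k, upper + 1)
    logpmf = (
        gammaln(K + 1) - gammaln(i + 1) - gammaln(K - i + 1)
        + gammaln(N - K + 1) - gammaln(n - i + 1) - gammaln(N - K - n + i + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )
    return float(min(0.0, logsumexp(logpmf)))


def gpea_pvalue(k: int, m_go: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric p-value over gene *pairs*.

    Parameters
    ----------
    k : observed edges among term genes.
    m_go : possible pairs within the term, ``p_GO (p_GO - 1) / 2``.
    n : total edges in the network.
    N : total possible pairs, ``p (p - 1) / 2``.
    """
    if not (0 <= k <= m_go <= N and 0 <= n <= N):
        raise ValueError(f"invalid GPEA arguments k={k} m_go={m_go} n={n} N={N}")
    if k > n:
        raise ValueError(f"observed k={k} exceeds the number of edges n={n}")
    return float(np.exp(_log_hypergeom_upper_tail(k, m_go, n, N)))


def gene_enrichment_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric p-value over *genes*.

    Population of ``N`` genes with ``K`` marked (e.g. census genes); a set of
    ``n`` genes containing ``k`` marked ones.
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValueError(f"invalid arguments k={k} K={K} n={n} N={N}")
    return float(np.exp(_log_hypergeom_upper_tail(k, K, n, N)))


@dataclass
class GPEAResult:
    """One tested gene set (an annotation term or a chromosome window)."""

    term_id: str
    description: str
    n_genes: int          # term genes present in the network
    m_go: int             # possible pairs within the term
    k: int                # observed within-term edges
    n: int                # total network edges
    N: int                # total possible pairs
    p_value: float
    p_adjusted: float = float("nan")
    gcc_size: int = 0     # giant component of the term-induced subnetwork
    census_count: int = 0
    census_enriched: bool = False


def _adjust(pvals: list[float], method: str) -> np.ndarray:
    if not pvals:
        return np.array([])
    mapped = {"bonferroni": "bonferroni", "bh": "fdr_bh"}[method]
    return multipletests(pvals, method=mapped)[1]


def run_gpea(
    net: nx.Graph,
    collection: GeneSetCollection,
    min_size: int = 3,
    max_size: int = 999,
    alpha: float = 0.001,
    correction: str = "bonferroni",
) -> list[GPEAResult]:
    """GPEA over every term of a collection against one network.

    Terms are restricted to genes present in the network before the size
    filter ``min_size <= size <= max_size`` is applied.  ``N`` and ``n``
    come from the network's full gene universe and edge count.  Results are
    sorted by raw p-value; ``p_adjusted`` uses the requested correction over
    the tested terms.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("network is empty")
    if correction not in ("bonferroni", "bh"):
        raise ValueError(f"unknown correction {correction!r}")
    nodes = set(net.nodes)
    p = len(nodes)
    N = p * (p - 1) // 2
    n = net.number_of_edges()
    results: list[GPEAResult] = []
    for term in sorted(collection):
        members = collection.genes(term) & nodes
        size = len(members)
        if not (min_size <= size <= max_size):
            continue
        sub = net.subgraph(members)
        k = sub.number_of_edges()
        m_go = size * (size - 1) // 2
        gcc = max((len(c) for c in nx.connected_components(sub)), default=0)
        results.append(
            GPEAResult(
                term_id=term,
                description=collection.description(term),
                n_genes=size,
                m_go=m_go,
                k=k,
                n=n,
                N=N,
                p_value=gpea_pvalue(k, m_go, n, N),
                gcc_size=gcc,
            )
        )
    if not results:
        log.warning("no terms left after size filtering; empty GPEA result")
        return []
    adjusted = _adjust([r.p_value for r in results], correction)
    for r, a in zip(results, adjusted):
        r.p_adjusted = float(a)
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results


def annotate_census(
    results: list[GPEAResult],
    collection: GeneSetCollection,
    census: set[str],
    universe: set[str],
    alpha: float = 0.05,
) -> list[GPEAResult]:
    """Add census-gene counts and BH-corrected enrichment flags in place.

    Census genes absent from the universe are dropped first (a genome-scale
    census list never maps fully onto one expression platform), so the
    effective number of marked genes is ``|census & universe|``.
    """
    eff_census = census & universe
    K, N = len(eff_census), len(universe)
    pvals = []
    for r in results:
        members = collection.genes(r.term_id) & universe
        r.census_count = len(members & eff_census)
        pvals.append(gene_enrichment_pvalue(r.census_count, K, len(members), N))
    if results:
        adjusted = _adjust(pvals, "bh")
        for r, a in zip(results, adjusted):
            r.census_enriched = bool(a < alpha)
    return results
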