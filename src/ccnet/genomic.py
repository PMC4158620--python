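"""Positional analyses: cis/trans edges, chromosome cooperativity, ECS, windows.

All operations consume a gene position table (one row per gene: chromosome
label, 1-based inclusive start/end) alongside an inferred network.

* cis/trans: an edge is *cis* when both endpoints sit on one chromosome and
  *trans* otherwise; edges with an unpositioned endpoint are "unmapped".
* cooperativity: for each chromosome pair (i, j) the observed number of
  edges s_ij joining them is compared with its distribution under gene-label
  randomization (positions permuted over genes, topology fixed), giving
  p_ij = #(s^e > s_ij) / E, BH-corrected over all (C^2 - C)/2 + C pairs.
* ensemble consensus sets (ECS): the multiset of per-edge ensemble consensus
  rates for each chromosome pair, summarised as per-chromosome means and the
  median of those means, separately for cis and trans.
* sliding windows: fixed-length windows stepped along each chromosome define
  positional gene sets that are tested with the pair-level GPEA statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ccnet._util import canonical_pair, log, rng_from
from ccnet.gpea import (
    GeneSetCollection,
    GPEAResult,
    gene_enrichment_pvalue,
    gpea_pvalue,
)
from ccnet.netstats import giant_connected_component


def _chrom_order(labels) -> list[str]:
    """Chromosome labels in genomic order: numerics ascending, then X, Y."""
    def key(c: str):
        return (0, int(c)) if str(c).isdigit() else (1, str(c))
    return sorted(set(map(str, labels)), key=key)


def classify_cis_trans(net: nx.Graph, pos: pd.DataFrame):
    """Label every edge cis / trans / unmapped and count them.

    Returns ``(cis_count, trans_count, labels)`` where ``labels`` maps the
    canonical edge tuple to its label.  Unmapped edges (an endpoint without
    a position) are excluded from both counts.
    """
    chrom = pos["chromosome"].astype(str)
    labels: dict[tuple[str, str], str] = {}
    cis = trans = 0
    for u, v in net.edges:
        e = canonical_pair(u, v)
        if u not in chrom.index or v not in chrom.index:
            labels[e] = "unmapped"
        elif chrom[u] == chrom[v]:
            labels[e] = "cis"
            cis += 1
        else:
            labels[e] = "trans"
            trans += 1
    return cis, trans, labels


def _edge_chrom_indices(net: nx.Graph, pos: pd.DataFrame):
    """Positioned-node index arrays for vectorised counting.

    Returns (chrom_labels, node_chrom_idx, edge_u_idx, edge_v_idx, nodes).
    """
    chrom = pos["chromosome"].astype(str)
    nodes = sorted(set(net.nodes) & set(chrom.index))
    node_pos = {g: i for i, g in enumerate(nodes)}
    chroms = _chrom_order(chrom.loc[nodes]) if nodes else []
    cidx = {c: i for i, c in enumerate(chroms)}
    node_chrom = np.array([cidx[chrom[g]] for g in nodes], dtype=np.int64)
    eu, ev = [], []
    for u, v in net.edges:
        if u in node_pos and v in node_pos:
            eu.append(node_pos[u])
            ev.append(node_pos[v])
    return chroms, node_chrom, np.array(eu, dtype=np.int64), np.array(ev, dtype=np.int64), nodes


def _count_matrix(node_chrom: np.ndarray, eu: np.ndarray, ev: np.ndarray, C: int) -> np.ndarray:
    """Symmetric s_ij from edge endpoint chromosome indices (diagonal once)."""
    c1 = node_chrom[eu]
    c2 = node_chrom[ev]
    lo = np.minimum(c1, c2)
    hi = np.maximum(c1, c2)
    flat = np.bincount(lo * C + hi, minlength=C * C).reshape(C, C)
    return flat + np.triu(flat, 1).T


def chromosome_interaction_counts(net: nx.Graph, pos: pd.DataFrame) -> pd.DataFrame:
    """Observed edge counts s_ij per chromosome pair (symmetric matrix).

    The diagonal counts intra-chromosome edges once; the matrix total over
    unordered pairs (including the diagonal) equals the number of edges with
    both endpoints positioned.
    """
    chroms, node_chrom, eu, ev, _ = _edge_chrom_indices(net, pos)
    if not chroms:
        return pd.DataFrame()
    s = _count_matrix(node_chrom, eu, ev, len(chroms))
    return pd.DataFrame(s, index=chroms, columns=chroms)


@dataclass
class CooperativityResult:
    """Permutation test of edge counts between chromosome pairs."""

    s: pd.DataFrame             # observed counts
    p_values: pd.DataFrame      # raw permutation p per pair
    p_adjusted: pd.DataFrame    # BH over all tested pairs
    E: int                      # number of randomizations
    n_tests: int

    def significant_pairs(self, alpha: float = 0.05) -> list[tuple[str, str, float]]:
        out = []
        chroms = list(self.s.index)
        for i, a in enumerate(chroms):
            for b in chroms[i:]:
                padj = float(self.p_adjusted.loc[a, b])
                if padj < alpha:
                    out.append((a, b, padj))
        return sorted(out, key=lambda t: t[2])


def cooperativity_test(
    net: nx.Graph,
    pos: pd.DataFrame,
    E: int = 100_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> CooperativityResult:
    """Gene-label permutation test for chromosome cooperativity.

    Each randomization permutes the gene -> position assignment over all
    positioned network genes while keeping the topology fixed, which
    conserves the total number of edges, the degree structure, and the
    uneven gene counts per chromosome.  The p-value for pair (i, j) is the
    fraction of randomizations with ``s^e_ij > s_ij`` (strict inequality, so
    an observation above every randomization gets p = 0).
    """
    if E < 1:
        raise ValueError("E must be >= 1")
    chroms, node_chrom, eu, ev, _ = _edge_chrom_indices(net, pos)
    if not chroms:
        raise ValueError("no positioned network genes")
    C = len(chroms)
    s = _count_matrix(node_chrom, eu, ev, C)
    rng = rng_from(np.random.SeedSequence([seed, 0xC0]))
    exceed = np.zeros((C, C), dtype=np.int64)
    for _ in range(E):
        perm = rng.permutation(node_chrom)
        se = _count_matrix(perm, eu, ev, C)
        exceed += se > s
    pmat = exceed / E
    iu = np.triu_indices(C)
    adj = multipletests(pmat[iu], method="fdr_bh")[1]
    padj = np.ones((C, C))
    padj[iu] = adj
    padj = np.minimum(padj, padj.T)
    n_tests = (C * C - C) // 2 + C
    return CooperativityResult(
        s=pd.DataFrame(s, index=chroms, columns=chroms),
        p_values=pd.DataFrame(np.minimum(pmat, pmat.T), index=chroms, columns=chroms),
        p_adjusted=pd.DataFrame(padj, index=chroms, columns=chroms),
        E=E,
        n_tests=n_tests,
    )


def ecs_sets(edge_stats: pd.DataFrame, pos: pd.DataFrame) -> dict[tuple[str, str], list[float]]:
    """Ensemble consensus sets: ECR values per unordered chromosome pair.

    ``edge_stats`` is indexed by (gene_a, gene_b) with an ``ecr`` column.
    Every unordered pair over the chromosomes present in ``pos`` appears in
    the result (possibly empty), so C chromosomes yield C cis sets and
    C (C - 1) / 2 trans sets.  Edges with an unpositioned endpoint are
    skipped.
    """
    chrom = pos["chromosome"].astype(str)
    chroms = _chrom_order(chrom)
    sets: dict[tuple[str, str], list[float]] = {}
    for i, a in enumerate(chroms):
        for b in chroms[i:]:
            sets[(a, b)] = []
    for (u, v), row in edge_stats.iterrows():
        if u not in chrom.index or v not in chrom.index:
            continue
        a, b = sorted((chrom[u], chrom[v]), key=lambda c: chroms.index(c))
        sets[(a, b)].append(float(row["ecr"]))
    return sets


@dataclass
class ECSSummary:
    per_pair_mean: pd.DataFrame      # mean ECR per chromosome pair (NaN if empty)
    per_pair_median: pd.DataFrame
    cis_means: pd.Series             # mean of ECS(m, m) per chromosome m
    trans_means: pd.Series           # mean of the integrated trans set per chromosome
    cis_median_of_means: float
    trans_median_of_means: float
    n_cis_sets: int = 0
    n_trans_sets: int = 0


def ecs_summary(sets: dict[tuple[str, str], list[float]]) -> ECSSummary:
    """Summarise ECS sets as per-chromosome means and their medians.

    The cis statistic is the median, over chromosomes, of the mean ECR of
    each diagonal set ECS(m, m).  The trans statistic pools, for each
    chromosome n, the ECR values of all off-diagonal sets involving n
    (the integrated trans set) and takes the median of those per-chromosome
    means.  Empty sets are reported as missing, never as zero.
    """
    chroms = _chrom_order({c for pair in sets for c in pair})
    mean = pd.DataFrame(np.nan, index=chroms, columns=chroms)
    med = pd.DataFrame(np.nan, index=chroms, columns=chroms)
    for (a, b), vals in sets.items():
        if vals:
            mean.loc[a, b] = mean.loc[b, a] = float(np.mean(vals))
            med.loc[a, b] = med.loc[b, a] = float(np.median(vals))
    cis_means = pd.Series(
        {m: (np.mean(sets[(m, m)]) if sets.get((m, m)) else np.nan) for m in chroms},
        name="cis_mean_ecr",
    )
    trans_means = {}
    for n in chroms:
        pooled: list[float] = []
        for m in chroms:
            if m == n:
                continue
            pooled.extend(sets.get((min(m, n, key=chroms.index), max(m, n, key=chroms.index)), []))
        trans_means[n] = float(np.mean(pooled)) if pooled else np.nan
    trans_means = pd.Series(trans_means, name="trans_mean_ecr")
    return ECSSummary(
        per_pair_mean=mean,
        per_pair_median=med,
        cis_means=cis_means,
        trans_means=trans_means,
        cis_median_of_means=float(np.nanmedian(cis_means.values))
        if cis_means.notna().any()
        else float("nan"),
        trans_median_of_means=float(np.nanmedian(trans_means.values))
        if trans_means.notna().any()
        else float("nan"),
        n_cis_sets=len(chroms),
        n_trans_sets=len(chroms) * (len(chroms) - 1) // 2,
    )


@dataclass
class Window:
    """One sliding-window interval, 1-based inclusive coordinates."""

    chromosome: str
    start: int
    end: int
    genes: set[str] = field(default_factory=set)


def make_windows(chrom_lengths: dict[str, int], window: int = 1_000_000, step: int = 500_000) -> list[Window]:
    """Tile each chromosome with overlapping windows.

    Starts run 1, 1+step, 1+2*step, ... while the start lies on the
    chromosome; each window spans ``[start, start + window - 1]`` clipped at
    the chromosome end, so consecutive full windows overlap by
    ``window - step`` bp and terminal windows may be shorter.
    """
    if step < 1 or window < step:
        raise ValueError("need window >= step >= 1")
    out = []
    for c in _chrom_order(chrom_lengths):
        length = int(chrom_lengths[c])
        start = 1
        while start <= length:
            out.append(Window(chromosome=c, start=start, end=min(start + window - 1, length)))
            start += step
    return out


def assign_window_genes(
    windows: list[Window], pos: pd.DataFrame, genes=None, anchor: str = "start"
) -> list[Window]:
    """Populate each window with the genes whose anchor coordinate it contains.

    ``anchor`` is the gene's start (default) or midpoint; a single anchor per
    gene avoids double counting genes straddling a window boundary.  If
    ``genes`` is given, only those (e.g. network genes) are assigned.
    """
    if anchor not in ("start", "midpoint"):
        raise ValueError(f"unknown anchor {anchor!r}")
    table = pos if genes is None else pos.loc[pos.index.intersection(set(genes))]
    coord = (
        table["start"]
        if anchor == "start"
        else ((table["start"] + table["end"]) // 2)
    ).astype(int)
    chrom = table["chromosome"].astype(str)
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for g in table.index:
        by_chrom.setdefault(chrom[g], []).append((int(coord[g]), g))
    for w in windows:
        w.genes = {
            g for c, g in by_chrom.get(w.chromosome, []) if w.start <= c <= w.end
        }
    return windows


def window_gpea(
    net: nx.Graph,
    pos: pd.DataFrame,
    windows: list[Window],
    min_genes: int = 2,
    alpha: float = 0.001,
    anchor: str = "start",
    gcc_flag_threshold: int = 10,
    collection: GeneSetCollection | None = None,
    annotation_alpha: float = 0.05,
) -> pd.DataFrame:
    """Pair-level GPEA for sliding-window positional gene sets.

    Each window containing at least ``min_genes`` network genes is tested
    with the GPEA statistic against the whole network's pair universe, with
    Bonferroni correction over the tested windows.  The giant component of
    every window subnetwork is reported; windows whose GCC reaches
    ``gcc_flag_threshold`` genes are flagged and, when a term collection is
    supplied, annotated with the most significant gene-level hypergeometric
    term over the GCC genes (BH at ``annotation_alpha``).
    """
    if min_genes < 2:
        raise ValueError("min_genes must be >= 2")
    nodes = set(net.nodes)
    p = len(nodes)
    N = p * (p - 1) // 2
    n = net.number_of_edges()
    windows = assign_window_genes(windows, pos, genes=nodes, anchor=anchor)
    rows = []
    for w in windows:
        if len(w.genes) < min_genes:
            continue
        sub = net.subgraph(w.genes)
        size = len(w.genes)
        k = sub.number_of_edges()
        gcc = giant_connected_component(sub)
        rows.append(
            {
                "chromosome": w.chromosome,
                "start": w.start,
                "end": w.end,
                "n_genes": size,
                "n_edges": k,
                "p_value": gpea_pvalue(k, size * (size - 1) // 2, n, N),
                "gcc_size": gcc.number_of_nodes(),
                "gcc_genes": ",".join(sorted(gcc.nodes)),
            }
        )
    if not rows:
        log.warning("no window holds %d network genes; empty result", min_genes)
        return pd.DataFrame(
            columns=["chromosome", "start", "end", "n_genes", "n_edges",
                     "p_value", "p_adjusted", "significant", "gcc_size",
                     "gcc_flagged", "top_term", "top_term_p_adjusted"]
        )
    frame = pd.DataFrame(rows)
    frame["p_adjusted"] = np.minimum(frame["p_value"] * len(frame), 1.0)  # Bonferroni
    frame["significant"] = frame["p_adjusted"] < alpha
    frame["gcc_flagged"] = frame["gcc_size"] >= gcc_flag_threshold
    frame["top_term"] = ""
    frame["top_term_p_adjusted"] = np.nan
    if collection is not None:
        universe = nodes
        terms = sorted(collection)
        term_sets = {t: collection.genes(t) & universe for t in terms}
        for i in frame.index[frame["gcc_flagged"]]:
            gcc_genes = set(frame.at[i, "gcc_genes"].split(","))
            pvals = [
                gene_enrichment_pvalue(
                    len(gcc_genes & term_sets[t]), len(term_sets[t]),
                    len(gcc_genes), len(universe),
                )
                if term_sets[t]
                else 1.0
                for t in terms
            ]
            if not terms:
                continue
            adj = multipletests(pvals, method="fdr_bh")[1]
            best = int(np.argmin(adj))
            if adj[best] < annotation_alpha:
                frame.at[i, "top_term"] = terms[best]
                frame.at[i, "top_term_p_adjusted"] = float(adj[best])
    frame = frame.drop(columns=["gcc_genes"])
    return frame.sort_values(["p_value", "chromosome", "start"]).reset_index(drop=True)
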