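"""C3Net / BC3Net mutual-information network inference.

C3Net keeps, for every gene, only the single most informative partner whose
mutual information (MI) passes a significance screen; the union of those
picks, as unordered pairs, is the inferred network.  BC3Net bags C3Net over
``B`` non-parametric bootstrap resamples of the samples, aggregates the edge
occurrence counts, and keeps the edges whose counts are larger than expected
under a binomial null.  The fraction of bootstrap networks containing an
edge is its ensemble consensus rate (ECR).

MI is estimated under a Gaussian model, ``MI = -0.5 * ln(1 - rho^2)``, with
``rho`` the Pearson (default) or Spearman correlation; this closed form has
analytic oracles and is monotone in |rho|.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from ccnet._util import canonical_pair, log, rng_from

RHO_CEILING = 1.0 - 1e-12  # |rho| clamp so MI stays finite on degenerate data


def _correlation(values: np.ndarray, estimator: str) -> np.ndarray:
    """Gene x gene correlation matrix; zero-variance genes get zero rows."""
    if estimator == "spearman_gaussian":
        values = np.apply_along_axis(scipy.stats.rankdata, 1, values)
    sd = values.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        log.warning("%d zero-variance genes; their MI rows are set to 0", degenerate.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(values)
    rho[degenerate, :] = 0.0
    rho[:, degenerate] = 0.0
    return np.nan_to_num(rho, nan=0.0)


def mi_matrix(expr: pd.DataFrame, estimator: str = "pearson_gaussian") -> pd.DataFrame:
    """Pairwise Gaussian MI matrix, symmetric with a zero diagonal.

    Parameters
    ----------
    expr : genes x samples expression frame (>= 3 samples).
    estimator : ``pearson_gaussian`` or ``spearman_gaussian``.
    """
    if estimator not in ("pearson_gaussian", "spearman_gaussian"):
        raise ValueError(f"unknown estimator {estimator!r}")
    if expr.shape[1] < 3:
        raise ValueError("MI estimation needs at least 3 samples")
    if expr.index.has_duplicates:
        raise ValueError("duplicate gene ids in expression matrix")
    rho = _correlation(np.asarray(expr, dtype=float), estimator)
    rho = np.clip(rho, -RHO_CEILING, RHO_CEILING)
    mi = -0.5 * np.log1p(-(rho**2))
    np.fill_diagonal(mi, 0.0)
    return pd.DataFrame(mi, index=expr.index, columns=expr.index)


def mi_null_threshold(
    expr: pd.DataFrame,
    n_permutations: int = 10,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
    estimator: str = "pearson_gaussian",
) -> float:
    """Empirical MI significance cutoff from per-gene sample permutations.

    Each permutation independently shuffles every gene's sample order,
    destroying all gene-gene dependence while keeping marginals; the
    ``1 - alpha`` quantile of the pooled off-diagonal null MI values is the
    screen used by the C3Net step.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else rng_from(seed)
    values = np.asarray(expr, dtype=float)
    g = values.shape[0]
    iu = np.triu_indices(g, k=1)
    pool = []
    for _ in range(n_permutations):
        permuted = np.array([row[rng.permutation(values.shape[1])] for row in values])
        rho = np.clip(_correlation(permuted, estimator), -RHO_CEILING, RHO_CEILING)
        pool.append((-0.5 * np.log1p(-(rho**2)))[iu])
    return float(np.quantile(np.concatenate(pool), 1.0 - alpha))


def c3net(mi: pd.DataFrame, threshold: float) -> nx.Graph:
    """Keep each gene's single highest-MI partner above ``threshold``.

    Ties in the row maximum are broken by the lexicographically smallest
    partner id, so the result is independent of input order.  Genes whose
    maximal MI does not exceed the threshold stay isolated.
    """
    genes = list(mi.index)
    m = np.asarray(mi, dtype=float)
    if m.shape[0] != m.shape[1] or not np.allclose(m, m.T):
        raise ValueError("MI matrix must be square and symmetric")
    g = nx.Graph()
    g.add_nodes_from(genes)
    order = np.argsort(genes)  # positions sorted by gene id for tie-breaking
    np.fill_diagonal(m, -np.inf)
    for i, gene in enumerate(genes):
        best = m[i].max()
        if best <= threshold or not np.isfinite(best):
            continue
        # smallest partner id among the argmax ties
        ties = np.flatnonzero(m[i] == best)
        partner = genes[min(ties, key=lambda j: genes[j])]
        g.add_edge(*canonical_pair(gene, partner))
    return g


@dataclass
class BootstrapEnsemble:
    """Edge occurrence counts over ``B`` bootstrap C3Net networks."""

    B: int
    edge_counts: Counter

    def ecr(self, u: str, v: str) -> float:
        return self.edge_counts[canonical_pair(u, v)] / self.B


def binomial_edge_test(count: int, B: int, p0: float) -> float:
    """One-sided upper-tail binomial p-value ``P(X >= count)``, X~Bin(B, p0)."""
    if not 0 <= count <= B:
        raise ValueError(f"count must be in [0, B]; got {count}, B={B}")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must be in (0, 1)")
    return float(scipy.stats.binom.sf(count - 1, B, p0))


def bc3net(
    expr: pd.DataFrame,
    B: int = 100,
    alpha_mi: float = 0.05,
    alpha_edge: float = 0.05,
    seed: int = 0,
    n_permutations: int | None = None,
    estimator: str = "pearson_gaussian",
    p0: float | None = None,
) -> tuple[nx.Graph, pd.DataFrame, BootstrapEnsemble]:
    """Bagged C3Net with a binomial significance test on edge counts.

    For each of ``B`` bootstrap resamples of the samples (columns), infer a
    C3Net network with its own permutation-based MI screen; count how often
    every edge occurs; test each observed edge against Binomial(B, p0) and
    keep those with BH-adjusted p below ``alpha_edge``.

    ``p0`` defaults to the mean number of edges per ensemble network divided
    by the number of possible pairs — the chance a random pair is hit if
    edges were thrown uniformly.  ``n_permutations`` defaults to enough
    permutations for a null pool of at least 1e5 MI values.

    Returns
    -------
    (network, edge_stats, ensemble) where ``edge_stats`` is a frame indexed
    by canonical gene pair with columns count, ecr, p_value, p_adjusted, and
    the network's edges carry the same attributes.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    genes = list(expr.index)
    p = len(genes)
    n_pairs = p * (p - 1) // 2
    if n_permutations is None:
        n_permutations = max(1, int(np.ceil(1e5 / max(n_pairs, 1))))
    rng = rng_from(np.random.SeedSequence([seed, 0xB3]))
    n_samples = expr.shape[1]
    counts: Counter = Counter()
    for _ in range(B):
        cols = rng.integers(0, n_samples, size=n_samples)
        boot = pd.DataFrame(np.asarray(expr)[:, cols], index=expr.index)
        mi = mi_matrix(boot, estimator)
        thr = mi_null_threshold(boot, n_permutations, alpha_mi, rng, estimator)
        counts.update(canonical_pair(u, v) for u, v in c3net(mi, thr).edges)
    ensemble = BootstrapEnsemble(B=B, edge_counts=Counter(dict(counts)))
    if not counts:
        log.warning("aggregate network is empty")
        empty = nx.Graph()
        empty.add_nodes_from(genes)
        return empty, _edge_frame({}), ensemble
    if p0 is None:
        p0 = (sum(counts.values()) / B) / n_pairs
        p0 = min(max(p0, 1e-12), 1.0 - 1e-12)
    pairs = sorted(counts)
    pvals = np.array([binomial_edge_test(counts[e], B, p0) for e in pairs])
    adjusted = multipletests(pvals, method="fdr_bh")[1]
    net = nx.Graph()
    net.add_nodes_from(genes)
    stats = {}
    for e, pv, pa in zip(pairs, pvals, adjusted):
        row = {
            "count": counts[e],
            "ecr": counts[e] / B,
            "p_value": float(pv),
            "p_adjusted": float(pa),
        }
        stats[e] = row
        if pa < alpha_edge:
            net.add_edge(*e, **row)
    kept = {e: stats[e] for e in net.edges}
    return net, _edge_frame({canonical_pair(*e): kept[canonical_pair(*e)] for e in net.edges}), ensemble


def _edge_frame(stats: dict[tuple[str, str], dict]) -> pd.DataFrame:
    idx = pd.MultiIndex.from_tuples(sorted(stats), names=["gene_a", "gene_b"]) if stats else (
        pd.MultiIndex.from_arrays([[], []], names=["gene_a", "gene_b"])
    )
    frame = pd.DataFrame(
        [stats[e] for e in sorted(stats)] if stats else [],
        index=idx,
        columns=["count", "ecr", "p_value", "p_adjusted"],
    )
    frame["count"] = frame["count"].astype(int) if len(frame) else frame["count"]
    return frame
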