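"""Synthetic ground truth: scale-free networks, gene positions, expression.

The generator emulates the statistical structure the downstream analyses
assume about real transcriptome data:

* a scale-free ground-truth regulatory network (preferential attachment);
* gene positions on 24 chromosomes with a tunable excess of co-located
  (cis) true interactions;
* expression sampled from a Gaussian graphical model whose precision matrix
  carries one off-diagonal entry per true edge, so true partners are
  partially correlated and everything else is conditionally independent;
* annotation terms that are either dense network neighborhoods ("module"
  terms, enriched for edges) or uniform gene draws ("random" terms), plus a
  census-style list of flagged genes.

Everything is deterministic given ``SimulationConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.linalg

from ccnet._util import canonical_pair, rng_from
from ccnet.gpea import GeneSetCollection

# GRCh37 chromosome lengths (bp), chr1..22, X, Y; used proportionally when a
# config asks for fewer than 24 chromosomes.
HUMAN_CHROM_LENGTHS = {
    "1": 249_250_621, "2": 243_199_373, "3": 198_022_430, "4": 191_154_276,
    "5": 180_915_260, "6": 171_115_067, "7": 159_138_663, "8": 146_364_022,
    "9": 141_213_431, "10": 135_534_747, "11": 135_006_516, "12": 133_851_895,
    "13": 115_169_878, "14": 107_349_540, "15": 102_531_392, "16": 90_354_753,
    "17": 81_195_210, "18": 78_077_248, "19": 59_128_983, "20": 63_025_520,
    "21": 48_129_895, "22": 51_304_566, "X": 155_270_560, "Y": 59_373_566,
}

GENE_LENGTH = 10_000  # nominal gene footprint in bp


class InvalidConfigError(ValueError):
    """Raised when a SimulationConfig violates its invariants."""


def _default_chrom_lengths(n_chromosomes: int) -> dict[str, int]:
    labels = list(HUMAN_CHROM_LENGTHS)[:n_chromosomes]
    return {c: HUMAN_CHROM_LENGTHS[c] for c in labels}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults describe a desk-scale analogue of a large tumour expression
    study: a few hundred genes on 24 human-proportioned chromosomes, a few
    hundred samples, a moderate per-edge partial correlation, and a modest
    excess of co-located true interactions (so roughly a fifth of true edges
    end up cis, as observed in genome-scale co-expression networks).
    """

    n_genes: int = 300
    n_samples: int = 200
    n_chromosomes: int = 24
    chromosome_lengths: dict[str, int] | None = None
    powerlaw_attachment: float = 1.0
    colocation_prob: float = 0.2
    colocation_span: int = 1_000_000
    edge_partial_corr: float = 0.3
    n_terms: int = 100
    term_size_range: tuple[int, int] = (5, 50)
    term_module_prob: float = 0.5
    n_census: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_samples <= 0:
            raise InvalidConfigError("n_genes and n_samples must be positive")
        if not 1 <= self.n_chromosomes <= 24:
            raise InvalidConfigError("n_chromosomes must be in [1, 24]")
        for p, name in [
            (self.colocation_prob, "colocation_prob"),
            (self.term_module_prob, "term_module_prob"),
        ]:
            if not 0.0 <= p <= 1.0:
                raise InvalidConfigError(f"{name} must be in [0, 1]")
        if self.powerlaw_attachment <= 0:
            raise InvalidConfigError("powerlaw_attachment must be positive")
        if not 0.0 <= self.edge_partial_corr < 1.0:
            raise InvalidConfigError("edge_partial_corr must be in [0, 1)")
        lo, hi = self.term_size_range
        if lo < 3 or hi < lo:
            raise InvalidConfigError("term_size_range must satisfy 3 <= lo <= hi")
        if self.n_terms < 0 or self.n_census < 0:
            raise InvalidConfigError("n_terms and n_census must be non-negative")
        if self.chromosome_lengths is None:
            self.chromosome_lengths = _default_chrom_lengths(self.n_chromosomes)
        if any(v <= 0 for v in self.chromosome_lengths.values()):
            raise InvalidConfigError("chromosome lengths must be positive")

    def gene_ids(self) -> list[str]:
        width = max(4, len(str(self.n_genes)))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]


@dataclass
class GroundTruth:
    """Bundle of everything the generator knows about one synthetic study."""

    true_network: nx.Graph
    positions: pd.DataFrame
    term_collection: GeneSetCollection
    census_genes: set[str]
    config: SimulationConfig
    term_modes: dict[str, str] = field(default_factory=dict)


def generate_truth_network(config: SimulationConfig) -> nx.Graph:
    """Grow a scale-free graph by preferential attachment (one edge per node).

    Each new node attaches to an existing node with probability proportional
    to ``degree + (powerlaw_attachment - 1)``; attachment strength 1 is pure
    linear preferential attachment (degree-distribution tail exponent near 3),
    larger values flatten the attachment kernel and steepen the tail.
    """
    if config.n_genes < 10:
        raise InvalidConfigError("need at least 10 genes for a truth network")
    rng = rng_from(np.random.SeedSequence([config.seed, 0x6E65]))
    genes = config.gene_ids()
    n = config.n_genes
    shift = config.powerlaw_attachment - 1.0
    deg = np.zeros(n)
    g = nx.Graph()
    g.add_nodes_from(genes)
    g.add_edge(genes[0], genes[1])
    deg[0] = deg[1] = 1.0
    for i in range(2, n):
        w = deg[:i] + shift
        w = np.clip(w, 1e-12, None)
        j = rng.choice(i, p=w / w.sum())
        g.add_edge(genes[i], genes[j])
        deg[i] += 1.0
        deg[j] += 1.0
    return g


def assign_positions(network: nx.Graph, config: SimulationConfig) -> pd.DataFrame:
    """Place every gene on a chromosome; co-locate a fraction of true edges.

    Genes are first placed uniformly (chromosome chosen proportionally to its
    length, start uniform along it).  Then, independently with probability
    ``colocation_prob``, each true edge pulls its second endpoint onto the
    first endpoint's chromosome within ``colocation_span`` bp, creating the
    cis-enrichment the positional analyses look for.  Coordinates are 1-based
    inclusive with ``start < end <= chromosome length``.
    """
    rng = rng_from(np.random.SeedSequence([config.seed, 0x706F]))
    lengths = config.chromosome_lengths
    chroms = list(lengths)
    total = sum(lengths.values())
    if config.n_genes * GENE_LENGTH > total:
        raise InvalidConfigError(
            f"{config.n_genes} genes of {GENE_LENGTH} bp exceed the "
            f"{total} bp of placeable span"
        )
    probs = np.array([lengths[c] for c in chroms], dtype=float) / total
    genes = sorted(network.nodes)
    chrom_of: dict[str, str] = {}
    start_of: dict[str, int] = {}
    for gene in genes:
        c = chroms[rng.choice(len(chroms), p=probs)]
        chrom_of[gene] = c
        start_of[gene] = int(rng.integers(1, lengths[c] - GENE_LENGTH + 2))
    for u, v in sorted(canonical_pair(a, b) for a, b in network.edges):
        if rng.random() < config.colocation_prob:
            c = chrom_of[u]
            lo = max(1, start_of[u] - config.colocation_span)
            hi = min(lengths[c] - GENE_LENGTH + 1, start_of[u] + config.colocation_span)
            chrom_of[v] = c
            start_of[v] = int(rng.integers(lo, hi + 1))
    return pd.DataFrame(
        {
            "chromosome": [chrom_of[g] for g in genes],
            "start": [start_of[g] for g in genes],
            "end": [start_of[g] + GENE_LENGTH - 1 for g in genes],
        },
        index=pd.Index(genes, name="gene"),
    )


def sample_expression(truth: GroundTruth, config: SimulationConfig | None = None) -> pd.DataFrame:
    """Draw a genes x samples matrix from the truth's Gaussian graphical model.

    The precision matrix has ``-edge_partial_corr`` at every true edge and a
    diagonally dominant diagonal ``1 + edge_partial_corr * degree``, which
    guarantees positive definiteness for any graph.
    """
    config = config or truth.config
    rng = rng_from(np.random.SeedSequence([config.seed, 0x6578]))
    genes = sorted(truth.true_network.nodes)
    idx = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    rho = config.edge_partial_corr
    omega = np.zeros((n, n))
    for u, v in truth.true_network.edges:
        omega[idx[u], idx[v]] = -rho
        omega[idx[v], idx[u]] = -rho
    deg = np.array([truth.true_network.degree[g] for g in genes], dtype=float)
    np.fill_diagonal(omega, 1.0 + rho * deg)
    # x = L^{-T} z has covariance Omega^{-1} when Omega = L L^T
    chol = scipy.linalg.cholesky(omega, lower=True)
    z = rng.standard_normal((n, config.n_samples))
    values = scipy.linalg.solve_triangular(chol, z, lower=True, trans="T")
    samples = [f"S{j:04d}" for j in range(1, config.n_samples + 1)]
    return pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples)


def _module_term(g: nx.Graph, size: int, rng: np.random.Generator) -> set[str]:
    """Breadth-first neighborhood of ``size`` genes around a random start."""
    genes = sorted(g.nodes)
    picked: set[str] = set()
    frontier: list[str] = []
    while len(picked) < size:
        if not frontier:
            remaining = [x for x in genes if x not in picked]
            frontier = [remaining[rng.integers(len(remaining))]]
        node = frontier.pop(0)
        if node in picked:
            continue
        picked.add(node)
        frontier.extend(sorted(set(g.neighbors(node)) - picked))
    return picked


def generate_gene_sets(
    truth: GroundTruth, config: SimulationConfig | None = None
) -> tuple[GeneSetCollection, dict[str, str]]:
    """Create annotation terms; returns (collection, term -> mode map).

    "module" terms (probability ``term_module_prob``) are breadth-first
    neighborhoods of the true network and therefore edge-dense; "random"
    terms are uniform draws from the gene universe.  The mode map exists for
    test oracles only and is never serialised.
    """
    config = config or truth.config
    rng = rng_from(np.random.SeedSequence([config.seed, 0x7465]))
    genes = sorted(truth.true_network.nodes)
    lo, hi = config.term_size_range
    if hi > len(genes):
        raise InvalidConfigError("term_size_range exceeds the gene universe")
    entries: dict[str, tuple[str, set[str]]] = {}
    modes: dict[str, str] = {}
    width = max(3, len(str(config.n_terms)))
    for t in range(1, config.n_terms + 1):
        size = int(rng.integers(lo, hi + 1))
        if rng.random() < config.term_module_prob:
            mode = "module"
            members = _module_term(truth.true_network, size, rng)
        else:
            mode = "random"
            members = set(rng.choice(genes, size=size, replace=False))
        term = f"T{t:0{width}d}"
        entries[term] = (f"synthetic term {t}", members)
        modes[term] = mode
    return GeneSetCollection(entries), modes


def generate_census(truth: GroundTruth, config: SimulationConfig | None = None) -> set[str]:
    """Uniformly flag ``n_census`` genes as a census-style cancer gene list."""
    config = config or truth.config
    rng = rng_from(np.random.SeedSequence([config.seed, 0x6367]))
    genes = sorted(truth.true_network.nodes)
    k = min(config.n_census, len(genes))
    return set(rng.choice(genes, size=k, replace=False))


def simulate(config: SimulationConfig) -> GroundTruth:
    """Generate the full ground truth for one synthetic study."""
    net = generate_truth_network(config)
    positions = assign_positions(net, config)
    truth = GroundTruth(
        true_network=net,
        positions=positions,
        term_collection=GeneSetCollection({}),
        census_genes=set(),
        config=config,
    )
    truth.term_collection, truth.term_modes = generate_gene_sets(truth, config)
    truth.census_genes = generate_census(truth, config)
    return truth
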