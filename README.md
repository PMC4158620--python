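# ccnet — regulatory-network inference and chromosomal-position analysis

`ccnet` is a tested pipeline for the systems-level analysis of a gene
regulatory network (GRN) inferred from tumour expression data.  It is aimed
at computational biologists who want to go beyond inferring a co-expression
network and ask *where* its structure comes from: which functional gene sets
are wired together, which chromosomes cooperate, and whether co-located
genes interact preferentially.

## What it computes

**Inference (BC3Net).**  From a genes × samples log2 expression matrix *D*,
mutual information is estimated under a Gaussian model,
MI(i,j) = −½ ln(1 − ρ²(i,j)), and C3Net keeps, for each gene, only its single
most informative partner above a permutation-derived significance threshold.
BC3Net bags C3Net over *B* bootstrap resamples of the samples, counts how
often each edge occurs, and keeps edges whose counts beat a Binomial(B, p₀)
null (BH-corrected).  The occurrence frequency of an edge is its *ensemble
consensus rate*, ecr(i,j) = count/B.

**GPEA.**  For *p* network genes there are N = p(p−1)/2 gene pairs; a term of
p_GO genes contributes m_GO = p_GO(p_GO−1)/2 of them.  With *n* network edges
of which *k* fall inside the term, the enrichment p-value is the upper
hypergeometric tail P(X ≥ k), X ~ Hypergeom(N, m_GO, n) — an edge-level
analogue of the classical gene-level hypergeometric test (also provided, for
census-gene enrichment and subnetwork annotation).

**Chromosome cooperativity.**  For chromosomes i, j the observed number of
connecting edges s_ij is compared with its distribution under gene-label
randomization (topology fixed, positions permuted):
p_ij = Σₑ I(s⁽ᵉ⁾_ij > s_ij)/E, BH-corrected over all (C² − C)/2 + C pairs.

**cis/trans and ECS.**  Edges joining genes on one chromosome are *cis*,
others *trans*.  The *ensemble consensus set* ECSᵐⁿ collects the ECR values
of all edges between chromosomes m and n; per-chromosome means and their
median ("median of means") contrast the reproducibility of cis vs trans
interactions.

**Windows.**  1 Mb windows stepped by 500 Kb along each chromosome define
positional gene sets tested with the GPEA statistic (Bonferroni), flagging
windows whose induced subnetwork has a large connected component.

**CSPNN.**  Given seed genes L₁, all genes on any shortest path between seed
pairs form L₂; the induced subgraph on L₂ plus the seeds' direct neighbors
is the connected shortest-path neighbor network.

A synthetic-data generator (scale-free truth network, Gaussian graphical
expression model, position table with tunable co-location of true edges,
module/random annotation terms) makes every stage testable with no download.

## Worked example

The `analysis/` scripts run the whole study on synthetic data, writing
tables under `results/`:

```
python analysis/01_simulate.py            # synthetic study (seed 0)
python analysis/02_infer_network.py       # BC3Net, B=20
python analysis/03_functional_enrichment.py
python analysis/04_core_subnetwork.py
python analysis/05_chromosomal_analysis.py
python analysis/06_window_enrichment.py
```

Output of the run above (seeds 0/1/2):

```
simulated 300 genes x 200 samples (seed 0)
truth network: 299 edges, 76 (25.4%) cis
inferred 773 edges over 300 genes (B=20, seed 1)
GCC 300 genes; mean shortest path 3.70; density 1.72e-02; power-law exponent 1.48
precision vs ground truth: 0.140 (108/773 edges correct)
tested 100 terms; 2 (2.0%) significant at Bonferroni alpha=0.001
CSPNN: 75 genes (6 seeds, 67 path, 2 neighbor), 116 interactions
cooperativity: 276 chromosome-pair tests (E=100000), 4 significant after BH
ECR median-of-means: cis 0.1938 vs trans 0.1537 (1.26-fold)
5543 windows tiled; 66 held >= 2 network genes
```

Reading these numbers: the inferred network recovers true edges 14× more
precisely than a random guesser (0.140 vs the 0.0067 truth density); module
terms drive the significant GPEA hits; the generator's co-location of true
edges surfaces as a higher cis than trans consensus rate; and a handful of
chromosome pairs carry significantly more edges than label permutation
explains.  The same pipeline runs on real data via the CLI
(`ccnet infer|gpea|cooccur|windows|cspnn|run`) given an expression TSV,
a positions TSV, a GMT file and a gene list.

## Layout

```
src/ccnet/        library: synthetic, inference, netstats, gpea, genomic,
                  io, pipeline, cli
analysis/         numbered narrative drivers over the library
tests/            pytest suite (unit, property, acceptance)
scripts/          acceptance.py
docs/methods.md   models, assumptions, parameter choices, limitations
```
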