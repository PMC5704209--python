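# mircoreg

Analysis of how microRNA (miRNA) binding sites are distributed across the
genes of a genome, through the lens of network science.

A miRNA represses mRNAs via short binding sites, usually in 3'-UTRs; one
miRNA family can target thousands of genes and one UTR can carry dozens of
sites. `mircoreg` turns a table of predicted (or experimentally supported)
miRNA target sites into a **co-regulation network**: genes are nodes, and two
genes are joined by an undirected edge whenever their 3'-UTRs share at least
one common miRNA. The package then characterises that network's small-world
statistics and asks whether designated gene sets (e.g. cancer driver genes) or
miRNA sets (e.g. tumor-suppressive miRNAs) occupy privileged positions in it.

It is written for computational biologists who work with TargetScan-style
conserved-site tables or miRTarBase-style interaction tables and want the
whole analysis — parsing, projection, statistics, enrichment — reproducible
from one seed.

## What it computes

Given a site table, the pipeline derives the bipartite miRNA→gene map and its
one-mode projection onto genes, and reports:

* **Connectivity** K_i — a gene's number of co-regulation partners; histograms
  on linear, square-root, and log-log scales, with a skewness diagnostic for
  the square-root transform.
* **Clustering coefficient** — for each gene *i* with K_i neighbours of which
  N_i pairs are mutually connected,

  C_i = 2 N_i / (K_i (K_i − 1)),

  computed exactly by sparse triangle counting, or by unbiased neighbour-pair
  sampling for hub-heavy graphs; plus the Pearson correlation between
  sqrt(K_i) and C_i.
* **Scale-free marginals** — per-miRNA target-gene counts and per-gene site
  counts, fitted to the discrete power law P(K) ∝ K^(−α) by zeta-normalised
  maximum likelihood (automatic lower cutoff by KS minimisation) or by
  log-log-binned regression.
* **Bootstrap gene-set tests** — the mean score (connectivity or site count)
  of a gene set located within the null distribution of means of random
  same-size gene sets, with raw and add-one empirical p-values; and a
  quantile overlay for miRNA sets on the target-count distribution.

A synthetic-data generator (configuration-model wiring of power-law degree
draws, with planted boosted gene/miRNA subsets) makes every stage testable
without downloads; synthetic tables are written in the same dialect the
TargetScan reader consumes.

## Worked example

```python
import mircoreg as mc

cfg = mc.SyntheticConfig(seed=42)          # 2000 genes, 300 miRNA families
table = mc.generate_bipartite_table(cfg)   # planted 5% gene subset, boost 3x
bimap = mc.build_bipartite(table)
network = mc.project_coregulation(bimap)
print(f"network: {network.n_nodes} nodes, {network.n_edges} edges")

clustering = mc.clustering_exact(network)
corr = mc.degree_clustering_correlation(clustering)
print(f"mean clustering coefficient: {clustering.mean_clustering():.3f}")
print(f"corr(sqrt K, C): {corr.r_sqrt:.3f}")

fit = mc.fit_power_law(list(bimap.mirna_target_counts.values()),
                       k_min_fit=cfg.k_min, k_max_fit=cfg.n_genes)
print(fit.summary())

scores = {g: float(c) for g, c in bimap.gene_site_counts.items()}
result = mc.bootstrap_set_test(scores, set(table.metadata["planted_genes"]),
                               seed=0)
print(result.summary())
```

prints

```
network: 1958 nodes, 61421 edges
mean clustering coefficient: 0.865
corr(sqrt K, C): -0.587
Discrete power-law fit  P(K) ~ K^-alpha
---------------------------------------
method        mle
alpha         2.2743
stderr(alpha) 0.0752
k_min         5
k_max         2000
n_tail        297
KS distance   0.0434
Bootstrap gene-set test
-----------------------
set size (matched)    100
unmatched names       0
replicates            1000
alternative           greater
observed mean         6.6500
null mean of means    2.1469
null sd of means      0.3755
empirical p (raw)     < 0.001
empirical p (add-one) 0.000999
t-test p (heuristic)  0
z p                   1.97e-33
seed                  0
```

Reading it: the projection is dense (mean connectivity ≈ 63) with high local
cliquishness (mean C ≈ 0.87) that *decreases* with connectivity — hub genes
have promiscuous, heterogeneous neighbourhoods while low-degree genes sit in
tight cliques, the small-world signature. The per-miRNA target-count exponent
is recovered near its generating value (α = 2.3), and the planted gene subset
(site counts boosted 3×) shows a mean of 6.65 sites against a bootstrap null
of 2.15 ± 0.38 — none of the 1000 resampled means reaches it, so the
empirical p-value is below 1/1000.

The same stages are available from a shell:

```sh
mircoreg simulate --seed 42 --out-dir run/
mircoreg build  --sites run/sites.tsv --source synthetic --out-dir run/
mircoreg stats  --sites run/sites.tsv --source synthetic --out-dir run/
mircoreg enrich --sites run/sites.tsv --source synthetic \
                --gene-list my_genes.txt --mirna-list my_mirnas.txt \
                --out-dir run/
```

Each command writes tab-delimited outputs plus a manifest (resolved options,
input checksums, package version). Real TargetScan conserved-site downloads
go through the identical path with `--source targetscan --species 9606`.
A list of 13 well-known tumor-suppressive miRNA families ships as package
data (`mircoreg/data/tumor_suppressive_mirnas.txt`).

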