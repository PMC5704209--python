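# Methods

## The co-regulation model

The object of study is the undirected simple graph G over genes in which an
edge joins genes a and b iff their 3'-UTRs contain at least one binding site
for a common miRNA (family). Formally, with R(g) the set of miRNA keys with
≥ 1 site in gene g, the edge relation is R(a) ∩ R(b) ≠ ∅. The graph is the
union over miRNAs m of complete graphs on m's target set, so hub miRNA
families dominate the edge count and the projection is dense even for
moderately sized tables. Edges are unweighted: the number of shared miRNAs
per pair is retained as optional metadata (`shared_counts`) but enters no
statistic. Genes present in the site table that share no miRNA with any
other gene remain in the node set with K = 0; histogram routines expose
`drop_isolated()` for the alternative convention.

Assumptions worth making explicit: miRNA identity is at the level the input
table provides (TargetScan conserved-site files key sites by *family*, so
"shared miRNA" means "shared family" there); sites are taken at face value
with no weighting by conservation score or site type; and the projection is
binary — co-regulation strength is deliberately not modelled.

### Counting conventions

Two per-gene counts coexist and are both reported, because site-level and
interaction-level sources mean different things by "K sites":

* **site rows** — one per predicted binding site; a family with three sites
  in one UTR contributes three (TargetScan semantics, the default);
* **distinct regulators** — the number of different miRNA keys with ≥ 1 site
  (the only well-defined count for interaction tables such as miRTarBase,
  where duplicate (miRNA, gene) evidence rows are not extra sites).

`build_bipartite` selects the convention from the table's `source_tag`;
`gene_regulator_counts()` exposes the deduplicated count for any source.

## Clustering coefficients

For gene i with K_i ≥ 2 neighbours of which N_i pairs are connected,
C_i = 2 N_i / (K_i (K_i − 1)). Genes with K_i < 2 are *undefined* (NaN), not
zero: the ratio divides by zero there, and imputing 0 would drag the
degree–clustering correlation toward artefactual negativity. Undefined genes
are excluded from mean-clustering summaries and from the correlation.

The exact path computes N_i as half the i-th row sum of (A·A) ∘ A on the
sparse boolean adjacency A, evaluated in row blocks (default 2048) so the
intermediate product stays bounded; this is identical to per-node
neighbour-pair enumeration (tested against it) and handles ~10⁴-node dense
projections in seconds. For hub nodes where K(K−1)/2 exceeds a budget,
`clustering_sampled` draws neighbour pairs uniformly with replacement and
uses the connected fraction — an unbiased binomial estimate whose error is
√(C(1−C)/budget); nodes under the budget fall back to the exact value, so
the estimator degrades to exactness as the budget grows.

## Degree–clustering correlation

The headline statistic is the signed Pearson correlation between sqrt(K_i)
and C_i over genes with defined C_i, with the OLS slope and the raw-K
correlation reported alongside. The square-root axis follows the
connectivity histogram's behaviour on this kind of network: heavily
right-skewed raw, approximately bell-shaped after the transform (the
`sqrt_normality_diagnostic` quantifies this with skewness before/after and a
D'Agostino normality statistic, without a hard-coded verdict). A strong
*negative* value — low-degree genes cliquish, hubs promiscuous — is the
small-world signature this analysis looks for; the package reports the sign
as computed and leaves interpretation to the caller.

## Power-law fitting

P(K) ∝ K^(−α) is fitted to positive integer counts two ways:

* **Discrete MLE** (default): maximise n·(−log Z(α)) − α·Σ log k over the
  tail k ≥ k_min, with Z the Hurwitz zeta ζ(α, k_min), or
  ζ(α, k_min) − ζ(α, k_max + 1) when a truncation bound is supplied (use the
  bound whenever the generating process has bounded support — fitting the
  open-tail law to bounded data biases α upward, noticeably so for shallow
  exponents). Standard error from the observed information (numerical second
  derivative); goodness of fit as the KS distance between the empirical tail
  CDF and the fitted law. `k_min_fit="auto"` scans candidate cutoffs (each
  keeping ≥ 10 tail observations) and keeps the KS-minimising one, the
  standard automatic-cutoff recipe for discrete power laws.
* **Log-log regression**: least-squares slope of log density on log K over
  multiplicatively binned counts (factor 2 by default), with density =
  count / bin width. This mirrors the visual analysis such distributions are
  usually presented with; it is known to be biased and is retained for
  comparability, never as the default.

## Bootstrap gene-set test

Given scores s(g) for the whole population and a member set M, each of n
replicates (default 1000) draws |M ∩ population| genes uniformly **without
replacement** from the full population — members included, matching a null
of "a random same-size gene set" — and records the mean score. Reported:

* the raw empirical p, #(null ≥ observed)/n, which can be exactly 0 and is
  then printed as "< 1/n";
* the add-one estimate (r + 1)/(n + 1), the canonical value (never 0, and
  exactly uniform under the null by exchangeability of the observed set with
  the replicates);
* a one-sample t-test of the null means against the observed mean, flagged
  as a heuristic — it treats a constant as a sample and its p-value mostly
  reflects n — and a z-value tail using the null means' moments, which is
  the better-behaved parametric summary.

Sampling is vectorised (top-m of uniform keys per replicate, chunked); a
with-replacement mode exists but is not the default. Member names absent
from the score population are reported, not silently dropped.

For miRNA sets, `mirna_set_overlay` reports each member's target-gene count
and its mid-rank quantile in the full count distribution, plus how many
members exceed the distribution's mode. Name matching is family-aware:
list entries like `miR-15/16` expand to tokens sharing the stem, and a token
matches a table key (itself possibly a bundle like `let-7-5p/miR-98-5p`) by
prefix at a non-digit boundary, so `miR-15` hits `miR-15a-5p` but not
`miR-155`.

## Synthetic data generator

The generator emulates the statistical shape of a conserved-site table, not
its sequences: per-miRNA target counts and per-gene site counts follow
discrete truncated power laws, and planted subsets carry boosted counts so
enrichment recovery is testable against known truth.

Mechanics: miRNA-side degree draws (P(K) ∝ K^(−α) on [k_min, k_max], exact
inverse-CDF sampling) are authoritative stub counts; gene-side draws act as
weights, apportioned to an integer stub vector matching the miRNA stub total
by largest remainder; the gene stub list is randomly permuted and split
across miRNAs. Stubs landing twice on one (miRNA, gene) pair become extra
sites on that pair — real UTRs do carry several sites for one family — which
slightly shaves the distinct-target tail relative to the nominal law.
Planted genes' weights and planted miRNAs' degree draws are multiplied by
their boost before wiring (miRNA draws clipped at n_genes; a configuration
whose boost forces the cap is rejected as infeasible).

Defaults — 2000 genes, 300 miRNA families, α = 2.3 on both sides,
k_min = 5, k_max = n_genes/10, planted 5% of genes and 4% of miRNAs at
boost 3 — give ~4–5k sites (≈ 2.4 sites per appearing gene), a connected
dense projection, and a planted signal comfortably detectable at 1000
bootstrap replicates. The k_min of 5 encodes that a conserved miRNA family
targets at least a handful of genes; with k_min = 1 most miRNAs would be
near-singletons and the table far sparser than any conserved-site download.

What the generator does **not** emulate: UTR sequence and seed-match
structure, conservation scores, correlated targeting of functionally related
genes, and the empirical exponents of any particular database release (α
defaults are illustrative). Passing tests therefore demonstrate correctness
of the machinery — projection, counting, estimation, calibration — under a
realistic marginal structure, not that any specific biological dataset will
reproduce particular values.

## Numerical choices and degenerate inputs

* Node order is lexicographic everywhere; files, matrices and iterators are
  deterministic, and every stochastic routine takes an explicit seed which
  is echoed in its outputs.
* MLE α is maximised on (1, 25] by bounded Brent; tails with no variation,
  fewer than 10 observations, or values above the stated truncation bound
  are rejected with parameter errors rather than returning garbage.
* Ranking ties break lexicographically; quantiles are mid-rank, so constant
  distributions give all members the same quantile.
* Constant inputs to skewness/correlation are flagged `undefined` rather
  than silently returning 0 or raising.
* Problem sizes in the test suite (graphs ≤ 500 nodes for oracle equality,
  10⁵ draws for exponent recovery, 1000-replicate bootstraps over 2000-trial
  calibration batches) are chosen so every independent oracle — brute-force
  projection, all-pairs clustering enumeration, exhaustive subset
  enumeration — remains exactly computable.

## Known limitations

* Average path length / diameter are not computed; the small-world
  characterisation rests on the degree and clustering statistics.
* The co-regulation projection is binary; shared-miRNA multiplicity is
  available as metadata only.
* Gene identifier matching is normalisation-only (case-fold, version-suffix
  stripping); no synonym resolution, and unmatched list names are reported
  rather than guessed.
* The t-test output reproduces a conventional but statistically loose
  procedure; use the empirical add-one p or the z-value for inference.
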