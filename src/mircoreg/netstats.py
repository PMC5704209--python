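"""Descriptive network statistics.

Implements the small-world diagnostics used on the co-regulation
network and the bipartite count marginals:

* per-gene clustering coefficients C_i = 2 N_i / (K_i (K_i - 1)), exact
  (triangle counting through sparse matrix products) or pair-sampled for
  hub genes;
* connectivity histograms on linear, square-root and log-log scales,
  with a skewness diagnostic for the square-root transform;
* the Pearson correlation between sqrt(K_i) and C_i;
* discrete power-law fits P(K) ~ K^-alpha, by zeta-normalised maximum
  likelihood (with automatic lower cutoff chosen by KS minimisation)
  or by least squares on log-binned log-counts;
* count rankings ("which genes carry the most sites?").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import optimize, special, stats

from .exceptions import ParameterError
from .network import BipartiteTargetMap, CoRegulationNetwork

__all__ = [
    "ClusteringResult",
    "DegreeDistribution",
    "PowerLawFit",
    "CorrelationResult",
    "clustering_exact",
    "clustering_sampled",
    "degree_histogram",
    "sqrt_normality_diagnostic",
    "degree_clustering_correlation",
    "fit_power_law",
    "rank_by_count",
]


# ---------------------------------------------------------------------------
# clustering coefficients
# ---------------------------------------------------------------------------

@dataclass
class ClusteringResult:
    """Per-gene (K_i, N_i, C_i) records.

    ``C_i`` is NaN (undefined, not zero) for genes with fewer than two
    neighbours, where the defining ratio divides by zero.  ``method`` is
    ``"exact"`` or ``"sampled"`` per gene.
    """

    table: pd.DataFrame  # columns: gene, k, n_i, c, method
    seed: int | None = None

    @property
    def defined(self) -> pd.Series:
        return self.table["c"].notna()

    def mean_clustering(self) -> float:
        """Mean C_i over genes where it is defined."""
        return float(self.table.loc[self.defined, "c"].mean())

    def as_mapping(self) -> dict[str, float]:
        return dict(zip(self.table["gene"], self.table["c"]))


def _result_frame(genes, k, n_i, c, method) -> pd.DataFrame:
    return pd.DataFrame(
        {"gene": genes, "k": k, "n_i": n_i, "c": c, "method": method}
    )


def clustering_exact(network: CoRegulationNetwork, block: int = 2048) -> ClusteringResult:
    """Exact clustering coefficients by triangle counting.

    N_i (the number of edges among gene i's neighbours) is half the i-th
    row sum of (A @ A) ∘ A; computed in row blocks so the intermediate
    product never materialises fully.
    """
    adj = network.adjacency_sparse().astype(np.int64)
    n = adj.shape[0]
    n_i = np.zeros(n, dtype=np.int64)
    for lo in range(0, n, block):
        hi = min(lo + block, n)
        rows = adj[lo:hi]
        paths = rows @ adj  # ordered 2-paths from each i
        n_i[lo:hi] = np.asarray(paths.multiply(rows).sum(axis=1)).ravel() // 2
    k = np.array([network.degree[g] for g in network.genes], dtype=np.int64)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(k >= 2, 2.0 * n_i / (k * (k - 1.0)), np.nan)
    return ClusteringResult(
        _result_frame(network.genes, k, n_i, c, "exact")
    )


def clustering_sampled(
    network: CoRegulationNetwork, pairs_per_node: int, seed: int
) -> ClusteringResult:
    """Pair-sampled clustering coefficients for hub-heavy graphs.

    Nodes whose total neighbour-pair count fits in ``pairs_per_node``
    get the exact value; larger nodes get the fraction of
    ``pairs_per_node`` uniformly drawn neighbour pairs (with
    replacement) that are connected — an unbiased estimate of C_i.
    """
    if pairs_per_node < 1:
        raise ParameterError("pairs_per_node must be >= 1")
    rng = np.random.default_rng(seed)
    adj = network.adjacency_sparse()
    genes = network.genes
    k_arr, n_arr, c_arr, meth = [], [], [], []
    for i, g in enumerate(genes):
        nbrs = adj.indices[adj.indptr[i] : adj.indptr[i + 1]]
        k = len(nbrs)
        k_arr.append(k)
        if k < 2:
            n_arr.append(0)
            c_arr.append(np.nan)
            meth.append("exact")
            continue
        total_pairs = k * (k - 1) // 2
        if total_pairs <= pairs_per_node:
            sub = adj[nbrs][:, nbrs]
            n_i = int(sub.nnz // 2)
            n_arr.append(n_i)
            c_arr.append(n_i / total_pairs)
            meth.append("exact")
        else:
            a = rng.integers(0, k, size=pairs_per_node)
            b = rng.integers(0, k - 1, size=pairs_per_node)
            b = np.where(b >= a, b + 1, b)  # uniform over ordered distinct pairs
            hits = np.asarray(adj[nbrs[a], nbrs[b]]).ravel()
            c_hat = float(hits.mean())
            n_arr.append(c_hat * total_pairs)
            c_arr.append(c_hat)
            meth.append("sampled")
    return ClusteringResult(_result_frame(genes, k_arr, n_arr, c_arr, meth), seed=seed)


# ---------------------------------------------------------------------------
# histograms & transforms
# ---------------------------------------------------------------------------

@dataclass
class DegreeDistribution:
    """Histogram view of a count distribution.

    ``values`` maps each observed K to its exact tally regardless of the
    binned view; ``bin_counts`` / ``bin_density`` follow ``bin_edges``.
    On the log-log scale the density is count / bin width, the standard
    correction for multiplicative binning.
    """

    values: dict[int, int]
    scale: str  # linear | sqrt | loglog
    bin_edges: np.ndarray
    bin_counts: np.ndarray
    bin_density: np.ndarray

    @property
    def n(self) -> int:
        return int(sum(self.values.values()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": self.bin_edges[:-1],
                "bin_right": self.bin_edges[1:],
                "count": self.bin_counts,
                "density": self.bin_density,
            }
        )


def degree_histogram(
    values, scale: str = "linear", bin_width_or_count: float | int = 1.0
) -> DegreeDistribution:
    """Histogram of non-negative integer counts on the requested scale.

    linear
        fixed-width bins of ``bin_width_or_count`` on the raw values;
    sqrt
        fixed-width bins on sqrt-transformed values;
    loglog
        multiplicative bins growing by factor ``bin_width_or_count``
        (default 2 when left at 1), counts divided by bin width reported
        alongside raw counts.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ParameterError("cannot histogram an empty value sequence")
    if (arr < 0).any():
        raise ParameterError("counts must be non-negative")
    tally: dict[int, int] = {}
    for v, c in zip(*np.unique(arr.astype(np.int64), return_counts=True)):
        tally[int(v)] = int(c)

    if scale == "linear":
        w = float(bin_width_or_count)
        lo = np.floor(arr.min() / w) * w
        edges = np.arange(lo, arr.max() + w, w)
        if edges[-1] <= arr.max():
            edges = np.append(edges, edges[-1] + w)
        counts, edges = np.histogram(arr, bins=edges)
        density = counts / (counts.sum() * np.diff(edges))
    elif scale == "sqrt":
        w = float(bin_width_or_count)
        t = np.sqrt(arr)
        edges = np.arange(0.0, t.max() + w, w)
        if edges[-1] <= t.max():
            edges = np.append(edges, edges[-1] + w)
        counts, edges = np.histogram(t, bins=edges)
        density = counts / (counts.sum() * np.diff(edges))
    elif scale == "loglog":
        factor = float(bin_width_or_count)
        if factor <= 1.0:
            factor = 2.0
        pos = arr[arr >= 1]
        if pos.size == 0:
            raise ParameterError("log-log binning needs values >= 1")
        lo = pos.min()
        edges = [lo]
        while edges[-1] <= pos.max():
            edges.append(edges[-1] * factor)
        edges = np.asarray(edges)
        counts, edges = np.histogram(pos, bins=edges)
        density = counts / np.diff(edges)  # per-bin count / width
    else:
        raise ParameterError(f"unknown scale {scale!r}")
    return DegreeDistribution(tally, scale, edges, counts, density)


@dataclass
class SqrtDiagnostic:
    """Skewness before/after square-root transform plus a normality test.

    No pass/fail judgment is made; ``undefined`` flags constant input
    where skewness does not exist.
    """

    skew_raw: float
    skew_sqrt: float
    stat: float
    p_value: float
    test: str
    undefined: bool = False


def sqrt_normality_diagnostic(values) -> SqrtDiagnostic:
    """Quantify how much a square-root transform symmetrises the histogram."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ParameterError("empty value sequence")
    if np.ptp(arr) == 0:
        return SqrtDiagnostic(np.nan, np.nan, np.nan, np.nan, "none", undefined=True)
    t = np.sqrt(arr)
    skew_raw = float(stats.skew(arr))
    skew_sqrt = float(stats.skew(t))
    if arr.size >= 20:
        stat, p = stats.normaltest(t)
        test = "dagostino"
    elif arr.size >= 8:
        stat, p = stats.skewtest(t)
        test = "skewtest"
    else:
        stat, p, test = np.nan, np.nan, "none"
    return SqrtDiagnostic(skew_raw, skew_sqrt, float(stat), float(p), test)


# ---------------------------------------------------------------------------
# degree / clustering correlation
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    """Pearson correlation of sqrt(K_i) against C_i over defined genes.

    ``r_sqrt`` is the headline signed coefficient; ``slope`` is the OLS
    slope of C_i on sqrt(K_i); ``r_raw`` the correlation on raw K_i.
    """

    r_sqrt: float
    slope: float
    intercept: float
    r_raw: float
    n: int
    undefined: bool = False


def degree_clustering_correlation(clustering: ClusteringResult) -> CorrelationResult:
    sub = clustering.table[clustering.defined]
    if len(sub) < 3:
        raise ParameterError(
            f"need >= 3 genes with defined clustering, have {len(sub)}"
        )
    k = sub["k"].to_numpy(dtype=float)
    c = sub["c"].to_numpy(dtype=float)
    sk = np.sqrt(k)
    if np.ptp(c) == 0 or np.ptp(sk) == 0:
        return CorrelationResult(np.nan, np.nan, np.nan, np.nan, len(sub), undefined=True)
    fit = stats.linregress(sk, c)
    r_raw = float(stats.pearsonr(k, c)[0])
    return CorrelationResult(
        float(fit.rvalue), float(fit.slope), float(fit.intercept), r_raw, len(sub)
    )


# ---------------------------------------------------------------------------
# power-law fitting
# ---------------------------------------------------------------------------

@dataclass
class PowerLawFit:
    """Fitted exponent of P(K) ~ K^-alpha on the tail K >= k_min_fit.

    ``gof`` is the Kolmogorov-Smirnov distance between the empirical
    tail and the fitted law (smaller is better).  ``k_max_fit`` is the
    truncation bound of the fitted support, or None for the open tail.
    """

    alpha: float
    k_min_fit: int
    method: str
    n_tail: int
    stderr_alpha: float
    gof: float
    k_max_fit: int | None = None
    details: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            "Discrete power-law fit  P(K) ~ K^-alpha",
            "---------------------------------------",
            f"method        {self.method}",
            f"alpha         {self.alpha:.4f}",
            f"stderr(alpha) {self.stderr_alpha:.4f}",
            f"k_min         {self.k_min_fit}",
            f"k_max         {self.k_max_fit if self.k_max_fit is not None else 'open tail'}",
            f"n_tail        {self.n_tail}",
            f"KS distance   {self.gof:.4f}",
        ]
        return "\n".join(lines)


def _tail_log_norm(alpha: float, k_min: int, k_max: int | None) -> float:
    """log of the normalising constant sum_{k_min}^{k_max} k^-alpha."""
    if k_max is None:
        return float(np.log(special.zeta(alpha, k_min)))
    return float(np.log(special.zeta(alpha, k_min) - special.zeta(alpha, k_max + 1)))


def _mle_alpha(tail: np.ndarray, k_min: int, k_max: int | None) -> tuple[float, float]:
    """Maximise the discrete power-law likelihood; return (alpha, stderr)."""
    mean_log = float(np.mean(np.log(tail)))
    n = tail.size

    def nll(alpha: float) -> float:
        return _tail_log_norm(alpha, k_min, k_max) + alpha * mean_log

    res = optimize.minimize_scalar(nll, bounds=(1.0 + 1e-6, 25.0), method="bounded")
    alpha = float(res.x)
    # observed information from a central second difference of the nll
    h = 1e-4
    d2 = (nll(alpha + h) - 2 * nll(alpha) + nll(alpha - h)) / h**2
    stderr = float(1.0 / np.sqrt(n * d2)) if d2 > 0 else np.inf
    return alpha, stderr


def _fitted_cdf(ks: np.ndarray, alpha: float, k_min: int, k_max: int | None) -> np.ndarray:
    top = k_max if k_max is not None else int(ks.max())
    support = np.arange(k_min, top + 1, dtype=float)
    pmf = support**-alpha
    if k_max is None:
        # add the open-tail mass beyond the largest observation
        total = special.zeta(alpha, k_min)
    else:
        total = pmf.sum()
    cdf = np.cumsum(pmf) / total
    return cdf[np.searchsorted(support, ks)]


def _ks_distance(tail: np.ndarray, alpha: float, k_min: int, k_max: int | None) -> float:
    ks, counts = np.unique(tail, return_counts=True)
    ecdf = np.cumsum(counts) / tail.size
    model = _fitted_cdf(ks.astype(float), alpha, k_min, k_max)
    return float(np.max(np.abs(ecdf - model)))


def fit_power_law(
    values,
    method: str = "mle",
    k_min_fit: int | str = "auto",
    k_max_fit: int | None = None,
) -> PowerLawFit:
    """Fit P(K) ~ K^-alpha to a sequence of positive integer counts.

    ``method="mle"`` maximises the zeta-normalised discrete likelihood on
    the tail K >= k_min_fit (truncated at ``k_max_fit`` when given, e.g.
    when the generating process has bounded support); the standard error
    comes from the observed information.  ``k_min_fit="auto"`` scans
    candidate cutoffs and keeps the one minimising the KS distance
    between data tail and fitted law.

    ``method="loglog-regression"`` reproduces the visual log-log
    analysis: least-squares slope of log density against log K over
    multiplicatively binned counts.  Known to be biased; retained for
    comparability with figure-based estimates.
    """
    arr = np.asarray(list(values), dtype=np.int64)
    arr = arr[arr >= 1]
    if arr.size < 10:
        raise ParameterError("need >= 10 positive observations to fit a power law")
    if np.ptp(arr) == 0:
        raise ParameterError("all values equal: no tail variation to fit")
    if k_max_fit is not None and arr.max() > k_max_fit:
        raise ParameterError(
            f"observations above the truncation bound k_max_fit={k_max_fit} "
            f"(max value {int(arr.max())})"
        )

    if method == "loglog-regression":
        hist = degree_histogram(arr, scale="loglog", bin_width_or_count=2.0)
        centers = np.sqrt(hist.bin_edges[:-1] * hist.bin_edges[1:])
        mask = hist.bin_counts > 0
        if mask.sum() < 3:
            raise ParameterError("fewer than 3 occupied log bins")
        fit = stats.linregress(np.log10(centers[mask]), np.log10(hist.bin_density[mask]))
        k_lo = int(arr.min())
        return PowerLawFit(
            alpha=float(-fit.slope),
            k_min_fit=k_lo,
            method="loglog-regression",
            n_tail=int(arr.size),
            stderr_alpha=float(fit.stderr),
            gof=float(1.0 - fit.rvalue**2),
            k_max_fit=k_max_fit,
            details={"r_value": float(fit.rvalue), "intercept": float(fit.intercept)},
        )

    if method != "mle":
        raise ParameterError(f"unknown method {method!r}")

    if k_min_fit == "auto":
        uniq = np.unique(arr)
        # cap the scan so the tail keeps enough mass to fit
        candidates = [int(k) for k in uniq if (arr >= k).sum() >= 10][:50]
        if not candidates:
            raise ParameterError("no viable lower cutoff with >= 10 tail observations")
        best = None
        for k0 in candidates:
            tail = arr[arr >= k0]
            if np.ptp(tail) == 0:
                continue
            alpha, stderr = _mle_alpha(tail, k0, k_max_fit)
            d = _ks_distance(tail, alpha, k0, k_max_fit)
            if best is None or d < best[0]:
                best = (d, k0, alpha, stderr, tail.size)
        if best is None:
            raise ParameterError("no viable lower cutoff with tail variation")
        d, k0, alpha, stderr, n_tail = best
        return PowerLawFit(alpha, k0, "mle", n_tail, stderr, d, k_max_fit)

    k0 = int(k_min_fit)
    tail = arr[arr >= k0]
    if tail.size < 10:
        raise ParameterError(f"fewer than 10 observations >= k_min_fit={k0}")
    if np.ptp(tail) == 0:
        raise ParameterError("tail values all equal: no variation to fit")
    alpha, stderr = _mle_alpha(tail, k0, k_max_fit)
    d = _ks_distance(tail, alpha, k0, k_max_fit)
    return PowerLawFit(alpha, k0, "mle", int(tail.size), stderr, d, k_max_fit)


# ---------------------------------------------------------------------------
# rankings
# ---------------------------------------------------------------------------

@dataclass
class RankTable:
    """Descending count ranking with lexicographic tie-break."""

    table: pd.DataFrame  # columns: key, count; rank = row order
    axis: str

    def top(self, n: int) -> list[str]:
        return self.table["key"].head(n).tolist()

    def is_in_top(self, key: str, n: int) -> bool:
        return key in set(self.top(n))


def rank_by_count(bimap: BipartiteTargetMap, axis: str, top_n: int | None = None) -> RankTable:
    """Rank genes by site count or miRNAs by distinct-target count.

    Descending by count, ties broken lexicographically by key; asking
    for more rows than exist returns the full ranking.
    """
    if axis == "gene":
        counts = bimap.gene_site_counts
    elif axis == "mirna":
        counts = bimap.mirna_target_counts
    else:
        raise ParameterError("axis must be 'gene' or 'mirna'")
    items = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if top_n is not None:
        items = items[: max(0, top_n)]
    frame = pd.DataFrame(items, columns=["key", "count"])
    return RankTable(frame, axis)
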