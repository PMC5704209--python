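"""Bootstrap gene-set tests and set-versus-population comparisons.

The core procedure: given a per-gene score (connectivity in the
co-regulation network, or miRNA binding-site count) and a gene set of
interest, draw many random same-size gene sets from the whole
population, record each replicate's mean score, and locate the observed
set mean within that null distribution of means.  The companion
descriptive views are a paired member/non-member histogram and, for
miRNA sets, a per-member quantile overlay on the target-count
distribution.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ParameterError
from .netstats import DegreeDistribution, degree_histogram

__all__ = [
    "BootstrapResult",
    "bootstrap_set_test",
    "set_vs_population_histogram",
    "mirna_set_overlay",
]


@dataclass
class BootstrapResult:
    """Null distribution of resampled set means and the observed mean's position.

    ``empirical_p_raw`` is the plain fraction of null means at least as
    extreme as the observed mean; it can be exactly zero, in which case
    it should be read as "< 1/n_replicates".  ``empirical_p_corrected``
    is the add-one estimate (r + 1) / (n + 1), the canonical value.
    ``t_p_value`` reproduces the one-sample t-test of the null means
    against the observed mean; it treats the observed mean as a fixed
    location, so it is a heuristic rather than a calibrated test —
    ``z_p_value`` (normal tail of the observed mean under the null
    means' moments) is reported alongside.
    """

    observed_mean: float
    set_size: int
    n_replicates: int
    null_means: np.ndarray
    empirical_p_raw: float
    empirical_p_corrected: float
    t_p_value: float
    z_p_value: float
    null_mean_of_means: float
    null_sd_of_means: float
    seed: int
    alternative: str = "greater"
    unmatched: list[str] = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            "Bootstrap gene-set test",
            "-----------------------",
            f"set size (matched)    {self.set_size}",
            f"unmatched names       {len(self.unmatched)}",
            f"replicates            {self.n_replicates}",
            f"alternative           {self.alternative}",
            f"observed mean         {self.observed_mean:.4f}",
            f"null mean of means    {self.null_mean_of_means:.4f}",
            f"null sd of means      {self.null_sd_of_means:.4f}",
            f"empirical p (raw)     "
            + (
                f"< {1.0 / self.n_replicates:.4g}"
                if self.empirical_p_raw == 0
                else f"{self.empirical_p_raw:.4g}"
            ),
            f"empirical p (add-one) {self.empirical_p_corrected:.4g}",
            f"t-test p (heuristic)  {self.t_p_value:.4g}",
            f"z p                   {self.z_p_value:.4g}",
            f"seed                  {self.seed}",
        ]
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "observed_mean": [self.observed_mean],
                "set_size": [self.set_size],
                "n_replicates": [self.n_replicates],
                "empirical_p_raw": [self.empirical_p_raw],
                "empirical_p_corrected": [self.empirical_p_corrected],
                "t_p_value": [self.t_p_value],
                "z_p_value": [self.z_p_value],
                "null_mean_of_means": [self.null_mean_of_means],
                "null_sd_of_means": [self.null_sd_of_means],
                "n_unmatched": [len(self.unmatched)],
                "alternative": [self.alternative],
                "seed": [self.seed],
            }
        )


def _sample_null_means(
    values: np.ndarray,
    m: int,
    n_replicates: int,
    rng: np.random.Generator,
    replace: bool,
    chunk: int = 200,
) -> np.ndarray:
    """Means of random size-m subsets of ``values`` (vectorised, chunked)."""
    npop = values.size
    out = np.empty(n_replicates, dtype=float)
    done = 0
    while done < n_replicates:
        b = min(chunk, n_replicates - done)
        if replace:
            idx = rng.integers(0, npop, size=(b, m))
        else:
            keys = rng.random((b, npop))
            idx = np.argpartition(keys, m - 1, axis=1)[:, :m]
        out[done : done + b] = values[idx].mean(axis=1)
        done += b
    return out


def bootstrap_set_test(
    scores: Mapping[str, float],
    member_set: Iterable[str],
    n_replicates: int = 1000,
    seed: int = 0,
    alternative: str = "greater",
    replace: bool = False,
) -> BootstrapResult:
    """Bootstrap test of a gene set's mean score against random same-size sets.

    Each replicate samples ``|matched members|`` keys uniformly without
    replacement (with replacement if ``replace=True``) from the full
    score population — members included in the pool — and records the
    mean.  ``alternative`` controls which tail of the null means counts
    as extreme relative to the observed set mean.
    """
    if n_replicates < 1:
        raise ParameterError("n_replicates must be >= 1")
    if alternative not in ("greater", "less", "two-sided"):
        raise ParameterError(f"unknown alternative {alternative!r}")
    keys = sorted(scores)
    values = np.asarray([scores[k] for k in keys], dtype=float)
    member_set = set(member_set)
    matched = sorted(member_set & set(keys))
    unmatched = sorted(member_set - set(keys))
    if not matched:
        raise ParameterError(
            f"no member names found in the score population; unmatched: {unmatched[:10]}"
        )
    m = len(matched)
    if m >= len(keys):
        raise ParameterError("member set must be smaller than the score population")

    observed = float(np.mean([scores[g] for g in matched]))
    rng = np.random.default_rng(seed)
    null_means = _sample_null_means(values, m, n_replicates, rng, replace)

    ge = int(np.sum(null_means >= observed))
    le = int(np.sum(null_means <= observed))
    if alternative == "greater":
        r = ge
    elif alternative == "less":
        r = le
    else:
        r = 2 * min(ge, le)
    p_raw = min(1.0, r / n_replicates)
    p_corr = min(1.0, (r + 1) / (n_replicates + 1))

    if np.std(null_means, ddof=1) > 0:
        t_alt = {"greater": "less", "less": "greater", "two-sided": "two-sided"}[alternative]
        t_p = float(stats.ttest_1samp(null_means, observed, alternative=t_alt).pvalue)
    else:
        t_p = float("nan")
    mu = float(null_means.mean())
    sd = float(null_means.std(ddof=1)) if n_replicates > 1 else float("nan")
    if sd and sd > 0:
        z = (observed - mu) / sd
        if alternative == "greater":
            z_p = float(stats.norm.sf(z))
        elif alternative == "less":
            z_p = float(stats.norm.cdf(z))
        else:
            z_p = float(2 * stats.norm.sf(abs(z)))
    else:
        z_p = float("nan")

    return BootstrapResult(
        observed_mean=observed,
        set_size=m,
        n_replicates=n_replicates,
        null_means=null_means,
        empirical_p_raw=p_raw,
        empirical_p_corrected=p_corr,
        t_p_value=t_p,
        z_p_value=z_p,
        null_mean_of_means=mu,
        null_sd_of_means=sd,
        seed=seed,
        alternative=alternative,
        unmatched=unmatched,
    )


@dataclass
class PairedHistogram:
    """Member vs non-member score histograms on shared bins."""

    member: DegreeDistribution
    non_member: DegreeDistribution
    member_mean: float
    population_mean: float

    @property
    def right_shift(self) -> float:
        """Member mean minus population mean (positive = shifted right)."""
        return self.member_mean - self.population_mean


def set_vs_population_histogram(
    scores: Mapping[str, float],
    member_set: Iterable[str],
    scale: str = "linear",
    bin_width: float | None = None,
) -> PairedHistogram:
    """Density-normalised member vs non-member histograms on shared binning."""
    member_set = set(member_set)
    matched = sorted(member_set & set(scores))
    if not matched:
        raise ParameterError("no member names found in the score population")
    all_vals = np.asarray([scores[k] for k in sorted(scores)], dtype=float)
    mem_vals = np.asarray([scores[k] for k in matched], dtype=float)
    non = sorted(set(scores) - member_set)
    non_vals = np.asarray([scores[k] for k in non], dtype=float)
    if non_vals.size == 0:
        raise ParameterError("member set must not cover the whole population")

    if bin_width is None:
        ref = np.sqrt(all_vals) if scale == "sqrt" else all_vals
        bin_width = max(np.ptp(ref) / 30.0, 1e-9)

    def _hist(vals: np.ndarray) -> DegreeDistribution:
        t = np.sqrt(vals) if scale == "sqrt" else vals
        ref = np.sqrt(all_vals) if scale == "sqrt" else all_vals
        edges = np.arange(ref.min(), ref.max() + bin_width, bin_width)
        if edges[-1] <= ref.max():
            edges = np.append(edges, edges[-1] + bin_width)
        counts, edges = np.histogram(t, bins=edges)
        density = counts / (counts.sum() * np.diff(edges))
        tally: dict[int, int] = {}
        for v, c in zip(*np.unique(vals.astype(np.int64), return_counts=True)):
            tally[int(v)] = int(c)
        return DegreeDistribution(tally, scale, edges, counts, density)

    return PairedHistogram(
        member=_hist(mem_vals),
        non_member=_hist(non_vals),
        member_mean=float(mem_vals.mean()),
        population_mean=float(all_vals.mean()),
    )


# ---------------------------------------------------------------------------
# miRNA-set overlay
# ---------------------------------------------------------------------------

_HSA_PREFIX = re.compile(r"^hsa-", re.IGNORECASE)


def _mirna_tokens(name: str) -> list[str]:
    """Split a list entry like 'miR-15/16' into match tokens."""
    name = _HSA_PREFIX.sub("", name.strip())
    parts = name.split("/")
    tokens = [parts[0]]
    # 'miR-15/16' -> second token inherits the 'miR-' stem
    stem = re.match(r"^(.*?-)\d", parts[0])
    for extra in parts[1:]:
        if re.match(r"^\d", extra) and stem:
            tokens.append(stem.group(1) + extra)
        else:
            tokens.append(extra)
    return [t.lower() for t in tokens if t]


def _token_matches_component(token: str, component: str) -> bool:
    """Prefix match with a digit boundary: miR-15 hits miR-15-5p, not miR-155."""
    component = _HSA_PREFIX.sub("", component.strip()).lower()
    if not component.startswith(token):
        return False
    rest = component[len(token) :]
    return rest == "" or not rest[0].isdigit()


def match_mirna_name(member_name: str, family_key: str) -> bool:
    """Family-aware name match between a list entry and a table miRNA key.

    Family keys may bundle several members ('let-7-5p/miR-98-5p'); a
    list entry matches if any of its tokens prefix-matches any family
    component at a digit boundary.
    """
    tokens = _mirna_tokens(member_name)
    components = family_key.split("/")
    # components after the first may also be bare numbers sharing the stem
    expanded = _mirna_tokens(family_key)
    for comp in components + expanded:
        for tok in tokens:
            if _token_matches_component(tok, comp):
                return True
    return False


@dataclass
class OverlayResult:
    """Per-member target-count quantiles within the full distribution."""

    table: pd.DataFrame  # columns: name, matched_key, count, quantile
    n_above_mode: int
    mode_count: int
    unmatched: list[str]

    @property
    def median_quantile(self) -> float:
        return float(self.table["quantile"].median())


def mirna_set_overlay(
    target_counts: Mapping[str, int], mirna_set: Iterable[str]
) -> OverlayResult:
    """Locate a miRNA set's target counts inside the whole distribution.

    Each member name is matched family-aware against the count keys; per
    matched key the table reports the target-gene count and its
    mid-rank quantile in the full population, plus how many members sit
    above the distribution's mode (its histogram peak).
    """
    keys = sorted(target_counts)
    counts = np.asarray([target_counts[k] for k in keys], dtype=float)
    vals, tallies = np.unique(counts, return_counts=True)
    mode_count = int(vals[np.argmax(tallies)])

    rows = []
    unmatched = []
    for name in sorted(set(mirna_set)):
        hits = [k for k in keys if match_mirna_name(name, k)]
        if not hits:
            unmatched.append(name)
            continue
        for k in hits:
            c = target_counts[k]
            below = np.sum(counts < c)
            equal = np.sum(counts == c)
            q = (below + 0.5 * equal) / counts.size  # mid-rank quantile
            rows.append({"name": name, "matched_key": k, "count": int(c), "quantile": float(q)})
    if not rows:
        raise ParameterError(
            f"no miRNA list entries matched any table key; unmatched: {unmatched}"
        )
    frame = pd.DataFrame(rows)
    n_above = int((frame["count"] > mode_count).sum())
    return OverlayResult(frame, n_above, mode_count, unmatched)
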