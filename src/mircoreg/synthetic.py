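"""Synthetic bipartite miRNA-target tables with planted enrichment.

The generator emulates the statistical shape of a conserved-site
prediction table: per-miRNA target-gene counts and per-gene site counts
both follow discrete truncated power laws P(K) ~ K^-alpha, a small
planted gene subset carries boosted site counts (standing in for cancer
driver genes) and a small planted miRNA subset carries boosted target
counts (standing in for tumor-suppressive miRNAs).

Wiring is a configuration model: each miRNA's target-count draw is
authoritative and fixes its number of stubs; gene-side draws act as
weights rescaled (largest-remainder apportionment) so both sides' stub
totals match exactly, and the gene stub list is matched to miRNA stubs
by a uniform random permutation.  Stubs landing twice on the same
(miRNA, gene) pair become additional sites on that pair, mirroring real
UTRs that carry several sites for one family.

All randomness flows through one ``numpy.random.Generator`` seeded from
the config; identical config + seed gives a byte-identical table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .exceptions import ParameterError
from .table import TargetSiteTable, make_table


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    Defaults describe a mid-sized conserved-site table: 2000 genes, 300
    miRNA families, exponent 2.3 on both marginals, planted subsets of
    5% of genes / 4% of miRNAs with a 3x boost on their expected counts.
    The lower cutoff of 5 reflects that a conserved miRNA family targets
    at least a handful of genes; with it the default table carries a few
    thousand sites, dense enough for the projection to be connected.
    """

    n_genes: int = 2000
    n_mirnas: int = 300
    alpha_mirna: float = 2.3
    alpha_gene: float = 2.3
    k_min: int = 5
    k_max: int | None = None  # defaults to n_genes // 10
    planted_gene_fraction: float = 0.05
    planted_gene_boost: float = 3.0
    planted_mirna_fraction: float = 0.04
    planted_mirna_boost: float = 3.0
    seed: int = 0

    def effective_k_max(self) -> int:
        return self.k_max if self.k_max is not None else max(self.k_min, self.n_genes // 10)

    def validate(self) -> None:
        if self.n_genes < 2 or self.n_mirnas < 1:
            raise ParameterError("need n_genes >= 2 and n_mirnas >= 1")
        if self.alpha_mirna <= 1 or self.alpha_gene <= 1:
            raise ParameterError("power-law exponents must exceed 1")
        k_max = self.effective_k_max()
        if not (1 <= self.k_min <= k_max):
            raise ParameterError(f"invalid degree range [{self.k_min}, {k_max}]")
        if k_max > self.n_genes:
            raise ParameterError("k_max cannot exceed n_genes (a miRNA cannot target more genes than exist)")
        for frac, name in (
            (self.planted_gene_fraction, "planted_gene_fraction"),
            (self.planted_mirna_fraction, "planted_mirna_fraction"),
        ):
            if not 0 <= frac < 1:
                raise ParameterError(f"{name} must lie in [0, 1)")
        if self.planted_gene_boost < 1 or self.planted_mirna_boost < 1:
            raise ParameterError("planted boosts must be >= 1")
        planted_mirnas_exist = (
            self.planted_mirna_fraction > 0 and self.planted_mirna_boost > 1
        )
        if planted_mirnas_exist and int(np.ceil(k_max * self.planted_mirna_boost)) > self.n_genes:
            raise ParameterError(
                "infeasible config: planted miRNA boost forces target counts above n_genes"
            )

    def to_dict(self) -> dict:
        return asdict(self)


def power_law_pmf(alpha: float, k_min: int, k_max: int) -> np.ndarray:
    """Exact normalised probabilities of P(K) ~ K^-alpha on [k_min, k_max]."""
    if not (1 <= k_min <= k_max):
        raise ParameterError(f"invalid support [{k_min}, {k_max}]")
    k = np.arange(k_min, k_max + 1, dtype=float)
    w = k ** (-alpha)
    return w / w.sum()


def sample_power_law_degrees(
    n: int,
    alpha: float,
    k_min: int,
    k_max: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Draw ``n`` iid values from the discrete power law on [k_min, k_max].

    Inverse-CDF sampling on the exact normalised mass function; any
    ``alpha > 1`` (and in fact any positive alpha, but the public
    contract requires > 1 so the untruncated law is normalisable).
    """
    if alpha <= 1:
        raise ParameterError("alpha must exceed 1")
    pmf = power_law_pmf(alpha, k_min, k_max)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cdf = np.cumsum(pmf)
    u = rng.random(n)
    return (k_min + np.searchsorted(cdf, u, side="right")).astype(np.int64)


@dataclass
class SyntheticGroundTruth:
    """Sidecar truth written next to generated tables."""

    planted_genes: list[str] = field(default_factory=list)
    planted_mirnas: list[str] = field(default_factory=list)
    alpha_mirna: float = 0.0
    alpha_gene: float = 0.0
    k_min: int = 1
    k_max: int = 1
    seed: int = 0

    def write(self, path: str | Path) -> None:
        import json

        Path(path).write_text(
            json.dumps(asdict(self), indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )


def generate_bipartite_table(config: SyntheticConfig) -> TargetSiteTable:
    """Generate one synthetic :class:`TargetSiteTable` under ``config``.

    Per-miRNA distinct-target counts follow the ``alpha_mirna`` law and
    per-gene site counts follow the ``alpha_gene`` law approximately
    (stub collisions shave a little off both tails).  Planted membership
    and true parameters are recorded in ``table.metadata``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    k_max = config.effective_k_max()

    gene_names = [f"SYNG{i:05d}" for i in range(config.n_genes)]
    mirna_names = [f"syn-miR-{j:04d}" for j in range(config.n_mirnas)]

    n_pg = int(round(config.planted_gene_fraction * config.n_genes))
    n_pm = int(round(config.planted_mirna_fraction * config.n_mirnas))
    planted_genes = sorted(rng.choice(config.n_genes, size=n_pg, replace=False).tolist())
    planted_mirnas = sorted(rng.choice(config.n_mirnas, size=n_pm, replace=False).tolist())

    # miRNA side: authoritative stub counts
    mirna_deg = sample_power_law_degrees(
        config.n_mirnas, config.alpha_mirna, config.k_min, k_max, rng
    ).astype(float)
    mirna_deg[planted_mirnas] *= config.planted_mirna_boost
    mirna_deg = np.clip(np.rint(mirna_deg).astype(np.int64), config.k_min, config.n_genes)

    # gene side: draws act as sampling weights (implicit stub rescaling)
    gene_w = sample_power_law_degrees(
        config.n_genes, config.alpha_gene, config.k_min, k_max, rng
    ).astype(float)
    gene_w[planted_genes] *= config.planted_gene_boost
    gene_p = gene_w / gene_w.sum()

    # apportion the miRNA-side stub total to genes by largest remainder,
    # proportional to the gene weights, then match stubs uniformly
    total_stubs = int(mirna_deg.sum())
    quota = total_stubs * gene_p
    gene_stubs = np.floor(quota).astype(np.int64)
    shortfall = total_stubs - int(gene_stubs.sum())
    if shortfall > 0:
        remainder = quota - gene_stubs
        top = np.argsort(-remainder, kind="stable")[:shortfall]
        gene_stubs[top] += 1

    stub_list = rng.permutation(np.repeat(np.arange(config.n_genes), gene_stubs))
    rows_gene = stub_list
    rows_mirna = np.repeat(np.arange(config.n_mirnas), mirna_deg)
    # deterministic row order: by gene, then miRNA
    order = np.lexsort((rows_mirna, rows_gene))
    rows_gene, rows_mirna = rows_gene[order], rows_mirna[order]

    # synthetic UTR coordinates: consecutive 7-mer windows per gene
    offsets = np.zeros(len(rows_gene), dtype=np.int64)
    counts: dict[int, int] = {}
    for i, g in enumerate(rows_gene):
        c = counts.get(int(g), 0)
        offsets[i] = 30 * c
        counts[int(g)] = c + 1

    table = make_table(
        gene_ids=[f"SYNT{g:05d}.1" for g in rows_gene],
        gene_symbols=[gene_names[g] for g in rows_gene],
        mirna_keys=[mirna_names[m] for m in rows_mirna],
        site_starts=offsets.tolist(),
        site_ends=(offsets + 6).tolist(),
        site_types=["synthetic"] * len(rows_gene),
        species=["0000"] * len(rows_gene),
        source_tag="synthetic",
        metadata={
            "planted_genes": [gene_names[i] for i in planted_genes],
            "planted_mirnas": [mirna_names[j] for j in planted_mirnas],
            "alpha_mirna": config.alpha_mirna,
            "alpha_gene": config.alpha_gene,
            "k_min": config.k_min,
            "k_max": k_max,
            "seed": config.seed,
        },
    )
    return table


def ground_truth(table: TargetSiteTable) -> SyntheticGroundTruth:
    """Extract the sidecar ground truth from a generated table."""
    md = table.metadata
    return SyntheticGroundTruth(
        planted_genes=list(md.get("planted_genes", [])),
        planted_mirnas=list(md.get("planted_mirnas", [])),
        alpha_mirna=float(md.get("alpha_mirna", 0.0)),
        alpha_gene=float(md.get("alpha_gene", 0.0)),
        k_min=int(md.get("k_min", 1)),
        k_max=int(md.get("k_max", 1)),
        seed=int(md.get("seed", 0)),
    )


def read_config_file(path: str | Path) -> SyntheticConfig:
    """Read a plain ``key = value`` config file into a SyntheticConfig."""
    import dataclasses

    fields = {f.name: f.type for f in dataclasses.fields(SyntheticConfig)}
    kwargs: dict = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ParameterError(f"malformed config line: {line!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if key not in fields:
            raise ParameterError(f"unknown config key: {key!r}")
        if key in ("alpha_mirna", "alpha_gene", "planted_gene_fraction",
                   "planted_gene_boost", "planted_mirna_fraction", "planted_mirna_boost"):
            kwargs[key] = float(value)
        else:
            kwargs[key] = int(value)
    return SyntheticConfig(**kwargs)
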