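"""Canonical site-level container.

A :class:`TargetSiteTable` holds one row per miRNA binding site (or per
experimentally supported miRNA-gene interaction, for interaction-database
sources).  Everything downstream — the bipartite target map, the gene
co-regulation network, the count distributions — is derived from it.

Key normalisation
-----------------
Gene symbols are case-folded to upper case and whitespace-trimmed; stable
gene identifiers have a trailing ``.N`` version suffix stripped; miRNA
family strings are kept verbatim apart from trimming.  Normalisation is
idempotent by construction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Any

import pandas as pd

from .exceptions import FormatError

#: canonical column order of the records frame
RECORD_COLUMNS = [
    "gene_id",
    "gene_symbol",
    "gene_key",
    "mirna_key",
    "site_start",
    "site_end",
    "site_type",
    "species",
]

_VERSION_SUFFIX = re.compile(r"\.\d+$")


def normalize_gene_id(raw: str) -> str:
    """Trim whitespace and strip a trailing ``.N`` version suffix."""
    return _VERSION_SUFFIX.sub("", str(raw).strip())


def normalize_gene_symbol(raw: str) -> str:
    """Trim whitespace and case-fold to upper case."""
    return str(raw).strip().upper()


def normalize_mirna_key(raw: str) -> str:
    """miRNA family strings are kept verbatim apart from trimming."""
    return str(raw).strip()


@dataclass
class TargetSiteTable:
    """Ordered collection of site records plus source bookkeeping.

    Parameters
    ----------
    records
        One row per site, with the columns in :data:`RECORD_COLUMNS`.
        ``gene_key`` is the normalised symbol when available, otherwise
        the normalised gene identifier; it is the node key used by every
        downstream stage.
    source_tag
        ``"targetscan"``, ``"mirtarbase"`` or ``"synthetic"``.  Controls
        per-gene count semantics downstream: site rows are counted for
        site-level sources, distinct regulators for interaction-level
        sources.
    rejected_rows
        Rows dropped during parsing (loss accounting:
        ``rows_in == n_sites + rejected_rows``).
    metadata
        Free-form provenance (synthetic ground truth, parse options...).
    """

    records: pd.DataFrame
    source_tag: str = "targetscan"
    rejected_rows: int = 0
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in RECORD_COLUMNS if c not in self.records.columns]
        if missing:
            raise FormatError(f"records frame missing columns: {missing}")
        self.records = self.records[RECORD_COLUMNS].reset_index(drop=True)
        bad = (self.records["gene_key"] == "") | (self.records["mirna_key"] == "")
        if bad.any():
            raise FormatError(
                f"{int(bad.sum())} records with empty gene/miRNA keys survived parsing"
            )

    @property
    def n_sites(self) -> int:
        return len(self.records)

    @property
    def n_genes(self) -> int:
        return int(self.records["gene_key"].nunique())

    @property
    def n_mirnas(self) -> int:
        return int(self.records["mirna_key"].nunique())

    def gene_keys(self) -> list[str]:
        return sorted(self.records["gene_key"].unique())

    def mirna_keys(self) -> list[str]:
        return sorted(self.records["mirna_key"].unique())

    def __len__(self) -> int:
        return self.n_sites

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"TargetSiteTable(source={self.source_tag!r}, n_sites={self.n_sites}, "
            f"n_genes={self.n_genes}, n_mirnas={self.n_mirnas})"
        )


def make_table(
    gene_ids,
    gene_symbols,
    mirna_keys,
    site_starts=None,
    site_ends=None,
    site_types=None,
    species=None,
    source_tag: str = "synthetic",
    metadata: dict | None = None,
) -> TargetSiteTable:
    """Assemble a table from parallel columns, applying key normalisation."""
    n = len(gene_ids)
    gid = [normalize_gene_id(g) for g in gene_ids]
    gsym = [normalize_gene_symbol(s) for s in gene_symbols]
    gkey = [s if s else i for s, i in zip(gsym, gid)]
    frame = pd.DataFrame(
        {
            "gene_id": gid,
            "gene_symbol": gsym,
            "gene_key": gkey,
            "mirna_key": [normalize_mirna_key(m) for m in mirna_keys],
            "site_start": site_starts if site_starts is not None else [pd.NA] * n,
            "site_end": site_ends if site_ends is not None else [pd.NA] * n,
            "site_type": site_types if site_types is not None else [""] * n,
            "species": species if species is not None else [""] * n,
        }
    )
    return TargetSiteTable(frame, source_tag=source_tag, metadata=metadata or {})
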