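"""Readers and writers for the external table dialects.

Supported inputs
----------------
* TargetScan conserved-site prediction tables (release-7 style,
  tab-delimited with a header row: gene ID, gene symbol, miRNA family,
  UTR start/end, seed-match type, species where present).
* miRTarBase-style interaction tables (one row per experimentally
  supported miRNA-gene pair; TSV or CSV).
* Plain one-name-per-line list files with ``#`` comments.

Outputs are UTF-8, tab-delimited, deterministically ordered.  Column
binding is by header name, case-insensitively, with a per-call override
mapping for dialect drift across releases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import FormatError
from .table import (
    TargetSiteTable,
    make_table,
    normalize_gene_symbol,
)

# header aliases recognised for each logical column, lower-cased
_TARGETSCAN_ALIASES: dict[str, tuple[str, ...]] = {
    "gene_id": ("gene id", "gene_id", "transcript id", "transcript_id"),
    "gene_symbol": ("gene symbol", "gene_symbol", "symbol"),
    "mirna_key": ("mir family", "mirna family", "mir_family", "miRNA family".lower()),
    "site_start": ("utr start", "utr_start", "site start"),
    "site_end": ("utr end", "utr_end", "site end"),
    "site_type": ("seed match", "seed_match", "site type", "site_type"),
    "species": ("species id", "species_id", "species"),
}

_MIRTARBASE_ALIASES: dict[str, tuple[str, ...]] = {
    "mirna_key": ("mirna", "mirna name"),
    "gene_symbol": ("target gene", "target_gene", "gene symbol", "target"),
    "gene_id": ("target gene (entrez id)", "target gene (entrez gene id)", "entrez id"),
    "species": ("species (target gene)", "species (mirna)", "species"),
}


def _bind_columns(
    header: Iterable[str],
    aliases: Mapping[str, tuple[str, ...]],
    required: tuple[str, ...],
    overrides: Mapping[str, str] | None,
) -> dict[str, str]:
    """Map logical column names onto actual header names."""
    lower = {str(h).strip().lower(): h for h in header}
    bound: dict[str, str] = {}
    for logical, names in aliases.items():
        if overrides and logical in overrides:
            actual = overrides[logical]
            if actual not in lower.values():
                raise FormatError(
                    f"column override {logical!r}={actual!r} not found in header"
                )
            bound[logical] = actual
            continue
        for name in names:
            if name in lower:
                bound[logical] = lower[name]
                break
    missing = [c for c in required if c not in bound]
    if missing:
        raise FormatError(
            f"required column(s) {missing} not found in header {sorted(lower.values())}"
        )
    return bound


def _read_delimited(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"input file does not exist: {path}")
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        frame = pd.read_csv(path, sep=sep, dtype=str, comment=None)
    except pd.errors.EmptyDataError:
        raise FormatError(f"empty input file: {path}") from None
    if frame.empty:
        raise FormatError(f"no data rows after header in {path}")
    return frame


def _parse_coordinates(frame: pd.DataFrame, bound: dict[str, str]) -> tuple[pd.Series, pd.Series]:
    """Parse optional start/end columns; unparseable values become NA with a warning."""
    n = len(frame)
    start = pd.Series([pd.NA] * n, dtype="Int64")
    end = pd.Series([pd.NA] * n, dtype="Int64")
    for logical, out in (("site_start", start), ("site_end", end)):
        if logical not in bound:
            continue
        raw = frame[bound[logical]]
        parsed = pd.to_numeric(raw, errors="coerce")
        bad = parsed.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
        if bad.any():
            warnings.warn(
                f"{int(bad.sum())} unparseable {logical} values; coordinates left unset",
                stacklevel=3,
            )
        out[:] = parsed.round().astype("Int64")
    # a site interval must not be inverted; drop coordinates where it is
    both = start.notna() & end.notna()
    inverted = both & (end < start)
    if inverted.any():
        warnings.warn(
            f"{int(inverted.sum())} sites with end < start; coordinates left unset",
            stacklevel=3,
        )
        start[inverted] = pd.NA
        end[inverted] = pd.NA
    return start, end


def read_targetscan(
    path: str | Path,
    species_filter: str | None = None,
    column_overrides: Mapping[str, str] | None = None,
) -> TargetSiteTable:
    """Read a TargetScan conserved-site table into a :class:`TargetSiteTable`.

    One record per site row; duplicate identical rows are retained, since
    each row is a distinct binding site.  ``species_filter`` keeps only
    rows whose species column equals the given value (e.g. ``"9606"``
    for human in release-7 files).
    """
    frame = _read_delimited(path)
    bound = _bind_columns(
        frame.columns,
        _TARGETSCAN_ALIASES,
        required=("gene_id", "gene_symbol", "mirna_key"),
        overrides=column_overrides,
    )
    rows_in = len(frame)
    if species_filter is not None:
        if "species" not in bound:
            raise FormatError("species_filter given but no species column found")
        frame = frame[frame[bound["species"]].astype(str).str.strip() == str(species_filter)]
    keep = frame[bound["gene_id"]].notna() & frame[bound["mirna_key"]].notna()
    frame = frame[keep]
    start, end = _parse_coordinates(frame.reset_index(drop=True), bound)
    table = make_table(
        gene_ids=frame[bound["gene_id"]].tolist(),
        gene_symbols=frame[bound["gene_symbol"]].fillna("").tolist(),
        mirna_keys=frame[bound["mirna_key"]].tolist(),
        site_starts=start,
        site_ends=end,
        site_types=(
            frame[bound["site_type"]].fillna("").tolist() if "site_type" in bound else None
        ),
        species=(
            frame[bound["species"]].fillna("").tolist() if "species" in bound else None
        ),
        source_tag="targetscan",
    )
    # loss accounting: rows_in = records_out + rejected_rows
    table.rejected_rows = rows_in - len(table)
    table.metadata["rows_in"] = rows_in
    table.metadata["rows_dropped_by_species_filter"] = (
        int(rows_in - keep.shape[0]) if species_filter is not None else 0
    )
    return table


def read_mirtarbase(
    path: str | Path,
    column_overrides: Mapping[str, str] | None = None,
) -> TargetSiteTable:
    """Read a miRTarBase-style interaction table.

    One record per (miRNA, gene) interaction row; coordinates unset.
    Duplicate pairs are retained here and deduplicated downstream when
    regulators per gene are counted.
    """
    frame = _read_delimited(path)
    bound = _bind_columns(
        frame.columns,
        _MIRTARBASE_ALIASES,
        required=("mirna_key", "gene_symbol"),
        overrides=column_overrides,
    )
    rows_in = len(frame)
    keep = frame[bound["gene_symbol"]].notna() & frame[bound["mirna_key"]].notna()
    frame = frame[keep]
    table = make_table(
        gene_ids=(
            frame[bound["gene_id"]].fillna("").tolist()
            if "gene_id" in bound
            else frame[bound["gene_symbol"]].tolist()
        ),
        gene_symbols=frame[bound["gene_symbol"]].tolist(),
        mirna_keys=frame[bound["mirna_key"]].tolist(),
        species=(
            frame[bound["species"]].fillna("").tolist() if "species" in bound else None
        ),
        source_tag="mirtarbase",
    )
    table.rejected_rows = rows_in - len(table)
    table.metadata["rows_in"] = rows_in
    return table


@dataclass(frozen=True)
class NameList:
    """Deduplicated, normalised name set with raw-line accounting."""

    names: frozenset[str]
    n_raw_lines: int

    def __iter__(self):
        return iter(sorted(self.names))

    def __len__(self) -> int:
        return len(self.names)

    def __contains__(self, item: str) -> bool:
        return item in self.names


def read_name_list(path: str | Path, uppercase: bool = True) -> NameList:
    """Read a plain name-list file (one name per line, ``#`` comments).

    Gene lists are case-folded to upper case to match table gene keys;
    pass ``uppercase=False`` for miRNA lists, whose names are
    case-sensitive by convention (``let-7`` vs ``LET-7``).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"name list does not exist: {path}")
    names: set[str] = set()
    n_raw = 0
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        n_raw += 1
        names.add(normalize_gene_symbol(line) if uppercase else line)
    if not names:
        raise FormatError(f"name list is empty: {path}")
    return NameList(frozenset(names), n_raw)


def write_edge_list(network, path: str | Path) -> None:
    """Write a co-regulation network as a 2-column TSV.

    Each undirected edge appears once with its endpoints in lexicographic
    order; lines are sorted.  Isolated nodes are preserved in
    ``# isolated:`` comment lines so that the round-trip through
    :func:`read_edge_list` reproduces the node set exactly.
    """
    lines = ["gene_a\tgene_b"]
    for g in network.genes:
        if network.degree[g] == 0:
            lines.append(f"# isolated: {g}")
    for a, b in sorted(network.edges()):
        lines.append(f"{a}\t{b}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_edge_list(path: str | Path):
    """Read a network written by :func:`write_edge_list`."""
    from .network import CoRegulationNetwork

    path = Path(path)
    if not path.exists():
        raise FormatError(f"edge list does not exist: {path}")
    nodes: set[str] = set()
    edges: list[tuple[str, str]] = []
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines or not lines[0].startswith("gene_a"):
        raise FormatError(f"not an edge-list file (missing header): {path}")
    for line in lines[1:]:
        if line.startswith("# isolated:"):
            nodes.add(line.split(":", 1)[1].strip())
            continue
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"malformed edge line: {line!r}")
        a, b = parts[0].strip(), parts[1].strip()
        nodes.update((a, b))
        edges.append((a, b))
    return CoRegulationNetwork.from_edges(sorted(nodes), edges)


def write_degree_table(network, path: str | Path) -> None:
    """Per-gene connectivity as a 2-column TSV (gene, degree)."""
    frame = pd.DataFrame(
        {"gene": network.genes, "degree": [network.degree[g] for g in network.genes]}
    )
    frame.to_csv(path, sep="\t", index=False)


def write_count_table(counts: Mapping[str, int], path: str | Path, key_name: str) -> None:
    """Generic (key, count) TSV, sorted by key."""
    keys = sorted(counts)
    frame = pd.DataFrame({key_name: keys, "count": [int(counts[k]) for k in keys]})
    frame.to_csv(path, sep="\t", index=False)


def write_site_table(table: TargetSiteTable, path: str | Path) -> None:
    """Write a table in the TargetScan dialect that :func:`read_targetscan` reads.

    Makes the pipeline format-closed: synthetic tables traverse the same
    reader as downloaded data.
    """
    out = pd.DataFrame(
        {
            "Gene ID": table.records["gene_id"],
            "Gene Symbol": table.records["gene_symbol"],
            "miR Family": table.records["mirna_key"],
            "UTR start": table.records["site_start"],
            "UTR end": table.records["site_end"],
            "Seed match": table.records["site_type"],
            "Species ID": table.records["species"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def score_table_to_mapping(path: str | Path) -> dict[str, float]:
    """Read a (key, value) score TSV into a mapping."""
    frame = pd.read_csv(path, sep="\t", dtype={0: str})
    if frame.shape[1] < 2:
        raise FormatError(f"score table needs >= 2 columns: {path}")
    keys = frame.iloc[:, 0].astype(str)
    values = pd.to_numeric(frame.iloc[:, 1], errors="coerce")
    if values.isna().any():
        raise FormatError(f"non-numeric score values in {path}")
    return dict(zip(keys, values.astype(float)))


def checksum(path: str | Path) -> str:
    """SHA-256 of a file, for run manifests."""
    import hashlib

    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
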