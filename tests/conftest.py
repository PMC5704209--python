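"""Shared fixtures: tiny hand-written tables and random-instance helpers."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from mircoreg import make_table
from mircoreg.network import BipartiteTargetMap, CoRegulationNetwork


TARGETSCAN_HEADER = "Gene ID\tGene Symbol\tmiR Family\tUTR start\tUTR end\tSeed match\tSpecies ID"


def targetscan_text(rows: list[tuple]) -> str:
    """Render rows as a TargetScan-dialect TSV."""
    lines = [TARGETSCAN_HEADER]
    for r in rows:
        lines.append("\t".join(str(x) for x in r))
    return "\n".join(lines) + "\n"


@pytest.fixture
def toy_table():
    """miR-A -> {G1, G2, G3}; miR-B -> {G3, G4}; G1 has 2 sites for miR-A."""
    return make_table(
        gene_ids=["g1.1", "g1.1", "g2", "g3", "g3", "g4"],
        gene_symbols=["G1", "G1", "G2", "G3", "G3", "G4"],
        mirna_keys=["miR-A", "miR-A", "miR-A", "miR-A", "miR-B", "miR-B"],
        source_tag="targetscan",
    )


def random_bipartite(rng: np.random.Generator, n_genes: int, n_mirnas: int,
                     p: float = 0.15) -> BipartiteTargetMap:
    """Random bipartite map built directly (independent of the generator)."""
    genes = [f"G{i:03d}" for i in range(n_genes)]
    mirnas = [f"m{j:03d}" for j in range(n_mirnas)]
    mask = rng.random((n_mirnas, n_genes)) < p
    m2g = {mirnas[j]: frozenset(genes[i] for i in np.flatnonzero(mask[j]))
           for j in range(n_mirnas)}
    g2m = {g: frozenset(m for m in mirnas if g in m2g[m]) for g in genes}
    # keep every gene in the map, even unregulated ones
    return BipartiteTargetMap(
        mirna_to_genes=m2g,
        gene_to_mirnas=g2m,
        gene_site_counts={g: len(g2m[g]) for g in genes},
        mirna_target_counts={m: len(m2g[m]) for m in mirnas},
    )


def brute_force_projection_edges(bimap: BipartiteTargetMap) -> set[frozenset]:
    """O(n^2) oracle: edge iff the regulator sets intersect."""
    genes = sorted(bimap.gene_to_mirnas)
    edges = set()
    for a, b in itertools.combinations(genes, 2):
        if bimap.gene_to_mirnas[a] & bimap.gene_to_mirnas[b]:
            edges.add(frozenset((a, b)))
    return edges


def brute_force_clustering(network: CoRegulationNetwork) -> dict[str, tuple[int, int, float]]:
    """All-neighbour-pairs enumeration oracle for (K_i, N_i, C_i)."""
    out = {}
    for g in network.genes:
        nbrs = network.neighbors(g)
        k = len(nbrs)
        n_i = sum(
            1 for a, b in itertools.combinations(nbrs, 2) if network.has_edge(a, b)
        )
        c = 2.0 * n_i / (k * (k - 1)) if k >= 2 else float("nan")
        out[g] = (k, n_i, c)
    return out
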