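"""The shared-AMP taxon network ("battle network") and its edge-list database.

Taxa are nodes; the weight of an edge is the number of distinct peptide
clusters to which both taxa contribute at least one putative AMP.  Counting
clusters (rather than raw member pairs) deduplicates near-identical peptides
and is invariant to within-taxon copy number; ``count_mode="pairs"`` switches
to raw member-pair counting for sensitivity analysis.

Taxa with no shared clusters remain as isolated nodes: they matter, because
an isolated node takes the maximal Die score.
"""

from __future__ import annotations

from collections import Counter
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from ampnet.clustering import ClusterSet
from ampnet.exceptions import ValidationError
from ampnet.ingest import TaxonPeptideProfile


def aggregate_to_genus(
    profiles: Sequence[TaxonPeptideProfile],
    taxonomy: Mapping[str, str] | None = None,
) -> list[TaxonPeptideProfile]:
    """Merge species profiles into genus profiles.

    ``taxonomy`` maps species to genus; if omitted, the genus is the
    binomial name up to the first space.  Peptide lists are concatenated and
    protein counts summed across the member species.
    """
    if taxonomy is not None:
        missing = [p.taxon_id for p in profiles if p.taxon_id not in taxonomy]
        if missing:
            raise ValidationError(f"species without genus mapping: {missing}")

    def genus_of(species: str) -> str:
        return taxonomy[species] if taxonomy is not None else species.split(" ")[0]

    merged: dict[str, TaxonPeptideProfile] = {}
    for prof in profiles:
        genus = genus_of(prof.taxon_id)
        agg = merged.setdefault(
            genus, TaxonPeptideProfile(taxon_id=genus, rank="genus", n_proteins=0)
        )
        agg.n_proteins += prof.n_proteins
        agg.peptides.extend(prof.peptides)
    return list(merged.values())


def shared_amp_counts(
    profiles: Sequence[TaxonPeptideProfile],
    cs: ClusterSet,
    count_mode: str = "clusters",
) -> pd.DataFrame:
    """Adjacency matrix of shared putative AMPs between all taxon pairs.

    ``count_mode="clusters"``: entry (i, j) = number of distinct clusters
    with members from both taxa.  ``count_mode="pairs"``: number of
    cross-taxon member pairs within shared clusters.
    """
    if count_mode not in ("clusters", "pairs"):
        raise ValidationError(f"unknown count_mode {count_mode!r}")
    taxa = [p.taxon_id for p in profiles]
    membership = cs.membership()
    for prof in profiles:
        for pep in prof.peptides:
            if (pep.sequence, prof.taxon_id) not in membership:
                raise ValidationError(
                    f"peptide {pep.sequence!r} of {prof.taxon_id} is not in the "
                    "cluster set"
                )
    # per-cluster member counts per taxon (restricted to the profiled taxa)
    taxon_set = set(taxa)
    cluster_counts: list[Counter] = []
    for cluster in cs.clusters:
        counts = Counter(t for _, t in cluster.members if t in taxon_set)
        if len(counts) > 1:
            cluster_counts.append(counts)

    n = len(taxa)
    idx = {t: i for i, t in enumerate(taxa)}
    adj = np.zeros((n, n))
    for counts in cluster_counts:
        present = sorted(counts)
        for a_pos, ta in enumerate(present):
            for tb in present[a_pos + 1:]:
                i, j = idx[ta], idx[tb]
                w = 1 if count_mode == "clusters" else counts[ta] * counts[tb]
                adj[i, j] += w
                adj[j, i] += w
    return pd.DataFrame(adj, index=taxa, columns=taxa)


def to_edge_list(adj: pd.DataFrame) -> nx.Graph:
    """Convert a symmetric zero-diagonal adjacency matrix to a weighted
    undirected graph (the edge-list database), keeping isolated nodes."""
    values = adj.to_numpy(dtype=float)
    if values.shape[0] != values.shape[1] or not np.allclose(values, values.T):
        raise ValidationError("adjacency matrix must be square and symmetric")
    if np.any(np.diag(values) != 0):
        raise ValidationError("adjacency matrix must have a zero diagonal")
    g = nx.Graph()
    g.add_nodes_from(adj.index)
    taxa = list(adj.index)
    rows, cols = np.nonzero(np.triu(values, k=1))
    for i, j in zip(rows, cols):
        g.add_edge(taxa[i], taxa[j], weight=float(values[i, j]))
    return g


def to_adjacency(g: nx.Graph) -> pd.DataFrame:
    """Inverse of :func:`to_edge_list` (lossless round-trip)."""
    taxa = list(g.nodes)
    return pd.DataFrame(
        nx.to_numpy_array(g, nodelist=taxa, weight="weight"), index=taxa, columns=taxa
    )


def query_subnetwork(
    db: nx.Graph, taxa: Sequence[str]
) -> tuple[nx.Graph, list[str]]:
    """Induced subgraph of the database on the requested taxa.

    Returns the subgraph (requested taxa found in the database, with the
    edges among them) and the list of requested-but-absent taxa, which
    drives the intersection step of validation.
    """
    if not taxa:
        raise ValidationError("empty taxon query")
    present = [t for t in taxa if t in db]
    absent = [t for t in taxa if t not in db]
    sub = nx.Graph(db.subgraph(present))
    return sub, absent


def write_edge_list_tsv(g: nx.Graph, path: str | Path) -> None:
    """Write the network as a TSV edge list; isolated nodes are preserved in
    a ``#nodes=`` comment so round-trips are lossless."""
    lines = ["#nodes=" + ",".join(str(n) for n in g.nodes)]
    lines.append("taxon_a\ttaxon_b\tweight")
    for a, b, w in g.edges(data="weight"):
        lines.append(f"{a}\t{b}\t{w}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_edge_list_tsv(path: str | Path) -> nx.Graph:
    g = nx.Graph()
    lines = Path(path).read_text().splitlines()
    for line in lines:
        if line.startswith("#nodes="):
            nodes = line[len("#nodes="):]
            if nodes:
                g.add_nodes_from(nodes.split(","))
    for line in lines:
        if line.startswith("#") or line.startswith("taxon_a") or not line.strip():
            continue
        a, b, w = line.split("\t")
        g.add_edge(a, b, weight=float(w))
    return g
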