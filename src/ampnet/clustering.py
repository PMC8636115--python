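"""Greedy identity-threshold peptide clustering.

Peptides from all taxa are grouped CD-HIT style: sorted longest-first, each
peptide joins the first existing cluster whose representative is at least
``threshold`` identical to it, otherwise it founds a new cluster.  Because
processing is longest-first, a cluster's representative is always its longest
member (ties broken lexicographically), and the procedure is deterministic.

Identity between two peptides is the maximum number of matched residues over
all global alignments, divided by the length of the shorter sequence (the
CD-HIT convention); ``denominator="longer"`` is available as a stricter
alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from Bio import Align

from ampnet.exceptions import ValidationError


def _max_match_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = 0.0
    aligner.extend_gap_score = 0.0
    return aligner


_ALIGNER = _max_match_aligner()


def pairwise_identity(a: str, b: str, denominator: str = "shorter") -> float:
    """Global-alignment identity between two peptides, in [0, 1].

    Matches are counted under the alignment maximizing them (match 1,
    mismatch 0, no gap penalty), which makes the measure symmetric and
    deterministic.  The denominator is the shorter sequence by default.
    """
    if not a or not b:
        raise ValidationError("pairwise_identity requires non-empty sequences")
    matches = _ALIGNER.score(a, b)
    if denominator == "shorter":
        denom = min(len(a), len(b))
    elif denominator == "longer":
        denom = max(len(a), len(b))
    else:
        raise ValidationError(f"unknown denominator {denominator!r}")
    return float(matches) / denom


@dataclass
class PeptideCluster:
    """A group of near-identical peptides; size 1 = a "unique AMP"."""

    cluster_id: int
    representative: str
    members: list[tuple[str, str]] = field(default_factory=list)  # (sequence, taxon_id)

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ClusterSet:
    """A full clustering of an input peptide list."""

    clusters: list[PeptideCluster]
    threshold: float

    @property
    def n_unique(self) -> int:
        return sum(1 for c in self.clusters if c.size == 1)

    def membership(self) -> dict[tuple[str, str], int]:
        """Map ``(sequence, taxon_id)`` to cluster_id.  Duplicate peptides
        within one taxon land in the same cluster, so the map is well
        defined."""
        out: dict[tuple[str, str], int] = {}
        for c in self.clusters:
            for m in c.members:
                out[m] = c.cluster_id
        return out

    def taxon_clusters(self) -> dict[str, set[int]]:
        """Map taxon_id to the set of cluster ids it contributes to."""
        out: dict[str, set[int]] = {}
        for c in self.clusters:
            for _, taxon in c.members:
                out.setdefault(taxon, set()).add(c.cluster_id)
        return out


def greedy_cluster(
    peptides: Sequence[tuple[str, str]],
    threshold: float = 0.8,
    *,
    strict: bool = False,
    denominator: str = "shorter",
) -> ClusterSet:
    """Cluster ``(sequence, taxon_id)`` peptides at an identity threshold.

    ``strict=False`` (default) admits members at identity >= threshold,
    matching CD-HIT's ``-c`` semantics for a ">80%" cutoff of 0.8;
    ``strict=True`` requires identity strictly above the threshold.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValidationError(f"threshold must be in (0, 1], got {threshold}")
    ordered = sorted(peptides, key=lambda p: (-len(p[0]), p[0], p[1]))
    clusters: list[PeptideCluster] = []
    for seq, taxon in ordered:
        placed = False
        for cluster in clusters:
            ident = pairwise_identity(seq, cluster.representative, denominator)
            if ident > threshold or (not strict and ident == threshold):
                cluster.members.append((seq, taxon))
                placed = True
                break
        if not placed:
            clusters.append(
                PeptideCluster(
                    cluster_id=len(clusters), representative=seq, members=[(seq, taxon)]
                )
            )
    return ClusterSet(clusters=clusters, threshold=threshold)


def cluster_size_histogram(cs: ClusterSet) -> dict[int, int]:
    """Cluster-size distribution: map size -> number of clusters."""
    hist: dict[int, int] = {}
    for c in cs.clusters:
        hist[c.size] = hist.get(c.size, 0) + 1
    return hist


def write_clusters_tsv(cs: ClusterSet, path: str | Path) -> None:
    """Write clusters in a .clstr-like TSV: one member per row with its
    identity to the representative."""
    lines = ["cluster_id\tis_representative\tpeptide\ttaxon_id\tidentity_to_rep"]
    for c in cs.clusters:
        for seq, taxon in c.members:
            is_rep = int(seq == c.representative)
            ident = pairwise_identity(seq, c.representative)
            lines.append(f"{c.cluster_id}\t{is_rep}\t{seq}\t{taxon}\t{ident:.4f}")
    Path(path).write_text("\n".join(lines) + "\n")
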