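"""The Die score: a node statistic marking taxa likely to be outcompeted.

For a node i in a network of n taxa,

    D_i = (N_i - S_i) / N_p

where N_p = (n^2 - n)/2 is the number of possible node pairs, deg_i the
number of (out-)neighbors of i, N_i = N_p - deg_i the number of pairs i is
not linked into, and S_i the node strength — the sum of i's (outgoing) edge
weights.  An isolated node attains D_i = 1 exactly (most likely to "die");
strongly and heavily connected nodes score low.

With ``normalize_weights=True`` (default) all weights are first divided by
the maximum weight, which guarantees S_i <= deg_i <= N_p and hence
D_i in [-1, 1].  With raw weights (e.g., shared-cluster counts) S_i can
exceed N_p and the score can fall below -1; that mode is retained for
sensitivity analysis.

Scores are z-normalized per network (subtract the mean, divide by the
sample standard deviation) before networks are compared.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from ampnet.exceptions import UndefinedStatisticError, ValidationError

#: Columns of a Die score table.
SCORE_COLUMNS = ["taxon_id", "network", "deg", "strength", "n_non_neighbors",
                 "raw_die", "z_die"]


def normalize_scores(raw: Sequence[float]) -> np.ndarray:
    """z-normalize: subtract the mean, divide by the sample SD (n-1).

    Strictly monotone, so ranks are preserved.
    """
    x = np.asarray(raw, dtype=float)
    if x.size < 2:
        raise UndefinedStatisticError("z-normalization needs at least 2 scores")
    sd = x.std(ddof=1)
    if sd == 0:
        raise UndefinedStatisticError(
            "all scores identical (zero SD); use raw scores instead"
        )
    return (x - x.mean()) / sd


def die_scores(
    net: nx.Graph | nx.DiGraph,
    *,
    normalize_weights: bool = True,
    network_label: str = "BW",
) -> pd.DataFrame:
    """Compute raw and z-normalized Die scores for every node.

    For undirected networks, deg_i counts neighbors and S_i sums incident
    edge weights; for bi-directed networks, deg_i counts out-neighbors and
    S_i sums outgoing edge weights (out-edges carry the source node's
    abundance by construction, in-edges are ignored).

    z-scores are computed over the full node set of this network, before any
    intersection with a partner network.  If all raw scores coincide the
    z column is NaN and a warning is issued.
    """
    n = net.number_of_nodes()
    if n < 2:
        raise ValidationError(f"Die score needs at least 2 nodes, got {n} (N_p = 0)")
    n_pairs = (n * n - n) / 2.0

    weights = [w for _, _, w in net.edges(data="weight", default=1.0)]
    scale = 1.0
    if normalize_weights and weights:
        max_w = max(weights)
        if max_w <= 0:
            raise ValidationError("non-positive edge weights")
        scale = max_w

    rows = []
    for node in net.nodes:
        if net.is_directed():
            deg = net.out_degree(node)
            strength = sum(w for _, _, w in net.out_edges(node, data="weight", default=1.0))
        else:
            deg = net.degree(node)
            strength = sum(w for _, _, w in net.edges(node, data="weight", default=1.0))
        strength /= scale
        n_non = n_pairs - deg
        raw = (n_non - strength) / n_pairs
        rows.append((str(node), network_label, int(deg), float(strength),
                     n_non, raw))
    df = pd.DataFrame(
        rows, columns=SCORE_COLUMNS[:6]
    ).sort_values("taxon_id", kind="stable", ignore_index=True)
    sd = df["raw_die"].std(ddof=1)
    if sd > 0:
        df["z_die"] = normalize_scores(df["raw_die"].to_numpy())
    else:
        warnings.warn(
            f"{network_label}: all raw Die scores identical; z_die set to NaN",
            stacklevel=2,
        )
        df["z_die"] = np.nan
    return df


def write_scores_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_scores_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
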