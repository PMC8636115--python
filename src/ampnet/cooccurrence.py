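"""Microbiome co-occurrence networks from taxon-by-sample count tables.

Edges link taxa whose per-sample relative abundances correlate beyond a
strength cutoff (|rho| >= ``rho_cut``) at a raw significance cutoff
(p <= ``p_cut``).  For Die scoring the undirected network is transformed
into a bi-directed graph in which every out-edge of a node carries that
node's relative abundance, so a node's out-strength reflects both how
connected and how abundant it is.

Abundance tables are plain TSVs: taxa as rows (first column ``taxon_id``),
samples as columns, counts as values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from ampnet.exceptions import ValidationError


@dataclass(frozen=True)
class CoocConfig:
    """Co-occurrence inference settings.

    method: "spearman" (default; robust on compositional proportions) or
    "pearson".  sign selects positive or negative co-occurrence.  p-values
    are raw by default; ``bh_correct=True`` applies Benjamini-Hochberg
    across all pairs before thresholding.
    """

    method: str = "spearman"
    rho_cut: float = 0.4
    p_cut: float = 0.05
    sign: str = "positive"
    bh_correct: bool = False

    def __post_init__(self) -> None:
        if self.method not in ("spearman", "pearson"):
            raise ValidationError(f"unknown method {self.method!r}")
        if not 0.0 < self.rho_cut < 1.0:
            raise ValidationError("rho_cut must be in (0, 1)")
        if not 0.0 < self.p_cut < 1.0:
            raise ValidationError("p_cut must be in (0, 1)")
        if self.sign not in ("positive", "negative"):
            raise ValidationError(f"unknown sign {self.sign!r}")


def read_abundance_tsv(path: str | Path) -> pd.DataFrame:
    """Read a taxa-by-samples count table (first column: taxon_id)."""
    tbl = pd.read_csv(path, sep="\t", index_col=0)
    if (tbl.to_numpy() < 0).any():
        raise ValidationError("abundance table contains negative counts")
    return tbl


def _proportions(tbl: pd.DataFrame) -> pd.DataFrame:
    colsums = tbl.sum(axis=0)
    zero = colsums[colsums == 0]
    if len(zero):
        raise ValidationError(f"all-zero sample column(s): {list(zero.index)}")
    return tbl / colsums


def relative_abundance(
    tbl: pd.DataFrame, samples: Sequence[str] | None = None
) -> dict[str, float]:
    """Mean per-sample proportion of each taxon over a sample group, rescaled
    by the maximum so values lie in (0, 1].

    The rescaling keeps out-strengths on the bi-directed network commensurate
    with max-normalized shared-AMP edge weights, so a single Die
    implementation serves both networks.
    """
    sub = tbl if samples is None else tbl[list(samples)]
    if sub.shape[1] < 1:
        raise ValidationError("relative_abundance needs at least one sample")
    mean_prop = _proportions(sub).mean(axis=1)
    top = mean_prop.max()
    if top == 0:
        raise ValidationError("all taxa have zero abundance in this group")
    return {t: float(v / top) for t, v in mean_prop.items()}


def _correlation_matrices(
    props: np.ndarray, method: str
) -> tuple[np.ndarray, np.ndarray]:
    """rho and p matrices over taxa (rows of ``props``)."""
    n_samples = props.shape[1]
    if method == "spearman":
        rho, p = stats.spearmanr(props.T)
        if props.shape[0] == 2:  # scipy returns scalars for two variables
            rho = np.array([[1.0, rho], [rho, 1.0]])
            p = np.array([[0.0, p], [p, 0.0]])
    else:
        rho = np.corrcoef(props)
        # two-sided t-approximation for Pearson's r
        with np.errstate(divide="ignore", invalid="ignore"):
            t = rho * np.sqrt((n_samples - 2) / np.clip(1 - rho**2, 1e-300, None))
        p = 2 * stats.t.sf(np.abs(t), df=n_samples - 2)
    return rho, p


def cooccurrence_network(
    tbl: pd.DataFrame,
    cfg: CoocConfig = CoocConfig(),
    samples: Sequence[str] | None = None,
) -> nx.Graph:
    """Infer the co-occurrence network over a sample group.

    Taxa constant across the group (including all-zero taxa) have undefined
    correlations and are excluded with a warning.  Edge weight = |rho|.
    """
    sub = tbl if samples is None else tbl[list(samples)]
    if sub.shape[1] < 3:
        raise ValidationError("co-occurrence needs at least 3 samples")
    props = _proportions(sub)
    constant = props.index[props.nunique(axis=1) <= 1]
    if len(constant):
        warnings.warn(
            f"excluding {len(constant)} constant taxa from co-occurrence: "
            f"{list(constant)}",
            stacklevel=2,
        )
        props = props.drop(index=constant)
    taxa = list(props.index)
    g = nx.Graph()
    g.add_nodes_from(taxa)
    if len(taxa) < 2:
        return g

    rho, p = _correlation_matrices(props.to_numpy(), cfg.method)
    iu, ju = np.triu_indices(len(taxa), k=1)
    pvals = p[iu, ju]
    if cfg.bh_correct:
        from statsmodels.stats.multitest import multipletests

        pvals = multipletests(pvals, method="fdr_bh")[1]
    for i, j, pv in zip(iu, ju, pvals):
        r = rho[i, j]
        if np.isnan(r) or np.isnan(pv):
            continue
        sign_ok = r > 0 if cfg.sign == "positive" else r < 0
        if sign_ok and abs(r) >= cfg.rho_cut and pv <= cfg.p_cut:
            g.add_edge(taxa[i], taxa[j], weight=float(abs(r)))
    return g


def to_bidirected(net: nx.Graph, abund: Mapping[str, float]) -> nx.DiGraph:
    """Transform a co-occurrence network into bi-directed form.

    Every undirected edge (i, j) becomes i->j weighted by i's relative
    abundance and j->i weighted by j's.  Nodes with zero abundance produce
    zero-weight out-edges, which are dropped.  Node count is preserved.
    """
    missing = [n for n in net.nodes if n not in abund]
    if missing:
        raise ValidationError(f"nodes without abundance values: {missing}")
    g = nx.DiGraph()
    for n in net.nodes:
        g.add_node(n, abundance=float(abund[n]))
    for a, b in net.edges:
        if abund[a] > 0:
            g.add_edge(a, b, weight=float(abund[a]))
        if abund[b] > 0:
            g.add_edge(b, a, weight=float(abund[b]))
    return g


def write_directed_edge_list_tsv(g: nx.DiGraph, path: str | Path) -> None:
    lines = ["#nodes=" + ",".join(str(n) for n in g.nodes)]
    lines.append("source\ttarget\tweight")
    for a, b, w in g.edges(data="weight"):
        lines.append(f"{a}\t{b}\t{w}")
    Path(path).write_text("\n".join(lines) + "\n")
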