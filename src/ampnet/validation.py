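"""Validation statistics comparing Die score lists from two networks.

Four procedures compare the ranking of taxa by Die score in the shared-AMP
(BW) network against the ranking in the microbiome co-occurrence (MB)
network, on the intersection of their taxon sets:

1. *Extreme-value Pearson correlation*: Pearson's r over the k highest- and
   k lowest-scoring taxa of the BW list, paired with their MB scores.  With
   k = 1 an r of 1 simply certifies that the most- and least-likely-to-die
   taxa agree in order between the networks.
2. *Dist rank distance*: rank both lists ascending (lowest Die = rank 1,
   average ranks on ties) and take the absolute rank difference per taxon.
3. *Skewness of Dist*: agreement between the rankings concentrates Dist near
   zero with a long right tail, i.e., positive skew.  Skewness is the
   type-2 sample statistic G1 = g1 * sqrt(n(n-1))/(n-2); the verdict is
   positive when G1 > 0.4 or the median of Dist lies strictly closer to the
   first quartile than to the third.
4. *Wilcoxon signed-rank* on the paired rank lists: a large p-value means no
   evidence that the two rankings differ in distribution.
"""

from __future__ import annotations

import importlib.resources
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ampnet.exceptions import UndefinedStatisticError, ValidationError


def rank_scores(values: Sequence[float]) -> np.ndarray:
    """Ascending ranks; the lowest value gets rank 1, ties get the average
    of the tied positions."""
    x = np.asarray(values, dtype=float)
    if x.size < 1:
        raise ValidationError("rank_scores needs at least one value")
    return stats.rankdata(x, method="average")


def dist_measure(rank_a, rank_b):
    """Absolute difference between two rank values (scalar or array)."""
    return np.abs(np.asarray(rank_a, dtype=float) - np.asarray(rank_b, dtype=float))


def skewness_g1(values: Sequence[float]) -> float:
    """Type-2 sample skewness G1 = g1 * sqrt(n(n-1))/(n-2), where g1 is the
    moment-estimator skewness m3 / m2^(3/2)."""
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise UndefinedStatisticError("skewness needs at least 3 values")
    if np.var(x) == 0:
        raise UndefinedStatisticError("skewness undefined for zero variance")
    g1 = stats.skew(x, bias=True)
    return float(g1 * np.sqrt(n * (n - 1)) / (n - 2))


@dataclass(frozen=True)
class SkewVerdict:
    """Outcome of the positive-skew assessment with both criteria recorded."""

    g1: float
    q1: float
    median: float
    q3: float
    skew_criterion: bool       # G1 > 0.4
    quartile_criterion: bool   # |median - Q1| < |median - Q3|
    positive: bool

    def as_dict(self) -> dict:
        return {
            "g1": self.g1, "q1": self.q1, "median": self.median, "q3": self.q3,
            "skew_criterion": self.skew_criterion,
            "quartile_criterion": self.quartile_criterion,
            "positive": self.positive,
        }


def assess_positive_skew(dists: Sequence[float]) -> SkewVerdict:
    """Positive-skew verdict for a Dist distribution: G1 > 0.4 and/or the
    median strictly closer to Q1 than to Q3 (linear-interpolation
    quartiles)."""
    x = np.asarray(dists, dtype=float)
    if x.size < 4:
        raise UndefinedStatisticError("skew assessment needs at least 4 values")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    try:
        g1 = skewness_g1(x)
    except UndefinedStatisticError:
        g1 = 0.0
    skew_ok = bool(g1 > 0.4)
    quart_ok = bool(abs(med - q1) < abs(med - q3))
    return SkewVerdict(
        g1=float(g1), q1=float(q1), median=float(med), q3=float(q3),
        skew_criterion=skew_ok, quartile_criterion=quart_ok,
        positive=skew_ok or quart_ok,
    )


def intersect_tables(
    bw: pd.DataFrame, mb: pd.DataFrame
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Inner-join two Die score tables on taxon_id.

    Returns the paired table (columns taxon_id, z_die_bw, z_die_mb) plus the
    taxa present only in the BW table and only in the MB table.
    """
    bw_taxa = set(bw["taxon_id"])
    mb_taxa = set(mb["taxon_id"])
    only_bw = sorted(bw_taxa - mb_taxa)
    only_mb = sorted(mb_taxa - bw_taxa)
    pairs = pd.merge(
        bw[["taxon_id", "z_die"]].rename(columns={"z_die": "z_die_bw"}),
        mb[["taxon_id", "z_die"]].rename(columns={"z_die": "z_die_mb"}),
        on="taxon_id",
    ).sort_values("taxon_id", kind="stable", ignore_index=True)
    if pairs.empty:
        raise UndefinedStatisticError("empty taxon intersection between networks")
    return pairs, only_bw, only_mb


def pearson_extremes(pairs: pd.DataFrame, k: int = 1) -> float:
    """Pearson's r over the k highest- and k lowest-BW-scoring taxa.

    Selection uses the BW z-scores only (order statistics); ties at the k-th
    extreme are broken lexicographically by taxon_id for determinism.
    """
    m = len(pairs)
    if k < 1:
        raise ValidationError("k must be >= 1")
    if m < 2 * k:
        raise ValidationError(f"need at least 2k={2 * k} paired taxa, got {m}")
    ordered = pairs.sort_values(
        ["z_die_bw", "taxon_id"], kind="stable", ignore_index=True
    )
    chosen = pd.concat([ordered.head(k), ordered.tail(k)])
    x = chosen["z_die_bw"].to_numpy(dtype=float)
    y = chosen["z_die_mb"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError(
            "Pearson correlation undefined: zero variance among selected extremes"
        )
    if len(x) == 2:
        # two-point correlation is analytically ±1; avoid fp round-off
        return 1.0 if (x[1] - x[0]) * (y[1] - y[0]) > 0 else -1.0
    return float(np.corrcoef(x, y)[0, 1])


def wilcoxon_signed_rank(
    rank_bw: Sequence[float], rank_mb: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired rank lists.

    Zero differences are dropped; the exact null distribution is used for up
    to 25 informative pairs when possible, otherwise the normal approximation
    with continuity correction.  If every difference is zero the test is
    degenerate and (0, 1) is returned with a warning.
    """
    d = np.asarray(rank_bw, dtype=float) - np.asarray(rank_mb, dtype=float)
    nonzero = d[d != 0]
    if nonzero.size == 0:
        warnings.warn("all rank differences are zero; degenerate test, p = 1",
                      stacklevel=2)
        return 0.0, 1.0
    method = "exact" if nonzero.size <= 25 else "approx"
    try:
        res = stats.wilcoxon(nonzero, alternative="two-sided", method=method,
                             correction=(method == "approx"))
    except ValueError:
        # exact method rejects ties in |d|; fall back to the approximation
        res = stats.wilcoxon(nonzero, alternative="two-sided", method="approx",
                             correction=True)
    return float(res.statistic), float(res.pvalue)


@dataclass
class ValidationReport:
    """All four validation outcomes for one BW/MB network pair."""

    pairs: pd.DataFrame  # taxon_id, z_die_bw, z_die_mb, rank_bw, rank_mb, dist
    only_bw: list[str]
    only_mb: list[str]
    pearson_extremes: dict[int, float]
    skew: SkewVerdict
    wilcoxon_statistic: float
    wilcoxon_p: float
    extra: dict = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "n_intersected": int(len(self.pairs)),
            "only_bw": self.only_bw,
            "only_mb": self.only_mb,
            "pearson_extremes": {str(k): v for k, v in self.pearson_extremes.items()},
            "skew": self.skew.as_dict(),
            "wilcoxon": {"statistic": self.wilcoxon_statistic, "p": self.wilcoxon_p},
            **self.extra,
        }

    def write(self, directory: str | Path, stem: str = "validation") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.pairs.to_csv(directory / f"{stem}.tsv", sep="\t", index=False)
        (directory / f"{stem}.json").write_text(
            json.dumps(self.summary(), indent=2) + "\n"
        )

    def plot_dist_histogram(self, path: str | Path) -> None:
        """Histogram of Dist values for visual skew inspection."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, 3))
        ax.hist(self.pairs["dist"], bins="auto", color="#557f9f", edgecolor="white")
        ax.set_xlabel("Dist (|rank difference|)")
        ax.set_ylabel("taxa")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def validate_networks(
    bw: pd.DataFrame, mb: pd.DataFrame, ks: Sequence[int] = (1, 2, 3)
) -> ValidationReport:
    """Run all four validation procedures on two Die score tables."""
    pairs, only_bw, only_mb = intersect_tables(bw, mb)
    pairs = pairs.copy()
    pairs["rank_bw"] = rank_scores(pairs["z_die_bw"])
    pairs["rank_mb"] = rank_scores(pairs["z_die_mb"])
    pairs["dist"] = dist_measure(pairs["rank_bw"], pairs["rank_mb"])

    extremes: dict[int, float] = {}
    for k in ks:
        if len(pairs) >= 2 * k:
            try:
                extremes[k] = pearson_extremes(pairs, k)
            except UndefinedStatisticError:
                extremes[k] = float("nan")
    skew = assess_positive_skew(pairs["dist"])
    w_stat, w_p = wilcoxon_signed_rank(pairs["rank_bw"], pairs["rank_mb"])
    return ValidationReport(
        pairs=pairs,
        only_bw=only_bw,
        only_mb=only_mb,
        pearson_extremes=extremes,
        skew=skew,
        wilcoxon_statistic=w_stat,
        wilcoxon_p=w_p,
    )


def load_nash_example() -> pd.DataFrame:
    """Worked example: published z-normalized Die scores for ten genera from
    a NASH (non-alcoholic steatohepatitis) gut-microbiome case study.

    The printed ranks are positions within that study's full ~32-genus
    intersection, so they are order-consistent with — but not re-derivable
    from — the ten excerpted score values alone.  ``dist`` is the absolute
    rank difference.
    """
    ref = importlib.resources.files("ampnet") / "data" / "nash_die_scores.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")
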