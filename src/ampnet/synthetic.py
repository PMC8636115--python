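"""Synthetic data with planted ground truth for the whole pipeline.

The generator emulates the statistical structure the shared-AMP competition
hypothesis assumes: taxa fall into *compatibility blocks*; every taxon in a
block carries (lightly mutated) copies of the block's AMP motifs, so
within-block pairs share peptide clusters and acquire network edges, while
between-block pairs do not.  Abundance tables are generated so that their
co-occurrence structure either mirrors the blocks (``concordant``),
opposes them (``discordant``: the block-size profile is reversed over the
taxa, so members of large AMP blocks become co-occurrence loners and vice
versa), or ignores them (``null``: all taxa independent).

Background protein sequence is uniform over the 20 residues; motif residues
are drawn from the low-index (antimicrobial) subset of the scanner's
propensity index, so planted motifs — and essentially nothing else — are
detected as putative AMPs.

Defaults were chosen with ``scripts/calibrate_synth.py``; see
docs/methods.md for the calibration summary.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from ampnet.exceptions import ValidationError
from ampnet.ingest import (
    AMINO_ACIDS,
    PropensityIndex,
    ProteinRecord,
    default_index,
)


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic benchmark.

    ``block_sizes`` partitions the taxa, in order, into compatibility
    blocks; unequal sizes give the Die score something to rank.  The
    mutation rate per planted motif copy is kept well below the clustering
    threshold's tolerance (0.02 on 20-mers leaves expected identity ~0.98).
    """

    n_taxa: int = 12
    block_sizes: tuple[int, ...] = (6, 3, 2, 1)
    motifs_per_block: int = 3
    unique_motifs_per_taxon: int = 2
    proteins_per_taxon: int = 10
    protein_length: int = 120
    motif_length: int = 20
    mutation_rate: float = 0.02
    n_samples: int = 40
    concordance: str = "concordant"
    seed: int = 0
    factor_sigma: float = 1.0
    nb_size: float = 5.0
    base_low: float = 50.0
    base_high: float = 200.0

    def __post_init__(self) -> None:
        if sum(self.block_sizes) != self.n_taxa:
            raise ValidationError(
                f"block_sizes {self.block_sizes} do not partition {self.n_taxa} taxa"
            )
        if self.motif_length > self.protein_length:
            raise ValidationError("motif longer than protein")
        if not 0.0 <= self.mutation_rate < 1.0:
            raise ValidationError("mutation_rate must be in [0, 1)")
        if self.proteins_per_taxon < self.motifs_per_block + self.unique_motifs_per_taxon:
            raise ValidationError(
                "need at least one protein per planted motif "
                f"({self.motifs_per_block + self.unique_motifs_per_taxon})"
            )
        if self.concordance not in ("concordant", "discordant", "null"):
            raise ValidationError(f"unknown concordance {self.concordance!r}")

    @property
    def taxa(self) -> list[str]:
        return [f"Taxon{i + 1:02d}" for i in range(self.n_taxa)]

    @property
    def blocks(self) -> list[list[str]]:
        """Compatibility blocks (AMP sharing), in taxa order."""
        return _partition(self.taxa, self.block_sizes)

    @property
    def abundance_blocks(self) -> list[list[str]]:
        """Co-occurrence blocks for the abundance table."""
        if self.concordance == "concordant":
            return self.blocks
        if self.concordance == "discordant":
            # same block-size profile, taxa order reversed: members of large
            # AMP blocks land in small co-occurrence blocks and vice versa
            return _partition(list(reversed(self.taxa)), self.block_sizes)
        return [[t] for t in self.taxa]


def _partition(taxa: list[str], sizes: tuple[int, ...]) -> list[list[str]]:
    out, i = [], 0
    for s in sizes:
        out.append(taxa[i:i + s])
        i += s
    return out


def _low_residues(index: PropensityIndex) -> list[str]:
    low = [a for a in AMINO_ACIDS if index.scores[a] < index.threshold]
    if not low:
        raise ValidationError("propensity index has no low-index residues")
    return low


def _random_motif(rng: np.random.Generator, low: list[str], length: int) -> str:
    return "".join(rng.choice(low, size=length))


def _mutate(rng: np.random.Generator, motif: str, rate: float, low: list[str]) -> str:
    if rate == 0:
        return motif
    out = list(motif)
    for i, c in enumerate(out):
        if rng.random() < rate:
            choices = [a for a in low if a != c]
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def generate_proteomes(
    cfg: SynthConfig,
    index: PropensityIndex | None = None,
    out_dir: str | Path | None = None,
) -> tuple[dict[str, list[ProteinRecord]], dict]:
    """Generate per-taxon proteomes with planted AMP motifs.

    Returns the records per taxon and a ground-truth manifest recording
    every plant (taxon, protein, position, motif id).  If ``out_dir`` is
    given, one FASTA per taxon plus ``manifest.json`` are written; output is
    byte-identical for a fixed config.
    """
    index = index or default_index()
    if cfg.motif_length < index.min_stretch:
        raise ValidationError(
            f"motif_length {cfg.motif_length} below scanner min_stretch "
            f"{index.min_stretch}: planted motifs would be invisible"
        )
    rng = np.random.default_rng(cfg.seed)
    low = _low_residues(index)
    aa = list(AMINO_ACIDS)

    block_motifs = {
        b: [_random_motif(rng, low, cfg.motif_length) for _ in range(cfg.motifs_per_block)]
        for b in range(len(cfg.block_sizes))
    }
    proteomes: dict[str, list[ProteinRecord]] = {}
    plants: list[dict] = []
    unique_motifs: dict[str, list[str]] = {}

    for b, block in enumerate(cfg.blocks):
        for taxon in block:
            uniques = [
                _random_motif(rng, low, cfg.motif_length)
                for _ in range(cfg.unique_motifs_per_taxon)
            ]
            unique_motifs[taxon] = uniques
            seqs = [
                "".join(rng.choice(aa, size=cfg.protein_length))
                for _ in range(cfg.proteins_per_taxon)
            ]
            # each planted motif goes into its own protein
            to_plant = [(f"block{b}_m{m}", motif) for m, motif in enumerate(block_motifs[b])]
            to_plant += [(f"{taxon}_u{m}", motif) for m, motif in enumerate(uniques)]
            hosts = rng.permutation(cfg.proteins_per_taxon)[: len(to_plant)]
            for (motif_id, motif), host in zip(to_plant, hosts):
                copy = _mutate(rng, motif, cfg.mutation_rate, low)
                pos = int(rng.integers(0, cfg.protein_length - cfg.motif_length + 1))
                s = seqs[host]
                seqs[host] = s[:pos] + copy + s[pos + cfg.motif_length:]
                plants.append(
                    {
                        "taxon": taxon,
                        "protein": f"{taxon}_P{host + 1:02d}",
                        "motif_id": motif_id,
                        "start": pos,
                        "end": pos + cfg.motif_length,
                        "sequence": copy,
                    }
                )
            proteomes[taxon] = [
                ProteinRecord(
                    accession=f"{taxon}_P{i + 1:02d}",
                    taxon_id=taxon,
                    description=f"sp|{taxon}_P{i + 1:02d}| synthetic protein",
                    sequence=seq,
                    curated=True,
                )
                for i, seq in enumerate(seqs)
            ]

    manifest = {
        "config": {
            "n_taxa": cfg.n_taxa,
            "block_sizes": list(cfg.block_sizes),
            "seed": cfg.seed,
            "concordance": cfg.concordance,
        },
        "blocks": [list(b) for b in cfg.blocks],
        "block_motifs": {str(k): v for k, v in block_motifs.items()},
        "unique_motifs": unique_motifs,
        "plants": plants,
    }
    if out_dir is not None:
        _write_outputs(proteomes, manifest, Path(out_dir))
    return proteomes, manifest


def _write_outputs(
    proteomes: Mapping[str, list[ProteinRecord]], manifest: dict, out_dir: Path
) -> None:
    import json

    out_dir.mkdir(parents=True, exist_ok=True)
    for taxon, records in proteomes.items():
        lines = []
        for r in records:
            lines.append(f">sp|{r.accession}|{r.accession} synthetic protein")
            lines.append(r.sequence)
        (out_dir / f"{taxon}.fasta").write_text("\n".join(lines) + "\n")
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def generate_abundances(cfg: SynthConfig) -> pd.DataFrame:
    """Generate a taxa-by-samples count table with block co-occurrence.

    Each abundance block shares a lognormal latent factor per sample; taxon
    counts are negative binomial around ``baseline * factor``, giving strong
    within-block rank correlation and independence across blocks.
    """
    if cfg.n_samples < 3:
        raise ValidationError("need at least 3 samples")
    rng = np.random.default_rng([cfg.seed, 7919])
    taxa = cfg.taxa
    baselines = rng.uniform(cfg.base_low, cfg.base_high, size=cfg.n_taxa)
    block_of = {
        t: b for b, block in enumerate(cfg.abundance_blocks) for t in block
    }
    n_blocks = len(cfg.abundance_blocks)
    factors = rng.lognormal(
        mean=0.0, sigma=cfg.factor_sigma, size=(n_blocks, cfg.n_samples)
    )
    counts = np.zeros((cfg.n_taxa, cfg.n_samples), dtype=int)
    for i, t in enumerate(taxa):
        mu = baselines[i] * factors[block_of[t]]
        p = cfg.nb_size / (cfg.nb_size + mu)
        counts[i] = rng.negative_binomial(cfg.nb_size, p)
    samples = [f"S{j + 1:02d}" for j in range(cfg.n_samples)]
    return pd.DataFrame(counts, index=pd.Index(taxa, name="taxon_id"), columns=samples)
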