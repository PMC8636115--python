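"""Proteome ingestion and putative-AMP scanning.

Putative antimicrobial peptides (AMPs) are detected with a sliding-window
propensity scanner: every residue carries an "antimicrobial index" derived
from IC50-like potency data, so **low index means antimicrobial** (a potent
peptide has a low inhibitory concentration).  Windows whose mean index falls
below a threshold are merged into stretches; stretches at least
``min_stretch`` residues long are reported as putative AMPs.

The scanner is a contract plus a configurable stand-in index: any per-residue
index in the same shape can be supplied as a TSV, and precomputed peptide
tables from an external predictor can be ingested unchanged via
:func:`read_peptides_tsv`.

All coordinates are 0-based, half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

from ampnet.exceptions import UndefinedStatisticError, ValidationError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID_CHARS = frozenset(AMINO_ACIDS + "X")

#: Stand-in per-residue antimicrobial index (low = antimicrobial).  Cationic
#: and bulky hydrophobic residues typical of membrane-active peptides score
#: low; acidic and small polar residues score high.  Values are on the same
#: 0-1 scale as the default threshold below.
DEFAULT_INDEX_SCORES: Mapping[str, float] = {
    "K": 0.05, "R": 0.06, "W": 0.08, "F": 0.10,
    "I": 0.11, "L": 0.12, "V": 0.13, "Y": 0.14,
    "H": 0.60, "A": 0.65, "G": 0.66, "C": 0.70,
    "M": 0.72, "T": 0.75, "S": 0.78, "P": 0.80,
    "Q": 0.82, "N": 0.85, "D": 0.90, "E": 0.95,
}


@dataclass(frozen=True)
class ProteinRecord:
    """One protein of a taxon's proteome."""

    accession: str
    taxon_id: str
    description: str
    sequence: str
    curated: bool

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"{self.accession}: empty sequence")
        bad = set(self.sequence) - _VALID_CHARS
        if bad:
            raise ValidationError(
                f"{self.accession}: invalid residue(s) {sorted(bad)!r} "
                "(expected the 20 standard amino acids or X)"
            )


@dataclass(frozen=True)
class PropensityIndex:
    """Per-residue antimicrobial index plus scanner settings.

    Parameters
    ----------
    scores
        Map from each of the 20 standard residues to its index value.
    window_length
        Sliding-window size in residues.
    threshold
        Windows with mean index strictly below this are antimicrobial.
    min_stretch
        Minimum reported stretch length in residues.
    """

    scores: Mapping[str, float]
    window_length: int = 7
    threshold: float = 0.225
    min_stretch: int = 12

    def __post_init__(self) -> None:
        missing = set(AMINO_ACIDS) - set(self.scores)
        if missing:
            raise ValidationError(f"index missing residues: {sorted(missing)}")
        if self.window_length < 1 or self.min_stretch < 1:
            raise ValidationError("window_length and min_stretch must be >= 1")

    def score_of(self, residue: str) -> float:
        if residue == "X":
            # ambiguous residue: mean of the 20 standard scores
            return float(np.mean([self.scores[a] for a in AMINO_ACIDS]))
        try:
            return float(self.scores[residue])
        except KeyError:
            raise ValidationError(f"residue {residue!r} absent from index") from None


@dataclass(frozen=True)
class PeptideHit:
    """A putative AMP stretch found in one protein."""

    sequence: str
    start: int
    end: int
    propensity: float


@dataclass(frozen=True)
class Peptide:
    """A putative AMP with provenance in its source protein."""

    sequence: str
    accession: str
    start: int
    end: int


@dataclass
class TaxonPeptideProfile:
    """All putative AMPs of one taxon, plus the protein count used to
    normalize AMP counts (AMP/protein ratio)."""

    taxon_id: str
    rank: str  # "species" or "genus"
    n_proteins: int
    peptides: list[Peptide] = field(default_factory=list)


def default_index() -> PropensityIndex:
    """The package's stand-in propensity index with default scanner settings."""
    return PropensityIndex(scores=dict(DEFAULT_INDEX_SCORES))


def read_index(path: str | Path) -> PropensityIndex:
    """Read a propensity index TSV.

    Lines starting ``#`` set scanner parameters (``#window_length=7``,
    ``#threshold=0.225``, ``#min_stretch=12``); the remaining lines are
    two-column ``residue<TAB>score``.
    """
    params: dict[str, float] = {}
    scores: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, val = line[1:].partition("=")
            params[key.strip()] = float(val)
            continue
        residue, _, score = line.partition("\t")
        scores[residue.strip()] = float(score)
    return PropensityIndex(
        scores=scores,
        window_length=int(params.get("window_length", 7)),
        threshold=float(params.get("threshold", 0.225)),
        min_stretch=int(params.get("min_stretch", 12)),
    )


def write_index(index: PropensityIndex, path: str | Path) -> None:
    lines = [
        f"#window_length={index.window_length}",
        f"#threshold={index.threshold}",
        f"#min_stretch={index.min_stretch}",
    ]
    lines += [f"{a}\t{index.scores[a]}" for a in AMINO_ACIDS]
    Path(path).write_text("\n".join(lines) + "\n")


def _is_curated(header: str, assume_curated: bool) -> bool:
    # UniProt convention: "sp|" = Swiss-Prot (curated), "tr|" = TrEMBL.
    if header.startswith("sp|"):
        return True
    if header.startswith("tr|"):
        return False
    return assume_curated


def read_proteome(
    path: str | Path, taxon_id: str, *, assume_curated: bool = False
) -> list[ProteinRecord]:
    """Read a FASTA proteome into :class:`ProteinRecord` objects.

    The curated flag is set from the UniProt header convention (``sp|`` vs
    ``tr|``); ``assume_curated=True`` marks every non-TrEMBL entry curated,
    for proteomes that do not use UniProt headers.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        accession = entry.id
        if accession in seen:
            raise ValidationError(f"duplicate accession {accession!r} in {path}")
        seen.add(accession)
        records.append(
            ProteinRecord(
                accession=accession,
                taxon_id=taxon_id,
                description=entry.description,
                sequence=str(entry.seq).upper(),
                curated=_is_curated(entry.id, assume_curated),
            )
        )
    return records


def filter_curated(records: Sequence[ProteinRecord]) -> list[ProteinRecord]:
    """Keep only curated records, preserving order (idempotent)."""
    kept = [r for r in records if r.curated]
    if records and not kept:
        warnings.warn(
            "no curated records after filtering; downstream profile will have "
            "n_proteins = 0",
            stacklevel=2,
        )
    return kept


def scan_amps(record: ProteinRecord, index: PropensityIndex) -> list[PeptideHit]:
    """Scan one protein for putative AMP stretches.

    A sliding window of ``index.window_length`` computes the mean per-residue
    index at each position; maximal runs of consecutive windows with mean
    strictly below ``index.threshold`` are merged into a stretch covering all
    their residues, and stretches shorter than ``index.min_stretch`` are
    dropped.  Returned hits are non-overlapping and sorted by start.
    """
    w = index.window_length
    seq = record.sequence
    if len(seq) < w:
        return []
    scores = np.array([index.score_of(c) for c in seq])
    csum = np.concatenate([[0.0], np.cumsum(scores)])
    window_means = (csum[w:] - csum[:-w]) / w
    low = window_means < index.threshold

    hits: list[PeptideHit] = []
    i = 0
    n_win = len(low)
    while i < n_win:
        if not low[i]:
            i += 1
            continue
        j = i
        while j + 1 < n_win and low[j + 1]:
            j += 1
        start, end = i, j + w  # residue coordinates, half-open
        if end - start >= index.min_stretch:
            hits.append(
                PeptideHit(
                    sequence=seq[start:end],
                    start=start,
                    end=end,
                    propensity=float(scores[start:end].mean()),
                )
            )
        i = j + 1
    return hits


def build_profile(
    records: Sequence[ProteinRecord],
    index: PropensityIndex,
    taxon_id: str,
    rank: str = "species",
) -> TaxonPeptideProfile:
    """Scan a (curated-filtered) record list into a taxon peptide profile."""
    peptides = [
        Peptide(hit.sequence, r.accession, hit.start, hit.end)
        for r in records
        for hit in scan_amps(r, index)
    ]
    return TaxonPeptideProfile(
        taxon_id=taxon_id, rank=rank, n_proteins=len(records), peptides=peptides
    )


def amp_per_protein_ratio(profile: TaxonPeptideProfile) -> float:
    """Number of putative AMPs per protein scanned."""
    if profile.n_proteins == 0:
        raise UndefinedStatisticError(
            f"{profile.taxon_id}: AMP/protein ratio undefined with 0 proteins"
        )
    return len(profile.peptides) / profile.n_proteins


def write_profile_tsv(profile: TaxonPeptideProfile, path: str | Path) -> None:
    lines = ["taxon_id\trank\taccession\tstart\tend\tpeptide"]
    lines += [
        f"{profile.taxon_id}\t{profile.rank}\t{p.accession}\t{p.start}\t{p.end}\t{p.sequence}"
        for p in profile.peptides
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_peptides_tsv(path: str | Path, n_proteins: int | None = None) -> list[TaxonPeptideProfile]:
    """Ingest precomputed peptide tables (e.g., output of an external AMP
    predictor) in the profile TSV format written by :func:`write_profile_tsv`.

    ``n_proteins`` overrides the protein count for every profile; by default
    it is the number of distinct source accessions seen per taxon.
    """
    profiles: dict[str, TaxonPeptideProfile] = {}
    lines = Path(path).read_text().splitlines()
    for line in lines[1:]:
        if not line.strip():
            continue
        taxon_id, rank, accession, start, end, seq = line.split("\t")
        prof = profiles.setdefault(
            taxon_id, TaxonPeptideProfile(taxon_id=taxon_id, rank=rank, n_proteins=0)
        )
        prof.peptides.append(Peptide(seq, accession, int(start), int(end)))
    for prof in profiles.values():
        prof.n_proteins = (
            n_proteins
            if n_proteins is not None
            else len({p.accession for p in prof.peptides})
        )
    return list(profiles.values())


def all_peptides(profiles: Iterable[TaxonPeptideProfile]) -> list[tuple[str, str]]:
    """Flatten profiles to ``(sequence, taxon_id)`` pairs for clustering."""
    return [(p.sequence, prof.taxon_id) for prof in profiles for p in prof.peptides]
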