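"""End-to-end orchestration: ingest -> cluster -> networks -> Die -> validation.

Every stage writes its intermediate artifact in the documented TSV format,
and the resolved configuration is persisted next to the outputs, so a
pipeline run is reproducible and equivalent to running the stage
subcommands by hand on the intermediate files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

from ampnet import clustering, cooccurrence, ingest, network, scoring, validation
from ampnet.cooccurrence import CoocConfig
from ampnet.exceptions import AmpnetError
from ampnet.synthetic import SynthConfig, generate_abundances, generate_proteomes

log = logging.getLogger("ampnet")


@dataclass
class RunConfig:
    """Resolved parameters for a full pipeline run."""

    proteome_paths: dict[str, str] = field(default_factory=dict)  # taxon -> FASTA
    abundance_path: str | None = None
    index_path: str | None = None
    assume_curated: bool = False
    aggregate_genus: bool = False
    cluster_threshold: float = 0.8
    count_mode: str = "clusters"
    cooc_method: str = "spearman"
    rho_cut: float = 0.4
    p_cut: float = 0.05
    normalize_weights: bool = True
    ks: tuple[int, ...] = (1, 2, 3)
    out_dir: str = "ampnet_out"

    def dump(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, default=str) + "\n")


def run_pipeline(cfg: RunConfig) -> validation.ValidationReport:
    """Execute the full workflow from FASTA proteomes and an abundance table.

    Raises :class:`AmpnetError` naming the failing stage; partial outputs
    written before the failure are retained.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.dump(out / "run_config.json")
    index = ingest.read_index(cfg.index_path) if cfg.index_path else ingest.default_index()

    stage = "ingest"
    try:
        profiles = []
        for taxon, path in cfg.proteome_paths.items():
            records = ingest.read_proteome(path, taxon, assume_curated=cfg.assume_curated)
            records = ingest.filter_curated(records)
            prof = ingest.build_profile(records, index, taxon)
            profiles.append(prof)
            ingest.write_profile_tsv(prof, out / f"profile_{taxon}.tsv")
        log.info("ingest: %d taxa, %d peptides", len(profiles),
                 sum(len(p.peptides) for p in profiles))
        if cfg.aggregate_genus:
            profiles = network.aggregate_to_genus(profiles)

        stage = "cluster"
        peptides = ingest.all_peptides(profiles)
        cs = clustering.greedy_cluster(peptides, cfg.cluster_threshold)
        clustering.write_clusters_tsv(cs, out / "clusters.tsv")
        log.info("cluster: %d clusters (%d unique) from %d peptides; weight mode=%s",
                 len(cs.clusters), cs.n_unique, len(peptides), cfg.count_mode)

        stage = "bw_network"
        adj = network.shared_amp_counts(profiles, cs, cfg.count_mode)
        bw = network.to_edge_list(adj)
        network.write_edge_list_tsv(bw, out / "bw_edges.tsv")

        stage = "mb_network"
        if cfg.abundance_path is None:
            raise AmpnetError("no abundance table provided")
        tbl = cooccurrence.read_abundance_tsv(cfg.abundance_path)
        cooc_cfg = CoocConfig(method=cfg.cooc_method, rho_cut=cfg.rho_cut, p_cut=cfg.p_cut)
        mb = cooccurrence.cooccurrence_network(tbl, cooc_cfg)
        abund = cooccurrence.relative_abundance(tbl)
        bi = cooccurrence.to_bidirected(mb, abund)
        cooccurrence.write_directed_edge_list_tsv(bi, out / "mb_edges.tsv")
        log.info("mb_network: %d nodes, %d directed edges (%s, rho>=%.2f, p<=%.2f)",
                 bi.number_of_nodes(), bi.number_of_edges(), cfg.cooc_method,
                 cfg.rho_cut, cfg.p_cut)

        stage = "scoring"
        bw_scores = scoring.die_scores(bw, normalize_weights=cfg.normalize_weights,
                                       network_label="BW")
        mb_scores = scoring.die_scores(bi, normalize_weights=cfg.normalize_weights,
                                       network_label="MB")
        scoring.write_scores_tsv(bw_scores, out / "die_bw.tsv")
        scoring.write_scores_tsv(mb_scores, out / "die_mb.tsv")

        stage = "validation"
        report = validation.validate_networks(bw_scores, mb_scores, ks=cfg.ks)
        report.write(out, "validation")
        return report
    except AmpnetError as err:
        raise AmpnetError(f"stage {stage!r} failed: {err}") from err


def run_synthetic_study(
    cfg: SynthConfig,
    *,
    ks: Sequence[int] = (1, 2, 3),
    normalize_weights: bool = True,
) -> validation.ValidationReport:
    """Generate a synthetic study and run the full pipeline in memory.

    This is the package's self-contained benchmark: proteomes with planted
    shared motifs define the expected network, abundances define the
    co-occurrence network, and the validation report measures their
    agreement.
    """
    index = ingest.default_index()
    proteomes, _ = generate_proteomes(cfg, index)
    profiles = [
        ingest.build_profile(ingest.filter_curated(records), index, taxon, rank="genus")
        for taxon, records in proteomes.items()
    ]
    cs = clustering.greedy_cluster(ingest.all_peptides(profiles), 0.8)
    adj = network.shared_amp_counts(profiles, cs)
    bw = network.to_edge_list(adj)

    tbl = generate_abundances(cfg)
    mb = cooccurrence.cooccurrence_network(tbl, CoocConfig())
    abund = cooccurrence.relative_abundance(tbl)
    bi = cooccurrence.to_bidirected(mb, abund)

    bw_scores = scoring.die_scores(bw, normalize_weights=normalize_weights,
                                   network_label="BW")
    mb_scores = scoring.die_scores(bi, normalize_weights=normalize_weights,
                                   network_label="MB")
    return validation.validate_networks(bw_scores, mb_scores, ks=ks)
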