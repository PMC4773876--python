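"""End-to-end pipeline: density -> promoters -> orientation -> scan ->
co-occurrence -> U1-PAS, with every stage's parameters logged and all report
tables written as TSV."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import gene_density, genome_model, orientation, promoter_builder
from .cooccurrence import pairwise_table
from .motif_scan import MotifModel, positional_profile, read_jaspar_pfm, read_meme_motifs, scan_motif, anchor_window_sequence
from .u1_pas_axis import PAS_CONSENSUS, cumulative_motif_frequency

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and parameters of a full pipeline run.

    Defaults follow the analysis conventions: 50 kb density windows,
    -150/+50 promoters, 1 kb bidirectional threshold, -400..+100 positional
    profiles in 10 bp bins, 500 bp U1-PAS span.
    """

    fasta: str = ""
    annotation: str = ""
    annotation_dialect: str = "gff3"
    motifs: str | None = None  # MEME (.meme/.txt) or JASPAR PFM file
    outdir: str = "promarch_out"
    window_size: int = 50_000
    upstream: int = 150
    downstream: int = 50
    min_scaffold_len: int = 10_000
    near_threshold: int = 1_000
    profile_window: tuple[int, int] = (-400, 100)
    bin_size: int = 10
    span: int = 500
    pas_consensus: str = PAS_CONSENSUS
    strand_mode: str = "sense_only"
    stages: tuple[str, ...] = (
        "density",
        "promoters",
        "orient",
        "scan",
        "cooccur",
        "u1pas",
    )
    seed: int = 0


def _header(fh, config: RunConfig) -> None:
    fh.write("# promarch parameters: ")
    fh.write(
        " ".join(f"{k}={v}" for k, v in asdict(config).items() if k != "stages")
    )
    fh.write("\n")


def _write_tsv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        _header(fh, config)
        df.to_csv(fh, sep="\t", index=False)


def load_motifs(path: str) -> list[MotifModel]:
    text = Path(path).read_text()
    if "letter-probability matrix" in text:
        return read_meme_motifs(path)
    return read_jaspar_pfm(path)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the selected stages; returns the paths of the written tables."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    logger.info("run parameters: %s", asdict(config))
    scaffolds = genome_model.read_genome(config.fasta)
    sc_map = {sc.id: sc for sc in scaffolds}
    genes = genome_model.read_gene_models(
        config.annotation, config.annotation_dialect, sc_map
    )
    tss = genome_model.derive_tss(genes)
    logger.info("%d scaffolds, %d genes, %d unique TSSs", len(scaffolds), len(genes), len(tss))

    promoters = None
    retained = None
    if "density" in config.stages:
        kept = gene_density.drop_mitochondrial(scaffolds)
        windows = gene_density.count_tss(
            gene_density.tile_windows(kept, config.window_size), tss
        )
        summary = gene_density.density_summary(kept, genes, windows)
        df = pd.DataFrame([vars(summary)])
        path = out / "density.tsv"
        _write_tsv(df, path, config)
        gene_density.write_windows_bed(windows, out / "windows.bed")
        written["density"] = path

    if {"promoters", "orient", "scan", "cooccur", "u1pas"} & set(config.stages):
        promoters = promoter_builder.extract_promoters(
            genes, sc_map, config.upstream, config.downstream
        )
        promoter_builder.filter_promoters(promoters, sc_map, config.min_scaffold_len)
        retained = [p for p in promoters if p.retained]
        logger.info("%d/%d promoters retained", len(retained), len(promoters))
    if "promoters" in config.stages:
        promoter_builder.write_promoters(
            promoters, out / "promoters.bed", out / "promoters.fa"
        )
        written["promoters"] = out / "promoters.bed"

    if "orient" in config.stages:
        pairs = orientation.adjacent_pairs(genes)
        table = orientation.orientation_table(pairs, config.near_threshold)
        path = out / "orientation.tsv"
        _write_tsv(table, path, config)
        written["orient"] = path
        calls = orientation.classify_directionality(retained, genes, config.near_threshold)
        _write_tsv(
            pd.DataFrame([vars(c) for c in calls]), out / "directionality.tsv", config
        )

    motifs = load_motifs(config.motifs) if config.motifs else []
    if "scan" in config.stages and motifs:
        frames = []
        for m in motifs:
            prof = positional_profile(
                tss, sc_map, m, config.profile_window, config.bin_size, config.strand_mode
            )
            df = prof.to_frame()
            df["motif"] = m.name
            frames.append(df)
        _write_tsv(pd.concat(frames), out / "profiles.tsv", config)
        written["scan"] = out / "profiles.tsv"

    if "cooccur" in config.stages and len(motifs) >= 2:
        hit_sets = {}
        for m in motifs:
            hits = set()
            for p in retained:
                if p.sequence and scan_motif(p.sequence, m, config.strand_mode):
                    hits.add(p.gene_id)
            hit_sets[m.name] = hits
        table = pairwise_table(hit_sets, n=len(retained))
        _write_tsv(table, out / "cooccurrence.tsv", config)
        written["cooccur"] = out / "cooccurrence.tsv"

    if "u1pas" in config.stages:
        pas = MotifModel.from_iupac("PAS", config.pas_consensus)
        frames = []
        for direction in ("sense_downstream", "antisense_upstream"):
            prof = cumulative_motif_frequency(
                tss, sc_map, pas, direction, config.span, config.bin_size
            )
            frames.append(prof.to_frame())
        _write_tsv(pd.concat(frames), out / "u1pas.tsv", config)
        written["u1pas"] = out / "u1pas.tsv"
    return written
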