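"""Synthetic genomes and annotations with planted regulatory structure.

The generator emulates the statistical features the pipeline measures on a
compact AT-rich genome: i.i.d. background sequence with configurable AT
fraction, genes laid out as two-gene cassettes whose internal pair is drawn
from a head-to-head / tail-to-tail / head-to-tail orientation mixture,
lognormal intergenic and intron size distributions, promoter motifs planted
at configurable offsets around TSSs, and strand-asymmetric PAS / 5' splice
sites planted in the TSS flanks.  Every planted feature is recorded in a
:class:`SyntheticTruth` so each pipeline stage can be tested against ground
truth.

Adjacent-pair orientation cannot be drawn i.i.d. for *every* consecutive
pair (a head-to-head pair forces its left gene onto the minus strand, so a
stationary strand chain would force equal head-to-head and tail-to-tail
probabilities); hence the cassette layout, in which only within-cassette
pairs carry a configured orientation label.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .genome_model import GeneModel, Scaffold, TSSRecord, revcomp, write_fasta, write_gff3
from .motif_scan import IUPAC_CLASSES

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class MotifPlant:
    consensus: str
    offset_mean: float
    offset_sd: float
    fraction: float  # fraction of promoters receiving one instance


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults follow a compact AT-rich sponge-like
    genome (64.2% AT, ~4.2 introns/gene of ~326 bp, ~587 bp median
    intergenic distance, near-equal divergent/convergent pair rates with a
    co-oriented majority)."""

    seed: int = 0
    n_scaffolds: int = 4
    scaffold_length_bp: int = 500_000
    at_fraction: float = 0.642
    n_genes: int = 400
    orientation_mix: tuple[float, float, float] = (0.223, 0.210, 0.567)
    intergenic_median_bp: float = 587.0
    intergenic_sigma: float = 0.8
    tss_distance_median_bp: float = 587.0  # head-to-head TSS spacing
    tss_distance_sigma: float = 0.5
    cassette_separation_bp: int = 1_500
    mean_introns_per_gene: float = 4.2
    exon_size_median_bp: float = 160.0
    exon_size_sigma: float = 0.5
    intron_size_median_bp: float = 280.0
    intron_size_sigma: float = 0.45
    utr5_len_range: tuple[int, int] = (20, 150)
    utr5_fraction: float = 1.0
    motif_plants: list[MotifPlant] = field(default_factory=list)
    promoter_window: tuple[int, int] = (-150, 50)
    pas_rates: tuple[float, float] = (0.0, 0.0)  # (sense_downstream, antisense_upstream) per kb
    ss5_rates: tuple[float, float] = (0.0, 0.0)
    flank_span_bp: int = 500

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.orientation_mix), 1.0):
            raise ValueError("orientation_mix must sum to 1")
        if not 0.0 <= self.at_fraction <= 1.0:
            raise ValueError("at_fraction must be in [0, 1]")
        if any(r < 0 for r in (*self.pas_rates, *self.ss5_rates)):
            raise ValueError("plant rates must be >= 0")


@dataclass(frozen=True)
class PlantedMotif:
    gene_id: str
    scaffold_id: str
    offset: int  # sense offset of the site's 5' end relative to the TSS
    site: str  # realised sequence, sense orientation
    genomic_start: int
    strand: str


@dataclass(frozen=True)
class PlantedSite:
    anchor_key: tuple[str, int, str]  # (scaffold, tss position, strand)
    motif_name: str
    direction: str  # sense_downstream | antisense_upstream
    distance: int  # 5' end of site, bases from the anchor (>= 1)
    site: str
    genomic_start: int


@dataclass
class SyntheticTruth:
    pair_categories: list[tuple[str, str, str]] = field(default_factory=list)
    # (left_gene_id, right_gene_id, category)
    tss_distances: dict[tuple[str, str], int] = field(default_factory=dict)
    planted_motifs: list[PlantedMotif] = field(default_factory=list)
    planted_sites: list[PlantedSite] = field(default_factory=list)


def _random_sequence(rng: np.random.Generator, length: int, at_fraction: float) -> str:
    p = np.array(
        [at_fraction / 2, (1 - at_fraction) / 2, (1 - at_fraction) / 2, at_fraction / 2]
    )
    return "".join(BASES[rng.choice(4, size=length, p=p)])


def _lognormal(rng: np.random.Generator, median: float, sigma: float) -> int:
    return max(1, int(round(median * np.exp(sigma * rng.standard_normal()))))


def _gene_structure(rng: np.random.Generator, cfg: SimulationConfig) -> tuple[int, tuple]:
    """Draw exon/intron sizes; returns (tx_length, exon intervals rel. to tx start)."""
    n_exons = 1 + rng.poisson(cfg.mean_introns_per_gene)
    pos = 0
    exons = []
    for i in range(n_exons):
        size = _lognormal(rng, cfg.exon_size_median_bp, cfg.exon_size_sigma)
        exons.append((pos, pos + size))
        pos += size
        if i < n_exons - 1:
            pos += _lognormal(rng, cfg.intron_size_median_bp, cfg.intron_size_sigma)
    return pos, tuple(exons)


def _make_gene(
    gene_id: str,
    scaffold_id: str,
    strand: str,
    tx_start: int,
    rng: np.random.Generator,
    cfg: SimulationConfig,
) -> GeneModel:
    length, rel_exons = _gene_structure(rng, cfg)
    exons = tuple((tx_start + s, tx_start + e) for s, e in rel_exons)
    tx_end = tx_start + length
    if rng.random() < cfg.utr5_fraction:
        utr = int(rng.integers(cfg.utr5_len_range[0], cfg.utr5_len_range[1] + 1))
    else:
        utr = 0
    utr = min(utr, length - 2)
    if strand == "+":
        cds_start, cds_end = tx_start + utr, tx_end
    else:
        cds_start, cds_end = tx_start, tx_end - utr
    return GeneModel(
        id=gene_id,
        scaffold_id=scaffold_id,
        strand=strand,
        tx_start=tx_start,
        tx_end=tx_end,
        cds_start=cds_start,
        cds_end=cds_end,
        exons=exons,
    )


def simulate_genome(
    config: SimulationConfig,
) -> tuple[list[Scaffold], list[GeneModel], SyntheticTruth]:
    """Generate scaffolds and gene models; deterministic under a fixed seed.

    Genes are placed as non-overlapping two-gene cassettes whose internal
    orientation is drawn from ``orientation_mix``; head-to-head cassettes get
    a TSS-to-TSS spacing from the configured lognormal.  Raises when the
    requested genes cannot be packed into the configured scaffolds.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    scaffolds: list[Scaffold] = []
    genes: list[GeneModel] = []
    truth = SyntheticTruth()
    n_pairs = cfg.n_genes // 2
    per_scaffold = [n_pairs // cfg.n_scaffolds] * cfg.n_scaffolds
    for i in range(n_pairs % cfg.n_scaffolds):
        per_scaffold[i] += 1
    margin = cfg.flank_span_bp + 10
    gene_no = 0
    for si in range(cfg.n_scaffolds):
        sc_id = f"scaffold_{si + 1}"
        seq = _random_sequence(rng, cfg.scaffold_length_bp, cfg.at_fraction)
        cursor = margin
        for _ in range(per_scaffold[si]):
            cat = ("head_to_head", "tail_to_tail", "head_to_tail")[
                rng.choice(3, p=np.array(cfg.orientation_mix))
            ]
            if cat == "head_to_head":
                s_left, s_right = "-", "+"
            elif cat == "tail_to_tail":
                s_left, s_right = "+", "-"
            else:
                s = "+" if rng.random() < 0.5 else "-"
                s_left = s_right = s
            left = _make_gene(
                f"g{gene_no + 1:05d}", sc_id, s_left, cursor, rng, cfg
            )
            if cat == "head_to_head":
                d = max(2, _lognormal(rng, cfg.tss_distance_median_bp, cfg.tss_distance_sigma))
                right_start = left.tx_end - 1 + d  # left TSS at tx_end - 1
            else:
                gap = _lognormal(rng, cfg.intergenic_median_bp, cfg.intergenic_sigma)
                right_start = left.tx_end + gap
            right = _make_gene(
                f"g{gene_no + 2:05d}", sc_id, s_right, right_start, rng, cfg
            )
            if right.tx_end + margin > cfg.scaffold_length_bp:
                raise ValueError(
                    f"infeasible packing: scaffold {sc_id} cannot hold the "
                    f"requested genes (ran out at gene {gene_no})"
                )
            genes.extend([left, right])
            gene_no += 2
            truth.pair_categories.append((left.id, right.id, cat))
            if cat == "head_to_head":
                truth.tss_distances[(left.id, right.id)] = abs(left.tss - right.tss)
            cursor = (
                right.tx_end
                + cfg.cassette_separation_bp
                + _lognormal(rng, cfg.intergenic_median_bp, cfg.intergenic_sigma)
            )
        scaffolds.append(Scaffold(id=sc_id, sequence=seq))
    return scaffolds, genes, truth


def _realise_iupac(rng: np.random.Generator, consensus: str) -> str:
    return "".join(
        rng.choice(list(IUPAC_CLASSES[c])) for c in consensus.upper().replace("U", "T")
    )


class _Collision:
    """Per-scaffold record of written intervals; planted sites never overlap."""

    def __init__(self) -> None:
        self.intervals: dict[str, list[tuple[int, int]]] = {}

    def claim(self, scaffold_id: str, start: int, end: int) -> bool:
        ivs = self.intervals.setdefault(scaffold_id, [])
        if any(start < e and s < end for s, e in ivs):
            return False
        ivs.append((start, end))
        return True


def _write_site(
    seqs: dict[str, bytearray], scaffold_id: str, start: int, site: str, strand: str
) -> None:
    text = site if strand == "+" else revcomp(site)
    seqs[scaffold_id][start : start + len(site)] = text.encode()


def plant_motifs(
    scaffolds: Sequence[Scaffold],
    genes: Sequence[GeneModel],
    motif_plants: Sequence[MotifPlant],
    seed: int,
    window: tuple[int, int] = (-150, 50),
    max_retries: int = 20,
) -> tuple[list[Scaffold], list[PlantedMotif]]:
    """Overwrite promoter bases with realised consensus sites.

    For each plant, a ``fraction`` subset of genes receives one site at a
    sense offset drawn from N(offset_mean, offset_sd), clipped so the site
    fits inside ``window``.  Collisions with already-planted sites are
    redrawn up to ``max_retries`` times, then raised.
    """
    rng = np.random.default_rng(seed)
    seqs = {sc.id: bytearray(sc.sequence.encode()) for sc in scaffolds}
    lengths = {sc.id: sc.length for sc in scaffolds}
    collisions = _Collision()
    truth: list[PlantedMotif] = []
    lo, hi = window
    for plant in motif_plants:
        w = len(plant.consensus)
        if w > hi - lo:
            raise ValueError(f"motif {plant.consensus} does not fit in the window")
        n_pick = int(round(plant.fraction * len(genes)))
        picked = rng.choice(len(genes), size=n_pick, replace=False)
        for gi in picked:
            g = genes[gi]
            for attempt in range(max_retries):
                off = int(round(rng.normal(plant.offset_mean, plant.offset_sd)))
                off = min(max(off, lo), hi - w)
                if g.strand == "+":
                    gstart = g.tss + off
                else:
                    gstart = g.tss - off - w + 1
                if gstart < 0 or gstart + w > lengths[g.scaffold_id]:
                    continue
                if collisions.claim(g.scaffold_id, gstart, gstart + w):
                    site = _realise_iupac(rng, plant.consensus)
                    _write_site(seqs, g.scaffold_id, gstart, site, g.strand)
                    truth.append(
                        PlantedMotif(
                            gene_id=g.id,
                            scaffold_id=g.scaffold_id,
                            offset=off,
                            site=site,
                            genomic_start=gstart,
                            strand=g.strand,
                        )
                    )
                    break
            else:
                raise ValueError(
                    f"could not place motif for gene {g.id} after {max_retries} tries"
                )
    out = [Scaffold(id=sc.id, sequence=seqs[sc.id].decode()) for sc in scaffolds]
    return out, truth


def plant_directionality_signals(
    scaffolds: Sequence[Scaffold],
    tss_records: Sequence[TSSRecord],
    pas_rates: tuple[float, float],
    ss5_rates: tuple[float, float],
    seed: int,
    span: int = 500,
    pas_consensus: str = "AWTAAA",
    ss5_site: str = "CAGGTAAGT",
    max_retries: int = 30,
) -> tuple[list[Scaffold], list[PlantedSite]]:
    """Plant PAS and 5'SS sites in TSS flanks at per-kb Poisson rates.

    ``*_rates`` are (sense_downstream, antisense_upstream) expected sites per
    kb of flank.  Sense-downstream sites go on the gene strand downstream of
    the TSS; antisense-upstream sites go on the opposite strand upstream,
    mirroring how the cumulative-profile scanner reads the flanks.
    """
    rng = np.random.default_rng(seed)
    seqs = {sc.id: bytearray(sc.sequence.encode()) for sc in scaffolds}
    lengths = {sc.id: sc.length for sc in scaffolds}
    collisions = _Collision()
    truth: list[PlantedSite] = []
    jobs = [("PAS", pas_consensus, pas_rates), ("SS5", ss5_site, ss5_rates)]
    for t in tss_records:
        p, strand, sid = t.position, t.strand, t.scaffold_id
        for name, consensus, (rate_down, rate_up) in jobs:
            w = len(consensus)
            for direction, rate in (
                ("sense_downstream", rate_down),
                ("antisense_upstream", rate_up),
            ):
                n_sites = rng.poisson(rate * span / 1000.0)
                for _ in range(n_sites):
                    placed = False
                    for _ in range(max_retries):
                        d = int(rng.integers(1, span - w + 2))
                        # map (distance, direction, gene strand) to genomic coords
                        right = (strand == "+") == (direction == "sense_downstream")
                        if right:
                            gstart = p + d
                        else:
                            gstart = p - d - w + 1
                        if gstart < 0 or gstart + w > lengths[sid]:
                            continue
                        if not collisions.claim(sid, gstart, gstart + w):
                            continue
                        site = _realise_iupac(rng, consensus)
                        # "right" flanks are read forward (plus strand), left
                        # flanks reverse-complemented, matching directional_flank
                        _write_site(seqs, sid, gstart, site, "+" if right else "-")
                        truth.append(
                            PlantedSite(
                                anchor_key=(sid, p, strand),
                                motif_name=name,
                                direction=direction,
                                distance=d,
                                site=site,
                                genomic_start=gstart,
                            )
                        )
                        placed = True
                        break
                    if not placed:
                        raise ValueError(
                            f"could not place {name} site near {sid}:{p} "
                            f"(rate too high for the flank)"
                        )
    out = [Scaffold(id=sc.id, sequence=seqs[sc.id].decode()) for sc in scaffolds]
    return out, truth


def save_simulation(
    scaffolds: Sequence[Scaffold],
    genes: Sequence[GeneModel],
    truth: SyntheticTruth,
    outdir: str | Path,
) -> None:
    """Write genome.fa, genes.gff3 and truth TSVs into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(scaffolds, outdir / "genome.fa")
    write_gff3(genes, outdir / "genes.gff3")
    with open(outdir / "truth_pairs.tsv", "w") as fh:
        fh.write("left_gene\tright_gene\tcategory\ttss_distance\n")
        for l, r, c in truth.pair_categories:
            d = truth.tss_distances.get((l, r), "")
            fh.write(f"{l}\t{r}\t{c}\t{d}\n")
    with open(outdir / "truth_motifs.tsv", "w") as fh:
        fh.write("gene_id\tscaffold\toffset\tsite\tgenomic_start\tstrand\n")
        for m in truth.planted_motifs:
            fh.write(
                f"{m.gene_id}\t{m.scaffold_id}\t{m.offset}\t{m.site}\t"
                f"{m.genomic_start}\t{m.strand}\n"
            )
    with open(outdir / "truth_sites.tsv", "w") as fh:
        fh.write("scaffold\tanchor_pos\tanchor_strand\tmotif\tdirection\tdistance\tsite\n")
        for s in truth.planted_sites:
            sid, pos, strand = s.anchor_key
            fh.write(
                f"{sid}\t{pos}\t{strand}\t{s.motif_name}\t{s.direction}\t"
                f"{s.distance}\t{s.site}\n"
            )
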