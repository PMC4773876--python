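"""Core-promoter window extraction and exclusion filters.

A core promoter is the sequence from 150 bp upstream to 50 bp downstream of
the TSS (configurable), reported 5'->3' on the gene's sense strand with the
TSS at sense offset 0.  Promoters are discarded when the window leaves the
scaffold, overlaps an assembly gap (run of N), lies on a short scaffold,
lies on a scaffold carrying a very long CpG island (a bacterial-contamination
heuristic), or shares any base with another extracted promoter (both members
of an overlapping pair are dropped).  Genes without an annotated 5' UTR have
no trustworthy TSS and are rejected up front.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .genome_model import GeneModel, Scaffold, revcomp

UPSTREAM_DEFAULT = 150
DOWNSTREAM_DEFAULT = 50
MIN_SCAFFOLD_LEN = 10_000  # retained promoters need scaffold length strictly above
CPG_MIN_LEN = 10_000

REJECTION_REASONS = (
    "off_scaffold",
    "overlaps_gap",
    "overlaps_promoter",
    "short_scaffold",
    "cpg_contamination",
    "no_5utr",
)


@dataclass
class PromoterRegion:
    gene_id: str
    scaffold_id: str
    strand: str
    start: int
    end: int
    tss_position: int
    sequence: str | None = None
    status: str = "retained"
    rejection_reason: str | None = None

    def reject(self, reason: str) -> None:
        assert reason in REJECTION_REASONS
        self.status = "rejected"
        self.rejection_reason = reason

    @property
    def retained(self) -> bool:
        return self.status == "retained"


@dataclass(frozen=True)
class CpGIsland:
    scaffold_id: str
    start: int
    end: int
    gc_fraction: float
    obs_exp_cpg: float

    @property
    def length(self) -> int:
        return self.end - self.start


def promoter_interval(
    tss: int, strand: str, upstream: int = UPSTREAM_DEFAULT, downstream: int = DOWNSTREAM_DEFAULT
) -> tuple[int, int]:
    """Genomic half-open interval of the promoter window around a TSS."""
    if strand == "+":
        return tss - upstream, tss + downstream
    return tss - downstream + 1, tss + upstream + 1


def extract_core_promoter(
    gene: GeneModel,
    scaffold: Scaffold,
    upstream: int = UPSTREAM_DEFAULT,
    downstream: int = DOWNSTREAM_DEFAULT,
) -> PromoterRegion:
    """Extract the sense-oriented promoter window around a gene's TSS.

    Rejections (no 5' UTR, window off scaffold) are recorded on the region,
    not raised.
    """
    tss = gene.tss
    start, end = promoter_interval(tss, gene.strand, upstream, downstream)
    region = PromoterRegion(
        gene_id=gene.id,
        scaffold_id=gene.scaffold_id,
        strand=gene.strand,
        start=start,
        end=end,
        tss_position=tss,
    )
    if not gene.has_annotated_5utr:
        region.reject("no_5utr")
        return region
    if start < 0 or end > scaffold.length:
        region.reject("off_scaffold")
        return region
    seq = scaffold.sequence[start:end]
    region.sequence = seq if gene.strand == "+" else revcomp(seq)
    return region


def extract_promoters(
    genes: Sequence[GeneModel],
    scaffolds: Mapping[str, Scaffold],
    upstream: int = UPSTREAM_DEFAULT,
    downstream: int = DOWNSTREAM_DEFAULT,
) -> list[PromoterRegion]:
    return [
        extract_core_promoter(g, scaffolds[g.scaffold_id], upstream, downstream)
        for g in genes
    ]


def detect_gaps(scaffold: Scaffold, min_run: int = 1) -> list[tuple[int, int]]:
    """Maximal runs of N of length >= min_run, as half-open intervals."""
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    return [
        (m.start(), m.end())
        for m in re.finditer(f"N{{{min_run},}}", scaffold.sequence)
    ]


def detect_cpg_islands(
    scaffold: Scaffold,
    min_len: int = CPG_MIN_LEN,
    min_gc: float = 0.50,
    min_obs_exp: float = 0.60,
    window: int = 200,
) -> list[CpGIsland]:
    """CpG islands by the classic sliding-window criteria.

    Every ``window``-length window with GC fraction >= ``min_gc`` and
    observed/expected CpG = (#CG * L) / (#C * #G) >= ``min_obs_exp`` is
    marked; overlapping marked windows are merged into maximal intervals and
    intervals shorter than ``min_len`` are discarded.  The default
    ``min_len`` targets the very long islands used as a contamination flag;
    pass a small value for conventional island calling.
    """
    L = scaffold.length
    if L < window:
        return []
    s = np.frombuffer(scaffold.sequence.encode(), dtype=np.uint8)
    is_c = (s == ord("C")).astype(np.int64)
    is_g = (s == ord("G")).astype(np.int64)
    is_cg = np.zeros(L, dtype=np.int64)
    is_cg[:-1] = is_c[:-1] & is_g[1:]
    cum_c = np.concatenate(([0], np.cumsum(is_c)))
    cum_g = np.concatenate(([0], np.cumsum(is_g)))
    cum_cg = np.concatenate(([0], np.cumsum(is_cg)))
    starts = np.arange(L - window + 1)
    nc = cum_c[starts + window] - cum_c[starts]
    ng = cum_g[starts + window] - cum_g[starts]
    # CG dinucleotides fully inside the window
    ncg = cum_cg[starts + window - 1] - cum_cg[starts]
    gc_ok = (nc + ng) / window >= min_gc
    with np.errstate(divide="ignore", invalid="ignore"):
        obs_exp = np.where((nc > 0) & (ng > 0), ncg * window / (nc * ng), 0.0)
    passing = gc_ok & (obs_exp >= min_obs_exp)
    islands: list[CpGIsland] = []
    idx = np.flatnonzero(passing)
    if idx.size == 0:
        return islands
    # merge overlapping passing windows into maximal intervals
    run_start = idx[0]
    prev = idx[0]
    spans = []
    for i in idx[1:]:
        if i > prev + window:  # next window does not touch the current union
            spans.append((run_start, prev + window))
            run_start = i
        prev = i
    spans.append((run_start, prev + window))
    for a, b in spans:
        if b - a < min_len:
            continue
        c = cum_c[b] - cum_c[a]
        g = cum_g[b] - cum_g[a]
        cg = cum_cg[b - 1] - cum_cg[a]
        islands.append(
            CpGIsland(
                scaffold_id=scaffold.id,
                start=int(a),
                end=int(b),
                gc_fraction=(c + g) / (b - a),
                obs_exp_cpg=cg * (b - a) / (c * g) if c and g else 0.0,
            )
        )
    return islands


def filter_promoters(
    promoters: Sequence[PromoterRegion],
    scaffolds: Mapping[str, Scaffold],
    min_scaffold_len: int = MIN_SCAFFOLD_LEN,
    cpg_islands: Sequence[CpGIsland] | None = None,
    gap_min_run: int = 1,
) -> list[PromoterRegion]:
    """Apply the exclusion filters; returns the same regions with statuses set.

    Rejection precedence: off_scaffold -> overlaps_gap -> short_scaffold ->
    cpg_contamination -> overlaps_promoter.  Both members of an overlapping
    promoter pair are rejected.  ``min_scaffold_len`` is strict: promoters on
    scaffolds of exactly that length are rejected.  When ``cpg_islands`` is
    None the contamination scan is run per scaffold.
    """
    if cpg_islands is None:
        cpg_islands = [
            isl for sc in scaffolds.values() for isl in detect_cpg_islands(sc)
        ]
    contaminated = {isl.scaffold_id for isl in cpg_islands if isl.length >= CPG_MIN_LEN}
    gaps = {sid: detect_gaps(sc, gap_min_run) for sid, sc in scaffolds.items()}

    candidates = [p for p in promoters if p.retained]
    for p in candidates:
        if any(p.start < ge and gs < p.end for gs, ge in gaps.get(p.scaffold_id, ())):
            p.reject("overlaps_gap")
        elif scaffolds[p.scaffold_id].length <= min_scaffold_len:
            p.reject("short_scaffold")
        elif p.scaffold_id in contaminated:
            p.reject("cpg_contamination")

    # overlap among all extracted promoters, applied to survivors last
    by_scaffold: dict[str, list[PromoterRegion]] = {}
    for p in candidates:
        by_scaffold.setdefault(p.scaffold_id, []).append(p)
    overlapping: set[int] = set()
    for ps in by_scaffold.values():
        ps.sort(key=lambda p: p.start)
        for a, b in zip(ps, ps[1:]):
            if b.start < a.end:
                overlapping.add(id(a))
                overlapping.add(id(b))
    for p in candidates:
        if p.retained and id(p) in overlapping:
            p.reject("overlaps_promoter")
    return list(promoters)


def write_promoters(
    promoters: Sequence[PromoterRegion], bed_path, fasta_path=None
) -> None:
    """Retained promoters as BED6 (+ optional sense-oriented FASTA)."""
    retained = [p for p in promoters if p.retained]
    with open(bed_path, "w") as fh:
        for p in retained:
            fh.write(
                f"{p.scaffold_id}\t{p.start}\t{p.end}\t{p.gene_id}\t0\t{p.strand}\n"
            )
    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            for p in retained:
                fh.write(f">{p.gene_id}\n{p.sequence}\n")
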