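"""Gene-density profiling: fixed non-overlapping windows and summary statistics.

Genomes are tiled into non-overlapping windows (default 50 kb) starting at
coordinate 0 of every scaffold at least one window long; the trailing partial
window is dropped so every window measures the same amount of sequence.
Unique TSSs are counted per window; a window with zero TSSs is a "gene
desert".
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .genome_model import GeneModel, Scaffold, TSSRecord

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 50_000
#: scaffold-id pattern used to drop mitochondrial sequences
DEFAULT_MITO_PATTERN = r"MT|mito|chrM"


@dataclass(frozen=True)
class GenomeWindow:
    scaffold_id: str
    start: int
    end: int
    tss_count: int = 0


@dataclass(frozen=True)
class DensitySummary:
    genome_size_mb: float
    n_genes: int
    genes_per_mb: float
    median_per_window: float
    n_desert_windows: int
    pct_desert: float
    pct_at: float
    mean_introns_per_gene: float
    mean_intron_size_bp: float


def drop_mitochondrial(
    scaffolds: Sequence[Scaffold], pattern: str = DEFAULT_MITO_PATTERN
) -> list[Scaffold]:
    rx = re.compile(pattern, re.IGNORECASE)
    return [sc for sc in scaffolds if not rx.search(sc.id)]


def genes_per_mb(n_genes: int, genome_size_mb: float) -> float:
    """Gene density in genes per megabase."""
    if genome_size_mb <= 0:
        raise ValueError("genome size must be positive")
    return n_genes / genome_size_mb


def tile_windows(
    scaffolds: Sequence[Scaffold],
    window_size: int = DEFAULT_WINDOW,
    min_scaffold_len: int | None = None,
) -> list[GenomeWindow]:
    """Tile scaffolds into full-length non-overlapping windows.

    Scaffolds shorter than ``min_scaffold_len`` (defaults to ``window_size``)
    are excluded; the trailing remainder of every scaffold is dropped.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    if min_scaffold_len is None:
        min_scaffold_len = window_size
    windows = []
    for sc in scaffolds:
        if sc.length < min_scaffold_len:
            continue
        for start in range(0, sc.length - window_size + 1, window_size):
            windows.append(GenomeWindow(sc.id, start, start + window_size))
    return windows


def count_tss(
    windows: Sequence[GenomeWindow], tss_records: Sequence[TSSRecord]
) -> list[GenomeWindow]:
    """Count TSSs per window; a TSS at p falls in the window with start <= p < end."""
    by_scaffold: dict[str, list[GenomeWindow]] = {}
    for w in windows:
        by_scaffold.setdefault(w.scaffold_id, []).append(w)
    counts: dict[tuple[str, int], int] = {}
    for sc_id, ws in by_scaffold.items():
        ws.sort(key=lambda w: w.start)
    for t in tss_records:
        ws = by_scaffold.get(t.scaffold_id)
        if not ws:
            continue
        size = ws[0].end - ws[0].start
        idx = t.position // size
        if idx < len(ws) and ws[idx].start <= t.position < ws[idx].end:
            counts[(t.scaffold_id, idx)] = counts.get((t.scaffold_id, idx), 0) + 1
    out = []
    for sc_id, ws in by_scaffold.items():
        for idx, w in enumerate(ws):
            out.append(replace(w, tss_count=counts.get((sc_id, idx), 0)))
    return out


def intron_stats(genes: Sequence[GeneModel]) -> tuple[float, float]:
    """(mean introns per gene, mean intron size in bp) over all genes/introns.

    Genes without exon structure contribute zero introns.  With no introns at
    all the mean size is reported as 0 with a warning.
    """
    if not genes:
        raise ValueError("no genes")
    n_introns = 0
    total_size = 0
    for g in genes:
        if not g.exons or len(g.exons) < 2:
            continue
        for (s1, e1), (s2, e2) in zip(g.exons, g.exons[1:]):
            n_introns += 1
            total_size += s2 - e1
    mean_per_gene = n_introns / len(genes)
    if n_introns == 0:
        logger.warning("no introns found; mean intron size reported as 0")
        return mean_per_gene, 0.0
    return mean_per_gene, total_size / n_introns


def density_summary(
    scaffolds: Sequence[Scaffold],
    genes: Sequence[GeneModel],
    windows: Sequence[GenomeWindow],
    mito_pattern: str = DEFAULT_MITO_PATTERN,
) -> DensitySummary:
    """Assemble the genome-statistics summary from tiled, counted windows."""
    if not windows:
        raise ValueError("empty window list")
    kept = drop_mitochondrial(scaffolds, mito_pattern)
    size_mb = sum(sc.length for sc in kept) / 1e6
    counts = np.array([w.tss_count for w in windows])
    n_desert = int((counts == 0).sum())
    at = acgt = 0
    for sc in kept:
        for base in "ACGT":
            n = sc.sequence.count(base)
            acgt += n
            if base in "AT":
                at += n
    mean_ipg, mean_isz = intron_stats(genes)
    return DensitySummary(
        genome_size_mb=size_mb,
        n_genes=len(genes),
        genes_per_mb=genes_per_mb(len(genes), size_mb),
        median_per_window=float(np.median(counts)),
        n_desert_windows=n_desert,
        pct_desert=100.0 * n_desert / len(windows),
        pct_at=100.0 * at / acgt if acgt else float("nan"),
        mean_introns_per_gene=mean_ipg,
        mean_intron_size_bp=mean_isz,
    )


def write_windows_bed(windows: Sequence[GenomeWindow], path) -> None:
    """BED4: name column carries the TSS count."""
    with open(path, "w") as fh:
        for w in windows:
            fh.write(f"{w.scaffold_id}\t{w.start}\t{w.end}\t{w.tss_count}\n")
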