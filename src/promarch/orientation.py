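"""Adjacent gene-pair orientation and promoter directionality classes.

Consecutive genes on a scaffold (sorted by tx_start, ties by tx_end) form
pair regions classified as head-to-head (divergent: left gene on -, right on
+), tail-to-tail (convergent) or head-to-tail (co-oriented).  A head-to-head
pair whose TSSs lie within a threshold distance (default 1 kb, inclusive,
TSS-to-TSS) is a candidate bidirectional promoter: if both genes carry a
retained promoter both are "bidirectional"; if exactly one does it is
"putative_bidirectional"; retained promoters in no such pair are
"unidirectional".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .genome_model import GeneModel
from .promoter_builder import PromoterRegion
from .reports import round_half_up

NEAR_THRESHOLD_DEFAULT = 1_000

CATEGORIES = ("head_to_head", "tail_to_tail", "head_to_tail")


@dataclass(frozen=True)
class GenePairRegion:
    scaffold_id: str
    left_gene_id: str
    right_gene_id: str
    category: str
    overlapping: bool
    gap_bp: int
    tss_distance_bp: int | None = None


@dataclass(frozen=True)
class DirectionalityCall:
    promoter_id: str
    gene_id: str
    cls: str  # bidirectional | putative_bidirectional | unidirectional


def _category(left: GeneModel, right: GeneModel) -> str:
    if left.strand == "-" and right.strand == "+":
        return "head_to_head"
    if left.strand == "+" and right.strand == "-":
        return "tail_to_tail"
    return "head_to_tail"


def adjacent_pairs(genes: Sequence[GeneModel]) -> list[GenePairRegion]:
    """One region per consecutive gene pair on each scaffold."""
    by_scaffold: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_scaffold.setdefault(g.scaffold_id, []).append(g)
    pairs = []
    for sc_id in sorted(by_scaffold):
        gs = sorted(by_scaffold[sc_id], key=lambda g: (g.tx_start, g.tx_end))
        for left, right in zip(gs, gs[1:]):
            cat = _category(left, right)
            pairs.append(
                GenePairRegion(
                    scaffold_id=sc_id,
                    left_gene_id=left.id,
                    right_gene_id=right.id,
                    category=cat,
                    overlapping=left.tx_end > right.tx_start,
                    gap_bp=max(0, right.tx_start - left.tx_end),
                    tss_distance_bp=(
                        abs(left.tss - right.tss) if cat == "head_to_head" else None
                    ),
                )
            )
    return pairs


def orientation_table_from_counts(
    counts: Mapping[str, tuple[int, int, int]]
) -> pd.DataFrame:
    """Summary table from per-category (overlapping, non-overlapping, near) counts.

    ``pct_regions`` is (overlapping + non-overlapping) over the grand total;
    ``pct_regions_near`` is (overlapping + near) over the total of
    overlapping + near regions.  Percentages are rounded half-up to 1 d.p.
    """
    total_all = sum(o + n for o, n, _ in counts.values())
    total_near = sum(o + nr for o, _, nr in counts.values())
    if total_all == 0:
        raise ValueError("no gene pairs")
    rows = []
    for cat in CATEGORIES:
        o, n, nr = counts.get(cat, (0, 0, 0))
        rows.append(
            {
                "category": cat,
                "overlapping": o,
                "non_overlapping": n,
                "non_overlapping_near": nr,
                "pct_regions": round_half_up(100.0 * (o + n) / total_all, 1),
                "pct_regions_near": (
                    round_half_up(100.0 * (o + nr) / total_near, 1)
                    if total_near
                    else float("nan")
                ),
            }
        )
    totals = {
        "category": "TOTAL",
        "overlapping": sum(r["overlapping"] for r in rows),
        "non_overlapping": sum(r["non_overlapping"] for r in rows),
        "non_overlapping_near": sum(r["non_overlapping_near"] for r in rows),
        "pct_regions": float(total_all),
        "pct_regions_near": float(total_near),
    }
    return pd.DataFrame(rows + [totals])


def orientation_table(
    pairs: Sequence[GenePairRegion], near_threshold: int = NEAR_THRESHOLD_DEFAULT
) -> pd.DataFrame:
    """Category counts of overlapping / non-overlapping / near pairs (gap < threshold)."""
    counts = {cat: [0, 0, 0] for cat in CATEGORIES}
    for p in pairs:
        if p.overlapping:
            counts[p.category][0] += 1
        else:
            counts[p.category][1] += 1
            if p.gap_bp < near_threshold:
                counts[p.category][2] += 1
    return orientation_table_from_counts(
        {c: tuple(v) for c, v in counts.items()}
    )


def classify_directionality(
    retained_promoters: Sequence[PromoterRegion],
    genes: Sequence[GeneModel],
    near_threshold: int = NEAR_THRESHOLD_DEFAULT,
) -> list[DirectionalityCall]:
    """Assign each retained promoter a directionality class (see module docs)."""
    retained = {p.gene_id: p for p in retained_promoters if p.retained}
    calls: dict[str, str] = {}
    for pair in adjacent_pairs(genes):
        if pair.category != "head_to_head":
            continue
        if pair.tss_distance_bp is None or pair.tss_distance_bp > near_threshold:
            continue
        left_in = pair.left_gene_id in retained
        right_in = pair.right_gene_id in retained
        if left_in and right_in:
            calls[pair.left_gene_id] = "bidirectional"
            calls[pair.right_gene_id] = "bidirectional"
        elif left_in:
            calls[pair.left_gene_id] = "putative_bidirectional"
        elif right_in:
            calls[pair.right_gene_id] = "putative_bidirectional"
    return [
        DirectionalityCall(
            promoter_id=gid, gene_id=gid, cls=calls.get(gid, "unidirectional")
        )
        for gid in retained
    ]
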