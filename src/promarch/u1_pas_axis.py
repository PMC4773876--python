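"""Cumulative PAS / 5' splice-site frequency away from TSS anchors.

For each anchor the 500 bp flank is read in one of two directions:

* ``sense_downstream`` — the coding strand from +1 to +span, 5'->3' in the
  direction of transcription;
* ``antisense_upstream`` — the non-coding strand over -span..-1, 5'->3'
  reading away from the anchor (the template of any divergent transcript).

Motif hits are binned by distance from the anchor (bin b covers distances
(10b, 10(b+1)]) and normalised per anchor; the cumulative profile is the
prefix sum.  An excess of polyadenylation signals on the antisense-upstream
side relative to sense-downstream is the signature of unstable divergent
transcription (the "U1-PAS axis"); at bidirectional promoters the two
profiles converge.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_model import Scaffold, TSSRecord, revcomp
from .motif_scan import MotifModel, positional_profile, scan_motif, PROFILE_WINDOW

SPAN_DEFAULT = 500
BIN_DEFAULT = 10

PAS_CONSENSUS = "AWTAAA"  # DNA form of the vertebrate poly(A) signal AWUAAA

DIRECTIONS = ("sense_downstream", "antisense_upstream")


@dataclass
class CumulativeProfile:
    motif_name: str
    direction: str
    span: int
    bin_size: int
    per_bin_frequency: np.ndarray
    cumulative: np.ndarray
    n_anchors: int
    n_dropped: int = 0

    def to_frame(self) -> pd.DataFrame:
        starts = np.arange(0, self.span, self.bin_size) + 1
        return pd.DataFrame(
            {
                "distance_from": starts,
                "distance_to": starts + self.bin_size - 1,
                "per_bin_frequency": self.per_bin_frequency,
                "cumulative": self.cumulative,
                "direction": self.direction,
                "motif": self.motif_name,
            }
        )


def directional_flank(
    anchor: TSSRecord, scaffold: Scaffold, direction: str, span: int
) -> str | None:
    """The flank sequence read 5'->3' away from the anchor on the requested
    strand; index i corresponds to distance i + 1.  None when truncated."""
    p = anchor.position
    if direction not in DIRECTIONS:
        raise ValueError(f"unknown direction: {direction!r}")
    # (+, downstream) and (-, antisense upstream) both read the plus strand
    # to the right of the anchor; the two mirror cases read the minus strand
    # to the left.  Either way index 0 sits adjacent to the anchor.
    right = (anchor.strand == "+") == (direction == "sense_downstream")
    if right:
        if p + 1 + span > scaffold.length:
            return None
        return scaffold.sequence[p + 1 : p + 1 + span]
    if p - span < 0:
        return None
    return revcomp(scaffold.sequence[p - span : p])


def cumulative_motif_frequency(
    anchors: Sequence[TSSRecord],
    scaffolds: Mapping[str, Scaffold],
    motif: MotifModel,
    direction: str,
    span: int = SPAN_DEFAULT,
    bin_size: int = BIN_DEFAULT,
) -> CumulativeProfile:
    """Per-bin and cumulative motif frequency in one direction from anchors.

    Anchors with truncated flanks are dropped and counted in ``n_dropped``.
    All (possibly overlapping) hits are counted.
    """
    if span % bin_size:
        raise ValueError("span must be a multiple of bin_size")
    n_bins = span // bin_size
    counts = np.zeros(n_bins)
    n_used = n_dropped = 0
    for a in anchors:
        sc = scaffolds.get(a.scaffold_id)
        seq = directional_flank(a, sc, direction, span) if sc else None
        if seq is None:
            n_dropped += 1
            continue
        n_used += 1
        for h in scan_motif(seq, motif, "sense_only"):
            counts[h.offset // bin_size] += 1  # distance = offset + 1
    if n_used == 0:
        raise ValueError("no anchors with complete flanks")
    per_bin = counts / n_used
    cumulative = np.cumsum(per_bin)
    assert np.all(np.diff(cumulative) >= -1e-12), "cumulative must be non-decreasing"
    return CumulativeProfile(
        motif_name=motif.name,
        direction=direction,
        span=span,
        bin_size=bin_size,
        per_bin_frequency=per_bin,
        cumulative=cumulative,
        n_anchors=n_used,
        n_dropped=n_dropped,
    )


def motif_hit_anchors(
    tss_anchors: Sequence[TSSRecord],
    scaffolds: Mapping[str, Scaffold],
    motif: MotifModel,
    window: tuple[int, int] = PROFILE_WINDOW,
    strand_mode: str = "sense_only",
) -> list[TSSRecord]:
    """Genomic anchors at the 5' ends of motif hits found around TSSs.

    Each hit inside ``window`` (sense offsets around a TSS) becomes an anchor
    carrying the host gene's strand, for motif-anchored cumulative profiles.
    """
    from .motif_scan import anchor_window_sequence

    out = []
    lo, hi = window
    for a in tss_anchors:
        seq = anchor_window_sequence(a, scaffolds, window)
        if seq is None:
            continue
        for h in scan_motif(seq, motif, strand_mode):
            off = h.offset + lo  # TSS-relative sense offset of the hit 5' end
            pos = a.position + off if a.strand == "+" else a.position - off
            out.append(TSSRecord(a.scaffold_id, pos, a.strand))
    return out


def anchored_on_motif(
    hit_anchors: Sequence[TSSRecord],
    scaffolds: Mapping[str, Scaffold],
    motif: MotifModel,
    direction: str,
    span: int = SPAN_DEFAULT,
    bin_size: int = BIN_DEFAULT,
) -> CumulativeProfile:
    """Cumulative profile anchored on motif-hit positions (see
    :func:`motif_hit_anchors`) instead of TSSs."""
    if not hit_anchors:
        raise ValueError("empty hit set")
    return cumulative_motif_frequency(
        hit_anchors, scaffolds, motif, direction, span, bin_size
    )
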