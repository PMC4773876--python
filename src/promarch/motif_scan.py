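"""Motif models and scanning: PFM-derived log-odds PWMs, IUPAC consensus
matching, positional binning around TSSs, and nucleotide/dinucleotide
composition profiles.

A PWM scores a window as the sum of per-column log2 odds of the observed
base against a background distribution; windows scoring at least
``score_threshold`` times the motif's maximum achievable score are hits.
IUPAC consensus scanning matches degenerate base classes exactly.  In both
modes a window containing N can never be a hit.  Hit coordinates are the
5'-most base of the matched site on the scanned (sense) strand, regardless
of hit strand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_model import Scaffold, TSSRecord, revcomp

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

IUPAC_CLASSES = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_IUPAC_COMP = str.maketrans("ACGTURYSWKMBDHVN", "TGCAAYRSWMKVHDBN")

PROFILE_WINDOW = (-400, 100)
BIN_SIZE = 10


def iupac_revcomp(consensus: str) -> str:
    return consensus.upper().translate(_IUPAC_COMP)[::-1]


def build_pwm(
    pfm: np.ndarray, background: np.ndarray | None = None, pseudocount: float = 0.25
) -> np.ndarray:
    """Log-odds matrix from a 4 x w position frequency (count) matrix.

    score(b, j) = log2(((pfm[b,j] + pc * bg[b]) / (N_j + pc)) / bg[b]),
    with N_j the column sum.
    """
    pfm = np.asarray(pfm, dtype=float)
    if pfm.ndim != 2 or pfm.shape[0] != 4 or pfm.shape[1] < 1 or (pfm < 0).any():
        raise ValueError("pfm must be a non-negative 4 x w matrix")
    if background is None:
        background = np.full(4, 0.25)
    background = np.asarray(background, dtype=float)
    if background.shape != (4,) or (background <= 0).any():
        raise ValueError("background must be 4 strictly positive frequencies")
    background = background / background.sum()
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    col_sums = pfm.sum(axis=0)
    if pseudocount == 0 and (col_sums == 0).any():
        raise ValueError("all-zero PFM column requires a pseudocount")
    probs = (pfm + pseudocount * background[:, None]) / (col_sums + pseudocount)
    with np.errstate(divide="ignore"):
        return np.log2(probs / background[:, None])


@dataclass
class MotifModel:
    """A scannable motif: either a count-matrix PWM or an IUPAC consensus."""

    name: str
    kind: str  # "pwm" | "iupac"
    pfm: np.ndarray | None = None
    consensus: str | None = None
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.25
    score_threshold: float = 0.8

    def __post_init__(self) -> None:
        if self.kind == "pwm":
            self.pfm = np.asarray(self.pfm, dtype=float)
            self.logodds = build_pwm(self.pfm, self.background, self.pseudocount)
        elif self.kind == "iupac":
            self.consensus = self.consensus.upper().replace("U", "T")
            bad = set(self.consensus) - set(IUPAC_CLASSES)
            if bad:
                raise ValueError(f"invalid IUPAC characters: {sorted(bad)}")
        else:
            raise ValueError(f"unknown motif kind: {self.kind!r}")
        if not 0.0 <= self.score_threshold <= 1.0:
            raise ValueError("score_threshold must be in [0, 1]")

    @classmethod
    def from_iupac(cls, name: str, consensus: str) -> "MotifModel":
        return cls(name=name, kind="iupac", consensus=consensus)

    @classmethod
    def from_pfm(cls, name: str, pfm, **kw) -> "MotifModel":
        return cls(name=name, kind="pwm", pfm=np.asarray(pfm, dtype=float), **kw)

    @property
    def width(self) -> int:
        return self.pfm.shape[1] if self.kind == "pwm" else len(self.consensus)

    @property
    def max_score(self) -> float:
        return float(self.logodds.max(axis=0).sum())


@dataclass(frozen=True)
class MotifHit:
    anchor_id: str
    offset: int  # 5'-most base on the scanned strand (sequence-relative unless rebased)
    strand: str  # "sense" | "antisense"
    score: float
    site: str  # matched substring, motif-oriented


def _encode(sequence: str) -> np.ndarray:
    s = np.frombuffer(sequence.encode(), dtype=np.uint8)
    enc = np.full(s.shape, 4, dtype=np.int64)
    for b, i in BASE_INDEX.items():
        enc[s == ord(b)] = i
    return enc


def _scan_pwm_one_strand(sequence: str, motif: MotifModel) -> list[tuple[int, float]]:
    w = motif.width
    if len(sequence) < w:
        return []
    lod = np.vstack([motif.logodds, np.full(w, -np.inf)])  # N row scores -inf
    enc = _encode(sequence)
    windows = np.lib.stride_tricks.sliding_window_view(enc, w)
    scores = lod[windows, np.arange(w)].sum(axis=1)
    cutoff = motif.score_threshold * motif.max_score - 1e-9
    idx = np.flatnonzero(scores >= cutoff)
    return [(int(i), float(scores[i])) for i in idx]


def scan_pwm(
    sequence: str, motif: MotifModel, strand_mode: str = "sense_only", anchor_id: str = ""
) -> list[MotifHit]:
    """All windows scoring >= threshold * max score; overlaps and ties kept."""
    if strand_mode not in ("sense_only", "both"):
        raise ValueError(f"unknown strand_mode: {strand_mode!r}")
    sequence = sequence.upper()
    w = motif.width
    hits = [
        MotifHit(anchor_id, off, "sense", sc, sequence[off : off + w])
        for off, sc in _scan_pwm_one_strand(sequence, motif)
    ]
    if strand_mode == "both":
        rc = revcomp(sequence)
        L = len(sequence)
        for off, sc in _scan_pwm_one_strand(rc, motif):
            hits.append(
                MotifHit(anchor_id, L - off - w, "antisense", sc, rc[off : off + w])
            )
    return sorted(hits, key=lambda h: (h.offset, h.strand))


def _iupac_regex(consensus: str) -> re.Pattern:
    # lookahead so overlapping matches are all reported; N in sequence never
    # matches because classes list concrete bases only
    body = "".join(
        c if len(IUPAC_CLASSES[c]) == 1 else "[" + IUPAC_CLASSES[c] + "]"
        for c in consensus
    )
    return re.compile(f"(?=({body}))")


def scan_iupac(
    sequence: str,
    consensus: str | MotifModel,
    strand_mode: str = "sense_only",
    anchor_id: str = "",
) -> list[MotifHit]:
    """Exact degenerate-consensus matches (score 1.0 per hit)."""
    if strand_mode not in ("sense_only", "both"):
        raise ValueError(f"unknown strand_mode: {strand_mode!r}")
    if isinstance(consensus, MotifModel):
        consensus = consensus.consensus
    consensus = consensus.upper().replace("U", "T")
    bad = set(consensus) - set(IUPAC_CLASSES)
    if bad:
        raise ValueError(f"invalid IUPAC characters: {sorted(bad)}")
    sequence = sequence.upper()
    rx = _iupac_regex(consensus)
    hits = [
        MotifHit(anchor_id, m.start(), "sense", 1.0, m.group(1))
        for m in rx.finditer(sequence)
    ]
    if strand_mode == "both":
        rc = revcomp(sequence)
        L, w = len(sequence), len(consensus)
        for m in rx.finditer(rc):
            hits.append(
                MotifHit(anchor_id, L - m.start() - w, "antisense", 1.0, m.group(1))
            )
    return sorted(hits, key=lambda h: (h.offset, h.strand))


def scan_motif(
    sequence: str, motif: MotifModel, strand_mode: str = "sense_only", anchor_id: str = ""
) -> list[MotifHit]:
    if motif.kind == "pwm":
        return scan_pwm(sequence, motif, strand_mode, anchor_id)
    return scan_iupac(sequence, motif.consensus, strand_mode, anchor_id)


@dataclass
class BinProfile:
    """Motif frequency per fixed-width bin across a window around an anchor."""

    motif_name: str
    window: tuple[int, int]
    bin_size: int
    frequency: np.ndarray
    n_regions: int

    @property
    def bin_starts(self) -> np.ndarray:
        return np.arange(self.window[0], self.window[1], self.bin_size)

    def argmax_bin(self) -> tuple[int, int]:
        """Half-open offset interval of the most populated bin."""
        b = int(np.argmax(self.frequency))
        start = self.window[0] + b * self.bin_size
        return start, start + self.bin_size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start": self.bin_starts,
                "bin_end": self.bin_starts + self.bin_size,
                "frequency": self.frequency,
            }
        )


def anchor_window_sequence(
    anchor: TSSRecord, scaffolds: Mapping[str, Scaffold], window: tuple[int, int]
) -> str | None:
    """Sense-oriented sequence covering [window[0], window[1]) around an anchor.

    Returns None when the window runs off the scaffold.
    """
    sc = scaffolds.get(anchor.scaffold_id)
    if sc is None:
        return None
    lo, hi = window
    if anchor.strand == "+":
        start, end = anchor.position + lo, anchor.position + hi
        if start < 0 or end > sc.length:
            return None
        return sc.sequence[start:end]
    start, end = anchor.position - hi + 1, anchor.position - lo + 1
    if start < 0 or end > sc.length:
        return None
    return revcomp(sc.sequence[start:end])


def positional_profile(
    anchors: Sequence[TSSRecord],
    scaffolds: Mapping[str, Scaffold],
    motif: MotifModel,
    window: tuple[int, int] = PROFILE_WINDOW,
    bin_size: int = BIN_SIZE,
    strand_mode: str = "sense_only",
) -> BinProfile:
    """Motif frequency per bin across ``window`` around each anchor's TSS.

    Anchors whose window is truncated by a scaffold end or contains an
    assembly gap (N) are excluded; frequency is hits per bin divided by the
    number of anchors profiled.
    """
    lo, hi = window
    if (hi - lo) % bin_size:
        raise ValueError("window span must be a multiple of bin_size")
    n_bins = (hi - lo) // bin_size
    counts = np.zeros(n_bins)
    n_regions = 0
    for a in anchors:
        seq = anchor_window_sequence(a, scaffolds, window)
        if seq is None or "N" in seq:
            continue
        n_regions += 1
        for h in scan_motif(seq, motif, strand_mode):
            counts[(h.offset) // bin_size] += 1
    if n_regions == 0:
        raise ValueError("no anchors with complete flanks")
    return BinProfile(
        motif_name=motif.name,
        window=window,
        bin_size=bin_size,
        frequency=counts / n_regions,
        n_regions=n_regions,
    )


@dataclass
class CompositionProfile:
    """Per-offset nucleotide and dinucleotide frequencies across anchors."""

    window: tuple[int, int]
    base_freq: pd.DataFrame  # index: offset; columns: A C G T N
    dinuc_freq: pd.DataFrame  # index: offset of first base; columns: 16 dinucleotides
    n_regions: int


def composition_profile(
    anchors: Sequence[TSSRecord],
    scaffolds: Mapping[str, Scaffold],
    window: tuple[int, int] = PROFILE_WINDOW,
) -> CompositionProfile:
    """Base and dinucleotide frequency at each sense offset around the TSS.

    CpG means C immediately followed by G on the sense strand.  Dinucleotides
    containing N are not tabulated.
    """
    lo, hi = window
    L = hi - lo
    seqs = []
    for a in anchors:
        seq = anchor_window_sequence(a, scaffolds, window)
        if seq is not None:
            seqs.append(seq)
    if not seqs:
        raise ValueError("no anchors with complete flanks")
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(len(seqs), L)
    offsets = np.arange(lo, hi)
    base_counts = {
        b: (arr == ord(b)).sum(axis=0) for b in "ACGTN"
    }
    base_freq = pd.DataFrame(base_counts, index=offsets) / len(seqs)
    dinucs = ["".join(p) for p in product(BASES, repeat=2)]
    din_counts = {}
    for d in dinucs:
        m = (arr[:, :-1] == ord(d[0])) & (arr[:, 1:] == ord(d[1]))
        din_counts[d] = m.sum(axis=0)
    dinuc_freq = pd.DataFrame(din_counts, index=offsets[:-1]) / len(seqs)
    return CompositionProfile(
        window=window, base_freq=base_freq, dinuc_freq=dinuc_freq, n_regions=len(seqs)
    )


# --- motif file readers -----------------------------------------------------

def read_jaspar_pfm(path: str | Path, **kw) -> list[MotifModel]:
    """JASPAR raw PFM format: '>name' header then four 'A [ 1 2 ... ]' rows."""
    motifs = []
    name = None
    rows: dict[str, list[float]] = {}
    order = "ACGT"

    def flush():
        if name is None:
            return
        if set(rows) != set(order):
            raise ValueError(f"motif {name}: expected rows A, C, G, T")
        pfm = np.array([rows[b] for b in order])
        motifs.append(MotifModel.from_pfm(name, pfm, **kw))

    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            name = line[1:].split()[0]
            rows = {}
        else:
            m = re.match(r"([ACGT])\s*\[?\s*([\d.\s]+?)\s*\]?\s*$", line)
            if not m:
                raise ValueError(f"unparseable PFM line: {line!r}")
            rows[m.group(1)] = [float(x) for x in m.group(2).split()]
    flush()
    if not motifs:
        raise ValueError(f"no motifs in {path}")
    return motifs


def read_meme_motifs(path: str | Path, **kw) -> list[MotifModel]:
    """MEME minimal motif format; probability rows are scaled by nsites."""
    text = Path(path).read_text()
    motifs = []
    for m in re.finditer(
        r"MOTIF\s+(\S+)[^\n]*\n.*?letter-probability matrix:([^\n]*)\n"
        r"((?:[\s\d.eE+-]+\n)+)",
        text,
        re.DOTALL,
    ):
        name, header, block = m.group(1), m.group(2), m.group(3)
        w_match = re.search(r"w=\s*(\d+)", header)
        if not w_match:
            raise ValueError(f"motif {name}: missing w= in matrix header")
        w = int(w_match.group(1))
        ns_match = re.search(r"nsites=\s*(\d+)", header)
        nsites = int(ns_match.group(1)) if ns_match else 20
        vals = np.array([float(x) for x in block.split()]).reshape(w, 4)
        motifs.append(MotifModel.from_pfm(name, (vals * nsites).T, **kw))
    if not motifs:
        raise ValueError(f"no MEME motifs in {path}")
    return motifs
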