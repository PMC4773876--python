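"""Core data types for genomes and gene annotations.

All coordinates are 0-based half-open on the forward (plus) strand of a
scaffold.  GFF3 input (1-based closed) is converted on read; BED is native.
The transcription start site (TSS) of a gene is ``tx_start`` on the plus
strand and ``tx_end - 1`` on the minus strand — always the first transcribed
base.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = frozenset("ACGTN")

#: transcript biotypes accepted as protein coding when a biotype tag is present
CODING_BIOTYPES = frozenset({"protein_coding", "coding", "mrna"})


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Scaffold:
    """A genomic sequence unit (contig/scaffold/chromosome)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence) - _VALID
        if bad:
            raise ValueError(f"scaffold {self.id}: invalid characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneModel:
    """A stranded transcript interval with optional CDS/exon structure.

    ``has_annotated_5utr`` is derived: true iff a CDS is present and its
    sense-strand start lies strictly downstream of the TSS, i.e. the model
    carries a non-empty 5' UTR from which the TSS was annotated.
    """

    id: str
    scaffold_id: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int | None = None
    cds_end: int | None = None
    exons: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"gene {self.id}: strand must be + or -")
        if not self.tx_start < self.tx_end:
            raise ValueError(f"gene {self.id}: tx_start must be < tx_end")
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError(f"gene {self.id}: partial CDS coordinates")
        if self.cds_start is not None:
            if not (self.tx_start <= self.cds_start < self.cds_end <= self.tx_end):
                raise ValueError(f"gene {self.id}: CDS outside transcript")
        if self.exons is not None:
            prev_end = None
            for s, e in self.exons:
                if not (self.tx_start <= s < e <= self.tx_end):
                    raise ValueError(f"gene {self.id}: exon outside transcript")
                if prev_end is not None and s < prev_end:
                    raise ValueError(f"gene {self.id}: exons overlap or unsorted")
                prev_end = e

    @property
    def tss(self) -> int:
        """Genomic coordinate of the first transcribed base."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def has_annotated_5utr(self) -> bool:
        if self.cds_start is None:
            return False
        if self.strand == "+":
            return self.cds_start > self.tx_start
        return self.cds_end < self.tx_end


@dataclass(frozen=True)
class TSSRecord:
    """A unique (scaffold, position, strand) transcription start site."""

    scaffold_id: str
    position: int
    strand: str
    n_collapsed: int = 1


def read_genome(fasta_source: str | Path) -> list[Scaffold]:
    """Read a multi-FASTA genome into :class:`Scaffold` records.

    Sequences are uppercased; IUPAC ambiguity codes other than N are mapped
    to N with a warning.  Duplicate headers are an error.
    """
    scaffolds: list[Scaffold] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(fasta_source), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate scaffold id: {rec.id}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if set(seq) - _VALID:
            n_bad = sum(c not in _VALID for c in seq)
            logger.warning(
                "scaffold %s: %d non-ACGTN characters mapped to N", rec.id, n_bad
            )
            seq = re.sub("[^ACGTN]", "N", seq)
        scaffolds.append(Scaffold(id=rec.id, sequence=seq))
    if not scaffolds:
        raise ValueError(f"no FASTA records in {fasta_source}")
    return scaffolds


def _coding(biotypes: Iterable[str]) -> bool:
    vals = [b.lower() for b in biotypes]
    return not vals or any(v in CODING_BIOTYPES for v in vals)


def _read_gff3(source: str | Path) -> list[GeneModel]:
    db = gffutils.create_db(
        str(source),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for ftype in ("mRNA", "transcript"):
        for tx in db.features_of_type(ftype):
            biotypes = [
                v
                for key in ("biotype", "transcript_biotype", "gene_biotype")
                for v in tx.attributes.get(key, [])
            ]
            if not _coding(biotypes):
                continue
            exons = tuple(
                sorted((f.start - 1, f.end) for f in db.children(tx, featuretype="exon"))
            )
            cds = sorted((f.start - 1, f.end) for f in db.children(tx, featuretype="CDS"))
            genes.append(
                GeneModel(
                    id=tx.id,
                    scaffold_id=tx.seqid,
                    strand=tx.strand,
                    tx_start=tx.start - 1,
                    tx_end=tx.end,
                    cds_start=cds[0][0] if cds else None,
                    cds_end=cds[-1][1] if cds else None,
                    exons=exons or None,
                )
            )
    return genes


_BED_COLS = (
    "chrom start end name score strand thick_start thick_end rgb "
    "block_count block_sizes block_starts".split()
)


def _read_bed(source: str | Path) -> list[GeneModel]:
    df = pd.read_csv(str(source), sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] not in (6, 12):
        raise ValueError(f"expected BED6 or BED12, got {df.shape[1]} columns")
    df.columns = _BED_COLS[: df.shape[1]]
    genes = []
    for row in df.itertuples(index=False):
        start, end = int(row.start), int(row.end)
        cds_start = cds_end = None
        exons = None
        if hasattr(row, "thick_start"):
            ts, te = int(row.thick_start), int(row.thick_end)
            if te > ts:
                cds_start, cds_end = ts, te
            sizes = [int(x) for x in str(row.block_sizes).rstrip(",").split(",")]
            offs = [int(x) for x in str(row.block_starts).rstrip(",").split(",")]
            if len(sizes) != int(row.block_count) or len(offs) != int(row.block_count):
                raise ValueError(f"malformed BED12 blocks for {row.name}")
            exons = tuple((start + o, start + o + s) for o, s in zip(offs, sizes))
        genes.append(
            GeneModel(
                id=str(row.name),
                scaffold_id=str(row.chrom),
                strand=str(row.strand),
                tx_start=start,
                tx_end=end,
                cds_start=cds_start,
                cds_end=cds_end,
                exons=exons,
            )
        )
    return genes


def read_gene_models(
    annotation_source: str | Path,
    dialect: str = "gff3",
    scaffolds: Mapping[str, Scaffold] | None = None,
) -> list[GeneModel]:
    """Read transcript models from GFF3 or BED6/BED12.

    One :class:`GeneModel` per transcript; records tagged with a non-coding
    biotype are excluded.  If ``scaffolds`` is given, features outside the
    declared scaffold bounds are an error.
    """
    if dialect == "gff3":
        genes = _read_gff3(annotation_source)
    elif dialect == "bed12":
        genes = _read_bed(annotation_source)
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")
    if scaffolds is not None:
        for g in genes:
            sc = scaffolds.get(g.scaffold_id)
            if sc is None or g.tx_end > sc.length:
                raise ValueError(
                    f"gene {g.id} outside declared scaffold {g.scaffold_id}"
                )
    return genes


def derive_tss(genes: Sequence[GeneModel]) -> list[TSSRecord]:
    """Extract TSSs and collapse duplicates on (scaffold, position, strand)."""
    counts: dict[tuple[str, int, str], int] = {}
    for g in genes:
        key = (g.scaffold_id, g.tss, g.strand)
        counts[key] = counts.get(key, 0) + 1
    return [
        TSSRecord(scaffold_id=s, position=p, strand=st, n_collapsed=n)
        for (s, p, st), n in sorted(counts.items())
    ]


def write_bed(
    records: Sequence[GeneModel | TSSRecord], path: str | Path
) -> None:
    """Write genes (tx interval) or TSSs (1 bp interval) as BED6."""
    with open(path, "w") as fh:
        for r in records:
            if isinstance(r, TSSRecord):
                fh.write(
                    f"{r.scaffold_id}\t{r.position}\t{r.position + 1}\t"
                    f"tss\t{r.n_collapsed}\t{r.strand}\n"
                )
            else:
                fh.write(
                    f"{r.scaffold_id}\t{r.tx_start}\t{r.tx_end}\t{r.id}\t0\t{r.strand}\n"
                )


def write_fasta(scaffolds: Sequence[Scaffold], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for sc in scaffolds:
            fh.write(f">{sc.id}\n")
            for i in range(0, sc.length, width):
                fh.write(sc.sequence[i : i + width] + "\n")


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write transcript models (mRNA + exon + CDS features) as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.id};biotype=protein_coding"
            fh.write(
                f"{g.scaffold_id}\tpromarch\tmRNA\t{g.tx_start + 1}\t{g.tx_end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            for i, (s, e) in enumerate(g.exons or ((g.tx_start, g.tx_end),)):
                fh.write(
                    f"{g.scaffold_id}\tpromarch\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.id}.e{i};Parent={g.id}\n"
                )
            if g.cds_start is not None:
                for i, (s, e) in enumerate(g.exons or ((g.tx_start, g.tx_end),)):
                    cs, ce = max(s, g.cds_start), min(e, g.cds_end)
                    if cs < ce:
                        fh.write(
                            f"{g.scaffold_id}\tpromarch\tCDS\t{cs + 1}\t{ce}\t.\t"
                            f"{g.strand}\t0\tID={g.id}.c{i};Parent={g.id}\n"
                        )
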