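"""Genome, annotation, and variant I/O under one coordinate convention.

Everything downstream of this module speaks 0-based half-open genomic
coordinates.  GFF3 (1-based inclusive) and VCF (1-based POS) are converted
on read; report writers emit both conventions.  Sequences are stored
uppercase over the alphabet {A, C, G, T, N}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import gffutils
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from cyvcf2 import VCF
from intervaltree import IntervalTree

from .errors import CoordinateError, FastaError, GffError, VcfError

log = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

STRANDS = ("+", "-", ".")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase {A,C,G,T,N} string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval: ``[start, end)`` on ``chrom``.

    ``strand`` is '+', '-' or '.' (unstranded).  Strand affects only how
    sequence is extracted, never the coordinates themselves.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise CoordinateError(f"invalid strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise CoordinateError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )

    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def contains_pos(self, pos: int) -> bool:
        return self.start <= pos < self.end


class GenomeAssembly:
    """Ordered mapping of sequence name -> uppercase nucleotide string."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs: dict[str, str] = {}
        for name, seq in sequences.items():
            if name in self._seqs:
                raise FastaError(f"duplicate sequence name {name!r}")
            s = seq.upper()
            bad = set(s) - _VALID_BASES
            if bad:
                raise FastaError(
                    f"sequence {name!r} contains non-IUPAC characters: "
                    f"{sorted(bad)}"
                )
            self._seqs[name] = s
        if not self._seqs:
            raise FastaError("assembly holds no sequences")
        self._encoded: dict[str, np.ndarray] = {}

    def names(self) -> list[str]:
        return list(self._seqs)

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    def __getitem__(self, name: str) -> str:
        try:
            return self._seqs[name]
        except KeyError:
            raise KeyError(f"unknown sequence {name!r}") from None

    def length(self, name: str) -> int:
        return len(self[name])

    def items(self) -> Iterable[tuple[str, str]]:
        return self._seqs.items()

    def encoded(self, name: str) -> np.ndarray:
        """Sequence as a uint8 array of ASCII codes (cached)."""
        arr = self._encoded.get(name)
        if arr is None:
            arr = np.frombuffer(self[name].encode("ascii"), dtype=np.uint8)
            self._encoded[name] = arr
        return arr

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GenomeAssembly) and self._seqs == other._seqs


@dataclass(frozen=True)
class Transcript:
    """One CDS chain: segments in genomic order, non-overlapping."""

    transcript_id: str
    cds: tuple[GenomicInterval, ...]

    def total_cds_length(self) -> int:
        return sum(seg.length() for seg in self.cds)


@dataclass(frozen=True)
class GeneModel:
    """A gene with one or more transcript CDS chains.

    Supplies the most-5' start codon, the most-3' stop codon, and the
    first/last coding exons that target-region selection works from.
    """

    gene_id: str
    chrom: str
    strand: str
    transcripts: tuple[Transcript, ...]
    source_lines: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise GffError(f"gene {self.gene_id}: invalid strand {self.strand!r}")
        if not self.transcripts or any(not t.cds for t in self.transcripts):
            raise GffError(
                f"gene {self.gene_id}: every transcript needs >=1 CDS segment"
            )
        for t in self.transcripts:
            prev_end = -1
            for seg in t.cds:
                if seg.chrom != self.chrom:
                    raise GffError(
                        f"gene {self.gene_id}: CDS on {seg.chrom}, gene on "
                        f"{self.chrom}"
                    )
                if seg.start < prev_end:
                    raise GffError(
                        f"gene {self.gene_id} transcript {t.transcript_id}: "
                        "CDS segments overlap or are unsorted"
                    )
                prev_end = seg.end

    def cds_intervals(self) -> Iterator[GenomicInterval]:
        for t in self.transcripts:
            yield from t.cds

    def span(self) -> GenomicInterval:
        starts = [seg.start for seg in self.cds_intervals()]
        ends = [seg.end for seg in self.cds_intervals()]
        return GenomicInterval(self.chrom, min(starts), max(ends), self.strand)


@dataclass(frozen=True)
class VariantRecord:
    """One SNP/indel from a labeled background genome, versus the reference.

    ``pos0`` is the 0-based start of the REF allele.  For overlap tests an
    insertion occupies one reference base: any insertion within a guide's
    footprint breaks targeting just as a substitution would.
    """

    chrom: str
    pos0: int
    ref: str
    alt: str
    type: str  # SNP | INS | DEL | MNP
    label: str

    def affected_interval(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.pos0, self.pos0 + max(1, len(self.ref))
        )


def classify_variant(ref: str, alt: str) -> str:
    if len(ref) == len(alt):
        return "SNP" if len(ref) == 1 else "MNP"
    return "INS" if len(alt) > len(ref) else "DEL"


class VariantSet:
    """Labeled collection of variant records with per-chromosome indexing."""

    def __init__(self, label: str, records: Iterable[VariantRecord]):
        self.label = label
        self.records: list[VariantRecord] = sorted(
            records, key=lambda r: (r.chrom, r.pos0, r.ref, r.alt)
        )
        self._trees: dict[str, IntervalTree] = {}
        for rec in self.records:
            iv = rec.affected_interval()
            self._trees.setdefault(rec.chrom, IntervalTree()).addi(
                iv.start, iv.end, rec
            )

    def __len__(self) -> int:
        return len(self.records)

    def overlapping(self, chrom: str, start: int, end: int) -> list[VariantRecord]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [hit.data for hit in tree.overlap(start, end)]
        hits.sort(key=lambda r: (r.pos0, r.ref, r.alt))
        return hits


# ---------------------------------------------------------------------------
# readers / writers


def read_fasta(path: str | Path) -> GenomeAssembly:
    """Read a (wrapped or unwrapped) multi-record FASTA into an assembly.

    Rejects empty files, duplicated headers, and characters outside
    {A,C,G,T,N} (case-insensitive), naming the offending record.
    """
    path = Path(path)
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FastaError(f"{path}: duplicate sequence name {rec.id!r}")
        seqs[rec.id] = str(rec.seq)
    if not seqs:
        raise FastaError(f"{path}: no FASTA records found")
    try:
        return GenomeAssembly(seqs)
    except FastaError as exc:
        raise FastaError(f"{path}: {exc}") from None


def write_fasta(assembly: GenomeAssembly, path: str | Path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in assembly.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def _gff_line_number(path: Path, ftype: str, start1: int, end1: int) -> int | None:
    """Best-effort lookup of the 1-based line number of a GFF3 feature."""
    try:
        with open(path) as fh:
            for i, line in enumerate(fh, start=1):
                cols = line.rstrip("\n").split("\t")
                if len(cols) >= 5 and cols[2] == ftype:
                    if cols[3] == str(start1) and cols[4] == str(end1):
                        return i
    except OSError:
        pass
    return None


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse gene/mRNA/CDS models from GFF3 into 0-based half-open intervals.

    GFF3 rows are linked by ID/Parent.  Genes without any CDS are dropped
    with a logged warning; orphan CDS rows and mixed-strand transcripts are
    hard errors reported with the offending line number.
    """
    path = Path(path)
    db = gffutils.create_db(
        str(path), ":memory:", keep_order=True, merge_strategy="create_unique"
    )

    known_ids = {f.id for f in db.all_features()}
    mrna_ids = {f.id for f in db.features_of_type("mRNA")}
    for cds in db.features_of_type("CDS"):
        for parent in cds.attributes.get("Parent", []):
            if parent not in known_ids or parent not in mrna_ids:
                line = _gff_line_number(path, "CDS", cds.start, cds.end)
                raise GffError(
                    f"{path}: CDS with unknown Parent {parent!r}"
                    + (f" at line {line}" if line else "")
                )

    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        transcripts: list[Transcript] = []
        lines: list[int] = []
        for mrna in db.children(gene, featuretype="mRNA", order_by="start"):
            segs: list[GenomicInterval] = []
            for cds in db.children(mrna, featuretype="CDS", order_by="start"):
                if cds.strand != mrna.strand or cds.strand != gene.strand:
                    line = _gff_line_number(path, "CDS", cds.start, cds.end)
                    raise GffError(
                        f"{path}: mixed-strand transcript {mrna.id!r}"
                        + (f" at line {line}" if line else "")
                    )
                # GFF3 1-based inclusive -> 0-based half-open
                segs.append(
                    GenomicInterval(
                        cds.seqid, cds.start - 1, cds.end, cds.strand
                    )
                )
                line = _gff_line_number(path, "CDS", cds.start, cds.end)
                if line:
                    lines.append(line)
            if not segs:
                log.warning(
                    "transcript %s of gene %s has no CDS rows; skipped",
                    mrna.id, gene.id,
                )
                continue
            transcripts.append(Transcript(mrna.id, tuple(segs)))
        if not transcripts:
            log.warning("gene %s has no coding transcripts; dropped", gene.id)
            continue
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                transcripts=tuple(transcripts),
                source_lines=tuple(sorted(set(lines))),
            )
        )
    return genes


def read_vcf(
    path: str | Path, label: str, assembly: GenomeAssembly | None = None
) -> VariantSet:
    """Read CHROM/POS/REF/ALT rows into a labeled variant set.

    Multi-allelic rows are split into one record per ALT.  When an assembly
    is supplied, every REF string is checked against it; the first
    disagreement aborts the read.
    """
    path = Path(path)
    records: list[VariantRecord] = []
    for v in VCF(str(path)):
        ref = v.REF.upper()
        pos0 = v.start  # cyvcf2 exposes 0-based start
        for alt in v.ALT:
            alt = alt.upper()
            if set(alt) - _VALID_BASES or alt.startswith("<"):
                log.warning(
                    "%s: skipping symbolic/non-nucleotide ALT %r at %s:%d",
                    path, alt, v.CHROM, v.POS,
                )
                continue
            if assembly is not None:
                if v.CHROM not in assembly:
                    raise VcfError(
                        f"{path}: record {v.CHROM}:{v.POS} on unknown "
                        f"chromosome {v.CHROM!r}"
                    )
                observed = assembly[v.CHROM][pos0 : pos0 + len(ref)]
                if observed != ref:
                    raise VcfError(
                        f"{path}: REF mismatch at {v.CHROM}:{v.POS}: VCF says "
                        f"{ref!r}, assembly has {observed!r}"
                    )
            records.append(
                VariantRecord(
                    chrom=v.CHROM,
                    pos0=pos0,
                    ref=ref,
                    alt=alt,
                    type=classify_variant(ref, alt),
                    label=label,
                )
            )
    return VariantSet(label, records)


def extract(assembly: GenomeAssembly, interval: GenomicInterval) -> str:
    """Sequence of ``interval``; minus strand returns the reverse complement."""
    if interval.chrom not in assembly:
        raise CoordinateError(f"unknown chromosome {interval.chrom!r}")
    if interval.end > assembly.length(interval.chrom):
        raise CoordinateError(
            f"interval [{interval.start}, {interval.end}) exceeds "
            f"{interval.chrom} length {assembly.length(interval.chrom)}"
        )
    seq = assembly[interval.chrom][interval.start : interval.end]
    return revcomp(seq) if interval.strand == "-" else seq
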