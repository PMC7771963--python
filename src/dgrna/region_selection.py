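"""Selection of the two ~100-bp guide target regions per gene.

One window sits at the most-5' start codon in the first coding exon, the
other ends at the most-3' stop codon in the exon containing it.  When a
default window would disrupt the coding sequence of a different gene (for
example an ORF nested in an intron of the host gene), the window slides
along the same transcript's CDS toward the ORF interior -- 3' for the START
window, 5' for the STOP window -- exon by exon, until a clean window is
found.  Only foreign CDS blocks a window; UTR-only overlap is permitted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

from intervaltree import IntervalTree

from .errors import NoCleanRegion
from .genome_io import GeneModel, GenomeAssembly, GenomicInterval, Transcript

START = "START"
STOP = "STOP"


@dataclass(frozen=True)
class TargetRegion:
    """A candidate guide window tied to a gene and a role (START or STOP).

    ``anchor`` is the genomic position of the start codon's first base
    (START) or the stop codon's last base (STOP).  ``shifted`` records that
    neighbor-avoidance moved the window away from its default position.
    """

    gene_id: str
    role: str
    interval: GenomicInterval
    anchor: int
    shifted: bool
    rationale: str

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


def coding_anchors(gene: GeneModel) -> tuple[int, int]:
    """(most-5' start-codon base, most-3' stop-codon base), genomic positions.

    On the plus strand these are the minimum first-CDS base and the maximum
    last-CDS base over all transcripts; mirrored on the minus strand.
    """
    starts = [t.cds[0].start for t in gene.transcripts]
    ends = [t.cds[-1].end for t in gene.transcripts]
    if gene.strand == "+":
        return min(starts), max(ends) - 1
    return max(ends) - 1, min(starts)


def _anchor_transcript(gene: GeneModel, role: str) -> Transcript:
    """Transcript achieving the role's anchor; longest CDS breaks ties."""
    start_anchor, stop_anchor = coding_anchors(gene)
    want = start_anchor if role == START else stop_anchor
    best: Transcript | None = None
    for t in gene.transcripts:
        if gene.strand == "+":
            edge = t.cds[0].start if role == START else t.cds[-1].end - 1
        else:
            edge = t.cds[-1].end - 1 if role == START else t.cds[0].start
        if edge != want:
            continue
        if best is None or t.total_cds_length() > best.total_cds_length():
            best = t
    assert best is not None  # anchor is a min/max over these same edges
    return best


def first_coding_exon(gene: GeneModel) -> GenomicInterval:
    """The CDS segment containing the most-5' start codon."""
    t = _anchor_transcript(gene, START)
    return t.cds[0] if gene.strand == "+" else t.cds[-1]


def last_coding_exon(gene: GeneModel) -> GenomicInterval:
    """The CDS segment containing the most-3' stop codon."""
    t = _anchor_transcript(gene, STOP)
    return t.cds[-1] if gene.strand == "+" else t.cds[0]


# ---------------------------------------------------------------------------
# window enumeration in transcript-local coordinates


def _tx_order(t: Transcript, strand: str) -> list[GenomicInterval]:
    return list(t.cds) if strand == "+" else list(reversed(t.cds))


def _local_to_genomic(
    exons_tx: list[GenomicInterval],
    cum: list[int],
    strand: str,
    a: int,
    b: int,
    exon_idx: int,
) -> GenomicInterval:
    """Map a local window [a, b) inside one exon back to genomic coordinates."""
    ex = exons_tx[exon_idx]
    off_a = a - cum[exon_idx]
    off_b1 = b - 1 - cum[exon_idx]
    if strand == "+":
        return GenomicInterval(ex.chrom, ex.start + off_a, ex.start + off_b1 + 1)
    return GenomicInterval(ex.chrom, ex.end - 1 - off_b1, ex.end - off_a)


def _enumerate_windows(
    t: Transcript, strand: str, role: str, window: int, min_window: int
) -> Iterator[GenomicInterval]:
    """Candidate windows in priority order, each within a single exon.

    Local coordinate 0 is the transcript's 5'-most CDS base.  START windows
    begin at local 0 and slide 3'; STOP windows end at the last local base
    and slide 5'.  Exons shorter than ``min_window`` are skipped.
    """
    exons_tx = _tx_order(t, strand)
    lens = [ex.length() for ex in exons_tx]
    cum = [0]
    for n in lens:
        cum.append(cum[-1] + n)
    total = cum[-1]

    if role == START:
        for i, ex in enumerate(exons_tx):
            cs, ce = cum[i], cum[i + 1]
            if ce - cs < min_window:
                continue
            for a in range(cs, ce - min_window + 1):
                b = min(a + window, ce)
                yield _local_to_genomic(exons_tx, cum, strand, a, b, i)
    else:
        for i in range(len(exons_tx) - 1, -1, -1):
            cs, ce = cum[i], cum[i + 1]
            if ce - cs < min_window:
                continue
            hi = ce if i < len(exons_tx) - 1 else total
            for b in range(hi, cs + min_window - 1, -1):
                a = max(b - window, cs)
                yield _local_to_genomic(exons_tx, cum, strand, a, b, i)


def build_cds_index(genes: Iterable[GeneModel]) -> dict[str, IntervalTree]:
    """Per-chromosome interval index of every CDS base, tagged with gene id."""
    trees: dict[str, IntervalTree] = {}
    for gene in genes:
        for seg in gene.cds_intervals():
            trees.setdefault(seg.chrom, IntervalTree()).addi(
                seg.start, seg.end, gene.gene_id
            )
    return trees


def _blocking(
    trees: dict[str, IntervalTree], iv: GenomicInterval, own_id: str
) -> set[str]:
    tree = trees.get(iv.chrom)
    if tree is None:
        return set()
    return {h.data for h in tree.overlap(iv.start, iv.end) if h.data != own_id}


def select_target_regions(
    gene: GeneModel,
    genome: GenomeAssembly,
    all_genes: Iterable[GeneModel],
    window: int = 100,
    min_window: int = 30,
    cds_index: dict[str, IntervalTree] | None = None,
) -> tuple[TargetRegion, TargetRegion]:
    """The START and STOP target windows for ``gene``.

    Raises :class:`NoCleanRegion` when every window of at least
    ``min_window`` bp overlaps foreign CDS, naming the blocking genes.
    """
    if cds_index is None:
        cds_index = build_cds_index(all_genes)
    start_anchor, stop_anchor = coding_anchors(gene)
    chrom_len = genome.length(gene.chrom)

    out: list[TargetRegion] = []
    for role, anchor in ((START, start_anchor), (STOP, stop_anchor)):
        t = _anchor_transcript(gene, role)
        blockers: set[str] = set()
        chosen: GenomicInterval | None = None
        first_iv: GenomicInterval | None = None
        for iv in _enumerate_windows(t, gene.strand, role, window, min_window):
            if iv.end > chrom_len:
                continue
            if first_iv is None:
                first_iv = iv
            hit = _blocking(cds_index, iv, gene.gene_id)
            if hit:
                blockers |= hit
                continue
            chosen = iv
            break
        if chosen is None:
            raise NoCleanRegion(gene.gene_id, role, tuple(sorted(blockers)))
        shifted = chosen != first_iv
        if shifted:
            rationale = (
                f"{role} window shifted toward ORF interior to avoid CDS of: "
                + ", ".join(sorted(blockers))
            )
        else:
            rationale = f"default {role} window at the codon anchor"
        out.append(
            TargetRegion(
                gene_id=gene.gene_id,
                role=role,
                interval=GenomicInterval(
                    gene.chrom, chosen.start, chosen.end, gene.strand
                ),
                anchor=anchor,
                shifted=shifted,
                rationale=rationale,
            )
        )
    return out[0], out[1]
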