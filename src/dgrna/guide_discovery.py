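"""SpCas9 protospacer enumeration and cloning-oligo emission.

A candidate is a 20-nt protospacer immediately 5' of an NGG PAM on either
strand, scanned within a target window (the PAM may poke a configurable few
bases past the window edge).  The blunt cut falls between protospacer
positions 17 and 18, i.e. 3 bp 5' of the PAM.  The emitted spacer follows
the G(N19) cloning scheme: the expression vector supplies the leading G and
the oligo carries the 19 PAM-proximal target bases.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

from .genome_io import GenomeAssembly, GenomicInterval, extract, revcomp
from .region_selection import TargetRegion

PROTOSPACER_LEN = 20
SEED_LEN = 12

# Constant arms of the vector-amplification oligos (U6-promoter vectors).
FORWARD_TAIL = "GTTTTAGAGCTAGAAATAGC"
REVERSE_OLIGO = "GAAGTATTGAGGAAAACATA"

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class GuideCandidate:
    """A protospacer+PAM occurrence with strand, cut site, and seed.

    ``protospacer`` is 5'->3' on the guide strand; ``cut0`` is the 0-based
    genomic position whose 5' bond is cleaved (the blunt SpCas9 cut).
    """

    gene_id: str
    region_role: str
    chrom: str
    strand: str
    protospacer: str
    pam: str
    protospacer_interval: GenomicInterval
    pam_interval: GenomicInterval
    cut0: int

    @property
    def seed12(self) -> str:
        """The 12 protospacer bases proximal to the PAM."""
        return self.protospacer[-SEED_LEN:]

    @property
    def n19(self) -> str:
        """The protospacer minus its 5'-most base (cloning target sequence)."""
        return self.protospacer[1:]

    def footprint(self) -> GenomicInterval:
        """Protospacer plus PAM as one genomic interval."""
        return GenomicInterval(
            self.chrom,
            min(self.protospacer_interval.start, self.pam_interval.start),
            max(self.protospacer_interval.end, self.pam_interval.end),
        )


def cut_site(strand: str, pam_interval: GenomicInterval) -> int:
    """Blunt cut position: 3 bp 5' of the PAM on the guide strand."""
    if strand == "+":
        return pam_interval.start - 3
    return pam_interval.end + 3


RegionLike = Union[TargetRegion, GenomicInterval]


def scan_protospacers(
    region: RegionLike,
    assembly: GenomeAssembly,
    pam_slack: int = 3,
) -> list[GuideCandidate]:
    """All 20-nt protospacers 5' of an NGG on either strand of ``region``.

    The protospacer must sit fully inside the region; the PAM may extend up
    to ``pam_slack`` bases past the region edge.  Candidates whose
    protospacer or PAM contains N are discarded.  Output is sorted by cut
    position, then strand.
    """
    if isinstance(region, TargetRegion):
        iv, gene_id, role = region.interval, region.gene_id, region.role
    else:
        iv, gene_id, role = region, "", ""
    chrom = iv.chrom
    seq = assembly[chrom]
    lo, hi = iv.start, iv.end
    ext_lo = max(0, lo - pam_slack)
    ext_hi = min(len(seq), hi + pam_slack)

    out: list[GuideCandidate] = []
    # plus strand: protospacer [p, p+20), PAM [p+20, p+23) with GG at +21,+22
    for p in range(lo, hi - PROTOSPACER_LEN + 1):
        pam_end = p + PROTOSPACER_LEN + 3
        if pam_end > ext_hi:
            break
        if seq[p + 21 : p + 23] != "GG":
            continue
        proto = seq[p : p + PROTOSPACER_LEN]
        pam = seq[p + PROTOSPACER_LEN : pam_end]
        if set(proto) - _ACGT or set(pam) - _ACGT:
            continue
        pam_iv = GenomicInterval(chrom, p + PROTOSPACER_LEN, pam_end)
        out.append(
            GuideCandidate(
                gene_id=gene_id,
                region_role=role,
                chrom=chrom,
                strand="+",
                protospacer=proto,
                pam=pam,
                protospacer_interval=GenomicInterval(chrom, p, p + PROTOSPACER_LEN),
                pam_interval=pam_iv,
                cut0=cut_site("+", pam_iv),
            )
        )
    # minus strand: protospacer [s, s+20), PAM [s-3, s); genomic CCN reads
    # NGG on the guide strand
    for s in range(lo, hi - PROTOSPACER_LEN + 1):
        pam_start = s - 3
        if pam_start < ext_lo:
            continue
        if seq[s - 3 : s - 1] != "CC":
            continue
        proto_plus = seq[s : s + PROTOSPACER_LEN]
        pam_plus = seq[pam_start:s]
        if set(proto_plus) - _ACGT or set(pam_plus) - _ACGT:
            continue
        pam_iv = GenomicInterval(chrom, pam_start, s)
        out.append(
            GuideCandidate(
                gene_id=gene_id,
                region_role=role,
                chrom=chrom,
                strand="-",
                protospacer=revcomp(proto_plus),
                pam=revcomp(pam_plus),
                protospacer_interval=GenomicInterval(chrom, s, s + PROTOSPACER_LEN),
                pam_interval=pam_iv,
                cut0=cut_site("-", pam_iv),
            )
        )
    out.sort(key=lambda c: (c.cut0, c.strand))
    return out


def cloning_oligos(candidate: GuideCandidate) -> tuple[str, str]:
    """(forward, reverse) vector-amplification oligos for one guide.

    forward = "G" + N19 + constant tail (40 nt); reverse is constant.
    """
    forward = "G" + candidate.n19 + FORWARD_TAIL
    return forward, REVERSE_OLIGO


def verify_candidate(candidate: GuideCandidate, assembly: GenomeAssembly) -> bool:
    """Round-trip check: protospacer and PAM re-extract from the assembly."""
    ps = extract(
        assembly,
        GenomicInterval(
            candidate.chrom,
            candidate.protospacer_interval.start,
            candidate.protospacer_interval.end,
            candidate.strand,
        ),
    )
    pm = extract(
        assembly,
        GenomicInterval(
            candidate.chrom,
            candidate.pam_interval.start,
            candidate.pam_interval.end,
            candidate.strand,
        ),
    )
    return ps == candidate.protospacer and pm == candidate.pam
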