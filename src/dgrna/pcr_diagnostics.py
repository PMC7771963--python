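"""Deletion-screening PCR prediction.

Given a primer pair and a designed deletion, predicts the wild-type and
deletion-junction amplicon sizes under the blunt re-ligation model, flags
whether each product is within amplifiable range, and notes the
small-product amplification bias: when the deletion product is much
shorter than the wild-type product, the wild-type band is often weak or
absent on a gel even though both templates are present.

Primer mapping is exact-match only and each primer must map to exactly one
site; sizes follow the standard gel convention, 5' end of the forward
primer to the 5' end of the reverse primer, inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Union

import pandas as pd

from .deletion_design import deletion_allele
from .errors import (
    AmbiguousPrimer,
    DivergentPrimers,
    PrimerError,
    PrimerLost,
    PrimerUnmapped,
)
from .genome_io import GenomeAssembly, GenomicInterval, revcomp

_ACGT = frozenset("ACGT")

OUTER = "OUTER"
INNER = "INNER"
SINGLE = "SINGLE"

BIAS_NOTE = (
    "deletion product is shorter than the wild-type product; preferential "
    "amplification of the small product may mask the wild-type band"
)


@dataclass(frozen=True)
class PrimerPair:
    name: str
    forward: str
    reverse: str
    tier: str = SINGLE

    def __post_init__(self) -> None:
        for role, seq in (("forward", self.forward), ("reverse", self.reverse)):
            if not 15 <= len(seq) <= 40:
                raise PrimerError(
                    f"{self.name}: {role} primer length {len(seq)} outside 15-40"
                )
            if set(seq) - _ACGT:
                raise PrimerError(
                    f"{self.name}: {role} primer contains non-ACGT characters"
                )
        if self.tier not in (OUTER, INNER, SINGLE):
            raise PrimerError(f"{self.name}: unknown tier {self.tier!r}")


@dataclass
class AmpliconPrediction:
    primer_pair: PrimerPair
    chrom: str
    wt_size: int | None
    del_size: int | None
    wt_interval: GenomicInterval | None  # reference coordinates
    del_interval: GenomicInterval | None  # deletion-allele coordinates
    wt_sequence: str | None
    del_sequence: str | None
    wt_detectable: bool
    del_detectable: bool
    wt_warn: bool  # amplifiable only marginally (WARN tier)
    del_warn: bool
    bias_note: str | None


SeqSource = Union[GenomeAssembly, Mapping[str, str]]


def _iter_seqs(source: SeqSource):
    if isinstance(source, GenomeAssembly):
        return source.items()
    return source.items()


def locate_primer(
    source: SeqSource, primer: str
) -> list[tuple[GenomicInterval, str]]:
    """All exact occurrences of ``primer`` on both strands, sorted."""
    primer = primer.upper()
    if set(primer) - _ACGT:
        raise PrimerError("primer contains characters outside ACGT")
    rc = revcomp(primer)
    hits: list[tuple[GenomicInterval, str]] = []
    for chrom, seq in _iter_seqs(source):
        for probe, strand in ((primer, "+"), (rc, "-")):
            pos = seq.find(probe)
            while pos != -1:
                hits.append(
                    (GenomicInterval(chrom, pos, pos + len(probe)), strand)
                )
                pos = seq.find(probe, pos + 1)
    hits.sort(key=lambda h: (h[0].chrom, h[0].start, h[1]))
    return hits


def _map_unique(
    source: SeqSource, primer: str, name: str, where: str
) -> tuple[GenomicInterval, str]:
    hits = locate_primer(source, primer)
    if not hits:
        raise PrimerUnmapped(f"{name}: no exact match on the {where}")
    if len(hits) > 1:
        raise AmbiguousPrimer(
            f"{name}: {len(hits)} sites on the {where}; unique mapping required"
        )
    return hits[0]


def _amplicon(
    plus: tuple[GenomicInterval, str],
    minus: tuple[GenomicInterval, str],
    name: str,
) -> GenomicInterval:
    """Span from the plus-primer 5' end to the minus-primer 5' end, inclusive."""
    if plus[0].chrom != minus[0].chrom:
        raise DivergentPrimers(f"{name}: primers map to different chromosomes")
    fwd5 = plus[0].start
    rev5 = minus[0].end - 1
    if rev5 <= fwd5 or minus[0].start < plus[0].end:
        raise DivergentPrimers(
            f"{name}: primers do not face each other across a template span"
        )
    return GenomicInterval(plus[0].chrom, fwd5, rev5 + 1)


def _orient(
    hit_f: tuple[GenomicInterval, str],
    hit_r: tuple[GenomicInterval, str],
    name: str,
) -> tuple[tuple[GenomicInterval, str], tuple[GenomicInterval, str]]:
    """Normalize so the first primer is the plus-strand one.

    Predictions are invariant to which primer the table calls forward.
    """
    strands = (hit_f[1], hit_r[1])
    if strands == ("+", "-"):
        return hit_f, hit_r
    if strands == ("-", "+"):
        return hit_r, hit_f
    raise DivergentPrimers(
        f"{name}: primers map to the same strand ({strands[0]})"
    )


def predict_amplicons(
    primer_pair: PrimerPair,
    assembly: GenomeAssembly,
    deletion: GenomicInterval | None = None,
    max_amplifiable: int = 5000,
    warn_amplifiable: int = 10000,
) -> AmpliconPrediction:
    """Wild-type and deletion-junction product sizes for one primer pair.

    ``deletion`` is the designed blunt-excision interval; ``None`` predicts
    the wild-type product only.  Raises AmbiguousPrimer / PrimerUnmapped /
    DivergentPrimers on mapping failures and PrimerLost when a primer falls
    inside the deleted interval.
    """
    name = primer_pair.name
    hit_f = _map_unique(assembly, primer_pair.forward, f"{name}/forward", "reference")
    hit_r = _map_unique(assembly, primer_pair.reverse, f"{name}/reverse", "reference")
    plus, minus = _orient(hit_f, hit_r, name)
    wt_iv = _amplicon(plus, minus, name)
    wt_size = wt_iv.length()
    wt_seq = assembly[wt_iv.chrom][wt_iv.start : wt_iv.end]

    del_size = None
    del_iv = None
    del_seq = None
    if deletion is not None:
        for role, (iv, _) in (("forward", hit_f), ("reverse", hit_r)):
            if iv.chrom == deletion.chrom and iv.overlaps(deletion):
                raise PrimerLost(
                    f"{name}/{role}: primer footprint overlaps the deleted "
                    f"interval [{deletion.start}, {deletion.end})"
                )
        allele = deletion_allele(assembly, deletion)
        d_f = _map_unique(
            allele, primer_pair.forward, f"{name}/forward", "deletion allele"
        )
        d_r = _map_unique(
            allele, primer_pair.reverse, f"{name}/reverse", "deletion allele"
        )
        d_plus, d_minus = _orient(d_f, d_r, name)
        del_iv = _amplicon(d_plus, d_minus, name)
        del_size = del_iv.length()
        del_seq = allele[del_iv.chrom][del_iv.start : del_iv.end]

    bias = None
    if del_size is not None and del_size < wt_size:
        bias = BIAS_NOTE
    return AmpliconPrediction(
        primer_pair=primer_pair,
        chrom=wt_iv.chrom,
        wt_size=wt_size,
        del_size=del_size,
        wt_interval=wt_iv,
        del_interval=del_iv,
        wt_sequence=wt_seq,
        del_sequence=del_seq,
        wt_detectable=wt_size <= max_amplifiable,
        del_detectable=del_size is not None and del_size <= max_amplifiable,
        wt_warn=max_amplifiable < wt_size <= warn_amplifiable,
        del_warn=del_size is not None
        and max_amplifiable < del_size <= warn_amplifiable,
        bias_note=bias,
    )


@dataclass
class NestedReport:
    """Outer/inner product sizes and containment on both alleles."""

    outer: AmpliconPrediction
    inner: AmpliconPrediction
    contained_ref: bool
    contained_del: bool | None

    @property
    def status(self) -> str:
        ok = self.contained_ref and self.contained_del in (True, None)
        return "OK" if ok else "InnerOutsideOuter"


def nested_plan(
    outer: PrimerPair,
    inner: PrimerPair,
    assembly: GenomeAssembly,
    deletion: GenomicInterval | None = None,
    max_amplifiable: int = 5000,
    warn_amplifiable: int = 10000,
) -> NestedReport:
    """Check that the inner amplicon nests inside the outer on both alleles.

    A violated containment is reported (audit use), not raised.
    """
    p_out = predict_amplicons(
        outer, assembly, deletion, max_amplifiable, warn_amplifiable
    )
    p_in = predict_amplicons(
        inner, assembly, deletion, max_amplifiable, warn_amplifiable
    )
    contained_ref = p_out.wt_interval.contains(p_in.wt_interval)
    contained_del = None
    if deletion is not None:
        contained_del = p_out.del_interval.contains(p_in.del_interval)
    return NestedReport(
        outer=p_out,
        inner=p_in,
        contained_ref=contained_ref,
        contained_del=contained_del,
    )


def read_primer_table(path: str | Path) -> list[PrimerPair]:
    """TSV with columns name, forward, reverse and optional tier."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"name", "forward", "reverse"}
    missing = required - set(df.columns)
    if missing:
        raise PrimerError(f"{path}: primer table missing columns {sorted(missing)}")
    pairs = []
    for _, row in df.iterrows():
        pairs.append(
            PrimerPair(
                name=row["name"],
                forward=row["forward"].upper(),
                reverse=row["reverse"].upper(),
                tier=row.get("tier", SINGLE) if "tier" in df.columns else SINGLE,
            )
        )
    return pairs
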