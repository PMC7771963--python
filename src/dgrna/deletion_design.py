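"""Pairing one START guide with one STOP guide to excise the whole ORF.

The designer scans both target windows, screens every candidate against
the background genomes and the whole assembly, then picks the best PASS
pair: highest combined efficiency, fewest variant-adjacent records, lowest
coordinates as the final tie-break.  Runner-up pairs are kept so a failed
pair can be swapped for the next candidate combination without re-running
the design.  The predicted deletion uses the blunt re-ligation model: the
reference with the inter-cut interval excised.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .config import RunConfig
from .errors import NoViablePair
from .genome_io import GeneModel, GenomeAssembly, GenomicInterval, VariantSet
from .guide_discovery import GuideCandidate, cloning_oligos, scan_protospacers
from .region_selection import select_target_regions
from .screening import PASS, OffTargetParams, ScreenReport, screen


@dataclass(frozen=True)
class GuidePair:
    guide1: GuideCandidate  # START region
    guide2: GuideCandidate  # STOP region
    deletion_size: int

    def deletion_interval(self) -> GenomicInterval:
        lo = min(self.guide1.cut0, self.guide2.cut0)
        hi = max(self.guide1.cut0, self.guide2.cut0)
        return GenomicInterval(self.guide1.chrom, lo, hi)


@dataclass
class DeletionDesign:
    """An ordered guide pair with its predicted deletion and cloning oligos."""

    gene_id: str
    guide1: GuideCandidate
    guide2: GuideCandidate
    deletion_interval: GenomicInterval
    deletion_size: int
    oligos1: tuple[str, str]
    oligos2: tuple[str, str]
    alternates: list[GuidePair]
    provenance: dict


def rank_candidates(reports: Iterable[ScreenReport]) -> list[ScreenReport]:
    """PASS reports ordered by efficiency desc, variant-adjacency asc,
    genomic coordinate asc, strand as the last tie-break.  Deterministic."""
    passing = [r for r in reports if r.verdict == PASS]
    passing.sort(
        key=lambda r: (
            -r.efficiency,
            r.variant_adjacent,
            r.candidate.protospacer_interval.start,
            r.candidate.strand,
        )
    )
    return passing


def _pair_key(r1: ScreenReport, r2: ScreenReport):
    c1, c2 = r1.candidate, r2.candidate
    return (
        -(r1.efficiency + r2.efficiency),
        r1.variant_adjacent + r2.variant_adjacent,
        min(c1.cut0, c2.cut0),
        max(c1.cut0, c2.cut0),
        c1.strand,
        c2.strand,
    )


def screen_gene(
    gene: GeneModel,
    assembly: GenomeAssembly,
    all_genes: Sequence[GeneModel],
    variant_sets: Sequence[VariantSet],
    config: RunConfig | None = None,
):
    """Regions plus the full screen report of every candidate in each.

    Returns ``(start_region, stop_region, {"START": [...], "STOP": [...]})``
    with reports in scan order, PASS and FAIL alike (audit completeness).
    """
    config = config or RunConfig()
    start_region, stop_region = select_target_regions(
        gene,
        assembly,
        all_genes,
        window=config.window,
        min_window=config.min_window,
    )
    ot_params = OffTargetParams(
        max_mm_total=config.max_mm_total,
        max_mm_seed=config.max_mm_seed,
        pams=tuple(config.pams),
    )
    weight_table = config.load_weights()
    reports: dict[str, list[ScreenReport]] = {}
    for region in (start_region, stop_region):
        cands = scan_protospacers(region, assembly, pam_slack=config.pam_slack)
        reports[region.role] = [
            screen(
                c,
                assembly,
                variant_sets,
                offtarget_params=ot_params,
                efficiency_floor=config.efficiency_floor,
                weight_table=weight_table,
                adjacency_flank=config.adjacency_flank,
            )
            for c in cands
        ]
    return start_region, stop_region, reports


def pair_from_reports(
    gene: GeneModel,
    reports: dict[str, list[ScreenReport]],
    config: RunConfig | None = None,
) -> DeletionDesign:
    """Best PASS pair over the START x STOP grid, plus ranked alternates."""
    config = config or RunConfig()
    ranked: dict[str, list[ScreenReport]] = {}
    for role in ("START", "STOP"):
        ranked[role] = rank_candidates(reports[role])
        if not ranked[role]:
            raise NoViablePair(
                gene.gene_id,
                stage=f"screening:{role}",
                detail=f"no PASS guide among {len(reports[role])} candidates "
                f"in the {role} region",
            )

    pairs = [
        (r1, r2)
        for r1 in ranked["START"]
        for r2 in ranked["STOP"]
        if abs(r2.candidate.cut0 - r1.candidate.cut0) >= config.min_separation
    ]
    if not pairs:
        raise NoViablePair(
            gene.gene_id,
            stage="pairing",
            detail=f"all PASS pairs fall under the minimum cut separation "
            f"({config.min_separation} bp)",
        )
    pairs.sort(key=lambda p: _pair_key(*p))

    best1, best2 = pairs[0]
    g1, g2 = best1.candidate, best2.candidate
    lo, hi = sorted((g1.cut0, g2.cut0))
    alternates = [
        GuidePair(r1.candidate, r2.candidate, abs(r2.candidate.cut0 - r1.candidate.cut0))
        for r1, r2 in pairs[1 : 1 + config.k_alternates]
    ]
    return DeletionDesign(
        gene_id=gene.gene_id,
        guide1=g1,
        guide2=g2,
        deletion_interval=GenomicInterval(gene.chrom, lo, hi),
        deletion_size=hi - lo,
        oligos1=cloning_oligos(g1),
        oligos2=cloning_oligos(g2),
        alternates=alternates,
        provenance=config.as_dict(),
    )


def design_deletion(
    gene: GeneModel,
    assembly: GenomeAssembly,
    all_genes: Sequence[GeneModel],
    variant_sets: Sequence[VariantSet],
    config: RunConfig | None = None,
) -> DeletionDesign:
    """Full per-gene design: regions -> candidates -> screens -> best pair.

    Raises :class:`NoViablePair` naming the failing stage when a region has
    no PASS guide or every pair falls under the minimum cut separation.
    """
    config = config or RunConfig()
    _start, _stop, reports = screen_gene(
        gene, assembly, all_genes, variant_sets, config
    )
    return pair_from_reports(gene, reports, config)


def predicted_deletion(design: DeletionDesign) -> tuple[GenomicInterval, int]:
    """(excised interval, size in bp) under the blunt re-ligation model."""
    return design.deletion_interval, design.deletion_size


def deletion_allele(
    assembly: GenomeAssembly, deletion: GenomicInterval
) -> GenomeAssembly:
    """The re-ligated deletion allele: reference with ``deletion`` excised."""
    seqs = dict(assembly.items())
    seq = seqs[deletion.chrom]
    seqs[deletion.chrom] = seq[: deletion.start] + seq[deletion.end :]
    return GenomeAssembly(seqs)
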