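"""Guide screening: background variants, off-targets, efficiency.

A guide passes only when (i) no SNP/indel from ANY labeled background
genome touches its protospacer or PAM, (ii) the genome holds no predicted
off-target site under the configured mismatch rule, and (iii) its
efficiency score clears the configured floor (0 by default, so efficiency
ranks rather than filters).

The default off-target rule is seed-exact: a site counts when it carries an
NGG or NAG PAM, has zero mismatches in the 12 PAM-proximal protospacer
bases, and at most three mismatches overall.  The enumeration is exhaustive
over both strands of every chromosome -- no heuristic misses.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import MissingWeightError
from .genome_io import GenomeAssembly, GenomicInterval, VariantRecord, VariantSet, revcomp
from .guide_discovery import PROTOSPACER_LEN, GuideCandidate

PASS = "PASS"
FAIL_VARIANT = "FAIL_VARIANT"
FAIL_OFFTARGET = "FAIL_OFFTARGET"
FAIL_EFFICIENCY = "FAIL_EFFICIENCY"

_G = ord("G")
_A = ord("A")
_C = ord("C")
_T = ord("T")


@dataclass(frozen=True)
class OffTargetParams:
    """Knobs of the off-target definition; all four are configurable."""

    max_mm_total: int = 3
    max_mm_seed: int = 0
    pams: tuple[str, ...] = ("NGG", "NAG")

    def __post_init__(self) -> None:
        for pam in self.pams:
            if pam not in ("NGG", "NAG"):
                raise ValueError(f"unsupported PAM class {pam!r}")


@dataclass(frozen=True)
class OffTargetHit:
    chrom: str
    strand: str
    site_interval: GenomicInterval
    pam_type: str
    mm_total: int
    mm_seed: int


@dataclass
class ScreenReport:
    """All screening evidence for one candidate; never short-circuited."""

    candidate: GuideCandidate
    variant_hits: list[tuple[VariantRecord, GenomicInterval]]
    offtargets: list[OffTargetHit]
    efficiency: float
    variant_adjacent: int  # variants near (not on) the footprint; rank input
    verdict: str


# ---------------------------------------------------------------------------
# variant screen


def variant_overlaps(
    candidate: GuideCandidate, variant_sets: Iterable[VariantSet]
) -> list[tuple[VariantRecord, GenomicInterval]]:
    """Every background variant touching the protospacer-plus-PAM footprint.

    A single hit in any labeled set fails the candidate: the guide must
    match the reference and every background genome exactly.
    """
    fp = candidate.footprint()
    hits: list[tuple[VariantRecord, GenomicInterval]] = []
    for vs in variant_sets:
        for rec in vs.overlapping(fp.chrom, fp.start, fp.end):
            iv = rec.affected_interval()
            sub = GenomicInterval(
                fp.chrom, max(fp.start, iv.start), min(fp.end, iv.end)
            )
            hits.append((rec, sub))
    hits.sort(key=lambda h: (h[0].label, h[0].pos0, h[0].ref, h[0].alt))
    return hits


def count_adjacent_variants(
    candidate: GuideCandidate,
    variant_sets: Iterable[VariantSet],
    flank: int = 10,
) -> int:
    """Variants within ``flank`` bp of the footprint but not touching it."""
    fp = candidate.footprint()
    n = 0
    for vs in variant_sets:
        near = vs.overlapping(fp.chrom, max(0, fp.start - flank), fp.end + flank)
        for rec in near:
            iv = rec.affected_interval()
            if iv.end <= fp.start or iv.start >= fp.end:
                n += 1
    return n


# ---------------------------------------------------------------------------
# off-target search


def _pam_masks_plus(
    enc: np.ndarray, n: int, params: OffTargetParams
) -> tuple[np.ndarray, np.ndarray]:
    """(NGG mask, NAG mask) over protospacer start positions, plus strand."""
    b21 = enc[21 : 21 + n]
    b22 = enc[22 : 22 + n]
    ngg = (b21 == _G) & (b22 == _G) if "NGG" in params.pams else np.zeros(n, bool)
    nag = (b21 == _A) & (b22 == _G) if "NAG" in params.pams else np.zeros(n, bool)
    return ngg, nag


def _pam_masks_minus(
    enc: np.ndarray, n: int, params: OffTargetParams
) -> tuple[np.ndarray, np.ndarray]:
    """PAM masks over protospacer start positions s in [3, 3+n), minus strand.

    Genomic CCN at [s-3, s) reads NGG on the guide strand; CTN reads NAG.
    """
    m3 = enc[0:n]  # genomic s-3 for s = 3..3+n-1
    m2 = enc[1 : 1 + n]
    ngg = (m3 == _C) & (m2 == _C) if "NGG" in params.pams else np.zeros(n, bool)
    nag = (m3 == _C) & (m2 == _T) if "NAG" in params.pams else np.zeros(n, bool)
    return ngg, nag


def _mismatch_profiles(
    enc: np.ndarray, offset: int, n: int, proto: str, seed_cols: range
) -> tuple[np.ndarray, np.ndarray]:
    mm_total = np.zeros(n, dtype=np.int16)
    mm_seed = np.zeros(n, dtype=np.int16)
    for j, base in enumerate(proto):
        neq = enc[offset + j : offset + j + n] != ord(base)
        mm_total += neq
        if j in seed_cols:
            mm_seed += neq
    return mm_total, mm_seed


def find_offtargets(
    candidate: GuideCandidate,
    assembly: GenomeAssembly,
    params: OffTargetParams | None = None,
) -> list[OffTargetHit]:
    """Exhaustively enumerate off-target sites for one candidate.

    Scans every position of both strands of every chromosome for an allowed
    PAM whose adjacent 20-mer satisfies the seed and total mismatch bounds,
    excluding the on-target locus itself.
    """
    params = params or OffTargetParams()
    proto = candidate.protospacer
    rc = revcomp(proto)
    hits: list[OffTargetHit] = []
    on_chrom = candidate.chrom
    on_start = candidate.protospacer_interval.start

    for chrom in assembly.names():
        enc = assembly.encoded(chrom)
        L = len(enc)
        if L < PROTOSPACER_LEN + 3:
            continue
        # plus strand: protospacer starts p in [0, L-23]
        n = L - PROTOSPACER_LEN - 2
        ngg, nag = _pam_masks_plus(enc, n, params)
        pam_ok = ngg | nag
        # seed = PAM-proximal 12 bases = protospacer columns 8..19
        mm_total, mm_seed = _mismatch_profiles(enc, 0, n, proto, range(8, 20))
        sel = pam_ok & (mm_seed <= params.max_mm_seed) & (
            mm_total <= params.max_mm_total
        )
        for p in np.nonzero(sel)[0]:
            p = int(p)
            if chrom == on_chrom and candidate.strand == "+" and p == on_start:
                continue
            hits.append(
                OffTargetHit(
                    chrom=chrom,
                    strand="+",
                    site_interval=GenomicInterval(chrom, p, p + PROTOSPACER_LEN),
                    pam_type="NGG" if ngg[p] else "NAG",
                    mm_total=int(mm_total[p]),
                    mm_seed=int(mm_seed[p]),
                )
            )
        # minus strand: protospacer starts s in [3, L-20]; compare to revcomp
        n = L - PROTOSPACER_LEN - 2
        ngg_m, nag_m = _pam_masks_minus(enc, n, params)
        pam_ok = ngg_m | nag_m
        # seed = genomic columns 0..11 of the site (PAM sits 5' in genome)
        mm_total, mm_seed = _mismatch_profiles(enc, 3, n, rc, range(0, 12))
        sel = pam_ok & (mm_seed <= params.max_mm_seed) & (
            mm_total <= params.max_mm_total
        )
        for k in np.nonzero(sel)[0]:
            s = int(k) + 3
            if chrom == on_chrom and candidate.strand == "-" and s == on_start:
                continue
            hits.append(
                OffTargetHit(
                    chrom=chrom,
                    strand="-",
                    site_interval=GenomicInterval(chrom, s, s + PROTOSPACER_LEN),
                    pam_type="NGG" if ngg_m[k] else "NAG",
                    mm_total=int(mm_total[k]),
                    mm_seed=int(mm_seed[k]),
                )
            )
    hits.sort(key=lambda h: (h.chrom, h.site_interval.start, h.strand))
    return hits


# ---------------------------------------------------------------------------
# efficiency scoring

# Shipped default position-weight table.  This is a heuristic ranking prior
# -- a mild composition preference (G-richness favored and T-richness
# penalized, increasingly so toward the PAM, plus a bonus for G at position
# 20) -- intended to order candidates within a ~100-bp window, not to
# predict absolute cutting rates.  Fully replaceable via a TSV table.
_BASE_BIAS = {"A": 0.02, "C": 0.04, "G": 0.06, "T": -0.06}
DEFAULT_WEIGHTS: dict[tuple[int, str], float] = {}
for _pos in range(1, 21):
    _prox = (_pos - 1) / 19.0
    for _base, _bias in _BASE_BIAS.items():
        DEFAULT_WEIGHTS[(_pos, _base)] = _bias * (0.5 + _prox)
DEFAULT_WEIGHTS[(20, "G")] += 0.30
DEFAULT_WEIGHTS[(20, "T")] -= 0.20


def load_weight_table(path: str | Path) -> dict[tuple[int, str], float]:
    """Read a TSV with columns position, A, C, G, T into a weight table."""
    df = pd.read_csv(path, sep="\t")
    table: dict[tuple[int, str], float] = {}
    for _, row in df.iterrows():
        pos = int(row["position"])
        for base in "ACGT":
            table[(pos, base)] = float(row[base])
    return table


def efficiency_score(
    candidate: GuideCandidate | str,
    weight_table: dict[tuple[int, str], float] | None = None,
) -> float:
    """Additive position-weight score, affinely rescaled to [0, 10].

    The rescaling maps the table's minimum achievable sum to 0 and its
    maximum to 10; a degenerate (constant) table scores every guide at the
    midpoint 5.  Missing (position, base) cells are an error.
    """
    table = DEFAULT_WEIGHTS if weight_table is None else weight_table
    proto = candidate if isinstance(candidate, str) else candidate.protospacer
    if len(proto) != PROTOSPACER_LEN:
        raise ValueError(f"protospacer must be {PROTOSPACER_LEN} nt")
    raw = 0.0
    for i, base in enumerate(proto):
        key = (i + 1, base)
        if key not in table:
            raise MissingWeightError(f"weight table missing entry {key}")
        raw += table[key]
    lo = 0.0
    hi = 0.0
    for pos in range(1, PROTOSPACER_LEN + 1):
        col = [table[(pos, b)] for b in "ACGT"]
        lo += min(col)
        hi += max(col)
    if hi == lo:
        return 5.0
    return round(10.0 * (raw - lo) / (hi - lo), 6)


# ---------------------------------------------------------------------------
# composite screen


def screen(
    candidate: GuideCandidate,
    assembly: GenomeAssembly,
    variant_sets: Sequence[VariantSet],
    offtarget_params: OffTargetParams | None = None,
    efficiency_floor: float = 0.0,
    weight_table: dict[tuple[int, str], float] | None = None,
    adjacency_flank: int = 10,
) -> ScreenReport:
    """Compose the three screens into one report (audit-complete).

    All three axes are always evaluated; the verdict records the first
    failing axis in the order variant, off-target, efficiency.
    """
    vhits = variant_overlaps(candidate, variant_sets)
    othits = find_offtargets(candidate, assembly, offtarget_params)
    eff = efficiency_score(candidate, weight_table)
    adjacent = count_adjacent_variants(candidate, variant_sets, adjacency_flank)
    if vhits:
        verdict = FAIL_VARIANT
    elif othits:
        verdict = FAIL_OFFTARGET
    elif eff < efficiency_floor:
        verdict = FAIL_EFFICIENCY
    else:
        verdict = PASS
    return ScreenReport(
        candidate=candidate,
        variant_hits=vhits,
        offtargets=othits,
        efficiency=eff,
        variant_adjacent=adjacent,
        verdict=verdict,
    )
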