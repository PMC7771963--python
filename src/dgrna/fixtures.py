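"""Deterministic synthetic genomes with recorded ground truth.

Every other module is testable without downloads: a bundle holds a random
genome, well-formed gene models (explicit start/stop codons and GT..AG
splice dinucleotides), two labeled background-variant sets emulating a
cell-line and an injection-stock genome, planted hazards, and a truth
record computed at generation time by naive oracles that are independent
of the production scanning/screening code.

Difficulty classes and the hazard each plants:

- CLEAN          no hazards; the designer must recover the naive optimum
- NESTED_ORF     a foreign CDS overlaps the host's first coding exon, so
                 the START window must shift to a downstream exon
- MULTI_ISOFORM  several transcripts with distinct start codons; anchors
                 must come from the most-5' start / most-3' stop
- SNP_DENSE      background SNP/indel load (default 0.004/bp, the scale of
                 a strain differing from reference by ~600k SNPs over a
                 ~140-Mb genome)
- OFFTARGET_TRAP near-duplicates of the best guides (seed-exact, <=2
                 mismatches elsewhere) planted in intergenic sequence
- SINGLE_EXON    a 150-bp single-exon ORF, too short for the default
                 minimum cut separation (documented NoViablePair)
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import FixtureError
from .genome_io import (
    GeneModel,
    GenomeAssembly,
    GenomicInterval,
    Transcript,
    VariantRecord,
    VariantSet,
    classify_variant,
    revcomp,
    write_fasta,
)
from .screening import DEFAULT_WEIGHTS

CHROM = "chr_sim"
DIFFICULTIES = (
    "CLEAN",
    "NESTED_ORF",
    "MULTI_ISOFORM",
    "SNP_DENSE",
    "OFFTARGET_TRAP",
    "SINGLE_EXON",
)

_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


@dataclass
class FixtureParams:
    """Documented parameter ranges: genome 10-200 kb, SNP density 0-0.01/bp."""

    genome_length: int = 12000
    gc: float = 0.43
    snp_density: float | None = None  # None -> per-difficulty default
    indel_fraction: float = 0.1
    window: int = 100
    min_window: int = 30
    min_separation: int = 200
    labels: tuple[str, str] = ("S2R+", "attP40")
    n_traps: int = 1  # per region (OFFTARGET_TRAP)
    force_snps_in_start_pams: bool = False

    def validate(self) -> None:
        if not 10_000 <= self.genome_length <= 200_000:
            raise FixtureError(
                f"genome_length {self.genome_length} outside 10-200 kb"
            )
        if self.snp_density is not None and not 0 <= self.snp_density <= 0.01:
            raise FixtureError("snp_density outside 0-0.01/bp")
        if len(self.labels) < 2:
            raise FixtureError("need >=2 background labels")


@dataclass
class FixtureBundle:
    seed: int
    difficulty: str
    params: FixtureParams
    assembly: GenomeAssembly
    genes: list[GeneModel]
    variant_sets: list[VariantSet]
    primer_rows: list[dict]  # name, forward, reverse, tier
    truth: dict

    @property
    def target_gene(self) -> GeneModel:
        return next(g for g in self.genes if g.gene_id == self.truth["gene"])

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        paths["genome"] = outdir / "genome.fa"
        write_fasta(self.assembly, paths["genome"])

        paths["annotation"] = outdir / "genes.gff3"
        _write_gff3(self.genes, paths["annotation"])

        for vs in self.variant_sets:
            key = f"variants:{vs.label}"
            paths[key] = outdir / f"variants_{vs.label}.vcf"
            _write_vcf(vs, self.assembly, paths[key])

        paths["primers"] = outdir / "primers.tsv"
        with open(paths["primers"], "w") as fh:
            fh.write("name\tforward\treverse\ttier\n")
            for row in self.primer_rows:
                fh.write(
                    f"{row['name']}\t{row['forward']}\t{row['reverse']}\t"
                    f"{row['tier']}\n"
                )

        paths["guides"] = outdir / "guides.tsv"
        with open(paths["guides"], "w") as fh:
            fh.write("gene\ttarget\n")
            design = self.truth.get("design")
            if design:
                fh.write(f"{self.truth['gene']}\t{design['guide1']}\n")
                fh.write(f"{self.truth['gene']}\t{design['guide2']}\n")

        paths["truth"] = outdir / "truth.json"
        with open(paths["truth"], "w") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return paths


# ---------------------------------------------------------------------------
# sequence building blocks


def random_sequence(rng: np.random.Generator, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def _random_orf(rng: np.random.Generator, length: int) -> str:
    """ATG + sense codons + TAA, exactly ``length`` (multiple of 3) bases."""
    assert length % 3 == 0 and length >= 9
    n_codons = (length - 6) // 3
    idx = rng.integers(0, len(_SENSE_CODONS), size=n_codons)
    return "ATG" + "".join(_SENSE_CODONS[i] for i in idx) + "TAA"


class _SeqEditor:
    """Mutable genome under construction."""

    def __init__(self, seq: str):
        self.chars = list(seq)

    def paste(self, pos: int, piece: str) -> None:
        if pos < 0 or pos + len(piece) > len(self.chars):
            raise FixtureError("paste outside genome bounds")
        self.chars[pos : pos + len(piece)] = piece

    def text(self) -> str:
        return "".join(self.chars)


def _build_spliced_gene(
    editor: _SeqEditor,
    rng: np.random.Generator,
    gene_id: str,
    gene_start: int,
    strand: str,
    exon_lens: list[int],
    intron_lens: list[int],
    alt_start_offsets: Sequence[int] = (),
) -> GeneModel:
    """Paste a well-formed gene and return its model.

    ``alt_start_offsets`` are CDS-space offsets (multiples of 3) where
    additional in-frame ATG codons are planted; each defines an extra
    transcript starting there and sharing the stop codon.
    """
    cds_len = sum(exon_lens)
    assert cds_len % 3 == 0
    cds_seq = list(_random_orf(rng, cds_len))
    for off in alt_start_offsets:
        assert off % 3 == 0 and 0 < off < cds_len - 3
        cds_seq[off : off + 3] = "ATG"
    cds_seq = "".join(cds_seq)

    # interleave exons and GT..AG introns in transcript orientation
    pieces: list[str] = []
    exon_tx_offsets: list[tuple[int, int]] = []  # CDS-space [a, b) per exon
    pos = 0
    for i, elen in enumerate(exon_lens):
        pieces.append(cds_seq[pos : pos + elen])
        exon_tx_offsets.append((pos, pos + elen))
        pos += elen
        if i < len(intron_lens):
            ilen = intron_lens[i]
            assert ilen >= 8
            pieces.append("GT" + random_sequence(rng, ilen - 4, 0.4) + "AG")
    gene_seq = "".join(pieces)
    total = len(gene_seq)
    editor.paste(gene_start, gene_seq if strand == "+" else revcomp(gene_seq))

    # genomic offsets of each exon within the pasted block, tx orientation
    gblock: list[tuple[int, int]] = []
    off = 0
    for i, elen in enumerate(exon_lens):
        gblock.append((off, off + elen))
        off += elen + (intron_lens[i] if i < len(intron_lens) else 0)

    def tx_block_to_genomic(a: int, b: int) -> GenomicInterval:
        # [a, b) are offsets in the gene block, tx orientation
        if strand == "+":
            return GenomicInterval(CHROM, gene_start + a, gene_start + b, strand)
        return GenomicInterval(
            CHROM, gene_start + total - b, gene_start + total - a, strand
        )

    def cds_offset_to_block(off_cds: int) -> int:
        for (a, b), (ga, _gb) in zip(exon_tx_offsets, gblock):
            if a <= off_cds < b:
                return ga + (off_cds - a)
        raise AssertionError(off_cds)

    def chain_from(start_cds: int) -> tuple[GenomicInterval, ...]:
        segs: list[GenomicInterval] = []
        for (a, b), (ga, gb) in zip(exon_tx_offsets, gblock):
            if b <= start_cds:
                continue
            lo = max(a, start_cds)
            block_lo = ga + (lo - a)
            block_hi = gb
            segs.append(tx_block_to_genomic(block_lo, block_hi))
        segs.sort(key=lambda iv: iv.start)
        return tuple(segs)

    transcripts = [Transcript(f"{gene_id}.t1", chain_from(0))]
    for k, off_cds in enumerate(alt_start_offsets, start=2):
        transcripts.append(Transcript(f"{gene_id}.t{k}", chain_from(off_cds)))
    return GeneModel(
        gene_id=gene_id,
        chrom=CHROM,
        strand=strand,
        transcripts=tuple(transcripts),
        source_lines=(),
    )


# ---------------------------------------------------------------------------
# naive oracles (generation-time truth; deliberately simple code paths)


def _naive_anchors(gene: GeneModel) -> tuple[int, int]:
    firsts = []
    lasts = []
    for t in gene.transcripts:
        positions = [p for seg in t.cds for p in (seg.start, seg.end - 1)]
        if gene.strand == "+":
            firsts.append(min(positions))
            lasts.append(max(positions))
        else:
            firsts.append(max(positions))
            lasts.append(min(positions))
    if gene.strand == "+":
        return min(firsts), max(lasts)
    return max(firsts), min(lasts)


def _naive_anchor_transcript(gene: GeneModel, role: str) -> Transcript:
    start_a, stop_a = _naive_anchors(gene)
    want = start_a if role == "START" else stop_a
    hits = []
    for t in gene.transcripts:
        edges = [p for seg in t.cds for p in (seg.start, seg.end - 1)]
        edge = (
            (min(edges) if gene.strand == "+" else max(edges))
            if role == "START"
            else (max(edges) if gene.strand == "+" else min(edges))
        )
        if edge == want:
            hits.append(t)
    hits.sort(key=lambda t: -sum(s.length() for s in t.cds))
    return hits[0]


def _overlaps_foreign(
    w_start: int, w_end: int, foreign: list[tuple[int, int]]
) -> bool:
    return any(w_start < fe and fs < w_end for fs, fe in foreign)


def _naive_windows(
    exons_tx: list[GenomicInterval],
    strand: str,
    role: str,
    anchor: int,
    window: int,
    min_window: int,
) -> list[tuple[int, int]]:
    """All candidate windows (genomic start, end) in priority order."""
    out: list[tuple[int, int]] = []
    if role == "START":
        for i, ex in enumerate(exons_tx):
            if ex.length() < min_window:
                continue
            if strand == "+":
                lo0 = anchor if i == 0 else ex.start
                for a in range(lo0, ex.end - min_window + 1):
                    out.append((a, min(a + window, ex.end)))
            else:
                hi0 = anchor + 1 if i == 0 else ex.end
                for b in range(hi0, ex.start + min_window - 1, -1):
                    out.append((max(b - window, ex.start), b))
    else:
        for i in range(len(exons_tx) - 1, -1, -1):
            ex = exons_tx[i]
            if ex.length() < min_window:
                continue
            last = i == len(exons_tx) - 1
            if strand == "+":
                hi0 = anchor + 1 if last else ex.end
                for b in range(hi0, ex.start + min_window - 1, -1):
                    out.append((max(b - window, ex.start), b))
            else:
                lo0 = anchor if last else ex.start
                for a in range(lo0, ex.end - min_window + 1):
                    out.append((a, min(a + window, ex.end)))
    return out


def _naive_regions(
    gene: GeneModel,
    all_genes: Iterable[GeneModel],
    window: int,
    min_window: int,
) -> dict | None:
    foreign = [
        (seg.start, seg.end)
        for g in all_genes
        if g.gene_id != gene.gene_id
        for seg in g.cds_intervals()
    ]
    start_a, stop_a = _naive_anchors(gene)
    result: dict = {}
    for role, anchor in (("START", start_a), ("STOP", stop_a)):
        t = _naive_anchor_transcript(gene, role)
        exons_tx = list(t.cds) if gene.strand == "+" else list(reversed(t.cds))
        wins = _naive_windows(exons_tx, gene.strand, role, anchor, window, min_window)
        chosen = None
        for j, (a, b) in enumerate(wins):
            if not _overlaps_foreign(a, b, foreign):
                chosen = (a, b, j > 0)
                break
        if chosen is None:
            return None
        result[role] = {
            "start": chosen[0],
            "end": chosen[1],
            "anchor": anchor,
            "shifted": chosen[2],
        }
    return result


def _naive_scan(seq: str, lo: int, hi: int, chrom_len: int) -> list[dict]:
    """Protospacer candidates in [lo, hi): plain character-loop scan."""
    out = []
    for p in range(lo, hi - 19):
        if p + 23 <= min(chrom_len, hi + 3) and seq[p + 21 : p + 23] == "GG":
            out.append(
                {
                    "strand": "+",
                    "start": p,
                    "protospacer": seq[p : p + 20],
                    "pam_lo": p + 20,
                    "cut0": p + 17,
                }
            )
        if p - 3 >= max(0, lo - 3) and seq[p - 3 : p - 1] == "CC":
            out.append(
                {
                    "strand": "-",
                    "start": p,
                    "protospacer": revcomp(seq[p : p + 20]),
                    "pam_lo": p - 3,
                    "cut0": p + 3,
                }
            )
    out.sort(key=lambda c: (c["cut0"], c["strand"]))
    return out


def _naive_pam_index(seq: str) -> tuple[dict, dict]:
    """Seed-keyed index of every NGG/NAG-adjacent 20-mer site, both strands."""
    plus: dict[str, list[tuple[int, int, str]]] = {}
    minus: dict[str, list[tuple[int, int, str]]] = {}
    L = len(seq)
    for q in range(L - 1):
        two = seq[q : q + 2]
        if two in ("GG", "AG") and q >= 21:
            p = q - 21
            plus.setdefault(seq[p + 8 : p + 20], []).append(
                (p, p + 20, "NGG" if two == "GG" else "NAG")
            )
        if two in ("CC", "CT") and q + 2 + 21 <= L:
            s = q + 3
            minus.setdefault(seq[s : s + 12], []).append(
                (s, s + 20, "NGG" if two == "CC" else "NAG")
            )
    return plus, minus


def _naive_offtarget_count(
    seq: str,
    cand: dict,
    index: tuple[dict, dict],
    max_mm_total: int = 3,
) -> int:
    """Seed-exact off-target count (max_mm_seed = 0 rule)."""
    proto = cand["protospacer"]
    rc = revcomp(proto)
    plus, minus = index
    n = 0
    for p, _pe, _pt in plus.get(proto[8:20], []):
        if cand["strand"] == "+" and p == cand["start"]:
            continue
        site = seq[p : p + 20]
        mm = sum(1 for x, y in zip(site, proto) if x != y)
        if mm <= max_mm_total:
            n += 1
    for s, _se, _pt in minus.get(rc[:12], []):
        if cand["strand"] == "-" and s == cand["start"]:
            continue
        site = seq[s : s + 20]
        mm = sum(1 for x, y in zip(site, rc) if x != y)
        if mm <= max_mm_total:
            n += 1
    return n


def _naive_efficiency(proto: str) -> float:
    raw = 0.0
    for i, base in enumerate(proto):
        raw += DEFAULT_WEIGHTS[(i + 1, base)]
    lo = sum(min(DEFAULT_WEIGHTS[(p, b)] for b in "ACGT") for p in range(1, 21))
    hi = sum(max(DEFAULT_WEIGHTS[(p, b)] for b in "ACGT") for p in range(1, 21))
    return round(10.0 * (raw - lo) / (hi - lo), 6)


def _naive_variant_hits(cand: dict, records: list[VariantRecord]) -> int:
    fp_lo = min(cand["start"], cand["pam_lo"])
    fp_hi = max(cand["start"] + 20, cand["pam_lo"] + 3)
    n = 0
    for rec in records:
        lo = rec.pos0
        hi = rec.pos0 + max(1, len(rec.ref))
        if lo < fp_hi and fp_lo < hi:
            n += 1
    return n


def _naive_adjacent(cand: dict, records: list[VariantRecord], flank: int = 10) -> int:
    fp_lo = min(cand["start"], cand["pam_lo"])
    fp_hi = max(cand["start"] + 20, cand["pam_lo"] + 3)
    n = 0
    for rec in records:
        lo = rec.pos0
        hi = rec.pos0 + max(1, len(rec.ref))
        inside = lo < fp_hi and fp_lo < hi
        near = lo < fp_hi + flank and fp_lo - flank < hi
        if near and not inside:
            n += 1
    return n


def _naive_screen_region(
    seq: str,
    region: dict,
    records: list[VariantRecord],
    index: tuple[dict, dict],
) -> list[dict]:
    """PASS candidates in a region, annotated with efficiency and adjacency."""
    out = []
    for cand in _naive_scan(seq, region["start"], region["end"], len(seq)):
        if _naive_variant_hits(cand, records):
            continue
        if _naive_offtarget_count(seq, cand, index):
            continue
        cand = dict(cand)
        cand["efficiency"] = _naive_efficiency(cand["protospacer"])
        cand["adjacent"] = _naive_adjacent(cand, records)
        out.append(cand)
    return out


def _naive_best_pair(
    starts: list[dict], stops: list[dict], min_separation: int
) -> tuple[dict, dict] | None:
    best = None
    best_key = None
    for c1 in starts:
        for c2 in stops:
            if abs(c2["cut0"] - c1["cut0"]) < min_separation:
                continue
            key = (
                -(c1["efficiency"] + c2["efficiency"]),
                c1["adjacent"] + c2["adjacent"],
                min(c1["cut0"], c2["cut0"]),
                max(c1["cut0"], c2["cut0"]),
                c1["strand"],
                c2["strand"],
            )
            if best_key is None or key < best_key:
                best_key = key
                best = (c1, c2)
    return best


# ---------------------------------------------------------------------------
# bundle generation


def _plant_variants(
    rng: np.random.Generator,
    seq: str,
    label: str,
    density: float,
    indel_fraction: float,
    n_far: int = 3,
) -> list[VariantRecord]:
    L = len(seq)
    records: list[VariantRecord] = []
    if density > 0:
        n = int(rng.binomial(L - 10, density))
        positions = sorted(rng.choice(L - 10, size=min(n, L - 10), replace=False))
    else:
        lo = int(L * 0.9)
        positions = sorted(rng.choice(L - 10 - lo, size=n_far, replace=False) + lo)
    used_until = -1
    for pos in positions:
        pos = int(pos)
        if pos <= used_until:
            continue
        ref1 = seq[pos]
        kind = rng.random()
        if density > 0 and kind < indel_fraction / 2:
            d = int(rng.integers(1, 4))
            ref = seq[pos : pos + 1 + d]
            records.append(
                VariantRecord(CHROM, pos, ref, ref1, "DEL", label)
            )
            used_until = pos + d
        elif density > 0 and kind < indel_fraction:
            ins = random_sequence(rng, int(rng.integers(1, 4)), 0.5)
            records.append(
                VariantRecord(CHROM, pos, ref1, ref1 + ins, "INS", label)
            )
            used_until = pos
        else:
            alt = "ACGT"[int(rng.integers(0, 4))]
            while alt == ref1:
                alt = "ACGT"[int(rng.integers(0, 4))]
            records.append(VariantRecord(CHROM, pos, ref1, alt, "SNP", label))
            used_until = pos
    return records


def _plant_trap(
    editor: _SeqEditor, rng: np.random.Generator, cand: dict, pos: int
) -> None:
    """Plant a seed-exact near-duplicate of a guide at an intergenic spot."""
    site = list(cand["protospacer"])
    n_mut = int(rng.integers(0, 3))
    for j in rng.choice(8, size=n_mut, replace=False):
        j = int(j)
        alt = "ACGT"[int(rng.integers(0, 4))]
        while alt == site[j]:
            alt = "ACGT"[int(rng.integers(0, 4))]
        site[j] = alt
    pam = "TGG" if rng.random() < 0.7 else "TAG"
    editor.paste(pos, "".join(site) + pam)


def _find_unique_primer(
    seq: str, allele: str, pos: int, length: int, rng: np.random.Generator
) -> str | None:
    """A primer at ~pos that maps exactly once on both templates."""
    for attempt in range(12):
        p = pos + attempt * 3
        if p < 0 or p + length > len(seq):
            return None
        primer = seq[p : p + length]
        if "N" in primer:
            continue
        rc = revcomp(primer)
        occ = seq.count(primer) + seq.count(rc)
        occ_allele = allele.count(primer) + allele.count(rc)
        if occ == 1 and occ_allele == 1:
            return primer
    return None


def make_bundle(
    seed: int,
    difficulty: str = "CLEAN",
    params: FixtureParams | None = None,
) -> FixtureBundle:
    """Generate one synthetic bundle; identical seeds give identical bundles."""
    if difficulty not in DIFFICULTIES:
        raise FixtureError(f"unknown difficulty {difficulty!r}")
    params = params or FixtureParams()
    params.validate()
    rng = np.random.default_rng(seed)
    L = params.genome_length
    editor = _SeqEditor(random_sequence(rng, L, params.gc))

    gene_start = int(L * 0.25)
    strand = "+" if rng.random() < 0.5 else "-"
    genes: list[GeneModel] = []

    def jitter(base: int, spread: int) -> int:
        return base + 3 * int(rng.integers(0, spread // 3 + 1))

    if difficulty == "SINGLE_EXON":
        exon_lens = [150]
        intron_lens: list[int] = []
        alt_offsets: Sequence[int] = ()
    elif difficulty == "MULTI_ISOFORM":
        exon_lens = [jitter(180, 30), jitter(210, 30), jitter(150, 30)]
        intron_lens = [jitter(150, 60), jitter(120, 60)]
        alt_offsets = (30, exon_lens[0] + 30, exon_lens[0] + 60)
    else:
        exon_lens = [jitter(150, 30), jitter(210, 30), jitter(150, 30)]
        intron_lens = [jitter(180, 60), jitter(120, 60)]
        alt_offsets = ()
    for i, elen in enumerate(exon_lens):  # keep total CDS a codon multiple
        assert elen % 3 == 0, exon_lens
    host_span = sum(exon_lens) + sum(intron_lens)
    if gene_start + host_span > int(L * 0.5):
        raise FixtureError("host gene does not fit the genome")

    host = _build_spliced_gene(
        editor, rng, "hostA", gene_start, strand, exon_lens, intron_lens,
        alt_offsets,
    )
    genes.append(host)

    if difficulty == "NESTED_ORF":
        first_exon = (
            host.transcripts[0].cds[0]
            if strand == "+"
            else host.transcripts[0].cds[-1]
        )
        fs = first_exon.start - 21
        fe = first_exon.end + 21
        flen = fe - fs
        fe -= flen % 3
        # single-exon foreign ORF on the minus strand: genomic CAT...TTA
        editor.paste(fe - 3, "CAT")
        editor.paste(fs, "TTA")
        genes.append(
            GeneModel(
                gene_id="nestedB",
                chrom=CHROM,
                strand="-",
                transcripts=(
                    Transcript(
                        "nestedB.t1",
                        (GenomicInterval(CHROM, fs, fe, "-"),),
                    ),
                ),
            )
        )

    # distant bystander gene (single exon, well away from the host)
    by_start = int(L * 0.75)
    genes.append(
        _build_spliced_gene(editor, rng, "bystanderC", by_start, "+", [120], [])
    )

    # hazard: near-duplicate guide sites planted in intergenic sequence
    if difficulty == "OFFTARGET_TRAP":
        regions_pre = _naive_regions(host, genes, params.window, params.min_window)
        if regions_pre is not None:
            seq_pre = editor.text()
            trap_pos = int(L * 0.55)
            for role in ("START", "STOP"):
                cands = _naive_scan(
                    seq_pre,
                    regions_pre[role]["start"],
                    regions_pre[role]["end"],
                    L,
                )
                cands.sort(key=lambda c: -_naive_efficiency(c["protospacer"]))
                for cand in cands[: params.n_traps]:
                    _plant_trap(editor, rng, cand, trap_pos)
                    trap_pos += 40

    seq = editor.text()
    assembly = GenomeAssembly({CHROM: seq})

    # background variants (VCF records against the reference assembly)
    density = params.snp_density
    if density is None:
        density = 0.004 if difficulty == "SNP_DENSE" else 0.0
    variant_sets = [
        VariantSet(
            label,
            _plant_variants(rng, seq, label, density, params.indel_fraction),
        )
        for label in params.labels
    ]

    # truth: naive region selection
    regions = _naive_regions(host, genes, params.window, params.min_window)
    truth: dict = {
        "seed": seed,
        "difficulty": difficulty,
        "gene": host.gene_id,
        "chrom": CHROM,
        "genome_length": L,
        "strand": strand,
    }
    if regions is None:
        truth["no_clean_region"] = True
        truth["regions"] = None
        truth["design"] = None
        return FixtureBundle(
            seed, difficulty, params, assembly, genes, variant_sets, [], truth
        )
    truth["no_clean_region"] = False

    if params.force_snps_in_start_pams:
        forced = []
        for cand in _naive_scan(
            seq, regions["START"]["start"], regions["START"]["end"], L
        ):
            pos = cand["pam_lo"] + 1  # middle PAM base (a G or C)
            ref1 = seq[pos]
            alt = "ACGT"[int(rng.integers(0, 4))]
            while alt == ref1:
                alt = "ACGT"[int(rng.integers(0, 4))]
            forced.append(VariantRecord(CHROM, pos, ref1, alt, "SNP", params.labels[1]))
        merged = list(variant_sets[1].records) + forced
        variant_sets[1] = VariantSet(params.labels[1], merged)

    all_records = [r for vs in variant_sets for r in vs.records]
    index = _naive_pam_index(seq)
    pass_start = _naive_screen_region(seq, regions["START"], all_records, index)
    pass_stop = _naive_screen_region(seq, regions["STOP"], all_records, index)
    truth["regions"] = regions
    truth["pass_guides"] = {
        "START": [c["protospacer"] for c in pass_start],
        "STOP": [c["protospacer"] for c in pass_stop],
    }

    pair = _naive_best_pair(pass_start, pass_stop, params.min_separation)
    primer_rows: list[dict] = []
    if pair is None:
        truth["design"] = None
        truth["no_viable_pair"] = True
    else:
        c1, c2 = pair
        d_lo, d_hi = sorted((c1["cut0"], c2["cut0"]))
        truth["no_viable_pair"] = False
        truth["design"] = {
            "guide1": c1["protospacer"],
            "guide1_strand": c1["strand"],
            "guide2": c2["protospacer"],
            "guide2_strand": c2["strand"],
            "cut1": c1["cut0"],
            "cut2": c2["cut0"],
            "deletion_start": d_lo,
            "deletion_end": d_hi,
            "deletion_size": d_hi - d_lo,
        }
        allele = seq[:d_lo] + seq[d_hi:]
        primers, sizes = _plant_primers(rng, seq, allele, d_lo, d_hi)
        primer_rows = primers
        truth["amplicons"] = sizes
    return FixtureBundle(
        seed, difficulty, params, assembly, genes, variant_sets, primer_rows, truth
    )


def _plant_primers(
    rng: np.random.Generator, seq: str, allele: str, d_lo: int, d_hi: int
) -> tuple[list[dict], dict]:
    """Concentric OUTER/INNER primer pairs flanking the deletion."""
    rows: list[dict] = []
    sizes: dict = {}
    specs = [("OUTER", 130 + int(rng.integers(0, 60))), ("INNER", 35 + int(rng.integers(0, 20)))]
    for tier, gap in specs:
        f_pos = d_lo - gap - 20
        r_pos = d_hi + gap
        fwd = _find_unique_primer(seq, allele, f_pos, 20, rng)
        rev_plus = _find_unique_primer(seq, allele, r_pos, 20, rng)
        if fwd is None or rev_plus is None:
            continue
        f_start = seq.find(fwd)
        r_start = seq.find(rev_plus)
        wt = (r_start + 20 - 1) - f_start + 1
        dl = wt - (d_hi - d_lo)
        rows.append(
            {
                "name": f"diag_{tier.lower()}",
                "forward": fwd,
                "reverse": revcomp(rev_plus),
                "tier": tier,
            }
        )
        sizes[tier] = {"wt_size": wt, "del_size": dl}
    return rows, sizes


# ---------------------------------------------------------------------------
# assembly mutation utility


@dataclass(frozen=True)
class Edit:
    """A substitution/insertion/deletion expressed as REF -> ALT at pos0."""

    chrom: str
    pos0: int
    ref: str
    alt: str


def mutate_assembly(
    assembly: GenomeAssembly, edits: Sequence[Edit], label: str = "edited"
) -> tuple[GenomeAssembly, list[VariantRecord]]:
    """Apply edits to an assembly; returns the new assembly and the implied
    variant records.  Overlapping edits are an error."""
    by_chrom: dict[str, list[Edit]] = {}
    records: list[VariantRecord] = []
    for e in edits:
        if e.chrom not in assembly:
            raise FixtureError(f"edit on unknown chromosome {e.chrom!r}")
        seq = assembly[e.chrom]
        if seq[e.pos0 : e.pos0 + len(e.ref)] != e.ref:
            raise FixtureError(
                f"edit REF mismatch at {e.chrom}:{e.pos0}: expected {e.ref!r}"
            )
        by_chrom.setdefault(e.chrom, []).append(e)
        records.append(
            VariantRecord(
                e.chrom, e.pos0, e.ref, e.alt, classify_variant(e.ref, e.alt), label
            )
        )
    seqs = dict(assembly.items())
    for chrom, chrom_edits in by_chrom.items():
        chrom_edits.sort(key=lambda e: e.pos0)
        prev_end = -1
        for e in chrom_edits:
            span = max(1, len(e.ref))
            if e.pos0 < prev_end:
                raise FixtureError(f"overlapping edits on {chrom} at {e.pos0}")
            prev_end = e.pos0 + span
        seq = seqs[chrom]
        for e in reversed(chrom_edits):
            seq = seq[: e.pos0] + e.alt + seq[e.pos0 + len(e.ref) :]
        seqs[chrom] = seq
    return GenomeAssembly(seqs), records


def apply_variants(
    assembly: GenomeAssembly, records: Sequence[VariantRecord]
) -> GenomeAssembly:
    """Reconstruct a background genome from the reference plus its records."""
    edits = [Edit(r.chrom, r.pos0, r.ref, r.alt) for r in records]
    new, _ = mutate_assembly(assembly, edits)
    return new


# ---------------------------------------------------------------------------
# amplicon micro-fixtures (for PCR-prediction validation)


@dataclass
class AmpliconCase:
    assembly: GenomeAssembly
    deletion: GenomicInterval
    forward: str
    reverse: str
    wt_size: int
    del_size: int
    junction_sequence: str  # expected deletion-allele amplicon


def make_amplicon_case(rng: np.random.Generator, genome_length: int = 3000) -> AmpliconCase:
    """Random genome + deletion + unique flanking primer pair + truth sizes."""
    for _ in range(50):
        seq = random_sequence(rng, genome_length, 0.45)
        d_lo = int(rng.integers(800, 1200))
        d_hi = d_lo + int(rng.integers(200, 1200))
        gap_f = int(rng.integers(30, 200))
        gap_r = int(rng.integers(30, 200))
        allele = seq[:d_lo] + seq[d_hi:]
        fwd = _find_unique_primer(seq, allele, d_lo - gap_f - 20, 20, rng)
        rev_plus = _find_unique_primer(seq, allele, d_hi + gap_r, 20, rng)
        if fwd is None or rev_plus is None:
            continue
        f_start = seq.find(fwd)
        r_start = seq.find(rev_plus)
        wt = r_start + 20 - f_start
        dl = wt - (d_hi - d_lo)
        a_start = allele.find(fwd)
        junction = allele[a_start : allele.find(rev_plus) + 20]
        return AmpliconCase(
            assembly=GenomeAssembly({CHROM: seq}),
            deletion=GenomicInterval(CHROM, d_lo, d_hi),
            forward=fwd,
            reverse=revcomp(rev_plus),
            wt_size=wt,
            del_size=dl,
            junction_sequence=junction,
        )
    raise FixtureError("could not place unique primers")


# ---------------------------------------------------------------------------
# file writers


def _write_gff3(genes: Sequence[GeneModel], path: Path) -> None:
    lines = ["##gff-version 3"]
    for gene in genes:
        span = gene.span()
        lines.append(
            "\t".join(
                [
                    gene.chrom,
                    "dgrna_fixture",
                    "gene",
                    str(span.start + 1),
                    str(span.end),
                    ".",
                    gene.strand,
                    ".",
                    f"ID={gene.gene_id}",
                ]
            )
        )
        for t in gene.transcripts:
            t_lo = min(seg.start for seg in t.cds)
            t_hi = max(seg.end for seg in t.cds)
            lines.append(
                "\t".join(
                    [
                        gene.chrom,
                        "dgrna_fixture",
                        "mRNA",
                        str(t_lo + 1),
                        str(t_hi),
                        ".",
                        gene.strand,
                        ".",
                        f"ID={t.transcript_id};Parent={gene.gene_id}",
                    ]
                )
            )
            # phase: bases of the next codon already used when the segment starts
            segs_tx = list(t.cds) if gene.strand == "+" else list(reversed(t.cds))
            cum = 0
            phases = []
            for seg in segs_tx:
                phases.append((3 - cum % 3) % 3)
                cum += seg.length()
            phase_of = dict(zip(segs_tx, phases))
            for k, seg in enumerate(t.cds):
                lines.append(
                    "\t".join(
                        [
                            gene.chrom,
                            "dgrna_fixture",
                            "CDS",
                            str(seg.start + 1),
                            str(seg.end),
                            ".",
                            gene.strand,
                            str(phase_of[seg]),
                            f"ID={t.transcript_id}.cds{k};Parent={t.transcript_id}",
                        ]
                    )
                )
    path.write_text("\n".join(lines) + "\n")


def _write_vcf(vs: VariantSet, assembly: GenomeAssembly, path: Path) -> None:
    lines = ["##fileformat=VCFv4.2"]
    for name, seq in assembly.items():
        lines.append(f"##contig=<ID={name},length={len(seq)}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for rec in vs.records:
        lines.append(
            f"{rec.chrom}\t{rec.pos0 + 1}\t.\t{rec.ref}\t{rec.alt}\t.\tPASS\t."
        )
    path.write_text("\n".join(lines) + "\n")
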