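# Methods

## Problem and model

The package designs a two-cut deletion of a gene's open reading frame.
SpCas9 guided by a 20-nt spacer cleaves double-stranded DNA bluntly
between protospacer positions 17 and 18, i.e. 3 bp 5′ of the NGG PAM. Two
guides — one near the most-5′ start codon, one near the most-3′ stop
codon — produce two blunt ends; the repair model used throughout is
perfect blunt re-ligation, so the predicted deletion allele is the
reference chromosome with the inter-cut interval `[min(cut1, cut2),
max(cut1, cut2))` excised. Real junctions often carry small indels; the
blunt model is used only for deletion-size and amplicon-size arithmetic,
where it is the appropriate expectation, and is a stated limitation for
any base-resolution use of the junction sequence.

Coordinates are 0-based half-open everywhere internally. GFF3 (1-based
inclusive) and VCF (1-based POS) are converted on read; all reports emit
both conventions. A cut site `cut0` denotes the bond 5′ of that base:
plus-strand guides cut at `pam_start − 3`, minus-strand guides at
`pam_end + 3`.

## Target-region selection

Anchors are taken over all annotated isoforms: the most-5′ first CDS base
and the most-3′ last CDS base (mirrored on the minus strand). The anchor
transcript is the isoform achieving the anchor; among several, the one
with the longest total CDS (first in file order on ties). Window
anchoring is a design choice the annotation alone cannot fix: the START
window starts at the start codon's first base and extends 3′, the STOP
window ends at the stop codon's last base and extends 5′. This keeps both
cuts inside coding sequence and maximizes the excised ORF fraction.

Windows are confined to single CDS exons of the anchor transcript
(default length 100 bp, clipped to the exon but never below 30 bp; exons
under 30 bp are skipped as offering too few PAMs). A window is *blocked*
if it overlaps any CDS base of a different gene — UTR overlap does not
block, since the criterion is that neighboring coding sequences must not
be disrupted. Blocked windows slide base-by-base toward the ORF interior
(3′ for START, 5′ for STOP), continuing into later/earlier exons, and the
first clean window wins; the emitted region records a `shifted` flag and
the blocking gene ids. This reproduces the situation of a host gene with
ORFs nested in its first introns, where the START guide must move to a
downstream exon. If no window of at least the minimum length is clean,
the gene fails with `NoCleanRegion` naming the blockers.

## Guide discovery and cloning oligos

All 20-nt protospacers immediately 5′ of an NGG on either strand of a
region are enumerated; the protospacer must lie fully inside the region,
the PAM may extend up to 3 nt past its edge (configurable). Candidates
containing N are discarded — designs come from fully resolved sequence.
NAG sites are never on-targets; they are admitted only in the off-target
search. The emitted cloning oligos follow the G(N19) vector-amplification
scheme: the expression vector supplies the leading G, the 40-nt forward
oligo is `G` + the 19 PAM-proximal protospacer bases + the constant arm
`GTTTTAGAGCTAGAAATAGC`, and the reverse oligo is the constant
`GAAGTATTGAGGAAAACATA`. Guide tables may therefore carry either 19- or
20-nt targets; the audit subcommand matches 19-mers as N19.

## Screening

**Variants.** A guide is rejected if any SNP/indel record from *any*
labeled background overlaps its 23-bp protospacer∪PAM footprint — a guide
must match every genome it will be used in, since even a single mismatch,
especially in the PAM-proximal core, can abolish cutting. Insertions
occupy one reference base for overlap purposes (conservative: an
insertion anywhere in the footprint breaks targeting). Variants are
compared in reference orientation only; overlap, not sequence identity,
is the criterion.

**Off-targets.** The default rule is seed-exact: a site counts as an
off-target when it has an NGG or NAG PAM, zero mismatches in the 12
PAM-proximal protospacer bases (the seed, where mismatches are most
disruptive), and at most 3 mismatches over the full 20-mer. All four
knobs (both mismatch bounds, the PAM set) are configurable. The search is
an exhaustive enumeration of every position on both strands of every
chromosome, vectorized with numpy (per-position mismatch accumulation
over the 20 protospacer columns); there are no heuristic misses, and the
test suite holds it equal to an independent brute-force oracle. The PAM's
N is a wildcard and PAM bases are never counted as mismatches. Guides
require zero off-target hits to pass.

**Efficiency.** The score is an additive position-weight model over
protospacer positions 1–20, affinely rescaled to [0, 10] (a degenerate
constant table maps to the midpoint 5). The shipped default table is a
heuristic ranking prior — mild G-preference and T-penalty growing toward
the PAM, plus a bonus for G at position 20 — intended to order candidates
within a window, not to predict absolute cutting rates; any table with
the same shape can be supplied as a TSV. The PASS floor defaults to 0 so
efficiency ranks rather than rejects, matching a workflow in which the
most efficient clean guide is simply tried first. Scores are rounded to
6 decimals so ranking tie-breaks cannot hinge on float noise.

## Pairing

PASS guides are ranked by efficiency (descending), then by the number of
background variants within 10 bp of (but not touching) the footprint
(ascending — a hedge against imperfect variant calling near the site),
then by genomic coordinate and strand for determinism. Pairs must
separate the two cuts by at least 200 bp — below the smallest whole-gene
deletion one would practically verify by PCR, while excluding degenerate
overlapping-window pairs; configurable. The chosen pair maximizes summed
efficiency with the same tie-break cascade, and up to 5 runner-up pairs
are emitted so a pair that fails empirically can be swapped without
re-running the design — an in-silico stand-in for iterating guide
combinations at the bench. Single-exon genes shorter than the minimum
separation correctly fail with `NoViablePair`.

## PCR diagnostics

Primers map by exact match only, and each must map to exactly one site on
the template; sizes follow the gel convention (5′ end of the forward
primer to the 5′ end of the reverse primer, inclusive), so
`wt_size − del_size` equals the deletion size whenever both products
amplify. Products are computed on both the reference and the blunt-join
deletion allele; a primer inside the excised interval raises
`PrimerLost`. Detectability uses a 5-kb default ceiling with a WARN tier
to 10 kb: a wild-type product beyond the ceiling explains an absent
wild-type band without treating it as evidence of editing. Whenever the
deletion product is the shorter one, the prediction carries a bias note:
short products are preferentially amplified, so the wild-type band may be
weak or absent even in mosaic tissue. Nested outer/inner pairs are
checked for strict containment of the inner amplicon on both alleles;
violations are reported, not raised. Melting temperature, mismatch
tolerance and primer design are deliberately out of scope — the
diagnostics here are presence/size predictions for gels.

## Synthetic fixtures

The generator emulates the structures the design rules must survive:
multi-exon genes with explicit ATG/stop codons, sense-codon bodies and
GT..AG splice dinucleotides; up to four alternative in-frame start sites
sharing a stop; a foreign single-exon ORF overlapping the host's first
coding exon (forcing the START shift); two labeled background variant
sets (defaults "S2R+" and "attP40", mirroring a two-background
consistency screen); planted seed-exact near-duplicate sites that trip
the off-target rule; and single-exon genes too short to pair. Background
SNP density defaults to 0.004/bp for the SNP-dense class — the scale of a
laboratory strain differing from its reference by several hundred
thousand SNPs over a ~140-Mb genome — and 0 elsewhere, with ~10% of
records as 1–3-bp indels. Random sequence is drawn at GC 0.43 (fly-like).
Genome length defaults to 12 kb (documented range 10–200 kb), chosen so
that thousands of full design runs fit in a routine test session while
leaving realistic intergenic space.

Ground truth is computed at generation time by naive oracles (character
loops, exhaustive window/pair scans, a seed-keyed site index) that share
no code with the production scanner/screener, and is emitted as
`truth.json` beside the FASTA/GFF3/VCF/TSV files. Bundles are
byte-reproducible from their seed.

What passing fixture tests does *not* show about real data: fixture
genomes are i.i.d. random sequence, so they lack repeat families,
paralogs, low-complexity tracts and biased PAM density — the regimes
where real off-target screening discards many more candidates. The
annotation is always well-formed, whereas real gene models include
non-canonical splice sites, CDS phase oddities and pseudo-ORFs. Variant
records are independent and uniformly placed, without linkage blocks or
calling artifacts. The pipeline's guarantees (exhaustive enumeration,
overlap semantics, conservation arithmetic, determinism) transfer; its
*yield* — how many genes get clean pairs — does not.

## Numerical and degenerate-input choices

- Duplicate FASTA headers, non-IUPAC characters, orphan CDS rows,
  mixed-strand transcripts and VCF REF/assembly disagreements are hard
  errors naming the record or line; genes without CDS are dropped with a
  warning.
- Multi-allelic VCF rows split into one record per ALT; symbolic ALTs are
  skipped with a warning.
- Ranking ties break on genomic coordinate then strand, making every
  report byte-reproducible; reports embed the full configuration and
  input SHA-256 checksums and contain no timestamps.
- Exit codes: 0 all genes designed, 2 some genes failed (each with a
  named stage), 1 fatal input error.

## Problem sizes used in validation

The shipped validation runs 50 random 50-kb genomes × 20 candidates × 5
parameter settings for off-target oracle equivalence, 1000 fixture
bundles across all six difficulty classes for planted-design recovery
through the CLI, the exhaustive 23-position × 3-variant-type boundary
test on 20 guides, 500 random deletion/primer fixtures for amplicon
conservation, and a byte-level determinism check of two identical runs.
`scripts/acceptance.py` recomputes the same quantities from scratch (600
bundles, 200 amplicon fixtures) from a single seed.
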