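# dgrna — dual-guide CRISPR whole-ORF deletion design

`dgrna` designs pairs of SpCas9 single-guide RNAs (sgRNAs) that excise an
entire open reading frame: one guide cutting in the first coding exon near
the most-5′ start codon, the other in the exon carrying the most-3′ stop
codon. It is built for screens over many genes — for example a library of
dual-gRNA (dgRNA) constructs targeting the *Drosophila melanogaster*
phosphoinositide-signaling gene set — where every guide must work
identically in several genetic backgrounds (a reference assembly, a
cultured cell line such as S2R⁺, and an isogenized injection stock such as
*attP40*, which can differ from the reference by hundreds of thousands of
SNPs and indels).

## What the pipeline does

For each gene, given a genome FASTA, gene models (GFF3 with
gene/mRNA/CDS), and one or more labeled background variant sets (VCF):

1. **Target regions** (`region_selection`). Two ~100-bp windows per gene:
   the START window begins at the most-5′ start codon (over all isoforms)
   and extends 3′; the STOP window ends at the most-3′ stop codon and
   extends 5′. If a window would disrupt another gene's coding sequence —
   e.g. an ORF nested in the host gene's introns — it slides toward the
   ORF interior, exon by exon, until a clean window is found.
2. **Guide scanning** (`guide_discovery`). Every 20-nt protospacer 5′ of
   an NGG PAM, on either strand, with the blunt cut placed between
   protospacer positions 17 and 18 (3 bp 5′ of the PAM).
3. **Screening** (`screening`). A candidate passes only if
   - no SNP/indel from *any* labeled background touches its
     protospacer∪PAM footprint (23 bp),
   - the genome contains zero predicted off-targets under a seed-exact
     rule: NGG or NAG PAM, 0 mismatches in the 12 PAM-proximal seed
     bases, ≤ 3 mismatches total (all four knobs configurable; the
     enumeration is exhaustive, not heuristic), and
   - its efficiency score clears a configurable floor (default 0, so
     efficiency ranks candidates rather than filtering them).
4. **Pairing** (`deletion_design`). The best PASS guide pair subject to a
   minimum cut separation (default 200 bp), with ranked runner-up pairs
   for retry, the predicted deletion interval under a blunt re-ligation
   model, and cloning oligos per the G(N19) scheme:
   `5'-G(N19)GTTTTAGAGCTAGAAATAGC-3'` plus the constant reverse oligo
   `5'-GAAGTATTGAGGAAAACATA-3'`.
5. **Deletion-diagnostic PCR** (`pcr_diagnostics`). Wild-type and
   deletion-junction amplicon sizes for user-supplied primer pairs
   (including nested outer/inner sets), detectability under a maximum
   amplifiable length, and a small-product bias flag explaining why the
   wild-type band of a large locus is often absent on a gel.

A deterministic synthetic-fixture generator (`fixtures`) builds genomes
with multi-isoform genes, nested ORFs, SNP-dense backgrounds, planted
near-duplicate off-target sites, and concentric diagnostic primers — with
ground truth recorded at generation time by independent naive oracles — so
the whole pipeline is testable without downloading any reference data.

## Worked example

Generate a synthetic bundle and design the deletion for its target gene:

```sh
dgrna fixtures --seed 7 --difficulty CLEAN --out fx
dgrna design \
    --genome fx/genome.fa --annotation fx/genes.gff3 \
    --variants "S2R+=fx/variants_S2R+.vcf" \
    --variants "attP40=fx/variants_attP40.vcf" \
    --gene hostA --out design_out
```

which logs

```
INFO module=dgrna gene=hostA status=OK deletion_size=757 guide1=ACACGCATGCTCAGGCCGGC guide2=GTCGTATGCTACTCGGACGG
```

meaning: guide 1 (START region) and guide 2 (STOP region) both passed the
variant, off-target and efficiency screens in every background, and their
cuts excise 757 bp spanning the ORF. `design_out/hostA.design.json` holds
the full record — regions (with a `shifted` flag and rationale when
neighbor avoidance moved a window), both guides with PAM, cut sites in 0-
and 1-based coordinates, cloning oligos, ranked alternate pairs, the run
configuration, and input checksums. Predicting the diagnostic PCR:

```sh
dgrna amplicon --genome fx/genome.fa --primers fx/primers.tsv \
    --design design_out/hostA.design.json --out amp_out
```

```
name        tier   wt_size  del_size  bias_note
diag_outer  OUTER  1125     368       deletion product is shorter ...
diag_inner  INNER  887      130       deletion product is shorter ...
```

The deletion allele yields a 368-bp outer product where the wild type
gives 1125 bp (the difference is exactly the 757-bp deletion); the inner
nested pair confirms with 130 bp vs 887 bp. The bias note records that
the short junction product tends to out-amplify the long wild-type one.

Two further subcommands: `dgrna audit` re-screens an existing guide table
(19-nt N19 or 20-nt targets) against backgrounds and an off-target
parameter grid, and `dgrna fixtures` (above) emits test bundles.

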