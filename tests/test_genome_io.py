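"""I/O layer: FASTA/GFF3/VCF parsing and the coordinate convention."""

import logging

import numpy as np
import pytest
from Bio.Seq import Seq

from dgrna.errors import CoordinateError, FastaError, GffError, VcfError
from dgrna.genome_io import (
    GenomeAssembly,
    GenomicInterval,
    extract,
    read_fasta,
    read_gff3,
    read_vcf,
    write_fasta,
)
from dgrna.fixtures import random_sequence


# ---------------------------------------------------------------------------
# FASTA


def test_fasta_uppercases_and_preserves_record_order(tmp_path):
    p = tmp_path / "g.fa"
    p.write_text(">c1\nacgt\n>c2\nNNggTT\n")
    asm = read_fasta(p)
    assert asm.names() == ["c1", "c2"]
    assert asm["c1"] == "ACGT"
    assert asm["c2"] == "NNGGTT"


@pytest.mark.parametrize(
    "content,match",
    [
        (">c1\nACGT\n>c1\nGGGG\n", "c1"),
        (">c1\nACXT\n", "c1"),
        ("", "no FASTA records"),
    ],
)
def test_fasta_rejects_malformed_input(tmp_path, content, match):
    p = tmp_path / "bad.fa"
    p.write_text(content)
    with pytest.raises(FastaError, match=match):
        read_fasta(p)


def test_fasta_write_read_round_trip(tmp_path, rng):
    asm = GenomeAssembly(
        {"a": random_sequence(rng, 301, 0.5), "b": random_sequence(rng, 60, 0.3)}
    )
    p = tmp_path / "rt.fa"
    write_fasta(asm, p)
    assert read_fasta(p) == asm


# ---------------------------------------------------------------------------
# GFF3

GFF_HEADER = "##gff-version 3\n"


def _gff(tmp_path, body):
    p = tmp_path / "t.gff3"
    p.write_text(GFF_HEADER + body)
    return p


def test_gff3_one_based_to_half_open_conversion(tmp_path):
    p = _gff(
        tmp_path,
        "c1\tx\tgene\t11\t40\t.\t+\t.\tID=g1\n"
        "c1\tx\tmRNA\t11\t40\t.\t+\t.\tID=t1;Parent=g1\n"
        "c1\tx\tCDS\t11\t40\t.\t+\t0\tID=cds1;Parent=t1\n",
    )
    genes = read_gff3(p)
    assert len(genes) == 1
    (seg,) = genes[0].transcripts[0].cds
    assert (seg.start, seg.end) == (10, 40)


def test_gff3_alternative_start_sites_yield_two_chains(tmp_path):
    # two transcripts sharing the stop but with different start codons
    p = _gff(
        tmp_path,
        "c1\tx\tgene\t101\t400\t.\t+\t.\tID=g1\n"
        "c1\tx\tmRNA\t101\t400\t.\t+\t.\tID=t1;Parent=g1\n"
        "c1\tx\tCDS\t101\t400\t.\t+\t0\tID=a;Parent=t1\n"
        "c1\tx\tmRNA\t151\t400\t.\t+\t.\tID=t2;Parent=g1\n"
        "c1\tx\tCDS\t151\t400\t.\t+\t0\tID=b;Parent=t2\n",
    )
    genes = read_gff3(p)
    starts = sorted(t.cds[0].start for t in genes[0].transcripts)
    assert starts == [100, 150]


def test_gff3_gene_without_cds_dropped_with_warning(tmp_path, caplog):
    p = _gff(
        tmp_path,
        "c1\tx\tgene\t11\t40\t.\t+\t.\tID=g1\n"
        "c1\tx\tmRNA\t11\t40\t.\t+\t.\tID=t1;Parent=g1\n",
    )
    with caplog.at_level(logging.WARNING):
        genes = read_gff3(p)
    assert genes == []
    assert any("g1" in rec.message for rec in caplog.records)


def test_gff3_orphan_cds_error_names_line(tmp_path):
    p = _gff(
        tmp_path,
        "c1\tx\tgene\t11\t40\t.\t+\t.\tID=g1\n"
        "c1\tx\tmRNA\t11\t40\t.\t+\t.\tID=t1;Parent=g1\n"
        "c1\tx\tCDS\t11\t40\t.\t+\t0\tID=cds1;Parent=ghost\n",
    )
    with pytest.raises(GffError, match="ghost"):
        read_gff3(p)


def test_gff3_mixed_strand_transcript_error(tmp_path):
    p = _gff(
        tmp_path,
        "c1\tx\tgene\t11\t90\t.\t+\t.\tID=g1\n"
        "c1\tx\tmRNA\t11\t90\t.\t+\t.\tID=t1;Parent=g1\n"
        "c1\tx\tCDS\t11\t40\t.\t+\t0\tID=a;Parent=t1\n"
        "c1\tx\tCDS\t61\t90\t.\t-\t0\tID=b;Parent=t1\n",
    )
    with pytest.raises(GffError, match="mixed-strand"):
        read_gff3(p)


# ---------------------------------------------------------------------------
# VCF

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=c1,length=100>\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
)


def _vcf(tmp_path, rows):
    p = tmp_path / "t.vcf"
    p.write_text(VCF_HEADER + "".join(rows))
    return p


def test_vcf_position_conversion_and_types(tmp_path):
    p = _vcf(
        tmp_path,
        ["c1\t5\t.\tA\tG\t.\tPASS\t.\n", "c1\t10\t.\tAT\tA\t.\tPASS\t.\n"],
    )
    vs = read_vcf(p, "bg1")
    snp, dele = vs.records
    assert (snp.pos0, snp.type, snp.label) == (4, "SNP", "bg1")
    assert dele.type == "DEL"
    assert dele.affected_interval().length() == 2


def test_vcf_multiallelic_rows_split_per_alt(tmp_path):
    rows = ["c1\t5\t.\tA\tG,T\t.\tPASS\t.\n", "c1\t9\t.\tC\tA\t.\tPASS\t.\n"]
    p = _vcf(tmp_path, rows)
    vs = read_vcf(p, "bg1")
    # naive line parse: one record per comma-separated ALT
    expected = sum(len(r.split("\t")[4].split(",")) for r in rows)
    assert len(vs) == expected == 3


def test_vcf_ref_assembly_mismatch_is_an_error(tmp_path):
    asm = GenomeAssembly({"c1": "A" * 100})
    p = _vcf(tmp_path, ["c1\t5\t.\tG\tT\t.\tPASS\t.\n"])
    with pytest.raises(VcfError, match="c1:5"):
        read_vcf(p, "bg1", asm)
    ok = _vcf(tmp_path, ["c1\t5\t.\tA\tT\t.\tPASS\t.\n"])
    assert len(read_vcf(ok, "bg1", asm)) == 1


# ---------------------------------------------------------------------------
# extract


def test_extract_plus_and_minus_examples():
    asm = GenomeAssembly({"c": "ACGTT"})
    assert extract(asm, GenomicInterval("c", 1, 4, "+")) == "CGT"
    assert extract(asm, GenomicInterval("c", 1, 4, "-")) == "ACG"


def test_extract_out_of_bounds():
    asm = GenomeAssembly({"c": "ACGTT"})
    with pytest.raises(CoordinateError):
        extract(asm, GenomicInterval("c", 2, 9))


def test_extract_strand_involution_against_biopython(rng):
    """Independent oracle: Biopython's reverse_complement."""
    seq = random_sequence(rng, 1000, 0.5)
    asm = GenomeAssembly({"c": seq})
    for _ in range(100):
        a = int(rng.integers(0, 980))
        b = a + int(rng.integers(1, 21))
        plus = extract(asm, GenomicInterval("c", a, b, "+"))
        minus = extract(asm, GenomicInterval("c", a, b, "-"))
        assert len(plus) == len(minus) == b - a
        assert minus == str(Seq(plus).reverse_complement())


def test_interval_invariants():
    with pytest.raises(CoordinateError):
        GenomicInterval("c", 5, 5)
    with pytest.raises(CoordinateError):
        GenomicInterval("c", -1, 4)
    assert GenomicInterval("c", 2, 7).length() == 5
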