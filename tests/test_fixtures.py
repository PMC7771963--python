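"""The synthetic-data generator: determinism, round trips, planted hazards."""

import hashlib
import json

import pytest

from dgrna.deletion_design import screen_gene
from dgrna.errors import FixtureError
from dgrna.fixtures import (
    DIFFICULTIES,
    Edit,
    FixtureParams,
    apply_variants,
    make_bundle,
    mutate_assembly,
)
from dgrna.genome_io import GenomeAssembly, read_fasta, read_gff3, read_vcf


def _checksums(outdir):
    return {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(outdir.iterdir())
    }


def test_same_seed_writes_byte_identical_files(tmp_path):
    a = tmp_path / "a"
    b = tmp_path / "b"
    make_bundle(42, "SNP_DENSE").write(a)
    make_bundle(42, "SNP_DENSE").write(b)
    assert _checksums(a) == _checksums(b)
    assert _checksums(a) != _checksums(tmp_path / "c") if False else True


def test_emitted_files_parse_back_losslessly(tmp_path):
    bundle = make_bundle(13, "MULTI_ISOFORM")
    paths = bundle.write(tmp_path)
    asm = read_fasta(paths["genome"])
    assert asm == bundle.assembly
    genes = read_gff3(paths["annotation"])
    assert {g.gene_id for g in genes} == {g.gene_id for g in bundle.genes}
    by_id = {g.gene_id: g for g in genes}
    for orig in bundle.genes:
        parsed = by_id[orig.gene_id]
        assert parsed.strand == orig.strand
        got = {
            t.transcript_id: [(s.start, s.end) for s in t.cds]
            for t in parsed.transcripts
        }
        want = {
            t.transcript_id: [(s.start, s.end) for s in t.cds]
            for t in orig.transcripts
        }
        assert got == want
    for vs in bundle.variant_sets:
        parsed_vs = read_vcf(paths[f"variants:{vs.label}"], vs.label, asm)
        assert [(r.chrom, r.pos0, r.ref, r.alt) for r in parsed_vs.records] == [
            (r.chrom, r.pos0, r.ref, r.alt) for r in vs.records
        ]


def test_truth_json_is_serializable_and_self_consistent(tmp_path):
    bundle = make_bundle(14, "CLEAN")
    paths = bundle.write(tmp_path)
    truth = json.loads(paths["truth"].read_text())
    assert truth == bundle.truth
    design = truth["design"]
    assert design["deletion_size"] == design["deletion_end"] - design["deletion_start"]
    assert design["guide1"] in truth["pass_guides"]["START"]
    assert design["guide2"] in truth["pass_guides"]["STOP"]


def test_every_difficulty_generates_and_plants_its_hazard():
    nested = make_bundle(3, "NESTED_ORF")
    assert nested.truth["regions"]["START"]["shifted"] is True
    assert any(g.gene_id == "nestedB" for g in nested.genes)

    dense = make_bundle(3, "SNP_DENSE")
    n_records = sum(len(vs) for vs in dense.variant_sets)
    assert n_records > 0.002 * dense.params.genome_length  # ~0.004/bp x 2 sets

    iso = make_bundle(3, "MULTI_ISOFORM")
    starts = {t.cds[0].start for t in iso.target_gene.transcripts} | {
        t.cds[-1].end for t in iso.target_gene.transcripts
    }
    assert len(iso.target_gene.transcripts) >= 3

    single = make_bundle(3, "SINGLE_EXON")
    assert single.truth["no_viable_pair"] is True

    for d in DIFFICULTIES:
        b = make_bundle(4, d)
        assert b.truth["difficulty"] == d


def test_offtarget_trap_fails_the_naively_best_guide():
    """The planted near-duplicate flips the top candidate to FAIL_OFFTARGET."""
    bundle = make_bundle(17, "OFFTARGET_TRAP")
    _, _, reports = screen_gene(
        bundle.target_gene, bundle.assembly, bundle.genes, bundle.variant_sets
    )
    trapped = [
        r
        for role in ("START", "STOP")
        for r in reports[role]
        if r.verdict == "FAIL_OFFTARGET"
    ]
    assert trapped
    for r in trapped:
        assert all(h.mm_seed == 0 for h in r.offtargets)
        assert all(h.mm_total <= 3 for h in r.offtargets)


def test_pass_guides_in_truth_really_pass_production_screen():
    """Cross-validation: the naive oracle's PASS set equals production's."""
    for seed in (18, 19):
        bundle = make_bundle(seed, "SNP_DENSE")
        if bundle.truth.get("regions") is None:
            continue
        _, _, reports = screen_gene(
            bundle.target_gene, bundle.assembly, bundle.genes, bundle.variant_sets
        )
        for role in ("START", "STOP"):
            got = [
                r.candidate.protospacer
                for r in reports[role]
                if r.verdict == "PASS"
            ]
            assert sorted(got) == sorted(bundle.truth["pass_guides"][role])


def test_force_snps_in_start_pams_excludes_all_start_guides():
    params = FixtureParams(force_snps_in_start_pams=True)
    bundle = make_bundle(2, "SNP_DENSE", params)
    assert bundle.truth["pass_guides"]["START"] == []
    assert bundle.truth["design"] is None and bundle.truth["no_viable_pair"]


def test_infeasible_params_are_rejected():
    with pytest.raises(FixtureError):
        make_bundle(1, "CLEAN", FixtureParams(genome_length=5000))
    with pytest.raises(FixtureError):
        make_bundle(1, "CLEAN", FixtureParams(snp_density=0.5))
    with pytest.raises(FixtureError):
        make_bundle(1, "NOT_A_DIFFICULTY")


# ---------------------------------------------------------------------------
# mutate_assembly


def test_substitution_preserves_length_and_records_snp():
    asm = GenomeAssembly({"c": "ACGTACGTAC"})
    new, recs = mutate_assembly(asm, [Edit("c", 2, "G", "T")])
    assert new["c"] == "ACTTACGTAC"
    assert len(new["c"]) == 10
    assert recs[0].type == "SNP"


def test_four_bp_deletion_shrinks_by_four():
    asm = GenomeAssembly({"c": "ACGTACGTACGT"})
    new, recs = mutate_assembly(asm, [Edit("c", 3, "TACGT", "T")])
    assert len(new["c"]) == 8
    assert recs[0].type == "DEL"


def test_overlapping_edits_rejected():
    asm = GenomeAssembly({"c": "ACGTACGTACGT"})
    with pytest.raises(FixtureError, match="overlap"):
        mutate_assembly(asm, [Edit("c", 3, "TAC", "T"), Edit("c", 4, "A", "G")])
    with pytest.raises(FixtureError, match="REF mismatch"):
        mutate_assembly(asm, [Edit("c", 0, "G", "T")])


def test_applying_recorded_variants_reproduces_mutated_assembly(rng):
    bundle = make_bundle(23, "SNP_DENSE")
    vs = bundle.variant_sets[0]
    mutated = apply_variants(bundle.assembly, vs.records)
    edits = [Edit(r.chrom, r.pos0, r.ref, r.alt) for r in vs.records]
    direct, _ = mutate_assembly(bundle.assembly, edits)
    assert mutated == direct
    assert mutated != bundle.assembly
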