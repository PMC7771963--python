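"""Variant overlap, off-target enumeration, efficiency scoring, verdicts."""

import numpy as np
import pytest

from dgrna.errors import MissingWeightError
from dgrna.fixtures import random_sequence
from dgrna.genome_io import (
    GenomeAssembly,
    GenomicInterval,
    VariantRecord,
    VariantSet,
    revcomp,
)
from dgrna.guide_discovery import scan_protospacers
from dgrna.screening import (
    FAIL_OFFTARGET,
    FAIL_VARIANT,
    PASS,
    OffTargetParams,
    efficiency_score,
    find_offtargets,
    screen,
    variant_overlaps,
)


def _first_candidate(seq, lo=100, hi=300):
    asm = GenomeAssembly({"c": seq})
    cands = scan_protospacers(GenomicInterval("c", lo, hi), asm)
    assert cands
    return asm, cands[0]


def _vs(records, label="bg"):
    return VariantSet(label, records)


# ---------------------------------------------------------------------------
# variant screen


def test_empty_variant_sets_pass(rng):
    asm, cand = _first_candidate(random_sequence(rng, 1000, 0.5))
    assert variant_overlaps(cand, []) == []
    assert variant_overlaps(cand, [_vs([])]) == []


def test_snp_in_seed_is_a_hit(rng):
    asm, cand = _first_candidate(random_sequence(rng, 1000, 0.5))
    # third seed base, counted from the PAM-proximal end of the footprint
    fp = cand.footprint()
    pos = fp.start + 10
    ref = asm["c"][pos]
    rec = VariantRecord("c", pos, ref, "A" if ref != "A" else "G", "SNP", "bg")
    hits = variant_overlaps(cand, [_vs([rec])])
    assert [h[0] for h in hits] == [rec]


def test_deletion_spanning_pam_boundary_is_a_hit(rng):
    asm, cand = _first_candidate(random_sequence(rng, 1000, 0.5))
    fp = cand.footprint()
    pos = fp.end - 2  # REF=4 bp crosses the footprint edge
    rec = VariantRecord("c", pos, asm["c"][pos : pos + 4], asm["c"][pos], "DEL", "bg")
    assert variant_overlaps(cand, [_vs([rec])])
    outside = VariantRecord(
        "c", fp.end, asm["c"][fp.end : fp.end + 4], asm["c"][fp.end], "DEL", "bg"
    )
    assert not variant_overlaps(cand, [_vs([outside])])


def test_variant_overlaps_equals_naive_scan(rng):
    seq = random_sequence(rng, 2000, 0.5)
    asm, cand = _first_candidate(seq)
    fp = cand.footprint()
    records = []
    for _ in range(300):
        pos = int(rng.integers(0, 1990))
        ref = seq[pos : pos + int(rng.integers(1, 4))]
        records.append(VariantRecord("c", pos, ref, "A", "MNP", "bg"))
    got = {id(h[0]) for h in variant_overlaps(cand, [_vs(records)])}
    naive = {
        id(r)
        for r in records
        if r.pos0 < fp.end and fp.start < r.pos0 + max(1, len(r.ref))
    }
    assert got == naive


def test_adding_a_variant_set_only_shrinks_pass(rng):
    """Label monotonicity of the any-set rejection rule."""
    seq = random_sequence(rng, 3000, 0.5)
    asm = GenomeAssembly({"c": seq})
    cands = scan_protospacers(GenomicInterval("c", 100, 400), asm)
    set_a = _vs(
        [
            VariantRecord("c", int(p), seq[int(p)], "A", "SNP", "a")
            for p in rng.integers(100, 400, size=8)
        ],
        "a",
    )
    set_b = _vs(
        [
            VariantRecord("c", int(p), seq[int(p)], "A", "SNP", "b")
            for p in rng.integers(100, 400, size=8)
        ],
        "b",
    )
    pass_one = {
        c.protospacer_interval
        for c in cands
        if not variant_overlaps(c, [set_a])
    }
    pass_two = {
        c.protospacer_interval
        for c in cands
        if not variant_overlaps(c, [set_a, set_b])
    }
    assert pass_two <= pass_one


# ---------------------------------------------------------------------------
# off-target search


def test_unique_candidate_has_no_offtargets(rng):
    asm, cand = _first_candidate(random_sequence(rng, 20000, 0.5))
    # a random 20-mer is essentially unique at this scale; verify exactly
    assert find_offtargets(cand, asm) == []


def test_exact_duplicate_is_one_zero_mismatch_hit(rng):
    seq = random_sequence(rng, 20000, 0.5)
    asm, cand = _first_candidate(seq)
    dup = cand.protospacer if cand.strand == "+" else revcomp(cand.protospacer)
    pam = "AGG" if cand.strand == "+" else None
    if cand.strand == "+":
        planted = dup + "AGG"
        seq2 = seq[:10000] + planted + seq[10000 + 23 :]
    else:
        planted = "CCT" + dup
        seq2 = seq[:10000] + planted + seq[10000 + 23 :]
    hits = find_offtargets(cand, GenomeAssembly({"c": seq2}))
    assert len(hits) == 1
    assert hits[0].mm_total == 0 and hits[0].mm_seed == 0


def test_seed_mismatch_excluded_but_tail_mismatches_admitted(rng):
    seq = random_sequence(rng, 20000, 0.5)
    asm, cand = _first_candidate(seq)

    def plant(site20, pam3):
        s2 = seq[:10000] + site20 + pam3 + seq[10023:]
        return GenomeAssembly({"c": s2})

    proto = list(cand.protospacer)
    # two mismatches outside the seed (positions 1 and 5), NAG PAM
    tail_mut = proto.copy()
    for j in (1, 5):
        tail_mut[j] = "A" if tail_mut[j] != "A" else "C"
    asm2 = plant("".join(tail_mut), "TAG")
    hits = [
        h
        for h in find_offtargets(cand, asm2)
        if h.site_interval.start == 10000
    ]
    assert len(hits) == 1
    assert (hits[0].mm_seed, hits[0].mm_total, hits[0].pam_type) == (0, 2, "NAG")

    # one seed mismatch: rejected under the default seed-exact rule
    seed_mut = proto.copy()
    seed_mut[12] = "A" if seed_mut[12] != "A" else "C"
    asm3 = plant("".join(seed_mut), "TGG")
    assert not [
        h
        for h in find_offtargets(cand, asm3)
        if h.site_interval.start == 10000
    ]
    # ... but admitted when one seed mismatch is allowed
    relaxed = find_offtargets(cand, asm3, OffTargetParams(max_mm_seed=1))
    assert [h for h in relaxed if h.site_interval.start == 10000]


@pytest.mark.parametrize("seed", [1, 2, 3])
def test_relaxing_params_never_drops_hits(rng, seed):
    local = np.random.default_rng(seed)
    seq = random_sequence(local, 15000, 0.5)
    asm, cand = _first_candidate(seq)
    tight = OffTargetParams(max_mm_total=2, max_mm_seed=0, pams=("NGG",))
    loose = OffTargetParams(max_mm_total=4, max_mm_seed=2, pams=("NGG", "NAG"))
    h_tight = {
        (h.chrom, h.strand, h.site_interval.start)
        for h in find_offtargets(cand, asm, tight)
    }
    h_loose = {
        (h.chrom, h.strand, h.site_interval.start)
        for h in find_offtargets(cand, asm, loose)
    }
    assert h_tight <= h_loose


# ---------------------------------------------------------------------------
# efficiency


def test_degenerate_table_scores_midpoint(rng):
    table = {(p, b): 0.0 for p in range(1, 21) for b in "ACGT"}
    assert efficiency_score("ACGT" * 5, table) == 5.0


def test_g_at_position_20_outscores_a():
    table = {(p, b): 0.0 for p in range(1, 21) for b in "ACGT"}
    table[(20, "G")] = 1.0
    base = "ACGTACGTACGTACGTACG"
    assert efficiency_score(base + "G", table) > efficiency_score(base + "A", table)


def test_ranking_matches_independent_sum(rng):
    """Oracle: plain python sum over the same weight table."""
    from dgrna.screening import DEFAULT_WEIGHTS

    guides = ["".join("ACGT"[i] for i in rng.integers(0, 4, 20)) for _ in range(16)]
    scored = sorted(guides, key=lambda g: -efficiency_score(g))
    naive = sorted(
        guides,
        key=lambda g: -sum(DEFAULT_WEIGHTS[(i + 1, b)] for i, b in enumerate(g)),
    )
    assert scored == naive


def test_missing_weight_entry_is_an_error():
    table = {(p, b): 0.0 for p in range(1, 20) for b in "ACGT"}  # pos 20 absent
    with pytest.raises(MissingWeightError):
        efficiency_score("A" * 20, table)


# ---------------------------------------------------------------------------
# composite verdicts


def test_screen_verdicts(rng):
    seq = random_sequence(rng, 20000, 0.5)
    asm, cand = _first_candidate(seq)
    clean = screen(cand, asm, [])
    assert clean.verdict == PASS

    pos = cand.footprint().start + 5
    rec = VariantRecord("c", pos, seq[pos], "A" if seq[pos] != "A" else "G", "SNP", "bg")
    withsnp = screen(cand, asm, [_vs([rec])])
    assert withsnp.verdict == FAIL_VARIANT
    assert len(withsnp.variant_hits) == 1

    if cand.strand == "+":
        seq2 = seq[:10000] + cand.protospacer + "TGG" + seq[10023:]
    else:
        seq2 = seq[:10000] + "CCT" + revcomp(cand.protospacer) + seq[10023:]
    withdup = screen(cand, GenomeAssembly({"c": seq2}), [])
    assert withdup.verdict == FAIL_OFFTARGET
    assert withdup.offtargets[0].mm_total == 0

    floored = screen(cand, asm, [], efficiency_floor=10.5)
    assert floored.verdict == "FAIL_EFFICIENCY"
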