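"""Frame classifier, translation and fusion assembly."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from orfselect.code import GeneticCode, STANDARD_CODE, reverse_complement, translate
from orfselect.core import (
    CloningContext,
    ConfigurationError,
    Fragment,
    assemble_fusion,
    classify_fragment,
    default_context,
    scan_stops,
)
from conftest import naive_stop_scan

dna = st.text(alphabet="ACGT", min_size=1, max_size=120)


@pytest.mark.parametrize(
    "seq,frame,expected",
    [
        ("ATGGGC", 0, "MG"),
        ("TAA", 0, "*"),
        ("ATGGG", 0, "M"),  # trailing partial codon dropped
        ("AATGGGC", 1, "MG"),
        ("ATGNNNGGC", 0, "MXG"),  # N codon -> unknown symbol
        ("", 0, ""),
    ],
)
def test_translate(seq, frame, expected):
    assert translate(seq, frame) == expected


def test_translate_rejects_non_dna():
    with pytest.raises(ValueError):
        translate("ATGQ", 0)
    with pytest.raises(ValueError):
        translate("ATG", 3)


def test_genetic_code_invariants():
    code = STANDARD_CODE
    assert len(code.codon_table) == 64
    assert code.stop_codons == {"TAA", "TAG", "TGA"}
    assert all(code.codon_table[c] == "*" for c in code.stop_codons)
    with pytest.raises(ValueError):
        GeneticCode(codon_table={"ATG": "M"})


@given(dna)
def test_reverse_complement_involution(seq):
    assert reverse_complement(reverse_complement(seq)) == seq


def test_classify_gc_only_is_open(ctx):
    # stop codons all contain A or T, so a GC-only fragment cannot close
    frag = Fragment("g", 0, 12, "+", "GGCGGCGGCGGC")
    call = classify_fragment(frag, ctx)
    assert call.cloning_frame_open
    assert call.stop_codon_positions == ()
    assert call.fusion_viable  # length 12 ≡ 0 (mod 3), the required residue


def test_classify_records_stop_position(ctx):
    call = classify_fragment(Fragment("g", 0, 9, "+", "GGCTAAGGC"), ctx)
    assert call.stop_codon_positions == (1,)
    assert not call.cloning_frame_open
    assert not call.fusion_viable


def test_classify_empty_rejected(ctx):
    with pytest.raises(ValueError):
        Fragment("g", 0, 0, "+", "")


def test_classify_ambiguous_n(ctx):
    # N codons never count as stops; the call is flagged ambiguous instead
    call = classify_fragment(Fragment("g", 0, 6, "+", "GGCNNA"), ctx)
    assert call.ambiguous
    assert call.cloning_frame_open


def test_native_frame_requires_forward_strand_and_phase(ctx):
    gene = "ATGGCAGGCGCA"
    plus = Fragment("g", 0, 9, "+", gene[:9])
    shifted = Fragment("g", 1, 10, "+", gene[1:10])
    minus = Fragment("g", 0, 9, "-", reverse_complement(gene[:9]))
    assert classify_fragment(plus, ctx, native_origin=gene).native_frame is True
    assert classify_fragment(shifted, ctx, native_origin=gene).native_frame is False
    assert classify_fragment(minus, ctx, native_origin=gene).native_frame is False
    # without an origin the flag is unknown
    assert classify_fragment(plus, ctx).native_frame is None


@given(dna.filter(lambda s: len(s) >= 3))
def test_classifier_matches_naive_scan(ctx, seq):
    call = classify_fragment(Fragment("g", 0, len(seq), "+", seq), ctx)
    assert list(call.stop_codon_positions) == naive_stop_scan(seq, ctx.frame_offset)
    assert call.cloning_frame_open == (not naive_stop_scan(seq, ctx.frame_offset))


@given(dna.filter(lambda s: len(s) >= 3))
def test_reverse_complement_symmetry(ctx, seq):
    """Classifying a minus-strand fragment equals classifying its cloned
    (reverse-complemented) sequence as a plus-strand fragment."""
    rc = reverse_complement(seq)
    minus = classify_fragment(Fragment("g", 0, len(seq), "-", rc), ctx)
    plus = classify_fragment(Fragment("g", 0, len(rc), "+", rc), ctx)
    assert minus.stop_codon_positions == plus.stop_codon_positions
    assert minus.cloning_frame_open == plus.cloning_frame_open
    assert minus.len_mod3 == plus.len_mod3


def test_native_phase_fragments_of_stopfree_gene_are_open(ctx, rng):
    """Forward-strand fragments starting on a codon boundary of a stop-free
    CDS can never contain a cloning-frame stop."""
    codons = [c for c in
              ["GCA", "GCC", "GGT", "TGC", "ACT", "CAT", "TAT", "TTG", "AAC", "CGG"]]
    gene = "".join(rng.choice(codons) for _ in range(100))
    assert not naive_stop_scan(gene)
    for _ in range(50):
        start = 3 * int(rng.integers(0, 80))
        length = 3 * int(rng.integers(5, 20))
        frag = Fragment("g", start, start + length, "+", gene[start : start + length])
        assert classify_fragment(frag, ctx, native_origin=gene).cloning_frame_open


def test_assemble_fusion_complete_when_viable(ctx):
    insert = "GGCGGCGGC"  # stop-free, length ≡ 0 (mod 3)
    frag = Fragment("g", 0, 9, "+", insert)
    peptide = assemble_fusion(frag, ctx)
    downstream_pep = translate(ctx.downstream_context).rstrip("*").split("*")[0]
    assert peptide.endswith(downstream_pep)


def test_assemble_fusion_truncates_at_insert_stop(ctx):
    frag = Fragment("g", 0, 9, "+", "GGCTAAGGC")
    peptide = assemble_fusion(frag, ctx)
    upstream_pep = translate(ctx.upstream_context + ctx.adapter5)
    assert peptide == upstream_pep + "G"  # one insert codon, then stop


def test_assemble_fusion_requires_contexts():
    bare = CloningContext(adapter5="GCTAGC", adapter3="GGTGGC")
    with pytest.raises(ConfigurationError):
        assemble_fusion(Fragment("g", 0, 3, "+", "GGC"), bare)


def test_assemble_fusion_length_matches_translation_oracle(ctx, rng):
    """For stop-free inserts of the required length residue, the fusion length
    equals the frame-aligned codon count of the concatenated DNA up to the
    first stop, computed by direct oracle translation."""
    gc_codons = ["GGC", "GCC", "CGC", "GCG", "CCG", "GGG"]
    for _ in range(100):
        insert = "".join(rng.choice(gc_codons) for _ in range(int(rng.integers(3, 40))))
        frag = Fragment("g", 0, len(insert), "+", insert)
        peptide = assemble_fusion(frag, ctx)
        full_dna = (ctx.upstream_context + ctx.adapter5 + insert
                    + ctx.adapter3 + ctx.downstream_context)
        oracle = translate(full_dna)
        expected_len = oracle.index("*")
        assert len(peptide) == expected_len


def test_cloning_context_validation():
    with pytest.raises(ValueError):
        CloningContext(adapter5="GCTAXC", adapter3="GGT")
    with pytest.raises(ValueError):
        CloningContext(adapter5="GCT", adapter3="GGT", frame_offset=5)
    d = default_context().to_dict()
    assert CloningContext.from_dict(d) == default_context()


def test_scan_stops_frame_offset():
    assert scan_stops("ATAAGC", 0) == []
    assert scan_stops("ATAAGC", 1) == [0]  # TAA at codon 0 of frame 1
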