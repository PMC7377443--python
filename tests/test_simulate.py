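"""Synthetic gene panels, libraries with ground truth, and simulated reads."""

import numpy as np
import pytest

from orfselect.code import reverse_complement, translate
from orfselect.core import default_context
from orfselect.io import iter_fastq_pairs, write_fastq
from orfselect.library import analytic_stopfree_probability, gc_base_freqs
from orfselect.pipeline import merge_pair, ReadPair
from orfselect.simulate import (
    SyntheticConfig,
    codon_weights,
    gc_fraction,
    make_dataset,
    make_genes,
    make_library,
    make_reads,
    select_survivors,
)


def test_codon_weights_hit_gc_target():
    for target in (0.4, 0.5, 0.65):
        w = codon_weights(target)
        assert len(w) == 61  # stop codons excluded
        gc = sum(p * (c.count("G") + c.count("C")) for c, p in w.items()) / 3
        assert gc == pytest.approx(target, abs=1e-9)


def test_make_genes_stop_free_and_gc(ctx):
    cfg = SyntheticConfig(n_genes=30, seed=4)
    genes = make_genes(cfg)
    assert len(genes) == 30
    for seq in genes.values():
        assert len(seq) % 3 == 0
        assert 300 <= len(seq) <= 1500
        assert "*" not in translate(seq)
    realized = gc_fraction("".join(genes.values()))
    assert 0.63 <= realized <= 0.67


def test_make_genes_deterministic():
    cfg = SyntheticConfig(n_genes=5, seed=99)
    assert make_genes(cfg) == make_genes(cfg)


def test_library_labels_and_adapter_deletions(ctx):
    cfg = SyntheticConfig(n_genes=5, n_fragments=400, adapter_indel_rate=0.0, seed=13)
    genes = make_genes(cfg, np.random.default_rng(1))
    constructs, truth = make_library(genes, cfg, ctx, np.random.default_rng(2))
    assert (truth["adapter5_del"] == 0).all()
    # module invariant: native-frame fragments of stop-free genes are open
    native = truth[truth["native_frame"]]
    assert native["cloning_frame_open"].all()
    # constructs carry intact adapters
    for (_, c), (_, row) in zip(constructs[:20], truth.iterrows()):
        assert c.startswith(ctx.adapter5) and c.endswith(ctx.adapter3)
        assert len(c) == len(ctx.adapter5) + row["length"] + len(ctx.adapter3)
    assert (truth["length"].between(150, 400)).all()


def test_library_open_fraction_within_analytic_bracket(ctx):
    """The label open fraction of a 65%-GC library of 200-bp fragments lies
    between the non-native-phase analytic stop-free rate (lower) and its
    mixture with the always-open native phase (upper, with margin)."""
    cfg = SyntheticConfig(
        n_genes=10, n_fragments=3000, size_window=(200, 200),
        adapter_indel_rate=0.0, seed=5,
    )
    genes = make_genes(cfg, np.random.default_rng(50))
    _, truth = make_library(genes, cfg, ctx, np.random.default_rng(51))
    q = truth["cloning_frame_open"].mean()
    p_nonnative = analytic_stopfree_probability(200, gc_base_freqs(0.65))
    # 1/6 of fragments are native-phase forward and always open
    lower = p_nonnative
    upper = 1 / 6 + 5 / 6 * p_nonnative + 0.15  # codon structure inflates the rate
    assert lower < q < upper


def test_adapter_deletion_rate_and_shifted_labels(ctx):
    cfg = SyntheticConfig(n_genes=5, n_fragments=4000, adapter_indel_rate=0.10, seed=17)
    genes = make_genes(cfg, np.random.default_rng(3))
    constructs, truth = make_library(genes, cfg, ctx, np.random.default_rng(4))
    frac_del = (truth["adapter5_del"] > 0).mean()
    se = np.sqrt(0.1 * 0.9 / len(truth))
    assert abs(frac_del - 0.10) < 4 * se
    dels = truth.loc[truth["adapter5_del"] > 0, "adapter5_del"]
    assert set(dels.unique()) <= {1, 2}
    # intact clones: shifted label equals the nominal label
    intact = truth[truth["adapter5_del"] == 0]
    assert (intact["shifted_frame_open"] == intact["cloning_frame_open"]).all()


def test_reads_roundtrip_error_free(ctx, small_dataset):
    """With no substitutions, merging the simulated mates reproduces every
    construct exactly."""
    ds = small_dataset
    for (cid, construct), (rid1, m1, q1), (rid2, m2, q2) in zip(
        ds.constructs[:100], ds.r1[:100], ds.r2[:100]
    ):
        assert cid == rid1 == rid2
        merged = merge_pair(ReadPair(rid1, m1, m2, q1, q2))
        assert merged is not None and merged.seq == construct


def test_reads_substitution_rate(ctx):
    cfg = SyntheticConfig(
        n_genes=3, n_fragments=2000, substitution_rate=0.005,
        adapter_indel_rate=0.0, seed=23,
    )
    genes = make_genes(cfg, np.random.default_rng(6))
    constructs, _ = make_library(genes, cfg, ctx, np.random.default_rng(7))
    r1, _ = make_reads(constructs, cfg, np.random.default_rng(8))
    n_mismatch = 0
    n_bases = 0
    for (_, construct), (_, m1, _) in zip(constructs, r1):
        ref = construct[: len(m1)]
        n_mismatch += sum(a != b for a, b in zip(ref, m1))
        n_bases += len(m1)
    rate = n_mismatch / n_bases
    se = np.sqrt(0.005 * 0.995 / n_bases)
    assert abs(rate - 0.005) < 4 * se


def test_fastq_roundtrip_bit_identical(ctx, small_dataset, tmp_path):
    ds = small_dataset
    write_fastq(ds.r1, tmp_path / "r1.fastq")
    write_fastq(ds.r2, tmp_path / "r2.fastq.gz")
    back = list(iter_fastq_pairs(tmp_path / "r1.fastq", tmp_path / "r2.fastq.gz"))
    assert len(back) == len(ds.r1)
    for (rid, s1, q1, s2, q2), (orig_id, orig_s1, orig_q1) in zip(back, ds.r1):
        assert rid == orig_id and s1 == orig_s1 and q1 == orig_q1


def test_dataset_deterministic_and_writes(ctx, tmp_path):
    cfg = SyntheticConfig(n_genes=3, n_fragments=50, seed=31)
    ds1 = make_dataset(cfg, ctx, out_dir=tmp_path / "a")
    ds2 = make_dataset(cfg, ctx, out_dir=tmp_path / "b")
    assert ds1.genes == ds2.genes
    assert ds1.constructs == ds2.constructs
    assert ds1.r1 == ds2.r1
    assert (tmp_path / "a" / "genes.fasta").read_bytes() == (
        tmp_path / "b" / "genes.fasta"
    ).read_bytes()
    for name in ("constructs.fasta", "reads_R1.fastq", "reads_R2.fastq",
                 "ground_truth.tsv"):
        assert (tmp_path / "a" / name).exists()


def test_strand_label_symmetry(ctx):
    cfg = SyntheticConfig(n_genes=8, n_fragments=6000, adapter_indel_rate=0.0, seed=37)
    genes = make_genes(cfg, np.random.default_rng(9))
    _, truth = make_library(genes, cfg, ctx, np.random.default_rng(10))
    # the native phase (1/3 of forward fragments) is always open, so compare
    # the non-native forward phases against the minus strand
    nonnative_plus = truth[(truth["strand"] == "+") & (truth["start"] % 3 != 0)]
    minus = truth[truth["strand"] == "-"]
    assert abs(nonnative_plus["cloning_frame_open"].mean()
               - minus["cloning_frame_open"].mean()) < 0.05


def test_select_survivors_mechanism(ctx, small_dataset):
    surv, struth = select_survivors(small_dataset.constructs, small_dataset.truth)
    assert len(surv) == len(struth)
    # with intact adapters survival is exactly cloning-frame openness
    assert len(surv) == int(small_dataset.truth["cloning_frame_open"].sum())
    assert struth["shifted_frame_open"].all()


def test_config_validation():
    with pytest.raises(ValueError):
        SyntheticConfig(gc_content=0.0)
    with pytest.raises(ValueError):
        SyntheticConfig(substitution_rate=1.5)
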