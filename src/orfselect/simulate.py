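"""Synthetic reference genes, fragment libraries and paired-end reads.

Emulates the study system end to end so the whole pipeline is testable
without external downloads: a panel of high-GC (~65%) stop-free coding
sequences, random fragmentation into a 150–400 bp size-selection window,
adapter ligation in both orientations with occasional 1–2 bp deletions in
the 5' adapter (the frame-correction leak), and 2×250 paired-end reads with
i.i.d. substitution errors and constant Phred quality.

Genes are built by *codon* sampling with stop codons excluded, which
guarantees a stop-free native frame (the real amplicons were amplified
without their stop codons); GC content is controlled by exponentially
reweighting codons by their G+C count. Every fragment carries ground-truth
frame labels computed on the pristine sequence before read errors.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .code import GeneticCode, STANDARD_CODE, reverse_complement
from .core import CloningContext, Fragment, classify_fragment, default_context, scan_stops
from .io import write_fasta, write_fastq, write_tsv
from .library import random_fragmentation_sim


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-condition defaults for the synthetic generator."""

    n_genes: int = 30
    gene_length_range: tuple[int, int] = (300, 1500)
    gc_content: float = 0.65
    n_fragments: int = 10_000
    size_window: tuple[int, int] = (150, 400)
    read_length: int = 250
    substitution_rate: float = 0.001
    adapter_indel_rate: float = 0.10
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be in (0, 1)")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        for name in ("substitution_rate", "adapter_indel_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_genes < 1 or self.n_fragments < 1:
            raise ValueError("n_genes and n_fragments must be >= 1")


def codon_weights(gc_content: float, code: GeneticCode = STANDARD_CODE) -> dict[str, float]:
    """Stop-free codon distribution whose expected base GC equals the target.

    Codon c gets weight w^gc(c) with the tilt w solved so that
    Σ w_c·gc(c) / 3 equals ``gc_content``; stop codons carry zero weight.
    """
    codons = ["".join(c) for c in itertools.product("ACGT", repeat=3)]
    sense = [c for c in codons if c not in code.stop_codons]
    gc_counts = np.array([c.count("G") + c.count("C") for c in sense], dtype=float)

    def expected_gc(log_w: float) -> float:
        w = np.exp(log_w * gc_counts)
        return float((w * gc_counts).sum() / (3.0 * w.sum())) - gc_content

    log_w = brentq(expected_gc, -30.0, 30.0)
    weights = np.exp(log_w * gc_counts)
    weights /= weights.sum()
    return dict(zip(sense, weights))


def make_genes(
    cfg: SyntheticConfig,
    rng: Optional[np.random.Generator] = None,
    code: GeneticCode = STANDARD_CODE,
) -> dict[str, str]:
    """Sample a panel of stop-free, GC-targeted coding sequences.

    Gene lengths are multiples of 3 inside ``gene_length_range``; the native
    (frame-0) translation of every gene is stop-free by construction.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    weights = codon_weights(cfg.gc_content, code)
    codons = np.array(list(weights))
    probs = np.array(list(weights.values()))
    lo, hi = cfg.gene_length_range
    n_min, n_max = -(-lo // 3), hi // 3
    if n_min > n_max:
        raise ValueError("gene_length_range admits no multiple-of-3 length")
    genes: dict[str, str] = {}
    for i in range(cfg.n_genes):
        n_codons = int(rng.integers(n_min, n_max + 1))
        genes[f"gene_{i + 1:03d}"] = "".join(rng.choice(codons, size=n_codons, p=probs))
    return genes


def gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq) if seq else float("nan")


TRUTH_COLUMNS = [
    "read_id",
    "gene_id",
    "start",
    "end",
    "strand",
    "length",
    "len_mod3",
    "n_stops",
    "cloning_frame_open",
    "fusion_viable",
    "native_frame",
    "adapter5_del",
    "shifted_frame_open",
]


def make_library(
    genes: dict[str, str],
    cfg: SyntheticConfig,
    ctx: Optional[CloningContext] = None,
    rng: Optional[np.random.Generator] = None,
    code: GeneticCode = STANDARD_CODE,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Fragment the gene panel, ligate adapters, and label every clone.

    Returns ``(constructs, truth)`` where each construct is
    ``(read_id, adapter5' + insert + adapter3)`` — the 5' adapter carries a
    1–2 bp deletion with probability ``adapter_indel_rate`` — and ``truth``
    holds the frame labels of the pristine fragment plus the effective-frame
    openness under the adapter deletion (``shifted_frame_open``), which is
    what decides leak survival during selection.
    """
    ctx = ctx if ctx is not None else default_context()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    fragments = random_fragmentation_sim(genes, cfg.size_window, cfg.n_fragments, rng)
    constructs: list[tuple[str, str]] = []
    rows: list[dict] = []
    a5 = ctx.adapter5
    for i, frag in enumerate(fragments):
        read_id = f"SYN:{i + 1:07d}"
        del_len = 0
        a5_obs = a5
        if cfg.adapter_indel_rate and rng.random() < cfg.adapter_indel_rate:
            del_len = int(rng.integers(1, 3))  # 1 or 2 bp, equiprobable
            pos = int(rng.integers(0, len(a5) - del_len + 1))
            a5_obs = a5[:pos] + a5[pos + del_len :]
        constructs.append((read_id, a5_obs + frag.seq + ctx.adapter3))
        call = classify_fragment(frag, ctx, code, native_origin=genes[frag.gene_id])
        shifted_open = (
            call.cloning_frame_open
            if del_len == 0
            else not scan_stops(frag.seq, (ctx.frame_offset + del_len) % 3, code)
        )
        rows.append(
            {
                "read_id": read_id,
                "gene_id": frag.gene_id,
                "start": frag.start,
                "end": frag.end,
                "strand": frag.strand,
                "length": len(frag),
                "len_mod3": call.len_mod3,
                "n_stops": len(call.stop_codon_positions),
                "cloning_frame_open": call.cloning_frame_open,
                "fusion_viable": call.fusion_viable,
                "native_frame": call.native_frame,
                "adapter5_del": del_len,
                "shifted_frame_open": shifted_open,
            }
        )
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    return constructs, truth


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0.0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    if hits.size:
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        for i in hits:
            choices = bases[bases != arr[i]]
            arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def make_reads(
    constructs: list[tuple[str, str]],
    cfg: SyntheticConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[tuple[str, str, str]], list[tuple[str, str, str]]]:
    """Simulate 2×``read_length`` paired-end reads of every construct.

    Mate 1 reads the construct 5'→3', mate 2 the reverse complement; each
    mate is truncated at the construct length when the construct is shorter
    than a full read. Substitution errors are i.i.d. per base; quality is a
    constant Q30 (only merge tie-breaking consumes qualities downstream).
    """
    if not constructs:
        raise ValueError("no constructs to sequence")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    q30 = chr(30 + 33)
    r1: list[tuple[str, str, str]] = []
    r2: list[tuple[str, str, str]] = []
    for read_id, construct in constructs:
        m1 = construct[: cfg.read_length]
        m2 = reverse_complement(construct)[: cfg.read_length]
        m1 = _mutate(m1, cfg.substitution_rate, rng)
        m2 = _mutate(m2, cfg.substitution_rate, rng)
        r1.append((read_id, m1, q30 * len(m1)))
        r2.append((read_id, m2, q30 * len(m2)))
    return r1, r2


def select_survivors(
    constructs: list[tuple[str, str]], truth: pd.DataFrame
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Sequence-level ampicillin selection of a synthetic library.

    A clone survives when its insert is stop-free in the reading frame the
    cell actually translates: the nominal cloning frame for intact adapters,
    or the deletion-shifted frame for clones with a 5' adapter indel
    (``shifted_frame_open``). Off-frame clones die; frame-corrected clones
    survive and are the leak that dilutes the post-selection in-frame
    fraction measured by re-sequencing.
    """
    keep = truth["shifted_frame_open"].to_numpy(dtype=bool)
    surviving = [c for c, k in zip(constructs, keep) if k]
    return surviving, truth.loc[keep].reset_index(drop=True)


@dataclass
class SyntheticDataset:
    genes: dict[str, str]
    constructs: list[tuple[str, str]]
    truth: pd.DataFrame
    r1: list[tuple[str, str, str]]
    r2: list[tuple[str, str, str]]
    ctx: CloningContext = field(default_factory=default_context)


def make_dataset(
    cfg: SyntheticConfig,
    ctx: Optional[CloningContext] = None,
    out_dir: Optional[str | Path] = None,
) -> SyntheticDataset:
    """Generate genes → library → reads with independent child seeds.

    When ``out_dir`` is given, writes genes.fasta, constructs.fasta, paired
    FASTQ and the ground-truth TSV there.
    """
    ctx = ctx if ctx is not None else default_context()
    ss = np.random.SeedSequence(cfg.seed)
    rng_genes, rng_lib, rng_reads = (np.random.default_rng(s) for s in ss.spawn(3))
    genes = make_genes(cfg, rng_genes)
    constructs, truth = make_library(genes, cfg, ctx, rng_lib)
    r1, r2 = make_reads(constructs, cfg, rng_reads)
    ds = SyntheticDataset(genes=genes, constructs=constructs, truth=truth, r1=r1, r2=r2, ctx=ctx)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_fasta(genes, out_dir / "genes.fasta")
        write_fasta(dict(constructs), out_dir / "constructs.fasta")
        write_fastq(r1, out_dir / "reads_R1.fastq")
        write_fastq(r2, out_dir / "reads_R2.fastq")
        write_tsv(truth, out_dir / "ground_truth.tsv")
    return ds


__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "TRUTH_COLUMNS",
    "codon_weights",
    "gc_fraction",
    "make_dataset",
    "make_genes",
    "make_library",
    "make_reads",
    "select_survivors",
]
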