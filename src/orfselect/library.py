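"""In silico fragment libraries and theoretical in-frame fractions.

Random shearing of a coding-sequence pool is approximated in two ways:

* *sliding (overlapping) libraries* — every fixed-length window of every
  gene at a fixed shift (1 bp by default), the deterministic idealisation
  used for theoretical in-frame fractions at 100/200/300 bp;
* *random fragmentation* — fragments with random breakpoints conditioned on
  a size-selection window (150–400 bp by default), the stochastic model the
  synthetic read generator builds on.

The module also holds the two closed-form baselines: the 18-configuration
junction enumeration (orientation × 5'-phase × length mod 3, exactly one of
which restores the native ORF → 1/18 ≈ 5.6%) and the stop-free probability
(1 − p_stop)^⌊L/3⌋ of an i.i.d. random sequence of length L.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import numpy as np

from .code import GeneticCode, STANDARD_CODE, reverse_complement
from .core import CloningContext, Fragment, classify_fragment

logger = logging.getLogger(__name__)

GeneSet = Mapping[str, str]  # gene_id -> CDS (forward strand, no terminal stop)


@dataclass(frozen=True)
class SlidingLibrarySpec:
    """Parameters of a sliding (overlapping) fragment library."""

    fragment_length: int
    shift: int = 1
    strands: str = "both"  # "both" or "forward"

    def __post_init__(self) -> None:
        if self.fragment_length < 3:
            raise ValueError("fragment_length must be >= 3")
        if self.shift < 1:
            raise ValueError("shift must be >= 1")
        if self.strands not in ("both", "forward"):
            raise ValueError("strands must be 'both' or 'forward'")


@dataclass
class GeneStats:
    n_fragments: int = 0
    n_open: int = 0
    covered: set[int] = field(default_factory=set)


@dataclass
class LibraryStats:
    """Aggregate in-frame statistics for a fragment library."""

    n_fragments: int = 0
    n_open: int = 0
    n_fusion_viable: int = 0
    n_ambiguous: int = 0
    per_gene: dict[str, GeneStats] = field(default_factory=dict)

    @property
    def open_fraction(self) -> float:
        """Fraction of unambiguous fragments with a stop-free cloning frame."""
        denom = self.n_fragments - self.n_ambiguous
        return self.n_open / denom if denom else float("nan")

    @property
    def fusion_viable_fraction(self) -> float:
        denom = self.n_fragments - self.n_ambiguous
        return self.n_fusion_viable / denom if denom else float("nan")

    def add(self, frag: Fragment, open_: bool, viable: bool, ambiguous: bool) -> None:
        self.n_fragments += 1
        gs = self.per_gene.setdefault(frag.gene_id, GeneStats())
        gs.n_fragments += 1
        gs.covered.update(range(frag.start, frag.end))
        if ambiguous:
            self.n_ambiguous += 1
            return
        if open_:
            self.n_open += 1
            gs.n_open += 1
        if viable:
            self.n_fusion_viable += 1

    def to_dict(self) -> dict:
        return {
            "n_fragments": self.n_fragments,
            "n_open": self.n_open,
            "n_fusion_viable": self.n_fusion_viable,
            "n_ambiguous": self.n_ambiguous,
            "open_fraction": self.open_fraction,
            "fusion_viable_fraction": self.fusion_viable_fraction,
            "per_gene": {
                g: {
                    "n_fragments": gs.n_fragments,
                    "n_open": gs.n_open,
                    "coverage_breadth": len(gs.covered),
                }
                for g, gs in sorted(self.per_gene.items())
            },
        }


def sliding_fragments(genes: GeneSet, spec: SlidingLibrarySpec) -> Iterator[Fragment]:
    """Emit every fixed-length window of every gene at the given shift.

    Order is deterministic: gene order, then start position, with the
    forward-strand window before its reverse complement. Genes shorter than
    the fragment length are skipped with a warning; trailing windows shorter
    than the fragment length are not emitted.
    """
    if not genes:
        raise ValueError("empty gene set")
    L, shift = spec.fragment_length, spec.shift
    for gene_id, seq in genes.items():
        G = len(seq)
        if G < L:
            logger.warning("gene %s (%d bp) shorter than fragment length %d; skipped",
                           gene_id, G, L)
            continue
        for start in range(0, G - L + 1, shift):
            window = seq[start : start + L]
            yield Fragment(gene_id, start, start + L, "+", window)
            if spec.strands == "both":
                yield Fragment(gene_id, start, start + L, "-", reverse_complement(window))


def insilico_inframe_fraction(
    genes: GeneSet,
    spec: SlidingLibrarySpec,
    ctx: CloningContext,
    code: GeneticCode = STANDARD_CODE,
) -> LibraryStats:
    """Classify every sliding-window fragment and aggregate library stats."""
    stats = LibraryStats()
    for frag in sliding_fragments(genes, spec):
        call = classify_fragment(frag, ctx, code, native_origin=genes[frag.gene_id])
        stats.add(frag, call.cloning_frame_open, call.fusion_viable, call.ambiguous)
    return stats


@dataclass(frozen=True)
class JunctionConfiguration:
    """One of the 18 cloning-junction geometries of a random fragment."""

    orientation: str  # '+' or '-'
    five_prime_phase: int  # 0, 1, 2 — insert 5' end relative to native codon frame
    length_mod3: int
    valid: bool  # restores the native open reading frame


def junction_configurations() -> list[JunctionConfiguration]:
    """Enumerate the 2 × 3 × 3 = 18 junction configurations.

    A randomly sheared, blunt-cloned fragment lands in one of 18 equally
    likely geometries; only forward orientation, 5' phase matching the
    native codon frame, and length ≡ 0 (mod 3) reconstitutes the source
    gene's reading frame through the cassette — 1/18 ≈ 5.6%. Internal stop
    codons are ignored by construction: this counts junction geometry only.
    """
    configs = []
    for orientation in ("+", "-"):
        for phase in (0, 1, 2):
            for length_mod3 in (0, 1, 2):
                valid = orientation == "+" and phase == 0 and length_mod3 == 0
                configs.append(JunctionConfiguration(orientation, phase, length_mod3, valid))
    return configs


def junction_valid_fraction() -> float:
    configs = junction_configurations()
    return sum(c.valid for c in configs) / len(configs)


def stop_codon_probability(
    base_freqs: Mapping[str, float] | Sequence[float],
    code: GeneticCode = STANDARD_CODE,
) -> float:
    """Probability that an i.i.d. random codon is a stop codon."""
    if not isinstance(base_freqs, Mapping):
        base_freqs = dict(zip("ACGT", base_freqs))
    freqs = {b: float(base_freqs.get(b, 0.0)) for b in "ACGT"}
    if any(f < 0 for f in freqs.values()) or not math.isclose(
        sum(freqs.values()), 1.0, abs_tol=1e-9
    ):
        raise ValueError("base frequencies must be non-negative and sum to 1")
    return sum(freqs[c[0]] * freqs[c[1]] * freqs[c[2]] for c in code.stop_codons)


def analytic_stopfree_probability(
    L: int,
    base_freqs: Mapping[str, float] | Sequence[float],
    code: GeneticCode = STANDARD_CODE,
) -> float:
    """Closed-form probability that an i.i.d. L-mer is stop-free in one frame.

    Returns (1 − p_stop)^⌊L/3⌋ where p_stop sums the base-frequency products
    over the stop codons; codons are independent under the i.i.d. model, and
    the trailing partial codon cannot be a stop.
    """
    if L < 0:
        raise ValueError("L must be non-negative")
    p_stop = stop_codon_probability(base_freqs, code)
    return (1.0 - p_stop) ** (L // 3)


def gc_base_freqs(gc_content: float) -> dict[str, float]:
    """Symmetric single-base frequencies for a given GC content."""
    if not 0.0 <= gc_content <= 1.0:
        raise ValueError("gc_content must be in [0, 1]")
    at = (1.0 - gc_content) / 2.0
    gc = gc_content / 2.0
    return {"A": at, "C": gc, "G": gc, "T": at}


def random_fragmentation_sim(
    genes: GeneSet,
    size_window: tuple[int, int],
    n: int,
    seed: Optional[int | np.random.Generator] = None,
) -> Iterator[Fragment]:
    """Draw ``n`` random fragments with lengths inside the size window.

    Breakpoint model: a gene is chosen with probability proportional to its
    length (mass-proportional shearing), the fragment length is uniform on
    the feasible part of [min, max] for that gene, and the start is uniform
    over valid positions. Strand is Bernoulli(1/2). Reproducible under seed.
    """
    lo, hi = size_window
    if n < 1:
        raise ValueError("n must be >= 1")
    if lo < 3 or hi < lo:
        raise ValueError("size window must satisfy 3 <= min <= max")
    eligible = [(gid, seq) for gid, seq in genes.items() if len(seq) >= lo]
    if not eligible:
        raise ValueError("size window minimum exceeds every gene length")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    weights = np.array([len(seq) for _, seq in eligible], dtype=float)
    weights /= weights.sum()
    gene_idx = rng.choice(len(eligible), size=n, p=weights)
    for i in gene_idx:
        gene_id, seq = eligible[i]
        G = len(seq)
        length = int(rng.integers(lo, min(hi, G) + 1))
        start = int(rng.integers(0, G - length + 1))
        window = seq[start : start + length]
        if rng.random() < 0.5:
            yield Fragment(gene_id, start, start + length, "+", window)
        else:
            yield Fragment(gene_id, start, start + length, "-", reverse_complement(window))


def fragments_to_bed(fragments: Iterable[Fragment]) -> str:
    """BED6 text of fragment intervals on the reference genes."""
    lines = [
        f"{f.gene_id}\t{f.start}\t{f.end}\t{f.gene_id}:{f.start}-{f.end}\t0\t{f.strand}"
        for f in fragments
    ]
    return "\n".join(lines) + ("\n" if lines else "")


__all__ = [
    "GeneSet",
    "JunctionConfiguration",
    "LibraryStats",
    "SlidingLibrarySpec",
    "analytic_stopfree_probability",
    "fragments_to_bed",
    "gc_base_freqs",
    "insilico_inframe_fraction",
    "junction_configurations",
    "junction_valid_fraction",
    "random_fragmentation_sim",
    "sliding_fragments",
    "stop_codon_probability",
]
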