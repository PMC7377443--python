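"""Cloning-context model and the fragment frame / stop-codon classifier.

This module defines what "in-frame" means throughout the package. A cloned
fragment sits between two adapters inside a split beta-lactamase cassette:
the upstream Bla-Alpha fragment plus a TEV-site adapter fixes the reading
frame imposed on the insert (the *cloning frame*), and a Gly-Ser spacer
adapter joins the insert to the downstream Bla-Omega fragment. A clone
survives ampicillin selection only when the insert can be translated through
to Bla-Omega, i.e. when its cloning-frame translation is free of stop codons.

Two in-frame notions are exposed:

* ``cloning_frame_open`` — no stop codon in the cloning-frame scan of the
  insert. This is the default library-selection metric.
* ``fusion_viable`` — additionally requires the insert length (mod 3) to
  keep the downstream Omega fragment in frame, when the context specifies
  that residue.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .code import (
    GeneticCode,
    STANDARD_CODE,
    STOP_SYMBOL,
    reverse_complement,
    translate,
    validate_dna,
)


class ConfigurationError(ValueError):
    """Raised when a CloningContext lacks data required by an operation."""


@dataclass(frozen=True)
class CloningContext:
    """Geometry of the split-bla cloning cassette.

    Parameters
    ----------
    adapter5, adapter3:
        Adapter sequences ligated at the insert 5' and 3' ends (the TEV-site
        duplex and the Gly-Ser spacer duplex respectively), as they appear in
        the sequenced construct.
    frame_offset:
        Codon position of the insert's first base in the fusion reading
        frame (0 means the insert starts on a codon boundary).
    required_len_mod3:
        Insert-length residue (mod 3) that keeps the downstream Omega
        fragment in frame, or ``None`` when unknown/not enforced.
    upstream_context, downstream_context:
        Optional flanking cassette sequence (tail of Bla-Alpha + linker;
        spacer + head of Bla-Omega) for full-fusion simulation.
    """

    adapter5: str
    adapter3: str
    frame_offset: int = 0
    required_len_mod3: Optional[int] = None
    upstream_context: str = ""
    downstream_context: str = ""

    def __post_init__(self) -> None:
        for name in ("adapter5", "adapter3"):
            seq = getattr(self, name).upper()
            if not seq or set(seq) - set("ACGT"):
                raise ValueError(f"{name} must be a non-empty string over ACGT")
            object.__setattr__(self, name, seq)
        for name in ("upstream_context", "downstream_context"):
            object.__setattr__(self, name, validate_dna(getattr(self, name), what=name))
        if self.frame_offset not in (0, 1, 2):
            raise ValueError("frame_offset must be 0, 1 or 2")
        if self.required_len_mod3 not in (None, 0, 1, 2):
            raise ValueError("required_len_mod3 must be None, 0, 1 or 2")

    @property
    def has_full_context(self) -> bool:
        return bool(self.upstream_context) and bool(self.downstream_context)

    @classmethod
    def from_dict(cls, d: dict) -> "CloningContext":
        known = {
            "adapter5",
            "adapter3",
            "frame_offset",
            "required_len_mod3",
            "upstream_context",
            "downstream_context",
        }
        return cls(**{k: v for k, v in d.items() if k in known})

    @classmethod
    def from_json(cls, path: str | Path) -> "CloningContext":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict:
        return {
            "adapter5": self.adapter5,
            "adapter3": self.adapter3,
            "frame_offset": self.frame_offset,
            "required_len_mod3": self.required_len_mod3,
            "upstream_context": self.upstream_context,
            "downstream_context": self.downstream_context,
        }


def default_context() -> CloningContext:
    """Synthetic default cloning context.

    The published construct ligates a 34-mer TEV-site duplex (Duplex L) and a
    31-mer Gly-Ser spacer duplex (Duplex K) to the fragment ends; the exact
    oligo sequences are not public, and the vendor lengths include ligation
    overhangs that are not retained in the open reading frame. This synthetic
    stand-in keeps the biology (a TEV protease site upstream, a (G4S)-type
    spacer downstream) with retained in-frame lengths that are multiples of
    3, so the default cassette reads as one contiguous frame and an insert of
    length ≡ 0 (mod 3) keeps Omega in frame.
    """
    return CloningContext(
        # NheI-ish flank + Ser-Gly-Ser + TEV site ENLYFQG
        adapter5="GCTAGCGGTAGCGAAAACCTGTATTTTCAGGGC",
        # (Gly4Ser)2 spacer
        adapter3="GGTGGCGGTGGCAGCGGCGGTGGCGGTTCT",
        frame_offset=0,
        required_len_mod3=0,
        # synthetic Bla-Alpha tail (starts at the fusion frame origin)
        upstream_context="ATGGCACTGGCCGAACGCATTGGC",
        # synthetic Bla-Omega head, terminated by its native stop
        downstream_context="GGCAGCCTGCTGAAAAGCGCGGGCTAA",
    )


@dataclass(frozen=True)
class Fragment:
    """A sub-sequence of a reference gene, as cloned.

    ``start``/``end`` are 0-based half-open coordinates on the reference
    forward strand; ``seq`` is the cloned sequence, i.e. already
    reverse-complemented when ``strand`` is ``'-'``.
    """

    gene_id: str
    start: int
    end: int
    strand: str
    seq: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid coordinates [{self.start}, {self.end})")
        object.__setattr__(self, "seq", validate_dna(self.seq))
        if len(self.seq) != self.end - self.start:
            raise ValueError("len(seq) must equal end - start")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class FrameCall:
    """Frame classification of one fragment or read."""

    stop_codon_positions: tuple[int, ...]
    cloning_frame_open: bool
    len_mod3: int
    fusion_viable: bool
    native_frame: Optional[bool] = None  # None = unknown (no origin given)
    ambiguous: bool = False  # sequence contained N

    def __post_init__(self) -> None:
        assert self.cloning_frame_open == (len(self.stop_codon_positions) == 0)
        assert not (self.fusion_viable and not self.cloning_frame_open)


def scan_stops(seq: str, frame_offset: int, code: GeneticCode = STANDARD_CODE) -> list[int]:
    """Codon indices (0-based, in the given frame) of stop codons in ``seq``.

    Trailing partial codons are ignored; codons containing N never count as
    stops (the caller decides how to treat ambiguity).
    """
    stops = code.stop_codons
    return [
        (i - frame_offset) // 3
        for i in range(frame_offset, len(seq) - 2, 3)
        if seq[i : i + 3] in stops
    ]


def classify_fragment(
    frag: Fragment,
    ctx: CloningContext,
    code: GeneticCode = STANDARD_CODE,
    native_origin: Optional[str] = None,
) -> FrameCall:
    """Classify a cloned fragment's reading frame in the cloning context.

    Scans the codons of ``frag.seq`` in the cloning frame (``ctx.frame_offset``
    applied), records every stop codon, and derives the open/viable flags.
    When ``native_origin`` (the source gene sequence, frame origin at base 0)
    is given, ``native_frame`` is True iff the fragment is forward-strand and
    its start coincides with the reference codon frame.
    """
    if not frag.seq:
        raise ValueError("cannot classify an empty fragment")
    stops = scan_stops(frag.seq, ctx.frame_offset, code)
    open_ = not stops
    len_mod3 = len(frag.seq) % 3
    if ctx.required_len_mod3 is None:
        viable = open_
    else:
        viable = open_ and len_mod3 == ctx.required_len_mod3
    native: Optional[bool] = None
    if native_origin is not None:
        # cloning-frame codons start at reference position start + frame_offset
        native = frag.strand == "+" and (frag.start + ctx.frame_offset) % 3 == 0
    return FrameCall(
        stop_codon_positions=tuple(stops),
        cloning_frame_open=open_,
        len_mod3=len_mod3,
        fusion_viable=viable,
        native_frame=native,
        ambiguous="N" in frag.seq,
    )


def assemble_fusion(
    frag: Fragment, ctx: CloningContext, code: GeneticCode = STANDARD_CODE
) -> str:
    """Translate the full Alpha–insert–Omega fusion, truncated at the first stop.

    Concatenates ``upstream_context + adapter5 + frag.seq + adapter3 +
    downstream_context`` and translates from the upstream frame origin
    (frame 0 of the upstream context). The returned peptide stops before the
    first stop codon, mimicking ribosomal termination.
    """
    if not ctx.has_full_context:
        raise ConfigurationError(
            "assemble_fusion requires upstream_context and downstream_context"
        )
    fusion_dna = (
        ctx.upstream_context + ctx.adapter5 + frag.seq + ctx.adapter3 + ctx.downstream_context
    )
    peptide = translate(fusion_dna, 0, code)
    stop_at = peptide.find(STOP_SYMBOL)
    return peptide if stop_at < 0 else peptide[:stop_at]


__all__ = [
    "CloningContext",
    "ConfigurationError",
    "Fragment",
    "FrameCall",
    "assemble_fusion",
    "classify_fragment",
    "default_context",
    "reverse_complement",
    "scan_stops",
]
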