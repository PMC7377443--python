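"""Genetic code table and frame-aware translation.

The default table is the standard (bacterial) code with stop codons
{TAA, TAG, TGA}, built from Biopython's codon-table data. Alternate
tables can be supplied by NCBI table id or as an explicit mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Data import CodonTable

DNA_BASES = "ACGT"
STOP_SYMBOL = "*"
UNKNOWN_SYMBOL = "X"

_VALID_CHARS = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


def _standard_table() -> dict[str, str]:
    ncbi = CodonTable.unambiguous_dna_by_id[1]
    table = dict(ncbi.forward_table)
    for codon in ncbi.stop_codons:
        table[codon] = STOP_SYMBOL
    return table


@dataclass(frozen=True)
class GeneticCode:
    """A codon→amino-acid map plus its stop-codon set.

    Invariants: exactly 64 codons mapped, stop codons are a subset of the
    mapped codons, and every stop codon translates to ``*``.
    """

    codon_table: dict[str, str] = field(default_factory=_standard_table)
    stop_codons: frozenset[str] = frozenset({"TAA", "TAG", "TGA"})

    def __post_init__(self) -> None:
        if len(self.codon_table) != 64:
            raise ValueError(
                f"codon table must map exactly 64 codons, got {len(self.codon_table)}"
            )
        object.__setattr__(self, "stop_codons", frozenset(self.stop_codons))
        missing = self.stop_codons - self.codon_table.keys()
        if missing:
            raise ValueError(f"stop codons not in codon table: {sorted(missing)}")
        for codon in self.stop_codons:
            if self.codon_table[codon] != STOP_SYMBOL:
                raise ValueError(f"stop codon {codon} does not translate to '{STOP_SYMBOL}'")

    @classmethod
    def from_ncbi_id(cls, table_id: int) -> "GeneticCode":
        ncbi = CodonTable.unambiguous_dna_by_id[table_id]
        table = dict(ncbi.forward_table)
        for codon in ncbi.stop_codons:
            table[codon] = STOP_SYMBOL
        return cls(codon_table=table, stop_codons=frozenset(ncbi.stop_codons))


STANDARD_CODE = GeneticCode()


def validate_dna(seq: str, *, what: str = "sequence") -> str:
    """Uppercase ``seq`` and reject characters outside {A,C,G,T,N}."""
    seq = seq.upper()
    bad = set(seq) - _VALID_CHARS
    if bad:
        raise ValueError(f"{what} contains non-DNA characters: {sorted(bad)}")
    return seq


def translate(seq: str, frame_offset: int = 0, code: GeneticCode = STANDARD_CODE) -> str:
    """Translate ``seq`` starting at ``frame_offset``.

    One symbol is emitted per complete codon; the trailing partial codon is
    dropped. Codons containing N yield the unknown symbol ``X``. Stop codons
    are emitted as ``*`` (no truncation here — see
    :func:`orfselect.core.assemble_fusion` for truncating translation).
    """
    if frame_offset not in (0, 1, 2):
        raise ValueError(f"frame_offset must be 0, 1 or 2, got {frame_offset}")
    seq = validate_dna(seq)
    out = []
    table = code.codon_table
    for i in range(frame_offset, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if "N" in codon:
            out.append(UNKNOWN_SYMBOL)
        else:
            out.append(table[codon])
    return "".join(out)
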