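"""File I/O: FASTA/FASTQ readers, TSV/JSON/SAM writers.

Standard formats go through Biopython; gzip-compressed FASTQ is detected by
the ``.gz`` suffix. The per-read report schema is shared between the in
silico library and the sequencing pipeline.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import Iterator, TextIO

import pandas as pd
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

FRAMECALL_COLUMNS = [
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
]


def _open_text(path: str | Path) -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: uppercase sequence} mapping."""
    with _open_text(path) as fh:
        genes = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}
    if not genes:
        raise ValueError(f"no FASTA records in {path}")
    return genes


def write_fasta(genes: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene_id, seq in genes.items():
            fh.write(f">{gene_id}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def iter_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (read_id, seq, qual) triples; id is the token before whitespace."""
    with _open_text(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            yield title.split()[0], seq.upper(), qual


def iter_fastq_pairs(
    r1_path: str | Path, r2_path: str | Path
) -> Iterator[tuple[str, str, str, str, str]]:
    """Yield (read_id, seq1, qual1, seq2, qual2) from two synced FASTQ files."""
    it1, it2 = iter_fastq(r1_path), iter_fastq(r2_path)
    for (id1, s1, q1), (id2, s2, q2) in zip(it1, it2, strict=True):
        if id1 != id2:
            raise ValueError(f"mate id mismatch: {id1!r} vs {id2!r}")
        yield id1, s1, q1, s2, q2


def write_fastq(records: list[tuple[str, str, str]], path: str | Path) -> None:
    """Write (read_id, seq, qual) records as FASTQ (gzip if path ends in .gz)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for read_id, seq, qual in records:
            fh.write(f"@{read_id}\n{seq}\n+\n{qual}\n")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_sam(alignments: pd.DataFrame, genes: dict[str, str], path: str | Path) -> None:
    """Minimal SAM export of insert alignments (one line per aligned insert).

    Uses ungapped full-length matches (<len>M CIGAR) since the mapper reports
    interval plus identity rather than a base-level alignment path.
    """
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": gid, "LN": len(seq)} for gid, seq in genes.items()],
    }
    ref_ids = {gid: i for i, gid in enumerate(genes)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for row in alignments.itertuples(index=False):
            a = pysam.AlignedSegment(out.header)
            a.query_name = row.read_id
            a.query_sequence = row.insert_seq
            a.flag = 16 if row.strand == "-" else 0
            a.reference_id = ref_ids[row.gene_id]
            a.reference_start = int(row.start)
            a.mapping_quality = 60
            a.cigarstring = f"{len(row.insert_seq)}M"
            out.write(a)
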