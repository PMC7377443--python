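"""Sequencing-analysis pipeline for amplicon fragment libraries.

Reimplements the selection-library read analysis as four pure stages:

1. merge the 2×250 paired-end mates on their overlap (quality-aware
   consensus),
2. trim the cloning adapters off the merged read by semi-global alignment
   (tolerating the small adapter indels the cloning chemistry produces),
3. map the enclosed insert to the small reference gene panel by exhaustive
   alignment of every gene on both strands (the panel is tens of genes, so
   the exact search is cheap and removes heuristic-mapper variability),
4. classify the insert's cloning frame (stop-codon scan) and aggregate
   library statistics with per-stage attrition counts.

The in-frame fraction is reported over reads that aligned to the reference,
with N-containing (ambiguous) reads excluded from the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import edlib
import numpy as np
import pandas as pd

from .code import GeneticCode, STANDARD_CODE, reverse_complement
from .core import CloningContext, Fragment, FrameCall, classify_fragment
from .io import FRAMECALL_COLUMNS, iter_fastq_pairs, read_fasta, write_json, write_tsv
from .library import LibraryStats


@dataclass(frozen=True)
class ReadPair:
    read_id: str
    seq1: str
    seq2: str
    qual1: str
    qual2: str

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError("sequence/quality length mismatch")
        if not self.seq1 or not self.seq2:
            raise ValueError("empty mate sequence")


@dataclass(frozen=True)
class MergedRead:
    read_id: str
    seq: str
    overlap_length: int
    n_mismatches_in_overlap: int


@dataclass(frozen=True)
class InsertAlignment:
    gene_id: str
    ref_start: int
    ref_end: int
    strand: str
    score: int  # negative edit distance of the best semi-global alignment
    identity: float
    ambiguous: bool = False


@dataclass(frozen=True)
class TrimResult:
    insert: str
    orientation: str  # orientation of the merged read that matched the adapters
    adapter5_edits: int
    adapter3_edits: int
    adapter5_dels: int  # bases of adapter5 missing from the read (frame-shift leak)
    adapter3_dels: int


@dataclass(frozen=True)
class PipelineConfig:
    """Stage thresholds. The published pipeline states none; these defaults
    are explicit, conservative substitutes and all are configurable."""

    min_overlap: int = 20
    max_mismatch_rate: float = 0.1
    adapter_max_errors: int = 3
    min_identity: float = 0.85
    min_insert_len: int = 20

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        names = set(cls.__dataclass_fields__)
        return cls(**{k: v for k, v in d.items() if k in names})


def merge_pair(
    pair: ReadPair, min_overlap: int = 20, max_mismatch_rate: float = 0.1
) -> Optional[MergedRead]:
    """Merge a read pair on the overlap maximizing the number of matches.

    Mate 2 is reverse-complemented, then every candidate overlap length in
    [min_overlap, min(len1, len2)] is scored; the merge succeeds when the
    best overlap's mismatch rate is within ``max_mismatch_rate``. Ties on
    match count prefer the lower mismatch rate, then the longer overlap.
    Disagreements in the overlap take the higher-quality base (mate 1 wins
    ties). Returns None when no overlap qualifies.
    """
    s1 = pair.seq1
    s2 = reverse_complement(pair.seq2)
    q2 = pair.qual2[::-1]
    n1, n2 = len(s1), len(s2)
    a1 = np.frombuffer(s1.encode(), dtype=np.uint8)
    a2 = np.frombuffer(s2.encode(), dtype=np.uint8)

    best_key: Optional[tuple] = None
    best: Optional[tuple[int, int]] = None  # (overlap, mismatches)
    for o in range(min_overlap, min(n1, n2) + 1):
        mism = int(np.count_nonzero(a1[n1 - o :] != a2[:o]))
        if mism > max_mismatch_rate * o:
            continue
        key = (o - mism, -mism / o, o)
        if best_key is None or key > best_key:
            best_key, best = key, (o, mism)
    if best is None:
        return None
    o, mism = best
    tail1, head2 = s1[n1 - o :], s2[:o]
    if mism == 0:
        consensus = tail1
    else:
        qt1, qh2 = pair.qual1[n1 - o :], q2[:o]
        consensus = "".join(
            b1 if b1 == b2 or qt1[i] >= qh2[i] else b2
            for i, (b1, b2) in enumerate(zip(tail1, head2))
        )
    merged = s1[: n1 - o] + consensus + s2[o:]
    return MergedRead(pair.read_id, merged, o, mism)


def _locate_adapter(
    adapter: str, seq: str, max_errors: int, end: str
) -> Optional[tuple[int, int, int, int]]:
    """Best semi-global match of ``adapter`` inside ``seq``.

    Returns (start, end_exclusive, edits, deletions_in_read) or None.
    ``end`` selects the leftmost ('5') or rightmost ('3') optimal location.
    """
    res = edlib.align(adapter, seq, mode="HW", task="path", k=max_errors)
    if res["editDistance"] < 0:
        return None
    loc = res["locations"][0] if end == "5" else res["locations"][-1]
    # query=adapter vs target=read: 'I' = adapter base absent from the read
    cigar = res["cigar"] or ""
    dels = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            if ch == "I":
                dels += int(num)
            num = ""
    return loc[0], loc[1] + 1, res["editDistance"], dels


def trim_adapters(
    merged: MergedRead | str, ctx: CloningContext, max_errors: int = 3
) -> Optional[TrimResult]:
    """Locate both cloning adapters and return the enclosed insert.

    Each adapter may differ from its reference sequence by at most
    ``max_errors`` edits (the cloning chemistry leaves 1–2 bp adapter
    deletions in a fraction of clones; these are recovered and reported in
    the deletion counts). If the 5' adapter is not found in the forward
    orientation the reverse complement of the merged read is tried, so the
    result does not depend on which mate led. Returns None when either
    adapter is missing in both orientations.
    """
    seq = merged.seq if isinstance(merged, MergedRead) else merged
    for orientation, s in (("+", seq), ("-", reverse_complement(seq))):
        hit5 = _locate_adapter(ctx.adapter5, s, max_errors, "5")
        if hit5 is None:
            continue
        hit3 = _locate_adapter(ctx.adapter3, s, max_errors, "3")
        if hit3 is None:
            continue
        start5, end5, edits5, dels5 = hit5
        start3, end3, edits3, dels3 = hit3
        if start3 < end5:  # adapters overlap — no insert between them
            insert = ""
        else:
            insert = s[end5:start3]
        return TrimResult(insert, orientation, edits5, edits3, dels5, dels3)
    return None


def map_insert(
    insert: str,
    genes: Mapping[str, str],
    min_identity: float = 0.85,
    min_insert_len: int = 20,
) -> Optional[InsertAlignment]:
    """Exhaustively align ``insert`` to every gene on both strands.

    The best-scoring (lowest edit distance) semi-global alignment wins;
    candidates tying on distance are resolved by lexicographic gene id then
    lower reference start, and the result is flagged ambiguous. Returns None
    for inserts that are too short or align below ``min_identity``.
    """
    if not genes:
        raise ValueError("empty gene set")
    if len(insert) < min_insert_len:
        return None
    max_dist = int(len(insert) * (1.0 - min_identity))
    best_dist = max_dist + 1
    candidates: list[tuple[str, int, int, str]] = []  # (gene_id, start, end, strand)
    for gene_id, gene_seq in genes.items():
        for strand, target in (("+", gene_seq), ("-", reverse_complement(gene_seq))):
            res = edlib.align(insert, target, mode="HW", task="locations", k=best_dist)
            dist = res["editDistance"]
            if dist < 0:
                continue
            locs = sorted(set(res["locations"]))
            G = len(gene_seq)
            coords = []
            for s, e in locs:
                if strand == "+":
                    coords.append((s, e + 1))
                else:
                    coords.append((G - 1 - e, G - s))
            if dist < best_dist:
                best_dist = dist
                candidates = [(gene_id, c[0], c[1], strand) for c in coords]
            elif dist == best_dist:
                candidates.extend((gene_id, c[0], c[1], strand) for c in coords)
    if not candidates or best_dist > max_dist:
        return None
    candidates.sort(key=lambda c: (c[0], c[1]))
    gene_id, ref_start, ref_end, strand = candidates[0]
    return InsertAlignment(
        gene_id=gene_id,
        ref_start=ref_start,
        ref_end=ref_end,
        strand=strand,
        score=-best_dist,
        identity=1.0 - best_dist / len(insert),
        ambiguous=len(candidates) > 1,
    )


@dataclass
class PipelineResult:
    stats: LibraryStats
    attrition: dict[str, int]
    per_read: pd.DataFrame

    @property
    def open_fraction(self) -> float:
        return self.stats.open_fraction

    def summary(self) -> dict:
        out = self.stats.to_dict()
        out["attrition"] = dict(self.attrition)
        return out


def classify_insert(
    insert: str, ctx: CloningContext, code: GeneticCode = STANDARD_CODE
) -> FrameCall:
    """Frame-classify a trimmed insert in the cloning frame (no origin info)."""
    frag = Fragment("insert", 0, len(insert), "+", insert)
    return classify_fragment(frag, ctx, code)


def run_pipeline(
    r1: str | Path,
    r2: str | Path,
    reference: str | Path | Mapping[str, str],
    ctx: CloningContext,
    config: PipelineConfig = PipelineConfig(),
    code: GeneticCode = STANDARD_CODE,
) -> PipelineResult:
    """Merge → trim → map → classify every read pair and aggregate stats.

    ``reference`` may be a FASTA path or an in-memory {gene_id: CDS} mapping.
    The per-read table records a status for every input pair; attrition
    counts are monotone (pairs ≥ merged ≥ trimmed ≥ aligned ≥ classified).
    """
    genes = reference if isinstance(reference, Mapping) else read_fasta(reference)
    if not genes:
        raise ValueError("empty reference gene set")

    attrition = {"total_pairs": 0, "merged": 0, "trimmed": 0, "aligned": 0, "classified": 0}
    rows: list[dict] = []
    stats = LibraryStats()

    for read_id, s1, q1, s2, q2 in iter_fastq_pairs(r1, r2):
        attrition["total_pairs"] += 1
        row: dict = {"read_id": read_id, "status": None}
        pair = ReadPair(read_id, s1, s2, q1, q2)
        merged = merge_pair(pair, config.min_overlap, config.max_mismatch_rate)
        if merged is None:
            row["status"] = "merge_failed"
            rows.append(row)
            continue
        attrition["merged"] += 1
        trimmed = trim_adapters(merged, ctx, config.adapter_max_errors)
        if trimmed is None:
            row["status"] = "adapter_missing"
            rows.append(row)
            continue
        if not trimmed.insert:
            row["status"] = "empty_insert"
            rows.append(row)
            continue
        attrition["trimmed"] += 1
        row["adapter5_edits"] = trimmed.adapter5_edits
        row["adapter3_edits"] = trimmed.adapter3_edits
        row["adapter5_dels"] = trimmed.adapter5_dels
        aln = map_insert(trimmed.insert, genes, config.min_identity, config.min_insert_len)
        if aln is None:
            row["status"] = "unaligned"
            rows.append(row)
            continue
        attrition["aligned"] += 1
        call = classify_insert(trimmed.insert, ctx, code)
        attrition["classified"] += 1
        # orientation relative to the reference combines the trim orientation
        # with the alignment strand of the insert as sequenced
        strand = aln.strand
        native = strand == "+" and (aln.ref_start + ctx.frame_offset) % 3 == 0
        frag = Fragment(aln.gene_id, aln.ref_start, aln.ref_end, strand,
                        genes[aln.gene_id][aln.ref_start:aln.ref_end]
                        if strand == "+"
                        else reverse_complement(genes[aln.gene_id][aln.ref_start:aln.ref_end]))
        stats.add(frag, call.cloning_frame_open, call.fusion_viable, call.ambiguous)
        row.update(
            status="ok",
            gene_id=aln.gene_id,
            start=aln.ref_start,
            end=aln.ref_end,
            strand=strand,
            length=len(trimmed.insert),
            len_mod3=call.len_mod3,
            n_stops=len(call.stop_codon_positions),
            cloning_frame_open=call.cloning_frame_open,
            fusion_viable=call.fusion_viable,
            native_frame=native,
            identity=round(aln.identity, 4),
            score=aln.score,
            map_ambiguous=aln.ambiguous,
            insert_seq=trimmed.insert,
        )
        rows.append(row)

    if attrition["total_pairs"] == 0:
        raise ValueError("no read pairs in input FASTQ")
    columns = ["read_id", "status"] + FRAMECALL_COLUMNS[1:] + [
        "identity", "score", "map_ambiguous",
        "adapter5_edits", "adapter3_edits", "adapter5_dels", "insert_seq",
    ]
    per_read = pd.DataFrame(rows).reindex(columns=columns)
    return PipelineResult(stats=stats, attrition=attrition, per_read=per_read)


def write_pipeline_outputs(
    result: PipelineResult,
    out_dir: str | Path,
    genes: Optional[Mapping[str, str]] = None,
    sam: bool = False,
) -> None:
    """Write the per-read TSV, summary JSON and (optionally) a SAM export."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_tsv(result.per_read.drop(columns=["insert_seq"]), out_dir / "per_read.tsv")
    write_json(result.summary(), out_dir / "library_stats.json")
    if sam:
        if genes is None:
            raise ValueError("SAM export requires the reference gene set")
        from .io import write_sam

        aligned = result.per_read[result.per_read["status"] == "ok"]
        write_sam(aligned, dict(genes), out_dir / "inserts.sam")


__all__ = [
    "InsertAlignment",
    "MergedRead",
    "PipelineConfig",
    "PipelineResult",
    "ReadPair",
    "TrimResult",
    "classify_insert",
    "map_insert",
    "merge_pair",
    "run_pipeline",
    "trim_adapters",
    "write_pipeline_outputs",
]
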