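"""Intron extraction from gene annotation and splice-junction read counting.

The per-intron unit of analysis is the gap between two consecutive annotated
exons of a transcript.  For each intron and alignment file three junction read
counts are collected:

``eejr``
    exon-exon junction reads: gapped alignments whose N-operation spans the
    intron exactly (spliced mRNA evidence).
``eijr`` / ``iejr``
    exon-intron / intron-exon junction reads: contiguous alignments crossing
    the intron's genomic start / end boundary (retained pre-mRNA evidence).

Coordinates are 0-based half-open internally; GTF input is 1-based inclusive
and SAM input 1-based (conversions happen only at the I/O boundary).
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

#: CIGAR operations the counter understands (M, I, D, N, S, H, =, X)
_SUPPORTED_OPS = {0, 1, 2, 3, 4, 5, 7, 8}
_CONSUME_REF_CONTIGUOUS = {0, 2, 7, 8}  # M, D, =, X extend the current block


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation input."""


@dataclass(frozen=True)
class IntronRecord:
    """One annotated intron.

    ``start``/``end`` are genomic, 0-based half-open.  ``index`` is the
    1-based position of the intron among its transcript's introns counted
    from the transcript 5' end (so on '-' transcripts the highest-coordinate
    gap has index 1).  On '+' the splice donor sits at ``start``, on '-' at
    ``end``.
    """

    intron_id: str
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    index: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise AnnotationError(
                f"intron {self.intron_id}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.strand not in {"+", "-"}:
            raise AnnotationError(f"intron {self.intron_id}: bad strand {self.strand!r}")
        if self.index < 1:
            raise AnnotationError(f"intron {self.intron_id}: index must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start


def introns_to_frame(introns: Sequence[IntronRecord]) -> pd.DataFrame:
    """Tabular view of intron records (intron_id, chrom, start, end, strand, index, length)."""
    return pd.DataFrame(
        {
            "intron_id": [i.intron_id for i in introns],
            "gene_id": [i.gene_id for i in introns],
            "chrom": [i.chrom for i in introns],
            "start": [i.start for i in introns],
            "end": [i.end for i in introns],
            "strand": [i.strand for i in introns],
            "index": [i.index for i in introns],
            "length": [i.length for i in introns],
        }
    )


def extract_introns(gtf: str | Path) -> list[IntronRecord]:
    """Derive introns from the exon features of a GTF file.

    One intron per gap between consecutive exons of each transcript,
    deduplicated on (chrom, start, end, strand) across transcripts of the
    same gene.  Zero-length gaps (book-ended exons) are skipped with a
    warning.
    """
    with open(gtf) as fh:  # gffutils drops malformed lines silently
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise AnnotationError(
                    f"{gtf}: line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            if not (fields[3].isdigit() and fields[4].isdigit()):
                raise AnnotationError(f"{gtf}: line {lineno}: non-numeric coordinates")
    try:
        db = gffutils.create_db(
            str(gtf),
            ":memory:",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
            keep_order=True,
        )
    except Exception as exc:  # gffutils reports the offending line in its message
        raise AnnotationError(f"failed to parse GTF {gtf}: {exc}") from exc

    # group exons per (gene, transcript); gffutils coordinates are 1-based inclusive
    transcripts: dict[tuple[str, str], list] = {}
    for exon in db.features_of_type("exon"):
        try:
            gene_id = exon.attributes["gene_id"][0]
            tx_id = exon.attributes["transcript_id"][0]
        except KeyError as exc:
            raise AnnotationError(
                f"exon at {exon.seqid}:{exon.start}-{exon.end} lacks {exc} attribute"
            ) from exc
        transcripts.setdefault((gene_id, tx_id), []).append(exon)

    introns: list[IntronRecord] = []
    seen: dict[str, set[tuple[str, int, int, str]]] = {}
    for (gene_id, tx_id), exons in transcripts.items():
        exons.sort(key=lambda e: e.start)
        for a, b in zip(exons, exons[1:]):
            if b.start <= a.end:
                raise AnnotationError(
                    f"transcript {tx_id}: overlapping exons "
                    f"{a.seqid}:{a.start}-{a.end} and {b.seqid}:{b.start}-{b.end}"
                )
        strand = exons[0].strand
        gaps = []  # internal half-open coordinates
        for a, b in zip(exons, exons[1:]):
            start, end = a.end, b.start - 1  # 1-based inclusive -> 0-based half-open
            if end <= start:
                logger.warning("transcript %s: zero-length gap at %s:%d skipped", tx_id, a.seqid, a.end)
                continue
            gaps.append((a.seqid, start, end))
        if strand == "-":
            gaps = gaps[::-1]  # index 1 = 5'-most intron of the transcript
        gene_seen = seen.setdefault(gene_id, set())
        for idx, (chrom, start, end) in enumerate(gaps, start=1):
            key = (chrom, start, end, strand)
            if key in gene_seen:
                continue
            gene_seen.add(key)
            introns.append(
                IntronRecord(
                    intron_id=f"{gene_id}.i{idx}",
                    gene_id=gene_id,
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    index=idx,
                )
            )
    introns.sort(key=lambda i: (i.chrom, i.start, i.end))
    return introns


class _IntronIndex:
    """Per-chromosome lookup structures for the counter."""

    def __init__(self, introns: Sequence[IntronRecord]):
        self.gap: dict[tuple[str, int, int], int] = {}
        self.starts: dict[str, tuple[list[int], list[int]]] = {}
        self.ends: dict[str, tuple[list[int], list[int]]] = {}
        by_chrom_start: dict[str, list[tuple[int, int]]] = {}
        by_chrom_end: dict[str, list[tuple[int, int]]] = {}
        for ordinal, intr in enumerate(introns):
            self.gap[(intr.chrom, intr.start, intr.end)] = ordinal
            by_chrom_start.setdefault(intr.chrom, []).append((intr.start, ordinal))
            by_chrom_end.setdefault(intr.chrom, []).append((intr.end, ordinal))
        for chrom, pairs in by_chrom_start.items():
            pairs.sort()
            self.starts[chrom] = ([p for p, _ in pairs], [o for _, o in pairs])
        for chrom, pairs in by_chrom_end.items():
            pairs.sort()
            self.ends[chrom] = ([p for p, _ in pairs], [o for _, o in pairs])

    def in_range(self, table, chrom: str, lo: int, hi: int) -> Iterable[int]:
        """Ordinals of introns whose indexed position lies in [lo, hi]."""
        if chrom not in table:
            return ()
        positions, ordinals = table[chrom]
        return ordinals[bisect_left(positions, lo) : bisect_right(positions, hi)]


def _read_blocks_and_gaps(read: pysam.AlignedSegment):
    """Contiguous reference blocks and N-gap intervals of one alignment.

    Deletions extend the current block (a small D still covers the junction
    for retention purposes); only N splits blocks.  Returns None for CIGARs
    with unsupported operations.
    """
    blocks: list[tuple[int, int]] = []
    gaps: list[tuple[int, int]] = []
    pos = read.reference_start
    cur_start = pos
    cur_end = pos
    for op, length in read.cigartuples:
        if op not in _SUPPORTED_OPS:
            return None
        if op in _CONSUME_REF_CONTIGUOUS:
            cur_end += length
        elif op == 3:  # N: splice gap
            blocks.append((cur_start, cur_end))
            gaps.append((cur_end, cur_end + length))
            cur_start = cur_end + length
            cur_end = cur_start
        # I, S, H do not consume reference
    blocks.append((cur_start, cur_end))
    return blocks, gaps


def count_junctions_in_file(
    alignments: str | Path | pysam.AlignmentFile,
    introns: Sequence[IntronRecord],
    min_anchor: int = 5,
):
    """Count EEJR/EIJR/IEJR per intron for one SAM/BAM file.

    A gapped alignment scores ``eejr`` for intron *i* iff one of its N gaps
    equals [start, end) of *i* exactly and both flanking aligned blocks span
    at least ``min_anchor`` nt.  A contiguous block scores ``eijr`` iff it
    covers [start - min_anchor, start + min_anchor) and ``iejr`` iff it covers
    [end - min_anchor, end + min_anchor).  A read contributes at most one
    junction type per intron, with deterministic priority
    eejr > eijr > iejr.  Secondary, supplementary and unmapped records are
    ignored; reads with unsupported CIGAR operations or unknown reference
    names are skipped and tallied.

    Returns ``(counts, skipped)`` where ``counts`` is an (n_introns, 3) list
    of [eejr, eijr, iejr] and ``skipped`` a dict of skip reasons.
    """
    if min_anchor < 1:
        raise ValueError("min_anchor must be >= 1")
    index = _IntronIndex(introns)
    counts = [[0, 0, 0] for _ in introns]
    skipped = {"unsupported_cigar": 0, "unknown_reference": 0}
    known_chroms = set(index.starts) | set(index.ends)

    own_handle = not isinstance(alignments, pysam.AlignmentFile)
    af = pysam.AlignmentFile(str(alignments), "r") if own_handle else alignments
    try:
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            chrom = read.reference_name
            if chrom not in known_chroms:
                if chrom not in af.references:
                    skipped["unknown_reference"] += 1
                continue
            parsed = _read_blocks_and_gaps(read)
            if parsed is None:
                skipped["unsupported_cigar"] += 1
                continue
            blocks, gaps = parsed
            assigned: dict[int, int] = {}  # intron ordinal -> column
            for k, (gs, ge) in enumerate(gaps):
                ordinal = index.gap.get((chrom, gs, ge))
                if ordinal is None:
                    continue
                left = blocks[k][1] - blocks[k][0]
                right = blocks[k + 1][1] - blocks[k + 1][0]
                if left >= min_anchor and right >= min_anchor:
                    assigned[ordinal] = 0  # eejr
            for bs, be in blocks:
                if be - bs < 2 * min_anchor:
                    continue
                lo, hi = bs + min_anchor, be - min_anchor
                for ordinal in index.in_range(index.starts, chrom, lo, hi):
                    assigned.setdefault(ordinal, 1)  # eijr
                for ordinal in index.in_range(index.ends, chrom, lo, hi):
                    assigned.setdefault(ordinal, 2)  # iejr
            for ordinal, col in assigned.items():
                counts[ordinal][col] += 1
    finally:
        if own_handle:
            af.close()
    return counts, skipped


def count_junctions(
    samples: pd.DataFrame,
    introns: Sequence[IntronRecord],
    min_anchor: int = 5,
) -> pd.DataFrame:
    """Junction counts for a set of samples.

    ``samples`` needs columns ``sample_id``, ``condition``, ``replicate`` and
    ``path`` (SAM/BAM).  The result has one row per intron x sample, including
    zero-count rows, with columns intron_id, chrom, start, end, strand,
    length, sample_id, condition, replicate, eejr, eijr, iejr.
    """
    required = {"sample_id", "condition", "replicate", "path"}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"sample sheet misses columns: {sorted(missing)}")
    if samples["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in sample sheet")

    frames = []
    base = introns_to_frame(introns).drop(columns=["gene_id", "index"])
    for row in samples.itertuples(index=False):
        counts, skipped = count_junctions_in_file(row.path, introns, min_anchor=min_anchor)
        if any(skipped.values()):
            logger.warning("sample %s: skipped reads %s", row.sample_id, skipped)
        df = base.copy()
        df["sample_id"] = row.sample_id
        df["condition"] = row.condition
        df["replicate"] = row.replicate
        df["eejr"] = [c[0] for c in counts]
        df["eijr"] = [c[1] for c in counts]
        df["iejr"] = [c[2] for c in counts]
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def filter_low_coverage(
    counts: pd.DataFrame, min_total: int = 10, all_introns=None
) -> tuple[set[str], set[str]]:
    """Split introns into kept / low-coverage sets.

    An intron is kept iff in *every* condition the sum of eejr + eijr + iejr
    over that condition's replicates reaches ``min_total`` (strictly fewer
    reads drops it).  Introns absent from ``counts`` cannot be kept; pass
    ``all_introns`` (ids or IntronRecords) to have them reported in the
    dropped set.
    """
    totals = (
        counts.assign(total=counts["eejr"] + counts["eijr"] + counts["iejr"])
        .groupby(["intron_id", "condition"], sort=False)["total"]
        .sum()
        .unstack(fill_value=0)
    )
    ok = (totals >= min_total).all(axis=1)
    kept = set(totals.index[ok])
    dropped = set(totals.index[~ok])
    if all_introns is not None:
        ids = {i.intron_id if isinstance(i, IntronRecord) else i for i in all_introns}
        dropped |= ids - kept
    return kept, dropped
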