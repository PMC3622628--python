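"""SAM / FASTA input: streaming per-read alignment groups against a
transcript catalog.

Alignments are single-end, possibly multi-mapping, aligned directly to
transcript sequences (no spliced genome coordinates). Positions are stored
0-based; SAM POS is converted on read. The parser requires records of one
read to be consecutive (aligner default order); :func:`sort_sam_by_name`
is provided for files that are not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pysam
from Bio import SeqIO

from .model import TranscriptCatalog

logger = logging.getLogger(__name__)

FORWARD = "forward"
REVERSE = "reverse"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class SamFormatError(ValueError):
    """Malformed or inconsistent SAM input."""


@dataclass
class ReadAlignmentGroup:
    """All candidate alignments of one read.

    ``transcripts``, ``starts`` and ``reverse`` are parallel arrays over
    the candidates (transcript index in the catalog, 0-based start of the
    leftmost aligned base, reverse-strand flag).
    """

    read_id: str
    transcripts: np.ndarray
    starts: np.ndarray
    reverse: np.ndarray
    sample_tag: str = "pure"

    def __post_init__(self) -> None:
        self.transcripts = np.asarray(self.transcripts, dtype=np.int64)
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.reverse = np.asarray(self.reverse, dtype=bool)
        if not (len(self.transcripts) == len(self.starts) == len(self.reverse)):
            raise ValueError("candidate arrays must be parallel")
        if len(self.transcripts) < 1:
            raise ValueError("a group must contain at least one candidate")

    @property
    def candidates(self) -> list[tuple[int, int, str]]:
        return [
            (int(t), int(p), REVERSE if r else FORWARD)
            for t, p, r in zip(self.transcripts, self.starts, self.reverse)
        ]

    def __len__(self) -> int:
        return len(self.transcripts)


@dataclass
class AlignmentStreamStats:
    """Counters accumulated while parsing one SAM file."""

    total_reads: int = 0
    aligned_reads: int = 0
    multimapped_reads: int = 0
    skipped_reads: int = 0
    out_of_range_alignments: int = 0
    truncated_groups: int = 0


def load_catalog(fasta_path: str) -> TranscriptCatalog:
    """Read a transcript catalog from FASTA; ids are the first header token."""
    ids: list[str] = []
    seqs: list[str] = []
    for rec in SeqIO.parse(fasta_path, "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
    if not ids:
        raise ValueError(f"no FASTA records found in {fasta_path}")
    lengths = np.array([len(s) for s in seqs], dtype=np.int64)
    return TranscriptCatalog(ids=tuple(ids), lengths=lengths, sequences=tuple(seqs))


def sort_sam_by_name(in_path: str, out_path: str) -> None:
    """Name-sort a SAM file (text output) so reads can be streamed in groups."""
    pysam.sort("-n", "-O", "sam", "-o", out_path, in_path)


def _finish_group(
    read_id: str,
    records: list[tuple[int, int, bool]],
    sample_tag: str,
    max_candidates: int,
    stats: AlignmentStreamStats,
) -> ReadAlignmentGroup:
    seen: set[tuple[int, int]] = set()
    kept: list[tuple[int, int, bool]] = []
    for t, p, r in records:
        key = (t, p)
        if key in seen:
            continue
        seen.add(key)
        kept.append((t, p, r))
    if len(kept) > max_candidates:
        kept = kept[:max_candidates]
        stats.truncated_groups += 1
    if len(kept) > 1:
        stats.multimapped_reads += 1
    stats.aligned_reads += 1
    t, p, r = zip(*kept)
    return ReadAlignmentGroup(
        read_id=read_id,
        transcripts=np.array(t, dtype=np.int64),
        starts=np.array(p, dtype=np.int64),
        reverse=np.array(r, dtype=bool),
        sample_tag=sample_tag,
    )


def parse_sam(
    path: str,
    catalog: TranscriptCatalog,
    max_candidates: int = 10,
    sample_tag: str = "pure",
    stats: AlignmentStreamStats | None = None,
    read_length_hint: int | None = None,
) -> Iterator[ReadAlignmentGroup]:
    """Stream per-read alignment groups from a name-grouped SAM file.

    Unaligned reads are counted as skipped; duplicate (transcript, start)
    candidates are dropped; at most ``max_candidates`` candidates are kept
    per read, in file order. Reference names absent from the catalog are a
    hard error.
    """
    if stats is None:
        stats = AlignmentStreamStats()
    index = catalog.index_map()
    lengths = catalog.lengths

    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        header_refs = list(sam.references or [])
        unknown = [r for r in header_refs if r not in index]
        if unknown:
            raise SamFormatError(
                f"SAM references absent from catalog: {', '.join(unknown[:10])}"
            )
        current_id: str | None = None
        current: list[tuple[int, int, bool]] = []
        record_no = 0
        iterator = sam.fetch(until_eof=True)
        while True:
            try:
                rec = next(iterator)
            except StopIteration:
                break
            except ValueError as exc:  # pragma: no cover - defensive
                raise SamFormatError(
                    f"malformed SAM record near record {record_no + 1} in {path}: {exc}"
                ) from exc
            record_no += 1
            qname = rec.query_name
            if qname is None:
                raise SamFormatError(f"record {record_no} in {path} has no QNAME")
            if qname != current_id:
                if current_id is not None:
                    stats.total_reads += 1
                    if current:
                        yield _finish_group(
                            current_id, current, sample_tag, max_candidates, stats
                        )
                    else:
                        stats.skipped_reads += 1
                current_id = qname
                current = []
            if rec.is_unmapped:
                continue
            ref = rec.reference_name
            if ref not in index:
                raise SamFormatError(
                    f"record {record_no} in {path}: reference {ref!r} not in catalog"
                )
            t = index[ref]
            pos = rec.reference_start  # already 0-based in pysam
            if pos < 0 or pos >= lengths[t]:
                raise SamFormatError(
                    f"record {record_no} in {path}: POS outside transcript {ref!r}"
                )
            rlen = rec.query_length or read_length_hint or 0
            if rlen and pos + rlen > lengths[t]:
                stats.out_of_range_alignments += 1
            current.append((t, pos, rec.is_reverse))
        if current_id is not None:
            stats.total_reads += 1
            if current:
                yield _finish_group(current_id, current, sample_tag, max_candidates, stats)
            else:
                stats.skipped_reads += 1


def load_alignments(
    path: str,
    catalog: TranscriptCatalog,
    max_candidates: int = 10,
    sample_tag: str = "pure",
) -> tuple[list[ReadAlignmentGroup], AlignmentStreamStats]:
    """Materialize :func:`parse_sam` output along with its counters."""
    stats = AlignmentStreamStats()
    groups = list(
        parse_sam(path, catalog, max_candidates=max_candidates, sample_tag=sample_tag, stats=stats)
    )
    return groups, stats


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def local_sequence(
    catalog: TranscriptCatalog,
    transcript_index: int,
    start_pos: int,
    strand: str,
    window_L: int,
) -> str:
    """Window of length ``window_L`` centered at an alignment start.

    Forward-strand windows are read off the transcript as-is; reverse-strand
    windows are the reverse complement of the window centered at the read's
    5' position. Positions beyond the transcript ends are padded with N.
    """
    if catalog.sequences is None:
        raise ValueError(
            "catalog has no sequences; provide a FASTA with sequences or disable the bias module"
        )
    if window_L < 1 or window_L % 2 == 0:
        raise ValueError("window_L must be a positive odd integer")
    seq = catalog.sequences[transcript_index]
    half = window_L // 2
    lo = start_pos - half
    hi = start_pos + half + 1
    left_pad = max(0, -lo)
    right_pad = max(0, hi - len(seq))
    window = "N" * left_pad + seq[max(0, lo) : min(len(seq), hi)] + "N" * right_pad
    if strand == REVERSE:
        window = reverse_complement(window)
    elif strand != FORWARD:
        raise ValueError(f"unknown strand {strand!r}")
    return window
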