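"""Lightweight aligned-read container decoupled from BAM I/O.

The encoder, prefilter and germline filter all operate on ``Read`` objects so
they can be tested on in-memory data; :func:`from_alignment` and
:func:`to_alignment` bridge to pysam at the BAM boundary.

CIGAR operations use the pysam integer codes: 0=M, 1=I, 2=D, 4=S.
Only M/I/D are produced by the simulator; soft clips are tolerated on input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pysam

CIGAR_MATCH = 0
CIGAR_INS = 1
CIGAR_DEL = 2
CIGAR_SOFTCLIP = 4

_CONSUMES_QUERY = {0, 1, 4, 7, 8}
_CONSUMES_REF = {0, 2, 3, 7, 8}


@dataclass
class Read:
    name: str
    contig: str
    start: int  # 0-based leftmost aligned reference position
    seq: str
    quals: np.ndarray  # phred per base, len == len(seq)
    cigar: list[tuple[int, int]]  # [(op, length), ...]
    mapq: int
    is_reverse: bool

    @property
    def end(self) -> int:
        """0-based exclusive end on the reference."""
        return self.start + sum(n for op, n in self.cigar if op in _CONSUMES_REF)

    def overlaps(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def aligned_pairs(self):
        """Yield (query_index, ref_pos) pairs, None on the unaligned side.

        Matches pysam ``get_aligned_pairs`` semantics for M/I/D/S.
        """
        q, r = 0, self.start
        for op, n in self.cigar:
            if op in (0, 7, 8):
                for _ in range(n):
                    yield q, r
                    q += 1
                    r += 1
            elif op in (CIGAR_INS, CIGAR_SOFTCLIP):
                for _ in range(n):
                    yield q, None
                    q += 1
            elif op in (CIGAR_DEL, 3):
                for _ in range(n):
                    yield None, r
                    r += 1

    def base_at(self, pos: int):
        """Query (base, qual) aligned over reference ``pos``.

        Returns ``("-", None)`` inside a deletion and ``None`` if the read
        does not cover the position.
        """
        if not self.overlaps(pos):
            return None
        q, r = 0, self.start
        for op, n in self.cigar:
            if op in (0, 7, 8):
                if r <= pos < r + n:
                    i = q + (pos - r)
                    return self.seq[i], int(self.quals[i])
                q += n
                r += n
            elif op in (CIGAR_INS, CIGAR_SOFTCLIP):
                q += n
            elif op in (CIGAR_DEL, 3):
                if r <= pos < r + n:
                    return "-", None
                r += n
        return None


def from_alignment(aln: pysam.AlignedSegment) -> Read:
    quals = aln.query_qualities
    return Read(
        name=aln.query_name,
        contig=aln.reference_name,
        start=aln.reference_start,
        seq=aln.query_sequence,
        quals=np.asarray(quals, dtype=np.int16)
        if quals is not None
        else np.full(len(aln.query_sequence), 30, dtype=np.int16),
        cigar=list(aln.cigartuples or []),
        mapq=aln.mapping_quality,
        is_reverse=aln.is_reverse,
    )


def to_alignment(read: Read, header: pysam.AlignmentHeader) -> pysam.AlignedSegment:
    a = pysam.AlignedSegment(header)
    a.query_name = read.name
    a.query_sequence = read.seq
    a.reference_id = header.get_tid(read.contig)
    a.reference_start = read.start
    a.mapping_quality = read.mapq
    a.cigartuples = read.cigar
    a.query_qualities = pysam.qualitystring_to_array(
        "".join(chr(q + 33) for q in read.quals)
    )
    a.flag = 16 if read.is_reverse else 0
    # single-end records: mate fields carry placeholder values
    a.next_reference_id = -1
    a.next_reference_start = -1
    a.template_length = 0
    return a


def fetch_reads(bam_path: str, contig: str, start: int = None, end: int = None) -> list[Read]:
    """Load reads from an indexed BAM into memory, coordinate order."""
    with pysam.AlignmentFile(bam_path, "rb") as bam:
        return [
            from_alignment(a)
            for a in bam.fetch(contig, start, end)
            if not a.is_unmapped
        ]
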