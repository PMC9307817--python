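"""Germline-contamination post-filter for somatic callsets.

For each somatic call the matched normal is scanned in a +/-10 bp window for
alleles with significant representation — strictly greater than 10% of the
quality-passing reads at that locus. Calls that overlap, or lie within one
base pair of, such a suspected germline SNP or indel are flagged
``GERMLINE_PROX``; everything else keeps its filter. Flagging is
non-destructive (records are retained) and idempotent.

Detection reuses the prefilter's quality gates (base quality >= 15, mapping
quality >= 10) and requires no local re-assembly.
"""

from __future__ import annotations

from dataclasses import replace

from .reads import Read
from .sites import GenomicSite, VariantCall
from .variants import left_align

GERMLINE_WINDOW_BP = 10
GERMLINE_MIN_FRACTION = 0.10
GERMLINE_PROXIMITY_BP = 1

_QUALITY_MIN_BQ = 15
_QUALITY_MIN_MAPQ = 10


def _column_counts(reads: list[Read], pos: int) -> tuple[dict[str, int], int]:
    """Quality-gated base counts and depth at one position."""
    counts: dict[str, int] = {}
    depth = 0
    for read in reads:
        if read.mapq < _QUALITY_MIN_MAPQ:
            continue
        hit = read.base_at(pos)
        if hit is None:
            continue
        base, qual = hit
        if base != "-" and (qual is None or qual < _QUALITY_MIN_BQ):
            continue
        depth += 1
        counts[base] = counts.get(base, 0) + 1
    return counts, depth


def _indel_events(reads: list[Read], lo: int, hi: int, reference: str) -> dict[tuple, int]:
    events: dict[tuple, int] = {}
    for read in reads:
        if read.mapq < _QUALITY_MIN_MAPQ:
            continue
        q, r = 0, read.start
        for op, ln in read.cigar:
            if op in (0, 7, 8):
                q += ln
                r += ln
            elif op in (1, 4):
                if op == 1 and r > 0 and lo <= r - 1 < hi:
                    anchor = r - 1
                    key = left_align(
                        anchor, reference[anchor], reference[anchor] + read.seq[q : q + ln], reference
                    )
                    events[key] = events.get(key, 0) + 1
                q += ln
            elif op in (2, 3):
                if r > 0 and lo <= r - 1 < hi:
                    anchor = r - 1
                    key = left_align(
                        anchor, reference[anchor] + reference[r : r + ln], reference[anchor], reference
                    )
                    events[key] = events.get(key, 0) + 1
                r += ln
    return events


def detect_normal_variants(
    normal_reads: list[Read],
    call_site: GenomicSite,
    reference: str,
    window_bp: int = GERMLINE_WINDOW_BP,
    min_fraction: float = GERMLINE_MIN_FRACTION,
) -> list[GenomicSite]:
    """Suspected germline variants near a call.

    Scans positions within ``+/-window_bp`` of the call locus and returns
    non-reference alleles whose read fraction in the normal strictly exceeds
    ``min_fraction`` (a fraction of exactly ``min_fraction`` is not
    germline-like). SNPs and short indels are both reported; returns an empty
    list when the normal has no coverage.
    """
    found: list[GenomicSite] = []
    lo = max(0, call_site.pos - window_bp)
    hi = min(len(reference), call_site.pos + window_bp + 1)
    nearby = [r for r in normal_reads if r.start < hi and r.end > lo]
    for pos in range(lo, hi):
        counts, depth = _column_counts(nearby, pos)
        if depth == 0:
            continue
        ref_base = reference[pos]
        for base, n in sorted(counts.items()):
            if base in (ref_base, "-"):
                continue
            if n / depth > min_fraction:
                found.append(GenomicSite(call_site.contig, pos, ref_base, base))
    for (pos, ref_a, alt_a), n in sorted(_indel_events(nearby, lo, hi, reference).items()):
        _, depth = _column_counts(nearby, pos)
        if depth and n / depth > min_fraction:
            found.append(GenomicSite(call_site.contig, pos, ref_a, alt_a))
    return found


def _span(site: GenomicSite) -> tuple[int, int]:
    """Closed interval of reference positions affected by a variant."""
    if site.variant_class.value == "INS":
        return site.pos, site.pos  # insertion sits between pos and pos+1
    return site.pos, site.end - 1


def _within(a: GenomicSite, b: GenomicSite, proximity_bp: int) -> bool:
    a0, a1 = _span(a)
    b0, b1 = _span(b)
    if a0 <= b1 and b0 <= a1:
        return True  # overlap
    gap = b0 - a1 if b0 > a1 else a0 - b1
    return gap <= proximity_bp


def apply_germline_filter(
    calls: list[VariantCall],
    normal_reads: list[Read],
    reference: str,
    proximity_bp: int = GERMLINE_PROXIMITY_BP,
    window_bp: int = GERMLINE_WINDOW_BP,
    min_fraction: float = GERMLINE_MIN_FRACTION,
) -> list[VariantCall]:
    """Flag calls that overlap or sit within ``proximity_bp`` of a detected
    germline variant; all records are retained."""
    out: list[VariantCall] = []
    for call in calls:
        germline = detect_normal_variants(
            normal_reads, call.site, reference, window_bp, min_fraction
        )
        hit = any(_within(call.site, g, proximity_bp) for g in germline)
        if hit:
            out.append(replace(call, filter="GERMLINE_PROX"))
        else:
            new_filter = "PASS" if call.filter == "GERMLINE_PROX" else call.filter
            out.append(replace(call, filter=new_filter))
    return out
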