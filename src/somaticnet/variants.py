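"""Variant representation normalization.

Indels can be written at several equivalent positions inside repeat tracts
(e.g. a 1 bp deletion in ``ATTT`` may be anchored at any T). Candidate
emission, truth matching and the set arithmetic behind weak labels all key
variants by a single canonical form: parsimony-trimmed and left-aligned
against the reference, with a VCF-style anchor base for indels.
"""

from __future__ import annotations

from .sites import GenomicSite


def trim(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Remove shared suffix then shared prefix bases (keeping one anchor base
    for indels)."""
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def left_align(pos: int, ref: str, alt: str, reference: str) -> tuple[int, str, str]:
    """Shift a trimmed indel to its leftmost equivalent position.

    ``reference`` is the full contig sequence (0-based indexing). SNVs and
    balanced substitutions are returned unchanged.
    """
    pos, ref, alt = trim(pos, ref, alt)
    if len(ref) == len(alt):
        return pos, ref, alt
    while ref and alt and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
        dropped = ref[-1]
        ref, alt = ref[:-1], alt[:-1]
        if not ref or not alt:
            if pos == 0:
                # cannot extend past the contig start; restore the base
                ref, alt = ref + dropped, alt + dropped
                break
            prev = reference[pos - 1]
            pos -= 1
            ref, alt = prev + ref, prev + alt
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt, pos = ref[1:], alt[1:], pos + 1
    return pos, ref, alt


def normalize_site(site: GenomicSite, reference: str | None) -> GenomicSite:
    """Canonical (trimmed, left-aligned) representation of a site.

    Without a reference sequence only trimming is possible.
    """
    if reference is None:
        pos, ref, alt = trim(site.pos, site.ref, site.alt)
    else:
        pos, ref, alt = left_align(site.pos, site.ref, site.alt, reference)
    if pos == site.pos and ref == site.ref and alt == site.alt:
        return site
    return GenomicSite(site.contig, pos, ref, alt)


def site_key(site: GenomicSite, reference: str | None = None) -> tuple[str, int, str, str]:
    """Identity used for set operations: contig + normalized pos/ref/alt."""
    n = normalize_site(site, reference)
    return (n.contig, n.pos, n.ref, n.alt)
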