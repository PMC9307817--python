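"""First-pass candidate scan of the tumor/normal pileup.

Walks every reference position, tallies quality-gated allele counts in both
samples, and emits candidate sites that show minimal tumor alternate-allele
support without germline-like representation in the normal. The scan is
deliberately permissive: its job is to discard the overwhelming majority of
positions that cannot plausibly be somatic while keeping essentially every
true mutation for the classifier to judge.

Indel candidates are keyed by their parsimony-trimmed, left-aligned
representation so they match truth/VCF conventions downstream; events longer
than 35 bp are dropped because the encoder cannot represent them in-place.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .reads import Read
from .sites import GenomicSite
from .variants import left_align

_BASE_IDX = np.full(128, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_IDX[ord(_b)] = _i


@dataclass
class PrefilterThresholds:
    min_alt_reads_tumor: int = 2
    min_alt_fraction_tumor: float = 0.02
    min_base_quality: int = 15
    min_mapping_quality: int = 10
    max_alt_fraction_normal: float = 0.25
    max_indel_len: int = 35

    def __post_init__(self) -> None:
        if self.min_alt_reads_tumor < 1:
            raise ValueError("min_alt_reads_tumor must be >= 1")
        for name in ("min_alt_fraction_tumor", "max_alt_fraction_normal"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")


@dataclass
class ColumnSummary:
    """Per-allele pileup summary at one locus, quality gates applied."""

    depth: int
    alt_count: int


@dataclass
class CandidateSite:
    site: GenomicSite
    tumor_alt_count: int
    tumor_depth: int
    normal_alt_count: int
    normal_depth: int

    @property
    def variant_class(self):
        return self.site.variant_class


def site_passes(
    tumor: ColumnSummary,
    normal: ColumnSummary,
    thresholds: PrefilterThresholds,
) -> tuple[bool, str]:
    """Pure decision core of the scan; the reason names the failed rule."""
    if tumor.depth == 0:
        return False, "no_tumor_coverage"
    if tumor.alt_count < thresholds.min_alt_reads_tumor:
        return False, "low_alt_reads"
    if tumor.alt_count / tumor.depth < thresholds.min_alt_fraction_tumor:
        return False, "low_alt_fraction"
    normal_fraction = normal.alt_count / normal.depth if normal.depth else 0.0
    if normal_fraction > thresholds.max_alt_fraction_normal:
        return False, "normal_alt_excess"
    return True, "pass"


def _count_sample(
    reads: list[Read],
    contig_length: int,
    thresholds: PrefilterThresholds,
    reference: str,
) -> tuple[np.ndarray, dict]:
    """Quality-gated base counts (L,4) and indel event counts per sample."""
    counts = np.zeros(contig_length * 4, dtype=np.int32)
    indels: dict[tuple[int, str, str], int] = {}
    chunk: list[np.ndarray] = []
    chunk_n = 0

    def flush() -> None:
        nonlocal chunk, chunk_n
        if chunk:
            flat = np.concatenate(chunk)
            counts[:] += np.bincount(flat, minlength=counts.size).astype(np.int32)
            chunk = []
            chunk_n = 0

    for read in reads:
        if read.mapq < thresholds.min_mapping_quality:
            continue
        seq_idx = _BASE_IDX[np.frombuffer(read.seq.encode(), dtype=np.uint8)]
        quals = np.asarray(read.quals)
        q, r = 0, read.start
        for op, ln in read.cigar:
            if op in (0, 7, 8):  # M
                idx = seq_idx[q : q + ln]
                ok = (idx >= 0) & (quals[q : q + ln] >= thresholds.min_base_quality)
                pos = np.arange(r, r + ln)[ok]
                chunk.append(pos * 4 + idx[ok])
                chunk_n += ok.sum()
                q += ln
                r += ln
            elif op in (1, 4):  # I / S
                if op == 1 and r > 0:
                    anchor = r - 1
                    ins = read.seq[q : q + ln]
                    p, ref_a, alt_a = left_align(
                        anchor, reference[anchor], reference[anchor] + ins, reference
                    )
                    key = (p, ref_a, alt_a)
                    indels[key] = indels.get(key, 0) + 1
                q += ln
            elif op in (2, 3):  # D / N
                if r > 0:
                    anchor = r - 1
                    deleted = reference[r : r + ln]
                    p, ref_a, alt_a = left_align(
                        anchor, reference[anchor] + deleted, reference[anchor], reference
                    )
                    key = (p, ref_a, alt_a)
                    indels[key] = indels.get(key, 0) + 1
                r += ln
        if chunk_n > 2_000_000:
            flush()
    flush()
    return counts.reshape(contig_length, 4), indels


def load_bed(path: str) -> list[tuple[str, int, int]]:
    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            regions.append((parts[0], int(parts[1]), int(parts[2])))
    return regions


def _region_mask(
    regions, contig: str, contig_length: int
) -> np.ndarray | None:
    if regions is None:
        return None
    if isinstance(regions, str):
        regions = load_bed(regions)
    mask = np.zeros(contig_length, dtype=bool)
    seen_contig = False
    for c, s, e in regions:
        if c == contig:
            seen_contig = True
            mask[max(0, s) : min(contig_length, e)] = True
    if regions and not seen_contig:
        names = sorted({c for c, _, _ in regions})
        raise ValueError(
            f"BED regions reference contig(s) {names}, none matching reference contig {contig!r}"
        )
    return mask


def scan_candidates(
    tumor_reads: list[Read],
    normal_reads: list[Read],
    reference: str,
    thresholds: PrefilterThresholds | None = None,
    regions=None,
    contig: str = "chr1",
) -> list[CandidateSite]:
    """Scan the pileup and emit candidate somatic sites, coordinate-sorted.

    ``regions`` may be a BED path or a list of (contig, start, end) 0-based
    half-open intervals; positions outside them are never emitted.
    """
    th = thresholds or PrefilterThresholds()
    L = len(reference)
    mask = _region_mask(regions, contig, L)
    t_counts, t_indels = _count_sample(tumor_reads, L, th, reference)
    n_counts, n_indels = _count_sample(normal_reads, L, th, reference)
    t_depth = t_counts.sum(axis=1)
    n_depth = n_counts.sum(axis=1)
    ref_idx = _BASE_IDX[np.frombuffer(reference.encode(), dtype=np.uint8)]

    candidates: list[CandidateSite] = []
    # SNVs: vectorized pre-screen, exact rules re-applied via site_passes
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = t_counts / np.maximum(t_depth, 1)[:, None]
    alt_hit = (t_counts >= th.min_alt_reads_tumor) & (frac >= th.min_alt_fraction_tumor)
    pos_grid = np.arange(L)
    alt_hit[pos_grid[ref_idx >= 0], ref_idx[ref_idx >= 0]] = False  # ref allele is not an alt
    alt_hit[ref_idx < 0, :] = False
    if mask is not None:
        alt_hit[~mask, :] = False
    for pos, b in zip(*np.nonzero(alt_hit)):
        tumor = ColumnSummary(int(t_depth[pos]), int(t_counts[pos, b]))
        normal = ColumnSummary(int(n_depth[pos]), int(n_counts[pos, b]))
        ok, _ = site_passes(tumor, normal, th)
        if ok:
            site = GenomicSite(contig, int(pos), reference[pos], "ACGT"[b])
            candidates.append(
                CandidateSite(site, tumor.alt_count, tumor.depth, normal.alt_count, normal.depth)
            )

    for (pos, ref_a, alt_a), count in t_indels.items():
        if abs(len(ref_a) - len(alt_a)) > th.max_indel_len:
            continue
        if mask is not None and not mask[pos]:
            continue
        tumor = ColumnSummary(int(t_depth[pos]), count)
        normal = ColumnSummary(int(n_depth[pos]), n_indels.get((pos, ref_a, alt_a), 0))
        ok, _ = site_passes(tumor, normal, th)
        if ok:
            site = GenomicSite(contig, int(pos), ref_a, alt_a)
            candidates.append(
                CandidateSite(site, tumor.alt_count, tumor.depth, normal.alt_count, normal.depth)
            )

    candidates.sort(key=lambda c: (c.site.pos, c.site.ref, c.site.alt))
    return candidates
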