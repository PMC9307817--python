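"""Tumor/normal pileup-image encoder.

Each candidate site becomes a fixed-shape numeric image: reads are rows,
alignment columns are columns, and five channels carry base identity, base
quality, mapping quality, strand, and the local reference base. The normal
sample occupies the left half of the width and the tumor the right half, so
the classifier sees both samples in one tensor.

Layout
------
SNV images are ``(100, 70, 5)``: 100 read rows per sample, 35 columns per
sample. The candidate locus is repeated in 5 adjacent columns (amplifying the
signal at the candidate), flanked by 15 reference-context columns on each
side. Indel images are ``(140, 150, 5)``: 140 rows, 75 columns per sample,
with the candidate anchor at column 37 of each half and indels encoded
in-place — inserted bases consume their own columns immediately right of the
anchor (marked in the reference channel with a no-reference sentinel) and
deleted bases show a dedicated deletion code. Indels longer than 35 bp do not
fit and are rejected. Repetition is applied to SNV images only, since it
would interact with the variable width of in-place indels.

Coverage above the row budget (100 reads per sample for SNVs, 140 for
indels) is handled by seeded uniform subsampling; missing rows are padded
with zeros in every channel.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .reads import Read
from .sites import GenomicSite, VariantClass

_CODES = {
    "A": 0.25,
    "C": 0.50,
    "G": 0.75,
    "T": 1.00,
    "deletion": -0.50,
    "padding": 0.00,
    "no_reference": -1.00,
}

PAD = _CODES["padding"]
DEL_CODE = _CODES["deletion"]
NO_REF = _CODES["no_reference"]

_BASE_LUT = np.zeros(128, dtype=np.float32)
for _b in "ACGT":
    _BASE_LUT[ord(_b)] = _CODES[_b]
_BASE_LUT[ord("-")] = DEL_CODE  # internal deletion marker


def channel_codes() -> dict[str, float]:
    """Numeric codes for base symbols and sentinels.

    Injective over {A, C, G, T, deletion, padding, no_reference}; all values
    in [-1, 1]; identical across processes (no hash salting involved).
    """
    return dict(_CODES)


@dataclass
class EncodingConfig:
    """Shape and channel constants of the pileup images."""

    snv_rows: int = 100          # reads per sample
    snv_width: int = 70          # both samples side by side
    snv_repeat: int = 5          # candidate-locus columns per read
    indel_rows: int = 140
    indel_width: int = 150
    indel_anchor_col: int = 37   # candidate anchor column within a half
    max_indel_len: int = 35
    channels: tuple[str, ...] = (
        "base",
        "base_quality",
        "mapping_quality",
        "strand",
        "reference_base",
    )
    seed: int = 0

    @property
    def snv_half(self) -> int:
        return self.snv_width // 2

    @property
    def snv_flank(self) -> int:
        return (self.snv_half - self.snv_repeat) // 2

    @property
    def indel_half(self) -> int:
        return self.indel_width // 2

    def __post_init__(self) -> None:
        if self.snv_width != 2 * self.snv_half or self.indel_width != 2 * self.indel_half:
            raise ValueError("widths must be even (two samples side by side)")
        if self.max_indel_len > self.indel_half - 1:
            raise ValueError("max_indel_len must fit within one half-image")


@dataclass
class SiteEncoding:
    """The multi-channel image for one candidate plus provenance."""

    values: np.ndarray  # (rows, width, 5) float32 in [-1, 1]
    site: GenomicSite
    n_tumor_reads_used: int
    n_normal_reads_used: int
    subsampled: bool = False

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


def _name_hash(name: str) -> int:
    # crc32, not hash(): stable across processes
    return zlib.crc32(name.encode())


def subsample_reads(reads: list[Read], cap: int, rng: np.random.Generator) -> list[Read]:
    """Uniformly subsample to ``cap`` reads, preserving input order.

    Returns the input list unchanged (same objects) when it already fits.
    """
    if cap <= 0:
        raise ValueError("cap must be > 0")
    if len(reads) <= cap:
        return list(reads)
    idx = rng.choice(len(reads), size=cap, replace=False)
    return [reads[i] for i in np.sort(idx)]


def _read_codes(read: Read) -> np.ndarray:
    codes = getattr(read, "_codes", None)
    if codes is None:
        codes = _BASE_LUT[np.frombuffer(read.seq.encode(), dtype=np.uint8)]
        read._codes = codes
    return codes


def _ref_codes(reference: str, start: int, end: int) -> np.ndarray:
    start_c, end_c = max(start, 0), min(end, len(reference))
    out = np.zeros(end - start, dtype=np.float32)
    if end_c > start_c:
        seg = _BASE_LUT[np.frombuffer(reference[start_c:end_c].encode(), dtype=np.uint8)]
        out[start_c - start : end_c - start] = seg
    return out


def _walk_window(read: Read, wstart: int, wend: int):
    """Per-reference-position view of a read inside [wstart, wend).

    Returns (bases, quals) arrays of length wend-wstart where bases are
    channel codes (deletion code inside deletions, PAD outside the read) —
    insertions carried by the read do not appear (they have no reference
    column in the SNV layout).
    """
    n = wend - wstart
    bases = np.full(n, PAD, dtype=np.float32)
    quals = np.zeros(n, dtype=np.float32)
    if len(read.cigar) == 1 and read.cigar[0][0] == 0:
        lo, hi = max(wstart, read.start), min(wend, read.end)
        if hi > lo:
            codes = _read_codes(read)
            bases[lo - wstart : hi - wstart] = codes[lo - read.start : hi - read.start]
            quals[lo - wstart : hi - wstart] = read.quals[lo - read.start : hi - read.start]
        return bases, quals
    q, r = 0, read.start
    for op, ln in read.cigar:
        if op in (0, 7, 8):  # M
            lo, hi = max(r, wstart), min(r + ln, wend)
            if hi > lo:
                codes = _read_codes(read)
                bases[lo - wstart : hi - wstart] = codes[q + lo - r : q + hi - r]
                quals[lo - wstart : hi - wstart] = read.quals[q + lo - r : q + hi - r]
            q += ln
            r += ln
        elif op in (1, 4):  # I / S consume query only
            q += ln
        elif op in (2, 3):  # D / N consume reference only
            lo, hi = max(r, wstart), min(r + ln, wend)
            if hi > lo:
                bases[lo - wstart : hi - wstart] = DEL_CODE
            r += ln
    return bases, quals


def _order_reads(reads: list[Read]) -> list[Read]:
    return sorted(reads, key=lambda r: (r.start, _name_hash(r.name)))


def _fill_common_channels(half: np.ndarray, row: int, covered: np.ndarray, read: Read) -> None:
    half[row, :, 2] = np.where(covered, min(read.mapq, 60) / 60.0, 0.0)
    half[row, :, 3] = np.where(covered, -1.0 if read.is_reverse else 1.0, 0.0)


def _encode_snv_half(
    site: GenomicSite,
    reads: list[Read],
    reference: str,
    config: EncodingConfig,
) -> np.ndarray:
    W, F, R = config.snv_half, config.snv_flank, config.snv_repeat
    half = np.zeros((config.snv_rows, W, 5), dtype=np.float32)
    wstart, wend = site.pos - F, site.pos + F + 1
    # column -> window offset; candidate occupies F..F+R-1
    col_off = np.concatenate(
        [np.arange(F), np.full(R, F), np.arange(F + 1, 2 * F + 1)]
    ).astype(int)
    ref_win = _ref_codes(reference, wstart, wend)
    ref_cols = ref_win[col_off]
    for i, read in enumerate(reads[: config.snv_rows]):
        bases, quals = _walk_window(read, wstart, wend)
        half[i, :, 0] = bases[col_off]
        half[i, :, 1] = np.clip(quals[col_off] / 40.0, 0.0, 1.0)
        covered = bases[col_off] != PAD
        _fill_common_channels(half, i, covered, read)
        half[i, :, 4] = ref_cols
    return half


def encode_indel_inplace(
    read: Read,
    site: GenomicSite,
    reference: str,
    config: EncodingConfig | None = None,
) -> np.ndarray:
    """Encode one read row of an indel image, in-place layout.

    Returns a ``(indel_half, 5)`` array. Columns advance with every aligned
    element of the read (match, insertion, deletion), anchored so the
    candidate position sits at ``indel_anchor_col``; flanking context is
    truncated on the right to keep the fixed width. Inserted columns carry
    the no-reference sentinel in the reference channel; deleted reference
    columns carry the deletion code in the base channel.
    """
    config = config or EncodingConfig()
    if site.indel_length > config.max_indel_len:
        raise ValueError(
            f"indel length {site.indel_length} exceeds the {config.max_indel_len} bp in-place limit"
        )
    W, A = config.indel_half, config.indel_anchor_col
    row = np.zeros((W, 5), dtype=np.float32)
    # default reference channel: global column->position map (no insertions)
    row[:, 4] = _ref_codes(reference, site.pos - A, site.pos - A + W)

    # pileup-space walk of the read: every M/I/D element takes one column
    cols_base: list[float] = []
    cols_qual: list[float] = []
    cols_ref: list[float] = []
    anchor_idx = None
    q, r = 0, read.start
    codes = _read_codes(read)
    for op, ln in read.cigar:
        if op in (0, 7, 8):
            for k in range(ln):
                if r == site.pos:
                    anchor_idx = len(cols_base)
                cols_base.append(float(codes[q]))
                cols_qual.append(float(read.quals[q]))
                cols_ref.append(float(_BASE_LUT[ord(reference[r])]) if r < len(reference) else PAD)
                q += 1
                r += 1
        elif op in (1, 4):
            if op == 1:
                for k in range(ln):
                    cols_base.append(float(codes[q]))
                    cols_qual.append(float(read.quals[q]))
                    cols_ref.append(NO_REF)
                    q += 1
            else:
                q += ln
        elif op in (2, 3):
            for k in range(ln):
                if r == site.pos:
                    anchor_idx = len(cols_base)
                cols_base.append(DEL_CODE)
                cols_qual.append(0.0)
                cols_ref.append(float(_BASE_LUT[ord(reference[r])]) if r < len(reference) else PAD)
                r += 1
    if anchor_idx is None:
        # read does not cover the anchor: align by reference projection
        anchor_idx = site.pos - read.start
    shift = A - anchor_idx
    n = len(cols_base)
    lo, hi = max(0, -shift), min(n, W - shift)
    if hi > lo:
        sl = slice(lo + shift, hi + shift)
        row[sl, 0] = cols_base[lo:hi]
        row[sl, 1] = np.clip(np.array(cols_qual[lo:hi]) / 40.0, 0.0, 1.0)
        row[sl, 4] = cols_ref[lo:hi]
        covered = row[:, 0] != PAD
        row[:, 2] = np.where(covered, min(read.mapq, 60) / 60.0, 0.0)
        row[:, 3] = np.where(covered, -1.0 if read.is_reverse else 1.0, 0.0)
    return row


def _encode_indel_half(
    site: GenomicSite,
    reads: list[Read],
    reference: str,
    config: EncodingConfig,
) -> np.ndarray:
    half = np.zeros((config.indel_rows, config.indel_half, 5), dtype=np.float32)
    for i, read in enumerate(reads[: config.indel_rows]):
        half[i] = encode_indel_inplace(read, site, reference, config)
    return half


def encode_site(
    site: GenomicSite,
    tumor_reads: list[Read],
    normal_reads: list[Read],
    reference: str,
    config: EncodingConfig | None = None,
    rng: np.random.Generator | None = None,
) -> SiteEncoding:
    """Encode one candidate site as a normal|tumor side-by-side image.

    ``tumor_reads``/``normal_reads`` should be the reads overlapping the
    candidate locus; reads not overlapping the encoded window contribute
    padding. Deterministic given ``rng`` (used only for subsampling above
    the row budget). Zero tumor coverage yields an all-padding tumor half;
    the caller decides what to do with such sites.
    """
    config = config or EncodingConfig()
    rng = rng or np.random.default_rng(config.seed)
    if not 0 <= site.pos < len(reference):
        raise ValueError(f"site {site} beyond contig of length {len(reference)}")
    is_snv = site.variant_class == VariantClass.SNV
    cap = config.snv_rows if is_snv else config.indel_rows
    t_overlap = [r for r in tumor_reads if r.overlaps(site.pos)]
    n_overlap = [r for r in normal_reads if r.overlaps(site.pos)]
    subsampled = len(t_overlap) > cap or len(n_overlap) > cap
    t_use = _order_reads(subsample_reads(t_overlap, cap, rng))
    n_use = _order_reads(subsample_reads(n_overlap, cap, rng))
    if is_snv:
        halves = (
            _encode_snv_half(site, n_use, reference, config),
            _encode_snv_half(site, t_use, reference, config),
        )
    else:
        halves = (
            _encode_indel_half(site, n_use, reference, config),
            _encode_indel_half(site, t_use, reference, config),
        )
    values = np.concatenate(halves, axis=1)
    return SiteEncoding(
        values=values,
        site=site,
        n_tumor_reads_used=len(t_use),
        n_normal_reads_used=len(n_use),
        subsampled=subsampled,
    )


class ReadIndex:
    """Sorted-start index for fast 'reads overlapping position' queries."""

    def __init__(self, reads: list[Read]):
        self.reads = sorted(reads, key=lambda r: r.start)
        self.starts = np.array([r.start for r in self.reads], dtype=np.int64)
        self.max_span = max((r.end - r.start for r in self.reads), default=0)

    def overlapping(self, pos: int) -> list[Read]:
        lo = np.searchsorted(self.starts, pos - self.max_span, side="left")
        hi = np.searchsorted(self.starts, pos, side="right")
        return [r for r in self.reads[lo:hi] if r.overlaps(pos)]
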