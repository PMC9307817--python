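"""Synthetic matched tumor/normal read simulator.

Generates a random reference contig, plants germline variants (shared by both
samples) and somatic SNVs/indels (tumor only, at designed allele fractions),
then synthesizes pre-aligned single-end reads with exact CIGARs, per-base
qualities, mapping qualities and uniform sequencing errors. Because reads are
emitted already aligned, the whole pipeline is exercised offline and
deterministically; no external aligner runs.

Sampling model
--------------
Read starts are uniform over the contig, so interior coverage is ~Binomial
around the configured depth. A tumor read overlapping a somatic site carries
the alternate allele with probability ``designed_vaf * purity``; germline
heterozygous sites are carried with probability 0.5 in both samples
(independent per read — phasing between neighboring variants is not
simulated). Sequencing errors are uniform substitutions at
``base_error_rate`` per base, with qualities drawn from the same law as
correct bases.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pysam

from .reads import CIGAR_DEL, CIGAR_INS, CIGAR_MATCH, Read, to_alignment
from .sites import GenomicSite, TruthSet, TruthVariant
from .variants import normalize_site

BASES = np.array(list("ACGT"))

# distribution laws are (name, *params) tuples so they survive YAML round trips
Law = tuple


def sample_law(law: Law, rng: np.random.Generator, size: int):
    """Draw ``size`` samples from a (name, *params) distribution spec.

    Supported: ("constant", v), ("uniform", lo, hi), ("uniform_int", lo, hi)
    (inclusive bounds), ("geometric", p) (support 1,2,...), ("normal", mu, sd).
    """
    name, *p = law
    if name == "constant":
        return np.full(size, p[0])
    if name == "uniform":
        return rng.uniform(p[0], p[1], size)
    if name == "uniform_int":
        return rng.integers(p[0], p[1] + 1, size)
    if name == "geometric":
        return rng.geometric(p[0], size)
    if name == "normal":
        return rng.normal(p[0], p[1], size)
    raise ValueError(f"unknown distribution law: {name!r}")


@dataclass
class SimConfig:
    """All simulator knobs.

    Depths are mean fold-coverages; ``purity`` is the fraction of tumor-sample
    cells that are cancerous (somatic alleles appear at ``vaf * purity``).
    Indel lengths are clipped to 1..35 to match the encoder's in-place limit.
    """

    contig: str = "chr1"
    contig_length: int = 100_000
    depth_tumor: float = 60.0
    depth_normal: float = 40.0
    read_length: int = 100
    purity: float = 1.0
    somatic_snv_count: int = 50
    somatic_indel_count: int = 10
    indel_length_law: Law = ("geometric", 0.35)
    vaf_law: Law = ("uniform", 0.2, 0.6)
    germline_het_rate: float = 1e-3
    germline_hom_rate: float = 3e-4
    base_error_rate: float = 0.002
    quality_law: Law = ("uniform_int", 25, 40)
    mapq_law: Law = ("constant", 60)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("purity", "germline_het_rate", "germline_hom_rate", "base_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.depth_tumor <= 0 or self.depth_normal <= 0:
            raise ValueError("depths must be > 0")
        if self.contig_length < 2 * self.read_length:
            raise ValueError(
                f"contig_length {self.contig_length} too short for "
                f"read_length {self.read_length}"
            )


MAX_SIM_INDEL = 35
_MIN_VARIANT_SPACING = 50  # keeps planted variants independently resolvable


def _plant_variants(reference: np.ndarray, config: SimConfig, rng: np.random.Generator) -> TruthSet:
    L = config.contig_length
    margin = config.read_length
    truth: list[TruthVariant] = []
    taken: dict[int, int] = {}  # bin index (pos // spacing) -> pos

    def place(n: int) -> np.ndarray:
        chosen = []
        attempts = 0
        while len(chosen) < n and attempts < 200 * n + 1000:
            pos = int(rng.integers(margin, L - margin))
            b = pos // _MIN_VARIANT_SPACING
            ok = all(
                abs(pos - taken[bb]) >= _MIN_VARIANT_SPACING
                for bb in (b - 1, b, b + 1)
                if bb in taken
            )
            if ok:
                taken[b] = pos
                chosen.append(pos)
            attempts += 1
        if len(chosen) < n:
            raise ValueError("contig too short to place requested variants")
        return np.array(sorted(chosen), dtype=int)

    # germline SNPs (het and hom) across the usable interior
    n_het = rng.binomial(L - 2 * margin, config.germline_het_rate)
    n_hom = rng.binomial(L - 2 * margin, config.germline_hom_rate)
    for pos in place(n_het):
        ref = reference[pos]
        alt = str(rng.choice(BASES[BASES != ref]))
        truth.append(TruthVariant(GenomicSite(config.contig, int(pos), str(ref), alt), 0.5, "germline"))
    for pos in place(n_hom):
        ref = reference[pos]
        alt = str(rng.choice(BASES[BASES != ref]))
        truth.append(TruthVariant(GenomicSite(config.contig, int(pos), str(ref), alt), 1.0, "germline"))

    vafs = np.clip(sample_law(config.vaf_law, rng, config.somatic_snv_count + config.somatic_indel_count), 0.01, 1.0)
    for i, pos in enumerate(place(config.somatic_snv_count)):
        ref = reference[pos]
        alt = str(rng.choice(BASES[BASES != ref]))
        truth.append(TruthVariant(GenomicSite(config.contig, int(pos), str(ref), alt), float(vafs[i]), "somatic"))
    lens = np.clip(
        sample_law(config.indel_length_law, rng, config.somatic_indel_count), 1, MAX_SIM_INDEL
    ).astype(int)
    ref_str = "".join(reference)
    for j, pos in enumerate(place(config.somatic_indel_count)):
        anchor = str(reference[pos])
        if rng.random() < 0.5:  # insertion
            ins = "".join(rng.choice(BASES, lens[j]))
            site = GenomicSite(config.contig, int(pos), anchor, anchor + ins)
        else:
            deleted = "".join(reference[pos + 1 : pos + 1 + lens[j]])
            site = GenomicSite(config.contig, int(pos), anchor + deleted, anchor)
        # store the canonical representation so truth matches VCF conventions
        truth.append(
            TruthVariant(
                normalize_site(site, ref_str),
                float(vafs[config.somatic_snv_count + j]),
                "somatic",
            )
        )
    truth.sort(key=lambda v: v.site.pos)
    return TruthSet(truth)


def _synthesize_reads(
    reference: str,
    truth: TruthSet,
    depth: float,
    config: SimConfig,
    rng: np.random.Generator,
    carry_somatic: bool,
    prefix: str,
) -> list[Read]:
    L = config.contig_length
    rl = config.read_length
    n_reads = int(round(depth * L / rl))
    starts = np.sort(rng.integers(0, L - rl + 1, n_reads))
    mapqs = np.clip(sample_law(config.mapq_law, rng, n_reads), 0, 60).astype(int)
    strands = rng.random(n_reads) < 0.5

    # events indexed by anchor position
    events = {v.site.pos: v for v in truth.variants if carry_somatic or v.origin == "germline"}
    event_pos = np.array(sorted(events), dtype=int)

    reads: list[Read] = []
    for i in range(n_reads):
        s = int(starts[i])
        # candidate events whose anchor lies inside the read span (indel
        # anchors need a following base, so exclude the last position)
        lo = np.searchsorted(event_pos, s)
        hi = np.searchsorted(event_pos, s + rl)
        carried: dict[int, GenomicSite] = {}
        for pos in event_pos[lo:hi]:
            v = events[int(pos)]
            p_carry = v.designed_vaf if v.origin == "germline" else v.designed_vaf * config.purity
            if v.site.variant_class.value != "SNV" and pos >= s + rl - 1:
                continue
            if rng.random() < p_carry:
                carried[int(pos)] = v.site

        if not carried:
            seq = list(reference[s : s + rl])
            cigar = [(CIGAR_MATCH, rl)]
        else:
            seq = []
            cigar = []

            def emit(op: int, n: int) -> None:
                if cigar and cigar[-1][0] == op:
                    cigar[-1] = (op, cigar[-1][1] + n)
                else:
                    cigar.append((op, n))

            pos = s
            while len(seq) < rl and pos < L:
                site = carried.get(pos)
                if site is None:
                    seq.append(reference[pos])
                    emit(CIGAR_MATCH, 1)
                    pos += 1
                elif site.variant_class.value == "SNV":
                    seq.append(site.alt)
                    emit(CIGAR_MATCH, 1)
                    pos += 1
                elif len(site.alt) > len(site.ref):  # insertion after anchor
                    seq.append(reference[pos])
                    emit(CIGAR_MATCH, 1)
                    ins = site.alt[1:][: rl - len(seq)]
                    if ins:
                        seq.extend(ins)
                        emit(CIGAR_INS, len(ins))
                    pos += 1
                else:  # deletion after anchor
                    seq.append(reference[pos])
                    emit(CIGAR_MATCH, 1)
                    d = len(site.ref) - 1
                    pos += 1
                    if len(seq) < rl and pos + d <= L:
                        emit(CIGAR_DEL, d)
                        pos += d
            while cigar and cigar[-1][0] == CIGAR_DEL:
                cigar.pop()

        nbases = len(seq)
        quals = np.clip(sample_law(config.quality_law, rng, nbases), 2, 40).astype(np.int16)
        n_err = rng.binomial(nbases, config.base_error_rate)
        if n_err:
            for j in rng.choice(nbases, size=min(n_err, nbases), replace=False):
                seq[j] = str(rng.choice(BASES[BASES != seq[j]]))
        reads.append(
            Read(
                name=f"{prefix}{i:07d}",
                contig=config.contig,
                start=s,
                seq="".join(seq),
                quals=quals,
                cigar=cigar,
                mapq=int(mapqs[i]),
                is_reverse=bool(strands[i]),
            )
        )
    return reads


def simulate_pair(config: SimConfig) -> tuple[str, list[Read], list[Read], TruthSet]:
    """Simulate a matched pair.

    Returns ``(reference_sequence, normal_reads, tumor_reads, truth)`` with
    reads in coordinate order. Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    ref_arr = rng.choice(BASES, config.contig_length)
    truth = _plant_variants(ref_arr, config, rng)
    reference = "".join(ref_arr)
    normal = _synthesize_reads(
        reference, truth, config.depth_normal, config, rng, carry_somatic=False, prefix="n"
    )
    tumor = _synthesize_reads(
        reference, truth, config.depth_tumor, config, rng, carry_somatic=True, prefix="t"
    )
    return reference, normal, tumor, truth


def dilute_tumor(
    tumor_reads: list[Read],
    normal_reads: list[Read],
    normal_fraction: float,
    seed: int,
) -> list[Read]:
    """In-silico purity dilution: mix normal reads into the tumor sample.

    Output size equals the tumor read count; an expected ``normal_fraction``
    of the output is drawn from the normal sample (both subsampled without
    replacement), emulating subsample-and-merge dilution experiments.
    """
    if not 0.0 <= normal_fraction <= 1.0:
        raise ValueError(f"normal_fraction must be in [0,1], got {normal_fraction}")
    rng = np.random.default_rng(seed)
    n_out = len(tumor_reads)
    k_normal = min(int(round(n_out * normal_fraction)), len(normal_reads))
    k_tumor = n_out - k_normal
    t_idx = rng.choice(len(tumor_reads), size=k_tumor, replace=False)
    mixed = [tumor_reads[i] for i in np.sort(t_idx)]
    if k_normal:
        n_idx = rng.choice(len(normal_reads), size=k_normal, replace=False)
        mixed.extend(normal_reads[i] for i in np.sort(n_idx))
    mixed.sort(key=lambda r: (r.start, r.name))
    return mixed


def write_fixtures(
    reference: str,
    normal_reads: list[Read],
    tumor_reads: list[Read],
    truth: TruthSet,
    directory: str,
    contig: str = "chr1",
) -> dict[str, str]:
    """Write simulator output as ref.fa(+.fai), indexed BAMs and truth.vcf.

    Truth VCF positions are 1-based per the format; INFO carries the designed
    VAF and origin. Returns a dict of the paths written.
    """
    os.makedirs(directory, exist_ok=True)
    paths = {
        "reference": os.path.join(directory, "ref.fa"),
        "normal": os.path.join(directory, "normal.bam"),
        "tumor": os.path.join(directory, "tumor.bam"),
        "truth": os.path.join(directory, "truth.vcf"),
    }
    with open(paths["reference"], "w") as fh:
        fh.write(f">{contig}\n")
        for i in range(0, len(reference), 70):
            fh.write(reference[i : i + 70] + "\n")
    pysam.faidx(paths["reference"])

    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "coordinate"}, "SQ": [{"SN": contig, "LN": len(reference)}]}
    )
    for key, reads in (("normal", normal_reads), ("tumor", tumor_reads)):
        unsorted = paths[key] + ".unsorted"
        with pysam.AlignmentFile(unsorted, "wb", header=header) as bam:
            for r in reads:
                bam.write(to_alignment(r, header))
        pysam.sort("-o", paths[key], unsorted)
        os.remove(unsorted)
        pysam.index(paths[key])

    vcf_header = pysam.VariantHeader()
    vcf_header.contigs.add(contig, length=len(reference))
    vcf_header.info.add("VAF", 1, "Float", "Designed variant allele fraction")
    vcf_header.info.add("ORIGIN", 1, "String", "somatic or germline")
    with pysam.VariantFile(paths["truth"], "w", header=vcf_header) as vcf:
        for v in sorted(truth.variants, key=lambda t: t.site.pos):
            rec = vcf.new_record(
                contig=v.site.contig,
                start=v.site.pos,  # pysam start is 0-based; VCF POS printed 1-based
                alleles=(v.site.ref, v.site.alt),
            )
            rec.info["VAF"] = v.designed_vaf
            rec.info["ORIGIN"] = v.origin
            vcf.write(rec)
    return paths


def read_truth_vcf(path: str) -> TruthSet:
    """Round-trip reader for :func:`write_fixtures` truth files."""
    variants = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            variants.append(
                TruthVariant(
                    GenomicSite(rec.contig, rec.start, rec.ref, rec.alts[0]),
                    float(rec.info["VAF"]),
                    str(rec.info["ORIGIN"]),
                )
            )
    return TruthSet(variants)
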