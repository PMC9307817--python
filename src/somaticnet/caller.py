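"""End-to-end somatic calling: BAMs in, VCF out.

Pipeline: prefilter scan -> pileup-image encoding -> CNN scoring ->
score threshold -> germline-proximity post-filter -> VCF. SNV and indel
candidates are routed to their respective models; candidates below the score
threshold are flagged ``LOW_SCORE``, the rest pass through the germline
filter. Given a fixed seed the full pipeline is deterministic, so two runs
produce byte-identical VCF bodies.
"""

from __future__ import annotations

import logging
import time

import numpy as np
import pysam

from .encoder import EncodingConfig, encode_site
from .germline_filter import apply_germline_filter
from .prefilter import PrefilterThresholds, scan_candidates
from .network import predict
from .reads import Read, fetch_reads
from .sites import GenomicSite, VariantCall, VariantClass

logger = logging.getLogger(__name__)

DEFAULT_SCORE_THRESHOLD = 0.5
_ENCODE_BATCH = 64


def call_from_reads(
    tumor_reads: list[Read],
    normal_reads: list[Read],
    reference: str,
    snv_model,
    indel_model=None,
    contig: str = "chr1",
    regions=None,
    thresholds: PrefilterThresholds | None = None,
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
    seed: int = 0,
    encoding_config: EncodingConfig | None = None,
) -> list[VariantCall]:
    """Core calling on in-memory reads for one contig.

    Candidates of a class with no model available are skipped with a
    warning. Returns coordinate-sorted calls (flag-only filtering; records
    below threshold are retained with ``LOW_SCORE``).
    """
    cfg = encoding_config or EncodingConfig()
    t0 = time.time()
    candidates = scan_candidates(
        tumor_reads, normal_reads, reference, thresholds, regions=regions, contig=contig
    )
    logger.info(
        "%s: %d candidate sites (%.1fs scan)", contig, len(candidates), time.time() - t0
    )
    from .encoder import ReadIndex

    t_index, n_index = ReadIndex(tumor_reads), ReadIndex(normal_reads)
    calls: list[VariantCall] = []
    for model, wanted in ((snv_model, {VariantClass.SNV}), (indel_model, {VariantClass.INS, VariantClass.DEL})):
        group = [c for c in candidates if c.variant_class in wanted]
        if not group:
            continue
        if model is None:
            logger.warning("no model for %s candidates; skipping %d sites", wanted, len(group))
            continue
        rng = np.random.default_rng(seed)
        # batched scoring keeps peak resident encodings bounded
        for i in range(0, len(group), _ENCODE_BATCH):
            batch = group[i : i + _ENCODE_BATCH]
            encs = [
                encode_site(
                    c.site,
                    t_index.overlapping(c.site.pos),
                    n_index.overlapping(c.site.pos),
                    reference,
                    cfg,
                    rng,
                )
                for c in batch
            ]
            scores = predict(model, encs)
            for cand, score in zip(batch, scores):
                calls.append(
                    VariantCall(
                        site=cand.site,
                        score=float(score),
                        filter="PASS" if score >= score_threshold else "LOW_SCORE",
                        depth_tumor=cand.tumor_depth,
                        depth_normal=cand.normal_depth,
                        alt_count_tumor=cand.tumor_alt_count,
                        alt_count_normal=cand.normal_alt_count,
                    )
                )
    retained = [c for c in calls if c.filter == "PASS"]
    flagged = apply_germline_filter(retained, normal_reads, reference)
    by_site = {(c.site.pos, c.site.ref, c.site.alt): c for c in flagged}
    calls = [
        by_site.get((c.site.pos, c.site.ref, c.site.alt), c) for c in calls
    ]
    calls.sort(key=lambda c: (c.site.pos, c.site.ref, c.site.alt))
    return calls


def call_variants(
    tumor_bam: str,
    normal_bam: str,
    reference_fasta: str,
    snv_model,
    indel_model=None,
    regions=None,
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
    thresholds: PrefilterThresholds | None = None,
    seed: int = 0,
) -> list[VariantCall]:
    """File-based pipeline entry point over every contig of the reference.

    All inputs must be indexed; contigs present in the FASTA but absent from
    either BAM raise an error.
    """
    for path, kind in ((tumor_bam, "BAM"), (normal_bam, "BAM")):
        try:
            pysam.AlignmentFile(path, "rb").check_index()
        except (ValueError, OSError) as exc:
            raise FileNotFoundError(
                f"{kind} {path} is missing its index (run samtools index)"
            ) from exc
    fasta = pysam.FastaFile(reference_fasta)
    calls: list[VariantCall] = []
    with pysam.AlignmentFile(tumor_bam, "rb") as tb, pysam.AlignmentFile(normal_bam, "rb") as nb:
        for contig in fasta.references:
            if contig not in tb.references or contig not in nb.references:
                raise ValueError(
                    f"contig {contig!r} in {reference_fasta} not present in both BAM headers"
                )
    for contig in fasta.references:
        reference = fasta.fetch(contig)
        tumor_reads = fetch_reads(tumor_bam, contig)
        normal_reads = fetch_reads(normal_bam, contig)
        calls.extend(
            call_from_reads(
                tumor_reads,
                normal_reads,
                reference,
                snv_model,
                indel_model,
                contig=contig,
                regions=regions,
                thresholds=thresholds,
                score_threshold=score_threshold,
                seed=seed,
            )
        )
    fasta.close()
    return calls


def _vcf_header(contigs: list[tuple[str, int]]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in contigs:
        header.contigs.add(name, length=length)
    header.filters.add("LOW_SCORE", None, None, "Model score below the calling threshold")
    header.filters.add("GERMLINE_PROX", None, None,
                       "Overlaps or within 1 bp of a suspected germline variant")
    header.info.add("SCORE", 1, "Float", "Somatic mutation probability from the model")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("AD", 2, "Integer", "Ref and alt supporting read counts")
    header.add_sample("NORMAL")
    header.add_sample("TUMOR")
    return header


def write_vcf(
    calls: list[VariantCall],
    path: str,
    contigs: list[tuple[str, int]],
) -> None:
    """Serialize calls to VCF 4.2 (positions 1-based on output).

    Scores are rounded to 6 decimal places so threshold sweeps on a re-read
    callset reproduce the original curve.
    """
    header = _vcf_header(contigs)
    with pysam.VariantFile(path, "w", header=header) as vcf:
        for call in calls:
            rec = vcf.new_record(
                contig=call.site.contig,
                start=call.site.pos,
                alleles=(call.site.ref, call.site.alt),
            )
            rec.info["SCORE"] = round(call.score, 6)
            if call.filter == "PASS":
                rec.filter.add("PASS")
            else:
                rec.filter.add(call.filter)
            rec.samples["NORMAL"]["DP"] = call.depth_normal
            rec.samples["NORMAL"]["AD"] = (
                call.depth_normal - call.alt_count_normal,
                call.alt_count_normal,
            )
            rec.samples["TUMOR"]["DP"] = call.depth_tumor
            rec.samples["TUMOR"]["AD"] = (
                call.depth_tumor - call.alt_count_tumor,
                call.alt_count_tumor,
            )
            vcf.write(rec)


def read_vcf_calls(path: str) -> list[VariantCall]:
    """Round-trip reader for :func:`write_vcf` output."""
    calls = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            filters = list(rec.filter.keys()) or ["PASS"]
            calls.append(
                VariantCall(
                    site=GenomicSite(rec.contig, rec.start, rec.ref, rec.alts[0]),
                    score=float(rec.info["SCORE"]),
                    filter=filters[0],
                    depth_tumor=int(rec.samples["TUMOR"]["DP"]),
                    depth_normal=int(rec.samples["NORMAL"]["DP"]),
                    alt_count_tumor=int(rec.samples["TUMOR"]["AD"][1]),
                    alt_count_normal=int(rec.samples["NORMAL"]["AD"][1]),
                )
            )
    return calls
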