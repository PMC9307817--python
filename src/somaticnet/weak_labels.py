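"""Weakly supervised training-set construction.

Positives ("mutated") come from a high-confidence ensemble callset; negatives
("non-mutated") are sites called by at least one constituent caller but
rejected by the ensemble — a deliberately hard negative pool that carries
more discriminative signal than random genome positions. The ensemble itself
is an input (any VCF); a simple consensus proxy (called by >= k of m
constituent callsets) is provided for self-contained runs. Simulator truth
can also label sites directly, with injectable label noise to emulate
pseudo-label error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pysam

from .sites import GenomicSite, TruthSet
from .variants import site_key


@dataclass
class LabelRecord:
    site: GenomicSite
    label: int  # 1 mutated, 0 non-mutated
    provenance: str  # ensemble | union_minus_ensemble | simulator_truth
    noise_flag: bool = False

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


def read_vcf_sites(path: str) -> list[GenomicSite]:
    sites = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                sites.append(GenomicSite(rec.contig, rec.start, rec.ref, alt))
    return sites


def consensus_ensemble(
    callsets: list[list[GenomicSite]], k: int = 3, reference: str | None = None
) -> list[GenomicSite]:
    """Proxy ensemble: sites called by >= k constituent callsets."""
    votes: dict[tuple, GenomicSite] = {}
    counts: dict[tuple, int] = {}
    for calls in callsets:
        seen = set()
        for site in calls:
            key = site_key(site, reference)
            if key in seen:
                continue
            seen.add(key)
            votes.setdefault(key, site)
            counts[key] = counts.get(key, 0) + 1
    return [votes[key] for key, n in sorted(counts.items()) if n >= k]


def build_training_set(
    ensemble: list[GenomicSite],
    constituents: list[list[GenomicSite]],
    balance: bool = True,
    seed: int = 0,
    reference: str | None = None,
) -> list[LabelRecord]:
    """Label sites: ensemble calls are positives; union-minus-ensemble are
    negatives. With ``balance`` the majority class is downsampled (seeded) to
    the minority count; output order is a deterministic shuffle.
    """
    rng = np.random.default_rng(seed)
    pos_map: dict[tuple, GenomicSite] = {}
    for site in ensemble:
        pos_map.setdefault(site_key(site, reference), site)
    neg_map: dict[tuple, GenomicSite] = {}
    for calls in constituents:
        for site in calls:
            key = site_key(site, reference)
            if key not in pos_map:
                neg_map.setdefault(key, site)
    positives = [LabelRecord(pos_map[k], 1, "ensemble") for k in sorted(pos_map)]
    negatives = [LabelRecord(neg_map[k], 0, "union_minus_ensemble") for k in sorted(neg_map)]
    if balance:
        if not positives or not negatives:
            raise ValueError(
                "cannot class-balance with an empty positive or negative pool; "
                "disable balancing"
            )
        n = min(len(positives), len(negatives))
        if len(positives) > n:
            idx = rng.choice(len(positives), size=n, replace=False)
            positives = [positives[i] for i in np.sort(idx)]
        if len(negatives) > n:
            idx = rng.choice(len(negatives), size=n, replace=False)
            negatives = [negatives[i] for i in np.sort(idx)]
    records = positives + negatives
    rng.shuffle(records)
    return records


def truth_training_set(
    truth: TruthSet,
    reference: str,
    n_negatives: int | None = None,
    seed: int = 0,
    margin: int = 150,
    hard_negatives=None,
) -> list[LabelRecord]:
    """Label directly from simulator truth: somatic sites are positives and
    non-mutated sites are negatives — class-balanced by default.

    ``hard_negatives`` may supply candidate sites (e.g. the prefilter's
    output) whose non-somatic members are used as negatives first; these
    carry real error-driven alternate reads, which mirrors the hard-negative
    character of ensemble-rejected sites and is what teaches the classifier
    to reject borderline candidates at calling time. The remainder is
    filled with random non-variant loci under a random alternate.
    """
    rng = np.random.default_rng(seed)
    contig = truth.variants[0].site.contig if truth.variants else "chr1"
    positives = [
        LabelRecord(v.site, 1, "simulator_truth") for v in truth.somatic
    ]
    if n_negatives is None:
        n_negatives = len(positives)
    occupied = {v.site.pos for v in truth.variants}
    negatives: list[LabelRecord] = []
    bases = "ACGT"
    if hard_negatives:
        truth_keys = {site_key(v.site, reference) for v in truth.variants}
        pool = [
            s for s in hard_negatives
            if site_key(s, reference) not in truth_keys and s.pos not in occupied
        ]
        take = min(len(pool), n_negatives)
        idx = rng.choice(len(pool), size=take, replace=False) if pool else []
        for i in np.sort(idx):
            occupied.add(pool[i].pos)
            negatives.append(LabelRecord(pool[i], 0, "simulator_truth"))
    while len(negatives) < n_negatives:
        pos = int(rng.integers(margin, len(reference) - margin))
        if pos in occupied or reference[pos] not in bases:
            continue
        occupied.add(pos)
        alts = [b for b in bases if b != reference[pos]]
        alt = alts[int(rng.integers(0, 3))]
        negatives.append(
            LabelRecord(GenomicSite(contig, pos, reference[pos], alt), 0, "simulator_truth")
        )
    records = positives + negatives
    rng.shuffle(records)
    return records


def inject_label_noise(
    records: list[LabelRecord], flip_rate: float, seed: int = 0
) -> list[LabelRecord]:
    """Flip an expected ``flip_rate`` fraction of labels (pseudo-label error
    emulation). Deterministic given the seed; flipped records carry
    ``noise_flag=True``.
    """
    if not 0.0 <= flip_rate < 0.5:
        raise ValueError(f"flip_rate must be in [0, 0.5), got {flip_rate}")
    rng = np.random.default_rng(seed)
    flips = rng.random(len(records)) < flip_rate
    out = []
    for rec, flip in zip(records, flips):
        if flip:
            out.append(LabelRecord(rec.site, 1 - rec.label, rec.provenance, True))
        else:
            out.append(LabelRecord(rec.site, rec.label, rec.provenance, rec.noise_flag))
    return out
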