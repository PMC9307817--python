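"""Benchmarking a scored callset against a truth set.

Matching is exact on normalized representations (contig, left-aligned
position, alleles); genotype is ignored — somatic calling is presence or
absence of the mutation. Precision is the fraction of predicted mutations
that are correct, recall the fraction of true mutations recovered, and F1
their harmonic mean. Precision-recall curves sweep the call score over every
distinct value, mirroring how callers are compared by varying their
confidence scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sites import GenomicSite, TruthSet, VariantCall
from .variants import site_key


@dataclass
class MatchResult:
    tp_flags: list[bool]          # per call (parallel to the input order)
    truth_found: list[bool]       # per truth variant
    n_tp: int
    n_fp: int
    n_fn: int


@dataclass
class PRPoint:
    threshold: float
    precision: float
    recall: float

    @property
    def f1(self) -> float:
        return f1_score(self.precision, self.recall)


@dataclass
class PRCurve:
    points: list[PRPoint]
    max_f1: float
    argmax_threshold: float


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def _truth_sites(truth) -> list[GenomicSite]:
    if isinstance(truth, TruthSet):
        return [v.site for v in truth.somatic]
    return [t.site if hasattr(t, "site") else t for t in truth]


def _call_site(call) -> GenomicSite:
    return call.site if isinstance(call, VariantCall) else call


def match_calls(calls, truth, reference: str | None = None) -> MatchResult:
    """Classify each call as TP/FP and each truth variant as found/missed.

    Duplicate call records (same normalized site) are rejected; each truth
    variant can be matched at most once.
    """
    truth_keys = {}
    truth_sites = _truth_sites(truth)
    for i, site in enumerate(truth_sites):
        truth_keys.setdefault(site_key(site, reference), i)
    seen: set = set()
    tp_flags: list[bool] = []
    truth_found = [False] * len(truth_sites)
    for call in calls:
        key = site_key(_call_site(call), reference)
        if key in seen:
            raise ValueError(f"duplicate call record at {key}")
        seen.add(key)
        idx = truth_keys.get(key)
        if idx is not None and not truth_found[idx]:
            truth_found[idx] = True
            tp_flags.append(True)
        else:
            tp_flags.append(False)
    n_tp = sum(tp_flags)
    return MatchResult(
        tp_flags=tp_flags,
        truth_found=truth_found,
        n_tp=n_tp,
        n_fp=len(tp_flags) - n_tp,
        n_fn=len(truth_sites) - n_tp,
    )


def precision_recall(calls, truth, reference: str | None = None) -> tuple[float, float, float]:
    """(precision, recall, F1) of a callset at a single operating point."""
    m = match_calls(calls, truth, reference)
    p = m.n_tp / (m.n_tp + m.n_fp) if (m.n_tp + m.n_fp) else 0.0
    r = m.n_tp / (m.n_tp + m.n_fn) if (m.n_tp + m.n_fn) else 0.0
    return p, r, f1_score(p, r)


def pr_curve(calls: list[VariantCall], truth, reference: str | None = None) -> PRCurve:
    """Precision-recall curve over the distinct call scores.

    Thresholds are the sorted unique scores; at each threshold only calls
    scoring >= threshold count. Matches a brute-force per-threshold recount
    exactly: matching is done once (score order does not affect exact-site
    matching) and counts are accumulated over descending score.
    """
    n_truth = len(_truth_sites(truth))
    if n_truth == 0:
        raise ValueError("empty truth set")
    if not calls:
        return PRCurve(points=[], max_f1=0.0, argmax_threshold=0.0)
    scores = np.array([c.score for c in calls])
    m = match_calls(calls, truth, reference)
    tp = np.array(m.tp_flags)
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    cum_tp = np.cumsum(tp[order])
    cum_n = np.arange(1, len(calls) + 1)
    # last index of each distinct score block = counts at that threshold
    thresholds = np.unique(sorted_scores)[::-1]
    idx = np.searchsorted(-sorted_scores, -thresholds, side="right") - 1
    points = []
    best_f1, best_thr = -1.0, 0.0
    for thr, i in zip(thresholds, idx):
        p = cum_tp[i] / cum_n[i]
        r = cum_tp[i] / n_truth
        pt = PRPoint(float(thr), float(p), float(r))
        points.append(pt)
        if pt.f1 > best_f1:
            best_f1, best_thr = pt.f1, float(thr)
    return PRCurve(points=points, max_f1=best_f1, argmax_threshold=best_thr)


def stratify_by_vaf(
    truth_variants,
    calls: list[VariantCall],
    bin_edges: list[float],
    reference: str | None = None,
) -> list[dict]:
    """Per-VAF-bin precision/recall/F1.

    ``truth_variants`` must carry ``designed_vaf``; bins are half-open
    [lo, hi). False positives are assigned to bins by their observed tumor
    VAF. Bins with no truth variants are reported with None metrics rather
    than zeros.
    """
    for v in truth_variants:
        if getattr(v, "designed_vaf", None) is None:
            raise ValueError("every truth variant needs a VAF for stratification")
    m = match_calls(calls, truth_variants, reference)
    edges = list(bin_edges)
    nbins = len(edges) - 1

    def bin_of(vaf: float) -> int | None:
        for b in range(nbins):
            if edges[b] <= vaf < edges[b + 1]:
                return b
        return None

    tp = [0] * nbins
    fp = [0] * nbins
    fn = [0] * nbins
    truth_bins = [bin_of(v.designed_vaf) for v in truth_variants]
    for v, found, b in zip(truth_variants, m.truth_found, truth_bins):
        if b is None:
            continue
        if found:
            tp[b] += 1
        else:
            fn[b] += 1
    for call, is_tp in zip(calls, m.tp_flags):
        if is_tp:
            continue
        vaf = call.tumor_vaf if isinstance(call, VariantCall) else None
        b = bin_of(vaf) if vaf is not None else None
        if b is not None:
            fp[b] += 1
    report = []
    for b in range(nbins):
        n_truth = tp[b] + fn[b]
        if n_truth == 0:
            report.append(
                {"bin": (edges[b], edges[b + 1]), "n_truth": 0,
                 "precision": None, "recall": None, "f1": None}
            )
            continue
        p = tp[b] / (tp[b] + fp[b]) if (tp[b] + fp[b]) else 0.0
        r = tp[b] / n_truth
        report.append(
            {"bin": (edges[b], edges[b + 1]), "n_truth": n_truth,
             "precision": p, "recall": r, "f1": f1_score(p, r)}
        )
    return report
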