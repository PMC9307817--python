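"""Reproducible study drivers built from the pipeline pieces.

These functions wire simulator -> encoder -> network -> caller -> metrics
into the two synthetic studies the package validates itself with:

* :func:`parameter_recovery` — can a desk-scale SNV model trained on
  simulated truth labels recover held-out mutation status, and how much does
  10% label noise (weak-supervision emulation) cost?
* :func:`purity_dilution` — how do recall and precision respond when the
  tumor sample is diluted with matched-normal reads, lowering effective
  purity?

Desk-scale defaults (sample counts, model scale, epochs, learning rate) are
chosen so each study runs in minutes on one CPU; the same drivers accept
larger sizes unchanged. The learning rate default here is 1e-3 rather than
the 1e-4 production default: with thousands (not millions) of training
sites, an epoch is only tens of optimizer steps and the smaller rate would
leave the model undertrained within the epoch budget.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .caller import call_from_reads
from .encoder import EncodingConfig, ReadIndex, encode_site
from .evalmetrics import precision_recall
from .network import NetSpec, TrainConfig, build_model, train_model, predict
from .prefilter import scan_candidates
from .simdata import SimConfig, dilute_tumor, simulate_pair
from .sites import VariantClass
from .weak_labels import inject_label_noise, truth_training_set

DESK_LR = 1e-3


def encode_labeled_sites(records, tumor_reads, normal_reads, reference, seed=0):
    """Encode a list of label records; returns (X, y) arrays."""
    t_index, n_index = ReadIndex(tumor_reads), ReadIndex(normal_reads)
    cfg = EncodingConfig(seed=seed)
    rng = np.random.default_rng(seed)
    X = np.stack(
        [
            encode_site(
                r.site,
                t_index.overlapping(r.site.pos),
                n_index.overlapping(r.site.pos),
                reference,
                cfg,
                rng,
            ).values
            for r in records
        ]
    )
    y = np.array([r.label for r in records], dtype=np.float32)
    return X, y


def fit_with_restarts(
    X,
    y,
    spec: NetSpec,
    epochs: int,
    learning_rate: float,
    seed: int,
    attempts: int = 3,
    accept_val_acc: float = 0.93,
    screen_val_acc: float = 0.80,
    screen_epochs: int = 5,
):
    """Train with random restarts, keeping the best-validation model.

    Training this non-convex objective from scratch lands in a visibly poor
    basin for a minority of initialization seeds (validation accuracy stuck
    near 0.75-0.8 while other seeds on identical data exceed 0.95); the
    stall is robust to learning-rate and optimizer-moment changes. As with
    other non-convex fits (k-means and friends), differently seeded
    restarts gated on *validation* accuracy make the outcome robust.
    Attempts that have not reached ``screen_val_acc`` validation accuracy
    after ``screen_epochs`` epochs are aborted early to keep restarts
    cheap; the first attempt whose restored weights reach
    ``accept_val_acc`` is accepted, and otherwise the best-validation
    attempt wins. Held-out test data are never consulted. Returns
    ``(model, history)``; the history carries the number of attempts used.
    """

    def screen(history: dict) -> bool:
        return (
            len(history["val_acc"]) >= screen_epochs
            and max(history["val_acc"]) < screen_val_acc
        )

    best = None
    used = 0
    for k in range(max(1, attempts)):
        s = seed + 1_000_003 * k
        model = build_model(spec, seed=s)
        history = train_model(
            model, X, y,
            TrainConfig(epochs=epochs, learning_rate=learning_rate, seed=s),
            stop_callback=screen,
        )
        restored = int(np.argmin(history["val_loss"]))
        val_acc = history["val_acc"][restored]
        used = k + 1
        if best is None or val_acc > best[0]:
            best = (val_acc, model, history)
        if val_acc >= accept_val_acc:
            break
    _, model, history = best
    history = dict(history, restarts=used)
    return model, history


@dataclass
class RecoveryResult:
    accuracy_clean: float
    accuracy_noisy: float
    history_clean: dict
    history_noisy: dict
    clean_model: object = None  # the clean-label model, reusable downstream

    @property
    def degradation(self) -> float:
        return self.accuracy_clean - self.accuracy_noisy


def parameter_recovery(
    seed: int,
    n_train: int = 3000,
    n_test: int = 500,
    scale: float = 0.25,
    epochs: int = 10,
    learning_rate: float = DESK_LR,
    noise_rate: float = 0.1,
    depth: float = 60.0,
    vaf_range: tuple[float, float] = (0.2, 0.6),
) -> RecoveryResult:
    """Held-out mutation-status recovery, clean versus noisy labels.

    Simulates a pure (purity 1.0) tumor at ``depth`` with somatic SNVs at
    VAF ~ Uniform(*vaf_range*), builds a class-balanced site set from
    simulator truth, trains one SNV model on clean labels and one on labels
    with ``noise_rate`` random flips, and scores both against the clean
    held-out truth.
    """
    n_sites = n_train + n_test
    config = SimConfig(
        contig_length=max(20_000, 60 * n_sites),
        depth_tumor=depth,
        depth_normal=40.0,
        purity=1.0,
        somatic_snv_count=(n_sites + 1) // 2,
        somatic_indel_count=0,
        vaf_law=("uniform", *vaf_range),
        seed=seed,
    )
    reference, normal, tumor, truth = simulate_pair(config)
    candidates = scan_candidates(tumor, normal, reference, contig=config.contig)
    records = truth_training_set(
        truth, reference, seed=seed,
        hard_negatives=[c.site for c in candidates],
    )
    X, y = encode_labeled_sites(records, tumor, normal, reference, seed=seed)
    X_train, y_train = X[:n_train], y[:n_train]
    X_test, y_test = X[n_train : n_train + n_test], y[n_train : n_train + n_test]

    def fit(labels, **restart_kw):
        model, history = fit_with_restarts(
            X_train, labels, NetSpec(scale=scale), epochs, learning_rate, seed,
            **restart_kw,
        )
        scores = predict(model, X_test)
        acc = float(np.mean((scores >= 0.5) == (y_test >= 0.5)))
        return acc, history, model

    acc_clean, hist_clean, clean_model = fit(y_train, attempts=3)
    noisy_records = inject_label_noise(records[:n_train], noise_rate, seed=seed)
    y_noisy = np.array([r.label for r in noisy_records], dtype=np.float32)
    # noisy-label validation caps below the flip rate's ceiling, and the
    # breakthrough arrives later; screen later and accept lower. The noisy
    # arm yields an attempt when the clean arm already restarted, keeping
    # the whole study minutes-scale.
    acc_noisy, hist_noisy, _ = fit(
        y_noisy,
        attempts=1 if hist_clean["restarts"] > 1 else 2,
        accept_val_acc=0.82,
        screen_val_acc=0.65,
        screen_epochs=7,
    )
    return RecoveryResult(acc_clean, acc_noisy, hist_clean, hist_noisy, clean_model)


def train_toy_snv_model(
    seed: int,
    n_sites: int = 3000,
    scale: float = 0.25,
    epochs: int = 10,
    learning_rate: float = DESK_LR,
    vaf_range: tuple[float, float] = (0.2, 0.6),
):
    """Desk-scale SNV model for end-to-end pipeline runs.

    Returns ``(model, history)``; the training data are simulated fresh from
    ``seed`` so the model never sees the evaluation datasets. The defaults
    are the smallest configuration we found that generalizes reliably to
    *other* simulations — with substantially fewer training sites the
    network leans on memorized local reference context instead of the
    allele signal and transfers poorly.
    """
    config = SimConfig(
        contig_length=max(20_000, 70 * n_sites),
        somatic_snv_count=(n_sites + 1) // 2,
        somatic_indel_count=0,
        vaf_law=("uniform", *vaf_range),
        seed=seed,
    )
    reference, normal, tumor, truth = simulate_pair(config)
    candidates = scan_candidates(tumor, normal, reference, contig=config.contig)
    records = truth_training_set(
        truth, reference, seed=seed,
        hard_negatives=[c.site for c in candidates],
    )
    X, y = encode_labeled_sites(records, tumor, normal, reference, seed=seed)
    return fit_with_restarts(
        X, y, NetSpec(scale=scale), epochs, learning_rate, seed, attempts=2
    )


def train_toy_indel_model(
    seed: int,
    n_sites: int = 240,
    scale: float = 0.1,
    epochs: int = 25,
    learning_rate: float = DESK_LR,
):
    """Small inception-style indel model.

    Positives are spiked somatic indels; negatives are non-variant loci
    encoded under a hypothetical 1 bp insertion (reads show no in-place
    signal there).
    """
    from .sites import GenomicSite
    from .weak_labels import LabelRecord

    config = SimConfig(
        contig_length=max(20_000, 140 * n_sites),
        somatic_snv_count=0,
        somatic_indel_count=(n_sites + 1) // 2,
        vaf_law=("uniform", 0.3, 0.6),
        seed=seed,
    )
    reference, normal, tumor, truth = simulate_pair(config)
    rng = np.random.default_rng(seed)
    positives = [LabelRecord(v.site, 1, "simulator_truth") for v in truth.somatic]
    occupied = {v.site.pos for v in truth.variants}
    negatives = []
    while len(negatives) < len(positives):
        pos = int(rng.integers(200, len(reference) - 200))
        if pos in occupied:
            continue
        occupied.add(pos)
        negatives.append(
            LabelRecord(
                GenomicSite(config.contig, pos, reference[pos], reference[pos] + "A"),
                0,
                "simulator_truth",
            )
        )
    records = positives + negatives
    rng.shuffle(records)
    X, y = encode_labeled_sites(records, tumor, normal, reference, seed=seed)
    spec = NetSpec(
        input_shape=(140, 150, 5),
        arch_style="inception_style",
        conv_blocks=4,
        pool_positions=(0, 2),  # downsample the wide indel image up front
        pool_sizes=(2, 2),
        scale=scale,
    )
    model = build_model(spec, seed=seed)
    history = train_model(
        model, X, y,
        TrainConfig(epochs=epochs, learning_rate=learning_rate, min_epochs=max(12, epochs - 5), seed=seed),
    )
    return model, history


def purity_dilution(
    model,
    seed: int,
    fractions: tuple[float, ...] = (0.0, 0.3, 0.5),
    n_snvs: int = 50,
    depth: float = 60.0,
    vaf: float = 0.5,
    score_threshold: float = 0.5,
) -> list[dict]:
    """Call variants on a tumor progressively diluted with normal reads.

    Returns one row per dilution fraction with precision/recall of PASS
    calls against the spiked SNV truth. Mixing reuses the matched-normal
    read pool, mirroring subsample-and-merge dilution of real samples.
    """
    config = SimConfig(
        contig_length=max(20_000, 220 * n_snvs),
        depth_tumor=depth,
        depth_normal=depth,  # dilution draws on the normal pool
        purity=1.0,
        somatic_snv_count=n_snvs,
        somatic_indel_count=0,
        vaf_law=("constant", vaf),
        seed=seed,
    )
    reference, normal, tumor, truth = simulate_pair(config)
    truth_snvs = [v for v in truth.somatic if v.site.variant_class == VariantClass.SNV]
    rows = []
    for fraction in fractions:
        mixed = dilute_tumor(tumor, normal, fraction, seed=seed + 1)
        calls = call_from_reads(
            mixed,
            normal,
            reference,
            model,
            contig=config.contig,
            score_threshold=score_threshold,
            seed=seed,
        )
        passing = [c for c in calls if c.filter == "PASS"]
        p, r, f1 = precision_recall(passing, truth_snvs, reference)
        rows.append(
            {
                "normal_fraction": fraction,
                "n_pass": len(passing),
                "precision": p,
                "recall": r,
                "f1": f1,
            }
        )
    return rows
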