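"""Shared fixtures: simulated datasets and small trained models.

Everything is generated programmatically at session start; heavy artifacts
(trained toy models) are session-scoped so the cost is paid once.
"""

from __future__ import annotations

import numpy as np
import pytest

from somaticnet.reads import Read
from somaticnet.simdata import SimConfig, simulate_pair


def make_read(
    start: int,
    seq: str,
    name: str = "r1",
    cigar=None,
    quals=None,
    mapq: int = 60,
    reverse: bool = False,
    contig: str = "chr1",
) -> Read:
    """Hand-build an aligned read (defaults: all-match CIGAR, Q30)."""
    return Read(
        name=name,
        contig=contig,
        start=start,
        seq=seq,
        quals=np.full(len(seq), 30, dtype=np.int16) if quals is None else np.asarray(quals, dtype=np.int16),
        cigar=cigar if cigar is not None else [(0, len(seq))],
        mapq=mapq,
        is_reverse=reverse,
    )


@pytest.fixture(scope="session")
def sim_small():
    """A small matched pair with SNV and indel truth."""
    config = SimConfig(
        contig_length=30_000,
        somatic_snv_count=30,
        somatic_indel_count=8,
        vaf_law=("uniform", 0.3, 0.6),
        seed=7,
    )
    reference, normal, tumor, truth = simulate_pair(config)
    return {
        "config": config,
        "reference": reference,
        "normal": normal,
        "tumor": tumor,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def recovery_result():
    """The parameter-recovery study (clean + noisy training at full desk
    scale). Computed once; its clean model is reused across the suite."""
    from somaticnet.experiments import parameter_recovery

    return parameter_recovery(101, n_train=3000, n_test=500, epochs=10)


@pytest.fixture(scope="session")
def toy_snv_model(recovery_result):
    """The clean-label SNV classifier from the recovery study.

    Models trained on only a few hundred loci memorize site context instead
    of the allele signal and do not generalize to unseen positions, so the
    suite shares this properly trained one.
    """
    return {"model": recovery_result.clean_model,
            "history": recovery_result.history_clean}


@pytest.fixture(scope="session")
def toy_indel_model():
    from somaticnet.experiments import train_toy_indel_model

    model, history = train_toy_indel_model(seed=303, n_sites=160, epochs=6)
    return {"model": model, "history": history}
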