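"""Simulator behavior: allele-fraction consistency, determinism, fixtures."""

import numpy as np
import pysam
import pytest

import somaticnet as sn
from somaticnet.simdata import SimConfig, dilute_tumor, read_truth_vcf, simulate_pair, write_fixtures
from somaticnet.sites import GenomicSite, TruthSet, TruthVariant, VariantClass


def _alt_fraction(reads, site):
    cov = alt = 0
    for r in reads:
        hit = r.base_at(site.pos) if r.overlaps(site.pos) else None
        if hit is None or hit[0] == "-":
            continue
        cov += 1
        alt += hit[0] == site.alt
    return alt, cov


@pytest.fixture(scope="module")
def pair():
    config = SimConfig(
        contig_length=30_000,
        somatic_snv_count=25,
        somatic_indel_count=5,
        vaf_law=("constant", 0.5),
        seed=42,
    )
    return config, simulate_pair(config)


def test_tumor_alt_fraction_tracks_designed_vaf(pair):
    """At purity 1 and VAF 0.5, tumor alt fractions sit within 3 binomial SDs
    and the normal shows nothing above the error rate."""
    config, (reference, normal, tumor, truth) = pair
    snvs = [v for v in truth.somatic if v.site.variant_class == VariantClass.SNV]
    assert snvs
    for v in snvs:
        alt, cov = _alt_fraction(tumor, v.site)
        p = v.designed_vaf * config.purity
        sd = np.sqrt(p * (1 - p) / cov)
        assert abs(alt / cov - p) <= 3 * sd
        n_alt, n_cov = _alt_fraction(normal, v.site)
        assert n_alt / max(n_cov, 1) <= 5 * config.base_error_rate + 3 / max(n_cov, 1)


def test_germline_hets_near_half_in_both_samples(pair):
    _, (reference, normal, tumor, truth) = pair
    hets = [v for v in truth.germline if v.designed_vaf == 0.5][:20]
    assert hets
    for v in hets:
        for reads in (normal, tumor):
            alt, cov = _alt_fraction(reads, v.site)
            sd = np.sqrt(0.25 / cov)
            assert abs(alt / cov - 0.5) <= 4 * sd


def test_zero_purity_removes_somatic_signal():
    config = SimConfig(
        contig_length=20_000, purity=0.0, somatic_snv_count=20,
        somatic_indel_count=0, vaf_law=("constant", 0.5), seed=3,
    )
    _, _, tumor, truth = simulate_pair(config)
    for v in truth.somatic:
        alt, cov = _alt_fraction(tumor, v.site)
        assert alt / max(cov, 1) < 0.08  # nothing beyond sequencing error


def test_same_seed_reproduces_everything():
    config = SimConfig(contig_length=20_000, seed=9)
    ref1, n1, t1, truth1 = simulate_pair(config)
    ref2, n2, t2, truth2 = simulate_pair(config)
    assert ref1 == ref2
    assert truth1.variants == truth2.variants
    assert [(r.name, r.start, r.seq, r.cigar, r.mapq) for r in t1] == [
        (r.name, r.start, r.seq, r.cigar, r.mapq) for r in t2
    ]
    assert all((a.quals == b.quals).all() for a, b in zip(n1, n2))


def test_mean_coverage_near_configured_depth(pair):
    config, (reference, normal, tumor, _) = pair
    L, rl = config.contig_length, config.read_length
    cover = np.zeros(L)
    for r in tumor:
        cover[r.start : r.end] += 1
    interior = cover[rl : L - rl]
    assert abs(interior.mean() - config.depth_tumor) / config.depth_tumor < 0.10


def test_vaf_regression_slope_near_unity():
    """Observed tumor alt fraction regresses on designed VAF x purity with
    slope in [0.9, 1.1] across >=1000 somatic sites."""
    config = SimConfig(
        contig_length=120_000,
        somatic_snv_count=1000,
        somatic_indel_count=0,
        vaf_law=("uniform", 0.1, 0.9),
        purity=0.8,
        seed=17,
    )
    _, _, tumor, truth = simulate_pair(config)
    xs, ys = [], []
    for v in truth.somatic:
        alt, cov = _alt_fraction(tumor, v.site)
        if cov:
            xs.append(v.designed_vaf * config.purity)
            ys.append(alt / cov)
    assert len(xs) >= 1000
    slope = np.polyfit(xs, ys, 1)[0]
    assert 0.9 <= slope <= 1.1


def test_contig_too_short_rejected():
    with pytest.raises(ValueError, match="too short"):
        SimConfig(contig_length=150, read_length=100)


@pytest.mark.parametrize("bad", [{"purity": 1.5}, {"base_error_rate": -0.1}, {"depth_tumor": 0}])
def test_invalid_config_rejected(bad):
    with pytest.raises(ValueError):
        SimConfig(**bad)


class TestDilution:
    def test_zero_fraction_is_pure_tumor(self, pair):
        _, (_, normal, tumor, _) = pair
        mixed = dilute_tumor(tumor, normal, 0.0, seed=1)
        assert len(mixed) == len(tumor)
        assert all(r.name.startswith("t") for r in mixed)

    def test_full_fraction_is_pure_normal(self, pair):
        config, (_, normal, tumor, truth) = pair
        # dilution pool must be large enough: subsample tumor to fit
        mixed = dilute_tumor(tumor[: len(normal)], normal, 1.0, seed=1)
        assert all(r.name.startswith("n") for r in mixed)

    def test_mixture_shifts_vaf_by_expectation(self):
        config = SimConfig(
            contig_length=40_000, depth_tumor=80, depth_normal=80,
            somatic_snv_count=30, somatic_indel_count=0,
            vaf_law=("constant", 0.5), seed=21,
        )
        _, normal, tumor, truth = simulate_pair(config)
        mixed = dilute_tumor(tumor, normal, 0.3, seed=5)
        fracs = []
        for v in truth.somatic:
            alt, cov = _alt_fraction(mixed, v.site)
            fracs.append(alt / cov)
        # expected observed VAF = 0.5 * (1 - 0.3) = 0.35
        assert abs(np.mean(fracs) - 0.35) < 0.03

    def test_deterministic_given_seed(self, pair):
        _, (_, normal, tumor, _) = pair
        a = dilute_tumor(tumor, normal, 0.3, seed=11)
        b = dilute_tumor(tumor, normal, 0.3, seed=11)
        assert [r.name for r in a] == [r.name for r in b]

    def test_invalid_fraction_rejected(self, pair):
        _, (_, normal, tumor, _) = pair
        with pytest.raises(ValueError):
            dilute_tumor(tumor, normal, 1.2, seed=0)


class TestFixtures:
    def test_round_trip_truth_and_reads(self, tmp_path, pair):
        config, (reference, normal, tumor, truth) = pair
        paths = write_fixtures(reference, normal, tumor, truth, str(tmp_path), contig=config.contig)
        back = read_truth_vcf(paths["truth"])
        assert [(v.site, v.origin) for v in back.variants] == [
            (v.site, v.origin) for v in sorted(truth.variants, key=lambda t: t.site.pos)
        ]
        from somaticnet.reads import fetch_reads

        got = fetch_reads(paths["tumor"], config.contig)
        assert len(got) == len(tumor)
        want = sorted(tumor, key=lambda r: (r.start, r.name))
        got = sorted(got, key=lambda r: (r.start, r.name))
        assert [(r.start, r.seq, r.cigar) for r in got] == [
            (r.start, r.seq, r.cigar) for r in want
        ]

    def test_vcf_positions_are_one_based(self, tmp_path):
        truth = TruthSet([TruthVariant(GenomicSite("chr1", 0, "A", "T"), 0.5, "somatic")])
        reference = "A" * 300
        write_fixtures(reference, [], [], truth, str(tmp_path))
        body = [
            line
            for line in open(tmp_path / "truth.vcf")
            if not line.startswith("#")
        ]
        assert body and body[0].split("\t")[1] == "1"  # internal 0 -> VCF POS 1

    def test_empty_truth_is_valid_vcf(self, tmp_path):
        write_fixtures("C" * 300, [], [], TruthSet([]), str(tmp_path))
        with pysam.VariantFile(str(tmp_path / "truth.vcf")) as vcf:
            assert list(vcf) == []
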