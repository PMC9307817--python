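"""Pileup-image encoder: shapes, channel codes, layout, CIGAR handling."""

import subprocess
import sys

import numpy as np
import pytest

from somaticnet.encoder import (
    EncodingConfig,
    channel_codes,
    encode_indel_inplace,
    encode_site,
    subsample_reads,
)
from somaticnet.sites import GenomicSite, VariantClass

from conftest import make_read

CFG = EncodingConfig()
CAND_COLS = slice(CFG.snv_half + CFG.snv_flank, CFG.snv_half + CFG.snv_flank + CFG.snv_repeat)


def _some_site(sim, variant_class):
    for v in sim["truth"].somatic:
        if (v.site.variant_class == VariantClass.SNV) == (variant_class == "snv"):
            return v.site
    raise AssertionError("fixture lacks a site of the requested class")


class TestChannelCodes:
    def test_codes_injective_and_bounded(self):
        codes = channel_codes()
        assert len(set(codes.values())) == len(codes)
        assert all(-1.0 <= v <= 1.0 for v in codes.values())
        assert len({codes[b] for b in "ACGT"} | {codes["deletion"]}) == 5

    def test_padding_is_zero_and_distinct(self):
        codes = channel_codes()
        assert codes["padding"] == 0.0
        assert all(codes[b] != 0.0 for b in "ACGT")

    def test_stable_across_processes(self):
        out = subprocess.run(
            [sys.executable, "-c",
             "from somaticnet.encoder import channel_codes; print(sorted(channel_codes().items()))"],
            capture_output=True, text=True, check=True,
        ).stdout.strip()
        assert out == str(sorted(channel_codes().items()))


class TestSubsample:
    def test_under_cap_keeps_all_in_order(self):
        reads = [make_read(i, "ACGT", name=f"r{i}") for i in range(80)]
        assert subsample_reads(reads, 100, np.random.default_rng(0)) == reads

    @pytest.mark.parametrize("cap", [100, 140])
    def test_over_cap_uniform_subset(self, cap):
        reads = [make_read(i, "ACGT", name=f"r{i}") for i in range(250)]
        out = subsample_reads(reads, cap, np.random.default_rng(1))
        assert len(out) == cap
        assert set(id(r) for r in out) <= set(id(r) for r in reads)
        starts = [r.start for r in out]
        assert starts == sorted(starts)  # order preserved

    def test_deterministic_given_seed(self):
        reads = [make_read(i, "ACGT", name=f"r{i}") for i in range(300)]
        a = subsample_reads(reads, 50, np.random.default_rng(5))
        b = subsample_reads(reads, 50, np.random.default_rng(5))
        assert [r.name for r in a] == [r.name for r in b]

    def test_bad_cap(self):
        with pytest.raises(ValueError):
            subsample_reads([], 0, np.random.default_rng(0))


class TestSnvEncoding:
    def test_shape_invariant(self, sim_small):
        site = _some_site(sim_small, "snv")
        enc = encode_site(site, sim_small["tumor"], sim_small["normal"], sim_small["reference"])
        assert enc.shape == (100, 70, 5)

    def test_candidate_repeated_five_times(self, sim_small):
        site = _some_site(sim_small, "snv")
        enc = encode_site(site, sim_small["tumor"], sim_small["normal"], sim_small["reference"])
        codes = channel_codes()
        found_alt_row = False
        for row in range(enc.n_tumor_reads_used):
            block = enc.values[row, CAND_COLS, 0]
            assert len(set(block.tolist())) == 1  # 5 identical adjacent values
            if block[0] == codes[site.alt]:
                found_alt_row = True
        assert found_alt_row

    def test_padding_rows_zero_in_all_channels(self, sim_small):
        site = _some_site(sim_small, "snv")
        tumor3 = [r for r in sim_small["tumor"] if r.overlaps(site.pos)][:3]
        enc = encode_site(site, tumor3, [], sim_small["reference"])
        assert enc.n_normal_reads_used == 0
        assert np.all(enc.values[:, :35, :] == 0.0)  # normal half fully padded
        assert np.all(enc.values[3:, 35:, :] == 0.0)  # tumor rows beyond 3

    def test_channel_ranges(self, sim_small):
        site = _some_site(sim_small, "snv")
        enc = encode_site(site, sim_small["tumor"], sim_small["normal"], sim_small["reference"])
        v = enc.values
        assert v.min() >= -1.0 and v.max() <= 1.0
        assert v[..., 1].min() >= 0.0 and v[..., 1].max() <= 1.0  # base quality
        assert v[..., 2].min() >= 0.0 and v[..., 2].max() <= 1.0  # mapping quality
        assert set(np.unique(v[..., 3])) <= {-1.0, 0.0, 1.0}  # strand

    def test_sample_swap_swaps_halves(self, sim_small):
        site = _some_site(sim_small, "snv")
        ref = sim_small["reference"]
        a = encode_site(site, sim_small["tumor"], sim_small["normal"], ref,
                        rng=np.random.default_rng(3))
        b = encode_site(site, sim_small["normal"], sim_small["tumor"], ref,
                        rng=np.random.default_rng(3))
        assert np.array_equal(a.values[:, :35], b.values[:, 35:])
        assert np.array_equal(a.values[:, 35:], b.values[:, :35])

    def test_deterministic_given_seed(self, sim_small):
        site = _some_site(sim_small, "snv")
        args = (site, sim_small["tumor"], sim_small["normal"], sim_small["reference"])
        a = encode_site(*args, rng=np.random.default_rng(9))
        b = encode_site(*args, rng=np.random.default_rng(9))
        assert np.array_equal(a.values, b.values)

    def test_site_beyond_contig_rejected(self, sim_small):
        with pytest.raises(ValueError, match="beyond contig"):
            encode_site(
                GenomicSite("chr1", 10**7, "A", "T"),
                sim_small["tumor"], sim_small["normal"], sim_small["reference"],
            )


def _naive_base_at(read, pos):
    """Independent per-base CIGAR walk used as the bookkeeping oracle."""
    for q, r in read.aligned_pairs():
        if r == pos:
            return read.seq[q] if q is not None else "-"
    return None


def test_base_channel_matches_bruteforce_walk():
    """On tiny images, the base channel equals a per-base walk of each CIGAR
    (matches, deletions, and positions outside the read)."""
    cfg = EncodingConfig(snv_rows=5, snv_width=22, snv_repeat=5)  # half=11, flank=3
    reference = "ACGTACGTACGTACGTACGT"
    reads = [
        make_read(2, "GTACGTAC", name="plain"),
        make_read(1, "CGTAAACGT", name="ins", cigar=[(0, 4), (1, 3), (0, 2)]),
        make_read(0, "ACGTCGT", name="del", cigar=[(0, 4), (2, 2), (0, 3)]),
        make_read(8, "ACGT", name="right"),
    ]
    site = GenomicSite("chr1", 6, "G", "A")
    enc = encode_site(site, reads, [], reference, cfg, np.random.default_rng(0))
    codes = channel_codes()
    offsets = [-3, -2, -1, 0, 0, 0, 0, 0, 1, 2, 3]  # column -> ref offset
    ordered = sorted(
        [r for r in reads if r.overlaps(site.pos)], key=lambda r: r.start
    )
    for row, read in enumerate(ordered):
        for col, off in enumerate(offsets):
            base = _naive_base_at(read, site.pos + off)
            expected = 0.0 if base is None else codes["deletion"] if base == "-" else codes[base]
            assert enc.values[row, 11 + col, 0] == pytest.approx(expected), (row, col)


class TestIndelEncoding:
    def test_shape_invariant(self, sim_small):
        site = _some_site(sim_small, "indel")
        enc = encode_site(site, sim_small["tumor"], sim_small["normal"], sim_small["reference"])
        assert enc.shape == (140, 150, 5)

    def test_35bp_insertion_fully_represented(self):
        reference = "A" * 40 + "C" * 60
        ins = "G" * 35
        site = GenomicSite("chr1", 39, "A", "A" + ins)
        read = make_read(20, "A" * 20 + ins + "C" * 20, cigar=[(0, 20), (1, 35), (0, 20)])
        row = encode_indel_inplace(read, site, reference)
        codes = channel_codes()
        anchor = EncodingConfig().indel_anchor_col
        block = row[anchor + 1 : anchor + 36]
        assert np.all(block[:, 0] == codes["G"])  # 35 inserted-base columns
        assert np.all(block[:, 4] == codes["no_reference"])

    def test_36bp_indel_rejected(self):
        site = GenomicSite("chr1", 10, "A", "A" + "G" * 36)
        with pytest.raises(ValueError, match="35"):
            encode_indel_inplace(make_read(0, "A" * 50), site, "A" * 100)

    def test_one_bp_deletion_single_deletion_column(self):
        reference = "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT" * 3
        pos = 50
        site = GenomicSite("chr1", pos, reference[pos : pos + 2], reference[pos])
        read = make_read(
            30,
            reference[30 : pos + 1] + reference[pos + 2 : pos + 2 + 19],
            cigar=[(0, pos + 1 - 30), (2, 1), (0, 19)],
        )
        row = encode_indel_inplace(read, site, reference)
        codes = channel_codes()
        del_cols = np.nonzero(row[:, 0] == codes["deletion"])[0]
        anchor = EncodingConfig().indel_anchor_col
        assert list(del_cols) == [anchor + 1]
        # reference channel still carries the deleted reference base
        assert row[anchor + 1, 4] == pytest.approx(codes[reference[pos + 1]])

    def test_read_without_indel_is_plain_reference_row(self):
        reference = "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT" * 4
        pos = 80
        site = GenomicSite("chr1", pos, reference[pos], reference[pos] + "TT")
        read = make_read(40, reference[40:140], name="noindel")
        row = encode_indel_inplace(read, site, reference)
        codes = channel_codes()
        anchor = EncodingConfig().indel_anchor_col
        # every covered column matches the reference channel
        covered = row[:, 3] != 0
        assert covered.any()
        assert np.array_equal(row[covered, 0], row[covered, 4])
        assert row[anchor, 0] == pytest.approx(codes[reference[pos]])
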