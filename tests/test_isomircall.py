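"""Collapsing, blacklist filtering, alignment and isomiR calling."""

from __future__ import annotations

import numpy as np
import pytest

from isomirseq.colorspace import ColorRead, encode
from isomirseq.isomircall import (
    CallConfig,
    PrecursorIndex,
    call_isomir,
    collapse_reads,
    filter_blacklist,
    label_isomir,
    process_sample,
)
from isomirseq.refio import Precursor, ReferenceSet

from conftest import random_sequence
from oracle import oracle_align

CFG = CallConfig()
A0 = CFG.adaptor[0]


def color_read(insert: str, rid: str = "r", n_adaptor: int = 8) -> ColorRead:
    return ColorRead(rid, "T", encode(insert + CFG.adaptor[:n_adaptor], "T"))


class TestCollapse:
    def test_counts(self):
        out = collapse_reads(["AAC", "AAC", "GGT"])
        assert [(seq, n) for _, seq, n in out] == [("AAC", 2), ("GGT", 1)]

    def test_empty(self):
        assert collapse_reads([]) == []

    def test_conservation_from_multinomial_draws(self):
        rng = np.random.default_rng(0)
        species = ["ACGT", "GGTT", "TTAA"]
        reads = [species[i] for i in rng.integers(0, 3, 1000)]
        out = collapse_reads(reads)
        assert len(out) == 3
        assert sum(n for _, _, n in out) == 1000

    def test_colorspace_reads_keyed_by_primer_and_colors(self):
        reads = [ColorRead("a", "T", "012"), ColorRead("b", "T", "012"),
                 ColorRead("c", "G", "012")]
        out = collapse_reads(reads)
        assert sorted((r.primer, r.colors, r.count) for r in out) == [
            ("G", "012", 1), ("T", "012", 2)]


class TestBlacklist:
    BL = [("tRNA-1", "ACGTACGTACGTACGTACGTACGTACGTAC")]

    def test_exact_fragment_removed(self):
        reads = [("r1", "ACGTACGTACGTACGTACGT", 1)]
        kept, removed = filter_blacklist(reads, self.BL)
        assert kept == [] and removed == 1

    def test_empty_blacklist_is_identity(self):
        reads = [("r1", "ACGTACGTACGTACGTACGT", 1)]
        kept, removed = filter_blacklist(reads, [])
        assert kept == reads and removed == 0

    def test_hamming_distance_one_kept_at_zero_tolerance(self):
        reads = [("r1", "ACGTACGTACCTACGTACGT", 1)]
        kept, _ = filter_blacklist(reads, self.BL, max_mm=0)
        assert kept == reads
        kept, _ = filter_blacklist(reads, self.BL, max_mm=1)
        assert kept == []

    def test_colorspace_read_matched_by_decoded_prefix(self):
        read = color_read("ACGTACGTACGTACGTACGT")
        kept, removed = filter_blacklist([read], self.BL)
        assert kept == [] and removed == 1


@pytest.fixture(scope="module")
def mir24_index(mir24_ref):
    return PrecursorIndex(mir24_ref, CFG)


class TestAlign:
    def test_canonical_span_hits_flag_none(self, mir24_ref, mir24_index):
        seq = mir24_ref.precursor("hsa-mir-24-1").sequence
        hit = mir24_index.align_colorspace(color_read(seq[43:65]))
        assert (hit.start, hit.aligned_len, hit.boundary_flag) == (44, 22, "none")
        assert hit.n_color_mismatches == 0

    def test_single_addition_detected(self, mir24_ref, mir24_index):
        seq = mir24_ref.precursor("hsa-mir-24-1").sequence
        # template 44..64 plus A; position 65 (0-based 64) differs from A
        assert seq[64] != "A"
        hit = mir24_index.align_colorspace(color_read(seq[43:64] + "A"))
        assert (hit.start, hit.template_len, hit.boundary_flag, hit.addition) == (
            44, 21, "single_nta", "A")

    def test_double_addition_detected(self, mir24_ref, mir24_index):
        seq = mir24_ref.precursor("hsa-mir-24-1").sequence
        # positions 66 and 67 are G in the fixture; AA is non-template twice
        hit = mir24_index.align_colorspace(color_read(seq[43:65] + "AA"))
        assert (hit.start, hit.template_len, hit.boundary_flag, hit.addition) == (
            44, 22, "double_nta", "AA")

    def test_two_internal_errors_reject_read(self, mir24_ref, mir24_index):
        seq = mir24_ref.precursor("hsa-mir-24-1").sequence
        read = color_read(seq[43:65])
        colors = list(read.colors)
        for pos in (4, 9):
            colors[pos] = str((int(colors[pos]) + 1) % 4)
        assert mir24_index.align_colorspace(ColorRead("r", "T", "".join(colors))) is None

    def test_one_internal_error_corrected(self, mir24_ref, mir24_index):
        seq = mir24_ref.precursor("hsa-mir-24-1").sequence
        read = color_read(seq[43:65])
        colors = list(read.colors)
        colors[7] = str((int(colors[7]) + 3) % 4)
        hit = mir24_index.align_colorspace(ColorRead("r", "T", "".join(colors)))
        assert (hit.start, hit.aligned_len, hit.n_color_mismatches) == (44, 22, 1)
        assert hit.boundary_flag == "none"

    def test_templated_extension_stays_templated(self, mir24_ref, mir24_index):
        # a trailing base equal to the template is a 3' template extension,
        # never an addition call
        seq = mir24_ref.precursor("hsa-mir-24-1").sequence
        hit = mir24_index.align_colorspace(color_read(seq[43:65] + seq[65]))
        assert hit.boundary_flag == "none"
        assert (hit.start, hit.aligned_len) == (44, 23)

    def test_basespace_equivalent_calls(self, mir24_ref, mir24_index):
        seq = mir24_ref.precursor("hsa-mir-24-1").sequence
        for insert in (seq[43:65], seq[43:64] + "A", seq[43:65] + "AA"):
            ch = mir24_index.align_colorspace(color_read(insert))
            bh = mir24_index.align_basespace(insert)
            assert (ch.precursor_id, ch.start, ch.template_len, ch.addition) == (
                bh.precursor_id, bh.start, bh.template_len, bh.addition)


@pytest.fixture(scope="module")
def toy():
    rng = np.random.default_rng(42)
    precursors = {
        f"p{i:02d}": random_sequence(int(rng.integers(60, 90)), seed=1000 + i)
        for i in range(10)
    }
    ref = ReferenceSet(
        precursors={k: Precursor(k, v) for k, v in precursors.items()},
        annotations=[],
    )
    return precursors, PrecursorIndex(ref, CFG), rng


class TestOracleEquivalence:
    """Production aligner vs brute-force enumeration on toy references."""

    def test_exact_agreement_on_synthetic_reads(self, toy):
        precursors, index, rng = toy
        ids = sorted(precursors)
        n_checked = 0
        for i in range(120):
            pid = ids[int(rng.integers(0, len(ids)))]
            seq = precursors[pid]
            length = int(rng.integers(16, 25))
            start = int(rng.integers(0, len(seq) - length))
            insert = seq[start : start + length]
            kind = i % 4
            if kind == 1:  # single addition
                forbidden = {CFG.adaptor[0]}
                if start + length < len(seq):
                    forbidden.add(seq[start + length])
                insert += [b for b in "ACGT" if b not in forbidden][
                    int(rng.integers(0, 4 - len(forbidden)))
                ]
            elif kind == 2:  # random junk tail
                insert += "".join(
                    "ACGT"[j] for j in rng.integers(0, 4, 4)
                )
            colors = list(encode(insert + CFG.adaptor[:8], "T"))
            n_err = int(rng.integers(0, 3)) if kind == 3 else 0
            for _ in range(n_err):
                pos = int(rng.integers(0, len(colors) - 2))
                colors[pos] = str((int(colors[pos]) + int(rng.integers(1, 4))) % 4)
            colors = "".join(colors)
            expected = oracle_align(colors, "T", precursors, CFG.adaptor,
                                    CFG.min_template, CFG.max_insert)
            hit = index.align_colorspace(ColorRead("r", "T", colors))
            if expected is None:
                assert hit is None
            else:
                assert hit is not None
                assert (
                    hit.precursor_id, hit.start, hit.template_len,
                    hit.boundary_flag, hit.n_color_mismatches, hit.addition,
                ) == expected
            n_checked += 1
        assert n_checked == 120


class TestCallAndLabel:
    def test_observation_spans_and_label(self, mir24_ref, mir24_index):
        seq = mir24_ref.precursor("hsa-mir-24-1").sequence
        hit = mir24_index.align_colorspace(color_read(seq[43:62] + "A"))
        obs = call_isomir(hit, mir24_ref)
        assert (obs.mature_id, obs.template_start, obs.template_end,
                obs.addition, obs.reported_end) == ("hsa-miR-24", 44, 62, "A", 63)
        assert label_isomir(obs, mir24_ref) == ("miR-24-A", "44-63 (44-65)")

    def test_canonical_label_has_no_ref_span(self, mir24_ref, mir24_index):
        seq = mir24_ref.precursor("hsa-mir-24-1").sequence
        hit = mir24_index.align_colorspace(color_read(seq[43:65]))
        obs = call_isomir(hit, mir24_ref)
        assert label_isomir(obs, mir24_ref) == ("miR-24", "44-65")

    def test_addition_ending_at_canonical_end(self, mir24_ref, mir24_index):
        # template 44..64 + A reports span 44-65, identical to the canonical
        # span, so no reference span is printed but the -A suffix remains
        seq = mir24_ref.precursor("hsa-mir-24-1").sequence
        hit = mir24_index.align_colorspace(color_read(seq[43:64] + "A"))
        obs = call_isomir(hit, mir24_ref)
        assert label_isomir(obs, mir24_ref) == ("miR-24-A", "44-65")

    def test_addition_prints_as_u(self, mir24_ref, mir24_index):
        seq = mir24_ref.precursor("hsa-mir-24-1").sequence
        assert seq[64] != "T"
        hit = mir24_index.align_colorspace(color_read(seq[43:64] + "T"))
        name, _ = label_isomir(call_isomir(hit, mir24_ref), mir24_ref)
        assert name == "miR-24-U"

    def test_unassigned_fragment_returns_none(self, mir24_ref, mir24_index):
        seq = mir24_ref.precursor("hsa-mir-24-1").sequence
        hit = mir24_index.align_colorspace(color_read(seq[2:20]))
        assert hit is not None
        assert call_isomir(hit, mir24_ref) is None


class TestProcessSample:
    def test_count_conservation(self, mir24_ref):
        seq = mir24_ref.precursor("hsa-mir-24-1").sequence
        reads = (
            [color_read(seq[43:65], f"a{i}") for i in range(5)]
            + [color_read(seq[43:64] + "A", f"b{i}") for i in range(3)]
            + [color_read(seq[2:20], "frag")]  # unassigned fragment
            + [ColorRead("junk", "T", "0123" * 8)]
        )
        result = process_sample(reads, mir24_ref, "s1", mode="color")
        assert result.n_input == 10
        assert (
            result.n_assigned + result.n_unaligned + result.n_unassigned
            + result.n_blacklisted
        ) == result.n_input
        frame = result.to_frame()
        assert frame["count"].tolist() == [5, 3]

    def test_nonsense_mode_raises(self, mir24_ref):
        with pytest.raises(ValueError):
            process_sample([], mir24_ref, "s1", mode="weird")
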