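"""Locus spectra, NTA panels, heterogeneity, lengths and correlation."""

from __future__ import annotations

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isomirseq.refio import MatureAnnotation, Precursor, ReferenceSet
from isomirseq.spectrum import (
    build_spectra,
    build_spectrum,
    end_heterogeneity,
    expression_vs_type_correlation,
    length_distribution,
    modal_length,
    nta_summary,
)

from conftest import obs_frame


def ref_for(mature_ids, start=44, end=65):
    return ReferenceSet(
        precursors={m.replace("miR", "mir"): Precursor(m.replace("miR", "mir"), "A" * 90)
                    for m in mature_ids},
        annotations=[
            MatureAnnotation(m, m.replace("miR", "mir"), start, end, "3p")
            for m in mature_ids
        ],
    )


class TestBuildSpectrum:
    def test_percentages_and_fold(self):
        obs = obs_frame([("s", "miR-24", 44, 65, "", 900),
                         ("s", "miR-24", 44, 63, "", 100)])
        spec = build_spectrum(obs, "miR-24")
        assert [round(e.percentage, 6) for e in spec.entries] == [90.0, 10.0]
        assert spec.fold_most_secondary == 9.0

    def test_min_count_floor_drops_species(self):
        obs = obs_frame([("s", "miR-24", 44, 65, "", 9)])
        assert build_spectrum(obs, "miR-24", min_count=10).entries == []

    def test_similar_abundance_fold(self):
        obs = obs_frame([("s", "miR-451", 17, 38, "", 117),
                         ("s", "miR-451", 17, 39, "", 100)])
        spec = build_spectrum(obs, "miR-451")
        assert spec.fold_most_secondary == pytest.approx(1.17)

    def test_single_species_fold_is_infinite(self):
        obs = obs_frame([("s", "miR-24", 44, 65, "", 50)])
        assert build_spectrum(obs, "miR-24").fold_most_secondary == math.inf

    @given(counts=st.lists(st.integers(1, 5000), min_size=1, max_size=12),
           floor=st.integers(1, 200))
    @settings(derandomize=True, deadline=None)
    def test_percentages_sum_to_100_and_monotone_in_floor(self, counts, floor):
        rows = [("s", "m", 40, 60 + i, "", c) for i, c in enumerate(counts)]
        spec = build_spectrum(obs_frame(rows), "m", min_count=floor)
        if spec.entries:
            assert sum(e.percentage for e in spec.entries) == pytest.approx(100.0)
        stricter = build_spectrum(obs_frame(rows), "m", min_count=floor + 50)
        assert len(stricter.entries) <= len(spec.entries)


class TestNtaSummary:
    def test_all_unmodified_gives_zero(self):
        obs = obs_frame([("s", "m1", 44, 65, "", 100), ("s", "m2", 44, 65, "", 40)])
        summary = nta_summary(build_spectra(obs, "s"))
        assert summary.type_fraction_total == 0.0
        assert summary.count_fraction_total == 0.0
        assert summary.modal_addition is None

    def test_type_versus_count_share(self):
        obs = obs_frame([("s", "m1", 44, 65, "A", 10), ("s", "m1", 44, 65, "", 90)])
        summary = nta_summary(build_spectra(obs, "s"))
        assert summary.type_fraction_total == 0.5
        assert summary.count_fraction_total == pytest.approx(0.1)

    def test_per_nucleotide_panels_sum_to_totals(self):
        obs = obs_frame([
            ("s", "m1", 44, 65, "", 500),
            ("s", "m1", 44, 65, "A", 60),
            ("s", "m1", 44, 64, "T", 30),
            ("s", "m2", 40, 61, "", 300),
            ("s", "m2", 40, 61, "AA", 12),
        ])
        summary = nta_summary(build_spectra(obs, "s"))
        assert sum(summary.type_by_nucleotide_of_all.values()) == pytest.approx(
            summary.type_fraction_total)
        assert sum(summary.count_by_nucleotide_of_all.values()) == pytest.approx(
            summary.count_fraction_total)
        assert sum(summary.type_by_nucleotide_of_modified.values()) == pytest.approx(1.0)
        assert summary.double_addition_type_fractions == {"AA": 1.0}
        # U printed for T additions
        assert "U" in summary.type_by_nucleotide_of_all

    def test_two_way_aggregation_agrees(self):
        # global pass over all loci == sum of per-locus passes
        obs = obs_frame([
            ("s", "m1", 44, 65, "", 500), ("s", "m1", 44, 65, "A", 60),
            ("s", "m2", 40, 61, "", 300), ("s", "m2", 40, 61, "T", 45),
        ])
        spectra = build_spectra(obs, "s")
        combined = nta_summary(spectra)
        per_locus = [nta_summary({m: s}) for m, s in spectra.items()]
        n_mod = sum(p.n_modified_species for p in per_locus)
        n_all = sum(p.n_species for p in per_locus)
        assert combined.type_fraction_total == pytest.approx(n_mod / n_all)


class TestEndHeterogeneity:
    def test_only_canonical_is_zero_zero(self):
        obs = obs_frame([("s", "miR-24", 44, 65, "", 100)])
        ref = ref_for(["miR-24"])
        assert end_heterogeneity(build_spectra(obs, "s"), ref) == (0.0, 0.0)

    def test_three_prime_variant_only(self):
        obs = obs_frame([("s", "miR-24", 44, 61, "", 50),
                         ("s", "miR-24", 44, 65, "", 50)])
        het5, het3 = end_heterogeneity(build_spectra(obs, "s"), ref_for(["miR-24"]))
        assert (het5, het3) == (0.0, 0.5)

    def test_modified_species_excluded(self):
        obs = obs_frame([("s", "miR-24", 44, 65, "", 50),
                         ("s", "miR-24", 44, 63, "A", 50)])
        het5, het3 = end_heterogeneity(build_spectra(obs, "s"), ref_for(["miR-24"]))
        assert (het5, het3) == (0.0, 0.0)

    def test_species_may_count_in_both_ends(self):
        obs = obs_frame([("s", "miR-24", 45, 64, "", 50)])
        het5, het3 = end_heterogeneity(build_spectra(obs, "s"), ref_for(["miR-24"]))
        assert (het5, het3) == (1.0, 1.0)


class TestLengthDistribution:
    def test_uniform_length(self):
        obs = obs_frame([("s", "m", 44, 65, "", 10)])
        counts, species = length_distribution(obs)
        assert counts == {22: 10} and species == {22: 1}

    def test_mixture_mode(self):
        obs = obs_frame([("s", "m", 44, 64, "", 1), ("s", "m", 44, 65, "", 8),
                         ("s", "m", 44, 66, "", 1)])
        counts, _ = length_distribution(obs)
        assert modal_length(counts) == 22

    def test_addition_extends_length(self):
        obs = obs_frame([("s", "m", 44, 65, "AA", 5)])
        counts, _ = length_distribution(obs)
        assert counts == {24: 5}

    def test_empty(self):
        counts, species = length_distribution(obs_frame([]))
        assert counts == {} and species == {}


class TestExpressionTypeCorrelation:
    def test_perfectly_coupled_gives_rho_one(self):
        rows = []
        for i in range(6):
            expr = 2000 * (i + 1)
            for j in range(i + 2):  # more types with more expression
                rows.append(("s", f"m{i}", 40, 60 + j, "", expr // (j + 1)))
        spectra = build_spectra(obs_frame(rows), "s")
        rho, table = expression_vs_type_correlation(spectra)
        assert rho == pytest.approx(1.0)
        assert len(table) == 6

    def test_decoupled_correlation_is_weak(self):
        import numpy as np

        rng = np.random.default_rng(3)
        rows = []
        for i in range(50):
            expr = int(rng.integers(1500, 80000))
            n_types = int(rng.integers(1, 8))
            for j in range(n_types):
                # the most abundant count (= expression) stays independent
                # of how many further species the locus carries
                rows.append(("s", f"m{i:02d}", 40, 58 + j, "",
                             expr if j == 0 else expr // 2))
        spectra = build_spectra(obs_frame(rows), "s")
        rho, _ = expression_vs_type_correlation(spectra)
        assert abs(rho) < 0.3

    def test_fewer_than_three_loci_undefined(self):
        rows = [("s", "m1", 40, 60, "", 5000), ("s", "m2", 40, 60, "", 4000)]
        rho, table = expression_vs_type_correlation(build_spectra(obs_frame(rows), "s"))
        assert rho is None
        assert len(table) == 2
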