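"""Per-locus isomiR spectra and repertoire statistics.

A species is keyed by (mature_id, template_start, template_end, addition);
identical sequences observed in different samples are the same species.  All
statistics run on one sample's observations at a stated count threshold
(>=10 for the full repertoire view, >99 for the abundant-species view).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .refio import MatureAnnotation, ReferenceSet, resolve_locus

OBS_KEY = ["mature_id", "template_start", "template_end", "addition"]


@dataclass
class SpectrumEntry:
    template_start: int
    template_end: int
    addition: str
    count: int
    percentage: float = 0.0

    @property
    def reported_end(self) -> int:
        return self.template_end + len(self.addition)

    @property
    def length(self) -> int:
        return self.template_end - self.template_start + 1 + len(self.addition)


@dataclass
class LocusSpectrum:
    """All retained isomiRs of one mature miRNA in one sample."""

    mature_id: str
    entries: list[SpectrumEntry] = field(default_factory=list)

    @property
    def total(self) -> int:
        return sum(e.count for e in self.entries)

    @property
    def most_abundant(self) -> SpectrumEntry | None:
        return self.entries[0] if self.entries else None

    @property
    def secondary_abundant(self) -> SpectrumEntry | None:
        return self.entries[1] if len(self.entries) > 1 else None

    @property
    def fold_most_secondary(self) -> float:
        """count(most) / count(secondary); inf for a single-species locus."""
        if not self.entries:
            return math.nan
        if len(self.entries) == 1:
            return math.inf
        return self.entries[0].count / self.entries[1].count


def build_spectrum(
    observations: pd.DataFrame, mature_id: str, min_count: int = 10
) -> LocusSpectrum:
    """Build a locus spectrum from one sample's observation rows.

    Species below ``min_count`` are dropped; remaining percentages are of
    the retained total.  Order is count descending, then species key
    ascending (the deterministic tie rule for "most abundant").
    """
    rows = observations[observations.mature_id == mature_id]
    entries = [
        SpectrumEntry(
            int(r.template_start), int(r.template_end), r.addition, int(r["count"])
        )
        for _, r in rows.iterrows()
        if int(r["count"]) >= min_count
    ]
    entries.sort(
        key=lambda e: (-e.count, e.template_start, e.template_end, e.addition)
    )
    total = sum(e.count for e in entries)
    for e in entries:
        e.percentage = 100.0 * e.count / total if total else 0.0
    return LocusSpectrum(mature_id=mature_id, entries=entries)


def build_spectra(
    observations: pd.DataFrame, sample_id: str, min_count: int = 10
) -> dict[str, LocusSpectrum]:
    """Spectra for every locus of one sample, dropping empty spectra."""
    sample = observations[observations.sample_id == sample_id]
    sample = (
        sample.groupby(OBS_KEY, as_index=False)
        .agg({"count": "sum"})
        if len(sample)
        else sample
    )
    spectra: dict[str, LocusSpectrum] = {}
    for mature_id in sorted(sample.mature_id.unique()) if len(sample) else []:
        spec = build_spectrum(sample, mature_id, min_count)
        if spec.entries:
            spectra[mature_id] = spec
    return spectra


@dataclass
class NTASummary:
    """The six-panel non-template-addition breakdown for one sample.

    ``type_*`` fractions are over distinct species, ``count_*`` over reads.
    ``*_of_all`` uses all retained species/reads as denominator;
    ``*_of_modified`` restricts the denominator to modified ones (both
    denominators are reported because figure captions in this field often
    leave the choice ambiguous).
    """

    type_fraction_total: float
    count_fraction_total: float
    type_by_nucleotide_of_all: dict[str, float]
    count_by_nucleotide_of_all: dict[str, float]
    type_by_nucleotide_of_modified: dict[str, float]
    count_by_nucleotide_of_modified: dict[str, float]
    double_addition_type_fractions: dict[str, float]
    double_addition_count_fractions: dict[str, float]
    n_species: int
    n_modified_species: int

    @property
    def modal_addition(self) -> str | None:
        d = self.type_by_nucleotide_of_all
        if not d or all(v == 0 for v in d.values()):
            return None
        return max(sorted(d), key=lambda k: d[k])


def _addition_class(addition: str) -> str:
    """Single additions keyed by nucleotide (U for T); doubles by pair."""
    return addition.replace("T", "U")


def nta_summary(spectra: dict[str, LocusSpectrum], min_count: int = 10) -> NTASummary:
    """Aggregate addition statistics over the retained species of one sample.

    ``min_count`` is documentation of the threshold the spectra were built
    at; the summary itself runs on whatever species the spectra retain.
    """
    n_species = 0
    n_reads = 0
    n_mod_species = 0
    n_mod_reads = 0
    type_by: dict[str, int] = {}
    count_by: dict[str, int] = {}
    dbl_type: dict[str, int] = {}
    dbl_count: dict[str, int] = {}
    n_dbl_species = 0
    n_dbl_reads = 0
    for spec in spectra.values():
        for e in spec.entries:
            n_species += 1
            n_reads += e.count
            if not e.addition:
                continue
            n_mod_species += 1
            n_mod_reads += e.count
            cls = _addition_class(e.addition)
            type_by[cls] = type_by.get(cls, 0) + 1
            count_by[cls] = count_by.get(cls, 0) + e.count
            if len(e.addition) == 2:
                n_dbl_species += 1
                n_dbl_reads += e.count
                dbl_type[cls] = dbl_type.get(cls, 0) + 1
                dbl_count[cls] = dbl_count.get(cls, 0) + e.count

    def frac(d: dict[str, int], denom: int) -> dict[str, float]:
        return {k: (v / denom if denom else 0.0) for k, v in sorted(d.items())}

    return NTASummary(
        type_fraction_total=n_mod_species / n_species if n_species else 0.0,
        count_fraction_total=n_mod_reads / n_reads if n_reads else 0.0,
        type_by_nucleotide_of_all=frac(type_by, n_species),
        count_by_nucleotide_of_all=frac(count_by, n_reads),
        type_by_nucleotide_of_modified=frac(type_by, n_mod_species),
        count_by_nucleotide_of_modified=frac(count_by, n_mod_reads),
        double_addition_type_fractions=frac(dbl_type, n_dbl_species),
        double_addition_count_fractions=frac(dbl_count, n_dbl_reads),
        n_species=n_species,
        n_modified_species=n_mod_species,
    )


def end_heterogeneity(
    spectra: dict[str, LocusSpectrum], ref: ReferenceSet
) -> tuple[float, float]:
    """(5'-variant, 3'-variant) species fractions, modified species excluded.

    A species is 5'-variant iff its template start differs from the canonical
    start, 3'-variant iff its template end differs; a species may count in
    both.  Loci without a canonical annotation are skipped.
    """
    n = 0
    n5 = 0
    n3 = 0
    for mature_id, spec in spectra.items():
        try:
            annotation: MatureAnnotation = resolve_locus(mature_id, ref)
        except Exception:
            continue
        for e in spec.entries:
            if e.addition:
                continue
            n += 1
            if e.template_start != annotation.start:
                n5 += 1
            if e.template_end != annotation.end:
                n3 += 1
    if n == 0:
        return (0.0, 0.0)
    return (n5 / n, n3 / n)


def length_distribution(
    observations: pd.DataFrame,
) -> tuple[dict[int, int], dict[int, int]]:
    """(count-weighted, species-weighted) read-length histograms.

    Length includes any non-template addition.
    """
    count_hist: dict[int, int] = {}
    species_hist: dict[int, int] = {}
    for _, r in observations.iterrows():
        length = int(r.template_end) - int(r.template_start) + 1 + len(r.addition)
        count_hist[length] = count_hist.get(length, 0) + int(r["count"])
        species_hist[length] = species_hist.get(length, 0) + 1
    return (
        dict(sorted(count_hist.items())),
        dict(sorted(species_hist.items())),
    )


def modal_length(hist: dict[int, int]) -> int | None:
    if not hist:
        return None
    return max(sorted(hist), key=lambda k: hist[k])


def expression_vs_type_correlation(
    spectra: dict[str, LocusSpectrum],
    abundant_species_count_min: int = 99,
    locus_min: int = 999,
    scheme: str = "most",
) -> tuple[float | None, pd.DataFrame]:
    """Spearman rank correlation of locus expression vs number of abundant
    isomiR species.

    Loci qualify when the most abundant isomiR exceeds ``locus_min`` counts;
    species count within a locus only considers species above
    ``abundant_species_count_min``.  With fewer than 3 qualifying loci the
    correlation is undefined (None) but the paired table is still returned.
    """
    rows = []
    for mature_id in sorted(spectra):
        spec = spectra[mature_id]
        most = spec.most_abundant
        if most is None or most.count <= locus_min:
            continue
        expression = most.count if scheme == "most" else spec.total
        n_types = sum(
            1 for e in spec.entries if e.count > abundant_species_count_min
        )
        rows.append(
            {"mature_id": mature_id, "expression": expression, "n_types": n_types}
        )
    table = pd.DataFrame(rows, columns=["mature_id", "expression", "n_types"])
    if len(table) < 3:
        return None, table
    rho = stats.spearmanr(table.expression, table.n_types).statistic
    return (None if pd.isna(rho) else float(rho)), table
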