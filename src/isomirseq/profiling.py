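"""Expression profiling, top-N ranking, Venn analysis and DE calling.

Differential expression here is the single-library, replicate-free kind: a
raw-count log2 fold change with a detection floor and a fixed imputation
rule, not a count-model test.  Counts below the imputation floor (default
100) are replaced by a default count of 10 on each side independently; a
locus/isomiR is only tested when it exceeds an abundance floor in at least
one of the two samples; |log2FC| strictly greater than the threshold
(default 4, i.e. 16-fold raw) is marked significant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

from .spectrum import LocusSpectrum


@dataclass
class ExpressionProfile:
    """Per-sample locus abundances under one estimation scheme."""

    sample_id: str
    scheme: str  # "most" (most abundant isomiR) or "sum" (all isomiRs)
    values: dict[str, int] = field(default_factory=dict)


def quantify(
    spectra: dict[str, LocusSpectrum], scheme: str, sample_id: str = ""
) -> ExpressionProfile:
    """Quantify each locus by its most abundant isomiR or the isomiR sum."""
    if scheme not in ("most", "sum"):
        raise ValueError(f"unknown scheme {scheme!r}")
    values: dict[str, int] = {}
    for mature_id, spec in spectra.items():
        if not spec.entries:
            continue
        values[mature_id] = (
            spec.most_abundant.count if scheme == "most" else spec.total
        )
    return ExpressionProfile(sample_id=sample_id, scheme=scheme, values=values)


def top_n(profile: ExpressionProfile, n: int = 10) -> list[str]:
    """Top-n loci by value, ties broken by mature_id ascending."""
    ranked = sorted(profile.values.items(), key=lambda kv: (-kv[1], kv[0]))
    return [mature_id for mature_id, _ in ranked[:n]]


def shared_species(lists: dict[str, list]) -> dict[tuple[str, ...], int]:
    """Venn region cardinalities for 2 or 3 per-sample species lists.

    Returns pairwise-EXCLUSIVE regions: the key (a,) counts species private
    to a, (a, b) species in exactly a and b, and (a, b, c) the triple
    intersection.  Plain intersections are available via
    :func:`plain_intersection`.  Duplicate entries within one list are an
    error (the lists are sets).
    """
    if len(lists) not in (2, 3):
        raise ValueError("shared_species expects 2 or 3 lists")
    sets: dict[str, set] = {}
    for name, items in lists.items():
        if len(items) != len(set(items)):
            raise ValueError(f"list {name!r} contains duplicates")
        sets[name] = set(items)
    names = sorted(sets)
    regions: dict[tuple[str, ...], int] = {}
    for r in range(len(names), 0, -1):
        for combo in combinations(names, r):
            members = set.intersection(*(sets[n] for n in combo))
            for other in names:
                if other not in combo:
                    members -= sets[other]
            regions[combo] = len(members)
    return regions


def plain_intersection(lists: dict[str, list], *names: str) -> set:
    """Plain (non-exclusive) intersection of the named lists."""
    use = names or tuple(lists)
    return set.intersection(*(set(lists[n]) for n in use))


@dataclass
class DECall:
    """One fold-change record between a pair of samples."""

    unit: str | tuple
    scheme: str
    log2fc: float
    sample_pair: tuple[str, str]
    count_a: int
    count_b: int
    imputed_a: bool
    imputed_b: bool
    significant: bool


def log2_fold_change(
    count_a: int,
    count_b: int,
    impute_floor: int = 100,
    impute_value: int = 10,
) -> tuple[float, bool, bool]:
    """log2(a/b) after imputing each side below the floor to the default.

    Imputation is applied to each side independently, so the statistic is
    antisymmetric in its arguments and always finite.
    """
    imputed_a = count_a < impute_floor
    imputed_b = count_b < impute_floor
    a = impute_value if imputed_a else count_a
    b = impute_value if imputed_b else count_b
    return math.log2(a / b), imputed_a, imputed_b


def _de_calls(
    values_a: dict,
    values_b: dict,
    scheme: str,
    sample_pair: tuple[str, str],
    min_count: int,
    lfc_threshold: float,
    impute_floor: int,
    impute_value: int,
) -> list[DECall]:
    calls = []
    for unit in sorted(set(values_a) | set(values_b), key=str):
        a = int(values_a.get(unit, 0))
        b = int(values_b.get(unit, 0))
        if max(a, b) <= min_count:
            continue
        lfc, ia, ib = log2_fold_change(a, b, impute_floor, impute_value)
        calls.append(
            DECall(
                unit=unit,
                scheme=scheme,
                log2fc=lfc,
                sample_pair=sample_pair,
                count_a=a,
                count_b=b,
                imputed_a=ia,
                imputed_b=ib,
                significant=abs(lfc) > lfc_threshold,
            )
        )
    calls.sort(key=lambda c: (-abs(c.log2fc), str(c.unit)))
    return calls


def de_mirnas(
    profile_a: ExpressionProfile,
    profile_b: ExpressionProfile,
    min_count: int = 999,
    lfc_threshold: float = 4.0,
    impute_floor: int = 100,
    impute_value: int = 10,
) -> list[DECall]:
    """Locus-level fold-change calls; only loci above ``min_count`` in at
    least one sample are tested (the floor applies to raw counts, before
    imputation)."""
    if profile_a.scheme != profile_b.scheme:
        raise ValueError("profiles must use the same scheme")
    return _de_calls(
        profile_a.values,
        profile_b.values,
        profile_a.scheme,
        (profile_a.sample_id, profile_b.sample_id),
        min_count,
        lfc_threshold,
        impute_floor,
        impute_value,
    )


def _modified_values(spectra: dict[str, LocusSpectrum]) -> dict[tuple, int]:
    values: dict[tuple, int] = {}
    for mature_id, spec in spectra.items():
        for e in spec.entries:
            if e.addition:
                key = (mature_id, e.template_start, e.template_end, e.addition)
                values[key] = values.get(key, 0) + e.count
    return values


def de_modified_isomirs(
    spectra_a: dict[str, LocusSpectrum],
    spectra_b: dict[str, LocusSpectrum],
    min_count: int = 300,
    lfc_threshold: float = 4.0,
    impute_floor: int = 100,
    impute_value: int = 10,
    sample_pair: tuple[str, str] = ("a", "b"),
) -> list[DECall]:
    """IsomiR-resolution fold-change calls for 3'-modified species only."""
    return _de_calls(
        _modified_values(spectra_a),
        _modified_values(spectra_b),
        "isomir",
        sample_pair,
        min_count,
        lfc_threshold,
        impute_floor,
        impute_value,
    )


@dataclass
class SchemeConsistency:
    jaccard: float
    only_most: set
    only_sum: set
    both: set


def scheme_consistency(
    de_most: list[DECall], de_sum: list[DECall]
) -> SchemeConsistency:
    """Agreement of significant sets between the two estimation schemes.

    Jaccard of two empty sets is defined as 1.0 (nothing disagrees).
    """
    sig_most = {c.unit for c in de_most if c.significant}
    sig_sum = {c.unit for c in de_sum if c.significant}
    union = sig_most | sig_sum
    jaccard = 1.0 if not union else len(sig_most & sig_sum) / len(union)
    return SchemeConsistency(
        jaccard=jaccard,
        only_most=sig_most - sig_sum,
        only_sum=sig_sum - sig_most,
        both=sig_most & sig_sum,
    )
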