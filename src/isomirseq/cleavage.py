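"""Dominant Drosha/Dicer cleavage-site inference from isomiR spectra.

The 5' and 3' template ends of the retained isomiRs of a locus are treated
as the observable footprints of the two endonucleolytic cuts that released
the mature strand from its hairpin.  On a 5p-arm mature the 5' end reflects
the Drosha cut (hairpin base) and the 3' end the Dicer cut (near the loop);
on a 3p arm the mapping is reversed.  Non-template additions are appended
after Dicer processing, so they never contribute to end positions: the
template end is used throughout.

The most abundant isomiR's ends are the dominant sites; when the most/
secondary count fold is below the dominance threshold (default 5) the
secondary isomiR's ends are flagged as additional, non-dominant sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .refio import MatureAnnotation
from .spectrum import LocusSpectrum


@dataclass
class CleavageCall:
    mature_id: str
    arm: str | None
    five_prime_sites: dict[int, float] = field(default_factory=dict)
    three_prime_sites: dict[int, float] = field(default_factory=dict)
    dominant_5p_end_sites: list[int] = field(default_factory=list)
    dominant_3p_end_sites: list[int] = field(default_factory=list)
    secondary_5p_end_sites: list[int] = field(default_factory=list)
    secondary_3p_end_sites: list[int] = field(default_factory=list)
    dominance: bool = False
    fold_most_secondary: float = math.nan

    @property
    def drosha_sites(self) -> list[int] | None:
        if self.arm == "5p":
            return self.dominant_5p_end_sites
        if self.arm == "3p":
            return self.dominant_3p_end_sites
        return None

    @property
    def dicer_sites(self) -> list[int] | None:
        if self.arm == "5p":
            return self.dominant_3p_end_sites
        if self.arm == "3p":
            return self.dominant_5p_end_sites
        return None

    def contiguous_5p(self) -> bool:
        return _contiguous(sorted(self.five_prime_sites))

    def contiguous_3p(self) -> bool:
        return _contiguous(sorted(self.three_prime_sites))


def _contiguous(sites: list[int]) -> bool:
    return all(b - a == 1 for a, b in zip(sites, sites[1:]))


def infer_cleavage(
    spectrum: LocusSpectrum,
    annotation: MatureAnnotation | None,
    dominance_fold: float = 5.0,
) -> CleavageCall | None:
    """Infer end-site distributions and dominant cut sites for one locus.

    Site weights are count-weighted fractions of the retained spectrum (so
    they are invariant to globally rescaling all counts and sum to 1 per
    end).  Returns None on an empty spectrum.  With an unknown arm the
    sites are still reported but carry no enzyme labels.
    """
    if not spectrum.entries:
        return None
    total = spectrum.total
    five: dict[int, float] = {}
    three: dict[int, float] = {}
    for e in spectrum.entries:
        five[e.template_start] = five.get(e.template_start, 0.0) + e.count / total
        three[e.template_end] = three.get(e.template_end, 0.0) + e.count / total
    most = spectrum.most_abundant
    secondary = spectrum.secondary_abundant
    fold = spectrum.fold_most_secondary
    dominance = fold >= dominance_fold
    call = CleavageCall(
        mature_id=spectrum.mature_id,
        arm=annotation.arm if annotation is not None else None,
        five_prime_sites=dict(sorted(five.items())),
        three_prime_sites=dict(sorted(three.items())),
        dominant_5p_end_sites=[most.template_start],
        dominant_3p_end_sites=[most.template_end],
        dominance=dominance,
        fold_most_secondary=fold,
    )
    if not dominance and secondary is not None:
        if secondary.template_start != most.template_start:
            call.secondary_5p_end_sites = [secondary.template_start]
        if secondary.template_end != most.template_end:
            call.secondary_3p_end_sites = [secondary.template_end]
    return call
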