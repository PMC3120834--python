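"""Shared fixtures: a deterministic hairpin reference with a miR-24-like
locus, and small helpers for building observation tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from isomirseq.refio import MatureAnnotation, Precursor, ReferenceSet


def random_sequence(length: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, length))


@pytest.fixture(scope="session")
def mir24_ref() -> ReferenceSet:
    """An 88-nt hairpin with a mature annotated at 44-65 on the 3p arm.

    Position 66 is fixed to G so that an appended A (or a C, the default
    adaptor's first base) is unambiguously non-template, and position 43 is
    fixed so 5'-shifted reads stay distinguishable.
    """
    seq = list(random_sequence(88, seed=2401))
    seq[64] = "G"  # canonical last base; A/U additions after 44..64 stay non-template
    seq[65] = "G"  # 1-based position 66, the first notional addition site
    seq[66] = "G"  # second notional addition site
    sequence = "".join(seq)
    return ReferenceSet(
        precursors={"hsa-mir-24-1": Precursor("hsa-mir-24-1", sequence)},
        annotations=[MatureAnnotation("hsa-miR-24", "hsa-mir-24-1", 44, 65, "3p")],
    )


def obs_frame(rows: list[tuple]) -> pd.DataFrame:
    """(sample, mature, start, end, addition, count) tuples -> observation
    table of the shape the calling stage emits."""
    return pd.DataFrame(
        [
            {
                "sample_id": s,
                "mature_id": m,
                "precursor_id": m.replace("miR", "mir"),
                "template_start": a,
                "template_end": b,
                "addition": add,
                "reported_end": b + len(add),
                "count": n,
                "sequence": "",
            }
            for s, m, a, b, add, n in rows
        ]
    )
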