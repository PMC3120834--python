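"""Published placental top-10 tables, as machine-readable inputs.

These are the printed per-sample top-10 rankings of a placental small-RNA
study of pre-eclampsia (one normal, one mild, one severe library): miRNA
loci ranked by the most abundant isomiR and by the sum of all isomiRs, and
the top-10 3'-modified isomiR species with their observed spans on the
(first) precursor.  The underlying sequencing data were never deposited, so
these rankings are the study's only machine-checkable per-sample output;
they drive the shared-species (Venn) worked examples.
"""

from __future__ import annotations

SAMPLES = ("normal", "mild", "severe")

#: Top 10 loci by the most abundant isomiR, in printed rank order.
TOP10_MOST: dict[str, list[str]] = {
    "normal": [
        "miR-24", "miR-521", "miR-29b", "miR-103", "miR-515",
        "miR-424", "miR-143", "miR-145", "miR-23a", "miR-29c",
    ],
    "mild": [
        "miR-24", "miR-517a", "miR-519a", "miR-519d", "miR-517c",
        "miR-521", "miR-23a", "miR-103", "miR-520g", "miR-451",
    ],
    "severe": [
        "miR-24", "miR-517a", "miR-519d", "miR-519a", "miR-103",
        "miR-29a", "miR-130a", "miR-517c", "miR-23a", "miR-29c",
    ],
}

#: Top 10 loci by the sum of all isomiRs, in printed rank order.
TOP10_SUM: dict[str, list[str]] = {
    "normal": [
        "miR-24", "miR-515", "miR-145", "miR-143", "miR-424",
        "miR-521", "miR-29b", "miR-103", "miR-23a", "miR-29c",
    ],
    "mild": [
        "miR-24", "miR-517a", "miR-519d", "miR-519a", "miR-23a",
        "miR-451", "miR-520g", "miR-517c", "miR-521", "miR-103",
    ],
    "severe": [
        "miR-24", "miR-517a", "miR-519d", "miR-519a", "miR-23a",
        "miR-103", "miR-29a", "miR-517c", "miR-130a", "miR-29c",
    ],
}

#: Top 10 modified isomiR species: (name, observed_start, observed_end,
#: canonical_start, canonical_end).  Canonical span equals the observed one
#: where the table printed no separate reference span.
TOP10_MODIFIED: dict[str, list[tuple[str, int, int, int, int]]] = {
    "normal": [
        ("miR-24-A", 44, 63, 44, 65),
        ("miR-143-U", 61, 82, 61, 81),
        ("miR-424-A", 11, 33, 11, 32),
        ("miR-145-A", 16, 36, 16, 38),
        ("miR-515-U", 51, 74, 51, 72),
        ("miR-103-U", 48, 70, 48, 70),
        ("miR-515-U", 51, 73, 51, 72),
        ("miR-199a-A", 47, 69, 47, 68),
        ("miR-24-A", 44, 65, 44, 65),
        ("miR-521-A", 54, 75, 54, 75),
    ],
    "mild": [
        ("miR-24-A", 44, 65, 44, 65),
        ("miR-24-U", 44, 66, 44, 65),
        ("miR-519d-A", 54, 76, 54, 75),
        ("miR-517a-A", 54, 75, 54, 75),
        ("miR-518e-A", 54, 75, 54, 74),
        ("miR-24-A", 44, 63, 44, 65),
        ("miR-24-U", 44, 65, 44, 65),
        ("miR-517a-C", 54, 75, 54, 75),
        ("miR-145-A", 16, 36, 16, 38),
        ("miR-521-A", 54, 75, 54, 75),
    ],
    "severe": [
        ("miR-24-A", 44, 65, 44, 65),
        ("miR-24-U", 44, 66, 44, 65),
        ("miR-519d-A", 54, 76, 54, 75),
        ("miR-24-A", 44, 66, 44, 65),
        ("miR-517a-A", 54, 75, 54, 75),
        ("miR-517a-C", 54, 75, 54, 75),
        ("miR-518c-A", 62, 84, 62, 84),
        ("miR-103-U", 48, 70, 48, 70),
        ("miR-29a-A", 42, 64, 42, 63),
        ("miR-519d-C", 54, 76, 54, 75),
    ],
}


def modified_species_keys(sample: str) -> list[str]:
    """Species keys "name@start-end" identifying each modified isomiR by its
    name and observed span (the pair that makes table rows unique)."""
    return [
        f"{name}@{start}-{end}"
        for name, start, end, _, _ in TOP10_MODIFIED[sample]
    ]
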