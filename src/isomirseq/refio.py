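"""Reference hairpins, mature annotations and blacklist sequences.

Coordinates are 1-based inclusive throughout the package (the convention of
miRBase-style annotation tables such as "44-65"); conversion to 0-based
happens only inside the aligner.  U and T are interchangeable on input and
stored internally as T; addition nucleotides are printed as U in labels.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGT")


class ReferenceError(ValueError):
    """Raised when a reference file violates its contract."""


def normalize_sequence(seq: str, *, name: str = "") -> str:
    """Uppercase and map U->T; reject anything outside {A,C,G,T,U}."""
    s = str(seq).upper().replace("U", "T")
    bad = set(s) - VALID_BASES
    if bad:
        raise ReferenceError(
            f"record {name!r}: invalid character(s) {sorted(bad)} in sequence"
        )
    return s


@dataclass(frozen=True)
class Precursor:
    """A miRNA hairpin precursor."""

    precursor_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ReferenceError(f"precursor {self.precursor_id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MatureAnnotation:
    """Canonical mature coordinates on a precursor (1-based inclusive)."""

    mature_id: str
    precursor_id: str
    start: int
    end: int
    arm: str  # "5p" or "3p"

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class ReferenceSet:
    """Precursors, mature annotations and an optional ncRNA blacklist."""

    precursors: dict[str, Precursor] = field(default_factory=dict)
    annotations: list[MatureAnnotation] = field(default_factory=list)
    blacklist: list[tuple[str, str]] = field(default_factory=list)

    def precursor(self, precursor_id: str) -> Precursor:
        try:
            return self.precursors[precursor_id]
        except KeyError:
            raise ReferenceError(f"unknown precursor {precursor_id!r}") from None

    def annotations_for(self, mature_id: str) -> list[MatureAnnotation]:
        return [a for a in self.annotations if a.mature_id == mature_id]

    def annotations_on(self, precursor_id: str) -> list[MatureAnnotation]:
        return [a for a in self.annotations if a.precursor_id == precursor_id]


def infer_arm(start: int, end: int, precursor_length: int) -> str:
    """A mature sits on the 5p arm iff its midpoint lies in the 5' half."""
    midpoint = (start + end) / 2.0
    return "5p" if midpoint <= precursor_length / 2.0 else "3p"


def read_precursor_fasta(path: str | Path) -> list[Precursor]:
    """Read precursors; the header token before the first whitespace is the id."""
    precursors: list[Precursor] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        pid = record.id  # Biopython already tokenizes on whitespace
        if pid in seen:
            raise ReferenceError(f"duplicate precursor id {pid!r} in {path}")
        seen.add(pid)
        precursors.append(Precursor(pid, normalize_sequence(record.seq, name=pid)))
    return precursors


def write_precursor_fasta(precursors: Iterable[Precursor], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(p.sequence), id=p.precursor_id, description="")
        for p in precursors
    ]
    SeqIO.write(records, str(path), "fasta")


def read_blacklist_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [
        (rec.id, normalize_sequence(rec.seq, name=rec.id))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


ANNOTATION_COLUMNS = ("mature_id", "precursor_id", "start", "end")


def read_mature_annotations(
    path: str | Path, precursors: Iterable[Precursor]
) -> list[MatureAnnotation]:
    """Read the mature-annotation TSV and validate against precursor lengths.

    Columns: mature_id, precursor_id, start, end, optional arm.  The arm is
    inferred from the midpoint when absent.
    """
    lengths = {p.precursor_id: len(p) for p in precursors}
    annotations: list[MatureAnnotation] = []
    seen: set[tuple[str, str]] = set()
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        missing = set(ANNOTATION_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ReferenceError(f"annotation table missing columns: {sorted(missing)}")
        for row in reader:
            mid, pid = row["mature_id"], row["precursor_id"]
            if pid not in lengths:
                raise ReferenceError(f"annotation {mid!r}: unknown precursor {pid!r}")
            start, end = int(row["start"]), int(row["end"])
            plen = lengths[pid]
            if not (1 <= start < end <= plen):
                raise ReferenceError(
                    f"annotation {mid!r} on {pid!r}: span {start}-{end} out of "
                    f"bounds for a {plen} nt precursor"
                )
            key = (mid, pid)
            if key in seen:
                raise ReferenceError(f"duplicate annotation {key}")
            seen.add(key)
            arm = (row.get("arm") or "").strip() or infer_arm(start, end, plen)
            if arm not in ("5p", "3p"):
                raise ReferenceError(f"annotation {mid!r}: bad arm {arm!r}")
            annotations.append(MatureAnnotation(mid, pid, start, end, arm))
    return annotations


def write_mature_annotations(
    annotations: Iterable[MatureAnnotation], path: str | Path
) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(ANNOTATION_COLUMNS + ("arm",))
        for a in annotations:
            writer.writerow([a.mature_id, a.precursor_id, a.start, a.end, a.arm])


def load_reference(
    precursor_fasta: str | Path,
    annotation_tsv: str | Path,
    blacklist_fasta: str | Path | None = None,
) -> ReferenceSet:
    precursors = read_precursor_fasta(precursor_fasta)
    annotations = read_mature_annotations(annotation_tsv, precursors)
    blacklist = read_blacklist_fasta(blacklist_fasta) if blacklist_fasta else []
    return ReferenceSet(
        precursors={p.precursor_id: p for p in precursors},
        annotations=annotations,
        blacklist=blacklist,
    )


def resolve_locus(mature_id: str, ref: ReferenceSet) -> MatureAnnotation:
    """Pick the annotation of a multicopy mature on its "first" precursor.

    "First" means lexicographically smallest precursor_id, so the choice is
    deterministic and reproducible across runs.
    """
    candidates = ref.annotations_for(mature_id)
    if not candidates:
        raise ReferenceError(f"unknown mature id {mature_id!r}")
    return min(candidates, key=lambda a: a.precursor_id)
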