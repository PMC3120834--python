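"""SOLiD two-base colorspace: codec, CSFASTA I/O and mismatch classification.

SOLiD reads each dinucleotide as one of four "colors".  With bases encoded as
two bits (A=0, C=1, G=2, T=3) the color of a base pair is the XOR of the two
codes, which reproduces the platform's published di-base matrix: identical
pairs give color 0, the code is symmetric, and fixing one base makes the map
to colors a bijection.  Decoding cascades from a known primer base, so a
single wrong color corrupts every downstream base -- the property that lets a
lone color mismatch be recognised as a sequencing error, and a mismatch at
the insert's last color paired with a mismatching adaptor-boundary color be
recognised as a 3' non-template addition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable

BASE_TO_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
CODE_TO_BASE = "ACGT"

#: Default SOLiD library primer base.
DEFAULT_PRIMER = "T"


class ColorspaceError(ValueError):
    """Raised on malformed colorspace input."""


def _code(base: str) -> int:
    try:
        return BASE_TO_CODE[base]
    except (KeyError, TypeError):
        raise ColorspaceError(f"invalid base {base!r}") from None


def color_of(b1: str, b2: str) -> int:
    """Color of the dinucleotide (b1, b2) in the SOLiD two-base code."""
    return _code(b1) ^ _code(b2)


def encode(seq: str, primer: str = DEFAULT_PRIMER) -> str:
    """Encode a base string as colors, starting from the primer base."""
    if not seq:
        raise ColorspaceError("cannot encode an empty sequence")
    prev = _code(primer)
    out = []
    for base in seq:
        code = _code(base)
        out.append(prev ^ code)
        prev = code
    return "".join(str(c) for c in out)


def decode(primer: str, colors: str) -> str:
    """Decode colors back to bases by cascading from the primer."""
    prev = _code(primer)
    out = []
    for ch in colors:
        if ch not in "0123":
            raise ColorspaceError(f"invalid color digit {ch!r}")
        prev ^= int(ch)
        out.append(CODE_TO_BASE[prev])
    return "".join(out)


@dataclass
class ColorRead:
    """A SOLiD read: primer base plus color digits, with a collapsed count."""

    read_id: str
    primer: str
    colors: str
    count: int = 1

    def __post_init__(self) -> None:
        if self.primer not in BASE_TO_CODE:
            raise ColorspaceError(f"read {self.read_id!r}: bad primer {self.primer!r}")
        if not self.colors or set(self.colors) - set("0123"):
            raise ColorspaceError(f"read {self.read_id!r}: bad color string")


def read_csfasta(path: str | Path) -> list[ColorRead]:
    """Read a CSFASTA file (">id" header, then "T0123..." sequence line).

    Lines beginning with '#' are comments and skipped.
    """
    reads: list[ColorRead] = []
    header: str | None = None
    with open(path) as handle:
        for lineno, raw in enumerate(handle, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                header = line[1:].split()[0]
                continue
            if header is None:
                raise ColorspaceError(f"{path}:{lineno}: sequence line before header")
            primer, colors = line[0], line[1:]
            if primer not in BASE_TO_CODE:
                raise ColorspaceError(
                    f"{path}:{lineno}: sequence line must start with a base"
                )
            if not colors or set(colors) - set("0123"):
                raise ColorspaceError(
                    f"{path}:{lineno}: colors must be digits in 0-3"
                )
            reads.append(ColorRead(header, primer, colors))
            header = None
    return reads


def write_csfasta(reads: Iterable[ColorRead], path: str | Path) -> None:
    with open(path, "w") as handle:
        for read in reads:
            handle.write(f">{read.read_id}\n{read.primer}{read.colors}\n")


class MismatchKind(Enum):
    SEQUENCING_ERROR = "sequencing_error"
    TERMINAL_ADDITION_CANDIDATE = "terminal_addition_candidate"
    TRUE_CHANGE = "true_change"


@dataclass
class MismatchClassification:
    """Color-mismatch positions (1-based) with their interpretation."""

    positions: list[int] = field(default_factory=list)
    kinds: dict[int, MismatchKind] = field(default_factory=dict)

    @property
    def is_perfect(self) -> bool:
        return not self.positions

    def kind_at(self, position: int) -> MismatchKind:
        return self.kinds[position]


def classify_boundary(
    read: ColorRead, ref_colors: str, aligned_len: int
) -> MismatchClassification:
    """Classify color mismatches over an alignment of length ``aligned_len``.

    ``ref_colors`` must hold the expected colors for positions 1..aligned_len
    plus the expected adaptor-boundary color at position aligned_len+1 (the
    color of the last template base against the adaptor's first base); the
    read must likewise carry at least one color beyond the insert.

    Rules: a lone mismatch at an internal position is a sequencing error to
    be corrected to the reference; a mismatch at the last aligned color whose
    following (boundary) color also mismatches marks a terminal non-template
    addition candidate; a terminal mismatch whose boundary color matches is a
    sequencing error in the last color; anything else (two or more internal
    mismatches, i.e. a real base change or a noisy read) is a true change.
    """
    if aligned_len + 1 > len(read.colors):
        raise ColorspaceError(
            f"read {read.read_id!r}: aligned_len {aligned_len} leaves no boundary "
            f"color in a {len(read.colors)}-color read"
        )
    if aligned_len + 1 > len(ref_colors):
        raise ColorspaceError("ref_colors must include the boundary expectation")

    mismatches = [
        i + 1
        for i in range(aligned_len)
        if read.colors[i] != ref_colors[i]
    ]
    boundary_mismatch = read.colors[aligned_len] != ref_colors[aligned_len]

    result = MismatchClassification(positions=list(mismatches))
    if not mismatches:
        return result

    terminal = [p for p in mismatches if p == aligned_len]
    internal = [p for p in mismatches if p < aligned_len]

    if terminal and boundary_mismatch:
        result.kinds[aligned_len] = MismatchKind.TERMINAL_ADDITION_CANDIDATE
    elif terminal:
        result.kinds[aligned_len] = MismatchKind.SEQUENCING_ERROR

    if len(internal) == 1:
        result.kinds[internal[0]] = MismatchKind.SEQUENCING_ERROR
    else:
        for p in internal:
            result.kinds[p] = MismatchKind.TRUE_CHANGE
    return result
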