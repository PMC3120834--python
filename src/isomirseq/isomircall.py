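"""Read collapsing, blacklist filtering, precursor alignment and isomiR calls.

The aligner scans every sense-strand offset of every precursor (desk-scale
references make this exact) and interprets each candidate insert length under
three hypotheses: pure template, template plus one 3' non-template base, or
template plus two.  In colorspace the hypotheses are separated by the
adaptor-boundary color: a mismatch at the insert's last color together with a
mismatching first adaptor color marks a non-template addition, while a lone
internal color mismatch is a sequencing error corrected to the reference.
At most one internal color (or base) mismatch is tolerated.

Among valid hits the best is chosen by: fewest corrected mismatches, then the
most parsimonious terminal interpretation (template beats single addition
beats double addition), then lexicographically smallest precursor id (the
"first" copy of a multicopy locus), then smallest start, then longest insert.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .colorspace import (
    BASE_TO_CODE,
    CODE_TO_BASE,
    DEFAULT_PRIMER,
    ColorRead,
    decode,
)
from .refio import MatureAnnotation, ReferenceSet, resolve_locus

#: Default 3' adaptor.  Only its leading colors matter to the boundary rule;
#: its first base deliberately never recurs in the leading stretch, so no
#: run of adaptor colors can mimic a template extension or a 3' addition
#: (each such mimic chain would need a later adaptor base equal to the
#: first).  CallConfig enforces the minimal form of this constraint.
DEFAULT_ADAPTOR = "CGTAGTGGTAGTAGGTTGTA"

FLAG_NONE = "none"
FLAG_SINGLE = "single_nta"
FLAG_DOUBLE = "double_nta"
_FLAG_RANK = {FLAG_NONE: 0, FLAG_SINGLE: 1, FLAG_DOUBLE: 2}

_SENTINEL = np.uint8(255)


@dataclass(frozen=True)
class AlignmentHit:
    """A candidate placement of a read insert on a precursor."""

    precursor_id: str
    start: int  # 1-based template start
    aligned_len: int  # insert length in bases, addition included
    n_color_mismatches: int
    boundary_flag: str
    addition: str = ""

    @property
    def template_len(self) -> int:
        return self.aligned_len - len(self.addition)

    @property
    def template_end(self) -> int:
        return self.start + self.template_len - 1


@dataclass
class IsomiRObservation:
    """A unique aligned small-RNA species with per-sample counts."""

    mature_id: str
    precursor_id: str
    template_start: int
    template_end: int
    addition: str
    sequence: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def reported_end(self) -> int:
        return self.template_end + len(self.addition)

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.mature_id, self.template_start, self.template_end, self.addition)


@dataclass
class CallConfig:
    """Knobs of the alignment / calling stage."""

    primer: str = DEFAULT_PRIMER
    adaptor: str = DEFAULT_ADAPTOR
    min_template: int = 15
    max_insert: int = 32
    max_mismatches: int = 1
    #: extra known adaptor colors (beyond the boundary color) that must match
    #: before an insert length is accepted.  With only the boundary color a
    #: read carrying one late sequencing error is re-interpretable as a
    #: truncated species with probability 1/4; each confirmation color
    #: divides that by 4.
    boundary_confirm: int = 2
    min_overlap_frac: float = 0.5  # of the annotated mature length
    blacklist_min_len: int = 16

    def __post_init__(self) -> None:
        if (
            len(self.adaptor) < 3
            or self.adaptor[0] == self.adaptor[1]
            or self.adaptor[0] == self.adaptor[2]
        ):
            raise ValueError(
                "adaptor needs >=3 bases, with the second and third differing "
                "from the first; otherwise the boundary rule cannot tell a "
                "3' addition from the adaptor itself (the adaptor's own "
                "colors would mimic an addition hit)"
            )


def collapse_reads(items: Iterable) -> list:
    """Collapse identical reads, summing counts.

    Accepts ColorRead objects (keyed by primer+colors) or (id, sequence)
    pairs / plain strings (keyed by sequence).  Output is ordered by count
    descending then key ascending, with synthetic ids ``u<rank>``.
    """
    counts: dict = {}
    is_color = None
    for item in items:
        if isinstance(item, ColorRead):
            key = (item.primer, item.colors)
            n = item.count
            is_color = True
        else:
            seq = item[1] if isinstance(item, tuple) else str(item)
            key = seq
            n = 1
            is_color = False if is_color is None else is_color
        counts[key] = counts.get(key, 0) + n
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    out = []
    for rank, (key, n) in enumerate(ordered, 1):
        if isinstance(key, tuple):
            out.append(ColorRead(f"u{rank}", key[0], key[1], count=n))
        else:
            out.append((f"u{rank}", key, n))
    return out


def _blacklist_concat(blacklist: Sequence[tuple[str, str]]) -> str:
    return "|".join(seq for _, seq in blacklist)


def _matches_blacklist(seq: str, concat: str, max_mm: int) -> bool:
    if not concat or not seq:
        return False
    if max_mm == 0:
        return seq in concat
    n = len(seq)
    for start in range(len(concat) - n + 1):
        window = concat[start : start + n]
        if "|" in window:
            continue
        mm = sum(a != b for a, b in zip(seq, window))
        if mm <= max_mm:
            return True
    return False


def filter_blacklist(
    reads: Sequence,
    blacklist: Sequence[tuple[str, str]],
    max_mm: int = 0,
    *,
    config: CallConfig | None = None,
) -> tuple[list, int]:
    """Drop reads matching an ncRNA blacklist; returns (kept, n_removed).

    Base-space reads are removed when the whole sequence occurs within a
    blacklist sequence.  Colorspace reads carry adaptor colors of unknown
    extent, so the decoded prefix of length ``blacklist_min_len`` is used as
    the match probe instead.
    """
    if not blacklist:
        return list(reads), 0
    config = config or CallConfig()
    concat = _blacklist_concat(blacklist)
    kept: list = []
    removed = 0
    for read in reads:
        if isinstance(read, ColorRead):
            probe = decode(read.primer, read.colors)[: config.blacklist_min_len]
            n = read.count
        else:
            probe = read[1]
            n = read[2] if len(read) > 2 else 1
        if _matches_blacklist(probe, concat, max_mm):
            removed += n
        else:
            kept.append(read)
    return kept, removed


class PrecursorIndex:
    """Vectorised colorspace/base-space scan over all precursor offsets."""

    def __init__(self, ref: ReferenceSet, config: CallConfig | None = None):
        self.ref = ref
        self.config = config or CallConfig()
        pad = self.config.max_insert + 4
        ids = sorted(ref.precursors)  # lexicographic = multicopy preference
        codes_parts: list[np.ndarray] = []
        offset_prec: list[int] = []
        offset_local: list[int] = []
        pos = 0
        for pi, pid in enumerate(ids):
            seq = ref.precursors[pid].sequence
            arr = np.fromiter(
                (BASE_TO_CODE[b] for b in seq), dtype=np.uint8, count=len(seq)
            )
            codes_parts.append(arr)
            codes_parts.append(np.full(pad, _SENTINEL, dtype=np.uint8))
            for j in range(len(seq)):
                offset_prec.append(pi)
                offset_local.append(j + 1)  # 1-based
            pos += len(seq) + pad
        self.precursor_ids = ids
        self.codes = np.concatenate(codes_parts) if codes_parts else np.array(
            [], dtype=np.uint8
        )
        # concat position of each candidate template start
        starts = []
        pos = 0
        for pi, pid in enumerate(ids):
            n = len(ref.precursors[pid].sequence)
            starts.extend(range(pos, pos + n))
            pos += n + pad
        self.offsets = np.asarray(starts, dtype=np.int64)
        self.offset_prec = np.asarray(offset_prec, dtype=np.int32)
        self.offset_local = np.asarray(offset_local, dtype=np.int32)
        # colref[j] = color of (codes[j-1], codes[j]); sentinel where invalid
        c = self.codes
        colref = np.full(len(c), _SENTINEL, dtype=np.uint8)
        if len(c) > 1:
            valid = (c[1:] != _SENTINEL) & (c[:-1] != _SENTINEL)
            colref[1:][valid] = c[1:][valid] ^ c[:-1][valid]
        self.colref = colref

    # -- colorspace ---------------------------------------------------------

    def _expected_matrix(self, n_cols: int, primer_code: int) -> np.ndarray:
        """Expected colors E[o, i] for insert position i at each offset."""
        offs = self.offsets
        kmax = min(n_cols, self.config.max_insert)
        e = np.empty((len(offs), kmax), dtype=np.uint8)
        e[:, 0] = np.where(
            self.codes[offs] != _SENTINEL,
            primer_code ^ self.codes[offs],
            _SENTINEL,
        )
        for i in range(1, kmax):
            e[:, i] = self.colref[offs + i]
        return e

    def align_colorspace(self, read: ColorRead) -> AlignmentHit | None:
        cfg = self.config
        colors = np.fromiter(
            (int(ch) for ch in read.colors), dtype=np.uint8, count=len(read.colors)
        )
        n = len(colors)
        if n < cfg.min_template + 1 or len(self.offsets) == 0:
            return None
        primer_code = BASE_TO_CODE[read.primer]
        a0 = BASE_TO_CODE[cfg.adaptor[0]]
        e = self._expected_matrix(n, primer_code)
        kmax = e.shape[1]
        mism = e != colors[np.newaxis, :kmax]
        cum = np.cumsum(mism, axis=1, dtype=np.int16)
        tvalid = e != _SENTINEL  # template color defined at position i
        offs = self.offsets
        codes = self.codes

        best: tuple | None = None

        def consider(nmm: int, flag: str, o: int, k: int, addition: str) -> None:
            # fewest corrected errors, then first precursor copy / smallest
            # start, then longest insert (so a coincidentally boundary-
            # matching truncation never hides a longer template or an
            # addition), then the most parsimonious terminal interpretation
            nonlocal best
            key = (nmm, o, -k, _FLAG_RANK[flag])
            if best is None or key < best[0]:
                best = (key, flag, o, k, int(nmm), addition)

        # colors of the adaptor against itself, used to confirm that the
        # adaptor really starts where an interpretation claims it does
        adaptor_codes = [BASE_TO_CODE[b] for b in cfg.adaptor]
        confirm = [
            adaptor_codes[j] ^ adaptor_codes[j + 1]
            for j in range(min(cfg.boundary_confirm, len(adaptor_codes) - 1))
        ]

        max_mm = cfg.max_mismatches
        for k in range(cfg.min_template, min(n - 1, kmax) + 1):
            ck = int(colors[k]) if k < n else -1  # boundary color
            if ck < 0:
                continue
            if any(
                k + 1 + j < n and int(colors[k + 1 + j]) != confirm[j]
                for j in range(len(confirm))
            ):
                continue  # the adaptor cannot start after insert length k
            # pure template of length k
            if k <= kmax:
                tv = tvalid[:, k - 1]
                nmm = cum[:, k - 1]
                last = codes[offs + k - 1]
                ok = tv & (nmm <= max_mm) & (ck == (last ^ a0))
                for o in np.flatnonzero(ok):
                    consider(int(nmm[o]), FLAG_NONE, int(o), k, "")
            # template k-1 + one addition
            if k - 1 >= cfg.min_template:
                tv = tvalid[:, k - 2]
                nmm = cum[:, k - 2]
                lastt = codes[offs + k - 2]
                a1 = lastt ^ colors[k - 1]
                notional = codes[offs + k - 1]
                nontmpl = (notional == _SENTINEL) | (a1 != notional)
                ok = tv & (nmm <= max_mm) & nontmpl & (ck == (a1 ^ a0))
                for o in np.flatnonzero(ok):
                    consider(
                        int(nmm[o]),
                        FLAG_SINGLE,
                        int(o),
                        k,
                        CODE_TO_BASE[int(a1[o])],
                    )
            # template k-2 + two additions
            if k - 2 >= cfg.min_template:
                tv = tvalid[:, k - 3]
                nmm = cum[:, k - 3]
                lastt = codes[offs + k - 3]
                a1 = lastt ^ colors[k - 2]
                n1 = codes[offs + k - 2]
                ok1 = (n1 == _SENTINEL) | (a1 != n1)
                a2 = a1 ^ colors[k - 1]
                n2 = codes[offs + k - 1]
                ok2 = (n2 == _SENTINEL) | (a2 != n2)
                ok = tv & (nmm <= max_mm) & ok1 & ok2 & (ck == (a2 ^ a0))
                for o in np.flatnonzero(ok):
                    consider(
                        int(nmm[o]),
                        FLAG_DOUBLE,
                        int(o),
                        k,
                        CODE_TO_BASE[int(a1[o])] + CODE_TO_BASE[int(a2[o])],
                    )
        return self._hit_from_best(best)

    # -- base space ---------------------------------------------------------

    def align_basespace(self, seq: str) -> AlignmentHit | None:
        cfg = self.config
        n = len(seq)
        if n < cfg.min_template or n > cfg.max_insert or len(self.offsets) == 0:
            return None
        q = np.fromiter((BASE_TO_CODE[b] for b in seq), dtype=np.uint8, count=n)
        offs = self.offsets
        codes = self.codes
        ref = np.empty((len(offs), n), dtype=np.uint8)
        for i in range(n):
            ref[:, i] = codes[offs + i]
        mism = ref != q[np.newaxis, :]
        cum = np.cumsum(mism, axis=1, dtype=np.int16)
        inb = ref != _SENTINEL

        best: tuple | None = None

        def consider(nmm: int, flag: str, o: int, addition: str) -> None:
            nonlocal best
            key = (nmm, o, -n, _FLAG_RANK[flag])
            if best is None or key < best[0]:
                best = (key, flag, o, n, int(nmm), addition)

        max_mm = cfg.max_mismatches
        # pure template
        ok = inb[:, n - 1] & (cum[:, n - 1] <= max_mm)
        for o in np.flatnonzero(ok):
            consider(int(cum[o, n - 1]), FLAG_NONE, int(o), "")
        # one trailing non-template base
        if n - 1 >= cfg.min_template:
            nontmpl = ~inb[:, n - 1] | (ref[:, n - 1] != q[n - 1])
            ok = inb[:, n - 2] & (cum[:, n - 2] <= max_mm) & nontmpl
            for o in np.flatnonzero(ok):
                consider(int(cum[o, n - 2]), FLAG_SINGLE, int(o), seq[n - 1])
        # two trailing non-template bases
        if n - 2 >= cfg.min_template:
            nt1 = ~inb[:, n - 2] | (ref[:, n - 2] != q[n - 2])
            nt2 = ~inb[:, n - 1] | (ref[:, n - 1] != q[n - 1])
            ok = inb[:, n - 3] & (cum[:, n - 3] <= max_mm) & nt1 & nt2
            for o in np.flatnonzero(ok):
                consider(int(cum[o, n - 3]), FLAG_DOUBLE, int(o), seq[n - 2 :])
        return self._hit_from_best(best)

    def _hit_from_best(self, best: tuple | None) -> AlignmentHit | None:
        if best is None:
            return None
        _, flag, o, k, nmm, addition = best
        return AlignmentHit(
            precursor_id=self.precursor_ids[self.offset_prec[o]],
            start=int(self.offset_local[o]),
            aligned_len=k,
            n_color_mismatches=nmm,
            boundary_flag=flag,
            addition=addition,
        )


def assign_mature(
    hit: AlignmentHit, ref: ReferenceSet, min_overlap_frac: float = 0.5
) -> MatureAnnotation | None:
    """Assign a hit to the mature annotation it overlaps by >=50% of the
    mature length; None marks an unassigned precursor fragment."""
    best: tuple | None = None
    for a in ref.annotations_on(hit.precursor_id):
        overlap = min(hit.template_end, a.end) - max(hit.start, a.start) + 1
        if overlap >= min_overlap_frac * a.length:
            key = (-overlap, a.start, a.mature_id)
            if best is None or key < best[0]:
                best = (key, a)
    return None if best is None else best[1]


def call_isomir(
    hit: AlignmentHit, ref: ReferenceSet, min_overlap_frac: float = 0.5
) -> IsomiRObservation | None:
    annotation = assign_mature(hit, ref, min_overlap_frac)
    if annotation is None:
        return None
    template = ref.precursor(hit.precursor_id).sequence[
        hit.start - 1 : hit.template_end
    ]
    return IsomiRObservation(
        mature_id=annotation.mature_id,
        precursor_id=hit.precursor_id,
        template_start=hit.start,
        template_end=hit.template_end,
        addition=hit.addition,
        sequence=template + hit.addition,
    )


def strip_species_prefix(mature_id: str) -> str:
    head, _, tail = mature_id.partition("-")
    if tail and head.lower() not in ("mir", "let"):
        return tail
    return mature_id


def label_isomir(
    obs: IsomiRObservation, ref: ReferenceSet
) -> tuple[str, str]:
    """Table-style name and span, e.g. ("miR-24-A", "44-63 (44-65)").

    The reference span is appended only when it differs from the observed
    span; addition nucleotides print as U.
    """
    annotation = resolve_locus(obs.mature_id, ref)
    name = strip_species_prefix(obs.mature_id)
    if obs.addition:
        name += "-" + obs.addition.replace("T", "U")
    span = f"{obs.template_start}-{obs.reported_end}"
    if (obs.template_start, obs.reported_end) != (annotation.start, annotation.end):
        span += f" ({annotation.start}-{annotation.end})"
    return name, span


@dataclass
class CallResult:
    """Per-sample calling output with count-conservation bookkeeping."""

    sample_id: str
    observations: list[IsomiRObservation]
    n_input: int = 0
    n_blacklisted: int = 0
    n_unaligned: int = 0
    n_unassigned: int = 0

    @property
    def n_assigned(self) -> int:
        return sum(o.counts.get(self.sample_id, 0) for o in self.observations)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sample_id": self.sample_id,
                "mature_id": o.mature_id,
                "precursor_id": o.precursor_id,
                "template_start": o.template_start,
                "template_end": o.template_end,
                "addition": o.addition,
                "reported_end": o.reported_end,
                "count": o.counts.get(self.sample_id, 0),
                "sequence": o.sequence,
            }
            for o in self.observations
        ]
        frame = pd.DataFrame(
            rows,
            columns=[
                "sample_id",
                "mature_id",
                "precursor_id",
                "template_start",
                "template_end",
                "addition",
                "reported_end",
                "count",
                "sequence",
            ],
        )
        return frame.sort_values(
            ["count", "mature_id", "template_start", "template_end", "addition"],
            ascending=[False, True, True, True, True],
            kind="mergesort",
        ).reset_index(drop=True)


def process_sample(
    reads: Sequence,
    ref: ReferenceSet,
    sample_id: str,
    *,
    mode: str = "color",
    config: CallConfig | None = None,
    blacklist_max_mm: int = 0,
) -> CallResult:
    """Collapse, filter, align and call one sample's reads end to end."""
    if mode not in ("color", "base"):
        raise ValueError(f"unknown mode {mode!r}")
    config = config or CallConfig()
    collapsed = collapse_reads(reads)
    n_input = sum(
        r.count if isinstance(r, ColorRead) else r[2] for r in collapsed
    )
    kept, n_blacklisted = filter_blacklist(
        collapsed, ref.blacklist, blacklist_max_mm, config=config
    )
    index = PrecursorIndex(ref, config)
    by_key: dict[tuple, IsomiRObservation] = {}
    n_unaligned = 0
    n_unassigned = 0
    for read in kept:
        if mode == "color":
            assert isinstance(read, ColorRead)
            hit = index.align_colorspace(read)
            count = read.count
        elif mode == "base":
            _, seq, count = read
            hit = index.align_basespace(seq)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        if hit is None:
            n_unaligned += count
            continue
        obs = call_isomir(hit, ref, config.min_overlap_frac)
        if obs is None:
            n_unassigned += count
            continue
        existing = by_key.get(obs.key)
        if existing is None:
            obs.counts[sample_id] = count
            by_key[obs.key] = obs
        else:
            existing.counts[sample_id] = existing.counts.get(sample_id, 0) + count
    observations = sorted(
        by_key.values(), key=lambda o: (-o.counts.get(sample_id, 0), o.key)
    )
    return CallResult(
        sample_id=sample_id,
        observations=observations,
        n_input=n_input,
        n_blacklisted=n_blacklisted,
        n_unaligned=n_unaligned,
        n_unassigned=n_unassigned,
    )


def combine_results(results: Iterable[CallResult]) -> pd.DataFrame:
    """Stack per-sample observation tables into one long-format frame."""
    frames = [r.to_frame() for r in results]
    if not frames:
        return CallResult("", []).to_frame()
    return pd.concat(frames, ignore_index=True)


def write_observations(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_observations(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", dtype={"addition": str}, keep_default_na=False
    ).assign(
        template_start=lambda d: d.template_start.astype(int),
        template_end=lambda d: d.template_end.astype(int),
        count=lambda d: d["count"].astype(int),
    )
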