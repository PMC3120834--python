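"""Synthetic three-sample SOLiD small-RNA libraries with planted truth.

The generator emulates the structure of a placental small-RNA study: per
locus, 1-3 abundant 3' isomiRs sharing the canonical 5' end plus a tail of
rare end-variants (3' shifts far more likely than 5' shifts); per read,
adenosine-biased single and double 3' non-template additions; per color, a
small uniform error rate; per sample, planted log2 abundance effects on the
largest loci and "spectrum shift" loci whose dominant isomiR swaps between
the normal and diseased samples.

Everything is driven by one integer seed through independent named
substreams, so reference, study plan and each sample library are each
byte-reproducible on their own.

Identifiability constraint: an injected addition base is re-drawn when it
equals the template base at its notional precursor position (otherwise it
would be a templated extension, not a non-template addition) and when it
equals the adaptor's first base (in colorspace such an addition produces
exactly the color string of the adaptor starting one position earlier and
is undetectable in principle).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .colorspace import ColorRead, encode
from .isomircall import DEFAULT_ADAPTOR
from .refio import MatureAnnotation, Precursor, ReferenceSet, infer_arm

BASES = "ACGT"


class SimConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass
class SampleSpec:
    """Per-sample conditions: library size, addition rate, planted effects."""

    sample_id: str
    n_reads: int = 100_000
    nta_prob: float = 0.05
    #: log2 abundance effects keyed by locus weight rank (1 = largest locus)
    log2_effects_by_rank: dict[int, float] = field(default_factory=dict)
    #: weight ranks whose most/secondary abundant isomiRs are swapped
    shift_ranks: frozenset[int] = frozenset()


def default_samples() -> list[SampleSpec]:
    """The three-sample study design: one normal, two diseased libraries.

    The normal sample carries a higher addition rate than the diseased ones,
    the diseased samples carry planted 64-fold knockdowns on the largest
    loci, and four mid-rank loci swap their dominant isomiR in disease.
    """
    shifts = frozenset({4, 5, 6, 7})
    return [
        SampleSpec("normal", nta_prob=0.06),
        SampleSpec(
            "mild",
            nta_prob=0.045,
            log2_effects_by_rank={1: -6.0},
            shift_ranks=shifts,
        ),
        SampleSpec(
            "severe",
            nta_prob=0.045,
            log2_effects_by_rank={2: -6.0, 3: -6.0},
            shift_ranks=shifts,
        ),
    ]


@dataclass
class SimConfig:
    """Study conditions for the synthetic libraries."""

    seed: int  # mandatory: no silent nondeterminism
    n_loci: int = 30
    precursor_length: tuple[int, int] = (70, 90)
    mature_length: tuple[int, int] = (20, 24)
    abundance_mu: float = 0.0
    abundance_sigma: float = 0.8
    locus_weights: Sequence[float] | None = None  # overrides the log-normal
    n_abundant_probs: tuple[float, float, float] = (0.3, 0.4, 0.3)  # P(1,2,3)
    abundant_folds: dict[int, float] = field(default_factory=dict)  # by locus idx
    abundant_share_range: tuple[float, float] = (0.78, 0.88)
    rare_species_range: tuple[int, int] = (5, 8)
    shift3_prob: float = 0.8
    shift5_prob: float = 0.1
    shift_decay: float = 0.45
    nta_weights: dict[str, float] = field(
        default_factory=lambda: {"A": 0.60, "T": 0.25, "C": 0.12, "G": 0.03}
    )
    double_prob: float = 0.06  # P(second addition | addition)
    error_rate: float = 0.005  # per color
    adaptor: str = DEFAULT_ADAPTOR
    n_adaptor_colors: int = 8
    primer: str = "T"
    count_mode: str = "multinomial"  # or "expected" (largest remainder)
    samples: list[SampleSpec] = field(default_factory=default_samples)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise SimConfigError("seed is mandatory")
        for p in (
            self.shift3_prob,
            self.shift5_prob,
            self.double_prob,
            self.error_rate,
            *(s.nta_prob for s in self.samples),
        ):
            if not 0.0 <= p <= 1.0:
                raise SimConfigError(f"probability {p} outside [0, 1]")
        if abs(sum(self.nta_weights.values()) - 1.0) > 1e-9:
            raise SimConfigError("nta base weights must sum to 1")
        if self.n_adaptor_colors < 2:
            raise SimConfigError("need >=2 adaptor colors for the boundary rule")
        if self.count_mode not in ("multinomial", "expected"):
            raise SimConfigError(f"unknown count_mode {self.count_mode!r}")
        if self.locus_weights is not None and len(self.locus_weights) != self.n_loci:
            raise SimConfigError("locus_weights length must equal n_loci")

    def sample(self, sample_id: str) -> SampleSpec:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise SimConfigError(f"unknown sample {sample_id!r}")


def _rng(config: SimConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed % (2**31), *stream])


# ---------------------------------------------------------------------------
# reference


def generate_reference(config: SimConfig, seed: int | None = None) -> ReferenceSet:
    """Random precursors (uniform base composition) with one mature each."""
    cfg = config if seed is None else replace(config, seed=seed)
    rng = _rng(cfg, 101)
    precursors: dict[str, Precursor] = {}
    annotations: list[MatureAnnotation] = []
    for i in range(cfg.n_loci):
        pid = f"syn-mir-{i + 1:03d}"
        mid = f"syn-miR-{i + 1:03d}"
        length = int(rng.integers(cfg.precursor_length[0], cfg.precursor_length[1] + 1))
        seq = "".join(BASES[c] for c in rng.integers(0, 4, size=length))
        mlen = int(rng.integers(cfg.mature_length[0], cfg.mature_length[1] + 1))
        arm = "5p" if rng.random() < 0.5 else "3p"
        if arm == "5p":
            start = int(rng.integers(5, 11))
            end = start + mlen - 1
        else:
            end = length - int(rng.integers(5, 11))
            start = end - mlen + 1
        precursors[pid] = Precursor(pid, seq)
        annotations.append(
            MatureAnnotation(mid, pid, start, end, infer_arm(start, end, length))
        )
    return ReferenceSet(precursors=precursors, annotations=annotations)


# ---------------------------------------------------------------------------
# study plan


@dataclass
class SpeciesPlan:
    template_start: int
    template_end: int
    proportion: float


@dataclass
class LocusPlan:
    index: int
    mature_id: str
    precursor_id: str
    weight: float  # base abundance weight, before per-sample effects
    rank: int  # 1 = largest weight
    species: list[SpeciesPlan] = field(default_factory=list)

    @property
    def planted_fold(self) -> float:
        if len(self.species) < 2:
            return float("inf")
        p = sorted((s.proportion for s in self.species), reverse=True)
        return p[0] / p[1]


def plan_study(ref: ReferenceSet, config: SimConfig) -> list[LocusPlan]:
    """Deterministic per-locus species tables shared by all samples."""
    rng = _rng(config, 202)
    annotations = sorted(ref.annotations, key=lambda a: a.mature_id)
    if config.locus_weights is not None:
        weights = np.asarray(config.locus_weights, dtype=float)
    else:
        weights = rng.lognormal(
            config.abundance_mu, config.abundance_sigma, size=len(annotations)
        )
    order = np.argsort(-weights, kind="stable")
    ranks = np.empty(len(weights), dtype=int)
    ranks[order] = np.arange(1, len(weights) + 1)

    plans: list[LocusPlan] = []
    for i, a in enumerate(annotations):
        plan = LocusPlan(
            index=i,
            mature_id=a.mature_id,
            precursor_id=a.precursor_id,
            weight=float(weights[i]),
            rank=int(ranks[i]),
        )
        plen = len(ref.precursor(a.precursor_id))
        used: set[tuple[int, int]] = set()

        def add(start: int, end: int, proportion: float) -> bool:
            if start < 1 or end > plen or end - start + 1 < 16:
                return False
            if (start, end) in used:
                return False
            used.add((start, end))
            plan.species.append(SpeciesPlan(start, end, proportion))
            return True

        if i in config.abundant_folds:
            # explicitly planted most/secondary fold, two abundant species
            fold = config.abundant_folds[i]
            add(a.start, a.end, fold / (1.0 + fold))
            add(a.start, a.end - 1, 1.0 / (1.0 + fold))
            n_rare = 0
        else:
            m = 1 + int(rng.choice(3, p=config.n_abundant_probs))
            # abundant isomiRs share the canonical 5' end (3' variants only)
            folds = [1.0]
            if m >= 2:
                folds.append(float(rng.uniform(1.1, 8.0)))
            if m >= 3:
                folds.append(float(rng.uniform(2.0, 12.0)) * folds[1])
            abundant_share = float(rng.uniform(*config.abundant_share_range))
            raw = np.array([1.0 / f for f in folds])
            props = abundant_share * raw / raw.sum()
            ends = [a.end, a.end - 1, a.end + 1]
            for j in range(m):
                add(a.start, ends[j], float(props[j]))
            n_rare = int(
                rng.integers(
                    config.rare_species_range[0], config.rare_species_range[1] + 1
                )
            )
            rare_share = 1.0 - sum(s.proportion for s in plan.species)
            if n_rare > 0:
                raw_r = rng.uniform(0.5, 1.5, size=n_rare)
                rare_props = rare_share * raw_r / raw_r.sum()
                for rp in rare_props:
                    for _ in range(8):  # retry until an unused end pair
                        d3 = 0
                        if rng.random() < config.shift3_prob:
                            mag = 1
                            while mag < 3 and rng.random() < config.shift_decay:
                                mag += 1
                            d3 = mag if rng.random() < 0.5 else -mag
                        d5 = 0
                        if rng.random() < config.shift5_prob:
                            d5 = 1 if rng.random() < 0.5 else -1
                        if add(a.start + d5, a.end + d3, float(rp)):
                            break
        # normalize exactly (retry failures can leave a small deficit)
        total = sum(s.proportion for s in plan.species)
        for s in plan.species:
            s.proportion /= total
        plans.append(plan)
    return plans


# ---------------------------------------------------------------------------
# truth table


@dataclass
class TruthTable:
    """Machine-readable ground truth for one or more generated libraries."""

    species: pd.DataFrame  # sample_id, mature_id, precursor_id, start, end, addition, count
    locus_effects: pd.DataFrame  # sample_id, mature_id, log2_effect
    reads: pd.DataFrame  # read_id, sample_id, mature_id, start, end, addition, n_errors

    SPECIES_COLUMNS = [
        "sample_id",
        "mature_id",
        "precursor_id",
        "template_start",
        "template_end",
        "addition",
        "count",
    ]
    EFFECT_COLUMNS = ["sample_id", "mature_id", "log2_effect"]
    READ_COLUMNS = [
        "read_id",
        "sample_id",
        "mature_id",
        "template_start",
        "template_end",
        "addition",
        "n_errors",
    ]

    def merge(self, other: "TruthTable") -> "TruthTable":
        return TruthTable(
            species=pd.concat([self.species, other.species], ignore_index=True),
            locus_effects=pd.concat(
                [self.locus_effects, other.locus_effects], ignore_index=True
            ),
            reads=pd.concat([self.reads, other.reads], ignore_index=True),
        )


def write_truth(truth: TruthTable, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    truth.species.to_csv(directory / "truth_species.tsv", sep="\t", index=False)
    truth.locus_effects.to_csv(
        directory / "truth_locus_effects.tsv", sep="\t", index=False
    )
    truth.reads.to_csv(directory / "truth_reads.tsv", sep="\t", index=False)


def read_truth(directory: str | Path) -> TruthTable:
    directory = Path(directory)

    def load(name: str, columns: list[str]) -> pd.DataFrame:
        frame = pd.read_csv(directory / name, sep="\t", keep_default_na=False)
        if "addition" in frame.columns:
            frame["addition"] = frame["addition"].astype(str)
        return frame[columns]

    return TruthTable(
        species=load("truth_species.tsv", TruthTable.SPECIES_COLUMNS),
        locus_effects=load("truth_locus_effects.tsv", TruthTable.EFFECT_COLUMNS),
        reads=load("truth_reads.tsv", TruthTable.READ_COLUMNS),
    )


# ---------------------------------------------------------------------------
# library generation


def _apportion(total: int, probs: np.ndarray, rng: np.random.Generator, mode: str):
    """Integer counts summing to ``total``: multinomial or largest remainder."""
    probs = np.asarray(probs, dtype=float)
    probs = probs / probs.sum()
    if mode == "multinomial":
        return rng.multinomial(total, probs)
    raw = probs * total
    counts = np.floor(raw).astype(int)
    short = total - counts.sum()
    if short > 0:
        order = np.argsort(-(raw - counts), kind="stable")
        counts[order[:short]] += 1
    return counts


def _allowed_weights(
    config: SimConfig, forbidden: set[str]
) -> tuple[list[str], np.ndarray]:
    bases = [b for b in BASES if b not in forbidden]
    w = np.array([config.nta_weights[b] for b in bases], dtype=float)
    if not len(bases) or w.sum() <= 0:
        raise SimConfigError("addition weights vanish after identifiability rules")
    return bases, w / w.sum()


def generate_library(
    ref: ReferenceSet,
    config: SimConfig,
    sample_id: str,
    seed: int | None = None,
    plan: list[LocusPlan] | None = None,
) -> tuple[list[ColorRead], list[tuple[str, str]], TruthTable]:
    """One sample's reads (colorspace and base-space) plus its ground truth.

    The base-space FASTA carries the clean insert sequences (colorspace
    sequencing errors are a colorspace phenomenon).  The same plan is used
    for every sample of a config, so within-locus proportions are conserved
    across samples except where a sample's shift_ranks swap them.
    """
    cfg = config if seed is None else replace(config, seed=seed)
    spec = cfg.sample(sample_id)
    if plan is None:
        plan = plan_study(ref, cfg)
    sample_index = [s.sample_id for s in cfg.samples].index(sample_id)
    rng = _rng(cfg, 303, sample_index)

    # per-locus expected shares with planted effects applied
    weights = np.array([p.weight for p in plan], dtype=float)
    for p in plan:
        effect = spec.log2_effects_by_rank.get(p.rank)
        if effect is not None:
            weights[p.index] *= 2.0**effect
    locus_counts = _apportion(spec.n_reads, weights, rng, cfg.count_mode)

    a0 = cfg.adaptor[0]
    adaptor_pad = cfg.adaptor[: cfg.n_adaptor_colors]
    color_reads: list[ColorRead] = []
    base_reads: list[tuple[str, str]] = []
    species_rows: list[dict] = []
    read_rows: list[dict] = []
    serial = 0

    for p in plan:
        n_locus = int(locus_counts[p.index])
        if n_locus == 0:
            continue
        seq = ref.precursor(p.precursor_id).sequence
        plen = len(seq)
        species = [replace(s) for s in p.species]
        if p.rank in spec.shift_ranks and len(species) >= 2:
            # swap the two most abundant species' proportions
            order = sorted(
                range(len(species)), key=lambda j: -species[j].proportion
            )
            j1, j2 = order[0], order[1]
            species[j1].proportion, species[j2].proportion = (
                species[j2].proportion,
                species[j1].proportion,
            )
        props = np.array([s.proportion for s in species])
        counts = _apportion(n_locus, props, rng, cfg.count_mode)
        for s, n_species in zip(species, counts):
            n_species = int(n_species)
            if n_species == 0:
                continue
            template = seq[s.template_start - 1 : s.template_end]
            # split this species' reads over addition classes
            n_add = (
                rng.binomial(n_species, spec.nta_prob) if spec.nta_prob else 0
            )
            n_double = rng.binomial(n_add, cfg.double_prob) if n_add else 0
            n_single = n_add - n_double
            by_addition: dict[str, int] = {"": n_species - n_add}
            pos1 = s.template_end  # 0-based index of first notional position
            tmpl1 = seq[pos1] if pos1 < plen else None
            bases1, w1 = _allowed_weights(cfg, {tmpl1, a0} - {None})
            if n_single:
                for b, k in zip(bases1, rng.multinomial(n_single, w1)):
                    if k:
                        by_addition[b] = by_addition.get(b, 0) + int(k)
            if n_double:
                pos2 = s.template_end + 1
                tmpl2 = seq[pos2] if pos2 < plen else None
                bases2, w2 = _allowed_weights(cfg, {tmpl2, a0} - {None})
                pairs = [(x, y) for x in bases1 for y in bases2]
                pw = np.array(
                    [w1[bases1.index(x)] * w2[bases2.index(y)] for x, y in pairs]
                )
                for (x, y), k in zip(pairs, rng.multinomial(n_double, pw / pw.sum())):
                    if k:
                        by_addition[x + y] = by_addition.get(x + y, 0) + int(k)
            for addition, n in sorted(by_addition.items()):
                if n == 0:
                    continue
                species_rows.append(
                    {
                        "sample_id": sample_id,
                        "mature_id": p.mature_id,
                        "precursor_id": p.precursor_id,
                        "template_start": s.template_start,
                        "template_end": s.template_end,
                        "addition": addition,
                        "count": n,
                    }
                )
                insert = template + addition
                colors = encode(insert + adaptor_pad, cfg.primer)
                base_colors = np.fromiter(
                    (int(ch) for ch in colors), dtype=np.int8, count=len(colors)
                )
                if cfg.error_rate > 0:
                    err_mask = rng.random((n, len(colors))) < cfg.error_rate
                    shifts = rng.integers(1, 4, size=err_mask.shape, dtype=np.int8)
                    matrix = np.where(
                        err_mask, (base_colors + shifts) % 4, base_colors
                    )
                    n_errors = err_mask.sum(axis=1)
                else:
                    matrix = np.broadcast_to(base_colors, (n, len(colors)))
                    n_errors = np.zeros(n, dtype=int)
                for row, ne in zip(matrix, n_errors):
                    serial += 1
                    rid = f"{sample_id}_r{serial}"
                    color_reads.append(
                        ColorRead(
                            rid, cfg.primer, "".join(str(int(c)) for c in row)
                        )
                    )
                    base_reads.append((rid, insert))
                    read_rows.append(
                        {
                            "read_id": rid,
                            "sample_id": sample_id,
                            "mature_id": p.mature_id,
                            "template_start": s.template_start,
                            "template_end": s.template_end,
                            "addition": addition,
                            "n_errors": int(ne),
                        }
                    )

    effects = pd.DataFrame(
        [
            {
                "sample_id": sample_id,
                "mature_id": p.mature_id,
                "log2_effect": spec.log2_effects_by_rank.get(p.rank, 0.0),
            }
            for p in plan
        ],
        columns=TruthTable.EFFECT_COLUMNS,
    )
    truth = TruthTable(
        species=pd.DataFrame(species_rows, columns=TruthTable.SPECIES_COLUMNS),
        locus_effects=effects,
        reads=pd.DataFrame(read_rows, columns=TruthTable.READ_COLUMNS),
    )
    return color_reads, base_reads, truth


def generate_study(
    config: SimConfig,
) -> tuple[ReferenceSet, list[LocusPlan], dict[str, tuple]]:
    """Reference, plan and all sample libraries in one call."""
    ref = generate_reference(config)
    plan = plan_study(ref, config)
    libraries = {
        s.sample_id: generate_library(ref, config, s.sample_id, plan=plan)
        for s in config.samples
    }
    return ref, plan, libraries


def write_fasta_reads(reads: Iterable[tuple[str, str]], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in reads]
    SeqIO.write(records, str(path), "fasta")


def read_fasta_reads(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
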