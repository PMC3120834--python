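# Methods

## The calling model

`isomirseq` treats a small-RNA read as `template + addition + adaptor`: a
contiguous sense-strand substring of a miRNA hairpin precursor (the
template), an optional 3′ non-template tail of one or two bases (the NTA),
and the sequencing adaptor. The calling problem is to recover, for every
read, the precursor, the template span, and the addition — under SOLiD
two-base encoding, where each "color" digit encodes a dinucleotide and
decoding cascades from a known primer base.

Two consequences of the encoding carry the whole method:

1. a single wrong color corrupts every downstream decoded base, so an
   isolated internal color mismatch against the reference is a *sequencing
   error* and is corrected to the reference;
2. a real terminal base change produces *two* adjacent color mismatches —
   the last insert color and the first adaptor-boundary color — so a
   mismatch at the insert's last color whose following boundary color also
   mismatches marks a *non-template addition*. A terminal color mismatch
   whose boundary color matches is a sequencing error in the last color and
   is corrected.

The aligner enumerates every (precursor, offset, insert-length) candidate —
references here are a few kilobases, so the scan is exhaustive and exact —
and evaluates three interpretations per candidate: pure template, template
plus one addition, template plus two. At most one internal color mismatch is
tolerated (base-space mode tolerates one base mismatch). An addition base is
decoded from its color and the preceding *template* base, and must differ
from the precursor base at its notional position (or lie beyond the
precursor end); an addition equal to the next template base is
indistinguishable from templated 3′ extension and is deliberately called
templated.

**Boundary confirmation.** The boundary rule as stated inspects one adaptor
color. We found that at any realistic color-error rate this is not
identifiable: a read with one late error can be re-interpreted as a
truncated template whose "boundary" matches by chance (probability 1/4 per
candidate truncation point), which inflates the spectrum with spurious short
species and spurious additions. The aligner therefore also requires the next
`boundary_confirm = 2` colors to equal the *known* adaptor-vs-adaptor colors
before accepting an insert length. The adaptor is still never aligned as
sequence; only its first three inter-base colors are used. Each confirmation
color divides the false-reinterpretation probability by 4; the cost is that
an error in those adaptor colors loses the read (~1.5 % extra loss at the
default error rate).

**Adaptor constraints.** Interpretations can also be faked by the adaptor
itself: if the adaptor's first base recurs shortly after position 0, a run of
adaptor colors can mimic a template extension or an addition. `CallConfig`
rejects adaptors whose second or third base equals the first; the packaged
default adaptor goes further and never repeats its first base within the
simulated adaptor stretch, making the clean-data mapping read → call exact.

**Hit ranking.** Among valid interpretations the best is chosen by
(1) fewest corrected mismatches, (2) lexicographically smallest precursor id
("first" copy of a multicopy locus, which is also how a read is counted only
once) then smallest start, (3) longest insert, (4) most parsimonious
terminal interpretation (template > single > double addition). Longest-insert
before interpretation rank matters: a coincidentally boundary-matching
truncation must never hide a longer template or a genuine addition. Reads
without a valid hit are logged unaligned; hits overlapping no annotated
mature by ≥ 50 % of the mature length are logged as unassigned precursor
fragments. Counts are conserved: assigned + unaligned + unassigned +
blacklist-removed = input, per sample.

## Downstream statistics

- **Spectra**: species are keyed by (mature id, template start, template end,
  addition); species below the reporting threshold (default ≥ 10 reads, the
  caption convention of the motivating study; ≥ 100 for the abundant-species
  view) are dropped, and percentages are of the retained locus total.
  "Most abundant" ties break by species key, deterministically.
- **NTA panels** are reported species-weighted ("type") and read-weighted
  ("count"), each with two denominators — all retained species, and modified
  species only — because figure captions in this field are ambiguous about
  the denominator; both are labeled. Double additions are tabulated
  separately. Additions print as U rather than T.
- **End heterogeneity** counts species whose template start (5′-variant) or
  end (3′-variant) differs from the canonical annotation, excluding modified
  species entirely; a species may be both.
- **Expression** is quantified per locus under both schemes: the most
  abundant isomiR's count ("most") and the sum over all isomiRs ("sum");
  sum ≥ most always. No library-size normalization is applied by default
  (the analysis convention is raw counts from single libraries).
- **Differential expression** is a thresholded fold change, not a test:
  counts below 100 are imputed to 10 on each side independently (making the
  statistic finite and antisymmetric), loci are only tested above a raw-count
  floor (> 999; > 300 for modified isomiRs) in at least one sample, and
  |log2FC| strictly greater than 4 is marked. There are no replicates, hence
  no p-values and nothing to correct for multiplicity.
- **Shared species** across 2–3 samples are reported as all exclusive Venn
  regions; plain intersections are a separate accessor. Both readings are
  exposed because published usage mixes them (plain intersections for
  locus-level "shared by three" statements, exclusive regions for
  modified-isomiR statements).
- **Cleavage sites**: the count-weighted distributions of template starts
  and template ends (additions stripped — they are appended after Dicer
  processing) are the footprints of the two cuts; the most abundant isomiR's
  ends are the dominant sites, the enzyme labels follow the arm (5p arm:
  5′ = Drosha, 3′ = Dicer; reversed on 3p), and dominance holds when
  most/secondary fold ≥ 5. Ties give fold 1.0 and non-dominance. Inference
  runs on the retained (post-threshold) spectrum. The expression-vs-type
  relationship uses Spearman rank correlation, since the claim of interest
  is about ordering, not linearity; with fewer than 3 qualifying loci the
  correlation is undefined and only the paired table is returned.

## The synthetic-data generator

The sequencing data of the motivating study were never deposited, so the
generator is the package's study stand-in. What it emulates:

- **Reference**: 30 random uniform-composition hairpins of 70–90 nt, one
  annotated mature of 20–24 nt per hairpin, arm random.
- **Per-locus spectra**: 1–3 abundant isomiRs (probabilities 0.3/0.4/0.3)
  sharing the canonical 5′ end and differing at the 3′ end, holding 78–88 %
  of the locus; a tail of 5–8 rare end-variants, each shifted at the 3′ end
  with probability 0.8 (geometrically decaying offset, max 3) and at the 5′
  end with probability 0.1 (±1). Within-locus proportions are shared by all
  samples (spectra are conserved) except at designated "spectrum shift"
  loci, where the most/secondary proportions swap in the diseased samples —
  four mid-rank loci by default, mirroring the observation that the dominant
  isomiR can differ between normal and diseased tissue.
- **Abundances**: log-normal locus weights (σ = 0.8) over 10⁵ reads per
  sample by default; the two diseased samples carry planted 64-fold
  (|log2| = 6) knockdowns on the largest loci. Knockdowns rather than
  inductions keep the renormalization of the remaining loci below ~0.2 in
  log2, so planted effects stay near their nominal size and conserved loci
  stay well inside the ±4 window.
- **Additions**: per read, an NTA with probability 0.06 (normal) / 0.045
  (diseased — the normal sample ran higher in the motivating study), base
  drawn from A 0.60, U 0.25, C 0.12, G 0.03; a second base with probability
  0.06 given the first. An addition base is re-drawn if it equals the
  template base at its notional position (it would be templated extension,
  not an addition) or the adaptor's first base (in colorspace such an
  addition yields exactly the colors of the adaptor starting one position
  earlier and is undetectable in principle). These two identifiability rules
  are what make the clean-data truth-table recovery exact rather than
  approximate.
- **Sequencing**: reads are encoded to colorspace with primer T, eight
  adaptor colors appended, and each color flipped uniformly with probability
  0.005.
- **Truth**: per-sample species counts, per-locus planted log2 effects and
  per-read origins with injected error counts, all round-trippable as TSV.

Counts are drawn multinomially by default; a largest-remainder "expected"
mode produces deterministic integer counts and is used when exact planted
ratios matter (e.g. most/secondary folds of 1.17, 4.9, 5.1, 29.6 for the
dominance-threshold checks, planted as two abundant species with proportions
f/(1+f) and 1/(1+f)).

What it does **not** emulate — and hence what passing tests do not show
about real data: ligation and RT biases, position- and quality-dependent
SOLiD error structure (.QV files are accepted but ignored), cross-mapping
between paralogous precursor families, genuine ncRNA background (blacklist
filtering is exercised with explicit fixtures instead), RNA editing, and
moRNAs. The generator's defaults are calibration choices that reproduce the
qualitative headline structure (~25–35 % modified species at the ≥ 10
threshold, < 15 % modified read share, modal length 22 nt, 3′ variation ≫ 5′
variation), not claims about any real library.

## Problem sizes and numerics

The test suite and the acceptance script run the full study at 30 loci ×
10⁵ reads per sample, the clean-recovery check at 10⁴ reads, the
aligner-oracle comparison on 500 reads × 10 toy precursors, and the codec
round trip exhaustively to length 8 — together about two minutes on one CPU.
Percentages sum to 100 within 1e-9 per spectrum; fold of a single-species
locus is +inf (dominant); empty DE sets compare with Jaccard 1.0 by
convention; the imputation rule makes every log2 fold change finite.
Coordinates are 1-based inclusive everywhere except inside the aligner's
index arithmetic; span labels print ASCII hyphens.

## Known limitations

- The boundary rule cannot see an addition equal to the adaptor's first
  base; on real libraries (where the adaptor is fixed by chemistry, not
  chosen) that class of additions is systematically missed, and additions
  equal to the next template base are counted as templated extension.
  Both are conservative undercounts.
- A read whose only error falls in the boundary/confirmation colors is lost
  even though its insert is error-free; loss is logged, never silently
  reassigned.
- With ≤ 1 mismatch tolerated, terminal classifications can be confounded on
  reads carrying both an error and an addition near the 3′ end; at the
  default error rate this affects well under 1 % of reads and is absorbed by
  the statistical tolerances, but single-read calls near the 3′ end should
  not be over-interpreted.
- DE calling is a fold-change screen for single libraries; it has no error
  control and is not a substitute for replicated count-model testing.
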