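# Methods

## Model

A specimen is modelled as one or more clones, each a `GenomeConfiguration`:
a set of derivative chromosomes, where a derivative is an ordered list of
reference segments (chromosome, half-open interval, orientation). Sequence
content is deliberately absent — every question the package answers depends
only on which reference bases are present, in what copy number, and in what
adjacency. Derivative structure is supplied explicitly (ordered segments
joined by validated junctions); inferring paths through a general breakend
graph is out of scope, because SV callers emit the calls and the
reconstruction of biologically plausible derivatives from them is a separate,
harder problem. The bounded event-shape builder in `bapfish.io`
(`config_from_events`) covers the shapes the package itself produces —
reciprocal translocation, one-sided juxtaposition, focal deletion, amplicon
gain, templated insertion, whole-chromosome gain — and refuses anything else.

Probe footprints are BED intervals. The shipped defaults place a ~400 kb red
block at chr8:127,335,000–127,735,000 (ending just centromeric of *MYC*) and
a ~400 kb green block at chr8:127,935,000–128,335,000 on GRCh38-like
coordinates. The vendor does not publish footprint coordinates, so these are
documented approximations; everything downstream depends only on the relative
order (red — *MYC* — green) which the assay design does specify.

## Signal simulation

In-silico hybridisation proceeds in three steps per clone:

1. **Projection.** Each footprint is intersected with every derivative
   segment and mapped into derivative coordinates (reversed for inverted
   segments).
2. **Spot emission.** Maximal contiguous runs of footprint bases emit one
   spot each if the run covers at least `min_visible_frac` of the footprint
   (default 0.3). The fraction stands in for the unknown relationship
   between partial probe deletion and visible signal (dim vs absent);
   exposing it as a parameter keeps the assumption explicit.
3. **Fusion merging.** On each derivative, red and green spots whose genomic
   gap is at most `d_fuse` (default 1 Mb) merge pairwise into fusion
   signals, greedily by smallest gap with a deterministic left-to-right tie
   break, each spot used at most once. Unmerged spots are isolated signals.
   Interphase colocalisation resolution is an optical property the
   nomenclature does not encode; 1 Mb is a deliberately conservative stand-in,
   and every shipped reconstruction classifies identically under two-fold
   changes of either parameter in both directions (tested).

Classification follows break-apart convention: isolated red and green →
RGF; isolated red only → RF; isolated green only → GF; no isolated signals
with fusion count equal to ploidy → NORMAL, otherwise FUSION_CN. Summaries
carrying count ranges are classified at both endpoints and reported
AMBIGUOUS when the endpoints disagree.

## Nomenclature

The `nuc ish` parser normalises the typographic chaos of published strings —
unicode primes (U+2032, U+2019) vs ASCII apostrophes, U+223C vs ASCII tilde
vs hyphen for ranges, arbitrary interior whitespace, a stray comma after
`nuc ish` — then tokenises and parses probe groups, relation groups, shared
multipliers (`(5'MYC,3'MYC)x2~4`), cell fractions (`[97/100]`, with `[100]`
meaning 100/100) and multiple `/`-separated clones. Count ranges are carried
as closed intervals end to end rather than collapsed, because collapsing
loses reported information. A clone mixing `con` and `sep` terms is
rejected: no published example defines its semantics, and failing loudly
beats guessing. Multi-clone results classify by the dominant abnormal clone
(the non-NORMAL clone with the most cells), since group labels describe the
abnormal population. The canonical writer emits ASCII primes, `~` ranges and
expanded multipliers; parse∘format is the identity on structure (verified on
the full cohort plus 1,000 fuzzed dialect variants).

## Reconciliation and interpretation

`reconcile` compares the class observed in nomenclature with the class the
simulator predicts from a genome reconstruction, and reports the fractional
copy number of each probe footprint (sum of segment overlaps divided by
footprint length — additive over derivatives and invariant under segment
subdivision). Across the validation cohort this reproduces the diagnostic
asymmetry: 5′ material at higher copy number in every RF case, 3′ in every
GF case.

`interpret_result` is a total function over pattern class × confirmation
status. The unbalanced branches key on a tri-state input — juxtaposition
confirmed, pure copy-number change confirmed, or unknown — that is never
inferred, because rearrangement status under classification schemes is a
clinical judgement. The full branch table lives in an editable JSON file;
prose sources describe the main branches but not every ordering detail
(e.g. priority among recommended confirmatory tests), so laboratories can
adjust the table rather than inherit hard-coded guesses. The defaults:
unknown → "likely positive, recommend IG/MYC D-FISH, MYC IHC, WGS/RNAseq";
confirmed juxtaposition → positive; confirmed pure CN → not classified as a
rearrangement; NORMAL carries the ≥ 4 % false-negative caveat of BAP-only
testing.

Survey tallies round half-up to integer percentages, matching how such
figures are conventionally printed (23/54 → 42.59… → 43).

## Synthetic data

The generator emulates the rearrangement archetypes observed at the locus.
Ground truth is fixed by the archetype's topology, not by running the
simulator — an unbalanced 3′ loss *is* RF by construction — so the recovery
property (simulate → classify equals truth, run over 500+ seeded scenarios)
genuinely tests the pipeline. Breakpoints are drawn uniformly within
archetype-legal windows (telomeric gap 127,743,500–127,930,000; intron-1
window 127,736,000–127,737,500; 5′ flank 127,100,000–127,330,000), with
window overrides validated against the modelled locus. Partners are abstract
labelled chromosomes, keeping the generator reference-free. Cohorts use
largest-remainder apportionment of the archetype weights, so frequencies are
exact whenever n×weight is integral and within one count otherwise; a
per-cohort seed then shuffles order and derives per-scenario seeds.

What the generator does **not** emulate: optical noise, signal dropout,
FFPE artefacts, cell-to-cell count heterogeneity (synthetic clones are
homogeneous), or sequence-level features. Passing tests therefore
demonstrate correctness of the topology-to-pattern logic, not robustness to
microscopy-level noise in real specimens.

## Validation cohort

The 14 encoded cases pair verbatim nomenclature with minimal derivative
reconstructions of the described events (unbalanced juxtapositions to TG,
IRF8, SPAG1/ADAM regions and ACTB; a pure 5′ copy gain; a focal deletion; and
seven balanced-pattern controls with IGH, RFTN1, DMD, ZCCHC7, IGLL5, IGL and
BCL11A partners, two with trisomy 8). Breakpoint coordinates are
**illustrative**: the source material describes breakpoints relative to
*MYC*/*PVT1* and partner introns, not as base positions, so each record is
one consistent reconstruction (flagged in its `events` note where multiple
orders are possible, e.g. the four-junction case 10 and complex case 13).
Concordance across the cohort is therefore a consistency check of the whole
pipeline — parser, simulator, classifier, copy-number logic — not a
reproduction of unpublished coordinates. The fixture file carries a SHA-256
checksum over its case payload, verified at load.

## Numerical and degenerate-input choices

- Coordinates: 0-based half-open internally; conversion to 1-based happens
  only at the VCF boundary. A LEFT-retaining breakend maps to VCF POS =
  boundary; RIGHT-retaining to POS = boundary + 1.
- Spot intensity is capped at 1.0 when tandem-duplicated footprint copies
  form one contiguous run.
- DEL/DUP records default to single-homolog semantics (copy number 1 / 3)
  unless an explicit `CN` INFO field overrides them.
- Whole-chromosome gains are modelled as extra full-length derivatives; a
  CN gain covering ≥ 90 % of a contig is treated as whole-chromosome.
- Empty derivative lists, zero-length intervals, descending count ranges,
  negative derived signal counts and clone fractions summing above the cell
  total are all rejected at construction with specific error types.
- All randomness flows through `numpy.random.default_rng` seeded from the
  scenario or cohort seed; serialised scenarios are byte-identical across
  runs.

## Problem sizes

The test suite runs the simulator-vs-oracle comparison on 250 random
configurations over a miniature 20 kb locus (where a per-base mask oracle is
exact and cheap), truth recovery on ~580 scenarios, and 1,050+ fuzzed
nomenclature round trips; the whole suite completes in a few seconds. These
sizes give multiple-of-the-required coverage for each property while keeping
the suite fast enough to run on every change.

## Known limitations

- RF/GF assignment from nomenclature inherits the reporting convention of
  the source strings; exotic multi-clone mixtures where no single clone
  dominates are classified by the largest abnormal clone only.
- A printed count range is treated as an interval, not as a subclone
  mixture; whether it reflects heterogeneity is not recoverable from the
  nomenclature.
- The event-shape builder intentionally rejects event sets outside its
  recognised vocabulary rather than guessing a derivative order.
- Three-colour and dual-fusion probe designs are out of scope; the D-FISH
  result enters only as an ancillary flag.
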