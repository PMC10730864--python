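# bapfish

Reconciling unbalanced *MYC* break-apart FISH results with structural
variants from genome sequencing.

## The problem

*MYC* rearrangements (*MYC*-R) are a defining feature in the classification
of aggressive B-cell lymphoma (DLBCL/HGBCL). They are usually sought with a
break-apart (BAP) probe pair: a red (R) probe hybridising 5′ (centromeric)
of *MYC* and a green (G) probe 3′ (telomeric), which colocalise into a
fusion (F) signal when the locus is intact. A typical rearrangement
separates them — isolated red *and* isolated green signals next to the
remaining fusion (an **RGF**-type pattern). But clinical laboratories also
encounter *unbalanced* patterns: isolated red without isolated green
(**RF**) or isolated green without isolated red (**GF**). Whether these
represent a genuine rearrangement, a copy-number change, or an artefact is a
recurring interpretive problem, and practice varies widely.

`bapfish` implements the desk side of resolving that question for people who
work with FISH nomenclature and SV calls — cytogeneticists, molecular
pathologists and pipeline developers:

- **`bapfish.iscn`** — a parser, signal-summary engine and canonical writer
  for ISCN interphase (`nuc ish`) nomenclature of the two-probe assay,
  including count ranges (`x2~5`), `con`/`sep` relation terms, multi-clone
  results and the typographic variants found in published tables. The core
  derivation: F = con count, or min(R, G) − sep count, or min(R, G); then
  isolated R = R − F and isolated G = G − F, evaluated at both endpoints of
  every count range.
- **`bapfish.locus_model`** — derivative chromosomes as ordered lists of
  reference segments, probe footprints as BED intervals, breakend junctions,
  and fractional probe-footprint copy numbers.
- **`bapfish.fish_sim`** — in-silico hybridisation: project footprints onto
  each derivative, emit spots for visible footprint runs, merge colocalised
  red/green spots (gap ≤ `d_fuse`) into fusions, classify the pattern into
  NORMAL / RGF / RF / GF / FUSION_CN / AMBIGUOUS.
- **`bapfish.interpret`** — observed-vs-predicted reconciliation (with the
  copy-number asymmetry that explains unbalanced patterns) and a data-driven
  interpretation table: unbalanced patterns without ancillary data are
  reported *likely positive* with confirmatory testing recommended; a
  confirmed pure copy-number change is explicitly not classified as a
  rearrangement; a normal result carries the ≥ 4 % false-negative caveat of
  BAP-only testing.
- **`bapfish.synthetic_data`** — seeded rearrangement archetypes (balanced
  translocation, unbalanced 5′ gain / 3′ loss, whole-locus gain, focal
  deletion of *MYC* and the 5′ probe, templated insertion, intron-1 genic
  breaks) with analytically fixed ground-truth classes.
- **`bapfish.cohort_cases`** — a 14-case DLBCL/HGBCL validation cohort:
  verbatim nomenclature strings, pattern groups, partner genes, IHC flags
  and minimal derivative reconstructions of the sequencing-confirmed events.

## Worked example

```sh
python examples/03_reconcile_cohort.py
```

prints, for the validation cohort:

```
case group  observed predicted concordant CN 5-prime CN 3-prime
   1    RF        RF        RF       True       3.00       2.00
   2    RF        RF        RF       True       2.00       1.00
   ...
   7    GF        GF        GF       True       1.00       2.00
   ...
  14   RGF       RGF       RGF       True       2.00       2.00
```

Each row parses a verbatim `nuc ish` string, simulates the break-apart
signals implied by that case's derivative-chromosome reconstruction, and
compares the two classifications. All 14 are concordant (5 RF, 2 GF, 7 RGF),
and the copy-number columns show why the unbalanced patterns arise: material
5′ of *MYC* sits at a higher copy number than 3′ material in every RF case,
and the reverse in every GF case.

The other example scripts cover nomenclature parsing
(`01_parse_nomenclature.py`), building and simulating a rearranged genome
(`02_simulate_rearrangement.py`), synthetic cohorts with truth recovery
(`04_synthetic_cohort.py`) and interpretation plus the laboratory-practice
survey tallies (`05_interpret_and_survey.py`).

## Command line

A thin CLI wraps the same library calls:

```sh
bapfish classify results.txt                 # nuc ish strings -> pattern classes
bapfish synth --archetype UNBALANCED_3P_LOSS --seed 5 --out-prefix scen
bapfish simulate --sv scen.vcf               # SV calls -> simulated pattern
bapfish reconcile --nuc-ish "nuc ish(5'MYCx2,3'MYCx1)(5'MYC con 3'MYCx1)[100]" --sv scen.vcf
bapfish interpret --pattern RF
bapfish survey
bapfish validate-cases                       # 14-row concordance table
```

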