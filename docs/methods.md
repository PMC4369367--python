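# Methods

## The screening design

`tillseq` implements mutation detection for TILLING by sequencing with
two-dimensional pooling.  A chemically mutagenized (EMS) population of 768
diploid M2 lines is arrayed in eight 96-well plates; the plates are stacked
into one micropool plate and collapsed along each axis into 20 superpool
libraries — 8 row pools of 96 individuals and 12 column pools of 64
individuals.  Target amplicons are PCR-amplified from every superpool,
barcoded with 5-base inline adapters, and sequenced as paired-end reads.

A rare induced mutation is visible as a small excess of a non-reference base
at one position, in exactly one row library and one column library; the
row × column intersection identifies the micropool well, leaving the
`n_plates` stacked individuals to be resolved by genotyping.  Expected
allele fractions follow from pool arithmetic: a homozygote contributes
2 of the 192 chromosomes in its row pool (1.04%) and 2 of 128 in its column
pool (1.56%); a heterozygote half of that (0.52% / 0.78%).  Because the
column pools are 2/3 the size of the row pools, column percentages are
multiplied by the exact dilution factor 2/3 (printed 0.67) before
thresholding, so one threshold serves both axes.

## The two callers

**Single-copy caller** (`call_single_copy`).  Evidence is a quality-
stratified counts tensor: per (library, reference, position), counts of
A/C/G/T at each exact Phred score, queried at minimum-quality cutoffs
(default 10, 12, 14, 15, 16, 17, 18, 19, 20, 21).  At each cutoff `q` an
alternate base is a candidate when its dilution-adjusted percentage lies in
`[min%(q), max%]` in exactly one row and exactly one column library, and
when in both hit libraries its count is at least `dominance_ratio` (default
2) times every other non-reference base at that position.  The per-cutoff
minimum percentages default to a table calibrated on known control mutants
(0.370% at cutoff 10 falling to 0.058% at cutoff 21, roughly 3–12× the
quality-filtered background error rate); `max%` defaults to 5%, rejecting
fixed polymorphisms and paralog bleed-through.  Candidates are then grouped
by the cutoffs at which they appear: `common` (every cutoff), `high` (only
≥ 17), `low` (only ≤ 16), else `mixed`; in practice the common group
validates best.  The dominance rule operationalizes "the candidate base
should clearly exceed other non-reference bases"; no formal test is implied
and the ratio is configurable.

**Multi-copy caller** (`call_multi_copy`).  Multi-copy gene families
(homeologs and near-identical paralogs) dilute the allele signal: reads
from all copies stack on each reference, so a mutant allele's percentage
falls below any workable fixed threshold.  Counting is therefore done in
`report_all` mapping mode (a read is counted once per copy it matches,
deliberately reproducing the dilution), and the statistic is the *variance
multiplier*: a library's non-reference fraction divided by the mean
fraction of the other libraries on its own axis.  A candidate needs a
multiplier ≥ m in exactly one row and one column library plus a small raw
floor (0.05%).  Sites of fixed divergence between copies light up every
library equally, giving multipliers near 1, and are rejected without any
special-casing.  The background denominator is floored at ε = one read
equivalent at the reference's mean depth (100/mean_depth percent), so
zero-background cells cannot produce infinite multipliers; when the
background exceeds ε the multiplier is exactly the ratio of fractions.
The working grid spans qualities 16–23 and multipliers 2–20; calibration
typically selects multipliers 8–14.

The phrase "ratio of row to column counts" admits several readings; this
implementation compares a library against its own axis's background, the
reading consistent with the motivating observation that true mutants are
counted ~10–20× more in one row/column than in the others.  The statistic
is isolated in one code block so alternative definitions can be swapped in.

## Calibration

`calibrate.grid_search` scores every parameter combination against a
control list of known-true and known-false sites: `true% = 100·n_true/total
predicted`, `false% = 100·n_false/total`, both rounded to one decimal
(round-half-even, which reproduces conventional printed tables: 11/16 →
68.8, 1/16 → 6.2), and ranks by `difference = true% − false%` computed on
the rounded values (68.8 − 6.2 = 62.6).  Ties break by higher `n_true`,
then smaller prediction list.  Predictions matching neither list count in
the denominator only, so the ranking rewards clean prediction lists over
raw sensitivity — the screen's stated philosophy.  `consensus_candidates`
intersects the prediction sets of the top-k combinations.

## Annotation and reporting

Effects are classified by mapping the position through the gene model's CDS
intervals (strand-aware), translating the affected codon before and after
(Biopython), and labelling silent / missense / nonsense; positions outside
the CDS are noncoding.  EMS canonicality is judged literally on the written
strand (G→A or C→T); strand-resolved G:C→A:T accounting would also count
the complements and is deliberately not the default, matching how such
spectra are conventionally tallied.  Mutation frequency is the conventional
`(screened kb / mutations) × lines`, rounded half away from zero to the
nearest kb.  `line_anomaly_report` flags lines carrying ≥ 3 non-canonical
changes as suspected contaminants; the packaged screen record flags line
07JKEMS1125 (7 of the screen's 9 non-canonical changes).  When frequencies
are recomputed without flagged lines, the overall figure excludes the
flagged lines' non-canonical changes (the changes that triggered the flag)
while the per-class figures exclude all their mutations — an asymmetry in
the original screen's bookkeeping that we reproduce rather than resolve
(the flagged line actually carries 8 tabulated mutations: 5 single-copy and
3 multi-copy).

The Ara h 2.02 change upstream of the start codon is classed `noncoding`
here (its original report labels it silent); the packaged table keeps the
published `noncoding`-equivalent label and the divergence is noted in this
paragraph rather than mimicked in code.

## The synthetic-data generator

The simulator provides ground-truthed inputs with the study's structure:

* **Population** — each of the 768 individuals accrues Poisson-distributed
  mutations; a fraction `canonical_fraction` (default 0.85, a realistic EMS
  spectrum with some non-canonical noise) are G→A/C→T on G/C sites;
  zygosity is heterozygous with probability 2/3, the selfed-M2
  expectation.  The default `mutation_rate` of 1.3e-5 /bp/individual puts
  ~30 mutations on two 1.5 kb amplicons across the population — the scale
  used by the end-to-end tests; real screens are ~30× sparser per base, and
  the rate is a parameter.  `unique_sites=True` forbids recurrent hits at
  one site, restoring the realistic regime (at real per-site rates the
  expected number of lines hitting one base is ~0.002) when the rate is
  compressed into a short region.
* **Pooling** — exact dosage arithmetic: `z/(2·pool size)` per axis.
* **Reads** — 94 bp total (5-base barcode + 89 genomic bases, mirroring
  full-length reads with inline barcodes).  Fragments have uniform lengths
  160–260 bp; a `terminal_fraction` (default 0.3) of fragments is pinned to
  the amplicon ends, because fragmenting an amplicon molecule always yields
  the two terminal fragments — without this, coverage collapses at the
  termini.  Mate 1 reads the fragment 5' end forward, mate 2 the 3' end
  reverse-complemented; a fragment carries a planted mutation with
  probability equal to the library dosage, so mates agree.  Base qualities
  are drawn from a discrete mixture over Q ∈ {11, 13, 16, 18, 37, 41} with
  probabilities {0.001, 0.0005, 0.006, 0.002, 0.55, 0.4405}; substitution
  errors are Phred-consistent (probability 10^(−Q/10), scalable by
  `error_scale`, plus an optional quality-blind `context_error_rate`).
  The small low-quality tail is chosen so that the quality-filtered
  background non-reference rate falls from ~0.043% at cutoff 10 to ~0.015%
  at cutoff ≥ 19 — the regime in which a per-cutoff minimum-percentage
  table is meaningful and the default thresholds sit 3–12× above
  background.  A flat error floor cannot produce that regime at both ends
  of the cutoff range simultaneously.

What the generator does **not** emulate: PCR chimeras and polymerase
errors shared across reads, GC- and position-dependent coverage bias,
indels (the callers target substitutions), uneven pooling of individuals,
and per-library depth skew beyond a settable mean.  Passing tests on this
generator therefore demonstrate the correctness of the pooling arithmetic,
demultiplexing, counting and calling logic under calibrated noise — not
robustness to the full error structure of a real sequencing run.

## Numerical and implementation choices

* Percentages are carried as exact fractions (`fractions.Fraction`) in the
  pool-arithmetic layer and as float64 in the callers; rounding happens
  only at presentation (2 d.p. for pool fractions, 1 d.p. in calibration
  tables).
* The counts tensor stores exact-quality counts (shape `L × 4 × 42`), so
  cutoff-filtered counts are suffix sums and monotonicity in the cutoff is
  structural rather than asserted.
* The internal mapper is exact k-mer seeding (length 20, anchors at the
  read start and midpoint, both strands) with ungapped extension and a
  3-mismatch budget — adequate for short reads on known amplicons, and
  validated against `samtools mpileup` output on the same alignments.
  `single` mode discards tied best placements as ambiguous; ties are never
  broken arbitrarily.
* Depth-0 cells are skipped and logged, never errors.  Equal-percentage
  double hits on one axis are rejected as non-unique.
* Demultiplexing tolerates no barcode mismatches beyond N repair from the
  mate (the default barcodes are Hamming-distance ≥ 3 apart, so single
  errors cannot convert one barcode into another); pairs with mean barcode
  quality < 10 are dropped before repair.
* Simulation problem sizes in the test suite (two 1.5 kb amplicons at
  5000× per library for the single-copy recovery check; a 99%-identical
  1.2 kb duplicated pair at 5000× for the multi-copy check) were chosen to
  keep the whole suite runnable on a laptop while leaving the planted
  signals many standard deviations above their thresholds.

## Known limitations

* The mapper is ungapped: reads spanning indels would be lost, so indels
  are out of scope end to end.
* Multi-copy candidates cannot be assigned to a specific gene copy inside
  conserved regions; the caller reports the echo on every matching copy.
* Zygosity inferred from pooled fractions (`infer_zygosity`) separates
  hom/het only by a factor of two and is flagged low-confidence outside a
  ±25% band; definitive zygosity needs individual genotyping.
* The per-cutoff minimum-percentage table is shipped as a calibrated
  default, not recomputed from first principles; re-calibration on new
  control mutants via `grid_search` is the supported route.
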