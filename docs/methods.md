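# Methods

## Scope and model

`archseq` models one screening design: ultra-deep single-end amplicon
sequencing of 15 recurrently mutated myeloid codons ("hotspots") in
blood DNA, used to detect small hemopoietic clones down to a variant
allele fraction (VAF) of 0.008 and to relate clone carriage to age.
The pipeline consumes aligned reads (alignment itself is out of scope;
the simulator emits pre-aligned records) and proceeds pileup → filtered
allele counts → threshold calls → cohort statistics.

## Panel and coordinates

Published hotspot panels list gene/codon pairs but not coordinates, and
a pipeline that required a human reference download would not be
self-contained. The shipped default panel therefore places each hotspot
on its own synthetic 300-bp contig with the codon at positions 150–152
(1-based, inclusive, the alignment-record convention; half-open
arithmetic is confined to private code). Background sequence is
generated deterministically from a CRC of the contig name, then the
configured codon bases are written in; for the NPM1 locus the four bases
ending at the insertion point are set to `TCTG` so that mutation A is a
true tandem duplication of reference sequence. Users with real
alignments supply a panel config (YAML/JSON) carrying genome
coordinates; validation enforces contiguous codon positions, A/C/G/T
reference bases, and unique (gene, codon) pairs.

The per-position alternate-allele whitelist used by the original screen
is not published; by default all three codon positions and all
alternates are interrogated, and a config field (`interrogated_alts`)
allows restriction.

## Clonal-mutation table fixture

The study's printed table of 112 clonal mutations is packaged verbatim
as a TSV (gene, hotspot, protein change, VAF %, age, same-sample
symbol; symbols transliterated to ASCII). VAF is stored as percent
exactly as printed and converted to a fraction on demand, avoiding a
double representation. Summaries derived from it (e.g. clones at or
below a VAF cut, multi-mutation individuals, minimum carrier age per
gene class) are recomputed from the rows, never hard-coded. Counting
the printed rows gives 18 spliceosome-gene clones with VAF ≤ 5 % and 14
with VAF ≤ 3 %; the study's prose summary quotes 19 and 13 for the same
quantities, an internal inconsistency of the source that the fixture
preserves rather than resolves (the overall count of 61/112 clones at
VAF ≤ 3 % agrees with the printed rows).

## Read and cohort simulation

The generator's defaults are the study conditions: read length 150 bp,
single-end, one fixed-start amplicon per hotspot fully spanning the
codon (mid-read); target depths 1,000–10,000× (default 5,000×);
per-base substitution error rate e = 10⁻³ (the study's own validated
per-site error spectrum is not published, so e is a free parameter);
clone VAFs on the detection scale 0.008–0.45, capped at 0.5 under the
heterozygous-autosomal assumption unless a clone is explicitly marked
homozygous.

Per clone, the number of variant-carrying reads is drawn
Binomial(depth, VAF) *before* error; substitution errors then flip each
base independently to a uniformly chosen other nucleotide. Base and
mapping qualities are two-point distributions (defaults: base quality
30/20 at 90 % passing, mapping quality 60/10 at 95 % passing) chosen to
straddle the filter bounds, so filter behaviour is exactly testable —
real MiSeq quality distributions are continuous, and nothing here
models PCR duplicates, paired ends, strand effects, or
context-dependent error, so passing tests demonstrate correctness of
the statistical machinery under the stated error model, not robustness
to every artefact of real data.

Reads live in a vectorised per-amplicon container (`ReadBlock`: numpy
matrices of bases and qualities plus per-read mapping quality and an
insertion side-table) with lossless conversion to coordinate-sorted SAM
via pysam. The pileup and the NPM1 detector accept either
representation; equivalence of the two routes is asserted by tests,
including a brute-force per-read recount oracle on random read sets.
The container exists because at cohort scale (thousands of samples ×
15 amplicons × thousands of reads) per-read Python objects dominate
runtime without changing any statistics.

Insertion-bearing reads keep the fixed read length, so their aligned
reference span is 4 bp shorter; the inserted bases are spliced into the
query and encoded as a CIGAR `I` operation on SAM export.

### Clone kinetics

Cohorts draw ages from a two-arm mixture echoing the study's sources
(broad 17–70 donor arm, weight 0.73; elderly 60–98 arm, weight 0.27).
Two kinetics classes govern clone carriage:

* **early-drift** (DNMT3A R882, JAK2 V617F, rare IDH/RAS classes):
  carriage probability rises linearly with years since an acquisition
  age (default 20), e.g. 5 × 10⁻⁴/yr for DNMT3A — ~0.2 % in the
  youngest bin rising to ~3 % in the ninth decade.
* **age-gated** (SRSF2 P95, SF3B1 K666/K700): zero carriage below the
  gate age (default 70), then a linear rise (jointly ~2 % shortly after
  the gate to ~9 % in the tenth decade). The gate is absolute by
  construction — the model device representing clonal advantage that
  emerges only in the aged hemopoietic environment.

A carrier's VAF is drawn log-uniformly between the detection floor
(0.008) and an age-dependent ceiling given by logistic growth of the
clone cell fraction (per-year logit increment; default 0.25/yr
early-drift, 0.5/yr age-gated; ceiling capped at VAF 0.45). Carriage
probability and VAF are the two observables the downstream analyses
use; the trajectory model is deliberately minimal.

Cohort simulation returns a truth table (with per-sample seeds) and
regenerates reads lazily and deterministically per sample, so
multi-thousand cohorts are cheap to hold.

## Counting and calling

* Filters: mapping quality > 15 (read-level, checked first), base
  quality at the position > 25. Strict inequalities, taken literally:
  boundary values fail. Depth accounting is invariant-checked:
  filtered + dropped(mq) + dropped(bq) + dropped(other) = raw.
* VAF = most-frequent non-reference nucleotide count / filtered depth;
  ties break alphabetically and are flagged; stored at full precision,
  displayed to 4 decimals.
* A call requires filtered depth ≥ 1,000 at *every* codon position
  (coverage adequacy is applied to filtered depth — only filtered reads
  inform the VAF) and max site VAF ≥ 0.008, inclusive. Only the
  most-frequent variant is called; secondary alternates are reported,
  not called.
* False-positive model: P[X ≥ ⌈threshold·D⌉], X ~ Binomial(D, e), with
  the ceiling matching the inclusive call rule. Treating all
  error-derived alternates as a single binomial with rate e is
  conservative by up to 3× relative to a per-alternate (e/3) model with
  a max over three alternates; the attached probabilities are upper
  bounds in that sense. At e = 10⁻³, D = 1,000 the tail is ≈ 1.0 × 10⁻⁵
  (marginally above 10⁻⁵); at the assay's typical depths ≥ 3,000 it is
  below 10⁻¹⁵.
* Error-rate estimation pools non-reference counts over
  mutation-negative sites, excluding designated hotspot alternates from
  the numerator, with an exact binomial CI.
* NPM1 detector: numerator = mapping-quality-passing reads with a 4-bp
  insertion within ±5 bp (configurable) of the canonical point,
  inserted sequence exactly TCTG by default (a switch accepts any 4-bp
  insertion, for non-A canonical NPM1 mutations); denominator = all
  quality-passing reads spanning the junction. The original study's
  bespoke detector logic is unpublished; these rules are explicit
  stand-ins. Base qualities of inserted bases are not filtered (an
  insertion is a read-level event here).

## Cohort statistics

Prevalence counts individuals, not clones (a person with two called
mutations counts once). Intervals are exact Clopper–Pearson (the
source shows no CI method; exact intervals are the defensible default
at small k). Age bins are config-driven (default 17–29 … 90–98)
because published analyses mix bin edges. Group comparisons default to
Welch's unequal-variance t test — "unpaired t test" does not specify a
variance assumption, and the compared groups are heavily unbalanced
(~10² carriers vs ~3.5 × 10³ non-carriers) — with a pooled-variance
switch. The hotspot-to-total projection is exposed as a formula
(`independent-union`: 1 − (1 − p)^r; `linear-capped`: min(1, r·p)) with
the ratio r a user input; the package does not claim to reproduce any
published projected incidence, which depended on unpublished
integration of external exome studies.

## Numerical and testing choices

* All randomness flows through `numpy.random.default_rng`; per-hotspot
  streams are spawned from the sample seed, per-sample seeds from the
  cohort seed, so outputs are byte-reproducible.
* Problem sizes in the test suite: the false-positive model is checked
  against a 10⁷-draw Monte-Carlo oracle on a grid of error rates
  {5 × 10⁻⁴, 10⁻³} × depths {1,000, 3,466, 5,000} (3-standard-error
  agreement; the sub-10⁻⁵ bound is asserted only where the oracle
  resolves it, since the e = 10⁻³/D = 1,000 tail sits within Monte-Carlo
  noise of the bound). Simulator fidelity uses a chi-square
  goodness-of-fit over 200 seeds and CI-coverage over 200 replicate
  cohorts of 400 individuals at a well-powered carriage rate
  (coverage of exact intervals is only near-nominal when expected bin
  counts are not tiny). The end-to-end check runs 500 individuals at
  depth 5,000 with one clone each at true VAF ≥ 0.012 (log-uniform to
  0.45), asserting ≥ 99 % sensitivity and a false-positive count
  consistent with the binomial model across the ~7,000 negative
  sample-hotspot pairs.
* Degenerate inputs raise: VAF at zero filtered depth, calls from empty
  counts, NPM1 VAF with no spanning reads, error-rate estimates at zero
  pooled depth, t tests on constant-vs-constant groups.

## Known limitations

* The simulator's quality model is two-point and its error model is
  context-free; it validates filter and threshold logic, not
  error-spectrum realism.
* One insertion per read at most; no deletions are simulated (deletion
  *handling* in the pileup is still exercised by constructed reads).
* The kinetics model is a sampling device for (age, carriage, VAF)
  triples, not a mechanistic model of hemopoietic stem-cell dynamics.
* Coordinates in the default panel are synthetic; results on real data
  require a user-supplied panel with genome coordinates and aligned
  reads from a real aligner.
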