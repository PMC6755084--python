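# Methods

## Assay model

The package models a pooled, single-end-point ligation assay of a ligase
ribozyme variant library. Each variant molecule either ligates its substrate
within the reaction window or does not; gel separation and barcoded
sequencing of the two bands turn this into a per-variant binomial
experiment. The fraction ligated, `FL = N_lig / (N_lig + N_unlig)`, is the
maximum-likelihood estimate of the per-molecule ligation probability, and
the relative activity `RA = FL / FL_wt` rescales it to the parental core.

Because the end point sits far into the reaction (30 min for a parent with
`k_obs` in the 0.5–10 min⁻¹ range), `RA` has a compressed dynamic range:
any variant with `k_obs` above roughly 0.1 min⁻¹ has already ligated almost
completely and reads out near `RA ≈ 1`. All landscape analyses in
`ligscan.activity` therefore treat `RA` as a semi-quantitative damage
score, not a rate, and the package never converts `RA` into `k_obs`.

## Library enumeration

Variants are enumerated over an annotated `CoreTemplate`: a mutable span
(substitutions and deletions), a bulge span (exhaustive replacement with
every sequence of length 0..3), and named stems (truncation). Closed-form
counts are `3L` single and `9·C(L,2)` double substitutions for `L` mutable
positions (93 and 4185 for the 31-position parent core).

Deletions require care: deleting different positions of a homopolymer run
yields the same molecule, and sequencing cannot tell collapsed variants
apart. Enumeration therefore deduplicates by resulting sequence, keeping
the leftmost-position label as the canonical `variant_id` and every
equivalent label in `source_labels`; `build_library` applies the same
sequence-level deduplication *across* classes (a bulge removal can equal a
triple deletion). The test suite checks the deduplicated enumeration
against a brute-force distinct-string oracle on random templates up to
length 12. When positional maps are rebuilt from deduplicated records, the
shared `RA` is expanded back onto every collapsed position — the only
defensible choice, since the collapsed variants are physically identical.

The bundled templates are synthetic stand-ins: they carry the documented
architecture (main core + P2 spacer stem + GAA bulge opposite the ligation
site) and the individually documented base identities of the F1-family
cores, but positions not pinned by any published observation were chosen
arbitrarily. They make the package runnable and testable; they are not a
substitute for a real construct's sequence, which is always supplied as
configuration.

## Read processing

Processing order is fixed: read-level quality filter → barcode demultiplex
→ constant-region trim → core-level quality filter → exact index lookup.
Two named policies cover the two screens modeled: `f1star` (read passes
with ≥ 70% of calls at QS ≥ 20, core must be all-QS ≥ 20) and `minf1`
(no read-level filter, core all-QS ≥ 30). Barcode and flank matching
default to 0 mismatches; both tolerances are exposed, with ambiguous
(equidistant) barcode matches always unassigned. Variant assignment is
exact-sequence only — no fuzzy matching — so any read with a core
sequencing error lands in `unassigned` rather than contaminating a
neighboring variant's counts. Every read increments exactly one counter;
`CountTable.check_partition()` enforces the identity after every run.
FASTQ I/O is Sanger-encoded (Phred+33), gzip-transparent, via Biopython's
fast FASTQ iterator.

## Activity statistics

FL uncertainty uses the Wilson 95% score interval (statsmodels), chosen
over Wald for its behavior at extreme counts; no pseudocounts are added.
Interval endpoints are clamped to bracket the point estimate, guarding
against sub-epsilon round-off at 0/n and n/n. Variants with fewer than 20
total reads are flagged, not suppressed — the assay itself defines no read
floor, so suppression is left to the consumer. Activity classes follow
strict upper comparisons (high > 0.90, active > 0.50, partial ≥ 0.10,
inactive < 0.10), making the classification monotone in `RA` with 0.90
classed "active" and 0.10 classed "partial".

Compensatory-pair detection quantifies the rescue pattern that is usually
described qualitatively: both single mutants below `single_cutoff`
(default 0.10) and the double at least `rescue_margin` (default 0.20)
above the better single. The two *mutant* bases are then classified
Watson-Crick / wobble / other; `infer_paired_positions` accumulates only
helix-compatible rescues as evidence for base pairing, since a rescue
through non-pairing bases more likely reflects a tertiary contact.

## Kinetics

Time courses follow `FL(t) = F_max (1 − e^(−k_obs·t))`, the
pseudo-first-order model for excess ribozyme over substrate. Fitting is
bounded nonlinear least squares (`scipy.optimize.least_squares`,
`k_obs ≥ 0`, `0 < F_max ≤ 1`) over the pooled, unweighted replicate
residuals. Initialization is deterministic: `F_max⁰ = max(FL_obs)` and
`k⁰` from the earliest informative point via the log-linear form
`log(1 − FL/F_max) = −kt`, falling back to the reciprocal median time.
All-zero observations short-circuit to the degenerate fit `k_obs = 0`.
`k_obs` carries its time unit (s/min/h); comparisons convert to min⁻¹, so
0.48 min⁻¹ vs 0.49 h⁻¹ gives 58.8-fold. Refitting the same observations
with times relabeled from minutes to hours changes `k_obs` by exactly 60.

## Synthetic data

The generator's defaults are the study conditions the analyses are
validated under:

* **Landscape presets.** `f1star-like`: wild-type FL 0.826; 66% of
  variants draw `RA = 0.90 + 0.31·Beta(2,2)` (the mutation-tolerant,
  near-parental class), 6% draw `RA = 0.10·Beta(1,3)` (inactive), the rest
  Uniform(0.10, 0.90). `minf1-like`: wild-type FL 0.76 with a sparser high
  class (25%) and a heavier inactive class (45%), reflecting a minimized,
  fragile core. `FL_true = RA·FL_wt` clipped to [0, 1]; WT is pinned
  exactly.
* **Reads.** Amplicon = 8-nt pool barcode + 16-nt constant flank + variant
  core (cDNA) + 16-nt constant flank. Default coverage 200 reads/variant
  (fixed; Poisson optional), iid substitution errors at 10⁻³ per base,
  qualities from a discretized Gaussian (mean 37, sd 4, floored at 2,
  capped at 41). Ligation fates are iid Bernoulli(FL_true). The two
  default barcodes are synthetic 8-mers at Hamming distance 8.
* **Time courses.** Gaussian noise (default sd 0.02, matching gel
  quantification scatter) added to the exponential model and clamped to
  [0, 1]; triplicates share time points.

What the simulator does *not* model — and what passing tests therefore do
not establish about real data: indel sequencing errors (irrelevant under
exact matching, which discards any error read), quality-by-cycle and other
MiSeq error structure, PCR amplification bias, variant-correlated coverage,
gel-extraction losses, and cross-contamination between gel bands. Recovery
results on synthetic reads validate the *bookkeeping and estimation*
chain, not robustness to those artifacts.

Every stochastic routine takes a single integer seed
(`numpy.random.default_rng`); identical seed and config give byte-identical
FASTQ output.

## Problem sizes and verification

The test suite exercises the full 4279-variant substitution library at 200
reads/variant (~856k reads, seconds on one CPU): ≥ 93% of variants must
cover their true FL with the Wilson 95% interval, and a 5000-read wild-type
run must recover the generating FL within binomial sampling error. Kinetics
recovery is checked on triplicate noisy courses over a 0–30 min window
(minutes-scale construct) and a 0–7 h window (hours-scale construct), each
within 10% of the generating rate, plus a 100-simulation median-error check
(≤ 5% at noise sd 0.02). `scripts/acceptance.py` reruns the wild-type
recovery from scratch at depth 5000 and reports the recovered FL.

## Known limitations

* Exact-sequence assignment discards all error-bearing reads; at high error
  rates or long cores this costs coverage (the loss is unbiased between
  pools, so FL remains consistent).
* The compensatory-pair thresholds (0.10 / 0.20) are heuristics exposed as
  parameters; inference of pairing from few rescues is hypothesis
  generation, not structure determination.
* `k_obs` values are single-condition observed rates, not `k_cat`; no
  substrate-concentration dependence is modeled, and no temperature
  extrapolation between constructs is attempted.
* The P2 truncation side (which stem end loses bases) differs between
  construct drawings; it is a parameter (`side`) with a bulge-proximal
  default rather than a fixed convention.
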