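# Methods

This note records the models, parameter choices and numerical decisions
behind `sfpkit`, in the spirit of a statistical-software methods appendix.
It states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## The problem

A 25-mer PM probe hybridized with material from a second strain loses
intensity when the strain-B target mismatches it — a single feature
polymorphism (SFP).  With both strain genomes sequenced, the set of probes
whose target is polymorphic can be predicted exactly and used as ground
truth for benchmarking intensity-based SFP callers.  `sfpkit` implements
that benchmark on synthetic strain pairs so that every stage is exercised at
desk scale.

## Probe annotation

Probes are aligned locally with match +1, mismatch −3, gap open 5, gap
extend 2 (a length-L gap costs 5 + 2L), keeping hits scoring ≥ 18.  The
resulting ladder — 25 for a complete match; 24..21 for a single mismatch
depending on whether the aligner trims a distal mismatch; 24..18 for a
single base inserted in the target — is asserted exactly in the tests, and
the aligner (Biopython's `PairwiseAligner` in local mode) is checked against
an independently written Smith–Waterman on 1,000 random probe/window pairs.

Completeness of the genome scan is an argument, not a hope: any hit of a
25-mer scoring ≥ 18 admits at most one mismatch (score ≥ 21 required before
the −3) or one length-1 target insertion, so it contains an exact match run
of at least 11 bp.  An 11-mer seed index of the genome followed by local
alignment of padded, merged seed windows therefore finds every hit; exact
full-length occurrences are additionally located by direct string search so
perfect hits are counted individually even when copies share a window.
This was chosen over wrapping an external BLASTN because the scan is
provably exhaustive at the genome sizes the package targets (≲ 1 Mb) and
carries no E-value machinery the analysis never uses.

Classification: *unique* = exactly one perfect (score-25) hit in strain A;
SFP truth for unique probes = no perfect hit anywhere in strain B
(genome-wide, not orthology-restricted; probes with multiple perfect
strain-B hits are retained as non-SFPs, since extra copies do not remove
the perfect target).  Coordinates are 0-based half-open internally; only
human-readable report output is 1-based, and says so.

## Synthetic data

### Genome pair

Strain A is uniform random over {A,C,G,T}; strain B is derived by per-bp
Bernoulli SNPs (default 0.004/bp, the ~4 SNPs/kb divergence of the
motivating rice pair in probe-target regions), per-bp indels (default
0.0004/bp, length 1–3), and optional segmental duplications (300–500 bp,
per-kb rate, default off so that designed probes are provably unique in A).
Inserted bases are chosen to differ from both flanking bases, so a single
insertion cannot leave a probe target intact by homopolymer slippage; this
keeps footprint-overlap truth and sequence-search truth identical in
SNP/indel simulations, which the tests verify.  Colliding variant
candidates are dropped deterministically.  With SNPs only, the expected
SFP fraction per 25-mer probe is 25 × rate (0.1 at 4 SNPs/kb — one probe
in ten), or exactly 1 − (1 − rate)²⁵ accounting for multiple hits.

### Probe design

`n_sets` spans of 400 bp (one per equal genome block, mirroring probe sets
concentrated in a few hundred bp near a transcript's 3' end), 11 PM/MM
pairs per set by default, probes allowed to overlap within a span, forward
strand only.  MM = complementary substitution at base 13.

### Intensity model

Per-probe expected log₁₀ PM signal:

    signal = baseline + amount/expression term
             + affinity_slope · (ΔG − mean ΔG)
             + strain term (B only: − per-probe SFP effect)

then a smooth soft-min toward the saturation ceiling, a hard
cross-hybridization floor, and finally i.i.d. Gaussian replicate noise.
MM rows follow the same model minus `mm_penalty` (the strain term applies
to both).  Raw intensity is 10^log₁₀.

Choices and defaults (log₁₀ units unless noted):

- `baseline_log10 = 2.5` (gDNA), `transcript_baseline_log10 = 1.8`;
  amount classes are categorical additive terms {1 µg: −0.5, 5 µg: 0,
  40 µg: +0.8} because the emulated study reports distributional shape
  changes with amount, not a dose–response law.
- `saturation_ceiling = 3.5` with sharpness 3: a smooth soft-min
  `x − log(1+e^{k(x−c)})/k`, since observed 40 µg distributions are
  compressed but not hard-clipped.  **The cap and floor act on the expected
  signal; replicate noise is added afterwards.**  This models replicate
  scatter as observation (scanner/hybridization) noise that does not vanish
  near saturation.  Had the noise been capped too, saturation would shrink
  within-strain variance faster than the between-strain contrast and the
  40 µg condition would spuriously *outperform* 5 µg; with observation
  noise, saturation attenuates contrast only, and the 5 µg-dominates-40 µg
  result emerges for the physically right reason.
- `affinity_slope = −0.05` per kcal/mol: stronger binders (more negative
  ΔG) are brighter; with the ~1.5 kcal/mol ΔG spread of random 25-mers this
  contributes ±0.2 of intensity range.
- SFP effect: per-probe lognormal with mean 0.5 and sd 0.15, drawn once per
  probe, emulating position- and sequence-dependent mismatch impact.  With
  `affinity_dependent_sfp` the effect is scaled linearly from 0.1× (the
  strongest binder) to 1.0× (the weakest), planting the
  false-negatives-bind-strongly phenomenon.
- `noise_sd = 0.25`: replicate scatter of raw, unnormalized array
  intensities on the log₁₀ scale.  This makes default simulations show
  *partial* sensitivity at realistic effect sizes — the regime the original
  evaluation operated in — rather than trivially perfect separation.
- `mm_penalty = 1.0`, `crosshyb_floor = 1.0` (10 raw units), raw floor 1
  before the log transform.
- Replicates: 4 per strain for gDNA, 5 for transcripts (the emulated
  experiments used four and five biological replicates; one figure-level
  analysis used four of the five transcript replicates, so both counts are
  configurable).
- Transcript expression: per-set two-component mixture per tissue (default
  ~40–45 % of sets in a low component centered at 0.2, the rest at 1.5),
  shared between strains, so a controllable fraction of sets falls below
  the 2.5 expression cutoff; expression polymorphism between strains is out
  of scope.
- Amplification-polymorphism mode: the genome is tiled into random
  100–250 bp fragments; each drops out of strain B with probability
  `fragment_dropout_rate`, suppressing every probe it covers — the planted
  mechanism for clustered false positives.

What the generator does **not** emulate: probe-sequence-specific
cross-hybridization, spatial array artifacts, fragment-level amplification
chemistry, heavy-tailed or intensity-dependent noise, and correlated
replicate effects.  Passing tests therefore demonstrate correctness of the
statistical machinery under a clean additive log-scale model, not
performance on real CEL-derived data.

## Callers

All callers consume log₁₀ of raw PM values (floor 1), with no background
correction or normalization — the emulated study found none helped — and
default to one-sided calling toward a strain-B deficit, because an SFP can
only lower the mismatched strain's intensity.  Sidedness is exposed as a
flag since legitimate two-sided variants exist.

- **SAM** (two-class unpaired): `d = (x̄_B − x̄_A)/(s + s₀)` with s the
  pooled standard error of the difference; s₀ is the percentile of s
  (candidates 0, 5, …, 100) minimizing the coefficient of variation of the
  windowed median absolute deviation of d across 100 s-quantile windows;
  when all s are equal the selection is degenerate and 5 % of that value is
  returned with a warning.  Expected order statistics come from strain-label
  permutations: fully enumerated when C(n, n_A) ≤ `n_perm` (so 4+4 designs
  always enumerate all 70), otherwise `n_perm` seeded draws.  Probe *i* is
  called when `d_(i) − d̄_(i) ≤ −δ`; the per-rank rule makes call sets nest
  in δ by construction.
- **ANOVA**: pooled-variance two-group t per probe (F = t² for two groups,
  asserted in tests).  The default call rule thresholds the one-sided
  p-value `P(T ≤ t)`, which is exactly α-calibrated under the null; a
  two-sided F-test p-value with a direction constraint (which calls α/2
  under the null) is available as `sided="two"`.  Zero within-strain
  variance is guarded by the smallest positive float and flagged
  `degenerate`.
- **SNEP-style**: per-probe difference of strain means within a probe set
  (transcript) or a random pseudo-set of 500 probes (gDNA; remainder groups
  ≥ 50 kept, else merged); robust center = median, scale = MAD × 1.4826;
  call when the lower standard-normal tail of z is below α.  This is a
  deliberate surrogate for the original robust-estimator procedure, whose
  exact estimator and p-value construction are defined elsewhere; its
  thresholds are not claimed to match that method numerically.  The
  MAD-based scale is biased upward under ≳ 10 % contamination, so null tail
  calls run below nominal α — conservative, and bounded in the tests by a
  2× inflation band.  Zero robust scale (constant differences) skips the
  set with a warning.  Significance grid: 10⁻⁶ default; 10⁻¹⁰·⁰⁵,
  10⁻¹¹·²⁵, 10⁻¹⁸ provided.
- No multiple-testing correction anywhere: thresholds (δ, α) are tuned
  against ground truth by ROC, which is the point of the benchmark.

## Thermodynamics

Unified nearest-neighbor DNA parameters (10 Watson–Crick stacks expanded to
all 16 dinucleotides by complementary symmetry), duplex initiation terms by
terminal base (A·T: ΔH 2.3, ΔS 4.1; G·C: ΔH 0.1, ΔS −2.8), no salt
correction, evaluated at the 50 °C wash (323.15 K):
ΔG(T) = Σ(ΔH − T·ΔS/1000) + initiation.  Whether the emulated analysis
included initiation/terminal terms is unstated; including them shifts all
ΔG by a near-constant and does not affect the relative comparisons, and the
table ships as a versioned TSV that round-trips bit-exactly.  The stack
values are cross-checked in the tests against an independently maintained
published table.  Self-complementary symmetry corrections are omitted
(odd-length probes cannot be self-complementary).  The `ΔG > −26 kcal/mol`
filter keeps weak binders, whose mismatch signal is detectable.

## Evaluation

- `sensitivity = n_true / n_expected_sfp`;
  `fpr = n_false / n_called` — the false-discovery proportion used by the
  array-genotyping literature.  Because this differs from 1 − specificity,
  the conventional quantity is always emitted as `fpr_conventional`.
  Zero calls define fpr = 0.
- ROC curves are tabulated per threshold (strict to loose, nesting
  enforced).  The operating threshold is where the adjacent-point secant
  slope Δsens/Δfpr first reaches ≤ 1 from the strict end, returning the
  stricter endpoint; adjacent secants are used instead of smoothing because
  they are reproducible and bandwidth-free, at the cost of sensitivity to
  point-level noise on fine grids (use coarser threshold grids on small
  simulations).
- Window tracks: left-aligned 0-based half-open windows (1 Mb / 0.1 Mb
  step by default), trailing windows truncated to true width; window
  sensitivity is *missing* (not zero) where no SFP is predicted, so
  genome-wide averages are not deflated.
- False-positive clustering: per set with n eligible (non-SFP) probes, the
  expected number of sets with k false calls is Σ C(n,k)pᵏ(1−p)ⁿ⁻ᵏ at the
  per-probe false-call rate p (estimated from the data unless given); a
  chi-square over k-bins with expected mass ≥ 1 (tail merged) summarizes
  departure.  Independent calling noise matches this expectation;
  fragment-dropout simulations exceed it at k ≥ 2.

## Problem sizes

The shipped tests and acceptance checks run on simulations of 2,200–10,010
probes (200–910 probe sets of 11) over 100–450 kb genomes, with 20-seed
replication for calibration and qualitative claims — sizes at which every
statistical property asserted (binomial counts, α-calibration within
3 binomial SDs, ROC dominance) has adequate resolution while the whole
suite stays fast on a single CPU.

## Known limitations

- The alignment scan's exhaustiveness argument is specific to 25-mer
  probes with min_score 18; other probe lengths or thresholds would need a
  different seed-length bound.
- The within-set outlier caller is a median/MAD surrogate, not the original
  robust estimator; its absolute significance levels are approximate.
- Truth equivalence between variant footprints and sequence search assumes
  the generator's homopolymer-safe indels; arbitrary indel processes can
  create shifted perfect matches that decouple the two definitions.
- The intensity model is additive on the log scale with homoscedastic
  observation noise; real arrays show intensity-dependent variance that
  none of the callers here are tuned for.
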