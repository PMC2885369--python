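# sfpkit

Single-feature-polymorphism (SFP) detection on 25-mer PM/MM expression
arrays, end to end: probe annotation against two strain genomes, SFP calling
from raw probe intensities, binding-affinity analysis, and a full evaluation
suite — driven by a synthetic-data generator with planted ground truth, so
every stage is testable without array downloads.

## Who this is for

Affymetrix-style 3'-expression arrays carry probe sets of ~11 perfect-match
(PM) 25-mers per transcript, each paired with a mismatch (MM) partner that
differs at the central (13th) base.  When genomic DNA or transcript cRNA
from a *second* strain is hybridized, probes whose target carries a
nucleotide polymorphism lose intensity — a single feature polymorphism.
With two sequenced strains (the motivating case is a *japonica* × *indica*
rice pair), sequence-predicted SFPs give exact ground truth, making the
array a benchmarkable genotyping instrument.  `sfpkit` re-implements that
workflow for anyone studying SFP-calling methodology or planning
array-based genotyping in a mid-sized genome.

## What it computes

**Probe annotation.**  Probes are searched in both genomes with a local
aligner under BLASTN scoring (match +1, mismatch −3, gap open 5, gap
extend 2), keeping hits with score ≥ 18.  A complete match scores 25, an
inner single mismatch 21, a single base inserted in the target as low
as 18.  Probes with exactly one perfect hit in strain A are *unique*;
a unique probe with no perfect hit anywhere in strain B is a
sequence-predicted SFP (the evaluation truth).

**Callers** (on log₁₀ raw PM intensities, no background correction or
normalization, one-sided toward a strain-B deficit):

- **SAM** — moderated d-statistic `d_i = (x̄_B − x̄_A)/(s_i + s₀)` with the
  fudge factor s₀ chosen by the coefficient-of-variation recipe and
  permutation-based expected order statistics; probe *i* is called when
  `d_(i) − d̄_(i) ≤ −δ`.
- **ANOVA** — per-probe two-group test (the two-group F equals the squared
  pooled t); the default rule uses the one-sided strain-B-deficit p-value.
- **SNEP-style outlier calling** — per probe, `d_i = x̄_B − x̄_A`; within each
  probe set (or random pseudo-set of 500 probes for gDNA) a robust center
  (median) and scale (MAD × 1.4826) give `z_i`, called at a normal-tail
  significance level (10⁻⁶ by default).  Transcript mode first keeps sets
  whose median log₁₀ PM exceeds 2.5 in both strains.

**Affinity model.**  Nearest-neighbor duplex free energy ΔG at the 50 °C
wash temperature (unified parameter set, initiation and terminal A·T terms
included); the `ΔG > −26 kcal/mol` filter removes strong binders whose SFPs
are hard to see.

**Evaluation.**  Sensitivity = true calls / expected SFPs and FPR = false
calls / all calls (a false-discovery proportion; the conventional
1 − specificity is reported alongside), ROC curves with the slope-1 optimal
threshold, PM/MM intensity summaries, 1-Mb sliding-window genome tracks,
and a binomial clustering test for per-set false-positive excess.

## Worked example

```python
import numpy as np
import sfpkit as sk

params = sk.SimParams()                        # rice-like 4 SNPs/kb defaults
pair   = sk.generate_genome_pair(100_000, params, seed=1)
probes = sk.design_probe_sets(pair, n_sets=200, probes_per_set=11, seed=2)
m      = sk.simulate_intensities(probes, pair, "gdna", 5, params, seed=3)

logm  = sk.log_transform(m)                    # log10 raw PM, floor 1
calls = sk.sam_call(logm, delta=0.378, seed=4)
rep   = sk.evaluate_calls(calls, m.truth)
print(f"called: {rep.n_called}  true: {rep.n_true}  false: {rep.n_false}")
print(f"sensitivity: {100*rep.sensitivity:.2f}%   fpr: {100*rep.fpr:.2f}%")
```

prints

```
called: 87  true: 86  false: 1
sensitivity: 39.45%   fpr: 1.15%
```

Of the 218 sequence-predicted SFPs planted among 2,200 probes, SAM at
δ = 0.378 recovers 86 with a single false call: at the default noise level
(0.25 log₁₀ between replicates of raw, unnormalized arrays) roughly 40 % of
SFPs stand out from four replicates per strain, while strongly binding
probes stay bright over their mismatched target and are missed — the
false-negative mechanism the affinity filter addresses.

The same pipeline runs from the shell:

```sh
sfpkit run --out run1 --seed 5          # simulate → annotate → call → evaluate
sfpkit report --run-dir run1            # Table-style summaries, 1-based positions
```

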