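"""Synthetic genome pairs, probe designs, and array-intensity simulation.

This module generates the inputs the SFP pipeline consumes, with planted
ground truth, emulating a pair of fully sequenced strains interrogated by a
25-mer PM/MM expression array:

* a reference genome (strain A) and a diverged genome (strain B) derived from
  it by SNPs, short indels, and segmental duplications, at rice-like densities
  (~4 SNPs/kb in probe-target regions by default);
* probe sets of typically 11 PM/MM pairs concentrated in a ~400 bp span per
  gene, with the MM partner differing at the central (13th) base;
* log-scale probe intensities for genomic-DNA or transcript hybridizations:
  affinity- and amount-dependent signal, MM cross-hybridization, an intensity
  deficit for probes whose strain-B target is mismatched, per-gene expression
  in transcript mode, and replicate-level Gaussian noise, with an optional
  saturation ceiling and a cross-hybridization floor.

Everything is seeded and deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .affinity import delta_g, revcomp

__all__ = [
    "Variant",
    "GenomePair",
    "ExpressionMixture",
    "SimParams",
    "ProbeRecord",
    "IntensityMatrix",
    "generate_genome_pair",
    "design_probe_sets",
    "simulate_intensities",
    "probe_truth_from_variants",
    "expected_sfp_fraction",
]

PROBE_LEN = 25
MM_POSITION = 12  # 0-based index of the 13th base
_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class Variant:
    """One planted difference between strain A and strain B.

    ``pos`` is 0-based in strain-A coordinates. ``detail`` holds the alternate
    base (snp), inserted bases (insertion), deleted length (deletion), or
    ``src:len`` for a duplicated strain-A segment inserted at ``pos``.
    """

    pos: int
    type: str
    detail: str


@dataclass(frozen=True)
class GenomePair:
    seq_a: str
    seq_b: str
    variants: tuple[Variant, ...]
    name_a: str = "chrA"
    name_b: str = "chrB"


@dataclass(frozen=True)
class ExpressionMixture:
    """Two-component per-gene log10 expression law for one tissue.

    A fraction ``p_low`` of genes is drawn from the low component, the rest
    from the high component; with the default transcript baseline this places
    the low component below and the high component above the 2.5 median
    log10-intensity expression cutoff.
    """

    p_low: float = 0.4
    low_mean: float = 0.2
    low_sd: float = 0.3
    high_mean: float = 1.5
    high_sd: float = 0.4


@dataclass(frozen=True)
class SimParams:
    """Simulation parameters (log10-intensity scale unless noted).

    Rates are per bp (``duplication_rate`` per gene-sized kb block).  The
    intensity model for a PM probe is::

        signal = baseline + amount/expression term
                 + affinity_slope * (dG - mean dG)
                 + strain term (B only: minus a per-probe SFP effect draw)
        log10 I = softcap_floor(signal) + N(0, noise_sd)

    The soft cap at ``saturation_ceiling`` and the floor at
    ``crosshyb_floor`` act on the expected signal; replicate noise is
    observation noise added afterwards, so saturation attenuates
    between-strain contrast but not measurement scatter.  The MM partner
    follows the same model minus ``mm_penalty``.
    """

    snp_rate: float = 0.004
    indel_rate: float = 0.0004
    duplication_rate: float = 0.0
    baseline_log10: float = 2.5
    transcript_baseline_log10: float = 1.8
    affinity_slope: float = -0.05  # per kcal/mol; stronger binding -> brighter
    amount_effect: dict = field(
        default_factory=lambda: {1: -0.5, 5: 0.0, 40: 0.8}
    )
    saturation_ceiling: float | None = 3.5
    saturation_sharpness: float = 3.0
    sfp_effect_mean: float = 0.5
    sfp_effect_sd: float = 0.15
    affinity_dependent_sfp: bool = False
    mm_penalty: float = 1.0
    crosshyb_floor: float = 1.0
    noise_sd: float = 0.25
    expression_law: dict = field(
        default_factory=lambda: {
            "shoot": ExpressionMixture(p_low=0.45),
            "young_panicle": ExpressionMixture(p_low=0.40),
        }
    )
    fragment_dropout_rate: float = 0.0
    fragment_len_range: tuple[int, int] = (100, 250)
    reps_gdna: int = 4
    reps_rna: int = 5

    def __post_init__(self) -> None:
        for name in ("snp_rate", "indel_rate", "duplication_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name}={rate} outside [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.sfp_effect_mean <= 0:
            raise ValueError("sfp_effect_mean must be > 0 (SFP lowers intensity)")

    def with_(self, **kw) -> "SimParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class ProbeRecord:
    """One PM/MM probe pair; coordinates 0-based half-open on strain A."""

    probe_id: str
    set_id: str
    pm_sequence: str
    chrom: str
    start: int
    strand: str
    mm_sequence: str

    def __post_init__(self) -> None:
        if len(self.pm_sequence) != PROBE_LEN:
            raise ValueError(f"PM sequence must be {PROBE_LEN}-mer")
        diff = [
            i
            for i in range(PROBE_LEN)
            if self.pm_sequence[i] != self.mm_sequence[i]
        ]
        if diff != [MM_POSITION]:
            raise ValueError("MM must differ from PM exactly at the 13th base")


def make_mm(pm_sequence: str) -> str:
    """MM partner: complementary substitution at the central (13th) base."""
    mid = pm_sequence[MM_POSITION].translate(str.maketrans("ACGT", "TGCA"))
    return pm_sequence[:MM_POSITION] + mid + pm_sequence[MM_POSITION + 1 :]


# ---------------------------------------------------------------------------
# genome pair


def _apply_variants(seq_a: str, variants: list[Variant]) -> str:
    out: list[str] = []
    cur = 0
    for v in sorted(variants, key=lambda v: v.pos):
        out.append(seq_a[cur : v.pos])
        if v.type == "snp":
            out.append(v.detail)
            cur = v.pos + 1
        elif v.type == "insertion":
            out.append(v.detail)
            cur = v.pos
        elif v.type == "deletion":
            cur = v.pos + int(v.detail)
        elif v.type == "duplication":
            src, length = (int(x) for x in v.detail.split(":"))
            out.append(seq_a[src : src + length])
            cur = v.pos
        else:  # pragma: no cover - guarded upstream
            raise ValueError(f"unknown variant type {v.type!r}")
    out.append(seq_a[cur:])
    return "".join(out)


def generate_genome_pair(
    length: int, params: SimParams | None = None, seed: int = 0
) -> GenomePair:
    """Random strain-A sequence plus a strain-B derivative.

    SNP and indel sites are independent Bernoulli draws per bp at the
    configured rates (so per-type counts are binomial); duplications are drawn
    per kb block at ``duplication_rate`` and copy a 300-500 bp strain-A
    segment to a new strain-B location.  Colliding variants are dropped
    deterministically (later candidates yield to earlier ones).  Inserted
    bases are chosen to differ from both flanking bases so a single insertion
    cannot leave a probe target intact through homopolymer slippage.
    """
    if length < 1000:
        raise ValueError("genome length must be >= 1000 bp")
    params = params or SimParams()
    rng = np.random.default_rng(seed)
    seq_a = "".join(rng.choice(_BASES, size=length))

    candidates: list[Variant] = []
    snp_pos = np.flatnonzero(rng.random(length) < params.snp_rate)
    for p in snp_pos:
        ref = seq_a[p]
        alt = rng.choice([b for b in "ACGT" if b != ref])
        candidates.append(Variant(int(p), "snp", str(alt)))
    indel_pos = np.flatnonzero(rng.random(length) < params.indel_rate)
    for p in indel_pos:
        p = int(p)
        if p < 1 or p > length - 4:
            continue
        if rng.random() < 0.5:
            left, right = seq_a[p - 1], seq_a[p]
            choices = [b for b in "ACGT" if b not in (left, right)]
            candidates.append(Variant(p, "insertion", str(rng.choice(choices))))
        else:
            candidates.append(Variant(p, "deletion", str(int(rng.integers(1, 4)))))
    n_blocks = length // 1000
    if params.duplication_rate > 0:
        dup_blocks = np.flatnonzero(
            rng.random(n_blocks) < params.duplication_rate
        )
        for b in dup_blocks:
            dlen = int(rng.integers(300, 501))
            src = int(rng.integers(b * 1000, min((b + 1) * 1000, length - dlen)))
            ins = int(rng.integers(0, length))
            candidates.append(Variant(ins, "duplication", f"{src}:{dlen}"))

    # drop later candidates whose strain-A footprint collides with an
    # already-accepted one (order of acceptance: position, then draw order)
    accepted: list[Variant] = []
    occupied: set[int] = set()
    for v in sorted(candidates, key=lambda v: (v.pos, v.type)):
        span = int(v.detail) if v.type == "deletion" else 1
        footprint = range(v.pos - 1, v.pos + span + 1)
        if any(p in occupied for p in footprint):
            continue
        accepted.append(v)
        if v.type != "duplication":  # duplications do not edit the source
            occupied.update(footprint)
    seq_b = _apply_variants(seq_a, accepted)
    return GenomePair(seq_a, seq_b, tuple(accepted))


# ---------------------------------------------------------------------------
# probe design


def design_probe_sets(
    genome: GenomePair,
    n_sets: int,
    probes_per_set: int = 11,
    set_span: int = 400,
    seed: int = 0,
) -> list[ProbeRecord]:
    """Design ``n_sets`` probe sets of ``probes_per_set`` PM/MM pairs each.

    Mimics 3'-expression array design: each set's probes are confined to one
    ``set_span`` bp region (sets placed one per equal-width genome block so
    spans never overlap).  Probes may overlap inside a span.  All probes are
    taken from the forward strand of strain A.
    """
    if set_span < PROBE_LEN:
        raise ValueError("set_span shorter than probe length")
    length = len(genome.seq_a)
    block = length // n_sets
    if block < set_span:
        raise ValueError(
            f"genome too short for {n_sets} non-overlapping {set_span} bp spans"
        )
    rng = np.random.default_rng(seed)
    records: list[ProbeRecord] = []
    n_starts = set_span - PROBE_LEN + 1
    for si in range(n_sets):
        span_start = si * block + int(rng.integers(0, block - set_span + 1))
        if probes_per_set <= n_starts:
            offsets = rng.choice(n_starts, size=probes_per_set, replace=False)
        else:
            offsets = rng.integers(0, n_starts, size=probes_per_set)
        set_id = f"set{si:05d}"
        for pi, off in enumerate(sorted(int(o) for o in offsets)):
            start = span_start + off
            pm = genome.seq_a[start : start + PROBE_LEN]
            records.append(
                ProbeRecord(
                    probe_id=f"{set_id}_p{pi:02d}",
                    set_id=set_id,
                    pm_sequence=pm,
                    chrom=genome.name_a,
                    start=start,
                    strand="+",
                    mm_sequence=make_mm(pm),
                )
            )
    return records


def probe_truth_from_variants(
    probes: list[ProbeRecord], variants: tuple[Variant, ...]
) -> pd.Series:
    """Planted SFP truth: does a probe footprint overlap a breaking variant?

    SNPs anywhere in [start, start+25), insertions strictly inside, and
    deletions overlapping the footprint break the strain-B target;
    duplications do not (they add copies without editing the source locus).
    """
    truth = {}
    breaking = [v for v in variants if v.type != "duplication"]
    for pr in probes:
        lo, hi = pr.start, pr.start + PROBE_LEN
        hit = False
        for v in breaking:
            if v.type == "snp" and lo <= v.pos < hi:
                hit = True
            elif v.type == "insertion" and lo < v.pos < hi:
                hit = True
            elif v.type == "deletion":
                if v.pos < hi and v.pos + int(v.detail) > lo:
                    hit = True
            if hit:
                break
        truth[pr.probe_id] = hit
    return pd.Series(truth, name="sfp_truth")


def expected_sfp_fraction(snp_rate: float, probe_len: int = PROBE_LEN) -> float:
    """Expected SFP-carrying probes per probe at a given SNP density.

    The linear (rare-variant) expectation ``probe_len * snp_rate``: at the
    rice-like 4 SNPs/kb this is 0.1, i.e. one SFP probe in ten.
    """
    return probe_len * snp_rate


# ---------------------------------------------------------------------------
# intensities


@dataclass
class IntensityMatrix:
    """Raw probe x sample intensities with sample metadata and planted truth.

    ``values`` is indexed by (probe_id, probe_type in {PM, MM}); columns are
    sample ids.  ``samples`` is indexed by sample id with columns strain,
    mode, amount_or_tissue, replicate.  ``truth`` and ``sets`` are per-probe
    Series (planted SFP status, set membership).
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    truth: pd.Series
    sets: pd.Series

    def pm(self) -> pd.DataFrame:
        return self.values.xs("PM", level="probe_type")

    def mm(self) -> pd.DataFrame:
        return self.values.xs("MM", level="probe_type")


def _soft_cap(x: np.ndarray, ceiling: float, k: float) -> np.ndarray:
    """Smooth soft-min toward ``ceiling``: identity well below, asymptote at."""
    return x - np.logaddexp(0.0, k * (x - ceiling)) / k


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, np.sqrt(sigma2)


def simulate_intensities(
    probes: list[ProbeRecord],
    genome: GenomePair,
    mode: str,
    amount_or_tissue,
    params: SimParams | None = None,
    seed: int = 0,
) -> IntensityMatrix:
    """Simulate raw PM/MM intensities for both strains with replicates.

    ``mode`` is ``"gdna"`` (amount_or_tissue in {1, 5, 40} ug, replicate count
    ``reps_gdna``) or ``"transcript"`` (amount_or_tissue a tissue key of
    ``params.expression_law``, replicate count ``reps_rna``).  See
    :class:`SimParams` for the intensity model.  Strain B's SFP-truth probes
    lose a per-probe lognormal intensity effect; with
    ``params.affinity_dependent_sfp`` the loss shrinks for strongly binding
    probes (more negative dG), planting affinity-dependent false negatives.
    With ``params.fragment_dropout_rate`` > 0, random 100-250 bp amplification
    fragments drop out of strain B, suppressing every probe they cover and
    planting clustered false positives.
    """
    params = params or SimParams()
    if mode not in ("gdna", "transcript"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "gdna":
        if amount_or_tissue not in params.amount_effect:
            raise ValueError(
                f"unknown amount class {amount_or_tissue!r}; "
                f"known: {sorted(params.amount_effect)}"
            )
        reps = params.reps_gdna
        base_term = params.baseline_log10 + params.amount_effect[amount_or_tissue]
    else:
        if amount_or_tissue not in params.expression_law:
            raise ValueError(
                f"unknown tissue {amount_or_tissue!r}; "
                f"known: {sorted(params.expression_law)}"
            )
        reps = params.reps_rna
        base_term = params.transcript_baseline_log10

    rng = np.random.default_rng(seed)
    n = len(probes)
    probe_ids = [p.probe_id for p in probes]
    sets = pd.Series([p.set_id for p in probes], index=probe_ids, name="set_id")
    truth = probe_truth_from_variants(probes, genome.variants)

    dg = np.array([delta_g(p.pm_sequence) for p in probes])
    base = base_term + params.affinity_slope * (dg - dg.mean())

    if mode == "transcript":
        law: ExpressionMixture = params.expression_law[amount_or_tissue]
        set_ids = sets.unique()
        is_low = rng.random(len(set_ids)) < law.p_low
        expr = np.where(
            is_low,
            rng.normal(law.low_mean, law.low_sd, len(set_ids)),
            rng.normal(law.high_mean, law.high_sd, len(set_ids)),
        )
        expr_by_set = dict(zip(set_ids, expr))
        base = base + np.array([expr_by_set[s] for s in sets])

    # per-probe SFP effect for strain B
    mu, sigma = _lognormal_params(params.sfp_effect_mean, params.sfp_effect_sd)
    effect = rng.lognormal(mu, sigma, n)
    if params.affinity_dependent_sfp:
        lo, hi = dg.min(), dg.max()
        scale = (dg - lo) / (hi - lo) if hi > lo else np.ones(n)
        effect = effect * (0.1 + 0.9 * scale)
    strain_b_deficit = np.where(truth.to_numpy(), effect, 0.0)

    if params.fragment_dropout_rate > 0:
        frag_lo, frag_hi = params.fragment_len_range
        starts = np.array([p.start for p in probes])
        dropped = np.zeros(n, dtype=bool)
        pos = 0
        glen = len(genome.seq_a)
        while pos < glen:
            flen = int(rng.integers(frag_lo, frag_hi + 1))
            if rng.random() < params.fragment_dropout_rate:
                dropped |= (starts >= pos) & (starts < pos + flen)
            pos += flen
        drop_effect = rng.lognormal(mu, sigma, n)
        strain_b_deficit = strain_b_deficit + np.where(dropped, drop_effect, 0.0)

    sample_meta = []
    columns = []
    for strain in ("A", "B"):
        for rep in range(1, reps + 1):
            sid = f"{strain}_r{rep}"
            columns.append(sid)
            sample_meta.append(
                {
                    "sample_id": sid,
                    "strain": strain,
                    "mode": mode,
                    "amount_or_tissue": str(amount_or_tissue),
                    "replicate": rep,
                }
            )
    samples = pd.DataFrame(sample_meta).set_index("sample_id")

    n_samp = 2 * reps
    strain_is_b = np.array([m["strain"] == "B" for m in sample_meta])
    pm_signal = base[:, None] - np.outer(strain_b_deficit, strain_is_b)
    mm_signal = pm_signal - params.mm_penalty
    if params.saturation_ceiling is not None:
        pm_signal = _soft_cap(
            pm_signal, params.saturation_ceiling, params.saturation_sharpness
        )
        mm_signal = _soft_cap(
            mm_signal, params.saturation_ceiling, params.saturation_sharpness
        )
    pm_signal = np.maximum(pm_signal, params.crosshyb_floor)
    mm_signal = np.maximum(mm_signal, params.crosshyb_floor)
    pm_log = pm_signal + rng.normal(0.0, params.noise_sd, (n, n_samp))
    mm_log = mm_signal + rng.normal(0.0, params.noise_sd, (n, n_samp))

    index = pd.MultiIndex.from_product(
        [probe_ids, ["PM", "MM"]], names=["probe_id", "probe_type"]
    )
    data = np.empty((2 * n, n_samp))
    data[0::2] = 10.0 ** pm_log
    data[1::2] = 10.0 ** mm_log
    values = pd.DataFrame(data, index=index, columns=columns)
    return IntensityMatrix(values=values, samples=samples, truth=truth, sets=sets)
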