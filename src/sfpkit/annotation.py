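"""Probe uniqueness classification and sequence-predicted SFP truth.

Each 25-mer PM probe is searched against both strain genomes with a local
aligner using BLASTN-style scoring (match +1, mismatch -3, gap open 5, gap
extend 2), keeping hits scoring >= 18.  A complete match scores 25; a single
inner mismatch 21 (24..22 when the mismatch sits in the distal three bases
and the aligner trims it); a single base inserted in the target scores
24..18.  Probes with exactly one perfect (score-25) hit in strain A are
"unique" and eligible for SFP calling; a unique probe with no perfect hit
anywhere in strain B is a sequence-predicted SFP (the ground truth used for
evaluation).

The genome scan is exhaustive at the scales this package targets: every hit
scoring >= 18 against a 25-mer must contain an exact match run of >= 11 bp,
so an 11-mer seed index of the genome followed by local alignment of the
seeded windows finds all of them.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import pandas as pd
from Bio import Align

from .affinity import revcomp
from .synthetic import PROBE_LEN, GenomePair, ProbeRecord

__all__ = [
    "AlignmentHit",
    "ProbeAnnotation",
    "GenomeIndex",
    "score_alignment",
    "find_hits",
    "classify_probes",
    "predict_sfp_truth",
    "annotate_probes",
    "select_transcript_sets",
    "annotation_summary",
]

MIN_SCORE = 18
SEED_LEN = 11  # any >=18-scoring hit of a 25-mer has an exact run >= 11 bp


@dataclass(frozen=True)
class AlignmentHit:
    chrom: str
    start: int  # 0-based, forward-strand coordinates
    strand: str
    score: int
    aligned_span: int


@dataclass
class ProbeAnnotation:
    probe_id: str
    set_id: str
    class_a: str  # unique | multi_hit | no_perfect_match
    hits_a: int  # perfect (score-25) hits in genome A
    hits_b: int | None = None  # perfect hits in genome B (unique probes only)
    best_score_b: int | None = None
    sfp_truth: bool | None = None  # defined only for unique probes


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    # BLASTN costs: gap of length L costs 5 + 2L, i.e. first gap base -7.
    return Align.PairwiseAligner(
        mode="local",
        match_score=1,
        mismatch_score=-3,
        open_gap_score=-7,
        extend_gap_score=-2,
    )


def score_alignment(probe: str, target: str) -> int:
    """Best local alignment score of a 25-mer probe against a target window."""
    if len(probe) != PROBE_LEN:
        raise ValueError(f"probe must be {PROBE_LEN}-mer, got {len(probe)}")
    if not target:
        return 0
    return int(_aligner().score(target, probe))


class GenomeIndex:
    """Seed index of one or more chromosomes for exhaustive probe search."""

    def __init__(self, genome: dict[str, str] | str, name: str = "chr1"):
        if isinstance(genome, str):
            genome = {name: genome}
        if not genome or all(len(s) == 0 for s in genome.values()):
            raise ValueError("empty genome")
        self.seqs = {c: s.upper() for c, s in genome.items()}
        self._seeds: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in self.seqs.items():
            for i in range(len(seq) - SEED_LEN + 1):
                self._seeds.setdefault(seq[i : i + SEED_LEN], []).append(
                    (chrom, i)
                )

    def seed_positions(self, kmer: str) -> list[tuple[str, int]]:
        return self._seeds.get(kmer, [])

    @classmethod
    def from_pair(cls, genome: GenomePair, which: str) -> "GenomeIndex":
        if which == "a":
            return cls(genome.seq_a, genome.name_a)
        return cls(genome.seq_b, genome.name_b)


def find_hits(
    probe: str,
    genome: dict[str, str] | str | GenomeIndex,
    min_score: int = MIN_SCORE,
    pad: int = 4,
) -> list[AlignmentHit]:
    """All alignment hits of ``probe`` scoring >= ``min_score``, both strands.

    Complete for min_score >= 18 (seed argument in the module docstring).
    Candidate loci are seeded by exact 11-mers, padded by ``pad`` bp, merged,
    and rescored with the local aligner; overlapping candidates collapse to
    the best-scoring locus.
    """
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome)
    hits: dict[tuple[str, int, str], AlignmentHit] = {}
    for strand, oriented in (("+", probe), ("-", revcomp(probe))):
        # exact full-length matches first: guarantees every perfect hit is
        # reported individually even when copies share a seeded window
        for chrom, seq in index.seqs.items():
            at = seq.find(oriented)
            while at != -1:
                hits[(chrom, at, strand)] = AlignmentHit(
                    chrom, at, strand, PROBE_LEN, PROBE_LEN
                )
                at = seq.find(oriented, at + 1)
        # candidate windows per chromosome
        windows: dict[str, list[tuple[int, int]]] = {}
        for off in range(PROBE_LEN - SEED_LEN + 1):
            for chrom, pos in index.seed_positions(oriented[off : off + SEED_LEN]):
                lo = max(0, pos - off - pad)
                hi = min(len(index.seqs[chrom]), pos - off + PROBE_LEN + pad)
                windows.setdefault(chrom, []).append((lo, hi))
        for chrom, ivals in windows.items():
            ivals.sort()
            merged: list[list[int]] = []
            for lo, hi in ivals:
                if merged and lo <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], hi)
                else:
                    merged.append([lo, hi])
            seq = index.seqs[chrom]
            for lo, hi in merged:
                window = seq[lo:hi]
                score = int(_aligner().score(window, oriented))
                if score < min_score:
                    continue
                aln = next(iter(_aligner().align(window, oriented)))
                t_start = int(aln.coordinates[0][0])
                t_end = int(aln.coordinates[0][-1])
                key = (chrom, lo + t_start, strand)
                prev = hits.get(key)
                if prev is None or score > prev.score:
                    hits[key] = AlignmentHit(
                        chrom=chrom,
                        start=lo + t_start,
                        strand=strand,
                        score=score,
                        aligned_span=t_end - t_start,
                    )
    return sorted(hits.values(), key=lambda h: (h.chrom, h.start, h.strand))


def classify_probes(
    probes: list[ProbeRecord],
    genome_a: dict[str, str] | str | GenomeIndex,
) -> list[ProbeAnnotation]:
    """Populate ``class_a``: unique / multi_hit / no_perfect_match in strain A."""
    index = (
        genome_a if isinstance(genome_a, GenomeIndex) else GenomeIndex(genome_a)
    )
    out = []
    for pr in probes:
        perfect = sum(
            1 for h in find_hits(pr.pm_sequence, index) if h.score == PROBE_LEN
        )
        if perfect == 1:
            cls = "unique"
        elif perfect >= 2:
            cls = "multi_hit"
        else:
            cls = "no_perfect_match"
        out.append(
            ProbeAnnotation(
                probe_id=pr.probe_id,
                set_id=pr.set_id,
                class_a=cls,
                hits_a=perfect,
            )
        )
    return out


def predict_sfp_truth(
    annotations: list[ProbeAnnotation],
    probes: list[ProbeRecord],
    genome_b: dict[str, str] | str | GenomeIndex,
) -> list[ProbeAnnotation]:
    """Fill ``sfp_truth`` for unique probes: no perfect full-length hit in B.

    The search is genome-wide, not orthology-restricted; probes with multiple
    perfect strain-B hits are retained (duplicated targets are not SFPs).
    """
    index = (
        genome_b if isinstance(genome_b, GenomeIndex) else GenomeIndex(genome_b)
    )
    by_id = {pr.probe_id: pr for pr in probes}
    for ann in annotations:
        if ann.class_a != "unique":
            continue
        hits = find_hits(by_id[ann.probe_id].pm_sequence, index)
        ann.hits_b = sum(1 for h in hits if h.score == PROBE_LEN)
        ann.best_score_b = max((h.score for h in hits), default=0)
        ann.sfp_truth = ann.hits_b == 0
    return annotations


def annotate_probes(
    probes: list[ProbeRecord], genome: GenomePair
) -> pd.DataFrame:
    """Full annotation against both strains, as a probe-indexed frame."""
    anns = classify_probes(probes, GenomeIndex.from_pair(genome, "a"))
    anns = predict_sfp_truth(anns, probes, GenomeIndex.from_pair(genome, "b"))
    df = pd.DataFrame([vars(a) for a in anns]).set_index("probe_id")
    return df


def select_transcript_sets(
    annotations: pd.DataFrame | list[ProbeAnnotation], min_unique: int = 7
) -> list[str]:
    """Sets with at least ``min_unique`` unique probes (default "more than six").

    Within-set outlier calling needs several clean probes per set; sets with
    six or fewer unique probes are excluded from transcript-mode analysis.
    """
    if not isinstance(annotations, pd.DataFrame):
        annotations = pd.DataFrame([vars(a) for a in annotations])
    counts = (
        annotations[annotations["class_a"] == "unique"]
        .groupby("set_id")
        .size()
    )
    return sorted(counts.index[counts >= min_unique])


def annotation_summary(
    annotations: pd.DataFrame, min_unique: int = 7
) -> pd.DataFrame:
    """Probe/probe-set level class counts, mirroring a BLAST-summary table."""
    n_probes = len(annotations)
    n_sets = annotations["set_id"].nunique()
    uniq = annotations[annotations["class_a"] == "unique"]
    sel = select_transcript_sets(annotations, min_unique)
    sel_mask = uniq["set_id"].isin(sel)
    rows = [
        ("total", n_probes, n_sets),
        (
            "no_perfect_match",
            int((annotations["class_a"] == "no_perfect_match").sum()),
            None,
        ),
        ("multi_hit", int((annotations["class_a"] == "multi_hit").sum()), None),
        ("unique", len(uniq), int(uniq["set_id"].nunique())),
        (
            "sfp_in_unique",
            int(uniq["sfp_truth"].fillna(False).sum()),
            int(uniq.loc[uniq["sfp_truth"].fillna(False), "set_id"].nunique()),
        ),
        (f"sets_ge_{min_unique}_unique", int(sel_mask.sum()), len(sel)),
        (
            "sfp_in_selected_sets",
            int(uniq.loc[sel_mask, "sfp_truth"].fillna(False).sum()),
            int(
                uniq.loc[
                    sel_mask & uniq["sfp_truth"].fillna(False), "set_id"
                ].nunique()
            ),
        ),
    ]
    return pd.DataFrame(rows, columns=["category", "probes", "probe_sets"])
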