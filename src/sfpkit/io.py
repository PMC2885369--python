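"""File formats and run configuration.

Everything is plain text: FASTA for genomes, header-bearing TSV for probes,
variants, intensities (with a sample-metadata sidecar), annotations, calls
and reports.  Coordinates in machine-readable files are 0-based half-open;
human-readable summaries use 1-based positions and say so.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .synthetic import IntensityMatrix, ProbeRecord, Variant, make_mm

__all__ = [
    "RunConfig",
    "read_fasta",
    "write_fasta",
    "write_probes",
    "read_probes",
    "write_variants",
    "read_variants",
    "write_intensities",
    "read_intensities",
    "write_table",
    "read_table",
]

_VALID_BASES = set("ACGTN")

PROBE_COLUMNS = [
    "probe_id",
    "set_id",
    "chrom",
    "start",
    "strand",
    "pm_sequence",
    "mm_sequence",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Named, uppercased sequences; rejects non-ACGTN characters."""
    seqs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        bad = set(seq) - _VALID_BASES
        if bad:
            raise ValueError(
                f"record {record.id!r}: invalid characters {sorted(bad)}"
            )
        seqs[record.id] = seq
    if not seqs:
        warnings.warn(f"no FASTA records in {path}", stacklevel=2)
    return seqs


def write_fasta(path: str | Path, seqs: dict[str, str]) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what}: missing mandatory column(s) {missing}")


def write_probes(path: str | Path, probes: list[ProbeRecord]) -> None:
    df = pd.DataFrame([vars(p) for p in probes])[PROBE_COLUMNS]
    df.to_csv(path, sep="\t", index=False)


def read_probes(path: str | Path) -> list[ProbeRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"start": int})
    _require_columns(df, PROBE_COLUMNS, "probe table")
    return [
        ProbeRecord(
            probe_id=row.probe_id,
            set_id=row.set_id,
            pm_sequence=row.pm_sequence,
            chrom=row.chrom,
            start=int(row.start),
            strand=row.strand,
            mm_sequence=row.mm_sequence
            if isinstance(row.mm_sequence, str)
            else make_mm(row.pm_sequence),
        )
        for row in df.itertuples()
    ]


def write_variants(path: str | Path, variants, chrom: str = "chrA") -> None:
    df = pd.DataFrame(
        [(chrom, v.pos, v.type, v.detail) for v in variants],
        columns=["chrom", "pos", "type", "detail"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_variants(path: str | Path) -> tuple[Variant, ...]:
    df = pd.read_csv(path, sep="\t", dtype={"detail": str})
    _require_columns(df, ["pos", "type", "detail"], "variant table")
    return tuple(
        Variant(int(r.pos), r.type, str(r.detail)) for r in df.itertuples()
    )


def write_intensities(
    values_path: str | Path, samples_path: str | Path, matrix: IntensityMatrix
) -> None:
    out = matrix.values.reset_index()
    out.to_csv(values_path, sep="\t", index=False)
    matrix.samples.reset_index().to_csv(samples_path, sep="\t", index=False)


def read_intensities(
    values_path: str | Path,
    samples_path: str | Path,
    truth: pd.Series | None = None,
) -> IntensityMatrix:
    values = pd.read_csv(values_path, sep="\t")
    _require_columns(values, ["probe_id", "probe_type"], "intensity table")
    values = values.set_index(["probe_id", "probe_type"])
    samples = pd.read_csv(samples_path, sep="\t")
    _require_columns(
        samples, ["sample_id", "strain", "replicate"], "sample metadata"
    )
    samples = samples.set_index("sample_id")
    unknown = set(values.columns) - set(samples.index)
    if unknown:
        raise ValueError(
            f"intensity samples absent from metadata: {sorted(unknown)}"
        )
    probe_ids = values.index.get_level_values("probe_id").unique()
    if truth is None:
        truth = pd.Series(False, index=probe_ids, name="sfp_truth")
    sets = pd.Series(
        [pid.rsplit("_", 1)[0] for pid in probe_ids], index=probe_ids, name="set_id"
    )
    return IntensityMatrix(
        values=values, samples=samples, truth=truth, sets=sets
    )


def write_table(path: str | Path, df: pd.DataFrame, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_table(path: str | Path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


@dataclass
class RunConfig:
    """Resolved configuration for one pipeline run.

    Written (with the seed) next to every run's outputs so the run can be
    reproduced bit-identically.
    """

    out_dir: str = "sfpkit_run"
    seed: int = 0
    mode: str = "gdna"
    amount_or_tissue: str = "5"
    caller: str = "sam"
    threshold: float = 0.378
    genome_length: int = 200_000
    n_sets: int = 500
    probes_per_set: int = 11
    group_size: int = 500
    n_perm: int = 1000
    expression_cutoff: float = 2.5
    min_unique: int = 7
    sim_overrides: dict = field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(vars(self), fh, sort_keys=True)
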