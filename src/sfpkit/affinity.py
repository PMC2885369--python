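"""Nearest-neighbor duplex thermodynamics for 25-mer probes.

Binding stability ``delta_g`` of a probe hybridized to its exact complement is
computed from the unified nearest-neighbor parameter set (SantaLucia 1998):
per-stack enthalpy/entropy terms plus duplex-initiation terms that depend on
the identity of the terminal base pairs.  The free energy is evaluated at the
array wash temperature (50 degC = 323.15 K) by default; more negative values
mean stronger binding.  No salt correction is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "NN_STACKS",
    "NN_INITIATION",
    "WASH_TEMPERATURE_K",
    "AffinityRecord",
    "delta_g",
    "affinity_filter",
    "affinity_histogram",
    "write_nn_table",
    "read_nn_table",
]

WASH_TEMPERATURE_K = 323.15  # 50 degC

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T string."""
    return seq.translate(_COMPLEMENT)[::-1]


# Unified nearest-neighbor parameters: dH in kcal/mol, dS in cal/(mol K).
# Ten unique Watson-Crick stacks; the remaining six dinucleotides are filled
# in below by complementary-stack symmetry (value(XY) == value(revcomp(XY))).
_UNIQUE_STACKS: dict[str, tuple[float, float]] = {
    "AA": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7),
    "GT": (-8.4, -22.4),
    "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}

NN_STACKS: dict[str, tuple[float, float]] = {}
for _stack, _hs in _UNIQUE_STACKS.items():
    NN_STACKS[_stack] = _hs
    NN_STACKS.setdefault(revcomp(_stack), _hs)

# Duplex initiation, keyed by the terminal base on the probe strand.
NN_INITIATION: dict[str, tuple[float, float]] = {
    "G": (0.1, -2.8),
    "C": (0.1, -2.8),
    "A": (2.3, 4.1),
    "T": (2.3, 4.1),
}


@dataclass(frozen=True)
class AffinityRecord:
    """Binding free energy of one probe at the wash temperature."""

    probe_id: str
    delta_g: float


def delta_g(sequence: str, temperature: float = WASH_TEMPERATURE_K) -> float:
    """Duplex free energy (kcal/mol) of ``sequence`` with its exact complement.

    Parameters
    ----------
    sequence
        Probe sequence over {A, C, G, T}, length >= 2.
    temperature
        Absolute temperature in kelvin; default is the 50 degC wash.

    Returns
    -------
    float
        ``sum_stacks (dH - T*dS) + initiation`` with dS converted from
        cal/(mol K) to kcal/(mol K).
    """
    seq = sequence.upper()
    if len(seq) < 2:
        raise ValueError(f"need at least 2 bases, got {len(seq)}")
    if set(seq) - set("ACGT"):
        bad = sorted(set(seq) - set("ACGT"))
        raise ValueError(f"ambiguous or invalid bases {bad} in sequence")
    dh = 0.0
    ds = 0.0
    for i in range(len(seq) - 1):
        h, s = NN_STACKS[seq[i : i + 2]]
        dh += h
        ds += s
    for terminal in (seq[0], seq[-1]):
        h, s = NN_INITIATION[terminal]
        dh += h
        ds += s
    return dh - temperature * ds / 1000.0


def affinity_filter(records: pd.Series, threshold: float = -26.0) -> list[str]:
    """Probe ids whose delta_g is strictly above ``threshold`` (weak binders).

    ``records`` maps probe_id -> delta_g (kcal/mol).  Probes binding more
    strongly than the threshold (delta_g <= threshold) are removed: strong
    binders stay bright even over a mismatched target, hiding the SFP signal.
    """
    records = pd.Series(records)
    return list(records.index[records > threshold])


def affinity_histogram(
    records: pd.Series,
    groups: dict[str, list[str]],
    binwidth: float = 0.5,
) -> pd.DataFrame:
    """Per-group normalized delta_g histograms on a shared bin grid.

    Bin edges are multiples of ``binwidth``; each group's frequencies sum to 1
    (empty groups yield an all-zero track with a warning).  Returns a frame
    indexed by bin left edge with one column per group.
    """
    records = pd.Series(records, dtype=float)
    if records.empty:
        raise ValueError("no affinity records")
    lo = np.floor(records.min() / binwidth) * binwidth
    hi = np.ceil(records.max() / binwidth) * binwidth + binwidth
    edges = np.arange(lo, hi + binwidth / 2, binwidth)
    out = {}
    for name, ids in groups.items():
        vals = records.reindex(ids).dropna().to_numpy()
        counts, _ = np.histogram(vals, bins=edges)
        if counts.sum() == 0:
            warnings.warn(f"affinity group {name!r} is empty", stacklevel=2)
            out[name] = np.zeros(len(edges) - 1)
        else:
            out[name] = counts / counts.sum()
    return pd.DataFrame(out, index=pd.Index(edges[:-1], name="bin_start"))


def write_nn_table(path: str | Path) -> None:
    """Write the stack/initiation parameter table as TSV (stack, dH, dS)."""
    rows = [("stack:" + k, h, s) for k, (h, s) in sorted(NN_STACKS.items())]
    rows += [("init:" + k, h, s) for k, (h, s) in sorted(NN_INITIATION.items())]
    df = pd.DataFrame(
        [(term, repr(h), repr(s)) for term, h, s in rows],
        columns=["term", "dH_kcal_mol", "dS_cal_mol_K"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_nn_table(path: str | Path) -> tuple[dict, dict]:
    """Read a parameter table written by :func:`write_nn_table`.

    Returns (stacks, initiation) dicts; values round-trip bit-exactly.
    """
    df = pd.read_csv(path, sep="\t")
    stacks: dict[str, tuple[float, float]] = {}
    init: dict[str, tuple[float, float]] = {}
    for _, row in df.iterrows():
        kind, key = row["term"].split(":")
        target = stacks if kind == "stack" else init
        target[key] = (float(row["dH_kcal_mol"]), float(row["dS_cal_mol_K"]))
    return stacks, init
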