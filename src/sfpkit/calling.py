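"""SFP callers on log10 PM intensities: SAM, per-probe ANOVA, and a robust
within-set outlier caller (SNEP-style), plus the gDNA random-grouping variant
and the transcript expression filter.

All callers work on log10-transformed raw PM values with no background
correction or normalization, and by default call one-sided: an SFP mismatches
the strain-B target, so the informative direction is a strain-B intensity
deficit.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import IntensityMatrix

__all__ = [
    "LogIntensityMatrix",
    "CallSet",
    "log_transform",
    "sam_statistic",
    "choose_s0",
    "sam_call",
    "anova_call",
    "group_random",
    "snep_call",
    "expression_filter",
    "pm_mm_pair_test",
    "strain_difference",
]

SIGNIFICANCE_GRID = (1e-6, 10 ** -10.05, 10 ** -11.25, 1e-18)


@dataclass
class LogIntensityMatrix:
    """Probes x samples log10 raw PM intensities with sample metadata."""

    values: pd.DataFrame  # index probe_id, columns sample_id
    samples: pd.DataFrame  # index sample_id; has a 'strain' column

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples missing from metadata: {sorted(missing)}")

    def strain_columns(self, strain: str) -> list[str]:
        cols = [
            c for c in self.values.columns if self.samples.loc[c, "strain"] == strain
        ]
        if not cols:
            raise ValueError(f"no samples for strain {strain!r}")
        return cols


@dataclass
class CallSet:
    """Per-probe calls from one caller at one threshold.

    ``table`` is indexed by probe_id with columns ``statistic`` (d for SAM,
    one-sided p for ANOVA and the outlier caller), ``called`` and
    ``direction`` ('loss' = strain-B deficit, 'gain', 'none').
    """

    caller: str
    threshold: float
    table: pd.DataFrame

    @property
    def called(self) -> pd.Series:
        return self.table["called"]


def log_transform(raw: IntensityMatrix, floor: float = 1.0) -> LogIntensityMatrix:
    """log10 of raw PM intensities, floored at ``floor`` raw units."""
    pm = raw.pm()
    if (pm.to_numpy() < 0).any():
        raise ValueError("negative raw intensities")
    return LogIntensityMatrix(
        values=np.log10(pm.clip(lower=floor)), samples=raw.samples
    )


def _group_arrays(matrix: LogIntensityMatrix) -> tuple[np.ndarray, np.ndarray]:
    xa = matrix.values[matrix.strain_columns("A")].to_numpy()
    xb = matrix.values[matrix.strain_columns("B")].to_numpy()
    if xa.shape[1] < 2 or xb.shape[1] < 2:
        raise ValueError("need >= 2 replicates per strain")
    return xa, xb


def _diff_and_se(xa: np.ndarray, xb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Between-strain mean difference (B - A) and its pooled standard error."""
    na, nb = xa.shape[1], xb.shape[1]
    r = xb.mean(axis=1) - xa.mean(axis=1)
    ss = ((xa - xa.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (xb - xb.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s = np.sqrt((1.0 / na + 1.0 / nb) * ss / (na + nb - 2))
    return r, s


def strain_difference(matrix: LogIntensityMatrix) -> pd.Series:
    """Per-probe mean log10 PM difference, strain B minus strain A."""
    xa, xb = _group_arrays(matrix)
    return pd.Series(
        xb.mean(axis=1) - xa.mean(axis=1), index=matrix.values.index, name="d"
    )


# ---------------------------------------------------------------------------
# SAM


def choose_s0(
    r: np.ndarray,
    s: np.ndarray,
    degenerate_fraction: float = 0.05,
    n_windows: int = 100,
) -> float:
    """SAM fudge factor: the percentile of s stabilizing the spread of d.

    Candidates are the 0th..100th percentiles of ``s`` in steps of 5; for each
    the probes are split into ``n_windows`` s-quantile windows and the
    coefficient of variation of the windowed median-absolute-deviation of
    ``d = r/(s + s0)`` is computed; the candidate minimizing it wins.
    Deterministic given the input.
    """
    r = np.asarray(r, dtype=float)
    s = np.asarray(s, dtype=float)
    if len(s) < 100:
        raise ValueError("need >= 100 probes to select s0")
    if np.allclose(s, s[0]):
        warnings.warn(
            "all per-probe scales equal; s0 selection degenerate", stacklevel=2
        )
        return float(s[0]) * degenerate_fraction
    order = np.argsort(s, kind="stable")
    windows = np.array_split(order, n_windows)
    candidates = np.percentile(s, np.arange(0, 101, 5))
    best, best_cv = candidates[0], np.inf
    for s0 in candidates:
        d = r / (s + s0)
        mads = np.array(
            [
                np.median(np.abs(d[w] - np.median(d[w])))
                for w in windows
                if len(w)
            ]
        )
        mean = mads.mean()
        if mean == 0:
            continue
        cv = mads.std() / mean
        if cv < best_cv:
            best, best_cv = s0, cv
    return float(best)


def sam_statistic(matrix: LogIntensityMatrix, s0: float | None = None) -> pd.Series:
    """Two-class unpaired SAM d-statistic, d = (mean_B - mean_A)/(s + s0)."""
    xa, xb = _group_arrays(matrix)
    r, s = _diff_and_se(xa, xb)
    if s0 is None:
        s0 = choose_s0(r, s)
    return pd.Series(r / (s + s0), index=matrix.values.index, name="d")


def _permutation_expected_order(
    matrix: LogIntensityMatrix, s0: float, n_perm: int, seed: int
) -> np.ndarray:
    """Mean of sorted permuted d over strain-label permutations."""
    x = matrix.values[
        matrix.strain_columns("A") + matrix.strain_columns("B")
    ].to_numpy()
    na = len(matrix.strain_columns("A"))
    n = x.shape[1]
    all_assignments = math.comb(n, na)
    if all_assignments < 2:
        raise ValueError("fewer than 2 distinct label permutations")
    if all_assignments <= n_perm:
        combos = list(itertools.combinations(range(n), na))
    else:
        rng = np.random.default_rng(seed)
        combos = [
            tuple(sorted(rng.choice(n, size=na, replace=False)))
            for _ in range(n_perm)
        ]
    acc = np.zeros(x.shape[0])
    for combo in combos:
        ia = np.array(combo)
        ib = np.setdiff1d(np.arange(n), ia)
        r, s = _diff_and_se(x[:, ia], x[:, ib])
        acc += np.sort(r / (s + s0))
    return acc / len(combos)


def sam_call(
    matrix: LogIntensityMatrix,
    delta: float,
    n_perm: int = 1000,
    seed: int = 0,
    s0: float | None = None,
    sided: str = "lower",
) -> CallSet:
    """SAM calls at threshold ``delta``.

    Observed order statistics d_(i) are compared with their expectation under
    strain-label permutations (full enumeration when the number of distinct
    assignments is <= ``n_perm``, else that many seeded random assignments);
    probe i is called when d_(i) - dbar_(i) <= -delta (``sided='lower'``, the
    strain-B-deficit side), with the symmetric rule added for
    ``sided='two'``.  Calls nest in delta by construction.
    """
    xa, xb = _group_arrays(matrix)
    r, s = _diff_and_se(xa, xb)
    if s0 is None:
        s0 = choose_s0(r, s)
    d = r / (s + s0)
    order = np.argsort(d, kind="stable")
    dbar_sorted = _permutation_expected_order(matrix, s0, n_perm, seed)
    exceed = np.empty_like(d)
    exceed[order] = d[order] - dbar_sorted  # per-probe d_(i) - dbar_(i)
    called = exceed <= -delta
    if sided == "two":
        called |= exceed >= delta
    elif sided != "lower":
        raise ValueError(f"unknown sidedness {sided!r}")
    direction = np.where(d < 0, "loss", np.where(d > 0, "gain", "none"))
    table = pd.DataFrame(
        {
            "statistic": d,
            "exceedance": exceed,
            "called": called,
            "direction": direction,
        },
        index=matrix.values.index,
    )
    return CallSet(caller="sam", threshold=delta, table=table)


# ---------------------------------------------------------------------------
# ANOVA


def _pooled_t(xa: np.ndarray, xb: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Pooled-variance t (B vs A) with zero-variance guard; returns t, r, df."""
    na, nb = xa.shape[1], xb.shape[1]
    r, s = _diff_and_se(xa, xb)
    tiny = np.finfo(float).tiny
    t = r / np.maximum(s, tiny)
    return t, s, na + nb - 2


def anova_call(
    matrix: LogIntensityMatrix, alpha: float, sided: str = "lower"
) -> CallSet:
    """Per-probe two-group test on log10 PM intensities.

    The two-group one-way ANOVA F equals the squared pooled t; the default
    one-sided rule calls a probe when the strain-B-deficit p-value
    ``P(T <= t)`` is below ``alpha``, which is alpha-calibrated under the
    null.  ``sided='two'`` uses the F-test p-value and additionally requires
    a strain-B deficit.  Probes with zero within-strain variance are flagged
    ``degenerate`` (their p collapses to 0 or 1).
    """
    xa, xb = _group_arrays(matrix)
    t, s, df = _pooled_t(xa, xb)
    degenerate = s == 0
    if sided == "lower":
        p = stats.t.cdf(t, df)
        called = p < alpha
    elif sided == "two":
        p = 2 * stats.t.sf(np.abs(t), df)
        called = (p < alpha) & (t < 0)
    else:
        raise ValueError(f"unknown sidedness {sided!r}")
    direction = np.where(t < 0, "loss", np.where(t > 0, "gain", "none"))
    table = pd.DataFrame(
        {
            "statistic": p,
            "t": t,
            "called": called,
            "direction": direction,
            "degenerate": degenerate,
        },
        index=matrix.values.index,
    )
    return CallSet(caller="anova", threshold=alpha, table=table)


def pm_mm_pair_test(pm_log: pd.DataFrame, mm_log: pd.DataFrame) -> pd.Series:
    """Two-sided two-group p-value PM vs MM replicate log10 intensities."""
    if not pm_log.index.equals(mm_log.index):
        raise ValueError("PM and MM rows are not paired")
    if pm_log.shape[1] < 2 or mm_log.shape[1] < 2:
        raise ValueError("need >= 2 replicates")
    t, s, df = _pooled_t(mm_log.to_numpy(), pm_log.to_numpy())
    p = 2 * stats.t.sf(np.abs(t), df)
    return pd.Series(p, index=pm_log.index, name="p")


# ---------------------------------------------------------------------------
# SNEP-style robust outlier calling


def group_random(
    probe_ids: list[str], group_size: int = 500, seed: int = 0
) -> pd.Series:
    """Random partition of probes into pseudo-sets of ``group_size``.

    gDNA hybridization has no meaningful transcript sets, so probes are
    randomly grouped (default 500 per group) before within-set outlier
    calling.  A remainder group of >= 50 probes is kept on its own, otherwise
    merged into the last full group.  Seeded and deterministic.
    """
    probe_ids = list(probe_ids)
    n = len(probe_ids)
    if n < group_size:
        warnings.warn(
            f"{n} probes < group size {group_size}; using a single group",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    labels = np.empty(n, dtype=object)
    n_full = max(n // group_size, 1)
    remainder = n - n_full * group_size
    for g in range(n_full):
        labels[perm[g * group_size : (g + 1) * group_size]] = f"group{g:04d}"
    if remainder > 0:
        tail = perm[n_full * group_size :]
        if remainder >= 50:
            labels[tail] = f"group{n_full:04d}"
        else:
            labels[tail] = f"group{n_full - 1:04d}"
    return pd.Series(labels, index=probe_ids, name="group")


def snep_call(
    matrix: LogIntensityMatrix,
    sets: pd.Series,
    alpha: float,
    min_set_size: int = 2,
) -> CallSet:
    """Robust within-set outlier calls on between-strain differences.

    Per probe, d = mean log10 PM(B) - mean log10 PM(A); within each set (or
    gDNA pseudo-set from :func:`group_random`) the center m (median) and
    scale s (MAD x 1.4826) of {d} are estimated and z = (d - m)/s formed.  A
    probe is called when the lower normal tail probability of z is below
    ``alpha`` — an approximation to the original robust-estimator procedure,
    adequate because clean probes dominate each set.  Sets with zero robust
    scale are skipped with a warning.
    """
    d = strain_difference(matrix)
    sets = sets.reindex(d.index)
    if sets.isna().any():
        raise ValueError("set assignment missing for some probes")
    p = pd.Series(np.nan, index=d.index)
    for set_id, idx in d.groupby(sets).groups.items():
        dv = d.loc[idx]
        if len(dv) < min_set_size:
            warnings.warn(f"set {set_id!r} too small; skipped", stacklevel=2)
            continue
        m = dv.median()
        scale = 1.4826 * (dv - m).abs().median()
        if scale == 0:
            warnings.warn(
                f"set {set_id!r} has zero robust scale; skipped", stacklevel=2
            )
            continue
        p.loc[idx] = stats.norm.cdf((dv - m) / scale)
    called = p < alpha
    direction = np.where(d < 0, "loss", np.where(d > 0, "gain", "none"))
    table = pd.DataFrame(
        {"statistic": p, "d": d, "called": called, "direction": direction},
        index=d.index,
    )
    return CallSet(caller="snep", threshold=alpha, table=table)


def expression_filter(
    matrix: LogIntensityMatrix, sets: pd.Series, cutoff: float = 2.5
) -> list[str]:
    """Sets whose median log10 PM exceeds ``cutoff`` in both strains.

    PM-vs-MM separation degrades at low expression, so transcript-mode SFP
    calling is restricted to sets expressed above the cutoff in both strains.
    """
    sets = sets.reindex(matrix.values.index)
    kept = []
    for set_id, idx in matrix.values.groupby(sets).groups.items():
        ok = True
        for strain in ("A", "B"):
            med = (
                matrix.values.loc[idx, matrix.strain_columns(strain)]
                .to_numpy()
                .flatten()
            )
            if np.median(med) <= cutoff:
                ok = False
                break
        if ok:
            kept.append(set_id)
    return sorted(kept)
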