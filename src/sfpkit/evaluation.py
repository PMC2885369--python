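"""Evaluation of SFP call sets against sequence-predicted truth.

Follows the array-genotyping convention for both headline metrics:
sensitivity = correctly called SFPs / expected (sequence-predicted) SFPs, and
FPR = falsely called SFPs / all called SFPs — a false-discovery proportion,
not 1 - specificity.  The conventional 1 - specificity is also reported,
labeled ``fpr_conventional``, to prevent misuse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .calling import CallSet

__all__ = [
    "EvalReport",
    "RocCurve",
    "evaluate_calls",
    "roc_curve",
    "optimal_threshold",
    "intensity_summary",
    "pm_mm_significance_by_bin",
    "window_track",
    "fp_cluster_test",
]


@dataclass(frozen=True)
class EvalReport:
    """Confusion counts and the two headline ratios for one call set."""

    n_expected_sfp: int
    n_called: int
    n_true: int
    n_false: int
    n_universe: int | None = None

    def __post_init__(self) -> None:
        if self.n_true + self.n_false != self.n_called:
            raise ValueError("n_true + n_false must equal n_called")

    @property
    def sensitivity(self) -> float:
        return self.n_true / self.n_expected_sfp if self.n_expected_sfp else 0.0

    @property
    def fpr(self) -> float:
        """False-call proportion: falsely called / total called (0 if none)."""
        return self.n_false / self.n_called if self.n_called else 0.0

    @property
    def fpr_conventional(self) -> float | None:
        """1 - specificity: false calls / non-SFP probes (needs the universe)."""
        if self.n_universe is None:
            return None
        n_neg = self.n_universe - self.n_expected_sfp
        return self.n_false / n_neg if n_neg else 0.0

    @classmethod
    def from_counts(
        cls, n_expected_sfp: int, n_called: int, n_true: int, n_universe=None
    ) -> "EvalReport":
        return cls(
            n_expected_sfp=n_expected_sfp,
            n_called=n_called,
            n_true=n_true,
            n_false=n_called - n_true,
            n_universe=n_universe,
        )


@dataclass
class RocCurve:
    """Ordered (threshold, sensitivity, fpr) points, strict to loose."""

    points: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        sens = self.points["sensitivity"].to_numpy()
        if np.any(np.diff(sens) < -1e-12):
            raise ValueError("sensitivity must be non-decreasing strict-to-loose")


def _as_called(calls) -> pd.Series:
    if isinstance(calls, CallSet):
        return calls.called
    return pd.Series(calls).astype(bool)


def evaluate_calls(calls, truth: pd.Series) -> EvalReport:
    """Score one call set against per-probe truth over the same universe."""
    called = _as_called(calls)
    truth = pd.Series(truth).astype(bool)
    if set(called.index) != set(truth.index):
        raise ValueError("calls and truth cover different probe universes")
    truth = truth.reindex(called.index)
    n_called = int(called.sum())
    n_true = int((called & truth).sum())
    return EvalReport(
        n_expected_sfp=int(truth.sum()),
        n_called=n_called,
        n_true=n_true,
        n_false=n_called - n_true,
        n_universe=len(truth),
    )


def roc_curve(
    statistic: pd.Series,
    truth: pd.Series,
    thresholds,
    direction: str = "le",
) -> RocCurve:
    """One evaluation per threshold on a per-probe statistic.

    ``direction='le'`` calls probes with statistic <= threshold (p-values,
    negative exceedances); ``'ge'`` the reverse.  ``thresholds`` must be
    ordered strict to loose so the induced call sets nest.
    """
    statistic = pd.Series(statistic)
    rows = []
    prev_called = None
    for thr in thresholds:
        if direction == "le":
            called = statistic <= thr
        elif direction == "ge":
            called = statistic >= thr
        else:
            raise ValueError(f"unknown direction {direction!r}")
        if prev_called is not None and (prev_called & ~called).any():
            raise ValueError("thresholds do not yield nested call sets")
        prev_called = called
        rep = evaluate_calls(called, truth)
        rows.append(
            {
                "threshold": thr,
                "sensitivity": rep.sensitivity,
                "fpr": rep.fpr,
                "n_called": rep.n_called,
                "n_true": rep.n_true,
                "n_false": rep.n_false,
            }
        )
    return RocCurve(points=pd.DataFrame(rows))


def optimal_threshold(roc: RocCurve) -> float:
    """Threshold where the ROC secant slope first crosses 1 from the strict end.

    Adjacent-point secants Δsensitivity/Δfpr are scanned strict to loose; the
    stricter endpoint of the first secant with slope <= 1 is returned (beyond
    that point each extra false call buys less than one extra true call).
    Falls back to the loosest threshold with a warning if the slope never
    crosses 1.
    """
    pts = roc.points
    if len(pts) < 3:
        raise ValueError("need >= 3 ROC points")
    sens = pts["sensitivity"].to_numpy()
    fpr = pts["fpr"].to_numpy()
    thr = pts["threshold"].to_numpy()
    for i in range(len(pts) - 1):
        dfpr = fpr[i + 1] - fpr[i]
        dsens = sens[i + 1] - sens[i]
        slope = np.inf if dfpr == 0 else dsens / dfpr
        if slope <= 1.0:
            return float(thr[i])
    warnings.warn("ROC slope never crossed 1; returning loosest threshold")
    return float(thr[-1])


def intensity_summary(
    pm_log: pd.Series, mm_log: pd.Series, binwidth: float = 0.1, step: float = 0.05
) -> tuple[pd.DataFrame, float]:
    """Overlapping-window intensity histograms for PM and MM, plus P(PM > MM).

    ``pm_log``/``mm_log`` are per-probe mean log10 intensities over the
    replicates of interest, paired on probe_id.  Windows of ``binwidth`` are
    tiled with ``step`` (each value falls in binwidth/step windows away from
    the range edges).  Returns (frame indexed by window start with pm_count /
    mm_count columns, fraction of pairs with PM > MM).
    """
    pm_log, mm_log = pd.Series(pm_log), pd.Series(mm_log)
    if not pm_log.index.equals(mm_log.index):
        raise ValueError("PM and MM probes are not paired")
    allv = np.concatenate([pm_log.to_numpy(), mm_log.to_numpy()])
    lo = np.floor(allv.min() / step) * step - (binwidth - step)
    starts = np.arange(lo, allv.max() + step / 2, step)
    rows = []
    pm = pm_log.to_numpy()
    mm = mm_log.to_numpy()
    for s in starts:
        rows.append(
            {
                "bin_start": s,
                "pm_count": int(((pm >= s) & (pm < s + binwidth)).sum()),
                "mm_count": int(((mm >= s) & (mm < s + binwidth)).sum()),
            }
        )
    frac = float((pm > mm).mean())
    return pd.DataFrame(rows).set_index("bin_start"), frac


def pm_mm_significance_by_bin(
    pvalues: pd.Series,
    mean_pm_log: pd.Series,
    binwidth: float = 0.1,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fraction of PM/MM pairs significantly different, per intensity bin.

    Supports choosing an expression cutoff for transcript-mode calling: the
    significant fraction rises with expression.  Empty bins are missing.
    """
    pvalues = pd.Series(pvalues)
    mean_pm_log = pd.Series(mean_pm_log).reindex(pvalues.index)
    bins = np.floor(mean_pm_log / binwidth) * binwidth
    rows = []
    for b, idx in pvalues.groupby(bins.round(9)).groups.items():
        pv = pvalues.loc[idx]
        rows.append(
            {
                "bin_start": float(b),
                "n_pairs": len(pv),
                "frac_significant": float((pv < alpha).mean()),
            }
        )
    return pd.DataFrame(rows).sort_values("bin_start").set_index("bin_start")


def window_track(
    positions: pd.DataFrame,
    truth: pd.Series,
    calls,
    window: int = 1_000_000,
    step: int = 100_000,
    chrom_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Sliding-window genome track of probe, SFP and call counts.

    ``positions`` has columns chrom / start (0-based) indexed by probe_id.
    Windows are left-aligned, 0-based half-open, length ``window`` stepping by
    ``step``; the trailing window is truncated to the chromosome end.  Window
    sensitivity is missing where no SFP is predicted.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    called = _as_called(calls).reindex(positions.index).fillna(False)
    truth = pd.Series(truth).astype(bool).reindex(positions.index)
    rows = []
    for chrom, sub in positions.groupby("chrom"):
        size = (
            chrom_sizes[chrom]
            if chrom_sizes
            else int(sub["start"].max()) + 25
        )
        starts = sub["start"].to_numpy()
        t = truth.loc[sub.index].to_numpy()
        c = called.loc[sub.index].to_numpy()
        for w0 in range(0, max(size - 1, 1), step):
            w1 = min(w0 + window, size)
            inw = (starts >= w0) & (starts < w1)
            n_probe = int(inw.sum())
            n_sfp = int((inw & t).sum())
            n_true_call = int((inw & t & c).sum())
            n_false_call = int((inw & ~t & c).sum())
            rows.append(
                {
                    "chrom": chrom,
                    "start": w0,
                    "end": w1,
                    "n_probes": n_probe,
                    "n_predicted_sfp": n_sfp,
                    "n_true_calls": n_true_call,
                    "n_false_calls": n_false_call,
                    "sensitivity": (n_true_call / n_sfp) if n_sfp else np.nan,
                }
            )
            if w1 >= size:
                break
    return pd.DataFrame(rows)


def fp_cluster_test(
    calls,
    truth: pd.Series,
    sets: pd.Series,
    p: float | None = None,
) -> pd.DataFrame:
    """Observed vs binomial-expected counts of sets with k false positives.

    Amplification polymorphisms suppress every probe on a 100-250 bp fragment
    and probe sets span only a few hundred bp, so clustered (super-binomial)
    false positives betray fragment-level artifacts rather than independent
    calling noise.  For each set, the number of eligible (non-SFP) probes
    n_set and its false-call count k are tallied; the expected number of sets
    with k false calls is sum_sets C(n_set, k) p^k (1-p)^(n_set-k) at the
    per-probe false-call probability ``p`` (estimated from the data when not
    given).  The result frame (indexed by k) carries observed and expected
    columns plus a chi-square attribute ``.attrs['chisq']`` over k-bins with
    expected mass >= 1 (tail merged).
    """
    called = _as_called(calls)
    truth = pd.Series(truth).astype(bool).reindex(called.index)
    sets = pd.Series(sets).reindex(called.index)
    eligible = ~truth
    false_call = called & eligible
    n_set = eligible.groupby(sets).sum()
    k_set = false_call.groupby(sets).sum()
    if p is None:
        p = float(false_call.sum() / eligible.sum())
    if not 0.0 < p < 1.0:
        raise ValueError(f"false-call probability p={p} outside (0, 1)")
    kmax = int(n_set.max())
    ks = np.arange(kmax + 1)
    expected = np.zeros(kmax + 1)
    for n in n_set.to_numpy():
        expected[: n + 1] += stats.binom.pmf(ks[: n + 1], n, p)
    observed = (
        k_set.value_counts().reindex(ks, fill_value=0).sort_index().to_numpy()
    )
    out = pd.DataFrame(
        {"observed": observed, "expected": expected},
        index=pd.Index(ks, name="k"),
    )
    # chi-square over bins with expected >= 1, tail merged
    cut = np.flatnonzero(expected >= 1.0)
    if len(cut) >= 2:
        last = cut[-1]
        obs = np.append(observed[:last], observed[last:].sum())
        exp = np.append(expected[:last], expected[last:].sum())
        keep = exp > 0
        out.attrs["chisq"] = float(((obs[keep] - exp[keep]) ** 2 / exp[keep]).sum())
        out.attrs["dof"] = int(keep.sum() - 1)
    return out
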