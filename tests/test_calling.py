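"""SAM, ANOVA and robust within-set outlier callers."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import sfpkit as sk
from sfpkit.calling import (
    LogIntensityMatrix,
    anova_call,
    choose_s0,
    expression_filter,
    group_random,
    log_transform,
    pm_mm_pair_test,
    sam_call,
    sam_statistic,
    snep_call,
)


def _matrix(values: np.ndarray, reps=4, probe_ids=None) -> LogIntensityMatrix:
    """Log matrix from an array with A replicates first, B replicates last."""
    n, m = values.shape
    cols = [f"A_r{i+1}" for i in range(reps)] + [
        f"B_r{i+1}" for i in range(m - reps)
    ]
    samples = pd.DataFrame(
        {
            "strain": ["A"] * reps + ["B"] * (m - reps),
            "replicate": list(range(1, reps + 1)) + list(range(1, m - reps + 1)),
        },
        index=pd.Index(cols, name="sample_id"),
    )
    idx = probe_ids if probe_ids is not None else [f"p{i}" for i in range(n)]
    return LogIntensityMatrix(
        values=pd.DataFrame(values, index=idx, columns=cols), samples=samples
    )


def _null_matrix(n_probes, seed, reps=4, sd=0.05):
    rng = np.random.default_rng(seed)
    return _matrix(2.5 + rng.normal(0, sd, (n_probes, 2 * reps)), reps=reps)


class TestLogTransform:
    def test_values_and_floor(self, gdna_matrix):
        logm = log_transform(gdna_matrix)
        assert np.allclose(
            logm.values.to_numpy(),
            np.log10(np.maximum(gdna_matrix.pm().to_numpy(), 1.0)),
        )

    def test_examples(self):
        import sfpkit.synthetic as syn

        values = pd.DataFrame(
            [[1000.0, 0.0, 10.0**1.7, 5.0]],
            index=pd.MultiIndex.from_tuples(
                [("p0", "PM")], names=["probe_id", "probe_type"]
            ),
            columns=["A_r1", "A_r2", "B_r1", "B_r2"],
        )
        samples = pd.DataFrame(
            {"strain": ["A", "A", "B", "B"], "replicate": [1, 2, 1, 2]},
            index=pd.Index(values.columns, name="sample_id"),
        )
        raw = syn.IntensityMatrix(
            values=values,
            samples=samples,
            truth=pd.Series({"p0": False}),
            sets=pd.Series({"p0": "s"}),
        )
        out = log_transform(raw).values.to_numpy()[0]
        assert out[0] == pytest.approx(3.0)
        assert out[1] == pytest.approx(0.0)  # floored at 1 raw unit
        assert out[2] == pytest.approx(1.7)

    def test_negative_rejected(self, gdna_matrix):
        bad = sk.IntensityMatrix(
            values=gdna_matrix.values * -1,
            samples=gdna_matrix.samples,
            truth=gdna_matrix.truth,
            sets=gdna_matrix.sets,
        )
        with pytest.raises(ValueError):
            log_transform(bad)


class TestSamStatistic:
    def test_identical_strains_give_zero_d(self):
        rng = np.random.default_rng(0)
        half = 2.5 + rng.normal(0, 0.1, (50, 4))
        m = _matrix(np.hstack([half, half]))
        d = sam_statistic(m, s0=0.1)
        assert np.allclose(d, 0.0)

    def test_label_swap_negates_d(self):
        rng = np.random.default_rng(1)
        x = 2.5 + rng.normal(0, 0.1, (50, 8))
        d1 = sam_statistic(_matrix(x), s0=0.05)
        d2 = sam_statistic(_matrix(x[:, [4, 5, 6, 7, 0, 1, 2, 3]]), s0=0.05)
        assert np.allclose(d1, -d2)

    def test_scale_equivariance(self):
        """Scaling intensities by a constant leaves d invariant when s0 scales."""
        rng = np.random.default_rng(2)
        x = 2.5 + rng.normal(0, 0.1, (200, 8))
        d1 = sam_statistic(_matrix(x), s0=0.05)
        d2 = sam_statistic(_matrix(10 * x), s0=0.5)
        assert np.allclose(d1, d2)


class TestChooseS0:
    def test_degenerate_equal_scales(self):
        rng = np.random.default_rng(3)
        r = rng.normal(0, 1, 200)
        s = np.full(200, 0.07)
        with pytest.warns(UserWarning, match="degenerate"):
            s0 = choose_s0(r, s)
        assert s0 == pytest.approx(0.07 * 0.05)

    def test_homoscedastic_null_close_to_median_choice(self):
        """On homoscedastic nulls the chosen s0 behaves like the median-s choice."""
        disagree = []
        for seed in range(20):
            m = _null_matrix(2000, seed)
            xa = m.values[m.strain_columns("A")].to_numpy()
            xb = m.values[m.strain_columns("B")].to_numpy()
            from sfpkit.calling import _diff_and_se

            r, s = _diff_and_se(xa, xb)
            d_auto = r / (s + choose_s0(r, s))
            d_med = r / (s + np.median(s))
            # compare the tails each statistic flags at a fixed quantile
            thr_auto = np.quantile(d_auto, 0.01)
            thr_med = np.quantile(d_med, 0.01)
            disagree.append(
                np.mean((d_auto <= thr_auto) != (d_med <= thr_med))
            )
        assert np.mean(disagree) < 0.01


class TestSamCall:
    def test_infinite_delta_calls_nothing(self):
        calls = sam_call(_null_matrix(300, 4), delta=np.inf, seed=0)
        assert calls.called.sum() == 0

    def test_threshold_nesting(self):
        m = _null_matrix(500, 5)
        loose = sam_call(m, delta=0.0, seed=0)
        strict = sam_call(m, delta=0.378, seed=0)
        assert (strict.called & ~loose.called).sum() == 0
        assert loose.called.sum() >= strict.called.sum()

    def test_full_enumeration_equals_capped_sampling(self):
        """With 4+4 samples every permutation is enumerated whenever
        n_perm >= C(8,4); results must be identical."""
        m = _null_matrix(400, 6)
        a = sam_call(m, delta=0.378, n_perm=70, seed=1)
        b = sam_call(m, delta=0.378, n_perm=10**6, seed=999)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_planted_probe_outranks_null(self):
        rng = np.random.default_rng(7)
        x = 2.5 + rng.normal(0, 0.05, (1000, 8))
        x[0, 4:] -= 0.5  # strain-B deficit on one probe
        m = _matrix(x)
        d = sam_statistic(m)
        assert d.idxmin() == "p0"
        calls = sam_call(m, delta=1.0, seed=0)
        assert bool(calls.called.iloc[0])

    def test_null_false_call_fraction_stable_across_seeds(self):
        fracs = []
        for seed in range(6):
            m = _null_matrix(3000, 100 + seed)
            calls = sam_call(m, delta=0.378, seed=0)
            fracs.append(calls.called.mean())
        p = np.mean(fracs)
        sd = np.sqrt(max(p * (1 - p), 1e-9) / 3000)
        for f in fracs:
            assert abs(f - p) < 3 * sd + 1e-3


class TestAnova:
    def test_identical_groups_not_called(self):
        x = np.tile(np.linspace(2, 3, 20)[:, None], (1, 8))
        calls = anova_call(_matrix(x), alpha=0.05)
        assert calls.called.sum() == 0

    def test_f_equals_t_squared(self):
        rng = np.random.default_rng(8)
        x = 2.5 + rng.normal(0, 0.1, (100, 8))
        m = _matrix(x)
        calls = anova_call(m, alpha=0.05, sided="two")
        f_ref = np.array(
            [stats.f_oneway(row[:4], row[4:]).statistic for row in x]
        )
        assert np.allclose(calls.table["t"].to_numpy() ** 2, f_ref)

    def test_planted_deficit_is_significant(self):
        rng = np.random.default_rng(9)
        x = 2.5 + rng.normal(0, 0.05, (50, 8))
        x[0, 4:] -= 0.5
        calls = anova_call(_matrix(x), alpha=1e-4)
        assert calls.table["statistic"].iloc[0] < 1e-4
        assert bool(calls.called.iloc[0])

    def test_alpha_nesting(self):
        m = _null_matrix(500, 10)
        loose = anova_call(m, alpha=0.10)
        strict = anova_call(m, alpha=0.01)
        assert (strict.called & ~loose.called).sum() == 0


class TestGroupRandom:
    def test_exact_partition(self):
        groups = group_random([f"p{i}" for i in range(1000)], seed=0)
        assert groups.value_counts().tolist() == [500, 500]

    def test_small_remainder_merged(self):
        groups = group_random([f"p{i}" for i in range(1001)], seed=0)
        assert sorted(groups.value_counts().tolist()) == [500, 501]

    def test_large_remainder_kept(self):
        groups = group_random([f"p{i}" for i in range(1060)], seed=0)
        assert sorted(groups.value_counts().tolist()) == [60, 500, 500]

    def test_deterministic(self):
        ids = [f"p{i}" for i in range(750)]
        assert group_random(ids, seed=5).equals(group_random(ids, seed=5))

    def test_single_group_warning(self):
        with pytest.warns(UserWarning, match="single group"):
            groups = group_random([f"p{i}" for i in range(100)], seed=0)
        assert groups.nunique() == 1


class TestSnep:
    def test_constant_differences_never_called(self):
        x = np.hstack([np.full((20, 4), 2.5), np.full((20, 4), 2.3)])
        m = _matrix(x)
        sets = pd.Series("s0", index=m.values.index)
        with pytest.warns(UserWarning, match="zero robust scale"):
            calls = snep_call(m, sets, alpha=0.4)
        assert calls.called.sum() == 0

    def test_location_equivariance(self):
        rng = np.random.default_rng(11)
        x = 2.5 + rng.normal(0, 0.05, (40, 8))
        m1 = _matrix(x.copy())
        x2 = x.copy()
        x2[:, 4:] += 0.3  # shift every strain-B value in the set
        m2 = _matrix(x2)
        sets = pd.Series("s0", index=m1.values.index)
        c1 = snep_call(m1, sets, alpha=1e-3)
        c2 = snep_call(m2, sets, alpha=1e-3)
        assert c1.called.equals(c2.called)

    def test_ten_sigma_outlier_called_alone(self):
        rng = np.random.default_rng(12)
        x = 2.5 + rng.normal(0, 0.05, (40, 8))
        m0 = _matrix(x.copy())
        sets = pd.Series("s0", index=m0.values.index)
        d0 = sk.strain_difference(m0)
        scale = 1.4826 * (d0 - d0.median()).abs().median()
        x[0, 4:] -= 10 * scale
        calls = snep_call(_matrix(x), sets, alpha=1e-6)
        assert bool(calls.called.iloc[0])
        assert calls.called.sum() == 1

    def test_null_tail_calls_bounded(self):
        """On clean nulls the robust caller's call rate stays within a 2x
        inflation bound of alpha (MAD scale bias is conservative)."""
        alpha = 0.01
        total = 0
        for seed in range(5):
            m = _null_matrix(3000, 40 + seed)
            groups = group_random(list(m.values.index), group_size=500, seed=seed)
            total += snep_call(m, groups, alpha=alpha).called.sum()
        assert total <= 2 * alpha * 5 * 3000 + 3 * np.sqrt(alpha * 5 * 3000)

    def test_alpha_nesting_with_pseudo_groups(self):
        m = _null_matrix(1500, 13)
        groups = group_random(list(m.values.index), group_size=500, seed=3)
        loose = snep_call(m, groups, alpha=1e-2)
        strict = snep_call(m, groups, alpha=1e-4)
        assert (strict.called & ~loose.called).sum() == 0


class TestExpressionFilter:
    def _matrix_with_medians(self, med_a, med_b):
        vals = np.hstack([np.full((8, 4), med_a), np.full((8, 4), med_b)])
        m = _matrix(vals)
        return m, pd.Series("s0", index=m.values.index)

    def test_kept_when_both_above(self):
        m, sets = self._matrix_with_medians(2.6, 2.6)
        assert expression_filter(m, sets) == ["s0"]

    def test_removed_when_one_below(self):
        m, sets = self._matrix_with_medians(2.6, 2.4)
        assert expression_filter(m, sets) == []

    def test_zero_cutoff_keeps_all(self):
        m, sets = self._matrix_with_medians(1.0, 1.2)
        assert expression_filter(m, sets, cutoff=0.0) == ["s0"]


class TestPmMmPairTest:
    def test_identical_pm_mm_not_significant(self):
        rng = np.random.default_rng(14)
        pm = pd.DataFrame(2.5 + rng.normal(0, 0.05, (30, 4)))
        p = pm_mm_pair_test(pm, pm.copy())
        assert (p > 0.99).all()

    def test_unit_log_gap_highly_significant(self):
        rng = np.random.default_rng(15)
        pm = pd.DataFrame(3.0 + rng.normal(0, 0.05, (30, 4)))
        mm = pm - 1.0 + rng.normal(0, 0.05, (30, 4))
        assert (pm_mm_pair_test(pm, mm) < 1e-4).all()

    def test_replicate_order_exchangeable(self):
        rng = np.random.default_rng(16)
        pm = pd.DataFrame(3.0 + rng.normal(0, 0.1, (20, 5)))
        mm = pd.DataFrame(2.2 + rng.normal(0, 0.1, (20, 5)))
        p1 = pm_mm_pair_test(pm, mm)
        p2 = pm_mm_pair_test(
            pm[[4, 2, 0, 1, 3]].set_axis(range(5), axis=1), mm
        )
        assert np.allclose(p1, p2)
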