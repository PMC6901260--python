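"""Normalization, exponential fitting, model selection, comparison, FDR."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from txnkinetics import (
    ConfigurationError,
    DataError,
    FitError,
    KineticParams,
    RawFrapTrace,
    RecoveryCurve,
    compare_curves,
    fdr_adjust,
    fit_recovery,
    fit_retention_time,
    get_schedule,
    normalize_frap,
    select_model,
    simulate_frap,
)
from txnkinetics.curves import AcquisitionSchedule

from conftest import biexp_curve


class TestNormalize:
    def test_four_frame_worked_example(self):
        """(roi-bg)/(whole-bg) = (0.5, 0.5, 0.1, 0.3); pre mean 0.5 -> (1, 1, 0.2, 0.6)."""
        tr = RawFrapTrace(
            times=[0.0, 1.0, 2.0, 3.0],
            roi=[10.0, 10.0, 2.0, 6.0],
            whole=[20.0, 20.0, 20.0, 20.0],
            background=[0.0, 0.0, 0.0, 0.0],
            n_prebleach=2,
        )
        curve = normalize_frap(tr)
        assert np.allclose(curve.mean, [1.0, 1.0, 0.2, 0.6])
        assert np.allclose(curve.times, [-2.0, -1.0, 0.0, 1.0])  # re-zeroed

    def test_constant_trace_normalizes_to_one(self):
        tr = RawFrapTrace(
            times=np.arange(6.0), roi=np.full(6, 30.0), whole=np.full(6, 30.0),
            background=np.zeros(6), n_prebleach=2,
        )
        assert np.allclose(normalize_frap(tr).mean, 1.0)

    def test_acquisition_bleaching_fully_cancelled(self):
        decay = 0.97 ** np.arange(8)
        tr = RawFrapTrace(
            times=np.arange(8.0), roi=50.0 * decay, whole=200.0 * decay,
            background=np.zeros(8), n_prebleach=3,
        )
        assert np.allclose(normalize_frap(tr).mean, 1.0)

    def test_prebleach_mean_exactly_one(self):
        rng = np.random.default_rng(0)
        tr = RawFrapTrace(
            times=np.arange(20.0), roi=100 + rng.random(20) * 50,
            whole=400 + rng.random(20) * 50, background=np.full(20, 10.0),
            n_prebleach=6,
        )
        curve = normalize_frap(tr)
        assert curve.mean[:6].mean() == pytest.approx(1.0, abs=1e-12)

    def test_nonpositive_whole_names_frame(self):
        tr = RawFrapTrace(
            times=np.arange(4.0), roi=[5.0, 5, 5, 5], whole=[10.0, 10, 3, 10],
            background=np.full(4, 3.0), n_prebleach=1,
        )
        with pytest.raises(DataError, match="frame 2"):
            normalize_frap(tr)

    def test_all_prebleach_rejected(self):
        with pytest.raises(DataError, match="post-bleach"):
            RawFrapTrace(
                times=np.arange(3.0), roi=np.ones(3), whole=np.ones(3),
                background=np.zeros(3), n_prebleach=3,
            )


class TestFitRecovery:
    def test_noiseless_monoexponential_recovered_exactly(self):
        sched = get_schedule("mrna-frap")
        curve = biexp_curve(sched, y0=0.1, amplitudes=(0.8,), rates=(0.05,))
        fit = fit_recovery(curve, 1)
        assert fit.y0 == pytest.approx(0.1, rel=1e-6)
        assert fit.amplitudes[0] == pytest.approx(0.8, rel=1e-6)
        assert fit.rates[0] == pytest.approx(0.05, rel=1e-6)
        assert fit.sse <= 1e-12

    def test_noiseless_biexponential_recovered_exactly(self):
        sched = get_schedule("mrna-frap")
        curve = biexp_curve(sched)
        fit = fit_recovery(curve, 2)
        assert fit.rates == pytest.approx((0.5, 0.02), rel=1e-5)
        assert fit.amplitudes == pytest.approx((0.45, 0.35), rel=1e-5)
        assert fit.fractions[0] == pytest.approx(0.45 / 0.8, rel=1e-5)

    def test_constant_curve_all_immobile(self):
        sched = get_schedule("mrna-frap")
        t = sched.postbleach_times()
        times = np.concatenate([sched.prebleach_times(), t])
        y = np.concatenate([np.ones(6), np.full(len(t), 0.4)])
        curve = RecoveryCurve(times, y, np.zeros_like(times), 1, sched, 6)
        fit = fit_recovery(curve, 1)
        assert sum(fit.amplitudes) == pytest.approx(0.0, abs=1e-6)
        assert fit.immobile_fraction == pytest.approx(0.6, abs=1e-3)

    def test_too_few_frames_raises(self):
        sched = AcquisitionSchedule(n_prebleach=2, segments=((8.0, 1.0),))
        curve = biexp_curve(sched)
        with pytest.raises(FitError, match="post-bleach frames"):
            fit_recovery(curve, 2)

    def test_rates_sorted_fast_first(self):
        curve = biexp_curve(get_schedule("mrna-frap"))
        fit = fit_recovery(curve, 2)
        assert fit.rates[0] > fit.rates[1]


class TestSelectModel:
    def test_biexponential_truth_selects_two(self):
        curve = biexp_curve(get_schedule("mrna-frap"), noise_sd=0.02, seed=3)
        fit = select_model(curve)
        assert fit.n_components == 2
        assert fit.aic_alternatives[2] < fit.aic_alternatives[1] - 2

    def test_monoexponential_truth_selects_one(self):
        curve = biexp_curve(
            get_schedule("mrna-frap"), y0=0.1, amplitudes=(0.8,), rates=(0.05,),
            noise_sd=0.02, seed=4,
        )
        assert select_model(curve).n_components == 1

    def test_constant_curve_selects_one_with_zero_amplitude(self):
        sched = get_schedule("mrna-frap")
        t = sched.postbleach_times()
        times = np.concatenate([sched.prebleach_times(), t])
        y = np.concatenate([np.ones(6), np.full(len(t), 0.4)])
        fit = select_model(RecoveryCurve(times, y, np.zeros_like(times), 1, sched, 6))
        assert fit.n_components == 1
        assert sum(fit.amplitudes) == pytest.approx(0.0, abs=1e-6)


class TestCompareCurves:
    def test_identical_sets_give_zero_statistic_p_one(self):
        reps = [biexp_curve(get_schedule("sf-frap"), noise_sd=0.02, seed=s)
                for s in range(5)]
        res = compare_curves(reps, list(reps), n_permutations=99, seed=0)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_clearly_different_conditions_detected(self):
        sched = get_schedule("sf-frap")
        a = [biexp_curve(sched, amplitudes=(0.8,), rates=(0.1,), noise_sd=0.02, seed=s)
             for s in range(6)]
        b = [biexp_curve(sched, amplitudes=(0.3,), rates=(0.1,), noise_sd=0.02, seed=100 + s)
             for s in range(6)]
        res = compare_curves(a, b, n_permutations=199, seed=1)
        assert res.p_value <= 0.05

    def test_requires_three_replicates(self):
        reps = [biexp_curve(get_schedule("sf-frap"), seed=s) for s in range(2)]
        with pytest.raises(ConfigurationError, match="3 replicates"):
            compare_curves(reps, reps)

    def test_non_overlapping_grids_rejected(self):
        sched = get_schedule("sf-frap")
        a = [biexp_curve(sched, seed=s) for s in range(3)]
        shifted = []
        for s in range(3):
            c = biexp_curve(sched, seed=10 + s)
            shifted.append(RecoveryCurve(
                c.times + 1000.0, c.mean, c.sem, 1, sched, 0,
            ))
        with pytest.raises(DataError, match="non-overlapping"):
            compare_curves(a, shifted)

    def test_seeded_determinism(self):
        sched = get_schedule("sf-frap")
        a = [biexp_curve(sched, noise_sd=0.05, seed=s) for s in range(4)]
        b = [biexp_curve(sched, noise_sd=0.05, seed=50 + s) for s in range(4)]
        r1 = compare_curves(a, b, n_permutations=99, seed=7)
        r2 = compare_curves(a, b, n_permutations=99, seed=7)
        assert r1 == r2


def _bh_reference(p):
    """Independent Benjamini-Hochberg: p*m/rank with step-up monotonicity."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, p[i] * m / (rank_idx + 1))
        adj[i] = running
    return np.clip(adj, 0, 1)


class TestFdr:
    def test_hand_computed_example(self):
        assert np.allclose(fdr_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_ones(self):
        assert np.allclose(fdr_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ConfigurationError):
            fdr_adjust([0.0, 0.5])
        with pytest.raises(ConfigurationError):
            fdr_adjust([0.5, 1.2])

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=20))
    @settings(max_examples=100, derandomize=True)
    def test_matches_reference_and_dominates_raw(self, ps):
        adj = fdr_adjust(ps)
        assert np.allclose(adj, _bh_reference(ps))
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestFitRetention:
    def test_matched_seed_gives_zero_sse_at_truth(self, gene_e3):
        params = KineticParams(dt=0.5)
        sched = AcquisitionSchedule(n_prebleach=4, segments=((80.0, 4.0),))
        obs = simulate_frap(gene_e3, params.with_(retention_mean=50.0), sched,
                            n_sites=20, seed=42)
        best, table = fit_retention_time(
            obs, gene_e3, params, [50.0, 200.0], n_sites=20, seed=42,
        )
        assert best == 50.0
        assert table.loc[table.retention_s == 50.0, "sse"].iloc[0] == 0.0

    def test_empty_grid_rejected(self, gene_e3, short_schedule):
        obs = biexp_curve(short_schedule)
        with pytest.raises(ConfigurationError, match="non-empty"):
            fit_retention_time(obs, gene_e3, KineticParams(dt=0.5), [])

    def test_curve_without_schedule_rejected(self, gene_e3, short_schedule):
        obs = biexp_curve(short_schedule)
        obs.schedule = None
        with pytest.raises(ConfigurationError, match="schedule"):
            fit_retention_time(obs, gene_e3, KineticParams(dt=0.5), [50.0])
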