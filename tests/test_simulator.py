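"""Core Monte-Carlo engine: stepping, conservation, steady state, bleaching."""

import numpy as np
import pytest

from txnkinetics import (
    ConfigurationError,
    KineticParams,
    NonConvergenceError,
    apply_bleach,
    init_state,
    run_to_steady_state,
    site_ms2_signal,
    site_probe_signal,
    step,
    transcript_count,
)
from txnkinetics.simulator import _run


def quiet_params(**kw):
    """No initiation, no pausing: a single hand-placed polymerase moves alone."""
    base = dict(
        init_rate=0.0, elong_rate=50.0, pause_on_rate=0.0, pause_off_rate=0.1,
        termination_rate=1.0, retention_mean=10.0, dt=0.1,
    )
    base.update(kw)
    return KineticParams(**base)


def place_polymerase(state, row, pos):
    state.pos[row, 0] = pos
    state.npol[row] = 1


class TestParams:
    def test_dt_stability_guard(self):
        with pytest.raises(ConfigurationError, match="stability guard"):
            KineticParams(termination_rate=2.0, dt=0.2)

    def test_negative_rate_rejected(self):
        with pytest.raises(ConfigurationError):
            KineticParams(init_rate=-0.1)

    def test_bad_retention_model(self):
        with pytest.raises(ConfigurationError, match="retention_model"):
            KineticParams(retention_model="gamma")

    def test_guard_boundary_is_admissible(self):
        # 0.1 / max-rate exactly
        KineticParams(termination_rate=0.2, dt=0.5)


class TestStep:
    def test_no_sources_stays_empty(self, toy_gene):
        st = init_state(toy_gene, quiet_params(), seed=0, start="empty")
        for _ in range(50):
            step(st)
        assert transcript_count(st).sum() == 0

    def test_deterministic_advance_without_pausing(self, toy_gene):
        p = quiet_params()
        st = init_state(toy_gene, p, seed=0, start="empty")
        place_polymerase(st, 0, 100.0)
        step(st)
        assert st.pos[0, 0] == pytest.approx(100.0 + p.elong_rate * p.dt)

    def test_advance_clamped_at_gene_end(self, toy_gene):
        p = quiet_params()
        st = init_state(toy_gene, p, seed=0, start="empty")
        place_polymerase(st, 0, toy_gene.length_bp - 1.0)
        step(st)
        assert st.pos[0, 0] == toy_gene.length_bp

    def test_intron_signal_window_matches_event_times(self, two_intron_gene):
        """A lone polymerase holds intron 1's full signal for exactly
        splice_depletion_bp / elong_rate seconds after passing its 3' end."""
        p = quiet_params(splice_depletion_bp=200.0, elong_rate=50.0, dt=0.1)
        st = init_state(two_intron_gene, p, seed=0, start="empty")
        place_polymerase(st, 0, 0.0)
        e_end = two_intron_gene.introns[0][1]  # 500
        full, gone = None, None
        for k in range(1, 400):
            step(st)
            intron, _ = site_probe_signal(st)
            pos = st.pos[0, 0]
            # intron 1 fully synthesized but intron 2 not yet started
            if full is None and pos >= e_end and pos < two_intron_gene.introns[1][0]:
                assert intron[0] == pytest.approx(1.0)
                full = st.clock
            if full is not None and gone is None and pos >= e_end + 200.0:
                gone = st.clock
                break
        adv = p.elong_rate * p.dt
        expected = (e_end + 200.0 - e_end) / p.elong_rate
        # crossing times are quantized to the step grid
        assert gone is not None
        assert abs((gone - full) - expected) <= 2 * p.dt + adv / p.elong_rate

    def test_conservation_of_transcripts(self, gene_e6):
        p = KineticParams(dt=0.5, retention_mean=20.0)
        st = init_state(gene_e6, p, n_sites=3, seed=4, start="empty")
        before = int(transcript_count(st).sum())
        _, _, _, n_init, n_rel = _run(st, 2000)
        after = int(transcript_count(st).sum())
        assert after - before == n_init - n_rel
        assert n_init > 0 and n_rel > 0

    def test_footprint_never_violated(self, gene_e6):
        p = KineticParams(dt=0.5)
        st = init_state(gene_e6, p, n_sites=2, seed=9, start="empty")
        _run(st, 1000)
        for r in range(st.pos.shape[0]):
            n = st.npol[r]
            if n > 1:
                gaps = st.pos[r, : n - 1] - st.pos[r, 1:n]
                assert np.all(gaps >= p.footprint_bp - 1e-9)


class TestBleach:
    def test_bleach_zeroes_unbleached_and_is_idempotent(self, gene_e6):
        p = KineticParams(dt=0.5)
        st = run_to_steady_state(gene_e6, p, seed=2, n_sites=2)
        apply_bleach(st)
        tot, ble = site_ms2_signal(st)
        assert np.allclose(tot - ble, 0.0)
        assert tot.sum() > 0
        snapshot = st.bfrac.copy()
        apply_bleach(st)
        assert np.array_equal(st.bfrac, snapshot)

    def test_bleach_on_empty_state(self, toy_gene):
        st = init_state(toy_gene, quiet_params(), seed=0, start="empty")
        apply_bleach(st)
        tot, ble = site_ms2_signal(st)
        assert tot.sum() == 0 and ble.sum() == 0


class TestSteadyState:
    def test_no_initiation_converges_to_empty(self, toy_gene):
        st = run_to_steady_state(toy_gene, quiet_params(), seed=0, n_sites=2)
        assert transcript_count(st).sum() == 0
        assert st.window_means[-1] == 0.0

    def test_same_seed_bit_reproducible(self, gene_e3):
        p = KineticParams(dt=0.5)
        a = run_to_steady_state(gene_e3, p, seed=11, n_sites=3)
        b = run_to_steady_state(gene_e3, p, seed=11, n_sites=3)
        assert a.equals(b)

    def test_different_seeds_differ(self, gene_e3):
        p = KineticParams(dt=0.5)
        a = run_to_steady_state(gene_e3, p, seed=11, n_sites=3)
        b = run_to_steady_state(gene_e3, p, seed=12, n_sites=3)
        assert not a.equals(b)

    def test_nonconvergence_reports_window_means(self, gene_e3):
        with pytest.raises(NonConvergenceError) as exc:
            run_to_steady_state(gene_e3, KineticParams(dt=0.5), seed=1, max_windows=1)
        assert exc.value.window_means is not None

    def test_exponential_retention_model_runs(self, gene_e3):
        p = KineticParams(dt=0.5, retention_model="exponential", retention_mean=30.0)
        st = run_to_steady_state(gene_e3, p, seed=3, n_sites=2)
        assert transcript_count(st).sum() > 0

    def test_stationary_and_empty_starts_agree(self, gene_e3):
        """Both initializations settle to the same stationary occupancy."""
        p = KineticParams(dt=0.5, retention_mean=30.0)
        a = run_to_steady_state(gene_e3, p, seed=21, n_sites=40, start="stationary")
        b = run_to_steady_state(gene_e3, p, seed=22, n_sites=40, start="empty",
                                max_windows=60)
        ca, cb = transcript_count(a), transcript_count(b)
        pooled = np.sqrt(ca.var(ddof=1) / len(ca) + cb.var(ddof=1) / len(cb))
        assert abs(ca.mean() - cb.mean()) < 4 * pooled + 0.05 * max(ca.mean(), cb.mean())
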