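"""Monte-Carlo engine for transcription at an MS2-tagged reporter gene array.

The model follows the kinetic scheme used throughout the study: on every gene
copy of the array, polymerases initiate stochastically, elongate at a fixed
velocity while randomly entering and exiting a paused state, and are
stochastically released at the gene end at a termination rate.  A released
transcript does not leave the site immediately: it is *retained* for a
retention time (the single parameter separating the fast E3 / E6+Clk1 regime,
50 s, from the slow E6 regime, 11 min = 660 s).  While a polymerase traverses
the MS2 cassette the nascent transcript accumulates MS2 fluorescence
proportionally to the fraction of the cassette synthesized, and keeps it
until the transcript leaves the site.  Splicing is modeled purely
positionally: an intron's probe signal grows proportionally with its
synthesis and is removed once the polymerase has moved ``splice_depletion_bp``
past the intron's 3' end (750 bp in the control regime, 500 bp under Clk1
overexpression).

Time is discretized in fixed steps of ``dt`` seconds; each stochastic event
fires when a uniform random number falls below rate*dt, with a stability
guard keeping every per-step probability <= 0.1.

All operations are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _kernel
from .curves import AcquisitionSchedule, RecoveryCurve, Trajectory
from .errors import ConfigurationError, NonConvergenceError, UnsupportedRegimeError
from .gene_model import GeneModel

RETENTION_MODELS = ("fixed", "exponential")


@dataclass(frozen=True)
class KineticParams:
    """Kinetic parameters of the Monte-Carlo model.

    Rates are per second; ``elong_rate`` is bp/s.  ``retention_mean`` is the
    post-termination residence of a finished transcript at the site (fixed
    delay by default, exponential optionally).  ``splice_depletion_bp`` is the
    distance past an intron's 3' end at which its signal is removed.  None of
    the rate values are printed in the study; the defaults below are
    documented, realistic choices and every packaged result is stated
    relative to the parameters actually used.
    """

    init_rate: float = 0.05
    elong_rate: float = 55.0
    pause_on_rate: float = 0.01
    pause_off_rate: float = 0.1
    termination_rate: float = 0.2
    retention_mean: float = 50.0
    retention_model: str = "fixed"
    splice_depletion_bp: float = 750.0
    dt: float = 0.1
    footprint_bp: float = 35.0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.elong_rate <= 0:
            raise ConfigurationError("elong_rate must be > 0")
        if self.dt <= 0:
            raise ConfigurationError("dt must be > 0")
        for name in ("init_rate", "pause_on_rate", "pause_off_rate",
                     "termination_rate", "retention_mean", "splice_depletion_bp"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.retention_model not in RETENTION_MODELS:
            raise ConfigurationError(
                f"retention_model must be one of {RETENTION_MODELS}, got {self.retention_model!r}"
            )
        if self.footprint_bp < 0:
            raise ConfigurationError("footprint_bp must be >= 0")
        guard = self.max_stable_dt()
        if self.dt > guard + 1e-12:
            raise ConfigurationError(
                f"dt={self.dt} violates the stability guard dt <= 0.1/rate "
                f"(max admissible dt is {guard:g})"
            )

    def max_stable_dt(self) -> float:
        rates = [self.init_rate, self.pause_on_rate, self.pause_off_rate,
                 self.termination_rate]
        active = [r for r in rates if r > 0]
        return min((0.1 / r for r in active), default=math.inf)

    def with_(self, **kw) -> "KineticParams":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return {
            "init_rate": self.init_rate,
            "elong_rate": self.elong_rate,
            "pause_on_rate": self.pause_on_rate,
            "pause_off_rate": self.pause_off_rate,
            "termination_rate": self.termination_rate,
            "retention_mean": self.retention_mean,
            "retention_model": self.retention_model,
            "splice_depletion_bp": self.splice_depletion_bp,
            "dt": self.dt,
            "footprint_bp": self.footprint_bp,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KineticParams":
        return cls(**d)

    def mean_transit_time(self, gene: GeneModel) -> float:
        """Expected promoter-to-end transit, including pausing slow-down."""
        base = gene.length_bp / self.elong_rate
        if self.pause_on_rate > 0:
            base *= 1.0 + self.pause_on_rate / self.pause_off_rate
        return base

    def mean_dwell_time(self, gene: GeneModel) -> float:
        """Expected residence of one transcript at the site, start to release."""
        term_wait = 1.0 / self.termination_rate if self.termination_rate > 0 else 0.0
        return self.mean_transit_time(gene) + term_wait + self.retention_mean


@dataclass
class SiteState:
    """Full simulation state for ``n_sites`` independent transcription sites.

    Nascent polymerases live in (n_sites*n_copies, K) arrays ordered by
    decreasing position per row; retained transcripts live in per-site ring
    buffers.  ``rng_token`` (seed, steps done) fully determines the future
    random stream, making every run bit-reproducible.
    """

    gene: GeneModel
    params: KineticParams
    n_sites: int
    seed: int
    clock: float
    n_steps_done: int
    pos: np.ndarray
    paused: np.ndarray
    bfrac: np.ndarray
    pause_cd: np.ndarray
    npol: np.ndarray
    init_cd: np.ndarray
    term_cd: np.ndarray
    rd_dead: np.ndarray
    rd_bl: np.ndarray
    ret_head: np.ndarray
    ret_count: np.ndarray
    ret_bsum: np.ndarray
    window_means: list = field(default_factory=list)

    @property
    def n_copies(self) -> int:
        return self.gene.n_copies

    @property
    def rng_token(self) -> tuple[int, int]:
        return (self.seed, self.n_steps_done)

    def equals(self, other: "SiteState") -> bool:
        return (
            self.n_sites == other.n_sites
            and self.clock == other.clock
            and self.n_steps_done == other.n_steps_done
            and np.array_equal(self.npol, other.npol)
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.paused, other.paused)
            and np.array_equal(self.bfrac, other.bfrac)
            and np.array_equal(self.ret_count, other.ret_count)
            and np.array_equal(self.ret_head, other.ret_head)
            and np.array_equal(self.rd_dead, other.rd_dead)
            and np.array_equal(self.rd_bl, other.rd_bl)
        )

    def _active_mask(self) -> np.ndarray:
        K = self.pos.shape[1]
        return np.arange(K)[None, :] < self.npol[:, None]


# ---------------------------------------------------------------------------
# state construction
# ---------------------------------------------------------------------------

def _capacities(gene: GeneModel, params: KineticParams) -> tuple[int, int]:
    K = max(4, int(math.ceil(gene.length_bp / max(params.footprint_bp, 1.0))) + 1)
    mean_ret = gene.n_copies * params.init_rate * params.retention_mean
    cap = max(64, int(4 * mean_ret + 20 * math.sqrt(mean_ret + 1) + 64))
    return K, cap


def init_state(
    gene: GeneModel,
    params: KineticParams,
    n_sites: int = 1,
    seed: int = 0,
    start: str = "stationary",
) -> SiteState:
    """Allocate a :class:`SiteState`, empty or sampled near stationarity.

    ``start="stationary"`` draws per-copy polymerase counts and retained
    transcripts from the stationary occupancy implied by the parameters
    (Poisson counts, uniform positions with footprint enforcement, residual
    retention times); this shortens the burn-in that
    :func:`run_to_steady_state` then verifies with its window test.
    """
    if n_sites < 1:
        raise ConfigurationError("n_sites must be >= 1")
    if start not in ("stationary", "empty"):
        raise ConfigurationError("start must be 'stationary' or 'empty'")
    C = gene.n_copies
    R = n_sites * C
    K, cap = _capacities(gene, params)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5EED]))

    def geom(p: float, size=None):
        if p <= 0:
            return (
                np.full(size, _kernel.NEVER, dtype=np.int64)
                if size is not None
                else _kernel.NEVER
            )
        return rng.geometric(min(p, 1.0), size).astype(np.int64) if size is not None \
            else np.int64(rng.geometric(min(p, 1.0)))

    state = SiteState(
        gene=gene,
        params=params,
        n_sites=n_sites,
        seed=int(seed),
        clock=0.0,
        n_steps_done=0,
        pos=np.zeros((R, K)),
        paused=np.zeros((R, K), dtype=np.bool_),
        bfrac=np.zeros((R, K)),
        pause_cd=np.full((R, K), _kernel.NEVER, dtype=np.int64),
        npol=np.zeros(R, dtype=np.int64),
        init_cd=geom(params.init_rate * params.dt, R),
        term_cd=np.full(R, -1, dtype=np.int64),
        rd_dead=np.zeros((n_sites, cap)),
        rd_bl=np.zeros((n_sites, cap)),
        ret_head=np.zeros(n_sites, dtype=np.int64),
        ret_count=np.zeros(n_sites, dtype=np.int64),
        ret_bsum=np.zeros(n_sites),
    )
    if start == "empty" or params.init_rate == 0:
        return state

    L = float(gene.length_bp)
    foot = params.footprint_bp
    v_eff = L / params.mean_transit_time(gene)
    p_paused = (
        params.pause_on_rate / (params.pause_on_rate + params.pause_off_rate)
        if params.pause_on_rate > 0
        else 0.0
    )
    lam_nascent = params.init_rate * L / v_eff
    for r in range(R):
        n = int(min(K, rng.poisson(lam_nascent)))
        if n == 0:
            continue
        p = np.sort(rng.uniform(0.0, L, n))[::-1]
        for i in range(1, n):  # enforce footprint spacing behind the leader
            p[i] = min(p[i], p[i - 1] - foot)
        keep = p >= 0
        p = p[keep]
        n = len(p)
        state.pos[r, :n] = p
        is_paused = rng.random(n) < p_paused
        state.paused[r, :n] = is_paused
        p_on = params.pause_on_rate * params.dt
        p_off = params.pause_off_rate * params.dt
        state.pause_cd[r, :n] = np.where(is_paused, geom(p_off, n), geom(p_on, n))
        state.npol[r] = n
    mean_ret = C * params.init_rate * params.retention_mean
    for s in range(n_sites):
        m = int(min(cap, rng.poisson(mean_ret)))
        if m == 0:
            continue
        if params.retention_model == "fixed":
            resid = np.sort(rng.uniform(0.0, params.retention_mean, m))
        else:
            resid = np.sort(rng.exponential(params.retention_mean, m))
        state.rd_dead[s, :m] = resid
        state.rd_bl[s, :m] = 0.0
        state.ret_count[s] = m
    return state


def _chunk_seed(state: SiteState) -> int:
    ss = np.random.SeedSequence([state.seed & 0x7FFFFFFF, state.n_steps_done])
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def _run(
    state: SiteState,
    n_steps: int,
    sample_steps: np.ndarray | None = None,
    measure_every: int = 0,
):
    """Advance the state; returns (per-sample per-site unbleached, window sum, n_meas)."""
    if sample_steps is None:
        sample_steps = np.empty(0, dtype=np.int64)
    sample_steps = np.asarray(sample_steps, dtype=np.int64)
    out_unb = np.empty((len(sample_steps), state.n_sites))
    g, p = state.gene, state.params
    clock, total_sum, n_meas, n_init, n_rel, n_over = _kernel.run_steps(
        _chunk_seed(state),
        state.pos, state.paused, state.bfrac, state.pause_cd,
        state.npol, state.init_cd, state.term_cd,
        state.rd_dead, state.rd_bl, state.ret_head, state.ret_count, state.ret_bsum,
        g.n_copies, float(g.length_bp), float(p.footprint_bp),
        float(g.ms2_start), float(g.ms2_length),
        p.init_rate * p.dt, p.pause_on_rate * p.dt, p.pause_off_rate * p.dt,
        p.termination_rate * p.dt,
        p.elong_rate * p.dt, p.dt,
        p.retention_model == "fixed", p.retention_mean,
        state.clock, int(n_steps),
        sample_steps, out_unb,
        int(measure_every),
    )
    state.clock = clock
    state.n_steps_done += int(n_steps)
    if n_over:
        raise RuntimeError(
            f"retained-transcript buffer overflowed {n_over} times; "
            "capacity heuristic violated (extreme parameters?)"
        )
    return out_unb, total_sum, n_meas, n_init, n_rel


def step(state: SiteState) -> SiteState:
    """Advance the state by one time step ``params.dt`` (in place).

    The random stream is derived from ``state.rng_token``, so repeated
    stepping from the same initial state reproduces bit-identically.
    Returns (n_initiations, n_releases) via ``state.last_events``.
    """
    _, _, _, n_init, n_rel = _run(state, 1)
    state.last_events = (n_init, n_rel)
    return state


# ---------------------------------------------------------------------------
# read-outs
# ---------------------------------------------------------------------------

def _ms2_fractions(state: SiteState) -> np.ndarray:
    g = state.gene
    f = (state.pos - g.ms2_start) / g.ms2_length
    return np.clip(f, 0.0, 1.0)


def site_ms2_signal(state: SiteState) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (total, bleached) MS2 signal, nascent plus retained."""
    mask = state._active_mask()
    f = np.where(mask, _ms2_fractions(state), 0.0)
    b = np.where(mask, state.bfrac, 0.0)
    C = state.n_copies
    tot = f.sum(axis=1).reshape(state.n_sites, C).sum(axis=1) + state.ret_count
    ble = b.sum(axis=1).reshape(state.n_sites, C).sum(axis=1) + state.ret_bsum
    return tot, ble


def transcript_count(state: SiteState) -> np.ndarray:
    """Per-site transcript count: engaged polymerases plus retained transcripts."""
    C = state.n_copies
    return state.npol.reshape(state.n_sites, C).sum(axis=1) + state.ret_count


def _retained_probe_constants(gene: GeneModel, params: KineticParams) -> tuple[float, float]:
    """(intron, exon) probe signal carried by one retained transcript."""
    L = gene.length_bp
    intron_const = sum(
        1.0
        for i in sorted(gene.intron_probe_indices)
        if L < gene.introns[i][1] + params.splice_depletion_bp
    )
    return intron_const, 1.0


def site_probe_signal(state: SiteState) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (intron, exon) probe signal.

    Probe signals accrue proportionally to the fraction of the target
    synthesized; an intron's signal is removed once the polymerase has moved
    ``splice_depletion_bp`` past its 3' end (co-transcriptional splicing as
    positional depletion).
    """
    g, p = state.gene, state.params
    mask = state._active_mask()
    pos = state.pos
    C = state.n_copies
    intron = np.zeros(pos.shape)
    for i in sorted(g.intron_probe_indices):
        s_, e_ = g.introns[i]
        frac = np.clip((pos - s_) / (e_ - s_), 0.0, 1.0)
        frac[pos >= e_ + p.splice_depletion_bp] = 0.0
        intron += frac
    es, ee = g.exon_probe
    exon = np.clip((pos - es) / (ee - es), 0.0, 1.0)
    intron = np.where(mask, intron, 0.0).sum(axis=1).reshape(state.n_sites, C).sum(axis=1)
    exon = np.where(mask, exon, 0.0).sum(axis=1).reshape(state.n_sites, C).sum(axis=1)
    ic, ec = _retained_probe_constants(g, p)
    return intron + ic * state.ret_count, exon + ec * state.ret_count


def apply_bleach(state: SiteState) -> SiteState:
    """Instantaneously photobleach every transcript at each site (in place).

    The already-synthesized MS2 fraction of every nascent and retained
    transcript is marked dark; loops synthesized afterwards are fluorescent
    (the free coat-protein pool is assumed unbleached and in excess).
    Idempotent; immediately afterwards the unbleached signal is exactly 0.
    """
    mask = state._active_mask()
    state.bfrac = np.where(mask, _ms2_fractions(state), 0.0)
    cap = state.rd_dead.shape[1]
    for s in range(state.n_sites):
        c = int(state.ret_count[s])
        if c:
            idx = (int(state.ret_head[s]) + np.arange(c)) % cap
            state.rd_bl[s, idx] = 1.0
        state.ret_bsum[s] = float(c)
    return state


# ---------------------------------------------------------------------------
# steady state
# ---------------------------------------------------------------------------

def run_to_steady_state(
    gene: GeneModel,
    params: KineticParams,
    seed: int = 0,
    n_sites: int = 1,
    rel_tol: float = 0.05,
    window_dwell: float = 5.0,
    max_windows: int = 40,
    start: str = "stationary",
    measure_every: int = 10,
) -> SiteState:
    """Simulate until the total MS2 signal is stationary.

    Convergence: the mean total signal over two consecutive windows, each
    ``window_dwell`` (default 5) mean transcript dwell times long, differs by
    less than ``rel_tol`` (relative, default 0.05).  Deterministic given
    ``seed``.  Raises :class:`NonConvergenceError` after ``max_windows``
    windows, reporting the last two window means.
    """
    state = init_state(gene, params, n_sites=n_sites, seed=seed, start=start)
    dwell = params.mean_dwell_time(gene)
    w_steps = max(int(math.ceil(window_dwell * dwell / params.dt)), 10)
    means: list[float] = []
    for _ in range(max_windows):
        _, total_sum, n_meas, _, _ = _run(state, w_steps, measure_every=measure_every)
        means.append(total_sum / max(n_meas, 1))
        if len(means) >= 2:
            m1, m2 = means[-2], means[-1]
            denom = max(abs(m1), abs(m2))
            if denom < 1e-9 or abs(m1 - m2) <= rel_tol * denom:
                state.window_means = means
                return state
    tail = ", ".join(f"{m:.4g}" for m in means[-2:])
    raise NonConvergenceError(
        f"no steady state within {max_windows} windows of {w_steps} steps; "
        f"last window means: {tail}",
        window_means=means,
    )


# ---------------------------------------------------------------------------
# FRAP
# ---------------------------------------------------------------------------

def _times_to_steps(times: np.ndarray, dt: float) -> np.ndarray:
    return np.asarray(np.round(np.asarray(times) / dt), dtype=np.int64)


def simulate_frap(
    gene: GeneModel,
    params: KineticParams,
    schedule: AcquisitionSchedule,
    n_sites: int = 100,
    seed: int = 0,
    rel_tol: float = 0.05,
    window_dwell: float = 5.0,
) -> RecoveryCurve:
    """Simulate a FRAP experiment on ``n_sites`` independent sites.

    Each site is run to steady state, photobleached at t = 0 and sampled at
    the schedule's frame times; per-site intensities are normalized by that
    site's pre-bleach mean.  The returned curve holds the across-site mean,
    standard error and ``n``.
    """
    if n_sites < 1:
        raise ConfigurationError("n_sites must be >= 1")
    if schedule.n_frames < 2:
        raise ConfigurationError("schedule must contain at least 2 frames")
    dt = params.dt
    min_iv = min(iv for _, iv in schedule.segments)
    if min_iv < dt - 1e-12:
        raise ConfigurationError(
            f"frame interval {min_iv} s is below the simulation step dt={dt} s"
        )
    state = run_to_steady_state(
        gene, params, seed=seed, n_sites=n_sites, rel_tol=rel_tol, window_dwell=window_dwell
    )

    # pre-bleach frames
    n_pre = max(schedule.n_prebleach, 1)
    spp = max(int(round(schedule.prebleach_interval / dt)), 1)
    pre_steps = spp * np.arange(1, n_pre + 1) - 1
    pre_unb, _, _, _, _ = _run(state, int(pre_steps[-1]) + 1, sample_steps=pre_steps)
    pre_mean = pre_unb.mean(axis=0)

    apply_bleach(state)
    tot0, bl0 = site_ms2_signal(state)
    frame0 = tot0 - bl0  # exactly zero by construction

    post_times = schedule.postbleach_times()
    later = post_times[1:]
    post_steps = _times_to_steps(later, dt) - 1
    post_unb, _, _, _, _ = _run(state, int(post_steps[-1]) + 1, sample_steps=post_steps)

    times = np.concatenate([
        -schedule.prebleach_interval * np.arange(n_pre, 0, -1),
        post_times,
    ])
    keep = pre_mean > 0
    if not np.any(keep):
        # no signal anywhere (e.g. init_rate = 0): the recovery is identically 0
        return RecoveryCurve(
            times=times, mean=np.zeros(len(times)), sem=np.zeros(len(times)),
            n=n_sites, schedule=schedule, n_prebleach=n_pre,
        )
    norm = np.vstack([pre_unb, frame0[None, :], post_unb])[:, keep] / pre_mean[keep]
    n_kept = int(keep.sum())
    return RecoveryCurve(
        times=times,
        mean=norm.mean(axis=1),
        sem=norm.std(axis=1, ddof=1) / math.sqrt(n_kept) if n_kept > 1 else np.zeros(len(times)),
        n=n_kept,
        schedule=schedule,
        n_prebleach=n_pre,
    )


# ---------------------------------------------------------------------------
# trajectory recording
# ---------------------------------------------------------------------------

def simulate_trajectory(
    gene: GeneModel,
    params: KineticParams,
    duration_s: float,
    sample_interval_s: float,
    seed: int = 0,
    n_sites: int = 1,
    start: str = "empty",
) -> tuple[Trajectory, SiteState]:
    """Record all four channel totals (summed over sites) on a regular grid."""
    if sample_interval_s < params.dt - 1e-12:
        raise ConfigurationError("sample interval is below dt")
    state = init_state(gene, params, n_sites=n_sites, seed=seed, start=start)
    k = max(int(round(sample_interval_s / params.dt)), 1)
    n_samples = int(round(duration_s / sample_interval_s))
    times = np.empty(n_samples)
    tot = np.empty(n_samples)
    ble = np.empty(n_samples)
    intr = np.empty(n_samples)
    exo = np.empty(n_samples)
    for j in range(n_samples):
        _run(state, k)
        t, b = site_ms2_signal(state)
        i_, e_ = site_probe_signal(state)
        times[j] = state.clock
        tot[j] = t.sum()
        ble[j] = b.sum()
        intr[j] = i_.sum()
        exo[j] = e_.sum()
    return Trajectory(times, tot, ble, intr, exo), state


# ---------------------------------------------------------------------------
# FISH snapshots and analytic oracles
# ---------------------------------------------------------------------------

@dataclass
class FishSnapshot:
    """Per-site steady-state intron/exon probe signals and their ratio."""

    table: pd.DataFrame
    n_dropped: int
    normalized_by: float | None = None

    @property
    def mean_ratio(self) -> float:
        return float(self.table["ratio"].mean())

    @property
    def median_ratio(self) -> float:
        return float(self.table["ratio"].median())


def simulate_fish_snapshot(
    gene: GeneModel,
    params: KineticParams,
    n_sites: int = 100,
    seed: int = 0,
    normalize_to: float | None = None,
) -> FishSnapshot:
    """Steady-state intron/exon probe signals for ``n_sites`` independent sites.

    Sites with zero exon signal are dropped and counted in ``n_dropped``.
    ``normalize_to`` divides the ratios by a control value (the E3-control
    normalization convention).
    """
    if n_sites < 1:
        raise ConfigurationError("n_sites must be >= 1")
    state = run_to_steady_state(gene, params, seed=seed, n_sites=n_sites)
    intron, exon = site_probe_signal(state)
    ok = exon > 0
    ratio = np.where(ok, intron / np.where(ok, exon, 1.0), np.nan)
    if normalize_to is not None:
        if normalize_to <= 0:
            raise ConfigurationError("normalize_to must be positive")
        ratio = ratio / normalize_to
    table = pd.DataFrame(
        {
            "site": np.arange(n_sites)[ok],
            "intron_signal": intron[ok],
            "exon_signal": exon[ok],
            "ratio": ratio[ok],
        }
    )
    return FishSnapshot(table=table, n_dropped=int((~ok).sum()), normalized_by=normalize_to)


def _no_pause_guard(params: KineticParams) -> None:
    if params.pause_on_rate > 0:
        raise UnsupportedRegimeError(
            "analytic oracle is valid only in the no-pause regime (pause_on_rate == 0)"
        )
    if params.retention_model != "fixed":
        raise UnsupportedRegimeError("analytic oracle requires the fixed retention model")
    if params.termination_rate <= 0:
        raise UnsupportedRegimeError("analytic oracle requires termination_rate > 0")


def expected_transcript_count(gene: GeneModel, params: KineticParams) -> float:
    """Stationary mean transcript count at one site (Little's law).

    occupancy = arrival rate x mean dwell, with dwell = transit + mean
    termination wait (1/termination_rate) + retention.  Valid at low
    initiation density (promoter-footprint blocking neglected).
    """
    return gene.n_copies * params.init_rate * params.mean_dwell_time(gene)


def expected_fish_ratio(gene: GeneModel, params: KineticParams) -> float:
    """Analytic stationary intron/exon probe ratio, no-pause regime.

    By stationarity each probe's expected signal is proportional to the
    signal-weighted lifetime per transcript.  A probe target of length l
    contributes l/(2v) while being synthesized; an intron then stays at full
    signal until depletion (splice_depletion_bp further downstream) or, if
    never depleted on the gene, until the transcript leaves the site; the
    exon probe stays until the transcript leaves (transit to the gene end,
    mean termination wait 1/k_term, then retention).
    """
    _no_pause_guard(params)
    v = params.elong_rate
    L = gene.length_bp
    tail = 1.0 / params.termination_rate + params.retention_mean
    num = 0.0
    for i in sorted(gene.intron_probe_indices):
        s_, e_ = gene.introns[i]
        l = e_ - s_
        if e_ + params.splice_depletion_bp <= L:
            num += (l / 2.0 + params.splice_depletion_bp) / v
        else:
            num += l / (2.0 * v) + (L - e_) / v + tail
    es, ee = gene.exon_probe
    den = (ee - es) / (2.0 * v) + (L - ee) / v + tail
    return num / den
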