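import numpy as np
import pytest

from txnkinetics import AcquisitionSchedule, KineticParams, build_gene
from txnkinetics.gene_model import GeneModel


@pytest.fixture(scope="session")
def gene_e3():
    return build_gene("E3")


@pytest.fixture(scope="session")
def gene_e6():
    return build_gene("E6")


@pytest.fixture
def toy_gene():
    """Single-exon, intron-free gene: deterministic FRAP timing is exact."""
    return GeneModel(
        name="toy",
        length_bp=4000,
        exons=((0, 300),),
        introns=(),
        ms2_region=(3000, 4000),
        exon_probe=(0, 300),
        n_copies=20,
    )


@pytest.fixture
def two_intron_gene():
    """Small two-intron gene used for hand-computed probe lifetimes."""
    return GeneModel(
        name="mini",
        length_bp=2000,
        exons=((0, 200), (500, 700), (1000, 1200)),
        introns=((200, 500), (700, 1000)),
        ms2_region=(1200, 1800),
        exon_probe=(0, 200),
        intron_probe_indices=frozenset({0, 1}),
        n_copies=5,
    )


@pytest.fixture
def no_pause_params():
    return KineticParams(
        init_rate=0.05,
        elong_rate=50.0,
        pause_on_rate=0.0,
        pause_off_rate=0.1,
        termination_rate=1.0,
        retention_mean=50.0,
        dt=0.1,
    )


def biexp_curve(schedule, y0=0.05, amplitudes=(0.45, 0.35), rates=(0.5, 0.02),
                noise_sd=0.0, seed=0):
    """Closed-form recovery curve on a schedule's frame grid."""
    from txnkinetics import RecoveryCurve

    tpost = schedule.postbleach_times()
    y = np.full(len(tpost), float(y0))
    for a, k in zip(amplitudes, rates):
        y = y + a * (1.0 - np.exp(-k * tpost))
    times = np.concatenate([schedule.prebleach_times(), tpost])
    full = np.concatenate([np.ones(schedule.n_prebleach), y])
    if noise_sd > 0:
        full = full + noise_sd * np.random.default_rng(seed).standard_normal(len(full))
    return RecoveryCurve(
        times=times, mean=full, sem=np.zeros(len(full)), n=1,
        schedule=schedule, n_prebleach=schedule.n_prebleach,
    )


@pytest.fixture
def make_biexp_curve():
    return biexp_curve


@pytest.fixture
def short_schedule():
    return AcquisitionSchedule(n_prebleach=5, segments=((60.0, 2.0),), name="short")
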