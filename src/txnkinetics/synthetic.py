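"""Synthetic raw data with known ground truth.

Every input the analysis pipeline consumes can be generated here without any
download: raw FRAP traces (with acquisition photobleaching, per-day effects
and Gaussian intensity noise, emulating the study's ">= 10 experiments on 3
independent days" replicate structure) and per-site FISH intensity tables
(simulator signals under multiplicative lognormal noise).  Each generator is
seed-deterministic and returns its ground truth alongside, so every
downstream operation has a recovery target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .curves import AcquisitionSchedule, get_schedule
from .errors import ConfigurationError
from .frap import RawFrapTrace
from .gene_model import GeneModel, build_gene
from .simulator import KineticParams, simulate_fish_snapshot, simulate_frap

# raw-intensity scales used to dress normalized curves as camera counts
_ROI_SCALE = 1000.0
_WHOLE_SCALE = 5000.0
_BACKGROUND = 100.0


@dataclass
class SynthFrapSpec:
    """Recipe for a synthetic FRAP dataset.

    ``model="biexp"`` uses the closed-form recovery
    y0 + A1(1-exp(-k1 t)) + A2(1-exp(-k2 t)); ``model="simulator"`` runs
    :func:`simulate_frap` per cell with a sub-seed.  ``day_sd`` is the
    standard deviation of a Gaussian multiplier applied to the amplitudes of
    all cells measured on the same day (default 5%).
    """

    model: str = "biexp"
    model_params: dict | KineticParams | None = None
    gene: GeneModel | str | None = None
    schedule: AcquisitionSchedule | str = "mrna-frap"
    noise_sd: float = 0.02
    acq_bleach_rate: float = 0.0
    n_cells: int = 10
    n_days: int = 3
    day_sd: float = 0.05
    n_sites_per_cell: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.model not in ("biexp", "simulator"):
            raise ConfigurationError("model must be 'biexp' or 'simulator'")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not (0 <= self.acq_bleach_rate < 1):
            raise ConfigurationError("acq_bleach_rate must be in [0, 1)")
        if self.n_cells < 1:
            raise ConfigurationError("n_cells must be >= 1")
        if self.n_days < 1:
            raise ConfigurationError("n_days must be >= 1")
        if self.day_sd < 0:
            raise ConfigurationError("day_sd must be >= 0")
        if self.model == "simulator" and self.gene is None:
            raise ConfigurationError("simulator model needs a gene")


@dataclass
class SynthFishSpec:
    """Recipe for a synthetic per-site FISH intensity table."""

    gene: GeneModel | str = "E6"
    params: KineticParams = field(default_factory=KineticParams)
    n_sites: int = 100
    lognormal_noise_sd: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_sites < 1:
            raise ConfigurationError("n_sites must be >= 1")
        if self.lognormal_noise_sd < 0:
            raise ConfigurationError("lognormal_noise_sd must be >= 0")


_DEFAULT_BIEXP = {"y0": 0.05, "amplitudes": (0.45, 0.35), "rates": (0.5, 0.02)}


def _biexp(t: np.ndarray, y0: float, amplitudes, rates) -> np.ndarray:
    y = np.full_like(t, float(y0))
    for a, k in zip(amplitudes, rates):
        y = y + a * (1.0 - np.exp(-k * t))
    return y


def _resolve_gene(g) -> GeneModel:
    return build_gene(g) if isinstance(g, str) else g


def gen_frap_dataset(spec: SynthFrapSpec) -> tuple[list[RawFrapTrace], dict[str, Any]]:
    """Generate raw FRAP traces plus a ground-truth record.

    Per cell: the true normalized curve is computed from the chosen model, a
    per-day Gaussian multiplier is applied to its amplitudes, the curve is
    dressed as raw ROI / whole-cell / background series (per-frame
    multiplicative acquisition bleaching on ROI and whole) and Gaussian noise
    of sd ``noise_sd`` is added on the normalized scale.  Ground truth holds
    per-cell parameters and day assignments.  Deterministic given
    ``spec.seed``.
    """
    spec.validate()
    schedule = get_schedule(spec.schedule)
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0xF4A9]))
    times = schedule.frame_times()
    post = times >= 0
    tpost = times[post]

    day_mult = 1.0 + spec.day_sd * rng.standard_normal(spec.n_days)
    days = rng.integers(0, spec.n_days, spec.n_cells)

    traces: list[RawFrapTrace] = []
    cells: list[dict[str, Any]] = []
    for c in range(spec.n_cells):
        m = float(day_mult[days[c]])
        if spec.model == "biexp":
            mp = dict(_DEFAULT_BIEXP)
            if isinstance(spec.model_params, dict):
                mp.update(spec.model_params)
            amps = tuple(float(a) * m for a in np.atleast_1d(mp["amplitudes"]))
            rates = tuple(float(k) for k in np.atleast_1d(mp["rates"]))
            y0 = float(mp["y0"])
            truth = np.ones_like(times)
            truth[post] = _biexp(tpost, y0, amps, rates)
            cells.append({"cell": c, "day": int(days[c]), "y0": y0,
                          "amplitudes": amps, "rates": rates})
        else:
            params = spec.model_params
            if not isinstance(params, KineticParams):
                raise ConfigurationError("simulator model needs KineticParams in model_params")
            sub = int(np.random.SeedSequence([int(spec.seed), 77, c]).generate_state(1)[0])
            sim = simulate_frap(
                _resolve_gene(spec.gene), params, schedule,
                n_sites=spec.n_sites_per_cell, seed=sub,
            )
            truth = sim.mean.copy()
            truth[post] = 1.0 + m * (truth[post] - 1.0)
            cells.append({"cell": c, "day": int(days[c]), "seed": sub,
                          "retention_mean": params.retention_mean})

        noisy = truth + spec.noise_sd * rng.standard_normal(len(times))
        decay = (1.0 - spec.acq_bleach_rate) ** np.arange(len(times))
        roi = noisy * _ROI_SCALE * decay + _BACKGROUND
        whole = _WHOLE_SCALE * decay + _BACKGROUND
        background = np.full(len(times), _BACKGROUND)
        traces.append(
            RawFrapTrace(
                times=times - times[0],
                roi=roi,
                whole=whole,
                background=background,
                n_prebleach=schedule.n_prebleach,
            )
        )
    truth_record = {
        "model": spec.model,
        "schedule": schedule.name or "custom",
        "noise_sd": spec.noise_sd,
        "acq_bleach_rate": spec.acq_bleach_rate,
        "day_multipliers": day_mult.tolist(),
        "cells": cells,
    }
    return traces, truth_record


def gen_fish_table(spec: SynthFishSpec) -> pd.DataFrame:
    """Per-site FISH intensity table with lognormal channel noise.

    Columns ``intron_channel`` / ``exon_channel`` carry noisy intensities
    (independent lognormal multipliers per channel, median-preserving);
    ``true_*`` columns carry the noiseless simulator output.
    """
    spec.validate()
    snap = simulate_fish_snapshot(
        _resolve_gene(spec.gene), spec.params, n_sites=spec.n_sites, seed=spec.seed
    )
    t = snap.table
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0xF15A]))
    sd = spec.lognormal_noise_sd
    m_i = np.exp(sd * rng.standard_normal(len(t))) if sd > 0 else np.ones(len(t))
    m_e = np.exp(sd * rng.standard_normal(len(t))) if sd > 0 else np.ones(len(t))
    out = pd.DataFrame(
        {
            "site": t["site"].to_numpy(),
            "intron_channel": t["intron_signal"].to_numpy() * m_i,
            "exon_channel": t["exon_signal"].to_numpy() * m_e,
            "true_intron": t["intron_signal"].to_numpy(),
            "true_exon": t["exon_signal"].to_numpy(),
            "true_ratio": t["ratio"].to_numpy(),
        }
    )
    out["ratio"] = out["intron_channel"] / out["exon_channel"]
    return out
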