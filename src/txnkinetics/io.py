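"""File formats, run configuration and the pipeline driver.

CSV dialect everywhere: comma-separated, ``.`` decimal, UTF-8, header row
required.  Documented table layouts:

* raw FRAP trace: ``time_s, roi, whole, background, phase`` with ``phase``
  in {pre, post} (``n_prebleach`` is the number of ``pre`` rows);
* recovery curve: ``time_s, mean, sem, n`` (times in seconds from the
  bleach, pre-bleach frames negative);
* FISH table: ``site, intron_signal, exon_signal, ratio``.

Every pipeline run writes a manifest JSON (command, inputs, seed, package
version, parameter hash, outputs) next to its outputs, and refuses to
overwrite existing files unless ``force`` is set.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .curves import AcquisitionSchedule, RecoveryCurve, get_schedule
from .errors import ConfigurationError, DataError, TxnKineticsError
from .frap import (
    RawFrapTrace,
    compare_curves,
    fit_retention_time,
    normalize_frap,
    select_model,
    fit_recovery,
)
from .gene_model import GeneModel, load_gene
from .simulator import KineticParams, simulate_fish_snapshot, simulate_frap
from .synthetic import SynthFishSpec, SynthFrapSpec, gen_fish_table, gen_frap_dataset

log = logging.getLogger("txnkinetics")


# ---------------------------------------------------------------------------
# curve CSV
# ---------------------------------------------------------------------------

_RAW_COLS = {"time_s", "roi", "whole", "background"}
_CURVE_COLS = {"time_s", "mean"}


def read_curve_csv(path: str | Path) -> RawFrapTrace | RecoveryCurve:
    """Read a curve CSV, auto-detecting raw trace vs recovery curve by columns."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    df = pd.read_csv(path)
    cols = set(df.columns)
    if "time_s" not in cols:
        raise DataError(f"{path.name}: missing required column 'time_s'")
    t = df["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise DataError(f"{path.name}: 'time_s' must be strictly increasing (no duplicates)")
    if _RAW_COLS <= cols:
        if "phase" in cols:
            n_pre = int((df["phase"] == "pre").sum())
        else:
            n_pre = int((t < 0).sum())
        return RawFrapTrace(
            times=t,
            roi=df["roi"].to_numpy(dtype=float),
            whole=df["whole"].to_numpy(dtype=float),
            background=df["background"].to_numpy(dtype=float),
            n_prebleach=n_pre,
        )
    if _CURVE_COLS <= cols:
        sem = df["sem"].to_numpy(dtype=float) if "sem" in cols else np.zeros(len(df))
        n = int(df["n"].iloc[0]) if "n" in cols else 1
        return RecoveryCurve(
            times=t, mean=df["mean"].to_numpy(dtype=float), sem=sem, n=n,
            n_prebleach=int((t < 0).sum()),
        )
    missing = sorted((_RAW_COLS | _CURVE_COLS) - cols)
    raise DataError(
        f"{path.name}: columns {sorted(cols)} match neither a raw trace "
        f"({sorted(_RAW_COLS)} + phase) nor a recovery curve "
        f"({sorted(_CURVE_COLS)} [+ sem, n]); missing e.g. {missing}"
    )


def write_curve_csv(obj: RawFrapTrace | RecoveryCurve, path: str | Path) -> None:
    path = Path(path)
    if isinstance(obj, RawFrapTrace):
        phase = ["pre"] * obj.n_prebleach + ["post"] * (len(obj.times) - obj.n_prebleach)
        df = pd.DataFrame(
            {"time_s": obj.times, "roi": obj.roi, "whole": obj.whole,
             "background": obj.background, "phase": phase}
        )
    elif isinstance(obj, RecoveryCurve):
        df = pd.DataFrame(
            {"time_s": obj.times, "mean": obj.mean, "sem": obj.sem,
             "n": np.full(len(obj.times), obj.n)}
        )
    else:
        raise ConfigurationError(f"cannot write object of type {type(obj).__name__}")
    df.to_csv(path, index=False)


def params_from(ref: str | Path | dict | KineticParams | None) -> KineticParams:
    if ref is None:
        return KineticParams()
    if isinstance(ref, KineticParams):
        return ref
    if isinstance(ref, dict):
        return KineticParams(**{**KineticParams().to_dict(), **ref})
    path = Path(ref)
    if not path.exists():
        raise ConfigurationError(f"no such parameter file: {path}")
    doc = yaml.safe_load(path.read_text())
    return params_from(doc or {})


# ---------------------------------------------------------------------------
# run configuration and pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """One reproducible pipeline invocation."""

    command: str
    gene: str | GeneModel | None = None
    params: str | dict | KineticParams | None = None
    schedule: str | AcquisitionSchedule | None = None
    seed: int = 0
    out_dir: str | Path = "."
    log_level: str = "INFO"
    force: bool = False
    options: dict[str, Any] = field(default_factory=dict)


def _params_hash(params: KineticParams) -> str:
    blob = json.dumps(params.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _prepare_out(cfg: RunConfig, names: list[str]) -> Path:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not cfg.force:
        clash = [n for n in names if (out / n).exists()]
        if clash:
            raise ConfigurationError(
                f"refusing to overwrite {clash} in {out} (use force)"
            )
    return out


def _write_manifest(cfg: RunConfig, out: Path, params: KineticParams | None,
                    inputs: list[str], outputs: list[str]) -> dict:
    manifest = {
        "command": cfg.command,
        "inputs": inputs,
        "seed": cfg.seed,
        "package_version": __version__,
        "params_hash": _params_hash(params) if params is not None else None,
        "params": params.to_dict() if params is not None else None,
        "outputs": outputs,
    }
    (out / f"{cfg.command.replace('-', '_')}_manifest.json").write_text(
        json.dumps(manifest, indent=2)
    )
    return manifest


def _resolve_gene(ref) -> GeneModel:
    if isinstance(ref, GeneModel):
        return ref
    if ref is None:
        raise ConfigurationError("a gene reference is required")
    return load_gene(ref)


def _cmd_simulate_frap(cfg: RunConfig) -> tuple[dict, list[str]]:
    gene = _resolve_gene(cfg.gene)
    params = params_from(cfg.params)
    schedule = get_schedule(cfg.schedule or "mrna-frap")
    n_sites = int(cfg.options.get("n_sites", 100))
    out = _prepare_out(cfg, ["curve.csv"])
    curve = simulate_frap(gene, params, schedule, n_sites=n_sites, seed=cfg.seed)
    write_curve_csv(curve, out / "curve.csv")
    return {"gene": gene.name, "n_sites": n_sites}, ["curve.csv"]


def _cmd_simulate_fish(cfg: RunConfig) -> tuple[dict, list[str]]:
    gene = _resolve_gene(cfg.gene)
    params = params_from(cfg.params)
    if "retention" in cfg.options:
        params = params.with_(retention_mean=float(cfg.options["retention"]))
    if "depletion" in cfg.options:
        params = params.with_(splice_depletion_bp=float(cfg.options["depletion"]))
    n_sites = int(cfg.options.get("n_sites", 100))
    out = _prepare_out(cfg, ["ratios.csv"])
    snap = simulate_fish_snapshot(gene, params, n_sites=n_sites, seed=cfg.seed)
    snap.table.to_csv(out / "ratios.csv", index=False)
    return {
        "gene": gene.name, "n_sites": n_sites, "n_dropped": snap.n_dropped,
        "mean_ratio": snap.mean_ratio,
    }, ["ratios.csv"]


def _cmd_fit_frap(cfg: RunConfig) -> tuple[dict, list[str]]:
    src = cfg.options.get("input")
    if not src:
        raise ConfigurationError("fit-frap needs an input curve CSV ('input')")
    obj = read_curve_csv(src)
    curve = normalize_frap(obj) if isinstance(obj, RawFrapTrace) else obj
    components = cfg.options.get("components", "auto")
    if components == "auto":
        fit = select_model(curve)
    else:
        fit = fit_recovery(curve, int(components))
    out = _prepare_out(cfg, ["fit.json"])
    (out / "fit.json").write_text(json.dumps(fit.to_dict(), indent=2))
    return {"input": str(src), "n_components": fit.n_components}, ["fit.json"]


def _cmd_fit_retention(cfg: RunConfig) -> tuple[dict, list[str]]:
    src = cfg.options.get("input")
    if not src:
        raise ConfigurationError("fit-retention needs an input curve CSV ('input')")
    obj = read_curve_csv(src)
    curve = normalize_frap(obj) if isinstance(obj, RawFrapTrace) else obj
    curve.schedule = get_schedule(cfg.schedule or "mrna-frap")
    gene = _resolve_gene(cfg.gene)
    params = params_from(cfg.params)
    grid = [float(x) for x in cfg.options.get("grid", (50.0, 660.0))]
    n_sites = int(cfg.options.get("n_sites", 200))
    out = _prepare_out(cfg, ["retention.json", "retention_sse.csv"])
    best, table = fit_retention_time(
        curve, gene, params, grid, n_sites=n_sites, seed=cfg.seed
    )
    table.to_csv(out / "retention_sse.csv", index=False)
    (out / "retention.json").write_text(
        json.dumps({"best_retention_s": best, "grid": grid, "n_sites": n_sites}, indent=2)
    )
    return {"input": str(src), "best_retention_s": best}, ["retention.json", "retention_sse.csv"]


def _cmd_compare_curves(cfg: RunConfig) -> tuple[dict, list[str]]:
    paths_a = cfg.options.get("a") or []
    paths_b = cfg.options.get("b") or []
    if not paths_a or not paths_b:
        raise ConfigurationError("compare-curves needs curve lists 'a' and 'b'")

    def load(paths):
        curves = []
        for p in paths:
            obj = read_curve_csv(p)
            curves.append(normalize_frap(obj) if isinstance(obj, RawFrapTrace) else obj)
        return curves

    n_perm = int(cfg.options.get("n_permutations", 999))
    out = _prepare_out(cfg, ["comparison.json"])
    cmp_ = compare_curves(load(paths_a), load(paths_b), n_permutations=n_perm, seed=cfg.seed)
    doc = {
        "statistic": cmp_.statistic, "p_value": cmp_.p_value,
        "n_permutations": cmp_.n_permutations, "n_a": cmp_.n_a, "n_b": cmp_.n_b,
    }
    (out / "comparison.json").write_text(json.dumps(doc, indent=2))
    return doc, ["comparison.json"]


def _cmd_gen_synthetic(cfg: RunConfig) -> tuple[dict, list[str]]:
    kind = cfg.options.get("kind")
    if kind == "frap":
        spec = SynthFrapSpec(seed=cfg.seed, **cfg.options.get("spec", {}))
        traces, truth = gen_frap_dataset(spec)
        names = [f"trace_{i:03d}.csv" for i in range(len(traces))] + ["ground_truth.json"]
        out = _prepare_out(cfg, names)
        for i, tr in enumerate(traces):
            write_curve_csv(tr, out / f"trace_{i:03d}.csv")
        (out / "ground_truth.json").write_text(json.dumps(truth, indent=2))
        return {"kind": kind, "n_cells": len(traces)}, names
    if kind == "fish":
        spec_kw = dict(cfg.options.get("spec", {}))
        if cfg.gene is not None:
            spec_kw.setdefault("gene", cfg.gene)
        if "params" in spec_kw and isinstance(spec_kw["params"], dict):
            spec_kw["params"] = params_from(spec_kw["params"])
        spec = SynthFishSpec(seed=cfg.seed, **spec_kw)
        out = _prepare_out(cfg, ["fish_table.csv"])
        table = gen_fish_table(spec)
        table.to_csv(out / "fish_table.csv", index=False)
        return {"kind": kind, "n_sites": len(table)}, ["fish_table.csv"]
    raise ConfigurationError("gen-synthetic needs kind in {'frap', 'fish'}")


_COMMANDS = {
    "simulate-frap": _cmd_simulate_frap,
    "simulate-fish": _cmd_simulate_fish,
    "fit-frap": _cmd_fit_frap,
    "fit-retention": _cmd_fit_retention,
    "compare-curves": _cmd_compare_curves,
    "gen-synthetic": _cmd_gen_synthetic,
}


def run_pipeline(cfg: RunConfig) -> tuple[int, dict]:
    """Execute one subcommand; returns (exit status, manifest).

    Exit status 0 on success; any package error is logged with its module
    and re-raised as the nonzero status path for the CLI.
    """
    logging.basicConfig(level=getattr(logging, str(cfg.log_level).upper(), logging.INFO))
    if cfg.command not in _COMMANDS:
        raise ConfigurationError(
            f"unknown command {cfg.command!r}; available: {sorted(_COMMANDS)}"
        )
    params = None
    try:
        params = params_from(cfg.params) if cfg.command not in ("fit-frap",) else None
    except ConfigurationError:
        raise
    info, outputs = _COMMANDS[cfg.command](cfg)
    out = Path(cfg.out_dir)
    manifest = _write_manifest(
        cfg, out, params,
        inputs=[str(v) for k, v in cfg.options.items() if k in ("input", "a", "b")],
        outputs=outputs,
    )
    manifest["info"] = info
    log.info("%s finished: %s", cfg.command, info)
    return 0, manifest
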