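"""File formats, run configuration and the end-to-end pipeline.

Traces travel as TSV with ``#`` metadata header lines (``# key=value``) and
columns ``time_s  extension_nm  magnet_turns  force_pN``; gzip is handled
transparently by extension. Analysis outputs are flat TSV tables and a
machine-readable JSON report that embeds the config and seed it ran with.
"""

from __future__ import annotations

import dataclasses
import gzip
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .mechanics import MechanicsParameters
from .trace import EventLog, Trace

__all__ = [
    "RunConfig",
    "read_trace",
    "write_trace",
    "write_eventlog",
    "read_table",
    "write_table",
    "run_pipeline",
]

TRACE_COLUMNS = ["time_s", "extension_nm", "magnet_turns", "force_pN"]
SCHEMA_TAG = "plectokin/1"


def _open(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def write_trace(trace: Trace, path) -> None:
    """Write a trace as TSV with a ``#`` metadata header."""
    with _open(path, "wt") as fh:
        fh.write(f"# schema={SCHEMA_TAG}\n")
        for key, value in trace.metadata.items():
            fh.write(f"# {key}={value}\n")
        fh.write("\t".join(TRACE_COLUMNS) + "\n")
        for row in zip(trace.time_s, trace.extension_nm, trace.magnet_turns, trace.force_pN):
            fh.write("\t".join(f"{v:.17g}" for v in row) + "\n")


def read_trace(path) -> Trace:
    """Read a TSV trace; errors name the first offending line."""
    metadata = {}
    header = None
    rows = []
    with _open(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    metadata[key.strip()] = value.strip()
                continue
            parts = line.split("\t")
            if header is None:
                header = parts
                missing = [c for c in TRACE_COLUMNS if c not in header]
                if missing:
                    raise ValueError(
                        f"{path}:{lineno}: missing column(s) {', '.join(missing)}"
                    )
                continue
            try:
                rows.append([float(parts[header.index(c)]) for c in TRACE_COLUMNS])
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: unparsable row ({exc})") from None
    if header is None or not rows:
        raise ValueError(f"{path}: empty trace file")
    arr = np.asarray(rows, dtype=float)
    t = arr[:, 0]
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        # +2: one for the header line offset, one for diff indexing
        raise ValueError(
            f"{path}: time not strictly increasing at data line {int(bad[0]) + 2}"
        )
    return Trace(t, arr[:, 1], arr[:, 2], arr[:, 3], metadata)


def write_eventlog(log: EventLog, path) -> None:
    with _open(path, "wt") as fh:
        fh.write(f"# schema={SCHEMA_TAG}\n")
        for key, value in log.metadata.items():
            fh.write(f"# {key}={value}\n")
        log.to_frame().to_csv(fh, sep="\t", index=False)


def write_table(df: pd.DataFrame, path) -> None:
    with _open(path, "wt") as fh:
        fh.write(f"# schema={SCHEMA_TAG}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


@dataclass
class RunConfig:
    """Declarative description of a full pipeline run.

    Round-trips losslessly through YAML; every report embeds the config it
    ran with, so results are reproducible from the report alone.
    """

    seed: int = 1
    output_dir: str = "plectokin_out"
    mechanics: dict = field(default_factory=dict)
    tcc: dict = field(default_factory=lambda: {
        "duration_s": 600.0, "tau_tcc_s": 3.0, "step_decay_nm": 45.0,
        "noise_sd_nm": 8.0,
    })
    relaxation: dict = field(default_factory=lambda: {
        "duration_s": 1200.0, "tau_apic_s": 30.0, "rebind_prob_per_turn": 0.3,
        "total_turns": 25, "noise_sd_nm": 8.0,
    })
    forcejump: dict = field(default_factory=lambda: {
        "tau0_days": 245.0, "delta_x_nm": 0.89,
        "forces_pN": [30.0, 40.0, 50.0], "n_per_force": [55, 41, 36],
    })
    kinetics: dict = field(default_factory=lambda: {
        "lengths_bp": [1800, 2686, 4361, 7249],
        "times_min": [0.0, 30.0, 60.0, 120.0, 240.0, 480.0],
        "f_active": 0.4, "k_hs": 0.05, "k_fs": 0.02,
        "k_on": {1800: 0.02, 2686: 0.025, 4361: 0.03, 7249: 0.035},
        "noise_sd": 0.02, "replicates": 3,
    })
    afm: dict = field(default_factory=lambda: {"n_oc": 2000, "n_sc": 2000})

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        path = Path(source)
        text = path.read_text() if path.exists() else str(source)
        data = yaml.safe_load(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "kinetics" in data and "k_on" in data.get("kinetics", {}):
            data["kinetics"]["k_on"] = {
                int(k): float(v) for k, v in data["kinetics"]["k_on"].items()
            }
        return cls(**data)

    def mechanics_params(self) -> MechanicsParameters:
        return MechanicsParameters(**self.mechanics)


def _stage(report: dict, name: str, fn) -> None:
    """Run one pipeline stage, isolating failures into the report."""
    try:
        report["stages"][name] = {"status": "ok", "result": fn()}
    except Exception as exc:  # surfaced, never silent
        report["stages"][name] = {"status": "error", "error": f"{type(exc).__name__}: {exc}"}
        report["failed_stages"].append(name)


def run_pipeline(config: RunConfig, output_dir=None) -> dict:
    """simulate -> step-find -> dwell/force/kinetics/afm analysis, reported.

    Returns the report dict and writes ``report.json`` plus a human-readable
    ``summary.txt`` under the output directory. Stage failures are isolated
    and listed in ``failed_stages``.
    """
    from . import dwellstats, forcespec, kinetics, stepfind, synthetic
    from .mechanics import extension_to_linking

    out = Path(output_dir if output_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    mech = config.mechanics_params()
    report = {
        "schema": SCHEMA_TAG,
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "stages": {},
        "failed_stages": [],
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    def tcc_stage():
        p = dict(config.tcc)
        cfg = synthetic.SimulationConfig(
            seed=config.seed, duration_s=p.pop("duration_s"),
            noise_sd_nm=p.pop("noise_sd_nm"), mechanics=mech,
        )
        trace, log = synthetic.simulate_tcc_trace(cfg, **p)
        write_trace(trace, out / "tcc_trace.tsv")
        write_eventlog(log, out / "tcc_events.tsv")
        fit = stepfind.find_steps(trace)
        write_table(fit.to_frame(), out / "tcc_steps.tsv")
        dwells = fit.dwell_times_s[fit.dwell_times_s > 0]
        est = dwellstats.fit_exponential_mle(dwells)
        return {"n_steps": fit.n_steps, "tau_s": est.tau,
                "ci95": [est.ci95_low, est.ci95_high], "n": est.n}

    def relaxation_stage():
        p = dict(config.relaxation)
        cfg = synthetic.SimulationConfig(
            seed=config.seed + 1, duration_s=p.pop("duration_s"),
            noise_sd_nm=p.pop("noise_sd_nm"), mechanics=mech,
        )
        trace, log = synthetic.simulate_relaxation_trace(cfg, **p)
        write_trace(trace, out / "relaxation_trace.tsv")
        fit = stepfind.find_steps(trace)
        dlk = np.array([
            extension_to_linking(s, mech.extension_per_turn_nm)
            for s in fit.step_sizes_nm
        ])
        sample = dwellstats.LinkingStepSample(dlk, slope_nm_per_turn=mech.extension_per_turn_nm)
        result = {"n_steps": fit.n_steps, "mean_delta_lk": float(np.mean(np.abs(dlk))) if dlk.size else None}
        if dlk.size >= 5:
            grid, dens = dwellstats.kde_linking_density(np.abs(dlk))
            freq, amp = dwellstats.periodicity_spectrum(grid, dens)
            result["dominant_freq_per_turn"] = dwellstats.dominant_frequency(freq, amp)
        result["large_step_fraction"] = dwellstats.fraction_large_steps(sample)["fraction"] if dlk.size else None
        return result

    def force_stage():
        p = dict(config.forcejump)
        cfg = synthetic.SimulationConfig(seed=config.seed + 2, mechanics=mech)
        table = synthetic.simulate_force_jump(cfg, **p)
        write_table(table, out / "ruptures.tsv")
        lifetimes = forcespec.fit_force_lifetimes(table, event="final")
        bell = forcespec.fit_bell(lifetimes, temperature_K=mech.temperature_mt_K)
        r, pval, n = forcespec.correlate_jump_with_sigma(table)
        return {
            "per_force_tau_s": {f: est.tau for f, est in lifetimes},
            "tau0_days": bell.tau0 / 86400.0,
            "delta_x_nm": bell.delta_x_nm,
            "se_delta_x_nm": bell.se_delta_x_nm,
            "jump_dsigma_r": r, "jump_dsigma_p": pval, "n_pairs": n,
        }

    def kinetics_stage():
        p = dict(config.kinetics)
        params = kinetics.KineticParameters(
            f_active=p["f_active"], k_on=p["k_on"], k_hs=p["k_hs"], k_fs=p["k_fs"],
        )
        table = synthetic.simulate_ensemble_kinetics(
            params, p["lengths_bp"], p["times_min"], noise_sd=p["noise_sd"],
            replicates=p["replicates"], seed=config.seed + 3,
        )
        write_table(table, out / "kinetics.tsv")
        datasets = {L: g for L, g in table.groupby("length_bp")}
        fit = kinetics.global_fit(datasets, multistart=3, seed=config.seed + 3)
        return {
            "success": fit.success, "ssr": fit.ssr,
            "f_active": fit.params.f_active, "k_hs": fit.params.k_hs,
            "k_fs": fit.params.k_fs,
            "k_on": {str(k): v for k, v in fit.params.k_on.items()},
            "se": fit.se,
        }

    def afm_stage():
        p = dict(config.afm)
        table = synthetic.simulate_afm_particles(p["n_oc"], p["n_sc"], seed=config.seed + 4)
        write_table(table, out / "afm_particles.tsv")
        from .afm import classification_error_rates
        mat = classification_error_rates(table)
        return {"error_rates": mat["error_rate"].to_dict()}

    _stage(report, "tcc", tcc_stage)
    _stage(report, "relaxation", relaxation_stage)
    _stage(report, "force", force_stage)
    _stage(report, "kinetics", kinetics_stage)
    _stage(report, "afm", afm_stage)

    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    lines = [f"plectokin {__version__} pipeline report (seed {config.seed})"]
    for name, info in report["stages"].items():
        lines.append(f"[{name}] {info['status']}")
        payload = info.get("result") or {"error": info.get("error")}
        for key, value in payload.items():
            lines.append(f"    {key}: {value}")
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
    return report
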