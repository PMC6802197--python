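"""Seeded generators for every input the analysis pipeline consumes.

The raw single-molecule recordings behind this kind of experiment are not
redistributable, so these generators produce statistically faithful stand-ins:
target-capture traces with exponential dwells (lifetime ~3 s) and two-sided
exponentially distributed repositioning steps (decay ~45 nm), supercoil-release
staircases whose integer-quantized step sizes are geometric (a fixed interface
reforming probability per released turn) rendered as 4 ms/turn ramps,
Bell-model rupture-time tables at 30/40/50 pN, ensemble integration kinetics
from the chain ODE, and AFM crossing-count tables (means 2.4 and 12.2,
SD 1.7). Every generator is a pure function of its config and seed, and each
trace generator returns the ground-truth :class:`~plectokin.trace.EventLog`
alongside the rendered trace so recovery can be benchmarked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinetics import KineticParameters, full_site_fraction
from .mechanics import MechanicsParameters, bell_lifetime
from .trace import EventLog, Trace

__all__ = [
    "SimulationConfig",
    "simulate_tcc_trace",
    "simulate_relaxation_trace",
    "simulate_force_jump",
    "simulate_ensemble_kinetics",
    "simulate_afm_particles",
]

SECONDS_PER_DAY = 86400.0


@dataclass(frozen=True)
class SimulationConfig:
    """Shared settings of the magnetic-tweezers trace generators.

    The camera frame rate of the emulated instrument is 58 Hz. The
    per-sample Gaussian extension noise (default 8 nm SD) is a stand-in for
    bead Brownian fluctuations, whose magnitude the emulated experiments do
    not state; it is therefore an explicit knob, not a fact.
    """

    seed: int = 0
    sampling_rate_hz: float = 58.0
    noise_sd_nm: float = 8.0
    duration_s: float = 60.0
    force_pN: float = 0.5
    mechanics: MechanicsParameters = field(default_factory=MechanicsParameters)

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be > 0")
        if self.noise_sd_nm < 0:
            raise ValueError("noise_sd_nm must be >= 0")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")


def _render(config: SimulationConfig, levels: np.ndarray, rng,
            noise_sd: np.ndarray | float, magnet_turns: np.ndarray | float = 0.0) -> Trace:
    n = levels.size
    t = np.arange(n) / config.sampling_rate_hz
    noise = rng.normal(0.0, 1.0, size=n) * noise_sd
    return Trace(
        time_s=t,
        extension_nm=levels + noise,
        magnet_turns=np.broadcast_to(np.asarray(magnet_turns, float), (n,)).copy(),
        force_pN=np.full(n, config.force_pN),
        metadata={"seed": config.seed, "sampling_rate_hz": config.sampling_rate_hz,
                  "noise_sd_nm": config.noise_sd_nm, "force_pN": config.force_pN},
    )


def simulate_tcc_trace(
    config: SimulationConfig,
    tau_tcc_s: float = 3.0,
    step_decay_nm: float = 45.0,
    sigma_z_reduction_nm: float = 4.0,
    capture_time_s: float | None = None,
    baseline_nm: float = 1000.0,
) -> tuple[Trace, EventLog]:
    """Target-capture trace: piecewise-constant extension with stepping.

    After the capture event (default at 10% of the trace) the intasome
    bridges DNA: the extension level jumps at exponentially distributed
    intervals (mean ``tau_tcc_s``) by signed two-sided-exponential step sizes
    (decay ``step_decay_nm``), and the per-sample fluctuation SD drops by
    ``sigma_z_reduction_nm``. Event times in the log are sample-aligned so a
    noiseless trace reproduces the log exactly.
    """
    if tau_tcc_s <= 0:
        raise ValueError("tau_tcc_s must be > 0")
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate_hz
    n = int(round(config.duration_s * fs))
    if capture_time_s is None:
        capture_time_s = 0.1 * config.duration_s

    # event schedule (continuous), then snapped to the sample grid
    ev_times = [capture_time_s]
    while True:
        t_next = ev_times[-1] + rng.exponential(tau_tcc_s)
        if t_next >= config.duration_s:
            break
        ev_times.append(t_next)
    idx = np.minimum((np.ceil(np.asarray(ev_times) * fs)).astype(int), n - 1)
    sizes = rng.laplace(0.0, step_decay_nm, size=len(ev_times))

    levels = np.full(n, baseline_nm)
    level = baseline_nm
    for i, s in zip(idx, sizes):
        level += s
        levels[i:] = level

    noise_sd = np.full(n, config.noise_sd_nm, dtype=float)
    reduced = max(config.noise_sd_nm - sigma_z_reduction_nm, 0.0)
    noise_sd[idx[0]:] = reduced
    trace = _render(config, levels, rng, noise_sd)

    times = idx / fs
    kinds = np.array(["bind"] + ["step"] * (len(idx) - 1), dtype=object)
    dwells = np.concatenate([[np.nan], np.diff(times)])
    log = EventLog(times, kinds, sizes, dwells,
                   metadata={"value_unit": "nm", "tau_tcc_s": tau_tcc_s,
                             "step_decay_nm": step_decay_nm,
                             "sigma_z_reduction_nm": sigma_z_reduction_nm})
    return trace, log


def simulate_relaxation_trace(
    config: SimulationConfig,
    tau_apic_s: float = 90.0,
    rebind_prob_per_turn: float = 0.3,
    turn_time_s: float = 0.004,
    total_turns: int = 25,
    baseline_nm: float = 500.0,
) -> tuple[Trace, EventLog]:
    """Stepwise supercoil-release staircase after strand transfer.

    Plateau dwells are exponential (mean ``tau_apic_s``, the apical interface
    lifetime); each unbinding event releases a geometric number of turns
    (success probability ``rebind_prob_per_turn`` of the interface reforming
    per turn), converted to extension via the plectonemic slope and rendered
    as a finite-speed ramp at ``turn_time_s`` per turn. The staircase ends
    when ``total_turns`` have been released or the trace runs out.
    """
    if tau_apic_s <= 0:
        raise ValueError("tau_apic_s must be > 0")
    if not 0.0 < rebind_prob_per_turn <= 1.0:
        raise ValueError("rebind_prob_per_turn must lie in (0, 1]")
    if total_turns < 1:
        raise ValueError("total_turns must be >= 1")
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate_hz
    n = int(round(config.duration_s * fs))
    c = config.mechanics.extension_per_turn_nm

    levels = np.full(n, baseline_nm, dtype=float)
    ev_t, ev_turns, released, t_now = [], [], 0, 0.0
    while released < total_turns:
        t_now += rng.exponential(tau_apic_s)
        if t_now >= config.duration_s:
            break
        turns = int(rng.geometric(rebind_prob_per_turn))
        turns = min(turns, total_turns - released)
        i0 = min(int(np.ceil(t_now * fs)), n - 1)
        ramp = max(int(round(turns * turn_time_s * fs)), 0)
        i1 = min(i0 + ramp, n - 1)
        start = levels[i0]
        if i1 > i0:
            levels[i0:i1 + 1] = start + np.linspace(0.0, turns * c, i1 - i0 + 1)
        levels[i1:] = start + turns * c
        ev_t.append(i0 / fs)
        ev_turns.append(turns)
        released += turns
        t_now = i1 / fs

    trace = _render(config, levels, rng, config.noise_sd_nm)
    ev_t = np.asarray(ev_t, dtype=float)
    dwells = np.concatenate([[np.nan], np.diff(ev_t)]) if ev_t.size else np.array([])
    log = EventLog(ev_t, np.array(["unbind"] * ev_t.size, dtype=object),
                   np.asarray(ev_turns, dtype=float), dwells,
                   metadata={"value_unit": "turns", "tau_apic_s": tau_apic_s,
                             "rebind_prob_per_turn": rebind_prob_per_turn,
                             "extension_per_turn_nm": c,
                             "released_turns": released})
    return trace, log


def simulate_force_jump(
    config: SimulationConfig,
    tau0_days: float = 245.0,
    delta_x_nm: float = 0.89,
    forces_pN=(30.0, 40.0, 50.0),
    n_per_force=55,
    loop_fraction: float = 0.9,
    loop_tau0_days: float = 1.25,
    loop_delta_x_nm: float = 0.51,
    jump_per_dsigma: float = 6.0,
    couple_jump: bool = True,
) -> pd.DataFrame:
    """Rupture-time table of force-jump experiments on reacted tethers.

    Final disassembly times are exponential with Bell-model means
    ``tau0 exp(-F dx / kBT)`` per force; a ``loop_fraction`` of tethers also
    carries a loop-release event with its own Bell parameters (recorded only
    when it precedes rupture, as in the experiment). The loop-jump size is
    drawn proportional to the tether's sigma_z reduction so the jump/dsigma
    correlation of real traces is reproduced; ``couple_jump=False`` breaks
    the coupling for null checks.
    """
    forces = list(np.atleast_1d(np.asarray(forces_pN, dtype=float)))
    if len(forces) == 0:
        raise ValueError("empty force list")
    if np.isscalar(n_per_force):
        n_per_force = [int(n_per_force)] * len(forces)
    if len(n_per_force) != len(forces):
        raise ValueError("n_per_force must match forces")
    rng = np.random.default_rng(config.seed)
    temperature = config.mechanics.temperature_mt_K

    rows = []
    tid = 0
    for force, n in zip(forces, n_per_force):
        mean_s = bell_lifetime(tau0_days * SECONDS_PER_DAY, delta_x_nm, force, temperature)
        loop_mean_s = bell_lifetime(
            loop_tau0_days * SECONDS_PER_DAY, loop_delta_x_nm, force, temperature
        )
        for _ in range(int(n)):
            rupture = rng.exponential(mean_s)
            dsigma = rng.uniform(1.0, 8.0)
            loop_t = loop_jump = np.nan
            if rng.random() < loop_fraction:
                cand = rng.exponential(loop_mean_s)
                if cand < rupture:
                    loop_t = cand
                    base = dsigma if couple_jump else rng.uniform(1.0, 8.0)
                    loop_jump = max(jump_per_dsigma * base + rng.normal(0.0, 2.0), 0.0)
            rows.append((f"t{tid:04d}", force, loop_t, loop_jump, rupture, dsigma))
            tid += 1
    return pd.DataFrame(
        rows,
        columns=["tether_id", "force_pN", "loop_time_s", "loop_jump_nm",
                 "rupture_time_s", "dsigma_nm"],
    )


def simulate_ensemble_kinetics(
    params: KineticParameters,
    lengths_bp,
    times_min,
    noise_sd: float = 0.02,
    replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Ensemble full-site kinetics table: mean +/- SD over replicates.

    Gaussian noise of absolute SD ``noise_sd`` (fraction units) is added per
    replicate measurement, mimicking gel-quantification error. Zero noise
    returns the ODE solution exactly with zero SDs.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    t = np.asarray(times_min, dtype=float)
    rows = []
    for length in lengths_bp:
        truth = full_site_fraction(params, int(length), t)
        reps = truth[None, :] + rng.normal(0.0, noise_sd, size=(replicates, t.size)) \
            if noise_sd > 0 else np.tile(truth, (replicates, 1))
        mean = reps.mean(axis=0)
        sd = reps.std(axis=0, ddof=1) if replicates > 1 else np.zeros_like(mean)
        for ti, m, s in zip(t, mean, sd):
            rows.append((int(length), ti, m, s))
    return pd.DataFrame(
        rows, columns=["length_bp", "time_min", "fs_fraction_mean", "fs_fraction_sd"]
    )


def simulate_afm_particles(
    n_oc: int,
    n_sc: int,
    seed: int = 0,
    mean_oc: float = 2.4,
    sd_oc: float = 1.7,
    mean_sc: float = 12.2,
    sd_sc: float = 1.7,
) -> pd.DataFrame:
    """Crossing-count table of open-circular and supercoiled plasmids.

    Counts are rounded Gaussian draws clipped at zero (which biases the OC
    mean upward by about 0.06 — the price of non-negative integer counts),
    labeled with the ground-truth topology class.
    """
    if n_oc < 0 or n_sc < 0:
        raise ValueError("particle counts must be >= 0")
    rng = np.random.default_rng(seed)
    oc = np.clip(np.round(rng.normal(mean_oc, sd_oc, size=n_oc)), 0, None).astype(int)
    sc = np.clip(np.round(rng.normal(mean_sc, sd_sc, size=n_sc)), 0, None).astype(int)
    return pd.DataFrame(
        {
            "particle_id": [f"p{i:05d}" for i in range(n_oc + n_sc)],
            "n_crossings": np.concatenate([oc, sc]),
            "class_label": ["open_circular"] * n_oc + ["covalently_closed"] * n_sc,
        }
    )
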