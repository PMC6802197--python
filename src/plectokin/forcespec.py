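"""Survival analysis of forced strand-transfer-complex disassembly.

Tethers held at high constant force (30-50 pN) survive for exponentially
distributed times; a loop-release extension jump usually precedes the final
rupture. Per-force lifetimes come from the exponential MLE, and their force
dependence is fitted to the Bell model

    tau(F) = tau0 exp(-F dx / kBT)

by weighted linear regression of ln(tau) on F. Weights are the per-force
sample counts: for an exponential MLE, Var[ln tau_hat] = 1/n exactly, so the
parameter covariance (X'WX)^-1 needs no residual rescaling (with three force
levels and two parameters a residual-scaled error would have a single degree
of freedom).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dwellstats import LifetimeEstimate, fit_exponential_mle
from .mechanics import kbt_pn_nm

__all__ = [
    "BellFit",
    "survival_curve",
    "fit_force_lifetimes",
    "fit_bell",
    "correlate_jump_with_sigma",
]

RUPTURE_COLUMNS = [
    "tether_id",
    "force_pN",
    "loop_time_s",
    "loop_jump_nm",
    "rupture_time_s",
    "dsigma_nm",
]


@dataclass(frozen=True)
class BellFit:
    """Zero-force lifetime and distance to the transition state."""

    tau0: float
    delta_x_nm: float
    se_tau0: float
    se_delta_x_nm: float
    temperature_K: float
    lifetimes: tuple  # ((force_pN, LifetimeEstimate), ...)
    cov_ln: np.ndarray  # covariance of (ln tau0, slope)

    @property
    def delta_x_angstrom(self) -> float:
        return self.delta_x_nm * 10.0

    @property
    def se_delta_x_angstrom(self) -> float:
        return self.se_delta_x_nm * 10.0

    def lifetime_at(self, force_pN: float) -> float:
        return self.tau0 * np.exp(
            -force_pN * self.delta_x_nm / kbt_pn_nm(self.temperature_K)
        )


def survival_curve(times):
    """Empirical cumulative fraction of ruptured tethers versus time.

    Returns ``(t, dissociated, surviving)`` with the right-continuous ECDF
    evaluated at the sorted rupture times.
    """
    t = np.sort(np.asarray(times, dtype=float))
    if t.size == 0:
        raise ValueError("no rupture times")
    frac = np.arange(1, t.size + 1) / t.size
    return t, frac, 1.0 - frac


def fit_force_lifetimes(
    table: pd.DataFrame, event: str = "final", censor_col: str | None = None
) -> list[tuple[float, LifetimeEstimate]]:
    """Exponential lifetime per force level for the chosen event type.

    ``event`` selects ``'final'`` (``rupture_time_s``) or ``'loop'``
    (``loop_time_s``; tethers without a loop event are skipped). Rows flagged
    truthy in ``censor_col`` (e.g. handle detachment) contribute their
    observation time to the MLE numerator but not to the event count
    (right censoring). Estimates from fewer than 5 events are flagged
    unreliable, never dropped.
    """
    col = {"final": "rupture_time_s", "loop": "loop_time_s"}.get(event)
    if col is None:
        raise ValueError("event must be 'final' or 'loop'")
    out: list[tuple[float, LifetimeEstimate]] = []
    for force, grp in table.groupby("force_pN", sort=True):
        times = grp[col].dropna()
        if times.empty:
            continue
        if censor_col is not None and censor_col in grp.columns:
            cens = grp.loc[times.index, censor_col].astype(bool).to_numpy()
            x = times.to_numpy(float)
            n_events = int((~cens).sum())
            if n_events < 2:
                continue
            tau = float(x.sum() / n_events)
            lo = 2 * n_events * tau / stats.chi2.ppf(0.975, 2 * n_events)
            hi = 2 * n_events * tau / stats.chi2.ppf(0.025, 2 * n_events)
            est = LifetimeEstimate(
                tau, float(lo), float(hi), n_events,
                float(-n_events * np.log(tau) - n_events), reliable=n_events >= 5,
            )
        else:
            est = fit_exponential_mle(times.to_numpy(float))
        out.append((float(force), est))
    return out


def fit_bell(
    lifetimes,
    temperature_K: float = 298.0,
    weighted: bool = True,
) -> BellFit:
    """Bell-model fit: weighted linear regression of ln(tau) on force.

    ``lifetimes`` is a sequence of ``(force_pN, LifetimeEstimate)`` or
    ``(force_pN, tau)`` pairs. Slope = -dx/kBT, intercept = ln tau0; standard
    errors are propagated from the linear fit. ``weighted=False`` gives the
    unweighted ordinary-least-squares variant for sensitivity analysis.
    """
    forces, taus, ns = [], [], []
    entries = []
    for force, item in lifetimes:
        if isinstance(item, LifetimeEstimate):
            tau, n = item.tau, item.n
        else:
            tau, n = float(item), 1
        if tau <= 0:
            raise ValueError("lifetimes must be strictly positive")
        forces.append(float(force))
        taus.append(tau)
        ns.append(n)
        entries.append((float(force), item))
    forces = np.asarray(forces)
    if np.unique(forces).size < 2:
        raise ValueError("need lifetimes at >= 2 distinct forces")
    y = np.log(np.asarray(taus))
    w = np.asarray(ns, dtype=float) if weighted else np.ones_like(forces)

    X = np.column_stack([np.ones_like(forces), forces])
    xtw = X.T * w
    cov = np.linalg.inv(xtw @ X)  # Var[ln tau_hat] = 1/n: no residual scaling
    beta = cov @ (xtw @ y)
    intercept, slope = beta
    kbt = kbt_pn_nm(temperature_K)
    tau0 = float(np.exp(intercept))
    delta_x = float(-slope * kbt)
    se_int = float(np.sqrt(cov[0, 0]))
    se_slope = float(np.sqrt(cov[1, 1]))
    return BellFit(
        tau0=tau0,
        delta_x_nm=delta_x,
        se_tau0=tau0 * se_int,
        se_delta_x_nm=se_slope * kbt,
        temperature_K=temperature_K,
        lifetimes=tuple(entries),
        cov_ln=cov,
    )


def correlate_jump_with_sigma(table: pd.DataFrame):
    """Pearson correlation of loop-jump size with sigma_z reduction.

    Uses tethers where both the loop jump and the fluctuation reduction were
    measured; returns ``(r, p, n)``.
    """
    d = table[["loop_jump_nm", "dsigma_nm"]].dropna()
    if len(d) < 3:
        raise ValueError("need >= 3 paired observations")
    r, p = stats.pearsonr(d["loop_jump_nm"], d["dsigma_nm"])
    return float(r), float(p), int(len(d))
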