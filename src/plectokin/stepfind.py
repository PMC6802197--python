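"""Unbiased decomposition of extension traces into plateaus and steps.

The step finder is an iterative chi-square fitter: at every round the single
step location that maximally reduces the squared residuals of a
piecewise-constant fit is added (ties broken toward the earliest sample).
The number of steps to accept is chosen by a counter-fit: steps deliberately
placed at the midpoints of the fitted plateaus. Where real steps exist the
counter-fit is much worse than the fit, so the ratio

    S(k) = SSE_counterfit(k) / SSE_fit(k)

peaks at the true step count; the candidate set is accepted when the peak
ratio reaches the acceptance threshold (default 1.3).

Samples recorded while the magnets are being rotated carry commanded, not
spontaneous, extension changes; runs of changing ``magnet_turns`` split the
trace into independently fitted segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trace import Trace

__all__ = ["StepFit", "SigmaSeries", "find_steps", "rolling_sigma", "detrended_step_sizes"]


@dataclass
class StepFit:
    """Piecewise-constant decomposition of a trace.

    ``dwell_times_s`` are the first differences of ``step_times_s`` (within a
    segment); plateau count equals step count + 1 in every segment.
    """

    plateau_levels_nm: np.ndarray
    step_times_s: np.ndarray
    step_sizes_nm: np.ndarray
    dwell_times_s: np.ndarray
    quality: np.ndarray  # residual-variance ratio per accepted step
    step_indices: np.ndarray
    segment_bounds: list  # [(lo, hi)] sample ranges fitted independently
    counterfit_ratio: float = np.inf
    warning: str | None = None
    sampling_rate_hz: float = float("nan")

    @property
    def n_steps(self) -> int:
        return self.step_times_s.size

    def reconstruction(self, n_samples: int | None = None) -> np.ndarray:
        """Piecewise-constant model trace implied by the fit."""
        if n_samples is None:
            n_samples = self.segment_bounds[-1][1] if self.segment_bounds else 0
        out = np.empty(n_samples, dtype=float)
        lvl = 0
        for lo, hi in self.segment_bounds:
            bounds = [lo] + [int(i) for i in self.step_indices if lo < i < hi] + [hi]
            for a, b in zip(bounds[:-1], bounds[1:]):
                out[a:b] = self.plateau_levels_nm[lvl]
                lvl += 1
        return out

    def to_frame(self) -> pd.DataFrame:
        dw = np.concatenate([[np.nan], self.dwell_times_s]) if self.n_steps else np.array([])
        lvl = self.plateau_levels_nm[1 : self.n_steps + 1] if self.n_steps else np.array([])
        return pd.DataFrame(
            {
                "step_time_s": self.step_times_s,
                "step_size_nm": self.step_sizes_nm,
                "dwell_s": dw[: self.n_steps],
                "level_nm": lvl,
            }
        )


@dataclass
class SigmaSeries:
    """Sliding-window SD of the extension signal (sigma_z)."""

    time_s: np.ndarray
    sigma_z_nm: np.ndarray
    window_s: float = 0.5


def _sse(c1: np.ndarray, c2: np.ndarray, lo: int, hi: int) -> float:
    """Squared residuals of a constant fit to samples [lo, hi)."""
    n = hi - lo
    if n <= 0:
        return 0.0
    s = c1[hi] - c1[lo]
    return float(c2[hi] - c2[lo] - s * s / n)


def _best_split(c1, c2, lo, hi, min_len):
    """Best single-step placement inside [lo, hi); returns (index, gain)."""
    cand = np.arange(lo + min_len, hi - min_len + 1)
    if cand.size == 0:
        return None
    n_l = cand - lo
    n_r = hi - cand
    s_l = c1[cand] - c1[lo]
    s_r = c1[hi] - c1[cand]
    explained = s_l * s_l / n_l + s_r * s_r / n_r
    j = int(np.argmax(explained))  # argmax takes the earliest index on ties
    s = c1[hi] - c1[lo]
    gain = float(explained[j] - s * s / (hi - lo))
    return int(cand[j]), gain


def _piecewise_sse(c1, c2, bounds) -> float:
    return sum(_sse(c1, c2, a, b) for a, b in zip(bounds[:-1], bounds[1:]))


def _noise_sd(y: np.ndarray) -> float:
    """Robust per-sample noise SD from first differences (steps are sparse)."""
    d = np.diff(y)
    if d.size == 0:
        return 0.0
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / np.sqrt(2.0))


def _fit_segment(y: np.ndarray, lo: int, hi: int, min_len: int,
                 acceptance_threshold: float, max_steps: int | None):
    """Greedy step placement + counter-fit model selection on y[lo:hi)."""
    c1 = np.concatenate([[0.0], np.cumsum(y)])
    c2 = np.concatenate([[0.0], np.cumsum(y * y)])
    n = hi - lo
    cap = n // (2 * min_len)
    if max_steps is not None:
        cap = min(cap, max_steps)

    total_sse = _sse(c1, c2, lo, hi)
    eps = 1e-12 * max(total_sse, 1.0)
    # an optimally placed split of pure noise gains ~sigma^2 * 2 ln(n);
    # growing past that level only chases noise
    sigma2 = _noise_sd(y[lo:hi]) ** 2
    min_gain = max(eps, 2.0 * sigma2 * np.log(max(n, 2)))

    # plateaus: dict boundary-tuple -> cached best split
    plateaus = {(lo, hi): _best_split(c1, c2, lo, hi, min_len)}
    added: list[int] = []
    fit_sse = [total_sse]
    while len(added) < cap:
        best = None
        for span, split in plateaus.items():
            if split is None:
                continue
            if best is None or split[1] > best[2] or (
                split[1] == best[2] and split[0] < best[1]
            ):
                best = (span, split[0], split[1])
        if best is None or best[2] <= min_gain:
            break
        (a, b), idx, gain = best
        del plateaus[(a, b)]
        plateaus[(a, idx)] = _best_split(c1, c2, a, idx, min_len)
        plateaus[(idx, b)] = _best_split(c1, c2, idx, b, min_len)
        added.append(idx)
        fit_sse.append(fit_sse[-1] - gain)

    if not added:
        return [], np.inf

    # counter-fit ratio S(k) = SSE(steps at plateau midpoints) / SSE(fit);
    # its peak certifies genuine step structure in the candidate set
    best_ratio = -np.inf
    for k in range(1, len(added) + 1):
        steps_k = sorted(added[:k])
        bounds = [lo] + steps_k + [hi]
        counter = [lo] + [(a + b) // 2 for a, b in zip(bounds[:-1], bounds[1:])] + [hi]
        counter = sorted(set(counter))
        sse_fit = fit_sse[k]
        if sse_fit <= eps:  # perfect staircase
            best_ratio = np.inf
            break
        best_ratio = max(best_ratio, _piecewise_sse(c1, c2, counter) / sse_fit)

    if best_ratio < acceptance_threshold:
        return [], best_ratio

    # per-step quality control: iteratively drop the weakest step whose
    # flanking-plateau residual-variance ratio falls below the threshold
    steps = sorted(added)
    while steps:
        bounds = [lo] + steps + [hi]
        ratios = []
        for j in range(1, len(bounds) - 1):
            with_step = _sse(c1, c2, bounds[j - 1], bounds[j]) + _sse(
                c1, c2, bounds[j], bounds[j + 1]
            )
            without = _sse(c1, c2, bounds[j - 1], bounds[j + 1])
            ratios.append(without / with_step if with_step > eps else np.inf)
        worst = int(np.argmin(ratios))
        if ratios[worst] >= acceptance_threshold:
            break
        del steps[worst]
    return steps, best_ratio


def find_steps(
    trace: Trace,
    min_dwell_s: float | None = None,
    acceptance_threshold: float = 1.3,
    max_steps: int | None = 2000,
) -> StepFit:
    """Decompose a trace into plateaus separated by discrete steps.

    Parameters
    ----------
    trace : Trace
        Uniformly sampled extension trace.
    min_dwell_s : float, optional
        Minimum plateau duration; default 3 samples.
    acceptance_threshold : float
        Minimum counter-fit/fit residual ratio for accepting any steps.
    max_steps : int, optional
        Cap on placed candidate steps per segment (guards run time on very
        long traces); ``None`` removes the cap.
    """
    y = np.asarray(trace.extension_nm, dtype=float)
    n = y.size
    if n == 0:
        raise ValueError("empty trace")
    fs = trace.sampling_rate_hz if n >= 2 else 1.0
    min_len = 3 if min_dwell_s is None else max(1, int(round(min_dwell_s * fs)))

    # segments of constant commanded magnet turns (rotation samples masked)
    rotating = np.concatenate([[False], np.diff(trace.magnet_turns) != 0])
    segments = []
    start = None
    for i in range(n):
        if not rotating[i]:
            if start is None:
                start = i
        else:
            if start is not None and i - start >= 2:
                segments.append((start, i))
            start = None
    if start is not None and n - start >= 2:
        segments.append((start, n))
    if not segments:
        segments = [(0, n)]

    warning = None
    all_steps: list[int] = []
    ratio = -np.inf
    kept_segments = []
    for lo, hi in segments:
        if hi - lo < 2 * min_len:
            warning = "segment shorter than twice the minimum dwell; zero-step fit"
            kept_segments.append((lo, hi))
            continue
        steps, r = _fit_segment(y, lo, hi, min_len, acceptance_threshold, max_steps)
        all_steps.extend(steps)
        ratio = max(ratio, r)
        kept_segments.append((lo, hi))

    all_steps = sorted(all_steps)
    levels, sizes, times, quality = [], [], [], []
    for lo, hi in kept_segments:
        seg_steps = [s for s in all_steps if lo < s < hi]
        bounds = [lo] + seg_steps + [hi]
        seg_levels = [float(np.mean(y[a:b])) for a, b in zip(bounds[:-1], bounds[1:])]
        levels.extend(seg_levels)
        for j, s in enumerate(seg_steps):
            sizes.append(seg_levels[j + 1] - seg_levels[j])
            times.append(trace.time_s[s])
            # local quality: residual variance without the step / with it
            a, b = bounds[j], bounds[j + 2]
            left, right = y[a:s], y[s:b]
            sse_with = float(np.sum((left - left.mean()) ** 2) + np.sum((right - right.mean()) ** 2))
            flat = y[a:b]
            sse_without = float(np.sum((flat - flat.mean()) ** 2))
            quality.append(sse_without / sse_with if sse_with > 0 else np.inf)

    times_arr = np.asarray(times, dtype=float)
    return StepFit(
        plateau_levels_nm=np.asarray(levels, dtype=float),
        step_times_s=times_arr,
        step_sizes_nm=np.asarray(sizes, dtype=float),
        dwell_times_s=np.diff(times_arr),
        quality=np.asarray(quality, dtype=float),
        step_indices=np.asarray(all_steps, dtype=int),
        segment_bounds=kept_segments,
        counterfit_ratio=float(ratio),
        warning=warning,
        sampling_rate_hz=fs,
    )


def rolling_sigma(trace: Trace, window_s: float = 0.5) -> SigmaSeries:
    """Sample SD of extension in a centered moving window (sigma_z).

    Edge windows are truncated. A constant trace gives zeros everywhere.
    """
    n = len(trace)
    fs = trace.sampling_rate_hz
    win = int(round(window_s * fs))
    if win < 2:
        raise ValueError("window must span at least 2 samples")
    if win > n:
        raise ValueError("window longer than trace")
    s = (
        pd.Series(trace.extension_nm)
        .rolling(window=win, center=True, min_periods=2)
        .std()
    )
    sig = s.bfill().ffill().to_numpy()
    return SigmaSeries(time_s=trace.time_s.copy(), sigma_z_nm=sig, window_s=window_s)


def detrended_step_sizes(stepfit: StepFit, direction: str = "both") -> np.ndarray:
    """Step magnitudes |dz| filtered by direction for distribution fitting."""
    sizes = stepfit.step_sizes_nm
    if direction == "up":
        sizes = sizes[sizes > 0]
    elif direction == "down":
        sizes = sizes[sizes < 0]
    elif direction != "both":
        raise ValueError("direction must be 'up', 'down' or 'both'")
    return np.abs(sizes)
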