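"""Statistics on AFM-derived particle measurements.

Topology of imaged plasmids is classified by the number of DNA self-crossings
(open-circular molecules cross themselves rarely, plectonemic supercoiled ones
often; the single-molecule decision threshold is n <= 6). Category fractions
carry Poisson counting errors sqrt(k)/n_tot, proportions are compared with a
two-proportion test (Fisher's exact test when expected cells are small), and
DNA entry/exit angles at intasomes are summarized with circular statistics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "classify_topology",
    "fraction_with_counting_error",
    "compare_fractions",
    "angle_statistics",
    "classification_error_rates",
]

OPEN_CIRCULAR = "open_circular"
COVALENTLY_CLOSED = "covalently_closed"
CROSSING_THRESHOLD = 6


def classify_topology(n_crossings) -> str | np.ndarray:
    """Assign topology from the self-crossing count: OC for n <= 6, else CC."""
    arr = np.asarray(n_crossings)
    if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.number):
        raise ValueError("crossing counts must be non-negative")
    out = np.where(arr <= CROSSING_THRESHOLD, OPEN_CIRCULAR, COVALENTLY_CLOSED)
    return out.item() if np.isscalar(n_crossings) or arr.ndim == 0 else out


def fraction_with_counting_error(k: int, n_tot: int) -> tuple[float, float]:
    """Category fraction k/n_tot with Poisson counting error sqrt(k)/n_tot."""
    if n_tot < 1:
        raise ValueError("n_tot must be >= 1")
    if not 0 <= k <= n_tot:
        raise ValueError("k must lie in [0, n_tot]")
    return k / n_tot, np.sqrt(k) / n_tot


def compare_fractions(k1: int, n1: int, k2: int, n2: int) -> float:
    """p-value for a difference between two proportions.

    Uses the pooled two-proportion z-test; falls back to Fisher's exact test
    whenever any expected cell count is below 5 (and for any degenerate
    table), so the result is never NaN.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1:
            raise ValueError("group sizes must be >= 1")
        if not 0 <= k <= n:
            raise ValueError("counts must lie in [0, n]")
    pooled = (k1 + k2) / (n1 + n2)
    expected = [n1 * pooled, n1 * (1 - pooled), n2 * pooled, n2 * (1 - pooled)]
    if min(expected) < 5 or pooled in (0.0, 1.0):
        table = [[k1, n1 - k1], [k2, n2 - k2]]
        return float(stats.fisher_exact(table)[1])
    z = (k1 / n1 - k2 / n2) / np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    return float(2 * stats.norm.sf(abs(z)))


def angle_statistics(
    angles_deg, mode_labels=None, fold_to_axis: bool = False
) -> dict:
    """Circular statistics of DNA entry/exit angles at the intasome.

    Vector-mean direction and circular SD (degrees); invariant to adding 360
    to any observation. ``fold_to_axis=True`` folds angles to [0, 180)
    relative to the (orientation-free) intasome long axis before averaging.
    With ``mode_labels`` (e.g. apical/longitudinal), per-mode occupancy
    fractions with sqrt(k)/n_tot errors are included.
    """
    a = np.asarray(angles_deg, dtype=float) % 360.0
    if a.size == 0:
        raise ValueError("empty angle sample")
    period = 360.0
    if fold_to_axis:
        a = a % 180.0
        period = 180.0
    mean = float(stats.circmean(a, high=period, low=0.0))
    csd = float(stats.circstd(a, high=period, low=0.0))
    out = {"mean_deg": mean, "circ_sd_deg": csd, "n": int(a.size)}
    if mode_labels is not None:
        labels = np.asarray(mode_labels)
        if labels.size != a.size:
            raise ValueError("mode_labels length mismatch")
        occupancy = {}
        for mode in np.unique(labels):
            k = int(np.sum(labels == mode))
            occupancy[str(mode)] = fraction_with_counting_error(k, a.size)
        out["occupancy"] = occupancy
    return out


def classification_error_rates(table: pd.DataFrame) -> pd.DataFrame:
    """Confusion matrix of the crossing-number classifier on labeled data.

    ``table`` needs ``n_crossings`` and ground-truth ``class_label`` columns;
    returns a matrix indexed by truth with predicted-class columns plus a
    per-class ``error_rate``.
    """
    if table.empty:
        raise ValueError("empty particle table")
    if "class_label" not in table.columns:
        raise ValueError("table lacks ground-truth class labels")
    pred = classify_topology(table["n_crossings"].to_numpy())
    classes = [OPEN_CIRCULAR, COVALENTLY_CLOSED]
    mat = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for truth, p in zip(table["class_label"], np.atleast_1d(pred)):
        mat.loc[truth, p] += 1
    totals = mat.sum(axis=1)
    errors = 1.0 - np.diag(mat.to_numpy()) / totals.replace(0, np.nan).to_numpy()
    out = mat.copy()
    out["error_rate"] = errors
    return out
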