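"""Accuracy measures for expression estimates: relative error, error
fraction EF_tau, median percent error (MPE) and r^2."""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

#: Table-style true-frequency bins for grouped error summaries.
DEFAULT_BINS = (0.0, 1e-6, 1e-5, 1e-4, 1e-3, 1e-2)


def relative_error(estimate: float, truth: float) -> float:
    """|estimate - truth| / truth, with the conventions 0 for 0/0 and
    infinity when the truth is 0 but the estimate is not."""
    if estimate < 0 or truth < 0:
        raise ValueError("frequencies must be non-negative")
    if truth == 0:
        return 0.0 if estimate == 0 else math.inf
    return abs(estimate - truth) / truth


def relative_errors(estimates: Sequence[float], truths: Sequence[float]) -> np.ndarray:
    est = np.asarray(estimates, dtype=float)
    tru = np.asarray(truths, dtype=float)
    if est.shape != tru.shape:
        raise ValueError("length mismatch")
    with np.errstate(divide="ignore", invalid="ignore"):
        err = np.abs(est - tru) / tru
    err[(tru == 0) & (est == 0)] = 0.0
    err[(tru == 0) & (est != 0)] = np.inf
    return err


def error_fraction(errors: Sequence[float], tau: float) -> float:
    """EF_tau: percentage of entries with relative error >= tau."""
    errors = np.asarray(errors, dtype=float)
    if errors.size == 0:
        raise ValueError("empty error list")
    if tau < 0:
        raise ValueError("tau must be >= 0")
    return float(100.0 * np.mean(errors >= tau))


def median_percent_error(errors: Sequence[float]) -> float:
    """MPE: the threshold tau at which EF_tau = 50%, i.e. the median relative
    error expressed in percent. Even-length inputs use the lower median so
    that EF at the returned tau is still >= 50%."""
    errors = np.sort(np.asarray(errors, dtype=float))
    if errors.size == 0:
        raise ValueError("empty error list")
    lower_median = errors[(errors.size - 1) // 2]
    return float(lower_median * 100.0)


def r_squared(estimates: Sequence[float], truths: Sequence[float]) -> float:
    """Squared Pearson correlation between estimates and truths."""
    est = np.asarray(estimates, dtype=float)
    tru = np.asarray(truths, dtype=float)
    if est.size != tru.size or est.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    if np.var(tru) == 0 or np.var(est) == 0:
        raise ValueError("zero variance input")
    r = np.corrcoef(est, tru)[0, 1]
    return float(r * r)


def r_squared_residual(estimates: Sequence[float], truths: Sequence[float]) -> float:
    """Alternative definition 1 - SS_res / SS_tot (not scale-invariant)."""
    est = np.asarray(estimates, dtype=float)
    tru = np.asarray(truths, dtype=float)
    ss_tot = float(np.sum((tru - tru.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("zero variance input")
    return 1.0 - float(np.sum((tru - est) ** 2)) / ss_tot


def error_summary(
    estimates: Sequence[float],
    truths: Sequence[float],
    thresholds: Sequence[float] = (0.05, 0.1, 0.15, 0.2, 0.5, 1.0),
    bins: Sequence[float] = DEFAULT_BINS,
) -> pd.DataFrame:
    """Per-bin MPE and EF_tau table, binned by true frequency.

    Bins follow the convention {0}, (0, b1], (b1, b2], ..., (b_last, 1].
    """
    est = np.asarray(estimates, dtype=float)
    tru = np.asarray(truths, dtype=float)
    errs = relative_errors(est, tru)
    edges = list(bins) + [np.inf]
    groups: list[tuple[str, np.ndarray]] = [("0", tru == 0.0)]
    for lo, hi in zip(edges[:-1], edges[1:]):
        label = f"({lo:g},{'inf' if np.isinf(hi) else f'{hi:g}'}]"
        groups.append((label, (tru > lo) & (tru <= hi)))
    groups.append(("all", np.ones(tru.size, dtype=bool)))
    rows = []
    for label, mask in groups:
        if not mask.any():
            continue
        sub = errs[mask]
        row = {"bin": label, "n": int(mask.sum()), "mpe": median_percent_error(sub)}
        for tau in thresholds:
            row[f"ef_{tau:g}"] = error_fraction(sub, tau)
        rows.append(row)
    return pd.DataFrame(rows)
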