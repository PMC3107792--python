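"""Expectation-maximization over read classes, one compatibility component
at a time.

The E-step allocates each class's multiplicity across isoforms in proportion
to f(j) * w_{c,j}; the M-step converts expected counts to length-normalized
coverages c(j) = n(j) / l_eff(j) and renormalizes. Components are solved
independently and assembled into a global frequency vector at the end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from isoem.read_classes import Component, ReadClass

logger = logging.getLogger(__name__)

DEFAULT_TOL = 1e-8
DEFAULT_MAX_ITER = 10_000


@dataclass
class ComponentProblem:
    """One compatibility component ready for EM: isoform ids, their
    effective lengths, and the read classes touching them."""

    isoforms: list[str]
    eff_lengths: np.ndarray
    classes: list[ReadClass]

    def __post_init__(self) -> None:
        self.eff_lengths = np.asarray(self.eff_lengths, dtype=float)
        if np.any(self.eff_lengths <= 0):
            raise ValueError("effective lengths must be positive")
        idx = {iso: i for i, iso in enumerate(self.isoforms)}
        rows, cols, vals, mult = [], [], [], []
        for ci, rc in enumerate(self.classes):
            mult.append(rc.multiplicity)
            for iso, w in rc.entries:
                rows.append(ci)
                cols.append(idx[iso])
                vals.append(w)
        self._rows = np.asarray(rows, dtype=np.intp)
        self._cols = np.asarray(cols, dtype=np.intp)
        self._vals = np.asarray(vals, dtype=float)
        self._mult = np.asarray(mult, dtype=float)

    @property
    def total_multiplicity(self) -> float:
        return float(self._mult.sum())


@dataclass
class FrequencyEstimate:
    """EM output: frequencies f(j), expected counts n(j) and normalized
    coverages c(j), indexed like ``isoforms``."""

    isoforms: list[str]
    f: np.ndarray
    n: np.ndarray
    c: np.ndarray
    iterations: int
    converged: bool
    log_likelihoods: list[float] = field(default_factory=list)


def e_step(problem: ComponentProblem, f: np.ndarray) -> np.ndarray:
    """Expected counts n(j) given frequencies f: each class's multiplicity is
    split across isoforms proportionally to f(j) * w_{c,j}; classes whose
    denominator is zero are skipped."""
    fw = f[problem._cols] * problem._vals
    denom = np.bincount(problem._rows, weights=fw, minlength=len(problem._mult))
    safe = denom[problem._rows]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(safe > 0, fw / safe, 0.0)
    contrib = frac * problem._mult[problem._rows]
    return np.bincount(problem._cols, weights=contrib, minlength=len(problem.isoforms))


def m_step(n: np.ndarray, eff_lengths: np.ndarray) -> np.ndarray:
    """New frequencies from expected counts: f(j) proportional to the
    length-normalized coverage c(j) = n(j) / l_eff(j)."""
    c = n / eff_lengths
    total = c.sum()
    if total <= 0:
        logger.warning("all coverages zero; falling back to uniform frequencies")
        return np.full(len(n), 1.0 / len(n))
    return c / total


def log_likelihood(problem: ComponentProblem, f: np.ndarray) -> float:
    """Observed-data log-likelihood of the class multiplicities under f:
    sum_c m_c * log(sum_j f(j) w_{c,j} / sum_j f(j) l_eff(j))."""
    fw = f[problem._cols] * problem._vals
    denom = np.bincount(problem._rows, weights=fw, minlength=len(problem._mult))
    norm = float(np.dot(f, problem.eff_lengths))
    if norm <= 0:
        return -np.inf
    with np.errstate(divide="ignore"):
        terms = np.log(denom) - np.log(norm)
    mask = problem._mult > 0
    return float(np.dot(problem._mult[mask], terms[mask]))


def run_component_em(
    problem: ComponentProblem,
    init: str = "uniform",
    seed: int | None = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    track_likelihood: bool = False,
) -> FrequencyEstimate:
    """Alternate E/M steps until the largest frequency change drops below
    ``tol`` or ``max_iter`` is reached."""
    n_iso = len(problem.isoforms)
    if init == "uniform":
        f = np.full(n_iso, 1.0 / n_iso)
    elif init == "random":
        rng = np.random.default_rng(seed)
        f = rng.random(n_iso) + 1e-6
        f /= f.sum()
    else:
        raise ValueError(f"unknown init {init!r}")

    lls: list[float] = []
    converged = False
    iterations = 0
    n = np.zeros(n_iso)
    for iterations in range(1, max_iter + 1):
        n = e_step(problem, f)
        f_new = m_step(n, problem.eff_lengths)
        if track_likelihood:
            lls.append(log_likelihood(problem, f_new))
        delta = float(np.max(np.abs(f_new - f)))
        f = f_new
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning(
            "EM did not converge in %d iterations (component of %d isoforms)",
            max_iter,
            n_iso,
        )
    n = e_step(problem, f)  # counts consistent with final f
    c = n / problem.eff_lengths
    return FrequencyEstimate(
        isoforms=list(problem.isoforms),
        f=f,
        n=n,
        c=c,
        iterations=iterations,
        converged=converged,
        log_likelihoods=lls,
    )


def make_problems(
    components: Sequence[Component],
    eff_length_of: Mapping[str, float],
) -> list[ComponentProblem]:
    return [
        ComponentProblem(
            isoforms=comp.isoforms,
            eff_lengths=np.array([eff_length_of[i] for i in comp.isoforms]),
            classes=comp.classes,
        )
        for comp in components
    ]


def combine_components(
    results: Sequence[FrequencyEstimate],
    all_isoforms: Sequence[str],
    eff_length_of: Mapping[str, float],
) -> FrequencyEstimate:
    """Assemble per-component estimates into one global frequency vector.

    Global coverages are the per-component coverages c(j) = n(j)/l_eff(j);
    frequencies renormalize them over all isoforms. Isoforms absent from
    every component get frequency 0.
    """
    idx = {iso: i for i, iso in enumerate(all_isoforms)}
    n = np.zeros(len(all_isoforms))
    for res in results:
        for iso, nj in zip(res.isoforms, res.n):
            n[idx[iso]] += nj
    lengths = np.array([eff_length_of[i] for i in all_isoforms], dtype=float)
    c = np.divide(n, lengths, out=np.zeros_like(n), where=lengths > 0)
    total = c.sum()
    f = c / total if total > 0 else np.zeros(len(all_isoforms))
    iterations = max((r.iterations for r in results), default=0)
    return FrequencyEstimate(
        isoforms=list(all_isoforms),
        f=f,
        n=n,
        c=c,
        iterations=iterations,
        converged=all(r.converged for r in results),
    )


def gene_expression(
    estimate: FrequencyEstimate, clusters: Mapping[str, Sequence[str]]
) -> dict[str, float]:
    """Gene expression as the sum of member-isoform frequencies."""
    idx = {iso: i for i, iso in enumerate(estimate.isoforms)}
    out = {}
    for gene, members in clusters.items():
        out[gene] = float(sum(estimate.f[idx[m]] for m in members if m in idx))
    return out


def grid_search_frequencies(
    problem: ComponentProblem, step: float = 1e-3
) -> np.ndarray:
    """Exhaustive simplex grid search of the likelihood for components of at
    most 3 isoforms; independent oracle for the EM path."""
    k = len(problem.isoforms)
    if k == 1:
        return np.array([1.0])
    ticks = np.arange(0.0, 1.0 + step / 2, step)
    if k == 2:
        cand = np.column_stack([ticks, 1.0 - ticks])
    elif k == 3:
        a, b = np.meshgrid(ticks, ticks, indexing="ij")
        a, b = a.ravel(), b.ravel()
        keep = a + b <= 1.0 + 1e-12
        a, b = a[keep], b[keep]
        cand = np.column_stack([a, b, 1.0 - a - b])
    else:
        raise ValueError("grid search supports at most 3 isoforms")
    cand = np.clip(cand, 0.0, 1.0)

    n_classes = len(problem._mult)
    W = np.zeros((n_classes, k))
    W[problem._rows, problem._cols] = problem._vals
    m = problem._mult

    best_f, best_ll = None, -np.inf
    for lo in range(0, len(cand), 20_000):
        F = cand[lo : lo + 20_000]
        denom = F @ W.T  # (chunk, classes)
        norm = F @ problem.eff_lengths
        with np.errstate(divide="ignore", invalid="ignore"):
            lls = (np.log(denom) @ m) - m.sum() * np.log(norm)
        lls = np.where(np.isnan(lls), -np.inf, lls)
        i = int(np.argmax(lls))
        if lls[i] > best_ll:
            best_ll, best_f = float(lls[i]), F[i]
    assert best_f is not None
    return best_f
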