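"""Discrete fragment-length distribution and insert-size-aware effective lengths."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class FragmentLengthDist:
    """Discrete distribution p(k) of sequenced fragment lengths.

    Support is the integer range ``[k_min, k_max]``; ``pmf[i]`` is the
    probability of length ``k_min + i``.
    """

    k_min: int
    k_max: int
    pmf: np.ndarray
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.k_min < 1 or self.k_max < self.k_min:
            raise ValueError("invalid support")
        if len(self.pmf) != self.k_max - self.k_min + 1:
            raise ValueError("pmf length does not match support")
        if np.any(self.pmf < 0) or abs(self.pmf.sum() - 1.0) > 1e-12:
            raise ValueError("pmf must be non-negative and sum to 1")
        object.__setattr__(self, "_cdf", np.cumsum(self.pmf))

    def p(self, k: int) -> float:
        """p(k): probability of a fragment of length exactly k."""
        if k < self.k_min or k > self.k_max:
            return 0.0
        return float(self.pmf[k - self.k_min])

    def cdf(self, u: int) -> float:
        """P(K <= u)."""
        if u < self.k_min:
            return 0.0
        if u >= self.k_max:
            return 1.0
        return float(self._cdf[u - self.k_min])

    @property
    def lengths(self) -> np.ndarray:
        return np.arange(self.k_min, self.k_max + 1)


def make_length_dist(
    mean: float,
    sd: float,
    k_min: int | None = None,
    k_max: int | None = None,
) -> FragmentLengthDist:
    """Discretized, renormalized normal distribution over integer lengths.

    Default support is ``[mean - 4 sd, mean + 4 sd]`` clipped at 1. ``sd=0``
    yields a point mass at ``round(mean)``.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if k_min is None:
        k_min = max(1, int(np.floor(mean - 4 * sd)))
    if k_max is None:
        k_max = max(k_min, int(np.ceil(mean + 4 * sd)))
    if k_min < 1 or k_max < k_min:
        raise ValueError("invalid support")
    n = k_max - k_min + 1
    if sd == 0:
        k0 = int(round(mean))
        if not (k_min <= k0 <= k_max):
            raise ValueError("point mass outside support")
        pmf = np.zeros(n)
        pmf[k0 - k_min] = 1.0
    else:
        ks = np.arange(k_min, k_max + 1, dtype=float)
        mass = stats.norm.cdf(ks + 0.5, mean, sd) - stats.norm.cdf(ks - 0.5, mean, sd)
        total = mass.sum()
        if total <= 0:
            raise ValueError("no probability mass on support")
        pmf = mass / total
    m = float(np.sum(pmf * np.arange(k_min, k_max + 1)))
    v = float(np.sum(pmf * (np.arange(k_min, k_max + 1) - m) ** 2))
    return FragmentLengthDist(k_min=k_min, k_max=k_max, pmf=pmf, mean=m, sd=v**0.5)


def empirical_length_dist(lengths: np.ndarray, smooth: int = 1) -> FragmentLengthDist:
    """Estimate p(k) from observed fragment lengths (histogram, optionally
    smoothed with a centered moving average of width ``2*smooth + 1``)."""
    lengths = np.asarray(lengths, dtype=int)
    if lengths.size == 0:
        raise ValueError("no fragment lengths observed")
    k_min, k_max = int(lengths.min()), int(lengths.max())
    counts = np.bincount(lengths - k_min, minlength=k_max - k_min + 1).astype(float)
    if smooth > 0 and counts.size > 1:
        kernel = np.ones(2 * smooth + 1)
        counts = np.convolve(counts, kernel / kernel.sum(), mode="same")
    pmf = counts / counts.sum()
    m = float(np.sum(pmf * np.arange(k_min, k_max + 1)))
    v = float(np.sum(pmf * (np.arange(k_min, k_max + 1) - m) ** 2))
    return FragmentLengthDist(k_min=k_min, k_max=k_max, pmf=pmf, mean=m, sd=v**0.5)


def effective_length(dist: FragmentLengthDist, l: int) -> float:
    """Expected number of valid fragment start positions in a transcript of
    length ``l``: sum over k of p(k) * max(l - k + 1, 0)."""
    if l < 0:
        raise ValueError("length must be >= 0")
    valid = np.maximum(l - dist.lengths + 1, 0)
    return float(np.dot(dist.pmf, valid))


def approx_effective_length(l: int, mu: float) -> float:
    """Fast approximation l - mu + 1, valid for transcripts much longer than
    the mean fragment length. Callers must fall back to
    :func:`effective_length` when ``l <= mu``."""
    if l <= mu:
        raise ValueError("approximation requires l > mean fragment length")
    return l - mu + 1


def effective_lengths(
    dist: FragmentLengthDist,
    lengths: np.ndarray,
    fast: bool = False,
    fast_margin: int = 100,
) -> np.ndarray:
    """Vectorized effective lengths for an array of transcript lengths.

    With ``fast=True``, lengths at least ``mean + fast_margin`` use the
    l - mu + 1 approximation; shorter ones always use the exact sum.
    """
    lengths = np.asarray(lengths)
    out = np.empty(len(lengths), dtype=float)
    exact = np.ones(len(lengths), dtype=bool)
    if fast:
        big = lengths >= dist.mean + fast_margin
        out[big] = lengths[big] - dist.mean + 1
        exact = ~big
    if exact.any():
        # outer max over (lengths, support) — support is small
        sub = np.maximum(lengths[exact, None] - dist.lengths[None, :] + 1, 0)
        out[exact] = sub @ dist.pmf
    return out
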