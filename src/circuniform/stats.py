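"""Test statistics for circular uniformity.

Pure functions from a sample of angles to a scalar statistic; p-values live
in :mod:`circuniform.pvalues`.  Every statistic here rejects uniformity for
LARGE values, which is what the Monte-Carlo engine assumes.

Two calling surfaces are provided: per-sample functions on
:class:`~circuniform.core.CircularSample` returning :class:`StatisticValue`,
and vectorised ``*_batch`` kernels on (B, n) arrays of radians used by the
Monte-Carlo engine and the simulation study.  The batch kernels are the same
mathematics; equivalence is enforced by tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import TWO_PI, CircularSample

__all__ = [
    "StatisticValue",
    "rayleigh_statistic",
    "kuiper_statistic",
    "watson_statistic",
    "rao_statistic",
    "gini_statistic",
    "hr_statistic",
    "chisq_statistic",
    "STATISTICS",
]

# HR sine-term weight from the Hermans-Rasson/Pycke formulation
HR_COEF = 2.895


@dataclass(frozen=True)
class StatisticValue:
    """A named test statistic evaluated on a sample of size n."""

    name: str
    value: float
    n: int


# ---------------------------------------------------------------------------
# batch kernels: angles with shape (..., n), radians in [0, 2pi)
# ---------------------------------------------------------------------------

def _spacings_batch(angles: np.ndarray) -> np.ndarray:
    s = np.sort(angles, axis=-1)
    t = np.empty_like(s)
    t[..., :-1] = np.diff(s, axis=-1)
    t[..., -1] = TWO_PI - s[..., -1] + s[..., 0]
    return t


def rayleigh_batch(angles: np.ndarray) -> np.ndarray:
    """Mean resultant length R-bar in [0, 1]."""
    n = angles.shape[-1]
    return np.hypot(np.cos(angles).sum(-1), np.sin(angles).sum(-1)) / n


def rao_batch(angles: np.ndarray) -> np.ndarray:
    """Rao spacing statistic U = 0.5 * sum |T_i - 2pi/n|."""
    t = _spacings_batch(angles)
    n = t.shape[-1]
    return 0.5 * np.abs(t - TWO_PI / n).sum(-1)


def gini_batch(angles: np.ndarray) -> np.ndarray:
    """Gini spacing statistic G_n via the sorted-spacings identity.

    G_n = (2/(n(n-1))) sum_{i<j} 0.5 |n T_i - n T_j|
        = (1/(n-1)) sum_{i<j} |T_i - T_j|,
    and for sorted spacings sum_{i<j} |T_i - T_j| = sum_k (2k-1-n) T_(k).
    """
    t = np.sort(_spacings_batch(angles), axis=-1)
    n = t.shape[-1]
    k = np.arange(1, n + 1)
    return ((2 * k - 1 - n) * t).sum(-1) / (n - 1)


def hr_batch(angles: np.ndarray, chunk: int = 256) -> np.ndarray:
    """Hermans-Rasson statistic V, full n x n double sum including i = j.

    V = (1/n) sum_i sum_j ( ||phi_i - phi_j| - pi| - pi/2
                            - 2.895 (|sin(phi_i - phi_j)| - 2/pi) ).
    Batches are processed in chunks to bound the (chunk, n, n) temporaries.
    """
    a = np.atleast_2d(angles)
    out = np.empty(a.shape[0])
    n = a.shape[-1]
    for lo in range(0, a.shape[0], chunk):
        blk = a[lo : lo + chunk]
        d = blk[:, :, None] - blk[:, None, :]
        term = (
            np.abs(np.abs(d) - np.pi)
            - np.pi / 2
            - HR_COEF * (np.abs(np.sin(d)) - 2 / np.pi)
        )
        out[lo : lo + chunk] = term.sum((-1, -2)) / n
    return out.reshape(angles.shape[:-1])


def kuiper_batch(angles: np.ndarray) -> np.ndarray:
    """Kuiper statistic V_n = sqrt(n) (D+ + D-) on u_i = phi_(i)/(2pi)."""
    n = angles.shape[-1]
    u = np.sort(angles, axis=-1) / TWO_PI
    i = np.arange(1, n + 1)
    dplus = (i / n - u).max(-1)
    dminus = (u - (i - 1) / n).max(-1)
    return np.sqrt(n) * (dplus + dminus)


def watson_batch(angles: np.ndarray) -> np.ndarray:
    """Watson statistic U^2 = sum (u_i - (2i-1)/(2n))^2 - n (u-bar - 1/2)^2 + 1/(12n)."""
    n = angles.shape[-1]
    u = np.sort(angles, axis=-1) / TWO_PI
    i = np.arange(1, n + 1)
    ubar = u.mean(-1)
    return ((u - (2 * i - 1) / (2 * n)) ** 2).sum(-1) - n * (ubar - 0.5) ** 2 + 1 / (12 * n)


def chisq_batch(angles: np.ndarray, m: int) -> np.ndarray:
    """Pearson X^2 over all m bins (empty bins included), expected n/m."""
    a = np.atleast_2d(angles)
    n = a.shape[-1]
    k = (np.floor(a / (TWO_PI / m) + 0.5).astype(np.int64)) % m
    counts = np.zeros((a.shape[0], m))
    rows = np.repeat(np.arange(a.shape[0]), n)
    np.add.at(counts, (rows, k.ravel()), 1.0)
    e = n / m
    x2 = ((counts - e) ** 2 / e).sum(-1)
    return x2.reshape(angles.shape[:-1])


BATCH_KERNELS = {
    "rayleigh": rayleigh_batch,
    "kuiper": kuiper_batch,
    "watson": watson_batch,
    "rao": rao_batch,
    "gini": gini_batch,
    "hr": hr_batch,
}

STATISTICS = ("rayleigh", "kuiper", "watson", "rao", "gini", "hr", "chisq")


# ---------------------------------------------------------------------------
# per-sample surface
# ---------------------------------------------------------------------------

def _require(sample: CircularSample, n_min: int) -> None:
    if sample.n < n_min:
        raise ValueError("need at least two points")


def rayleigh_statistic(sample: CircularSample) -> StatisticValue:
    """Mean resultant length R-bar: 0 for balanced data, 1 for identical angles."""
    return StatisticValue("rayleigh", float(rayleigh_batch(sample.angles)), sample.n)


def kuiper_statistic(sample: CircularSample) -> StatisticValue:
    """Kuiper's rotation-invariant V_n (classical sqrt(n)-scaled form)."""
    _require(sample, 2)
    return StatisticValue("kuiper", float(kuiper_batch(sample.angles)), sample.n)


def watson_statistic(sample: CircularSample) -> StatisticValue:
    """Watson's U^2, origin-invariant Cramer-von Mises analogue."""
    _require(sample, 2)
    return StatisticValue("watson", float(watson_batch(sample.angles)), sample.n)


def rao_statistic(sample: CircularSample) -> StatisticValue:
    """Rao spacing U: half the L1 distance of the spacings from 2pi/n each."""
    _require(sample, 2)
    return StatisticValue("rao", float(rao_batch(sample.angles)), sample.n)


def gini_statistic(sample: CircularSample, brute_force: bool = False) -> StatisticValue:
    """Gini mean-difference of scaled spacings.

    ``brute_force=True`` evaluates the literal O(n^2) double sum
    (2/(n(n-1))) sum_{i<j} 0.5 |n T_i - n T_j|; the default sorted-spacings
    path is algebraically identical and must match it to 1e-12.
    """
    _require(sample, 2)
    if brute_force:
        from .core import spacings as _sp

        t = _sp(sample).spacings
        n = sample.n
        acc = 0.0
        for i in range(n - 1):
            for j in range(i + 1, n):
                acc += 0.5 * abs(n * t[i] - n * t[j])
        return StatisticValue("gini", 2.0 * acc / (n * (n - 1)), n)
    return StatisticValue("gini", float(gini_batch(sample.angles)), sample.n)


def hr_statistic(sample: CircularSample) -> StatisticValue:
    """Hermans-Rasson V; the n=1 sample gives the single diagonal term."""
    return StatisticValue("hr", float(hr_batch(sample.angles)), sample.n)


def chisq_statistic(sample: CircularSample, m: int) -> StatisticValue:
    """Pearson X^2 against equal expected counts n/m in m bins, df = m - 1.

    Restricted to n > 5: with very small samples the chi-square reference
    distribution is unreliable for goodness-of-fit on sparse bins.
    """
    if sample.n <= 5:
        raise ValueError("chi-squared requires n > 5")
    if m < 2:
        raise ValueError("need at least two bins")
    return StatisticValue("chisq", float(chisq_batch(sample.angles, m)), sample.n)
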