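"""Seeded generators for the circular null and alternative distributions.

Only random generation is provided (no densities or fitting): the simulation
study needs draws, not likelihoods.  Each family is described by a
:class:`DistributionSpec` (a name plus a parameter map), and
:data:`ALTERNATIVES` registers the twelve alternatives of the power study
with their canonical parameters:

- ``vonmises``       kappa = 1
- ``skewnormal``     dispersion 1, skewness 30 (wrapped linear skew normal)
- ``bimodal_sym``    von Mises mixture, kappa = 5, means 0 and 180 deg
- ``bimodal_asym``   von Mises mixture, kappa = 5, means 0 and 120 deg
- ``trimodal_sym``   von Mises mixture, kappa = 10, means 0/120/240 deg
- ``trimodal_asym``  von Mises mixture, kappa = 10, means 0/90/200 deg
- ``cardioid``       rho = 0.3
- ``katojones``      r = 0.7, kappa = 2.3 (Moebius transform of a von Mises)
- ``triangular``     rho = 0.3
- ``wrappedcauchy``  rho = 0.7
- ``wrappednormal``  sigma chosen so the resultant is 0.7
- ``wrappedstable``  scale 1, index 0.3, skewness 1 (Chambers-Mallows-Stuck)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .core import TWO_PI, CircularSample

__all__ = ["DistributionSpec", "sample", "mixture", "ALTERNATIVES", "UNIFORM"]


@dataclass(frozen=True)
class DistributionSpec:
    """A named circular distribution family with a complete parameter set."""

    name: str
    params: Dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"name": self.name, "params": dict(self.params)}

    @staticmethod
    def from_dict(d: dict) -> "DistributionSpec":
        return DistributionSpec(d["name"], dict(d.get("params", {})))


def _wrap(x: np.ndarray) -> np.ndarray:
    return np.mod(x, TWO_PI)


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


# -- individual samplers (n draws in radians on [0, 2pi)) -------------------

def _uniform(n, rng, **_):
    return rng.uniform(0.0, TWO_PI, n)


def _vonmises(n, rng, mu=0.0, kappa=1.0):
    return _wrap(rng.vonmises(mu, kappa, n))


def _skewnormal(n, rng, scale=1.0, shape=30.0, loc=0.0):
    # wrapped linear skew normal (Azzalini): location loc, dispersion scale
    return _wrap(sps.skewnorm.rvs(shape, loc=loc, scale=scale, size=n, random_state=rng))


def _cardioid(n, rng, rho=0.3, mu=0.0):
    # density (1 + 2 rho cos(theta - mu)) / (2 pi); rejection from uniform
    if not 0 <= rho <= 0.5:
        raise ValueError("cardioid requires 0 <= rho <= 0.5")
    out = np.empty(n)
    got = 0
    while got < n:
        k = max(int((n - got) * 1.6) + 16, 32)
        theta = rng.uniform(0.0, TWO_PI, k)
        u = rng.uniform(0.0, 1.0, k)
        acc = theta[u * (1 + 2 * rho) <= 1 + 2 * rho * np.cos(theta - mu)]
        take = min(acc.size, n - got)
        out[got : got + take] = acc[:take]
        got += take
    return out


def _triangular(n, rng, rho=0.3):
    # density (1/(8 pi)) (4 - pi^2 rho + 2 pi rho |pi - theta|): symmetric
    # about 0 with mode at 0 and resultant length rho; 0 <= rho <= 4/pi^2
    if not 0 <= rho <= 4 / np.pi**2:
        raise ValueError("triangular requires 0 <= rho <= 4/pi^2")
    fmax = (4 + np.pi**2 * rho) / (8 * np.pi)
    out = np.empty(n)
    got = 0
    while got < n:
        k = max(int((n - got) * 1.6) + 16, 32)
        theta = rng.uniform(0.0, TWO_PI, k)
        u = rng.uniform(0.0, fmax, k)
        f = (4 - np.pi**2 * rho + 2 * np.pi * rho * np.abs(np.pi - theta)) / (8 * np.pi)
        acc = theta[u <= f]
        take = min(acc.size, n - got)
        out[got : got + take] = acc[:take]
        got += take
    return out


def _wrappedcauchy(n, rng, rho=0.7, mu=0.0):
    if not 0 < rho < 1:
        raise ValueError("wrapped Cauchy requires 0 < rho < 1")
    return _wrap(mu + sps.wrapcauchy.rvs(rho, size=n, random_state=rng))


def _wrappednormal(n, rng, sigma=None, rho=0.7, mu=0.0):
    # resultant length of the wrapped normal is exp(-sigma^2/2)
    if sigma is None:
        sigma = float(np.sqrt(-2.0 * np.log(rho)))
    return _wrap(rng.normal(mu, sigma, n))


def _stable_cms(n, rng, index, skewness):
    """Standard stable draws, Chambers-Mallows-Stuck, 1-parameterization."""
    alpha, beta = index, skewness
    u = rng.uniform(-np.pi / 2, np.pi / 2, n)
    w = rng.exponential(1.0, n)
    if alpha == 1.0:
        return (2 / np.pi) * (
            (np.pi / 2 + beta * u) * np.tan(u)
            - beta * np.log((np.pi / 2 * w * np.cos(u)) / (np.pi / 2 + beta * u))
        )
    theta0 = np.arctan(beta * np.tan(np.pi * alpha / 2)) / alpha
    factor = (1 + beta**2 * np.tan(np.pi * alpha / 2) ** 2) ** (1 / (2 * alpha))
    return (
        factor
        * np.sin(alpha * (u + theta0))
        / np.cos(u) ** (1 / alpha)
        * (np.cos(u - alpha * (u + theta0)) / w) ** ((1 - alpha) / alpha)
    )


def _wrappedstable(n, rng, scale=1.0, index=0.3, skewness=1.0):
    if not 0 < index <= 2:
        raise ValueError("stable index must lie in (0, 2]")
    return _wrap(scale * _stable_cms(n, rng, index, skewness))


def _katojones(n, rng, r=0.7, kappa=2.3, mu=0.0, nu=0.0):
    """Moebius transformation of a von Mises draw (Kato-Jones family).

    With Theta ~ vM(0, kappa) and zeta = exp(i Theta),
    exp(i (X - mu)) = (zeta + r e^{i nu}) / (r e^{-i nu} zeta + 1);
    r in [0, 1) controls the distortion, r = 0 recovers the von Mises.
    """
    if not 0 <= r < 1:
        raise ValueError("katojones requires 0 <= r < 1")
    theta = rng.vonmises(0.0, kappa, n)
    zeta = np.exp(1j * theta)
    w = (zeta + r * np.exp(1j * nu)) / (r * np.exp(-1j * nu) * zeta + 1)
    return _wrap(mu + np.angle(w))


_SAMPLERS = {
    "uniform": _uniform,
    "vonmises": _vonmises,
    "skewnormal": _skewnormal,
    "cardioid": _cardioid,
    "triangular": _triangular,
    "wrappedcauchy": _wrappedcauchy,
    "wrappednormal": _wrappednormal,
    "wrappedstable": _wrappedstable,
    "katojones": _katojones,
}

_MIXTURES: Dict[str, tuple] = {
    # name -> (component kappa, component means in radians)
    "bimodal_sym": (5.0, (0.0, np.pi)),
    "bimodal_asym": (5.0, (0.0, 2 * np.pi / 3)),
    "trimodal_sym": (10.0, (0.0, 2 * np.pi / 3, 4 * np.pi / 3)),
    "trimodal_asym": (10.0, (0.0, np.pi / 2, np.deg2rad(200.0))),
}


def sample(spec: DistributionSpec, n: int, seed=None) -> CircularSample:
    """Draw n i.i.d. angles from the named family; deterministic given seed.

    ``seed`` may be an int (or None) or an existing numpy Generator.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = _rng(seed)
    if spec.name in _MIXTURES:
        kappa, means = _MIXTURES[spec.name]
        kappa = spec.params.get("kappa", kappa)
        comps = [DistributionSpec("vonmises", {"mu": m, "kappa": kappa}) for m in means]
        return mixture(comps, [1 / len(comps)] * len(comps), n, rng)
    if spec.name not in _SAMPLERS:
        known = sorted(_SAMPLERS) + sorted(_MIXTURES)
        raise ValueError(f"unknown distribution {spec.name!r}; supported: {known}")
    angles = _SAMPLERS[spec.name](n, rng, **spec.params)
    return CircularSample(angles)


def mixture(
    components: Sequence[DistributionSpec],
    weights: Sequence[float],
    n: int,
    seed=None,
) -> CircularSample:
    """Draw from a finite mixture: pick a component by weight, then sample it."""
    weights = np.asarray(weights, dtype=float)
    if len(components) != weights.size:
        raise ValueError("one weight per component required")
    if np.any(weights < 0) or abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be non-negative and sum to 1")
    rng = _rng(seed)
    which = rng.choice(len(components), size=n, p=weights)
    out = np.empty(n)
    for k, comp in enumerate(components):
        idx = np.flatnonzero(which == k)
        if idx.size:
            out[idx] = sample(comp, idx.size, rng).angles
    return CircularSample(out)


UNIFORM = DistributionSpec("uniform")

#: the twelve alternatives of the power study, canonical parameters
ALTERNATIVES: Dict[str, DistributionSpec] = {
    "vonmises": DistributionSpec("vonmises", {"mu": 0.0, "kappa": 1.0}),
    "skewnormal": DistributionSpec("skewnormal", {"scale": 1.0, "shape": 30.0}),
    "bimodal_sym": DistributionSpec("bimodal_sym"),
    "bimodal_asym": DistributionSpec("bimodal_asym"),
    "trimodal_sym": DistributionSpec("trimodal_sym"),
    "trimodal_asym": DistributionSpec("trimodal_asym"),
    "cardioid": DistributionSpec("cardioid", {"rho": 0.3}),
    "katojones": DistributionSpec("katojones", {"r": 0.7, "kappa": 2.3}),
    "triangular": DistributionSpec("triangular", {"rho": 0.3}),
    "wrappedcauchy": DistributionSpec("wrappedcauchy", {"rho": 0.7}),
    "wrappednormal": DistributionSpec("wrappednormal", {"rho": 0.7}),
    "wrappedstable": DistributionSpec("wrappedstable", {"scale": 1.0, "index": 0.3, "skewness": 1.0}),
}
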