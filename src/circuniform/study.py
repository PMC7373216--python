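"""Type-I-error and power simulation experiments.

Each experiment cell is a combination of (test, variant, distribution,
sample size, grouping).  For a cell, ``n_datasets`` samples are drawn from
the distribution, grouped if the cell says so, tested at level ``alpha``,
and the rejection fraction is recorded.  Monte-Carlo tests share one
simulated null distribution per cell (``n_reps`` replicates): every dataset
in a cell has the identical null pipeline, so sharing the null changes
nothing about the rejection-rate estimand, only the Monte-Carlo noise
structure.  ``paranoid=True`` disables sharing and simulates a fresh null
per dataset.

Per-cell seeds are derived from the master seed by hashing the cell
coordinates, so any cell can be reproduced in isolation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .core import TWO_PI, group_angles
from .distributions import ALTERNATIVES, UNIFORM, DistributionSpec, sample as draw
from .pvalues import DEFAULT_KAPPA, DEFAULT_TB_GROUPING, NullDistribution, simulate_null
from .stats import BATCH_KERNELS, chisq_batch

from scipy import stats as sps

__all__ = [
    "StudyConfig",
    "type1_experiment",
    "power_experiment",
    "shared_null",
    "plot_rejection_rates",
]

MC_TESTS = tuple(BATCH_KERNELS)  # rayleigh, kuiper, watson, rao, gini, hr


@dataclass
class StudyConfig:
    """Configuration of a simulation experiment.

    ``tests`` holds (name, variant) pairs; variant is ``standard`` or ``tb``.
    The Rayleigh standard test uses its closed-form p-value and chi-squared
    its chi-square tail; all other (test, variant) combinations are
    Monte-Carlo with ``n_reps`` null replicates.  Defaults are desk-scale
    (2,000 datasets / 2,000 replicates); pass 10,000/10,000 for full scale.
    """

    tests: List[Tuple[str, str]] = field(
        default_factory=lambda: [(t, v) for t in MC_TESTS for v in ("standard", "tb")]
    )
    sample_sizes: List[int] = field(default_factory=lambda: [5, 10, 15, 25, 50])
    grouping: Optional[int] = 36
    distributions: List[DistributionSpec] = field(default_factory=lambda: [UNIFORM])
    n_datasets: int = 2000
    n_reps: int = 2000
    alpha: float = 0.05
    kappa: float = DEFAULT_KAPPA
    seed: int = 0
    paranoid: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if min(self.n_datasets, self.n_reps) < 1:
            raise ValueError("n_datasets and n_reps must be positive")
        if not self.tests:
            raise ValueError("tests list is empty")
        if not self.sample_sizes or min(self.sample_sizes) < 2:
            raise ValueError("sample sizes must be at least 2")
        for name, variant in self.tests:
            if name not in MC_TESTS + ("chisq",):
                raise ValueError(f"unknown test {name!r}")
            if variant not in ("standard", "tb"):
                raise ValueError(f"unknown variant {variant!r}")
            if name == "chisq" and variant == "tb":
                raise ValueError("chi-squared has no tie-breaking variant")
            if name == "chisq" and self.grouping is None:
                raise ValueError("chi-squared requires grouped data")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "tests": [f"{t}:{v}" for t, v in self.tests],
            "sample_sizes": list(self.sample_sizes),
            "grouping": self.grouping,
            "distributions": [d.to_dict() for d in self.distributions],
            "n_datasets": self.n_datasets,
            "n_reps": self.n_reps,
            "alpha": self.alpha,
            "kappa": self.kappa,
            "seed": self.seed,
            "paranoid": self.paranoid,
        }

    @staticmethod
    def from_dict(d: dict) -> "StudyConfig":
        cfg = dict(d)
        if "tests" in cfg:
            tests = []
            for item in cfg["tests"]:
                if isinstance(item, str):
                    name, _, variant = item.partition(":")
                    tests.append((name.strip(), (variant or "standard").strip()))
                else:
                    tests.append((item["name"], item.get("variant", "standard")))
            cfg["tests"] = tests
        if "distributions" in cfg:
            dists = []
            for item in cfg["distributions"]:
                if isinstance(item, str):
                    dists.append(ALTERNATIVES.get(item, DistributionSpec(item)))
                else:
                    dists.append(DistributionSpec.from_dict(item))
            cfg["distributions"] = dists
        return StudyConfig(**cfg)

    @staticmethod
    def from_yaml(path) -> "StudyConfig":
        with open(path) as fh:
            return StudyConfig.from_dict(yaml.safe_load(fh))


def _cell_seed(master: int, *coords) -> np.random.SeedSequence:
    key = zlib.crc32("|".join(map(str, coords)).encode())
    return np.random.SeedSequence([int(master), key])


def shared_null(
    test: str,
    variant: str,
    n: int,
    grouping: Optional[int],
    n_reps: int,
    kappa: float,
    seed,
) -> NullDistribution:
    """Simulate a cell's null distribution once, for reuse across its datasets.

    For the TB variant the null samples are grouped to the cell's resolution
    (36 when the cell is continuous, mirroring the TB convention) before
    perturbation.
    """
    rng = np.random.default_rng(seed)
    if variant == "tb":
        gm = grouping if grouping is not None else DEFAULT_TB_GROUPING
        return simulate_null(test, n, n_reps, rng, variant="tb", grouping_m=gm, kappa=kappa)
    return simulate_null(test, n, n_reps, rng, variant="standard")


def _rayleigh_p_batch(angles: np.ndarray) -> np.ndarray:
    """Closed-form Rayleigh p (second-order series), vectorised over rows."""
    n = angles.shape[-1]
    rbar = np.hypot(np.cos(angles).sum(-1), np.sin(angles).sum(-1)) / n
    s = n * rbar**2
    p = np.exp(-s) * (
        1 + (2 * s - s**2) / (4 * n)
        - (24 * s - 132 * s**2 + 76 * s**3 - 9 * s**4) / (288 * n**2)
    )
    return np.clip(p, np.nextafter(0, 1), 1.0)


def _mc_pvalues(obs_stats: np.ndarray, null_values: np.ndarray) -> np.ndarray:
    sn = np.sort(null_values)
    n_e = sn.size - np.searchsorted(sn, obs_stats, side="left")
    return (n_e + 1) / (sn.size + 1)


def _cell_rejection_rate(
    test: str,
    variant: str,
    dist: DistributionSpec,
    n: int,
    cfg: StudyConfig,
) -> float:
    ss = _cell_seed(cfg.seed, test, variant, dist.name, n, cfg.grouping)
    rng_data, rng_null, rng_perturb = (np.random.default_rng(s) for s in ss.spawn(3))

    data = draw(dist, cfg.n_datasets * n, rng_data).angles.reshape(cfg.n_datasets, n)
    if cfg.grouping is not None:
        data = group_angles(data, cfg.grouping)

    if test == "chisq":
        if n <= 5:
            raise ValueError("chi-squared requires n > 5")
        x2 = chisq_batch(data, cfg.grouping)
        p = sps.chi2.sf(x2, df=cfg.grouping - 1)
        return float((p < cfg.alpha).mean())

    if test == "rayleigh" and variant == "standard":
        p = _rayleigh_p_batch(data)
        return float((p < cfg.alpha).mean())

    if variant == "tb":
        data = np.mod(data + rng_perturb.vonmises(0.0, cfg.kappa, data.shape), TWO_PI)

    kernel = BATCH_KERNELS[test]
    obs = kernel(data)
    if cfg.paranoid:
        rejections = 0
        for i in range(cfg.n_datasets):
            null = shared_null(test, variant, n, cfg.grouping, cfg.n_reps, cfg.kappa, rng_null)
            p_i = _mc_pvalues(obs[i : i + 1], null.values)[0]
            rejections += p_i < cfg.alpha
        return rejections / cfg.n_datasets
    null = shared_null(test, variant, n, cfg.grouping, cfg.n_reps, cfg.kappa, rng_null)
    p = _mc_pvalues(obs, null.values)
    return float((p < cfg.alpha).mean())


def _run(cfg: StudyConfig, distributions: Sequence[DistributionSpec], progress=None) -> pd.DataFrame:
    rows = []
    for dist in distributions:
        for test, variant in cfg.tests:
            for n in cfg.sample_sizes:
                if test == "chisq" and n <= 5:
                    continue  # outside the chi-squared test's validity rule
                rate = _cell_rejection_rate(test, variant, dist, n, cfg)
                rows.append(
                    {
                        "test": test,
                        "variant": variant,
                        "distribution": dist.name,
                        "n": n,
                        "grouping_m": cfg.grouping,
                        "rejection_rate": rate,
                        "n_datasets": cfg.n_datasets,
                        "n_reps": cfg.n_reps,
                        "seed": cfg.seed,
                    }
                )
                if progress is not None:
                    progress(rows[-1])
    return pd.DataFrame(rows)


def type1_experiment(config: StudyConfig, progress=None) -> pd.DataFrame:
    """Rejection rates under the null: uniform data, optionally grouped.

    A rate is the fraction of ``n_datasets`` uniform samples with p < alpha;
    under correct type-I control it should sit near alpha.
    """
    for d in config.distributions:
        if d.name != "uniform":
            raise ValueError("type-I experiment uses the uniform distribution only")
    return _run(config, [UNIFORM], progress)


def power_experiment(config: StudyConfig, progress=None) -> pd.DataFrame:
    """Rejection rates under the configured alternative distributions.

    Grouping, when set, is applied after generation (continuous draw, then
    rounding), matching how rounded field measurements arise.
    """
    alts = [d for d in config.distributions if d.name != "uniform"]
    if not alts:
        raise ValueError("power experiment needs at least one non-uniform distribution")
    return _run(config, alts, progress)


def plot_rejection_rates(results: pd.DataFrame, path) -> None:
    """One panel per distribution: rejection rate vs n, a line per test:variant."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    dists = sorted(results["distribution"].unique())
    fig, axes = plt.subplots(1, len(dists), figsize=(4.2 * len(dists), 3.4), squeeze=False)
    for ax, dist in zip(axes[0], dists):
        sub = results[results["distribution"] == dist]
        for (test, variant), grp in sub.groupby(["test", "variant"]):
            grp = grp.sort_values("n")
            ax.plot(grp["n"], grp["rejection_rate"], marker="o", label=f"{test}:{variant}")
        ax.axhline(0.05, ls="--", c="grey", lw=0.8)
        ax.set_title(dist)
        ax.set_xlabel("sample size n")
        ax.set_ylabel("rejection rate")
    axes[0][-1].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
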