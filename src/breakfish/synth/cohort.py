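"""Labelled cohorts of inter-signal distances with planted broken alleles."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DistSpec", "make_cohort_distances"]


@dataclass(frozen=True)
class DistSpec:
    """A small family of non-negative distance distributions.

    Supported names: ``gamma`` (shape, scale), ``lognormal`` (mu_log,
    sigma_log), ``normal`` (mean, sd) and ``constant`` (value).  Samples
    are magnitudes: negative draws are resampled.
    """

    name: str
    params: tuple[float, ...]

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.name == "gamma":
            shape, scale = self.params
            out = rng.gamma(shape, scale, size)
        elif self.name == "lognormal":
            mu, sigma = self.params
            out = rng.lognormal(mu, sigma, size)
        elif self.name == "normal":
            mean, sd = self.params
            out = rng.normal(mean, sd, size)
            while np.any(out < 0):  # distances are magnitudes
                bad = out < 0
                out[bad] = rng.normal(mean, sd, int(bad.sum()))
        elif self.name == "constant":
            out = np.full(size, float(self.params[0]))
        else:
            raise ValueError(f"unknown distribution {self.name!r}")
        return out

    def mean(self) -> float:
        if self.name == "gamma":
            return self.params[0] * self.params[1]
        if self.name == "lognormal":
            return float(np.exp(self.params[0] + self.params[1] ** 2 / 2))
        if self.name in ("normal", "constant"):
            return float(self.params[0])
        raise ValueError(self.name)


DEFAULT_INTACT = DistSpec("gamma", (4.0, 75.0))  # mean 300 nm


def make_cohort_distances(
    n_alleles: int,
    intact_dist: DistSpec = DEFAULT_INTACT,
    broken_fraction: float = 0.0,
    broken_shift: float = 1500.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample a labelled cohort of allele pair distances.

    ``round(broken_fraction * n_alleles)`` alleles receive an extra
    separation of ``broken_shift`` nm on top of an intact draw; the rest
    are intact draws.  Returns a DataFrame with columns ``distance_nm``
    and ``broken`` (the planted label), in shuffled order, fully
    reproducible under ``seed``.
    """
    if not 0.0 <= broken_fraction <= 1.0:
        raise ValueError("broken_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_broken = int(round(broken_fraction * n_alleles))
    n_intact = n_alleles - n_broken
    intact = intact_dist.sample(rng, n_intact)
    broken = intact_dist.sample(rng, n_broken) + broken_shift
    dist = np.concatenate([intact, broken])
    label = np.concatenate([np.zeros(n_intact, bool), np.ones(n_broken, bool)])
    order = rng.permutation(n_alleles)
    return pd.DataFrame({"distance_nm": dist[order], "broken": label[order]})
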