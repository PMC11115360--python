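"""Posterior distributions over fine-grained hypotheses.

A trial's stimulus (e.g. a briefly flashed cloud of dots) induces, via Bayes'
rule, a posterior over fine-grained hypotheses (e.g. every candidate dot
count). The model never evaluates this posterior globally; the sampler only
needs the (possibly unnormalized) log density at individual points. Response
alternatives are intervals of the hypothesis space defined by a
:class:`Partition`.

Two posterior families are supported: a continuous Gaussian (the default for
the numerosity-style running task) and an arbitrary tabulated discrete grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp, ndtr


@dataclass(frozen=True)
class PosteriorSpec:
    """Target distribution over fine-grained hypotheses for one trial.

    Parameters
    ----------
    family:
        ``"gaussian"`` or ``"discrete_grid"``.
    mean, sd:
        Location and spread in hypothesis units (Gaussian family). ``sd > 0``.
    grid_values, grid_logmass:
        Strictly increasing support points and unnormalized log masses
        (discrete family).
    """

    family: str
    mean: float = 0.0
    sd: float = 1.0
    grid_values: np.ndarray | None = None
    grid_logmass: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.family == "gaussian":
            if not np.isfinite(self.mean):
                raise ValueError("gaussian mean must be finite")
            if not (self.sd > 0):
                raise ValueError("gaussian sd must be > 0")
        elif self.family == "discrete_grid":
            v = np.asarray(self.grid_values, dtype=float)
            lm = np.asarray(self.grid_logmass, dtype=float)
            if v.ndim != 1 or v.size < 1 or v.shape != lm.shape:
                raise ValueError("grid_values and grid_logmass must be equal-length 1-d")
            if v.size > 1 and not np.all(np.diff(v) > 0):
                raise ValueError("grid_values must be strictly increasing")
            if np.all(np.isneginf(lm)):
                raise ValueError("degenerate posterior: all mass is zero")
            if np.any(np.isnan(lm)) or np.any(np.isposinf(lm)):
                raise ValueError("grid_logmass must be finite or -inf")
            object.__setattr__(self, "grid_values", v)
            object.__setattr__(self, "grid_logmass", lm)
        else:
            raise ValueError(f"unknown posterior family {self.family!r}")

    # -- derived quantities ------------------------------------------------
    def probabilities(self) -> np.ndarray:
        """Normalized probability mass on the grid (discrete family only)."""
        if self.family != "discrete_grid":
            raise ValueError("probabilities() requires a discrete_grid posterior")
        lm = self.grid_logmass - logsumexp(self.grid_logmass)
        return np.exp(lm)

    def cdf(self, x: float) -> float:
        """P(h <= x) under the normalized posterior."""
        if self.family == "gaussian":
            return float(ndtr((x - self.mean) / self.sd))
        p = self.probabilities()
        return float(p[self.grid_values <= x].sum())

    def interval_mass(self, lo: float, hi: float) -> float:
        """Posterior mass of the closed interval [lo, hi]."""
        if self.family == "gaussian":
            return self.cdf(hi) - self.cdf(lo)
        p = self.probabilities()
        inside = (self.grid_values >= lo) & (self.grid_values <= hi)
        return float(p[inside].sum())

    def quantile(self, q: float) -> float:
        if self.family == "gaussian":
            from scipy.special import ndtri

            return float(self.mean + self.sd * ndtri(q))
        cum = np.cumsum(self.probabilities())
        return float(self.grid_values[int(np.searchsorted(cum, q))])

    def sample_direct(self, rng: np.random.Generator, size: int | None = None):
        """i.i.d. draws from the normalized posterior (the direct-sampling route)."""
        if self.family == "gaussian":
            return rng.normal(self.mean, self.sd, size=size)
        idx = rng.choice(self.grid_values.size, size=size, p=self.probabilities())
        return self.grid_values[idx]


def gaussian(mean: float, sd: float) -> PosteriorSpec:
    """Gaussian posterior over a continuous hypothesis space."""
    return PosteriorSpec(family="gaussian", mean=float(mean), sd=float(sd))


def discrete_grid(values, logmass) -> PosteriorSpec:
    """Tabulated posterior on a strictly increasing grid (unnormalized log mass)."""
    return PosteriorSpec(family="discrete_grid", grid_values=np.asarray(values, float),
                         grid_logmass=np.asarray(logmass, float))


def posterior_from_prior_likelihood(prior_logmass, likelihood_logmass) -> PosteriorSpec:
    """Combine tabulated log prior and log likelihood by Bayes' rule.

    Returns a normalized :class:`PosteriorSpec` on the implicit grid
    ``0..K-1``; use :func:`discrete_grid` directly to attach hypothesis
    values. The normalizer corresponds to the marginal probability of the
    stimulus.
    """
    lp = np.asarray(prior_logmass, dtype=float)
    ll = np.asarray(likelihood_logmass, dtype=float)
    if lp.shape != ll.shape or lp.ndim != 1 or lp.size < 1:
        raise ValueError("prior and likelihood must be equal-length 1-d sequences")
    post = lp + ll
    if np.all(np.isneginf(post)):
        raise ValueError("degenerate posterior: prior and likelihood share no support")
    log_z = logsumexp(post)
    return discrete_grid(np.arange(lp.size, dtype=float), post - log_z)


def log_density(spec: PosteriorSpec, h: float) -> float:
    """Unnormalized log posterior density/mass at ``h``.

    Only local evaluation is ever needed by the sampler; normalization
    constants cancel in Metropolis-Hastings acceptance ratios. For a discrete
    grid, ``h`` must be one of the support points.
    """
    if spec.family == "gaussian":
        z = (h - spec.mean) / spec.sd
        return -0.5 * z * z
    i = int(np.searchsorted(spec.grid_values, h))
    if i >= spec.grid_values.size or spec.grid_values[i] != h:
        raise ValueError(f"h={h!r} is not a grid value of the discrete posterior")
    return float(spec.grid_logmass[i])


@dataclass(frozen=True)
class Partition:
    """Division of the hypothesis space into M ordered response alternatives.

    ``boundaries`` are strictly increasing cut points; alternative ``k`` is
    the half-open interval ``[b_{k-1}, b_k)`` (values exactly on a boundary
    belong to the upper interval — a deterministic convention that is
    measure-zero for continuous posteriors).
    """

    boundaries: tuple
    labels: tuple | None = None

    def __post_init__(self) -> None:
        b = tuple(float(x) for x in self.boundaries)
        if len(b) < 1 or any(y <= x for x, y in zip(b, b[1:])):
            raise ValueError("boundaries must be nonempty and strictly increasing")
        object.__setattr__(self, "boundaries", b)
        if self.labels is not None and len(self.labels) != len(b) + 1:
            raise ValueError("need len(boundaries)+1 labels")

    @property
    def n_alternatives(self) -> int:
        return len(self.boundaries) + 1

    def masses(self, spec: PosteriorSpec) -> np.ndarray:
        """Posterior mass of each alternative's interval."""
        cdf = [0.0, *(spec.cdf(b - 1e-12) for b in self.boundaries), 1.0]
        return np.diff(np.asarray(cdf))


def classify(partition: Partition, h: float) -> int:
    """Index of the alternative whose interval contains ``h``.

    A sample of 23 with a boundary at 25 supports the "fewer than 25"
    alternative (index 0); 27 supports "25 or more" (index 1); exactly 25
    falls in the upper interval.
    """
    return int(np.searchsorted(partition.boundaries, h, side="right"))


def load_grid_csv(path) -> PosteriorSpec:
    """Read a two-column CSV (value, unnormalized_mass) into a grid posterior."""
    import pandas as pd

    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("expected two columns: value, unnormalized_mass")
    values = df.iloc[:, 0].to_numpy(dtype=float)
    mass = df.iloc[:, 1].to_numpy(dtype=float)
    if np.any(mass < 0):
        raise ValueError("masses must be nonnegative")
    with np.errstate(divide="ignore"):
        logmass = np.log(mass)
    return discrete_grid(values, logmass)
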