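"""Population parameter distributions.

Two representations are used side by side:

* :class:`DiscretePopulation` — the nonparametric maximum-likelihood
  estimate produced by the adaptive-grid fitter: a finite set of support
  points in (CLs, V) space with probabilities.
* :class:`ParametricPopulation` — a parametric stand-in (log-normal by
  default, truncated normal selectable) parameterized by the published
  mean and CV% of each parameter.  It stands in for the unpublished
  nonparametric joint distribution when simulating virtual patients.

Both expose ``sample`` (draws of (CLs, V)), ``mean``/``sd`` summaries and
the covariate model that scales clearance by creatinine clearance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray

from .pk_model import CovariateModel

__all__ = ["DiscretePopulation", "ParametricPopulation", "PopulationModel"]

PARAMETER_NAMES = ("CLs", "V")

#: Final-model population summaries: mean (units L/h for CLs, L for V)
#: and coefficient of variation (fraction) of each parameter.
DEFAULT_MEANS = {"CLs": 2.25, "V": 18.0}
DEFAULT_CVS = {"CLs": 0.346, "V": 0.189}


def _weighted_quantile(x: NDArray, w: NDArray, q: float) -> float:
    order = np.argsort(x)
    xs, cw = x[order], np.cumsum(w[order])
    target = q * cw[-1]
    idx = int(np.searchsorted(cw, target))
    # exact boundary: split the difference (median of two equal weights)
    if idx < len(xs) - 1 and np.isclose(cw[idx], target):
        return float(0.5 * (xs[idx] + xs[idx + 1]))
    return float(xs[min(idx, len(xs) - 1)])


@dataclass(frozen=True)
class DiscretePopulation:
    """Discrete joint distribution over (CLs, V): support points + weights."""

    support: NDArray[np.float64]  # shape (k, d), columns per parameter
    probabilities: NDArray[np.float64]  # shape (k,)
    covariate_model: CovariateModel | None = None
    log_likelihood: float | None = None
    aic: float | None = None
    parameter_names: tuple[str, ...] = PARAMETER_NAMES

    def __post_init__(self) -> None:
        s = np.atleast_2d(np.asarray(self.support, dtype=float))
        p = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "support", s)
        object.__setattr__(self, "probabilities", p)
        if s.shape[0] != p.shape[0]:
            raise ValueError("support and probabilities must align")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must be non-negative and sum to 1")
        if np.any(s <= 0):
            raise ValueError("support points must be strictly positive")

    @property
    def n_support(self) -> int:
        return self.support.shape[0]

    def mean(self) -> dict[str, float]:
        m = self.probabilities @ self.support
        return dict(zip(self.parameter_names, map(float, m)))

    def variance(self) -> dict[str, float]:
        m = self.probabilities @ self.support
        v = self.probabilities @ (self.support - m) ** 2
        return dict(zip(self.parameter_names, map(float, v)))

    def sd(self) -> dict[str, float]:
        return {k: v**0.5 for k, v in self.variance().items()}

    def median(self) -> dict[str, float]:
        return {
            name: _weighted_quantile(self.support[:, j], self.probabilities, 0.5)
            for j, name in enumerate(self.parameter_names)
        }

    def cv_percent(self) -> dict[str, float]:
        m, s = self.mean(), self.sd()
        return {k: 100.0 * s[k] / m[k] for k in self.parameter_names}

    def sample(self, n: int, rng: np.random.Generator) -> NDArray[np.float64]:
        """Draw n (CLs, V) pairs from the discrete distribution."""
        idx = rng.choice(self.n_support, size=n, p=self.probabilities)
        return self.support[idx]


@dataclass(frozen=True)
class ParametricPopulation:
    """Log-normal (or truncated-normal) stand-in for the population.

    Parameterized by the mean and CV (fraction) of each parameter;
    draws are truncated to ``truncation`` times the mean (resampled),
    guaranteeing positivity and excluding physiologically absurd values.
    """

    means: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MEANS))
    cvs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CVS))
    family: str = "lognormal"
    truncation: tuple[float, float] = (0.1, 10.0)
    covariate_model: CovariateModel | None = field(default_factory=CovariateModel)

    def __post_init__(self) -> None:
        if self.family not in ("lognormal", "truncnorm"):
            raise ValueError(f"unknown distribution family: {self.family!r}")
        for name in PARAMETER_NAMES:
            if self.means[name] <= 0 or self.cvs[name] <= 0:
                raise ValueError("means and CVs must be positive")

    def mean(self) -> dict[str, float]:
        return dict(self.means)

    def sd(self) -> dict[str, float]:
        return {k: self.means[k] * self.cvs[k] for k in PARAMETER_NAMES}

    def cv_percent(self) -> dict[str, float]:
        return {k: 100.0 * self.cvs[k] for k in PARAMETER_NAMES}

    def sample(self, n: int, rng: np.random.Generator) -> NDArray[np.float64]:
        """Draw n (CLs, V) pairs; out-of-truncation draws are resampled."""
        out = np.empty((n, len(PARAMETER_NAMES)))
        for j, name in enumerate(PARAMETER_NAMES):
            m, cv = self.means[name], self.cvs[name]
            lo, hi = self.truncation[0] * m, self.truncation[1] * m
            if self.family == "lognormal":
                sigma2 = np.log1p(cv**2)
                mu = np.log(m) - 0.5 * sigma2

                def draw(k, rng=rng, mu=mu, s=np.sqrt(sigma2)):
                    return rng.lognormal(mu, s, size=k)

            else:  # truncnorm: plain normal, resampled into bounds

                def draw(k, rng=rng, m=m, s=m * cv):
                    return rng.normal(m, s, size=k)

            x = draw(n)
            bad = (x < lo) | (x > hi)
            while bad.any():
                x[bad] = draw(int(bad.sum()))
                bad = (x < lo) | (x > hi)
            out[:, j] = x
        return out


#: Either population representation is accepted wherever a population
#: distribution is required.
PopulationModel = DiscretePopulation | ParametricPopulation
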