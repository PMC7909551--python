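"""Model evaluation: visual predictive check, bootstrap, outcome test.

The visual predictive check follows the dose history of each subject
(no time-after-dose binning): for every subject, virtual replicates are
drawn from the population distribution, pushed through that subject's
own dose schedule and observation times, and perturbed with assay
noise; the simulated 5th/25th/50th/75th/95th percentiles at each
observation time are compared with the observed concentration.  The
summary statistic is the proportion of observations falling inside the
5th-95th percentile band (a priori acceptable when above 90%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.typing import NDArray
from scipy import stats

from .cohort_sim import AssayErrorModel, Subject
from .pk_model import one_compartment_grid
from .pop_fit import FitOptions, npag_fit
from .population import PARAMETER_NAMES, PopulationModel

__all__ = ["VPCResult", "vpc", "bootstrap_ci", "association_test"]

VPC_PERCENTILES = (5.0, 25.0, 50.0, 75.0, 95.0)


def _clearance_spec(model: PopulationModel) -> tuple[str, float] | None:
    """Covariate scaling carried by either population representation."""
    name = getattr(model, "covariate_name", None)
    if name is not None:
        return name, getattr(model, "covariate_center")
    cov = getattr(model, "covariate_model", None)
    if cov is not None:
        return "ccr", cov.reference_ccr
    return None


@dataclass(frozen=True)
class VPCResult:
    bands: pd.DataFrame  # one row per observation with percentile columns
    inclusion_proportion: float  # share of observations inside 5th-95th
    n_sim: int


def vpc(
    model: PopulationModel,
    cohort: list[Subject],
    error_model: AssayErrorModel,
    n_sim: int = 1000,
    seed: int | np.random.Generator = 0,
) -> VPCResult:
    """Visual predictive check over the cohort's own dose histories."""
    if n_sim < 100:
        raise ValueError("n_sim must be at least 100")
    rng = np.random.default_rng(seed)
    spec = _clearance_spec(model)
    rows = []
    inside = total = 0
    for s in cohort:
        params = model.sample(n_sim, rng)
        factor = 1.0
        if spec is not None:
            factor = float(getattr(s.covariates, spec[0])) / spec[1]
        cl = params[:, 0] * factor
        pred = one_compartment_grid(cl, params[:, 1], s.doses, s.times)
        sd = np.asarray(error_model.sd(pred), dtype=float)
        sim = pred + rng.normal(size=pred.shape) * sd
        np.clip(sim, 0.0, None, out=sim)
        pct = np.percentile(sim, VPC_PERCENTILES, axis=0)
        for k in range(s.n_obs):
            obs = float(s.concentrations[k])
            row = {"id": s.id, "time_h": float(s.times[k]), "observed": obs,
                   "blq": bool(s.blq[k])}
            row.update(
                {f"p{int(q)}": float(pct[i, k])
                 for i, q in enumerate(VPC_PERCENTILES)}
            )
            rows.append(row)
            if not s.blq[k]:
                total += 1
                inside += int(pct[0, k] <= obs <= pct[-1, k])
    bands = pd.DataFrame(rows)
    return VPCResult(
        bands=bands,
        inclusion_proportion=inside / total if total else float("nan"),
        n_sim=n_sim,
    )


def bootstrap_ci(
    cohort: list[Subject],
    options: FitOptions | None = None,
    error_model: AssayErrorModel | None = None,
    covariate_model=None,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Nonparametric bootstrap of the population fit.

    Subjects are resampled with replacement and refitted ``n_boot``
    times; the table reports, per parameter, the mean of the bootstrap
    population means, their SD (the bootstrap SE) and 2.5/97.5
    percentile limits, plus the replicate bookkeeping (a replicate that
    fails to fit is dropped and counted).
    """
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    rng = np.random.default_rng(seed)
    options = options or FitOptions()
    error_model = error_model or AssayErrorModel()
    means: list[dict[str, float]] = []
    failures = 0
    for _ in range(n_boot):
        idx = rng.integers(0, len(cohort), size=len(cohort))
        sample = [cohort[i] for i in idx]
        try:
            fit = npag_fit(sample, options, error_model, covariate_model)
        except (RuntimeError, ValueError):
            failures += 1
            continue
        means.append(fit.mean())
    if not means:
        raise RuntimeError("all bootstrap replicates failed to fit")
    boot = pd.DataFrame(means)
    out = pd.DataFrame(
        {
            "mean": boot.mean(),
            "se": boot.std(ddof=1),
            "ci_lo": boot.quantile(0.025),
            "ci_hi": boot.quantile(0.975),
        }
    ).loc[list(PARAMETER_NAMES)]
    out.attrs["n_boot"] = n_boot
    out.attrs["n_failed"] = failures
    out.attrs["n_used"] = len(means)
    return out


def association_test(table: NDArray | list) -> tuple[float, float]:
    """Pearson chi-square test of independence on a 2x2 table.

    No continuity correction, 1 degree of freedom — the convention that
    reproduces the study's printed outcome p-values.  Returns
    (statistic, p-value).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0) or t.sum() < 1:
        raise ValueError("need a 2x2 table of non-negative counts, n >= 1")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero marginal: association is undefined")
    res = stats.chi2_contingency(t, correction=False)
    return float(res.statistic), float(res.pvalue)
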