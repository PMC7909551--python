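"""Nonparametric adaptive-grid (NPAG) population estimation.

The population distribution of (CLs, V) is estimated as a discrete
distribution — support points with probabilities — by maximum
likelihood over the mixture

    L(w, theta) = prod_i  sum_j  w_j * p(y_i | theta_j)

where p(y_i | theta_j) is the subject likelihood under a Gaussian
observation model with the assay-error SD.  The algorithm alternates

1. probability-weight optimization over the current candidate grid by
   expectation-maximization to a fixed point of the mixture likelihood;
2. grid condensation — points carrying negligible probability are
   dropped, near-duplicate points merged;
3. local grid expansion — new candidates are proposed around every
   surviving support point at a radius that shrinks as the fit refines.

The cycle stops once a full pass at the finest radius improves the
total log-likelihood by less than the tolerance.

Covariates enter multiplicatively on clearance: CL_i = CLs_j * f_i,
where f_i is the subject's covariate value over a reference value
(creatinine clearance over 52.9 mL/min in the final model).  The
covariate-building scan refits the model with each candidate covariate
and admits it when minus twice the log-likelihood improves by more than
3.84 (chi-square, 1 df, 5%) and the AIC decreases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.typing import NDArray
from scipy.stats import qmc

from .cohort_sim import AssayErrorModel, Subject
from .pk_model import (
    CovariateModel,
    PKParams,
    one_compartment_grid,
    two_compartment_profile,
)
from .population import PARAMETER_NAMES, DiscretePopulation

__all__ = [
    "FitOptions",
    "NPAGFit",
    "subject_loglik",
    "npag_fit",
    "covariate_scan",
    "fit_summary",
    "predictions",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class FitOptions:
    """Tuning knobs of the adaptive-grid estimator.

    Bounds default to CLs in [0.1, 10] L/h and V in [1, 60] L, which
    bracket the final-model estimates by more than four population SDs.
    Convergence: stop when a full cycle at the smallest expansion
    radius improves the log-likelihood by less than ``tol`` (default
    0.01) or after ``max_cycles`` cycles.
    """

    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"CLs": (0.1, 10.0), "V": (1.0, 60.0)}
    )
    #: "one_compartment" (production) or "two_compartment" (comparator;
    #: adds Q and Vp dimensions to the support grid)
    structural: str = "one_compartment"
    n_initial: int = 256
    tol: float = 0.01
    max_cycles: int = 100
    seed: int = 0
    prune_rel: float = 1e-8
    delta_init: float = 0.2
    delta_min: float = 1e-3
    merge_rel: float = 1e-3
    include_blq: bool = False  # include below-LOD observations at LOD/2
    n_error_params: int = 0  # assay polynomial fixed by default

    def parameter_names(self) -> tuple[str, ...]:
        if self.structural == "two_compartment":
            return PARAMETER_NAMES + ("Q", "Vp")
        if self.structural != "one_compartment":
            raise ValueError(f"unknown structural model: {self.structural!r}")
        return PARAMETER_NAMES

    def bound_array(self) -> NDArray:
        defaults = {"Q": (0.01, 20.0), "Vp": (1.0, 60.0)}
        return np.array(
            [
                self.bounds.get(name, defaults.get(name))
                for name in self.parameter_names()
            ],
            dtype=float,
        )


@dataclass(frozen=True)
class NPAGFit(DiscretePopulation):
    """A fitted nonparametric population model with fit metadata."""

    covariate_name: str | None = None
    covariate_center: float | None = None
    posterior_means: NDArray | None = None
    n_cycles: int = 0
    converged: bool = True
    ll_history: tuple[float, ...] = ()

    @property
    def minus_two_ll(self) -> float:
        return -2.0 * self.log_likelihood


# ---------------------------------------------------------------------------
# likelihood machinery


def _covariate_value(subject: Subject, name: str) -> float:
    return float(getattr(subject.covariates, name))


def _covariate_factor(
    subject: Subject, spec: tuple[str, float] | None
) -> float:
    """Multiplier on clearance for one subject: value / center, or 1."""
    if spec is None:
        return 1.0
    name, center = spec
    return _covariate_value(subject, name) / center


def _obs_mask(subject: Subject, include_blq: bool) -> NDArray:
    return np.ones(subject.n_obs, bool) if include_blq else ~subject.blq


def _predict_support(
    subject: Subject, support: NDArray, factor: float, times: NDArray
) -> NDArray:
    """Model predictions at every support point, shape (k, n_times)."""
    cl = support[:, 0] * factor
    if support.shape[1] == 2:
        return one_compartment_grid(cl, support[:, 1], subject.doses, times)
    return np.stack(
        [
            two_compartment_profile(
                PKParams(row[0], row[1], row[2], row[3]), c,
                subject.doses, times,
            )
            for row, c in zip(support, cl)
        ]
    )


def _loglik_columns(
    subject: Subject,
    support: NDArray,
    factor: float,
    error_model: AssayErrorModel,
    include_blq: bool = False,
) -> NDArray:
    """Log-likelihood of one subject at every support point, shape (k,)."""
    mask = _obs_mask(subject, include_blq)
    if not mask.any():
        return np.zeros(support.shape[0])
    times = subject.times[mask]
    obs = subject.concentrations[mask]
    pred = _predict_support(subject, support, factor, times)
    sd = np.asarray(error_model.sd(pred), dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (obs[None, :] - pred) / sd
        ll = -0.5 * z**2 - np.log(sd) - 0.5 * _LOG_2PI
    ll = np.where(sd > 0, ll, -np.inf)
    return ll.sum(axis=1)


def subject_loglik(
    CLs: float,
    V: float,
    subject: Subject,
    covariate_model: CovariateModel | None,
    error_model: AssayErrorModel,
    include_blq: bool = False,
) -> float:
    """Gaussian log-likelihood of one subject at a single (CLs, V).

    Predictions come from the one-compartment model with
    CL = CLs * CCr / reference when a covariate model is given; the
    observation SD is the assay polynomial evaluated at the prediction.
    Returns -inf for impossible inputs rather than raising.
    """
    if CLs <= 0 or V <= 0:
        return -np.inf
    spec = None
    if covariate_model is not None:
        spec = ("ccr", covariate_model.reference_ccr)
    factor = _covariate_factor(subject, spec)
    return float(
        _loglik_columns(
            subject, np.array([[CLs, V]]), factor, error_model, include_blq
        )[0]
    )


def _loglik_matrix(
    cohort: list[Subject],
    support: NDArray,
    factors: NDArray,
    error_model: AssayErrorModel,
    include_blq: bool,
) -> NDArray:
    return np.stack(
        [
            _loglik_columns(s, support, f, error_model, include_blq)
            for s, f in zip(cohort, factors)
        ]
    )


def _em_weights(
    logL: NDArray, w0: NDArray, tol: float = 1e-10, max_iter: int = 2000
) -> tuple[NDArray, float]:
    """Mixture-weight EM on the simplex; monotone in the log-likelihood.

    Works on the row-normalized likelihood matrix A_ij =
    exp(logL_ij - max_j logL_ij) so each iteration is a pair of BLAS
    matrix-vector products: d = A w, w_j <- w_j * mean_i(A_ij / d_i).
    """
    rowmax = logL.max(axis=1)
    if not np.isfinite(rowmax).all():
        bad = int(np.flatnonzero(~np.isfinite(rowmax))[0])
        raise RuntimeError(
            f"no grid point has finite likelihood for subject index {bad}"
        )
    A = np.exp(logL - rowmax[:, None])
    n = logL.shape[0]
    w = np.clip(w0, 1e-300, None)
    w = w / w.sum()
    offset = float(rowmax.sum())
    prev = -np.inf
    ll = prev
    for _ in range(max_iter):
        d = A @ w
        ll = float(np.log(d).sum()) + offset
        if ll - prev < tol:
            break
        prev = ll
        w = w * (A.T @ (1.0 / d)) / n
    return w, ll


def _condense(
    support: NDArray, w: NDArray, options: FitOptions
) -> tuple[NDArray, NDArray]:
    keep = w > options.prune_rel * w.max()
    support, w = support[keep], w[keep]
    # merge near-duplicates (relative to the search box size)
    span = np.ptp(options.bound_array(), axis=1)
    key = np.round(support / (span * options.merge_rel)).astype(np.int64)
    _, inv = np.unique(key, axis=0, return_inverse=True)
    k = inv.max() + 1
    merged_w = np.bincount(inv, weights=w, minlength=k)
    merged_s = np.zeros((k, support.shape[1]))
    for j in range(support.shape[1]):
        merged_s[:, j] = (
            np.bincount(inv, weights=w * support[:, j], minlength=k) / merged_w
        )
    return merged_s, merged_w / merged_w.sum()


def _expand(
    support: NDArray, delta: float, bounds: NDArray
) -> NDArray:
    """Axis-aligned +/- delta*span probes around every support point."""
    span = np.ptp(bounds, axis=1)
    probes = []
    for j in range(support.shape[1]):
        for sign in (-1.0, 1.0):
            cand = support.copy()
            cand[:, j] = cand[:, j] + sign * delta * span[j]
            probes.append(cand)
    cand = np.concatenate(probes)
    cand = np.clip(cand, bounds[:, 0], bounds[:, 1])
    return np.unique(cand, axis=0)


def npag_fit(
    cohort: list[Subject],
    options: FitOptions | None = None,
    error_model: AssayErrorModel | None = None,
    covariate_model: CovariateModel | None = None,
    covariate_spec: tuple[str, float] | None = None,
) -> NPAGFit:
    """Fit the discrete population distribution by adaptive-grid ML.

    ``covariate_model`` applies the final model's renal scaling
    (CL = CLs * CCr / reference); ``covariate_spec`` = (name, center)
    scales clearance by any covariate over a center value and is used
    by the covariate scan.  At most one of the two may be given.

    Returns an :class:`NPAGFit` carrying support points, probabilities,
    the final log-likelihood, AIC = -2LL + 2 * (structural dimensions +
    estimated error parameters), and posterior-mean individual
    parameters.
    """
    if not cohort:
        raise ValueError("cohort must contain at least one subject")
    if any(s.n_obs == 0 for s in cohort):
        raise ValueError("every subject needs at least one observation")
    options = options or FitOptions()
    error_model = error_model or AssayErrorModel()
    if covariate_model is not None and covariate_spec is not None:
        raise ValueError("give covariate_model or covariate_spec, not both")
    if covariate_model is not None:
        covariate_spec = ("ccr", covariate_model.reference_ccr)

    factors = np.array([_covariate_factor(s, covariate_spec) for s in cohort])
    bounds = options.bound_array()
    names = options.parameter_names()

    sampler = qmc.Sobol(d=len(names), scramble=True, seed=options.seed)
    unit = sampler.random(options.n_initial)
    support = qmc.scale(unit, bounds[:, 0], bounds[:, 1])

    logL = _loglik_matrix(cohort, support, factors, error_model,
                          options.include_blq)
    w, ll = _em_weights(logL, np.full(support.shape[0], 1.0 / support.shape[0]))
    support, w = _condense(support, w, options)
    logL = _loglik_matrix(cohort, support, factors, error_model,
                          options.include_blq)

    delta = options.delta_init
    history = [ll]
    converged = False
    cycle = 0
    for cycle in range(1, options.max_cycles + 1):
        cand = _expand(support, delta, bounds)
        cand_logL = _loglik_matrix(cohort, cand, factors, error_model,
                                   options.include_blq)
        all_support = np.concatenate([support, cand])
        all_logL = np.concatenate([logL, cand_logL], axis=1)
        eps = 1e-6
        w0 = np.concatenate(
            [w * (1.0 - eps), np.full(cand.shape[0], eps / cand.shape[0])]
        )
        w_new, ll_new = _em_weights(all_logL, w0)
        support, w = _condense(all_support, w_new, options)
        logL = _loglik_matrix(cohort, support, factors, error_model,
                              options.include_blq)
        improvement = ll_new - ll
        ll = max(ll, ll_new)
        history.append(ll)
        if improvement < options.tol:
            if delta <= options.delta_min:
                converged = True
                break
            delta = max(delta * 0.5, options.delta_min)

    w, ll = _em_weights(logL, w)
    w = w / w.sum()
    history.append(ll)

    # posterior-mean individual parameters (Bayes over the support)
    post = _posterior_weights(logL, w)
    post_means = post @ support

    d = len(names)
    aic = -2.0 * ll + 2.0 * (d + options.n_error_params)
    return NPAGFit(
        support=support,
        probabilities=w,
        parameter_names=names,
        covariate_model=covariate_model,
        log_likelihood=ll,
        aic=aic,
        covariate_name=covariate_spec[0] if covariate_spec else None,
        covariate_center=covariate_spec[1] if covariate_spec else None,
        posterior_means=post_means,
        n_cycles=cycle,
        converged=converged,
        ll_history=tuple(history),
    )


def _posterior_weights(logL: NDArray, w: NDArray) -> NDArray:
    """Per-subject posterior over support points: prior x likelihood."""
    a = logL + np.log(np.clip(w, 1e-300, None))[None, :]
    a -= a.max(axis=1, keepdims=True)
    p = np.exp(a)
    return p / p.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# covariate model building


def covariate_scan(
    cohort: list[Subject],
    base_model: NPAGFit,
    candidates: list[str],
    options: FitOptions | None = None,
    error_model: AssayErrorModel | None = None,
) -> pd.DataFrame:
    """Screen candidate covariates on clearance against a base model.

    Each candidate is centered at its cohort median and refitted with
    CL = CLs * (value / center).  A candidate is flagged for inclusion
    when minus twice the log-likelihood improves by more than 3.84 and
    the AIC decreases; among qualifying candidates the largest
    improvement wins (column ``selected``).

    Returns one row per candidate with delta(-2LL), delta(AIC), the
    r-squared of posterior individual clearance against the covariate,
    and the include/exclude decision.  Constant covariates are skipped.
    """
    options = options or FitOptions()
    error_model = error_model or AssayErrorModel()
    rows = []
    for name in candidates:
        values = np.array([_covariate_value(s, name) for s in cohort])
        if np.ptp(values) == 0:
            rows.append(
                {"covariate": name, "delta_m2ll": np.nan, "delta_aic": np.nan,
                 "r_squared": np.nan, "included": False, "skipped": True}
            )
            continue
        center = float(np.median(values))
        fit = npag_fit(cohort, options, error_model,
                       covariate_spec=(name, center))
        delta_m2ll = base_model.minus_two_ll - fit.minus_two_ll
        delta_aic = fit.aic - base_model.aic
        factors = values / center
        post_cl = fit.posterior_means[:, 0] * factors
        r = np.corrcoef(post_cl, values)[0, 1]
        rows.append(
            {"covariate": name, "delta_m2ll": float(delta_m2ll),
             "delta_aic": float(delta_aic), "r_squared": float(r**2),
             "included": bool(delta_m2ll > 3.84 and delta_aic < 0),
             "skipped": False}
        )
    report = pd.DataFrame(rows).set_index("covariate")
    report["selected"] = False
    winners = report.index[report["included"]]
    if len(winners):
        best = report.loc[winners, "delta_m2ll"].idxmax()
        report.loc[best, "selected"] = True
    return report


# ---------------------------------------------------------------------------
# summaries and predictions


def fit_summary(
    model: DiscretePopulation,
    se: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Parameter summary table: mean, SD, median, SE, CV%, variance and
    shrinkage per parameter.

    Moments are probability-weighted over the support points.  SE comes
    from the bootstrap (``diagnostics.bootstrap_ci``) and is filled in
    when supplied.  Shrinkage is
    100 * (1 - SD(posterior individual means) / SD(population)) and is
    available only for fitted models that carry posterior means.
    """
    names = getattr(model, "parameter_names", PARAMETER_NAMES)
    mean, sd = model.mean(), model.sd()
    med, var = model.median(), model.variance()
    shrink: dict[str, float] = {}
    post = getattr(model, "posterior_means", None)
    for j, name in enumerate(names):
        if post is not None and len(post) > 1 and sd[name] > 0:
            shrink[name] = 100.0 * (1.0 - post[:, j].std(ddof=0) / sd[name])
        else:
            shrink[name] = np.nan
    rows = {
        name: {
            "mean": mean[name],
            "sd": sd[name],
            "median": med[name],
            "se": np.nan if se is None else se.get(name, np.nan),
            "cv_pct": 100.0 * sd[name] / mean[name],
            "var": var[name],
            "shrink_pct": shrink[name],
        }
        for name in names
    }
    return pd.DataFrame(rows).T


def predictions(
    model: NPAGFit,
    cohort: list[Subject],
    error_model: AssayErrorModel | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Population and individual-posterior predictions per observation.

    The population prediction is the probability-weighted mean over
    support points; the individual prediction weights each support
    point by its posterior probability for that subject.  Weighted
    residuals are (obs - pred) / SD(pred).  The accompanying dict
    reports bias (mean weighted prediction error) and imprecision
    (mean squared weighted prediction error minus bias^2) for both
    prediction levels.
    """
    error_model = error_model or AssayErrorModel()
    spec = None
    if model.covariate_name is not None:
        spec = (model.covariate_name, model.covariate_center)
    rows = []
    for s in cohort:
        factor = _covariate_factor(s, spec)
        pred = _predict_support(s, model.support, factor, s.times)
        ll = _loglik_columns(s, model.support, factor, error_model)
        post = _posterior_weights(ll[None, :], model.probabilities)[0]
        pop_pred = model.probabilities @ pred
        ind_pred = post @ pred
        for k in range(s.n_obs):
            obs = s.concentrations[k]
            rows.append(
                {
                    "id": s.id,
                    "time_h": float(s.times[k]),
                    "observed": float(obs),
                    "blq": bool(s.blq[k]),
                    "pop_pred": float(pop_pred[k]),
                    "ind_pred": float(ind_pred[k]),
                    "wres_pop": float(
                        (obs - pop_pred[k]) / error_model.sd(pop_pred[k])
                    ),
                    "wres_ind": float(
                        (obs - ind_pred[k]) / error_model.sd(ind_pred[k])
                    ),
                }
            )
    table = pd.DataFrame(rows)
    used = ~table["blq"]
    stats: dict[str, float] = {}
    for level in ("pop", "ind"):
        w = table.loc[used, f"wres_{level}"].to_numpy()
        bias = float(w.mean())
        stats[f"bias_{level}"] = bias
        stats[f"imprecision_{level}"] = float((w**2).mean() - bias**2)
    return table, stats
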