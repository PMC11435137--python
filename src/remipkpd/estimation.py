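"""Likelihood machinery and estimators.

Three layers, all built on Gaussian residual models matching the
residual-error specification (proportional for parent concentrations and
BIS, combined proportional + additive for the metabolite):

* :func:`individual_nll` / :func:`map_estimate` — empirical-Bayes (MAP)
  estimation of one subject's random effects around population typicals;
* :func:`pooled_fit` — naive-pooled maximum-likelihood estimation of the
  11 structural PK typical values, run sequentially (parent block, then
  metabolite block with the parent fixed, then a joint polish);
* :func:`fit_pd` — sequential PK/PD: individual PK parameters are MAP
  estimates, the effect compartment is driven by each subject's own
  predicted plasma profile, and the five PD typicals are fitted by a
  Laplace-approximate marginal likelihood (the random effects on Imax and
  Hill integrated out, variances fixed);
* :func:`covariate_screen` — stepwise forward-inclusion (dOFV > 3.84) /
  backward-elimination (retained only if removal raises OFV > 6.63)
  screening of age, height and sex on the empirical-Bayes random effects.

This is a deliberate simplification of the original FOCE-I mixed-effects
analysis: no variance components are estimated, and the PK typicals come
from a pooled likelihood with empirical-Bayes recentring rather than from
full marginal-likelihood integration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm

from .model import bis_from_ce, system_matrix, solve_linear_system, \
    MG_PER_L_TO_NG_PER_ML, IDX_CE
from .parameters import (CovariateModel, PDParameters, PKParameters,
                         VariabilitySpec)
from .population import individual_parameters
from .study import SubjectData, iter_subjects

__all__ = [
    "FitResult",
    "individual_nll",
    "map_estimate",
    "pooled_fit",
    "fit_pd",
    "covariate_screen",
]

log = logging.getLogger(__name__)

_LOG_2PI = float(np.log(2.0 * np.pi))

# parent structural block / metabolite structural block
_PARENT_PARAMS = ("CL_p", "V1", "Q2", "V2", "Q3", "V3")
_METAB_PARAMS = ("K_tr", "CL_m", "V5", "Q4", "V6")


@dataclass
class FitResult:
    """Outcome of an estimation run."""

    estimates: dict
    objective: float               # -2 log-likelihood at the optimum
    converged: bool
    se: dict | None = None
    etas: pd.DataFrame | None = None
    n_obs: int = 0
    message: str = ""
    extra: dict = field(default_factory=dict)


def _as_subjects(dataset) -> list[SubjectData]:
    if isinstance(dataset, pd.DataFrame):
        return list(iter_subjects(dataset))
    return list(dataset)


# ---------------------------------------------------------------------------
# Individual likelihood and MAP estimation
# ---------------------------------------------------------------------------

def _predict_subject(pk_i: PKParameters, data: SubjectData,
                     ke0: float | None = None):
    """Noise-free parent/metabolite (and optionally effect-site)
    concentrations at the subject's sampling times."""
    if ke0 is None:
        A = system_matrix(pk_i)
        states = solve_linear_system(A, data.regimen, data.pk_times)
        ce = None
    else:
        times = np.unique(np.concatenate([data.pk_times, data.bis_times]))
        A = system_matrix(pk_i, ke0)
        st = solve_linear_system(A, data.regimen, times)
        states = st[np.searchsorted(times, data.pk_times)]
        ce = st[np.searchsorted(times, data.bis_times), IDX_CE]
    cp = MG_PER_L_TO_NG_PER_ML * states[:, 0] / pk_i.V1
    cm = MG_PER_L_TO_NG_PER_ML * states[:, 4] / pk_i.V5
    return cp, cm, ce


def _gauss_nll(y: np.ndarray, f: np.ndarray, sd: np.ndarray) -> float:
    """Sum of Gaussian -log densities over non-missing observations."""
    mask = np.isfinite(y)
    if not mask.any():
        return 0.0
    f, sd, y = f[mask], sd[mask], y[mask]
    if np.any(sd <= 0):
        raise ZeroDivisionError(
            "zero residual SD at an observed record (prediction 0 with "
            "proportional-only error)")
    z = (y - f) / sd
    return float(np.sum(0.5 * z ** 2 + np.log(sd) + 0.5 * _LOG_2PI))


#: BIS monitors report on a bounded 0-100 scale; readings at the upper
#: bound are treated as right-censored in the likelihood.
BIS_UPPER = 100.0


def _bis_nll(y: np.ndarray, f: np.ndarray, sd: np.ndarray) -> float:
    """BIS -log likelihood: Gaussian for interior observations, a censored
    (survival) term for readings pinned at the instrument maximum."""
    mask = np.isfinite(y)
    if not mask.any():
        return 0.0
    f, sd, y = f[mask], sd[mask], y[mask]
    if np.any(sd <= 0):
        raise ZeroDivisionError("zero residual SD at an observed BIS record")
    cens = y >= BIS_UPPER - 1e-9
    out = _gauss_nll(y[~cens], f[~cens], sd[~cens]) if (~cens).any() else 0.0
    if cens.any():
        out -= float(np.sum(norm.logsf((BIS_UPPER - f[cens]) / sd[cens])))
    return out


def individual_nll(eta, data: SubjectData, pk: PKParameters,
                   pd_params: PDParameters | None, spec: VariabilitySpec,
                   cov: CovariateModel | None = None,
                   include: tuple[str, ...] = ("parent", "metabolite", "bis"),
                   ) -> float:
    """-log p(observations | eta) for one subject.

    Residual SDs: parent ``sigma_prop * F``; metabolite
    ``sqrt((sigma_prop F)^2 + sigma_add^2)``; BIS ``sigma_prop_bis * F``.
    BLQ/missing rows (NaN values) are skipped.
    """
    pk_i, pd_i = individual_parameters(pk, pd_params, data.subject, cov, eta)
    want_bis = "bis" in include and pd_i is not None and data.bis_times.size
    cp, cm, ce = _predict_subject(pk_i, data,
                                  ke0=pd_i.ke0 if want_bis else None)
    nll = 0.0
    if "parent" in include:
        nll += _gauss_nll(data.dv_parent, cp, spec.sigma_prop_parent * cp)
    if "metabolite" in include:
        sd = np.sqrt((spec.sigma_prop_metab * cm) ** 2
                     + spec.sigma_add_metab ** 2)
        nll += _gauss_nll(data.dv_metab, cm, sd)
    if want_bis:
        f_bis = np.asarray(bis_from_ce(pd_i, np.clip(ce, 0.0, None)))
        nll += _bis_nll(data.dv_bis, f_bis, spec.sigma_prop_bis * f_bis)
    return nll


def map_estimate(data: SubjectData, pk: PKParameters,
                 pd_params: PDParameters | None, spec: VariabilitySpec,
                 cov: CovariateModel | None = None,
                 include: tuple[str, ...] = ("parent", "metabolite"),
                 n_restarts: int = 4) -> FitResult:
    """Empirical-Bayes (MAP) estimate of one subject's random effects.

    Minimises ``individual_nll(eta) + sum(eta^2 / (2 omega^2))`` over the
    parameters that carry BSV (omega > 0) and are visible through the
    included observation types. Restarts from perturbed points if the
    gradient-based optimiser fails; a persistent failure is flagged, not
    raised.
    """
    pd_names = set(PDParameters.names())
    names = [k for k, w in spec.omega.items() if w > 0]
    if "bis" not in include:
        names = [k for k in names if k not in pd_names]
    if pd_params is None:
        names = [k for k in names if k not in pd_names]
    omegas = np.array([spec.omega[k] for k in names])
    if not names:
        return FitResult(estimates={}, objective=0.0, converged=True)

    def objective(vec):
        eta = dict(zip(names, vec))
        try:
            nll = individual_nll(eta, data, pk, pd_params, spec, cov,
                                 include=include)
        except (ZeroDivisionError, FloatingPointError, OverflowError):
            return 1e12
        return nll + float(np.sum(vec ** 2 / (2.0 * omegas ** 2)))

    rng = np.random.default_rng(0)
    best = None
    x0 = np.zeros(len(names))
    for attempt in range(1 + n_restarts):
        res = minimize(objective, x0, method="L-BFGS-B",
                       bounds=[(-4 * w, 4 * w) for w in omegas])
        if best is None or res.fun < best.fun:
            best = res
        if res.success:
            break
        x0 = rng.normal(0.0, omegas)
    eta_hat = dict(zip(names, best.x))
    pk_i, pd_i = individual_parameters(pk, pd_params, data.subject, cov,
                                       eta_hat)
    return FitResult(
        estimates=eta_hat, objective=2.0 * float(best.fun),
        converged=bool(best.success),
        message=str(getattr(best, "message", "")),
        extra={"pk": pk_i, "pd": pd_i},
    )


# ---------------------------------------------------------------------------
# Naive-pooled PK fit
# ---------------------------------------------------------------------------

def _pooled_nll(pk: PKParameters, subjects: list[SubjectData],
                spec: VariabilitySpec, cov: CovariateModel,
                include: tuple[str, ...],
                etas: list[dict] | None = None) -> float:
    total = 0.0
    for i, data in enumerate(subjects):
        try:
            total += individual_nll(etas[i] if etas else {}, data, pk, None,
                                    spec, cov, include=include)
        except (ZeroDivisionError, FloatingPointError, OverflowError):
            return 1e12
    return total


def _stage_fit(subjects, base_pk: PKParameters, free: tuple[str, ...],
               spec, cov, include, starts: list[np.ndarray],
               bounds_factor: float, maxiter: int,
               etas: list[dict] | None = None):
    """Minimise the pooled NLL over ``free`` parameters on the log scale,
    trying each start and keeping the best optimum. ``etas`` optionally
    fixes each subject's random effects during the fit."""
    base = np.array([getattr(base_pk, k) for k in free])
    bounds = [(np.log(b / bounds_factor), np.log(b * bounds_factor))
              for b in base]

    def objective(logx):
        pk = base_pk.with_values(**dict(zip(free, np.exp(logx))))
        return _pooled_nll(pk, subjects, spec, cov, include, etas=etas)

    best = None
    for x0 in starts:
        res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": maxiter, "ftol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
    pk_hat = base_pk.with_values(**dict(zip(free, np.exp(best.x))))
    return pk_hat, float(best.fun), bool(best.success)


def pooled_fit(dataset, init_pk: PKParameters, spec: VariabilitySpec,
               cov: CovariateModel | None = None, sequential: bool = True,
               n_starts: int = 3, start_sd: float = 0.35,
               bounds_factor: float = 100.0, seed: int = 0,
               maxiter: int = 400, map_refine: int = 2,
               compute_se: bool = False) -> FitResult:
    """Pooled maximum-likelihood fit of the 11 PK typical values.

    Stage A is a naive-pooled fit (random effects fixed at zero; every
    subject contributes through the residual-error likelihood after
    allometric weight scaling). With ``sequential=True`` the parent
    parameters are fitted on parent data first, then the metabolite block
    with the parent fixed, then all 11 jointly polished (each stage starts
    at the previous optimum, so the objective is non-increasing across
    stages). The first stage is multi-started from log-normally perturbed
    copies of ``init_pk``.

    Stage B (``map_refine`` iterations) is an iterative two-stage
    refinement of the joint penalized likelihood
    ``sum_i [nll_i(theta, eta_i) + sum eta^2/(2 omega^2)]``: alternate
    empirical-Bayes (MAP) estimation of each subject's eta with a refit of
    the typicals holding the etas fixed. This block-coordinate descent
    never increases the joint objective and largely removes the shrinkage
    of typical values toward the population mean curve that plain naive
    pooling exhibits under wide log-normal BSV. ``map_refine=0`` gives the
    plain naive-pooled estimator.
    """
    subjects = _as_subjects(dataset)
    if len(subjects) < 2:
        raise ValueError("pooled_fit needs at least 2 subjects")
    cov = cov or CovariateModel()
    rng = np.random.default_rng(seed)

    def perturbed_starts(base_pk, free):
        x0 = np.log([getattr(base_pk, k) for k in free])
        starts = [x0]
        for _ in range(max(0, n_starts - 1)):
            starts.append(x0 + rng.normal(0.0, start_sd, size=len(free)))
        return starts

    stage_ofv = {}
    if sequential:
        pk1, nll1, ok1 = _stage_fit(
            subjects, init_pk, _PARENT_PARAMS, spec, cov, ("parent",),
            perturbed_starts(init_pk, _PARENT_PARAMS), bounds_factor, maxiter)
        stage_ofv["parent"] = 2.0 * nll1
        pk2, nll2, ok2 = _stage_fit(
            subjects, pk1, _METAB_PARAMS, spec, cov, ("metabolite",),
            perturbed_starts(pk1, _METAB_PARAMS), bounds_factor, maxiter)
        stage_ofv["metabolite"] = 2.0 * nll2
        free = _PARENT_PARAMS + _METAB_PARAMS
        pk3, nll3, ok3 = _stage_fit(
            subjects, pk2, free, spec, cov, ("parent", "metabolite"),
            [np.log([getattr(pk2, k) for k in free])], bounds_factor, maxiter)
        stage_ofv["joint"] = 2.0 * nll3
        pk_hat, nll, ok = pk3, nll3, ok1 and ok2 and ok3
    else:
        free = _PARENT_PARAMS + _METAB_PARAMS
        pk_hat, nll, ok = _stage_fit(
            subjects, init_pk, free, spec, cov, ("parent", "metabolite"),
            perturbed_starts(init_pk, free), bounds_factor, maxiter)
        stage_ofv["joint"] = 2.0 * nll

    etas_frame = None
    free = _PARENT_PARAMS + _METAB_PARAMS
    free_bsv = tuple(k for k in free if spec.omega.get(k, 0.0) > 0)
    free_nobsv = tuple(k for k in free if k not in free_bsv)
    for it in range(map_refine):
        eta_fits = [map_estimate(d, pk_hat, None, spec, cov,
                                 include=("parent", "metabolite"))
                    for d in subjects]
        etas_frame = pd.DataFrame([f.estimates for f in eta_fits])
        # recentre: move the mean of the MAP etas into the typical values,
        # so typicals track the geometric mean of the individual estimates
        mean_eta = etas_frame.mean()
        pk_hat = pk_hat.with_values(**{
            k: getattr(pk_hat, k) * float(np.exp(mean_eta[k]))
            for k in free_bsv if k in mean_eta})
        etas_frame = etas_frame - mean_eta
        eta_list = [row.dropna().to_dict()
                    for _, row in etas_frame.iterrows()]
        if free_nobsv:
            pk_hat, nll, ok_r = _stage_fit(
                subjects, pk_hat, free_nobsv, spec, cov,
                ("parent", "metabolite"),
                [np.log([getattr(pk_hat, k) for k in free_nobsv])],
                bounds_factor, maxiter, etas=eta_list)
            ok = ok and ok_r
        nll = _pooled_nll(pk_hat, subjects, spec, cov,
                          ("parent", "metabolite"), etas=eta_list) \
            + sum(float(np.sum(np.array(list(e.values())) ** 2
                               / (2 * np.array([spec.omega[k]
                                                for k in e]) ** 2)))
                  for e in eta_list)
        stage_ofv[f"map_refine_{it + 1}"] = 2.0 * nll

    n_obs = sum(int(np.isfinite(s.dv_parent).sum()
                    + np.isfinite(s.dv_metab).sum()) for s in subjects)
    result = FitResult(
        estimates=pk_hat.as_dict(), objective=2.0 * nll, converged=ok,
        n_obs=n_obs, etas=etas_frame,
        extra={"pk": pk_hat, "stage_ofv": stage_ofv},
    )
    if compute_se:
        result.se = _pooled_se(subjects, pk_hat, free, spec, cov,
                               ("parent", "metabolite"))
    return result


def _pooled_se(subjects, pk_hat, free, spec, cov, include,
               rel_step: float = 1e-3) -> dict:
    """Delta-method standard errors from a central-difference Hessian of the
    -2LL surface in log-parameters."""
    x0 = np.log([getattr(pk_hat, k) for k in free])

    def f(x):
        pk = pk_hat.with_values(**dict(zip(free, np.exp(x))))
        return 2.0 * _pooled_nll(pk, subjects, spec, cov, include)

    n = len(x0)
    H = np.zeros((n, n))
    h = rel_step
    f0 = f(x0)
    for i in range(n):
        for j in range(i, n):
            xi, xj = np.zeros(n), np.zeros(n)
            xi[i] = h
            xj[j] = h
            if i == j:
                H[i, i] = (f(x0 + xi) - 2 * f0 + f(x0 - xi)) / h ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(x0 + xi + xj) - f(x0 + xi - xj)
                    - f(x0 - xi + xj) + f(x0 - xi - xj)) / (4 * h ** 2)
    try:
        cov_log = 2.0 * np.linalg.inv(H)   # -2LL Hessian -> 2 H^-1
        var_log = np.clip(np.diag(cov_log), 0.0, None)
    except np.linalg.LinAlgError:
        return {k: float("nan") for k in free}
    # SE on the natural scale: SE(P) ~ P * SE(log P)
    return {k: float(np.exp(x0[i]) * np.sqrt(var_log[i]))
            for i, k in enumerate(free)}


# ---------------------------------------------------------------------------
# Sequential PD fit
# ---------------------------------------------------------------------------

def _individual_pd(pd_try: PDParameters, eta: dict) -> PDParameters:
    if not eta:
        return pd_try
    vals = pd_try.as_dict()
    for k, v in eta.items():
        vals[k] = vals[k] * float(np.exp(v))
    vals["Imax"] = min(vals["Imax"], vals["BIS_baseline"])
    return PDParameters(**vals)


def _subject_ce(pk_i: PKParameters, ke0: float, data: SubjectData):
    A = system_matrix(pk_i, ke0)
    ce = solve_linear_system(A, data.regimen, data.bis_times)[:, IDX_CE]
    return np.clip(ce, 0.0, None)


def _make_inner_objective(pd_try: PDParameters, ce: np.ndarray,
                          dv: np.ndarray, sigma_prop_bis: float,
                          omegas: np.ndarray):
    """Batched inner eta objective for one subject.

    Returns ``G(pts)`` evaluating the penalized -log-likelihood of the
    subject's BIS data at a batch of (eta_Imax, eta_Hill) points at once
    (shape (K, 2) -> (K,)), with the upper-bound censoring term.
    """
    mask = np.isfinite(dv)
    y = dv[mask]
    ce_obs = ce[mask]
    cens = y >= BIS_UPPER - 1e-9
    y_int = y[~cens]
    b0, imax0, ic50, hill0 = (pd_try.BIS_baseline, pd_try.Imax,
                              pd_try.IC50, pd_try.Hill)
    with np.errstate(divide="ignore"):
        log_ratio = np.where(ce_obs > 0, np.log(ic50 / np.where(
            ce_obs > 0, ce_obs, 1.0)), np.inf)

    def G(pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        imax = np.minimum(imax0 * np.exp(pts[:, 0]), b0)     # (K,)
        hill = hill0 * np.exp(pts[:, 1])
        with np.errstate(over="ignore"):
            frac = 1.0 / (1.0 + np.exp(np.minimum(
                np.multiply.outer(hill, log_ratio), 700.0)))  # (K, n)
        f = b0 - imax[:, None] * frac
        sd = sigma_prop_bis * f
        bad = np.any(sd <= 0, axis=1)
        sd = np.where(sd > 0, sd, 1.0)
        z = (y[None, :] - f) / sd
        nll = np.where(cens[None, :],
                       -norm.logsf((BIS_UPPER - f) / sd),
                       0.5 * z ** 2 + np.log(sd) + 0.5 * _LOG_2PI)
        out = nll.sum(axis=1) + np.sum(pts ** 2 / (2 * omegas ** 2), axis=1)
        return np.where(bad, 1e12, out)

    return G


_FD_H = 1e-4
# FD stencil for gradient + Hessian of a 2-parameter function: center,
# +/- each axis, and the 4 diagonal cross points
_STENCIL_2D = np.array([[0, 0], [1, 0], [-1, 0], [0, 1], [0, -1],
                        [1, 1], [1, -1], [-1, 1], [-1, -1]]) * _FD_H


def _grad_hess_2d(G, x):
    v = G(x[None, :] + _STENCIL_2D)
    f0 = v[0]
    g = np.array([(v[1] - v[2]) / (2 * _FD_H), (v[3] - v[4]) / (2 * _FD_H)])
    H = np.empty((2, 2))
    H[0, 0] = (v[1] - 2 * f0 + v[2]) / _FD_H ** 2
    H[1, 1] = (v[3] - 2 * f0 + v[4]) / _FD_H ** 2
    H[0, 1] = H[1, 0] = (v[5] - v[6] - v[7] + v[8]) / (4 * _FD_H ** 2)
    return f0, g, H


def _newton_mode(G, x0, lo, hi, tol=1e-7, max_iter=30):
    """Damped-Newton minimiser for the 2-parameter inner eta problem;
    returns the mode, its value and the Hessian there (reused for the
    Laplace determinant)."""
    x = np.clip(np.asarray(x0, dtype=float), lo, hi)
    lam = 1e-6
    f0, g, H = _grad_hess_2d(G, x)
    for _ in range(max_iter):
        if np.linalg.norm(g) < tol:
            break
        improved = False
        for _ in range(12):
            try:
                step = np.linalg.solve(H + lam * np.eye(2), -g)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            x_new = np.clip(x + step, lo, hi)
            if G(x_new[None, :])[0] < f0:
                x = x_new
                lam = max(lam / 3.0, 1e-8)
                improved = True
                break
            lam *= 10.0
        if not improved:
            break
        f0, g, H = _grad_hess_2d(G, x)
    return x, f0, H


def fit_pd(dataset, pk: PKParameters, init_pd: PDParameters,
           spec: VariabilitySpec, cov: CovariateModel | None = None,
           n_starts: int = 3, start_sd: float = 0.3,
           bounds_factor: float = 20.0, seed: int = 0,
           maxiter: int = 400, marginal: bool = True) -> FitResult:
    """Sequential PK/PD fit of the five PD typicals (Imax, IC50,
    BIS_baseline, ke0, Hill).

    Individual PK parameters are first MAP-estimated from each subject's
    own concentration data (empirical Bayes around ``pk``); the effect
    compartment is then driven by the individual plasma prediction while
    the PD typicals are optimised on the pooled BIS likelihood. A
    naive-pooled fit (PD random effects at zero, multi-started) provides
    the starting point; with ``marginal=True`` the typicals are then
    re-estimated by maximising the Laplace-approximate marginal likelihood
    in which the random effects on Imax and the Hill exponent are
    integrated out (omega and sigma stay fixed at their supplied values).
    The naive-pooled objective is demonstrably inconsistent along the
    weakly identified Imax-IC50-Hill ridge when BSV on Imax/Hill is
    substantial; restoring the integral (mode + curvature term) removes
    that drift.
    """
    subjects = _as_subjects(dataset)
    cov = cov or CovariateModel()
    rng = np.random.default_rng(seed)

    # stage 1: empirical-Bayes individual PK
    pk_ind: list[PKParameters] = []
    for data in subjects:
        fit = map_estimate(data, pk, None, spec, cov,
                           include=("parent", "metabolite"))
        pk_ind.append(fit.extra["pk"])

    with_bis = [(d, p) for d, p in zip(subjects, pk_ind) if d.bis_times.size]
    if not with_bis:
        raise ValueError("dataset contains no BIS observations")

    names = PDParameters.names()
    base = np.array([getattr(init_pd, k) for k in names])
    bounds = [(np.log(b / bounds_factor), np.log(b * bounds_factor))
              for b in base]

    def objective(logx, eta_list=None, free=names, current=None):
        vals = dict(current.as_dict()) if current is not None else {}
        vals.update(zip(free, np.exp(logx)))
        if vals["Imax"] > vals["BIS_baseline"]:
            return 1e12
        pd_try = PDParameters(**vals)
        total = 0.0
        for i, (data, pk_i) in enumerate(with_bis):
            pd_i = _individual_pd(pd_try,
                                  eta_list[i] if eta_list else {})
            ce = _subject_ce(pk_i, pd_i.ke0, data)
            f = np.asarray(bis_from_ce(pd_i, ce))
            try:
                total += _bis_nll(data.dv_bis, f, spec.sigma_prop_bis * f)
            except ZeroDivisionError:
                return 1e12
        return total

    def fit_typicals(x0s, eta_list=None, free=names, current=None):
        fbounds = [bounds[names.index(k)] for k in free]
        best = None
        for s in x0s:
            res = minimize(objective, s, args=(eta_list, free, current),
                           method="L-BFGS-B", bounds=fbounds,
                           options={"maxiter": maxiter, "ftol": 1e-10})
            if best is None or res.fun < best.fun:
                best = res
        return best

    # stage 2: naive-pooled PD fit, multi-started
    x0 = np.log(base)
    starts = [x0] + [x0 + rng.normal(0.0, start_sd, size=len(names))
                     for _ in range(max(0, n_starts - 1))]
    best = fit_typicals(starts)
    pd_hat = PDParameters(**dict(zip(names, np.exp(best.x))))

    # stage 3: Laplace marginal fit over the eta on Imax and Hill
    eta_names = [k for k in PDParameters.names()
                 if spec.omega.get(k, 0.0) > 0]
    omegas = np.array([spec.omega[k] for k in eta_names])
    eta_frame = None
    objective_value = 2.0 * float(best.fun)
    converged = bool(best.success)
    if marginal and eta_names:
        lo, hi = -4 * omegas, 4 * omegas
        log_det_omega2 = float(np.sum(2 * np.log(omegas)))
        ce_cache: list[dict] = [{} for _ in with_bis]
        warm = [np.zeros(len(eta_names)) for _ in with_bis]
        modes = [w.copy() for w in warm]

        def marginal_ofv(logx):
            vals = dict(zip(names, np.exp(logx)))
            if vals["Imax"] > vals["BIS_baseline"]:
                return 1e12
            pd_try = PDParameters(**vals)
            key = round(pd_try.ke0, 14)
            total = 0.0
            for i, (data, pk_i) in enumerate(with_bis):
                ce = ce_cache[i].get(key)
                if ce is None:
                    ce = _subject_ce(pk_i, pd_try.ke0, data)
                    if len(ce_cache[i]) > 512:
                        ce_cache[i].clear()
                    ce_cache[i][key] = ce
                G = _make_inner_objective(pd_try, ce, data.dv_bis,
                                          spec.sigma_prop_bis, omegas)
                mode, g0, H = _newton_mode(G, warm[i], lo, hi)
                warm[i] = mode
                modes[i] = mode
                # -log integral ~ G(mode) + log det(Omega H)/2
                sign, logdet = np.linalg.slogdet(H)
                if sign <= 0:   # flat/indefinite curvature: fall back to
                    logdet = 0.0  # the penalized mode contribution
                total += g0 + 0.5 * (logdet + log_det_omega2)
            return total

        best_m = minimize(marginal_ofv,
                          np.log([getattr(pd_hat, k) for k in names]),
                          method="L-BFGS-B", bounds=bounds,
                          options={"maxiter": maxiter, "ftol": 1e-10})
        polish = minimize(marginal_ofv, best_m.x, method="Nelder-Mead",
                          options={"maxiter": 200, "xatol": 1e-6,
                                   "fatol": 1e-8})
        if polish.fun < best_m.fun:
            best_m = polish
        marginal_ofv(best_m.x)   # refresh modes at the optimum
        pd_hat = PDParameters(**dict(zip(names, np.exp(best_m.x))))
        eta_frame = pd.DataFrame(modes, columns=eta_names)
        objective_value = 2.0 * float(best_m.fun)
        converged = bool(best_m.success) or polish.fun <= best_m.fun

    n_obs = sum(int(np.isfinite(d.dv_bis).sum()) for d, _ in with_bis)
    return FitResult(
        estimates=pd_hat.as_dict(), objective=objective_value,
        converged=converged, etas=eta_frame, n_obs=n_obs,
        extra={"pd": pd_hat, "pk_individual": pk_ind},
    )


# ---------------------------------------------------------------------------
# Stepwise covariate screening
# ---------------------------------------------------------------------------

_FORWARD_DOFV = 3.84    # chi-square, 1 df, p < 0.05
_BACKWARD_DOFV = 6.63   # chi-square, 1 df, p < 0.01


def _design_column(covariate: str, subjects: list[SubjectData]) -> np.ndarray:
    """Regression column for one covariate: log(cov / median) for
    continuous covariates, a 0/1 indicator for sex."""
    if covariate == "sex":
        return np.array([float(d.subject.sex) for d in subjects])
    vals = np.array([float(getattr(d.subject, covariate)) for d in subjects])
    return np.log(vals / np.median(vals))


def _regression_m2ll(y: np.ndarray, X: np.ndarray) -> float:
    """-2 log-likelihood of a Gaussian linear model at the MLE
    (profile over the residual variance)."""
    n = len(y)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    rss = max(rss, 1e-300)
    return n * (np.log(rss / n) + 1.0 + _LOG_2PI)


def covariate_screen(dataset, base_fit: FitResult | pd.DataFrame,
                     spec: VariabilitySpec | None = None,
                     pk: PKParameters | None = None,
                     cov: CovariateModel | None = None,
                     candidates: tuple[tuple[str, str], ...] | None = None,
                     forward_dofv: float = _FORWARD_DOFV,
                     backward_dofv: float = _BACKWARD_DOFV,
                     ) -> tuple[list[dict], pd.DataFrame]:
    """Stepwise covariate screening on the empirical-Bayes random effects.

    For every candidate (parameter, covariate) pair the change in objective
    function (dOFV) is the likelihood-ratio statistic of regressing the
    MAP eta estimates of that parameter on the covariate (log-transformed
    and median-centred for age/height, 0/1 for sex), on top of the terms
    already included for that parameter. Forward inclusion requires
    dOFV > 3.84 per added term; backward elimination then removes any term
    whose deletion raises the OFV by <= 6.63, so a covariate is only
    retained at the stricter p < 0.01 level.

    Returns ``(selected, ledger)``: the selected covariate relationships
    (with regression coefficients convertible to power/proportional model
    parameters) and the full dOFV table of every step.

    ``base_fit`` may be a :class:`FitResult` whose ``etas`` frame holds the
    MAP estimates; otherwise MAP estimation is run here (requires ``spec``
    and ``pk``).
    """
    subjects = _as_subjects(dataset)
    etas = base_fit.etas if isinstance(base_fit, FitResult) else base_fit
    if etas is None:
        if spec is None or pk is None:
            raise ValueError("need spec and pk to MAP-estimate etas")
        rows = [map_estimate(d, pk, None, spec, cov,
                             include=("parent", "metabolite")).estimates
                for d in subjects]
        etas = pd.DataFrame(rows)
    if candidates is None:
        params = [p for p in ("CL_p", "V1") if p in etas.columns]
        candidates = tuple((p, c) for p in params
                           for c in ("age", "height", "sex"))

    cols = {c: _design_column(c, subjects)
            for c in {c for _, c in candidates}}
    n = len(subjects)
    ones = np.ones((n, 1))

    def m2ll(param: str, terms: list[str]) -> float:
        y = etas[param].to_numpy(dtype=float)
        X = np.hstack([ones] + [cols[c][:, None] for c in terms])
        return _regression_m2ll(y, X)

    included: dict[str, list[str]] = {}
    ledger_rows = []

    # forward inclusion
    step = 0
    while True:
        step += 1
        best = None
        for param, c in candidates:
            terms = included.get(param, [])
            if c in terms:
                continue
            dofv = m2ll(param, terms) - m2ll(param, terms + [c])
            ledger_rows.append({"step": step, "phase": "forward",
                                "parameter": param, "covariate": c,
                                "dofv": dofv,
                                "included": dofv > forward_dofv})
            if best is None or dofv > best[2]:
                best = (param, c, dofv)
        if best is None or best[2] <= forward_dofv:
            break
        included.setdefault(best[0], []).append(best[1])

    # backward elimination
    changed = True
    while changed and any(included.values()):
        changed = False
        step += 1
        for param, terms in list(included.items()):
            for c in list(terms):
                kept = [t for t in terms if t != c]
                rise = m2ll(param, kept) - m2ll(param, terms)
                keep = rise > backward_dofv
                ledger_rows.append({"step": step, "phase": "backward",
                                    "parameter": param, "covariate": c,
                                    "dofv": rise, "included": keep})
                if not keep:
                    terms.remove(c)
                    changed = True
        included = {p: t for p, t in included.items() if t}

    selected = []
    for param, terms in included.items():
        y = etas[param].to_numpy(dtype=float)
        X = np.hstack([ones] + [cols[c][:, None] for c in terms])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        for c, b in zip(terms, beta[1:]):
            selected.append({
                "parameter": param, "covariate": c,
                "coefficient": float(b),
                # theta for Eq.-style models: power exponent for continuous
                # covariates, multiplicative factor for sex
                "theta": float(np.exp(b)) if c == "sex" else float(b),
            })
    ledger = pd.DataFrame(ledger_rows,
                          columns=["step", "phase", "parameter", "covariate",
                                   "dofv", "included"])
    return selected, ledger
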