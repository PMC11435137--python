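"""Between-subject variability, covariate scaling and residual error.

Typical values become individual parameters through

``P_i = P_hat * (WT_i/60)^theta_allo * cov_terms * exp(eta_P)``

with ``eta_P ~ N(0, omega_P^2)`` (log-normal BSV). Noise-free predictions
become observations through a proportional error for parent concentrations
and BIS and a combined proportional + additive error for the metabolite;
the two proportional concentration errors are correlated because both
analytes are assayed from the same blood sample.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .parameters import (CovariateModel, PDParameters, PKParameters, Subject,
                         VariabilitySpec)

__all__ = [
    "sample_etas",
    "individual_parameters",
    "sample_eps",
    "apply_ruv",
]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_etas(spec: VariabilitySpec, n_subjects: int,
                seed) -> pd.DataFrame:
    """Draw independent normal random effects, one row per subject, one
    column per parameter carrying BSV (SD = omega). Deterministic under a
    fixed seed."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = _as_rng(seed)
    names = list(spec.omega)
    sds = np.array([spec.omega[k] for k in names])
    draws = rng.standard_normal((n_subjects, len(names))) * sds
    return pd.DataFrame(draws, columns=names)


def individual_parameters(pk: PKParameters, pd_params: PDParameters | None,
                          subject: Subject,
                          cov: CovariateModel | None = None,
                          eta: Mapping[str, float] | None = None,
                          ) -> tuple[PKParameters, PDParameters | None]:
    """Individual parameter set for one subject.

    Covariate multipliers (allometric weight scaling plus any screened
    effects) apply to the PK parameters; random effects ``eta`` apply to any
    parameter named in the mapping. Parameters absent from ``eta`` get
    eta = 0.
    """
    cov = cov or CovariateModel()
    eta = dict(eta or {})
    known = set(pk.names()) | (set(pd_params.names()) if pd_params else set())
    unknown = set(eta) - known
    if unknown:
        raise KeyError(f"unknown parameter(s) in eta: {sorted(unknown)}")

    pk_vals = {}
    for name, value in pk.as_dict().items():
        pk_vals[name] = (value * cov.multiplier(name, subject)
                         * float(np.exp(eta.get(name, 0.0))))
    pk_i = PKParameters(**pk_vals)

    pd_i = None
    if pd_params is not None:
        pd_vals = {name: value * float(np.exp(eta.get(name, 0.0)))
                   for name, value in pd_params.as_dict().items()}
        # keep the Hill-model range valid under extreme Imax draws
        pd_vals["Imax"] = min(pd_vals["Imax"], pd_vals["BIS_baseline"])
        pd_i = PDParameters(**pd_vals)
    return pk_i, pd_i


def sample_eps(spec: VariabilitySpec, n_pk: int, n_bis: int,
               seed) -> dict[str, np.ndarray]:
    """Residual-error draws for ``n_pk`` paired concentration samples and
    ``n_bis`` BIS observations.

    The parent and metabolite proportional errors at the same sampling time
    are drawn from a bivariate normal with correlation ``rho_pm``; the
    metabolite additive error and the BIS error are independent.
    """
    rng = _as_rng(seed)
    sp, sm = spec.sigma_prop_parent, spec.sigma_prop_metab
    cov = np.array([[sp ** 2, spec.rho_pm * sp * sm],
                    [spec.rho_pm * sp * sm, sm ** 2]])
    if n_pk:
        pair = rng.multivariate_normal(np.zeros(2), cov, size=n_pk,
                                       method="cholesky")
    else:
        pair = np.zeros((0, 2))
    return {
        "prop_parent": pair[:, 0],
        "prop_metab": pair[:, 1],
        "add_metab": rng.standard_normal(n_pk) * spec.sigma_add_metab,
        "prop_bis": rng.standard_normal(n_bis) * spec.sigma_prop_bis,
    }


def apply_ruv(pred_parent, pred_metab, pred_bis, spec: VariabilitySpec,
              eps: Mapping[str, np.ndarray]) -> tuple[np.ndarray, np.ndarray,
                                                      np.ndarray]:
    """Turn noise-free predictions into observations.

    ``Y_parent = F (1 + eps1p)``; ``Y_metab = F (1 + eps1m) + eps2m``;
    ``Y_bis = F (1 + eps1b)``. Negative values are allowed here; censoring
    against the assay LLOQ is the study generator's job.
    """
    fp = np.asarray(pred_parent, dtype=float)
    fm = np.asarray(pred_metab, dtype=float)
    fb = np.asarray(pred_bis, dtype=float)
    y_p = fp * (1.0 + eps["prop_parent"])
    y_m = fm * (1.0 + eps["prop_metab"]) + eps["add_metab"]
    y_b = fb * (1.0 + eps["prop_bis"])
    return y_p, y_m, y_b
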