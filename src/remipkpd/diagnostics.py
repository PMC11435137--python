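"""Goodness-of-fit summaries and visual predictive checks.

The VPC simulates many replicate studies on the *observed* design (doses,
sampling times and demographics are taken from the observation table),
recomputes percentiles per time bin in each replicate, and overlays the
observed percentiles on the simulated percentile bands. BLQ records are
excluded from percentile computation on both sides; a BLQ-fraction summary
is reported instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import bis_from_ce, system_matrix, solve_linear_system, \
    MG_PER_L_TO_NG_PER_ML, IDX_CE
from .parameters import (CovariateModel, LLOQ_NG_ML, PDParameters,
                         PKParameters, VariabilitySpec)
from .population import apply_ruv, individual_parameters, sample_eps, sample_etas
from .study import SubjectData, iter_subjects

__all__ = ["gof_table", "vpc", "VPCResult"]


def _as_subjects(dataset) -> list[SubjectData]:
    if isinstance(dataset, pd.DataFrame):
        return list(iter_subjects(dataset))
    return list(dataset)


def _predict_all(pk_i: PKParameters, pd_i: PDParameters, data: SubjectData):
    times = np.unique(np.concatenate([data.pk_times, data.bis_times])) \
        if data.bis_times.size else np.asarray(data.pk_times)
    A = system_matrix(pk_i, pd_i.ke0)
    st = solve_linear_system(A, data.regimen, times)
    i_pk = np.searchsorted(times, data.pk_times)
    cp = MG_PER_L_TO_NG_PER_ML * st[i_pk, 0] / pk_i.V1
    cm = MG_PER_L_TO_NG_PER_ML * st[i_pk, 4] / pk_i.V5
    if data.bis_times.size:
        ce = st[np.searchsorted(times, data.bis_times), IDX_CE]
        bis = np.asarray(bis_from_ce(pd_i, np.clip(ce, 0.0, None)))
    else:
        bis = np.empty(0)
    return cp, cm, bis


def gof_table(dataset, pk: PKParameters, pd_params: PDParameters,
              spec: VariabilitySpec, cov: CovariateModel | None = None,
              etas: pd.DataFrame | None = None,
              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-record goodness-of-fit quantities and a per-analyte summary.

    For every observed record: the population prediction PRED (random
    effects at zero, covariates applied), the individual prediction IPRED
    (random effects from ``etas``, one row per subject in dataset order),
    the proportional residual (DV - IPRED)/IPRED and the standardized
    residual (DV - IPRED)/SD with the residual-error SD of the analyte.
    Returns ``(records, summary)``; summary holds mean and SD of the
    standardized residuals per analyte.
    """
    subjects = _as_subjects(dataset)
    cov = cov or CovariateModel()
    rows = []
    for i, data in enumerate(subjects):
        eta = {} if etas is None else \
            {k: v for k, v in etas.iloc[i].items() if np.isfinite(v)}
        pk_p, pd_p = individual_parameters(pk, pd_params, data.subject, cov, {})
        pk_i, pd_i = individual_parameters(pk, pd_params, data.subject, cov, eta)
        pred = _predict_all(pk_p, pd_p, data)
        ipred = _predict_all(pk_i, pd_i, data)
        series = [
            ("parent", data.pk_times, data.dv_parent, pred[0], ipred[0],
             lambda f: spec.sigma_prop_parent * f),
            ("metabolite", data.pk_times, data.dv_metab, pred[1], ipred[1],
             lambda f: np.sqrt((spec.sigma_prop_metab * f) ** 2
                               + spec.sigma_add_metab ** 2)),
            ("bis", data.bis_times, data.dv_bis, pred[2], ipred[2],
             lambda f: spec.sigma_prop_bis * f),
        ]
        for dvid, times, dv, pr, ipr, sd_fn in series:
            for t, y, p, ip in zip(times, dv, pr, ipr):
                if not np.isfinite(y):
                    continue
                sd = float(sd_fn(ip))
                rows.append({
                    "ID": data.subject.id, "TIME": t, "DVID": dvid, "DV": y,
                    "PRED": p, "IPRED": ip,
                    "prop_residual": (y - ip) / ip if ip != 0 else np.nan,
                    "std_residual": (y - ip) / sd if sd > 0 else np.nan,
                })
    records = pd.DataFrame(rows)
    if records.empty:
        return records, pd.DataFrame()
    summary = (records.groupby("DVID")["std_residual"]
               .agg(["mean", "std", "count"]).reset_index())
    return records, summary


# ---------------------------------------------------------------------------
# Visual predictive check
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VPCResult:
    """Tidy VPC output.

    ``table`` rows: one per (observation type, time bin, percentile) with
    the observed percentile, the median of that percentile across simulated
    replicate studies, and its simulation CI. ``blq`` summarises the BLQ
    fraction per bin for concentrations.
    """

    table: pd.DataFrame
    blq: pd.DataFrame
    n_simulations: int
    percentiles: tuple[float, ...]

    def coverage(self, percentile: float = 50.0) -> float:
        """Fraction of bins whose observed percentile lies inside the
        simulated CI of the same percentile."""
        sub = self.table[self.table["percentile"] == percentile]
        if sub.empty:
            return float("nan")
        ok = (sub["observed"] >= sub["sim_ci_low"]) & \
             (sub["observed"] <= sub["sim_ci_high"])
        return float(ok.mean())


def _default_bins(times: np.ndarray, values: np.ndarray,
                  min_per_bin: int = 3) -> list[np.ndarray]:
    """Design-based bins: one bin per scheduled time, merging sparse bins
    into their right neighbour."""
    uniq = np.unique(times)
    groups: list[list[float]] = []
    pending: list[float] = []
    for t in uniq:
        n = int(np.isfinite(values[times == t]).sum())
        pending.append(t)
        if sum(int(np.isfinite(values[times == u]).sum())
               for u in pending) >= min_per_bin:
            groups.append(pending)
            pending = []
    if pending:
        if groups:
            groups[-1].extend(pending)
        else:
            groups.append(pending)
    return [np.asarray(g) for g in groups]


def _simulate_replicate(subjects, pk, pd_params, spec, cov, rng):
    """One replicate study on the observed design; returns per-subject
    (parent, metabolite, bis) observation arrays with BLQ as NaN."""
    etas = sample_etas(spec, len(subjects), rng)
    out = []
    for i, data in enumerate(subjects):
        eta = etas.iloc[i].to_dict()
        pk_i, pd_i = individual_parameters(pk, pd_params, data.subject,
                                           cov, eta)
        cp, cm, bis = _predict_all(pk_i, pd_i, data)
        bis = np.where(data.bis_times == 0.0, pd_i.BIS_baseline, bis) \
            if bis.size else bis
        eps = sample_eps(spec, len(data.pk_times), len(data.bis_times), rng)
        y_p, y_m, y_b = apply_ruv(cp, cm, bis, spec, eps)
        y_p = np.where((data.pk_times == 0) | (y_p < LLOQ_NG_ML), np.nan, y_p)
        y_m = np.where((data.pk_times == 0) | (y_m < LLOQ_NG_ML), np.nan, y_m)
        y_b = np.clip(y_b, 0.0, 100.0) if y_b.size else y_b
        out.append((y_p, y_m, y_b))
    return out


def vpc(dataset, pk: PKParameters, pd_params: PDParameters,
        spec: VariabilitySpec, cov: CovariateModel | None = None,
        n_sim: int = 1000, percentiles: tuple[float, ...] = (2.5, 50.0, 97.5),
        bins: dict | None = None, seed=0, ci: float = 95.0) -> VPCResult:
    """Visual predictive check of a model against an observation table.

    ``n_sim`` replicate studies are simulated on the observed design with
    full between-subject variability and residual error, then censored at
    the LLOQ exactly as real data would be. Percentile bands are computed
    per time bin; the CI of each simulated percentile is its spread across
    replicates. ``bins`` optionally maps an observation type to an array of
    bin edges; the default is one bin per scheduled sampling time (sparse
    bins merged right). Deterministic under a fixed seed.
    """
    subjects = _as_subjects(dataset)
    cov = cov or CovariateModel()
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    rng = np.random.default_rng(seed)

    obs = {"parent": ([], []), "metabolite": ([], []), "bis": ([], [])}
    for data in subjects:
        obs["parent"][0].append(data.pk_times)
        obs["parent"][1].append(data.dv_parent)
        obs["metabolite"][0].append(data.pk_times)
        obs["metabolite"][1].append(data.dv_metab)
        obs["bis"][0].append(data.bis_times)
        obs["bis"][1].append(data.dv_bis)
    obs_flat = {k: (np.concatenate(t), np.concatenate(v))
                for k, (t, v) in obs.items() if len(t)}

    # bin membership per observation type
    bin_groups: dict[str, list[np.ndarray]] = {}
    for dvid, (times, values) in obs_flat.items():
        if bins is not None and dvid in bins:
            edges = np.asarray(bins[dvid], dtype=float)
            uniq = np.unique(times)
            groups = [uniq[(uniq >= lo) & (uniq < hi)]
                      for lo, hi in zip(edges[:-1], edges[1:])]
            groups[-1] = np.append(groups[-1],
                                   uniq[uniq >= edges[-1]])  # right edge
            bin_groups[dvid] = [g for g in groups if g.size]
        else:
            bin_groups[dvid] = _default_bins(times, values)

    def percentiles_for(dvid, times, values):
        res = np.full((len(bin_groups[dvid]), len(percentiles)), np.nan)
        for b, group in enumerate(bin_groups[dvid]):
            mask = np.isin(times, group) & np.isfinite(values)
            if mask.sum() >= 1:
                res[b] = np.percentile(values[mask], percentiles)
        return res

    obs_pct = {dvid: percentiles_for(dvid, t, v)
               for dvid, (t, v) in obs_flat.items()}

    sim_pct = {dvid: np.full((n_sim,) + obs_pct[dvid].shape, np.nan)
               for dvid in obs_flat}
    sim_blq = {dvid: np.zeros((n_sim, len(bin_groups[dvid])))
               for dvid in ("parent", "metabolite") if dvid in obs_flat}
    for r in range(n_sim):
        rep = _simulate_replicate(subjects, pk, pd_params, spec, cov, rng)
        rep_flat = {
            "parent": np.concatenate([x[0] for x in rep]),
            "metabolite": np.concatenate([x[1] for x in rep]),
            "bis": np.concatenate([x[2] for x in rep]),
        }
        for dvid, (times, _) in obs_flat.items():
            sim_pct[dvid][r] = percentiles_for(dvid, times, rep_flat[dvid])
            if dvid in sim_blq:
                for b, group in enumerate(bin_groups[dvid]):
                    mask = np.isin(times, group)
                    sim_blq[dvid][r, b] = float(
                        np.mean(~np.isfinite(rep_flat[dvid][mask])))

    lo, hi = (100.0 - ci) / 2.0, 100.0 - (100.0 - ci) / 2.0
    rows = []
    for dvid, (times, values) in obs_flat.items():
        for b, group in enumerate(bin_groups[dvid]):
            mask = np.isin(times, group) & np.isfinite(values)
            for p_idx, p in enumerate(percentiles):
                band = sim_pct[dvid][:, b, p_idx]
                band = band[np.isfinite(band)]
                rows.append({
                    "dvid": dvid, "bin": b,
                    "bin_lo": float(group.min()),
                    "bin_hi": float(group.max()),
                    "n_obs": int(mask.sum()),
                    "percentile": p,
                    "observed": obs_pct[dvid][b, p_idx],
                    "sim_median": float(np.median(band)) if band.size else np.nan,
                    "sim_ci_low": float(np.percentile(band, lo)) if band.size else np.nan,
                    "sim_ci_high": float(np.percentile(band, hi)) if band.size else np.nan,
                })
    blq_rows = []
    for dvid in sim_blq:
        times, values = obs_flat[dvid]
        for b, group in enumerate(bin_groups[dvid]):
            mask = np.isin(times, group)
            blq_rows.append({
                "dvid": dvid, "bin": b, "bin_lo": float(group.min()),
                "bin_hi": float(group.max()),
                "observed_blq_fraction": float(
                    np.mean(~np.isfinite(values[mask]))),
                "sim_blq_fraction": float(np.mean(sim_blq[dvid][:, b])),
            })
    return VPCResult(table=pd.DataFrame(rows), blq=pd.DataFrame(blq_rows),
                     n_simulations=n_sim, percentiles=tuple(percentiles))
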