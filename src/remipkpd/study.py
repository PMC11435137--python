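"""Synthetic clinical studies with the remimazolam phase-I design.

Two studies are emulated. Study 1: single IV bolus across seven dose
levels (0.025-0.4 mg/kg) with a 21-point plasma schedule over 12 h and a
10-point BIS schedule over 1 h. Study 2: a 1-min loading infusion
(0.2 mg/kg/min) followed by a 2-h maintenance infusion (1 mg/kg/h), with
on-infusion (Part I) and post-infusion (Part II) sampling schedules.
Generated observations carry log-normal between-subject variability,
correlated proportional(+additive) residual error, and censoring at the
2 ng/mL assay LLOQ.

Datasets use a NONMEM-style rectangular CSV with columns
ID, TIME, AMT, RATE, EVID, CMT, DV, DVID, MDV, BLQ, WT, AGE, HGT, SEX;
times are absolute minutes since first dose.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator

import numpy as np
import pandas as pd

from .model import analytic_solution, bis_from_ce
from .parameters import (CovariateModel, LLOQ_NG_ML, PDParameters,
                         PKParameters, Subject, VariabilitySpec)
from .population import apply_ruv, individual_parameters, sample_eps, sample_etas
from .regimen import DoseEvent, Regimen

__all__ = [
    "Arm",
    "StudyDesign",
    "default_design",
    "generate_dataset",
    "read_dataset",
    "write_dataset",
    "SubjectData",
    "iter_subjects",
    "DATASET_COLUMNS",
]

DATASET_COLUMNS = ["ID", "TIME", "AMT", "RATE", "EVID", "CMT", "DV", "DVID",
                   "MDV", "BLQ", "WT", "AGE", "HGT", "SEX"]

DVID_PARENT = "parent"
DVID_METABOLITE = "metabolite"
DVID_BIS = "bis"


@dataclass(frozen=True)
class Arm:
    """One treatment arm: weight-normalised doses plus sampling schedules.

    ``doses_per_kg`` holds (start time min, dose mg/kg, duration min)
    triples; duration 0 is an instantaneous bolus.
    """

    label: str
    n_subjects: int
    doses_per_kg: tuple[tuple[float, float, float], ...]
    pk_times: tuple[float, ...]
    bis_times: tuple[float, ...]

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for times in (self.pk_times, self.bis_times):
            arr = np.asarray(times)
            if arr.size and (np.any(np.diff(arr) < 0) or arr[0] < 0):
                raise ValueError("sampling times must be sorted, >= 0")

    def regimen(self, weight_kg: float) -> Regimen:
        return Regimen(events=tuple(
            DoseEvent(t, dose * weight_kg, dur)
            for t, dose, dur in self.doses_per_kg))


@dataclass(frozen=True)
class StudyDesign:
    """Arms plus the demographic sampling ranges of the study population."""

    arms: tuple[Arm, ...]
    wt_range: tuple[float, float] = (52.0, 75.0)
    age_range: tuple[float, float] = (19.0, 43.0)
    bmi_range: tuple[float, float] = (19.3, 24.0)
    p_female: float = 15.0 / 55.0

    @property
    def n_subjects(self) -> int:
        return sum(a.n_subjects for a in self.arms)


# Study 1 plasma schedule: minutes, then 1-12 h converted to min.
_S1_PK = (0, 1, 2, 3, 4, 5, 6, 8, 10, 12, 15, 20, 30, 45,
          60, 90, 120, 180, 240, 480, 720)
_S1_BIS = (0, 1, 2, 5, 10, 20, 30, 40, 50, 60)

# Study 2: maintenance infusion runs from 1 to 121 min (after the 1-min
# loading infusion); Part II times are offsets from end of infusion.
_S2_STOP = 121.0
_S2_PK_PART1 = (0, 1, 15, 45, 60, 90, 120)
_S2_PK_PART2 = (1, 2, 3, 4, 5, 6, 8, 10, 12, 15, 20, 30, 45,
                60, 90, 120, 180, 240, 360, 600)
_S2_BIS_PART1 = (0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 15, 20, 25, 30, 35,
                 40, 45, 50, 55, 60, 70, 80, 90, 100, 110)
_S2_BIS_PART2 = (1, 2, 5, 10, 15, 20, 25, 30, 35, 40, 45, 50, 55, 60)

# Single-bolus dose levels (mg/kg) and arm sizes. The printed per-arm counts
# sum to 48 against a stated single-bolus total of 46; the 0.3 mg/kg arm is
# taken as n = 8 so the totals (46 + 9 = 55) hold.
_S1_ARMS = ((0.025, 3), (0.05, 3), (0.075, 8), (0.1, 8),
            (0.2, 8), (0.3, 8), (0.4, 8))


def default_design() -> StudyDesign:
    """The two-study phase-I design: 46 single-bolus subjects over seven
    dose levels plus 9 loading + maintenance infusion subjects."""
    arms = [
        Arm(label=f"bolus_{dose}", n_subjects=n,
            doses_per_kg=((0.0, dose, 0.0),),
            pk_times=tuple(float(t) for t in _S1_PK),
            bis_times=tuple(float(t) for t in _S1_BIS))
        for dose, n in _S1_ARMS
    ]
    arms.append(Arm(
        label="infusion",
        n_subjects=9,
        doses_per_kg=((0.0, 0.2, 1.0), (1.0, 2.0, 120.0)),
        pk_times=tuple(float(t) for t in _S2_PK_PART1)
        + tuple(_S2_STOP + t for t in _S2_PK_PART2),
        bis_times=tuple(float(t) for t in _S2_BIS_PART1)
        + tuple(_S2_STOP + t for t in _S2_BIS_PART2),
    ))
    return StudyDesign(arms=tuple(arms))


def _sample_subject(design: StudyDesign, sid: int,
                    rng: np.random.Generator) -> Subject:
    wt = rng.uniform(*design.wt_range)
    bmi = rng.uniform(*design.bmi_range)
    height = 100.0 * np.sqrt(wt / bmi)
    age = rng.uniform(*design.age_range)
    sex = int(rng.random() < design.p_female)
    return Subject(id=sid, WT=wt, age=age, height=height, sex=sex)


def generate_dataset(design: StudyDesign, pk: PKParameters,
                     pd_params: PDParameters, spec: VariabilitySpec,
                     seed, cov: CovariateModel | None = None,
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one complete study.

    Returns ``(table, truth)``: the observation table in the rectangular
    dataset format, and the per-subject ground truth (demographics, eta
    draws, individual parameter values) for recovery tests. Deterministic
    under a fixed seed.

    Pre-dose records (t = 0): concentrations are emitted as BLQ
    placeholders; BIS carries the subject's true baseline plus residual
    error. Concentrations below the 2 ng/mL LLOQ are flagged BLQ with no
    reported value. Observed BIS is clipped to the instrument's 0-100 scale.
    """
    rng = np.random.default_rng(seed)
    cov = cov or CovariateModel()
    etas = sample_etas(spec, design.n_subjects, rng)

    rows: list[dict] = []
    truth_rows: list[dict] = []
    sid = 0
    for arm in design.arms:
        for _ in range(arm.n_subjects):
            sid += 1
            subject = _sample_subject(design, sid, rng)
            eta = etas.iloc[sid - 1].to_dict()
            pk_i, pd_i = individual_parameters(pk, pd_params, subject, cov, eta)
            regimen = arm.regimen(subject.WT)

            demo = {"WT": subject.WT, "AGE": subject.age,
                    "HGT": subject.height, "SEX": subject.sex}
            for ev in regimen.events:
                rows.append({"ID": sid, "TIME": ev.time, "AMT": ev.amount,
                             "RATE": ev.rate, "EVID": 1, "CMT": 1,
                             "DV": np.nan, "DVID": "", "MDV": 1, "BLQ": 0,
                             **demo})

            pk_times = np.asarray(arm.pk_times, dtype=float)
            bis_times = np.asarray(arm.bis_times, dtype=float)
            all_times = np.unique(np.concatenate([pk_times, bis_times]))
            sim = analytic_solution(pk_i, pd_i.ke0, regimen, all_times)
            cp = np.interp(pk_times, all_times, sim.cp)
            cm = np.interp(pk_times, all_times, sim.cm)
            ce = np.interp(bis_times, all_times, sim.ce)
            bis_pred = bis_from_ce(pd_i, np.clip(ce, 0.0, None))
            # pre-dose BIS is the subject's own baseline
            bis_pred = np.where(bis_times == 0.0, pd_i.BIS_baseline, bis_pred)

            eps = sample_eps(spec, len(pk_times), len(bis_times), rng)
            y_p, y_m, y_b = apply_ruv(cp, cm, bis_pred, spec, eps)
            y_b = np.clip(y_b, 0.0, 100.0)

            for dvid, y in ((DVID_PARENT, y_p), (DVID_METABOLITE, y_m)):
                for t, val in zip(pk_times, y):
                    blq = int(t == 0.0 or val < LLOQ_NG_ML)
                    rows.append({"ID": sid, "TIME": t, "AMT": 0.0,
                                 "RATE": 0.0, "EVID": 0, "CMT": 0,
                                 "DV": np.nan if blq else val, "DVID": dvid,
                                 "MDV": blq, "BLQ": blq, **demo})
            for t, val in zip(bis_times, y_b):
                rows.append({"ID": sid, "TIME": t, "AMT": 0.0, "RATE": 0.0,
                             "EVID": 0, "CMT": 0, "DV": val,
                             "DVID": DVID_BIS, "MDV": 0, "BLQ": 0, **demo})

            truth_rows.append({
                "ID": sid, "arm": arm.label, **demo,
                **{f"eta_{k}": v for k, v in eta.items()},
                **{f"pk_{k}": v for k, v in pk_i.as_dict().items()},
                **{f"pd_{k}": v for k, v in pd_i.as_dict().items()},
            })

    table = pd.DataFrame(rows, columns=DATASET_COLUMNS)
    truth = pd.DataFrame(truth_rows)
    return table, truth


def write_dataset(table: pd.DataFrame, path) -> None:
    """Write an observation table as CSV (lossless round trip with
    :func:`read_dataset`)."""
    missing = [c for c in DATASET_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"table is missing columns: {missing}")
    table.to_csv(path, index=False, float_format="%.10g")


def read_dataset(path) -> pd.DataFrame:
    """Read a rectangular dataset CSV, validating the column schema."""
    try:
        table = pd.read_csv(path, dtype={"DVID": "string"},
                            on_bad_lines="error")
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed dataset {path}: {exc}") from exc
    missing = [c for c in DATASET_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"dataset {path} is missing columns: {missing}")
    table["DVID"] = table["DVID"].fillna("").astype(str)
    for col in ("TIME", "AMT", "RATE", "DV", "WT", "AGE", "HGT"):
        table[col] = pd.to_numeric(table[col], errors="raise")
    for col in ("EVID", "CMT", "MDV", "BLQ", "SEX"):
        table[col] = pd.to_numeric(table[col], errors="raise").astype(int)
    return table[DATASET_COLUMNS]


@dataclass
class SubjectData:
    """Per-subject view of an observation table, ready for estimation."""

    subject: Subject
    regimen: Regimen
    pk_times: np.ndarray        # shared parent/metabolite sampling times
    dv_parent: np.ndarray       # NaN where BLQ/missing
    dv_metab: np.ndarray
    bis_times: np.ndarray
    dv_bis: np.ndarray

    def replace(self, **kw) -> "SubjectData":
        return replace(self, **kw)


def iter_subjects(table: pd.DataFrame) -> Iterator[SubjectData]:
    """Split an observation table into per-subject records.

    Dose rows (EVID = 1) become the regimen (RATE = 0 encodes an
    instantaneous bolus, RATE > 0 a zero-order infusion of AMT over
    AMT/RATE min). BLQ rows keep their time with a NaN value so schedules
    stay aligned across subjects.
    """
    for sid, grp in table.groupby("ID", sort=True):
        first = grp.iloc[0]
        subject = Subject(id=sid, WT=float(first["WT"]),
                          age=float(first["AGE"]),
                          height=float(first["HGT"]),
                          sex=int(first["SEX"]))
        doses = grp[grp["EVID"] == 1]
        if doses.empty:
            raise ValueError(f"subject {sid} has no dose records")
        events = []
        for _, d in doses.iterrows():
            rate = float(d["RATE"])
            dur = 0.0 if rate == 0.0 else float(d["AMT"]) / rate
            events.append(DoseEvent(float(d["TIME"]), float(d["AMT"]), dur))
        regimen = Regimen(events=tuple(events))

        obs = grp[grp["EVID"] == 0]
        par = obs[obs["DVID"] == DVID_PARENT].sort_values("TIME")
        met = obs[obs["DVID"] == DVID_METABOLITE].sort_values("TIME")
        bis = obs[obs["DVID"] == DVID_BIS].sort_values("TIME")
        pk_times = par["TIME"].to_numpy(dtype=float)
        if not np.array_equal(pk_times, met["TIME"].to_numpy(dtype=float)):
            raise ValueError(
                f"subject {sid}: parent and metabolite schedules differ")
        yield SubjectData(
            subject=subject, regimen=regimen, pk_times=pk_times,
            dv_parent=par["DV"].to_numpy(dtype=float),
            dv_metab=met["DV"].to_numpy(dtype=float),
            bis_times=bis["TIME"].to_numpy(dtype=float),
            dv_bis=bis["DV"].to_numpy(dtype=float),
        )
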