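"""Parameter containers for the remimazolam / CNS 7054 population PK/PD model.

Units follow the clinical reporting scale throughout the package: amounts in
mg, volumes in L, clearances in L/min, rate constants in 1/min, time in min,
concentrations in ng/mL (= 1000 x mg/L), BIS dimensionless on 0-100.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict, replace
from typing import Mapping

import yaml

__all__ = [
    "PKParameters",
    "PDParameters",
    "VariabilitySpec",
    "Subject",
    "CovariateEffect",
    "CovariateModel",
    "REMIMAZOLAM_PK",
    "REMIMAZOLAM_PD",
    "DEFAULT_VARIABILITY",
    "LLOQ_NG_ML",
    "load_config",
    "save_config",
    "default_config_path",
]

#: Lower limit of quantification of the LC/MS/MS assay, ng/mL.
LLOQ_NG_ML = 2.0


def _check_positive(obj, names):
    for name in names:
        v = getattr(obj, name)
        if not (v > 0.0) or not (v < float("inf")):
            raise ValueError(f"{type(obj).__name__}.{name} must be strictly "
                             f"positive and finite, got {v!r}")


@dataclass(frozen=True)
class PKParameters:
    """Structural PK typical values (three-compartment parent, transit,
    two-compartment metabolite).

    CL_p : parent (remimazolam) clearance, L/min
    V1, V2, V3 : parent central / peripheral volumes, L
    Q2, Q3 : parent intercompartmental clearances, L/min
    K_tr : transit rate constant for metabolite formation, 1/min
    CL_m : metabolite (CNS 7054) clearance, L/min
    V5, V6 : metabolite central / peripheral volumes, L
    Q4 : metabolite intercompartmental clearance, L/min
    """

    CL_p: float
    V1: float
    Q2: float
    V2: float
    Q3: float
    V3: float
    K_tr: float
    CL_m: float
    V5: float
    Q4: float
    V6: float

    def __post_init__(self):
        _check_positive(self, [f.name for f in fields(self)])

    def as_dict(self) -> dict[str, float]:
        return asdict(self)

    def with_values(self, **kwargs) -> "PKParameters":
        return replace(self, **kwargs)

    @classmethod
    def names(cls) -> list[str]:
        return [f.name for f in fields(cls)]


@dataclass(frozen=True)
class PDParameters:
    """Sigmoid Imax BIS model parameters with an effect compartment.

    Imax : maximal BIS depression (BIS units)
    IC50 : effect-site concentration at half-maximal depression, ng/mL
    BIS_baseline : pre-dose BIS
    ke0 : effect-compartment equilibration rate constant, 1/min
    Hill : sigmoidicity exponent
    """

    Imax: float
    IC50: float
    BIS_baseline: float
    ke0: float
    Hill: float

    def __post_init__(self):
        _check_positive(self, [f.name for f in fields(self)])
        if self.Imax > self.BIS_baseline:
            raise ValueError("Imax must not exceed BIS_baseline "
                             "(BIS cannot go negative)")

    def as_dict(self) -> dict[str, float]:
        return asdict(self)

    def with_values(self, **kwargs) -> "PDParameters":
        return replace(self, **kwargs)

    @classmethod
    def names(cls) -> list[str]:
        return [f.name for f in fields(cls)]


@dataclass(frozen=True)
class VariabilitySpec:
    """Between-subject variability and residual-error magnitudes.

    omega maps a parameter name (PK or PD) to the standard deviation of its
    log-normal random effect eta. Residual errors: parent concentrations use
    a proportional model, metabolite concentrations a combined proportional +
    additive model, BIS a proportional model; the parent and metabolite
    proportional errors are jointly normal with correlation ``rho_pm``
    (both analytes are assayed from the same sample).
    """

    omega: Mapping[str, float] = field(default_factory=dict)
    sigma_prop_parent: float = 0.0
    sigma_prop_metab: float = 0.0
    sigma_add_metab: float = 0.0
    rho_pm: float = 0.0
    sigma_prop_bis: float = 0.0

    def __post_init__(self):
        for k, v in self.omega.items():
            if v < 0:
                raise ValueError(f"omega[{k!r}] must be >= 0, got {v}")
        for name in ("sigma_prop_parent", "sigma_prop_metab",
                     "sigma_add_metab", "sigma_prop_bis"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if abs(self.rho_pm) > 1:
            raise ValueError("rho_pm must lie in [-1, 1]")
        object.__setattr__(self, "omega", dict(self.omega))

    def zeroed(self) -> "VariabilitySpec":
        """A copy with all variability switched off (typical-subject runs)."""
        return VariabilitySpec(omega={k: 0.0 for k in self.omega})


@dataclass(frozen=True)
class Subject:
    """Demographics of one subject."""

    id: int | str
    WT: float          # body weight, kg
    age: float = 28.0  # years
    height: float = 167.5  # cm
    sex: int = 0       # 0 male, 1 female

    def __post_init__(self):
        if not self.WT > 0:
            raise ValueError("WT must be > 0")
        if not self.age > 0:
            raise ValueError("age must be > 0")
        if self.sex not in (0, 1):
            raise ValueError("sex must be 0 (male) or 1 (female)")


@dataclass(frozen=True)
class CovariateEffect:
    """One covariate-parameter relationship.

    For continuous covariates (age, height): power model
    ``P_i = P * (cov / reference) ** theta``.
    For the categorical covariate sex: proportional model
    ``P_i = P * theta ** sex``.
    """

    parameter: str
    covariate: str   # 'age' | 'height' | 'sex'
    theta: float
    reference: float = 1.0  # median used for normalisation (continuous only)

    def multiplier(self, subject: Subject) -> float:
        value = getattr(subject, self.covariate)
        if self.covariate == "sex":
            return self.theta ** value
        return (value / self.reference) ** self.theta


# Parameters scaled allometrically with weight: exponent 0.75 for
# clearance-like terms, 1 for volumes; rate constants are not scaled.
_ALLOMETRIC_CLEARANCES = ("CL_p", "Q2", "Q3", "CL_m", "Q4")
_ALLOMETRIC_VOLUMES = ("V1", "V2", "V3", "V5", "V6")


@dataclass(frozen=True)
class CovariateModel:
    """Fixed allometric weight scaling plus optional screened covariates."""

    reference_weight: float = 60.0
    clearance_exponent: float = 0.75
    volume_exponent: float = 1.0
    effects: tuple[CovariateEffect, ...] = ()

    def __post_init__(self):
        if not self.reference_weight > 0:
            raise ValueError("reference_weight must be > 0")

    def multiplier(self, parameter: str, subject: Subject) -> float:
        wt_ratio = subject.WT / self.reference_weight
        if parameter in _ALLOMETRIC_CLEARANCES:
            m = wt_ratio ** self.clearance_exponent
        elif parameter in _ALLOMETRIC_VOLUMES:
            m = wt_ratio ** self.volume_exponent
        else:
            m = 1.0
        for eff in self.effects:
            if eff.parameter == parameter:
                m *= eff.multiplier(subject)
        return m


# ---------------------------------------------------------------------------
# Published final estimates (healthy Chinese adults, 60 kg reference)
# ---------------------------------------------------------------------------

#: Final population PK typical values.
REMIMAZOLAM_PK = PKParameters(
    CL_p=1.21, V1=16.0, Q2=2.61, V2=22.6, Q3=0.227, V3=23.5,
    K_tr=0.447, CL_m=0.0637, V5=3.72, Q4=0.166, V6=5.15,
)

#: Final population PD typical values.
REMIMAZOLAM_PD = PDParameters(
    Imax=54.5, IC50=504.0, BIS_baseline=92.5, ke0=1.38, Hill=1.44,
)

#: Published BSV (IIV% read as 100*omega) and residual-error magnitudes.
DEFAULT_VARIABILITY = VariabilitySpec(
    omega={
        "CL_p": 0.20, "V1": 0.55, "Q2": 0.243, "V2": 0.321, "K_tr": 0.401,
        "CL_m": 0.221, "V5": 0.301, "V6": 0.175,
        "Imax": 0.272, "Hill": 0.488,
    },
    sigma_prop_parent=0.232,
    sigma_prop_metab=0.064,
    sigma_add_metab=43.13,
    rho_pm=0.0066,
    sigma_prop_bis=0.112,
)


# ---------------------------------------------------------------------------
# Config round-trip (flat YAML)
# ---------------------------------------------------------------------------

def save_config(path, pk: PKParameters | None = None,
                pd: PDParameters | None = None,
                variability: VariabilitySpec | None = None) -> None:
    """Serialise parameter sets to a flat YAML file."""
    doc: dict = {}
    if pk is not None:
        doc["pk"] = pk.as_dict()
    if pd is not None:
        doc["pd"] = pd.as_dict()
    if variability is not None:
        doc["variability"] = {
            "omega": dict(variability.omega),
            "sigma_prop_parent": variability.sigma_prop_parent,
            "sigma_prop_metab": variability.sigma_prop_metab,
            "sigma_add_metab": variability.sigma_add_metab,
            "rho_pm": variability.rho_pm,
            "sigma_prop_bis": variability.sigma_prop_bis,
        }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def default_config_path():
    """Path of the bundled YAML config holding the published final model
    (identical to the in-code defaults)."""
    from importlib.resources import files
    return files("remipkpd") / "data" / "published_model.yaml"


def load_config(path) -> dict:
    """Load a YAML config written by :func:`save_config`.

    Returns a dict with any of the keys ``pk``, ``pd``, ``variability``
    mapped to the corresponding typed objects.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    out: dict = {}
    if "pk" in doc:
        out["pk"] = PKParameters(**doc["pk"])
    if "pd" in doc:
        out["pd"] = PDParameters(**doc["pd"])
    if "variability" in doc:
        v = doc["variability"]
        out["variability"] = VariabilitySpec(
            omega=v.get("omega", {}),
            sigma_prop_parent=v.get("sigma_prop_parent", 0.0),
            sigma_prop_metab=v.get("sigma_prop_metab", 0.0),
            sigma_add_metab=v.get("sigma_add_metab", 0.0),
            rho_pm=v.get("rho_pm", 0.0),
            sigma_prop_bis=v.get("sigma_prop_bis", 0.0),
        )
    return out
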