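"""Parameter sets for the phenotypic-switch model with stress response (PSMSR).

The model describes a co-culture of drug-sensitive (fast-growing) and
drug-tolerant (slow-growing, stress-neutralising) cancer cell phenotypes.
Nine rate constants govern the drug-free dynamics; seven more describe the
cisplatin dose response.  All rates are per day; drug exposure is tracked as
AUC (concentration x time) in uM*h.

Published point estimates for the co-culture conditions are provided as
presets (:data:`PRESETS`), together with the search ranges used for fitting
(:data:`SEARCH_BOUNDS`).
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from typing import Mapping

__all__ = [
    "PhenotypeParams",
    "DrugParams",
    "PRESETS",
    "DRUG_PRESETS",
    "SEARCH_BOUNDS",
    "PHENOTYPE_KEYS",
    "DRUG_KEYS",
    "params_to_config",
    "params_from_config",
]


@dataclass(frozen=True)
class PhenotypeParams:
    """Drug-free PSMSR rate constants.

    Parameters
    ----------
    K0 : float
        Baseline equilibrium constant of phenotypic switching
        (dimensionless); T/S at zero stress when growth is off.
    Kb : float
        Tolerant -> sensitive switch rate (1/day); held fixed with respect
        to stress.  The reverse rate is Ka = K * Kb.
    KGs0, KGt0 : float
        Baseline effective growth rates of the sensitive and tolerant
        phenotypes (1/day), net of proliferation and death.
    Kstr : float
        Stress generation rate per sensitive cell (stress-units/cell/day).
    Kstrd : float
        Stress removal rate per tolerant cell (stress-units/cell/day).
    a, b : float
        Stress coupling of the sensitive / tolerant growth rates
        (1/day per stress-unit); growth decreases with stress.
    g : float
        Stress coupling of the switch equilibrium (1/stress-unit); the
        equilibrium shifts toward the tolerant phenotype as stress rises.
    """

    K0: float
    Kb: float
    KGs0: float
    KGt0: float
    Kstr: float
    Kstrd: float
    a: float
    b: float
    g: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (v >= 0.0):
                raise ValueError(f"PhenotypeParams.{f.name} must be >= 0, got {v!r}")

    def locked_for_drug(self) -> "PhenotypeParams":
        """Return the parameter set with community cooperation disabled.

        Under cisplatin the best description of the data has phenotypic
        switching and stress removal turned off: Kb = 0 (hence Ka = 0),
        Kstrd = 0, and the sensitive-growth stress coupling a unused.
        """
        return replace(self, Kb=0.0, Kstrd=0.0, a=0.0)


@dataclass(frozen=True)
class DrugParams:
    """Cisplatin-response constants.

    The kill rate of each phenotype is SCALE * sigmoid(AUC), where the
    sigmoid rises from 5% of maximum at AUC5 to 95% at AUC95 (AUC in uM*h,
    SCALE in 1/day).  ``Sdrug`` is stored for round-trip fidelity with the
    published parameter table; it is not part of the default dynamics but
    can optionally act as a drug-on stress source (see
    :func:`psmsr.model.rhs`).
    """

    Sdrug: float
    AUC5_s: float
    AUC95_s: float
    SCALE_s: float
    AUC5_t: float
    AUC95_t: float
    SCALE_t: float

    def __post_init__(self) -> None:
        if not (self.AUC5_s < self.AUC95_s):
            raise ValueError("AUC5_s must be < AUC95_s")
        if not (self.AUC5_t < self.AUC95_t):
            raise ValueError("AUC5_t must be < AUC95_t")
        if self.SCALE_s < 0 or self.SCALE_t < 0:
            raise ValueError("SCALE parameters must be >= 0")


#: Published drug-free point estimates per cohabitation condition.
#: ``heterotypic``: cells mixed and monitored immediately (12 h);
#: ``heterotypic-3wk``: co-cultured for three weeks before monitoring.
PRESETS: dict[str, PhenotypeParams] = {
    "heterotypic": PhenotypeParams(
        K0=0.049, Kb=3.57, KGs0=0.713, KGt0=0.687,
        Kstr=7.14e-4, Kstrd=5.64e-3, a=0.046, b=0.038, g=0.018,
    ),
    "heterotypic-3wk": PhenotypeParams(
        K0=0.052, Kb=2.6, KGs0=0.708, KGt0=0.189,
        Kstr=6.74e-4, Kstrd=5.52e-3, a=0.05, b=0.038, g=0.02,
    ),
    "heterotypic-cisplatin": PhenotypeParams(
        K0=0.033, Kb=0.0, KGs0=1.033, KGt0=0.976,
        Kstr=5.9e-4, Kstrd=0.0, a=0.0, b=0.04, g=0.034,
    ),
    "heterotypic-3wk-cisplatin": PhenotypeParams(
        K0=0.033, Kb=0.0, KGs0=0.966, KGt0=0.967,
        Kstr=5.8e-4, Kstrd=0.0, a=0.0, b=0.039, g=0.036,
    ),
}

#: Published cisplatin-response estimates for the two fitted drug conditions.
DRUG_PRESETS: dict[str, DrugParams] = {
    "heterotypic-cisplatin": DrugParams(
        Sdrug=108.0, AUC5_s=239.0, AUC95_s=1153.0, SCALE_s=8.61,
        AUC5_t=233.0, AUC95_t=1201.0, SCALE_t=5.79,
    ),
    "heterotypic-3wk-cisplatin": DrugParams(
        Sdrug=96.8, AUC5_s=271.0, AUC95_s=1098.0, SCALE_s=8.91,
        AUC5_t=250.0, AUC95_t=1098.0, SCALE_t=6.89,
    ),
}

#: Parameter search ranges used for fitting, keyed by attribute name.
SEARCH_BOUNDS: dict[str, tuple[float, float]] = {
    "K0": (0.0, 0.1),
    "Kb": (0.0, 5.0),
    "KGs0": (0.0, 2.0),
    "KGt0": (0.0, 2.0),
    "Kstr": (0.0, 0.001),
    "Kstrd": (0.0, 0.02),
    "a": (0.0, 0.1),
    "b": (0.0, 0.1),
    "g": (0.0, 0.1),
    "Sdrug": (1.0, 500.0),
    "AUC5_s": (1.0, 500.0),
    "AUC95_s": (10.0, 1500.0),
    "SCALE_s": (0.1, 20.0),
    "AUC5_t": (1.0, 500.0),
    "AUC95_t": (10.0, 1500.0),
    "SCALE_t": (0.1, 20.0),
}

# Flat-config keys exactly matching the published table's column names.
PHENOTYPE_KEYS = {
    "K": "K0", "Kb": "Kb", "KGs0": "KGs0", "KGt0": "KGt0",
    "Kstr": "Kstr", "Kstrd": "Kstrd", "a": "a", "b": "b", "g": "g",
}
DRUG_KEYS = {
    "Sdrug": "Sdrug",
    "AUCs5": "AUC5_s", "AUCs95": "AUC95_s", "SCALEs": "SCALE_s",
    "AUCt5": "AUC5_t", "AUCt95": "AUC95_t", "SCALEt": "SCALE_t",
}


def params_to_config(
    p: PhenotypeParams,
    d: DrugParams | None = None,
    *,
    coupling: str = "linear",
    auc_mode: str = "hold",
) -> dict:
    """Serialize parameter sets to a flat key-value mapping.

    Keys match the published table's column names (``K``, ``Kb``, ...,
    ``SCALEt``) plus ``coupling`` (linear|sigmoidal) and ``auc_mode``
    (hold|decay|reset).
    """
    cfg: dict = {key: getattr(p, attr) for key, attr in PHENOTYPE_KEYS.items()}
    if d is not None:
        cfg.update({key: getattr(d, attr) for key, attr in DRUG_KEYS.items()})
    cfg["coupling"] = coupling
    cfg["auc_mode"] = auc_mode
    return cfg


def params_from_config(cfg: Mapping) -> tuple[PhenotypeParams, DrugParams | None, str, str]:
    """Inverse of :func:`params_to_config`.

    Returns ``(phenotype_params, drug_params_or_None, coupling, auc_mode)``.
    The drug block is returned only if every drug key is present.
    """
    missing = [k for k in PHENOTYPE_KEYS if k not in cfg]
    if missing:
        raise KeyError(f"parameter config missing keys: {missing}")
    p = PhenotypeParams(**{attr: float(cfg[key]) for key, attr in PHENOTYPE_KEYS.items()})
    d = None
    if all(k in cfg for k in DRUG_KEYS):
        d = DrugParams(**{attr: float(cfg[key]) for key, attr in DRUG_KEYS.items()})
    coupling = str(cfg.get("coupling", "linear"))
    auc_mode = str(cfg.get("auc_mode", "hold"))
    return p, d, coupling, auc_mode
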