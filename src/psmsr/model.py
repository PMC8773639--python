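"""Core rate laws and ODE right-hand side of the PSMSR model.

State and dynamics
------------------
The population is tracked at two levels simultaneously:

* **label** (what the microscope sees): red cells, seeded from the
  sensitive line, and green cells, seeded from the tolerant line;
* **phenotype** (what the dynamics act on): sensitive (S) or tolerant (T).

Cells switch phenotype but keep their fluorescent label, so the state is
the four-way split ``(Rs, Rt, Gs, Gt)`` plus two hidden variables: the
stress level ``Cstr`` (generated by sensitive cells, removed by tolerant
cells) and the accumulated drug exposure ``AUC`` (uM*h).  Summing the two
labels recovers the two-variable phenotype model

.. math::

    dS/dt = -K_a S + K_b T + K_{GS} S  [- SCALE_s \\cdot sigmoid(AUC) S]
    dT/dt = +K_a S - K_b T + K_{GT} T  [- SCALE_t \\cdot sigmoid(AUC) T]
    dC_{str}/dt = K_{str} S - K_{str,d} T

with the growth rates and switch equilibrium coupled to stress (linearly by
default) and the bracketed kill terms active when drug parameters are
supplied.  Time is measured in days.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import DrugParams, PhenotypeParams

__all__ = [
    "LineageState",
    "RateSet",
    "stress_coupled_rates",
    "sigmoid_kill",
    "death_rates",
    "rhs",
    "rhs_vector",
]

#: Slope matching constant: ln(19) makes the kill sigmoid pass through
#: 5% at AUC5 and 95% at AUC95.
_LN19 = float(np.log(19.0))

#: Hours per day — AUC is kept in uM*h while time is integrated in days.
HOURS_PER_DAY = 24.0


@dataclass
class LineageState:
    """Population state split by label (red/green) x phenotype (S/T).

    Red cells are seeded from the sensitive line, green from the tolerant
    line; ``Rs`` is e.g. the count of red cells currently in the sensitive
    phenotype.  ``Cstr`` is the hidden stress level and ``AUC`` the
    accumulated drug exposure in uM*h.
    """

    Rs: float = 0.0
    Rt: float = 0.0
    Gs: float = 0.0
    Gt: float = 0.0
    Cstr: float = 0.0
    AUC: float = 0.0

    def __post_init__(self) -> None:
        for name in ("Rs", "Rt", "Gs", "Gt", "Cstr", "AUC"):
            if getattr(self, name) < 0:
                raise ValueError(f"LineageState.{name} must be >= 0")

    # -- phenotype / label totals ------------------------------------
    @property
    def S(self) -> float:
        """Sensitive-phenotype total across labels."""
        return self.Rs + self.Gs

    @property
    def T(self) -> float:
        """Tolerant-phenotype total across labels."""
        return self.Rt + self.Gt

    @property
    def R(self) -> float:
        """Red-label (sensitive-seeded lineage) total."""
        return self.Rs + self.Rt

    @property
    def G(self) -> float:
        """Green-label (tolerant-seeded lineage) total."""
        return self.Gs + self.Gt

    @property
    def total(self) -> float:
        return self.Rs + self.Rt + self.Gs + self.Gt

    def as_vector(self) -> np.ndarray:
        return np.array(
            [self.Rs, self.Rt, self.Gs, self.Gt, self.Cstr, self.AUC], dtype=float
        )

    @classmethod
    def from_vector(cls, y: np.ndarray) -> "LineageState":
        y = np.maximum(np.asarray(y, dtype=float), 0.0)
        return cls(*y)

    @classmethod
    def from_seeding(
        cls, red: float, green: float, Cstr: float = 0.0, AUC: float = 0.0
    ) -> "LineageState":
        """Seed red cells 100% sensitive and green cells 100% tolerant."""
        return cls(Rs=red, Rt=0.0, Gs=0.0, Gt=green, Cstr=Cstr, AUC=AUC)


@dataclass(frozen=True)
class RateSet:
    """Instantaneous rates at a given stress level and drug exposure."""

    KGS: float  # sensitive effective growth rate (1/day); may be negative
    KGT: float  # tolerant effective growth rate (1/day); may be negative
    K: float    # switch equilibrium constant T/S (dimensionless)
    Ka: float   # sensitive -> tolerant switch rate, K * Kb (1/day)
    deathS: float = 0.0  # drug kill rate of sensitive phenotype (1/day)
    deathT: float = 0.0  # drug kill rate of tolerant phenotype (1/day)


def stress_coupled_rates(
    p: PhenotypeParams,
    Cstr: float,
    coupling: str = "linear",
    *,
    saturation: float = 1.0,
) -> RateSet:
    """Growth and switching rates at stress level ``Cstr``.

    Linear coupling (default)::

        KGS = KGs0 - a*Cstr      KGT = KGt0 - b*Cstr
        K   = K0 + g*Cstr        Ka  = K * Kb

    Growth rates may go negative (net death under high stress); no
    clamping is applied.  The sigmoidal alternative replaces each linear
    map by a saturating tanh (a rescaled logistic) with identical value
    and slope at ``Cstr = 0``; ``saturation`` sets the excursion amplitude
    as a multiple of the baseline value, so e.g. KGS stays within
    ``KGs0 * (1 - saturation, 1]``.  Both variants keep the monotone
    contract: KGS, KGT non-increasing and K, Ka non-decreasing in stress.

    Raises
    ------
    ValueError
        If ``Cstr`` is negative or ``coupling`` is unknown.
    """
    if Cstr < 0:
        raise ValueError(f"stress level must be >= 0, got {Cstr}")
    if coupling == "linear":
        KGS = p.KGs0 - p.a * Cstr
        KGT = p.KGt0 - p.b * Cstr
        K = p.K0 + p.g * Cstr
    elif coupling == "sigmoidal":
        KGS = p.KGs0 - _sat(p.a, Cstr, saturation * p.KGs0)
        KGT = p.KGt0 - _sat(p.b, Cstr, saturation * p.KGt0)
        K = p.K0 + _sat(p.g, Cstr, saturation * p.K0)
    else:
        raise ValueError(f"unknown coupling mode {coupling!r}")
    return RateSet(KGS=KGS, KGT=KGT, K=K, Ka=K * p.Kb)


def _sat(slope: float, Cstr: float, amplitude: float) -> float:
    """Saturating stress response: amplitude * tanh(slope*Cstr/amplitude).

    Matches the linear law's value (0) and slope at Cstr = 0 and levels
    off at ``amplitude``.  Degenerates gracefully to 0 when either the
    slope or the amplitude is 0.
    """
    if amplitude <= 0.0 or slope == 0.0:
        return 0.0
    return amplitude * np.tanh(slope * Cstr / amplitude)


def sigmoid_kill(AUC, AUC5: float, AUC95: float):
    """Fractional cisplatin kill effect as a function of drug exposure.

    Logistic in AUC, anchored so that the curve passes through 0.05 at
    ``AUC5`` and 0.95 at ``AUC95``::

        sigmoid(AUC) = 1 / (1 + exp[ln19 * (1 - 2*(AUC-AUC5)/(AUC95-AUC5))])

    Strictly increasing, 0 as AUC -> -inf and 1 as AUC -> +inf.  Accepts
    scalars or arrays.

    Raises
    ------
    ValueError
        If ``AUC5 >= AUC95``.
    """
    if not (AUC5 < AUC95):
        raise ValueError(f"require AUC5 < AUC95, got {AUC5} >= {AUC95}")
    AUC = np.asarray(AUC, dtype=float)
    z = _LN19 * (1.0 - 2.0 * (AUC - AUC5) / (AUC95 - AUC5))
    # clip the exponent to keep the tails exact instead of overflowing
    out = 1.0 / (1.0 + np.exp(np.clip(z, -700.0, 700.0)))
    return out if out.ndim else float(out)


def death_rates(d: DrugParams | None, AUC: float) -> tuple[float, float]:
    """Kill rates (1/day) of the sensitive and tolerant phenotypes.

    Gated on actual exposure: with AUC = 0 (drug never applied) the kill
    rates are exactly zero rather than the sigmoid's small left-tail
    value, so an untreated run with drug parameters present coincides
    with a drug-free run.
    """
    if d is None or AUC <= 0.0:
        return 0.0, 0.0
    return (
        d.SCALE_s * sigmoid_kill(AUC, d.AUC5_s, d.AUC95_s),
        d.SCALE_t * sigmoid_kill(AUC, d.AUC5_t, d.AUC95_t),
    )


def rhs_vector(
    y: np.ndarray,
    p: PhenotypeParams,
    d: DrugParams | None = None,
    conc: float = 0.0,
    *,
    coupling: str = "linear",
    auc_mode: str = "hold",
    auc_half_life: float = 1.0,
    sdrug_stress: bool = False,
) -> np.ndarray:
    """Time derivative of the raw state vector [Rs, Rt, Gs, Gt, Cstr, AUC].

    ``conc`` is the current drug concentration in uM (0 when off).  AUC
    accumulates at ``24 * conc`` uM*h per day while drug is present; after
    washout it is held (``auc_mode='hold'``, the memory-effect default),
    decays exponentially with ``auc_half_life`` days (``'decay'``), or is
    zeroed by the integrator at washout (``'reset'``, handled at episode
    boundaries, not here).  ``sdrug_stress`` optionally adds the stored
    Sdrug constant as a drug-on stress source.
    """
    Rs, Rt, Gs, Gt, Cstr, AUC = y
    r = stress_coupled_rates(p, max(Cstr, 0.0), coupling)
    deathS, deathT = death_rates(d, AUC)

    # identical first-order exchange within each label; switching keeps the
    # label, so lineage sums reproduce the two-variable phenotype equations
    dRs = -r.Ka * Rs + p.Kb * Rt + r.KGS * Rs - deathS * Rs
    dRt = +r.Ka * Rs - p.Kb * Rt + r.KGT * Rt - deathT * Rt
    dGs = -r.Ka * Gs + p.Kb * Gt + r.KGS * Gs - deathS * Gs
    dGt = +r.Ka * Gs - p.Kb * Gt + r.KGT * Gt - deathT * Gt

    S = Rs + Gs
    T = Rt + Gt
    dCstr = p.Kstr * S - p.Kstrd * T
    if sdrug_stress and d is not None and conc > 0.0:
        dCstr += d.Sdrug
    # stress is a non-negative quantity: removal saturates at zero stress
    if Cstr <= 0.0 and dCstr < 0.0:
        dCstr = 0.0

    drug_on = conc > 0.0
    if drug_on:
        dAUC = HOURS_PER_DAY * conc
    elif auc_mode == "decay":
        dAUC = -np.log(2.0) / auc_half_life * AUC
    else:  # hold (and reset, which acts at boundaries)
        dAUC = 0.0

    return np.array([dRs, dRt, dGs, dGt, dCstr, dAUC])


def rhs(
    state: LineageState,
    p: PhenotypeParams,
    d: DrugParams | None = None,
    conc: float = 0.0,
    **kwargs,
) -> LineageState:
    """Typed wrapper of :func:`rhs_vector` (derivative as a LineageState-
    shaped record; fields may be negative)."""
    dy = rhs_vector(state.as_vector(), p, d, conc, **kwargs)
    out = LineageState.__new__(LineageState)
    out.Rs, out.Rt, out.Gs, out.Gt, out.Cstr, out.AUC = dy
    return out
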