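"""Surrogate bioregulatory model of fracture healing in a virtual NF1 subject.

A compartmental ODE system tracks four cell populations (mesenchymal
progenitors, fibroblasts, chondrocytes, osteoblasts), three matrix
fractions (fibrous tissue, cartilage, bone), two growth factors
(osteochondrogenic, angiogenic) and vascularity over a 49-day healing
window.  The eight subject-level parameters (:class:`NF1ParameterSet`)
encode the aberrant cellular behaviour of NF1-mutated cells; everything
else is a fixed, calibrated surrogate constant (:class:`SurrogateConstants`).

The surrogate replaces a far richer spatio-temporal model: its constants
are calibrated to a behavioural contract (normal parameters heal, the
severe parameter corner fails, growth-factor treatment shifts outcomes),
not derived from experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, asdict
from typing import Mapping

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "PARAM_NAMES",
    "NORMAL_CASE",
    "NF1ParameterSet",
    "TreatmentArm",
    "SurrogateConstants",
    "HealingTimeCourse",
    "SolverConfig",
    "bmp_release_rate",
    "derivatives",
    "simulate_subject",
    "tissue_fractions",
]

#: Canonical column order for parameter tables.
PARAM_NAMES = ("c_f_BC", "A_f0", "F_4", "Y_11", "Y_3cb", "P_mc", "P_mf", "G_gvc")

#: Healthy reference values for the eight subject parameters.
NORMAL_CASE = {
    "c_f_BC": 3.0,
    "A_f0": 0.1,
    "F_4": 0.01,
    "Y_11": 20.0,
    "Y_3cb": 1000.0,
    "P_mc": 0.2,
    "P_mf": 0.2,
    "G_gvc": 1e3,
}

#: Inclusive sampling bounds for each subject parameter (pathological range).
PARAM_BOUNDS = {
    "c_f_BC": (0.0, 50.0),
    "A_f0": (0.1, 10.0),
    "F_4": (0.01, 1.0),
    "Y_11": (0.0, 20.0),
    "Y_3cb": (0.0, 1000.0),
    "P_mc": (0.0, 0.2),
    "P_mf": (0.2, 10.0),
    "G_gvc": (1e3, 1e5),
}

#: Simulation horizon in days.
T_END = 49

#: Names of the state variables in integration order.
STATE_NAMES = ("c_m", "c_f", "c_c", "c_b", "m_f", "m_c", "m_b", "g_b", "g_v", "v")


@dataclass(frozen=True)
class NF1ParameterSet:
    """Eight-dimensional subject phenotype vector.

    Parameters
    ----------
    c_f_BC : float
        Duration of the fibrous-lesion-cell influx, days.
    A_f0 : float
        Fibroblastic proliferation rate, per day.
    F_4 : float
        Fibroblastic differentiation rate of progenitors, per day.
    Y_11 : float
        Osteogenic differentiation factor, dimensionless (0-20 scale).
    Y_3cb : float
        Endochondral ossification factor, dimensionless (0-1000 scale).
    P_mc : float
        Cartilage formation rate, per day.
    P_mf : float
        Fibrous tissue formation rate, per day.
    G_gvc : float
        Angiogenic growth-factor production factor (1e3-1e5 scale).
    """

    c_f_BC: float
    A_f0: float
    F_4: float
    Y_11: float
    Y_3cb: float
    P_mc: float
    P_mf: float
    G_gvc: float

    def __post_init__(self) -> None:
        for f in fields(self):
            val = getattr(self, f.name)
            if not math.isfinite(val) or val < 0:
                raise ValueError(
                    f"parameter {f.name}={val!r} must be finite and non-negative"
                )

    @classmethod
    def normal(cls) -> "NF1ParameterSet":
        """The healthy reference subject."""
        return cls(**NORMAL_CASE)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "NF1ParameterSet":
        return cls(**{name: float(mapping[name]) for name in PARAM_NAMES})

    def as_dict(self) -> dict[str, float]:
        return asdict(self)

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in PARAM_NAMES])


@dataclass(frozen=True)
class TreatmentArm:
    """One trial arm: an exponentially decaying growth-factor source.

    ``g_star`` is the initial source amplitude (0 for the untreated arm)
    and ``tau`` the release time constant in days (default 10).
    """

    label: str
    g_star: float = 0.0
    tau: float = 10.0

    def __post_init__(self) -> None:
        if self.label not in ("untreated", "bmp"):
            raise ValueError(f"unknown arm label {self.label!r}")
        if self.g_star < 0:
            raise ValueError("g_star must be non-negative")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.label == "untreated" and self.g_star != 0:
            raise ValueError("untreated arm must have g_star == 0")

    @classmethod
    def untreated(cls) -> "TreatmentArm":
        return cls(label="untreated", g_star=0.0)

    @classmethod
    def bmp(cls, g_star: float = 2.0, tau: float = 10.0) -> "TreatmentArm":
        return cls(label="bmp", g_star=g_star, tau=tau)


@dataclass(frozen=True)
class SurrogateConstants:
    """Fixed rate constants of the surrogate system (calibrated defaults).

    These are calibrated so that the healthy reference subject reaches
    bony union by day 49 while the severe pathological corner does not;
    they carry no experimental provenance.
    """

    a_m: float = 1.0      # mesenchymal proliferation, /d
    a_c: float = 0.2      # basal chondrocyte proliferation, /d
    a_ch: float = 3.0     # growth-factor-stimulated chondrocyte proliferation, /d
    a_b: float = 0.2      # osteoblast proliferation, /d
    y_c0: float = 0.5     # base chondrogenic differentiation, /d
    y_b0: float = 0.3     # base osteogenic differentiation, /d
    k_e0: float = 0.6     # base endochondral replacement, /d
    d_f: float = 0.3      # fibroblast death, /d
    d_c: float = 0.05     # chondrocyte death, /d
    d_b: float = 0.05     # osteoblast death, /d
    i_f0: float = 0.1     # fibrous lesion-cell influx amplitude, /d
    q_cb: float = 2.5     # cartilage-to-bone matrix remodelling, /d
    r_fc: float = 2.0     # fibrous-to-cartilage matrix replacement, /d
    p_mb: float = 0.02    # direct (intramembranous) bone matrix deposition, /d
    g_prod: float = 0.5   # osteochondrogenic GF production, /d
    d_gb: float = 0.25    # osteochondrogenic GF decay, /d
    d_gv: float = 0.3     # angiogenic GF decay, /d
    g_vprod: float = 1.0  # angiogenic GF production, /d
    gv_amp: float = 3.0   # pathological amplification of angiogenic production
    a_v: float = 1.0      # vascular growth rate, /d
    theta_c: float = 1.0  # avascular-cartilage impedance of vessel ingrowth


@dataclass(frozen=True)
class SolverConfig:
    """Integration settings (adaptive explicit Runge-Kutta)."""

    method: str = "RK45"
    rtol: float = 1e-6
    atol: float = 1e-9
    constants: SurrogateConstants = field(default_factory=SurrogateConstants)


@dataclass(frozen=True)
class HealingTimeCourse:
    """Daily state trajectory of one subject-arm over days 0..49.

    Each state attribute is a length-50 array indexed by day.
    """

    days: np.ndarray
    c_m: np.ndarray
    c_f: np.ndarray
    c_c: np.ndarray
    c_b: np.ndarray
    m_f: np.ndarray
    m_c: np.ndarray
    m_b: np.ndarray
    g_b: np.ndarray
    g_v: np.ndarray
    v: np.ndarray

    def state_at(self, day: int) -> np.ndarray:
        idx = self._day_index(day)
        return np.array([getattr(self, name)[idx] for name in STATE_NAMES])

    def _day_index(self, day: int) -> int:
        if isinstance(day, float) and not float(day).is_integer():
            raise ValueError(f"day must be an integer, got {day!r}")
        day = int(day)
        if day < 0 or day > T_END:
            raise ValueError(f"day {day} outside simulated grid 0..{T_END}")
        return day


def bmp_release_rate(t: float, arm: TreatmentArm) -> float:
    """Exponentially decaying growth-factor source rate at time ``t`` (days).

    Returns ``g_star * exp(-t / tau)``; identically zero for the
    untreated arm.  ``t`` must be non-negative.
    """
    if t < 0:
        raise ValueError(f"time must be non-negative, got {t}")
    if arm.g_star == 0:
        return 0.0
    return arm.g_star * math.exp(-t / arm.tau)


def _normalized_factors(params: NF1ParameterSet) -> tuple[float, float, float]:
    """Map the dimensioned subject factors onto [0, 1] response scales."""
    yb = params.Y_11 / 20.0
    ye = params.Y_3cb / 1000.0
    gv = math.log10(max(params.G_gvc, 1e3) / 1e3) / 2.0
    return yb, ye, gv


def derivatives(
    state: np.ndarray,
    t: float,
    params: NF1ParameterSet,
    arm: TreatmentArm,
    constants: SurrogateConstants | None = None,
) -> np.ndarray:
    """Time derivative of the 10-dimensional surrogate state.

    State layout follows :data:`STATE_NAMES`:
    ``(c_m, c_f, c_c, c_b, m_f, m_c, m_b, g_b, g_v, v)``.
    """
    k = constants or SurrogateConstants()
    state = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(state)):
        raise FloatingPointError(
            f"non-finite state at t={t}: {dict(zip(STATE_NAMES, state))}"
        )
    c_m, c_f, c_c, c_b, m_f, m_c, m_b, g_b, g_v, v = state
    yb, ye, gv = _normalized_factors(params)

    C = c_m + c_f + c_c + c_b
    M = m_f + m_c + m_b
    h_gb = g_b / (1.0 + g_b)  # saturating growth-factor response

    chond = k.y_c0 * (1.0 - v) * h_gb * c_m  # hypoxic route -> cartilage
    osteo = k.y_b0 * yb * v * h_gb * c_m     # vascularised route -> bone
    endo = k.k_e0 * ye * v * c_c             # cartilage-to-bone cell transition
    # Lesion-cell influx competes for the same space as resident cells:
    # gating by free capacity keeps total cell density bounded by 1.
    free = max(0.0, 1.0 - C)
    influx = k.i_f0 * (0.5 + 0.5 * gv) * free if t <= params.c_f_BC else 0.0

    d_cm = k.a_m * c_m * (1.0 - C) - params.F_4 * c_m - chond - osteo
    d_cf = params.A_f0 * c_f * (1.0 - C) + params.F_4 * c_m + influx - k.d_f * c_f
    d_cc = (k.a_c + k.a_ch * h_gb) * c_c * (1.0 - C) + chond - endo - k.d_c * c_c
    d_cb = k.a_b * c_b * (1.0 - C) + osteo + endo - k.d_b * c_b

    # Matrix remodelling chains: fibrous tissue is replaced by cartilage
    # (requires chondrocytes with intact matrix production, P_mc), which is
    # in turn remodelled into bone by vascularised osteoblasts.  Both terms
    # transfer mass between fractions, so the total matrix balance is
    # unchanged by them.
    t_cb = k.q_cb * v * c_b * m_c
    t_fc = k.r_fc * (params.P_mc / 0.2) * c_c * m_f
    d_mf = params.P_mf * c_f * (1.0 - M) - t_fc
    d_mc = params.P_mc * c_c * (1.0 - M) + t_fc - t_cb
    d_mb = k.p_mb * c_b * (1.0 - M) + t_cb

    d_gb = k.g_prod * (c_b + c_c) - k.d_gb * g_b + bmp_release_rate(t, arm)
    d_gv = (1.0 + k.gv_amp * gv) * k.g_vprod * c_c * (1.0 - v) - k.d_gv * g_v
    # Avascular soft tissue (fibrous and cartilage) impedes vessel ingrowth.
    block = max(0.0, 1.0 - m_f - k.theta_c * m_c)
    d_v = k.a_v * g_v * v * (1.0 - v) * block

    return np.array([d_cm, d_cf, d_cc, d_cb, d_mf, d_mc, d_mb, d_gb, d_gv, d_v])


#: Initial condition: sparse progenitors, trace growth factors, low vascularity.
INITIAL_STATE = np.array([0.1, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.1, 0.1, 0.05])

_INVARIANT_TOL = 1e-6


def simulate_subject(
    params: NF1ParameterSet,
    arm: TreatmentArm,
    config: SolverConfig | None = None,
) -> HealingTimeCourse:
    """Integrate the surrogate system over days 0..49 for one subject-arm.

    Deterministic for a fixed configuration.  Raises ``RuntimeError`` if
    the solver fails or the trajectory violates the state invariants
    beyond tolerance.
    """
    cfg = config or SolverConfig()
    t_eval = np.arange(0, T_END + 1, dtype=float)

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        return derivatives(y, t, params, arm, cfg.constants)

    sol = solve_ivp(
        rhs,
        (0.0, float(T_END)),
        INITIAL_STATE,
        method=cfg.method,
        t_eval=t_eval,
        rtol=cfg.rtol,
        atol=cfg.atol,
    )
    if not sol.success:
        raise RuntimeError(
            f"solver failed for params={params.as_dict()} arm={arm.label}: "
            f"{sol.message}"
        )

    y = sol.y
    # Clip tiny negative underflow from the adaptive integrator.
    worst = float(y.min())
    if worst < -_INVARIANT_TOL * 100:
        raise RuntimeError(
            f"state went negative ({worst:.3e}) for params={params.as_dict()} "
            f"arm={arm.label}"
        )
    y = np.clip(y, 0.0, None)

    # The matrix fractions approach 1 asymptotically; the adaptive solver
    # may overshoot by ~rtol.  Renormalize small overshoots, reject large ones.
    m = y[4:7]
    M = m.sum(axis=0)
    over = M > 1.0
    if np.any(M > 1.0 + 1e-4):
        raise RuntimeError(
            f"matrix fractions exceed 1 by {M.max() - 1.0:.3e} for "
            f"params={params.as_dict()} arm={arm.label}"
        )
    if np.any(over):
        m[:, over] /= M[over]

    tc = HealingTimeCourse(days=sol.t.astype(int), **dict(zip(STATE_NAMES, y)))
    _check_invariants(tc, params, arm)
    return tc


def _check_invariants(
    tc: HealingTimeCourse, params: NF1ParameterSet, arm: TreatmentArm
) -> None:
    M = tc.m_f + tc.m_c + tc.m_b
    C = tc.c_m + tc.c_f + tc.c_c + tc.c_b
    ctx = f"params={params.as_dict()} arm={arm.label}"
    if float(M.max()) > 1.0 + _INVARIANT_TOL:
        raise RuntimeError(f"matrix fractions exceed 1 ({M.max():.8f}) for {ctx}")
    if float(C.max()) > 1.0 + 1e-3:
        raise RuntimeError(f"cell density exceeds capacity ({C.max():.8f}) for {ctx}")
    if float(tc.v.max()) > 1.0 + _INVARIANT_TOL:
        raise RuntimeError(f"vascularity exceeds 1 ({tc.v.max():.8f}) for {ctx}")


def tissue_fractions(tc: HealingTimeCourse, day: int) -> tuple[float, float, float]:
    """(fibrous, cartilage, bone) matrix fractions at an integer day."""
    idx = tc._day_index(day)
    return float(tc.m_f[idx]), float(tc.m_c[idx]), float(tc.m_b[idx])
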