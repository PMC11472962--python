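"""Core data model and dynamics of the smoking-alcohol dual-addiction system.

The population is split into eleven compartments: susceptible ``S``, protected
``P``, the smoking pathway ``ES -> IS -> PS`` (exposed, addicted, permanently
addicted), the alcohol pathway ``EA -> IA -> PA``, the dual-addiction pathway
``CSA -> PSA``, and the rehabilitated class ``T``.  New addictions arise by
standard (frequency-dependent) incidence: the per-capita force of addiction
for each pathway is a dissemination rate times the weighted prevalence of the
addicted classes, where dual-addicted individuals count with modification
weights ``theta1``/``theta2`` >= 1.

Besides the full eleven-compartment system, two six-compartment sub-models
(one addiction circulating at a time) are provided; they are exact restrictions
of the full system to the corresponding invariant subspaces.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "COMPARTMENTS",
    "ALCOHOL_COMPARTMENTS",
    "SMOKING_COMPARTMENTS",
    "SUBMODELS",
    "ALT_ALPHA1",
    "DEFAULT_INITIAL_STATE",
    "DEFAULT_T_FINAL",
    "DEFAULT_N_STEPS",
    "ModelParameters",
    "StateVector",
    "Trajectory",
    "ValidationReport",
    "force_of_addiction",
    "rhs",
    "simulate",
    "validate_parameters",
]

COMPARTMENTS = ("S", "P", "ES", "IS", "PS", "EA", "IA", "PA", "CSA", "PSA", "T")
ALCOHOL_COMPARTMENTS = ("S", "P", "EA", "IA", "PA", "T")
SMOKING_COMPARTMENTS = ("S", "P", "ES", "IS", "PS", "T")
SUBMODELS = ("full", "alcohol", "smoking")

#: Alternative value for alpha1; the published parameter table assigns the
#: exposed-to-addicted alcohol progression rate twice (0.0002 and 0.0003).
#: The first listed value is the default.
ALT_ALPHA1 = 0.0003

DEFAULT_T_FINAL = 5.0
DEFAULT_N_STEPS = 1000


@dataclass(frozen=True)
class ModelParameters:
    """Rate and modification constants of the dual-addiction model.

    Defaults are the published simulation values (units: year^-1 for rates;
    ``K`` in persons/year; ``pi`` and the modification multipliers
    dimensionless).
    """

    K: float = 20.0        # recruitment rate
    mu: float = 0.0135     # natural death rate
    pi: float = 0.5        # protected fraction of recruits
    delta: float = 0.21    # protection rate S -> P
    delta1: float = 1.1    # protected susceptibility multiplier, smoking
    delta2: float = 1.1    # alcohol-addicted susceptibility multiplier to smoking (IA)
    delta3: float = 1.1    # as delta2, for permanently alcohol-addicted (PA)
    rho1: float = 1.2      # protected susceptibility multiplier, alcohol
    rho2: float = 1.2      # smoking-addicted susceptibility multiplier to alcohol (PS)
    rho3: float = 1.2      # as rho2, for the IS class
    eps1: float = 0.223    # improvement (rehabilitation) rate, alcohol addicted
    eps2: float = 0.01     # improvement rate, smoking addicted
    eps3: float = 0.313    # improvement rate, dual addicted
    beta1: float = 0.75    # alcohol dissemination rate
    beta2: float = 0.38    # smoking dissemination rate
    alpha1: float = 0.0002  # progression EA -> IA
    alpha2: float = 0.56   # progression IA -> PA
    alpha: float = 0.54    # progression CSA -> PSA
    gamma1: float = 0.01   # progression ES -> IS
    gamma2: float = 0.321  # progression IS -> PS
    theta1: float = 1.05   # dual-addicted weighting in the alcohol force
    theta2: float = 1.05   # dual-addicted weighting in the smoking force
    dS: float = 0.035      # addiction death rate, IS
    dA: float = 0.075      # addiction death rate, IA
    dPS: float = 0.87      # addiction death rate, PS
    dPA: float = 0.091     # addiction death rate, PA
    dC: float = 0.11       # addiction death rate, CSA
    dSA: float = 0.23      # addiction death rate, PSA

    def replace(self, **changes: float) -> "ModelParameters":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in dataclasses.fields(cls))

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "ModelParameters":
        known = set(cls.field_names())
        unknown = sorted(set(mapping) - known)
        if unknown:
            raise KeyError(f"unknown parameter name(s): {', '.join(unknown)}")
        return cls(**{k: float(v) for k, v in mapping.items()})


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of parameter validation: hard violations and soft warnings."""

    violations: tuple[str, ...]
    warnings: tuple[str, ...]

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_parameters(params: ModelParameters) -> ValidationReport:
    """Check parameter constraints, separating errors from warnings.

    Hard violations: negative rates, ``mu <= 0``, ``K <= 0``, ``pi`` outside
    [0, 1], and ``theta1``/``theta2`` below 1.  Soft warnings flag
    ``delta1 >= 1`` or ``rho1 >= 1``: the model description requires both
    multipliers below 1 (protection reduces susceptibility) while the
    published simulation values assign 1.1 and 1.2, a documented
    contradiction that does not break any mathematical property used here.
    """
    violations: list[str] = []
    warnings: list[str] = []
    for name, value in params.to_dict().items():
        if not np.isfinite(value):
            violations.append(f"{name} = {value} is not finite")
        elif value < 0:
            violations.append(f"{name} = {value} must be nonnegative")
    if params.mu <= 0:
        violations.append(f"mu = {params.mu} must be positive")
    if params.K <= 0:
        violations.append(f"K = {params.K} must be positive")
    if not 0 <= params.pi <= 1:
        violations.append(f"pi = {params.pi} must lie in [0, 1]")
    if params.theta1 < 1:
        violations.append(f"theta1 = {params.theta1} must be >= 1")
    if params.theta2 < 1:
        violations.append(f"theta2 = {params.theta2} must be >= 1")
    if params.delta1 >= 1:
        warnings.append(
            f"delta1 = {params.delta1} >= 1: protected individuals are modelled "
            "as MORE susceptible to smoking than the unprotected"
        )
    if params.rho1 >= 1:
        warnings.append(
            f"rho1 = {params.rho1} >= 1: protected individuals are modelled "
            "as MORE susceptible to alcohol than the unprotected"
        )
    return ValidationReport(tuple(violations), tuple(warnings))


@dataclass(frozen=True)
class StateVector:
    """Compartment occupancies (person counts) of the full model."""

    S: float
    P: float
    ES: float = 0.0
    IS: float = 0.0
    PS: float = 0.0
    EA: float = 0.0
    IA: float = 0.0
    PA: float = 0.0
    CSA: float = 0.0
    PSA: float = 0.0
    T: float = 0.0

    @property
    def N(self) -> float:
        return float(sum(getattr(self, c) for c in COMPARTMENTS))

    def to_array(self, submodel: str = "full") -> np.ndarray:
        names = compartment_names(submodel)
        return np.array([getattr(self, c) for c in names], dtype=float)

    @classmethod
    def from_array(cls, values: Sequence[float], submodel: str = "full") -> "StateVector":
        names = compartment_names(submodel)
        values = np.asarray(values, dtype=float)
        if values.shape != (len(names),):
            raise ValueError(
                f"expected {len(names)} components for submodel '{submodel}', "
                f"got shape {values.shape}"
            )
        return cls(**dict(zip(names, values.tolist())))


DEFAULT_INITIAL_STATE = StateVector(
    S=800.0, P=300.0, ES=60.0, IS=40.0, PS=20.0,
    EA=60.0, IA=40.0, PA=20.0, CSA=20.0, PSA=10.0, T=30.0,
)


def compartment_names(submodel: str) -> tuple[str, ...]:
    if submodel == "full":
        return COMPARTMENTS
    if submodel == "alcohol":
        return ALCOHOL_COMPARTMENTS
    if submodel == "smoking":
        return SMOKING_COMPARTMENTS
    raise ValueError(f"unknown submodel '{submodel}'; expected one of {SUBMODELS}")


def _as_state_array(state, submodel: str) -> np.ndarray:
    if isinstance(state, StateVector):
        return state.to_array(submodel)
    arr = np.asarray(state, dtype=float)
    dim = len(compartment_names(submodel))
    if arr.shape[0] != dim:
        raise ValueError(
            f"submodel '{submodel}' expects {dim} compartments, got {arr.shape[0]}"
        )
    return arr


def force_of_addiction(state, params: ModelParameters, addiction: str,
                       submodel: str = "full"):
    """Per-capita force of addiction (standard incidence).

    Full model: ``lambda_A = beta1 (IA + PA + theta1 (CSA + PSA)) / N`` and
    ``lambda_S = beta2 (IS + PS + theta2 (CSA + PSA)) / N``.  The sub-models
    drop the dual-addicted terms and use their six-compartment population.

    ``state`` may be a :class:`StateVector`, a 1-d array, or an array with a
    trailing batch axis.  Raises ``ValueError`` for a zero total population
    or an addiction that does not circulate in the requested sub-model.
    """
    if addiction not in ("alcohol", "smoking"):
        raise ValueError(f"unknown addiction '{addiction}'")
    if submodel != "full" and submodel != addiction:
        raise ValueError(
            f"the {submodel} sub-model carries no {addiction} pathway"
        )
    arr = _as_state_array(state, submodel)
    N = arr.sum(axis=0)
    if np.any(N <= 0):
        raise ValueError("total population must be positive to evaluate the force of addiction")
    if submodel == "full":
        dual = arr[8] + arr[9]  # CSA + PSA
        if addiction == "alcohol":
            return params.beta1 * (arr[6] + arr[7] + params.theta1 * dual) / N
        return params.beta2 * (arr[3] + arr[4] + params.theta2 * dual) / N
    # six-compartment sub-models: addicted classes sit at indices 3, 4
    beta = params.beta1 if addiction == "alcohol" else params.beta2
    return beta * (arr[3] + arr[4]) / N


def _rhs_full(arr: np.ndarray, p: ModelParameters) -> np.ndarray:
    S, P, ES, IS, PS, EA, IA, PA, CSA, PSA, T = arr
    N = arr.sum(axis=0)
    lamA = p.beta1 * (IA + PA + p.theta1 * (CSA + PSA)) / N
    lamS = p.beta2 * (IS + PS + p.theta2 * (CSA + PSA)) / N
    dS = (1 - p.pi) * p.K - (lamS + lamA + p.delta + p.mu) * S
    dP = p.pi * p.K + p.delta * S - (p.rho1 * lamA + p.delta1 * lamS + p.mu) * P
    dES = lamS * S + p.delta1 * lamS * P - (p.mu + p.gamma1) * ES
    dIS = p.gamma1 * ES - (p.eps2 + p.gamma2 + p.rho3 * lamA + p.mu + p.dS) * IS
    dPS = p.gamma2 * IS - (p.rho2 * lamA + p.mu + p.dPS) * PS
    dEA = lamA * S + p.rho1 * lamA * P - (p.mu + p.alpha1) * EA
    dIA = p.alpha1 * EA - (p.alpha2 + p.eps1 + p.delta2 * lamS + p.mu + p.dA) * IA
    dPA = p.alpha2 * IA - (p.delta3 * lamS + p.mu + p.dPA) * PA
    dCSA = (p.delta2 * lamS * IA + p.delta3 * lamS * PA
            + p.rho3 * lamA * IS + p.rho2 * lamA * PS
            - (p.alpha + p.eps3 + p.mu + p.dC) * CSA)
    dPSA = p.alpha * CSA - (p.mu + p.dSA) * PSA
    dT = p.eps3 * CSA + p.eps1 * IA + p.eps2 * IS - p.mu * T
    return np.stack([dS, dP, dES, dIS, dPS, dEA, dIA, dPA, dCSA, dPSA, dT])


def _rhs_alcohol(arr: np.ndarray, p: ModelParameters) -> np.ndarray:
    S, P, EA, IA, PA, T = arr
    N = arr.sum(axis=0)
    lamA = p.beta1 * (IA + PA) / N
    dS = (1 - p.pi) * p.K - (lamA + p.delta + p.mu) * S
    dP = p.pi * p.K + p.delta * S - (p.rho1 * lamA + p.mu) * P
    dEA = lamA * S + p.rho1 * lamA * P - (p.mu + p.alpha1) * EA
    dIA = p.alpha1 * EA - (p.alpha2 + p.eps1 + p.mu + p.dA) * IA
    dPA = p.alpha2 * IA - (p.mu + p.dPA) * PA
    dT = p.eps1 * IA - p.mu * T
    return np.stack([dS, dP, dEA, dIA, dPA, dT])


def _rhs_smoking(arr: np.ndarray, p: ModelParameters) -> np.ndarray:
    S, P, ES, IS, PS, T = arr
    N = arr.sum(axis=0)
    lamS = p.beta2 * (IS + PS) / N
    dS = (1 - p.pi) * p.K - (lamS + p.delta + p.mu) * S
    dP = p.pi * p.K + p.delta * S - (p.delta1 * lamS + p.mu) * P
    dES = lamS * S + p.delta1 * lamS * P - (p.mu + p.gamma1) * ES
    dIS = p.gamma1 * ES - (p.eps2 + p.gamma2 + p.mu + p.dS) * IS
    dPS = p.gamma2 * IS - (p.mu + p.dPS) * PS
    dT = p.eps2 * IS - p.mu * T
    return np.stack([dS, dP, dES, dIS, dPS, dT])


_RHS = {"full": _rhs_full, "alcohol": _rhs_alcohol, "smoking": _rhs_smoking}


def rhs(t: float, state, params: ModelParameters, submodel: str = "full",
        check: bool = True) -> np.ndarray:
    """Time derivative of the compartment vector.

    The component-wise sum obeys the demographic identity
    ``dN/dt = K - mu N - sum(addiction death terms)``.  ``state`` may carry a
    trailing batch axis.  With ``check=True`` (default) negative compartment
    values raise ``ValueError``; derivative-based analyses (Jacobians,
    center-manifold coefficients) evaluate with ``check=False``.
    """
    del t  # autonomous system
    arr = _as_state_array(state, submodel)
    if check and np.any(arr < 0):
        raise ValueError("state has negative compartment value(s)")
    return _RHS[submodel](arr, params)


@dataclass(frozen=True)
class Trajectory:
    """Solution of one simulation on a uniform time grid.

    ``states`` has shape ``(n_times, n_compartments)`` or, for batched
    initial conditions, ``(n_times, n_compartments, batch)``.
    """

    t: np.ndarray
    states: np.ndarray
    submodel: str = "full"

    @property
    def N(self) -> np.ndarray:
        return self.states.sum(axis=1)

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]

    def to_dataframe(self) -> pd.DataFrame:
        if self.states.ndim != 2:
            raise ValueError("to_dataframe supports only unbatched trajectories")
        frame = pd.DataFrame(self.states, columns=list(compartment_names(self.submodel)))
        frame.insert(0, "t", self.t)
        frame["N"] = self.states.sum(axis=1)
        return frame

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def rk4_integrate(f, y0: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Classical fixed-step RK4 on a uniform grid; returns (len(t), *y0.shape)."""
    y = np.empty((len(t),) + y0.shape, dtype=float)
    y[0] = y0
    for k in range(len(t) - 1):
        h = t[k + 1] - t[k]
        yk = y[k]
        k1 = f(t[k], yk)
        k2 = f(t[k] + h / 2, yk + h / 2 * k1)
        k3 = f(t[k] + h / 2, yk + h / 2 * k2)
        k4 = f(t[k + 1], yk + h * k3)
        y[k + 1] = yk + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(y[k + 1])):
            raise RuntimeError(f"non-finite state at integration step {k + 1}")
    return y


def simulate(params: ModelParameters, init=None, t_final: float = DEFAULT_T_FINAL,
             n_steps: int = DEFAULT_N_STEPS, submodel: str = "full") -> Trajectory:
    """Integrate the selected system with fixed-step classical RK4.

    ``init`` defaults to :data:`DEFAULT_INITIAL_STATE` (restricted to the
    sub-model compartments when applicable) and may be batched with a
    trailing axis.  Initial compartments must be nonnegative.  The integrator
    uses a uniform grid of ``n_steps + 1`` points; no clipping of small
    negative overshoot is applied, so positivity holds only up to the
    integrator tolerance.
    """
    if init is None:
        init = DEFAULT_INITIAL_STATE
    y0 = _as_state_array(init, submodel)
    if np.any(y0 < 0):
        raise ValueError("initial state must be nonnegative")
    if t_final <= 0:
        raise ValueError("t_final must be positive")
    if n_steps < 1:
        raise ValueError("n_steps must be at least 1")
    t = np.linspace(0.0, float(t_final), int(n_steps) + 1)

    def f(ti, yi):
        return rhs(ti, yi, params, submodel, check=False)

    states = rk4_integrate(f, y0, t)
    return Trajectory(t=t, states=states, submodel=submodel)
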