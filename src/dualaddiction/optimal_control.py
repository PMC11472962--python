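"""Optimal control of the dual-addiction model via the Pontryagin principle.

Six bounded controls act on the system: education-based protection against
smoking (w1), alcohol (w2) and dual addiction (w3, acting on the S -> P
protection flow), and treatment of smoking-addicted (w4), alcohol-addicted
(w5) and dual-addicted (w6) individuals.  The objective is the integrated
addicted burden (weights D1..D6 on IS, PS, IA, PA, CSA, PSA) plus quadratic
control effort (weights psi1..psi6).

The Hamiltonian is the single source of truth: the adjoint (costate) system
is generated symbolically as -dH/dx, and the pointwise control update is the
clipped minimiser of H, which is an explicit quadratic in each control.  The
two-point boundary-value optimality system is solved with the classical
forward-backward sweep: forward RK4 of the state, backward RK4 of the
adjoint from the zero terminal (transversality) condition, and a relaxed
control update, iterated to convergence.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import sympy as sp

from .model_core import (
    DEFAULT_INITIAL_STATE,
    DEFAULT_N_STEPS,
    DEFAULT_T_FINAL,
    ModelParameters,
    Trajectory,
    _as_state_array,
)

__all__ = [
    "Weights",
    "ControlSchedule",
    "SweepResult",
    "N_CONTROLS",
    "strategy_catalog",
    "controlled_rhs",
    "objective_functional",
    "hamiltonian",
    "adjoint_rhs",
    "adjoint_rhs_printed",
    "control_update",
    "forward_backward_sweep",
]

N_CONTROLS = 6

# parameters entering the controlled dynamics, in lambdify argument order
_PARAM_NAMES = (
    "K", "mu", "pi", "delta", "delta1", "delta2", "delta3",
    "rho1", "rho2", "rho3", "eps1", "eps2", "eps3",
    "beta1", "beta2", "alpha1", "alpha2", "alpha",
    "gamma1", "gamma2", "theta1", "theta2",
    "dS", "dA", "dPS", "dPA", "dC", "dSA",
)


@dataclass(frozen=True)
class Weights:
    """Objective weights: addicted-burden costs D and control-effort costs psi."""

    D1: float = 7.0
    D2: float = 7.0
    D3: float = 7.0
    D4: float = 7.0
    D5: float = 7.0
    D6: float = 7.0
    psi1: float = 10.0
    psi2: float = 10.0
    psi3: float = 10.0
    psi4: float = 10.0
    psi5: float = 10.0
    psi6: float = 10.0

    def __post_init__(self) -> None:
        for name, value in dataclasses.asdict(self).items():
            if value <= 0:
                raise ValueError(f"weight {name} must be strictly positive, got {value}")

    @property
    def D(self) -> np.ndarray:
        return np.array([self.D1, self.D2, self.D3, self.D4, self.D5, self.D6])

    @property
    def psi(self) -> np.ndarray:
        return np.array([self.psi1, self.psi2, self.psi3,
                         self.psi4, self.psi5, self.psi6])


def strategy_catalog() -> dict[str, frozenset[int]]:
    """Named intervention strategies -> set of active control indices (1-based).

    A and B combine three protection or three treatment controls; C-E add one
    treatment to all protections; F-H add two; I applies all six.
    """
    return {
        "A": frozenset({1, 2, 3}),
        "B": frozenset({4, 5, 6}),
        "C": frozenset({1, 2, 3, 4}),
        "D": frozenset({1, 2, 3, 5}),
        "E": frozenset({1, 2, 3, 6}),
        "F": frozenset({1, 2, 3, 4, 5}),
        "G": frozenset({1, 2, 3, 4, 6}),
        "H": frozenset({1, 2, 3, 5, 6}),
        "I": frozenset({1, 2, 3, 4, 5, 6}),
    }


def _resolve_mask(strategy) -> frozenset[int]:
    if isinstance(strategy, str):
        catalog = strategy_catalog()
        if strategy not in catalog:
            raise KeyError(f"unknown strategy '{strategy}'; expected one of "
                           f"{sorted(catalog)} or an explicit control set")
        return catalog[strategy]
    mask = frozenset(int(i) for i in strategy)
    if not mask or not mask <= {1, 2, 3, 4, 5, 6}:
        raise ValueError(f"control mask must be a nonempty subset of 1..6, got {set(strategy)}")
    return mask


@dataclass(frozen=True)
class ControlSchedule:
    """Time-gridded control values w1..w6, each in [0, 1]."""

    t: np.ndarray
    values: np.ndarray  # shape (6, len(t))
    mask: frozenset[int] = frozenset({1, 2, 3, 4, 5, 6})

    def __post_init__(self) -> None:
        if self.values.shape != (N_CONTROLS, len(self.t)):
            raise ValueError(
                f"control values must have shape (6, {len(self.t)}), got {self.values.shape}"
            )
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("control values must lie in [0, 1]")
        inactive = [i for i in range(1, 7) if i not in self.mask]
        if inactive and np.any(self.values[[i - 1 for i in inactive]] != 0):
            raise ValueError("controls outside the strategy mask must be identically 0")


@dataclass(frozen=True)
class SweepResult:
    """Converged (or final) output of the forward-backward sweep."""

    trajectory: Trajectory
    controls: ControlSchedule
    adjoint: np.ndarray  # shape (11, len(t))
    objective: float
    n_iter: int
    converged: bool
    objective_history: tuple[float, ...]


def _check_controls(w) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.shape[0] != N_CONTROLS:
        raise ValueError(f"expected {N_CONTROLS} controls, got shape {w.shape}")
    if np.any(w < 0) or np.any(w > 1):
        raise ValueError("controls must lie in [0, 1]")
    return w


def controlled_rhs(t, state, w, params: ModelParameters, check: bool = True) -> np.ndarray:
    """Derivatives of the eleven compartments under the six controls.

    Protection controls scale the forces of addiction by (1 - w1)/(1 - w2)
    and gate the protection flow by w3; treatment controls gate the
    improvement rates (w4 eps2, w5 eps1, w6 eps3).  Note two consequences of
    the published controlled system that differ from the uncontrolled model
    at w = 0: the protection flow S -> P and all improvement flows switch
    off entirely, and the CSA inflow from IS/PS carries (1 - w2) while the
    matching outflow carries (1 - w4) (an imbalance kept as published).

    Accepts a trailing batch axis on ``state`` and ``w``.
    """
    del t
    arr = _as_state_array(state, "full")
    w = _check_controls(w) if check else np.asarray(w, dtype=float)
    w1, w2, w3, w4, w5, w6 = w
    p = params
    S, P, ES, IS, PS, EA, IA, PA, CSA, PSA, T = arr
    N = arr.sum(axis=0)
    lamA = p.beta1 * (IA + PA + p.theta1 * (CSA + PSA)) / N
    lamS = p.beta2 * (IS + PS + p.theta2 * (CSA + PSA)) / N
    dS = (1 - p.pi) * p.K - (1 - w1) * lamS * S - (1 - w2) * lamA * S - w3 * p.delta * S - p.mu * S
    dP = (p.pi * p.K + w3 * p.delta * S - (1 - w2) * p.rho1 * lamA * P
          - (1 - w1) * p.delta1 * lamS * P - p.mu * P)
    dES = (1 - w1) * lamS * S + (1 - w1) * p.delta1 * lamS * P - (p.mu + p.gamma1) * ES
    dIS = (p.gamma1 * ES - w4 * p.eps2 * IS - p.gamma2 * IS
           - (1 - w4) * p.rho3 * lamA * IS - (p.mu + p.dS) * IS)
    dPS = p.gamma2 * IS - (1 - w4) * p.rho2 * lamA * PS - (p.mu + p.dPS) * PS
    dEA = (1 - w2) * lamA * S + (1 - w2) * p.rho1 * lamA * P - (p.mu + p.alpha1) * EA
    dIA = (p.alpha1 * EA - p.alpha2 * IA - w5 * p.eps1 * IA
           - (1 - w1) * p.delta2 * lamS * IA - (p.mu + p.dA) * IA)
    dPA = p.alpha2 * IA - (1 - w1) * p.delta3 * lamS * PA - (p.mu + p.dPA) * PA
    dCSA = ((1 - w1) * p.delta2 * lamS * IA + (1 - w1) * p.delta3 * lamS * PA
            + (1 - w2) * p.rho3 * lamA * IS + (1 - w2) * p.rho2 * lamA * PS
            - (p.alpha + w6 * p.eps3 + p.mu + p.dC) * CSA)
    dPSA = p.alpha * CSA - (p.mu + p.dSA) * PSA
    dT = w6 * p.eps3 * CSA + w5 * p.eps1 * IA + w4 * p.eps2 * IS - p.mu * T
    return np.stack([dS, dP, dES, dIS, dPS, dEA, dIA, dPA, dCSA, dPSA, dT])


def _running_cost(state, w, weights: Weights):
    burden = state[[3, 4, 6, 7, 8, 9]]  # IS, PS, IA, PA, CSA, PSA
    D = weights.D.reshape((6,) + (1,) * (np.ndim(state) - 1))
    psi = weights.psi.reshape((6,) + (1,) * (np.ndim(w) - 1))
    return (D * burden).sum(axis=0) + 0.5 * (psi * np.asarray(w) ** 2).sum(axis=0)


def objective_functional(traj: Trajectory, controls: ControlSchedule,
                         weights: Weights) -> float:
    """Trapezoid-rule value of the cost functional J on the shared grid."""
    if len(traj.t) != len(controls.t) or not np.allclose(traj.t, controls.t):
        raise ValueError("trajectory and control schedule use different time grids")
    integrand = _running_cost(traj.states.T, controls.values, weights)
    return float(np.trapezoid(integrand, traj.t))


def hamiltonian(state, w, adjoint, weights: Weights, params: ModelParameters):
    """Running cost plus adjoint-weighted controlled dynamics (vectorised)."""
    chi = controlled_rhs(0.0, state, w, params, check=False)
    return _running_cost(np.asarray(state, dtype=float), np.asarray(w, dtype=float),
                         weights) + (np.asarray(adjoint) * chi).sum(axis=0)


@lru_cache(maxsize=1)
def _adjoint_function():
    """Symbolically derived adjoint right-hand side, -dH/dx, lambdified.

    Differentiates the implemented Hamiltonian exactly, including the
    standard-incidence terms from the dependence of the forces of addiction
    on every compartment through N.
    """
    z = sp.symbols("z1:12", real=True)
    w = sp.symbols("w1:7", real=True)
    f = sp.symbols("f1:12", real=True)
    pars = sp.symbols(_PARAM_NAMES, positive=True)
    D = sp.symbols("D1:7", positive=True)
    p = dict(zip(_PARAM_NAMES, pars))
    S, P, ES, IS, PS, EA, IA, PA, CSA, PSA, T = z
    w1, w2, w3, w4, w5, w6 = w
    N = sum(z)
    lamA = p["beta1"] * (IA + PA + p["theta1"] * (CSA + PSA)) / N
    lamS = p["beta2"] * (IS + PS + p["theta2"] * (CSA + PSA)) / N
    chi = [
        (1 - p["pi"]) * p["K"] - (1 - w1) * lamS * S - (1 - w2) * lamA * S
        - w3 * p["delta"] * S - p["mu"] * S,
        p["pi"] * p["K"] + w3 * p["delta"] * S - (1 - w2) * p["rho1"] * lamA * P
        - (1 - w1) * p["delta1"] * lamS * P - p["mu"] * P,
        (1 - w1) * lamS * S + (1 - w1) * p["delta1"] * lamS * P
        - (p["mu"] + p["gamma1"]) * ES,
        p["gamma1"] * ES - w4 * p["eps2"] * IS - p["gamma2"] * IS
        - (1 - w4) * p["rho3"] * lamA * IS - (p["mu"] + p["dS"]) * IS,
        p["gamma2"] * IS - (1 - w4) * p["rho2"] * lamA * PS - (p["mu"] + p["dPS"]) * PS,
        (1 - w2) * lamA * S + (1 - w2) * p["rho1"] * lamA * P
        - (p["mu"] + p["alpha1"]) * EA,
        p["alpha1"] * EA - p["alpha2"] * IA - w5 * p["eps1"] * IA
        - (1 - w1) * p["delta2"] * lamS * IA - (p["mu"] + p["dA"]) * IA,
        p["alpha2"] * IA - (1 - w1) * p["delta3"] * lamS * PA - (p["mu"] + p["dPA"]) * PA,
        (1 - w1) * p["delta2"] * lamS * IA + (1 - w1) * p["delta3"] * lamS * PA
        + (1 - w2) * p["rho3"] * lamA * IS + (1 - w2) * p["rho2"] * lamA * PS
        - (p["alpha"] + w6 * p["eps3"] + p["mu"] + p["dC"]) * CSA,
        p["alpha"] * CSA - (p["mu"] + p["dSA"]) * PSA,
        w6 * p["eps3"] * CSA + w5 * p["eps1"] * IA + w4 * p["eps2"] * IS - p["mu"] * T,
    ]
    H = (D[0] * IS + D[1] * PS + D[2] * IA + D[3] * PA + D[4] * CSA + D[5] * PSA
         + sum(fi * ci for fi, ci in zip(f, chi)))
    # the quadratic effort term does not depend on the state, so it is omitted
    adj = [sp.together(-sp.diff(H, zi)) for zi in z]
    return sp.lambdify(z + w + f + pars + D, adj, modules="numpy", cse=True)


def _param_args(params: ModelParameters) -> tuple[float, ...]:
    return tuple(getattr(params, name) for name in _PARAM_NAMES)


def adjoint_rhs(t, state, w, adjoint, weights: Weights,
                params: ModelParameters) -> np.ndarray:
    """Costate derivatives df/dt = -dH/dx (exact gradient of the Hamiltonian)."""
    del t
    func = _adjoint_function()
    state = np.asarray(state, dtype=float)
    w = np.asarray(w, dtype=float)
    adjoint = np.asarray(adjoint, dtype=float)
    out = func(*state, *w, *adjoint, *_param_args(params),
               weights.D1, weights.D2, weights.D3, weights.D4, weights.D5, weights.D6)
    return np.stack([np.broadcast_to(o, state.shape[1:]) if np.ndim(o) == 0 else o
                     for o in out]) if state.ndim > 1 else np.array(out, dtype=float)


def adjoint_rhs_printed(t, state, w, adjoint, weights: Weights,
                        params: ModelParameters) -> np.ndarray:
    """Costate equations transcribed from the published optimality system.

    Kept as a secondary reference implementation.  The published equations
    treat the forces of addiction as frozen coefficients (dropping the
    standard-incidence dN corrections of the exact gradient) and contain
    transcription slips (e.g. w5*eps2 where the dynamics use w4*eps2; N* in
    place of S* in the f5 bracket; a stray beta1*alpha1 factor in f9/f10);
    they coincide with :func:`adjoint_rhs` on the costates f1, f2, f3, f6,
    f11 at addiction-free states.  Fraction slashes lost in the published
    typography are restored following the force-of-addiction notation
    (beta N == beta / N).
    """
    del t
    p = params
    S, P, ES, IS, PS, EA, IA, PA, CSA, PSA, T = np.asarray(state, dtype=float)
    w1, w2, w3, w4, w5, w6 = np.asarray(w, dtype=float)
    f1, f2, f3, f4, f5, f6, f7, f8, f9, f10, f11 = np.asarray(adjoint, dtype=float)
    N = np.asarray(state, dtype=float).sum(axis=0)
    lamA = p.beta1 * (IA + PA + p.theta1 * (CSA + PSA)) / N
    lamS = p.beta2 * (IS + PS + p.theta2 * (CSA + PSA)) / N
    df1 = (1 - w1) * lamS * (f1 - f3) + (1 - w2) * lamA * (f1 - f6) \
        + w3 * p.delta * (f1 - f2) + p.mu * f1
    df2 = (1 - w2) * p.rho1 * lamA * (f2 - f6) + (1 - w1) * p.delta1 * lamS * (f2 - f3) \
        + p.mu * f2
    df3 = p.mu * f3 + p.gamma1 * (f3 - f4)
    df4 = (-weights.D1 + (1 - w1) * p.beta2 / N
           * (S * (f1 - f3) + p.delta1 * P * (f2 - f3)
              + IA * p.delta2 * (f7 - f9) + PA * p.delta3 * (f8 - f9))
           + p.gamma2 * (f4 - f5) + (1 - w2) * (f4 - f9) * p.rho3 * lamA
           + (w5 * p.eps2 + p.mu) * f4)
    df5 = (-weights.D2 + (1 - w1) * p.beta2 / N
           * (N * (f1 - f3) + p.delta1 * P * (f2 - f3)
              + p.delta2 * IA * (f7 - f9) + p.rho2 * PA * (f8 - f9))
           + (1 - w2) * p.rho2 * lamA * (f5 - f9))
    df6 = p.mu * f6 + p.alpha1 * (f6 - f7)
    df7 = (-weights.D3 + (1 - w2) * p.beta1 / N
           * (S * (f1 - f6) + p.rho1 * P * (f2 - f6)
              + p.rho3 * IS * (f4 - f9) + p.rho2 * P * (f5 - f9))
           + (1 - w1) * p.delta2 * lamS * (f7 - f9) + p.alpha2 * (f7 - f8)
           + w4 * p.eps1 * (f7 - f11) + p.mu * f7)
    df8 = (-weights.D4 + (1 - w2) * p.beta1 / N
           * (S * (f1 - f6) + p.rho1 * P * (f2 - f6)
              + p.rho3 * IS * (f4 - f9) + p.rho2 * PA * (f5 - f5))
           + (1 - w1) * p.delta3 * lamS * (f8 - f9) + p.mu * f8)
    df9 = (-weights.D5 + (1 - w1) * p.beta2 * p.theta1 / N
           * (S * (f1 - f3) + p.delta1 * P * (f2 - f3)
              + p.delta2 * IA * (f7 - f9) + p.rho3 * PA * (f8 - f9))
           + (1 - w2) * p.beta1 * p.alpha1 / N
           * (S * (f1 - f6) + p.rho3 * IS * (f4 - f9)
              + p.rho1 * P * (f2 - f6) + p.rho2 * PA * (f5 - f9))
           + p.mu * f9 + p.alpha * (f9 - f10) + w6 * p.eps3 * (f9 - f11))
    df10 = (-weights.D6 + (1 - w1) * p.beta2 * p.theta1 / S
            * (S * (f1 - f3) + p.delta1 * P * (f2 - f3)
               + p.delta2 * IA * (f7 - f9) + p.delta3 * PA * (f8 - f9))
            + (1 - w2) * p.beta1 * p.alpha1 / N
            * (S * (f1 - f6) + p.rho3 * IS * (f4 - f9)
               + p.rho1 * P * (f2 - f6) + p.rho2 * PA * (f5 - f9))
            + p.mu * f10)
    df11 = p.mu * f11
    return np.stack([df1, df2, df3, df4, df5, df6, df7, df8, df9, df10,
                     np.broadcast_to(df11, np.shape(df1))])


def control_update(state, adjoint, weights: Weights, params: ModelParameters,
                   mask=frozenset({1, 2, 3, 4, 5, 6})) -> np.ndarray:
    """Pointwise minimiser of the Hamiltonian over the admissible controls.

    H is an explicit quadratic (psi_i/2) w_i^2 + L_i w_i + const in each
    control with no cross terms; L_i is extracted from two Hamiltonian
    evaluations (at w_i = 0 and w_i = 1), so the update is robust to any
    transcription error in a printed formula.  The unconstrained minimiser
    -L_i/psi_i is clipped to [0, 1]; controls outside the mask return 0.
    """
    mask = _resolve_mask(mask)
    state = np.asarray(state, dtype=float)
    adjoint = np.asarray(adjoint, dtype=float)
    batch = state.shape[1:]
    psi = weights.psi
    w_out = np.zeros((N_CONTROLS,) + batch)
    zero = np.zeros((N_CONTROLS,) + batch)
    H0 = hamiltonian(state, zero, adjoint, weights, params)
    for i in sorted(mask):
        wi = zero.copy()
        wi[i - 1] = 1.0
        L = hamiltonian(state, wi, adjoint, weights, params) - H0 - 0.5 * psi[i - 1]
        w_out[i - 1] = np.clip(-L / psi[i - 1], 0.0, 1.0)
    return w_out


def _forward_pass(params: ModelParameters, init: np.ndarray, t: np.ndarray,
                  w: np.ndarray) -> np.ndarray:
    m = len(t)
    x = np.empty((11, m))
    x[:, 0] = init
    for k in range(m - 1):
        h = t[k + 1] - t[k]
        wk, wk1 = w[:, k], w[:, k + 1]
        wmid = 0.5 * (wk + wk1)
        xk = x[:, k]
        k1 = controlled_rhs(t[k], xk, wk, params, check=False)
        k2 = controlled_rhs(t[k] + h / 2, xk + h / 2 * k1, wmid, params, check=False)
        k3 = controlled_rhs(t[k] + h / 2, xk + h / 2 * k2, wmid, params, check=False)
        k4 = controlled_rhs(t[k + 1], xk + h * k3, wk1, params, check=False)
        x[:, k + 1] = xk + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(x[:, k + 1])):
            raise RuntimeError(f"non-finite state at forward step {k + 1}")
    return x


def _backward_pass(params: ModelParameters, weights: Weights, x: np.ndarray,
                   t: np.ndarray, w: np.ndarray) -> np.ndarray:
    m = len(t)
    f = np.zeros((11, m))  # transversality: f(T_F) = 0
    for k in range(m - 2, -1, -1):
        h = t[k + 1] - t[k]
        xk, xk1 = x[:, k], x[:, k + 1]
        xmid = 0.5 * (xk + xk1)
        wk, wk1 = w[:, k], w[:, k + 1]
        wmid = 0.5 * (wk + wk1)
        fk1 = f[:, k + 1]
        k1 = adjoint_rhs(t[k + 1], xk1, wk1, fk1, weights, params)
        k2 = adjoint_rhs(t[k] + h / 2, xmid, wmid, fk1 - h / 2 * k1, weights, params)
        k3 = adjoint_rhs(t[k] + h / 2, xmid, wmid, fk1 - h / 2 * k2, weights, params)
        k4 = adjoint_rhs(t[k], xk, wk, fk1 - h * k3, weights, params)
        f[:, k] = fk1 - h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(f[:, k])):
            raise RuntimeError(f"non-finite costate at backward step {k}")
    return f


def forward_backward_sweep(params: ModelParameters, weights: Weights | None = None,
                           strategy="I", init=None,
                           t_final: float = DEFAULT_T_FINAL,
                           n_steps: int = DEFAULT_N_STEPS,
                           tol: float = 1e-3, max_iter: int = 100,
                           relaxation: float = 0.5) -> SweepResult:
    """Solve the optimality system by the relaxed forward-backward sweep.

    Each iteration integrates the state forward under the current controls,
    the adjoint backward from zero terminal values, updates the controls by
    the clipped Hamiltonian minimiser, and relaxes
    ``w <- (1-c) w_old + c w_new``.  Convergence is declared when the
    largest control change on the grid falls below ``tol`` (controls live in
    [0, 1], so the absolute change is the relative change on the control
    scale).  Non-convergence within ``max_iter`` is flagged on the result,
    not raised.
    """
    if weights is None:
        weights = Weights()
    if tol <= 0:
        raise ValueError("tol must be positive")
    if not 0 < relaxation <= 1:
        raise ValueError("relaxation must lie in (0, 1]")
    mask = _resolve_mask(strategy)
    if init is None:
        init = DEFAULT_INITIAL_STATE
    y0 = _as_state_array(init, "full")
    t = np.linspace(0.0, float(t_final), int(n_steps) + 1)
    m = len(t)
    w = np.zeros((N_CONTROLS, m))
    history: list[float] = []
    converged = False
    n_iter = 0
    x = _forward_pass(params, y0, t, w)
    f = np.zeros((11, m))
    for n_iter in range(1, max_iter + 1):
        x = _forward_pass(params, y0, t, w)
        f = _backward_pass(params, weights, x, t, w)
        w_new = control_update(x, f, weights, params, mask)
        w_next = (1 - relaxation) * w + relaxation * w_new
        change = float(np.max(np.abs(w_next - w)))
        traj = Trajectory(t=t, states=x.T, submodel="full")
        schedule = ControlSchedule(t=t, values=w, mask=mask)
        history.append(objective_functional(traj, schedule, weights))
        w = w_next
        if change < tol:
            converged = True
            break
    x = _forward_pass(params, y0, t, w)
    traj = Trajectory(t=t, states=x.T, submodel="full")
    schedule = ControlSchedule(t=t, values=w, mask=mask)
    J = objective_functional(traj, schedule, weights)
    return SweepResult(trajectory=traj, controls=schedule, adjoint=f,
                       objective=J, n_iter=n_iter, converged=converged,
                       objective_history=tuple(history))
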