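"""Equilibria, reproduction numbers, stability, and bifurcation analysis.

The addiction-free equilibrium (DFE) exists for all parameter values; its
local stability is governed by the effective reproduction number computed
with the next-generation-matrix (NGM) construction.  Endemic (dominance)
equilibria of each sub-model are roots of a scalar fixed-point equation in
the equilibrium force of addiction; clearing denominators turns that
equation into a quadratic, whose coefficient signs classify forward versus
backward bifurcation.  The dual model's behaviour at the critical point is
characterised by the Castillo-Chavez--Song center-manifold coefficients
``a`` and ``b`` (backward bifurcation iff both positive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .model_core import (
    ModelParameters,
    compartment_names,
    rhs,
)

__all__ = [
    "ReproductionNumbers",
    "QuadraticCoefficients",
    "EquilibriumReport",
    "CenterManifoldResult",
    "addiction_free_equilibrium",
    "r0_closed_form",
    "reproduction_numbers",
    "ngm_spectral_radius",
    "endemic_state_from_force",
    "endemic_fixed_point_map",
    "quadratic_coefficients",
    "endemic_equilibria",
    "jacobian",
    "jacobian_eigenvalues",
    "routh_hurwitz_cubic",
    "bifurcation_curve",
    "center_manifold_coefficients",
]

# addicted compartments of each six-compartment sub-model (E, I, P pathway)
_ADDICTED_IDX = {"alcohol": (2, 3, 4), "smoking": (2, 3, 4)}


@dataclass(frozen=True)
class ReproductionNumbers:
    """Effective reproduction numbers; the dual value is the max of the two."""

    R0A: float
    R0S: float

    @property
    def R0AS(self) -> float:
        return max(self.R0A, self.R0S)

    @property
    def dominant(self) -> str:
        return "alcohol" if self.R0A >= self.R0S else "smoking"


@dataclass(frozen=True)
class QuadraticCoefficients:
    """Coefficients c2 x^2 + c1 x + c0 of the endemic fixed-point quadratic."""

    c2: float
    c1: float
    c0: float

    def positive_roots(self) -> tuple[float, ...]:
        roots = np.roots([self.c2, self.c1, self.c0])
        real = roots[np.abs(roots.imag) < 1e-9 * (1 + np.abs(roots.real))].real
        return tuple(sorted(r for r in real if r > 0))


@dataclass(frozen=True)
class EquilibriumReport:
    """An equilibrium state with its Jacobian spectrum and stability verdict."""

    state: np.ndarray
    kind: str  # "addiction-free" | "endemic"
    eigenvalues: np.ndarray
    stable: bool
    force: float = 0.0  # equilibrium force of addiction (0 at the DFE)

    @property
    def verdict(self) -> str:
        return "locally stable" if self.stable else "unstable"


@dataclass(frozen=True)
class CenterManifoldResult:
    """Center-manifold data at the critical dissemination rate.

    ``a`` and ``b`` are the Castillo-Chavez--Song bifurcation coefficients;
    ``a > 0`` together with ``b > 0`` signals a backward bifurcation (a
    stable endemic branch bending into the region where the reproduction
    number is below one).
    """

    beta_star: float
    dominant: str
    u: np.ndarray  # right null vector of the critical Jacobian
    v: np.ndarray  # left null vector, normalised so v @ u = 1
    a: float
    b: float

    @property
    def backward(self) -> bool:
        return self.a > 0 and self.b > 0


def addiction_free_equilibrium(params: ModelParameters, submodel: str = "full") -> np.ndarray:
    """The DFE: S0 = (1-pi)K/(delta+mu), P0 = K(delta+pi*mu)/(mu(delta+mu)).

    All addicted compartments and the rehabilitated class are zero; note
    ``S0 + P0 = K/mu``, the demographic carrying capacity.
    """
    names = compartment_names(submodel)
    S0 = (1 - params.pi) * params.K / (params.delta + params.mu)
    P0 = params.K * (params.delta + params.pi * params.mu) / (params.mu * (params.delta + params.mu))
    state = np.zeros(len(names))
    state[0] = S0
    state[1] = P0
    return state


def r0_closed_form(params: ModelParameters, submodel: str) -> float:
    """Closed-form effective reproduction number.

    Derived from the next-generation construction over the addicted
    compartments (E, I, P of one pathway) at the DFE:

        R0A = beta1 a1 (a2 + mu + dPA) [mu(1-pi) + rho1(delta + pi mu)]
              / [(mu+a1)(a2+e1+mu+dA)(mu+dPA)(delta+mu)]

    and symmetrically for smoking with (beta2, gamma1, gamma2, delta1, eps2,
    dS, dPS).  ``submodel='dual'`` returns the max of the two.
    """
    p = params
    if submodel == "alcohol":
        num = (p.beta1 * p.alpha1 * (p.alpha2 + p.mu + p.dPA)
               * (p.mu * (1 - p.pi) + p.rho1 * (p.delta + p.pi * p.mu)))
        den = ((p.mu + p.alpha1) * (p.alpha2 + p.eps1 + p.mu + p.dA)
               * (p.mu + p.dPA) * (p.delta + p.mu))
        return num / den
    if submodel == "smoking":
        num = (p.beta2 * p.gamma1 * (p.gamma2 + p.mu + p.dPS)
               * (p.mu * (1 - p.pi) + p.delta1 * (p.delta + p.pi * p.mu)))
        den = ((p.mu + p.gamma1) * (p.eps2 + p.gamma2 + p.mu + p.dS)
               * (p.mu + p.dPS) * (p.delta + p.mu))
        return num / den
    if submodel in ("dual", "full"):
        return max(r0_closed_form(params, "alcohol"), r0_closed_form(params, "smoking"))
    raise ValueError(f"unknown submodel '{submodel}'")


def reproduction_numbers(params: ModelParameters) -> ReproductionNumbers:
    return ReproductionNumbers(
        R0A=r0_closed_form(params, "alcohol"),
        R0S=r0_closed_form(params, "smoking"),
    )


def _new_addiction_vector(addicted: np.ndarray, params: ModelParameters,
                          submodel: str, dfe: np.ndarray) -> np.ndarray:
    """Rate of appearance of new addictions in (E, I, P), susceptibles at DFE."""
    state = dfe.copy()
    state[[2, 3, 4]] = addicted
    beta = params.beta1 if submodel == "alcohol" else params.beta2
    mod = params.rho1 if submodel == "alcohol" else params.delta1
    N = state.sum()
    lam = beta * (state[3] + state[4]) / N
    return np.array([lam * (state[0] + mod * state[1]), 0.0, 0.0])


def _transition_vector(addicted: np.ndarray, params: ModelParameters,
                       submodel: str, dfe: np.ndarray) -> np.ndarray:
    state = dfe.copy()
    state[[2, 3, 4]] = addicted
    f = _new_addiction_vector(addicted, params, submodel, dfe)
    deriv = rhs(0.0, state, params, submodel, check=False)[[2, 3, 4]]
    return f - deriv


def ngm_spectral_radius(params: ModelParameters, submodel: str) -> float:
    """Spectral radius of F V^-1, linearised numerically at the DFE.

    Serves as the independent oracle for :func:`r0_closed_form`: F collects
    new-addiction inflows into the (E, I, P) compartments, V the remaining
    transitions, both differentiated centrally at the addiction-free state.
    """
    if submodel in ("dual", "full"):
        return max(ngm_spectral_radius(params, "alcohol"),
                   ngm_spectral_radius(params, "smoking"))
    dfe = addiction_free_equilibrium(params, submodel)
    n = 3
    scale = max(1.0, float(dfe.sum()))
    h = 1e-6 * scale
    F = np.empty((n, n))
    V = np.empty((n, n))
    for j in range(n):
        e = np.zeros(n)
        e[j] = h
        F[:, j] = (_new_addiction_vector(e, params, submodel, dfe)
                   - _new_addiction_vector(-e, params, submodel, dfe)) / (2 * h)
        V[:, j] = (_transition_vector(e, params, submodel, dfe)
                   - _transition_vector(-e, params, submodel, dfe)) / (2 * h)
    K = F @ np.linalg.inv(V)
    return float(np.max(np.abs(np.linalg.eigvals(K))))


def endemic_state_from_force(params: ModelParameters, submodel: str, lam: float) -> np.ndarray:
    """Sub-model equilibrium compartments as functions of the force lambda*.

    Solves the steady-state balance sequentially: S*, then P*, then the
    addiction pathway E*, I*, P(perm)*, then T*.
    """
    p = params
    if submodel == "alcohol":
        prot_mod, prog1, out_I, out_P, improve = (
            p.rho1, p.alpha1, p.alpha2 + p.eps1 + p.mu + p.dA, p.mu + p.dPA, p.eps1)
        prog2 = p.alpha2
    elif submodel == "smoking":
        prot_mod, prog1, out_I, out_P, improve = (
            p.delta1, p.gamma1, p.eps2 + p.gamma2 + p.mu + p.dS, p.mu + p.dPS, p.eps2)
        prog2 = p.gamma2
    else:
        raise ValueError(f"endemic analysis applies to the sub-models, not '{submodel}'")
    S = (1 - p.pi) * p.K / (lam + p.delta + p.mu)
    P = (p.pi * p.K + p.delta * S) / (prot_mod * lam + p.mu)
    E = lam * (S + prot_mod * P) / (p.mu + prog1)
    I = prog1 * E / out_I
    Pperm = prog2 * I / out_P
    T = improve * I / p.mu
    return np.array([S, P, E, I, Pperm, T])


def endemic_fixed_point_map(params: ModelParameters, submodel: str, lam: float) -> float:
    """Residual g(lambda) = lambda - beta (I* + Pperm*) / N*(lambda).

    Positive roots are endemic equilibria; lambda = 0 always solves g = 0
    (the DFE).
    """
    if lam < 0:
        raise ValueError("the force of addiction must be nonnegative")
    state = endemic_state_from_force(params, submodel, lam)
    beta = params.beta1 if submodel == "alcohol" else params.beta2
    return lam - beta * (state[3] + state[4]) / state.sum()


def quadratic_coefficients(params: ModelParameters, submodel: str) -> QuadraticCoefficients:
    """Numerically recover the cleared-denominator quadratic in lambda*.

    Multiplying g(lambda) by N*(lambda) and the compartment denominators and
    dividing by lambda leaves a quadratic Q(lambda); its coefficients are
    fitted exactly from three evaluations.  For valid parameters c2 > 0 and
    sign(c0) = sign(1 - R0).
    """
    p = params
    prot_mod = p.rho1 if submodel == "alcohol" else p.delta1
    beta = p.beta1 if submodel == "alcohol" else p.beta2

    def Q(lam: float) -> float:
        state = endemic_state_from_force(params, submodel, lam)
        g = endemic_fixed_point_map(params, submodel, lam)
        denom = (lam + p.delta + p.mu) * (prot_mod * lam + p.mu)
        return g * state.sum() * denom / (lam * p.K)

    # three well-separated sample points; Q is exactly quadratic so any
    # non-degenerate Vandermonde solve recovers the coefficients
    pts = np.array([0.25, 0.5, 1.0]) * max(beta, 1.0)
    vals = np.array([Q(x) for x in pts])
    V = np.vander(pts, 3)
    c2, c1, c0 = np.linalg.solve(V, vals)
    return QuadraticCoefficients(c2=float(c2), c1=float(c1), c0=float(c0))


def _positive_roots_scan(params: ModelParameters, submodel: str,
                         n_scan: int = 10_000) -> list[float]:
    beta = params.beta1 if submodel == "alcohol" else params.beta2
    lam_max = beta  # the weighted prevalence fraction never exceeds 1
    grid = np.linspace(lam_max * 1e-7, lam_max, n_scan)
    vals = np.array([endemic_fixed_point_map(params, submodel, x) for x in grid])
    roots: list[float] = []
    sign = np.sign(vals)
    for k in np.nonzero(sign[:-1] * sign[1:] < 0)[0]:
        root = brentq(lambda x: endemic_fixed_point_map(params, submodel, x),
                      grid[k], grid[k + 1], xtol=1e-14, rtol=1e-14)
        roots.append(float(root))
    # exact grid hits (rare): zero value at a grid point
    for k in np.nonzero(vals == 0)[0]:
        roots.append(float(grid[k]))
    roots = sorted(set(roots))
    if len(roots) > 2:
        raise RuntimeError(
            f"found {len(roots)} positive endemic roots; the fixed-point "
            "equation is quadratic so at most 2 are possible"
        )
    return roots


def jacobian(params: ModelParameters, state: np.ndarray, submodel: str = "full") -> np.ndarray:
    """Central finite-difference Jacobian of the RHS (relative step 1e-6)."""
    state = np.asarray(state, dtype=float)
    n = state.size
    scale = max(1.0, float(np.abs(state).max()))
    h = 1e-6 * scale
    J = np.empty((n, n))
    for j in range(n):
        e = np.zeros(n)
        e[j] = h
        J[:, j] = (rhs(0.0, state + e, params, submodel, check=False)
                   - rhs(0.0, state - e, params, submodel, check=False)) / (2 * h)
    return J


def jacobian_eigenvalues(params: ModelParameters, state: np.ndarray,
                         submodel: str = "full", require_equilibrium: bool = True) -> np.ndarray:
    """Eigenvalues of the Jacobian at an equilibrium state."""
    state = np.asarray(state, dtype=float)
    if require_equilibrium:
        resid = np.linalg.norm(rhs(0.0, state, params, submodel, check=False))
        tol = 1e-8 * max(1.0, float(np.linalg.norm(state)))
        if resid > tol:
            raise ValueError(
                f"state is not an equilibrium: |rhs| = {resid:.3e} > {tol:.3e}"
            )
    return np.linalg.eigvals(jacobian(params, state, submodel))


def _stability(eigenvalues: np.ndarray) -> bool:
    return bool(np.max(eigenvalues.real) < 0)


def endemic_equilibria(params: ModelParameters, submodel: str
                       ) -> tuple[list[EquilibriumReport], QuadraticCoefficients]:
    """All endemic equilibria of a sub-model, with stability verdicts.

    Roots of the fixed-point map are located by a dense sign scan plus
    bisection on (0, beta]; the quadratic coefficients are recovered
    numerically for the forward/backward classification (0, 1, or 2
    positive roots).
    """
    coeffs = quadratic_coefficients(params, submodel)
    reports = []
    for lam in _positive_roots_scan(params, submodel):
        state = endemic_state_from_force(params, submodel, lam)
        eig = jacobian_eigenvalues(params, state, submodel)
        reports.append(EquilibriumReport(
            state=state, kind="endemic", eigenvalues=eig,
            stable=_stability(eig), force=lam,
        ))
    return reports, coeffs


def routh_hurwitz_cubic(a: float, b: float, c: float) -> bool:
    """Stability of x^3 + a x^2 + b x + c: stable iff a > 0, c > 0, a b > c."""
    return a > 0 and c > 0 and a * b > c


def bifurcation_curve(params: ModelParameters, submodel: str,
                      beta_grid) -> pd.DataFrame:
    """Equilibrium branches and their stability along a dissemination-rate grid.

    Returns rows ``(beta, R0, lambda_star, branch, stable)``; the
    addiction-free branch (lambda* = 0) is present for every beta.
    """
    beta_grid = np.asarray(beta_grid, dtype=float)
    if np.any(beta_grid <= 0) or np.any(np.diff(beta_grid) <= 0):
        raise ValueError("beta_grid must be positive and strictly increasing")
    beta_name = "beta1" if submodel == "alcohol" else "beta2"
    rows = []
    for beta in beta_grid:
        p = params.replace(**{beta_name: float(beta)})
        r0 = r0_closed_form(p, submodel)
        dfe = addiction_free_equilibrium(p, submodel)
        eig = jacobian_eigenvalues(p, dfe, submodel)
        rows.append({"beta": beta, "R0": r0, "lambda_star": 0.0,
                     "branch": "addiction-free", "stable": _stability(eig)})
        reports, _ = endemic_equilibria(p, submodel)
        for rep in reports:
            rows.append({"beta": beta, "R0": r0, "lambda_star": rep.force,
                         "branch": "endemic", "stable": rep.stable})
    return pd.DataFrame(rows)


def critical_beta(params: ModelParameters, submodel: str) -> float:
    """The dissemination rate at which the sub-model R0 equals one."""
    beta_name = "beta1" if submodel == "alcohol" else "beta2"
    r0 = r0_closed_form(params, submodel)
    if r0 <= 0:
        raise ValueError("R0 must be positive to solve for the critical rate")
    return getattr(params, beta_name) / r0  # R0 is linear in beta


def center_manifold_coefficients(params: ModelParameters,
                                 eig_tol: float = 1e-6) -> CenterManifoldResult:
    """Castillo-Chavez--Song coefficients a, b of the dual model at R0 = 1.

    The dominant pathway's dissemination rate is scaled to its critical
    value beta*, the right/left null vectors u, v of the 11x11 Jacobian at
    the DFE are computed (normalised v.u = 1, with the dominant exposed
    compartment of u positive), and a, b are evaluated by second-order
    central differences of the vector field:

        a = v . D2h(x0)[u, u],    b = v . d(Dh u)/d(beta) .
    """
    rn = reproduction_numbers(params)
    dominant = rn.dominant
    beta_name = "beta1" if dominant == "alcohol" else "beta2"
    beta_star = critical_beta(params, dominant)
    p_star = params.replace(**{beta_name: beta_star})

    dfe = addiction_free_equilibrium(p_star, "full")
    J = jacobian(p_star, dfe, "full")
    eig = np.linalg.eigvals(J)
    order = np.argsort(np.abs(eig))
    scale = max(1.0, float(np.max(np.abs(eig))))
    if np.abs(eig[order[0]]) > eig_tol * scale:
        raise ValueError(
            f"no near-zero eigenvalue at beta* (closest: {eig[order[0]]:.3e})"
        )
    if np.abs(eig[order[1]]) < eig_tol * scale:
        raise ValueError("the zero eigenvalue at beta* is not simple")

    # null vectors via SVD (most accurate for the near-singular direction)
    U_, s, Vt = np.linalg.svd(J)
    u = Vt[-1]
    v = np.linalg.svd(J.T)[2][-1]
    exposed = 2 if dominant == "smoking" else 5  # ES or EA in the full ordering
    if u[exposed] < 0:
        u = -u
    vu = float(v @ u)
    if abs(vu) < 1e-12:
        raise ValueError("left and right null vectors are numerically orthogonal")
    v = v / vu

    x0 = dfe
    h = 1e-4 * max(1.0, float(np.linalg.norm(x0)))

    def vh(state, pp):
        return float(v @ rhs(0.0, state, pp, "full", check=False))

    # a: directional second derivative of v.h along u
    a = (vh(x0 + h * u, p_star) - 2 * vh(x0, p_star) + vh(x0 - h * u, p_star)) / h**2

    # b: mixed derivative with respect to state (along u) and beta
    db = 1e-4 * beta_star
    p_hi = params.replace(**{beta_name: beta_star + db})
    p_lo = params.replace(**{beta_name: beta_star - db})
    b = (vh(x0 + h * u, p_hi) - vh(x0 + h * u, p_lo)
         - vh(x0 - h * u, p_hi) + vh(x0 - h * u, p_lo)) / (4 * h * db)

    return CenterManifoldResult(beta_star=float(beta_star), dominant=dominant,
                                u=u, v=v, a=float(a), b=float(b))
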