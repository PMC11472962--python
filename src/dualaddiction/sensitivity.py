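"""Normalized forward sensitivity (elasticity) indices of the reproduction numbers.

The elasticity of R0 with respect to a parameter p is (dR0/dp) * (p/R0): the
fractional change in R0 per fractional change in p.  Indices are computed
analytically by symbolic differentiation of the NGM-certified closed form and
cross-checked by central finite differences; the recruitment rate K cancels
from every R0 (standard incidence), so its index is identically zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
import sympy as sp

from .equilibria import r0_closed_form
from .model_core import ModelParameters

__all__ = [
    "SensitivityRecord",
    "R0_PARAMETERS",
    "sensitivity_index",
    "finite_difference_index",
    "sensitivity_table",
    "sensitivity_barplot",
]

#: parameters structurally present in each sub-model reproduction number
R0_PARAMETERS = {
    "alcohol": ("beta1", "alpha1", "alpha2", "eps1", "dA", "dPA",
                "mu", "pi", "rho1", "delta"),
    "smoking": ("beta2", "gamma1", "gamma2", "eps2", "dS", "dPS",
                "mu", "pi", "delta1", "delta"),
}


@dataclass(frozen=True)
class SensitivityRecord:
    parameter: str
    index: float
    method: str  # "analytic" | "finite-difference"


@lru_cache(maxsize=None)
def _elasticity_functions(which: str):
    """Lambdified elasticity p -> (dR0/dp)(p/R0) for each parameter of R0."""
    names = R0_PARAMETERS[which]
    syms = sp.symbols(names, positive=True)
    s = dict(zip(names, syms))
    if which == "alcohol":
        num = (s["beta1"] * s["alpha1"] * (s["alpha2"] + s["mu"] + s["dPA"])
               * (s["mu"] * (1 - s["pi"]) + s["rho1"] * (s["delta"] + s["pi"] * s["mu"])))
        den = ((s["mu"] + s["alpha1"]) * (s["alpha2"] + s["eps1"] + s["mu"] + s["dA"])
               * (s["mu"] + s["dPA"]) * (s["delta"] + s["mu"]))
    else:
        num = (s["beta2"] * s["gamma1"] * (s["gamma2"] + s["mu"] + s["dPS"])
               * (s["mu"] * (1 - s["pi"]) + s["delta1"] * (s["delta"] + s["pi"] * s["mu"])))
        den = ((s["mu"] + s["gamma1"]) * (s["eps2"] + s["gamma2"] + s["mu"] + s["dS"])
               * (s["mu"] + s["dPS"]) * (s["delta"] + s["mu"]))
    r0 = num / den
    funcs = {}
    for name in names:
        # cancel instead of full simplify: lambdify needs no canonical form,
        # and simplify is two orders of magnitude slower here
        elast = sp.cancel(sp.diff(r0, s[name]) * s[name] / r0)
        funcs[name] = sp.lambdify(syms, elast, modules="numpy")
    return names, funcs


def _resolve_branch(params: ModelParameters, which: str) -> str:
    if which in ("alcohol", "smoking"):
        return which
    if which in ("dual", "full"):
        # the dual reproduction number is the max of the two sub-model values
        return ("alcohol"
                if r0_closed_form(params, "alcohol") >= r0_closed_form(params, "smoking")
                else "smoking")
    raise ValueError(f"unknown reproduction-number selector '{which}'")


def sensitivity_index(params: ModelParameters, name: str,
                      which: str = "dual") -> SensitivityRecord:
    """Elasticity of the selected R0 with respect to one parameter.

    Parameters absent from the chosen closed form (including K, which
    cancels) have index exactly 0.  For the dual model the index is that of
    the dominant sub-model branch.
    """
    if name not in ModelParameters.field_names():
        raise KeyError(f"unknown parameter name '{name}'")
    branch = _resolve_branch(params, which)
    names, funcs = _elasticity_functions(branch)
    if name not in names:
        return SensitivityRecord(parameter=name, index=0.0, method="analytic")
    args = [getattr(params, n) for n in names]
    return SensitivityRecord(parameter=name, index=float(funcs[name](*args)),
                             method="analytic")


def finite_difference_index(params: ModelParameters, name: str,
                            which: str = "dual", rel_step: float = 1e-6) -> SensitivityRecord:
    """Central finite-difference elasticity; oracle for the analytic route."""
    if name not in ModelParameters.field_names():
        raise KeyError(f"unknown parameter name '{name}'")
    branch = _resolve_branch(params, which)
    value = getattr(params, name)
    if value == 0:
        raise ValueError(f"cannot form a relative step at {name} = 0")
    h = rel_step * value
    r_hi = r0_closed_form(params.replace(**{name: value + h}), branch)
    r_lo = r0_closed_form(params.replace(**{name: value - h}), branch)
    r0 = r0_closed_form(params, branch)
    index = (r_hi - r_lo) / (2 * h) * value / r0
    return SensitivityRecord(parameter=name, index=float(index),
                             method="finite-difference")


def sensitivity_table(params: ModelParameters, which: str = "dual") -> pd.DataFrame:
    """Elasticities of every parameter entering the chosen R0, ranked by |index|."""
    branch = _resolve_branch(params, which)
    records = [sensitivity_index(params, name, branch)
               for name in R0_PARAMETERS[branch]]
    frame = pd.DataFrame(
        {"parameter": [r.parameter for r in records],
         "index": [r.index for r in records],
         "method": [r.method for r in records]}
    )
    return (frame.reindex(frame["index"].abs().sort_values(ascending=False).index)
            .reset_index(drop=True))


def sensitivity_barplot(table: pd.DataFrame, path) -> None:
    """Horizontal tornado plot of a sensitivity table."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ordered = table.sort_values("index")
    fig, ax = plt.subplots(figsize=(6, 0.4 * len(ordered) + 1.5))
    colors = np.where(ordered["index"] >= 0, "tab:blue", "tab:red")
    ax.barh(ordered["parameter"], ordered["index"], color=colors)
    ax.axvline(0, color="k", lw=0.8)
    ax.set_xlabel("elasticity of $R_0$")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
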