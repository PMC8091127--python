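"""Deterministic exposure-response model for the SOFA score.

The model separates two effects acting on a septic patient's SOFA score:

* a standard-of-care (placebo) effect that removes at most a fraction
  ``f_placebo`` of the baseline score with first-order rate ``k``, and
* a drug effect driven by a latent response variable ``R(t)`` following
  an inhibitory indirect-response (turnover) model in which steady-state
  drug exposure (AUC0-8h) inhibits the zero-order production of R:

      dR/dt = kin * (1 - AUC / (AUC + EAUC50)) - kout * R,   R(0) = 1.

With the baseline condition R(0) = 1 the production and elimination
rates are tied, kin = kout, and the ODE has the closed form

      R(t) = 1 - I * (1 - exp(-kout * t)),   I = AUC / (AUC + EAUC50),

so that R decays from 1 toward its steady state 1 - I.  The SOFA
prediction combines both effects multiplicatively with the observed
baseline:

      SOFA(t) = Base - f_placebo*Base*(1 - exp(-(k + eta_k)*t))
                     - (1 - f_placebo)*Base*(1 - R(t)).

The closed form is the production path used inside the likelihood; the
ODE integrator is retained as an independent numerical oracle (and as a
hook for any future kin != kout extension).

Units: t and the rate constants are in days; AUC and EAUC50 in h*ng/mL,
exactly as the exposure metric is reported — no unit conversion happens
inside the model.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "StructuralParams",
    "SubjectEffects",
    "DomainError",
    "NumericalError",
    "latent_response",
    "latent_response_ode",
    "predict_sofa",
    "sofa_asymptote",
]


class DomainError(ValueError):
    """An argument lies outside the model's mathematical domain."""


class NumericalError(RuntimeError):
    """A numerical routine failed to converge."""


@dataclass(frozen=True)
class StructuralParams:
    """Fixed effects of the exposure-response model.

    Parameters
    ----------
    f_placebo
        Maximal fraction of baseline SOFA removable by standard care
        alone (dimensionless, in [0, 1]); 1 - f_placebo is the drug's
        maximal fraction.
    k
        Standard-care amelioration rate constant, 1/day.
    kin
        Zero-order production rate of the latent response, 1/day.
        The baseline condition R(0)=1 ties kout to kin.
    eauc50
        Steady-state AUC0-8h giving half-maximal inhibition, h*ng/mL.
    kout
        Optional; if given it must equal kin (the tie is enforced at
        construction, not estimated).
    """

    f_placebo: float
    k: float
    kin: float
    eauc50: float
    kout: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.f_placebo <= 1.0):
            raise DomainError(f"f_placebo must lie in [0, 1], got {self.f_placebo}")
        if self.k <= 0:
            raise DomainError(f"k must be > 0, got {self.k}")
        if self.kin <= 0:
            raise DomainError(f"kin must be > 0, got {self.kin}")
        if self.eauc50 <= 0:
            raise DomainError(f"eauc50 must be > 0, got {self.eauc50}")
        if self.kout is None:
            object.__setattr__(self, "kout", self.kin)
        elif abs(self.kout - self.kin) > 1e-12 * max(1.0, abs(self.kin)):
            raise DomainError(
                f"kin ({self.kin}) and kout ({self.kout}) must be equal: "
                "the baseline condition R(0)=1 ties them"
            )


@dataclass(frozen=True)
class SubjectEffects:
    """Subject-level random quantities: eta_k shifts k additively, and
    epsilon is the additive residual on SOFA (used only by simulators)."""

    eta_k: float = 0.0
    epsilon: float = 0.0


def _inhibition(auc, eauc50: float):
    return np.asarray(auc, dtype=float) / (np.asarray(auc, dtype=float) + eauc50)


def _check_nonnegative(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0) or not np.all(np.isfinite(arr)):
        raise DomainError(f"{name} must be finite and >= 0")
    return arr


def latent_response(t, auc, params: StructuralParams):
    """Closed-form latent response R(t) in (0, 1].

    R(t) = 1 - I*(1 - exp(-kout*t)) with I = auc/(auc + eauc50); for
    auc=0 the trajectory is identically 1 (no drug effect).  Vectorised
    over ``t`` and ``auc`` (broadcast together).
    """
    t = _check_nonnegative("t", t)
    auc = _check_nonnegative("auc", auc)
    inh = _inhibition(auc, params.eauc50)
    out = 1.0 - inh * (1.0 - np.exp(-params.kout * t))
    return out if out.ndim else float(out)


def latent_response_ode(t, auc, params: StructuralParams, tol: float = 1e-10):
    """Latent response by adaptive-step numerical integration of the turnover ODE.

    Independent oracle for :func:`latent_response`; agrees with the
    closed form to well within 10*tol.  ``t`` may be a scalar or an
    increasing array of times (days).
    """
    t_arr = np.atleast_1d(_check_nonnegative("t", t)).astype(float)
    auc = float(_check_nonnegative("auc", auc))
    if tol <= 0:
        raise DomainError(f"tol must be > 0, got {tol}")
    inh = auc / (auc + params.eauc50)
    production = params.kin * (1.0 - inh)

    def rhs(_t, r):
        return production - params.kout * r

    t_end = float(t_arr.max())
    if t_end == 0.0:
        out = np.ones_like(t_arr)
    else:
        order = np.argsort(t_arr)
        sol = solve_ivp(
            rhs,
            (0.0, t_end),
            [1.0],
            t_eval=t_arr[order],
            rtol=tol,
            atol=tol * 1e-2,
            method="LSODA",
        )
        if not sol.success:
            raise NumericalError(f"ODE integration failed: {sol.message}")
        out = np.empty_like(t_arr)
        out[order] = sol.y[0]
    return out if np.ndim(t) else float(out[0])


def predict_sofa(t, base, auc, params: StructuralParams, eta_k: float = 0.0):
    """Deterministic SOFA prediction at time ``t`` (days).

    ``eta_k`` shifts the standard-care rate additively; a negative
    effective rate k + eta_k is allowed (the prediction can then exceed
    baseline, as seen in non-responding patients) and no clipping is
    applied here.  The residual epsilon is *not* added.
    """
    t = _check_nonnegative("t", t)
    auc = _check_nonnegative("auc", auc)
    base_arr = np.asarray(base, dtype=float)
    if np.any(base_arr <= 0) or not np.all(np.isfinite(base_arr)):
        raise DomainError("base must be finite and > 0")
    r = latent_response(t, auc, params)
    placebo_term = params.f_placebo * base_arr * (1.0 - np.exp(-(params.k + eta_k) * t))
    drug_term = (1.0 - params.f_placebo) * base_arr * (1.0 - r)
    out = base_arr - placebo_term - drug_term
    return out if np.ndim(out) else float(out)


def sofa_asymptote(base, auc, params: StructuralParams):
    """t -> infinity limit of the prediction (eta=0):
    base*(1 - f_placebo) - (1 - f_placebo)*base*I, the floor the score
    relaxes to under standard care plus drug."""
    base = np.asarray(base, dtype=float)
    inh = _inhibition(auc, params.eauc50)
    return base - params.f_placebo * base - (1.0 - params.f_placebo) * base * inh
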