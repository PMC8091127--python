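"""Nonlinear mixed-effects estimation for the SOFA exposure-response model.

One subject-level random effect eta_k ~ N(0, omega^2) shifts the
standard-care rate k additively; the residual is additive Gaussian,
epsilon ~ N(0, sigma^2).  The marginal likelihood per subject is the
1-D integral over eta_k of the joint density, handled two ways:

* ``foce`` (default): Laplace approximation at the per-subject mode
  with the Gauss-Newton Hessian — the classical first-order conditional
  estimate.  With a purely additive residual, FOCE with interaction
  coincides with FOCE, so this matches the original analysis method.
* ``agq``: adaptive Gauss-Hermite quadrature centred and scaled at the
  mode; the reference method that bounds the FOCE approximation error.

The objective reported is the NONMEM-convention OFV, -2 log marginal
likelihood.  Fixed effects are optimised on a transformed scale
(logit for f_placebo, log for the positive parameters) by L-BFGS-B with
multi-start jitter; kin = kout is tied and IIV is carried by k only.

The observed pre-dose baseline enters as a covariate and is never
estimated.  Day-0 rows are excluded from the likelihood by default:
they equal the baseline by construction and would understate sigma.
"""
from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit, logsumexp

from .data import SubjectRecord, TrialDataset
from .model import StructuralParams

__all__ = [
    "VarianceParams",
    "FitConfig",
    "FitResult",
    "ExposureResponseModel",
    "EstimationError",
    "IdentifiabilityError",
    "subject_nll",
    "marginal_ofv",
    "fit",
]

logger = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)

#: omega below this is treated as exactly zero (no random effect).
_OMEGA_ZERO = 1e-10

_PARAM_ORDER = ("f_placebo", "k", "kin", "eauc50", "omega", "sigma")

# Plausible natural-scale boxes for the optimiser.  EAUC50 beyond ~4x
# the largest observable AUC (~5000 h*ng/mL) renders the inhibition
# curve indistinguishable from linear and is unidentifiable.
_NATURAL_BOUNDS = {
    "f_placebo": (1e-6, 1.0 - 1e-6),
    "k": (1e-3, 10.0),
    "kin": (1e-4, 10.0),
    "eauc50": (10.0, 2e4),
    "omega": (1e-8, 10.0),
    "sigma": (1e-3, 100.0),
}


class EstimationError(RuntimeError):
    """The estimation machinery failed numerically."""


class IdentifiabilityError(ValueError):
    """The dataset cannot identify the requested parameters."""


@dataclass(frozen=True)
class VarianceParams:
    """Random-effect SD omega (on k, 1/day) and residual SD sigma (SOFA units).

    sigma = 0 is allowed so simulators can express the degenerate
    noise-free case; the likelihood itself requires sigma > 0.
    """

    omega: float
    sigma: float

    def __post_init__(self) -> None:
        if self.omega < 0:
            raise ValueError(f"omega must be >= 0, got {self.omega}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")


# ---------------------------------------------------------------------------
# parameter transforms


def _to_transformed(values: np.ndarray) -> np.ndarray:
    out = np.empty(6)
    out[0] = logit(values[0])
    out[1:] = np.log(values[1:])
    return out


def _to_natural(theta: np.ndarray) -> np.ndarray:
    out = np.empty(6)
    out[0] = expit(theta[0])
    out[1:] = np.exp(theta[1:])
    return out


def _transformed_bounds() -> list[tuple[float, float]]:
    bounds = []
    for i, name in enumerate(_PARAM_ORDER):
        lo, hi = _NATURAL_BOUNDS[name]
        if i == 0:
            bounds.append((float(logit(lo)), float(logit(hi))))
        else:
            bounds.append((float(np.log(lo)), float(np.log(hi))))
    return bounds


def _unpack(natural: np.ndarray) -> tuple[StructuralParams, VarianceParams]:
    sp = StructuralParams(
        f_placebo=float(natural[0]), k=float(natural[1]),
        kin=float(natural[2]), eauc50=float(natural[3]),
    )
    vp = VarianceParams(omega=float(natural[4]), sigma=float(natural[5]))
    return sp, vp


# ---------------------------------------------------------------------------
# vectorised likelihood engine


class _LikelihoodEngine:
    """Stacked-array likelihood over all subjects.

    Precomputes per-observation arrays once per dataset; every OFV
    evaluation then runs fully vectorised, with per-subject reductions
    via bincount.
    """

    def __init__(self, dataset: TrialDataset, include_day0: bool = False) -> None:
        t, y, base, auc, sidx = [], [], [], [], []
        self.subject_ids = [s.id for s in dataset.subjects]
        for i, subj in enumerate(dataset.subjects):
            for obs in subj.observations:
                if not include_day0 and obs.day == 0.0:
                    continue
                t.append(obs.day)
                y.append(obs.sofa)
                base.append(subj.base)
                auc.append(subj.auc)
                sidx.append(i)
        self.t = np.asarray(t, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.base = np.asarray(base, dtype=float)
        self.auc = np.asarray(auc, dtype=float)
        self.sidx = np.asarray(sidx, dtype=np.intp)
        self.n_sub = len(dataset.subjects)
        self.n_obs = self.t.size
        self.nobs_per_sub = np.bincount(self.sidx, minlength=self.n_sub).astype(float)

    # -- residual pieces ---------------------------------------------------

    def _eta_free_parts(self, sp: StructuralParams) -> tuple[np.ndarray, np.ndarray]:
        """Return (c, A): residual = c + A*(1 - exp(-(k+eta)*t))."""
        inh = self.auc / (self.auc + sp.eauc50)
        drug = (1.0 - sp.f_placebo) * self.base * inh * (1.0 - np.exp(-sp.kin * self.t))
        c = self.y - self.base + drug
        a = sp.f_placebo * self.base
        return c, a

    def _residual(self, sp: StructuralParams, eta: np.ndarray,
                  parts: tuple[np.ndarray, np.ndarray] | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Residual r = y - pred and dr/deta = A*t*exp(-(k+eta)*t) per observation."""
        c, a = parts if parts is not None else self._eta_free_parts(sp)
        e = np.exp(-(sp.k + eta[self.sidx]) * self.t)
        r = c + a * (1.0 - e)
        dr = a * self.t * e
        return r, dr

    def _sub_sum(self, values: np.ndarray) -> np.ndarray:
        return np.bincount(self.sidx, weights=values, minlength=self.n_sub)

    def _nll_per_subject(self, sp, vp, eta: np.ndarray,
                         parts=None) -> np.ndarray:
        """Joint -log density per subject at the given eta vector."""
        r, _ = self._residual(sp, eta, parts)
        sig2 = vp.sigma**2
        out = 0.5 * self._sub_sum(r * r) / sig2
        out += 0.5 * self.nobs_per_sub * (_LOG2PI + np.log(sig2))
        if vp.omega > _OMEGA_ZERO:
            om2 = vp.omega**2
            out += 0.5 * (_LOG2PI + np.log(om2)) + eta**2 / (2.0 * om2)
        return out

    # -- inner problem: per-subject posterior modes -----------------------

    def modes(self, sp: StructuralParams, vp: VarianceParams,
              tol: float = 1e-11, max_iter: int = 80) -> np.ndarray:
        """Per-subject posterior modes of eta by safeguarded Newton.

        Vectorised across subjects; uses the full Hessian where positive
        and the Gauss-Newton surrogate otherwise, with per-subject
        backtracking to guarantee descent.
        """
        if vp.omega <= _OMEGA_ZERO:
            return np.zeros(self.n_sub)
        parts = self._eta_free_parts(sp)
        sig2, om2 = vp.sigma**2, vp.omega**2
        eta = np.zeros(self.n_sub)
        nll = self._nll_per_subject(sp, vp, eta, parts)
        for _ in range(max_iter):
            r, dr = self._residual(sp, eta, parts)
            grad = self._sub_sum(r * dr) / sig2 + eta / om2
            gn = self._sub_sum(dr * dr) / sig2 + 1.0 / om2
            full = gn - self._sub_sum(r * self.t * dr) / sig2
            hess = np.where(full > 1e-12, full, gn)
            step = -grad / hess
            # trust region: never move more than 4 prior SDs at once
            cap = 4.0 * vp.omega
            step = np.clip(step, -cap, cap)
            if np.max(np.abs(step)) < tol:
                break
            new_eta = eta + step
            new_nll = self._nll_per_subject(sp, vp, new_eta, parts)
            for _bt in range(25):
                worse = new_nll > nll + 1e-14
                if not np.any(worse):
                    break
                step = np.where(worse, 0.5 * step, step)
                new_eta = eta + step
                new_nll = self._nll_per_subject(sp, vp, new_eta, parts)
            eta, nll = new_eta, new_nll
        return eta

    # -- marginal OFV ------------------------------------------------------

    def ofv(self, sp: StructuralParams, vp: VarianceParams,
            method: str = "foce", n_nodes: int = 31) -> float:
        if method not in ("foce", "agq"):
            raise ValueError(f"unknown method {method!r}")
        if vp.sigma <= 0:
            raise ValueError("the likelihood requires sigma > 0")
        parts = self._eta_free_parts(sp)
        sig2 = vp.sigma**2
        if vp.omega <= _OMEGA_ZERO:
            # exact marginal: eta degenerate at 0
            r, _ = self._residual(sp, np.zeros(self.n_sub), parts)
            return float(np.sum(_LOG2PI + np.log(sig2) + r * r / sig2))
        eta_hat = self.modes(sp, vp)
        _, dr = self._residual(sp, eta_hat, parts)
        gn_h = self._sub_sum(dr * dr) / sig2 + 1.0 / vp.omega**2
        nll_hat = self._nll_per_subject(sp, vp, eta_hat, parts)
        if method == "foce":
            m2ll = 2.0 * nll_hat - _LOG2PI + np.log(gn_h)
            return float(np.sum(m2ll))
        if n_nodes < 1 or n_nodes % 2 == 0:
            raise ValueError("n_nodes must be odd and >= 1 for agq")
        nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
        scale = np.sqrt(2.0 / gn_h)
        log_terms = np.empty((n_nodes, self.n_sub))
        for j, (x, w) in enumerate(zip(nodes, weights)):
            eta_j = eta_hat + scale * x
            log_terms[j] = np.log(w) + x * x - self._nll_per_subject(sp, vp, eta_j, parts)
        log_li = logsumexp(log_terms, axis=0) + np.log(scale)
        return float(-2.0 * np.sum(log_li))


# ---------------------------------------------------------------------------
# public likelihood surface


def subject_nll(subject: SubjectRecord, params: StructuralParams,
                variance: VarianceParams, eta: float,
                include_day0: bool = False) -> float:
    """Joint -log density of one subject's observations and its eta.

    sum over observations of [0.5*log(2*pi*sigma^2) + (dv - pred)^2 /
    (2*sigma^2)] plus the N(0, omega^2) prior term for eta.  For
    omega=0 the prior term is omitted and eta forced to 0.
    """
    if variance.sigma <= 0:
        raise ValueError("the likelihood requires sigma > 0")
    engine = _LikelihoodEngine(TrialDataset(subjects=(subject,)), include_day0=include_day0)
    eta_val = 0.0 if variance.omega <= _OMEGA_ZERO else float(eta)
    return float(engine._nll_per_subject(params, variance, np.array([eta_val]))[0])


def marginal_ofv(dataset: TrialDataset, params: StructuralParams,
                 variance: VarianceParams, method: str = "foce",
                 n_nodes: int = 31, include_day0: bool = False) -> float:
    """-2 log marginal likelihood of the whole dataset (OFV)."""
    engine = _LikelihoodEngine(dataset, include_day0=include_day0)
    return engine.ofv(params, variance, method=method, n_nodes=n_nodes)


# ---------------------------------------------------------------------------
# configuration and results


@dataclass(frozen=True)
class FitConfig:
    """Estimation settings.

    ``n_starts`` jittered starting points guard against local optima;
    the jitter is seeded so a fit is reproducible given its config.
    """

    method: str = "foce"
    n_nodes: int = 31
    n_starts: int = 5
    seed: int = 0
    maxfun: int = 2000
    ftol: float = 1e-10
    include_day0: bool = False
    compute_se: bool = True
    jitter_sd: float = 0.4


@dataclass
class FitResult:
    """Estimates, uncertainty and empirical Bayes summaries of one fit.

    ``se``/``rse_pct`` are on the natural scale (delta method from the
    transformed-scale observed information); ``ebes`` maps subject id
    to the posterior mode of eta_k.
    """

    params: StructuralParams
    variance: VarianceParams
    ofv: float
    method: str
    converged: bool
    n_function_evals: int
    se: dict[str, float] = field(default_factory=dict)
    rse_pct: dict[str, float] = field(default_factory=dict)
    ebes: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    eta_shrinkage_pct: float = float("nan")
    eps_shrinkage_pct: float = float("nan")
    model: "ExposureResponseModel | None" = None

    def estimates(self) -> dict[str, float]:
        return {
            "f_placebo": self.params.f_placebo,
            "k": self.params.k,
            "kin": self.params.kin,
            "eauc50": self.params.eauc50,
            "omega": self.variance.omega,
            "sigma": self.variance.sigma,
        }

    # -- statsmodels-style results surface --------------------------------

    def summary(self) -> str:
        units = {"f_placebo": "", "k": "1/day", "kin": "1/day",
                 "eauc50": "h*ng/mL", "omega": "1/day", "sigma": "SOFA"}
        lines = [
            "SOFA exposure-response model fit",
            "=" * 64,
            f"Method: {self.method.upper()}    OFV: {self.ofv:.4f}    "
            f"Converged: {self.converged}    Fevals: {self.n_function_evals}",
            "-" * 64,
            f"{'Parameter':<12}{'Estimate':>12}{'Units':>10}{'SE':>10}{'RSE%':>8}",
        ]
        for name, value in self.estimates().items():
            se = self.se.get(name, float("nan"))
            rse = self.rse_pct.get(name, float("nan"))
            lines.append(f"{name:<12}{value:>12.5g}{units[name]:>10}{se:>10.3g}{rse:>8.1f}")
        lines.append("-" * 64)
        lines.append(
            f"eta-shrinkage: {self.eta_shrinkage_pct:.1f}%    "
            f"eps-shrinkage: {self.eps_shrinkage_pct:.1f}%"
        )
        return "\n".join(lines)

    def param_table(self) -> pd.DataFrame:
        units = {"f_placebo": "", "k": "1/day", "kin": "1/day",
                 "eauc50": "h*ng/mL", "omega": "1/day", "sigma": "SOFA"}
        shrink = {"omega": self.eta_shrinkage_pct, "sigma": self.eps_shrinkage_pct}
        rows = [
            (name, value, units[name], self.se.get(name, np.nan),
             self.rse_pct.get(name, np.nan), shrink.get(name, np.nan))
            for name, value in self.estimates().items()
        ]
        return pd.DataFrame(rows, columns=["PARAM", "ESTIMATE", "UNITS", "SE", "RSE_PCT", "SHRINK_PCT"])

    def residual_table(self) -> pd.DataFrame:
        from . import diagnostics

        return diagnostics.residual_table(self._dataset(), self)

    def pcvpc(self, n_sim: int = 1000, seed: int = 0, ci: float = 80.0, **kw):
        from . import diagnostics

        return diagnostics.pcvpc(self._dataset(), self, n_sim=n_sim, seed=seed, ci=ci, **kw)

    def simulate_day7(self, **kw):
        from . import simulation

        return simulation.simulate_day7_vs_auc(self.params, self.variance, **kw)

    def _dataset(self) -> TrialDataset:
        if self.model is None:
            raise ValueError("fit result is detached from its model/dataset")
        return self.model.dataset


# ---------------------------------------------------------------------------
# model object


class ExposureResponseModel:
    """NLME exposure-response model bound to a trial dataset.

    Parameters
    ----------
    dataset
        A validated :class:`~sofaer.data.TrialDataset`.
    include_day0
        Whether day-0 (baseline) rows enter the likelihood; default
        False because they equal the baseline covariate by construction.

    Examples
    --------
    >>> model = ExposureResponseModel(dataset)
    >>> res = model.fit(seed=1)
    >>> print(res.summary())
    """

    def __init__(self, dataset: TrialDataset, include_day0: bool = False) -> None:
        self.dataset = dataset
        self.include_day0 = include_day0
        self._engine = _LikelihoodEngine(dataset, include_day0=include_day0)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, include_day0: bool = False) -> "ExposureResponseModel":
        return cls(TrialDataset.from_dataframe(df), include_day0=include_day0)

    # -- likelihood --------------------------------------------------------

    def ofv(self, params: StructuralParams, variance: VarianceParams,
            method: str = "foce", n_nodes: int = 31) -> float:
        return self._engine.ofv(params, variance, method=method, n_nodes=n_nodes)

    def _default_init(self) -> np.ndarray:
        resid = self._engine.y - self._engine.base
        sigma0 = float(np.clip(np.std(resid) if resid.size else 2.0, 0.5, 10.0))
        pos_auc = self._engine.auc[self._engine.auc > 0]
        eauc0 = float(np.median(pos_auc)) if pos_auc.size else 1000.0
        return np.array([0.6, 0.3, 0.1, eauc0, 0.1, sigma0])

    # -- fitting -----------------------------------------------------------

    def fit(self, init: dict[str, float] | None = None,
            config: FitConfig | None = None, **overrides) -> FitResult:
        """Maximise the marginal likelihood; returns the best of the
        multi-start runs as a :class:`FitResult`.

        ``overrides`` are field-level shortcuts into :class:`FitConfig`
        (e.g. ``model.fit(seed=3, n_starts=2)``).
        """
        cfg = config or FitConfig()
        if overrides:
            cfg = dataclasses.replace(cfg, **overrides)
        eng = self._engine
        if eng.n_obs == 0:
            raise IdentifiabilityError("no usable observations in the dataset")
        if not np.any(eng.auc > 0):
            raise IdentifiabilityError(
                "all-placebo dataset: kin and eauc50 are unidentifiable; "
                "fix the drug parameters or add drug-arm subjects"
            )

        x0 = self._default_init()
        if init:
            natural = {name: val for name, val in zip(_PARAM_ORDER, x0)}
            natural.update(init)
            x0 = np.array([natural[name] for name in _PARAM_ORDER], dtype=float)
        bounds = _transformed_bounds()
        theta0 = np.clip(_to_transformed(x0),
                         [b[0] for b in bounds], [b[1] for b in bounds])

        n_evals = 0

        def objective(theta: np.ndarray) -> float:
            nonlocal n_evals
            n_evals += 1
            sp, vp = _unpack(_to_natural(theta))
            try:
                value = eng.ofv(sp, vp, method=cfg.method, n_nodes=cfg.n_nodes)
            except FloatingPointError:
                return 1e12
            return value if np.isfinite(value) else 1e12

        rng = np.random.default_rng(cfg.seed)
        starts = [theta0]
        for _ in range(cfg.n_starts - 1):
            jitter = rng.normal(0.0, cfg.jitter_sd, size=6)
            starts.append(np.clip(theta0 + jitter, [b[0] for b in bounds], [b[1] for b in bounds]))

        best = None
        any_converged = False
        for theta_start in starts:
            res = optimize.minimize(
                objective, theta_start, method="L-BFGS-B", bounds=bounds,
                options={"maxfun": cfg.maxfun, "ftol": cfg.ftol, "gtol": 1e-7},
            )
            any_converged = any_converged or bool(res.success)
            if best is None or res.fun < best.fun:
                best = res
        if best is None:  # pragma: no cover - n_starts >= 1 always
            raise EstimationError("no optimisation start completed")
        if not any_converged:
            logger.warning("no start converged; reporting the best OFV found")

        sp, vp = _unpack(_to_natural(best.x))
        result = FitResult(
            params=sp, variance=vp, ofv=float(best.fun), method=cfg.method,
            converged=bool(any_converged and np.isfinite(best.fun)),
            n_function_evals=n_evals, model=self,
        )
        self._attach_ebes(result)
        if cfg.compute_se:
            standard_errors(result, config=cfg)
        return result

    # -- EBEs and shrinkage -------------------------------------------------

    def _attach_ebes(self, result: FitResult) -> None:
        eng = self._engine
        eta_hat = eng.modes(result.params, result.variance)
        result.ebes = pd.Series(eta_hat, index=eng.subject_ids, name="eta_k")
        omega, sigma = result.variance.omega, result.variance.sigma
        if omega <= _OMEGA_ZERO or eng.n_sub < 2:
            result.eta_shrinkage_pct = float("nan")
        else:
            result.eta_shrinkage_pct = float(100.0 * (1.0 - np.std(eta_hat, ddof=1) / omega))
        r, _ = eng._residual(result.params, eta_hat)
        if r.size >= 2:
            iwres = r / sigma
            result.eps_shrinkage_pct = float(100.0 * (1.0 - np.std(iwres, ddof=1)))
        if np.isfinite(result.eta_shrinkage_pct) and result.eta_shrinkage_pct < 0:
            logger.warning("negative eta-shrinkage (%.1f%%): EBEs overdispersed vs omega",
                           result.eta_shrinkage_pct)


# ---------------------------------------------------------------------------
# free-function surface


def fit(dataset: TrialDataset, init: dict[str, float] | None = None,
        config: FitConfig | None = None, **overrides) -> FitResult:
    """Convenience wrapper: build the model and fit in one call."""
    cfg = config or FitConfig()
    if overrides:
        cfg = dataclasses.replace(cfg, **overrides)
    return ExposureResponseModel(dataset, include_day0=cfg.include_day0).fit(init=init, config=cfg)


def _fd_hessian(f, x: np.ndarray, step: np.ndarray) -> np.ndarray:
    """Central finite-difference Hessian of a scalar function."""
    n = x.size
    h = np.diag(step)
    hess = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        fpp = f(x + 2 * h[i])
        fmm = f(x - 2 * h[i])
        hess[i, i] = (fpp - 2.0 * f0 + fmm) / (4.0 * step[i] ** 2)
        for j in range(i + 1, n):
            fa = f(x + h[i] + h[j])
            fb = f(x + h[i] - h[j])
            fc = f(x - h[i] + h[j])
            fd = f(x - h[i] - h[j])
            hess[i, j] = hess[j, i] = (fa - fb - fc + fd) / (4.0 * step[i] * step[j])
    return hess


def standard_errors(result: FitResult, dataset: TrialDataset | None = None,
                    config: FitConfig | None = None) -> tuple[dict[str, float], dict[str, float]]:
    """Asymptotic SEs from the observed information of the marginal log-likelihood.

    The Hessian of OFV/2 is taken by central finite differences on the
    transformed scale and back-transformed by the delta method; RSE% is
    100*SE/|estimate|.  A non-positive-definite information matrix
    produces NaN for the affected parameters with a warning.
    """
    cfg = config or FitConfig()
    if result.model is not None:
        engine = result.model._engine
    elif dataset is not None:
        engine = _LikelihoodEngine(dataset, include_day0=cfg.include_day0)
    else:
        raise ValueError("need either an attached model or an explicit dataset")

    natural = np.array([result.params.f_placebo, result.params.k, result.params.kin,
                        result.params.eauc50, result.variance.omega, result.variance.sigma])
    theta = _to_transformed(natural)

    def half_ofv(th: np.ndarray) -> float:
        sp, vp = _unpack(_to_natural(th))
        return 0.5 * engine.ofv(sp, vp, method=result.method, n_nodes=cfg.n_nodes)

    step = 1e-3 * np.maximum(1.0, np.abs(theta))
    info = _fd_hessian(half_ofv, theta, step)

    se_nat = np.full(6, np.nan)
    try:
        eigvals = np.linalg.eigvalsh(info)
        if np.min(eigvals) <= 0:
            warnings.warn("observed information is not positive definite; "
                          "reporting NaN standard errors where undefined")
            cov = np.linalg.pinv(info)
            diag = np.diag(cov).copy()
            diag[diag <= 0] = np.nan
        else:
            cov = np.linalg.inv(info)
            diag = np.diag(cov).copy()
        se_trans = np.sqrt(diag)
        # delta method: d(natural)/d(transformed)
        jac = np.empty(6)
        fp = natural[0]
        jac[0] = fp * (1.0 - fp)
        jac[1:] = natural[1:]
        se_nat = np.abs(jac) * se_trans
    except np.linalg.LinAlgError:
        warnings.warn("information matrix inversion failed; standard errors unavailable")

    names = list(_PARAM_ORDER)
    result.se = {n: float(s) for n, s in zip(names, se_nat)}
    result.rse_pct = {
        n: float(100.0 * s / abs(v)) if np.isfinite(s) and v != 0 else float("nan")
        for n, s, v in zip(names, se_nat, natural)
    }
    return result.se, result.rse_pct


def ebes_and_shrinkage(result: FitResult, dataset: TrialDataset | None = None,
                       include_day0: bool = False) -> tuple[pd.Series, float, float]:
    """Empirical Bayes estimates and eta/eps shrinkage for a fit.

    eta-shrinkage% = 100*(1 - SD(eta_hat)/omega); eps-shrinkage% =
    100*(1 - SD(IWRES)).  For omega=0 the eta-shrinkage is undefined
    (NaN).
    """
    if result.model is None:
        if dataset is None:
            raise ValueError("need either an attached model or an explicit dataset")
        result.model = ExposureResponseModel(dataset, include_day0=include_day0)
    result.model._attach_ebes(result)
    return result.ebes, result.eta_shrinkage_pct, result.eps_shrinkage_pct
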