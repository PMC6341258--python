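"""One-compartment IV-bolus population PK: simulation and FO-REML estimation.

Model
-----
Structural model (single intravenous bolus, first-order elimination):

    Cp(t) = (D / V) * exp(-(Cl / V) * t)

Two-stage nonlinear mixed-effects (NLME) model:

    y_ij   = f(x_ij, phi_i) + eps_ij,   eps_ij ~ N(0, sigma^2)   (residual)
    phi_i  = g(z_i; theta) + eta_i,     eta_i  ~ N(0, Omega)     (between-subject)

with phi_i = (V_i, Cl_i), a linear covariate model g for each parameter
(intercept plus per-covariate coefficients) and diagonal
Omega = diag(omega2_V, omega2_Cl).

Estimation linearizes f around eta_i = 0 (first-order, FO), giving each
subject a Gaussian marginal y_i ~ N(f_i(theta), Z_i Omega Z_i' + sigma^2 I)
with Z_i the sensitivity of f to (V, Cl). The objective is -2x the
linearized log-likelihood with the REML adjustment
log det(sum_i X_i' V_i^-1 X_i), X_i being the Jacobian with respect to the
fixed effects, maximized by a quasi-Newton optimizer (L-BFGS-B) entered
from the configured fixed-effect initial values through a pooled
nonlinear-least-squares warm-up.

Simulated concentrations keep the additive-error model's occasional
negative values; they are not truncated.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .criteria import FitSummary

logger = logging.getLogger("fuzzpk")

_LOG2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# Structural model
# ---------------------------------------------------------------------------

def conc_bolus(dose: float, v: float, cl: float, t):
    """Plasma concentration (mg/L) after a single IV bolus.

    ``Cp(t) = (dose / v) * exp(-(cl / v) * t)`` — scalar or array ``t`` (h).
    """
    if np.any(np.asarray(v) <= 0):
        raise ValueError(f"volume of distribution must be positive, got {v}")
    t = np.asarray(t, dtype=float)
    out = (dose / v) * np.exp(-(cl / v) * t)
    return out if out.ndim else float(out)


def _bolus_sensitivities(dose: float, v: float, cl: float, t: np.ndarray):
    """f, df/dV and df/dCl of the bolus model at (V, Cl)."""
    f = (dose / v) * np.exp(-(cl / v) * t)
    df_dv = (f / v) * (cl * t / v - 1.0)
    df_dcl = -f * t / v
    return f, df_dv, df_dcl


# ---------------------------------------------------------------------------
# Population model and study design
# ---------------------------------------------------------------------------

@dataclass
class CovariateModel:
    """Linear covariate model for V and Cl with diagonal random effects.

    ``v_coef`` / ``cl_coef`` map ``"intercept"`` and covariate names to
    linear coefficients: ``V_i = v_coef["intercept"] + sum_k coef_k * z_ik``.
    ``omega2_*`` are the between-subject variances (units of the parameter,
    squared).
    """

    v_coef: dict[str, float]
    cl_coef: dict[str, float]
    omega2_v: float = 0.0
    omega2_cl: float = 0.0

    def __post_init__(self) -> None:
        for name, coefs in (("v_coef", self.v_coef), ("cl_coef", self.cl_coef)):
            if "intercept" not in coefs:
                raise ValueError(f"{name} must contain an 'intercept' entry")
        if self.omega2_v < 0 or self.omega2_cl < 0:
            raise ValueError("random-effect variances must be non-negative")

    def typical_values(self, covariates: dict[str, float]) -> tuple[float, float]:
        """Population-typical (V, Cl) for one subject's covariates."""
        v = sum(c * (1.0 if k == "intercept" else covariates[k])
                for k, c in self.v_coef.items())
        cl = sum(c * (1.0 if k == "intercept" else covariates[k])
                 for k, c in self.cl_coef.items())
        return v, cl

    @property
    def n_fixed(self) -> int:
        return len(self.v_coef) + len(self.cl_coef)


@dataclass
class StudyDesign:
    """Sampling design: one bolus dose, shared sampling times, covariate
    distributions (``("normal", mean, sd)`` or ``("bernoulli", p)``).
    BMI, when requested, is derived from WT and HT rather than drawn."""

    dose: float = 100.0
    times: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0, 6.0, 8.0)
    covariates: dict[str, tuple] = field(default_factory=lambda: {
        "WT": ("normal", 70.0, 12.0),
        "AGE": ("normal", 45.0, 15.0),
        "HT": ("normal", 170.0, 10.0),
        "SEX": ("bernoulli", 0.5),
    })

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.size == 0:
            raise ValueError("a study design needs at least one sampling time")
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ValueError("sampling times must be non-negative and strictly increasing")

    def draw_covariates(self, rng: np.random.Generator) -> dict[str, float]:
        z: dict[str, float] = {}
        for name, spec in self.covariates.items():
            if spec[0] == "normal":
                z[name] = float(rng.normal(spec[1], spec[2]))
            elif spec[0] == "bernoulli":
                z[name] = float(rng.random() < spec[1])
            else:
                raise ValueError(f"unknown covariate distribution {spec[0]!r}")
        if "WT" in z and "HT" in z:
            z["BMI"] = z["WT"] / (z["HT"] / 100.0) ** 2
        return z


#: Tobramycin-like adult reference population used as the default study
#: conditions: V = 20 L, Cl = 5 L/h, ~10% between-subject SD on each.
TOBRAMYCIN_MODEL = CovariateModel(
    v_coef={"intercept": 20.0},
    cl_coef={"intercept": 5.0},
    omega2_v=4.0,
    omega2_cl=0.25,
)

DEFAULT_SIGMA2 = 0.04  # residual variance, (mg/L)^2


@dataclass
class Subject:
    """One individual's dosing, covariates and concentration-time data."""

    id: str
    dose: float
    covariates: dict[str, float]
    times: np.ndarray
    concentrations: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.times.size != self.concentrations.size:
            raise ValueError(f"subject {self.id}: times and concentrations differ in length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError(f"subject {self.id}: times must be strictly increasing")


def simulate_population(model: CovariateModel, design: StudyDesign,
                        n_subjects: int, sigma2: float = DEFAULT_SIGMA2,
                        seed: int | None = None) -> list[Subject]:
    """Simulate a PopPK dataset under the two-stage NLME model.

    Per subject: draw covariates and eta ~ N(0, Omega), form the individual
    (V_i, Cl_i), evaluate the bolus model at the design times, and add
    eps ~ N(0, sigma2). Subjects whose drawn V is non-positive (or Cl
    negative) are redrawn and the redraw logged. Fully reproducible from
    ``seed``.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    rng = np.random.default_rng(seed)
    t = np.asarray(design.times, dtype=float)
    subjects: list[Subject] = []
    for i in range(n_subjects):
        while True:
            z = design.draw_covariates(rng)
            v_typ, cl_typ = model.typical_values(z)
            v_i = v_typ + rng.normal(0.0, math.sqrt(model.omega2_v))
            cl_i = cl_typ + rng.normal(0.0, math.sqrt(model.omega2_cl))
            if v_i > 0 and cl_i >= 0:
                break
            logger.info("subject %d redrawn: non-physical V=%.3g or Cl=%.3g", i + 1, v_i, cl_i)
        conc = conc_bolus(design.dose, v_i, cl_i, t)
        conc = conc + rng.normal(0.0, math.sqrt(sigma2), size=t.size)
        subjects.append(Subject(id=f"S{i + 1:03d}", dose=design.dose,
                                covariates=z, times=t, concentrations=conc))
    return subjects


# ---------------------------------------------------------------------------
# Long-format dataset IO
# ---------------------------------------------------------------------------

def dataset_to_frame(subjects: list[Subject]) -> pd.DataFrame:
    rows = []
    for s in subjects:
        for t, c in zip(s.times, s.concentrations):
            rows.append({"id": s.id, "time": t, "conc": c, "dose": s.dose,
                         **s.covariates})
    return pd.DataFrame(rows)


def write_dataset(subjects: list[Subject], path, seed: int | None = None) -> None:
    """Write a long-format CSV plus a sidecar metadata JSON recording the seed."""
    df = dataset_to_frame(subjects)
    df.to_csv(path, index=False)
    meta = {"seed": seed, "n_subjects": len(subjects),
            "n_obs": int(df.shape[0]), "columns": list(df.columns)}
    with open(f"{path}.meta.json", "w") as fh:
        json.dump(meta, fh, indent=2)


def read_dataset(path) -> list[Subject]:
    """Read a long-format CSV (columns id, time, conc, dose, covariates...)."""
    df = pd.read_csv(path)
    required = {"id", "time", "conc", "dose"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"dataset {path} is missing column(s) {sorted(missing)}")
    cov_cols = [c for c in df.columns if c not in required]
    subjects = []
    for sid, g in df.groupby("id", sort=False):
        g = g.sort_values("time")
        subjects.append(Subject(
            id=str(sid), dose=float(g["dose"].iloc[0]),
            covariates={c: float(g[c].iloc[0]) for c in cov_cols},
            times=g["time"].to_numpy(), concentrations=g["conc"].to_numpy()))
    return subjects


# ---------------------------------------------------------------------------
# FO-REML estimation
# ---------------------------------------------------------------------------

@dataclass
class NLMEFit:
    """Result of an FO-REML fit: estimates, approximate log-likelihood,
    population-level fitted values and the FitSummary feeding the criteria."""

    theta_v: dict[str, float]
    theta_cl: dict[str, float]
    omega2: dict[str, float]
    sigma2: float
    log_likelihood: float
    fitted: np.ndarray
    residuals: np.ndarray
    summary: FitSummary
    converged: bool
    n_iter: int
    message: str = ""


class _FOModel:
    """Precomputed per-subject data and the FO-REML objective."""

    def __init__(self, subjects: list[Subject], template: CovariateModel):
        self.v_names = [k for k in template.v_coef if k != "intercept"]
        self.cl_names = [k for k in template.cl_coef if k != "intercept"]
        self.p_v = 1 + len(self.v_names)
        self.p_cl = 1 + len(self.cl_names)
        self.p = self.p_v + self.p_cl
        self.subjects = subjects
        self.doses = np.array([s.dose for s in subjects])
        self.times = [s.times for s in subjects]
        self.y = [s.concentrations for s in subjects]
        self.n_obs = int(sum(t.size for t in self.times))
        # per-subject covariate rows (intercept first)
        self.xv = np.array([[1.0] + [s.covariates[k] for k in self.v_names]
                            for s in subjects])
        self.xcl = np.array([[1.0] + [s.covariates[k] for k in self.cl_names]
                             for s in subjects])

    def split(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return theta[:self.p_v], theta[self.p_v:self.p]

    def individual_params(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        tv, tcl = self.split(theta)
        return self.xv @ tv, self.xcl @ tcl

    def pooled_residuals(self, theta: np.ndarray) -> np.ndarray:
        """Residual vector for the NLS warm-up; non-physical V is penalized
        smoothly so the optimizer can escape the 0.01 starting point."""
        v, cl = self.individual_params(theta)
        v_safe = np.maximum(v, 1e-6)
        cl_safe = np.maximum(cl, 0.0)
        res = []
        for i, (t, y) in enumerate(zip(self.times, self.y)):
            f = (self.doses[i] / v_safe[i]) * np.exp(-(cl_safe[i] / v_safe[i]) * t)
            res.append(y - f)
        penalty = 1e3 * (np.minimum(v - 1e-6, 0.0).sum()
                         + np.minimum(cl, 0.0).sum())
        return np.concatenate(res + [[penalty]])

    def neg2_reml(self, x: np.ndarray) -> float:
        """-2 x FO-linearized REML log-likelihood at packed parameters
        ``x = (theta, log omega2_V, log omega2_Cl, log sigma2)``."""
        theta = x[:self.p]
        w2v, w2cl, s2 = np.exp(x[self.p:])
        v, cl = self.individual_params(theta)
        if np.any(v <= 0) or np.any(~np.isfinite(v)) or np.any(~np.isfinite(cl)):
            return 1e12
        xtvx = np.zeros((self.p, self.p))
        total = self.n_obs * _LOG2PI
        try:
            for i, (t, y) in enumerate(zip(self.times, self.y)):
                f, dfv, dfc = _bolus_sensitivities(self.doses[i], v[i], cl[i], t)
                Z = np.column_stack([dfv, dfc])
                X = np.column_stack([dfv[:, None] * self.xv[i][None, :],
                                     dfc[:, None] * self.xcl[i][None, :]])
                Vm = (w2v * np.outer(Z[:, 0], Z[:, 0])
                      + w2cl * np.outer(Z[:, 1], Z[:, 1])
                      + s2 * np.eye(t.size))
                L = np.linalg.cholesky(Vm)
                r = y - f
                sol_r = np.linalg.solve(L, r)
                sol_X = np.linalg.solve(L, X)
                total += 2.0 * np.log(np.diag(L)).sum() + sol_r @ sol_r
                xtvx += sol_X.T @ sol_X
            sign, logdet = np.linalg.slogdet(xtvx)
            if sign <= 0:
                return 1e12
            total += logdet
        except np.linalg.LinAlgError:
            return 1e12
        if not np.isfinite(total):
            return 1e12
        return float(total)


def fit_nlme_fo(data: list[Subject], template: CovariateModel,
                init_fixed: float = 0.01, max_iter: int = 100) -> NLMEFit:
    """Fit the one-compartment NLME model by FO-linearized REML.

    ``template`` declares the structure (which covariates enter V and Cl);
    its coefficient values are ignored. All fixed effects start at
    ``init_fixed``; a pooled nonlinear-least-squares warm-up moves them to
    the data scale before the quasi-Newton (L-BFGS-B) REML stage, capped at
    ``max_iter`` iterations. Non-convergence is flagged on the result, not
    raised, so criteria can still be computed downstream.
    """
    if len(data) < 2:
        raise ValueError("FO-REML estimation needs at least 2 subjects")
    if any(s.times.size < 2 for s in data):
        raise ValueError("every subject needs at least 2 observations")
    fo = _FOModel(data, template)

    theta0 = np.full(fo.p, float(init_fixed))
    nls = optimize.least_squares(fo.pooled_residuals, theta0, method="trf",
                                 max_nfev=200 * fo.p)
    theta_nls = nls.x
    # moment-style variance starts: project each subject's pooled residuals
    # onto its (V, Cl) sensitivities to get crude eta estimates, then use
    # their spread for omega2 and the leftover within-subject spread for
    # sigma2; this keeps the quasi-Newton stage off the theta/omega ridge
    v0, cl0 = fo.individual_params(theta_nls)
    etas = []
    within = []
    for i, (t, y) in enumerate(zip(fo.times, fo.y)):
        f, dfv, dfc = _bolus_sensitivities(fo.doses[i], max(v0[i], 1e-6),
                                           max(cl0[i], 0.0), t)
        Z = np.column_stack([dfv, dfc])
        r = y - f
        eta, *_ = np.linalg.lstsq(Z, r, rcond=None)
        etas.append(eta)
        within.append(r - Z @ eta)
    etas_arr = np.array(etas)
    w2v_0 = max(float(etas_arr[:, 0].var()), 1e-6)
    w2cl_0 = max(float(etas_arr[:, 1].var()), 1e-6)
    s2_0 = max(float(np.concatenate(within).var()), 1e-8)

    x0 = np.concatenate([theta_nls, np.log([w2v_0, w2cl_0, s2_0])])
    res = optimize.minimize(fo.neg2_reml, x0, method="L-BFGS-B",
                            options={"maxiter": max_iter, "ftol": 1e-11,
                                     "gtol": 1e-7})
    theta = res.x[:fo.p]
    w2v, w2cl, s2 = np.exp(res.x[fo.p:])
    converged = bool(res.success)
    if not converged:
        logger.warning("FO-REML fit did not converge in %d iterations: %s",
                       max_iter, res.message)

    v, cl = fo.individual_params(theta)
    fitted = np.concatenate([
        conc_bolus(fo.doses[i], max(v[i], 1e-6), max(cl[i], 0.0), fo.times[i])
        for i in range(len(data))])
    y_all = np.concatenate(fo.y)
    residuals = y_all - fitted
    n_params = fo.p + 3  # fixed effects + (omega2_V, omega2_Cl, sigma2)
    summary = FitSummary(n_obs=fo.n_obs, n_params=n_params,
                         residuals=residuals, ofv=float(res.fun))
    tv, tcl = fo.split(theta)
    return NLMEFit(
        theta_v=dict(zip(["intercept"] + fo.v_names, tv.tolist())),
        theta_cl=dict(zip(["intercept"] + fo.cl_names, tcl.tolist())),
        omega2={"V": float(w2v), "Cl": float(w2cl)},
        sigma2=float(s2),
        log_likelihood=-0.5 * float(res.fun),
        fitted=fitted,
        residuals=residuals,
        summary=summary,
        converged=converged,
        n_iter=int(res.nit),
        message=str(res.message),
    )
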