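"""Two-compartment oral PK model with absorption lag: closed forms and covariates.

Structural model: first-order absorption (rate ``ka``, lag ``alag``) into a
central compartment with first-order elimination (``cl``/``vc``) exchanging
with a peripheral compartment (``q``, ``vp``).  All clearances and volumes are
apparent (scaled by oral bioavailability F).  The closed-form tri-exponential
solution is the primary evaluation path throughout the package; numerical ODE
integration exists only as an independent oracle in the test suite.

Covariate submodel (final model):

    CL/F  = cl_typ  * exp(eta1) * (BSA/1.66)^1.11
    Vc/F  = vc_typ  * exp(eta2) * (BSA/1.66)^2.41 * (TP/68.95)^-3.1
    Q/F   = q_typ   * exp(eta3) * (BSA/1.66)^2.20
    Vp/F  = vp_typ  * exp(eta4) * (BSA/1.66)^3.84 * (1 + 0.751*[female])
    F1    = 1 (melanoma) or 1.29 (NF1)

Units: doses mg, concentrations ng/mL, volumes L, clearances L/h, times h.
The single internal unit conversion is mg -> ug (x1000) so that amount/volume
comes out in ug/L = ng/mL.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml
from scipy.optimize import minimize_scalar

from .datamodel import CovariateVector

__all__ = [
    "FixedEffects",
    "RandomEffects",
    "IndividualParameters",
    "MacroCoefficients",
    "Regimen",
    "ExposureMetrics",
    "apply_covariates",
    "macro_constants",
    "concentration",
    "exposure",
    "exposure_batch",
    "covariate_effects",
    "load_model",
    "final_model_path",
    "MG_TO_UG",
]

MG_TO_UG = 1000.0  # dose mg -> ug so that ug/L == ng/mL

BSA_REF = 1.66  # m^2, population median
TP_REF = 68.95  # g/L, population median


@dataclass
class FixedEffects:
    """Typical-value (fixed-effect) parameters of the final model.

    Defaults are the published final estimates; covariate exponents are the
    fitted allometric/power terms with BSA normalized to 1.66 m^2 and total
    protein to 68.95 g/L.
    """

    cl_typ: float = 13.2  # CL/F, L/h
    vc_typ: float = 48.7  # Vc/F, L
    q_typ: float = 35.1  # Q/F, L/h
    vp_typ: float = 314.0  # Vp/F, L
    ka: float = 0.5  # 1/h
    alag: float = 0.211  # h
    f_nf1: float = 1.29  # relative bioavailability, NF1 vs melanoma
    exp_cl_bsa: float = 1.11
    exp_q_bsa: float = 2.20
    exp_vp_bsa: float = 3.84
    exp_vc_bsa: float = 2.41
    exp_vc_tp: float = -3.1
    frac_vp_female: float = 0.751
    bsa_ref: float = BSA_REF
    tp_ref: float = TP_REF

    def __post_init__(self) -> None:
        for name in ("cl_typ", "vc_typ", "q_typ", "vp_typ", "ka", "f_nf1"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be positive")
        if self.alag < 0:
            raise ValueError("alag must be non-negative")
        if not (1 + self.frac_vp_female > 0):
            raise ValueError("1 + frac_vp_female must be positive")


@dataclass
class RandomEffects:
    """Lognormal between-subject variability (SD scale) and residual error.

    ``omega_*`` are the standard deviations of the normal random effects on the
    log scale (the published percentages divided by 100); ``sigma_prop`` is the
    SD of the proportional residual error.
    """

    omega_cl: float = 0.19
    omega_vc: float = 0.694
    omega_q: float = 0.26
    omega_vp: float = 0.265
    sigma_prop: float = 0.258
    sigma_add: float = 0.0  # ng/mL; base-model option, zero in the final model

    def __post_init__(self) -> None:
        for name in ("omega_cl", "omega_vc", "omega_q", "omega_vp", "sigma_prop", "sigma_add"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def omegas(self) -> np.ndarray:
        return np.array([self.omega_cl, self.omega_vc, self.omega_q, self.omega_vp])


@dataclass(frozen=True)
class IndividualParameters:
    """Realized per-subject parameters after covariates and eta application."""

    cl: float
    vc: float
    q: float
    vp: float
    ka: float
    alag: float
    f: float = 1.0

    def __post_init__(self) -> None:
        for name in ("cl", "vc", "q", "vp", "ka", "f"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be positive")
        if self.alag < 0:
            raise ValueError("alag must be non-negative")


@dataclass(frozen=True)
class MacroCoefficients:
    """Disposition exponents and partial-fraction coefficients.

    alpha > beta > 0 are the roots of
    lambda^2 - (k10+k12+k21) lambda + k10 k21 = 0; the three coefficients sum
    to zero (continuity of the absorbed profile at t=0).
    """

    alpha: float
    beta: float
    coef_alpha: float
    coef_beta: float
    coef_ka: float


@dataclass(frozen=True)
class Regimen:
    """Repeated oral dosing: ``n_doses`` is an int or "steady-state"."""

    dose: float  # mg
    tau: float = 24.0  # h
    n_doses: int | str = "steady-state"

    def __post_init__(self) -> None:
        if not (self.dose > 0):
            raise ValueError("dose must be positive")
        if not (self.tau > 0):
            raise ValueError("tau must be positive")
        if isinstance(self.n_doses, str) and self.n_doses != "steady-state":
            raise ValueError("n_doses must be an int or 'steady-state'")


@dataclass(frozen=True)
class ExposureMetrics:
    auc24_ss: float  # ng*h/mL over one daily interval at steady state
    cmax_ss: float  # ng/mL
    tmax_ss: float  # h after dose


def apply_covariates(
    fe: FixedEffects, cov: CovariateVector, eta: np.ndarray | None = None
) -> IndividualParameters:
    """Realize individual parameters from covariates and the eta 4-vector.

    ``eta`` is ordered (cl, vc, q, vp); zeros give the covariate-typical
    subject.  Requires complete bsa, tp, sex and cancer_type.
    """
    if eta is None:
        eta = np.zeros(4)
    eta = np.asarray(eta, dtype=float)
    if eta.shape != (4,) or not np.all(np.isfinite(eta)):
        raise ValueError("eta must be a finite 4-vector")
    if cov.tp is None or cov.sex is None or cov.cancer_type is None:
        raise ValueError("covariates must be complete (bsa, tp, sex, cancer_type)")
    if not (cov.bsa > 0 and cov.tp > 0):
        raise ValueError("bsa and tp must be positive")
    b = cov.bsa / fe.bsa_ref
    cl = fe.cl_typ * math.exp(eta[0]) * b**fe.exp_cl_bsa
    vc = fe.vc_typ * math.exp(eta[1]) * b**fe.exp_vc_bsa * (cov.tp / fe.tp_ref) ** fe.exp_vc_tp
    q = fe.q_typ * math.exp(eta[2]) * b**fe.exp_q_bsa
    vp = fe.vp_typ * math.exp(eta[3]) * b**fe.exp_vp_bsa
    if cov.sex == "female":
        vp *= 1 + fe.frac_vp_female
    f = fe.f_nf1 if cov.cancer_type == "nf1" else 1.0
    return IndividualParameters(cl=cl, vc=vc, q=q, vp=vp, ka=fe.ka, alag=fe.alag, f=f)


def macro_constants(p: IndividualParameters, ka_tol: float = 1e-9) -> MacroCoefficients:
    """Disposition roots and partial-fraction coefficients for ``p``.

    Raises if ``ka`` coincides with a disposition root (degenerate partial
    fractions); callers should perturb ka by ~1e-8 relative and retry.
    """
    k10 = p.cl / p.vc
    k12 = p.q / p.vc
    k21 = p.q / p.vp
    s = k10 + k12 + k21
    disc = math.sqrt(max(s * s - 4.0 * k10 * k21, 0.0))
    alpha = (s + disc) / 2.0
    beta = (s - disc) / 2.0
    if min(abs(p.ka - alpha), abs(p.ka - beta)) < ka_tol * max(p.ka, alpha):
        raise ValueError(
            "ka coincides with a disposition rate constant; perturb ka by ~1e-8 relative"
        )
    coef_alpha = (k21 - alpha) / ((p.ka - alpha) * (beta - alpha))
    coef_beta = (k21 - beta) / ((p.ka - beta) * (alpha - beta))
    coef_ka = (k21 - p.ka) / ((alpha - p.ka) * (beta - p.ka))
    return MacroCoefficients(alpha, beta, coef_alpha, coef_beta, coef_ka)


def _profile_terms(p: IndividualParameters, mc: MacroCoefficients):
    lam = np.array([mc.alpha, mc.beta, p.ka])
    coef = np.array([mc.coef_alpha, mc.coef_beta, mc.coef_ka])
    return lam, coef


def concentration(
    p: IndividualParameters, regimen: Regimen, t: float | np.ndarray
) -> float | np.ndarray:
    """Plasma concentration (ng/mL) at time(s) ``t``.

    For finite ``n_doses``, ``t`` is hours since the first dose and the
    profile is the superposition of single-dose closed forms.  For
    steady state, ``t`` is reduced modulo the dosing interval and each
    exponential term carries the accumulation factor 1/(1 - exp(-lambda tau)).
    """
    scalar_in = np.ndim(t) == 0
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative")
    mc = macro_constants(p)
    lam, coef = _profile_terms(p, mc)
    scale = p.f * regimen.dose * MG_TO_UG * p.ka / p.vc
    if regimen.n_doses == "steady-state":
        tprime = np.mod(t_arr, regimen.tau) - p.alag
        tprime = np.where(tprime < 0, tprime + regimen.tau, tprime)
        acc = 1.0 / (1.0 - np.exp(-lam * regimen.tau))
        conc = scale * np.sum(coef * acc * np.exp(-np.outer(tprime, lam)), axis=-1)
    else:
        dose_times = np.arange(int(regimen.n_doses)) * regimen.tau
        dt = t_arr[..., None] - dose_times - p.alag
        active = dt > 0
        dt = np.where(active, dt, 0.0)
        terms = np.einsum("j,...dj->...d", coef, np.exp(-dt[..., None] * lam))
        conc = scale * np.sum(np.where(active, terms, 0.0), axis=-1)
    return float(conc[0]) if scalar_in else conc


def exposure(p: IndividualParameters, regimen: Regimen | None = None) -> ExposureMetrics:
    """Steady-state exposure metrics for a QD regimen.

    AUC over one interval uses the linear-PK identity F*Dose/CL; Cmax and Tmax
    come from a 0.001 h grid over the interval followed by bounded local
    refinement of the smooth closed-form profile.
    """
    if regimen is None:
        raise ValueError("regimen is required")
    ss = Regimen(dose=regimen.dose, tau=regimen.tau, n_doses="steady-state")
    auc = p.f * regimen.dose * MG_TO_UG / p.cl
    grid = np.arange(0.0, ss.tau, 0.001)
    prof = concentration(p, ss, grid)
    i = int(np.argmax(prof))
    lo = grid[max(i - 2, 0)]
    hi = grid[min(i + 2, len(grid) - 1)]
    res = minimize_scalar(
        lambda x: -concentration(p, ss, float(x)),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-6},
    )
    tmax = float(res.x)
    cmax = float(-res.fun)
    if prof[i] > cmax:  # guard: refinement can only improve
        cmax, tmax = float(prof[i]), float(grid[i])
    return ExposureMetrics(auc24_ss=float(auc), cmax_ss=cmax, tmax_ss=tmax)


def exposure_batch(
    cl: np.ndarray,
    vc: np.ndarray,
    q: np.ndarray,
    vp: np.ndarray,
    ka: np.ndarray,
    alag: np.ndarray,
    f: np.ndarray,
    dose: float | np.ndarray,
    tau: float = 24.0,
    grid_step: float = 0.002,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized steady-state (auc24, cmax, tmax) for many subjects at once.

    AUC is the analytic F*Dose/CL; Cmax/Tmax come from a dense grid over one
    interval followed by one parabolic refinement around the peak.  Used by
    the population and dose-band simulators where thousands of profiles are
    evaluated.
    """
    cl, vc, q, vp, ka, alag, f = np.broadcast_arrays(
        *(np.atleast_1d(np.asarray(a, float)) for a in (cl, vc, q, vp, ka, alag, f))
    )
    dose = np.broadcast_to(np.asarray(dose, float), cl.shape)
    n_total = len(cl)
    chunk = max(1, int(2_000_000 * grid_step / tau))
    if n_total > chunk:
        parts = [
            exposure_batch(
                cl[i : i + chunk], vc[i : i + chunk], q[i : i + chunk],
                vp[i : i + chunk], ka[i : i + chunk], alag[i : i + chunk],
                f[i : i + chunk], dose[i : i + chunk], tau, grid_step,
            )
            for i in range(0, n_total, chunk)
        ]
        return tuple(np.concatenate([p[k] for p in parts]) for k in range(3))
    auc = f * dose * MG_TO_UG / cl
    k10 = cl / vc
    k12 = q / vc
    k21 = q / vp
    s = k10 + k12 + k21
    disc = np.sqrt(np.maximum(s * s - 4.0 * k10 * k21, 0.0))
    alpha = (s + disc) / 2.0
    beta = (s - disc) / 2.0
    ca = (k21 - alpha) / ((ka - alpha) * (beta - alpha))
    cb = (k21 - beta) / ((ka - beta) * (alpha - beta))
    ck = (k21 - ka) / ((alpha - ka) * (beta - ka))
    lam = np.stack([alpha, beta, ka], axis=-1)  # (n, 3)
    coef = np.stack([ca, cb, ck], axis=-1) / (1.0 - np.exp(-lam * tau))
    scale = f * dose * MG_TO_UG * ka / vc
    t = np.arange(0.0, tau, grid_step)  # time since dose; lag shifts within interval
    tp = t[None, :, None] - alag[:, None, None]
    tp = np.where(tp < 0, tp + tau, tp)
    prof = scale[:, None] * np.einsum("nk,ntk->nt", coef, np.exp(-lam[:, None, :] * tp))
    i = np.argmax(prof, axis=1)
    n = len(cl)
    idx = np.arange(n)
    im = np.clip(i - 1, 0, len(t) - 1)
    ip = np.clip(i + 1, 0, len(t) - 1)
    y0, y1, y2 = prof[idx, im], prof[idx, i], prof[idx, ip]
    denom = y0 - 2 * y1 + y2
    shift = np.where(np.abs(denom) > 1e-300, 0.5 * (y0 - y2) / denom, 0.0)
    shift = np.clip(shift, -1.0, 1.0)
    tmax = t[i] + shift * grid_step
    cmax = y1 - 0.25 * (y0 - y2) * shift
    cmax = np.maximum(cmax, y1)
    return auc, cmax, tmax


def covariate_effects(
    fe: FixedEffects,
    regimen: Regimen | None = None,
    bsa_points: tuple[float, ...] = (1.42, 2.01),
    tp_points: tuple[float, ...] = (76.89,),
) -> "pd.DataFrame":
    """Forest-plot table: exposure ratios when one covariate moves off reference.

    The reference subject has BSA 1.66 m^2, TP 68.95 g/L, male, melanoma.
    Ratios are steady-state AUC0-24 and Cmax at the perturbed covariate divided
    by the reference value; ``pct_change`` is the rounded percent difference.
    """
    import pandas as pd

    if regimen is None:
        regimen = Regimen(dose=8.0)
    ref_cov = CovariateVector(bsa=fe.bsa_ref, tp=fe.tp_ref, sex="male", cancer_type="melanoma")
    ref = exposure(apply_covariates(fe, ref_cov), regimen)
    rows = []

    def add(label: str, cov: CovariateVector) -> None:
        m = exposure(apply_covariates(fe, cov), regimen)
        for metric, val, refval in (
            ("auc24_ss", m.auc24_ss, ref.auc24_ss),
            ("cmax_ss", m.cmax_ss, ref.cmax_ss),
        ):
            ratio = val / refval
            rows.append(
                {
                    "covariate": label,
                    "metric": metric,
                    "ratio": ratio,
                    "pct_change": int(round((ratio - 1) * 100)),
                }
            )

    for bsa in bsa_points:
        add(f"bsa={bsa}", CovariateVector(bsa=bsa, tp=fe.tp_ref, sex="male", cancer_type="melanoma"))
    for tp in tp_points:
        add(f"tp={tp}", CovariateVector(bsa=fe.bsa_ref, tp=tp, sex="male", cancer_type="melanoma"))
    add("sex=female", CovariateVector(bsa=fe.bsa_ref, tp=fe.tp_ref, sex="female", cancer_type="melanoma"))
    add("type=nf1", CovariateVector(bsa=fe.bsa_ref, tp=fe.tp_ref, sex="male", cancer_type="nf1"))
    return pd.DataFrame(rows)


def final_model_path() -> str:
    """Path to the shipped final-model parameter YAML."""
    return str(resources.files("fcn159pk").joinpath("params/fcn159_final_model.yaml"))


def load_model(path: str | None = None, iiv_as_cv: bool = False) -> tuple[FixedEffects, RandomEffects]:
    """Load (FixedEffects, RandomEffects) from YAML; defaults to the shipped file.

    With ``iiv_as_cv`` the omega entries are treated as lognormal CVs and
    converted via omega = sqrt(log(1 + cv^2)).
    """
    if path is None:
        path = final_model_path()
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    fe = FixedEffects(**raw.get("fixed_effects", {}))
    re_kwargs = dict(raw.get("random_effects", {}))
    if iiv_as_cv:
        for key in ("omega_cl", "omega_vc", "omega_q", "omega_vp"):
            cv = re_kwargs[key]
            re_kwargs[key] = math.sqrt(math.log(1 + cv * cv))
    re = RandomEffects(**re_kwargs)
    return fe, re
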