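"""FOCE-with-interaction estimation for the nonlinear mixed-effects PK model.

Implements the classic first-order-conditional objective: for each subject the
empirical Bayes eta maximizes the conditional joint density (inner Newton with
Gauss-Newton curvature and Armijo backtracking, warm-started across outer
iterations); the marginal -2 log-likelihood is assembled from the
eta-linearized sensitivities at the conditional mode, with the proportional
residual variance evaluated at the individual prediction (the "interaction").

Outer optimization is quasi-Newton (L-BFGS-B) on transformed parameters
(log for positives, log1p for categorical fractions).  Standard errors come
from a central finite-difference Hessian of the objective; the condition
number is the eigenvalue ratio of the correlation-scaled covariance of the
fixed effects.

Derivatives of the prediction with respect to eta use complex-step
differentiation through the closed-form profile, which is exact to machine
precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._engine import SubjectDesign, build_design, predict_conc
from .datamodel import PKDataset
from .model import FixedEffects, RandomEffects

__all__ = [
    "CovariateTerm",
    "ModelSpec",
    "EstimationResult",
    "StepwiseStep",
    "StepwiseLog",
    "FitOptions",
    "final_model_spec",
    "base_model_spec",
    "default_candidate_terms",
    "foce_objective",
    "fit",
    "diagnostics",
    "stepwise_search",
    "perturb_spec",
]

_THETA_NAMES = ("cl", "vc", "q", "vp", "ka", "alag")
_FORMS = ("power", "linear", "exponential", "categorical")
_BIG = 1e10
_CSTEP = 1e-20
_FP_FLOOR = 0.1  # ng/mL; half the assay LLOQ — variance floor for the
# proportional error model, bounding the weight of grossly mispredicted points


@dataclass(frozen=True)
class CovariateTerm:
    """One covariate-parameter relationship contributing one coefficient.

    Forms: ``power`` (x/ref)^theta, ``linear`` 1 + theta (x - ref),
    ``exponential`` exp(theta (x - ref)), ``categorical`` 1 + theta * x for a
    0/1 indicator (x: female=1 for sex, NF1=1 for cancer_type).
    """

    parameter: str
    covariate: str
    form: str
    init: float
    reference: float = 0.0
    locked: bool = False  # default-included terms exempt from stepwise testing

    def __post_init__(self) -> None:
        if self.parameter not in _THETA_NAMES + ("f",):
            raise ValueError(f"unknown parameter {self.parameter!r}")
        if self.form not in _FORMS:
            raise ValueError(f"form must be one of {_FORMS}")

    @property
    def label(self) -> str:
        return f"{self.parameter}~{self.covariate}"


@dataclass
class ModelSpec:
    """Structural flavour, covariate terms, and parameters to estimate."""

    structural: str = "2cpt-lag-final"
    thetas: dict[str, float] = field(
        default_factory=lambda: {
            "cl": 13.2, "vc": 48.7, "q": 35.1, "vp": 314.0, "ka": 0.5, "alag": 0.211,
        }
    )
    covariate_terms: list[CovariateTerm] = field(default_factory=list)
    omegas: dict[str, float] = field(
        default_factory=lambda: {"cl": 0.19, "vc": 0.694, "q": 0.26, "vp": 0.265}
    )
    sigma_prop: float = 0.258
    sigma_add: float | None = None  # estimated additive SD when not None

    @property
    def omega_names(self) -> list[str]:
        return list(self.omegas)

    @property
    def n_parameters(self) -> int:
        return (
            len(self.thetas)
            + len(self.covariate_terms)
            + len(self.omegas)
            + 1
            + (1 if self.sigma_add is not None else 0)
        )

    def parameter_labels(self) -> list[str]:
        labels = list(self.thetas)
        labels += [t.label for t in self.covariate_terms]
        labels += [f"omega_{p}" for p in self.omegas]
        labels.append("sigma_prop")
        if self.sigma_add is not None:
            labels.append("sigma_add")
        return labels

    def with_term(self, term: CovariateTerm) -> "ModelSpec":
        return replace(self, covariate_terms=self.covariate_terms + [term])

    def without_term(self, term: CovariateTerm) -> "ModelSpec":
        return replace(
            self, covariate_terms=[t for t in self.covariate_terms if t is not term]
        )


def final_model_spec(
    fe: FixedEffects | None = None, re: RandomEffects | None = None
) -> ModelSpec:
    """The published final model as an estimable specification."""
    fe = fe or FixedEffects()
    re = re or RandomEffects()
    terms = [
        CovariateTerm("cl", "bsa", "power", fe.exp_cl_bsa, fe.bsa_ref, locked=True),
        CovariateTerm("vc", "bsa", "power", fe.exp_vc_bsa, fe.bsa_ref, locked=True),
        CovariateTerm("q", "bsa", "power", fe.exp_q_bsa, fe.bsa_ref, locked=True),
        CovariateTerm("vp", "bsa", "power", fe.exp_vp_bsa, fe.bsa_ref, locked=True),
        CovariateTerm("vc", "tp", "power", fe.exp_vc_tp, fe.tp_ref),
        CovariateTerm("vp", "sex", "categorical", fe.frac_vp_female),
        CovariateTerm("f", "cancer_type", "categorical", fe.f_nf1 - 1.0),
    ]
    return ModelSpec(
        structural="2cpt-lag-final",
        thetas={
            "cl": fe.cl_typ, "vc": fe.vc_typ, "q": fe.q_typ,
            "vp": fe.vp_typ, "ka": fe.ka, "alag": fe.alag,
        },
        covariate_terms=terms,
        omegas={
            "cl": re.omega_cl, "vc": re.omega_vc, "q": re.omega_q, "vp": re.omega_vp,
        },
        sigma_prop=re.sigma_prop,
    )


def base_model_spec(additive: bool = False) -> ModelSpec:
    """Covariate-free two-compartment lagged-absorption base model."""
    return ModelSpec(
        structural="2cpt-lag-base",
        covariate_terms=[],
        sigma_add=0.1 if additive else None,
    )


def default_candidate_terms() -> list[CovariateTerm]:
    """Candidate covariates of the published screening (BSA excluded: it is
    included by default as the allometric term, never subjected to the test)."""
    return [
        CovariateTerm("cl", "age", "linear", 0.0, 49.0),
        CovariateTerm("cl", "albumin", "linear", 0.0, 40.0),
        CovariateTerm("cl", "tp", "power", 0.0, 68.95),
        CovariateTerm("vc", "tp", "power", 0.0, 68.95),
        CovariateTerm("vp", "sex", "categorical", 0.0),
        CovariateTerm("f", "cancer_type", "categorical", 0.0),
    ]


# ---------------------------------------------------------------------------
# parameter packing


def _pack(spec: ModelSpec) -> np.ndarray:
    x = [math.log(spec.thetas[k]) for k in spec.thetas]
    for t in spec.covariate_terms:
        x.append(math.log1p(t.init) if t.form == "categorical" else t.init)
    x += [math.log(max(v, 1e-12)) for v in spec.omegas.values()]
    x.append(math.log(max(spec.sigma_prop, 1e-12)))
    if spec.sigma_add is not None:
        x.append(math.log(max(spec.sigma_add, 1e-12)))
    return np.array(x)


def _unpack(spec: ModelSpec, x: np.ndarray):
    nt = len(spec.thetas)
    nc = len(spec.covariate_terms)
    no = len(spec.omegas)
    theta = {k: math.exp(v) for k, v in zip(spec.thetas, x[:nt])}
    coefs = []
    for t, v in zip(spec.covariate_terms, x[nt : nt + nc]):
        coefs.append(math.expm1(v) if t.form == "categorical" else float(v))
    omegas = np.exp(x[nt + nc : nt + nc + no])
    sigma_prop = math.exp(x[nt + nc + no])
    sigma_add = math.exp(x[nt + nc + no + 1]) if spec.sigma_add is not None else 0.0
    return theta, coefs, omegas, sigma_prop, sigma_add


_THETA_BOUNDS = {
    "cl": (0.05, 500.0),  # L/h
    "vc": (0.5, 5000.0),  # L
    "q": (0.05, 1000.0),  # L/h
    "vp": (1.0, 20000.0),  # L
    "ka": (0.005, 50.0),  # 1/h
    "alag": (1e-3, 6.0),  # h
}


def _bounds(spec: ModelSpec, alag_hi: float | None = None) -> list[tuple[float, float]]:
    """Wide physiological sanity box on the transformed scale.

    ``alag_hi`` caps the absorption lag below the earliest observed
    time-after-dose: beyond it the lag is unidentifiable and the likelihood
    cliff-edged (a sample would predate absorption entirely).
    """
    b: list[tuple[float, float]] = []
    for name in spec.thetas:
        lo, hi = _THETA_BOUNDS[name]
        if name == "alag" and alag_hi is not None:
            hi = max(alag_hi, 2.0 * lo)
        b.append((math.log(lo), math.log(hi)))
    for t in spec.covariate_terms:
        if t.form == "categorical":
            b.append((math.log1p(-0.95), math.log1p(20.0)))
        else:
            b.append((-15.0, 15.0))
    for _ in spec.omegas:
        b.append((math.log(1e-3), math.log(3.0)))
    b.append((math.log(1e-3), math.log(1.0)))  # sigma_prop: <= 100% CV
    if spec.sigma_add is not None:
        b.append((math.log(1e-6), math.log(100.0)))
    return b


def _natural_jacobian(spec: ModelSpec, x: np.ndarray) -> np.ndarray:
    """d(natural)/d(transformed), diagonal."""
    theta, coefs, omegas, sigma_prop, sigma_add = _unpack(spec, x)
    j = [theta[k] for k in spec.thetas]
    for t, c in zip(spec.covariate_terms, coefs):
        j.append(1.0 + c if t.form == "categorical" else 1.0)
    j += list(omegas)
    j.append(sigma_prop)
    if spec.sigma_add is not None:
        j.append(sigma_add)
    return np.array(j)


def _natural_values(spec: ModelSpec, x: np.ndarray) -> dict[str, float]:
    theta, coefs, omegas, sigma_prop, sigma_add = _unpack(spec, x)
    out = dict(theta)
    for t, c in zip(spec.covariate_terms, coefs):
        out[t.label] = c
    for name, w in zip(spec.omegas, omegas):
        out[f"omega_{name}"] = float(w)
    out["sigma_prop"] = sigma_prop
    if spec.sigma_add is not None:
        out["sigma_add"] = sigma_add
    return out


# ---------------------------------------------------------------------------
# model evaluation


def _subject_params(
    spec: ModelSpec,
    design: SubjectDesign,
    theta: dict[str, float],
    coefs: list[float],
    etas: np.ndarray,
) -> dict[str, np.ndarray] | None:
    """Per-subject parameter arrays; None when a multiplier goes non-positive."""
    n = design.n_subjects
    dtype = complex if np.iscomplexobj(etas) else float
    vals: dict[str, np.ndarray] = {
        k: np.full(n, theta[k], dtype=dtype) for k in _THETA_NAMES
    }
    vals["f"] = np.ones(n, dtype=dtype)
    for term, c in zip(spec.covariate_terms, coefs):
        xcov = design.covariate_array(term.covariate)
        if term.form == "power":
            mult = (xcov / term.reference) ** c
        elif term.form == "linear":
            mult = 1.0 + c * (xcov - term.reference)
        elif term.form == "exponential":
            mult = np.exp(c * (xcov - term.reference))
        else:  # categorical 0/1 indicator
            mult = 1.0 + c * xcov
        if np.any(np.real(mult) <= 0):
            return None
        vals[term.parameter] = vals[term.parameter] * mult
    for k, pname in enumerate(spec.omega_names):
        vals[pname] = vals[pname] * np.exp(etas[:, k])
    return vals


def _predict(spec, design, theta, coefs, etas) -> np.ndarray | None:
    vals = _subject_params(spec, design, theta, coefs, etas)
    if vals is None:
        return None
    with np.errstate(all="ignore"):
        return predict_conc(
            design, vals["cl"], vals["vc"], vals["q"], vals["vp"],
            vals["ka"], vals["alag"], vals["f"],
        )


def _eta_gradient_matrix(spec, design, theta, coefs, etas) -> np.ndarray:
    """dF/deta via complex step: (n, J, K)."""
    n, J = design.obs_t.shape
    K = etas.shape[1]
    F = np.empty((n, J, K))
    for k in range(K):
        ec = etas.astype(complex)
        ec[:, k] += 1j * _CSTEP
        fp = _predict(spec, design, theta, coefs, ec)
        F[:, :, k] = fp.imag / _CSTEP
    return F


def _residual_var(fp: np.ndarray, sigma_prop: float, sigma_add: float, mask) -> np.ndarray:
    fpc = np.maximum(fp, _FP_FLOOR)
    d = sigma_prop**2 * fpc**2 + sigma_add**2
    return np.where(mask, d, 1.0)


def _inner_objective(design, y, fp, sigma_prop, sigma_add, etas, omegas) -> np.ndarray:
    mask = design.obs_mask
    d = _residual_var(fp, sigma_prop, sigma_add, mask)
    e = np.where(mask, y - fp, 0.0)
    h = np.sum((e * e) / d + np.where(mask, np.log(d), 0.0), axis=1)
    h = h + np.sum(etas * etas / np.maximum(omegas, 1e-12) ** 2, axis=1)
    return h


@dataclass
class _InnerResult:
    etas: np.ndarray  # (n, K) conditional modes
    fp: np.ndarray  # predictions at the mode
    F: np.ndarray  # (n, J, K) sensitivities at the mode
    converged: np.ndarray  # (n,) bool
    n_iter: int


_ETA_CLAMP = 12.0  # |eta| bound; generating etas are O(1), this only guards blow-ups


def _inner_newton(
    spec, design, theta, coefs, omegas, sigma_prop, sigma_add,
    eta0: np.ndarray, max_iter: int = 100, gtol: float = 1e-8,
) -> _InnerResult | None:
    """Batched Levenberg-Marquardt Newton for the conditional modes.

    Gauss-Newton curvature with the exact small-residual weight
    2(1 - sigma^2)/d plus per-subject adaptive damping; rejected steps raise
    the damping instead of moving.
    """
    n = design.n_subjects
    K = len(omegas)
    y = design.y
    mask = design.obs_mask
    om2 = np.maximum(omegas, 1e-12) ** 2
    etas = np.clip(eta0, -_ETA_CLAMP, _ETA_CLAMP)
    fp = _predict(spec, design, theta, coefs, etas)
    if fp is None or not np.all(np.isfinite(fp[mask])):
        return None
    h = _inner_objective(design, y, fp, sigma_prop, sigma_add, etas, omegas)
    lam = np.zeros(n)
    eyeK = np.arange(K)
    F = np.zeros((n, design.obs_t.shape[1], K))
    active = np.ones(n, bool)
    it = 0
    for it in range(1, max_iter + 1):
        F = _eta_gradient_matrix(spec, design, theta, coefs, etas)
        d = _residual_var(fp, sigma_prop, sigma_add, mask)
        fpc = np.maximum(fp, _FP_FLOOR)
        # below the variance floor d is constant in f: no variance-derivative terms
        vmask = mask & (fp >= _FP_FLOOR)
        e = np.where(mask, y - fp, 0.0)
        s2 = sigma_prop**2
        gw = np.where(mask, -2.0 * e / d, 0.0) + np.where(
            vmask,
            -2.0 * s2 * fpc * (e * e) / (d * d) + 2.0 * s2 * fpc / d,
            0.0,
        )
        grad = np.einsum("nj,njk->nk", gw, F) + 2.0 * etas / om2
        # attainable precision is limited by eps * h; 1e-5 on the gradient maps
        # to eta errors orders of magnitude below omega
        gcut = np.maximum(gtol * np.maximum(1.0, np.abs(h)), 1e-5)
        active = np.any(np.abs(grad) > gcut[:, None], axis=1)
        if not active.any():
            return _InnerResult(etas, fp, F, np.ones(n, bool), it)
        if np.all(lam[active] > 1e8):  # numerically stagnant
            return _InnerResult(etas, fp, F, ~active, it)
        # exact d^2/df^2 of e^2/d + log d (Gauss-Newton drops only the f'' term),
        # clamped to stay positive definite
        curv = 2.0 / d + np.where(
            vmask,
            8.0 * s2 * fpc * e / (d * d)
            - 2.0 * s2 * e * e / (d * d)
            + 8.0 * s2 * s2 * fpc**2 * e * e / (d**3)
            + 2.0 * s2 / d
            - 4.0 * s2 * s2 * fpc**2 / (d * d),
            0.0,
        )
        W = np.where(mask, np.maximum(curv, 0.2 / d) / 2.0, 0.0)
        H = 2.0 * np.einsum("njk,nj,njl->nkl", F, W, F)
        H[:, eyeK, eyeK] += 2.0 / om2
        Hd = H.copy()
        Hd[:, eyeK, eyeK] *= (1.0 + lam)[:, None]
        try:
            step = -np.linalg.solve(Hd, grad[..., None])[..., 0]
        except np.linalg.LinAlgError:
            return None
        trial = np.clip(etas + np.where(active[:, None], step, 0.0), -_ETA_CLAMP, _ETA_CLAMP)
        fp_t = _predict(spec, design, theta, coefs, trial)
        if fp_t is None:
            lam = np.where(active, np.maximum(lam * 4.0, 1e-3), lam)
            continue
        with np.errstate(all="ignore"):
            h_t = _inner_objective(design, y, fp_t, sigma_prop, sigma_add, trial, omegas)
        ok = active & np.isfinite(h_t) & (h_t <= h)
        etas[ok] = trial[ok]
        h[ok] = h_t[ok]
        fp = np.where(ok[:, None], fp_t, fp)
        lam = np.where(ok, lam / 3.0, np.where(active, np.maximum(lam * 4.0, 1e-3), lam))
        lam = np.where(lam < 1e-10, 0.0, lam)
    # ran out of iterations: report which subjects still have large gradients
    return _InnerResult(etas, fp, F, ~active, it)


def _foce_ofv_from_mode(design, inner: _InnerResult, omegas, sigma_prop, sigma_add):
    """Marginal -2LL from the linearization at the conditional mode."""
    mask = design.obs_mask
    y = design.y
    fp, F, etas = inner.fp, inner.F, inner.etas
    K = len(omegas)
    om2 = np.maximum(omegas, 1e-12) ** 2
    d = _residual_var(fp, sigma_prop, sigma_add, mask)
    dinv = np.where(mask, 1.0 / d, 0.0)
    r = np.where(mask, y - fp, 0.0) + np.einsum("njk,nk->nj", F, etas) * mask
    A = np.einsum("njk,nj,njl->nkl", F, dinv, F)
    A[:, np.arange(K), np.arange(K)] += 1.0 / om2
    sign, logdetA = np.linalg.slogdet(A)
    if np.any(sign <= 0):
        return None, None
    logdet = (
        np.sum(np.where(mask, np.log(d), 0.0), axis=1)
        + np.sum(np.log(om2))
        + logdetA
    )
    FtDr = np.einsum("njk,nj->nk", F, dinv * r)
    Ainv_FtDr = np.linalg.solve(A, FtDr[..., None])[..., 0]
    Vinv_r = dinv * r - dinv * np.einsum("njk,nk->nj", F, Ainv_FtDr)
    quad = np.sum(r * Vinv_r, axis=1)
    per_subject = logdet + quad
    ofv = float(np.sum(per_subject) + mask.sum() * math.log(2.0 * math.pi))
    return ofv, per_subject


class _Objective:
    """FOCE-I objective with warm-started conditional modes."""

    def __init__(self, spec: ModelSpec, design: SubjectDesign, inner_tol: float = 1e-8):
        self.spec = spec
        self.design = design
        self.inner_tol = inner_tol
        self.K = len(spec.omegas)
        self.eta_cache = np.zeros((design.n_subjects, self.K))
        self.n_calls = 0
        self.last_inner: _InnerResult | None = None

    def __call__(self, x: np.ndarray) -> float:
        self.n_calls += 1
        theta, coefs, omegas, sigma_prop, sigma_add = _unpack(self.spec, x)
        if self.K == 0 or np.all(omegas < 1e-10):
            etas = np.zeros((self.design.n_subjects, max(self.K, 1)))
            fp = _predict(self.spec, self.design, theta, coefs, np.zeros((self.design.n_subjects, max(self.K, 1))))
            if fp is None or not np.all(np.isfinite(fp[self.design.obs_mask])):
                return _BIG
            mask = self.design.obs_mask
            d = _residual_var(fp, sigma_prop, sigma_add, mask)
            e = np.where(mask, self.design.y - fp, 0.0)
            return float(
                np.sum((e * e) / d + np.where(mask, np.log(d), 0.0))
                + mask.sum() * math.log(2.0 * math.pi)
            )
        inner = _inner_newton(
            self.spec, self.design, theta, coefs, omegas, sigma_prop, sigma_add,
            eta0=self.eta_cache, gtol=self.inner_tol,
        )
        if inner is None:
            return _BIG
        self.eta_cache = inner.etas
        self.last_inner = inner
        ofv, _ = _foce_ofv_from_mode(self.design, inner, omegas, sigma_prop, sigma_add)
        if ofv is None or not math.isfinite(ofv):
            return _BIG
        return ofv


def foce_objective(
    spec: ModelSpec, ds: PKDataset, x: np.ndarray | None = None
) -> tuple[float, pd.DataFrame]:
    """OFV and per-subject conditional eta estimates at the spec's parameters."""
    design = build_design(ds)
    obj = _Objective(spec, design)
    ofv = obj(_pack(spec) if x is None else x)
    etas = (
        obj.last_inner.etas
        if obj.last_inner is not None
        else np.zeros((design.n_subjects, max(obj.K, 1)))
    )
    eta_df = pd.DataFrame(
        etas, index=design.subject_ids,
        columns=[f"eta_{p}" for p in spec.omega_names] or ["eta"],
    )
    return ofv, eta_df


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FitOptions:
    maxiter: int = 400
    ftol: float = 1e-9
    gtol: float = 1e-2
    fd_step: float = 3e-5
    compute_se: bool = True
    hessian_step: float = 1e-2
    condition_number_scale: str = "correlation"  # or 'covariance'
    staged: bool = True  # naive-pooled pre-fit of the fixed effects first


@dataclass
class EstimationResult:
    spec: ModelSpec
    estimates: dict[str, float]
    x: np.ndarray  # transformed optimum
    ofv: float
    converged: bool
    n_subjects: int
    n_obs: int
    se: dict[str, float] | None = None
    rse_percent: dict[str, float] | None = None
    covariance: pd.DataFrame | None = None
    condition_number: float | None = None
    etas: pd.DataFrame | None = None
    shrinkage: dict[str, float] | None = None
    message: str = ""

    @property
    def aic(self) -> float:
        return self.ofv + 2 * self.spec.n_parameters

    def to_fixed_effects(self) -> FixedEffects:
        """Map a final-structure estimate back onto FixedEffects."""
        est = self.estimates
        get = lambda lbl, dflt: est.get(lbl, dflt)
        return FixedEffects(
            cl_typ=est["cl"], vc_typ=est["vc"], q_typ=est["q"], vp_typ=est["vp"],
            ka=est["ka"], alag=est["alag"],
            f_nf1=1.0 + get("f~cancer_type", 0.0),
            exp_cl_bsa=get("cl~bsa", 0.0), exp_q_bsa=get("q~bsa", 0.0),
            exp_vp_bsa=get("vp~bsa", 0.0), exp_vc_bsa=get("vc~bsa", 0.0),
            exp_vc_tp=get("vc~tp", 0.0),
            frac_vp_female=get("vp~sex", 0.0),
        )

    def to_random_effects(self) -> RandomEffects:
        est = self.estimates
        return RandomEffects(
            omega_cl=est.get("omega_cl", 0.0), omega_vc=est.get("omega_vc", 0.0),
            omega_q=est.get("omega_q", 0.0), omega_vp=est.get("omega_vp", 0.0),
            sigma_prop=est["sigma_prop"], sigma_add=est.get("sigma_add", 0.0),
        )


def _fd_hessian(fun, x: np.ndarray, step: float) -> np.ndarray:
    k = len(x)
    H = np.empty((k, k))
    f0 = fun(x)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = step
        fpp = fun(x + 2 * ei)
        fmm = fun(x - 2 * ei)
        H[i, i] = (fpp - 2 * f0 + fmm) / (4 * step * step)
    for i in range(k):
        for j in range(i + 1, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = step
            ej[j] = step
            H[i, j] = H[j, i] = (
                fun(x + ei + ej) - fun(x + ei - ej) - fun(x - ei + ej) + fun(x - ei - ej)
            ) / (4 * step * step)
    return H


def fit(
    spec: ModelSpec,
    ds: PKDataset,
    init: np.ndarray | None = None,
    options: FitOptions | None = None,
) -> EstimationResult:
    """Minimize the FOCE-I objective; see :class:`FitOptions` for tolerances."""
    options = options or FitOptions()
    design = build_design(ds)
    if design.n_subjects < 2:
        raise ValueError("fit requires at least 2 subjects")
    x0 = _pack(spec) if init is None else np.asarray(init, float)
    if options.staged and spec.omegas and init is None:
        # stage 1: naive-pooled fit (eta = 0) localizes the fixed effects;
        # standard initial-estimate practice before a conditional fit
        pooled_spec = replace(spec, omegas={})
        pooled = fit(
            pooled_spec, ds,
            options=replace(options, staged=False, compute_se=False),
        )
        nfix = len(spec.thetas) + len(spec.covariate_terms)
        x0 = x0.copy()
        x0[:nfix] = pooled.x[:nfix]
    obj = _Objective(spec, design)
    from ._engine import time_after_dose

    min_tad = float(np.min(time_after_dose(design)[design.obs_mask]))
    res = optimize.minimize(
        obj, x0, method="L-BFGS-B",
        bounds=_bounds(spec, alag_hi=0.95 * min_tad if min_tad > 0 else None),
        options={
            "maxiter": options.maxiter,
            "ftol": options.ftol,
            "gtol": options.gtol,
            "maxcor": 20,
            # FD step large enough to dominate the inner-optimization noise
            "eps": options.fd_step,
        },
    )
    x_hat = res.x
    ofv = obj(x_hat)  # refresh cache at the optimum
    estimates = _natural_values(spec, x_hat)
    labels = spec.parameter_labels()
    se = rse = cov_df = None
    cond = None
    message = str(res.message)
    converged = bool(res.success)
    if options.compute_se:
        H = _fd_hessian(obj, x_hat, options.hessian_step)
        try:
            eigvals = np.linalg.eigvalsh(H)
            if np.min(eigvals) <= 0:
                raise np.linalg.LinAlgError("Hessian not positive definite")
            cov_x = 2.0 * np.linalg.inv(H)
            jac = _natural_jacobian(spec, x_hat)
            cov_nat = cov_x * np.outer(jac, jac)
            cov_df = pd.DataFrame(cov_nat, index=labels, columns=labels)
            sd = np.sqrt(np.diag(cov_nat))
            se = dict(zip(labels, sd))
            rse = {
                lbl: (100.0 * s / abs(estimates[lbl]) if estimates[lbl] != 0 else math.inf)
                for lbl, s in se.items()
            }
            nfix = len(spec.thetas) + len(spec.covariate_terms)
            block = cov_nat[:nfix, :nfix]
            if options.condition_number_scale == "correlation":
                d = np.sqrt(np.diag(block))
                block = block / np.outer(d, d)
            ev = np.linalg.eigvalsh(block)
            cond = float(ev.max() / ev.min()) if ev.min() > 0 else math.inf
        except np.linalg.LinAlgError as exc:
            message += f"; covariance step failed ({exc})"
    eta_df = None
    shrink = None
    if obj.last_inner is not None and len(spec.omegas) > 0:
        eta_df = pd.DataFrame(
            obj.last_inner.etas, index=design.subject_ids,
            columns=[f"eta_{p}" for p in spec.omega_names],
        )
        _, _, omegas, _, _ = _unpack(spec, x_hat)
        shrink = {}
        for k, p in enumerate(spec.omega_names):
            if omegas[k] < 1e-8:
                shrink[p] = None
            else:
                shrink[p] = float(1.0 - np.std(obj.last_inner.etas[:, k], ddof=1) / omegas[k])
    return EstimationResult(
        spec=spec, estimates=estimates, x=x_hat, ofv=float(ofv), converged=converged,
        n_subjects=design.n_subjects, n_obs=design.n_obs,
        se=se, rse_percent=rse, covariance=cov_df, condition_number=cond,
        etas=eta_df, shrinkage=shrink, message=message,
    )


def perturb_spec(spec: ModelSpec, rng: np.random.Generator, frac: float = 0.3) -> ModelSpec:
    """Multiplicatively perturb all initial values by U(1-frac, 1+frac)."""
    u = lambda: rng.uniform(1.0 - frac, 1.0 + frac)
    thetas = {k: v * u() for k, v in spec.thetas.items()}
    terms = [replace(t, init=t.init * u()) for t in spec.covariate_terms]
    omegas = {k: v * u() for k, v in spec.omegas.items()}
    return replace(
        spec, thetas=thetas, covariate_terms=terms, omegas=omegas,
        sigma_prop=spec.sigma_prop * u(),
        sigma_add=None if spec.sigma_add is None else spec.sigma_add * u(),
    )


# ---------------------------------------------------------------------------
# diagnostics


def diagnostics(res: EstimationResult, ds: PKDataset) -> tuple[pd.DataFrame, dict]:
    """PRED, IPRED, IWRES and CWRES per observation, plus eta shrinkage.

    CWRES standardizes the FOCE residual y - (f(etahat) - G etahat) by the
    model-implied marginal covariance expanded at the conditional mode.
    """
    design = build_design(ds)
    spec = res.spec
    theta, coefs, omegas, sigma_prop, sigma_add = _unpack(spec, res.x)
    K = len(omegas)
    zeros = np.zeros((design.n_subjects, max(K, 1)))
    pred = _predict(spec, design, theta, coefs, zeros)
    obj = _Objective(spec, design)
    obj(res.x)
    inner = obj.last_inner
    if inner is None:
        raise ValueError("diagnostics require a converged estimation result")
    ipred = inner.fp
    mask = design.obs_mask
    d = _residual_var(ipred, sigma_prop, sigma_add, mask)
    iwres = np.where(mask, (design.y - ipred) / np.sqrt(d), np.nan)
    cwres = np.full_like(ipred, np.nan)
    om2 = np.maximum(omegas, 1e-12) ** 2
    for i in range(design.n_subjects):
        m = mask[i]
        G = inner.F[i][m]
        V = np.diag(d[i][m]) + G @ np.diag(om2) @ G.T
        L = np.linalg.cholesky(V)
        resid = design.y[i][m] - (ipred[i][m] - G @ inner.etas[i])
        cwres[i][m] = np.linalg.solve(L, resid)
    rows = []
    for i, sid in enumerate(design.subject_ids):
        for j in np.nonzero(mask[i])[0]:
            rows.append(
                {
                    "subject": sid,
                    "time": design.obs_t[i, j],
                    "dv": design.y[i, j],
                    "pred": pred[i, j],
                    "ipred": ipred[i, j],
                    "iwres": iwres[i, j],
                    "cwres": cwres[i, j],
                }
            )
    table = pd.DataFrame(rows)
    shrink = {}
    for k, p in enumerate(spec.omega_names):
        if omegas[k] < 1e-8:
            shrink[p] = None
        else:
            shrink[p] = float(1.0 - np.std(inner.etas[:, k], ddof=1) / omegas[k])
    return table, shrink


def reassess_iiv(
    res: EstimationResult,
    ds: PKDataset,
    options: FitOptions | None = None,
    omega_floor: float = 1e-3,
    rse_cut: float = 200.0,
) -> EstimationResult:
    """Post-covariate-search IIV pruning: drop random effects that are
    estimated near zero or with extreme imprecision, then refit once."""
    drop = set()
    for name in res.spec.omegas:
        label = f"omega_{name}"
        if res.estimates.get(label, 1.0) < omega_floor:
            drop.add(name)
        elif res.rse_percent and res.rse_percent.get(label, 0.0) > rse_cut:
            drop.add(name)
    if not drop:
        return res
    new_spec = replace(
        res.spec,
        thetas={k: res.estimates[k] for k in res.spec.thetas},
        covariate_terms=[
            replace(t, init=res.estimates[t.label]) for t in res.spec.covariate_terms
        ],
        omegas={
            k: res.estimates[f"omega_{k}"]
            for k in res.spec.omegas
            if k not in drop
        },
        sigma_prop=res.estimates["sigma_prop"],
    )
    return fit(new_spec, ds, options=options)


# ---------------------------------------------------------------------------
# stepwise covariate search


@dataclass(frozen=True)
class StepwiseStep:
    phase: str  # 'forward' or 'backward'
    term: str
    delta_ofv: float | None
    decision: str
    reason: str = ""


@dataclass
class StepwiseLog:
    steps: list[StepwiseStep] = field(default_factory=list)

    def record(self, *args, **kwargs) -> None:
        self.steps.append(StepwiseStep(*args, **kwargs))


def _categorical_frequency_ok(design: SubjectDesign, covariate: str, min_frac: float = 0.10) -> bool:
    x = design.covariate_array(covariate)
    p = float(np.mean(x))
    return min(p, 1.0 - p) >= min_frac


def stepwise_search(
    base: ModelSpec,
    candidates: list[CovariateTerm],
    ds: PKDataset,
    options: FitOptions | None = None,
    forward_alpha: float = 0.05,
    backward_alpha: float = 0.01,
) -> tuple[ModelSpec, EstimationResult, StepwiseLog]:
    """Forward inclusion (chi^2 p<0.05) then backward elimination (p<0.01).

    Each candidate adds one coefficient (df 1).  Categorical candidates whose
    minority level holds less than 10% of subjects are excluded up front with
    a logged reason.  Locked terms of the base spec are never tested.
    """
    options = options or FitOptions(compute_se=False)
    design = build_design(ds)
    for cand in candidates:
        try:
            design.covariate_array(cand.covariate)
        except KeyError as exc:
            raise ValueError(str(exc)) from exc
    log = StepwiseLog()
    fwd_cut = float(stats.chi2.ppf(1 - forward_alpha, 1))
    bwd_cut = float(stats.chi2.ppf(1 - backward_alpha, 1))
    pool = []
    for cand in candidates:
        if cand.form == "categorical" and not _categorical_frequency_ok(design, cand.covariate):
            log.record("forward", cand.label, None, "excluded",
                       "minority level below 10% of subjects")
        else:
            pool.append(cand)
    current_spec = base
    current_fit = fit(base, ds, options=options)
    while pool:
        results = []
        for cand in pool:
            trial = fit(current_spec.with_term(cand), ds, options=options)
            d_ofv = current_fit.ofv - trial.ofv
            results.append((d_ofv, cand, trial))
            log.record("forward", cand.label, d_ofv,
                       "tested" if d_ofv > fwd_cut else "rejected")
        results.sort(key=lambda r: -r[0])
        best_d, best_cand, best_fit_res = results[0]
        if best_d <= fwd_cut:
            break
        log.record("forward", best_cand.label, best_d, "included")
        current_spec = best_fit_res.spec
        current_fit = best_fit_res
        pool = [c for c in pool if c is not best_cand]
    # backward elimination over unlocked terms that came from the candidates
    while True:
        removable = [t for t in current_spec.covariate_terms if not t.locked]
        if not removable:
            break
        trials = []
        for term in removable:
            reduced = fit(current_spec.without_term(term), ds, options=options)
            rise = reduced.ofv - current_fit.ofv
            trials.append((rise, term, reduced))
        trials.sort(key=lambda r: r[0])
        rise, term, reduced = trials[0]
        if rise < bwd_cut:
            log.record("backward", term.label, rise, "removed")
            current_spec = reduced.spec
            current_fit = reduced
        else:
            for rise_i, term_i, _ in trials:
                log.record("backward", term_i.label, rise_i, "retained")
            break
    return current_spec, current_fit, log
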