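"""Vectorized multi-subject prediction engine.

Converts a :class:`~fcn159pk.datamodel.PKDataset` into padded arrays (one row
per subject) and evaluates the closed-form two-compartment lagged-absorption
profile for all subjects and observations at once.  Repeated equal doses are
collapsed into "dose trains" (start, interval, count, amount) so that the
superposition over doses becomes a stabilized geometric sum — every
exponential argument is non-positive, so the evaluation cannot overflow no
matter how long the dosing history is.

The evaluator is polymorphic in dtype: complex inputs propagate, which the
estimation module exploits for complex-step derivatives with respect to the
random effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import PKDataset

__all__ = [
    "SubjectDesign",
    "build_design",
    "predict_conc",
    "individual_param_arrays",
    "time_after_dose",
]

_MAX_EXP = 700.0  # exp underflow guard on the negative side


@dataclass
class SubjectDesign:
    """Padded per-subject arrays describing doses, observations, covariates."""

    subject_ids: list[str]
    obs_t: np.ndarray  # (n, J) h
    obs_mask: np.ndarray  # (n, J) bool
    y: np.ndarray  # (n, J) ng/mL, NaN where masked
    train_start: np.ndarray  # (n, T) h
    train_tau: np.ndarray  # (n, T) h
    train_n: np.ndarray  # (n, T) int
    train_amt: np.ndarray  # (n, T) mg
    train_mask: np.ndarray  # (n, T) bool
    bsa: np.ndarray  # (n,)
    tp: np.ndarray  # (n,)
    female: np.ndarray  # (n,) 0/1
    nf1: np.ndarray  # (n,) 0/1
    age: np.ndarray  # (n,)
    albumin: np.ndarray  # (n,)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_obs(self) -> int:
        return int(self.obs_mask.sum())

    def covariate_array(self, name: str) -> np.ndarray:
        mapping = {
            "bsa": self.bsa,
            "tp": self.tp,
            "sex": self.female,
            "cancer_type": self.nf1,
            "age": self.age,
            "albumin": self.albumin,
        }
        try:
            return mapping[name]
        except KeyError:
            raise KeyError(f"unknown covariate {name!r}") from None


def _doses_to_trains(times: list[float], amts: list[float], rtol: float = 1e-9):
    """Run-length encode a dose list into (start, tau, n, amt) trains."""
    trains: list[tuple[float, float, int, float]] = []
    i = 0
    while i < len(times):
        start, amt = times[i], amts[i]
        j = i + 1
        if j < len(times) and abs(amts[j] - amt) <= rtol * max(amt, 1.0):
            tau = times[j] - times[i]
            if tau > 0:
                while (
                    j + 1 < len(times)
                    and abs(amts[j + 1] - amt) <= rtol * max(amt, 1.0)
                    and abs((times[j + 1] - times[j]) - tau) <= 1e-9 * max(tau, 1.0)
                ):
                    j += 1
                trains.append((start, tau, j - i + 1, amt))
                i = j + 1
                continue
        trains.append((start, 24.0, 1, amt))
        i += 1
    return trains


def build_design(ds: PKDataset, require_covariates: bool = True) -> SubjectDesign:
    """Pack a dataset into padded arrays; observations must carry a DV."""
    ids = ds.subject_ids
    per_obs_t: dict[str, list[float]] = {s: [] for s in ids}
    per_obs_y: dict[str, list[float]] = {s: [] for s in ids}
    per_dose_t: dict[str, list[float]] = {s: [] for s in ids}
    per_dose_a: dict[str, list[float]] = {s: [] for s in ids}
    cov: dict[str, object] = {}
    for rec in ds.records:
        cov.setdefault(rec.subject_id, rec.covariates)
        if rec.is_dose:
            per_dose_t[rec.subject_id].append(rec.time)
            per_dose_a[rec.subject_id].append(rec.amt)
        elif rec.mdv == 0 and rec.dv is not None:
            per_obs_t[rec.subject_id].append(rec.time)
            per_obs_y[rec.subject_id].append(rec.dv)
    trains = {s: _doses_to_trains(per_dose_t[s], per_dose_a[s]) for s in ids}
    n = len(ids)
    J = max((len(v) for v in per_obs_t.values()), default=0)
    T = max((len(v) for v in trains.values()), default=0)
    if J == 0:
        raise ValueError("dataset has no usable observations")
    if T == 0:
        raise ValueError("dataset has no dose records")
    obs_t = np.zeros((n, J))
    obs_mask = np.zeros((n, J), bool)
    y = np.full((n, J), np.nan)
    tr_start = np.zeros((n, T))
    tr_tau = np.full((n, T), 24.0)
    tr_n = np.zeros((n, T), int)
    tr_amt = np.zeros((n, T))
    tr_mask = np.zeros((n, T), bool)
    for i, s in enumerate(ids):
        k = len(per_obs_t[s])
        obs_t[i, :k] = per_obs_t[s]
        y[i, :k] = per_obs_y[s]
        obs_mask[i, :k] = True
        for t_idx, (start, tau, nd, amt) in enumerate(trains[s]):
            tr_start[i, t_idx] = start
            tr_tau[i, t_idx] = tau
            tr_n[i, t_idx] = nd
            tr_amt[i, t_idx] = amt
            tr_mask[i, t_idx] = True

    def cov_arr(attr, default=np.nan):
        out = np.full(n, default, float)
        for i, s in enumerate(ids):
            v = getattr(cov[s], attr)
            if attr == "sex":
                v = None if v is None else (1.0 if v == "female" else 0.0)
            elif attr == "cancer_type":
                v = None if v is None else (1.0 if v == "nf1" else 0.0)
            if v is not None:
                out[i] = v
        return out

    bsa = cov_arr("bsa")
    tp = cov_arr("tp")
    female = cov_arr("sex")
    nf1 = cov_arr("cancer_type")
    if require_covariates and (np.isnan(bsa).any() or np.isnan(tp).any()
                               or np.isnan(female).any() or np.isnan(nf1).any()):
        raise ValueError("model application requires complete bsa, tp, sex, cancer_type")
    return SubjectDesign(
        subject_ids=ids,
        obs_t=obs_t,
        obs_mask=obs_mask,
        y=y,
        train_start=tr_start,
        train_tau=tr_tau,
        train_n=tr_n,
        train_amt=tr_amt,
        train_mask=tr_mask,
        bsa=bsa,
        tp=tp,
        female=female,
        nf1=nf1,
        age=cov_arr("age"),
        albumin=cov_arr("albumin"),
    )


def _nexp(x: np.ndarray) -> np.ndarray:
    """exp(-x) for x with non-negative real part, underflow-guarded."""
    if np.iscomplexobj(x):
        re = np.clip(x.real, 0.0, _MAX_EXP)
        return np.exp(-(re + 1j * x.imag))
    return np.exp(-np.clip(x, 0.0, _MAX_EXP))


def predict_conc(
    design: SubjectDesign,
    cl: np.ndarray,
    vc: np.ndarray,
    q: np.ndarray,
    vp: np.ndarray,
    ka: np.ndarray,
    alag: np.ndarray,
    f: np.ndarray,
) -> np.ndarray:
    """Model-predicted concentration (ng/mL) for every (subject, observation).

    All parameter arrays are (n,) and may be complex; masked entries of the
    output are zero.
    """
    k10 = cl / vc
    k12 = q / vc
    k21 = q / vp
    s = k10 + k12 + k21
    prod = k10 * k21
    disc2 = s * s - 4.0 * prod
    if np.iscomplexobj(disc2):
        disc = np.sqrt(disc2)
    else:
        disc = np.sqrt(np.maximum(disc2, 0.0))
    alpha = (s + disc) / 2.0
    beta = (s - disc) / 2.0
    ca = (k21 - alpha) / ((ka - alpha) * (beta - alpha))
    cb = (k21 - beta) / ((ka - beta) * (alpha - beta))
    ck = (k21 - ka) / ((alpha - ka) * (beta - ka))
    lam = np.stack([alpha, beta, ka], axis=-1)  # (n, 3)
    coef = np.stack([ca, cb, ck], axis=-1)  # (n, 3)

    # (n, J, T): time from each train start to each observation, minus lag
    rel = (
        design.obs_t[:, :, None]
        - design.train_start[:, None, :]
        - np.real(alag)[:, None, None]
    )
    tau = design.train_tau[:, None, :]
    m = np.floor(rel / tau) + 1
    m = np.clip(m, 0, design.train_n[:, None, :])
    active = (m >= 1) & design.train_mask[:, None, :] & design.obs_mask[:, :, None]
    u = np.where(active, rel - (m - 1) * tau, 0.0)  # h since last contributing dose
    if np.iscomplexobj(alag):
        u = u - (alag[:, None, None] - np.real(alag)[:, None, None])

    lam4 = lam[:, None, None, :]  # (n,1,1,3)
    geom = (
        _nexp(lam4 * u[..., None])
        * (1.0 - _nexp(lam4 * (m * tau)[..., None]))
        / (1.0 - _nexp(lam4 * tau[..., None]))
    )
    terms = np.einsum("nk,njtk->njt", coef, geom)
    dose_sum = np.sum(np.where(active, terms, 0.0) * design.train_amt[:, None, :], axis=-1)
    scale = (f * ka / vc * 1000.0)[:, None]  # mg -> ug => ug/L = ng/mL
    return scale * dose_sum * design.obs_mask


def time_after_dose(design: SubjectDesign) -> np.ndarray:
    """(n, J) hours since the most recent dose; +inf for pre-first-dose/padded."""
    n, J = design.obs_t.shape
    tad = np.full((n, J), np.inf)
    for i in range(n):
        starts = design.train_start[i][design.train_mask[i]]
        taus = design.train_tau[i][design.train_mask[i]]
        nds = design.train_n[i][design.train_mask[i]]
        dose_times = np.concatenate(
            [s + t * np.arange(nd) for s, t, nd in zip(starts, taus, nds)]
        )
        dose_times.sort()
        # side='left': a sample at exactly a dose time precedes that dose
        idx = np.searchsorted(dose_times, design.obs_t[i], side="left") - 1
        ok = idx >= 0
        tad[i, ok] = design.obs_t[i, ok] - dose_times[idx[ok]]
        tad[i][~design.obs_mask[i]] = np.inf
    return tad


def individual_param_arrays(fe, design: SubjectDesign, etas: np.ndarray) -> dict[str, np.ndarray]:
    """Final-model individual parameters for every subject in ``design``.

    ``etas`` is (n, 4) ordered (cl, vc, q, vp); entries may be complex.
    """
    b = design.bsa / fe.bsa_ref
    e = np.exp(etas) if not np.iscomplexobj(etas) else np.exp(etas)
    cl = fe.cl_typ * e[:, 0] * b**fe.exp_cl_bsa
    vc = fe.vc_typ * e[:, 1] * b**fe.exp_vc_bsa * (design.tp / fe.tp_ref) ** fe.exp_vc_tp
    q = fe.q_typ * e[:, 2] * b**fe.exp_q_bsa
    vp = fe.vp_typ * e[:, 3] * b**fe.exp_vp_bsa * (1 + fe.frac_vp_female * design.female)
    n = design.n_subjects
    ones = np.ones(n)
    return {
        "cl": cl,
        "vc": vc,
        "q": q,
        "vp": vp,
        "ka": fe.ka * ones,
        "alag": fe.alag * ones,
        "f": 1.0 + (fe.f_nf1 - 1.0) * design.nf1,
    }
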