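"""Stochastic population simulation: IIV sampling, residual error, replicates.

Random-number discipline: every subject gets a named substream derived from
(seed, replicate, subject index) so populations are stable when the number of
replicates or subjects changes, and all outputs are bit-reproducible given
(seed, config).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from ._engine import build_design, predict_conc, individual_param_arrays
from .datamodel import CovariateVector, PKDataset, PKRecord
from .model import (
    FixedEffects,
    IndividualParameters,
    RandomEffects,
    Regimen,
    apply_covariates,
    exposure,
)

__all__ = [
    "SimulationConfig",
    "SimulatedPopulation",
    "ReplicateSet",
    "sample_population",
    "simulate_observations",
    "simulate_replicates",
]


@dataclass
class SimulationConfig:
    n_subjects: int
    seed: int
    regimen: Regimen
    observation_times: Sequence[float] = ()
    include_residual: bool = False
    covariate_source: str = "parametric-generator"  # or 'fixed', 'resample-from-dataset'
    fixed_covariates: CovariateVector | None = None
    resample_dataset: PKDataset | None = None
    population_spec: "PopulationSpec | None" = None  # type: ignore[name-defined]
    lloq: float | None = None  # flag observations below this as BQL

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if any(t < 0 for t in self.observation_times):
            raise ValueError("observation_times must be non-negative")
        allowed = {"parametric-generator", "fixed", "resample-from-dataset"}
        if self.covariate_source not in allowed:
            raise ValueError(f"covariate_source must be one of {sorted(allowed)}")


@dataclass
class SimulatedPopulation:
    subjects: pd.DataFrame  # one row per subject: covariates, etas, parameters, exposures
    observations: pd.DataFrame | None = None  # time, true & observed concentration

    def __len__(self) -> int:
        return len(self.subjects)


def _subject_rng(seed: int, index: int, replicate: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, replicate, index]))


def _resolve_covariates(config: SimulationConfig) -> list[CovariateVector]:
    if config.covariate_source == "fixed":
        if config.fixed_covariates is None:
            raise ValueError("fixed covariate_source requires fixed_covariates")
        return [config.fixed_covariates] * config.n_subjects
    if config.covariate_source == "resample-from-dataset":
        if config.resample_dataset is None:
            raise ValueError("resample-from-dataset requires resample_dataset")
        pool: list[CovariateVector] = []
        seen = set()
        for rec in config.resample_dataset.records:
            if rec.subject_id not in seen:
                seen.add(rec.subject_id)
                pool.append(rec.covariates)
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 911]))
        idx = rng.integers(0, len(pool), config.n_subjects)
        return [pool[i] for i in idx]
    from .synthetic import PopulationSpec, generate_population

    spec = config.population_spec or PopulationSpec(n=config.n_subjects)
    if spec.n != config.n_subjects:
        raise ValueError("population_spec.n must equal n_subjects")
    return generate_population(spec, seed=config.seed)


def sample_population(
    fe: FixedEffects, re: RandomEffects, config: SimulationConfig
) -> SimulatedPopulation:
    """Draw a virtual population and its steady-state exposure metrics.

    eta_k ~ N(0, omega_k^2) independently (diagonal Omega); parameters via the
    covariate submodel; exposure at ``config.regimen``.
    """
    covs = _resolve_covariates(config)
    omegas = re.omegas
    rows = []
    for i, cov in enumerate(covs):
        rng = _subject_rng(config.seed, i)
        eta = rng.normal(0.0, 1.0, 4) * omegas
        p = apply_covariates(fe, cov, eta)
        rows.append(
            {
                "subject": i,
                "bsa": cov.bsa,
                "tp": cov.tp,
                "sex": cov.sex,
                "cancer_type": cov.cancer_type,
                "age": cov.age,
                "eta_cl": eta[0],
                "eta_vc": eta[1],
                "eta_q": eta[2],
                "eta_vp": eta[3],
                "cl": p.cl,
                "vc": p.vc,
                "q": p.q,
                "vp": p.vp,
                "ka": p.ka,
                "alag": p.alag,
                "f": p.f,
            }
        )
    subjects = pd.DataFrame(rows)
    from .model import exposure_batch

    auc, cmax, tmax = exposure_batch(
        subjects["cl"].to_numpy(), subjects["vc"].to_numpy(), subjects["q"].to_numpy(),
        subjects["vp"].to_numpy(), subjects["ka"].to_numpy(), subjects["alag"].to_numpy(),
        subjects["f"].to_numpy(), config.regimen.dose, tau=config.regimen.tau,
    )
    subjects["auc24_ss"] = auc
    subjects["cmax_ss"] = cmax
    subjects["tmax_ss"] = tmax
    observations = None
    if config.observation_times:
        observations = simulate_observations(
            SimulatedPopulation(subjects), re, config.observation_times, config.seed,
            regimen=config.regimen,
            include_residual=config.include_residual,
            lloq=config.lloq,
        )
    return SimulatedPopulation(subjects=subjects, observations=observations)


def simulate_observations(
    pop: SimulatedPopulation,
    re: RandomEffects,
    times: Sequence[float],
    seed: int,
    regimen: Regimen | None = None,
    include_residual: bool = True,
    lloq: float | None = None,
) -> pd.DataFrame:
    """Observation table for a simulated population at steady state.

    observed = true * (1 + eps), eps ~ N(0, sigma_prop^2) independent per
    observation; negative observed values are floored at zero and flagged.
    """
    if regimen is None:
        raise ValueError("regimen is required")
    from .model import concentration

    times = np.asarray(list(times), float)
    rows = []
    for i, row in pop.subjects.iterrows():
        p = IndividualParameters(
            cl=row["cl"], vc=row["vc"], q=row["q"], vp=row["vp"],
            ka=row["ka"], alag=row["alag"], f=row["f"],
        )
        reg = Regimen(dose=regimen.dose, tau=regimen.tau, n_doses=regimen.n_doses)
        true = concentration(p, reg, times)
        rng = _subject_rng(seed, int(row["subject"]), replicate=1)
        if include_residual and re.sigma_prop > 0:
            obs = true * (1.0 + re.sigma_prop * rng.normal(0.0, 1.0, len(times)))
        else:
            obs = true.copy()
        floored = obs < 0
        obs = np.maximum(obs, 0.0)
        for t, tv, ov, fl in zip(times, true, obs, floored):
            rows.append(
                {
                    "subject": int(row["subject"]),
                    "time": float(t),
                    "true_conc": float(tv),
                    "observed": float(ov),
                    "floored": bool(fl),
                    "bql": bool(lloq is not None and ov < lloq),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class ReplicateSet:
    """Replicated simulated datasets sharing one design, in long format.

    ``table`` has columns replicate, subject, time, tad, dose_group, study,
    dv; :meth:`iter_datasets` lazily yields one :class:`PKDataset` per
    replicate for consumers that want the record API.
    """

    table: pd.DataFrame
    template: PKDataset

    @property
    def n_replicates(self) -> int:
        return int(self.table["replicate"].nunique())

    def iter_datasets(self) -> Iterator[PKDataset]:
        cov_by_subject = {}
        doses_by_subject: dict[str, list[PKRecord]] = {}
        for rec in self.template.records:
            cov_by_subject.setdefault(rec.subject_id, rec.covariates)
            if rec.is_dose:
                doses_by_subject.setdefault(rec.subject_id, []).append(rec)
        for rep, grp in self.table.groupby("replicate"):
            records: list[tuple] = []
            for sid, sub in grp.groupby("subject"):
                for rec in doses_by_subject.get(sid, []):
                    records.append((rec.time, 1, rec))
                for _, row in sub.iterrows():
                    records.append(
                        (
                            row["time"],
                            0,
                            PKRecord(
                                sid, row["time"], 0.0, 0, float(row["dv"]), 0,
                                float(row["dv"]) < self.template.lloq,
                                cov_by_subject[sid],
                            ),
                        )
                    )
            records.sort(key=lambda e: (e[2].subject_id, e[0], -e[1]))
            yield PKDataset([r for _, _, r in records], lloq=self.template.lloq)


def simulate_replicates(
    template: PKDataset,
    fe: FixedEffects,
    re: RandomEffects,
    n_rep: int,
    seed: int,
) -> ReplicateSet:
    """Simulate ``n_rep`` datasets with the template's design and covariates.

    Fresh eta per (replicate, subject) and fresh eps per observation; the
    replicate index is recorded in the output table.
    """
    if not any(r.is_dose for r in template.records):
        raise ValueError("template has no dose records")
    design = build_design(template)
    n = design.n_subjects
    omegas = re.omegas

    # time-after-dose and dose group for each observation, from the template
    from ._engine import time_after_dose

    tad = time_after_dose(design)
    dose_group = np.array(
        [design.train_amt[i][design.train_mask[i]][0] for i in range(n)]
    )

    frames = []
    for rep in range(n_rep):
        etas = np.empty((n, 4))
        eps = np.empty_like(design.obs_t)
        for i in range(n):
            rng = _subject_rng(seed, i, replicate=rep + 1)
            etas[i] = rng.normal(0.0, 1.0, 4) * omegas
            eps[i] = rng.normal(0.0, 1.0, design.obs_t.shape[1])
        params = individual_param_arrays(fe, design, etas)
        true = predict_conc(design, **params)
        dv = true * (1.0 + re.sigma_prop * eps)
        if re.sigma_add > 0:
            add_rng = _subject_rng(seed, n + 1, replicate=rep + 1)
            dv = dv + re.sigma_add * add_rng.normal(0.0, 1.0, dv.shape)
        dv = np.maximum(dv, 0.0)
        mask = design.obs_mask
        sub_idx, obs_idx = np.nonzero(mask)
        frames.append(
            pd.DataFrame(
                {
                    "replicate": rep,
                    "subject": [design.subject_ids[i] for i in sub_idx],
                    "time": design.obs_t[mask],
                    "tad": tad[mask],
                    "dose_group": dose_group[sub_idx],
                    "study": ["nf1" if design.nf1[i] else "melanoma" for i in sub_idx],
                    "dv": dv[mask],
                }
            )
        )
    return ReplicateSet(table=pd.concat(frames, ignore_index=True), template=template)
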