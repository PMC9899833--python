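"""Virtual study generator emulating the two adult trials.

FCN-159-001: 33 melanoma patients, QD doses 0.2-15 mg with a single-dose PK
run-in (72 h washout) before continuous QD dosing (21 days for the 0.2-4 mg
arms, 28 days for 6-15 mg).  FCN-159-002: 12 NF1 adults, QD 4-12 mg for
28 days.  Demographics follow the reported adult ranges: BSA truncated normal
(mean 1.66 m^2, bounds 1.33-2.16), age uniform 20-71 y, total protein normal
around the 68.95 g/L median.  Observations carry lognormal between-subject
variability and proportional residual error from the final model; values below
the 0.2 ng/mL LLOQ are flagged BQL.

``fixture_mode`` reproduces the published dataset bookkeeping exactly: 45
subjects, 1090 observation rows of which exactly 60 are BQL.  The schedule is
densified to 1089 rows plus one deterministic pad sample, and borderline
values are nudged across the LLOQ deterministically to land on 60 BQL rows;
BQL rows are excluded before any estimation, so the nudge never touches
analyzed data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datamodel import CovariateVector, PKDataset, PKRecord, DEFAULT_LLOQ
from .model import FixedEffects, RandomEffects, apply_covariates

__all__ = [
    "Arm",
    "StudyDesign",
    "PopulationSpec",
    "generate_population",
    "generate_study_dataset",
    "default_designs",
    "default_population_spec",
    "load_designs",
]


@dataclass(frozen=True)
class Arm:
    dose: float  # mg
    n_subjects: int
    qd_days: int  # continuous QD duration
    run_in: bool  # single-dose PK run-in with 72 h washout before QD


@dataclass
class StudyDesign:
    """Dose arms plus sampling schedule for one study."""

    label: str
    cancer_type: str  # 'melanoma' or 'nf1'
    arms: list[Arm]
    # sampling offsets in h
    run_in_times: list[float] = field(default_factory=list)  # post single dose
    day1_times: list[float] = field(default_factory=list)  # post first QD dose
    trough_days: list[int] = field(default_factory=list)  # QD day numbers (pre-dose)
    last_day_times: list[float] = field(default_factory=list)  # post last-day dose

    @property
    def n_subjects(self) -> int:
        return sum(a.n_subjects for a in self.arms)


@dataclass
class PopulationSpec:
    """Parametric adult covariate generator."""

    n: int
    cancer_type: str = "melanoma"
    bsa_mean: float = 1.66
    bsa_sd: float = 0.20
    bsa_bounds: tuple[float, float] = (1.33, 2.16)
    age_bounds: tuple[float, float] = (20.0, 71.0)
    tp_mean: float = 68.95
    tp_sd: float = 4.83  # puts the 95th percentile near 76.89 g/L
    alb_mean: float = 40.0
    alb_sd: float = 4.0
    female_fraction: float = 0.4

    def __post_init__(self) -> None:
        lo, hi = self.bsa_bounds
        if not (lo < hi):
            raise ValueError("bsa bounds must be increasing")
        if hi < self.bsa_mean - 6 * self.bsa_sd or lo > self.bsa_mean + 6 * self.bsa_sd:
            raise ValueError("bsa truncation bounds exclude mean +/- 6 sd")


def load_designs(path: str | None = None) -> dict[str, StudyDesign]:
    """Load a study-design library from YAML (the shipped file by default)."""
    import yaml
    from importlib import resources

    if path is None:
        path = str(
            resources.files("fcn159pk").joinpath("params/fcn159_study_designs.yaml")
        )
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    designs = {}
    for label, d in raw.items():
        designs[label] = StudyDesign(
            label=label,
            cancer_type=d["cancer_type"],
            arms=[Arm(*a) for a in d["arms"]],
            run_in_times=[float(t) for t in d.get("run_in_times", [])],
            day1_times=[float(t) for t in d.get("day1_times", [])],
            trough_days=[int(t) for t in d.get("trough_days", [])],
            last_day_times=[float(t) for t in d.get("last_day_times", [])],
        )
    return designs


def default_designs() -> dict[str, StudyDesign]:
    """The two shipped study designs (invented sampling schedules)."""
    run_in = [0.25, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 24.0, 36.0, 48.0, 72.0]
    rich = [0.0, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 24.0]
    d001 = StudyDesign(
        label="FCN-159-001",
        cancer_type="melanoma",
        arms=[
            Arm(0.2, 3, 21, True),
            Arm(0.5, 3, 21, True),
            Arm(1.0, 3, 21, True),
            Arm(2.0, 4, 21, True),
            Arm(4.0, 4, 21, True),
            Arm(6.0, 4, 28, True),
            Arm(8.0, 4, 28, True),
            Arm(12.0, 4, 28, True),
            Arm(15.0, 4, 28, True),
        ],
        run_in_times=run_in,
        last_day_times=rich,
    )
    d002 = StudyDesign(
        label="FCN-159-002",
        cancer_type="nf1",
        arms=[
            Arm(4.0, 3, 28, False),
            Arm(6.0, 3, 28, False),
            Arm(8.0, 3, 28, False),
            Arm(12.0, 3, 28, False),
        ],
        day1_times=[0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0],
        trough_days=[8, 15, 22],
        last_day_times=rich,
    )
    return {"FCN-159-001": d001, "FCN-159-002": d002}


def default_population_spec() -> list[PopulationSpec]:
    return [
        PopulationSpec(n=33, cancer_type="melanoma"),
        PopulationSpec(n=12, cancer_type="nf1"),
    ]


def _trunc_normal(rng: np.random.Generator, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_population(spec: PopulationSpec, seed: int) -> list[CovariateVector]:
    """Draw ``spec.n`` covariate vectors; reproducible under ``seed``."""
    covs = []
    for i in range(spec.n):
        rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
        bsa = float(_trunc_normal(rng, spec.bsa_mean, spec.bsa_sd, *spec.bsa_bounds, size=1)[0])
        tp = float(_trunc_normal(rng, spec.tp_mean, spec.tp_sd, 40.0, 100.0, size=1)[0])
        alb = float(_trunc_normal(rng, spec.alb_mean, spec.alb_sd, 20.0, 60.0, size=1)[0])
        age = float(rng.uniform(*spec.age_bounds))
        sex = "female" if rng.uniform() < spec.female_fraction else "male"
        # invert the Livingston relation for a consistent (synthetic) weight
        weight = float((bsa / 0.1173) ** (1.0 / 0.6466))
        covs.append(
            CovariateVector(
                bsa=bsa, tp=tp, sex=sex, cancer_type=spec.cancer_type,
                age=age, albumin=alb, weight=weight,
            )
        )
    return covs


def _subject_schedule(design: StudyDesign, arm: Arm) -> tuple[list[tuple[float, float]], list[float]]:
    """(dose events, observation times) in h since first dose for one subject."""
    doses: list[tuple[float, float]] = []
    obs: list[float] = []
    qd_start = 0.0
    if arm.run_in:
        doses.append((0.0, arm.dose))
        obs.extend(design.run_in_times)
        qd_start = 72.0
    for d in range(arm.qd_days):
        doses.append((qd_start + 24.0 * d, arm.dose))
    obs.extend(qd_start + t for t in design.day1_times)
    for day in design.trough_days:
        if day <= arm.qd_days:
            obs.append(qd_start + 24.0 * (day - 1))  # pre-dose trough
    last_dose_t = qd_start + 24.0 * (arm.qd_days - 1)
    obs.extend(last_dose_t + t for t in design.last_day_times)
    return doses, sorted(obs)


def generate_study_dataset(
    designs: list[StudyDesign] | StudyDesign | None = None,
    populations: list[list[CovariateVector]] | None = None,
    fe: FixedEffects | None = None,
    re: RandomEffects | None = None,
    seed: int = 0,
    fixture_mode: bool = False,
    lloq: float = DEFAULT_LLOQ,
) -> PKDataset:
    """Simulate a full study dataset from the final model.

    ``populations`` must match the designs' arm totals; by default the shipped
    two-study designs and parametric adult generators are used.  In
    ``fixture_mode`` the observation and BQL counts are pinned to the
    published bookkeeping (1090 rows, 60 BQL).
    """
    if designs is None:
        designs = list(default_designs().values())
    if isinstance(designs, StudyDesign):
        designs = [designs]
    if fe is None:
        fe = FixedEffects()
    if re is None:
        re = RandomEffects()
    if populations is None:
        populations = []
        for k, design in enumerate(designs):
            populations.append(
                generate_population(
                    PopulationSpec(n=design.n_subjects, cancer_type=design.cancer_type),
                    seed=seed * 1009 % (2**31 - 1) + k,
                )
            )
    records: list[PKRecord] = []
    sid = 0
    pad_done = False
    for design, pop in zip(designs, populations):
        if len(pop) != design.n_subjects:
            raise ValueError(
                f"population size {len(pop)} does not match design {design.label} "
                f"({design.n_subjects} subjects)"
            )
        pop_iter = iter(pop)
        for arm in design.arms:
            for _ in range(arm.n_subjects):
                sid += 1
                cov = next(pop_iter)
                doses, obs_times = _subject_schedule(design, arm)
                if fixture_mode and not pad_done and design.cancer_type == "nf1":
                    # one deterministic pad sample to reach the published total
                    obs_times = obs_times + [doses[-1][0] + 48.0]
                    pad_done = True
                rng = np.random.default_rng(np.random.SeedSequence([seed, 7919 + sid]))
                eta = rng.normal(0.0, 1.0, 4) * np.array(
                    [re.omega_cl, re.omega_vc, re.omega_q, re.omega_vp]
                )
                p = apply_covariates(fe, cov, eta)
                true = _conc_from_doses(p, doses, np.array(obs_times))
                eps = rng.normal(0.0, 1.0, len(obs_times))
                dv = true * (1.0 + re.sigma_prop * eps)
                if re.sigma_add > 0:
                    dv = dv + re.sigma_add * rng.normal(0.0, 1.0, len(obs_times))
                dv = np.maximum(dv, 0.0)
                events: list[tuple[float, int, float, float | None]] = []
                for t_dose, amt in doses:
                    events.append((t_dose, 1, amt, None))
                for t_obs, v in zip(obs_times, dv):
                    events.append((t_obs, 0, 0.0, float(v)))
                # doses sort before observations at the same instant
                events.sort(key=lambda e: (e[0], -e[1]))
                subject = f"S{sid:03d}"
                for t_ev, evid, amt, v in events:
                    if evid == 1:
                        records.append(
                            PKRecord(subject, t_ev, amt, 1, None, 1, False, cov)
                        )
                    else:
                        records.append(
                            PKRecord(subject, t_ev, 0.0, 0, v, 0, v < lloq, cov)
                        )
    ds = PKDataset(records=records, lloq=lloq)
    if fixture_mode:
        ds = _pin_bql_count(ds, target_bql=60, lloq=lloq)
    return ds


def _conc_from_doses(p, doses, times: np.ndarray) -> np.ndarray:
    """Superposition over an explicit dose list (single subject)."""
    from .model import macro_constants, MG_TO_UG

    mc = macro_constants(p)
    lam = np.array([mc.alpha, mc.beta, p.ka])
    coef = np.array([mc.coef_alpha, mc.coef_beta, mc.coef_ka])
    out = np.zeros_like(times, dtype=float)
    for t_dose, amt in doses:
        dt = times - t_dose - p.alag
        mask = dt > 0
        if not mask.any():
            continue
        e = np.exp(-np.outer(dt[mask], lam))
        out[mask] += amt * (e @ coef)
    return out * (p.f * p.ka / p.vc * MG_TO_UG)


def _pin_bql_count(ds: PKDataset, target_bql: int, lloq: float) -> PKDataset:
    """Deterministically nudge borderline DVs so exactly ``target_bql`` are BQL."""
    obs_idx = [
        (i, r.dv)
        for i, r in enumerate(ds.records)
        if r.is_observation and r.dv is not None
    ]
    bql = [(i, v) for i, v in obs_idx if v < lloq]
    above = [(i, v) for i, v in obs_idx if v >= lloq]
    records = list(ds.records)

    def rebuild(i: int, new_dv: float) -> None:
        r = records[i]
        records[i] = PKRecord(
            r.subject_id, r.time, r.amt, r.evid, new_dv, r.mdv, new_dv < lloq, r.covariates
        )

    if len(bql) < target_bql:
        # push the smallest quantifiable values just below the LLOQ
        above.sort(key=lambda iv: iv[1])
        for i, _ in above[: target_bql - len(bql)]:
            rebuild(i, lloq * 0.9)
    elif len(bql) > target_bql:
        # lift the largest BQL values to the LLOQ (barely quantifiable)
        bql.sort(key=lambda iv: -iv[1])
        for i, _ in bql[: len(bql) - target_bql]:
            rebuild(i, lloq)
    return PKDataset(records=records, lloq=lloq)
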