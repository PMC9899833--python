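"""Model qualification: visual predictive check and nonparametric bootstrap.

The VPC bins observations by time after dose (quantile-spaced edges, small
bins merged), computes observed 5th/50th/95th percentiles per bin and
stratum, and overlays the 2.5-97.5 percentile band of the same percentiles
across model-simulated replicates of the original design.

The bootstrap resamples subjects with replacement, stratified by study
population so the melanoma/NF1 mix — and with it the identifiability of the
relative-bioavailability term — is preserved, refits each resample, and
summarizes converged runs by mean and percentile interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._engine import build_design, time_after_dose
from .datamodel import PKDataset, PKRecord
from .estimation import EstimationResult, FitOptions, ModelSpec, fit
from .model import FixedEffects, RandomEffects
from .simulate import simulate_replicates

__all__ = ["VPCResult", "BootstrapResult", "vpc", "bootstrap", "plot_vpc"]


@dataclass
class VPCResult:
    strata: list[str]
    table: pd.DataFrame  # stratum, bin, tad_lo, tad_hi, n_obs, percentile, observed, ci_lo, ci_hi
    bin_edges: dict[str, np.ndarray]
    n_replicates: int
    merged_bins: list[str] = field(default_factory=list)

    def coverage(self) -> float:
        """Fraction of (bin, percentile) cells whose observed value falls
        inside its simulation band."""
        t = self.table
        inside = (t["observed"] >= t["ci_lo"]) & (t["observed"] <= t["ci_hi"])
        return float(inside.mean())


@dataclass
class BootstrapResult:
    n_runs: int
    n_converged: int
    estimates: pd.DataFrame  # per converged run, one column per parameter
    summary: pd.DataFrame  # parameter, original, mean, ci_lo, ci_hi

    @property
    def success_rate(self) -> float:
        return self.n_converged / self.n_runs if self.n_runs else 0.0


_PCTS = (5.0, 50.0, 95.0)


def _quantile_edges(tad: np.ndarray, n_bins: int) -> np.ndarray:
    qs = np.linspace(0.0, 1.0, n_bins + 1)
    edges = np.quantile(tad, qs)
    edges[0] -= 1e-9
    edges[-1] += 1e-9
    return np.unique(edges)


def vpc(
    ds: PKDataset,
    fe: FixedEffects,
    re: RandomEffects,
    n_rep: int = 1000,
    n_bins: int = 8,
    stratify_by: str | None = "study",
    seed: int = 0,
    min_bin_obs: int = 5,
) -> VPCResult:
    """Visual predictive check of ``fe``/``re`` against the observed dataset."""
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    design = build_design(ds)
    tad = time_after_dose(design)
    mask = design.obs_mask
    obs = pd.DataFrame(
        {
            "subject": np.repeat(design.subject_ids, mask.sum(axis=1)),
            "tad": tad[mask],
            "dv": design.y[mask],
            "study": np.repeat(
                np.where(design.nf1 > 0, "nf1", "melanoma"), mask.sum(axis=1)
            ),
        }
    )
    reps = simulate_replicates(ds, fe, re, n_rep=n_rep, seed=seed).table
    if stratify_by is None:
        obs["stratum"] = "all"
        reps["stratum"] = "all"
    else:
        obs["stratum"] = obs[stratify_by]
        reps["stratum"] = reps[stratify_by]
    rows = []
    edges_by_stratum: dict[str, np.ndarray] = {}
    merged: list[str] = []
    for stratum, og in obs.groupby("stratum"):
        edges = _quantile_edges(og["tad"].to_numpy(), n_bins)
        # merge small bins with their left neighbor
        while True:
            counts, _ = np.histogram(og["tad"], bins=edges)
            small = np.nonzero(counts < min_bin_obs)[0]
            if len(small) == 0 or len(edges) <= 2:
                break
            k = small[0]
            drop = k if k > 0 else 1
            merged.append(f"{stratum}: merged edge {edges[drop]:.3g}")
            edges = np.delete(edges, drop)
        edges_by_stratum[str(stratum)] = edges
        rg = reps[reps["stratum"] == stratum]
        obin = np.digitize(og["tad"], edges) - 1
        rbin = np.digitize(rg["tad"], edges) - 1
        rep_ids = rg["replicate"].to_numpy()
        rdv = rg["dv"].to_numpy()
        for b in range(len(edges) - 1):
            osel = og["dv"].to_numpy()[obin == b]
            if len(osel) == 0:
                continue
            obs_pcts = np.percentile(osel, _PCTS)
            in_bin = rbin == b
            sim_pcts = np.full((n_rep, len(_PCTS)), np.nan)
            sel_rep = rep_ids[in_bin]
            sel_dv = rdv[in_bin]
            order = np.argsort(sel_rep, kind="stable")
            sel_rep, sel_dv = sel_rep[order], sel_dv[order]
            bounds = np.searchsorted(sel_rep, np.arange(n_rep + 1))
            for r in range(n_rep):
                chunk = sel_dv[bounds[r] : bounds[r + 1]]
                if len(chunk):
                    sim_pcts[r] = np.percentile(chunk, _PCTS)
            ci_lo = np.nanpercentile(sim_pcts, 2.5, axis=0)
            ci_hi = np.nanpercentile(sim_pcts, 97.5, axis=0)
            for k, pct in enumerate(_PCTS):
                rows.append(
                    {
                        "stratum": stratum,
                        "bin": b,
                        "tad_lo": edges[b],
                        "tad_hi": edges[b + 1],
                        "n_obs": len(osel),
                        "percentile": pct,
                        "observed": obs_pcts[k],
                        "ci_lo": ci_lo[k],
                        "ci_hi": ci_hi[k],
                    }
                )
    table = pd.DataFrame(rows)
    for _, grp in table.groupby(["stratum", "bin"]):
        g = grp.sort_values("percentile")
        if not g["observed"].is_monotonic_increasing:
            raise AssertionError("observed percentiles out of order")
    return VPCResult(
        strata=sorted(obs["stratum"].unique().tolist()),
        table=table,
        bin_edges=edges_by_stratum,
        n_replicates=n_rep,
        merged_bins=merged,
    )


def plot_vpc(result: VPCResult, path: str | None = None):
    """Percentile-vs-TAD panels per stratum; returns the matplotlib figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    strata = result.strata
    fig, axes = plt.subplots(1, len(strata), figsize=(5 * len(strata), 4), squeeze=False)
    for ax, stratum in zip(axes[0], strata):
        t = result.table[result.table["stratum"] == stratum]
        for pct, color in zip(_PCTS, ("tab:blue", "tab:red", "tab:blue")):
            g = t[t["percentile"] == pct].sort_values("tad_lo")
            mid = (g["tad_lo"] + g["tad_hi"]) / 2
            ax.fill_between(mid, g["ci_lo"], g["ci_hi"], alpha=0.25, color=color)
            ax.plot(mid, g["observed"], "o-", color=color, ms=3, lw=1)
        ax.set_xlabel("time after dose (h)")
        ax.set_ylabel("concentration (ng/mL)")
        ax.set_title(str(stratum))
        ax.set_yscale("log")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
    return fig


def _resample_dataset(
    ds: PKDataset, rng: np.random.Generator, stratify: bool
) -> PKDataset:
    by_subject: dict[str, list[PKRecord]] = {}
    stratum: dict[str, str] = {}
    for rec in ds.records:
        by_subject.setdefault(rec.subject_id, []).append(rec)
        stratum.setdefault(rec.subject_id, rec.covariates.cancer_type or "unknown")
    ids = list(by_subject)
    chosen: list[str] = []
    if stratify:
        for s in sorted(set(stratum.values())):
            members = [i for i in ids if stratum[i] == s]
            idx = rng.integers(0, len(members), len(members))
            chosen.extend(members[i] for i in idx)
    else:
        idx = rng.integers(0, len(ids), len(ids))
        chosen = [ids[i] for i in idx]
    records: list[PKRecord] = []
    for new_i, sid in enumerate(chosen):
        for rec in by_subject[sid]:
            records.append(replace(rec, subject_id=f"B{new_i:03d}"))
    return PKDataset(records=records, lloq=ds.lloq)


def bootstrap(
    ds: PKDataset,
    spec: ModelSpec,
    n_runs: int = 1000,
    seed: int = 0,
    stratify_by_study: bool = True,
    options: FitOptions | None = None,
    original: EstimationResult | None = None,
    identity_resample: bool = False,
) -> BootstrapResult:
    """Nonparametric bootstrap of the model fit.

    Non-converged runs are counted but excluded from the percentile summary
    (converged-runs-only convention).  ``identity_resample`` replaces the
    resampling by the original subjects — every run then reproduces the
    original estimates, which is the degenerate self-check.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    options = options or FitOptions(compute_se=False, staged=True)
    if original is None:
        original = fit(spec, ds, options=options)
    runs = []
    n_conv = 0
    for r in range(n_runs):
        rng = np.random.default_rng(np.random.SeedSequence([seed, r]))
        bds = ds if identity_resample else _resample_dataset(ds, rng, stratify_by_study)
        try:
            res = fit(spec, bds, options=options)
        except Exception:
            continue
        if res.converged:
            n_conv += 1
            runs.append({"run": r, "ofv": res.ofv, **res.estimates})
    if n_conv == 0:
        raise RuntimeError(f"all {n_runs} bootstrap runs failed to converge")
    est = pd.DataFrame(runs).set_index("run")
    params = [c for c in est.columns if c != "ofv"]
    summary = pd.DataFrame(
        {
            "original": [original.estimates[p] for p in params],
            "mean": est[params].mean(),
            "ci_lo": est[params].quantile(0.025),
            "ci_hi": est[params].quantile(0.975),
        },
        index=params,
    )
    return BootstrapResult(
        n_runs=n_runs, n_converged=n_conv, estimates=est, summary=summary
    )
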