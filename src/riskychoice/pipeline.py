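"""End-to-end pipeline: simulate -> screen -> fit -> compare -> metrics -> stats.

Everything is driven by a PipelineConfig (loadable from YAML) with one
mandatory seed; a run writes its artifacts (CSV/JSON, one figure) plus a
deterministic manifest into a run directory.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior import UtilityMaximizerScreen, loss_sensitivity_by, proportion_accepted
from .cohort import CohortConfig, generate_cohort
from .evidence import compare_models, evidence_for
from .gstats import (
    bootstrap_median_se,
    correlation,
    drug_effect_table,
    fisher_rz_compare,
    mann_whitney_u,
    mixed_anova,
    route_by_normality,
    wilcoxon_signed_rank,
)
from .hierarchical import fit_hierarchical, screen_boundary

log = logging.getLogger("riskychoice")


@dataclass
class PipelineConfig:
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    tol: float = 1e-4
    max_iter: int = 500
    variants: tuple = ("full", "no_bias")
    strategy: str = "patients_only"
    fit_controls: bool = True
    n_boot: int = 10_000
    alpha: float = 0.05

    def validate(self) -> None:
        if self.tol <= 0 or self.max_iter <= 0 or self.n_boot <= 0:
            raise ValueError("tolerances and resample counts must be positive")
        self.cohort.validate()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort = CohortConfig(**raw.pop("cohort", {}))
        return cls(cohort=cohort, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["variants"] = list(self.variants)
        return d


def render_parameter_table(
    fits_frame: pd.DataFrame, n_boot: int = 10_000, seed: int = 0
) -> pd.DataFrame:
    """Median, range (max - min) and bootstrap SE of the median per
    group x session x parameter."""
    if len(fits_frame) == 0:
        raise ValueError("no fitted parameters to summarize")
    rows = []
    for i, ((group, session), df) in enumerate(fits_frame.groupby(["group", "session"], sort=True)):
        if len(df) == 0:
            raise ValueError(f"empty stratum {group}/{session}")
        for param in ("c", "lam", "mu"):
            x = df[param].to_numpy(float)
            se = 0.0 if len(x) < 2 else bootstrap_median_se(x, n_boot=n_boot, seed=seed + i)
            rows.append(
                {"group": group, "session": session, "param": param,
                 "median": float(np.median(x)), "range": float(np.ptp(x)),
                 "se_median": se, "n": len(x)}
            )
    return pd.DataFrame(rows)


def _stats_battery(fits_frame: pd.DataFrame, clinical: pd.DataFrame,
                   trials: pd.DataFrame, alpha: float) -> dict:
    """The study's statistical analyses, applied to the fitted cohort."""
    results = {}
    effects = drug_effect_table(fits_frame, clinical)
    nd = effects[effects["group"] == "PD_nondep"]
    dp = effects[effects["group"] == "PD_dep_hist"]

    # normality routing per parameter (pooled patient values)
    pooled = fits_frame[fits_frame["group"] != "HC"]
    for param in ("lam", "mu", "c"):
        try:
            results[f"normality_route:{param}"] = route_by_normality(pooled[param], alpha)
        except ValueError:
            results[f"normality_route:{param}"] = "nonparametric"

    # within-subject drug effects per patient group
    for label, sub in (("ndPD", nd), ("dPD", dp)):
        for param in ("c", "lam", "mu"):
            try:
                r = wilcoxon_signed_rank(
                    sub[f"{param}_on"], sub[f"{param}_off"],
                    name=f"{param}: ON vs OFF, {label}, Wilcoxon",
                )
                results[r.test_name] = r.to_dict()
            except ValueError as e:
                results[f"{param}: ON vs OFF, {label}, Wilcoxon"] = {"error": str(e)}

    # Group x Drug interaction as U on paired differences
    for param in ("c", "lam", "mu"):
        r = mann_whitney_u(nd[f"d_{param}"], dp[f"d_{param}"],
                           name=f"{param}: Group x Drug, U on differences")
        results[r.test_name] = r.to_dict()

    # correlations of the lambda drug effect with depression; small strata
    # are recorded as not-computable rather than aborting the battery
    pat = effects.dropna(subset=["d_bdi"])
    corr_results = {}
    for label, x, y in (
        ("d_lam vs BDI_OFF, patients, Spearman", pat["bdi_off"], pat["d_lam"]),
        ("d_lam vs d_BDI, patients, Spearman", pat["d_bdi"], pat["d_lam"]),
        ("d_lam vs d_BDI, dPD, Spearman", dp["d_bdi"], dp["d_lam"]),
        ("d_lam vs d_BDI, ndPD, Spearman", nd["d_bdi"], nd["d_lam"]),
    ):
        try:
            r = correlation(x, y, "spearman", name=label)
            corr_results[label] = r
            results[label] = r.to_dict()
        except ValueError as e:
            results[label] = {"error": str(e)}
    key_dp = "d_lam vs d_BDI, dPD, Spearman"
    key_nd = "d_lam vs d_BDI, ndPD, Spearman"
    fz_name = "d_lam vs d_BDI: dPD vs ndPD, Fisher r-z"
    if key_dp in corr_results and key_nd in corr_results:
        try:
            fz = fisher_rz_compare(corr_results[key_dp].statistic, len(dp),
                                   corr_results[key_nd].statistic, len(nd), name=fz_name)
            results[fz.test_name] = fz.to_dict()
        except ValueError as e:
            results[fz_name] = {"error": str(e)}

    # mixed ANOVAs on BDI and acceptance rate (drug within, group between)
    long_bdi = pd.concat([
        pat.assign(session="OFF", bdi=pat["bdi_off"]),
        pat.assign(session="ON", bdi=pat["bdi_on"]),
    ])
    for key, r in mixed_anova(long_bdi, "bdi", "session", "group", "subject_id",
                              name="BDI mixed ANOVA").items():
        results[r.test_name] = r.to_dict()
    acc = proportion_accepted(trials[trials["group"] != "HC"],
                              by=("subject_id", "group", "session"))
    for key, r in mixed_anova(acc, "p_accept", "session", "group", "subject_id",
                              name="p_accept mixed ANOVA").items():
        results[r.test_name] = r.to_dict()
    return results


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Execute all stages and write artifacts plus a deterministic manifest.

    Stages: cohort simulation, utility-maximizer screening (excluded
    subjects are dropped before fitting), hierarchical fits of each model
    variant on patients, NLME comparison, optional per-session fits pooling
    controls, behavioral metrics, statistics battery, Table-2-style
    parameter summary.  Any stage failure aborts with the stage named.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__, "seed": config.seed,
        "config": config.to_dict(), "stages": [], "outputs": [],
    }

    def stage(name):
        log.info("stage: %s", name)
        manifest["stages"].append(name)
        return time.time()

    def write_df(df: pd.DataFrame, fname: str):
        df.to_csv(outdir / fname, index=False)
        manifest["outputs"].append(fname)

    def write_json(obj, fname: str):
        (outdir / fname).write_text(json.dumps(obj, indent=2, default=_jsonable, sort_keys=True))
        manifest["outputs"].append(fname)

    try:
        t = stage("simulate")
        trials, clinical, truth = generate_cohort(config.cohort, seed=config.seed)
        write_df(trials, "trials.csv")
        write_df(clinical, "clinical.csv")
        write_df(truth, "truth.csv")
    except Exception as e:
        raise RuntimeError(f"pipeline stage 'simulate' failed: {e}") from e

    try:
        stage("screen")
        screen = UtilityMaximizerScreen().fit(trials)
        write_df(screen.results_, "screen.csv")
        manifest["excluded_subjects"] = screen.excluded_subjects_
        kept = screen.transform(trials)
    except Exception as e:
        raise RuntimeError(f"pipeline stage 'screen' failed: {e}") from e

    try:
        stage("fit+compare")
        fitted = {}
        comparison = {}
        for variant in config.variants:
            m = fit_hierarchical(kept, variant=variant, strategy="patients_only",
                                 tol=config.tol, max_iter=config.max_iter, seed=config.seed)
            fitted[variant] = m
            ev = evidence_for(m)
            comparison[variant] = {
                "nlme": ev.nlme, "m": ev.m, "n_units": ev.n_units,
                "converged": m.converged_, "n_iter": m.n_iter_,
                "prior_mean": m.prior_.mean.tolist(), "prior_var": m.prior_.var.tolist(),
            }
        if {"full", "no_bias"} <= set(fitted):
            comparison["winner"] = (
                "full" if comparison["full"]["nlme"] < comparison["no_bias"]["nlme"] else "no_bias"
            )
        write_json(comparison, "comparison.json")
        main = fitted.get("full") or next(iter(fitted.values()))
        write_df(main.fits_frame_, "fits_patients.csv")
        write_df(screen_boundary(main.fits_), "boundary_report.csv")
        fits_frame = main.fits_frame_
    except Exception as e:
        raise RuntimeError(f"pipeline stage 'fit+compare' failed: {e}") from e

    if config.fit_controls:
        try:
            stage("fit_controls")
            per_session = fit_hierarchical(
                kept, variant="full", strategy="controls_plus_patients_per_session",
                tol=config.tol, max_iter=config.max_iter, seed=config.seed,
            )
            hc = pd.concat(
                [m.fits_frame_[m.fits_frame_["group"] == "HC"] for m in per_session.values()]
            ).drop_duplicates(subset=["subject_id", "session"])
            write_df(pd.concat([fits_frame, hc], ignore_index=True), "fits_all.csv")
            fits_all = pd.concat([fits_frame, hc], ignore_index=True)
        except Exception as e:
            raise RuntimeError(f"pipeline stage 'fit_controls' failed: {e}") from e
    else:
        fits_all = fits_frame

    try:
        stage("metrics")
        write_df(proportion_accepted(kept, by=("group", "session")), "acceptance.csv")
        curves = loss_sensitivity_by(kept)
        write_df(curves, "loss_sensitivity.csv")
        _plot_curves(curves, outdir / "loss_sensitivity.png")
        manifest["outputs"].append("loss_sensitivity.png")
    except Exception as e:
        raise RuntimeError(f"pipeline stage 'metrics' failed: {e}") from e

    try:
        stage("stats")
        battery = _stats_battery(fits_frame, clinical, kept, config.alpha)
        write_json(battery, "stats.json")
    except Exception as e:
        raise RuntimeError(f"pipeline stage 'stats' failed: {e}") from e

    try:
        stage("report")
        write_df(render_parameter_table(fits_all, n_boot=config.n_boot, seed=config.seed),
                 "parameter_table.csv")
        write_json(manifest, "manifest.json")
    except Exception as e:
        raise RuntimeError(f"pipeline stage 'report' failed: {e}") from e
    return outdir


def _plot_curves(curves: pd.DataFrame, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for (group, session), df in curves.groupby(["group", "session"], sort=True):
        ax.plot(df["relative_loss"], df["log_ratio"], marker="o", ms=3,
                label=f"{group} {session}")
    ax.set_xlabel("relative loss (euros)")
    ax.set_ylabel("log(rejected / accepted)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
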