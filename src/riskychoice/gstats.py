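"""Group-level statistics for fitted parameters, acceptance rates and BDI.

All tests are two-tailed.  Normality (Shapiro-Wilk at alpha = 0.05) routes
between parametric and nonparametric branches: Wilcoxon signed-rank for
within-subject contrasts, Mann-Whitney U between groups, a drug-by-group
mixed ANOVA for normally distributed measures, Pearson/Spearman
correlations with p from the t-approximation, a Fisher r-to-z comparison of
two independent correlations, and bootstrap standard errors of medians
(10^5 resamples by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

DEFAULT_N_BOOT = 100_000
#: sample size above which the rank tests switch to the normal approximation
EXACT_N_MAX = 25


@dataclass
class StatResult:
    test_name: str
    statistic: float
    stat_label: str           # "W", "Z", "U", "F", "r", "rho", "z", ...
    p: float
    df: tuple | None = None
    n: tuple | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or np.isnan(self.p)):
            raise ValueError(f"p out of range: {self.p}")

    def to_dict(self) -> dict:
        return {
            "test": self.test_name, "stat": self.stat_label,
            "value": self.statistic, "p": self.p, "df": self.df, "n": self.n,
            **self.extra,
        }


def route_by_normality(values, alpha: float = 0.05) -> str:
    """Shapiro-Wilk routing: "parametric" if p >= alpha, else "nonparametric"."""
    x = np.asarray(values, float)
    if len(x) < 3:
        raise ValueError("normality routing needs n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: normality undefined")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p = stats.shapiro(x)
    return "parametric" if p >= alpha else "nonparametric"


def wilcoxon_signed_rank(x, y=None, name: str = "wilcoxon") -> StatResult:
    """Two-tailed Wilcoxon signed-rank test on paired data (or differences).

    Zero differences are dropped.  Exact enumeration up to n = 25 when the
    absolute differences are tie-free; the continuity-corrected normal
    approximation otherwise.
    """
    d = np.asarray(x, float) - (np.asarray(y, float) if y is not None else 0.0)
    d = d[d != 0]
    if len(d) == 0:
        raise ValueError("all paired differences are zero")
    ties = len(np.unique(np.abs(d))) < len(d)
    method = "exact" if (len(d) <= EXACT_N_MAX and not ties) else "approx"
    res = stats.wilcoxon(d, method=method, correction=(method == "approx"))
    extra = {"method": method}
    if method == "approx":
        extra["z"] = float(res.zstatistic)
    return StatResult(name, float(res.statistic), "W", float(res.pvalue),
                      n=(len(d),), extra=extra)


def mann_whitney_u(a, b, name: str = "mann-whitney") -> StatResult:
    """Two-tailed Mann-Whitney U test; exact for small tie-free samples."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (max(len(a), len(b)) <= EXACT_N_MAX and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return StatResult(name, float(res.statistic), "U", float(res.pvalue),
                      n=(len(a), len(b)), extra={"method": method})


def mixed_anova(
    data: pd.DataFrame, dv: str, within: str, between: str, subject: str,
    name: str = "mixed-anova",
) -> dict[str, StatResult]:
    """Split-plot ANOVA: one within factor (drug) by one between factor (group).

    Returns StatResults keyed "between", "within" and "interaction".
    Requires complete cases (every subject observed at every within level).
    """
    counts = data.groupby([subject, within], observed=True)[dv].count().unstack()
    if counts.isna().any().any() or (counts != 1).any().any():
        raise ValueError("mixed ANOVA requires exactly one observation per subject x session")
    if np.ptp(data[dv].to_numpy(float)) == 0:
        # constant outcome: every sum of squares is zero, define F = 0
        a = data[between].nunique()
        b = data[within].nunique()
        n_subj = data[subject].nunique()
        dfs = {"between": (a - 1, n_subj - a), "within": (b - 1, (n_subj - a) * (b - 1)),
               "interaction": (a - 1, (n_subj - a) * (b - 1))}
        return {k: StatResult(f"{name}:{k}", 0.0, "F", 1.0, df=dfs[k]) for k in dfs}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = pg.mixed_anova(data=data, dv=dv, within=within, between=between, subject=subject)
    table = table.set_index("Source")
    out = {}
    for key, source in (("between", between), ("within", within), ("interaction", "Interaction")):
        row = table.loc[source]
        out[key] = StatResult(
            f"{name}:{key}", float(row["F"]), "F", float(row["p_unc"]),
            df=(int(row["DF1"]), int(row["DF2"])),
        )
    return out


def correlation_p_from_r(r: float, n: int) -> float:
    """Two-tailed p for a correlation coefficient via t = r*sqrt((n-2)/(1-r^2))."""
    if not -1.0 < r < 1.0:
        raise ValueError("|r| must be < 1")
    if n < 4:
        raise ValueError("need n >= 4")
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def correlation(x, y, method: str = "pearson", name: str | None = None) -> StatResult:
    """Pearson or Spearman correlation, two-tailed p via the t-approximation."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need paired samples with n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    if method == "pearson":
        r = float(stats.pearsonr(x, y).statistic)
        label = "r"
    elif method == "spearman":
        r = float(stats.spearmanr(x, y).statistic)  # midranks
        label = "rho"
    else:
        raise ValueError(f"unknown method {method!r}")
    p = correlation_p_from_r(r, len(x)) if abs(r) < 1 else 0.0
    return StatResult(name or method, r, label, p, df=(len(x) - 2,), n=(len(x),))


def fisher_rz_compare(r1: float, n1: int, r2: float, n2: int,
                      name: str = "fisher-rz") -> StatResult:
    """Compare two independent correlations via Fisher's r-to-z transform."""
    for r, n in ((r1, n1), (r2, n2)):
        if not -1.0 < r < 1.0:
            raise ValueError("|r| must be < 1")
        if n <= 3:
            raise ValueError("need n > 3")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = float(2.0 * stats.norm.sf(abs(z)))
    return StatResult(name, float(z), "z", p, n=(n1, n2))


def bootstrap_median_se(values, n_boot: int = DEFAULT_N_BOOT, seed: int = 0) -> float:
    """SD of the median over ``n_boot`` with-replacement resamples (seeded)."""
    x = np.asarray(values, float)
    if len(x) < 2:
        raise ValueError("need n >= 2")
    rng = np.random.default_rng(seed)
    # chunked so 10^5 resamples of large groups stay memory-friendly
    meds = np.empty(n_boot)
    chunk = max(1, int(5e6) // len(x))
    for start in range(0, n_boot, chunk):
        stop = min(start + chunk, n_boot)
        idx = rng.integers(0, len(x), size=(stop - start, len(x)))
        meds[start:stop] = np.median(x[idx], axis=1)
    return float(meds.std(ddof=0))


def drug_effect_table(params: pd.DataFrame, clinical: pd.DataFrame) -> pd.DataFrame:
    """Per-patient drug-effect scores joined with clinical covariates.

    ``params`` has one row per subject-session with columns lam, mu, c.
    Sign conventions: d_lam = lam_ON - lam_OFF (negative = reduced loss
    aversion ON); d_bdi = BDI_OFF - BDI_ON (positive = improvement ON).
    """
    pat = params[params["session"].isin(["ON", "OFF"])]
    wide = pat.pivot_table(index=["subject_id", "group"], columns="session",
                           values=["lam", "mu", "c"], aggfunc="first")
    missing = wide.isna().any(axis=1)
    if missing.any():
        bad = [i[0] for i in wide.index[missing]]
        raise ValueError(f"subjects missing a session: {bad}")
    out = pd.DataFrame({
        "lam_off": wide[("lam", "OFF")], "lam_on": wide[("lam", "ON")],
        "mu_off": wide[("mu", "OFF")], "mu_on": wide[("mu", "ON")],
        "c_off": wide[("c", "OFF")], "c_on": wide[("c", "ON")],
    }).reset_index()
    out["d_lam"] = out["lam_on"] - out["lam_off"]
    out["d_mu"] = out["mu_on"] - out["mu_off"]
    out["d_c"] = out["c_on"] - out["c_off"]
    out = out.merge(clinical, on=["subject_id", "group"], how="left")
    out["d_bdi"] = out["bdi_off"] - out["bdi_on"]
    return out
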