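"""Hierarchical empirical-Bayes fitting of the gamble-choice model.

Each subject-session is one unit n with its own parameters theta_n = (lam,
mu, c) (or (lam, mu) when the gambling bias is fixed at zero).  All units in
the fitted pool share a diagonal normal prior N(Theta, Sigma) whose moments
are themselves estimated: the algorithm alternates

  E-step  per-unit MAP under the current prior (box-constrained L-BFGS-B
          with analytic gradients), plus a Laplace approximation of each
          unit's posterior (inverse Hessian of the negative log-posterior),
  M-step  moment updates Theta <- mean(theta_n),
          Sigma <- mean(theta_n^2 + Var_post_n) - Theta^2,

until the moments stop moving.  This is the standard EM scheme for a
random-effects normal with Laplace posteriors; the per-unit Hessians feed
straight into the model-evidence computation.

Because the linear predictor mu*SUG(lam) + c is smooth in the parameters,
the log-likelihood gradient and Hessian are analytic:

    dz/dlam = -0.5*mu*loss,  dz/dmu = SUG,  dz/dc = 1,
    d2z/dlam dmu = -0.5*loss  (all other second derivatives vanish),

    grad  = sum (y - p) dz,
    H_ab  = sum [(y - p) d2z_ab - p(1-p) dz_a dz_b].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit
from sklearn.base import BaseEstimator

from .model import C_BOUNDS, LAM_BOUNDS, MU_BOUNDS

VARIANCE_FLOOR = 1e-3
BOUNDARY_TOL = 1e-3

_FULL_BOUNDS = (LAM_BOUNDS, MU_BOUNDS, C_BOUNDS)
_FULL_NAMES = ("lam", "mu", "c")


def variant_spec(variant: str) -> tuple[tuple[str, ...], tuple[tuple[float, float], ...]]:
    """Free-parameter names and box bounds for a model variant."""
    if variant == "full":
        return _FULL_NAMES, _FULL_BOUNDS
    if variant == "no_bias":
        return _FULL_NAMES[:2], _FULL_BOUNDS[:2]
    raise ValueError(f"unknown model variant {variant!r}")


@dataclass(frozen=True)
class GroupPrior:
    """Diagonal normal group prior: mean Theta and variance Sigma per parameter."""

    mean: np.ndarray
    var: np.ndarray
    names: tuple[str, ...] = _FULL_NAMES

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", np.asarray(self.mean, float))
        object.__setattr__(self, "var", np.asarray(self.var, float))
        if self.mean.shape != self.var.shape or self.mean.ndim != 1:
            raise ValueError("prior mean and variance must be 1-D and the same length")
        if np.any(self.var <= 0):
            raise ValueError("prior variances must be positive")

    def logpdf(self, theta: np.ndarray) -> float:
        """Log density of the diagonal normal prior at theta."""
        theta = np.asarray(theta, float)
        return float(
            np.sum(-0.5 * np.log(2 * np.pi * self.var) - (theta - self.mean) ** 2 / (2 * self.var))
        )

    @classmethod
    def flat(cls, n_params: int, var: float = 1e6) -> "GroupPrior":
        """Effectively uninformative prior (MAP ~ ML)."""
        return cls(mean=np.zeros(n_params), var=np.full(n_params, var), names=_FULL_NAMES[:n_params])


@dataclass
class SubjectFit:
    """MAP fit of one subject-session unit plus its Laplace bookkeeping."""

    subject_id: str
    session: str
    theta_map: np.ndarray
    log_posterior: float
    log_likelihood: float
    log_prior: float
    hessian: np.ndarray          # of the NEGATIVE log-posterior at theta_map
    log_det_hessian: float
    converged: bool
    at_boundary: bool
    group: str = ""
    names: tuple[str, ...] = _FULL_NAMES
    hessian_fallback: bool = False

    @property
    def posterior_var(self) -> np.ndarray:
        """Diagonal of the inverse Hessian (Laplace posterior variances)."""
        return np.diag(np.linalg.inv(self.hessian)).copy()


def _loglik_terms(theta, g, l, y, mu_bounds_free=False):
    """Log-likelihood, gradient and weights; theta = (lam, mu[, c])."""
    lam, mu = theta[0], theta[1]
    c = theta[2] if len(theta) == 3 else 0.0
    sug = 0.5 * g - 0.5 * l * lam
    z = mu * sug + c
    ll = float(np.sum(y * z - np.logaddexp(0.0, z)))
    p = expit(z)
    r = y - p
    return ll, sug, p, r


def neg_log_posterior(theta, g, l, y, prior: GroupPrior):
    """Negative log-posterior and its analytic gradient (for the optimizer)."""
    theta = np.asarray(theta, float)
    ll, sug, p, r = _loglik_terms(theta, g, l, y)
    lam, mu = theta[0], theta[1]
    grad_ll = np.empty(len(theta))
    grad_ll[0] = np.sum(r * (-0.5 * mu * l))
    grad_ll[1] = np.sum(r * sug)
    if len(theta) == 3:
        grad_ll[2] = np.sum(r)
    lp = prior.logpdf(theta)
    grad_lp = -(theta - prior.mean) / prior.var
    return -(ll + lp), -(grad_ll + grad_lp)


def neg_log_posterior_hessian(theta, g, l, y, prior: GroupPrior) -> np.ndarray:
    """Analytic Hessian of the negative log-posterior at theta."""
    theta = np.asarray(theta, float)
    lam, mu = theta[0], theta[1]
    k = len(theta)
    sug = 0.5 * g - 0.5 * l * lam
    z = mu * sug + (theta[2] if k == 3 else 0.0)
    p = expit(z)
    w = p * (1.0 - p)
    r = y - p
    dz = np.empty((k, len(g)))
    dz[0] = -0.5 * mu * l
    dz[1] = sug
    if k == 3:
        dz[2] = 1.0
    h_ll = -(dz * w) @ dz.T
    h_ll[0, 1] += np.sum(r * (-0.5 * l))
    h_ll[1, 0] = h_ll[0, 1]
    return -h_ll + np.diag(1.0 / prior.var)


def _unit_arrays(data: pd.DataFrame):
    g = data["gain"].to_numpy(float)
    l = data["loss"].to_numpy(float)
    y = data["accepted"].to_numpy(float)
    return g, l, y


def fit_map_individual(
    data: pd.DataFrame,
    prior: GroupPrior,
    variant: str = "full",
    n_starts: int = 5,
    seed: int = 0,
    extra_starts: list[np.ndarray] | None = None,
) -> SubjectFit:
    """Box-constrained MAP fit of one subject-session unit.

    Runs ``n_starts`` seeded starts (prior mean plus draws from the prior,
    clipped to the bounds) and keeps the best optimum; ``extra_starts`` can
    add warm starts (used by the EM loop).  The Hessian of the negative
    log-posterior is evaluated analytically at the optimum; if it is not
    positive definite (possible when the MAP sits on a box bound) its
    eigenvalues are floored at 1e-6 and the fit is flagged.
    """
    if len(data) == 0:
        raise ValueError("empty choice dataset")
    names, bounds = variant_spec(variant)
    k = len(names)
    if len(prior.mean) != k:
        raise ValueError(f"prior has {len(prior.mean)} parameters, variant {variant!r} needs {k}")
    g, l, y = _unit_arrays(data)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    rng = np.random.default_rng(seed)
    starts = [np.clip(prior.mean, lo, hi)]
    sd = np.sqrt(np.minimum(prior.var, 9.0))  # keep random starts in a sane range
    while len(starts) < n_starts:
        starts.append(np.clip(prior.mean + rng.standard_normal(k) * sd, lo, hi))
    if extra_starts:
        starts = [np.clip(np.asarray(s, float), lo, hi) for s in extra_starts] + starts

    best = None
    any_success = False
    for x0 in starts:
        res = optimize.minimize(
            neg_log_posterior,
            x0,
            args=(g, l, y, prior),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
        )
        any_success = any_success or res.success
        if best is None or res.fun < best.fun:
            best = res
    if not any_success:
        warnings.warn("MAP optimization did not report success from any start; keeping best point")

    theta = np.asarray(best.x, float)
    at_boundary = bool(np.any(theta - lo < BOUNDARY_TOL) or np.any(hi - theta < BOUNDARY_TOL))
    hess = neg_log_posterior_hessian(theta, g, l, y, prior)
    hess = 0.5 * (hess + hess.T)
    fallback = False
    eigvals = np.linalg.eigvalsh(hess)
    if eigvals[0] <= 0:
        # non-PD Hessian (boundary optimum): floor eigenvalues so the
        # Laplace terms stay defined, and flag the unit
        w, v = np.linalg.eigh(hess)
        hess = (v * np.maximum(w, 1e-6)) @ v.T
        fallback = True
    sign, logdet = np.linalg.slogdet(hess)
    ll, *_ = _loglik_terms(theta, g, l, y)
    lp = prior.logpdf(theta)

    subject_id = str(data["subject_id"].iloc[0]) if "subject_id" in data else "unit"
    session = str(data["session"].iloc[0]) if "session" in data else "single"
    group = str(data["group"].iloc[0]) if "group" in data else ""
    return SubjectFit(
        subject_id=subject_id,
        session=session,
        group=group,
        theta_map=theta,
        log_posterior=-float(best.fun),
        log_likelihood=ll,
        log_prior=lp,
        hessian=hess,
        log_det_hessian=float(logdet),
        converged=bool(any_success),
        at_boundary=at_boundary,
        names=names,
        hessian_fallback=fallback,
    )


def update_group_moments(fits: list[SubjectFit], variance_floor: float = VARIANCE_FLOOR) -> GroupPrior:
    """EM moment update of the group prior from Laplace posteriors.

    Theta_new = mean_n theta_n;
    Sigma_new = mean_n(theta_n^2 + diag(H_n^-1)) - Theta_new^2, floored.
    """
    if not fits:
        raise ValueError("no fits to update from")
    theta = np.stack([f.theta_map for f in fits])
    post_var = np.empty_like(theta)
    for i, f in enumerate(fits):
        try:
            post_var[i] = np.diag(np.linalg.inv(f.hessian))
        except np.linalg.LinAlgError:
            warnings.warn(f"singular Hessian for unit {f.subject_id}/{f.session}; using pseudo-inverse")
            post_var[i] = np.diag(np.linalg.pinv(f.hessian))
    mean = theta.mean(axis=0)
    var = (theta**2 + post_var).mean(axis=0) - mean**2
    var = np.maximum(var, variance_floor)
    return GroupPrior(mean=mean, var=var, names=fits[0].names)


def _trimmed_moments(x: np.ndarray, proportion: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """5%-trimmed mean and variance per column, for robust prior initialization."""
    n, k = x.shape
    cut = int(np.floor(n * proportion))
    xs = np.sort(x, axis=0)
    core = xs[cut : n - cut if cut else n]
    return core.mean(axis=0), core.var(axis=0, ddof=1) if len(core) > 1 else np.ones(k)


class HierarchicalGambleModel(BaseEstimator):
    """Hierarchical empirical-Bayes estimator for the gamble-choice model.

    Parameters
    ----------
    variant : {"full", "no_bias"}
        "full" fits (lam, mu, c); "no_bias" fixes the gambling bias c at 0
        and fits (lam, mu).
    tol : float
        Convergence threshold on the max absolute change of the group mean
        and variance between iterations.
    max_iter : int
        Cap on EM iterations; non-convergence is flagged, not raised.
    n_starts : int
        Seeded multi-starts per unit in the initial ML pass and the first
        E-step.
    refine_starts : int
        Random starts per unit in later E-steps (each unit is additionally
        warm-started from its previous MAP and the prior mean).
    variance_floor : float
        Elementwise lower bound for the group variance.
    seed : int
        Seed for the optimizer starts.

    Attributes
    ----------
    prior_ : GroupPrior
        Estimated group mean and variance.
    fits_ : list of SubjectFit
        Per-unit MAP fits under the final prior.
    fits_frame_ : DataFrame
        One row per unit with the MAP parameters.
    trace_ : DataFrame
        Per-iteration group moments, max parameter change, and the Laplace
        approximation of the log model evidence (excluding the group-level
        BIC penalty).
    n_iter_ : int
    converged_ : bool
    """

    def __init__(
        self,
        variant: str = "full",
        tol: float = 1e-4,
        max_iter: int = 500,
        n_starts: int = 5,
        refine_starts: int = 1,
        variance_floor: float = VARIANCE_FLOOR,
        seed: int = 0,
    ):
        self.variant = variant
        self.tol = tol
        self.max_iter = max_iter
        self.n_starts = n_starts
        self.refine_starts = refine_starts
        self.variance_floor = variance_floor
        self.seed = seed

    # -- helpers -----------------------------------------------------------
    @staticmethod
    def _units(X: pd.DataFrame) -> list[tuple[tuple[str, str], pd.DataFrame]]:
        if len(X) == 0:
            raise ValueError("empty choice dataset")
        for col in ("subject_id", "session", "gain", "loss", "accepted"):
            if col not in X.columns:
                raise ValueError(f"choice data must have a {col!r} column")
        return [(key, df) for key, df in X.groupby(["subject_id", "session"], sort=True)]

    def _objective(self, fits: list[SubjectFit]) -> float:
        # per-unit Laplace log evidence: ll + log prior + (k/2) log 2pi - 0.5 log|H|
        k = len(fits[0].names)
        return sum(
            f.log_likelihood + f.log_prior + 0.5 * k * np.log(2 * np.pi) - 0.5 * f.log_det_hessian
            for f in fits
        )

    # -- sklearn API -------------------------------------------------------
    def fit(self, X: pd.DataFrame, y=None) -> "HierarchicalGambleModel":
        """Run the EM loop on trial-level choice data.

        ``X`` is a trial table with columns subject_id, session, gain, loss,
        accepted (group optional); every subject-session in it becomes one
        unit of the hierarchy, all sharing one prior.
        """
        names, bounds = variant_spec(self.variant)
        k = len(names)
        units = self._units(X)
        seeds = np.random.SeedSequence(self.seed).generate_state(len(units)) % (2**31)

        # initialization: per-unit ML (flat prior), robust moments
        flat = GroupPrior.flat(k)
        fits = [
            fit_map_individual(df, flat, self.variant, n_starts=self.n_starts, seed=int(s))
            for (_, df), s in zip(units, seeds)
        ]
        theta0 = np.stack([f.theta_map for f in fits])
        mean0, var0 = _trimmed_moments(theta0)
        prior = GroupPrior(
            mean=mean0, var=np.maximum(var0, self.variance_floor), names=names
        )

        rows = []
        converged = False
        for it in range(self.max_iter):
            extra = [[f.theta_map] for f in fits]
            n_starts = self.n_starts if it == 0 else self.refine_starts
            fits = [
                fit_map_individual(
                    df, prior, self.variant, n_starts=n_starts, seed=int(s) + it + 1,
                    extra_starts=ex,
                )
                for (_, df), s, ex in zip(units, seeds, extra)
            ]
            new_prior = update_group_moments(fits, self.variance_floor)
            delta = float(
                max(
                    np.max(np.abs(new_prior.mean - prior.mean)),
                    np.max(np.abs(new_prior.var - prior.var)),
                )
            )
            rows.append(
                {
                    "iteration": it,
                    **{f"mean_{n}": m for n, m in zip(names, new_prior.mean)},
                    **{f"var_{n}": v for n, v in zip(names, new_prior.var)},
                    "max_delta": delta,
                    "objective": self._objective(fits),
                }
            )
            prior = new_prior
            if delta < self.tol:
                converged = True
                break

        self.prior_ = prior
        self.fits_ = fits
        self.trace_ = pd.DataFrame(rows)
        self.n_iter_ = len(rows)
        self.converged_ = converged
        recs = []
        for f in fits:
            rec = {"subject_id": f.subject_id, "group": f.group, "session": f.session}
            rec.update(dict(zip(f.names, f.theta_map)))
            if "c" not in rec:
                rec["c"] = 0.0
            rec.update(
                log_likelihood=f.log_likelihood,
                log_det_hessian=f.log_det_hessian,
                at_boundary=f.at_boundary,
            )
            recs.append(rec)
        self.fits_frame_ = pd.DataFrame(recs)
        return self

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Per-trial acceptance probability under each trial's unit MAP."""
        from .model import acceptance_probability, subjective_utility

        if not hasattr(self, "fits_"):
            raise AttributeError("model is not fitted")
        lookup = {(f.subject_id, f.session): f for f in self.fits_}
        p = np.empty(len(X))
        for i, row in enumerate(X.itertuples(index=False)):
            f = lookup.get((str(row.subject_id), str(row.session)))
            if f is None:
                raise KeyError(f"unit {(row.subject_id, row.session)} not in the fitted pool")
            lam, mu = f.theta_map[0], f.theta_map[1]
            c = f.theta_map[2] if len(f.theta_map) == 3 else 0.0
            p[i] = acceptance_probability(subjective_utility(row.gain, row.loss, lam), mu, c)
        return p

    def score(self, X: pd.DataFrame, y=None) -> float:
        """Mean per-trial log-likelihood under the fitted unit MAPs."""
        p = np.clip(self.predict_proba(X), 1e-12, 1 - 1e-12)
        acc = X["accepted"].to_numpy().astype(bool)
        return float(np.mean(np.where(acc, np.log(p), np.log1p(-p))))


def fit_hierarchical(
    data: pd.DataFrame,
    variant: str = "full",
    strategy: str = "patients_only",
    tol: float = 1e-4,
    max_iter: int = 500,
    seed: int = 0,
    **kwargs,
):
    """Fit the hierarchy under one of the study's two pooling strategies.

    "patients_only" pools both patient groups and both drug sessions under a
    single prior (controls excluded) and returns one fitted model.
    "controls_plus_patients_per_session" runs one fit per drug session, each
    pooling the controls' single session with that session's patient data,
    and returns a dict {"OFF": model, "ON": model}.
    """
    def _one(sub: pd.DataFrame, s: int) -> HierarchicalGambleModel:
        return HierarchicalGambleModel(
            variant=variant, tol=tol, max_iter=max_iter, seed=s, **kwargs
        ).fit(sub)

    if strategy == "patients_only":
        sub = data[data["group"] != "HC"] if "group" in data.columns else data
        if len(sub) == 0:
            raise ValueError("no patient data to fit")
        return _one(sub, seed)
    if strategy == "controls_plus_patients_per_session":
        if "group" not in data.columns:
            raise ValueError("strategy requires a group column")
        out = {}
        for i, session in enumerate(("OFF", "ON")):
            mask = (data["group"] == "HC") | (data["session"] == session)
            out[session] = _one(data[mask], seed + i)
        return out
    raise ValueError(f"unknown strategy {strategy!r}")


def screen_boundary(fits: list[SubjectFit], tol: float = BOUNDARY_TOL) -> pd.DataFrame:
    """List subject-sessions whose MAP sits within ``tol`` of a box bound."""
    rows = []
    for f in fits:
        _, bounds = variant_spec("full" if len(f.theta_map) == 3 else "no_bias")
        for name, value, (lo, hi) in zip(f.names, f.theta_map, bounds):
            if value - lo < tol or hi - value < tol:
                rows.append(
                    {"subject_id": f.subject_id, "session": f.session, "param": name, "value": value}
                )
    return pd.DataFrame(rows, columns=["subject_id", "session", "param", "value"])
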