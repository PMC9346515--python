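"""Joint longitudinal-survival model and progression bands.

The longitudinal sub-model is a linear mixed model on the transformed
outcome (log body weight, or the disease severity score on the identity
scale) with fixed effects ``(1, sqrt(week))`` and correlated per-mouse
random intercept and slope:

    y_ij = beta0 + b0_i + (beta1 + b1_i) sqrt(w_ij) + eps_ij,
    (b0, b1) ~ N(0, G),  eps ~ N(0, sigma_e^2).

The survival sub-model is a Weibull baseline hazard with a current-value
association to the longitudinal linear predictor:

    h_i(t | b) = (k / lam) (t / lam)^(k-1) exp(alpha * m_i(t)),
    m_i(t) = beta0 + b0_i + (beta1 + b1_i) sqrt(t),

with left truncation at the first observed week (mice enter the study alive
at weaning). The joint marginal likelihood integrates the product of the
two conditional likelihoods over the random effects by two-dimensional
Gauss-Hermite quadrature; the cumulative hazard is integrated numerically
on a fixed-step time grid (trapezoid rule, 0.05-week default).

``predict_band`` turns a fit into the study's "expected disease
progression" envelope: it simulates mice from the fitted model and reports,
at each grid week and among simulated mice still alive, the median and the
outer quantiles of the outcome (back-transformed to grams for weight,
clamped to [0, 5] for the severity score).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import logsumexp

from .cohort import CohortDataset

__all__ = [
    "JointModelSpec",
    "JointModelFit",
    "ProgressionBand",
    "JointModelError",
    "fit_lmm",
    "fit_joint",
    "joint_loglik",
    "predict_band",
    "band_from_reference",
    "simulate_outcome_paths",
]


class JointModelError(ValueError):
    """Invalid input or numerical failure in the joint model."""


@dataclass
class JointModelSpec:
    """Model options: outcome, association structure, quadrature, optimizer."""

    outcome: str = "log_weight"  # "log_weight" | "dss"
    association: str = "current_value"  # "current_value" | "none"
    baseline_hazard: str = "weibull"
    quadrature_points: int = 9  # per random-effect dimension, odd
    cumhaz_step: float = 0.05  # weeks, trapezoid grid for the cumulative hazard
    max_iter: int = 300
    scoring_version: str = "optimized"  # used when outcome == "dss"

    def validate(self) -> "JointModelSpec":
        if self.outcome not in ("log_weight", "dss"):
            raise JointModelError(f"unknown outcome {self.outcome!r}")
        if self.association not in ("current_value", "none"):
            raise JointModelError(f"unknown association {self.association!r}")
        if self.baseline_hazard != "weibull":
            raise JointModelError(f"unknown baseline hazard {self.baseline_hazard!r}")
        if self.quadrature_points < 5 or self.quadrature_points % 2 == 0:
            raise JointModelError("quadrature_points must be odd and >= 5")
        return self


@dataclass
class JointModelFit:
    """Estimated parameters of the (joint) model."""

    outcome: str
    beta: np.ndarray  # (intercept, sqrt-week slope)
    G: np.ndarray  # 2x2 random-effect covariance
    sigma_e: float
    haz_scale: float | None
    haz_shape: float | None
    alpha: float | None
    loglik: float
    converged: bool
    n_mice: int
    n_obs: int
    entry_week: float = 3.0
    spec: JointModelSpec = field(default_factory=JointModelSpec)

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "beta": list(map(float, self.beta)),
            "G": np.asarray(self.G, dtype=float).tolist(),
            "sigma_e": float(self.sigma_e),
            "haz_scale": None if self.haz_scale is None else float(self.haz_scale),
            "haz_shape": None if self.haz_shape is None else float(self.haz_shape),
            "alpha": None if self.alpha is None else float(self.alpha),
            "loglik": float(self.loglik),
            "converged": bool(self.converged),
            "n_mice": self.n_mice,
            "n_obs": self.n_obs,
            "entry_week": float(self.entry_week),
            "spec": asdict(self.spec),
        }

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "JointModelFit":
        spec = JointModelSpec(**d.get("spec", {}))
        return cls(
            outcome=d["outcome"],
            beta=np.asarray(d["beta"], dtype=float),
            G=np.asarray(d["G"], dtype=float),
            sigma_e=float(d["sigma_e"]),
            haz_scale=d.get("haz_scale"),
            haz_shape=d.get("haz_shape"),
            alpha=d.get("alpha"),
            loglik=float(d["loglik"]),
            converged=bool(d["converged"]),
            n_mice=int(d["n_mice"]),
            n_obs=int(d["n_obs"]),
            entry_week=float(d.get("entry_week", 3.0)),
            spec=spec,
        )

    @classmethod
    def read(cls, path: str | Path) -> "JointModelFit":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class ProgressionBand:
    """Week grid with the median profile and pointwise prediction limits."""

    outcome: str
    weeks: np.ndarray
    median: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float
    n_sim: int
    n_alive: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "week": self.weeks,
                "median": self.median,
                "lower": self.lower,
                "upper": self.upper,
            }
        )

    def at_week(self, week: int) -> tuple[float, float, float]:
        idx = np.flatnonzero(self.weeks == week)
        if idx.size == 0:
            raise JointModelError(f"week {week} not on the band grid")
        i = idx[0]
        return float(self.lower[i]), float(self.median[i]), float(self.upper[i])


# -- outcome extraction -------------------------------------------------


def _outcome_table(
    dataset: CohortDataset, spec: JointModelSpec, scores: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Tidy (mouse_id, week, y) table on the model's transformed scale."""
    if spec.outcome == "log_weight":
        df = dataset.observations[["mouse_id", "week", "body_weight"]].copy()
        df["y"] = np.log(df["body_weight"].to_numpy(dtype=float))
    else:
        if scores is None:
            from .scoring import score_cohort

            scores = score_cohort(dataset, spec.scoring_version)
        df = scores[["mouse_id", "week", "total"]].copy()
        df["y"] = df["total"].astype(float)
    return df[["mouse_id", "week", "y"]]


def _blocks(
    dataset: CohortDataset, spec: JointModelSpec, scores: pd.DataFrame | None = None
):
    """Per-mouse design blocks plus survival rows, in a fixed mouse order."""
    table = _outcome_table(dataset, spec, scores).sort_values(
        ["mouse_id", "week"], kind="mergesort"
    )
    surv = dataset.survival.set_index("mouse_id")
    blocks = []
    for mid, grp in table.groupby("mouse_id", sort=True):
        w = grp["week"].to_numpy(dtype=float)
        y = grp["y"].to_numpy(dtype=float)
        X = np.column_stack([np.ones_like(w), np.sqrt(w)])
        blocks.append(
            {
                "mouse_id": mid,
                "y": y,
                "X": X,
                "entry": float(w.min()),
                "time": float(surv.loc[mid, "time"]),
                "event": int(surv.loc[mid, "event"]),
            }
        )
    return blocks


# -- linear mixed model --------------------------------------------------


def _unpack_lmm(theta: np.ndarray):
    beta = theta[:2]
    L = np.array(
        [[math.exp(theta[2]), 0.0], [theta[3], math.exp(theta[4])]], dtype=float
    )
    sigma = math.exp(theta[5])
    return beta, L, sigma


def _lmm_nll(theta: np.ndarray, blocks) -> float:
    beta, L, sigma = _unpack_lmm(theta)
    G = L @ L.T
    nll = 0.0
    for blk in blocks:
        X, y = blk["X"], blk["y"]
        n = len(y)
        V = X @ G @ X.T + sigma**2 * np.eye(n)
        try:
            cf = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return 1e12
        r = y - X @ beta
        sol = np.linalg.solve(cf, r)
        logdet = 2.0 * np.sum(np.log(np.diag(cf)))
        nll += 0.5 * (logdet + sol @ sol + n * math.log(2.0 * math.pi))
    return float(nll)


def fit_lmm(
    dataset: CohortDataset,
    spec: JointModelSpec | None = None,
    scores: pd.DataFrame | None = None,
) -> JointModelFit:
    """Maximum-likelihood linear mixed model (no survival linkage).

    The per-mouse marginal likelihood is the closed-form multivariate
    normal ``N(X beta, X G X' + sigma^2 I)``. Used standalone and as the
    initializer of :func:`fit_joint`.
    """
    spec = (spec or JointModelSpec(association="none")).validate()
    blocks = _blocks(dataset, spec, scores)
    if len(blocks) < 2 or sum(len(b["y"]) >= 2 for b in blocks) < 2:
        raise JointModelError("need >= 2 mice with >= 2 observations each")
    weeks = np.concatenate([b["X"][:, 1] for b in blocks])
    if np.unique(weeks).size < 2:
        raise JointModelError("single observation week: slope not identifiable")

    X_all = np.vstack([b["X"] for b in blocks])
    y_all = np.concatenate([b["y"] for b in blocks])
    beta_ols, *_ = np.linalg.lstsq(X_all, y_all, rcond=None)
    resid_sd = float(np.std(y_all - X_all @ beta_ols)) or 1e-3

    theta0 = np.array(
        [
            beta_ols[0],
            beta_ols[1],
            math.log(max(resid_sd * 0.7, 1e-4)),
            0.0,
            math.log(max(resid_sd * 0.25, 1e-4)),
            math.log(max(resid_sd * 0.7, 1e-4)),
        ]
    )
    res = optimize.minimize(
        _lmm_nll,
        theta0,
        args=(blocks,),
        method="L-BFGS-B",
        options={"maxiter": spec.max_iter, "maxfun": 4000},
    )
    beta, L, sigma = _unpack_lmm(res.x)
    n_obs = sum(len(b["y"]) for b in blocks)
    return JointModelFit(
        outcome=spec.outcome,
        beta=np.asarray(beta, dtype=float),
        G=L @ L.T,
        sigma_e=sigma,
        haz_scale=None,
        haz_shape=None,
        alpha=None,
        loglik=-float(res.fun),
        converged=bool(res.success),
        n_mice=len(blocks),
        n_obs=n_obs,
        entry_week=float(min(b["entry"] for b in blocks)),
        spec=spec,
    )


# -- joint likelihood ----------------------------------------------------

_EXP_CLIP = 600.0


def _unpack_joint(theta: np.ndarray):
    beta = theta[:2]
    L = np.array(
        [[math.exp(theta[2]), 0.0], [theta[3], math.exp(theta[4])]], dtype=float
    )
    sigma = math.exp(theta[5])
    lam = math.exp(theta[6])
    k = math.exp(theta[7])
    alpha = theta[8]
    return beta, L, sigma, lam, k, alpha


class _JointData:
    """Precomputed sufficient statistics for fast joint-likelihood evaluation.

    The random-effect integral uses *adaptive* Gauss-Hermite quadrature:
    nodes are centered and scaled per mouse on the Gaussian posterior of the
    random effects given the longitudinal data alone (available in closed
    form), which keeps a 9x9 grid accurate even though that posterior is
    far narrower than the prior. The cumulative hazard over [entry, T] is
    evaluated by fixed-order Gauss-Legendre in s = sqrt(t), where the
    integrand ``(2k/lam^k) s^(2k-1) exp(c s)`` is smooth.
    """

    _GL_POINTS = 40

    def __init__(self, blocks, spec: JointModelSpec):
        self.spec = spec
        self.n = len(blocks)
        self.n_i = np.array([len(b["y"]) for b in blocks])
        self.yty = np.array([b["y"] @ b["y"] for b in blocks])
        self.Xty = np.stack([b["X"].T @ b["y"] for b in blocks])  # (n, 2)
        self.XtX = np.stack([b["X"].T @ b["X"] for b in blocks])  # (n, 2, 2)
        self.T = np.array([b["time"] for b in blocks])
        self.delta = np.array([b["event"] for b in blocks])
        self.entry = np.array([b["entry"] for b in blocks])
        self.sqrtT = np.sqrt(self.T)
        # Gauss-Legendre nodes in s = sqrt(t) on [sqrt(entry), sqrt(T)]
        gl_z, gl_w = np.polynomial.legendre.leggauss(self._GL_POINTS)
        lo = np.sqrt(self.entry)[:, None]
        hi = self.sqrtT[:, None]
        half = 0.5 * (hi - lo)
        self.s_nodes = lo + half * (gl_z[None, :] + 1.0)  # (n, P)
        self.s_weights = half * gl_w[None, :]  # (n, P)
        # standardized Gauss-Hermite grid (Q, 2) with log-weights
        q = spec.quadrature_points
        z, wq = np.polynomial.hermite.hermgauss(q)
        z1, z2 = np.meshgrid(z, z, indexing="ij")
        self.z_nodes = np.column_stack([z1.ravel(), z2.ravel()])  # (Q, 2)
        self.z_sq = np.sum(self.z_nodes**2, axis=1)  # (Q,)
        self.log_w = np.log(np.outer(wq, wq).ravel())

    def loglik(self, theta: np.ndarray) -> float:
        beta, L, sigma, lam, k, alpha = _unpack_joint(theta)
        G = L @ L.T
        det_G = G[0, 0] * G[1, 1] - G[0, 1] ** 2
        if det_G <= 0 or sigma <= 0:
            return -np.inf
        Ginv = np.array([[G[1, 1], -G[0, 1]], [-G[0, 1], G[0, 0]]]) / det_G

        # Gaussian posterior of b given the longitudinal data:
        # Prec_i = X'X / sigma^2 + G^-1, mu_i = Sigma_i X'r_i / sigma^2
        Ztr = self.Xty - np.einsum("nab,b->na", self.XtX, beta)  # (n, 2)
        prec = self.XtX / sigma**2 + Ginv[None, :, :]  # (n, 2, 2)
        det_p = prec[:, 0, 0] * prec[:, 1, 1] - prec[:, 0, 1] ** 2
        cov = (
            np.stack(
                [
                    np.stack([prec[:, 1, 1], -prec[:, 0, 1]], axis=-1),
                    np.stack([-prec[:, 0, 1], prec[:, 0, 0]], axis=-1),
                ],
                axis=1,
            )
            / det_p[:, None, None]
        )  # (n, 2, 2)
        mu = np.einsum("nab,nb->na", cov, Ztr) / sigma**2  # (n, 2)
        # closed-form 2x2 Cholesky of the posterior covariance
        l11 = np.sqrt(cov[:, 0, 0])
        l21 = cov[:, 1, 0] / l11
        l22 = np.sqrt(np.maximum(cov[:, 1, 1] - l21**2, 1e-300))
        log_det_l = np.log(l11) + np.log(l22)

        # node positions b = mu + sqrt(2) L_i z   -> (n, Q, 2)
        s2 = math.sqrt(2.0)
        z = self.z_nodes
        b0 = mu[:, None, 0] + s2 * l11[:, None] * z[None, :, 0]
        b1 = (
            mu[:, None, 1]
            + s2 * (l21[:, None] * z[None, :, 0] + l22[:, None] * z[None, :, 1])
        )

        # longitudinal log-density at the nodes
        r2 = (
            self.yty
            - 2.0 * self.Xty @ beta
            + np.einsum("nab,a,b->n", self.XtX, beta, beta)
        )  # (n,)
        cross = b0 * Ztr[:, None, 0] + b1 * Ztr[:, None, 1]  # (n, Q)
        quad = (
            self.XtX[:, None, 0, 0] * b0**2
            + 2.0 * self.XtX[:, None, 0, 1] * b0 * b1
            + self.XtX[:, None, 1, 1] * b1**2
        )
        ssr = r2[:, None] - 2.0 * cross + quad
        ly = (
            -0.5 * self.n_i[:, None] * math.log(2.0 * math.pi * sigma**2)
            - ssr / (2.0 * sigma**2)
        )

        # random-effect prior log-density at the nodes
        prior_quad = (
            Ginv[0, 0] * b0**2 + 2.0 * Ginv[0, 1] * b0 * b1 + Ginv[1, 1] * b1**2
        )
        log_prior = -0.5 * (
            prior_quad + math.log((2.0 * math.pi) ** 2 * det_G)
        )

        # survival log-likelihood at the nodes (left-truncated at entry)
        a = alpha * (beta[0] + b0)  # (n, Q)
        c = alpha * (beta[1] + b1)
        expo = np.clip(
            c[:, :, None] * self.s_nodes[:, None, :], -_EXP_CLIP, _EXP_CLIP
        )
        # s-dependent factor is independent of the quadrature node
        s_part = (
            (2.0 * k / lam**k)
            * self.s_nodes ** (2.0 * k - 1.0)
            * self.s_weights
        )  # (n, P)
        cumhaz = np.exp(np.clip(a, -_EXP_CLIP, _EXP_CLIP)) * np.einsum(
            "nqp,np->nq", np.exp(expo), s_part
        )
        log_h = (
            math.log(k)
            - k * math.log(lam)
            + (k - 1.0) * np.log(self.T)[:, None]
            + a
            + c * self.sqrtT[:, None]
        )
        ls = self.delta[:, None] * log_h - cumhaz

        # adaptive-quadrature weights: w_q e^{|z|^2} * 2 det(L_i)
        log_terms = (
            self.log_w[None, :]
            + self.z_sq[None, :]
            + math.log(2.0)
            + log_det_l[:, None]
            + ly
            + log_prior
            + ls
        )
        total = logsumexp(log_terms, axis=1)
        if not np.all(np.isfinite(total)):
            return -np.inf
        return float(np.sum(total))


def joint_loglik(
    dataset: CohortDataset,
    fit: JointModelFit,
    spec: JointModelSpec | None = None,
    scores: pd.DataFrame | None = None,
) -> float:
    """Evaluate the joint marginal log-likelihood at a fit's parameters.

    Useful for quadrature-convergence checks (re-evaluate with a different
    ``quadrature_points``).
    """
    spec = (spec or fit.spec).validate()
    blocks = _blocks(dataset, spec, scores)
    data = _JointData(blocks, spec)
    theta = _pack_joint(fit)
    return data.loglik(theta)


def _pack_joint(fit: JointModelFit) -> np.ndarray:
    L = np.linalg.cholesky(np.asarray(fit.G, dtype=float) + 1e-12 * np.eye(2))
    return np.array(
        [
            fit.beta[0],
            fit.beta[1],
            math.log(max(L[0, 0], 1e-8)),
            L[1, 0],
            math.log(max(L[1, 1], 1e-8)),
            math.log(max(fit.sigma_e, 1e-8)),
            math.log(max(fit.haz_scale if fit.haz_scale else 1.0, 1e-8)),
            math.log(max(fit.haz_shape if fit.haz_shape else 1.0, 1e-8)),
            0.0 if fit.alpha is None else fit.alpha,
        ]
    )


def _marginal_weibull_start(blocks) -> tuple[float, float]:
    """Weibull fit to (entry, time, event), ignoring the longitudinal data."""
    from lifelines import WeibullFitter

    T = np.array([b["time"] for b in blocks], dtype=float)
    delta = np.array([b["event"] for b in blocks], dtype=int)
    entry = np.array([b["entry"] for b in blocks], dtype=float)
    wf = WeibullFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            wf.fit(T, event_observed=delta, entry=entry)
        return float(wf.lambda_), float(wf.rho_)
    except Exception:
        return float(np.median(T)), 2.0


def fit_joint(
    dataset: CohortDataset,
    spec: JointModelSpec | None = None,
    scores: pd.DataFrame | None = None,
) -> JointModelFit:
    """Fit the joint longitudinal-survival model by maximum likelihood.

    Initialization: :func:`fit_lmm` for the longitudinal parameters and a
    marginal Weibull fit for the baseline hazard, with ``alpha = 0``. The
    joint marginal likelihood is then maximized with L-BFGS-B; by
    construction the optimum's log-likelihood is at least the starting
    value's.
    """
    spec = (spec or JointModelSpec()).validate()
    if spec.association != "current_value":
        raise JointModelError("fit_joint requires association='current_value'")
    blocks = _blocks(dataset, spec, scores)
    if sum(b["event"] for b in blocks) == 0:
        raise JointModelError(
            "no death events: association parameter is not identifiable"
        )

    lmm = fit_lmm(dataset, JointModelSpec(**{**asdict(spec), "association": "none"}),
                  scores)
    lam0, k0 = _marginal_weibull_start(blocks)
    start = JointModelFit(
        outcome=spec.outcome,
        beta=lmm.beta,
        G=lmm.G,
        sigma_e=lmm.sigma_e,
        haz_scale=lam0,
        haz_shape=k0,
        alpha=0.0,
        loglik=np.nan,
        converged=False,
        n_mice=lmm.n_mice,
        n_obs=lmm.n_obs,
        entry_week=lmm.entry_week,
        spec=spec,
    )
    theta0 = _pack_joint(start)
    data = _JointData(blocks, spec)

    def nll(theta):
        ll = data.loglik(theta)
        return 1e12 if not np.isfinite(ll) else -ll

    bounds = [
        (None, None),
        (None, None),
        (math.log(1e-5), math.log(5.0)),
        (-5.0, 5.0),
        (math.log(1e-5), math.log(5.0)),
        (math.log(1e-5), math.log(5.0)),
        (math.log(0.05), math.log(1e4)),
        (math.log(0.3), math.log(15.0)),
        (-20.0, 20.0),
    ]
    res = optimize.minimize(
        nll,
        theta0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": spec.max_iter, "maxfun": 20000},
    )
    if not np.isfinite(res.fun):
        raise JointModelError("joint likelihood not finite at the optimum")
    beta, L, sigma, lam, k, alpha = _unpack_joint(res.x)
    return JointModelFit(
        outcome=spec.outcome,
        beta=np.asarray(beta, dtype=float),
        G=L @ L.T,
        sigma_e=sigma,
        haz_scale=lam,
        haz_shape=k,
        alpha=alpha,
        loglik=-float(res.fun),
        converged=bool(res.success),
        n_mice=len(blocks),
        n_obs=int(sum(len(b["y"]) for b in blocks)),
        entry_week=float(min(b["entry"] for b in blocks)),
        spec=spec,
    )


# -- simulation from a fit & prediction bands ----------------------------


def simulate_outcome_paths(
    fit: JointModelFit,
    weeks: np.ndarray,
    n_sim: int,
    seed: int,
    horizon: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw outcome paths and survival from a fitted joint model.

    Returns ``(values, alive)`` of shape ``(n_sim, len(weeks))``: outcome
    values on the natural scale (grams for ``log_weight``, score points
    clamped to [0, 5] for ``dss``) and a boolean aliveness mask. Survival
    is conditional on being alive at the fit's entry week. A fit without
    hazard parameters (plain LMM) yields fully alive paths.
    """
    rng = np.random.default_rng(seed)
    weeks = np.asarray(weeks, dtype=float)
    L = np.linalg.cholesky(np.asarray(fit.G, dtype=float) + 1e-12 * np.eye(2))
    b = rng.standard_normal((n_sim, 2)) @ L.T
    m = (
        fit.beta[0]
        + b[:, [0]]
        + (fit.beta[1] + b[:, [1]]) * np.sqrt(weeks)[None, :]
    )
    y = m + rng.normal(0.0, fit.sigma_e, size=m.shape)

    if fit.haz_scale is None:
        alive = np.ones_like(y, dtype=bool)
    else:
        lam, k = fit.haz_scale, fit.haz_shape
        alpha = fit.alpha or 0.0
        step = fit.spec.cumhaz_step
        end = horizon if horizon is not None else weeks.max() + 1.0
        t = np.arange(0.0, end + step, step)
        with np.errstate(divide="ignore"):
            base = (k / lam) * (t / lam) ** (k - 1.0)
        base = np.where(t > 0, base, 0.0)
        c = alpha * (fit.beta[1] + b[:, 1])  # (n,)
        a = alpha * (fit.beta[0] + b[:, 0])
        M = base[None, :] * np.exp(
            np.clip(c[:, None] * np.sqrt(t)[None, :] + a[:, None],
                    -_EXP_CLIP, _EXP_CLIP)
        )
        H = np.concatenate(
            [np.zeros((n_sim, 1)), np.cumsum((M[:, 1:] + M[:, :-1]) * 0.5 * step,
                                             axis=1)],
            axis=1,
        )
        entry_idx = int(np.searchsorted(t, fit.entry_week))
        target = H[:, entry_idx] + rng.exponential(size=n_sim)
        # first grid index where H >= target; beyond grid end = survives
        idx = (H < target[:, None]).sum(axis=1)
        death = np.where(idx >= len(t), np.inf, t[np.minimum(idx, len(t) - 1)])
        alive = death[:, None] > weeks[None, :]

    if fit.outcome == "log_weight":
        values = np.exp(y)
    else:
        values = np.clip(y, 0.0, 5.0)
    return values, alive


def predict_band(
    fit: JointModelFit,
    week_grid: np.ndarray,
    level: float = 0.95,
    n_sim: int = 2000,
    seed: int = 0,
    min_survivors: int = 50,
    conditional: bool = True,
) -> ProgressionBand:
    """Monte-Carlo prediction band from a fitted model.

    At each grid week the band is the median and the ``(1 -+ level)/2``
    quantiles of the outcome among simulated mice still alive at that week
    (the study's bands are drawn only over ages where mice are alive).
    The grid is truncated with a warning when fewer than ``min_survivors``
    simulated mice remain. With ``conditional=False`` the quantiles are
    taken over *all* simulated trajectories regardless of survival — the
    extrapolated "expected progression" envelope that stays defined at ages
    almost no untreated mice reach. Deterministic given ``seed``.
    """
    if not fit.converged:
        warnings.warn("prediction band from a non-converged fit", stacklevel=2)
    week_grid = np.asarray(week_grid, dtype=float)
    values, alive = simulate_outcome_paths(fit, week_grid, n_sim, seed)
    if not conditional:
        alive = np.ones_like(alive, dtype=bool)
    n_alive = alive.sum(axis=0)
    usable = n_alive >= min_survivors
    if not usable.all():
        first_bad = int(np.argmin(usable))
        if first_bad == 0 and not usable[0]:
            raise JointModelError("fewer than min_survivors at the first grid week")
        warnings.warn(
            f"band truncated at week {week_grid[first_bad]:g}: "
            f"fewer than {min_survivors} simulated survivors",
            stacklevel=2,
        )
        week_grid = week_grid[:first_bad]
        values, alive, n_alive = (
            values[:, :first_bad],
            alive[:, :first_bad],
            n_alive[:first_bad],
        )

    lo_q, hi_q = (1.0 - level) / 2.0, (1.0 + level) / 2.0
    med = np.empty(len(week_grid))
    lower = np.empty(len(week_grid))
    upper = np.empty(len(week_grid))
    for j in range(len(week_grid)):
        vals = values[alive[:, j], j]
        med[j] = np.quantile(vals, 0.5)
        lower[j] = np.quantile(vals, lo_q)
        upper[j] = np.quantile(vals, hi_q)
    return ProgressionBand(
        outcome=fit.outcome,
        weeks=week_grid.astype(int)
        if np.allclose(week_grid, np.round(week_grid))
        else week_grid,
        median=med,
        lower=lower,
        upper=upper,
        level=level,
        n_sim=n_sim,
        n_alive=n_alive,
    )


def band_from_reference(
    training: CohortDataset,
    outcome: str = "log_weight",
    extrapolate_to: int = 12,
    level: float = 0.95,
    n_sim: int = 2000,
    seed: int = 0,
    spec: JointModelSpec | None = None,
    scores: pd.DataFrame | None = None,
    conditional: bool = True,
) -> tuple[JointModelFit, ProgressionBand]:
    """Fit the joint model on a reference cohort and build its band.

    This is the "expected disease progression" object: the composition
    ``fit_joint -> predict_band`` on the week grid from the first observed
    week to ``extrapolate_to`` (extrapolation past the observed range is
    allowed and expected; pass ``conditional=False`` to keep the band
    defined at ages nearly no untreated mice reach).
    """
    spec = spec or JointModelSpec(outcome=outcome)
    if spec.outcome != outcome:
        raise JointModelError("spec.outcome does not match requested outcome")
    fit = fit_joint(training, spec, scores)
    first = int(training.observations["week"].min())
    grid = np.arange(first, extrapolate_to + 1)
    band = predict_band(
        fit, grid, level=level, n_sim=n_sim, seed=seed, conditional=conditional
    )
    return fit, band
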