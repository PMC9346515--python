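"""Independent oracles used by the test suite.

Everything here is deliberately written from first principles — explicit
product-limit construction, dense-grid numerical integration, permutation
nulls — so the package implementation is checked against a second route,
not against itself.
"""

from __future__ import annotations

import numpy as np


def km_oracle(times, events):
    """Explicit hand product-limit estimate.

    Returns (event_times, survival) by walking the distinct event times and
    counting risk sets directly.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    out_t, out_s = [], []
    s = 1.0
    for t in sorted(set(times[events == 1])):
        n_risk = int(np.sum(times >= t))
        d = int(np.sum((times == t) & (events == 1)))
        s *= 1.0 - d / n_risk
        out_t.append(t)
        out_s.append(s)
    return np.array(out_t), np.array(out_s)


def dense_grid_joint_loglik(
    blocks,
    beta,
    G,
    sigma,
    lam,
    k,
    alpha,
    n_b=401,
    span=5.0,
    n_t=1500,
):
    """Joint marginal log-likelihood by dense 2-D trapezoid integration.

    For each mouse the random-effect integral is evaluated on an explicit
    (b0, b1) grid spanning ``span`` prior SDs, with the conditional
    longitudinal normal density, the left-truncated Weibull-by-association
    survival density (cumulative hazard by plain trapezoid on a fine time
    grid) and the bivariate normal prior all computed from scratch.
    """
    beta = np.asarray(beta, dtype=float)
    G = np.asarray(G, dtype=float)
    sd0, sd1 = np.sqrt(G[0, 0]), np.sqrt(G[1, 1])
    b0_grid = np.linspace(-span * sd0, span * sd0, n_b)
    b1_grid = np.linspace(-span * sd1, span * sd1, n_b)
    B0, B1 = np.meshgrid(b0_grid, b1_grid, indexing="ij")
    Ginv = np.linalg.inv(G)
    log_prior = -0.5 * (
        Ginv[0, 0] * B0**2 + 2 * Ginv[0, 1] * B0 * B1 + Ginv[1, 1] * B1**2
    ) - 0.5 * np.log((2 * np.pi) ** 2 * np.linalg.det(G))

    total = 0.0
    for blk in blocks:
        y, X = blk["y"], blk["X"]
        T, delta, entry = blk["time"], blk["event"], blk["entry"]

        ly = np.zeros_like(B0)
        for j in range(len(y)):
            mean = beta[0] + B0 + (beta[1] + B1) * X[j, 1]
            ly += -0.5 * np.log(2 * np.pi * sigma**2) - (y[j] - mean) ** 2 / (
                2 * sigma**2
            )

        # cumulative hazard over [entry, T] on a fine time grid; the
        # b0-dependence factorizes out of the integral
        t = np.linspace(entry, T, n_t)
        base = (k / lam) * (t / lam) ** (k - 1.0)
        expo = alpha * (beta[1] + b1_grid[:, None]) * np.sqrt(t)[None, :]
        inner = np.trapezoid(base[None, :] * np.exp(expo), t, axis=1)  # (n_b,)
        cumhaz = np.exp(alpha * (beta[0] + B0)) * inner[None, :]

        log_h = (
            np.log(k)
            - k * np.log(lam)
            + (k - 1.0) * np.log(T)
            + alpha * (beta[0] + B0 + (beta[1] + B1) * np.sqrt(T))
        )
        ls = delta * log_h - cumhaz

        log_int = ly + ls + log_prior
        mx = log_int.max()
        integral = np.trapezoid(
            np.trapezoid(np.exp(log_int - mx), b1_grid, axis=1), b0_grid
        )
        total += mx + np.log(integral)
    return float(total)


def kruskal_permutation_p(groups, n_perm, seed):
    """Monte-Carlo permutation p-value for the Kruskal-Wallis H statistic."""
    from scipy import stats

    groups = [np.asarray(g, dtype=float) for g in groups]
    sizes = [len(g) for g in groups]
    pooled = np.concatenate(groups)
    h_obs = stats.kruskal(*groups).statistic
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        parts = np.split(perm, np.cumsum(sizes)[:-1])
        if stats.kruskal(*parts).statistic >= h_obs - 1e-12:
            count += 1
    return count / n_perm


def jt_statistic(groups):
    """Plain Jonckheere-Terpstra statistic (ties count 1/2)."""
    J = 0.0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            a = np.asarray(groups[i])[:, None]
            b = np.asarray(groups[j])[None, :]
            J += np.sum(b > a) + 0.5 * np.sum(b == a)
    return J


def jt_permutation_p(groups, n_perm, seed):
    """Monte-Carlo permutation p-value for an increasing JT alternative."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    sizes = [len(g) for g in groups]
    pooled = np.concatenate(groups)
    j_obs = jt_statistic(groups)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        parts = np.split(perm, np.cumsum(sizes)[:-1])
        if jt_statistic(parts) >= j_obs - 1e-12:
            count += 1
    return count / n_perm
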