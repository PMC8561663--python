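"""Dirichlet-multinomial likelihood, maximum-likelihood fit, and
structure-matched neutral simulation.

The Dirichlet-multinomial (DMN) is the neutral sampling model for per-host
community counts: each host's composition ``p_i`` is drawn from a Dirichlet
distribution with parameter vector ``gamma``, and counts are then drawn
multinomially given the host's total ``N_i``.  The distribution is
parameterized here by the expected relative abundances ``pi`` (a point on
the probability simplex) and the overdispersion ``theta`` in (0, 1), with

    gamma_j = pi_j * (1 - theta) / theta,       sum_j gamma_j = (1-theta)/theta.

``theta -> 0`` recovers plain multinomial sampling (no between-host
compositional variance beyond counting noise); larger ``theta`` means hosts
differ more in composition than multinomial sampling alone would allow.
Species differ in their colonization probability ``pi_j`` but not in
within-host competitive ability — no interactions are encoded.

The log-likelihood includes the multinomial coefficient, so reported values
differ from coefficient-free conventions only by a data-dependent additive
constant; comparisons between fits on the *same* data are unaffected.

"Structure-matched" simulation draws synthetic data with the same number of
hosts and the same per-host total count as an empirical table, which is the
null ensemble used by the co-occurrence test in :mod:`dmnull.neutral`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import digamma, gammaln

from .data_io import CommunityMatrix

__all__ = [
    "DMFit",
    "dm_log_likelihood",
    "fit_dmn",
    "simulate_structure_matched",
    "theta_standard_error",
]


@dataclass(frozen=True)
class DMFit:
    """Maximum-likelihood Dirichlet-multinomial fit.

    Attributes
    ----------
    species_names : labels of the species actually fitted (all-zero columns
        are excluded beforehand and listed in ``dropped_species``).
    pi : expected relative abundance per fitted species (simplex vector).
    theta : overdispersion in (0, 1).
    gamma : ``pi * (1-theta)/theta``.
    loglik : maximized log-likelihood (natural log, multinomial
        coefficients included).
    """

    species_names: tuple[str, ...]
    pi: np.ndarray
    theta: float
    loglik: float
    n_hosts: int
    converged: bool
    iterations: int
    dropped_species: tuple[str, ...] = field(default_factory=tuple)

    @property
    def gamma(self) -> np.ndarray:
        return self.pi * (1.0 - self.theta) / self.theta

    def to_dict(self) -> dict:
        return {
            "pi": {s: float(p) for s, p in zip(self.species_names, self.pi)},
            "theta": float(self.theta),
            "loglik": float(self.loglik),
            "n_hosts": int(self.n_hosts),
            "converged": bool(self.converged),
            "iterations": int(self.iterations),
            "dropped_species": list(self.dropped_species),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DMFit":
        names = tuple(d["pi"].keys())
        return cls(
            species_names=names,
            pi=np.array([d["pi"][s] for s in names], dtype=float),
            theta=float(d["theta"]),
            loglik=float(d["loglik"]),
            n_hosts=int(d["n_hosts"]),
            converged=bool(d["converged"]),
            iterations=int(d["iterations"]),
            dropped_species=tuple(d.get("dropped_species", ())),
        )


def _check_pi_theta(pi: np.ndarray, theta: float, k: int) -> np.ndarray:
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (k,):
        raise ValueError(f"pi has shape {pi.shape}, expected ({k},)")
    if np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-8:
        raise ValueError("pi must be a nonnegative vector summing to 1")
    if not (0.0 < theta < 1.0):
        raise ValueError("theta must lie in the open interval (0, 1)")
    return pi


def _dm_loglik_gamma(counts: np.ndarray, totals: np.ndarray, gamma: np.ndarray) -> float:
    """Sum over hosts of the DMN log-pmf with parameter vector gamma.

    log-gamma differences are used throughout (never factorials), which is
    stable for totals of order 1e5.
    """
    gplus = gamma.sum()
    coef = gammaln(totals + 1.0).sum() - gammaln(counts + 1.0).sum()
    ll = (
        coef
        + len(totals) * gammaln(gplus)
        - gammaln(totals + gplus).sum()
        + gammaln(counts + gamma).sum()
        - len(totals) * gammaln(gamma).sum()
    )
    return float(ll)


def dm_log_likelihood(m: CommunityMatrix, pi, theta: float) -> float:
    """Dirichlet-multinomial log-likelihood of a count table.

    Returns ``sum_i log P(x_i | N_i, pi, theta)`` with
    ``gamma_j = pi_j (1-theta)/theta``, multinomial coefficients included.
    A zero ``pi_j`` is only admissible if species ``j`` has all-zero counts
    (the corresponding factor is then 1).
    """
    counts = m.counts.astype(float)
    totals = m.totals.astype(float)
    pi = _check_pi_theta(pi, theta, m.n_species)
    zero = pi == 0.0
    if zero.any():
        if counts[:, zero].sum() > 0:
            return -np.inf
        counts = counts[:, ~zero]
        pi = pi[~zero] / pi[~zero].sum()
    gamma = pi * (1.0 - theta) / theta
    return _dm_loglik_gamma(counts, totals, gamma)


def _neg_loglik_and_grad(eta, counts, totals, coef):
    """Negative log-likelihood and gradient in eta = log(gamma)."""
    gamma = np.exp(eta)
    gplus = gamma.sum()
    n = len(totals)
    ll = (
        coef
        + n * gammaln(gplus)
        - gammaln(totals + gplus).sum()
        + gammaln(counts + gamma).sum()
        - n * gammaln(gamma).sum()
    )
    # d ll / d gamma_j = n psi(g+) - sum_i psi(N_i+g+) + sum_i psi(x_ij+g_j) - n psi(g_j)
    common = n * digamma(gplus) - digamma(totals + gplus).sum()
    per_j = digamma(counts + gamma).sum(axis=0) - n * digamma(gamma)
    grad = gamma * (common + per_j)
    return -ll, -grad


def _moment_init(counts: np.ndarray, totals: np.ndarray) -> tuple[np.ndarray, float]:
    """Method-of-moments (pi, theta) from per-host proportions."""
    props = counts / totals[:, None]
    pbar = props.mean(axis=0)
    pbar = pbar / pbar.sum()
    s2 = props.var(axis=0, ddof=1)
    inv_n = float(np.mean(1.0 / totals))
    # Var(x_j/N) = p_j (1-p_j) (theta + (1-theta)/N): solve for theta per species
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = s2 / (pbar * (1.0 - pbar))
    valid = np.isfinite(ratio) & (pbar > 0) & (pbar < 1)
    if valid.any() and inv_n < 1.0:
        theta = float(np.mean((ratio[valid] - inv_n) / (1.0 - inv_n)))
    else:
        theta = 0.1
    theta = float(np.clip(theta, 1e-3, 0.95))
    return pbar, theta


def fit_dmn(m: CommunityMatrix) -> DMFit:
    """Maximum-likelihood Dirichlet-multinomial fit to a count table.

    All-zero species columns are excluded before fitting and reported in
    ``dropped_species`` (their maximum-likelihood abundance is the boundary
    value 0, which the Dirichlet parameterization cannot represent).
    Optimization runs in the unconstrained coordinates ``log(gamma)`` from a
    method-of-moments start, by quasi-Newton ascent with the exact gradient;
    ``pi = gamma/gamma_+`` and ``theta = 1/(1+gamma_+)`` are recovered from
    the optimum.

    Species are canonicalized to name-sorted order internally, so the fit is
    exactly invariant to the column order of the input.
    """
    totals = m.totals
    if int((totals > 0).sum()) < 2:
        raise ValueError("insufficient samples: need >= 2 hosts with positive totals")
    colsums = m.counts.sum(axis=0)
    dropped = tuple(s for s, c in zip(m.species_names, colsums) if c == 0)
    if dropped:
        warnings.warn(
            f"excluding all-zero species from fit: {list(dropped)}", stacklevel=2
        )
    kept = [j for j, c in enumerate(colsums) if c > 0]
    if len(kept) < 2:
        raise ValueError("need >= 2 species with nonzero counts")
    names = [m.species_names[j] for j in kept]
    order = np.argsort(names)  # canonical order: fit invariant to column order
    names_sorted = [names[i] for i in order]
    pos = totals > 0
    counts = m.counts[np.ix_(pos, kept)][:, order].astype(float)
    totals = totals[pos].astype(float)

    pbar, theta0 = _moment_init(counts, totals)
    gamma0 = pbar * (1.0 - theta0) / theta0
    coef = gammaln(totals + 1.0).sum() - gammaln(counts + 1.0).sum()

    res = minimize(
        _neg_loglik_and_grad,
        np.log(gamma0),
        args=(counts, totals, coef),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 500, "ftol": 1e-11, "gtol": 1e-8},
    )
    gamma = np.exp(res.x)
    gplus = gamma.sum()
    pi_sorted = gamma / gplus
    theta = 1.0 / (1.0 + gplus)
    loglik = _dm_loglik_gamma(counts, totals, gamma)

    inv = np.empty_like(order)
    inv[order] = np.arange(len(order))
    return DMFit(
        species_names=tuple(names),
        pi=pi_sorted[inv],
        theta=float(theta),
        loglik=float(loglik),
        n_hosts=int(len(totals)),
        converged=bool(res.success),
        iterations=int(res.nit),
        dropped_species=dropped,
    )


def theta_standard_error(fit: DMFit, m: CommunityMatrix) -> float:
    """Asymptotic standard error of the fitted overdispersion.

    Observed information in ``log(gamma)`` coordinates (finite differences of
    the exact gradient), inverted and pushed through the delta method with
    ``d theta / d eta_j = -gamma_j / (1 + gamma_+)^2``.
    """
    kept = [j for j, s in enumerate(m.species_names) if s in fit.species_names]
    pos = m.totals > 0
    counts = m.counts[np.ix_(pos, kept)].astype(float)
    # align columns to fit.species_names order
    name_by_col = [m.species_names[j] for j in kept]
    perm = [name_by_col.index(s) for s in fit.species_names]
    counts = counts[:, perm]
    totals = m.totals[pos].astype(float)
    coef = gammaln(totals + 1.0).sum() - gammaln(counts + 1.0).sum()

    eta = np.log(fit.gamma)
    k = len(eta)
    h = 1e-5
    hess = np.empty((k, k))
    for j in range(k):
        e = np.zeros(k)
        e[j] = h
        _, gp = _neg_loglik_and_grad(eta + e, counts, totals, coef)
        _, gm = _neg_loglik_and_grad(eta - e, counts, totals, coef)
        hess[:, j] = (gp - gm) / (2.0 * h)
    hess = 0.5 * (hess + hess.T)
    cov = np.linalg.pinv(hess)
    gamma = fit.gamma
    dtheta = -gamma / (1.0 + gamma.sum()) ** 2
    var = float(dtheta @ cov @ dtheta)
    return float(np.sqrt(max(var, 0.0)))


def sample_dirichlet_multinomial(
    rng: np.random.Generator,
    gamma: np.ndarray,
    totals: np.ndarray,
    size: int | None = None,
) -> np.ndarray:
    """Draw DMN count arrays with a canonical (sorted-gamma) RNG stream.

    Returns shape ``(len(totals), k)`` or ``(size, len(totals), k)``.  The
    underlying Dirichlet and multinomial draws are made in a canonical
    component order (ascending gamma, stable) and mapped back, so results
    for permuted gamma vectors are the exact permutation of each other.
    """
    gamma = np.asarray(gamma, dtype=float)
    totals = np.asarray(totals)
    if np.any(totals < 0):
        raise ValueError("totals must be nonnegative")
    order = np.argsort(gamma, kind="stable")
    inv = np.empty_like(order)
    inv[order] = np.arange(len(order))
    shape = (len(totals),) if size is None else (size, len(totals))
    p = rng.dirichlet(gamma[order], size=shape)
    counts = rng.multinomial(totals, p)
    return counts[..., inv]


def simulate_structure_matched(
    fit: DMFit,
    totals,
    seed: int,
    lineage: str = "simulated",
) -> CommunityMatrix:
    """Simulate a count table matching the structure of an empirical one.

    For each host ``i`` a composition ``p_i ~ Dirichlet(gamma)`` is drawn and
    counts ``~ Multinomial(totals[i], p_i)``; row sums therefore equal
    ``totals`` exactly.  The same seed reproduces the same table.
    """
    totals = np.asarray(totals)
    if totals.ndim != 1:
        raise ValueError("totals must be a 1-D integer vector")
    rng = np.random.default_rng(seed)
    counts = sample_dirichlet_multinomial(rng, fit.gamma, totals)
    host_ids = [f"sim_{i:05d}" for i in range(len(totals))]
    return CommunityMatrix(
        host_ids, [lineage] * len(totals), fit.species_names, counts
    )
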