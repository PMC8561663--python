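"""Synthetic per-host community count data.

Generates count tables with the statistical structure the analysis assumes,
so every stage of the package can be exercised without any experimental
data:

* **neutral** communities — Dirichlet-multinomial: composition
  ``p ~ Dirichlet(pi (1-theta)/theta)`` per host, counts multinomial given
  the host's total.  This is exactly the null process of the co-occurrence
  test.
* **interacting** communities — logistic-normal-multinomial: a latent
  log-abundance vector ``z ~ N(mu, sigma)`` per host, composition
  ``softmax(z)``, counts multinomial.  Off-diagonal structure in ``sigma``
  injects true interspecies correlations of either sign, the alternative
  the neutral test is designed to detect.  This alternative is a modeling
  choice of the package: it nests compositional coupling and arbitrary sign
  structure with few parameters.

Per-host totals are either a fixed list or draws from a truncated
log-normal.  The default preset emulates the wild-type (N2) worm data: 8
species named MYb120...MYb71, ``pi`` and ``theta`` from the N2
maximum-likelihood fit (theta = 0.1698, MYb71 dominant at 0.662), and totals
spanning 1,680-67,200 CFU/worm with median ~1.3e4.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import CommunityMatrix
from .dmn import sample_dirichlet_multinomial

__all__ = [
    "TotalModel",
    "SyntheticSpec",
    "generate_totals",
    "generate_neutral",
    "generate_interacting",
    "generate",
    "n2_neutral_spec",
    "n2_interacting_spec",
    "competition_factor_sigma",
    "N2_SPECIES",
    "N2_PI",
    "N2_THETA",
]

# Wild-type (N2) maximum-likelihood DMN parameters; pi renormalized to the
# simplex (the printed 4-decimal values sum to 1.0001).
N2_SPECIES = (
    "MYb120",
    "MYb181",
    "MYb238",
    "MYb27",
    "MYb45",
    "MYb53",
    "MYb56",
    "MYb71",
)
_N2_PI_RAW = np.array(
    [0.0096, 0.0015, 0.0384, 0.0866, 0.0290, 0.0828, 0.0903, 0.6619]
)
N2_PI = _N2_PI_RAW / _N2_PI_RAW.sum()
N2_THETA = 0.1698

# Totals envelope of the wild-type data: 1,680-67,200 CFU/worm, median 13,000.
TOTAL_MIN = 1_680
TOTAL_MAX = 67_200
TOTAL_MEANLOG = float(np.log(13_000.0))
TOTAL_SDLOG = 0.8


@dataclass(frozen=True)
class TotalModel:
    """Per-host total-count model: fixed list or truncated log-normal."""

    kind: str = "lognormal"  # "fixed" | "lognormal"
    values: tuple[int, ...] | None = None
    meanlog: float = TOTAL_MEANLOG
    sdlog: float = TOTAL_SDLOG
    min_total: int = TOTAL_MIN
    max_total: int = TOTAL_MAX

    def __post_init__(self):
        if self.kind not in ("fixed", "lognormal"):
            raise ValueError(f"unknown total model {self.kind!r}")
        if self.kind == "fixed":
            if not self.values:
                raise ValueError("fixed total model needs values")
            if any(v < 0 for v in self.values):
                raise ValueError("totals must be nonnegative")
        else:
            if not (0 < self.min_total <= self.max_total):
                raise ValueError("need 0 < min_total <= max_total")
            if self.sdlog <= 0:
                raise ValueError("sdlog must be positive")

    @classmethod
    def fixed(cls, values) -> "TotalModel":
        return cls(kind="fixed", values=tuple(int(v) for v in values))


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of one synthetic data set.

    ``model='neutral'`` uses ``pi``/``theta``; ``model='interacting'`` uses
    ``mu``/``sigma`` (sigma symmetric positive semi-definite).
    """

    n_hosts: int = 164
    species_names: tuple[str, ...] = N2_SPECIES
    model: str = "neutral"
    pi: np.ndarray | None = None
    theta: float | None = N2_THETA
    mu: np.ndarray | None = None
    sigma: np.ndarray | None = None
    total_model: TotalModel = field(default_factory=TotalModel)
    seed: int = 0
    lineage: str = "synthetic"

    def __post_init__(self):
        k = len(self.species_names)
        if self.n_hosts < 1:
            raise ValueError("n_hosts must be >= 1")
        if self.model == "neutral":
            pi = N2_PI if self.pi is None else np.asarray(self.pi, dtype=float)
            if pi.shape != (k,) or np.any(pi < 0) or abs(pi.sum() - 1) > 1e-8:
                raise ValueError("pi must be a simplex vector matching species")
            if not (0.0 < float(self.theta) < 1.0):
                raise ValueError("theta must lie in (0, 1)")
            object.__setattr__(self, "pi", pi)
        elif self.model == "interacting":
            if self.mu is None or self.sigma is None:
                raise ValueError("interacting model needs mu and sigma")
            mu = np.asarray(self.mu, dtype=float)
            sigma = np.asarray(self.sigma, dtype=float)
            if mu.shape != (k,) or sigma.shape != (k, k):
                raise ValueError("mu/sigma shapes must match species count")
            if not np.allclose(sigma, sigma.T):
                raise ValueError("sigma must be symmetric")
            if np.linalg.eigvalsh(sigma).min() < -1e-8:
                raise ValueError("sigma must be positive semi-definite")
            object.__setattr__(self, "mu", mu)
            object.__setattr__(self, "sigma", sigma)
        else:
            raise ValueError(f"unknown model {self.model!r}")


def generate_totals(spec: SyntheticSpec) -> np.ndarray:
    """Per-host integer totals; reproducible from ``spec.seed``."""
    tm = spec.total_model
    if tm.kind == "fixed":
        vals = np.asarray(tm.values, dtype=np.int64)
        if len(vals) != spec.n_hosts:
            raise ValueError(
                f"fixed totals length {len(vals)} != n_hosts {spec.n_hosts}"
            )
        return vals
    rng = np.random.default_rng(spec.seed)
    out = np.empty(spec.n_hosts, dtype=np.int64)
    filled = 0
    while filled < spec.n_hosts:
        draw = rng.lognormal(tm.meanlog, tm.sdlog, size=2 * (spec.n_hosts - filled))
        draw = np.rint(draw).astype(np.int64)
        draw = draw[(draw >= tm.min_total) & (draw <= tm.max_total)]
        take = min(len(draw), spec.n_hosts - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    return out


def _host_ids(n: int) -> list[str]:
    return [f"synth_{i:05d}" for i in range(n)]


def generate_neutral(spec: SyntheticSpec) -> CommunityMatrix:
    """Neutral (Dirichlet-multinomial) community table."""
    if spec.model != "neutral":
        raise ValueError("spec.model must be 'neutral'")
    totals = generate_totals(spec)
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 1]))
    gamma = spec.pi * (1.0 - spec.theta) / spec.theta
    counts = sample_dirichlet_multinomial(rng, gamma, totals)
    return CommunityMatrix(
        _host_ids(spec.n_hosts),
        [spec.lineage] * spec.n_hosts,
        spec.species_names,
        counts,
    )


def generate_interacting(spec: SyntheticSpec) -> CommunityMatrix:
    """Interacting (logistic-normal-multinomial) community table."""
    if spec.model != "interacting":
        raise ValueError("spec.model must be 'interacting'")
    totals = generate_totals(spec)
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 2]))
    z = rng.multivariate_normal(
        spec.mu, spec.sigma, size=spec.n_hosts, method="svd"
    )
    z -= z.max(axis=1, keepdims=True)
    p = np.exp(z)
    p /= p.sum(axis=1, keepdims=True)
    counts = rng.multinomial(totals, p)
    return CommunityMatrix(
        _host_ids(spec.n_hosts),
        [spec.lineage] * spec.n_hosts,
        spec.species_names,
        counts,
    )


def generate(spec: SyntheticSpec) -> CommunityMatrix:
    """Dispatch on ``spec.model``."""
    if spec.model == "neutral":
        return generate_neutral(spec)
    return generate_interacting(spec)


def competition_factor_sigma(loading: float = 1.5) -> np.ndarray:
    """Rank-1 covariance for a single competitive trade-off axis.

    Half the species load ``+loading`` on a latent factor and half
    ``-loading``, so every between-block species pair is strongly
    anticorrelated in latent log-abundance.  This is the canonical
    "interacting" alternative used in the package's power checks: a single
    competition axis is the simplest structure that drives many pairwise
    correlations negative at once (a lone anticorrelated species pair is
    largely masked by the positive compositional coupling that total-size
    variation induces among the remaining species).
    """
    b = np.array([1.0, -1.0, -1.0, 1.0, 1.0, -1.0, -1.0, 1.0])
    return float(loading) ** 2 * np.outer(b, b)


def n2_interacting_spec(
    n_hosts: int = 164,
    seed: int = 0,
    loading: float = 1.5,
    lineage: str = "interacting",
) -> SyntheticSpec:
    """Interacting preset: N2-like mean composition plus a competition axis."""
    return SyntheticSpec(
        n_hosts=n_hosts,
        species_names=N2_SPECIES,
        model="interacting",
        theta=None,
        mu=np.log(N2_PI),
        sigma=competition_factor_sigma(loading),
        total_model=TotalModel(),
        seed=seed,
        lineage=lineage,
    )


def n2_neutral_spec(
    n_hosts: int = 164, seed: int = 0, lineage: str = "N2-like"
) -> SyntheticSpec:
    """Wild-type-like neutral preset: 8 MYb species, N2 (pi, theta), realistic totals."""
    return SyntheticSpec(
        n_hosts=n_hosts,
        species_names=N2_SPECIES,
        model="neutral",
        pi=N2_PI,
        theta=N2_THETA,
        total_model=TotalModel(),
        seed=seed,
        lineage=lineage,
    )
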