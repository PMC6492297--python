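"""Synthetic-data generators for the three study designs.

* ``gen_toy`` — a single pair of underlying variables: one trait vector a,
  and many replicate corruptions b = kappa*a + noise with a fresh coupling
  kappa ~ U(0, c) per replicate.  The 1,000 replicate datasets play the
  role of replications of one unobserved relation.
* ``gen_fc_dataset`` — the functional-connectivity scenario: each subject
  has a latent coupling beta_n between two "neural" channels, a behavioural
  trait noisily reflecting the implied channel correlation, and R noisy
  short-window correlation estimates (Fisher-z transformed) as replications.
* ``perturb_replications`` — corrupts a fraction of replication columns by
  shuffling them across subjects, emulating re-runs of a stochastic
  inference algorithm that lost the subject-level signal.

All generators are pure functions of their config: same seed, same data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import ReplicationMatrix

__all__ = [
    "ToyConfig",
    "FCSimConfig",
    "PerturbConfig",
    "gen_toy",
    "beta_to_corr",
    "gen_fc_dataset",
    "perturb_replications",
]


@dataclass
class ToyConfig:
    """Settings for the toy generator.

    ``c`` is the maximum coupling: each replicate dataset draws its own
    kappa ~ U(0, c), so c = 0 is the global null and larger c makes the
    underlying relation stronger on average.
    """

    N: int = 100
    n_datasets: int = 1000
    c: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 3:
            raise ValueError("need N >= 3 subjects")
        if self.c < 0:
            raise ValueError("c must be nonnegative")
        if self.n_datasets < 1:
            raise ValueError("need at least one dataset")


@dataclass
class FCSimConfig:
    """Settings for the functional-connectivity simulation.

    Each subject n gets a coupling beta_n ~ U(beta_lo, beta_hi) (forced to 0
    when ``effect`` is False), a latent two-channel series of ``latent_len``
    samples with corr(s1, s2) = beta_n / sqrt(beta_n^2 + 1), and a trait
    x_n = corr + 0.5 * N(0, 1).  Every replication subsamples T time points
    (without replacement, independently per replication), adds N(0, sigma^2)
    measurement noise to both channels, and records the Fisher-z of the
    sample correlation.
    """

    N: int = 200
    R: int = 100
    T: int = 100
    sigma: float = 0.25
    beta_lo: float = -0.2
    beta_hi: float = 0.2
    latent_len: int = 10_000
    effect: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.T < 3:
            raise ValueError("need T >= 3 samples per measurement")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.beta_lo > self.beta_hi:
            raise ValueError("beta_lo must not exceed beta_hi")
        if self.latent_len < self.T:
            raise ValueError("latent series must be at least T samples long")


@dataclass
class PerturbConfig:
    """Fraction of replication columns to subject-shuffle, and the seed."""

    fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")


def gen_toy(cfg: ToyConfig) -> tuple[np.ndarray, np.ndarray]:
    """Generate the toy trait a and its N x n_datasets replicate matrix B.

    ``a`` is drawn once (standard normal); every column j of B uses a fresh
    coupling kappa_j ~ U(0, c) and fresh unit-variance Gaussian noise:
    ``B[:, j] = kappa_j * a + eps_j``.
    """
    rng = np.random.default_rng(cfg.seed)
    a = rng.standard_normal(cfg.N)
    kappa = rng.uniform(0.0, cfg.c, size=cfg.n_datasets) if cfg.c > 0 else np.zeros(cfg.n_datasets)
    eps = rng.standard_normal((cfg.N, cfg.n_datasets))
    b = a[:, None] * kappa[None, :] + eps
    return a, b


def beta_to_corr(beta):
    """Latent channel correlation implied by coupling beta: beta/sqrt(beta^2+1).

    Exact for s2 = beta*s1 + eps with unit-variance s1 and eps.
    """
    beta = np.asarray(beta, dtype=float)
    out = beta / np.sqrt(beta * beta + 1.0)
    return float(out) if out.ndim == 0 else out


def gen_fc_dataset(
    cfg: FCSimConfig,
) -> tuple[ReplicationMatrix, np.ndarray, np.ndarray]:
    """Generate one FC dataset: (Y, trait vector x, per-subject couplings beta)."""
    rng = np.random.default_rng(cfg.seed)
    n, r, t, latent = cfg.N, cfg.R, cfg.T, cfg.latent_len

    if cfg.effect:
        beta = rng.uniform(cfg.beta_lo, cfg.beta_hi, size=n)
    else:
        beta = np.zeros(n)
    s1 = rng.standard_normal((n, latent))
    s2 = beta[:, None] * s1 + rng.standard_normal((n, latent))
    corr = beta_to_corr(beta)
    x = corr + 0.5 * rng.standard_normal(n)

    idx = np.empty((n, r, t), dtype=np.intp)
    for sub in range(n):
        for rep in range(r):
            idx[sub, rep] = rng.choice(latent, size=t, replace=False)
    rows = np.arange(n)[:, None, None]
    d1 = s1[rows, idx] + cfg.sigma * rng.standard_normal((n, r, t))
    d2 = s2[rows, idx] + cfg.sigma * rng.standard_normal((n, r, t))

    d1 -= d1.mean(axis=2, keepdims=True)
    d2 -= d2.mean(axis=2, keepdims=True)
    num = np.sum(d1 * d2, axis=2)
    den = np.sqrt(np.sum(d1 * d1, axis=2) * np.sum(d2 * d2, axis=2))
    rho = np.clip(num / den, -1.0 + 1e-15, 1.0 - 1e-15)
    y = np.arctanh(rho)
    return ReplicationMatrix(y), x, beta


def perturb_replications(
    Y: ReplicationMatrix | np.ndarray,
    cfg: PerturbConfig,
) -> ReplicationMatrix:
    """Shuffle a random ceil(fraction * R) subset of columns across subjects.

    Values are only re-assigned to different subjects, never altered, so each
    column keeps its multiset of values; untouched columns are copied as is.
    """
    Y = Y if isinstance(Y, ReplicationMatrix) else ReplicationMatrix(np.asarray(Y))
    rng = np.random.default_rng(cfg.seed)
    n, r = Y.values.shape
    n_corrupt = int(np.ceil(cfg.fraction * r))
    out = Y.values.copy()
    if n_corrupt:
        cols = rng.choice(r, size=n_corrupt, replace=False)
        for j in cols:
            out[:, j] = out[rng.permutation(n), j]
    return ReplicationMatrix(
        out,
        subject_ids=list(Y.subject_ids),
        replication_ids=list(Y.replication_ids),
    )
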