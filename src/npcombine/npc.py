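"""Two-level permutation non-parametric combination (NPC) inference.

The procedure tests, for each observed variable x_i, whether it is
associated with the unobserved quantity of which the R columns of Y are
noisy replications:

I.   First level: a parametric two-sided Pearson-correlation test between
     every replication y_j and x_i gives an R-vector of p-values, which is
     summarised by its geometric mean (Fisher-style combining, working in
     log space) or arithmetic mean (Edgington-style).
II.  Second level: the rows of X are permuted K times — the *same*
     permutations for every variable and replication, so cross-variable
     dependence is carried through — and the summary is recomputed for
     each permutation, giving its null distribution.
III. The NPC p-value is the (+1-corrected) proportion of permuted
     summaries at least as small as the observed one,
     ``p = (#{k: s_k <= s_obs} + 1) / (K + 1)``.

Family-wise error control uses the min-p distribution (the minimum
permuted summary across variables per permutation); FDR control applies
Benjamini-Hochberg to the per-variable NPC p-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np
from scipy import special
from statsmodels.stats.multitest import multipletests

from .data import (
    DimensionMismatchError,
    ReplicationMatrix,
    TraitMatrix,
    check_matched,
)

__all__ = [
    "DEFAULT_P_FLOOR",
    "FirstLevelResult",
    "PermutationScheme",
    "NPCResult",
    "combine_mean",
    "combine_gmean",
    "fisher_z",
    "first_level_pvalues",
    "make_permutation_scheme",
    "second_level_pvalue",
    "fwe_correct",
    "fdr_bh",
    "npc_test",
]

#: Floor applied to first-level p-values before taking logs, so that a
#: numerically zero p (perfect correlation at machine precision) does not
#: send the geometric mean to exp(-inf).
DEFAULT_P_FLOOR = 1e-300


# ---------------------------------------------------------------------------
# combining functions
# ---------------------------------------------------------------------------

def combine_mean(p: np.ndarray) -> float:
    """Arithmetic mean of a vector of p-values (Edgington-style summary).

    The result is a combining statistic, not itself a p-value: under the
    null it concentrates around 0.5 rather than distributing uniformly.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("cannot combine an empty p-value vector")
    if np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    return float(p.mean())


def combine_gmean(p: np.ndarray) -> float:
    """Geometric mean of a vector of p-values, computed in log space.

    ``exp(mean(log p))`` amplifies the contribution of p-values near zero
    relative to the arithmetic mean (Fisher-style combining).  Entries must
    be strictly positive; flooring tiny values is the caller's job.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("cannot combine an empty p-value vector")
    if np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    return float(np.exp(np.mean(np.log(p))))


def fisher_z(r):
    """Fisher z-transformation ``atanh(r)`` of a correlation coefficient.

    Variance-stabilising, which makes the transformed correlations suitable
    for parametric testing.  Requires ``|r| < 1``.
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        raise ValueError("fisher_z requires |r| < 1")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# first level
# ---------------------------------------------------------------------------

@dataclass
class FirstLevelResult:
    """Per-replication parametric test results.

    Attributes
    ----------
    p0
        R x P matrix of two-sided p-values (floored at ``p_floor``).
    r
        R x P matrix of Pearson correlations.
    df
        Degrees of freedom of the t reference distribution, ``N - 2``.
    """

    p0: np.ndarray
    r: np.ndarray
    df: int


def _standardize_columns(values: np.ndarray) -> np.ndarray:
    """Center columns and scale to unit Euclidean norm.

    After this, correlations are plain inner products, which lets the
    permutation loop run as one matrix product per batch.
    """
    c = values - values.mean(axis=0)
    norms = np.linalg.norm(c, axis=0)
    if np.any(norms == 0.0):
        raise ValueError("constant column encountered during standardisation")
    return c / norms


def _corr_pvalues(r: np.ndarray, df: int, p_floor: float) -> np.ndarray:
    """Two-sided p for Pearson r via t = r*sqrt(df/(1-r^2)) with df = N-2."""
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r * r))
        # |r| == 1 gives t = +/-inf and p = 0, which the floor then lifts.
        t = np.where(np.abs(r) >= 1.0, np.copysign(np.inf, r), t)
    p = 2.0 * special.stdtr(df, -np.abs(t))
    return np.maximum(p, p_floor)


def first_level_pvalues(
    Y: ReplicationMatrix | np.ndarray,
    X: TraitMatrix | np.ndarray,
    p_floor: float = DEFAULT_P_FLOOR,
) -> FirstLevelResult:
    """Pearson-correlation t-tests between every replication and every trait.

    Returns an ``R x P`` matrix of two-sided parametric p-values, obtained by
    referring ``t = r * sqrt((N-2)/(1-r^2))`` to the t distribution with
    ``N - 2`` degrees of freedom, floored at ``p_floor``.
    """
    Y = Y if isinstance(Y, ReplicationMatrix) else ReplicationMatrix(np.asarray(Y))
    X = X if isinstance(X, TraitMatrix) else TraitMatrix(np.asarray(X))
    check_matched(Y, X)
    n = Y.n_subjects
    df = n - 2
    yn = _standardize_columns(Y.values)
    xn = _standardize_columns(X.values)
    r = yn.T @ xn
    p0 = _corr_pvalues(r, df, p_floor)
    return FirstLevelResult(p0=p0, r=np.clip(r, -1.0, 1.0), df=df)


# ---------------------------------------------------------------------------
# permutation scheme
# ---------------------------------------------------------------------------

@dataclass
class PermutationScheme:
    """K row-permutations of the subject index, shared by all tests.

    ``perms`` is a K x N integer array; row k holds the permuted subject
    order used for the k-th surrogate.  The identity permutation is never
    among the surrogates — the observed data enter the second-level
    estimator through its "+1" correction instead.  When ``blocks`` is
    given, shuffling happens only within blocks (exchangeability blocks,
    e.g. families).
    """

    K: int
    perms: np.ndarray
    blocks: np.ndarray | None
    seed: int

    @property
    def n_subjects(self) -> int:
        return self.perms.shape[1]


def make_permutation_scheme(
    n: int,
    k: int,
    seed: int,
    blocks: np.ndarray | None = None,
) -> PermutationScheme:
    """Draw K subject permutations uniformly (within blocks if given).

    Sampling is with replacement from the (block-restricted) permutation
    group, excluding the identity; duplicates are allowed since K is tiny
    compared to N! in any intended use.
    """
    if n < 2:
        raise ValueError("need at least 2 subjects to permute")
    if k < 1:
        raise ValueError("need at least one permutation")
    if blocks is not None:
        blocks = np.asarray(blocks)
        if blocks.shape != (n,):
            raise ValueError("blocks must be one label per subject")
        groups = [np.flatnonzero(blocks == b) for b in np.unique(blocks)]
        if all(len(g) < 2 for g in groups):
            raise ValueError(
                "all exchangeability blocks are singletons; only the identity "
                "permutation is available"
            )
    else:
        groups = None

    rng = np.random.default_rng(seed)
    identity = np.arange(n)
    perms = np.empty((k, n), dtype=np.intp)
    for i in range(k):
        while True:
            if groups is None:
                p = rng.permutation(n)
            else:
                p = identity.copy()
                for g in groups:
                    p[g] = g[rng.permutation(len(g))]
            if not np.array_equal(p, identity):
                break
        perms[i] = p
    return PermutationScheme(K=k, perms=perms, blocks=blocks, seed=seed)


# ---------------------------------------------------------------------------
# second level
# ---------------------------------------------------------------------------

def second_level_pvalue(observed: np.ndarray, null: np.ndarray) -> np.ndarray:
    """Monte-Carlo permutation p: ``(#{k: null_k <= observed} + 1) / (K + 1)``.

    Small summaries are extreme, so surrogates no larger than the observed
    summary count against the null; ties count (conservative).
    """
    observed = np.atleast_1d(np.asarray(observed, dtype=float))
    null = np.asarray(null, dtype=float)
    if null.ndim == 1:
        null = null[:, None]
    if null.shape[1] != observed.shape[0]:
        raise DimensionMismatchError("null matrix and observed vector disagree on P")
    k = null.shape[0]
    count = (null <= observed[None, :]).sum(axis=0)
    return (count + 1.0) / (k + 1.0)


def fwe_correct(observed: np.ndarray, null: np.ndarray) -> np.ndarray:
    """Min-p family-wise-error-corrected p-values.

    For variable j, the reference distribution is the per-permutation
    minimum summary across all variables; with a single variable this
    reduces to the uncorrected second-level p.
    """
    observed = np.atleast_1d(np.asarray(observed, dtype=float))
    null = np.asarray(null, dtype=float)
    if null.ndim == 1:
        null = null[:, None]
    if null.shape[1] != observed.shape[0]:
        raise DimensionMismatchError("null matrix and observed vector disagree on P")
    k = null.shape[0]
    min_null = null.min(axis=1)
    count = (min_null[:, None] <= observed[None, :]).sum(axis=0)
    return (count + 1.0) / (k + 1.0)


def fdr_bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (PRDS form)."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# the full NPC test
# ---------------------------------------------------------------------------

_COMBINERS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    # axis-0 reductions over the R replications, vectorised over columns
    "gmean": lambda p0: np.exp(np.log(p0).mean(axis=0)),
    "mean": lambda p0: p0.mean(axis=0),
}


@dataclass
class NPCResult:
    """Per-variable NPC inference output.

    ``p_mean`` and ``p_gmean`` are the observed combining statistics (not
    p-values); ``p_npc`` is the second-level permutation p using the chosen
    combiner, with ``p_fwe`` (min-p) and ``p_fdr`` (Benjamini-Hochberg)
    corrections.  ``null_summaries`` holds the K x P surrogate summaries so
    the estimators can be audited or recomputed.
    """

    variable_ids: list[str]
    p_mean: np.ndarray
    p_gmean: np.ndarray
    p_npc: np.ndarray
    p_fwe: np.ndarray
    p_fdr: np.ndarray
    null_summaries: np.ndarray
    first_level: FirstLevelResult
    combiner: str
    K: int

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "variable_id": self.variable_ids,
                "p_mean": self.p_mean,
                "p_gmean": self.p_gmean,
                "p_npc": self.p_npc,
                "p_fwe": self.p_fwe,
                "p_fdr": self.p_fdr,
            }
        )


def npc_test(
    Y: ReplicationMatrix | np.ndarray,
    X: TraitMatrix | np.ndarray,
    scheme: PermutationScheme,
    combiner: Literal["gmean", "mean"] = "gmean",
    p_floor: float = DEFAULT_P_FLOOR,
    batch_size: int = 2000,
) -> NPCResult:
    """Run the full two-level NPC procedure.

    The rows of X are permuted (equivalent, under the null, to permuting the
    rows of Y, and cheaper when P < R), with every variable permuted by the
    same scheme so that the joint null distribution across variables is
    preserved for the min-p FWE correction.

    Parameters
    ----------
    combiner
        ``"gmean"`` (geometric mean of first-level p-values; default) or
        ``"mean"`` (arithmetic mean).
    batch_size
        Number of permutations evaluated per matrix product; a memory/speed
        trade-off with no effect on the result.
    """
    if combiner not in _COMBINERS:
        raise ValueError(f"unknown combiner {combiner!r}; use 'gmean' or 'mean'")
    Y = Y if isinstance(Y, ReplicationMatrix) else ReplicationMatrix(np.asarray(Y))
    X = X if isinstance(X, TraitMatrix) else TraitMatrix(np.asarray(X))
    check_matched(Y, X)
    if scheme.n_subjects != Y.n_subjects:
        raise DimensionMismatchError(
            "permutation scheme is over a different number of subjects"
        )
    combine = _COMBINERS[combiner]
    n, p_vars = X.n_subjects, X.n_variables
    df = n - 2

    yn = _standardize_columns(Y.values)
    xn = _standardize_columns(X.values)

    r_obs = yn.T @ xn
    p0 = _corr_pvalues(r_obs, df, p_floor)
    obs_mean = p0.mean(axis=0)
    obs_gmean = np.exp(np.log(p0).mean(axis=0))
    observed = obs_gmean if combiner == "gmean" else obs_mean

    k_total = scheme.K
    null = np.empty((k_total, p_vars))
    for start in range(0, k_total, batch_size):
        batch = scheme.perms[start : start + batch_size]
        nb = batch.shape[0]
        if p_vars == 1:
            xp = xn[batch.T, 0]  # N x nb, each column a permuted copy of x
            p_k = _corr_pvalues(yn.T @ xp, df, p_floor)  # R x nb
            null[start : start + nb, 0] = combine(p_k)
        else:
            # xn[batch] has shape (nb, N, P); fold into N x (nb*P) so all
            # permuted copies go through one matrix product
            stacked = np.transpose(xn[batch], (1, 0, 2)).reshape(n, nb * p_vars)
            p_k = _corr_pvalues(yn.T @ stacked, df, p_floor)
            null[start : start + nb] = combine(p_k).reshape(nb, p_vars)

    p_npc = second_level_pvalue(observed, null)
    p_fwe = fwe_correct(observed, null)
    p_fdr = fdr_bh(p_npc)
    return NPCResult(
        variable_ids=list(X.variable_ids),
        p_mean=obs_mean,
        p_gmean=obs_gmean,
        p_npc=p_npc,
        p_fwe=p_fwe,
        p_fdr=p_fdr,
        null_summaries=null,
        first_level=FirstLevelResult(p0=p0, r=np.clip(r_obs, -1, 1), df=df),
        combiner=combiner,
        K=k_total,
    )
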