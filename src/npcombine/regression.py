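"""Ridge-regression permutation baseline.

Instead of combining R univariate first-level p-values, this comparison
method regresses each trait on *all* replications at once (ridge-penalised
to tame R close to or above N), summarises the fit with an F statistic,
converts it parametrically to a p-value, and embeds that statistic in the
same synchronised permutation loop as the NPC.  The parametric p is only a
ranking statistic inside the loop — any monotone transform of F would give
the identical permutation p — so validity comes from the permutations, not
from the F reference distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats

from .data import (
    DimensionMismatchError,
    ReplicationMatrix,
    TraitMatrix,
    check_matched,
)
from .npc import PermutationScheme, second_level_pvalue

__all__ = ["RidgeConfig", "RegressionTestResult", "ridge_f_pvalue", "regression_perm_test"]


@dataclass
class RidgeConfig:
    """Ridge penalty settings.

    ``lambda_rel`` scales the penalty relative to the mean diagonal of the
    (column-centered) replication Gram matrix, so the default 1e-3 is a
    minimal penalty whatever the units of Y.  A strictly positive value is
    required whenever R >= N, where the unpenalised system is singular.
    """

    lambda_rel: float = 1e-3
    include_intercept: bool = True


@dataclass
class RegressionTestResult:
    """Observed F statistics, their parametric p-values, and permutation p."""

    variable_ids: list[str]
    f_stat: np.ndarray
    p_parametric: np.ndarray
    p_regr: np.ndarray
    K: int

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "variable_id": self.variable_ids,
                "f_stat": self.f_stat,
                "p_parametric": self.p_parametric,
                "p_regr": self.p_regr,
            }
        )


def _prepare(Y: np.ndarray, cfg: RidgeConfig):
    """Center Y, build and factorise the penalised Gram matrix."""
    n, r = Y.shape
    yc = Y - Y.mean(axis=0) if cfg.include_intercept else Y.copy()
    gram = yc.T @ yc
    lam = cfg.lambda_rel * float(np.mean(np.diag(gram)))
    if lam > 0.0:
        gram = gram + lam * np.eye(r)
    try:
        cho = linalg.cho_factor(gram)
    except linalg.LinAlgError as exc:
        raise linalg.LinAlgError(
            "replication Gram matrix is singular; set a positive lambda_rel "
            "(required whenever R >= N)"
        ) from exc
    return yc, cho


def _f_from_columns(yc: np.ndarray, cho, xc: np.ndarray, df2: int):
    """F statistics for one or more (already centered) trait columns.

    F compares the ridge fit against the intercept-only model with
    numerator df = R and denominator df = df2, using the ridge residual
    sum of squares.
    """
    r = yc.shape[1]
    coefs = linalg.cho_solve(cho, yc.T @ xc)
    fitted = yc @ coefs
    rss1 = np.sum((xc - fitted) ** 2, axis=0)
    rss0 = np.sum(xc**2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((rss0 - rss1) / r) / (rss1 / df2)
    return np.maximum(f, 0.0)


def ridge_f_pvalue(
    Y: ReplicationMatrix | np.ndarray,
    x: np.ndarray,
    cfg: RidgeConfig | None = None,
) -> tuple[float, float]:
    """Ridge-regress one trait on all replications; return (F, parametric p).

    Degrees of freedom are (R, max(N - R - 1, 1)), as for unpenalised
    regression; when R >= N the parametric p is meaningful only as a
    ranking statistic for the permutation test.
    """
    cfg = cfg or RidgeConfig()
    Y = Y if isinstance(Y, ReplicationMatrix) else ReplicationMatrix(np.asarray(Y))
    x = np.asarray(x, dtype=float).reshape(-1)
    if x.shape[0] != Y.n_subjects:
        raise DimensionMismatchError("trait vector length does not match Y")
    n, r = Y.values.shape
    yc, cho = _prepare(Y.values, cfg)
    xc = x - x.mean() if cfg.include_intercept else x
    df2 = max(n - r - 1, 1)
    f = float(_f_from_columns(yc, cho, xc[:, None], df2)[0])
    p = float(stats.f.sf(f, r, df2))
    return f, max(p, np.finfo(float).tiny)


def regression_perm_test(
    Y: ReplicationMatrix | np.ndarray,
    X: TraitMatrix | np.ndarray,
    scheme: PermutationScheme,
    cfg: RidgeConfig | None = None,
    batch_size: int = 2000,
) -> RegressionTestResult:
    """Permutation test with the ridge F-test as the per-variable statistic.

    Uses the same synchronised permutation scheme as ``npc_test``:
    ``p_regr[i] = (#{k: p_param^k <= p_param^obs} + 1) / (K + 1)``.
    """
    cfg = cfg or RidgeConfig()
    Y = Y if isinstance(Y, ReplicationMatrix) else ReplicationMatrix(np.asarray(Y))
    X = X if isinstance(X, TraitMatrix) else TraitMatrix(np.asarray(X))
    check_matched(Y, X)
    if scheme.n_subjects != Y.n_subjects:
        raise DimensionMismatchError(
            "permutation scheme is over a different number of subjects"
        )
    n, r = Y.values.shape
    p_vars = X.n_variables
    df2 = max(n - r - 1, 1)
    yc, cho = _prepare(Y.values, cfg)
    xc = X.values - X.values.mean(axis=0) if cfg.include_intercept else X.values

    f_obs = _f_from_columns(yc, cho, xc, df2)
    p_obs = stats.f.sf(f_obs, r, df2)

    k_total = scheme.K
    null_p = np.empty((k_total, p_vars))
    for start in range(0, k_total, batch_size):
        batch = scheme.perms[start : start + batch_size]
        nb = batch.shape[0]
        # centering commutes with row permutation, so permute the centered X
        stacked = np.transpose(xc[batch], (1, 0, 2)).reshape(n, nb * p_vars)
        f_k = _f_from_columns(yc, cho, stacked, df2)
        null_p[start : start + nb] = stats.f.sf(f_k, r, df2).reshape(nb, p_vars)

    p_regr = second_level_pvalue(p_obs, null_p)
    return RegressionTestResult(
        variable_ids=list(X.variable_ids),
        f_stat=f_obs,
        p_parametric=p_obs,
        p_regr=p_regr,
        K=k_total,
    )
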