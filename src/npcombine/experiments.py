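"""Experiment runners: the toy study and the power / type-I-error grids.

A single master seed deterministically spawns independent seeds for every
(sigma, repetition) cell, and within a cell every method sees the same
dataset and the same permutation scheme — method comparisons are paired,
as they should be.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .npc import make_permutation_scheme, npc_test
from .regression import RidgeConfig, regression_perm_test
from .simulate import FCSimConfig, ToyConfig, gen_fc_dataset, gen_toy

__all__ = [
    "GridSpec",
    "ExperimentReport",
    "run_toy_experiment",
    "run_power_grid",
    "run_null_grid",
]

METHODS = ("mean", "gmean", "regr", "npc")


def _spawn_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class GridSpec:
    """One power/null experiment grid.

    ``sigma_values`` must be strictly increasing; ``repetitions`` datasets
    are generated per sigma; every method is evaluated on each with ``K``
    permutations.
    """

    sigma_values: tuple[float, ...] = (0.25, 0.75, 1.5)
    repetitions: int = 20
    K: int = 500
    methods: tuple[str, ...] = METHODS

    def __post_init__(self) -> None:
        sig = tuple(float(s) for s in self.sigma_values)
        if any(b <= a for a, b in zip(sig, sig[1:])):
            raise ValueError("sigma_values must be strictly increasing")
        self.sigma_values = sig
        if self.repetitions < 1:
            raise ValueError("need at least one repetition")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")


@dataclass
class ExperimentReport:
    """Raw per-repetition p-values plus their per-(sigma, method) summary.

    ``summary`` carries the mean p-value, its standard error across
    repetitions, and the 95% band (mean -/+ twice the standard error).
    """

    raw: pd.DataFrame = field(repr=False)
    summary: pd.DataFrame = field(repr=False)

    @staticmethod
    def from_raw(raw: pd.DataFrame) -> "ExperimentReport":
        grouped = raw.groupby(["sigma", "method"], sort=True)["p"]
        summary = grouped.agg(mean_p="mean", sd="std", n="count").reset_index()
        summary["se"] = summary["sd"] / np.sqrt(summary["n"])
        summary["ci_lo"] = summary["mean_p"] - 2.0 * summary["se"]
        summary["ci_hi"] = summary["mean_p"] + 2.0 * summary["se"]
        return ExperimentReport(
            raw=raw, summary=summary.drop(columns=["sd"])
        )

    def rejection_rate(self, method: str, alpha: float = 0.05) -> float:
        """Fraction of all (sigma, repetition) cells with p < alpha."""
        sub = self.raw[self.raw["method"] == method]
        if sub.empty:
            raise ValueError(f"no rows for method {method!r}")
        return float((sub["p"] < alpha).mean())


def run_toy_experiment(
    cfg: ToyConfig, K: int = 10_000
) -> tuple[float, float, float]:
    """Run the full two-level procedure on one toy family of replicate datasets.

    The ``n_datasets`` replicate columns are treated as replications of a
    single underlying relation between a and b.  Returns the observed
    arithmetic-mean and geometric-mean summaries of the first-level p-values
    and the second-level NPC p-value (geometric-mean combining).
    """
    root = np.random.SeedSequence(cfg.seed)
    data_ss, perm_ss = root.spawn(2)
    a, b = gen_toy(replace(cfg, seed=_spawn_seed(data_ss)))
    scheme = make_permutation_scheme(cfg.N, K, seed=_spawn_seed(perm_ss))
    res = npc_test(b, a, scheme, combiner="gmean")
    return float(res.p_mean[0]), float(res.p_gmean[0]), float(res.p_npc[0])


def _run_grid(fc_cfg: FCSimConfig, grid: GridSpec, master_seed: int) -> ExperimentReport:
    rows = []
    for sigma in grid.sigma_values:
        for rep in range(grid.repetitions):
            cell_ss = np.random.SeedSequence(
                entropy=master_seed,
                spawn_key=(int(round(sigma * 1e6)), rep),
            )
            data_ss, perm_ss = cell_ss.spawn(2)
            cfg = replace(fc_cfg, sigma=sigma, seed=_spawn_seed(data_ss))
            Y, x, _ = gen_fc_dataset(cfg)
            scheme = make_permutation_scheme(
                cfg.N, grid.K, seed=_spawn_seed(perm_ss)
            )
            if {"mean", "gmean", "npc"} & set(grid.methods):
                res = npc_test(Y, x, scheme, combiner="gmean")
                if "mean" in grid.methods:
                    rows.append((sigma, rep, "mean", float(res.p_mean[0])))
                if "gmean" in grid.methods:
                    rows.append((sigma, rep, "gmean", float(res.p_gmean[0])))
                if "npc" in grid.methods:
                    rows.append((sigma, rep, "npc", float(res.p_npc[0])))
            if "regr" in grid.methods:
                reg = regression_perm_test(Y, x, scheme, RidgeConfig())
                rows.append((sigma, rep, "regr", float(reg.p_regr[0])))
    raw = pd.DataFrame(rows, columns=["sigma", "rep", "method", "p"])
    return ExperimentReport.from_raw(raw)


def run_power_grid(
    fc_cfg: FCSimConfig, grid: GridSpec, master_seed: int = 0
) -> ExperimentReport:
    """Power study: datasets generated *with* a coupling between trait and FC."""
    return _run_grid(replace(fc_cfg, effect=True), grid, master_seed)


def run_null_grid(
    fc_cfg: FCSimConfig, grid: GridSpec, master_seed: int = 0
) -> ExperimentReport:
    """Type-I-error study: beta_n = 0 for all subjects (global null)."""
    return _run_grid(replace(fc_cfg, effect=False), grid, master_seed)
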