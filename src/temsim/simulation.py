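"""Monte Carlo orchestration: scenario grid, replicates and performance measures.

The experiment crosses the moderator-confounder interaction sizes on the
treatment scale (alpha_mx1 in {0, 0.1, 0.2}) and outcome scale (beta_mx1 in
{0, 0.2, 0.4}) with two TEM effect sizes (beta_tm in {0.3, 0.6}) and two
moderator prevalences (0.5, 0.1): 9 interaction scenarios per
(beta_tm, prev_m) block, 36 scenarios in total, 500 replicates each by
default, every replicate pushed through all 16 method x model combinations.

Performance measures per scenario and combination:

* mean estimate over completed replicates
* empirical SE: sample SD of the estimates (n-1 denominator)
* average model SE: sqrt of the mean squared model SE
* bias: mean estimate minus the generating truth
* 95% interval: mean +/- 1.96 * empirical SE
* Monte Carlo SE of the mean: empirical SE / sqrt(reps)

A bias table condenses one (beta_tm, prev_m) block into a 4 x 4 grid of
average absolute bias: per method x model, the mean over the block's nine
interaction scenarios of |mean(b_TM) - beta_TM|.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .adjustment import AdjustmentModel, AdjustmentSpec, Method, estimate_all
from .dgp import DGPCoefficients, generate_cohort

__all__ = [
    "ScenarioGrid", "GridResults", "replicate_seed", "run_replicate",
    "run_scenario", "summarize", "bias_table", "run_full_grid",
    "SCENARIO_KEYS", "ESTIMANDS",
]

SCENARIO_KEYS = ("alpha_mx1", "beta_mx1", "beta_tm", "prev_m")
ESTIMANDS = ("bt_m1", "bt_m0", "btm")

ALL_SPECS = [AdjustmentSpec(me, mo) for me in Method for mo in AdjustmentModel]


@dataclass(frozen=True)
class ScenarioGrid:
    """The full factorial scenario grid of the simulation study."""

    alpha_mx1_values: tuple[float, ...] = (0.0, 0.1, 0.2)
    beta_mx1_values: tuple[float, ...] = (0.0, 0.2, 0.4)
    beta_tm_values: tuple[float, ...] = (0.3, 0.6)
    prev_m_values: tuple[float, ...] = (0.5, 0.1)
    n_reps: int = 500
    n: int = 1000
    base_seed: int = 0
    base_coeffs: DGPCoefficients = field(default_factory=DGPCoefficients)

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be positive")

    def scenarios(self) -> Iterator[tuple[dict, DGPCoefficients]]:
        """Yield (scenario-id dict, coefficients) over the grid."""
        for prev_m in self.prev_m_values:
            for beta_tm in self.beta_tm_values:
                for alpha_mx1 in self.alpha_mx1_values:
                    for beta_mx1 in self.beta_mx1_values:
                        key = {"alpha_mx1": alpha_mx1, "beta_mx1": beta_mx1,
                               "beta_tm": beta_tm, "prev_m": prev_m}
                        coeffs = self.base_coeffs.with_(
                            alpha_mx1=alpha_mx1, beta_mx1=beta_mx1,
                            beta_tm=beta_tm, prev_m=prev_m, n=self.n)
                        yield key, coeffs

    def __len__(self) -> int:
        return (len(self.alpha_mx1_values) * len(self.beta_mx1_values)
                * len(self.beta_tm_values) * len(self.prev_m_values))


def replicate_seed(base_seed: int, coeffs: DGPCoefficients, rep: int) -> np.random.SeedSequence:
    """Deterministic per-(scenario, replicate) seed stream.

    Keyed on the scenario's varying coefficients (not its position in the
    grid) so that any subset of the grid reproduces the full grid's draws.
    """
    key = (int(base_seed),
           int(round(coeffs.alpha_mx1 * 1000)),
           int(round(coeffs.beta_mx1 * 1000)),
           int(round(coeffs.beta_tm * 1000)),
           int(round(coeffs.prev_m * 1000)),
           int(rep))
    return np.random.SeedSequence(key)


def run_replicate(coeffs: DGPCoefficients, seed, specs=None) -> pd.DataFrame:
    """Generate one cohort and estimate all requested combinations.

    Returns one row per combination; failed combinations carry NaN
    estimates and ``failed=True``.
    """
    specs = ALL_SPECS if specs is None else specs
    cohort = generate_cohort(coeffs, np.random.default_rng(seed))
    results = estimate_all(cohort.to_frame(), specs)
    rows = []
    for spec, est in results.items():
        row = {"method": spec.method.value, "model": spec.model.value}
        if est is None:
            row.update({k: np.nan for k in
                        ("bt_m1", "bt_m0", "btm", "se_m1", "se_m0", "se_tm")})
            row["failed"] = True
        else:
            row.update(bt_m1=est.bt_m1, bt_m0=est.bt_m0, btm=est.btm,
                       se_m1=est.se_m1, se_m0=est.se_m0, se_tm=est.se_tm,
                       failed=False)
        rows.append(row)
    return pd.DataFrame(rows)


def run_scenario(coeffs: DGPCoefficients, n_reps: int, base_seed: int = 0,
                 specs=None) -> pd.DataFrame:
    """Run all replicates of one scenario; deterministic given the seed.

    Raises if every replicate failed for some combination.
    """
    frames = []
    for rep in range(n_reps):
        df = run_replicate(coeffs, replicate_seed(base_seed, coeffs, rep), specs)
        df.insert(0, "rep", rep)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    all_failed = out.groupby(["method", "model"])["failed"].all()
    if all_failed.any():
        bad = list(all_failed[all_failed].index)
        raise RuntimeError(f"all replicates failed for combinations: {bad}")
    return out


def summarize(replicates: pd.DataFrame, coeffs: DGPCoefficients) -> pd.DataFrame:
    """Monte Carlo performance measures per method x model combination."""
    truth = {"bt_m1": coeffs.true_effect_m1, "bt_m0": coeffs.true_effect_m0,
             "btm": coeffs.beta_tm}
    rows = []
    for (method, model), grp in replicates.groupby(["method", "model"], sort=False):
        done = grp[~grp["failed"]]
        if len(done) < 2:
            raise RuntimeError(
                f"need >=2 completed replicates for {method}/{model}, got {len(done)}")
        row = {"method": method, "model": model,
               "n_completed": len(done), "n_failed": int(grp["failed"].sum())}
        for est, se_col in zip(ESTIMANDS, ("se_m1", "se_m0", "se_tm")):
            vals = done[est].to_numpy()
            mean = vals.mean()
            emp_se = vals.std(ddof=1)
            avg_model_se = float(np.sqrt(np.mean(done[se_col].to_numpy() ** 2)))
            row[f"mean_{est}"] = mean
            row[f"emp_se_{est}"] = emp_se
            row[f"avg_model_se_{est}"] = avg_model_se
            row[f"bias_{est}"] = mean - truth[est]
            row[f"ci_low_{est}"] = mean - 1.96 * emp_se
            row[f"ci_high_{est}"] = mean + 1.96 * emp_se
            row[f"mc_se_{est}"] = emp_se / np.sqrt(len(done))
        rows.append(row)
    return pd.DataFrame(rows)


def bias_table(summaries: dict[tuple[float, float], pd.DataFrame]) -> pd.DataFrame:
    """Average absolute bias of the TEM estimate over one block's nine
    (alpha_mx1, beta_mx1) scenarios, as a 4-method x 4-model table."""
    if len(summaries) != 9:
        raise ValueError(f"need all 9 (alpha_mx1, beta_mx1) scenarios, got {len(summaries)}")
    stacked = pd.concat(summaries.values(), ignore_index=True)
    cell = (stacked.assign(abs_bias=stacked["bias_btm"].abs())
            .groupby(["method", "model"])["abs_bias"].mean().unstack("model"))
    order = [m.value for m in Method]
    return cell.reindex(index=order, columns=[m.value for m in AdjustmentModel])


@dataclass
class GridResults:
    """All per-scenario replicate tables, summaries and block bias tables."""
    replicates: dict[tuple, pd.DataFrame]
    summaries: dict[tuple, pd.DataFrame]
    bias_tables: dict[tuple[float, float], pd.DataFrame]

    def summary_frame(self) -> pd.DataFrame:
        """All scenario summaries stacked with scenario metadata columns."""
        frames = []
        for key, summ in self.summaries.items():
            df = summ.copy()
            for name, val in zip(SCENARIO_KEYS, key):
                df.insert(0, name, val)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def bias_frame(self) -> pd.DataFrame:
        """All bias tables stacked in long form."""
        if not self.bias_tables:
            return pd.DataFrame(
                columns=["beta_tm", "prev_m", "method", "model", "avg_abs_bias"])
        frames = []
        for (beta_tm, prev_m), tbl in self.bias_tables.items():
            df = tbl.reset_index().melt(id_vars="method", var_name="model",
                                        value_name="avg_abs_bias")
            df.insert(0, "prev_m", prev_m)
            df.insert(0, "beta_tm", beta_tm)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def _scenario_key(key: dict) -> tuple:
    return tuple(key[k] for k in SCENARIO_KEYS)


def run_full_grid(grid: ScenarioGrid, n_jobs: int = 1, specs=None,
                  keep_replicates: bool = True) -> GridResults:
    """Run every scenario of the grid and assemble summaries and bias tables.

    Parallel execution (``n_jobs > 1``) gives bit-identical results to
    serial because every (scenario, replicate) has its own seed stream.
    """
    items = list(grid.scenarios())

    def _one(key, coeffs):
        reps = run_scenario(coeffs, grid.n_reps, grid.base_seed, specs)
        return key, reps, summarize(reps, coeffs)

    results = Parallel(n_jobs=n_jobs)(delayed(_one)(k, c) for k, c in items)
    replicates, summaries = {}, {}
    for key, reps, summ in results:
        replicates[_scenario_key(key)] = reps if keep_replicates else None
        summaries[_scenario_key(key)] = summ
    tables = {}
    for prev_m in grid.prev_m_values:
        for beta_tm in grid.beta_tm_values:
            block = {
                (a, b): summaries[(a, b, beta_tm, prev_m)]
                for a in grid.alpha_mx1_values for b in grid.beta_mx1_values
                if (a, b, beta_tm, prev_m) in summaries
            }
            if len(block) == 9:
                tables[(beta_tm, prev_m)] = bias_table(block)
    if not keep_replicates:
        replicates = {}
    return GridResults(replicates=replicates, summaries=summaries, bias_tables=tables)
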