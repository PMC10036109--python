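"""Threshold sweep: clustering probability vs normalised cell killing.

For a grid of candidate lethal-volume thresholds v_th, the clustering
probability p(v_th) is compared condition by condition with the
R_hit-normalised cell killing effect.  The concordance statistic per v_th
is the mean (± sample sd) over conditions of |p − normalised killing|;
the optimal threshold is the grid point minimising the mean difference.
Conditions may be monoenergetic beams (keyed by LET) or SOBP beams (keyed
by width, with p evaluated at the dose-averaged LET) — both share this
code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .foci_model import LETLaws, clustering_probability, extract_max_volumes, \
    fit_let_laws, fit_max_volume_gaussian
from .survival import summarize_survival
from .synthetic_data import (
    GeneratorConfig,
    gen_clonogenic_table,
    gen_foci_table,
    gen_occupancy_table,
)
from .unhit_model import UnhitLaw, fit_unhit_law, unhit_fraction

__all__ = [
    "DEFAULT_VTH_GRID",
    "ConcordanceResult",
    "probability_table",
    "difference_profile",
    "optimal_threshold",
    "rank_correlation",
    "run_pipeline",
]

#: Default lethal-volume threshold grid, μm³ (0.1 to 2.0 in 0.1 steps).
DEFAULT_VTH_GRID = tuple(np.round(np.arange(0.1, 2.0 + 1e-9, 0.1), 10))


@dataclass(frozen=True)
class ConcordanceResult:
    """Threshold-sweep outcome.

    ``diff`` holds |p − normalised killing| with one row per condition and
    one column per v_th; ``mean_diff``/``sd_diff`` aggregate over
    conditions; ``v_th_opt`` is the grid argmin (ties toward smaller v_th).
    """

    v_th_grid: np.ndarray
    conditions: np.ndarray
    p: np.ndarray
    killing: np.ndarray
    diff: np.ndarray
    mean_diff: np.ndarray
    sd_diff: np.ndarray
    v_th_opt: float

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (condition, v_th, p, killing, diff)."""
        records = []
        for i, cond in enumerate(self.conditions):
            for j, vth in enumerate(self.v_th_grid):
                records.append(
                    {
                        "condition": cond,
                        "v_th": vth,
                        "p": self.p[i, j],
                        "killing": self.killing[i],
                        "diff": self.diff[i, j],
                    }
                )
        return pd.DataFrame.from_records(records)


def probability_table(
    lets_by_condition: "pd.Series | dict",
    laws: LETLaws,
    v_th_grid: "np.ndarray | tuple" = DEFAULT_VTH_GRID,
) -> pd.DataFrame:
    """p(v_th) per condition: rows = conditions, columns = v_th grid.

    ``lets_by_condition`` maps each condition label to the LET at which p
    is evaluated (the condition's own LET for monoenergetic beams, the
    dose-averaged LET for SOBP beams).
    """
    series = pd.Series(lets_by_condition)
    grid = np.asarray(v_th_grid, dtype=float)
    data = {
        cond: [clustering_probability(v, let, laws) for v in grid]
        for cond, let in series.items()
    }
    return pd.DataFrame.from_dict(data, orient="index", columns=grid)


def difference_profile(
    p_table: pd.DataFrame, killing_by_condition: "pd.Series | dict"
) -> ConcordanceResult:
    """Absolute differences |p − normalised killing| over the threshold grid.

    ``p_table`` has conditions as index and v_th grid as columns (as from
    :func:`probability_table`); ``killing_by_condition`` maps the same
    condition labels to their normalised killing.  Differences are computed
    on fractions.
    """
    killing = pd.Series(killing_by_condition)
    if set(p_table.index) != set(killing.index):
        raise ValueError(
            "condition mismatch between probability table and killing values"
        )
    if len(p_table.index) < 2:
        raise ValueError("need at least 2 conditions for a concordance profile")
    killing = killing.loc[p_table.index]

    grid = np.asarray(p_table.columns, dtype=float)
    p = p_table.to_numpy(dtype=float)
    k = killing.to_numpy(dtype=float)
    diff = np.abs(p - k[:, None])
    mean_diff = diff.mean(axis=0)
    sd_diff = diff.std(axis=0, ddof=1)
    v_th_opt = float(grid[int(np.argmin(mean_diff))])  # first minimum = smaller v_th
    return ConcordanceResult(
        v_th_grid=grid,
        conditions=np.asarray(p_table.index),
        p=p,
        killing=k,
        diff=diff,
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        v_th_opt=v_th_opt,
    )


def optimal_threshold(result: ConcordanceResult) -> float:
    """Grid v_th minimising the mean difference; ties go to the smaller v_th."""
    if result.v_th_grid.size == 0:
        raise ValueError("empty concordance result")
    return float(result.v_th_grid[int(np.argmin(result.mean_diff))])


def rank_correlation(x, y) -> tuple[float, float]:
    """Spearman rank correlation (mid-rank ties) with two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("inputs must be paired")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("rank correlation undefined for constant input")
    rho, pval = stats.spearmanr(x, y)
    return float(rho), float(pval)


def run_pipeline(
    config: GeneratorConfig,
    v_th_grid: "np.ndarray | tuple" = DEFAULT_VTH_GRID,
) -> dict:
    """End-to-end synthetic run: simulate, fit, normalise, sweep thresholds.

    Generates foci, occupancy and clonogenic tables under ``config``; fits
    the per-LET gaussians and the linear LET laws; fits the quadratic unhit
    law; summarises survival into R_hit-normalised killing; and sweeps the
    threshold grid.  Returns a dict with the fitted ``laws``, ``unhit_law``,
    the survival ``summary`` frame and the ``concordance`` result.
    """
    foci = gen_foci_table(config)
    samples = extract_max_volumes(foci, config.volume_floor)
    fits = [
        (let, fit_max_volume_gaussian(s)) for let, s in samples.items() if s.n >= 5
    ]
    laws = fit_let_laws(fits)

    occupancy = gen_occupancy_table(config)
    points = [(let, unhit_fraction(occupancy, let)) for let in config.let_values]
    unhit_law = fit_unhit_law(points)

    survival_table = gen_clonogenic_table(config)
    summary = summarize_survival(survival_table, unhit_law=unhit_law)

    lets_by_condition = pd.Series(
        {let: let for let in summary.index}, dtype=float
    )
    p_table = probability_table(lets_by_condition, laws, v_th_grid)
    result = difference_profile(p_table, summary["normalized_killing"])
    return {
        "laws": laws,
        "unhit_law": unhit_law,
        "summary": summary,
        "concordance": result,
    }
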