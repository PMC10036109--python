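"""Parameter-recovery experiments on synthetic data.

Each experiment generates data under known truth with the synthetic
generators, runs the corresponding fitting stage, and reports how well the
generating parameters are recovered.  They are the package's built-in
calibration checks and the basis of the reproduction script.
"""

from __future__ import annotations

import warnings

import numpy as np

from .concordance import optimal_threshold, run_pipeline
from .foci_model import (
    A549_LET_LAWS,
    FitError,
    LETLaws,
    MaxVolumeSample,
    fit_let_laws,
    fit_max_volume_gaussian,
)
from .synthetic_data import DEFAULT_LET_VALUES, GeneratorConfig, sample_max_volumes
from .unhit_model import fit_unhit_law, unhit_fraction
from .synthetic_data import gen_occupancy_table

__all__ = [
    "recover_let_laws",
    "recover_unhit_coefficient",
    "recover_threshold",
]


def recover_let_laws(
    seed: int,
    n_replicates: int = 500,
    n_nuclei: int = 30,
    let_values: tuple[float, ...] = DEFAULT_LET_VALUES,
    true_laws: LETLaws = A549_LET_LAWS,
) -> dict:
    """Recover the linear mu/sigma-vs-LET laws from repeated small samples.

    For each replicate, ``n_nuclei`` per-nucleus maximum volumes are drawn
    per LET from the generating normal laws, fitted per LET by binned least
    squares, and the four linear-law coefficients are fitted across LETs.
    Returns the replicate means (and sds) of the four coefficients.  A rare
    replicate whose gaussian fit fails to converge at this small n is
    dropped and counted.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(10,)))
    coeffs: list[tuple[float, float, float, float]] = []
    n_failed = 0
    for _ in range(n_replicates):
        fits = []
        try:
            for let in let_values:
                values = sample_max_volumes(rng, let, n_nuclei, true_laws)
                sample = MaxVolumeSample(let=let, values=values, n_excluded=0)
                fits.append((let, fit_max_volume_gaussian(sample)))
            laws = fit_let_laws(fits)
        except FitError:
            n_failed += 1
            continue
        coeffs.append(
            (laws.mu_slope, laws.mu_intercept, laws.sigma_slope, laws.sigma_intercept)
        )
    arr = np.array(coeffs)
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    return {
        "mu_slope": float(mean[0]),
        "mu_intercept": float(mean[1]),
        "sigma_slope": float(mean[2]),
        "sigma_intercept": float(mean[3]),
        "sd": {
            "mu_slope": float(sd[0]),
            "mu_intercept": float(sd[1]),
            "sigma_slope": float(sd[2]),
            "sigma_intercept": float(sd[3]),
        },
        "n_replicates": len(coeffs),
        "n_failed": n_failed,
    }


def recover_unhit_coefficient(
    seed: int,
    n_cells: int = 10_000,
    let_values: tuple[float, ...] = DEFAULT_LET_VALUES,
    true_c: float = 0.0618,
) -> dict:
    """Recover the quadratic unhit-law coefficient from Bernoulli occupancy data.

    Generates ``n_cells`` occupancy-scored cells per LET with the true
    coefficient, computes per-LET unhit fractions, and refits the
    one-parameter law.
    """
    config = GeneratorConfig(
        let_values=let_values,
        n_cells_occupancy=n_cells,
        true_unhit_coefficient=true_c,
        seed=seed,
    )
    table = gen_occupancy_table(config)
    points = [(let, unhit_fraction(table, let)) for let in let_values]
    law = fit_unhit_law(points)
    return {"c": law.c, "points": points, "n_cells_per_let": n_cells}


def recover_threshold(
    seed: int,
    n_runs: int = 100,
    tolerance: float = 0.1,
    **config_overrides,
) -> dict:
    """Recover the lethal-volume threshold with the full synthetic pipeline.

    Runs the end-to-end pipeline ``n_runs`` times with independent seeds
    derived from ``seed``; each run simulates all three tables under the
    default study conditions, fits every law, and sweeps the threshold
    grid.  Reports the recovered optima and the fraction within
    ``tolerance`` of the generating threshold.
    """
    seeds = np.random.SeedSequence(entropy=seed, spawn_key=(20,)).generate_state(
        n_runs
    ) % (2**31)
    optima = []
    for s in seeds:
        config = GeneratorConfig(seed=int(s), **config_overrides)
        with warnings.catch_warnings():
            # SF slightly above 1 is expected binomial noise at low LET
            warnings.simplefilter("ignore", UserWarning)
            result = run_pipeline(config)
        optima.append(optimal_threshold(result["concordance"]))
    optima_arr = np.array(optima)
    true_vth = GeneratorConfig(**config_overrides).true_lethal_threshold
    within = np.abs(optima_arr - true_vth) <= tolerance + 1e-9
    return {
        "optima": optima,
        "fraction_within_tolerance": float(within.mean()),
        "true_threshold": true_vth,
        "n_runs": n_runs,
    }
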