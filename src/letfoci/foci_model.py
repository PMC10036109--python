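"""Gaussian modelling of per-nucleus maximum γH2AX focus volumes.

After carbon-ion irradiation at a fixed dose, the largest γH2AX focus in a
nucleus is a proxy for the most clustered double-strand-break lesion that
nucleus received.  Across a population of hit nuclei the maximum focus
volume ``v`` (μm³) is well approximated by a normal distribution whose mean
and standard deviation grow linearly with the beam's linear energy transfer
(LET, keV/μm).  This module fits that normal law to binned volume data,
regresses the per-LET parameters on LET, and evaluates the clustering
probability

    p_LET(v_th) = P[v >= v_th]  under  v ~ Normal(mu_LET, sigma_LET),

the probability that 1 Gy of carbon ions of the given LET induces at least
one focus of volume ``v_th`` or greater in a nucleus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "FitError",
    "MaxVolumeSample",
    "GaussianFit",
    "LETLaws",
    "A549_LET_LAWS",
    "DEFAULT_VOLUME_FLOOR",
    "DEFAULT_BIN_WIDTH",
    "extract_max_volumes",
    "fit_max_volume_gaussian",
    "fit_let_laws",
    "foci_density",
    "clustering_probability",
    "empirical_probability",
]

#: Foci smaller than this volume (μm³) are treated as segmentation noise and
#: removed before per-nucleus maxima are taken.
DEFAULT_VOLUME_FLOOR = 0.01

#: Histogram bin width (μm³) used for the binned least-squares gaussian fit.
DEFAULT_BIN_WIDTH = 0.1

#: Required columns of a focus-volume table.
FOCI_COLUMNS = ("cell_line", "let", "nucleus_id", "focus_id", "volume")


class FitError(RuntimeError):
    """A least-squares fit failed to converge or the input was degenerate."""


@dataclass(frozen=True)
class MaxVolumeSample:
    """Per-nucleus maximum focus volumes at one LET.

    Attributes
    ----------
    let : float
        Beam LET in keV/μm.
    values : numpy.ndarray
        One maximum volume (μm³) per hit nucleus, all at or above the
        exclusion floor.
    n_excluded : int
        Number of individual foci removed by the volume floor before the
        maxima were taken.
    """

    let: float
    values: np.ndarray
    n_excluded: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    @property
    def n(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class GaussianFit:
    """Result of a binned least-squares normal fit.

    ``sse`` is the sum of squared residuals between the fitted density and
    the histogram density (units of density squared).
    """

    mu: float
    sigma: float
    bin_width: float
    n: int
    sse: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise FitError(f"fitted sigma must be positive, got {self.sigma}")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")


@dataclass(frozen=True)
class LETLaws:
    """Linear laws mu_LET = a·LET + b and sigma_LET = c·LET + d.

    Slopes are in μm³ per keV/μm, intercepts in μm³.  The laws are only
    meaningful on the LET range they were fitted over; ``sigma`` must stay
    positive there.
    """

    mu_slope: float
    mu_intercept: float
    sigma_slope: float
    sigma_intercept: float

    def mu(self, let: float) -> float:
        return self.mu_slope * let + self.mu_intercept

    def sigma(self, let: float) -> float:
        return self.sigma_slope * let + self.sigma_intercept


#: Laws fitted to the A549 monoenergetic carbon-ion data set (valid for
#: LET in [13, 100] keV/μm): mu = 0.0158·LET + 0.126, sigma = 0.00724·LET + 0.0312.
A549_LET_LAWS = LETLaws(
    mu_slope=0.0158, mu_intercept=0.126, sigma_slope=0.00724, sigma_intercept=0.0312
)


def extract_max_volumes(
    table: pd.DataFrame, floor: float = DEFAULT_VOLUME_FLOOR
) -> dict[float, MaxVolumeSample]:
    """Reduce a per-focus volume table to per-nucleus maxima, one sample per LET.

    Foci with volume below ``floor`` are excluded first; a nucleus whose foci
    are all sub-floor contributes no sample.  Returns a mapping keyed by LET.
    """
    if table is None or len(table) == 0:
        raise ValueError("focus table is empty")
    if floor < 0:
        raise ValueError(f"volume floor must be non-negative, got {floor}")
    missing = [c for c in ("let", "nucleus_id", "volume") if c not in table.columns]
    if missing:
        raise ValueError(f"focus table lacks columns {missing}")

    out: dict[float, MaxVolumeSample] = {}
    for let, grp in table.groupby("let", sort=True):
        kept = grp[grp["volume"] >= floor]
        n_excluded = len(grp) - len(kept)
        if len(kept) == 0:
            out[float(let)] = MaxVolumeSample(float(let), np.empty(0), n_excluded)
            continue
        maxima = kept.groupby("nucleus_id", sort=True)["volume"].max()
        out[float(let)] = MaxVolumeSample(
            float(let), maxima.to_numpy(dtype=float), n_excluded
        )
    return out


def _histogram_density(
    values: np.ndarray, bin_width: float
) -> tuple[np.ndarray, np.ndarray]:
    """Bin centers and fraction-per-bin-width density, bins anchored at 0."""
    upper = math.ceil(values.max() / bin_width) * bin_width
    n_bins = max(int(round(upper / bin_width)), 1)
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(values, bins=edges)
    density = counts / values.size / bin_width
    centers = (edges[:-1] + edges[1:]) / 2.0
    return centers, density


def fit_max_volume_gaussian(
    sample: MaxVolumeSample, bin_width: float = DEFAULT_BIN_WIDTH
) -> GaussianFit:
    """Fit a unit-area normal density to the binned max-volume histogram.

    The histogram uses bins of ``bin_width`` anchored at zero, normalised to
    density (bin fraction ÷ bin width), and the normal pdf is fitted to the
    bin centers by nonlinear least squares initialised at the sample
    mean/standard deviation.  Convergence failure raises :class:`FitError`.
    """
    values = np.asarray(sample.values, dtype=float)
    if values.size < 5:
        raise FitError(f"need at least 5 samples to fit, got {values.size}")
    sd0 = float(values.std(ddof=1))
    if sd0 == 0.0:
        raise FitError("degenerate sample: all values identical")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")

    centers, density = _histogram_density(values, bin_width)
    if np.count_nonzero(density) < 2:
        raise FitError("histogram has fewer than 2 occupied bins")

    def model(v: np.ndarray, mu: float, sigma: float) -> np.ndarray:
        return stats.norm.pdf(v, loc=mu, scale=sigma)

    try:
        popt, _ = optimize.curve_fit(
            model,
            centers,
            density,
            p0=(float(values.mean()), sd0),
            bounds=([-np.inf, 1e-9], [np.inf, np.inf]),
            xtol=1e-10,
            ftol=1e-10,
            maxfev=20000,
        )
    except (RuntimeError, optimize.OptimizeWarning) as exc:  # no convergence
        raise FitError(f"gaussian fit did not converge: {exc}") from exc

    mu, sigma = float(popt[0]), float(popt[1])
    sse = float(np.sum((model(centers, mu, sigma) - density) ** 2))
    return GaussianFit(mu=mu, sigma=sigma, bin_width=bin_width, n=values.size, sse=sse)


def fit_let_laws(fits: Iterable[tuple[float, GaussianFit]]) -> LETLaws:
    """Ordinary least-squares lines through (LET, mu) and (LET, sigma)."""
    pairs = list(fits)
    lets = np.array([let for let, _ in pairs], dtype=float)
    if np.unique(lets).size < 3:
        raise ValueError("need at least 3 distinct LET values to fit linear laws")
    mus = np.array([f.mu for _, f in pairs], dtype=float)
    sigmas = np.array([f.sigma for _, f in pairs], dtype=float)
    mu_fit = stats.linregress(lets, mus)
    sigma_fit = stats.linregress(lets, sigmas)
    return LETLaws(
        mu_slope=float(mu_fit.slope),
        mu_intercept=float(mu_fit.intercept),
        sigma_slope=float(sigma_fit.slope),
        sigma_intercept=float(sigma_fit.intercept),
    )


def _sigma_checked(let: float, laws: LETLaws) -> tuple[float, float]:
    mu = laws.mu(let)
    sigma = laws.sigma(let)
    if sigma <= 0:
        raise ValueError(f"sigma_LET({let}) = {sigma} is not positive")
    return mu, sigma


def foci_density(v: float, let: float, laws: LETLaws) -> float:
    """Normal density of the per-nucleus maximum focus volume at LET."""
    mu, sigma = _sigma_checked(let, laws)
    return float(stats.norm.pdf(v, loc=mu, scale=sigma))


def clustering_probability(v_th: float, let: float, laws: LETLaws) -> float:
    """Upper-tail probability P[v >= v_th] of the max-volume normal law.

    Evaluated via the complementary error function; equals 0.5 at
    ``v_th = mu_LET`` and is non-increasing in ``v_th``.
    """
    mu, sigma = _sigma_checked(let, laws)
    return float(stats.norm.sf(v_th, loc=mu, scale=sigma))


def empirical_probability(sample: MaxVolumeSample, v_th: float) -> float:
    """Fraction of hit nuclei whose maximum focus volume is >= v_th.

    The boundary is inclusive, matching the tail convention of
    :func:`clustering_probability`.  The denominator is the number of nuclei
    contributing a max-volume sample (hit nuclei only).
    """
    values = np.asarray(sample.values, dtype=float)
    if values.size == 0:
        raise ValueError("empty max-volume sample")
    return float(np.mean(values >= v_th))
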