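"""Unhit-cell classification and the quadratic unhit-fraction law.

At a fixed absorbed dose, higher-LET carbon ions deposit their energy in
fewer, denser tracks, so an increasing fraction of nuclei is traversed by
no particle at all.  Operationally a cell is *unhit* when less than 1% of
its nucleus area is occupied by γH2AX signal.  The unhit fraction versus
LET is modelled with a one-parameter quadratic law

    R_unhit(LET) = (c · LET)² / 100,          R_hit = 1 − R_unhit,

a deliberate empirical choice over a Poisson zero-class model, since one
particle traversal does not demonstrably map to one detectable focus.
All fractions here are plain fractions in [0, 1]; percent appears only at
I/O edges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "UnhitLaw",
    "HTERT_UNHIT_LAW",
    "DEFAULT_OCCUPANCY_THRESHOLD",
    "classify_unhit",
    "unhit_fraction",
    "fit_unhit_law",
    "hit_fraction",
]

#: Occupancy fraction below which a cell is called unhit.
DEFAULT_OCCUPANCY_THRESHOLD = 0.01

OCCUPANCY_COLUMNS = ("let", "cell_id", "signal_area", "nucleus_area")


@dataclass(frozen=True)
class UnhitLaw:
    """The single coefficient c of R_unhit(LET) = (c·LET)²/100.

    ``domain_max_let`` (= 10/c) is the LET at which the law reaches an
    unhit fraction of 1; evaluation beyond it is an error.
    """

    c: float

    def __post_init__(self) -> None:
        if self.c < 0:
            raise ValueError(f"unhit coefficient must be non-negative, got {self.c}")

    @property
    def domain_max_let(self) -> float:
        return math.inf if self.c == 0 else 10.0 / self.c

    def r_unhit(self, let: float) -> float:
        if let < 0 or let > self.domain_max_let:
            raise ValueError(
                f"LET {let} outside law domain [0, {self.domain_max_let:.4g}] keV/μm"
            )
        return (self.c * let) ** 2 / 100.0

    def r_hit(self, let: float) -> float:
        return 1.0 - self.r_unhit(let)


#: Coefficient fitted to 1BR hTERT monoenergetic carbon-ion occupancy data
#: (LET 13–100 keV/μm): c = 0.0618, so the law's domain ends near 161.8 keV/μm.
HTERT_UNHIT_LAW = UnhitLaw(c=0.0618)


def classify_unhit(
    signal_area: float,
    nucleus_area: float,
    threshold: float = DEFAULT_OCCUPANCY_THRESHOLD,
) -> bool:
    """True iff γH2AX occupancy signal_area/nucleus_area is strictly below threshold."""
    if nucleus_area <= 0:
        raise ValueError(f"nucleus area must be positive, got {nucleus_area}")
    return (signal_area / nucleus_area) < threshold


def unhit_fraction(
    table: pd.DataFrame,
    let: float,
    threshold: float = DEFAULT_OCCUPANCY_THRESHOLD,
) -> float:
    """Fraction of unhit cells among all cells recorded at one LET."""
    rows = table[table["let"] == let]
    if len(rows) == 0:
        raise ValueError(f"no cells recorded at LET {let}")
    flags = [
        classify_unhit(s, a, threshold)
        for s, a in zip(rows["signal_area"], rows["nucleus_area"])
    ]
    return float(np.mean(flags))


def fit_unhit_law(points: Iterable[tuple[float, float]]) -> UnhitLaw:
    """One-parameter least squares of R(LET) = (c·LET)²/100 over c >= 0.

    The model is linear in c², so the minimiser has the closed form
    c² = 100 · Σ R_k L_k² / Σ L_k⁴; negative fitted c² (impossible for
    non-negative fractions) is clipped to zero.
    """
    pts = list(points)
    lets = np.array([l for l, _ in pts], dtype=float)
    fracs = np.array([r for _, r in pts], dtype=float)
    if np.count_nonzero(lets) == 0:
        raise ValueError("need at least one non-zero LET to fit the unhit law")
    if np.unique(lets[lets > 0]).size < 2:
        raise ValueError("need at least 2 distinct positive LET values")
    c_sq = 100.0 * np.sum(fracs * lets**2) / np.sum(lets**4)
    return UnhitLaw(c=math.sqrt(max(c_sq, 0.0)))


def hit_fraction(let: float, law: UnhitLaw) -> float:
    """R_hit = 1 − R_unhit at the given LET; errors outside the law's domain."""
    return law.r_hit(let)
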