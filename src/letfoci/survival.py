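"""Clonogenic survival: plating efficiency, surviving fraction, killing.

The clonogenic assay seeds a known number of single cells, irradiates, and
counts colonies of at least 50 cells ten days later.  The surviving
fraction is (colonies / seeded) divided by the plating efficiency measured
on unirradiated controls.  The cell killing effect is 1 − SF, and because
a fraction R_unhit of cells receives no particle traversal at all, the
killing attributable to traversed cells is killing / R_hit (the
R_hit-normalised killing effect).
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd

from .unhit_model import UnhitLaw

__all__ = [
    "SURVIVAL_COLUMNS",
    "plating_efficiency",
    "surviving_fraction",
    "killing_effect",
    "normalized_killing",
    "summarize_survival",
]

SURVIVAL_COLUMNS = ("condition", "replicate", "colonies", "n_seeded", "control")


def plating_efficiency(controls: pd.DataFrame) -> float:
    """Pooled plating efficiency: total control colonies / total control seeded.

    Pooling across wells (rather than averaging per-well ratios) weights
    each seeded cell equally and is robust to unequal well sizes.
    """
    if len(controls) == 0:
        raise ValueError("no control wells provided")
    total_colonies = int(controls["colonies"].sum())
    total_seeded = int(controls["n_seeded"].sum())
    if total_seeded <= 0:
        raise ValueError("control wells have no seeded cells")
    if total_colonies == 0:
        raise ValueError("zero colonies in controls: plating efficiency undefined")
    return total_colonies / total_seeded


def surviving_fraction(colonies: float, n_seeded: float, pe: float) -> float:
    """(colonies / n_seeded) / pe.  Warns (does not error) if the result exceeds 1."""
    if pe <= 0:
        raise ValueError(f"plating efficiency must be positive, got {pe}")
    if n_seeded <= 0:
        raise ValueError(f"n_seeded must be positive, got {n_seeded}")
    sf = (colonies / n_seeded) / pe
    if sf > 1:
        warnings.warn(f"surviving fraction {sf:.3f} exceeds 1", stacklevel=2)
    return sf


def killing_effect(sf: float) -> float:
    """Cell killing effect 1 − SF; SF must be a fraction in [0, 1]."""
    if not (0.0 <= sf <= 1.0):
        raise ValueError(f"surviving fraction must lie in [0, 1], got {sf}")
    return 1.0 - sf


def normalized_killing(killing: float, r_hit: float) -> float:
    """Killing divided by the hit fraction; warns if the quotient exceeds 1."""
    if r_hit <= 0:
        raise ValueError(f"R_hit must be positive, got {r_hit}")
    if r_hit > 1:
        raise ValueError(f"R_hit must not exceed 1, got {r_hit}")
    nk = killing / r_hit
    if nk > 1:
        warnings.warn(f"normalized killing {nk:.3f} exceeds 1", stacklevel=2)
    return nk


def summarize_survival(
    table: pd.DataFrame,
    unhit_law: Optional[UnhitLaw] = None,
    pe: Optional[float] = None,
) -> pd.DataFrame:
    """Per-condition replicate summary of SF, killing and normalised killing.

    Parameters
    ----------
    table : DataFrame with SURVIVAL_COLUMNS.  Rows with ``control`` True
        supply the plating efficiency unless ``pe`` is given explicitly.
    unhit_law : if given, conditions are interpreted as LET in keV/μm and a
        ``normalized_killing`` column (killing / R_hit) is added.
    pe : plating efficiency override.

    Returns
    -------
    DataFrame indexed by condition with columns ``sf_mean``, ``sf_sd``,
    ``killing``, ``n_replicates`` (and ``r_hit``, ``normalized_killing``
    when a law is supplied).  Replicate dispersion is the sample standard
    deviation.
    """
    controls = table[table["control"].astype(bool)]
    treated = table[~table["control"].astype(bool)]
    if len(treated) == 0:
        raise ValueError("no irradiated wells in survival table")
    if pe is None:
        pe = plating_efficiency(controls)

    records = []
    for condition, grp in treated.groupby("condition", sort=True):
        sfs = np.array(
            [
                surviving_fraction(c, n, pe)
                for c, n in zip(grp["colonies"], grp["n_seeded"])
            ]
        )
        sf_mean = float(sfs.mean())
        sf_sd = float(sfs.std(ddof=1)) if sfs.size > 1 else 0.0
        rec = {
            "condition": condition,
            "sf_mean": sf_mean,
            "sf_sd": sf_sd,
            "killing": killing_effect(min(sf_mean, 1.0)),
            "n_replicates": int(sfs.size),
        }
        if unhit_law is not None:
            r_hit = unhit_law.r_hit(float(condition))
            rec["r_hit"] = r_hit
            rec["normalized_killing"] = normalized_killing(rec["killing"], r_hit)
        records.append(rec)
    return pd.DataFrame.from_records(records).set_index("condition")
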