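"""Synthetic inputs for the LET / focus-volume / cell-killing pipeline.

The study conditions emulated here: six monoenergetic carbon-ion LETs
between the clinical entrance value (13 keV/μm) and the onset of the
overkill region (100 keV/μm), 1 Gy absorbed dose, 30 nuclei per LET for
3D focus volumetry, at least 200 cells per LET for γH2AX occupancy
scoring, and triplicate clonogenic assays.  Generation starts at the
measured-quantity level (volumes, areas, colony counts); there is no image
synthesis and no particle transport beyond a parametric Bragg-curve
stand-in.

The generative model, per LET L:

* a nucleus is unhit with probability R_unhit(L) = (c·L)²/100 (Bernoulli,
  not a Poisson zero class);
* a hit nucleus's *maximum* focus volume is Normal(mu_L, sigma_L) with the
  linear-in-LET laws, resampled if below the 0.01 μm³ exclusion floor;
* the number of foci in a hit nucleus is Poisson with mean proportional to
  1/L (equal dose in fewer, denser tracks at high LET), at least 1;
* non-maximum focus volumes are a plausibility-only log-normal bounded
  above by the nucleus maximum and floored at the exclusion threshold —
  only the maximum feeds the downstream model;
* colony counts are Binomial(n_seeded, PE·SF) with
  SF = 1 − R_hit(L)·p_L(v_th*) at the lethal-volume threshold v_th*.

All generators draw from independent substreams of one global seed and are
bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .foci_model import (
    A549_LET_LAWS,
    DEFAULT_VOLUME_FLOOR,
    LETLaws,
    clustering_probability,
)
from .let_mixing import (
    DEPTH_STEP_MM,
    DepthProfile,
    SOBPComponent,
    SOBPSpec,
    composed_dose,
)
from .unhit_model import UnhitLaw

__all__ = [
    "GeneratorConfig",
    "BeamParams",
    "sample_max_volumes",
    "gen_foci_table",
    "gen_occupancy_table",
    "gen_clonogenic_table",
    "gen_mono_depth_profiles",
    "gen_sobp_spec",
]

#: Default monoenergetic LET panel, keV/μm.
DEFAULT_LET_VALUES = (13.0, 20.0, 40.0, 60.0, 80.0, 100.0)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for all synthetic generators.

    Defaults reproduce the experimental design: LET panel 13–100 keV/μm,
    30 nuclei per LET, 200 occupancy-scored cells per LET, triplicate
    clonogenic wells, 1 Gy.  ``true_laws``, ``true_unhit_coefficient`` and
    ``true_lethal_threshold`` (0.7 μm³) are the generating truth that
    recovery experiments measure against.  ``foci_count_scale`` is the
    expected focus count of a hit nucleus at ``reference_let``; counts
    scale as reference_let/LET.
    """

    let_values: tuple[float, ...] = DEFAULT_LET_VALUES
    n_nuclei_per_let: int = 30
    n_cells_occupancy: int = 200
    n_seeded: int = 2000
    replicates: int = 3
    dose: float = 1.0
    true_laws: LETLaws = field(default_factory=lambda: A549_LET_LAWS)
    true_unhit_coefficient: float = 0.0618
    true_lethal_threshold: float = 0.7
    plating_efficiency: float = 0.8
    foci_count_scale: float = 40.0
    reference_let: float = 13.0
    volume_floor: float = DEFAULT_VOLUME_FLOOR
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nuclei_per_let < 1 or self.n_cells_occupancy < 1:
            raise ValueError("cell/nucleus counts must be at least 1")
        if self.n_seeded < 1 or self.replicates < 1:
            raise ValueError("n_seeded and replicates must be at least 1")
        if self.dose <= 0:
            raise ValueError("dose must be positive")
        if any(l <= 0 for l in self.let_values):
            raise ValueError("LET values must be strictly positive")
        if not (0.0 < self.plating_efficiency <= 1.0):
            raise ValueError("plating efficiency must lie in (0, 1]")
        if self.true_unhit_coefficient < 0:
            raise ValueError("unhit coefficient must be non-negative")
        object.__setattr__(self, "let_values", tuple(float(l) for l in self.let_values))

    @property
    def unhit_law(self) -> UnhitLaw:
        return UnhitLaw(c=self.true_unhit_coefficient)

    def _check_let_domain(self) -> None:
        law = self.unhit_law
        for let in self.let_values:
            if self.true_unhit_coefficient > 0 and let >= law.domain_max_let:
                raise ValueError(
                    f"LET {let} gives unhit fraction >= 1 "
                    f"(law domain ends at {law.domain_max_let:.4g} keV/μm)"
                )

    def _rng(self, stream: str) -> np.random.Generator:
        # independent named substreams of the one global seed
        offsets = {"foci": 0, "occupancy": 1, "clonogenic": 2, "beam": 3}
        ss = np.random.SeedSequence(entropy=self.seed, spawn_key=(offsets[stream],))
        return np.random.default_rng(ss)


def sample_max_volumes(
    rng: np.random.Generator,
    let: float,
    n: int,
    laws: LETLaws,
    floor: float = DEFAULT_VOLUME_FLOOR,
) -> np.ndarray:
    """Draw n per-nucleus maximum volumes from Normal(mu_LET, sigma_LET).

    Draws below the exclusion floor are resampled (truncation) so exactly
    n values are returned; downstream fitting never sees sub-floor foci.
    """
    mu, sigma = laws.mu(let), laws.sigma(let)
    if sigma <= 0:
        raise ValueError(f"sigma_LET({let}) = {sigma} is not positive")
    values = rng.normal(mu, sigma, size=n)
    bad = values < floor
    while bad.any():
        values[bad] = rng.normal(mu, sigma, size=int(bad.sum()))
        bad = values < floor
    return values


def _sub_max_volumes(
    rng: np.random.Generator, max_volume: float, count: int, floor: float
) -> np.ndarray:
    """Plausibility-only log-normal volumes bounded by the nucleus maximum."""
    if count == 0:
        return np.empty(0)
    # median at ~max/3, resampled into [floor, max]; only the maximum matters
    # downstream, this just gives the per-focus table realistic bulk.
    log_med = math.log(max(max_volume / 3.0, floor))
    values = rng.lognormal(mean=log_med, sigma=0.7, size=count)
    for _ in range(200):
        bad = (values < floor) | (values > max_volume)
        if not bad.any():
            break
        values[bad] = rng.lognormal(mean=log_med, sigma=0.7, size=int(bad.sum()))
    return np.clip(values, floor, max_volume)


def gen_foci_table(config: GeneratorConfig) -> pd.DataFrame:
    """Per-focus volume table (cell_line, let, nucleus_id, focus_id, volume).

    Each LET contributes ``n_nuclei_per_let`` nuclei; an unhit nucleus
    (Bernoulli R_unhit) carries no foci and thus no rows.  The largest
    focus of each hit nucleus is drawn from the max-volume normal law.
    """
    config._check_let_domain()
    rng = config._rng("foci")
    law = config.unhit_law
    rows: list[tuple] = []
    for let in config.let_values:
        r_unhit = law.r_unhit(let)
        mean_count = config.foci_count_scale * config.reference_let / let
        for k in range(config.n_nuclei_per_let):
            nucleus = f"L{let:g}_n{k:03d}"
            if rng.random() < r_unhit:
                continue  # unhit: zero foci
            max_v = sample_max_volumes(
                rng, let, 1, config.true_laws, config.volume_floor
            )[0]
            count = max(int(rng.poisson(mean_count)), 1)
            others = _sub_max_volumes(rng, max_v, count - 1, config.volume_floor)
            volumes = np.concatenate([[max_v], others])
            for j, v in enumerate(volumes):
                rows.append(("A549", let, nucleus, f"f{j:03d}", float(v)))
    return pd.DataFrame(
        rows, columns=["cell_line", "let", "nucleus_id", "focus_id", "volume"]
    )


def gen_occupancy_table(config: GeneratorConfig) -> pd.DataFrame:
    """Per-cell γH2AX occupancy table (let, cell_id, signal_area, nucleus_area).

    A cell is unhit with probability R_unhit(LET), in which case its
    occupancy is drawn uniformly below the 1% threshold; hit cells draw an
    occupancy of at least 1%.  Nucleus areas emulate G0/G1-synchronised
    fibroblast monolayers (similar nuclear size across cells).
    """
    config._check_let_domain()
    rng = config._rng("occupancy")
    law = config.unhit_law
    rows: list[tuple] = []
    for let in config.let_values:
        r_unhit = law.r_unhit(let)
        for k in range(config.n_cells_occupancy):
            area = float(rng.normal(120.0, 12.0))
            while area <= 0:
                area = float(rng.normal(120.0, 12.0))
            if rng.random() < r_unhit:
                occupancy = rng.uniform(0.0, 0.01)
            else:
                occupancy = 0.01 + 0.6 * rng.beta(1.5, 6.0)
            rows.append((let, f"L{let:g}_c{k:05d}", occupancy * area, area))
    return pd.DataFrame(
        rows, columns=["let", "cell_id", "signal_area", "nucleus_area"]
    )


def gen_clonogenic_table(config: GeneratorConfig) -> pd.DataFrame:
    """Clonogenic counts (condition, replicate, colonies, n_seeded, control).

    The generating survival model couples killing to DSB clustering:
    SF(L) = 1 − R_hit(L) · p_L(v_th*), so only traversed cells can die and
    they die exactly when their maximum focus reaches the lethal-volume
    threshold.  Colony counts are Binomial(n_seeded, PE·SF); unirradiated
    control wells (condition 0, control=True) succeed with probability PE.
    """
    config._check_let_domain()
    rng = config._rng("clonogenic")
    law = config.unhit_law
    rows: list[tuple] = []
    for rep in range(config.replicates):
        colonies = int(rng.binomial(config.n_seeded, config.plating_efficiency))
        rows.append((0.0, f"r{rep}", colonies, config.n_seeded, True))
    for let in config.let_values:
        p = clustering_probability(
            config.true_lethal_threshold, let, config.true_laws
        )
        sf_true = 1.0 - law.r_hit(let) * p
        if not (0.0 <= sf_true <= 1.0):
            raise ValueError(f"generating SF {sf_true} at LET {let} outside [0, 1]")
        for rep in range(config.replicates):
            colonies = int(
                rng.binomial(config.n_seeded, config.plating_efficiency * sf_true)
            )
            rows.append((let, f"r{rep}", colonies, config.n_seeded, False))
    return pd.DataFrame(
        rows, columns=["condition", "replicate", "colonies", "n_seeded", "control"]
    )


@dataclass(frozen=True)
class BeamParams:
    """Parametric stand-in for a monoenergetic carbon-ion depth profile.

    ``range_mm`` is the depth of the Bragg peak (about 150 mm of water for
    290 MeV/n carbon); ``entrance_let`` the LET at z = 0 (13 keV/μm, the
    clinical entrance value); ``peak_let`` the LET reached at the peak
    (above the 100 keV/μm overkill cap, as physically expected near the
    Bragg peak).  The dose has a gentle entrance rise, a gaussian peak of
    width ``peak_width_mm`` at the range, and a sharp distal falloff.
    """

    range_mm: float = 150.0
    entrance_let: float = 13.0
    peak_let: float = 200.0
    peak_dose_ratio: float = 4.0
    peak_width_mm: float = 3.0
    distal_falloff_mm: float = 1.5
    grid_max_mm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.range_mm <= 0:
            raise ValueError(f"beam range must be positive, got {self.range_mm}")
        if self.entrance_let <= 0 or self.peak_let < self.entrance_let:
            raise ValueError("need 0 < entrance_let <= peak_let")


def gen_mono_depth_profiles(
    beam_params: "BeamParams | Sequence[BeamParams]" = BeamParams(),
) -> list[DepthProfile]:
    """Build parametric monoenergetic depth profiles on a 0.1 mm grid.

    LET(z) rises monotonically from the entrance value to ``peak_let`` at
    the Bragg peak (a steep power law, so LET stays near the entrance value
    over most of the track); dose(z) has a single maximum at the peak.
    """
    params_list = (
        [beam_params] if isinstance(beam_params, BeamParams) else list(beam_params)
    )
    profiles = []
    for p in params_list:
        grid_max = p.grid_max_mm if p.grid_max_mm is not None else p.range_mm + 40.0
        n = int(round(grid_max / DEPTH_STEP_MM)) + 1
        z = np.arange(n) * DEPTH_STEP_MM
        r = np.minimum(z / p.range_mm, 1.0)

        # LET rises as a power of inverse residual range (stopping-power
        # behaviour): entrance value exact at z = 0, peak value exact at the
        # Bragg peak, held there beyond it.
        if p.peak_let == p.entrance_let:
            let = np.full_like(z, p.entrance_let)
        else:
            q = 0.63
            delta = p.range_mm / ((p.peak_let / p.entrance_let) ** (1.0 / q) - 1.0)
            residual = np.maximum(p.range_mm - z, 0.0) + delta
            let = p.entrance_let * ((p.range_mm + delta) / residual) ** q

        rising = 1.0 + 0.3 * r**2 + (p.peak_dose_ratio - 1.0) * np.exp(
            -((z - p.range_mm) ** 2) / (2.0 * p.peak_width_mm**2)
        )
        peak_val = 1.3 + (p.peak_dose_ratio - 1.0)
        falling = peak_val * np.exp(
            -((z - p.range_mm) ** 2) / (2.0 * p.distal_falloff_mm**2)
        )
        dose = np.where(z <= p.range_mm, rising, falling)
        profiles.append(DepthProfile(depth=z, let_mono=let, dose_mono=dose))
    return profiles


def gen_sobp_spec(
    width_mm: float,
    mono: Optional[DepthProfile] = None,
    shift_step_mm: float = 2.0,
    plateau_margin_mm: float = 2.0,
) -> SOBPSpec:
    """Ridge-filter weights and shifts producing a flat SOBP of given width.

    Shifts span exactly [0, width_mm]; weights are obtained by non-negative
    least squares of the shifted mono dose profiles against a flat unit
    target over the plateau [range − width, range] (edges trimmed by
    ``plateau_margin_mm``), then normalised to sum 1.  The evaluation depth
    is the dose-weighted midpoint of the composed plateau.  Deterministic
    for a given width and mono profile.
    """
    if width_mm <= 0:
        raise ValueError(f"SOBP width must be positive, got {width_mm}")
    if mono is None:
        # grid must cover every shifted lookup depth z + s_j
        base = BeamParams()
        mono = gen_mono_depth_profiles(
            replace(base, grid_max_mm=base.range_mm + width_mm + 20.0)
        )[0]

    peak_depth = float(mono.depth[np.argmax(mono.dose_mono)])
    n_shift = max(int(round(width_mm / shift_step_mm)), 1)
    shifts = np.linspace(0.0, width_mm, n_shift + 1)

    z_lo = peak_depth - width_mm + plateau_margin_mm
    z_hi = peak_depth - plateau_margin_mm
    if z_lo <= mono.depth[0]:
        raise ValueError("SOBP width exceeds the usable range of the mono profile")
    z_grid = np.arange(z_lo, z_hi + 1e-9, 1.0)

    a = np.array([[mono.dose_at(zk + s) for s in shifts] for zk in z_grid])
    weights, _ = nnls(a, np.ones(len(z_grid)))
    if weights.sum() <= 0:
        raise ValueError("ridge-filter weight optimisation returned all zeros")
    weights = weights / weights.sum()

    components = tuple(
        SOBPComponent(w=float(w), s=float(s)) for w, s in zip(weights, shifts)
    )
    # dose-weighted midpoint of the plateau
    trial = SOBPSpec(components=components, width=width_mm, eval_depth=z_lo)
    doses = np.array([composed_dose(mono, trial, zk) for zk in z_grid])
    eval_depth = float(np.sum(z_grid * doses) / np.sum(doses))
    return SOBPSpec(components=components, width=width_mm, eval_depth=eval_depth)
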