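"""Mixed-LET spectra at the SOBP center and the dose-averaged LET.

A clinical carbon-ion beam is a superposition of range-shifted
monoenergetic beams: a ridge filter assigns each component j a weight w_j
and a range shift s_j.  At an evaluation depth z inside the spread-out
Bragg peak (SOBP) each component contributes an LET value

    L_j = L_mono(z + s_j)

and a dose d_j = w_j · dose_mono(z + s_j).  The scalar LET assigned to the
mixed beam is the dose-averaged LET

    L_mix = Σ L_j d_j / D,   D = Σ d_j,

with every component's LET capped at 100 keV/μm beforehand, since beyond
roughly 100 keV/μm additional LET no longer increases killing per unit
dose (the overkill region).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "DEPTH_STEP_MM",
    "OVERKILL_CAP",
    "DepthProfile",
    "SOBPComponent",
    "SOBPSpec",
    "LETSpectrum",
    "compose_spectrum",
    "cap_spectrum",
    "dose_averaged_let",
    "composed_dose",
]

#: Depth grid resolution in mm.
DEPTH_STEP_MM = 0.1

#: Overkill cap applied to component LET before dose averaging, keV/μm.
OVERKILL_CAP = 100.0


@dataclass(frozen=True)
class DepthProfile:
    """Monoenergetic depth profile on a uniform 0.1 mm grid.

    ``let_mono`` is the LET (keV/μm) and ``dose_mono`` the relative dose at
    each depth.  Depths must be strictly increasing with uniform 0.1 mm
    spacing; LET is positive and dose non-negative everywhere.
    """

    depth: np.ndarray
    let_mono: np.ndarray
    dose_mono: np.ndarray

    def __post_init__(self) -> None:
        depth = np.asarray(self.depth, dtype=float)
        let_mono = np.asarray(self.let_mono, dtype=float)
        dose_mono = np.asarray(self.dose_mono, dtype=float)
        if not (depth.size == let_mono.size == dose_mono.size):
            raise ValueError("depth, let_mono and dose_mono must have equal length")
        if depth.size < 2:
            raise ValueError("profile needs at least two depth points")
        steps = np.diff(depth)
        if not np.allclose(steps, DEPTH_STEP_MM, rtol=0, atol=1e-9):
            raise ValueError("depth grid must have uniform 0.1 mm spacing")
        if np.any(let_mono <= 0):
            raise ValueError("let_mono must be positive everywhere")
        if np.any(dose_mono < 0):
            raise ValueError("dose_mono must be non-negative")
        object.__setattr__(self, "depth", depth)
        object.__setattr__(self, "let_mono", let_mono)
        object.__setattr__(self, "dose_mono", dose_mono)

    def _check_in_range(self, z: float) -> None:
        if z < self.depth[0] or z > self.depth[-1]:
            raise ValueError(
                f"depth {z:.2f} mm outside profile grid "
                f"[{self.depth[0]:.2f}, {self.depth[-1]:.2f}] mm"
            )

    def let_at(self, z: float) -> float:
        """LET at depth z (mm), linearly interpolated; error off-grid."""
        self._check_in_range(z)
        return float(np.interp(z, self.depth, self.let_mono))

    def dose_at(self, z: float) -> float:
        """Relative dose at depth z (mm), linearly interpolated; error off-grid."""
        self._check_in_range(z)
        return float(np.interp(z, self.depth, self.dose_mono))


@dataclass(frozen=True)
class SOBPComponent:
    """One ridge-filter leg: weight w (dimensionless) and range shift s (mm)."""

    w: float
    s: float

    def __post_init__(self) -> None:
        if self.w < 0:
            raise ValueError(f"weight must be non-negative, got {self.w}")


@dataclass(frozen=True)
class SOBPSpec:
    """Ridge-filter composition of an SOBP.

    ``width`` is the SOBP plateau width in mm and ``eval_depth`` the depth
    (mm) at which the mixed spectrum is evaluated — by construction the
    dose-weighted midpoint of the plateau.
    """

    components: tuple[SOBPComponent, ...]
    width: float
    eval_depth: float

    def __post_init__(self) -> None:
        comps = tuple(self.components)
        if not comps:
            raise ValueError("SOBP spec needs at least one component")
        if sum(c.w for c in comps) <= 0:
            raise ValueError("total component weight must be positive")
        object.__setattr__(self, "components", comps)


@dataclass(frozen=True)
class LETSpectrum:
    """A mixed beam's LET components: LET values ``let`` with doses ``dose``."""

    let: np.ndarray
    dose: np.ndarray

    def __post_init__(self) -> None:
        let = np.asarray(self.let, dtype=float)
        dose = np.asarray(self.dose, dtype=float)
        if let.size != dose.size:
            raise ValueError("let and dose must have equal length")
        if np.any(dose < 0):
            raise ValueError("component doses must be non-negative")
        object.__setattr__(self, "let", let)
        object.__setattr__(self, "dose", dose)

    @property
    def total_dose(self) -> float:
        return float(self.dose.sum())


def compose_spectrum(
    monos: "DepthProfile | Sequence[DepthProfile]", spec: SOBPSpec
) -> LETSpectrum:
    """Evaluate the mixed spectrum at the SOBP evaluation depth.

    Each ridge-filter leg j, applied to each monoenergetic profile,
    contributes one (LET, dose) pair: the profile's LET looked up at
    z + s_j, and its dose there scaled by w_j.  All shifted depths must lie
    inside every profile's grid.
    """
    profiles = [monos] if isinstance(monos, DepthProfile) else list(monos)
    if not profiles:
        raise ValueError("no monoenergetic profiles given")
    z = spec.eval_depth
    lets: list[float] = []
    doses: list[float] = []
    for prof in profiles:
        for comp in spec.components:
            lets.append(prof.let_at(z + comp.s))
            doses.append(comp.w * prof.dose_at(z + comp.s))
    return LETSpectrum(let=np.array(lets), dose=np.array(doses))


def cap_spectrum(spec: LETSpectrum, cap: float = OVERKILL_CAP) -> LETSpectrum:
    """Clamp every component's LET to ``cap``; doses are unchanged."""
    if cap <= 0:
        raise ValueError(f"cap must be positive, got {cap}")
    return LETSpectrum(let=np.minimum(spec.let, cap), dose=spec.dose.copy())


def dose_averaged_let(spec: LETSpectrum) -> float:
    """Σ L_i d_i / D; lies between the smallest and largest component LET."""
    total = spec.total_dose
    if total <= 0:
        raise ValueError("total dose must be positive for dose averaging")
    return float(np.sum(spec.let * spec.dose) / total)


def composed_dose(mono: DepthProfile, spec: SOBPSpec, z: float) -> float:
    """Total SOBP dose at depth z: Σ_j w_j · dose_mono(z + s_j)."""
    return sum(c.w * mono.dose_at(z + c.s) for c in spec.components)
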