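"""CSV/JSON readers and writers for the pipeline's tables and fitted laws.

Tables (foci, occupancy, survival) travel as plain CSV with the column
names used throughout the package; fitted laws and SOBP specs as JSON;
depth profiles as CSV (depth_mm, let_kev_um, dose_rel) with an optional
JSON sidecar of generation parameters.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .foci_model import GaussianFit, LETLaws
from .let_mixing import DepthProfile, LETSpectrum, SOBPComponent, SOBPSpec
from .unhit_model import UnhitLaw

__all__ = [
    "read_table",
    "write_table",
    "write_let_laws",
    "read_let_laws",
    "write_unhit_law",
    "read_unhit_law",
    "write_depth_profile",
    "read_depth_profile",
    "write_sobp_spec",
    "read_sobp_spec",
    "write_spectrum",
]


def read_table(path: "str | Path") -> pd.DataFrame:
    return pd.read_csv(path)


def write_table(table: pd.DataFrame, path: "str | Path") -> None:
    table.to_csv(path, index=False)


def write_let_laws(laws: LETLaws, path: "str | Path") -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(laws), indent=2) + "\n")


def read_let_laws(path: "str | Path") -> LETLaws:
    return LETLaws(**json.loads(Path(path).read_text()))


def write_unhit_law(law: UnhitLaw, path: "str | Path") -> None:
    Path(path).write_text(json.dumps({"c": law.c}, indent=2) + "\n")


def read_unhit_law(path: "str | Path") -> UnhitLaw:
    return UnhitLaw(**json.loads(Path(path).read_text()))


def write_depth_profile(
    profile: DepthProfile, path: "str | Path", params: Optional[dict] = None
) -> None:
    """Write a profile as CSV; generation parameters go to a .json sidecar."""
    frame = pd.DataFrame(
        {
            "depth_mm": profile.depth,
            "let_kev_um": profile.let_mono,
            "dose_rel": profile.dose_mono,
        }
    )
    frame.to_csv(path, index=False)
    if params is not None:
        sidecar = Path(path).with_suffix(".json")
        sidecar.write_text(json.dumps(params, indent=2) + "\n")


def read_depth_profile(path: "str | Path") -> DepthProfile:
    frame = pd.read_csv(path)
    return DepthProfile(
        depth=frame["depth_mm"].to_numpy(),
        let_mono=frame["let_kev_um"].to_numpy(),
        dose_mono=frame["dose_rel"].to_numpy(),
    )


def write_sobp_spec(spec: SOBPSpec, path: "str | Path") -> None:
    payload = {
        "width": spec.width,
        "eval_depth": spec.eval_depth,
        "components": [{"w": c.w, "s": c.s} for c in spec.components],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_sobp_spec(path: "str | Path") -> SOBPSpec:
    payload = json.loads(Path(path).read_text())
    return SOBPSpec(
        components=tuple(
            SOBPComponent(w=c["w"], s=c["s"]) for c in payload["components"]
        ),
        width=payload["width"],
        eval_depth=payload["eval_depth"],
    )


def write_spectrum(spectrum: LETSpectrum, path: "str | Path") -> None:
    pd.DataFrame({"let_kev_um": spectrum.let, "dose": spectrum.dose}).to_csv(
        path, index=False
    )
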