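"""Materials: HU assignments and the HU -> relative stopping power (RSP) table.

The conversion is the usual piecewise-linear calibration anchored at water
(0 HU -> RSP 1.0), clamped at the table endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import ScalarVolume, VolumeKind

__all__ = ["MATERIAL_HU", "MaterialTable", "hu_to_rsp"]

#: declared HU per phantom material
MATERIAL_HU = {
    "air": -1000.0,
    "lung": -700.0,
    "adipose": -90.0,
    "water": 0.0,
    "muscle": 40.0,
    "bone": 700.0,
}


@dataclass(frozen=True)
class MaterialTable:
    """Piecewise-linear HU -> RSP calibration (water = 1.0 at 0 HU)."""

    hu_breakpoints: tuple[float, ...] = (-1000.0, -700.0, -90.0, 0.0, 40.0, 700.0)
    rsp_values: tuple[float, ...] = (0.001, 0.30, 0.93, 1.0, 1.04, 1.40)

    def __post_init__(self):
        hu = np.asarray(self.hu_breakpoints, dtype=float)
        rsp = np.asarray(self.rsp_values, dtype=float)
        if hu.size != rsp.size or hu.size < 2:
            raise ValueError("breakpoints and RSP values must have equal length >= 2")
        if np.any(np.diff(hu) <= 0):
            raise ValueError("HU breakpoints must be strictly increasing")
        if np.any(rsp < 0):
            raise ValueError("RSP values must be non-negative")

    def rsp_of(self, hu) -> np.ndarray:
        """Interpolate RSP at arbitrary HU, clamped to the table endpoints."""
        return np.interp(
            np.asarray(hu, dtype=float), self.hu_breakpoints, self.rsp_values
        )


DEFAULT_TABLE = MaterialTable()


def hu_to_rsp(ct: ScalarVolume, table: MaterialTable = DEFAULT_TABLE) -> ScalarVolume:
    """Convert a CT volume to relative stopping power."""
    if ct.kind is not VolumeKind.CT_HU:
        raise ValueError(f"expected a CT_HU volume, got {ct.kind}")
    return ScalarVolume(ct.grid, table.rsp_of(ct.values), VolumeKind.RSP)
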