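"""Hypercube data model and reflectance calibration.

Axis convention for all cubes is ``(line, pixel, band)``, matching
push-broom acquisition: the stage sweeps the sample line by line under the
spectrograph slit, and each pixel of each line carries a full spectrum.

Raw sensor counts are converted to relative reflectance with white and
dark reference frames::

    R_corrected = (R_raw - R_dark) / (R_white - R_dark)

where the white reference is a high-reflectance ceramic tile (~99 %) and
the dark reference is recorded with the lens capped.  References may be
full frames, per-band vectors, or anything in between, as long as they
broadcast against the cube.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .grid import WavelengthGrid

__all__ = [
    "HypercubeRaw",
    "ReferenceFrame",
    "ReflectanceCube",
    "ColorTriplet",
    "correct_reflectance",
]

logger = logging.getLogger(__name__)

#: Reflectance outside this range is physically suspect (the white tile is
#: ~99 % reflective, so values slightly above 1 can occur); the fraction of
#: out-of-range values is reported, never silently clipped.
REFLECTANCE_RANGE = (0.0, 1.1)


class ColorTriplet(NamedTuple):
    """CIELAB colour: L* lightness (0–100), a* red–green, b* yellow–blue."""

    L: float
    a: float
    b: float

    def validate(self) -> "ColorTriplet":
        if not 0.0 <= self.L <= 100.0:
            raise ValueError(f"L* must lie in [0, 100], got {self.L}")
        return self


def _check_cube_array(data: np.ndarray, grid: WavelengthGrid, what: str) -> np.ndarray:
    data = np.asarray(data, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"{what} must be 3-D (lines, pixels, bands), got shape {data.shape}")
    if data.shape[2] != len(grid):
        raise ValueError(
            f"{what} has {data.shape[2]} bands but the grid has {len(grid)}"
        )
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{what} contains non-finite values")
    return data


@dataclass
class HypercubeRaw:
    """Uncalibrated sensor counts, shape (lines, pixels, bands)."""

    data: np.ndarray
    grid: WavelengthGrid
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = _check_cube_array(self.data, self.grid, "raw cube")
        if np.any(self.data < 0):
            raise ValueError("raw counts must be non-negative")

    @property
    def shape(self) -> tuple:
        return self.data.shape


@dataclass
class ReferenceFrame:
    """White or dark reference, broadcastable to a cube's shape."""

    data: np.ndarray
    kind: str  # "white" | "dark"

    def __post_init__(self) -> None:
        if self.kind not in ("white", "dark"):
            raise ValueError(f"reference kind must be 'white' or 'dark', got {self.kind!r}")
        self.data = np.asarray(self.data, dtype=float)
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"{self.kind} reference contains non-finite values")


@dataclass
class ReflectanceCube:
    """Calibrated relative reflectance, shape (lines, pixels, bands)."""

    data: np.ndarray
    grid: WavelengthGrid
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = _check_cube_array(self.data, self.grid, "reflectance cube")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def out_of_range_fraction(self) -> float:
        lo, hi = REFLECTANCE_RANGE
        return float(np.mean((self.data < lo) | (self.data > hi)))


def correct_reflectance(
    raw: HypercubeRaw, white: ReferenceFrame, dark: ReferenceFrame
) -> ReflectanceCube:
    """Convert raw counts to relative reflectance with reference frames.

    Applies ``(raw - dark) / (white - dark)`` elementwise after
    broadcasting.  The white counts must strictly exceed the dark counts
    at every element that is actually used; violations raise with the
    offending indices rather than producing infinities.

    Out-of-range reflectance (outside [0, 1.1]) is retained — downstream
    stages decide how to treat it — but its fraction is logged and stored
    in the cube's provenance.
    """
    if white.kind != "white" or dark.kind != "dark":
        raise ValueError("references must be passed as (white, dark)")
    w = np.broadcast_to(white.data, raw.data.shape)
    d = np.broadcast_to(dark.data, raw.data.shape)
    denom = w - d
    bad = denom <= 0
    if np.any(bad):
        idx = np.argwhere(bad)[:10]
        raise ValueError(
            "white reference does not exceed dark reference at "
            f"{int(np.count_nonzero(bad))} elements, e.g. (line, pixel, band) "
            f"indices {[tuple(int(i) for i in row) for row in idx]}"
        )
    corrected = (raw.data - d) / denom
    cube = ReflectanceCube(
        data=corrected,
        grid=raw.grid,
        provenance={
            "calibration": "(raw - dark) / (white - dark)",
            "white_shape": tuple(white.data.shape),
            "dark_shape": tuple(dark.data.shape),
            "meta": dict(raw.meta),
        },
    )
    frac = cube.out_of_range_fraction
    cube.provenance["out_of_range_fraction"] = frac
    if frac > 0:
        logger.info("reflectance outside [%.1f, %.1f] at %.3f%% of elements",
                    *REFLECTANCE_RANGE, 100 * frac)
    return cube
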