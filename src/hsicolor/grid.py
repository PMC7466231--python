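"""Wavelength grids for visible/near-infrared hyperspectral cubes.

A :class:`WavelengthGrid` is the spectral axis shared by cubes, spectra
matrices and fitted models.  The instrument convention emulated here is a
uniform grid, by default 380–1000 nm sampled every 5 nm (125 bands).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["WavelengthGrid", "make_wavelength_grid", "default_grid"]


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing, uniformly spaced wavelengths in nanometres."""

    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 1:
            raise ValueError("wavelength grid must be a non-empty 1-D array")
        if values.size > 1:
            diffs = np.diff(values)
            if np.any(diffs <= 0):
                raise ValueError("wavelengths must be strictly increasing")
            if not np.allclose(diffs, diffs[0], rtol=0, atol=1e-9 * max(1.0, diffs[0])):
                raise ValueError("wavelength grid must be uniformly spaced")
        object.__setattr__(self, "values", values)

    @property
    def step(self) -> float:
        """Grid spacing in nm (0.0 for a single-band grid)."""
        if len(self) < 2:
            return 0.0
        return float(self.values[1] - self.values[0])

    @property
    def span(self) -> float:
        return float(self.values[-1] - self.values[0])

    def __len__(self) -> int:
        return int(self.values.size)

    def __iter__(self):
        return iter(self.values)

    def index_of(self, nm: float) -> int:
        """Snap ``nm`` to the nearest grid band.

        The match must fall within half a grid step of a band centre;
        anything further is outside the grid and raises ``ValueError``.
        """
        idx = int(np.argmin(np.abs(self.values - nm)))
        half = self.step / 2.0 if len(self) > 1 else 0.0
        tol = half if half > 0 else 1e-9
        if abs(self.values[idx] - nm) > tol + 1e-9:
            raise ValueError(
                f"wavelength {nm} nm is outside the grid "
                f"({self.values[0]}–{self.values[-1]} nm, step {self.step} nm)"
            )
        return idx

    def subset(self, indices) -> "WavelengthGrid":
        """Subset of grid wavelengths; the result may be non-uniform, so it
        is returned as a plain array rather than a grid."""
        return np.asarray(self.values[np.asarray(indices, dtype=int)])


def make_wavelength_grid(start_nm: float, stop_nm: float, step_nm: float) -> WavelengthGrid:
    """Build a uniform wavelength grid including both endpoints.

    Parameters
    ----------
    start_nm, stop_nm : float
        First and last wavelength in nm; ``stop_nm >= start_nm``.
    step_nm : float
        Positive band spacing; ``stop_nm - start_nm`` must be an integer
        multiple of it.

    Returns
    -------
    WavelengthGrid
        Grid of ``(stop - start)/step + 1`` bands.
    """
    if step_nm <= 0:
        raise ValueError(f"step_nm must be positive, got {step_nm}")
    if stop_nm < start_nm:
        raise ValueError(f"stop_nm ({stop_nm}) must be >= start_nm ({start_nm})")
    span = stop_nm - start_nm
    n_steps = span / step_nm
    remainder = abs(n_steps - round(n_steps)) * step_nm
    if remainder > 1e-6:
        raise ValueError(
            f"range {start_nm}–{stop_nm} nm is not divisible by step {step_nm} nm "
            f"(remainder {remainder:.6g} nm)"
        )
    n = int(round(n_steps)) + 1
    return WavelengthGrid(start_nm + step_nm * np.arange(n))


def default_grid() -> WavelengthGrid:
    """The 380–1000 nm, 5 nm instrument grid (125 bands)."""
    return make_wavelength_grid(380.0, 1000.0, 5.0)
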