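"""ROI extraction, threshold segmentation, and spectral pre-treatments.

The pre-treatments are the chemometrics standards used ahead of PLSR
calibration on diffuse-reflectance spectra:

* **SNV** — per-spectrum centring and scaling to unit sample standard
  deviation, correcting multiplicative scatter.
* **MSC** — per-spectrum least-squares regression onto a reference
  spectrum (by convention the calibration-set mean), removing additive
  and multiplicative scatter.
* **area normalisation** — scale each spectrum so its trapezoidal area
  over the wavelength grid is 1, making spectra directly comparable.
* **first/second Savitzky–Golay derivatives** — local polynomial
  derivatives separating overlapping absorption bands and removing
  baseline drift; scaled by the grid step to per-nm units.

Each pre-treatment is also available as a fit/apply object so that
statistics estimated on a calibration set (the MSC reference) are frozen
and reused on validation rows and pixel spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import savgol_filter

from .cube import ReflectanceCube
from .grid import WavelengthGrid

__all__ = [
    "PixelMask",
    "SpectraMatrix",
    "extract_center_roi",
    "segment_threshold",
    "snv",
    "msc",
    "area_normalize",
    "sg_derivative",
    "Pretreatment",
    "get_pretreatment",
    "PRETREATMENTS",
]

#: Segmentation bands used per colour attribute (nm) and the reflectance
#: threshold separating sample pixels from the black background.
SEGMENTATION_BANDS_NM = {"L": 690.0, "a": 685.0, "b": 685.0}
SEGMENTATION_THRESHOLD = 0.05


@dataclass
class PixelMask:
    """Boolean sample mask over a cube's spatial plane, with the rule
    that produced it."""

    mask: np.ndarray
    rule: str

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D (lines, pixels)")

    @property
    def count(self) -> int:
        return int(np.count_nonzero(self.mask))


@dataclass
class SpectraMatrix:
    """Samples (or pixels) × bands matrix tied to a wavelength grid."""

    X: np.ndarray
    grid: WavelengthGrid
    treatment: str = "raw"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("spectra matrix must be 2-D")
        if self.X.shape[1] != len(self.grid):
            raise ValueError(
                f"matrix has {self.X.shape[1]} bands but grid has {len(self.grid)}"
            )
        if not np.all(np.isfinite(self.X)):
            raise ValueError("spectra matrix contains missing or non-finite values")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_bands(self) -> int:
        return self.X.shape[1]


def extract_center_roi(cube: ReflectanceCube, size: int = 50):
    """Centred square ROI of ``size`` × ``size`` pixels, unfolded row-wise.

    The window is centred on the spatial centre; when a dimension minus
    ``size`` is odd, the extra pixel goes to the bottom/right (floor
    convention).  Returns the unfolded pixel spectra and their mean
    spectrum, which is the quantity used for model calibration.
    """
    lines, pixels, _ = cube.shape
    if size < 1:
        raise ValueError("ROI size must be >= 1")
    if lines < size or pixels < size:
        raise ValueError(
            f"cube spatial shape {(lines, pixels)} is smaller than ROI {(size, size)}"
        )
    r0 = (lines - size) // 2
    c0 = (pixels - size) // 2
    window = cube.data[r0:r0 + size, c0:c0 + size, :]
    X = window.reshape(size * size, -1)
    matrix = SpectraMatrix(X=X, grid=cube.grid, treatment="raw")
    return matrix, X.mean(axis=0)


def segment_threshold(
    cube: ReflectanceCube,
    band_nm: float,
    threshold: float = SEGMENTATION_THRESHOLD,
) -> PixelMask:
    """Mask of pixels whose reflectance at ``band_nm`` strictly exceeds
    ``threshold``; the band snaps to the nearest grid wavelength."""
    idx = cube.grid.index_of(band_nm)
    plane = cube.data[:, :, idx]
    return PixelMask(
        mask=plane > threshold,
        rule=f"reflectance@{cube.grid.values[idx]:g}nm > {threshold:g}",
    )


def snv(X: SpectraMatrix) -> SpectraMatrix:
    """Standard normal variate: each row to mean 0, sample SD 1."""
    data = X.X
    means = data.mean(axis=1, keepdims=True)
    sds = data.std(axis=1, ddof=1, keepdims=True)
    flat = np.flatnonzero(sds.ravel() == 0)
    if flat.size:
        raise ValueError(f"constant spectra cannot be SNV-scaled: rows {flat.tolist()}")
    return replace(X, X=(data - means) / sds, treatment="snv")


def msc(X: SpectraMatrix, reference: np.ndarray | None = None) -> SpectraMatrix:
    """Multiplicative scatter correction against a reference spectrum.

    Each row ``x`` is regressed on the reference ``r`` as
    ``x ≈ a + b·r`` and replaced by ``(x - a)/b``.  The reference
    defaults to the column mean of ``X``.
    """
    data = X.X
    if data.shape[1] < 2:
        raise ValueError("MSC needs at least 2 bands")
    ref = data.mean(axis=0) if reference is None else np.asarray(reference, dtype=float)
    if ref.shape != (data.shape[1],):
        raise ValueError("reference length must match band count")
    ref_c = ref - ref.mean()
    denom = ref_c @ ref_c
    if denom == 0:
        raise ValueError("MSC reference has zero variance")
    # per-row OLS of x on (1, ref), vectorised
    slopes = (data - data.mean(axis=1, keepdims=True)) @ ref_c / denom
    if np.any(slopes == 0):
        raise ValueError("MSC slope of zero for at least one spectrum")
    intercepts = data.mean(axis=1) - slopes * ref.mean()
    corrected = (data - intercepts[:, None]) / slopes[:, None]
    return replace(X, X=corrected, treatment="msc")


def area_normalize(X: SpectraMatrix) -> SpectraMatrix:
    """Scale each row to unit trapezoidal area over the wavelength grid."""
    areas = np.trapezoid(X.X, X.grid.values, axis=1)
    flat = np.flatnonzero(areas == 0)
    if flat.size:
        raise ValueError(f"zero-area spectra cannot be normalised: rows {flat.tolist()}")
    return replace(X, X=X.X / areas[:, None], treatment="normalisation")


def sg_derivative(
    X: SpectraMatrix,
    order: int,
    window: int = 11,
    polyorder: int | None = None,
) -> SpectraMatrix:
    """Savitzky–Golay derivative of each spectrum, in per-nm units.

    Defaults: polynomial order 2 for the first derivative, 3 for the
    second.  Edges are handled by evaluating the edge-window polynomial
    fit, so the band count is preserved.
    """
    if order not in (1, 2):
        raise ValueError("derivative order must be 1 or 2")
    if polyorder is None:
        polyorder = 2 if order == 1 else 3
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if not (window > polyorder >= order):
        raise ValueError(
            f"need window > polyorder >= order, got window={window}, "
            f"polyorder={polyorder}, order={order}"
        )
    if window > X.n_bands:
        raise ValueError(f"window {window} exceeds band count {X.n_bands}")
    step = X.grid.step
    if step <= 0:
        raise ValueError("derivatives need a multi-band grid")
    deriv = savgol_filter(X.X, window_length=window, polyorder=polyorder,
                          deriv=order, delta=step, axis=1, mode="interp")
    return replace(X, X=deriv, treatment=f"d{order}")


# ---------------------------------------------------------------------------
# fit/apply pre-treatment objects (so calibration statistics are frozen)

@dataclass
class Pretreatment:
    """A named pre-treatment with fit/apply semantics.

    Only MSC carries fitted state (its reference spectrum); the others
    are stateless row transforms, but all share the interface so models
    can freeze and replay their pre-treatment chain.
    """

    name: str
    window: int = 11
    polyorder: int | None = None
    reference: np.ndarray | None = None
    fitted: bool = field(default=False, repr=False)

    _NAMES = ("raw", "snv", "msc", "normalisation", "d1", "d2")

    def __post_init__(self) -> None:
        if self.name not in self._NAMES:
            raise ValueError(f"unknown pre-treatment {self.name!r}; choose from {self._NAMES}")
        if self.reference is not None:
            self.reference = np.asarray(self.reference, dtype=float)
            self.fitted = True

    def fit(self, X: SpectraMatrix) -> "Pretreatment":
        if self.name == "msc" and self.reference is None:
            self.reference = X.X.mean(axis=0)
        self.fitted = True
        return self

    def apply(self, X: SpectraMatrix) -> SpectraMatrix:
        if self.name == "raw":
            return replace(X, treatment="raw")
        if self.name == "snv":
            return snv(X)
        if self.name == "msc":
            if not self.fitted:
                raise ValueError("MSC pre-treatment must be fitted before apply")
            return msc(X, reference=self.reference)
        if self.name == "normalisation":
            return area_normalize(X)
        order = int(self.name[1])
        return sg_derivative(X, order=order, window=self.window, polyorder=self.polyorder)

    def fit_apply(self, X: SpectraMatrix) -> SpectraMatrix:
        return self.fit(X).apply(X)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "window": self.window,
            "polyorder": self.polyorder,
            "reference": None if self.reference is None else self.reference.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Pretreatment":
        return cls(name=d["name"], window=d.get("window", 11),
                   polyorder=d.get("polyorder"),
                   reference=None if d.get("reference") is None else np.asarray(d["reference"]))


PRETREATMENTS = Pretreatment._NAMES


def get_pretreatment(name: str, window: int = 11, polyorder: int | None = None) -> Pretreatment:
    """Factory for pre-treatment objects; accepts 'norm' as an alias."""
    if name == "norm":
        name = "normalisation"
    return Pretreatment(name=name, window=window, polyorder=polyorder)
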