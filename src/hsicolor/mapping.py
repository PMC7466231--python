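"""Pixel-wise colour prediction maps (unfold → predict → fold).

A reflectance cube is unfolded into a 2-D matrix whose rows are the
spectra of the masked sample pixels and whose columns are the selected
wavelengths; the matrix is multiplied through the reduced PLSR model's
regression coefficients; and the predictions are folded back onto the
spatial plane as a colour-attribute map on a linear scale.  Background
pixels carry NaN (0 is a valid a*/b* value, so a numeric sentinel would
be ambiguous) and are rendered in a distinct colour.

Pre-treatments that need the full spectrum for context (derivatives,
SNV, MSC, area normalisation) are applied to the complete pixel spectra
*before* subsetting to the selected wavelengths, so the transform
semantics match those used at calibration time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cube import ReflectanceCube
from .plsr import PLSRModel, predict
from .preprocess import (PixelMask, Pretreatment, SpectraMatrix,
                         SEGMENTATION_BANDS_NM, SEGMENTATION_THRESHOLD,
                         segment_threshold)
from .selection import IOWSet

__all__ = [
    "UnfoldedPixels",
    "PredictionMap",
    "unfold",
    "predict_pixels",
    "fold_map",
    "predict_map",
    "save_map_png",
]


@dataclass
class UnfoldedPixels:
    """Masked pixel spectra with the row ↔ pixel index mapping retained."""

    matrix: np.ndarray        # n_pixels × n_selected_bands
    flat_indices: np.ndarray  # row-major flat index of each row's pixel
    spatial_shape: tuple


@dataclass
class PredictionMap:
    """2-D predicted colour attribute, NaN off-mask, with render scale."""

    values: np.ndarray
    mask: PixelMask
    attribute: str
    scale: tuple

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        lo, hi = self.scale
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError(f"scale limits must be finite with min < max, got {self.scale}")


def unfold(
    cube: ReflectanceCube,
    mask: PixelMask,
    iow: IOWSet,
    pretreatment: Pretreatment | None = None,
) -> UnfoldedPixels:
    """Unfold masked pixels into an (n_pixels × n_IOW) matrix.

    Rows follow row-major (line, then pixel) order of the masked
    positions.  When a pre-treatment is given it is applied to the full
    125-band pixel spectra first, then columns are subset to the IOW.
    """
    lines, pixels, bands = cube.shape
    if mask.mask.shape != (lines, pixels):
        raise ValueError(
            f"mask shape {mask.mask.shape} does not match cube spatial shape {(lines, pixels)}"
        )
    if mask.count == 0:
        raise ValueError("mask selects no pixels")
    flat = cube.data.reshape(lines * pixels, bands)
    flat_idx = np.flatnonzero(mask.mask.ravel())
    X = flat[flat_idx]
    if pretreatment is not None and pretreatment.name != "raw":
        X = pretreatment.apply(SpectraMatrix(X, cube.grid)).X
    return UnfoldedPixels(
        matrix=X[:, iow.indices],
        flat_indices=flat_idx,
        spatial_shape=(lines, pixels),
    )


def predict_pixels(matrix: np.ndarray, model: PLSRModel) -> np.ndarray:
    """Row-wise prediction: ``matrix @ coefficients + intercept``."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[1] != model.n_bands:
        raise ValueError(
            f"matrix has {matrix.shape[1]} bands but the model expects {model.n_bands}"
        )
    return predict(model, matrix)


def fold_map(
    values: np.ndarray,
    mask: PixelMask,
    spatial_shape: tuple,
    attribute: str,
    scale: tuple | None = None,
) -> PredictionMap:
    """Place predicted values back onto the spatial plane.

    The value order must match the row-major order produced by
    :func:`unfold`; the background is NaN.
    """
    values = np.asarray(values, dtype=float).ravel()
    if mask.mask.shape != tuple(spatial_shape):
        raise ValueError("mask shape does not match the requested spatial shape")
    if values.size != mask.count:
        raise ValueError(
            f"{values.size} values for {mask.count} masked pixels"
        )
    out = np.full(spatial_shape, np.nan)
    out[mask.mask] = values
    if scale is None:
        lo, hi = float(np.min(values)), float(np.max(values))
        if lo == hi:  # constant map still needs a valid render scale
            lo, hi = lo - 0.5, hi + 0.5
        scale = (lo, hi)
    return PredictionMap(values=out, mask=mask, attribute=attribute, scale=scale)


def predict_map(
    cube: ReflectanceCube,
    model: PLSRModel,
    iow: IOWSet,
    attribute: str,
    mask: PixelMask | None = None,
) -> PredictionMap:
    """Segment (attribute-specific band, 0.05 threshold), unfold, predict,
    and fold into a prediction map in one call."""
    if mask is None:
        band = SEGMENTATION_BANDS_NM[attribute]
        mask = segment_threshold(cube, band, SEGMENTATION_THRESHOLD)
    unfolded = unfold(cube, mask, iow, pretreatment=model.pretreatment)
    values = predict_pixels(unfolded.matrix, model)
    return fold_map(values, mask, unfolded.spatial_shape, attribute)


def save_map_png(pmap: PredictionMap, path, cmap: str = "jet", dpi: int = 150):
    """Render the map with a linear colour bar; background in grey."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cm = plt.get_cmap(cmap).copy()
    cm.set_bad("0.35")
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(pmap.values, cmap=cm, vmin=pmap.scale[0], vmax=pmap.scale[1])
    ax.set_title(f"Predicted {pmap.attribute}*")
    ax.set_xlabel("pixel")
    ax.set_ylabel("line")
    fig.colorbar(im, ax=ax, label=f"{pmap.attribute}*")
    fig.savefig(path, dpi=dpi, bbox_inches="tight")
    plt.close(fig)
    return path
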