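"""Important-optimal-wavelength (IOW) selection from PLSR coefficients.

Bands are ranked by the magnitude of the weighted regression
coefficients (BW) irrespective of sign; backward elimination repeatedly
discards the least-important band whenever doing so does not
significantly degrade cross-validated accuracy, refitting (and
re-ranking) after every removal.  "Not significantly degrade" is
operationalised as a relative RMSECV tolerance (default 5 %) against the
best RMSECV seen so far; the component count of each candidate model is
re-optimised by cross-validation so reduced models are not
over-parameterised.

The module also carries the published reduced wavelength sets for the
sausage core-colour application (10 bands for L*, 10 for a*, 7 for b*),
usable directly with the mapping module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import WavelengthGrid
from .plsr import PLSRModel, CVResult, cross_validate, fit_plsr, compute_metrics, ModelMetrics, predict
from .preprocess import SpectraMatrix

__all__ = [
    "IOWSet",
    "PUBLISHED_IOW_NM",
    "rank_by_bw",
    "backward_eliminate",
    "refit_iow",
]

#: Published reduced wavelength sets (nm) per colour attribute, selected
#: on the original 89-image dataset; shipped for map construction and
#: formatting, not as a selection target.
PUBLISHED_IOW_NM = {
    "L": [385, 400, 415, 570, 690, 855, 880, 990, 995, 1000],
    "a": [390, 400, 410, 415, 435, 515, 610, 630, 685, 795],
    "b": [390, 400, 415, 420, 435, 515, 685],
}


@dataclass
class IOWSet:
    """Selected wavelength subset with the elimination audit trail."""

    wavelengths_nm: np.ndarray
    indices: np.ndarray
    source_model: PLSRModel | None = None
    criterion_log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        idx = np.asarray(self.indices, dtype=int)
        if wl.size == 0:
            raise ValueError("IOW set must be non-empty")
        order = np.argsort(wl)
        self.wavelengths_nm = wl[order]
        self.indices = idx[order]

    def __len__(self) -> int:
        return int(self.wavelengths_nm.size)

    def removal_fraction(self, n_bands_full: int) -> float:
        """Fraction of the full grid removed, as a percentage."""
        return 100.0 * (n_bands_full - len(self)) / n_bands_full

    @classmethod
    def from_wavelengths(cls, wavelengths_nm, grid: WavelengthGrid, **kw) -> "IOWSet":
        idx = np.array([grid.index_of(w) for w in wavelengths_nm])
        return cls(wavelengths_nm=grid.values[idx], indices=idx, **kw)


def rank_by_bw(model: PLSRModel) -> np.ndarray:
    """Wavelengths ordered by descending |BW|, ties by ascending nm."""
    if model.grid is None:
        raise ValueError("model carries no wavelength grid")
    wl = model.grid.values
    order = np.lexsort((wl, -np.abs(model.coefficients)))
    return wl[order]


def _cv_best(X: np.ndarray, y: np.ndarray, max_components: int,
             scheme: str, k: int, seed) -> tuple[CVResult, float, int]:
    maxc = min(max_components, X.shape[1], X.shape[0] - 2)
    cv = cross_validate(X, y, maxc, scheme=scheme, k=k, seed=seed)
    a = cv.optimal_n_components
    return cv, cv.rmsecv_at(a), a


def backward_eliminate(
    X,
    y,
    start_model: PLSRModel | None = None,
    tolerance: float = 0.05,
    max_components: int = 10,
    scheme: str = "loo",
    k: int = 5,
    seed: int | None = None,
    min_keep: int = 1,
) -> IOWSet:
    """Backward elimination of wavelengths by |BW| with an RMSECV guard.

    At each step candidates are tried in ascending |BW| order (of the
    current model); the first whose removal keeps RMSECV within
    ``(1 + tolerance) ×`` the best RMSECV observed so far is discarded
    and the model refitted.  The procedure stops when no candidate is
    removable or ``min_keep`` bands remain.  Every trial is recorded in
    the criterion log, making runs replayable under the same CV seed.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    if isinstance(X, SpectraMatrix):
        Xd, grid = X.X, X.grid
    else:
        Xd = np.asarray(X, dtype=float)
        grid = start_model.grid if start_model is not None else None
    if grid is None:
        raise ValueError("a wavelength grid is required (SpectraMatrix or fitted start_model)")
    y = np.asarray(y, dtype=float).ravel()

    keep = list(range(Xd.shape[1]))
    _, best, a = _cv_best(Xd, y, max_components, scheme, k, seed)
    model = fit_plsr(Xd, y, a)
    log: list = []
    step = 0
    while len(keep) > min_keep:
        bw = model.coefficients
        wl = grid.values[keep]
        order = np.lexsort((wl, np.abs(bw)))  # ascending |BW|, ties by nm
        removed = False
        for pos in order:
            cand = keep[:pos] + keep[pos + 1:]
            _, rmsecv, a_c = _cv_best(Xd[:, cand], y, max_components, scheme, k, seed)
            accepted = rmsecv <= (1.0 + tolerance) * best
            log.append({
                "step": step,
                "tried_nm": float(grid.values[keep[pos]]),
                "rmsecv_if_removed": float(rmsecv),
                "best_rmsecv": float(best),
                "n_components": int(a_c),
                "accepted": bool(accepted),
            })
            if accepted:
                keep = cand
                best = min(best, rmsecv)
                model = fit_plsr(Xd[:, keep], y, a_c)
                # reattach the reduced grid for the next BW ranking
                removed = True
                step += 1
                break
        if not removed:
            break

    return IOWSet(
        wavelengths_nm=grid.values[keep],
        indices=np.asarray(keep),
        source_model=start_model,
        criterion_log=log,
    )


def refit_iow(
    X,
    y,
    iow: IOWSet,
    n_components: int,
    split=None,
    scheme: str = "loo",
    k: int = 5,
    seed: int | None = None,
) -> tuple[PLSRModel, ModelMetrics]:
    """Refit a PLSR model restricted to the selected wavelengths.

    Metrics use the same split and CV scheme as the full-spectrum model
    so full-vs-reduced comparisons are like for like.
    """
    if len(iow) == 0:
        raise ValueError("IOW set is empty")
    if n_components > len(iow):
        raise ValueError(
            f"n_components={n_components} exceeds the {len(iow)} selected bands"
        )
    if isinstance(X, SpectraMatrix):
        Xd, grid = X.X, X.grid
    else:
        Xd, grid = np.asarray(X, dtype=float), None
    y = np.asarray(y, dtype=float).ravel()
    Xr = Xd[:, iow.indices]

    if split is not None:
        cal, val = split.calibration_indices, split.validation_indices
    else:
        cal, val = np.arange(Xr.shape[0]), np.array([], dtype=int)

    maxc = min(n_components, len(cal) - 2, Xr.shape[1])
    cv = cross_validate(Xr[cal], y[cal], maxc, scheme=scheme, k=k, seed=seed)
    model = fit_plsr(Xr[cal], y[cal], n_components)
    r2_c, rmsec = compute_metrics(y[cal], predict(model, Xr[cal]))
    r2_p, rmsep = (None, None)
    if val.size >= 2:
        r2_p, rmsep = compute_metrics(y[val], predict(model, Xr[val]))
    metrics = ModelMetrics(
        r2_c=r2_c, rmsec=rmsec, r2_p=r2_p, rmsep=rmsep,
        r2_cv=float(cv.r2cv[min(n_components, maxc) - 1]),
        rmsecv=float(cv.rmsecv[min(n_components, maxc) - 1]),
    )
    return model, metrics
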