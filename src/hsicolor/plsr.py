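"""Partial least squares regression (PLS1, NIPALS) for colour calibration.

The calibration models relate pre-treated reflectance spectra to a single
colour attribute (L*, a* or b*).  Components are extracted by NIPALS with
deflation of both the predictor matrix and the response; X and y are
mean-centred but not variance-scaled, the usual chemometrics convention
for spectra.  The component loadings are folded into a single vector of
weighted regression coefficients (BW) plus an intercept, so prediction is
a plain affine map — and BW doubles as the per-band importance measure
used for wavelength selection.

Model quality is summarised with the chemometrics triple of calibration,
prediction and cross-validation statistics (R²c/RMSEC, R²p/RMSEP,
R²cv/RMSECV); a small |RMSEC − RMSECV| gap indicates a robust model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .grid import WavelengthGrid
from .preprocess import Pretreatment, SpectraMatrix

__all__ = [
    "SplitPlan",
    "PLSRModel",
    "ModelMetrics",
    "CVResult",
    "split_samples",
    "fit_plsr",
    "predict",
    "cross_validate",
    "compute_metrics",
    "grade_model",
    "evaluate_model",
]

_NIPALS_TOL = 1e-12
_NIPALS_MAX_ITER = 500
#: a component count is "optimal" if its RMSECV is within this relative
#: margin of the global minimum (smallest such count wins)
CV_OPTIMAL_TOLERANCE = 0.02


@dataclass(frozen=True)
class SplitPlan:
    """Disjoint calibration/validation index sets covering all samples."""

    calibration_indices: np.ndarray
    validation_indices: np.ndarray
    fraction: float
    seed: int | None

    def __post_init__(self) -> None:
        cal = np.asarray(self.calibration_indices, dtype=int)
        val = np.asarray(self.validation_indices, dtype=int)
        if np.intersect1d(cal, val).size:
            raise ValueError("calibration and validation sets overlap")
        object.__setattr__(self, "calibration_indices", cal)
        object.__setattr__(self, "validation_indices", val)


def split_samples(n: int, fraction: float = 2.0 / 3.0, seed: int | None = None) -> SplitPlan:
    """Random calibration/validation split.

    The calibration set takes ``round(n * fraction)`` samples drawn
    uniformly without replacement (e.g. 89 samples at 2/3 → 59 + 30).
    """
    if n < 3:
        raise ValueError(f"need at least 3 samples to split, got {n}")
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must lie in (0, 1), got {fraction}")
    n_cal = int(np.rint(n * fraction))
    n_cal = min(max(n_cal, 1), n - 1)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return SplitPlan(
        calibration_indices=np.sort(perm[:n_cal]),
        validation_indices=np.sort(perm[n_cal:]),
        fraction=fraction,
        seed=seed,
    )


@dataclass
class PLSRModel:
    """Fitted PLS1 model.

    ``coefficients`` is the BW vector on the (pre-treated, uncentred)
    spectra scale: prediction is ``X @ coefficients + intercept``.
    """

    n_components: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray      # W, bands × components
    x_loadings: np.ndarray   # P, bands × components
    y_loadings: np.ndarray   # q, components
    coefficients: np.ndarray  # BW, per band
    intercept: float
    grid: WavelengthGrid | None = None
    pretreatment: Pretreatment | None = None
    fitted_values: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_bands(self) -> int:
        return self.coefficients.shape[0]

    def to_json(self, path=None) -> str:
        payload = {
            "n_components": self.n_components,
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean,
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "coefficients": self.coefficients.tolist(),
            "intercept": self.intercept,
            "wavelength_nm": None if self.grid is None else self.grid.values.tolist(),
            "pretreatment": None if self.pretreatment is None else self.pretreatment.to_dict(),
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "PLSRModel":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            payload = json.loads(Path(source).read_text())
        return cls(
            n_components=payload["n_components"],
            x_mean=np.asarray(payload["x_mean"]),
            y_mean=payload["y_mean"],
            weights=np.asarray(payload["weights"]),
            x_loadings=np.asarray(payload["x_loadings"]),
            y_loadings=np.asarray(payload["y_loadings"]),
            coefficients=np.asarray(payload["coefficients"]),
            intercept=payload["intercept"],
            grid=None if payload.get("wavelength_nm") is None
            else WavelengthGrid(np.asarray(payload["wavelength_nm"])),
            pretreatment=None if payload.get("pretreatment") is None
            else Pretreatment.from_dict(payload["pretreatment"]),
        )


def _as_matrix(X) -> tuple[np.ndarray, WavelengthGrid | None]:
    if isinstance(X, SpectraMatrix):
        return X.X, X.grid
    return np.asarray(X, dtype=float), None


def nipals_pls1(Xc: np.ndarray, yc: np.ndarray, n_components: int):
    """NIPALS decomposition of centred data.

    Per component: weight ``w ∝ Xᵀy`` (unit norm), score ``t = Xw``,
    loadings ``p = Xᵀt/tᵀt`` and ``q = yᵀt/tᵀt``, then deflation of X
    and y by the rank-one reconstructions.  For a single response the
    weight step is closed-form; the power iteration is retained so the
    implementation matches the general algorithm and its convergence
    criterion (1e-12 or 500 iterations).
    """
    X = Xc.copy()
    y = yc.copy().astype(float)
    n, p = X.shape
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    q = np.zeros(n_components)
    for a in range(n_components):
        w = X.T @ y
        norm = np.linalg.norm(w)
        if norm == 0:
            raise ValueError(
                f"NIPALS: residual covariance vanished at component {a + 1}; "
                f"reduce n_components"
            )
        w /= norm
        for _ in range(_NIPALS_MAX_ITER):
            t = X @ w
            tt = t @ t
            if tt == 0:
                raise ValueError(f"NIPALS: zero score variance at component {a + 1}")
            w_new = X.T @ y
            w_new /= np.linalg.norm(w_new)
            if np.linalg.norm(w_new - w) < _NIPALS_TOL:
                w = w_new
                break
            w = w_new
        t = X @ w
        tt = t @ t
        p_a = X.T @ t / tt
        q_a = y @ t / tt
        X = X - np.outer(t, p_a)
        y = y - t * q_a
        W[:, a], P[:, a], T[:, a], q[a] = w, p_a, t, q_a
    return W, P, T, q


def fit_plsr(X, y, n_components: int, pretreatment: Pretreatment | None = None) -> PLSRModel:
    """Fit a PLS1 model on (already pre-treated) spectra.

    ``X`` may be a :class:`SpectraMatrix` or a plain array; ``y`` is the
    colour attribute.  ``pretreatment`` is stored on the model purely as
    provenance so pixel-wise prediction can replay the same chain.
    """
    Xd, grid = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    n, p = Xd.shape
    if y.shape[0] != n:
        raise ValueError(f"X has {n} rows but y has {y.shape[0]}")
    if np.ptp(y) == 0:
        raise ValueError("response has zero variance")
    max_comp = min(n - 1, p)
    if not 1 <= n_components <= max_comp:
        raise ValueError(
            f"n_components must lie in [1, min(n-1, n_bands)] = [1, {max_comp}], "
            f"got {n_components}"
        )
    x_mean = Xd.mean(axis=0)
    y_mean = float(y.mean())
    W, P, T, q = nipals_pls1(Xd - x_mean, y - y_mean, n_components)
    # BW: fold the component pipeline into one coefficient vector
    coef = W @ np.linalg.solve(P.T @ W, q)
    intercept = y_mean - float(x_mean @ coef)
    model = PLSRModel(
        n_components=n_components,
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        coefficients=coef,
        intercept=intercept,
        grid=grid,
        pretreatment=pretreatment,
    )
    model.fitted_values = predict(model, Xd)
    return model


def predict(model: PLSRModel, X) -> np.ndarray:
    """Predict the colour attribute: ``X @ BW + intercept``."""
    Xd, _ = _as_matrix(X)
    if Xd.ndim == 1:
        Xd = Xd[None, :]
    if Xd.shape[1] != model.n_bands:
        raise ValueError(
            f"X has {Xd.shape[1]} bands but the model expects {model.n_bands}"
        )
    return Xd @ model.coefficients + model.intercept


def compute_metrics(y_true, y_pred) -> tuple[float, float]:
    """(R², RMSE) for a set of predictions.

    R² is 1 − SS_res/SS_tot; RMSE is the root mean squared error in the
    units of the response (colour units here).
    """
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred lengths differ")
    if y_true.size < 2:
        raise ValueError("need at least 2 observations")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("y_true has zero variance; R² undefined")
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    rmse = float(np.sqrt(np.mean((y_true - y_pred) ** 2)))
    return r2, rmse


@dataclass
class CVResult:
    """Cross-validation curve over component counts 1..max."""

    rmsecv: np.ndarray
    r2cv: np.ndarray
    optimal_n_components: int
    scheme: str

    def rmsecv_at(self, n_components: int) -> float:
        return float(self.rmsecv[n_components - 1])


def cross_validate(
    X,
    y,
    max_components: int,
    scheme: str = "loo",
    k: int = 5,
    seed: int | None = None,
    pretreatment: Pretreatment | None = None,
) -> CVResult:
    """Cross-validated RMSECV/R²cv per component count.

    Every fold refits from scratch, including the pre-treatment: when a
    ``pretreatment`` is given, ``X`` must be *untreated* spectra and the
    chain (e.g. the MSC reference) is fitted within each training fold
    before being applied to the held-out rows.

    The optimal component count is the smallest one whose RMSECV lies
    within 2 % of the global minimum — parsimony before marginal gains.
    """
    Xd, grid = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    n = Xd.shape[0]
    if scheme == "loo":
        folds = [np.array([i]) for i in range(n)]
    elif scheme == "kfold":
        if k > n:
            raise ValueError(f"k={k} folds exceed sample count {n}")
        if k < 2:
            raise ValueError("k must be >= 2")
        rng = np.random.default_rng(seed)
        folds = np.array_split(rng.permutation(n), k)
    else:
        raise ValueError(f"unknown CV scheme {scheme!r}; use 'loo' or 'kfold'")
    max_fold = max(len(f) for f in folds)
    limit = min(n - max_fold - 1, Xd.shape[1])
    if max_components > limit:
        raise ValueError(
            f"max_components={max_components} too large for CV "
            f"(limit {limit} given fold sizes)"
        )

    preds = np.zeros((n, max_components))
    for test_idx in folds:
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        Xtr, Xte = Xd[train_idx], Xd[test_idx]
        if pretreatment is not None:
            if grid is None:
                raise ValueError("pretreatment in CV requires a SpectraMatrix input")
            pt = Pretreatment(name=pretreatment.name, window=pretreatment.window,
                              polyorder=pretreatment.polyorder)
            tr = pt.fit_apply(SpectraMatrix(Xtr, grid))
            te = pt.apply(SpectraMatrix(Xte, grid))
            Xtr, Xte = tr.X, te.X
        for a in range(1, max_components + 1):
            model = fit_plsr(Xtr, y[train_idx], a)
            preds[test_idx, a - 1] = predict(model, Xte)

    rmsecv = np.sqrt(np.mean((preds - y[:, None]) ** 2, axis=0))
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2cv = 1.0 - np.sum((preds - y[:, None]) ** 2, axis=0) / ss_tot
    best = float(rmsecv.min())
    optimal = int(np.flatnonzero(rmsecv <= (1.0 + CV_OPTIMAL_TOLERANCE) * best)[0]) + 1
    return CVResult(rmsecv=rmsecv, r2cv=r2cv, optimal_n_components=optimal, scheme=scheme)


@dataclass
class ModelMetrics:
    """Calibration / prediction / cross-validation summary for one model."""

    r2_c: float
    rmsec: float
    r2_p: float | None
    rmsep: float | None
    r2_cv: float | None
    rmsecv: float | None

    def __post_init__(self) -> None:
        for name in ("rmsec", "rmsep", "rmsecv"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def rmse_gap(self) -> float | None:
        """|RMSEC − RMSECV|: small values indicate a robust model."""
        if self.rmsecv is None:
            return None
        return abs(self.rmsec - self.rmsecv)


def grade_model(r2: float) -> str:
    """Qualitative prediction-quality band for an R² value.

    Below 0.66 the model is insufficient for quantitative use; 0.66–0.81
    supports approximate quantitative prediction; above 0.81 up to 0.90
    is good; above 0.90 is excellent.
    """
    if r2 > 1:
        raise ValueError(f"R² cannot exceed 1, got {r2}")
    if r2 < 0.66:
        return "insufficient"
    if r2 <= 0.81:
        return "acceptable"
    if r2 <= 0.90:
        return "good"
    return "excellent"


def evaluate_model(
    X,
    y,
    n_components: int | None = None,
    max_components: int = 10,
    split: SplitPlan | None = None,
    scheme: str = "loo",
    k: int = 5,
    seed: int | None = None,
    pretreatment: Pretreatment | None = None,
) -> tuple[PLSRModel, ModelMetrics]:
    """Split, cross-validate, fit, and summarise one calibration model.

    Convenience wrapper: splits samples 2/3–1/3 (unless a plan is given),
    picks the component count by cross-validation on the calibration set
    when not fixed, and reports the full metrics set.
    """
    Xd, grid = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    if split is None:
        split = split_samples(Xd.shape[0], seed=seed)
    cal, val = split.calibration_indices, split.validation_indices

    Xcal_raw = Xd[cal]
    max_components = min(max_components, len(cal) - (2 if scheme == "loo" else len(cal) // k + 1),
                         Xd.shape[1])
    cv_input = SpectraMatrix(Xcal_raw, grid) if (pretreatment is not None and grid is not None) else Xcal_raw
    cv = cross_validate(cv_input, y[cal], max_components, scheme=scheme, k=k,
                        seed=seed, pretreatment=pretreatment)
    a = n_components or cv.optimal_n_components

    if pretreatment is not None and grid is not None:
        pt = Pretreatment(name=pretreatment.name, window=pretreatment.window,
                          polyorder=pretreatment.polyorder)
        Xcal = pt.fit_apply(SpectraMatrix(Xcal_raw, grid)).X
        Xval = pt.apply(SpectraMatrix(Xd[val], grid)).X
    else:
        pt = pretreatment
        Xcal, Xval = Xcal_raw, Xd[val]

    model = fit_plsr(SpectraMatrix(Xcal, grid) if grid is not None else Xcal,
                     y[cal], a, pretreatment=pt)
    r2_c, rmsec = compute_metrics(y[cal], predict(model, Xcal))
    r2_p, rmsep = (None, None)
    if len(val) >= 2:
        r2_p, rmsep = compute_metrics(y[val], predict(model, Xval))
    metrics = ModelMetrics(
        r2_c=r2_c, rmsec=rmsec, r2_p=r2_p, rmsep=rmsep,
        r2_cv=float(cv.r2cv[a - 1]), rmsecv=float(cv.rmsecv[a - 1]),
    )
    return model, metrics
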