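"""Canonical discriminant analysis and one-way ANOVA group comparison.

Casing treatments are compared on the measured CIELAB triplets.  CDA
solves the generalized eigenproblem of the between-groups scatter
against the within-groups scatter, ``S_B v = λ S_W v``, yielding
``min(g − 1, p)`` canonical functions.  Per function the usual SPSS-style
statistics are reported:

* eigenvalue λ and its share of the summed eigenvalues ("variance %"),
* canonical correlation ``sqrt(λ / (1 + λ))``,
* Wilks' lambda of the function sequence k.., ``Λ_k = Π_{i≥k} 1/(1+λ_i)``,
  with Bartlett's chi-square significance test,
* standardized canonical coefficients (raw coefficients scaled by the
  pooled within-group standard deviations), and
* a nearest-centroid classification in canonical score space with its
  confusion matrix and correct-classification rate.

One-way ANOVA with Tukey HSD pairwise comparisons produces the familiar
compact letter display: groups sharing a letter are not significantly
different at the chosen alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "CDAResult",
    "GroupSummary",
    "fit_cda",
    "wilks_lambda",
    "canonical_correlation",
    "evaluate_functions",
    "classify",
    "anova_letters",
    "summarize_groups",
]


def wilks_lambda(eigenvalues, k: int = 1) -> float:
    """Wilks' Λ for the canonical-function sequence starting at ``k``.

    ``Λ_k = Π_{i≥k} 1/(1 + λ_i)`` (1-based ``k``); small values indicate
    strong residual discrimination in functions k and beyond.
    """
    eigenvalues = np.asarray(eigenvalues, dtype=float)
    if np.any(eigenvalues < 0):
        raise ValueError("eigenvalues must be >= 0")
    if not 1 <= k <= eigenvalues.size:
        raise ValueError(f"k must lie in [1, {eigenvalues.size}], got {k}")
    return float(np.prod(1.0 / (1.0 + eigenvalues[k - 1:])))


def canonical_correlation(eigenvalue: float) -> float:
    """Canonical correlation ``sqrt(λ / (1 + λ))`` of one function."""
    if eigenvalue < 0:
        raise ValueError(f"eigenvalue must be >= 0, got {eigenvalue}")
    return float(np.sqrt(eigenvalue / (1.0 + eigenvalue)))


@dataclass
class CDAResult:
    """Fitted canonical discriminant analysis."""

    eigenvalues: np.ndarray
    coefficients: np.ndarray        # standardized, variables × functions
    raw_coefficients: np.ndarray    # variables × functions
    variance_pct: np.ndarray
    canonical_correlations: np.ndarray
    wilks: np.ndarray               # Λ_k for k = 1..m
    p_values: np.ndarray
    chi_square: np.ndarray
    group_names: list
    group_centroids: np.ndarray     # groups × functions
    grand_mean: np.ndarray
    within_sd: np.ndarray           # pooled within-group SDs per variable
    variable_names: list
    classification: pd.DataFrame = field(repr=False, default=None)
    correct_rate_pct: float = float("nan")
    scores: np.ndarray = field(repr=False, default=None)

    @property
    def n_functions(self) -> int:
        return int(self.eigenvalues.size)


def _scatter_matrices(X: np.ndarray, labels: np.ndarray):
    groups = list(dict.fromkeys(labels.tolist()))
    grand = X.mean(axis=0)
    p = X.shape[1]
    Sw = np.zeros((p, p))
    Sb = np.zeros((p, p))
    for g in groups:
        Xg = X[labels == g]
        mg = Xg.mean(axis=0)
        dev = Xg - mg
        Sw += dev.T @ dev
        dm = (mg - grand)[:, None]
        Sb += len(Xg) * (dm @ dm.T)
    return Sw, Sb, groups, grand


def fit_cda(features, groups, variable_names=("L", "a", "b")) -> CDAResult:
    """Fit a canonical discriminant analysis of features by group.

    ``features`` is an (n × p) array (colour triplets here); ``groups``
    the per-row labels.  Requires at least two groups of at least two
    observations each and an invertible within-group scatter matrix.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D array")
    labels = np.asarray(list(groups))
    if labels.shape[0] != X.shape[0]:
        raise ValueError("one group label is required per feature row")
    names, counts = np.unique(labels, return_counts=True)
    if names.size < 2:
        raise ValueError("need at least 2 groups")
    if np.any(counts < 2):
        small = names[counts < 2].tolist()
        raise ValueError(f"each group needs >= 2 observations; too small: {small}")

    n, p = X.shape
    g = names.size
    Sw, Sb, group_order, grand = _scatter_matrices(X, labels)
    if np.linalg.matrix_rank(Sw) < p:
        raise ValueError(
            "within-group scatter matrix is singular; remove collinear or "
            "constant variables before fitting"
        )

    # generalized symmetric-definite eigenproblem Sb v = λ Sw v
    eigvals, eigvecs = linalg.eigh(Sb, Sw)
    order = np.argsort(eigvals)[::-1]
    m = min(g - 1, p)
    lam = np.clip(eigvals[order[:m]], 0.0, None)
    V = eigvecs[:, order[:m]]  # normalized so Vᵀ Sw V = I

    # SPSS convention: raw coefficients give unit pooled within-group
    # variance of the scores → scale by sqrt(n - g)
    raw = V * np.sqrt(n - g)
    within_sd = np.sqrt(np.diag(Sw) / (n - g))
    standardized = raw * within_sd[:, None]
    # deterministic sign: largest-|loading| coefficient positive
    for j in range(m):
        i = int(np.argmax(np.abs(standardized[:, j])))
        if standardized[i, j] < 0:
            standardized[:, j] *= -1
            raw[:, j] *= -1

    total = lam.sum()
    variance_pct = 100.0 * lam / total if total > 0 else np.full(m, 100.0 / m)
    can_corr = np.array([canonical_correlation(v) for v in lam])
    wilks = np.array([wilks_lambda(lam, k) for k in range(1, m + 1)])
    # Bartlett's chi-square approximation for Λ_k
    chi = np.empty(m)
    pvals = np.empty(m)
    for k in range(1, m + 1):
        factor = n - 1 - (p + g) / 2.0
        chi[k - 1] = -factor * np.log(wilks[k - 1])
        df = (p - k + 1) * (g - k)
        pvals[k - 1] = stats.chi2.sf(chi[k - 1], df) if df > 0 else np.nan

    scores = (X - grand) @ raw
    centroids = np.vstack([scores[labels == gname].mean(axis=0) for gname in group_order])

    result = CDAResult(
        eigenvalues=lam,
        coefficients=standardized,
        raw_coefficients=raw,
        variance_pct=variance_pct,
        canonical_correlations=can_corr,
        wilks=wilks,
        p_values=pvals,
        chi_square=chi,
        group_names=list(group_order),
        group_centroids=centroids,
        grand_mean=grand,
        within_sd=within_sd,
        variable_names=list(variable_names)[:p],
        scores=scores,
    )
    predicted, rate, confusion = classify(result, X, true_labels=labels)
    result.classification = confusion
    result.correct_rate_pct = rate
    return result


def evaluate_functions(coefficients, triplet, standardization=None) -> float | np.ndarray:
    """Score canonical functions on one observation.

    ``coefficients`` may be one function's coefficient vector or a
    (variables × functions) matrix.  With ``standardization`` (pooled
    within-group SDs), variables are divided by their SD first — the
    convention under which *standardized* coefficients apply.
    """
    coeffs = np.asarray(coefficients, dtype=float)
    x = np.asarray(triplet, dtype=float)
    nvar = coeffs.shape[0]
    if x.shape[0] != nvar:
        raise ValueError(f"{nvar} coefficients but {x.shape[0]} variables")
    if standardization is not None:
        sds = np.asarray(standardization, dtype=float)
        if np.any(sds <= 0):
            raise ValueError("standardization SDs must be positive")
        x = x / sds
    out = x @ coeffs
    return float(out) if np.ndim(out) == 0 else out


def classify(result: CDAResult, features, true_labels=None):
    """Nearest-centroid assignment in canonical score space.

    Returns ``(labels, correct_rate_pct, confusion)``; the rate and
    confusion matrix are computed against ``true_labels`` when given
    (rate is NaN otherwise).
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != result.grand_mean.shape[0]:
        raise ValueError(
            f"features have {X.shape[1]} variables, model expects {result.grand_mean.shape[0]}"
        )
    scores = (X - result.grand_mean) @ result.raw_coefficients
    d2 = ((scores[:, None, :] - result.group_centroids[None, :, :]) ** 2).sum(axis=2)
    assigned = np.asarray(result.group_names, dtype=object)[np.argmin(d2, axis=1)]
    rate = float("nan")
    confusion = None
    if true_labels is not None:
        true = np.asarray(list(true_labels))
        rate = 100.0 * float(np.mean(assigned == true))
        confusion = pd.crosstab(
            pd.Series(true, name="actual"), pd.Series(assigned, name="predicted")
        ).reindex(index=result.group_names, columns=result.group_names, fill_value=0)
    return assigned, rate, confusion


def _letter_display(names, means, different: dict) -> dict:
    """Compact letter display: groups sharing a letter are not
    significantly different.  Greedy sweep over groups in descending
    mean order; adequate for the small group counts used here."""
    order = [names[i] for i in np.argsort(means)[::-1]]
    letter_groups: list[set] = []
    for g in order:
        placed = False
        for s in letter_groups:
            if all(not different.get(frozenset((g, other)), False) for other in s):
                s.add(g)
                placed = True
        if not placed:
            letter_groups.append({g})
    # absorb letter sets fully contained in another
    letter_groups = [s for i, s in enumerate(letter_groups)
                     if not any(s < t for j, t in enumerate(letter_groups) if j != i)]
    letters = {g: "" for g in names}
    for idx, s in enumerate(letter_groups):
        ch = chr(ord("a") + idx)
        for g in order:
            if g in s:
                letters[g] += ch
    return letters


@dataclass
class GroupSummary:
    """Mean ± SD per group for one variable, with significance letters."""

    group_names: list
    means: np.ndarray
    sds: np.ndarray
    letters: dict
    f_statistic: float
    p_value: float
    alpha: float


def anova_letters(values_per_group: dict, alpha: float = 0.05) -> GroupSummary:
    """One-way ANOVA with Tukey-HSD letters for one variable.

    ``values_per_group`` maps group name → 1-D array of observations.
    If the omnibus F-test is not significant at ``alpha``, all groups
    share the letter "a"; otherwise Tukey HSD pairwise tests are
    compressed into a compact letter display.
    """
    names = list(values_per_group)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(values_per_group[g], dtype=float) for g in names]
    for g, arr in zip(names, arrays):
        if arr.size < 2:
            raise ValueError(f"group {g!r} needs at least 2 values")
    means = np.array([a.mean() for a in arrays])
    sds = np.array([a.std(ddof=1) for a in arrays])
    f_stat, p_val = stats.f_oneway(*arrays)

    different: dict = {}
    if p_val < alpha:
        flat = np.concatenate(arrays)
        labels = np.concatenate([[g] * len(a) for g, a in zip(names, arrays)])
        tukey = pairwise_tukeyhsd(flat, labels, alpha=alpha)
        for (g1, g2), reject in zip(
            ((tukey.groupsunique[i], tukey.groupsunique[j])
             for i in range(len(tukey.groupsunique))
             for j in range(i + 1, len(tukey.groupsunique))),
            tukey.reject,
        ):
            different[frozenset((g1, g2))] = bool(reject)
    letters = _letter_display(names, means, different)
    return GroupSummary(
        group_names=names, means=means, sds=sds, letters=letters,
        f_statistic=float(f_stat), p_value=float(p_val), alpha=alpha,
    )


def summarize_groups(colours, groups, alpha: float = 0.05) -> pd.DataFrame:
    """Mean ± SD with significance letters per colour channel — the
    familiar left half of a treatment-comparison table."""
    colours = np.asarray(colours, dtype=float)
    labels = np.asarray(list(groups))
    names = list(dict.fromkeys(labels.tolist()))
    rows = {}
    for ci, ch in enumerate(("L", "a", "b")):
        summary = anova_letters(
            {g: colours[labels == g, ci] for g in names}, alpha=alpha
        )
        for g, m, s in zip(summary.group_names, summary.means, summary.sds):
            rows.setdefault(g, {})[ch] = f"{m:.2f} ± {s:.2f} {summary.letters[g]}"
    return pd.DataFrame(rows).T.loc[names]
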