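"""Orthogonal PLS discriminant analysis with cross-validated diagnostics.

OPLS-DA splits predictor variation into one class-predictive component
(scores t[1], loadings p[1]) and a chosen number of class-orthogonal
components (t0), for a two-class contrast coded as a single 0/1 response.
The fit is the deterministic single-y NIPALS/O-PLS sequence: the predictive
weight vector is initialized from the response, orthogonal components are
peeled off the predictor matrix one at a time, and no step involves random
initialization, so refitting the same matrix reproduces the same model
bit for bit (up to the fixed sign convention: the second-listed class has
positive mean predictive score).

Model quality is reported as R²Y(cum) (fraction of class variance explained
on the training fit), Q²(cum) (1 − PRESS/SSY under k-fold cross-validation,
default 7-fold with deterministic, class-stratified fold assignment), and a
CV-ANOVA p-value (F-test of the cross-validated predictive residuals
against the total class variation, with degrees of freedom total = N − 1,
regression = number of fitted components, residual = the difference).
"""

from __future__ import annotations

import sys
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tables import FeatureTable, TableError


@dataclass(frozen=True)
class ClassDesign:
    """Two-class contrast: sample → class label.

    ``classes`` is ordered (negative, positive); the positive (second) class
    defines the positive direction of the predictive axis.
    """

    labels: Mapping[str, str]
    classes: tuple[str, str]
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.classes) != 2 or self.classes[0] == self.classes[1]:
            raise TableError("a class design needs exactly two distinct classes")
        extra = set(self.labels.values()) - set(self.classes)
        if extra:
            raise TableError(f"labels outside the declared classes: {sorted(extra)}")
        for cls in self.classes:
            n = sum(1 for v in self.labels.values() if v == cls)
            if n < 2:
                raise TableError(f"class {cls!r} has fewer than 2 samples")

    def y(self, sample_ids: Sequence[str]) -> np.ndarray:
        """0/1 response vector for the given samples."""
        missing = [s for s in sample_ids if s not in self.labels]
        if missing:
            raise TableError(f"samples without a class label: {missing[:5]}")
        return np.array(
            [1.0 if self.labels[s] == self.classes[1] else 0.0 for s in sample_ids]
        )

    @staticmethod
    def from_meta(
        meta: pd.DataFrame, contrast: tuple[str, str], column: str = "diet"
    ) -> "ClassDesign":
        """Build a design from sample metadata, e.g. contrast=('baseline','HRS')."""
        subset = meta[meta[column].isin(contrast)]
        labels = dict(zip(subset["sample_id"], subset[column]))
        return ClassDesign(labels, tuple(contrast), name=f"{contrast[0]} versus {contrast[1]}")


def uv_scale(
    matrix: pd.DataFrame,
) -> tuple[pd.DataFrame, tuple[pd.Series, pd.Series]]:
    """Unit-variance scale: per feature, subtract the mean and divide by the
    sample (n−1) standard deviation.

    Zero-variance features are dropped with a warning rather than failing.
    """
    means = matrix.mean(axis=0)
    sds = matrix.std(axis=0, ddof=1)
    zero = sds[sds == 0].index
    if len(zero):
        warnings.warn(
            f"dropping {len(zero)} zero-variance feature(s) before UV scaling",
            stacklevel=2,
        )
        matrix = matrix.drop(columns=list(zero))
        means = means.drop(list(zero))
        sds = sds.drop(list(zero))
    scaled = (matrix - means) / sds
    return scaled, (means, sds)


@dataclass
class OplsModel:
    """A fitted two-class OPLS-DA model."""

    design: ClassDesign
    feature_ids: list[str]
    sample_ids: list[str]
    scaling: str  # "uv" | "none"
    n_orthogonal: int
    # fitted quantities
    weights: np.ndarray  # w, predictive weight vector
    scores: np.ndarray  # t[1]
    loadings: np.ndarray  # p[1]
    c: float  # regression of y on t
    ortho_weights: np.ndarray  # (n_orthogonal, p)
    ortho_scores: np.ndarray  # t0, (n, n_orthogonal)
    ortho_loadings: np.ndarray  # (n_orthogonal, p)
    x_means: np.ndarray
    x_sds: np.ndarray
    y_mean: float
    r2y_cum: float
    q2_cum: float | None = None
    cv_anova_p: float | None = None

    def transform(self, matrix: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """Predictive and orthogonal scores for new samples."""
        X = matrix.loc[:, self.feature_ids].to_numpy(dtype=float)
        X = (X - self.x_means) / self.x_sds
        T0 = np.zeros((X.shape[0], self.n_orthogonal))
        for i in range(self.n_orthogonal):
            t0 = X @ self.ortho_weights[i]
            X = X - np.outer(t0, self.ortho_loadings[i])
            T0[:, i] = t0
        return X @ self.weights, T0

    def predict(self, matrix: pd.DataFrame) -> np.ndarray:
        """Continuous class prediction (0/1 scale)."""
        t, _ = self.transform(matrix)
        return self.c * t + self.y_mean

    def feature_score_correlation(self, matrix: pd.DataFrame) -> pd.Series:
        """Pearson correlation of each (scaled) feature with t[1]."""
        X = matrix.loc[:, self.feature_ids].to_numpy(dtype=float)
        X = (X - self.x_means) / self.x_sds
        t = self.scores - self.scores.mean()
        Xc = X - X.mean(axis=0)
        denom = np.sqrt((t**2).sum() * (Xc**2).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (Xc * t[:, None]).sum(axis=0) / denom
        return pd.Series(r, index=self.feature_ids)


_NIPALS_TOL = 1e-10
_NIPALS_MAX_ITER = 500


def _pls1_weight(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Predictive weight vector by NIPALS, initialized from the response.

    For a single-column response the NIPALS loop converges immediately, but
    the iteration is kept for numerical fidelity.
    """
    u = y.copy()
    w = X.T @ u / (u @ u)
    norm = np.linalg.norm(w)
    if norm == 0:
        raise TableError("response is orthogonal to every feature")
    w = w / norm
    for _ in range(_NIPALS_MAX_ITER):
        t = X @ w
        c = y @ t / (t @ t)
        u_new = y * c / (c * c) if c != 0 else y.copy()
        w_new = X.T @ u_new / (u_new @ u_new)
        w_new /= np.linalg.norm(w_new)
        if np.linalg.norm(w_new - w) < _NIPALS_TOL:
            w = w_new
            break
        w = w_new
    return w


def fit_opls_da(
    matrix: pd.DataFrame,
    design: ClassDesign,
    n_orthogonal: int | str = 0,
    scaling: str = "uv",
    folds: int = 7,
) -> OplsModel:
    """Fit a two-class OPLS-DA model.

    ``n_orthogonal='auto'`` keeps adding orthogonal components while the
    7-fold Q² improves by more than 0.01 (a standard stopping rule).  With
    ``n_orthogonal=0`` the model reduces to a plain two-class PLS-DA with a
    single component.
    """
    sample_ids = [s for s in matrix.index if s in design.labels]
    if len(sample_ids) < 4:
        raise TableError("OPLS-DA needs at least 4 labelled samples")
    matrix = matrix.loc[sample_ids]
    folds = min(folds, len(sample_ids))  # fall back to leave-one-out

    if n_orthogonal == "auto":
        best_n, best_q2 = 0, q2_cv(matrix, design, 0, folds=folds, scaling=scaling)
        max_n = min(len(sample_ids) - 3, 10)
        for n in range(1, max_n + 1):
            try:
                q2 = q2_cv(matrix, design, n, folds=folds, scaling=scaling)
            except TableError:
                break
            if q2 > best_q2 + 0.01:
                best_n, best_q2 = n, q2
            else:
                break
        n_orthogonal = best_n

    model = _fit_raw(matrix, design, int(n_orthogonal), scaling)
    model.q2_cum = q2_cv(matrix, design, int(n_orthogonal), folds=folds, scaling=scaling)
    model.cv_anova_p = cv_anova(matrix, design, int(n_orthogonal), folds=folds, scaling=scaling)
    return model


def _fit_raw(
    matrix: pd.DataFrame,
    design: ClassDesign,
    n_orthogonal: int,
    scaling: str,
) -> OplsModel:
    if scaling not in ("uv", "none"):
        raise TableError(f"unknown scaling {scaling!r}")
    sample_ids = list(matrix.index)
    y_raw = design.y(sample_ids)

    if scaling == "uv":
        scaled, (means, sds) = uv_scale(matrix)
    else:
        means = matrix.mean(axis=0)
        sds = pd.Series(1.0, index=matrix.columns)
        scaled = matrix - means
    feature_ids = list(scaled.columns)
    X = scaled.to_numpy(dtype=float)
    rank = min(X.shape)
    if n_orthogonal >= rank:
        raise TableError(
            f"n_orthogonal={n_orthogonal} must be below the matrix rank bound {rank}"
        )
    y_mean = y_raw.mean()
    y = y_raw - y_mean
    ssy = float(y @ y)

    w = _pls1_weight(X, y)
    W0, T0, P0 = [], [], []
    for _ in range(n_orthogonal):
        t = X @ w
        p = X.T @ t / (t @ t)
        w0 = p - (w @ p) * w
        norm = np.linalg.norm(w0)
        if norm < 1e-12:
            break  # no orthogonal variation left
        w0 = w0 / norm
        t0 = X @ w0
        p0 = X.T @ t0 / (t0 @ t0)
        X = X - np.outer(t0, p0)
        W0.append(w0)
        T0.append(t0)
        P0.append(p0)

    t = X @ w
    p = X.T @ t / (t @ t)
    c = float(y @ t / (t @ t))

    # sign convention: positive class has positive mean predictive score
    pos = y_raw == 1.0
    if t[pos].mean() < t[~pos].mean():
        w, t, p, c = -w, -t, -p, -c

    resid = y - c * t
    r2y = 1.0 - float(resid @ resid) / ssy

    n_o = len(W0)
    return OplsModel(
        design=design,
        feature_ids=feature_ids,
        sample_ids=sample_ids,
        scaling=scaling,
        n_orthogonal=n_o,
        weights=w,
        scores=t,
        loadings=p,
        c=c,
        ortho_weights=np.array(W0) if n_o else np.zeros((0, len(feature_ids))),
        ortho_scores=np.array(T0).T if n_o else np.zeros((len(sample_ids), 0)),
        ortho_loadings=np.array(P0) if n_o else np.zeros((0, len(feature_ids))),
        x_means=means.to_numpy(dtype=float),
        x_sds=sds.to_numpy(dtype=float),
        y_mean=float(y_mean),
        r2y_cum=float(r2y),
    )


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


def cv_folds(
    sample_ids: Sequence[str], design: ClassDesign, folds: int
) -> list[list[str]]:
    """Deterministic, class-stratified fold assignment.

    Samples are sorted by ID within each class and dealt round-robin, so the
    assignment is reproducible across runs and platforms.
    """
    if folds < 2:
        raise TableError("folds must be >= 2")
    if folds > len(sample_ids):
        raise TableError(f"folds={folds} exceeds the {len(sample_ids)} samples")
    assignment: list[list[str]] = [[] for _ in range(folds)]
    counter = 0
    for cls in design.classes:
        members = sorted(s for s in sample_ids if design.labels[s] == cls)
        for s in members:
            assignment[counter % folds].append(s)
            counter += 1
    return [fold for fold in assignment if fold]


def _cv_residuals(
    matrix: pd.DataFrame,
    design: ClassDesign,
    n_orthogonal: int,
    folds: int,
    scaling: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Out-of-fold predictions for every sample: returns (y, y_hat_cv)."""
    sample_ids = [s for s in matrix.index if s in design.labels]
    matrix = matrix.loc[sample_ids]
    fold_sets = cv_folds(sample_ids, design, folds)
    y_all = design.y(sample_ids)
    y_hat = pd.Series(np.nan, index=sample_ids)
    for held_out in fold_sets:
        train = [s for s in sample_ids if s not in set(held_out)]
        sub = matrix.loc[train]
        model = _fit_raw(sub, design, n_orthogonal, scaling)
        y_hat.loc[held_out] = model.predict(matrix.loc[held_out])
    return y_all, y_hat.to_numpy(dtype=float)


def q2_cv(
    matrix: pd.DataFrame,
    design: ClassDesign,
    n_orthogonal: int = 0,
    folds: int = 7,
    scaling: str = "uv",
) -> float:
    """Cross-validated Q² = 1 − PRESS/SSY (may be negative)."""
    y, y_hat = _cv_residuals(matrix, design, n_orthogonal, folds, scaling)
    press = float(((y - y_hat) ** 2).sum())
    ssy = float(((y - y.mean()) ** 2).sum())
    return 1.0 - press / ssy


def cv_anova(
    matrix: pd.DataFrame,
    design: ClassDesign,
    n_orthogonal: int = 0,
    folds: int = 7,
    scaling: str = "uv",
) -> float:
    """CV-ANOVA p-value for the model.

    F-test of the cross-validated predictive residuals against the total
    class variation: SS_total (DF = N − 1) splits into SS_regression =
    SS_total − PRESS (DF = number of fitted components A = 1 + n_orthogonal)
    and PRESS (DF = N − 1 − A).  A model whose cross-validated predictions
    explain nothing (PRESS ≥ SS_total) gets p = 1; a perfect prediction
    (PRESS = 0) is reported at the machine floor with a warning.
    """
    y, y_hat = _cv_residuals(matrix, design, n_orthogonal, folds, scaling)
    n = len(y)
    a = 1 + n_orthogonal
    df_resid = n - 1 - a
    if df_resid <= 0:
        raise TableError("too few samples for the CV-ANOVA degrees of freedom")
    ss_tot = float(((y - y.mean()) ** 2).sum())
    press = float(((y - y_hat) ** 2).sum())
    ss_reg = ss_tot - press
    if press <= 0:
        warnings.warn("perfect cross-validated prediction; p at machine floor",
                      stacklevel=2)
        return sys.float_info.min
    if ss_reg <= 0:
        return 1.0
    f_stat = (ss_reg / a) / (press / df_resid)
    p = float(stats.f.sf(f_stat, a, df_resid))
    return max(p, sys.float_info.min)


# ---------------------------------------------------------------------------
# Significant-feature bookkeeping
# ---------------------------------------------------------------------------


def vip_scores(model: OplsModel) -> pd.Series:
    """VIP of the predictive component: sqrt(p · w²) with w normalized."""
    w2 = model.weights**2
    w2 = w2 / w2.sum()
    return pd.Series(np.sqrt(len(w2) * w2), index=model.feature_ids)


def significant_features(
    models: Sequence[OplsModel],
    matrices: Sequence[pd.DataFrame],
    criterion: str = "correlation",
    alpha: float = 0.05,
    model_alpha: float = 0.05,
) -> tuple[set[str], dict[str, set[str]]]:
    """Merge discriminating features across valid OPLS-DA models.

    A model is *valid* when its CV-ANOVA p is below ``model_alpha``.  Per
    valid model, features are selected by the chosen criterion —
    ``correlation`` (default): the p-value of each feature's Pearson
    correlation with t[1] below ``alpha``; ``vip``: VIP ≥ 1 — and attributed
    to the class on whose side of the predictive axis they load.  Returns
    the union of selected features and a feature → classes attribution map.
    """
    if criterion not in ("correlation", "vip"):
        raise TableError(f"unknown criterion {criterion!r}")
    valid = [
        (m, x)
        for m, x in zip(models, matrices)
        if m.cv_anova_p is not None and m.cv_anova_p < model_alpha
    ]
    if not valid:
        warnings.warn("no valid model (CV-ANOVA p < threshold); empty selection",
                      stacklevel=2)
        return set(), {}
    selected: set[str] = set()
    attribution: dict[str, set[str]] = {}
    for model, matrix in valid:
        corr = model.feature_score_correlation(matrix.loc[model.sample_ids])
        n = len(model.sample_ids)
        if criterion == "correlation":
            r = corr.to_numpy()
            with np.errstate(invalid="ignore", divide="ignore"):
                t_stat = r * np.sqrt((n - 2) / np.clip(1 - r**2, 1e-300, None))
            pvals = 2 * stats.t.sf(np.abs(t_stat), n - 2)
            chosen = corr.index[(pvals < alpha) & np.isfinite(r) & (r != 0)]
        else:
            vip = vip_scores(model)
            chosen = vip.index[(vip >= 1.0) & (corr.reindex(vip.index) != 0)]
        for fid in chosen:
            cls = model.design.classes[1] if corr[fid] > 0 else model.design.classes[0]
            selected.add(fid)
            attribution.setdefault(fid, set()).add(cls)
    return selected, attribution


def class_composition_report(
    selected: set[str],
    total: int,
    attribution: Mapping[str, set[str]],
) -> dict:
    """Summarize a merged selection: percent of all features selected
    (integer-rounded) and percent of the selection attributed to each class
    (1 decimal place; a feature may count toward several classes)."""
    if total < len(selected):
        raise TableError("total cannot be below the selection size")
    classes = sorted({c for cs in attribution.values() for c in cs})
    n_sel = len(selected)
    per_class = {
        cls: round(
            100.0 * sum(1 for f in selected if cls in attribution.get(f, ())) / n_sel,
            1,
        )
        if n_sel
        else 0.0
        for cls in classes
    }
    return {
        "n_selected": n_sel,
        "n_total": total,
        "percent_selected": round(100.0 * n_sel / total) if total else 0,
        "percent_by_class": per_class,
    }


def model_summary(model: OplsModel) -> dict:
    """JSON-ready summary mirroring the usual model-statistics table."""
    return {
        "contrast": model.design.name,
        "n_samples": len(model.sample_ids),
        "n_features": len(model.feature_ids),
        "n_orthogonal": model.n_orthogonal,
        "scaling": model.scaling,
        "R2Y(cum)": model.r2y_cum,
        "Q2(cum)": model.q2_cum,
        "P(CV-ANOVA)": model.cv_anova_p,
    }
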