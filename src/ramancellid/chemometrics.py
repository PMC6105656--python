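"""PCA and PLS-DA chemometrics with venetian-blinds model selection,
VIP scores, ROC/AUC, and per-class sensitivity/specificity/RMSE reporting.

PLS-DA regresses a one-indicator-column-per-class response on the
preprocessed spectra using the SIMPLS algorithm (de Jong 1993): latent
variables are extracted directly from the deflated cross-product matrix
X'Y, giving deterministic, orthogonal score vectors.  Class assignment is
the argmax of the predicted indicator scores, with ties broken toward the
first class in the model's class order.

Model complexity (the number of latent variables) is chosen with
venetian-blinds cross-validation: fold j holds out every n_splits-th
spectrum starting at j, the model is refit on the remainder, and the
"classification error average" - the mean over classes of
(false-negative rate + false-positive rate)/2 - is pooled over folds.
The selected complexity is the smallest one whose calibration and CV
error averages both reach the target (5% by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .preprocess import PreprocessRecipe, apply_recipe, rowwise_recipe
from .spectral_data import (
    SpectralDataError,
    SpectralDataset,
    StructuralError,
    WavenumberAxis,
)

__all__ = [
    "PCAResult",
    "PLSDAModel",
    "ErrorCurves",
    "VIPResult",
    "ClassificationReport",
    "fit_pca",
    "split_every_fourth",
    "fit_plsda",
    "predict",
    "venetian_cv",
    "select_n_lv",
    "vip_scores",
    "roc_auc",
    "classification_report",
    "error_average",
]


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PCAResult:
    """Principal components of a preprocessed, column-centered dataset."""

    loadings: np.ndarray  # n_components x n_wavenumbers, orthonormal rows
    scores: np.ndarray  # n_spectra x n_components
    explained_variance_fraction: np.ndarray
    recipe: PreprocessRecipe


def _fix_signs(loadings: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic sign convention: largest-|element| loading entry positive."""
    loadings = loadings.copy()
    scores = scores.copy()
    for i in range(loadings.shape[0]):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] *= -1
            scores[:, i] *= -1
    return loadings, scores


def fit_pca(
    d: SpectralDataset, n_components: int, recipe: PreprocessRecipe | None = None
) -> PCAResult:
    """PCA via SVD of the recipe-preprocessed, column-centered matrix."""
    if recipe is None:
        recipe = PreprocessRecipe()
    X = apply_recipe(d, rowwise_recipe(recipe)).matrix
    if n_components > min(X.shape):
        raise SpectralDataError(
            f"n_components={n_components} exceeds min(n_spectra, n_wavenumbers)"
            f"={min(X.shape)}"
        )
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total_var = float((s**2).sum())
    loadings = Vt[:n_components]
    scores = U[:, :n_components] * s[:n_components]
    loadings, scores = _fix_signs(loadings, scores)
    frac = (s[:n_components] ** 2) / total_var if total_var > 0 else np.zeros(n_components)
    return PCAResult(loadings, scores, frac, recipe)


# ---------------------------------------------------------------------------
# Calibration / validation split
# ---------------------------------------------------------------------------

def split_every_fourth(d: SpectralDataset) -> tuple[SpectralDataset, SpectralDataset]:
    """Every fourth spectrum (acquisition order) becomes the validation set."""
    if d.n_spectra < 4:
        raise SpectralDataError("need at least 4 spectra to split")
    idx = np.arange(d.n_spectra)
    val_mask = (idx % 4) == 3
    return d.select(~val_mask), d.select(val_mask)


# ---------------------------------------------------------------------------
# SIMPLS PLS-DA
# ---------------------------------------------------------------------------

def _indicator_matrix(labels: np.ndarray, class_order: list[str]) -> np.ndarray:
    Y = np.zeros((labels.size, len(class_order)))
    for j, c in enumerate(class_order):
        Y[labels == c, j] = 1.0
    return Y


def _simpls(X0: np.ndarray, Y0: np.ndarray, n_lv: int):
    """SIMPLS decomposition of centered X0 (n x p) and Y0 (n x q).

    Returns weights R (p x A) such that T = X0 R has orthonormal columns,
    loadings P (p x A) and Q (q x A), and the per-component explained
    Y sum of squares.
    """
    n, p = X0.shape
    q = Y0.shape[1]
    R = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    Q = np.zeros((q, n_lv))
    V = np.zeros((p, n_lv))
    ssy = np.zeros(n_lv)
    S = X0.T @ Y0
    sv_tol = 0.0
    for a in range(n_lv):
        U, sv, Wt = np.linalg.svd(S, full_matrices=False)
        if a == 0:
            sv_tol = max(n, p) * np.finfo(float).eps * sv[0]
        if sv[0] <= sv_tol:
            # X carries no remaining covariance with Y; stop early
            R, P, Q, V, ssy = R[:, :a], P[:, :a], Q[:, :a], V[:, :a], ssy[:a]
            break
        r = U[:, 0]
        t = X0 @ r
        normt = np.linalg.norm(t)
        if normt == 0:
            R, P, Q, V, ssy = R[:, :a], P[:, :a], Q[:, :a], V[:, :a], ssy[:a]
            break
        t /= normt
        r /= normt
        p_a = X0.T @ t
        q_a = Y0.T @ t
        v = p_a.copy()
        if a > 0:
            v -= V[:, :a] @ (V[:, :a].T @ p_a)
        v /= np.linalg.norm(v)
        S = S - np.outer(v, v @ S)
        R[:, a], P[:, a], Q[:, a], V[:, a] = r, p_a, q_a, v
        ssy[a] = float(q_a @ q_a)  # scores are unit norm
    return R, P, Q, ssy


@dataclass(frozen=True)
class PLSDAModel:
    """Fitted PLS-DA model (SIMPLS) with its preprocessing recipe."""

    n_lv: int
    x_weights: np.ndarray  # p x A (SIMPLS R)
    x_loadings: np.ndarray  # p x A
    y_loadings: np.ndarray  # q x A
    ssy_per_lv: np.ndarray
    x_mean: np.ndarray
    y_mean: np.ndarray
    class_order: list[str]
    recipe: PreprocessRecipe
    axis: WavenumberAxis

    @property
    def regression_coefficients(self) -> np.ndarray:
        """p x q coefficient matrix mapping centered spectra to indicators."""
        return self.x_weights @ self.y_loadings.T

    def coefficients_at(self, n_lv: int) -> np.ndarray:
        return self.x_weights[:, :n_lv] @ self.y_loadings[:, :n_lv].T

    def to_json(self) -> str:
        """Serialize the fitted model (axis, recipe, matrices) to JSON."""
        import json

        return json.dumps(
            {
                "n_lv": self.n_lv,
                "x_weights": self.x_weights.tolist(),
                "x_loadings": self.x_loadings.tolist(),
                "y_loadings": self.y_loadings.tolist(),
                "ssy_per_lv": self.ssy_per_lv.tolist(),
                "x_mean": self.x_mean.tolist(),
                "y_mean": self.y_mean.tolist(),
                "class_order": self.class_order,
                "recipe": self.recipe.to_config(),
                "axis": self.axis.values.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "PLSDAModel":
        import json

        obj = json.loads(text)
        return cls(
            n_lv=int(obj["n_lv"]),
            x_weights=np.asarray(obj["x_weights"]),
            x_loadings=np.asarray(obj["x_loadings"]),
            y_loadings=np.asarray(obj["y_loadings"]),
            ssy_per_lv=np.asarray(obj["ssy_per_lv"]),
            x_mean=np.asarray(obj["x_mean"]),
            y_mean=np.asarray(obj["y_mean"]),
            class_order=list(obj["class_order"]),
            recipe=PreprocessRecipe.from_config(obj["recipe"]),
            axis=WavenumberAxis(np.asarray(obj["axis"])),
        )


def fit_plsda(
    calibration: SpectralDataset,
    n_lv: int,
    recipe: PreprocessRecipe | None = None,
) -> PLSDAModel:
    """Fit a PLS2 discriminant model of class indicators on spectra.

    Row-wise recipe steps are applied first; mean centering (of both the
    spectra and the indicator columns) is part of the fit itself, against
    the calibration means, so that held-out spectra are centered
    consistently at prediction time.
    """
    if recipe is None:
        recipe = PreprocessRecipe()
    classes = calibration.classes
    if len(classes) < 2:
        raise SpectralDataError("PLS-DA needs at least 2 classes")
    if n_lv < 1:
        raise SpectralDataError("n_lv must be >= 1")
    X = apply_recipe(calibration, rowwise_recipe(recipe)).matrix
    Y = _indicator_matrix(calibration.class_labels, classes)
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    R, P, Q, ssy = _simpls(X - x_mean, Y - y_mean, n_lv)
    if R.shape[1] == 0:
        raise SpectralDataError("calibration matrix has no covariance with classes")
    return PLSDAModel(
        n_lv=R.shape[1],
        x_weights=R,
        x_loadings=P,
        y_loadings=Q,
        ssy_per_lv=ssy,
        x_mean=x_mean,
        y_mean=y_mean,
        class_order=list(classes),
        recipe=recipe,
        axis=calibration.axis,
    )


def predict(
    m: PLSDAModel, d: SpectralDataset, n_lv: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Continuous indicator scores and argmax class assignments.

    Returns ``(scores, labels)`` where scores is n x n_classes and labels
    the assigned class per spectrum.  Ties go to the first class in
    ``class_order`` (numpy argmax convention).
    """
    if d.axis != m.axis:
        raise StructuralError("dataset axis differs from the model's axis")
    X = apply_recipe(d, rowwise_recipe(m.recipe)).matrix
    B = m.regression_coefficients if n_lv is None else m.coefficients_at(n_lv)
    scores = (X - m.x_mean) @ B + m.y_mean
    labels = np.array([m.class_order[i] for i in np.argmax(scores, axis=1)])
    return scores, labels


# ---------------------------------------------------------------------------
# Cross-validation and model selection
# ---------------------------------------------------------------------------

def error_average(
    truth: np.ndarray, assigned: np.ndarray, class_order: list[str]
) -> float:
    """Mean over classes of (false-negative rate + false-positive rate)/2."""
    errs = []
    for c in class_order:
        pos = truth == c
        neg = ~pos
        if pos.sum() == 0 or neg.sum() == 0:
            continue
        fnr = np.mean(assigned[pos] != c)
        fpr = np.mean(assigned[neg] == c)
        errs.append((fnr + fpr) / 2.0)
    return float(np.mean(errs)) if errs else float("nan")


@dataclass(frozen=True)
class ErrorCurves:
    """Calibration and cross-validation error averages per model complexity."""

    n_lv: np.ndarray
    calibration_error: np.ndarray
    cv_error: np.ndarray
    cv_predictions: np.ndarray  # A x n x q pooled held-out indicator scores
    class_order: list[str]


def venetian_cv(
    calibration: SpectralDataset,
    n_lv_max: int,
    n_splits: int = 10,
    recipe: PreprocessRecipe | None = None,
) -> ErrorCurves:
    """Venetian-blinds cross-validation of PLS-DA complexity.

    Fold j holds out rows with index = j (mod ``n_splits``); the model is
    refit on the remaining rows and the held-out indicator predictions are
    pooled.  No randomness is involved, so curves are bit-reproducible.
    """
    if recipe is None:
        recipe = PreprocessRecipe()
    if n_splits < 2:
        raise SpectralDataError("n_splits must be >= 2")
    classes = calibration.classes
    counts = calibration.meta["cell_line"].value_counts()
    if (counts < n_splits).any():
        warnings.warn(
            "some class has fewer members than n_splits; folds will be "
            "imbalanced", stacklevel=2,
        )
    X = apply_recipe(calibration, rowwise_recipe(recipe)).matrix
    truth = calibration.class_labels
    Y = _indicator_matrix(truth, classes)
    n, q = Y.shape
    idx = np.arange(n)

    cv_pred = np.zeros((n_lv_max, n, q))
    for j in range(n_splits):
        held = (idx % n_splits) == j
        Xt, Yt = X[~held], Y[~held]
        xm, ym = Xt.mean(axis=0), Yt.mean(axis=0)
        R, P, Q, _ = _simpls(Xt - xm, Yt - ym, n_lv_max)
        Xh = X[held] - xm
        for a in range(1, n_lv_max + 1):
            aa = min(a, R.shape[1])
            B = R[:, :aa] @ Q[:, :aa].T
            cv_pred[a - 1, held] = Xh @ B + ym

    # calibration curve: fit on everything, predict everything
    xm, ym = X.mean(axis=0), Y.mean(axis=0)
    R, P, Q, _ = _simpls(X - xm, Y - ym, n_lv_max)
    cal_err = np.zeros(n_lv_max)
    cv_err = np.zeros(n_lv_max)
    for a in range(1, n_lv_max + 1):
        aa = min(a, R.shape[1])
        cal_scores = (X - xm) @ (R[:, :aa] @ Q[:, :aa].T) + ym
        cal_lab = np.array([classes[i] for i in np.argmax(cal_scores, axis=1)])
        cv_lab = np.array([classes[i] for i in np.argmax(cv_pred[a - 1], axis=1)])
        cal_err[a - 1] = error_average(truth, cal_lab, classes)
        cv_err[a - 1] = error_average(truth, cv_lab, classes)
    return ErrorCurves(
        np.arange(1, n_lv_max + 1), cal_err, cv_err, cv_pred, list(classes)
    )


def select_n_lv(curves: ErrorCurves, target_error: float = 0.05) -> tuple[int, bool]:
    """Smallest complexity with calibration AND CV error <= target.

    Returns ``(n_lv, met_target)``; when no complexity meets the target the
    CV-minimizing one is returned with ``met_target=False``.
    """
    ok = (curves.calibration_error <= target_error) & (curves.cv_error <= target_error)
    if ok.any():
        return int(curves.n_lv[np.argmax(ok)]), True
    return int(curves.n_lv[np.argmin(curves.cv_error)]), False


# ---------------------------------------------------------------------------
# VIP scores
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VIPResult:
    """Variable importance in projection, one score per wavenumber."""

    vip: np.ndarray
    axis: WavenumberAxis

    @property
    def discriminatory_mask(self) -> np.ndarray:
        return self.vip > 1.0

    @property
    def discriminatory_bands(self) -> np.ndarray:
        """Wavenumbers with VIP > 1."""
        return self.axis.values[self.discriminatory_mask]


def vip_scores(m: PLSDAModel) -> VIPResult:
    """VIP_j = sqrt( p * sum_a SSY_a (w_ja/||w_a||)^2 / sum_a SSY_a ).

    SSY_a is the Y sum of squares explained by latent variable a; by
    construction mean(VIP^2) over wavenumbers equals 1.
    """
    W = m.x_weights
    p = W.shape[0]
    wnorm2 = (W**2).sum(axis=0)
    wnorm2[wnorm2 == 0] = 1.0
    ssy = m.ssy_per_lv
    denom = ssy.sum()
    if denom == 0:
        raise SpectralDataError("model explains no Y variance")
    vip = np.sqrt(p * ((W**2) / wnorm2) @ ssy / denom)
    return VIPResult(vip, m.axis)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def roc_auc(truth: np.ndarray, scores: np.ndarray) -> float:
    """Mann-Whitney AUC: P(random positive outscores random negative),
    ties counted 1/2."""
    truth = np.asarray(truth, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(truth.sum())
    n_neg = int((~truth).sum())
    if n_pos == 0 or n_neg == 0:
        raise SpectralDataError("roc_auc needs both classes present")
    ranks = rankdata(scores)
    u = ranks[truth].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# Classification report (Tables 1-2 twin)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassificationReport:
    """Per-class metrics plus confusion matrix at spectrum or cell level."""

    per_class: pd.DataFrame  # sensitivity/specificity/auc/rmsec/rmsecv/rmsep
    confusion_matrix: pd.DataFrame  # true class x assigned class counts
    level: str
    error_curves: ErrorCurves | None = None

    @property
    def average_sensitivity(self) -> float:
        return float(self.per_class["sensitivity"].mean())

    @property
    def average_specificity(self) -> float:
        return float(self.per_class["specificity"].mean())


def _per_class_rmse(Y: np.ndarray, scores: np.ndarray) -> np.ndarray:
    return np.sqrt(np.mean((Y - scores) ** 2, axis=0))


def classification_report(
    m: PLSDAModel,
    calibration: SpectralDataset,
    validation: SpectralDataset,
    cv_curves: ErrorCurves | None = None,
    level: str = "spectrum",
) -> ClassificationReport:
    """Sensitivity/specificity/AUC/RMSEC/RMSECV/RMSEP per class.

    At ``level='cell'`` the 10 point spectra of each cell are averaged
    (raw, before preprocessing) and the same model predicts the averaged
    spectra; cross-validation predictions are pooled per cell the same
    way.  Metrics whose class is absent from the validation set are
    reported as NaN rather than fabricated.
    """
    if level not in ("spectrum", "cell"):
        raise SpectralDataError(f"unknown level {level!r}")
    classes = m.class_order

    if level == "cell":
        cal_ds = calibration.average_by_cell()
        val_ds = validation.average_by_cell()
    else:
        cal_ds, val_ds = calibration, validation

    cal_scores, _ = predict(m, cal_ds)
    val_scores, val_assigned = predict(m, val_ds)
    Y_cal = _indicator_matrix(cal_ds.class_labels, classes)
    Y_val = _indicator_matrix(val_ds.class_labels, classes)
    rmsec = _per_class_rmse(Y_cal, cal_scores)
    rmsep = _per_class_rmse(Y_val, val_scores)

    rmsecv = np.full(len(classes), np.nan)
    if cv_curves is not None:
        pooled = cv_curves.cv_predictions[m.n_lv - 1]
        if level == "cell":
            pooled = np.vstack(
                [pooled[ix].mean(axis=0) for ix in calibration.cell_group_indices()]
            )
            Y_cv = _indicator_matrix(cal_ds.class_labels, classes)
        else:
            Y_cv = _indicator_matrix(calibration.class_labels, classes)
        rmsecv = _per_class_rmse(Y_cv, pooled)

    truth = val_ds.class_labels
    rows = []
    for j, c in enumerate(classes):
        pos = truth == c
        neg = ~pos
        sens = float(np.mean(val_assigned[pos] == c)) if pos.any() else np.nan
        spec = float(np.mean(val_assigned[neg] != c)) if neg.any() else np.nan
        auc = (
            roc_auc(pos, val_scores[:, j]) if pos.any() and neg.any() else np.nan
        )
        rows.append(
            {
                "cell_line": c,
                "sensitivity": sens,
                "specificity": spec,
                "auc": auc,
                "rmsec": float(rmsec[j]),
                "rmsecv": float(rmsecv[j]),
                "rmsep": float(rmsep[j]),
            }
        )
    per_class = pd.DataFrame(rows).set_index("cell_line")

    confusion = pd.DataFrame(
        0, index=classes, columns=classes, dtype=int
    )
    for t, a in zip(truth, val_assigned):
        confusion.loc[t, a] += 1

    return ClassificationReport(per_class, confusion, level, cv_curves)
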