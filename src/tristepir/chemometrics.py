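"""PCA, SIMCA class modelling and OPLS-DA with full validation statistics.

The discrimination workflow mirrors mainstream chemometrics practice for
spectral fingerprints:

* a stratified 60/40 calibration/validation split,
* PCA by mean-centred SVD with cross-validated Q² (seven cancellation
  groups, element-exclusion reconstruction of held-out entries),
* SIMCA (one PCA model per class) with membership decided by the
  distance-to-model statistic DModX against an F-based critical limit,
* OPLS-DA: one-hot class response, Y-orthogonal variation stripped from X
  before a NIPALS PLS2 regression; validated by R²Y, Q²Y (7-group CV),
  RMSEE/RMSECV/RMSEP and a 100-permutation test whose R²Y/Q²Y intercepts
  must stay below 0.3 and 0.05 for a non-overfitted model,
* one-vs-rest sensitivity / specificity / accuracy in percent.

Matrices are plain numpy arrays; models are frozen dataclasses with
JSON-serialisable exports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ConvergenceError,
    DegenerateDataError,
    GridError,
    ParameterError,
)
from .spectra_io import SpectrumCollection

# ---------------------------------------------------------------------------
# Data container
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DataMatrix:
    """Samples x features matrix with class labels and a feature grid.

    ``classes`` fixes the declared class order (first occurrence by
    default); it drives one-hot encoding and argmax tie-breaking.
    """

    X: np.ndarray
    y: np.ndarray | None = None
    grid: np.ndarray | None = None
    classes: tuple = ()

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        if X.ndim != 2:
            raise ParameterError("X must be 2-D (samples x features)")
        if not np.all(np.isfinite(X)):
            raise ParameterError("X contains missing/non-finite values")
        object.__setattr__(self, "X", X)
        if self.y is not None:
            y = np.asarray(self.y, dtype=object)
            if y.shape[0] != X.shape[0]:
                raise ParameterError("labels do not match the number of rows")
            object.__setattr__(self, "y", y)
            if not self.classes:
                seen: list = []
                for lab in y:
                    if lab not in seen:
                        seen.append(lab)
                object.__setattr__(self, "classes", tuple(seen))
        if self.grid is not None:
            grid = np.asarray(self.grid, dtype=float)
            if grid.size != X.shape[1]:
                raise GridError("feature grid length does not match X columns")
            object.__setattr__(self, "grid", grid)

    @classmethod
    def from_collection(cls, coll: SpectrumCollection) -> "DataMatrix":
        X, y = coll.to_matrix()
        return cls(X=X, y=y, grid=coll.grid, classes=coll.classes)

    @property
    def n_samples(self) -> int:
        return int(self.X.shape[0])

    @property
    def n_features(self) -> int:
        return int(self.X.shape[1])

    def subset(self, idx: np.ndarray) -> "DataMatrix":
        return DataMatrix(
            X=self.X[idx],
            y=None if self.y is None else self.y[idx],
            grid=self.grid,
            classes=self.classes,
        )

    def one_hot(self) -> np.ndarray:
        """One-hot response matrix in declared class order."""
        if self.y is None:
            raise ParameterError("no labels available for one-hot encoding")
        Y = np.zeros((self.n_samples, len(self.classes)))
        for k, c in enumerate(self.classes):
            Y[np.asarray(self.y == c, dtype=bool), k] = 1.0
        return Y


# ---------------------------------------------------------------------------
# Splitting and cancellation groups
# ---------------------------------------------------------------------------


def stratified_split(data: DataMatrix, calibration_fraction: float = 0.6,
                     seed: int = 0) -> tuple[DataMatrix, DataMatrix]:
    """Per-class random split; calibration size is ceil(fraction * n_class).

    The split is disjoint and exhaustive, and reproducible for a given seed.
    """
    if not 0 < calibration_fraction < 1:
        raise ParameterError("calibration_fraction must lie in (0, 1)")
    if data.y is None:
        raise ParameterError("stratified split needs class labels")
    rng = np.random.default_rng(seed)
    cal_idx: list[int] = []
    val_idx: list[int] = []
    for c in data.classes:
        members = np.flatnonzero(data.y == c)
        if members.size < 2:
            raise DegenerateDataError(
                f"class {c!r} has {members.size} sample(s); need >= 2 to split"
            )
        perm = rng.permutation(members)
        n_cal = math.ceil(calibration_fraction * members.size)
        cal_idx.extend(perm[:n_cal])
        val_idx.extend(perm[n_cal:])
    return data.subset(np.sort(cal_idx)), data.subset(np.sort(val_idx))


def cancellation_groups(y: np.ndarray, n_groups: int = 7, seed: int = 0) -> np.ndarray:
    """Seeded round-robin group assignment, stratified by class.

    Returns an integer group id per sample; groups partition the set exactly
    and every class is spread as evenly as possible across groups.
    """
    y = np.asarray(y, dtype=object)
    n = y.shape[0]
    if n_groups < 2:
        raise ParameterError("need at least 2 cancellation groups")
    if n_groups > n:
        raise ParameterError("more cancellation groups than samples")
    rng = np.random.default_rng(seed)
    groups = np.empty(n, dtype=int)
    offset = 0
    seen: list = []
    for lab in y:
        if lab not in seen:
            seen.append(lab)
    for c in seen:
        members = np.flatnonzero(y == c)
        perm = rng.permutation(members)
        for i, idx in enumerate(perm):
            groups[idx] = (offset + i) % n_groups
        offset += members.size
    return groups


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PCAModel:
    """Mean-centred SVD principal components with variance bookkeeping."""

    mean: np.ndarray
    loadings: np.ndarray           # features x A, orthonormal columns
    scores: np.ndarray             # samples x A
    singular_values: np.ndarray
    explained_variance_ratio: np.ndarray
    total_variance: float          # sum of squares of the centred matrix
    q2: np.ndarray | None = None   # per-component cross-validated Q²

    @property
    def n_components(self) -> int:
        return int(self.loadings.shape[1])

    @property
    def r2x_cumulative(self) -> float:
        return float(np.sum(self.explained_variance_ratio))

    def project(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) @ self.loadings

    def residuals(self, X: np.ndarray) -> np.ndarray:
        Xc = np.asarray(X, dtype=float) - self.mean
        return Xc - (Xc @ self.loadings) @ self.loadings.T


def pca_fit(data: DataMatrix | np.ndarray, n_components: int) -> PCAModel:
    """Principal components by SVD of the mean-centred matrix."""
    X = data.X if isinstance(data, DataMatrix) else np.asarray(data, dtype=float)
    n, p = X.shape
    if not 1 <= n_components <= min(n - 1, p):
        raise ParameterError(
            f"n_components must lie in [1, {min(n - 1, p)}] for a {n}x{p} matrix"
        )
    mean = X.mean(axis=0)
    Xc = X - mean
    total = float(np.sum(Xc ** 2))
    if total == 0:
        raise DegenerateDataError("constant matrix has no principal components")
    U, sv, Vt = np.linalg.svd(Xc, full_matrices=False)
    A = n_components
    return PCAModel(
        mean=mean,
        loadings=Vt[:A].T,
        scores=U[:, :A] * sv[:A],
        singular_values=sv[:A],
        explained_variance_ratio=sv[:A] ** 2 / total,
        total_variance=total,
    )


def _held_out_press(P: np.ndarray, xc: np.ndarray) -> float:
    """PRESS contribution of one held-out row under element exclusion.

    Scores for predicting element j are estimated from all features except
    j (Sherman-Morrison on the loadings normal equations), so an element is
    never predicted from itself — pure-noise matrices therefore get Q² <= 0.
    """
    t = P.T @ xc                               # A
    pj = P                                     # p x A rows p_j
    denom = 1.0 - np.sum(pj * pj, axis=1)      # 1 - ||p_j||^2
    denom = np.maximum(denom, 1e-8)
    b = t[None, :] - pj * xc[:, None]          # p x A
    corr = np.sum(pj * b, axis=1) / denom      # p
    t_excl = b + pj * corr[:, None]            # p x A
    xhat = np.sum(pj * t_excl, axis=1)         # p
    return float(np.sum((xc - xhat) ** 2))


def pca_q2(data: DataMatrix | np.ndarray, n_components: int,
           n_groups: int = 7, seed: int = 0) -> np.ndarray:
    """Per-component cross-validated Q² with ``n_groups`` cancellation groups.

    Q²(a) = 1 - PRESS(a)/SS(a-1) where SS(a-1) is the residual sum of
    squares of the full-data model with a-1 components.
    """
    X = data.X if isinstance(data, DataMatrix) else np.asarray(data, dtype=float)
    n, p = X.shape
    if n_groups > n:
        raise ParameterError("more cancellation groups than samples")
    a_max = min(n_components, n - math.ceil(n / n_groups) - 1, p)
    if a_max < 1:
        raise ParameterError("too few samples for even one cross-validated component")
    rng = np.random.default_rng(seed)
    groups = rng.permutation(n) % n_groups
    press = np.zeros(a_max)
    for g in range(n_groups):
        held = groups == g
        Xtr = X[~held]
        mean = Xtr.mean(axis=0)
        _, _, Vt = np.linalg.svd(Xtr - mean, full_matrices=False)
        for i in np.flatnonzero(held):
            xc = X[i] - mean
            for a in range(1, a_max + 1):
                press[a - 1] += _held_out_press(Vt[:a].T, xc)
    mean_full = X.mean(axis=0)
    Xc = X - mean_full
    sv = np.linalg.svd(Xc, compute_uv=False)
    ss_total = float(np.sum(Xc ** 2))
    ss_after = ss_total - np.concatenate(([0.0], np.cumsum(sv ** 2)))
    q2 = np.empty(a_max)
    for a in range(1, a_max + 1):
        denom = ss_after[a - 1]
        q2[a - 1] = 1.0 - press[a - 1] / denom if denom > 0 else 0.0
    return q2


# ---------------------------------------------------------------------------
# SIMCA (PCA-class)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SIMCAClassModel:
    """One class's PCA model plus its DModX bookkeeping."""

    pca: PCAModel
    n_samples: int
    s0: float                 # pooled residual standard deviation
    critical_dmodx: float
    n_components: int
    q2: np.ndarray | None = None


@dataclass(frozen=True)
class SIMCAModel:
    """Soft independent modelling of class analogy: one PCA model per class."""

    class_models: Mapping[str, SIMCAClassModel]
    classes: tuple
    alpha: float

    def dmodx(self, X: np.ndarray, class_label) -> np.ndarray:
        """Normalised distance to the class model for each row of X."""
        cm = self.class_models[class_label]
        res = cm.pca.residuals(X)
        p = X.shape[1]
        a = cm.n_components
        s = np.sqrt(np.sum(res ** 2, axis=1) / (p - a))
        return s / cm.s0


def _cv_residual_ss(rows: np.ndarray, a_c: int, n_groups: int,
                    seed: int) -> np.ndarray:
    """Held-out residual sums of squares of class rows under k-fold PCA.

    Each calibration sample's residual is computed against a model fitted
    without it, so the returned SS values estimate the residual distribution
    of *new* in-class observations (the in-model residuals of a wide-matrix
    PCA are optimistically deflated and would undersize the limit).
    """
    n = rows.shape[0]
    rng = np.random.default_rng(seed)
    groups = rng.permutation(n) % n_groups
    ss = np.empty(n)
    for g in range(n_groups):
        held = groups == g
        train = rows[~held]
        mean = train.mean(axis=0)
        _, _, Vt = np.linalg.svd(train - mean, full_matrices=False)
        P = Vt[:a_c].T
        Xc = rows[held] - mean
        res = Xc - (Xc @ P) @ P.T
        ss[held] = np.sum(res ** 2, axis=1)
    return ss


def simca_fit(calibration: DataMatrix,
              components_per_class: Mapping | None = None,
              alpha: float = 0.05, max_components: int = 5,
              n_groups: int = 7, seed: int = 0) -> SIMCAModel:
    """Fit one PCA model per class and derive DModX critical limits.

    Component counts default to the cross-validated Q² maximum per class
    (capped at ``max_components``).  The residual scale s0 and the critical
    limit at significance ``alpha`` are estimated from cross-validated
    calibration residuals via a moment-matched scaled-chi-square
    (Nomikos-MacGregor style), so membership coverage is calibrated for new
    observations even when features far outnumber samples or residuals
    retain structured within-class variation.
    """
    if calibration.y is None:
        raise ParameterError("SIMCA needs class labels")
    if not 0 < alpha < 1:
        raise ParameterError("alpha must lie in (0, 1)")
    p = calibration.n_features
    models: dict = {}
    for c in calibration.classes:
        rows = calibration.X[np.asarray(calibration.y == c, dtype=bool)]
        n_c = rows.shape[0]
        if n_c == 0:
            raise DegenerateDataError(f"class {c!r} has no calibration samples")
        requested = None if components_per_class is None else components_per_class.get(c)
        cap = min(max_components, n_c - 2, p)
        if cap < 1:
            raise DegenerateDataError(f"class {c!r} is too small for a PCA model")
        q2 = None
        if requested is None:
            q2 = pca_q2(rows, cap, n_groups=min(n_groups, n_c), seed=seed)
            a_c = int(np.argmax(q2)) + 1
        else:
            a_c = int(requested)
            if not 1 <= a_c <= n_c - 2:
                raise ParameterError(
                    f"class {c!r}: {a_c} components not supported by {n_c} samples"
                )
        pca = pca_fit(rows, a_c)
        ss_cv = _cv_residual_ss(rows, a_c, min(n_groups, n_c), seed)
        m = float(np.mean(ss_cv))
        v = float(np.var(ss_cv, ddof=1)) if n_c > 1 else 0.0
        if m > 0 and v > 0:
            # scaled chi-square matched to the CV residual moments
            g = v / (2.0 * m)
            h = 2.0 * m ** 2 / v
            ss_crit = g * stats.chi2.ppf(1.0 - alpha, h)
            s0 = math.sqrt(m / (p - a_c))
        else:
            # degenerate (e.g. noiseless) fallback: classic F-based limit
            res = pca.residuals(rows)
            dof_model = (n_c - a_c - 1) * (p - a_c)
            s0 = math.sqrt(max(float(np.sum(res ** 2)), 1e-300) / dof_model)
            ss_crit = (s0 ** 2) * (p - a_c) * stats.f.ppf(1.0 - alpha,
                                                          p - a_c, dof_model)
        crit = math.sqrt(ss_crit / (s0 ** 2 * (p - a_c)))
        models[c] = SIMCAClassModel(pca, n_c, s0, crit, a_c, q2)
    return SIMCAModel(models, calibration.classes, alpha)


def simca_classify(model: SIMCAModel, query: DataMatrix) -> pd.DataFrame:
    """Per-class membership verdicts for each query sample.

    A sample belongs to class c iff DModX_c <= the class critical limit; it
    may belong to zero, one or several classes.  Returns a DataFrame with
    one DModX and one membership column per class.
    """
    first = next(iter(model.class_models.values()))
    if query.n_features != first.pca.mean.size:
        raise GridError("query feature grid does not match the fitted model")
    out = pd.DataFrame(index=np.arange(query.n_samples))
    for c in model.classes:
        d = model.dmodx(query.X, c)
        out[f"dmodx_{c}"] = d
        out[f"member_{c}"] = d <= model.class_models[c].critical_dmodx
    if query.y is not None:
        out.insert(0, "true_class", query.y)
    return out


# ---------------------------------------------------------------------------
# PLS2 / OPLS-DA
# ---------------------------------------------------------------------------


def _pls2_nipals(Xc: np.ndarray, Yc: np.ndarray, n_components: int):
    """PLS2 on centred matrices with X and Y both deflated per component.

    Each weight vector is the dominant left singular vector of the current
    cross-covariance X'Y — the exact fixed point the NIPALS inner iteration
    converges to, computed directly so that near-degenerate covariance
    spectra (e.g. permuted class labels) cannot stall the estimation.

    Returns (W, P, Q) with weights, X-loadings and Y-loadings as columns.
    """
    X = Xc.copy()
    Y = Yc.copy()
    p = X.shape[1]
    k = Y.shape[1]
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros((k, n_components))
    for a in range(n_components):
        C = X.T @ Y
        cnorm = np.linalg.norm(C)
        if cnorm == 0 or not np.isfinite(cnorm):
            break
        try:
            U, _, _ = np.linalg.svd(C, full_matrices=False)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(
                "PLS2 weight estimation failed to converge"
            ) from exc
        w = U[:, 0]
        t = X @ w
        tt = t @ t
        if tt == 0:
            break
        pv = X.T @ t / tt
        qv = Y.T @ t / tt
        X -= np.outer(t, pv)
        Y -= np.outer(t, qv)
        W[:, a] = w
        P[:, a] = pv
        Q[:, a] = qv
    return W, P, Q


def _pls2_scores(W: np.ndarray, P: np.ndarray, Xc: np.ndarray) -> np.ndarray:
    """Scores of (possibly new) centred rows under a fitted PLS2 model."""
    X = Xc.copy()
    A = W.shape[1]
    T = np.zeros((X.shape[0], A))
    for a in range(A):
        t = X @ W[:, a]
        X -= np.outer(t, P[:, a])
        T[:, a] = t
    return T


@dataclass(frozen=True)
class OPLSDAModel:
    """Fitted OPLS-DA: orthogonal filter plus a PLS2 discriminant core."""

    classes: tuple
    x_mean: np.ndarray
    y_mean: np.ndarray
    w_orth: np.ndarray             # features x n_orth
    p_orth: np.ndarray
    t_orth: np.ndarray             # calibration orthogonal scores
    weights: np.ndarray            # features x n_pred (predictive W)
    x_loadings: np.ndarray         # predictive P
    y_loadings: np.ndarray         # K x n_pred (predictive Q)
    scores: np.ndarray             # calibration predictive scores
    r2x: float
    r2y: float
    q2y: float
    cv_predictions: np.ndarray | None = None   # calibration Yhat under CV
    n_groups: int = 7
    seed: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def n_predictive(self) -> int:
        return int(self.weights.shape[1])

    @property
    def n_orthogonal(self) -> int:
        return int(self.w_orth.shape[1])

    def _filter(self, X: np.ndarray) -> np.ndarray:
        """Centre and remove the Y-orthogonal components from new rows."""
        Xc = np.asarray(X, dtype=float) - self.x_mean
        for a in range(self.n_orthogonal):
            t_o = Xc @ self.w_orth[:, a]
            Xc = Xc - np.outer(t_o, self.p_orth[:, a])
        return Xc

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        return _pls2_scores(self.weights, self.x_loadings, self._filter(X))

    def predict_yhat(self, X: np.ndarray) -> np.ndarray:
        """Continuous one-hot predictions (rows need not sum to one)."""
        T = self.predict_scores(X)
        return self.y_mean + T @ self.y_loadings.T

    def predict_labels(self, X: np.ndarray) -> np.ndarray:
        """Argmax class per row; exact ties resolve to the lowest class index."""
        yhat = self.predict_yhat(X)
        idx = np.argmax(yhat, axis=1)
        return np.asarray([self.classes[i] for i in idx], dtype=object)


def _fit_opls_core(Xc: np.ndarray, Yc: np.ndarray, n_predictive: int,
                   n_orthogonal: int):
    """Extract Y-orthogonal components, then the predictive PLS2 core.

    The orthogonal weight is the first PLS loading minus its projection onto
    the column space of X'Y, so orthogonal scores have exactly zero
    covariance with every response column.
    """
    X = Xc.copy()
    p = X.shape[1]
    W_o = np.zeros((p, 0))
    P_o = np.zeros((p, 0))
    T_o = np.zeros((X.shape[0], 0))
    for _ in range(n_orthogonal):
        C = X.T @ Yc
        # orthonormal basis of the Y-covariance space
        Qb, Rb = np.linalg.qr(C)
        keep = np.abs(np.diag(Rb)) > 1e-12 * max(1.0, np.abs(np.diag(Rb)).max())
        B = Qb[:, keep]
        if B.shape[1] == 0:
            break
        U, sv, Vt = np.linalg.svd(C, full_matrices=False)
        w = U[:, 0]
        t = X @ w
        tt = t @ t
        if tt == 0:
            break
        pv = X.T @ t / tt
        w_o = pv - B @ (B.T @ pv)
        norm = np.linalg.norm(w_o)
        if norm < 1e-10 * max(np.linalg.norm(pv), 1.0):
            break       # no structured Y-orthogonal variation left
        w_o /= norm
        t_o = X @ w_o
        p_o = X.T @ t_o / (t_o @ t_o)
        X -= np.outer(t_o, p_o)
        W_o = np.hstack([W_o, w_o[:, None]])
        P_o = np.hstack([P_o, p_o[:, None]])
        T_o = np.hstack([T_o, t_o[:, None]])
    W, P, Q = _pls2_nipals(X, Yc, n_predictive)
    T = _pls2_scores(W, P, X)
    return W_o, P_o, T_o, W, P, Q, T


def oplsda_fit(calibration: DataMatrix, n_predictive: int | None = None,
               n_orthogonal: int | str = "auto", n_groups: int = 7,
               seed: int = 0, max_orthogonal: int = 5) -> OPLSDAModel:
    """Fit OPLS-DA on a labelled calibration set.

    ``n_predictive`` defaults to K-1 for K classes.  With
    ``n_orthogonal="auto"`` orthogonal components are added while the
    cross-validated Q²Y improves by more than 0.01 (capped at
    ``max_orthogonal``).  Q²Y uses ``n_groups`` stratified cancellation
    groups; the same groups also provide the CV predictions for RMSECV.
    """
    if calibration.y is None:
        raise ParameterError("OPLS-DA needs class labels")
    K = len(calibration.classes)
    if K < 2:
        raise DegenerateDataError("OPLS-DA needs at least two classes")
    if n_predictive is None:
        n_predictive = K - 1
    if n_predictive < 1:
        raise ParameterError("need at least one predictive component")

    X = calibration.X
    Y = calibration.one_hot()
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xc = X - x_mean
    Yc = Y - y_mean
    ss_y = float(np.sum(Yc ** 2))
    groups = cancellation_groups(calibration.y, n_groups, seed)

    def cv_press(n_orth: int) -> tuple[float, np.ndarray]:
        yhat_cv = np.zeros_like(Y)
        for g in range(n_groups):
            held = groups == g
            sub = calibration.subset(~held)
            Xtr = sub.X
            Ytr = sub.one_hot()
            xm = Xtr.mean(axis=0)
            ym = Ytr.mean(axis=0)
            W_o, P_o, _, W, P, Q, _ = _fit_opls_core(
                Xtr - xm, Ytr - ym, n_predictive, n_orth)
            Xh = X[held] - xm
            for a in range(W_o.shape[1]):
                t_o = Xh @ W_o[:, a]
                Xh = Xh - np.outer(t_o, P_o[:, a])
            T = _pls2_scores(W, P, Xh)
            yhat_cv[held] = ym + T @ Q.T
        return float(np.sum((Y - yhat_cv) ** 2)), yhat_cv

    if n_orthogonal == "auto":
        press, yhat_cv = cv_press(0)
        chosen = 0
        for k in range(1, max_orthogonal + 1):
            press_k, yhat_k = cv_press(k)
            if (press - press_k) / ss_y > 0.01:
                press, yhat_cv, chosen = press_k, yhat_k, k
            else:
                break
        n_orth = chosen
    else:
        n_orth = int(n_orthogonal)
        if n_orth < 0:
            raise ParameterError("n_orthogonal must be >= 0")
        press, yhat_cv = cv_press(n_orth)

    W_o, P_o, T_o, W, P, Q, T = _fit_opls_core(Xc, Yc, n_predictive, n_orth)
    yhat = y_mean + T @ Q.T
    r2y = 1.0 - float(np.sum((Y - yhat) ** 2)) / ss_y
    q2y = 1.0 - press / ss_y
    ss_x = float(np.sum(Xc ** 2))
    modelled = 0.0
    for a in range(T_o.shape[1]):
        modelled += float(T_o[:, a] @ T_o[:, a]) * float(P_o[:, a] @ P_o[:, a])
    for a in range(T.shape[1]):
        modelled += float(T[:, a] @ T[:, a]) * float(P[:, a] @ P[:, a])
    r2x = modelled / ss_x if ss_x > 0 else 0.0
    return OPLSDAModel(
        classes=calibration.classes, x_mean=x_mean, y_mean=y_mean,
        w_orth=W_o, p_orth=P_o, t_orth=T_o,
        weights=W, x_loadings=P, y_loadings=Q, scores=T,
        r2x=r2x, r2y=r2y, q2y=q2y, cv_predictions=yhat_cv,
        n_groups=n_groups, seed=seed,
    )


def oplsda_predict(model: OPLSDAModel, query: DataMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Predicted labels and continuous Y-hat for query rows."""
    if query.n_features != model.x_mean.size:
        raise GridError("query feature grid does not match the fitted model")
    return model.predict_labels(query.X), model.predict_yhat(query.X)


# ---------------------------------------------------------------------------
# Error metrics, permutation test, classification statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RMSEMetrics:
    """RMSEE / RMSECV / RMSEP, averaged over response columns."""

    rmsee: float
    rmsecv: float
    rmsep: float
    per_column: pd.DataFrame | None = None


def rmse_metrics(model: OPLSDAModel, calibration: DataMatrix,
                 validation: DataMatrix,
                 cv_predictions: np.ndarray | None = None) -> RMSEMetrics:
    """Estimation, cross-validation and prediction errors of an OPLS-DA model.

    RMSEE uses the dof-corrected convention sqrt(SSres / (N - 1 - A)) with
    A = total fitted components (predictive + orthogonal); RMSECV and RMSEP
    are plain root mean squares of the CV and validation residuals.  All
    three are computed per response column and averaged.
    """
    A = model.n_predictive + model.n_orthogonal
    N = calibration.n_samples
    if N <= A + 1:
        raise ParameterError(f"RMSEE undefined: N={N} <= A+1={A + 1}")
    Y_cal = calibration.one_hot()
    yhat_cal = model.predict_yhat(calibration.X)
    res_cal = Y_cal - yhat_cal
    rmsee_cols = np.sqrt(np.sum(res_cal ** 2, axis=0) / (N - 1 - A))

    cv = cv_predictions if cv_predictions is not None else model.cv_predictions
    if cv is None:
        raise ParameterError("no cross-validation predictions available")
    res_cv = Y_cal - cv
    rmsecv_cols = np.sqrt(np.mean(res_cv ** 2, axis=0))

    Y_val = validation.one_hot()
    res_val = Y_val - model.predict_yhat(validation.X)
    rmsep_cols = np.sqrt(np.mean(res_val ** 2, axis=0))

    per_col = pd.DataFrame(
        {"RMSEE": rmsee_cols, "RMSECV": rmsecv_cols, "RMSEP": rmsep_cols},
        index=list(model.classes),
    )
    return RMSEMetrics(
        rmsee=float(np.mean(rmsee_cols)),
        rmsecv=float(np.mean(rmsecv_cols)),
        rmsep=float(np.mean(rmsep_cols)),
        per_column=per_col,
    )


@dataclass(frozen=True)
class PermutationResult:
    """Outcome of the label-permutation test for an OPLS-DA configuration."""

    r2y_intercept: float
    q2y_intercept: float
    table: pd.DataFrame          # correlation, r2y, q2y per permutation
    valid: bool                  # r2y-int < 0.3 and q2y-int < 0.05


def permutation_test(calibration: DataMatrix, n_permutations: int = 100,
                     seed: int = 0, n_predictive: int | None = None,
                     n_orthogonal: int = 0, n_groups: int = 7) -> PermutationResult:
    """Refit the OPLS-DA configuration on label-permuted data.

    Class labels are permuted jointly ``n_permutations`` times; for each
    permutation the model is refitted with the same component counts and
    (|correlation to the original Y|, R²Y, Q²Y) recorded.  Intercepts come
    from ordinary least-squares lines through all permutations plus the
    unpermuted point, evaluated at correlation 0.  The model is declared
    valid when the R²Y intercept is below 0.3 and the Q²Y intercept below
    0.05.
    """
    if n_permutations < 2:
        raise ParameterError("need at least 2 permutations")
    if calibration.y is None:
        raise ParameterError("permutation test needs class labels")
    rng = np.random.default_rng(seed)
    base = oplsda_fit(calibration, n_predictive=n_predictive,
                      n_orthogonal=n_orthogonal, n_groups=n_groups, seed=seed)
    Y0 = calibration.one_hot()
    Y0c = (Y0 - Y0.mean(axis=0)).ravel()
    norm0 = np.linalg.norm(Y0c)

    rows = [{"correlation": 1.0, "r2y": base.r2y, "q2y": base.q2y,
             "permuted": False}]
    n = calibration.n_samples
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        permuted = DataMatrix(X=calibration.X, y=calibration.y[perm],
                              grid=calibration.grid, classes=calibration.classes)
        Yp = permuted.one_hot()
        Ypc = (Yp - Yp.mean(axis=0)).ravel()
        corr = abs(float(Y0c @ Ypc) / (norm0 * np.linalg.norm(Ypc)))
        m = oplsda_fit(permuted, n_predictive=n_predictive,
                       n_orthogonal=n_orthogonal, n_groups=n_groups, seed=seed)
        rows.append({"correlation": corr, "r2y": m.r2y, "q2y": m.q2y,
                     "permuted": True})
    table = pd.DataFrame(rows)
    x = table["correlation"].to_numpy()
    design = np.column_stack([np.ones_like(x), x])
    r2_int = float(np.linalg.lstsq(design, table["r2y"].to_numpy(), rcond=None)[0][0])
    q2_int = float(np.linalg.lstsq(design, table["q2y"].to_numpy(), rcond=None)[0][0])
    return PermutationResult(
        r2y_intercept=r2_int, q2y_intercept=q2_int, table=table,
        valid=(r2_int < 0.3) and (q2_int < 0.05),
    )


@dataclass(frozen=True)
class ClassMetrics:
    """One-vs-rest sensitivity / specificity / accuracy in percent.

    Undefined ratios (zero denominator) are reported as NaN and flagged in
    ``undefined`` rather than silently zeroed.
    """

    sensitivity: float
    specificity: float
    accuracy: float
    undefined: tuple = ()


def confusion_matrix(y_true: Sequence, y_pred: Sequence,
                     classes: Sequence) -> np.ndarray:
    """Rows = true class, columns = predicted class, in the given order."""
    classes = list(classes)
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[classes.index(t), classes.index(p)] += 1
    return cm


def classification_metrics(confusion: np.ndarray, positive_index: int) -> ClassMetrics:
    """One-vs-rest metrics for one class of a confusion matrix."""
    cm = np.asarray(confusion)
    if cm.size == 0:
        raise ParameterError("empty confusion matrix")
    if np.any(cm < 0) or not np.issubdtype(cm.dtype, np.integer):
        raise ParameterError("confusion matrix must hold nonnegative integers")
    k = positive_index
    tp = cm[k, k]
    fn = cm[k].sum() - tp
    fp = cm[:, k].sum() - tp
    tn = cm.sum() - tp - fn - fp
    undefined = []
    if tp + fn > 0:
        sens = 100.0 * tp / (tp + fn)
    else:
        sens, undefined = float("nan"), undefined + ["sensitivity"]
    if tn + fp > 0:
        spec = 100.0 * tn / (tn + fp)
    else:
        spec, undefined = float("nan"), undefined + ["specificity"]
    acc = 100.0 * (tp + tn) / cm.sum()
    return ClassMetrics(sens, spec, acc, tuple(undefined))


def per_class_metrics(y_true: Sequence, y_pred: Sequence,
                      classes: Sequence) -> pd.DataFrame:
    """Per-class one-vs-rest metrics table (percent)."""
    cm = confusion_matrix(y_true, y_pred, classes)
    rows = {}
    for i, c in enumerate(classes):
        m = classification_metrics(cm, i)
        rows[c] = {"sensitivity": m.sensitivity, "specificity": m.specificity,
                   "accuracy": m.accuracy}
    return pd.DataFrame(rows).T
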