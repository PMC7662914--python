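"""Multivariate binary model of colony behavior (bloated vs. non-bloated).

The response is the bloated coverage percentage discretized at 50%.  The
predictor block has seven base variables — time of day as a unit fraction of
24 h, chlorophyll, temperature, depth, turbidity, salinity (continuous,
standardized on the training partition) and a binary field-of-view (FOV)
camera-geometry dummy — expanded into every unique monomial of degree <= 3
by multiplying columns combinatorially (squares and cubes included; powers
of the binary dummy collapse, since FOV^2 = FOV).  The number of features
actually used, k, is chosen where the cross-validation RMS error curve is
lowest.

The classifier is a single-hidden-layer feed-forward network: 9 sigmoid
hidden nodes and a 2-way softmax output, trained by minimizing a sum-of-
squares error with Bayesian regularization — an L2 weight penalty whose
strength is re-estimated from the evidence framework (MacKay/Foresee-Hagan
style Gauss-Newton updates of alpha and beta) — with a 1e-10 gradient
threshold.  The train/test split is a deterministic Kennard-Stone maximin
selection on Euclidean distances, not a random draw.

Interpretation tools: per-feature importance as the maximum absolute hidden
weight over nodes, and "activation profile" correlations — the Pearson r
between the sorted bloated percentages and the logistic sigmoid of the
smoothed, standardized environmental variable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations_with_replacement

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import pearsonr
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "CONTINUOUS_VARS", "BASE_VARS", "binarize", "Standardizer", "FeatureBlock",
    "expand_features", "enumerate_monomials", "partition_euclidean", "MlfnModel",
    "train_mlfn", "ConfusionMetrics", "confusion_metrics", "feature_importance",
    "sigmoid_profile", "select_feature_count", "fit_activity_model", "ActivityFit",
]

CONTINUOUS_VARS = ("hour_frac", "chlorophyll", "temperature", "depth", "turbidity", "salinity")
BASE_VARS = CONTINUOUS_VARS + ("fov",)


def binarize(bloated_pct):
    """1 where bloated coverage >= 50%, else 0; input must lie in [0, 100]."""
    arr = np.asarray(bloated_pct, dtype=float)
    if np.any(arr < 0) or np.any(arr > 100):
        raise ValueError("bloated percentage outside [0, 100]")
    out = (arr >= 50.0).astype(int)
    return int(out) if np.isscalar(bloated_pct) else out


@dataclass
class Standardizer:
    """Center/scale chosen columns; fit on the training partition only."""

    columns: tuple[int, ...]
    mean_: np.ndarray | None = None
    sd_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        cols = list(self.columns)
        self.mean_ = X[:, cols].mean(axis=0)
        sd = X[:, cols].std(axis=0, ddof=0)
        if np.any(sd == 0):
            raise ValueError("zero-variance continuous column; cannot standardize")
        self.sd_ = sd
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("Standardizer not fitted")
        X = np.asarray(X, dtype=float).copy()
        cols = list(self.columns)
        X[:, cols] = (X[:, cols] - self.mean_) / self.sd_
        return X


def enumerate_monomials(
    n_base: int = 7, max_degree: int = 3, binary_cols: tuple[int, ...] = (6,)
) -> list[tuple[int, ...]]:
    """Unique monomial provenances, degree-ascending then lexicographic.

    A provenance is the sorted tuple of base-column indices whose product
    forms the feature.  Powers of binary columns collapse (x^2 = x for a 0/1
    dummy), and the collapsed duplicates are dropped, keeping the first
    occurrence in enumeration order.
    """
    seen: set[tuple[int, ...]] = set()
    out: list[tuple[int, ...]] = []
    for deg in range(1, max_degree + 1):
        for combo in combinations_with_replacement(range(n_base), deg):
            canon: list[int] = []
            for i in combo:
                if i in binary_cols and i in canon:
                    continue  # idempotent dummy
                canon.append(i)
            key = tuple(canon)
            if key not in seen:
                seen.add(key)
                out.append(key)
    return out


@dataclass
class FeatureBlock:
    """Expanded predictor matrix with per-column provenance."""

    X: np.ndarray  # n x m
    provenance: tuple[tuple[int, ...], ...]
    names: tuple[str, ...]
    base_names: tuple[str, ...]

    def first_k(self, k: int) -> "FeatureBlock":
        if not 1 <= k <= self.X.shape[1]:
            raise ValueError(f"k={k} outside 1..{self.X.shape[1]}")
        return FeatureBlock(self.X[:, :k], self.provenance[:k], self.names[:k], self.base_names)


def _monomial_name(prov: tuple[int, ...], base_names) -> str:
    parts = []
    for idx in sorted(set(prov)):
        power = prov.count(idx)
        parts.append(base_names[idx] + (f"^{power}" if power > 1 else ""))
    return "*".join(parts)


def expand_features(
    X: np.ndarray,
    max_degree: int = 3,
    base_names: tuple[str, ...] = BASE_VARS,
    binary_cols: tuple[int, ...] = (6,),
) -> FeatureBlock:
    """All unique degree-<= max_degree monomials over the base columns."""
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in the base block")
    if X.shape[1] != len(base_names):
        raise ValueError(f"expected {len(base_names)} base columns, got {X.shape[1]}")
    provs = enumerate_monomials(X.shape[1], max_degree, binary_cols)
    cols = [np.prod(X[:, list(p)], axis=1) for p in provs]
    names = tuple(_monomial_name(p, base_names) for p in provs)
    return FeatureBlock(np.column_stack(cols), tuple(provs), names, tuple(base_names))


def partition_euclidean(X: np.ndarray, train_frac: float = 0.70) -> tuple[np.ndarray, np.ndarray]:
    """Kennard-Stone maximin split: training points cover the predictor space.

    Seeds with the two most distant points, then repeatedly adds the point
    whose minimal Euclidean distance to the selected set is largest, until
    ceil(train_frac * n) points are chosen.  Deterministic; ties resolve to
    the lowest index.
    """
    X = np.asarray(X, dtype=float)
    n = len(X)
    if n < 4:
        raise ValueError("need at least 4 observations to partition")
    n_train = int(np.ceil(train_frac * n))
    sq = (X**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2 * X @ X.T
    np.fill_diagonal(d2, 0.0)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)  # first max => lowest indices on ties
    selected = [min(i, j), max(i, j)]
    min_d2 = np.minimum(d2[selected[0]], d2[selected[1]])
    min_d2[selected] = -np.inf
    while len(selected) < n_train:
        nxt = int(np.argmax(min_d2))
        selected.append(nxt)
        min_d2 = np.minimum(min_d2, d2[nxt])
        min_d2[nxt] = -np.inf
    train = np.sort(np.asarray(selected))
    test = np.setdiff1d(np.arange(n), train)
    return train, test


# --------------------------------------------------------------------------
# the network
# --------------------------------------------------------------------------


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class MlfnModel:
    """Trained single-hidden-layer network with its regularization state."""

    w1: np.ndarray  # nodes x k
    b1: np.ndarray  # nodes
    w2: np.ndarray  # 2 x nodes
    b2: np.ndarray  # 2
    alpha: float  # weight-penalty strength
    beta: float  # data-misfit strength
    gamma: float  # effective number of parameters
    converged: bool
    bayes: bool  # evidence updates used (False = fixed-decay fallback)
    n_iter: int
    feature_names: tuple[str, ...] = ()
    provenance: tuple[tuple[int, ...], ...] = ()
    log: list = field(default_factory=list)

    @property
    def n_features(self) -> int:
        return self.w1.shape[1]

    def _forward(self, X: np.ndarray):
        H = expit(X @ self.w1.T + self.b1)
        P = _softmax(H @ self.w2.T + self.b2)
        return H, P

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """P(bloated) per observation (softmax output for class 1)."""
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features:
            raise ValueError(f"model expects {self.n_features} features, got {X.shape[1]}")
        return self._forward(X)[1][:, 1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(int)

    def rms_error(self, X: np.ndarray, y: np.ndarray) -> float:
        p = self.predict_proba(X)
        return float(np.sqrt(np.mean((p - np.asarray(y)) ** 2)))


def _pack(w1, b1, w2, b2):
    return np.concatenate([w1.ravel(), b1, w2.ravel(), b2])


def _unpack(theta, k, nodes, n_out=2):
    s0 = nodes * k
    w1 = theta[:s0].reshape(nodes, k)
    b1 = theta[s0 : s0 + nodes]
    w2 = theta[s0 + nodes : s0 + nodes + n_out * nodes].reshape(n_out, nodes)
    b2 = theta[s0 + nodes + n_out * nodes :]
    return w1, b1, w2, b2


def _sse_and_grad(theta, X, Y, alpha, beta, k, nodes):
    """F = beta * 0.5*SSE + alpha * 0.5*||theta||^2 and its gradient."""
    w1, b1, w2, b2 = _unpack(theta, k, nodes)
    H = expit(X @ w1.T + b1)
    P = _softmax(H @ w2.T + b2)
    R = P - Y
    e_d = 0.5 * float((R**2).sum())
    e_w = 0.5 * float(theta @ theta)
    # dE_D/dz_j = P_j * (r_j - r.P)
    dz = P * (R - (R * P).sum(axis=1, keepdims=True))
    gw2 = dz.T @ H
    gb2 = dz.sum(axis=0)
    dh = (dz @ w2) * H * (1 - H)
    gw1 = dh.T @ X
    gb1 = dh.sum(axis=0)
    grad = beta * _pack(gw1, gb1, gw2, gb2) + alpha * theta
    return beta * e_d + alpha * e_w, grad, e_d, e_w


def _residual_jacobian(theta, X, Y, k, nodes):
    """J[i*2+c, p] = d(P_ic - Y_ic)/d theta_p (Gauss-Newton building block)."""
    w1, b1, w2, b2 = _unpack(theta, k, nodes)
    n = len(X)
    H = expit(X @ w1.T + b1)
    P = _softmax(H @ w2.T + b2)
    G = H * (1 - H)  # n x nodes
    # S[i] = diag(P_i) - P_i P_i^T, 2x2 per sample
    S = np.einsum("ic,cd->icd", P, np.eye(2)) - np.einsum("ic,id->icd", P, P)
    SW = np.einsum("icd,dm->icm", S, w2)  # n x 2 x nodes
    T = SW * G[:, None, :]  # chain through the sigmoid
    Jw1 = np.einsum("icm,il->icml", T, X).reshape(n, 2, nodes * k)
    Jb1 = T
    Jw2 = np.einsum("icd,im->icdm", S, H).reshape(n, 2, 2 * nodes)
    Jb2 = S
    J = np.concatenate([Jw1, Jb1, Jw2.reshape(n, 2, -1), Jb2], axis=2)
    return J.reshape(2 * n, -1)


def train_mlfn(
    X: np.ndarray,
    y: np.ndarray,
    nodes: int = 9,
    max_iter: int = 500,
    grad_tol: float = 1e-10,
    seed: int = 0,
    bayes: bool = True,
    noise_update: bool = False,
    fixed_decay: float = 1e-3,
    feature_names: tuple[str, ...] = (),
    provenance: tuple[tuple[int, ...], ...] = (),
) -> MlfnModel:
    """Fit the network by Bayesian-regularized sum-of-squares minimization.

    Outer evidence iterations re-estimate the weight-prior strength alpha
    from the Gauss-Newton Hessian (effective parameter count gamma); the
    inner problem is solved with L-BFGS.  By default the noise scale beta
    stays fixed at 1, the classification form of the evidence framework:
    0/1 targets behind a softmax have no free noise variance, and letting
    beta float rewards driving the residuals to zero — memorizing label
    noise.  ``noise_update=True`` enables the regression-style joint
    (alpha, beta) update for completeness.  If the evidence update turns
    ill-conditioned (non-finite or non-positive gamma), the model falls back
    to a fixed weight decay of ``fixed_decay`` and records that in
    ``bayes``/``log``.  Returns the model even when the gradient threshold
    was not reached, flagged via ``converged``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("X must be n x k with k >= 1")
    k = X.shape[1]
    Y = np.eye(2)[y]
    rng = np.random.default_rng(seed)
    theta = rng.normal(0, 0.5 / np.sqrt(k), nodes * k + nodes + 2 * nodes + 2)
    n_params = theta.size

    if len(np.unique(y)) < 2:
        warnings.warn("constant response; returning a trivial constant classifier")

    alpha, beta = (0.01, 1.0) if bayes else (fixed_decay, 1.0)
    n_outer = 5 if bayes else 1
    inner_iter = max(20, max_iter // n_outer)
    log: list[dict] = []
    used_bayes = bayes
    total_nit = 0
    gamma = float(n_params)
    inner_converged = False

    for outer in range(n_outer):
        res = minimize(
            _sse_and_grad, theta, args=(X, Y, alpha, beta, k, nodes),
            jac=True, method="L-BFGS-B",
            options={"maxiter": inner_iter, "gtol": grad_tol},
        )
        theta = res.x
        total_nit += res.nit
        inner_converged = bool(res.status == 0)
        _, grad, e_d, e_w = _sse_and_grad(theta, X, Y, alpha, beta, k, nodes)
        log.append({"outer": outer, "alpha": alpha, "beta": beta,
                    "sse": 2 * e_d, "wnorm": 2 * e_w, "nit": int(res.nit)})
        if not bayes or outer == n_outer - 1:
            break
        J = _residual_jacobian(theta, X, Y, k, nodes)
        try:
            eig = np.linalg.eigvalsh(J.T @ J)
            eig = np.clip(eig, 0.0, None)
            tr_hinv = float(np.sum(1.0 / (beta * eig + alpha)))
            gamma = n_params - alpha * tr_hinv
            if not np.isfinite(gamma) or gamma <= 0 or e_w <= 0:
                raise np.linalg.LinAlgError("ill-conditioned evidence update")
            alpha_new = gamma / (2 * e_w)
            if noise_update:
                m_terms = Y.size
                beta_new = max(1e-8, (m_terms - gamma)) / (2 * max(e_d, 1e-12))
            else:
                beta_new = beta
            if not (np.isfinite(alpha_new) and np.isfinite(beta_new)):
                raise np.linalg.LinAlgError("non-finite hyperparameters")
            alpha, beta = float(alpha_new), float(beta_new)
        except np.linalg.LinAlgError as exc:
            used_bayes = False
            alpha, beta = fixed_decay, 1.0
            log.append({"outer": outer, "fallback": str(exc)})

    grad_norm = float(np.max(np.abs(grad)))
    converged = inner_converged or grad_norm <= max(grad_tol, 1e-6)
    if not converged:
        warnings.warn(f"MLFN training hit the iteration cap at gradient {grad_norm:.2e}")
    w1, b1, w2, b2 = _unpack(theta, k, nodes)
    return MlfnModel(w1, b1, w2, b2, alpha, beta, float(gamma), converged, used_bayes,
                     total_nit, tuple(feature_names), tuple(provenance), log)


# --------------------------------------------------------------------------
# metrics and interpretation
# --------------------------------------------------------------------------


def _trunc3(v: float) -> float:
    return np.trunc(v * 1000) / 1000.0


@dataclass
class ConfusionMetrics:
    """2x2 confusion summary; targets on rows, positive class = bloated."""

    confusion: np.ndarray  # rows: (bloated, non-bloated) targets
    precision: float
    recall: float
    pct_bad: float
    n_bad: int

    @classmethod
    def from_matrix(cls, conf: np.ndarray) -> "ConfusionMetrics":
        conf = np.asarray(conf, dtype=int)
        if conf.shape != (2, 2):
            raise ValueError("confusion matrix must be 2x2")
        tp, fn = conf[0]
        fp, tn = conf[1]
        n = conf.sum()
        precision = tp / (tp + fp) if tp + fp else np.nan
        recall = tp / (tp + fn) if tp + fn else np.nan
        n_bad = int(fn + fp)
        return cls(conf, float(precision), float(recall), 100.0 * n_bad / n, n_bad)

    @property
    def precision_3dp(self) -> float:
        """Precision truncated (not rounded) to 3 decimals, the printing convention."""
        return _trunc3(self.precision)

    @property
    def recall_3dp(self) -> float:
        return _trunc3(self.recall)

    def summary(self) -> str:
        c = self.confusion
        return (
            "              pred blo  pred non\n"
            f"target blo    {c[0,0]:8d}  {c[0,1]:8d}\n"
            f"target non    {c[1,0]:8d}  {c[1,1]:8d}\n"
            f"P={self.precision_3dp:.3f}  R={self.recall_3dp:.3f}  "
            f"bad={self.n_bad} ({self.pct_bad:.1f}%)"
        )


def confusion_metrics(y_true, y_pred) -> ConfusionMetrics:
    """Confusion matrix with targets on rows (bloated row first) and P/R/%bad."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if len(y_true) == 0:
        raise ValueError("empty input")
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch")
    conf = np.array([
        [np.sum((y_true == 1) & (y_pred == 1)), np.sum((y_true == 1) & (y_pred == 0))],
        [np.sum((y_true == 0) & (y_pred == 1)), np.sum((y_true == 0) & (y_pred == 0))],
    ])
    return ConfusionMetrics.from_matrix(conf)


def interval_error_summary(
    bloated_pct, correct, interval: tuple[float, float] = (20.0, 80.0)
) -> dict[str, float]:
    """Where do the misclassifications sit relative to the ambiguous mid-range?

    Splits observations at the ``interval`` of bloated coverage (by default
    20-80%, where the colony is in a genuinely mixed state) and reports how
    the classification errors distribute: the share of all errors falling in
    the interval, the error rate inside it, and the error rate outside it.
    A strongly bimodal behavior shows up as a low outside-interval error rate.
    """
    b = np.asarray(bloated_pct, dtype=float)
    ok = np.asarray(correct, dtype=bool)
    if len(b) != len(ok) or len(b) == 0:
        raise ValueError("bloated_pct and correct must be equal-length and non-empty")
    lo, hi = interval
    mid = (b >= lo) & (b <= hi)
    err = ~ok
    n_err = int(err.sum())
    out = {
        "n": len(b),
        "n_interval": int(mid.sum()),
        "n_errors": n_err,
        "pct_obs_in_interval": 100.0 * mid.mean(),
        "pct_errors_in_interval": 100.0 * err[mid].sum() / n_err if n_err else np.nan,
        "error_rate_in_interval_pct": 100.0 * err[mid].mean() if mid.any() else np.nan,
        "error_rate_outside_pct": 100.0 * err[~mid].mean() if (~mid).any() else np.nan,
    }
    return out


def feature_importance(model: MlfnModel, top: int = 15) -> pd.DataFrame:
    """Rank features by the largest absolute hidden weight they receive.

    importance(j) = max over hidden nodes of |W1[node, j]|; descending, ties
    broken by column index.  Returns the ``top`` rows with provenance labels.
    """
    imp = np.abs(model.w1).max(axis=0)
    order = np.lexsort((np.arange(len(imp)), -imp))
    names = model.feature_names or tuple(f"x{j}" for j in range(len(imp)))
    provs = model.provenance or tuple((j,) for j in range(len(imp)))
    df = pd.DataFrame({
        "rank": np.arange(1, len(order) + 1),
        "feature": [names[j] for j in order],
        "column": order,
        "importance": imp[order],
        "provenance": [provs[j] for j in order],
    })
    return df.head(top).reset_index(drop=True)


def sigmoid_profile(bloated_pct, variable, smooth_window: int = 25) -> tuple[float, float]:
    """Activation-profile correlation of one environmental variable.

    Observations are sorted by increasing bloated percentage; the variable is
    standardized, smoothed with a centered moving average of ``smooth_window``
    samples, mapped through the logistic sigmoid, and correlated (Pearson)
    with the sorted bloated percentages.  Returns (r, p); (nan, nan) with a
    warning when the smoothed profile has no variance.
    """
    b = np.asarray(bloated_pct, dtype=float)
    v = np.asarray(variable, dtype=float)
    keep = np.isfinite(b) & np.isfinite(v)
    b, v = b[keep], v[keep]
    if len(b) < 3:
        raise ValueError("need at least 3 paired finite observations")
    order = np.argsort(b, kind="stable")
    b, v = b[order], v[order]
    sd = v.std()
    if sd == 0:
        warnings.warn("variable has zero variance; r undefined")
        return float("nan"), float("nan")
    z = (v - v.mean()) / sd
    w = max(1, min(smooth_window, len(z)))
    # centered moving average with shrinking windows at the edges (a plain
    # zero-padded convolution would bias the profile ends toward sigma(0))
    half = w // 2
    csum = np.cumsum(np.r_[0.0, z])
    idx = np.arange(len(z))
    lo = np.maximum(0, idx - half)
    hi = np.minimum(len(z), idx + half + 1)
    sm = (csum[hi] - csum[lo]) / (hi - lo)
    sig = expit(sm)
    if np.ptp(sig) == 0 or np.ptp(b) == 0:
        warnings.warn("degenerate profile after smoothing; r undefined")
        return float("nan"), float("nan")
    r, p = pearsonr(b, sig)
    return float(r), float(p)


def select_feature_count(
    Xexp: FeatureBlock | np.ndarray,
    y: np.ndarray,
    ks,
    cv_folds: int = 5,
    seed: int = 0,
    nodes: int = 9,
    max_iter: int = 80,
) -> tuple[int, pd.DataFrame]:
    """Cross-validated RMS error versus feature count; returns (k*, curve).

    For each candidate k the network is trained on the first k columns in
    enumeration order; the reported RMS is the mean validation RMS over the
    stratified folds.  k* is the argmin (first on ties).
    """
    X = Xexp.X if isinstance(Xexp, FeatureBlock) else np.asarray(Xexp)
    y = np.asarray(y, dtype=int)
    ks = [int(k) for k in ks]
    if any(k < 1 or k > X.shape[1] for k in ks):
        raise ValueError(f"ks must lie in 1..{X.shape[1]}")
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    rows = []
    for k in ks:
        errs = []
        for fold, (tr, va) in enumerate(skf.split(X, y)):
            model = train_mlfn(X[tr, :k], y[tr], nodes=nodes, max_iter=max_iter,
                               seed=seed + fold, bayes=False)
            errs.append(model.rms_error(X[va, :k], y[va]))
        rows.append({"k": k, "cv_rms": float(np.mean(errs)), "cv_rms_sd": float(np.std(errs))})
    curve = pd.DataFrame(rows)
    k_star = int(curve.loc[curve["cv_rms"].idxmin(), "k"])
    return k_star, curve


# --------------------------------------------------------------------------
# end-to-end activity model
# --------------------------------------------------------------------------


@dataclass
class ActivityFit:
    """Everything the behavior model produced on one series."""

    model: MlfnModel
    k: int
    train_idx: np.ndarray
    test_idx: np.ndarray
    train_metrics: ConfusionMetrics
    test_metrics: ConfusionMetrics
    importance: pd.DataFrame
    rms_curve: pd.DataFrame | None
    standardizer: Standardizer

    def summary(self) -> str:
        lines = [
            f"MLFN activity model: k={self.k} features, "
            f"{self.model.w1.shape[0]} hidden nodes, "
            f"{'Bayesian' if self.model.bayes else 'fixed-decay'} regularization",
            f"train n={len(self.train_idx)}  " + self.train_metrics.summary().splitlines()[-1],
            f"test  n={len(self.test_idx)}  " + self.test_metrics.summary().splitlines()[-1],
            "top features: " + ", ".join(self.importance["feature"].head(5)),
        ]
        return "\n".join(lines)


def build_base_block(series: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Extract (X_base, y) from an activity series DataFrame.

    Expects a DatetimeIndex plus columns ``bloated_pct``, ``chl_fluorescence``
    (or ``chl_a``), ``temperature_C``, ``depth_m``, ``turbidity_NTU``,
    ``salinity_PSU`` and optionally ``fov`` (defaults to 0).  Rows with any
    missing predictor are dropped, mirroring the exclusion of behavioral
    records that fall inside sensor gaps.
    """
    if not isinstance(series.index, pd.DatetimeIndex):
        raise TypeError("series must be indexed by timestamp")
    chl = series["chl_a"] if "chl_a" in series.columns else series["chl_fluorescence"]
    hour_frac = (series.index.hour * 60 + series.index.minute) / (24.0 * 60)
    fov = series["fov"] if "fov" in series.columns else pd.Series(0, index=series.index)
    X = np.column_stack([
        hour_frac, chl, series["temperature_C"], series["depth_m"],
        series["turbidity_NTU"], series["salinity_PSU"], fov,
    ]).astype(float)
    y = binarize(series["bloated_pct"].to_numpy())
    keep = np.all(np.isfinite(X), axis=1)
    return X[keep], y[keep]


def fit_activity_model(
    series: pd.DataFrame,
    k: int | None = None,
    ks=None,
    nodes: int = 9,
    train_frac: float = 0.70,
    max_degree: int = 3,
    max_iter: int = 500,
    seed: int = 0,
) -> ActivityFit:
    """Run the full multivariate procedure on an activity series.

    Pipeline: base block -> Kennard-Stone 70/30 partition (on a whole-set
    standardized copy, geometry only) -> standardization fit on the training
    rows -> monomial expansion -> optional CV choice of k -> Bayesian-
    regularized training -> train/test confusion metrics and importances.
    """
    X_base, y = build_base_block(series)
    cont = tuple(range(len(CONTINUOUS_VARS)))

    geom = Standardizer(cont).fit(X_base).transform(X_base)
    train_idx, test_idx = partition_euclidean(geom, train_frac)

    std = Standardizer(cont).fit(X_base[train_idx])
    Xtr = expand_features(std.transform(X_base[train_idx]), max_degree)
    Xte = expand_features(std.transform(X_base[test_idx]), max_degree)

    rms_curve = None
    if k is None:
        if ks is None:
            m = Xtr.X.shape[1]
            ks = sorted({7, 14, 28, 49, 77, m} & set(range(1, m + 1))) or [m]
        k, rms_curve = select_feature_count(Xtr, y[train_idx], ks, seed=seed)

    blk_tr, blk_te = Xtr.first_k(k), Xte.first_k(k)
    model = train_mlfn(blk_tr.X, y[train_idx], nodes=nodes, max_iter=max_iter, seed=seed,
                       feature_names=blk_tr.names, provenance=blk_tr.provenance)
    tr_m = confusion_metrics(y[train_idx], model.predict(blk_tr.X))
    te_m = confusion_metrics(y[test_idx], model.predict(blk_te.X))
    imp = feature_importance(model)
    return ActivityFit(model, k, train_idx, test_idx, tr_m, te_m, imp, rms_curve, std)
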