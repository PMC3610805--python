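"""The per-gene expression predictors: single best-SNP, elastic net, KNN.

All models share a fit/predict contract over a training genotype matrix
``X`` (minor-allele counts, individuals x cis-SNPs) and a centered
expression vector ``y``:

* **single best-SNP** — ordinary least squares on the one SNP with the
  highest absolute Pearson correlation to expression in the training set;
* **elastic net** — L1/L2-penalized linear regression over all cis-SNPs,
  penalty strength chosen by internal cross-validation on the training set;
* **KNN** — predicts an individual as the unweighted mean expression of its
  ``k`` nearest training neighbors under a weighted L1 genotype distance
  (all-ones weights for the simple variant; learned feature-induced weights
  for the extended variant in :mod:`cisxpred.metric_learning`), ``k`` chosen
  to maximize leave-one-out R-squared inside the training set;
* **combined** — the element-wise mean of the KNN and elastic-net
  predictions.

Neighbor ties at the k-th rank are broken by ascending training-individual
index, so runs are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import enet_path
from sklearn.model_selection import KFold

__all__ = [
    "SingleSnpModel",
    "ElasticNetModel",
    "KnnModel",
    "GeneFitResult",
    "fit_single_best_snp",
    "predict_single_snp",
    "fit_elastic_net",
    "predict_linear",
    "knn_distance_matrix",
    "fit_simple_knn",
    "predict_knn",
    "combine_predictions",
]


@dataclasses.dataclass
class SingleSnpModel:
    snp_index: int
    snp_id: Optional[str]
    slope: float
    intercept: float
    train_corr: float  # Pearson r of the chosen SNP on the training set
    train_r2: float  # in-sample R-squared of the OLS line


@dataclasses.dataclass
class ElasticNetModel:
    snp_weights: np.ndarray
    intercept: float
    lam: float  # selected penalty strength
    l1_ratio: float
    train_r2_cv: float  # mean internal-validation R-squared at the chosen lambda
    lambda_grid: np.ndarray


@dataclasses.dataclass
class KnnModel:
    k: int
    snp_weights: np.ndarray
    train_X: np.ndarray
    train_y: np.ndarray
    train_r2: float  # leave-one-out R-squared at the selected k
    loo_r2_by_k: Optional[np.ndarray] = None
    k_grid: Optional[np.ndarray] = None
    alpha: Optional[np.ndarray] = None  # genomic-feature weights (extended KNN)
    mrc_history: Optional[list] = None


@dataclasses.dataclass
class GeneFitResult:
    """One gene x model x fold outcome of a cross-validation run."""

    gene_id: str
    model_name: str
    scheme: str
    fold_id: str
    train_r2: float
    test_r2: float
    predictions: dict  # test individual id -> predicted expression
    params: dict


# ---------------------------------------------------------------------------
# single best-SNP


def _pearson_by_column(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of each SNP column with y; zero-variance columns get r = 0."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc.T @ yc) / (sx * sy)
    r[~np.isfinite(r)] = 0.0
    return r


def fit_single_best_snp(
    X: np.ndarray, y: np.ndarray, snp_ids: Optional[Sequence[str]] = None
) -> SingleSnpModel:
    """OLS on the cis-SNP most correlated (in absolute value) with y.

    Ties in |r| resolve to the lower SNP index. Raises if every SNP is
    constant on the training set or fewer than 3 individuals are given.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 training individuals")
    if np.std(y) == 0:
        raise ValueError("degenerate expression vector (zero variance)")
    r = _pearson_by_column(X, y)
    if (X.std(axis=0) == 0).all():
        raise ValueError("no informative SNP: all cis-SNPs constant in training set")
    j = int(np.argmax(np.abs(r)))  # first max -> lowest index on ties
    x = X[:, j]
    slope = float(np.cov(x, y, bias=True)[0, 1] / np.var(x))
    intercept = float(y.mean() - slope * x.mean())
    pred = intercept + slope * x
    ss_tot = float(((y - y.mean()) ** 2).sum())
    train_r2 = 1.0 - float(((y - pred) ** 2).sum()) / ss_tot
    return SingleSnpModel(
        snp_index=j,
        snp_id=snp_ids[j] if snp_ids is not None else None,
        slope=slope,
        intercept=intercept,
        train_corr=float(r[j]),
        train_r2=train_r2,
    )


def predict_single_snp(model: SingleSnpModel, X: np.ndarray) -> np.ndarray:
    return model.intercept + model.slope * np.asarray(X, dtype=float)[:, model.snp_index]


# ---------------------------------------------------------------------------
# elastic net


def lambda_grid(
    X: np.ndarray,
    y: np.ndarray,
    l1_ratio: float = 0.5,
    n_lambdas: int = 50,
    eps: float = 1e-3,
) -> np.ndarray:
    """Log-spaced penalty grid from the data-driven maximum down by ``eps``.

    The maximum is the smallest penalty at which every coefficient is zero,
    ``max|X_c' y_c| / (n * l1_ratio)`` with centered X and y.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    lam_max = float(np.max(np.abs(Xc.T @ yc))) / (len(y) * max(l1_ratio, 1e-3))
    lam_max = max(lam_max, 1e-12)
    return np.geomspace(lam_max, lam_max * eps, n_lambdas)


def _path_predictions(
    X_tr: np.ndarray, y_tr: np.ndarray, X_ev: np.ndarray, lambdas: np.ndarray,
    l1_ratio: float,
) -> np.ndarray:
    """Coordinate-descent path fit on (X_tr, y_tr); predictions on X_ev.

    Returns an (n_eval, n_lambdas) array, columns in the order of ``lambdas``
    (which must be decreasing).
    """
    mu_x = X_tr.mean(axis=0)
    mu_y = y_tr.mean()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        _, coefs, _ = enet_path(
            X_tr - mu_x, y_tr - mu_y, l1_ratio=l1_ratio, alphas=lambdas,
            max_iter=3000,
        )
    return (X_ev - mu_x) @ coefs + mu_y


def fit_elastic_net(
    X: np.ndarray,
    y: np.ndarray,
    internal_folds: int = 5,
    l1_ratio: float = 0.5,
    seed: int = 0,
    lambdas: Optional[np.ndarray] = None,
) -> ElasticNetModel:
    """Elastic net with the penalty chosen by internal cross-validation.

    The training set is split into ``internal_folds`` learning/validation
    folds; the penalty maximizing the mean validation R-squared over the grid
    is selected (ties go to the stronger penalty) and the final weights are
    refit on the full training set at that penalty. ``train_r2_cv`` is the
    mean validation R-squared — an honest, not in-sample, training score.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if np.std(y) == 0:
        raise ValueError("degenerate expression vector (zero variance)")
    if n < internal_folds:
        raise ValueError("need at least as many training individuals as internal folds")
    if lambdas is None:
        lambdas = lambda_grid(X, y, l1_ratio=l1_ratio)
    lambdas = np.sort(np.asarray(lambdas, dtype=float))[::-1]

    kf = KFold(n_splits=internal_folds, shuffle=True, random_state=seed)
    val_r2 = np.full((internal_folds, len(lambdas)), np.nan)
    for f, (tr, va) in enumerate(kf.split(X)):
        if np.std(y[va]) == 0:
            continue  # validation R-squared undefined; fold carries no signal
        preds = _path_predictions(X[tr], y[tr], X[va], lambdas, l1_ratio)
        resid = (y[va][:, None] - preds) ** 2
        ss_tot = float(((y[va] - y[va].mean()) ** 2).sum())
        val_r2[f] = 1.0 - resid.sum(axis=0) / ss_tot
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_r2 = np.nanmean(val_r2, axis=0)
    if np.isnan(mean_r2).all():
        raise ValueError("internal cross-validation produced no usable folds")
    best = int(np.nanargmax(mean_r2))  # first max -> largest lambda on ties
    lam = float(lambdas[best])

    mu_x = X.mean(axis=0)
    mu_y = y.mean()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        _, coefs, _ = enet_path(
            X - mu_x, y - mu_y, l1_ratio=l1_ratio, alphas=lambdas, max_iter=3000
        )
    w = coefs[:, best]
    intercept = float(mu_y - mu_x @ w)
    return ElasticNetModel(
        snp_weights=w,
        intercept=intercept,
        lam=lam,
        l1_ratio=l1_ratio,
        train_r2_cv=float(mean_r2[best]),
        lambda_grid=lambdas,
    )


def predict_linear(model: ElasticNetModel, X: np.ndarray) -> np.ndarray:
    return np.asarray(X, dtype=float) @ model.snp_weights + model.intercept


# ---------------------------------------------------------------------------
# KNN


def knn_distance_matrix(
    X_a: np.ndarray, X_b: np.ndarray, snp_weights: Optional[np.ndarray] = None
) -> np.ndarray:
    """Weighted L1 genotype distance, d_ab = sum_i w_i |X_ai - X_bi|.

    Weights must be non-negative; ``None`` means all-ones (the simple-KNN
    metric, integral on {0,1,2} genotypes).
    """
    X_a = np.asarray(X_a, dtype=float)
    X_b = np.asarray(X_b, dtype=float)
    if X_a.shape[1] != X_b.shape[1]:
        raise ValueError("SNP dimension mismatch")
    if snp_weights is None:
        return cdist(X_a, X_b, metric="cityblock")
    w = np.asarray(snp_weights, dtype=float)
    if w.shape != (X_a.shape[1],):
        raise ValueError("snp_weights length must equal SNP count")
    if (w < 0).any():
        raise ValueError("snp_weights must be non-negative")
    return cdist(X_a * w, X_b * w, metric="cityblock")


def _neighbor_order(D: np.ndarray) -> np.ndarray:
    """Row-wise neighbor ranking; distance ties break by ascending column index."""
    return np.argsort(D, axis=1, kind="stable")


def loo_r2_by_k(D: np.ndarray, y: np.ndarray, k_grid: np.ndarray) -> np.ndarray:
    """Leave-one-out training R-squared for each candidate k.

    ``D`` is the train-train distance matrix; each individual is predicted
    from its k nearest *other* training individuals.
    """
    n = len(y)
    Dm = D.astype(float, copy=True)
    np.fill_diagonal(Dm, np.inf)
    order = _neighbor_order(Dm)[:, : n - 1]
    neigh_y = y[order]
    cums = np.cumsum(neigh_y, axis=1)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    out = np.empty(len(k_grid))
    for i, k in enumerate(k_grid):
        pred = cums[:, k - 1] / k
        out[i] = 1.0 - float(((y - pred) ** 2).sum()) / ss_tot
    return out


def fit_simple_knn(
    X: np.ndarray,
    y: np.ndarray,
    k_grid: Optional[Sequence[int]] = None,
    snp_weights: Optional[np.ndarray] = None,
    k_max: int = 50,
) -> KnnModel:
    """Select k by exhaustive leave-one-out search inside the training set.

    The default grid is 1..min(k_max, N_train - 1); ties in leave-one-out
    R-squared resolve to the smallest k.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 training individuals")
    if np.std(y) == 0:
        raise ValueError("degenerate expression vector (zero variance)")
    if k_grid is None:
        k_grid = np.arange(1, min(k_max, n - 1) + 1)
    k_grid = np.asarray(k_grid, dtype=int)
    if (k_grid < 1).any() or (k_grid > n - 1).any():
        raise ValueError("k grid must lie in [1, N_train - 1]")
    w = np.ones(X.shape[1]) if snp_weights is None else np.asarray(snp_weights, float)
    D = knn_distance_matrix(X, X, w)
    r2 = loo_r2_by_k(D, y, k_grid)
    best = int(np.argmax(r2))  # first max -> smallest k on ties
    return KnnModel(
        k=int(k_grid[best]),
        snp_weights=w,
        train_X=X,
        train_y=y,
        train_r2=float(r2[best]),
        loo_r2_by_k=r2,
        k_grid=k_grid,
    )


def predict_knn(model: KnnModel, X_test: np.ndarray) -> np.ndarray:
    """Mean training expression of each test individual's k nearest neighbors."""
    X_test = np.asarray(X_test, dtype=float)
    n_train = model.train_X.shape[0]
    if model.k > n_train:
        raise ValueError(f"k={model.k} exceeds training-set size {n_train}")
    if X_test.shape[1] != model.train_X.shape[1]:
        raise ValueError("test genotype SNP dimension mismatch")
    D = knn_distance_matrix(X_test, model.train_X, model.snp_weights)
    order = _neighbor_order(D)[:, : model.k]
    return model.train_y[order].mean(axis=1)


def combine_predictions(pred_knn: np.ndarray, pred_linear: np.ndarray) -> np.ndarray:
    """Element-wise mean of the two multi-SNP models' predictions."""
    a = np.asarray(pred_knn, dtype=float)
    b = np.asarray(pred_linear, dtype=float)
    if a.shape != b.shape:
        raise ValueError("prediction vectors have different lengths")
    return 0.5 * (a + b)
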