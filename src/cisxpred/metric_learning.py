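"""Extended KNN (KNN-IGF): learn genomic-feature weights for the SNP metric.

Instead of weighting every cis-SNP equally, the extended KNN assigns each
genomic feature a coefficient ``alpha_m``; a SNP's weight in the L1 distance
is the feature-weighted sum ``w_i = sum_m alpha_m f_im`` of its annotations.
Because every coefficient is shared across all SNPs carrying the feature,
the number of free parameters is the number of features, not of SNPs,
which limits overfitting.

The coefficients are learned by a greedy search maximizing the
metric-to-response correlation (MRC): the Pearson correlation, over all
unordered pairs of training individuals, between the pairwise genotype
distance under the metric and the absolute difference in expression. The
MRC is independent of k; the number of neighbors is selected afterwards by
the same leave-one-out sweep as the simple KNN, which decouples metric
learning from neighbor-count selection.

The search keeps a pool of candidate coefficient vectors. It starts from
the M one-hot vectors (one per feature), and in each iteration keeps the
``r_max`` best by MRC and forms all ``r_max**2`` pairwise combinations
(including self-pairs) as the next pool. A combination is the objective-
weighted convex mix of the two parents, so good predictors dominate mixes
with mediocre ones; because self-pairs reproduce each parent exactly, the
best objective in the pool can never decrease. Iteration stops when the
best objective stops improving.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import List, Optional, Tuple

import numpy as np
from scipy.stats import rankdata

from .models import KnnModel, fit_simple_knn, knn_distance_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "Predictor",
    "MetricLearningConfig",
    "induced_snp_weights",
    "mrc_objective",
    "combine_predictors",
    "greedy_metric_learning",
    "fit_knn_igf",
]

_EPS_WEIGHT = 1e-6  # floor for non-positive objectives in combinations


@dataclasses.dataclass
class Predictor:
    """One member of the greedy search's pool: coefficients and their MRC."""

    alpha: np.ndarray  # length-M genomic-feature coefficients
    objective: float  # MRC value on the training data, in [-1, 1]

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        if not self.alpha.any():
            raise ValueError("predictor coefficients must not be all zero")


@dataclasses.dataclass
class MetricLearningConfig:
    r_max: int = 5  # pool truncation size; pool of r_max**2 per iteration
    max_iterations: int = 50
    convergence_tol: float = 1e-6
    correlation: str = "pearson"  # or "spearman"
    standardize_features: bool = False
    k_max: int = 50

    def __post_init__(self) -> None:
        if self.r_max < 1:
            raise ValueError("r_max must be >= 1")


def induced_snp_weights(alpha: np.ndarray, F_gene: np.ndarray) -> np.ndarray:
    """SNP weights from feature coefficients: w_i = sum_m alpha_m f_im.

    Negative induced weights are clamped to zero — the weights enter an L1
    metric, which is only a metric for non-negative weights.
    """
    alpha = np.asarray(alpha, dtype=float)
    F_gene = np.asarray(F_gene, dtype=float)
    if F_gene.ndim != 2 or F_gene.shape[1] != alpha.shape[0]:
        raise ValueError(
            f"feature matrix {F_gene.shape} incompatible with alpha length {alpha.shape[0]}"
        )
    return np.clip(F_gene @ alpha, 0.0, None)


def _pair_upper(v: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    n = v.shape[0]
    return np.triu_indices(n, k=1)


def mrc_objective(
    distance_matrix: np.ndarray, y: np.ndarray, correlation: str = "pearson"
) -> float:
    """Metric-to-response correlation over all unordered individual pairs.

    Correlates d_ab with |y_a - y_b| for a < b; +1 means individuals close
    under the metric are close in expression. A degenerate pair vector
    (zero variance in distances or response gaps) returns 0 with a log
    warning — a constant metric carries no information.
    """
    D = np.asarray(distance_matrix, dtype=float)
    y = np.asarray(y, dtype=float)
    if D.shape[0] != D.shape[1] or D.shape[0] != y.shape[0]:
        raise ValueError("distance matrix and y are inconsistent")
    if y.shape[0] < 3:
        raise ValueError("need at least 3 individuals")
    iu = _pair_upper(y)
    dv = D[iu]
    gv = np.abs(y[iu[0]] - y[iu[1]])
    return _mrc_from_pairs(dv, gv, correlation)


def _mrc_from_pairs(dv: np.ndarray, gv: np.ndarray, correlation: str) -> float:
    if correlation == "spearman":
        dv = rankdata(dv)
        gv = rankdata(gv)
    elif correlation != "pearson":
        raise ValueError(f"unknown correlation {correlation!r}")
    sd, sg = dv.std(), gv.std()
    if sd == 0.0 or sg == 0.0:
        logger.warning("degenerate metric or response in MRC; returning 0")
        return 0.0
    dv = dv - dv.mean()
    gv = gv - gv.mean()
    return float((dv @ gv) / (np.sqrt(dv @ dv) * np.sqrt(gv @ gv)))


def combine_predictors(p_i: Predictor, p_j: Predictor) -> np.ndarray:
    """Objective-weighted convex combination of two coefficient vectors.

    Weights are the parents' objective values floored at a small positive
    epsilon (so non-positive objectives never flip signs); self-combination
    reproduces the parent exactly.
    """
    g_i = max(p_i.objective, _EPS_WEIGHT)
    g_j = max(p_j.objective, _EPS_WEIGHT)
    return (g_i * p_i.alpha + g_j * p_j.alpha) / (g_i + g_j)


def greedy_metric_learning(
    X: np.ndarray,
    y: np.ndarray,
    F_gene: np.ndarray,
    config: Optional[MetricLearningConfig] = None,
) -> Tuple[np.ndarray, List[float]]:
    """Greedy pool search for the feature coefficients maximizing the MRC.

    Returns ``(alpha, history)`` where ``history[t]`` is the best pool
    objective after iteration t (``history[0]`` evaluates the one-hot
    initializations). The history is non-decreasing because every iteration
    retains each surviving predictor through its self-combination.
    """
    if config is None:
        config = MetricLearningConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    F = np.asarray(F_gene, dtype=float)
    if F.ndim != 2 or F.shape[1] == 0:
        raise ValueError("no genomic features")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 training individuals")
    if config.standardize_features:
        sd = F.std(axis=0)
        sd[sd == 0] = 1.0
        F = (F - F.mean(axis=0)) / sd
    M = F.shape[1]

    iu = np.triu_indices(X.shape[0], k=1)
    gaps = np.abs(y[iu[0]] - y[iu[1]])

    def evaluate(alpha: np.ndarray) -> float:
        w = induced_snp_weights(alpha, F)
        D = knn_distance_matrix(X, X, w)
        return _mrc_from_pairs(D[iu], gaps, config.correlation)

    pool = []
    for m in range(M):
        alpha = np.zeros(M)
        alpha[m] = 1.0
        pool.append(Predictor(alpha, evaluate(alpha)))

    best = max(pool, key=lambda p: p.objective)
    best_alpha = best.alpha.copy()
    history = [best.objective]

    for _ in range(config.max_iterations):
        top = sorted(pool, key=lambda p: -p.objective)[: config.r_max]
        new_pool = []
        for p_i in top:
            for p_j in top:
                alpha = combine_predictors(p_i, p_j)
                if not alpha.any():
                    continue
                new_pool.append(Predictor(alpha, evaluate(alpha)))
        pool = new_pool
        current = max(pool, key=lambda p: p.objective)
        history.append(current.objective)
        if current.objective > history[-2] + 1e-15:
            best_alpha = current.alpha.copy()
        if current.objective < history[-2] + config.convergence_tol:
            break
    return best_alpha, history


def fit_knn_igf(
    X: np.ndarray,
    y: np.ndarray,
    F_gene: np.ndarray,
    config: Optional[MetricLearningConfig] = None,
    k_grid=None,
) -> KnnModel:
    """Fit the extended KNN: learn the metric, then select k leave-one-out.

    When the learned coefficients induce an all-zero SNP weighting (no
    feature annotates any cis-SNP of the gene) the metric carries no
    information and the unweighted simple-KNN metric is used instead.
    """
    if config is None:
        config = MetricLearningConfig()
    alpha, history = greedy_metric_learning(X, y, F_gene, config)
    w = induced_snp_weights(alpha, F_gene)
    if not w.any():
        logger.warning("learned metric is all-zero; falling back to unweighted KNN")
        w = np.ones(np.asarray(X).shape[1])
    model = fit_simple_knn(X, y, k_grid=k_grid, snp_weights=w, k_max=config.k_max)
    model.alpha = alpha
    model.mrc_history = history
    return model
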