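"""Cross-validation schemes, R-squared, robustness statistics and gene
characterization.

Three population-aware schemes are supported:

* **cross_pop** — each fold holds out one entire population; the model is
  trained on the union of the others (the hardest task: predictive SNPs
  must be shared across populations);
* **mixed_pop** — individuals from all populations are partitioned into
  ``n_folds`` near-equal test sets, stratified so every fold mirrors the
  global population proportions within one individual;
* **intra_pop** — an ordinary ``n_folds``-fold split applied separately
  within each population, so train and test always share a population.

R-squared is the proportion of variance explained on the evaluated set,
``1 - SS_res / SS_tot`` with the evaluated set's own mean as baseline; it
is negative when the predictor does worse than that mean.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from . import models as _m
from .io_core import Dataset
from .metric_learning import MetricLearningConfig, fit_knn_igf
from .preprocess import build_gene_task, center_expression_by_population

logger = logging.getLogger(__name__)

__all__ = [
    "FoldAssignment",
    "RobustnessReport",
    "RunConfig",
    "make_cv_folds",
    "r_squared",
    "run_gene_cv",
    "summarize_by_gene",
    "robustness_fraction",
    "robustness_curve",
    "concordance_and_bins",
    "rank_genes",
    "model_overlap",
    "characterize_genes",
]

SCHEMES = ("cross_pop", "mixed_pop", "intra_pop")
MODEL_NAMES = ("single", "enet", "knn", "knn_igf", "combined")


@dataclasses.dataclass
class FoldAssignment:
    scheme: str
    folds: List[Tuple[tuple, tuple]]  # (train ids, test ids) per fold
    fold_labels: List[str]
    seed: int


@dataclasses.dataclass
class RobustnessReport:
    pearson: float
    spearman: float
    bins: pd.DataFrame  # bin_lo, bin_hi, n_genes, mean_train_r2, mean_test_r2


@dataclasses.dataclass
class RunConfig:
    """Knobs of a cross-validation run; defaults mirror the standard study."""

    window_bp: int = 100_000
    n_folds: int = 5
    center_scope: str = "global"  # or "train_only" (leakage-free)
    impute: str = "mode"
    pca_components: int = 0
    l1_ratio: float = 0.5
    internal_folds: int = 5
    k_max: int = 50
    stratify_mixed: bool = True
    metric: MetricLearningConfig = dataclasses.field(
        default_factory=MetricLearningConfig
    )


def _cyclic_buckets(
    ids: Sequence[str], n_folds: int, rng: np.random.Generator
) -> List[list]:
    """Shuffle ids and deal them round-robin from a random offset: bucket
    sizes differ by at most one."""
    ids = list(ids)
    rng.shuffle(ids)
    offset = int(rng.integers(n_folds))
    buckets: List[list] = [[] for _ in range(n_folds)]
    for i, ind in enumerate(ids):
        buckets[(i + offset) % n_folds].append(ind)
    return buckets


def make_cv_folds(
    populations, scheme: str, n_folds: int = 5, seed: int = 0, stratified: bool = True
) -> FoldAssignment:
    """Construct train/test folds for one of the three schemes.

    ``populations`` is an :class:`~cisxpred.io_core.PopulationLabels` (or any
    object with ``individual_ids`` and ``labels``). Deterministic given
    ``seed``.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    ids = list(populations.individual_ids)
    labels = list(populations.labels)
    by_pop: Dict[str, list] = {}
    for ind, pop in zip(ids, labels):
        by_pop.setdefault(pop, []).append(ind)
    pops = sorted(by_pop)
    rng = np.random.default_rng(seed)
    folds: List[Tuple[tuple, tuple]] = []
    fold_labels: List[str] = []

    if scheme == "cross_pop":
        if len(pops) < 2:
            raise ValueError("cross_pop requires at least 2 populations")
        for pop in pops:
            test = tuple(by_pop[pop])
            train = tuple(i for p in pops if p != pop for i in by_pop[p])
            folds.append((train, test))
            fold_labels.append(pop)
    elif scheme == "mixed_pop":
        if len(ids) < n_folds:
            raise ValueError("fewer individuals than folds")
        buckets: List[list] = [[] for _ in range(n_folds)]
        if stratified:
            for pop in pops:
                for f, part in enumerate(_cyclic_buckets(by_pop[pop], n_folds, rng)):
                    buckets[f].extend(part)
        else:
            buckets = _cyclic_buckets(ids, n_folds, rng)
        all_set = set(ids)
        for f in range(n_folds):
            test = tuple(buckets[f])
            train = tuple(i for i in ids if i in (all_set - set(test)))
            folds.append((train, test))
            fold_labels.append(f"fold{f}")
    else:  # intra_pop
        for pop in pops:
            if len(by_pop[pop]) < n_folds:
                raise ValueError(
                    f"population {pop!r} has fewer individuals than folds"
                )
        for pop in pops:
            buckets = _cyclic_buckets(by_pop[pop], n_folds, rng)
            pop_set = set(by_pop[pop])
            for f in range(n_folds):
                test = tuple(buckets[f])
                train = tuple(i for i in by_pop[pop] if i in (pop_set - set(test)))
                folds.append((train, test))
                fold_labels.append(f"{pop}:fold{f}")
    return FoldAssignment(scheme=scheme, folds=folds, fold_labels=fold_labels, seed=seed)


def r_squared(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Proportion of variance explained on the evaluated set (may be < 0)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise ValueError("need two equal-length vectors of size >= 2")
    ss_tot = float(((y_true - y_true.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise ValueError("zero variance in evaluated expression")
    return 1.0 - float(((y_true - y_pred) ** 2).sum()) / ss_tot


def _fit_predict_one(
    name: str,
    X_tr: np.ndarray,
    y_tr: np.ndarray,
    X_te: np.ndarray,
    cfg: RunConfig,
    F_gene: np.ndarray,
    seed: int,
    cache: dict,
):
    """Returns (train_r2, test predictions, params dict) for one model."""
    if name == "single":
        m = _m.fit_single_best_snp(X_tr, y_tr)
        return m.train_r2, _m.predict_single_snp(m, X_te), {
            "snp_index": m.snp_index,
            "slope": m.slope,
            "train_corr": m.train_corr,
        }
    if name == "enet":
        if "enet" not in cache:
            m = _m.fit_elastic_net(
                X_tr, y_tr, internal_folds=cfg.internal_folds,
                l1_ratio=cfg.l1_ratio, seed=seed,
            )
            cache["enet"] = (m, _m.predict_linear(m, X_te))
        m, pred = cache["enet"]
        return m.train_r2_cv, pred, {
            "lambda": m.lam,
            "n_nonzero": int((np.abs(m.snp_weights) > 1e-8).sum()),
        }
    if name == "knn":
        if "knn" not in cache:
            m = _m.fit_simple_knn(X_tr, y_tr, k_max=cfg.k_max)
            cache["knn"] = (m, _m.predict_knn(m, X_te))
        m, pred = cache["knn"]
        return m.train_r2, pred, {"k": m.k}
    if name == "knn_igf":
        m = fit_knn_igf(X_tr, y_tr, F_gene, config=cfg.metric)
        return m.train_r2, _m.predict_knn(m, X_te), {
            "k": m.k,
            "alpha": m.alpha.tolist() if m.alpha is not None else None,
        }
    if name == "combined":
        _fit_predict_one("knn", X_tr, y_tr, X_te, cfg, F_gene, seed, cache)
        _fit_predict_one("enet", X_tr, y_tr, X_te, cfg, F_gene, seed, cache)
        knn_m, knn_pred = cache["knn"]
        en_m, en_pred = cache["enet"]
        pred = _m.combine_predictions(knn_pred, en_pred)
        # training score of the average: KNN side uses leave-one-out train
        # predictions, elastic-net side its in-sample fit at the chosen lambda
        D = _m.knn_distance_matrix(X_tr, X_tr, knn_m.snp_weights)
        np.fill_diagonal(D, np.inf)
        order = np.argsort(D, axis=1, kind="stable")[:, : knn_m.k]
        knn_loo = y_tr[order].mean(axis=1)
        en_in = _m.predict_linear(en_m, X_tr)
        train_r2 = r_squared(y_tr, _m.combine_predictions(knn_loo, en_in))
        return train_r2, pred, {"k": knn_m.k, "lambda": en_m.lam}
    raise ValueError(f"unknown model {name!r}")


def run_gene_cv(
    ds: Dataset,
    gene_ids: Sequence[str],
    model_names: Sequence[str],
    scheme: str,
    config: Optional[RunConfig] = None,
    seed: int = 0,
) -> Tuple[List[_m.GeneFitResult], Dict[str, str]]:
    """Fit and evaluate the requested models gene by gene under one scheme.

    Returns ``(results, failures)``: one :class:`GeneFitResult` per
    gene x fold x model, and a map of failed gene ids to error messages
    (a failing gene never aborts the run). Genes without cis-SNPs are
    skipped with a log line. Deterministic given ``seed``.
    """
    if config is None:
        config = RunConfig()
    for name in model_names:
        if name not in MODEL_NAMES:
            raise ValueError(f"unknown model {name!r}")
    fold_assign = make_cv_folds(
        ds.populations, scheme, n_folds=config.n_folds, seed=seed,
        stratified=config.stratify_mixed,
    )
    results: List[_m.GeneFitResult] = []
    failures: Dict[str, str] = {}
    for g, gene_id in enumerate(gene_ids):
        try:
            task = build_gene_task(
                ds, gene_id,
                window_bp=config.window_bp,
                impute=config.impute,
                center_scope=config.center_scope,
                pca_components=config.pca_components,
            )
            if task is None:
                logger.info("gene %s skipped: no cis-SNPs", gene_id)
                continue
            pos = {ind: i for i, ind in enumerate(task.individual_ids)}
            for fold_label, (train_ids, test_ids) in zip(
                fold_assign.fold_labels, fold_assign.folds
            ):
                tr = np.array([pos[i] for i in train_ids], dtype=int)
                te = np.array([pos[i] for i in test_ids], dtype=int)
                if config.center_scope == "train_only":
                    mask = np.zeros(task.n_individuals, dtype=bool)
                    mask[tr] = True
                    y_all = center_expression_by_population(
                        task.y_raw, task.population_labels,
                        scope="train_only", train_mask=mask,
                    )
                else:
                    y_all = task.y
                X_tr, y_tr = task.X[tr], y_all[tr]
                X_te, y_te = task.X[te], y_all[te]
                cache: dict = {}
                for name in model_names:
                    train_r2, pred, params = _fit_predict_one(
                        name, X_tr, y_tr, X_te, config, task.F_gene,
                        seed + 31 * g, cache,
                    )
                    results.append(
                        _m.GeneFitResult(
                            gene_id=gene_id,
                            model_name=name,
                            scheme=scheme,
                            fold_id=fold_label,
                            train_r2=float(train_r2),
                            test_r2=r_squared(y_te, pred),
                            predictions=dict(
                                zip(test_ids, np.asarray(pred, float))
                            ),
                            params=params,
                        )
                    )
        except Exception as exc:  # noqa: BLE001 - per-gene isolation
            logger.warning("gene %s failed: %s", gene_id, exc)
            failures[gene_id] = str(exc)
            results = [r for r in results if r.gene_id != gene_id]
    return results, failures


def summarize_by_gene(results: Sequence[_m.GeneFitResult]) -> pd.DataFrame:
    """Cross-fold mean train/test R-squared per gene x model x scheme."""
    df = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "model": [r.model_name for r in results],
            "scheme": [r.scheme for r in results],
            "train_r2": [r.train_r2 for r in results],
            "test_r2": [r.test_r2 for r in results],
        }
    )
    return (
        df.groupby(["gene_id", "model", "scheme"], as_index=False)[
            ["train_r2", "test_r2"]
        ]
        .mean()
        .sort_values(["model", "scheme", "gene_id"], kind="stable")
        .reset_index(drop=True)
    )


def robustness_fraction(
    train_r2s: np.ndarray,
    test_r2s: np.ndarray,
    threshold: float,
    min_train: float = 0.05,
) -> float:
    """Fraction of genes (with train R2 > ``min_train``) whose test R2 is at
    least ``threshold`` times their train R2."""
    tr = np.asarray(train_r2s, dtype=float)
    te = np.asarray(test_r2s, dtype=float)
    if tr.shape != te.shape:
        raise ValueError("train and test vectors must align")
    mask = tr > min_train
    if not mask.any():
        raise ValueError("empty gene set: no gene exceeds the training threshold")
    return float((te[mask] >= threshold * tr[mask]).mean())


def robustness_curve(
    train_r2s: np.ndarray,
    test_r2s: np.ndarray,
    thresholds: Sequence[float],
    min_train: float = 0.05,
) -> pd.DataFrame:
    rows = [
        (t, robustness_fraction(train_r2s, test_r2s, t, min_train))
        for t in thresholds
    ]
    return pd.DataFrame(rows, columns=["threshold", "fraction_robust"])


def concordance_and_bins(
    train_r2s: np.ndarray,
    test_r2s: np.ndarray,
    bin_edges: Sequence[float],
) -> RobustnessReport:
    """Train/test R-squared concordance across genes, plus binned means.

    Bins are half-open ``[lo, hi)`` on training R-squared; empty bins are
    reported with NaN means rather than raising.
    """
    tr = np.asarray(train_r2s, dtype=float)
    te = np.asarray(test_r2s, dtype=float)
    if tr.size < 3:
        raise ValueError("need at least 3 genes")
    pearson = float(stats.pearsonr(tr, te)[0])
    spearman = float(stats.spearmanr(tr, te)[0])
    rows = []
    edges = list(bin_edges)
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (tr >= lo) & (tr < hi)
        rows.append(
            (
                lo,
                hi,
                int(mask.sum()),
                float(tr[mask].mean()) if mask.any() else np.nan,
                float(te[mask].mean()) if mask.any() else np.nan,
            )
        )
    bins = pd.DataFrame(
        rows, columns=["bin_lo", "bin_hi", "n_genes", "mean_train_r2", "mean_test_r2"]
    )
    return RobustnessReport(pearson=pearson, spearman=spearman, bins=bins)


def rank_genes(summary: pd.DataFrame, model: str, scheme: str) -> List[str]:
    """Genes ranked by cross-fold mean test R-squared, ties by gene id."""
    sub = summary[(summary["model"] == model) & (summary["scheme"] == scheme)]
    sub = sub.sort_values(
        ["test_r2", "gene_id"], ascending=[False, True], kind="stable"
    )
    return list(sub["gene_id"])


def model_overlap(
    top_gene_lists: Dict[str, Sequence[str]], n_top: int
) -> Dict[str, int]:
    """Sizes of top-``n_top`` intersections for every model pair and for all.

    Keys are ``"modelA|modelB"`` (sorted) and ``"all"``.
    """
    for name, lst in top_gene_lists.items():
        if n_top > len(lst):
            raise ValueError(f"n_top={n_top} exceeds list length for {name!r}")
    tops = {name: set(list(lst)[:n_top]) for name, lst in top_gene_lists.items()}
    names = sorted(tops)
    out: Dict[str, int] = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            out[f"{a}|{b}"] = len(tops[a] & tops[b])
    inter = set.intersection(*tops.values()) if tops else set()
    out["all"] = len(inter)
    return out


def characterize_genes(
    gene_features: pd.DataFrame,
    group_mask: np.ndarray,
    welch: bool = True,
) -> pd.DataFrame:
    """Compare per-gene scalars between predictable and unpredictable genes.

    For every column, reports the two group means and a two-sample t-test
    p-value (Welch by default; ``welch=False`` for the classic pooled test).
    A feature constant in both groups gets p = 1.
    """
    mask = np.asarray(group_mask, dtype=bool)
    if mask.all() or not mask.any():
        raise ValueError("both groups must be non-empty")
    rows = []
    for col in gene_features.columns:
        a = gene_features[col].to_numpy(dtype=float)[mask]
        b = gene_features[col].to_numpy(dtype=float)[~mask]
        if np.std(a) == 0 and np.std(b) == 0:
            p = 1.0
        else:
            p = float(stats.ttest_ind(a, b, equal_var=not welch).pvalue)
        rows.append((col, float(a.mean()), float(b.mean()), p))
    return pd.DataFrame(
        rows, columns=["feature", "mean_group", "mean_rest", "p_value"]
    )
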