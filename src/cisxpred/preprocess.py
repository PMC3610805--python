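"""Per-gene task construction: cis-window extraction, imputation, centering,
SNP entropy and optional principal-component correction of genotypes.

A *cis*-SNP of a gene is one on the same chromosome whose position falls
inside the gene body or within ``window_bp`` of either end (default 100 kb,
1-based inclusive on both ends). Expression is mean-centered within each
population so that population-level expression offsets do not masquerade as
genotype signal.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import List, Optional, Sequence

import numpy as np

from .io_core import Dataset, DatasetError, GenotypeMatrix, PopulationLabels

logger = logging.getLogger(__name__)

__all__ = [
    "GeneTask",
    "extract_cis_snps",
    "impute_and_encode",
    "center_expression_by_population",
    "snp_entropy",
    "gene_average_entropy",
    "pca_correct_genotypes",
    "build_gene_task",
]


@dataclasses.dataclass
class GeneTask:
    """Everything a per-gene predictor needs: y, cis-genotypes, features, labels."""

    gene_id: str
    individual_ids: List[str]
    y: np.ndarray  # centered expression (global scope) over all individuals
    y_raw: np.ndarray  # uncentered expression, for fold-aware centering
    X: np.ndarray  # (N, D_gene) imputed minor-allele counts
    snp_ids: List[str]
    F_gene: np.ndarray  # (D_gene, M)
    feature_names: List[str]
    population_labels: np.ndarray  # (N,) object
    constant_snps: np.ndarray = dataclasses.field(
        default_factory=lambda: np.zeros(0, dtype=bool)
    )

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)


def extract_cis_snps(
    gene_chrom: str,
    gene_start: int,
    gene_end: int,
    genotypes: GenotypeMatrix,
    window_bp: int = 100_000,
) -> List[str]:
    """SNP ids inside the gene body or within ``window_bp`` of either end.

    Coordinates are 1-based inclusive; the window is
    ``[start - window_bp, end + window_bp]`` on the gene's chromosome.
    Returns an empty list when no SNP falls in the window.
    """
    lo = gene_start - window_bp
    hi = gene_end + window_bp
    mask = (
        (genotypes.snp_chrom == gene_chrom)
        & (genotypes.snp_pos >= lo)
        & (genotypes.snp_pos <= hi)
    )
    return [genotypes.snp_ids[i] for i in np.nonzero(mask)[0]]


def impute_and_encode(X_raw: np.ndarray, method: str = "mode") -> tuple:
    """Fill missing calls per SNP; returns ``(X, constant_mask)``.

    ``mode`` (default) replaces missing entries with the most frequent
    non-missing count of that SNP (ties broken toward the smaller count),
    keeping the {0,1,2} support so L1 genotype distances stay integral.
    ``mean`` substitutes the rounded mean instead. Columns that end up with
    zero variance are retained but flagged in ``constant_mask``.
    """
    X = np.array(X_raw, dtype=float, copy=True)
    if X.ndim != 2:
        raise ValueError("genotype submatrix must be 2-D")
    for j in range(X.shape[1]):
        col = X[:, j]
        miss = np.isnan(col)
        if not miss.any():
            continue
        obs = col[~miss]
        if obs.size == 0:
            raise DatasetError(f"SNP column {j} has no observed genotype calls")
        if method == "mode":
            vals, counts = np.unique(obs, return_counts=True)
            fill = vals[np.argmax(counts)]  # np.unique sorts, so ties -> smaller
        elif method == "mean":
            fill = float(np.clip(np.round(obs.mean()), 0, 2))
        else:
            raise ValueError(f"unknown imputation method {method!r}")
        col[miss] = fill
    constant = X.std(axis=0) == 0.0
    return X, constant


def center_expression_by_population(
    y_raw: np.ndarray,
    labels: Sequence,
    scope: str = "global",
    train_mask: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Subtract the per-population mean expression.

    ``scope="global"`` computes each population's mean over all individuals
    (centering done once, before cross-validation). ``scope="train_only"``
    computes means on ``train_mask`` individuals only and applies them to
    everyone — the leakage-free variant for fold-aware evaluation.
    """
    y = np.asarray(y_raw, dtype=float)
    labels = np.asarray(labels, dtype=object)
    if y.shape[0] != labels.shape[0]:
        raise ValueError("y and labels length mismatch")
    if scope == "global":
        ref = np.ones(y.shape[0], dtype=bool)
    elif scope == "train_only":
        if train_mask is None:
            raise ValueError("train_only centering requires train_mask")
        ref = np.asarray(train_mask, dtype=bool)
    else:
        raise ValueError(f"unknown centering scope {scope!r}")
    out = y.copy()
    for pop in np.unique(labels):
        members = labels == pop
        basis = members & ref
        if not basis.any():
            raise DatasetError(
                f"population {pop!r} has no individuals in the mean-defining subset"
            )
        out[members] = y[members] - y[basis].mean()
    return out


def _binary_entropy(p: float) -> float:
    if p <= 0.0 or p >= 1.0:
        return 0.0
    return float(-(p * np.log2(p) + (1.0 - p) * np.log2(1.0 - p)))


def snp_entropy(counts: np.ndarray) -> float:
    """Average Shannon entropy (bits) of a SNP's two derived binary alleles.

    The minor-allele count is split into alleles A and B —
    0 -> (A=0, B=0), 1 -> (A=0, B=1), 2 -> (A=1, B=1) — and the mean of the
    two Bernoulli entropies is returned, so the value lies in [0, 1] bits
    and reaches 1 only when both derived alleles sit at frequency 0.5.
    """
    c = np.asarray(counts, dtype=float)
    if c.size == 0:
        raise ValueError("empty genotype column")
    if np.isnan(c).any() or not np.isin(c, (0.0, 1.0, 2.0)).all():
        raise ValueError("snp_entropy requires imputed counts in {0,1,2}")
    a = (c == 2.0).mean()
    b = (c >= 1.0).mean()
    return 0.5 * (_binary_entropy(a) + _binary_entropy(b))


def gene_average_entropy(X: np.ndarray) -> float:
    """Mean :func:`snp_entropy` over the cis-SNP columns of a gene."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError("need at least one SNP column")
    return float(np.mean([snp_entropy(X[:, j]) for j in range(X.shape[1])]))


def pca_correct_genotypes(X: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Regress the top principal-component scores out of every SNP column.

    The corrected matrix has (numerically) zero variance along the removed
    axes; column means are preserved. ``n_components=0`` is the identity.
    If the centered matrix has fewer nonzero singular values than requested,
    only the available components are removed and a warning is issued.
    """
    X = np.asarray(X, dtype=float)
    if n_components == 0:
        return X.copy()
    if X.shape[0] < 3:
        raise ValueError("need at least 3 individuals for PCA correction")
    if np.isnan(X).any():
        raise ValueError("impute genotypes before PCA correction")
    mu = X.mean(axis=0)
    Xc = X - mu
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = max(X.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    avail = int((s > tol).sum())
    k = min(n_components, avail)
    if k < n_components:
        warnings.warn(
            f"requested {n_components} components but rank is {avail}; removing {k}",
            RuntimeWarning,
            stacklevel=2,
        )
    if k == 0:
        return X.copy()
    Uk = U[:, :k]
    return Xc - Uk @ (Uk.T @ Xc) + mu


def build_gene_task(
    ds: Dataset,
    gene_id: str,
    window_bp: int = 100_000,
    impute: str = "mode",
    center_scope: str = "global",
    pca_components: int = 0,
) -> Optional[GeneTask]:
    """Assemble the :class:`GeneTask` for one gene, or None if it has no cis-SNPs.

    Individuals follow the genotype-table order throughout. With the default
    ``center_scope="global"`` the returned ``y`` is centered once within each
    population; ``y_raw`` is always carried for fold-aware re-centering.
    """
    chrom, start, end = ds.genes.loc(gene_id)
    snp_ids = extract_cis_snps(chrom, start, end, ds.genotypes, window_bp)
    if not snp_ids:
        logger.info("gene %s: no cis-SNPs in %d bp window; skipped", gene_id, window_bp)
        return None
    col_idx = [ds.genotypes.snp_ids.index(s) for s in snp_ids]
    X_raw = ds.genotypes.counts[:, col_idx]
    X, constant = impute_and_encode(X_raw, method=impute)
    if pca_components:
        X = pca_correct_genotypes(X, pca_components)

    individual_ids = ds.genotypes.individual_ids
    expr_order = [ds.expression.individual_ids.index(i) for i in individual_ids]
    y_raw = ds.expression.row(gene_id)[expr_order]
    labels = ds.populations.labels_for(individual_ids)
    if center_scope == "global":
        y = center_expression_by_population(y_raw, labels, scope="global")
    else:
        y = y_raw.copy()  # fold-aware centering happens at evaluation time

    feat_index = {s: i for i, s in enumerate(ds.features.snp_ids)}
    M = len(ds.features.feature_names)
    F_gene = np.zeros((len(snp_ids), M))
    for r, s in enumerate(snp_ids):
        if s in feat_index:
            F_gene[r] = ds.features.values[feat_index[s]]
    return GeneTask(
        gene_id=gene_id,
        individual_ids=list(individual_ids),
        y=y,
        y_raw=np.asarray(y_raw, dtype=float),
        X=X,
        snp_ids=snp_ids,
        F_gene=F_gene,
        feature_names=list(ds.features.feature_names),
        population_labels=labels,
        constant_snps=constant,
    )
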