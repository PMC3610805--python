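"""Hypergeometric enrichment/depletion of genomic features among selected
entities, with Benjamini-Hochberg FDR control.

Two study-specific modes share the same machinery:

* **extended-KNN mode** — an entity is a (gene, feature) pair; a feature's
  carriers are its own pairs and a pair is *drawn* when the feature received
  a non-zero coefficient for that gene, so the test asks whether a feature
  is selected across genes more (or less) often than the overall selection
  rate;
* **elastic-net mode** — an entity is a (gene, SNP) pair; carriers are SNPs
  annotated with the feature and draws are SNPs with a non-zero regression
  weight, so the test asks whether annotated SNPs are preferentially given
  weight.

A feature is *called* enriched (or depleted) only when its BH-adjusted tail
p-value is below ``alpha`` in every cross-validation partition supplied.
The same machinery doubles as a generic gene-set (e.g. GO term) enrichment
test via :func:`hypergeometric_test` + :func:`bh_fdr`.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnrichmentResult",
    "hypergeometric_test",
    "bh_fdr",
    "enrichment_table",
    "feature_enrichment_across_genes",
]


@dataclasses.dataclass
class EnrichmentResult:
    feature_name: str
    population_size: int  # N: all entities
    feature_carriers: int  # K: entities carrying the feature
    draws: int  # n: selected entities
    observed: int  # k: selected entities carrying the feature
    p_enriched: float  # P(X >= k)
    p_depleted: float  # P(X <= k)
    q_enriched: float = np.nan
    q_depleted: float = np.nan
    direction: str = ""  # "enriched", "depleted" or ""


def hypergeometric_test(N: int, K: int, n: int, k: int) -> tuple:
    """Exact tail probabilities for X ~ Hypergeometric(N, K, n).

    Returns ``(p_enriched, p_depleted)`` = (P(X >= k), P(X <= k)). The two
    overlap at the observed count: p_enriched + p_depleted = 1 + P(X = k).
    """
    for name, v in (("N", N), ("K", K), ("n", n), ("k", k)):
        if int(v) != v:
            raise ValueError(f"{name} must be an integer")
    N, K, n, k = int(N), int(K), int(n), int(k)
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("require 0 <= K <= N and 0 <= n <= N")
    if not (max(0, n + K - N) <= k <= min(K, n)):
        raise ValueError("observed count k outside its attainable range")
    rv = hypergeom(N, K, n)
    p_enr = float(rv.sf(k - 1))
    p_dep = float(rv.cdf(k))
    return min(max(p_enr, 0.0), 1.0), min(max(p_dep, 0.0), 1.0)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p <= 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _as_feature_sets(
    items: Iterable, feature_map: Optional[Mapping]
) -> Dict[object, Set[str]]:
    out = {}
    for item in items:
        if feature_map is None:
            out[item] = {item}  # the item *is* the feature (extended-KNN mode)
        else:
            out[item] = set(feature_map[item])
    return out


def enrichment_table(
    selections: Mapping[str, Set],
    background: Mapping[str, Sequence],
    feature_map: Optional[Mapping] = None,
    feature_names: Optional[Sequence[str]] = None,
) -> List[EnrichmentResult]:
    """Per-feature hypergeometric tests pooled over genes, one partition.

    ``background[gene]`` lists the candidate items of that gene (features in
    extended-KNN mode, cis-SNP ids in elastic-net mode); ``selections[gene]``
    is the subset that received non-zero weight and must be contained in the
    background. ``feature_map`` maps an item to the features it carries;
    ``None`` means items are themselves features. BH adjustment is applied
    across features, separately for the enriched and depleted tails.
    """
    if not background:
        raise ValueError("empty background")
    N = 0
    n = 0
    carriers: Dict[str, int] = {}
    observed: Dict[str, int] = {}
    for gene, items in background.items():
        items = list(items)
        if not items:
            raise ValueError(f"empty background for gene {gene!r}")
        sel = set(selections.get(gene, set()))
        extra = sel - set(items)
        if extra:
            raise ValueError(
                f"selected item {sorted(extra)[0]!r} of gene {gene!r} "
                "not in its background"
            )
        fsets = _as_feature_sets(items, feature_map)
        N += len(items)
        n += len(sel)
        for item in items:
            for f in fsets[item]:
                carriers[f] = carriers.get(f, 0) + 1
                if item in sel:
                    observed[f] = observed.get(f, 0) + 1
    if feature_names is None:
        feature_names = sorted(carriers)
    results = []
    for f in feature_names:
        K = carriers.get(f, 0)
        k = observed.get(f, 0)
        p_enr, p_dep = hypergeometric_test(N, K, n, k)
        results.append(
            EnrichmentResult(
                feature_name=f,
                population_size=N,
                feature_carriers=K,
                draws=n,
                observed=k,
                p_enriched=p_enr,
                p_depleted=p_dep,
            )
        )
    q_enr = bh_fdr([r.p_enriched for r in results])
    q_dep = bh_fdr([r.p_depleted for r in results])
    for r, qe, qd in zip(results, q_enr, q_dep):
        r.q_enriched = float(qe)
        r.q_depleted = float(qd)
    return results


def feature_enrichment_across_genes(
    per_partition_selections: Sequence[Mapping[str, Set]],
    background: Mapping[str, Sequence],
    feature_map: Optional[Mapping] = None,
    feature_names: Optional[Sequence[str]] = None,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Call features enriched/depleted consistently across CV partitions.

    A feature is called only when its BH-adjusted tail p-value is below
    ``alpha`` in *every* partition. Returns one row per feature with the
    worst-case (maximum over partitions) adjusted p-values and boolean
    ``enriched`` / ``depleted`` calls.
    """
    if not per_partition_selections:
        raise ValueError("need at least one partition of selections")
    tables = [
        enrichment_table(sel, background, feature_map, feature_names)
        for sel in per_partition_selections
    ]
    names = [r.feature_name for r in tables[0]]
    rows = []
    for i, f in enumerate(names):
        qe = max(t[i].q_enriched for t in tables)
        qd = max(t[i].q_depleted for t in tables)
        enriched = all(t[i].q_enriched < alpha for t in tables)
        depleted = all(t[i].q_depleted < alpha for t in tables)
        rows.append((f, qe, qd, enriched, depleted))
    return pd.DataFrame(
        rows,
        columns=["feature", "max_q_enriched", "max_q_depleted", "enriched", "depleted"],
    )
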