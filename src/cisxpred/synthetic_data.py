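"""Synthetic multi-population genotype/expression/annotation panels with
planted cis effects.

The generator emulates the statistical structure a genotype-only expression
predictor is tested against: several populations with population-specific
minor-allele frequencies, genes whose cis windows hold a fixed number of
SNPs, expression driven by a handful of causal cis-SNPs (linear, dominant
or epistatic effects) at a tunable heritability h2, optional
population-specific effects (``share_across_pops`` < 1), and genomic
features that preferentially tag causal SNPs. SNPs are independent by
default; an optional first-order autocorrelation induces LD blocks.

Everything is deterministic given the spec's seed, and the planted truth
(causal SNPs, effects, realized h2) travels with the dataset so predictions
can be joined back to ground truth.
"""

from __future__ import annotations

import dataclasses
import os
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .io_core import (
    Dataset,
    ExpressionPanel,
    FeatureMatrix,
    GeneTable,
    GenotypeMatrix,
    PopulationLabels,
    write_dataset,
)

__all__ = [
    "SimulationSpec",
    "simulate_genotypes",
    "simulate_expression",
    "simulate_features",
    "simulate_dataset",
    "write_simulated_dataset",
]

_GENE_LENGTH = 50_000
_GENE_SPACING = 1_000_000  # > gene length + two 100 kb windows: windows never overlap


@dataclasses.dataclass
class SimulationSpec:
    """Study conditions for one synthetic panel.

    Defaults describe the standard desk-scale study: four populations of the
    size of a HapMap-era panel, a modest number of cis-SNPs per gene (a
    scaled-down stand-in for the few hundred seen in real windows), three
    causal SNPs per gene with fully shared linear effects and h2 = 0.4.
    """

    n_per_pop: int = 60
    n_populations: int = 4
    n_genes: int = 30
    snps_per_gene: int = 30
    maf_range: Tuple[float, float] = (0.05, 0.5)
    h2: float = 0.4
    n_causal: int = 3
    effect_model: str = "linear"  # linear | dominant | epistatic
    share_across_pops: float = 1.0
    n_features: int = 10
    n_informative_features: int = 1
    p_tag_causal: float = 0.9
    p_tag_null: float = 0.05
    noise_feature_density: float = 0.2
    ld_rho: float = 0.0  # first-order genotype autocorrelation across SNPs
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must lie in [0, 1]")
        if self.n_causal > self.snps_per_gene:
            raise ValueError("n_causal cannot exceed snps_per_gene")
        for p in (self.p_tag_causal, self.p_tag_null, self.share_across_pops,
                  self.noise_feature_density):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        lo, hi = self.maf_range
        if not 0.0 <= lo <= hi <= 0.5:
            raise ValueError("maf_range must satisfy 0 <= lo <= hi <= 0.5")


def _pop_names(spec: SimulationSpec):
    return [f"POP{p + 1}" for p in range(spec.n_populations)]


def simulate_genotypes(
    spec: SimulationSpec, rng: Optional[np.random.Generator] = None
):
    """Draw the genotype panel, population labels and gene coordinates.

    Allele counts are binomial(2, p) with a population-specific frequency p
    drawn uniformly from ``maf_range`` per (population, SNP). Genes sit
    1 Mb apart on one chromosome, so each gene's 100 kb cis window contains
    exactly its own ``snps_per_gene`` SNPs. With ``ld_rho`` > 0, adjacent
    SNPs within a gene share haplotype draws with that probability,
    inducing first-order LD.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    pops = _pop_names(spec)
    individual_ids = [
        f"{pop}_{i:03d}" for pop in pops for i in range(spec.n_per_pop)
    ]
    labels = [pop for pop in pops for _ in range(spec.n_per_pop)]
    n_total = len(individual_ids)

    gene_ids, chrom, start, end = [], [], [], []
    snp_ids, snp_chrom, snp_pos = [], [], []
    for g in range(spec.n_genes):
        gid = f"gene{g:04d}"
        s = 1 + g * _GENE_SPACING + 200_000  # keep window off the chromosome edge
        e = s + _GENE_LENGTH - 1
        gene_ids.append(gid)
        chrom.append("chr1")
        start.append(s)
        end.append(e)
        positions = np.linspace(s, e, spec.snps_per_gene).astype(np.int64)
        for j, p in enumerate(positions):
            snp_ids.append(f"{gid}_snp{j:03d}")
            snp_chrom.append("chr1")
            snp_pos.append(int(p))

    D = len(snp_ids)
    lo, hi = spec.maf_range
    counts = np.empty((n_total, D), dtype=float)
    row = 0
    for pop in pops:
        if lo == hi:
            freqs = np.full(D, lo)
        else:
            freqs = rng.uniform(lo, hi, size=D)
        haps = rng.random((spec.n_per_pop, D, 2)) < freqs[None, :, None]
        if spec.ld_rho > 0.0:
            per_gene = spec.snps_per_gene
            copy_mask = rng.random((spec.n_per_pop, D)) < spec.ld_rho
            copy_mask[:, ::per_gene] = False  # no carry-over across genes
            for j in range(1, D):
                m = copy_mask[:, j]
                haps[m, j, :] = haps[m, j - 1, :]
        counts[row: row + spec.n_per_pop] = haps.sum(axis=2)
        row += spec.n_per_pop
    genotypes = GenotypeMatrix(
        individual_ids, snp_ids, counts, np.array(snp_chrom, dtype=object),
        np.array(snp_pos, dtype=np.int64),
    )
    genotypes.validate()
    populations = PopulationLabels(list(individual_ids), labels)
    genes = GeneTable(gene_ids, np.array(chrom, dtype=object),
                      np.array(start), np.array(end))
    return genotypes, populations, genes


def _genetic_value(
    X: np.ndarray, causal: np.ndarray, effects: np.ndarray, model: str
) -> np.ndarray:
    G = X[:, causal]
    if model == "linear":
        return G @ effects
    if model == "dominant":
        return (G >= 1).astype(float) @ effects
    if model == "epistatic":
        # chain of pairwise products over consecutive causal SNPs
        if len(causal) < 2:
            return G @ effects
        pairs = np.stack(
            [G[:, i] * G[:, i + 1] for i in range(len(causal) - 1)], axis=1
        )
        return pairs @ effects[:-1]
    raise ValueError(f"unknown effect model {model!r}")


def simulate_expression(
    spec: SimulationSpec,
    genotypes: GenotypeMatrix,
    populations: PopulationLabels,
    genes: GeneTable,
    rng: Optional[np.random.Generator] = None,
):
    """Plant genotype effects and noise; returns the panel and truth record.

    Per gene, ``n_causal`` SNPs get standard-normal effect sizes. A causal
    SNP is *shared* (identical effect in every population) with probability
    ``share_across_pops``, otherwise each population draws its own effect.
    Noise is Gaussian, scaled so the genetic share of expression variance
    equals h2 in expectation; h2 = 0 plants no genotype signal at all.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    labels = np.asarray(populations.labels, dtype=object)
    pop_names = sorted(set(labels))
    n_total = genotypes.n_individuals
    values = np.empty((len(genes.gene_ids), n_total))
    truth_rows = []
    per_gene = spec.snps_per_gene
    for gi, gene_id in enumerate(genes.gene_ids):
        cols = np.arange(gi * per_gene, (gi + 1) * per_gene)
        causal_local = np.sort(
            rng.choice(per_gene, size=spec.n_causal, replace=False)
        )
        causal = cols[causal_local]
        shared = rng.random(spec.n_causal) < spec.share_across_pops
        base_effects = rng.standard_normal(spec.n_causal)

        g_val = np.zeros(n_total)
        if spec.h2 > 0.0:
            for pop in pop_names:
                members = labels == pop
                eff = base_effects.copy()
                if (~shared).any():
                    eff[~shared] = rng.standard_normal((~shared).sum())
                g_val[members] = _genetic_value(
                    genotypes.counts[members], causal, eff, spec.effect_model
                )
        var_g = float(np.var(g_val))
        if spec.h2 >= 1.0:
            if var_g == 0.0:
                raise ValueError(
                    f"h2=1 requires a non-degenerate genetic value (gene {gene_id})"
                )
            noise_sd = 0.0
        elif spec.h2 == 0.0:
            noise_sd = 1.0
        else:
            if var_g == 0.0:
                noise_sd = 1.0
            else:
                noise_sd = float(np.sqrt(var_g * (1.0 - spec.h2) / spec.h2))
        y = g_val + noise_sd * rng.standard_normal(n_total)
        values[gi] = y
        realized = var_g / float(np.var(y)) if np.var(y) > 0 else 0.0
        truth_rows.append(
            {
                "gene_id": gene_id,
                "causal_snps": ",".join(genotypes.snp_ids[c] for c in causal),
                "effects": ",".join(f"{e:.6g}" for e in base_effects),
                "shared": ",".join(str(int(s)) for s in shared),
                "noise_sd": noise_sd,
                "realized_h2": realized,
            }
        )
    panel = ExpressionPanel(
        list(genes.gene_ids), list(genotypes.individual_ids), values
    )
    panel.validate()
    return panel, pd.DataFrame(truth_rows)


def simulate_features(
    spec: SimulationSpec,
    genotypes: GenotypeMatrix,
    truth: pd.DataFrame,
    rng: Optional[np.random.Generator] = None,
) -> FeatureMatrix:
    """Binary SNP annotations; informative columns preferentially tag causal SNPs.

    The first ``n_informative_features`` columns are 1 on causal SNPs with
    probability ``p_tag_causal`` and on the rest with ``p_tag_null``;
    remaining columns are pure-noise indicators of density
    ``noise_feature_density``.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed + 2)
    D = genotypes.n_snps
    causal_ids = set()
    for snps in truth["causal_snps"]:
        causal_ids.update(snps.split(","))
    causal_mask = np.array([s in causal_ids for s in genotypes.snp_ids])
    M = spec.n_features
    values = np.zeros((D, M))
    for m in range(M):
        if m < spec.n_informative_features:
            p = np.where(causal_mask, spec.p_tag_causal, spec.p_tag_null)
        else:
            p = np.full(D, spec.noise_feature_density)
        values[:, m] = (rng.random(D) < p).astype(float)
    fm = FeatureMatrix(
        list(genotypes.snp_ids),
        [f"feat{m:03d}" for m in range(M)],
        values,
    )
    fm.validate()
    return fm


def simulate_dataset(spec: SimulationSpec) -> Tuple[Dataset, pd.DataFrame]:
    """Full panel: genotypes, expression, features, genes, populations + truth."""
    rng = np.random.default_rng(spec.seed)
    genotypes, populations, genes = simulate_genotypes(spec, rng)
    expression, truth = simulate_expression(spec, genotypes, populations, genes, rng)
    features = simulate_features(spec, genotypes, truth, rng)
    return (
        Dataset(genotypes, expression, features, genes, populations),
        truth,
    )


def write_simulated_dataset(spec: SimulationSpec, out_dir: str) -> Dict[str, str]:
    """Simulate and write the five tables plus ``truth.tsv`` under ``out_dir``."""
    ds, truth = simulate_dataset(spec)
    paths = write_dataset(ds, out_dir)
    truth_path = os.path.join(out_dir, "truth.tsv")
    truth.to_csv(truth_path, sep="\t", index=False)
    paths["truth"] = truth_path
    return paths
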