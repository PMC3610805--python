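"""Validated containers and TSV readers/writers for a cis-eQTL prediction study.

A study consists of five tables that cross-reference each other:

* genotypes      individuals x SNPs, minor-allele counts in {0, 1, 2} or ``NA``,
                 with per-SNP chromosome/position carried as two metadata rows
                 (row-ids ``#chrom`` and ``#pos``) before the individual rows;
* expression     genes x individuals, continuous values;
* features       SNPs x genomic features (binary or continuous annotations);
* genes          gene_id, chromosome, start, end (1-based, inclusive);
* populations    individual_id -> population label.

All files are tab-separated UTF-8 with a header row and the row-id in the
first column. Loading validates every invariant (value domains, unique ids,
cross-references); corrupt cells raise :class:`ParseError` naming the cell
and dangling ids raise :class:`CrossReferenceError` naming the id.
"""

from __future__ import annotations

import dataclasses
import json
import os
from typing import Dict, List, NamedTuple, Sequence

import numpy as np
import pandas as pd

MISSING_TOKEN = "NA"
_CHROM_ROW = "#chrom"
_POS_ROW = "#pos"

__all__ = [
    "DatasetError",
    "ParseError",
    "CrossReferenceError",
    "GenotypeMatrix",
    "ExpressionPanel",
    "FeatureMatrix",
    "GeneTable",
    "PopulationLabels",
    "Dataset",
    "load_dataset",
    "write_dataset",
    "write_results",
]


class DatasetError(ValueError):
    """Base class for dataset validation failures."""


class ParseError(DatasetError):
    """A cell value outside its declared domain."""


class CrossReferenceError(DatasetError):
    """An id referenced in one table is absent from its home table."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise DatasetError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclasses.dataclass
class GenotypeMatrix:
    """Minor-allele counts for N individuals at D SNPs (NaN = missing call)."""

    individual_ids: List[str]
    snp_ids: List[str]
    counts: np.ndarray  # (N, D) float; entries in {0, 1, 2} or NaN
    snp_chrom: np.ndarray  # (D,) object
    snp_pos: np.ndarray  # (D,) int, 1-based

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.snp_chrom = np.asarray(self.snp_chrom, dtype=object)
        self.snp_pos = np.asarray(self.snp_pos, dtype=np.int64)

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def validate(self) -> None:
        _check_unique(self.individual_ids, "individual")
        _check_unique(self.snp_ids, "SNP")
        if self.counts.shape != (self.n_individuals, self.n_snps):
            raise DatasetError(
                f"genotype matrix shape {self.counts.shape} does not match "
                f"{self.n_individuals} individuals x {self.n_snps} SNPs"
            )
        vals = self.counts[~np.isnan(self.counts)]
        bad = ~np.isin(vals, (0.0, 1.0, 2.0))
        if bad.any():
            rows, cols = np.nonzero(
                ~np.isnan(self.counts) & ~np.isin(self.counts, (0.0, 1.0, 2.0))
            )
            r, c = rows[0], cols[0]
            raise ParseError(
                f"genotype value {self.counts[r, c]!r} outside {{0,1,2,NA}} at "
                f"individual {self.individual_ids[r]!r}, SNP {self.snp_ids[c]!r}"
            )
        if len(self.snp_chrom) != self.n_snps or len(self.snp_pos) != self.n_snps:
            raise DatasetError("SNP metadata length does not match SNP count")
        if (self.snp_pos <= 0).any():
            bad_id = self.snp_ids[int(np.argmax(self.snp_pos <= 0))]
            raise DatasetError(f"non-positive position for SNP {bad_id!r}")


@dataclasses.dataclass
class ExpressionPanel:
    """Continuous expression for G genes over the study individuals."""

    gene_ids: List[str]
    individual_ids: List[str]
    values: np.ndarray  # (G, N) float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def validate(self) -> None:
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.individual_ids, "individual")
        if self.values.shape != (len(self.gene_ids), len(self.individual_ids)):
            raise DatasetError("expression matrix shape mismatch")
        if not np.isfinite(self.values).all():
            raise DatasetError("expression values must be finite")

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]


@dataclasses.dataclass
class FeatureMatrix:
    """Genomic-feature annotations, one row per SNP and one column per feature."""

    snp_ids: List[str]
    feature_names: List[str]
    values: np.ndarray  # (D, M) float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def validate(self) -> None:
        _check_unique(self.snp_ids, "SNP")
        _check_unique(self.feature_names, "feature")
        if self.values.shape != (len(self.snp_ids), len(self.feature_names)):
            raise DatasetError("feature matrix shape mismatch")
        if not np.isfinite(self.values).all():
            raise DatasetError("feature values must be finite")


@dataclasses.dataclass
class GeneTable:
    """Gene coordinates, 1-based inclusive on both ends."""

    gene_ids: List[str]
    chromosome: np.ndarray
    start: np.ndarray
    end: np.ndarray

    def __post_init__(self) -> None:
        self.chromosome = np.asarray(self.chromosome, dtype=object)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)

    def validate(self) -> None:
        _check_unique(self.gene_ids, "gene")
        n = len(self.gene_ids)
        if not (len(self.chromosome) == len(self.start) == len(self.end) == n):
            raise DatasetError("gene table column length mismatch")
        if (self.start <= 0).any() or (self.end <= 0).any():
            raise DatasetError("gene coordinates must be positive")
        bad = self.start > self.end
        if bad.any():
            raise DatasetError(
                f"gene {self.gene_ids[int(np.argmax(bad))]!r} has start > end"
            )

    def loc(self, gene_id: str) -> tuple:
        i = self.gene_ids.index(gene_id)
        return str(self.chromosome[i]), int(self.start[i]), int(self.end[i])


@dataclasses.dataclass
class PopulationLabels:
    """One population label per individual."""

    individual_ids: List[str]
    labels: List[str]

    def validate(self) -> None:
        _check_unique(self.individual_ids, "individual")
        if len(self.individual_ids) != len(self.labels):
            raise DatasetError("population table length mismatch")

    def as_dict(self) -> Dict[str, str]:
        return dict(zip(self.individual_ids, self.labels))

    def labels_for(self, individual_ids: Sequence[str]) -> np.ndarray:
        m = self.as_dict()
        return np.array([m[i] for i in individual_ids], dtype=object)


class Dataset(NamedTuple):
    genotypes: GenotypeMatrix
    expression: ExpressionPanel
    features: FeatureMatrix
    genes: GeneTable
    populations: PopulationLabels


def _read_tsv(path: str) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)


def _load_genotypes(path: str) -> GenotypeMatrix:
    df = _read_tsv(path)
    if _CHROM_ROW not in df.index or _POS_ROW not in df.index:
        raise ParseError(
            f"genotype table {path!r} must contain metadata rows "
            f"{_CHROM_ROW!r} and {_POS_ROW!r}"
        )
    snp_ids = [str(c) for c in df.columns]
    chrom = df.loc[_CHROM_ROW].to_numpy(dtype=object)
    try:
        pos = df.loc[_POS_ROW].astype(np.int64).to_numpy()
    except ValueError as exc:
        raise ParseError(f"non-integer SNP position in {path!r}: {exc}") from exc
    body = df.drop(index=[_CHROM_ROW, _POS_ROW])
    individual_ids = [str(i) for i in body.index]
    counts = np.empty(body.shape, dtype=float)
    raw = body.to_numpy(dtype=object)
    for (r, c), cell in np.ndenumerate(raw):
        cell = str(cell).strip()
        if cell == MISSING_TOKEN:
            counts[r, c] = np.nan
        elif cell in ("0", "1", "2"):
            counts[r, c] = float(cell)
        else:
            raise ParseError(
                f"genotype value {cell!r} outside {{0,1,2,NA}} at individual "
                f"{individual_ids[r]!r}, SNP {snp_ids[c]!r}"
            )
    gm = GenotypeMatrix(individual_ids, snp_ids, counts, chrom, pos)
    gm.validate()
    return gm


def _load_expression(path: str) -> ExpressionPanel:
    df = _read_tsv(path)
    try:
        values = df.astype(float).to_numpy()
    except ValueError as exc:
        raise ParseError(f"non-numeric expression value in {path!r}: {exc}") from exc
    ep = ExpressionPanel([str(i) for i in df.index], [str(c) for c in df.columns], values)
    ep.validate()
    return ep


def _load_features(path: str) -> FeatureMatrix:
    df = _read_tsv(path)
    try:
        values = df.astype(float).to_numpy()
    except ValueError as exc:
        raise ParseError(f"non-numeric feature value in {path!r}: {exc}") from exc
    fm = FeatureMatrix([str(i) for i in df.index], [str(c) for c in df.columns], values)
    fm.validate()
    return fm


def _load_genes(path: str) -> GeneTable:
    df = _read_tsv(path)
    for col in ("chromosome", "start", "end"):
        if col not in df.columns:
            raise ParseError(f"gene table {path!r} missing column {col!r}")
    try:
        start = df["start"].astype(np.int64).to_numpy()
        end = df["end"].astype(np.int64).to_numpy()
    except ValueError as exc:
        raise ParseError(f"non-integer gene coordinate in {path!r}: {exc}") from exc
    gt = GeneTable(
        [str(i) for i in df.index], df["chromosome"].to_numpy(dtype=object), start, end
    )
    gt.validate()
    return gt


def _load_populations(path: str) -> PopulationLabels:
    df = _read_tsv(path)
    if "population" not in df.columns:
        raise ParseError(f"population table {path!r} missing column 'population'")
    pl = PopulationLabels([str(i) for i in df.index], [str(v) for v in df["population"]])
    pl.validate()
    return pl


def validate_cross_references(ds: Dataset) -> None:
    """Check id consistency across the five tables of a loaded dataset."""
    geno_inds = set(ds.genotypes.individual_ids)
    geno_snps = set(ds.genotypes.snp_ids)
    for ind in ds.expression.individual_ids:
        if ind not in geno_inds:
            raise CrossReferenceError(
                f"expression individual {ind!r} absent from genotype table"
            )
    missing = geno_inds - set(ds.expression.individual_ids)
    if missing:
        raise CrossReferenceError(
            f"genotyped individual {sorted(missing)[0]!r} absent from expression table"
        )
    for snp in ds.features.snp_ids:
        if snp not in geno_snps:
            raise CrossReferenceError(
                f"feature-table SNP {snp!r} absent from genotype table"
            )
    pop = ds.populations.as_dict()
    for ind in ds.genotypes.individual_ids:
        if ind not in pop:
            raise CrossReferenceError(f"individual {ind!r} has no population label")
    for ind in ds.populations.individual_ids:
        if ind not in geno_inds:
            raise CrossReferenceError(
                f"population-table individual {ind!r} absent from genotype table"
            )


def load_dataset(
    genotype_path: str,
    expression_path: str,
    feature_path: str,
    gene_path: str,
    population_path: str,
) -> Dataset:
    """Load and fully validate the five study tables.

    Missing genotype calls are preserved as NaN; imputation belongs to
    :mod:`cisxpred.preprocess`.
    """
    ds = Dataset(
        genotypes=_load_genotypes(genotype_path),
        expression=_load_expression(expression_path),
        features=_load_features(feature_path),
        genes=_load_genes(gene_path),
        populations=_load_populations(population_path),
    )
    validate_cross_references(ds)
    return ds


def _fmt_count(v: float) -> str:
    return MISSING_TOKEN if np.isnan(v) else str(int(v))


def write_dataset(ds: Dataset, out_dir: str) -> Dict[str, str]:
    """Write the five tables under ``out_dir``; returns the path of each."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "genotypes": os.path.join(out_dir, "genotypes.tsv"),
        "expression": os.path.join(out_dir, "expression.tsv"),
        "features": os.path.join(out_dir, "features.tsv"),
        "genes": os.path.join(out_dir, "genes.tsv"),
        "populations": os.path.join(out_dir, "populations.tsv"),
    }
    g = ds.genotypes
    with open(paths["genotypes"], "w", encoding="utf-8") as fh:
        fh.write("individual_id\t" + "\t".join(g.snp_ids) + "\n")
        fh.write(_CHROM_ROW + "\t" + "\t".join(str(c) for c in g.snp_chrom) + "\n")
        fh.write(_POS_ROW + "\t" + "\t".join(str(p) for p in g.snp_pos) + "\n")
        for i, ind in enumerate(g.individual_ids):
            fh.write(ind + "\t" + "\t".join(_fmt_count(v) for v in g.counts[i]) + "\n")
    pd.DataFrame(
        ds.expression.values,
        index=pd.Index(ds.expression.gene_ids, name="gene_id"),
        columns=ds.expression.individual_ids,
    ).to_csv(paths["expression"], sep="\t", float_format="%.10g")
    pd.DataFrame(
        ds.features.values,
        index=pd.Index(ds.features.snp_ids, name="snp_id"),
        columns=ds.features.feature_names,
    ).to_csv(paths["features"], sep="\t", float_format="%.10g")
    pd.DataFrame(
        {
            "chromosome": ds.genes.chromosome,
            "start": ds.genes.start,
            "end": ds.genes.end,
        },
        index=pd.Index(ds.genes.gene_ids, name="gene_id"),
    ).to_csv(paths["genes"], sep="\t")
    pd.DataFrame(
        {"population": ds.populations.labels},
        index=pd.Index(ds.populations.individual_ids, name="individual_id"),
    ).to_csv(paths["populations"], sep="\t")
    return paths


def write_results(results, out_dir: str) -> List[str]:
    """Write per-(model, scheme) fold summaries and test-prediction tables.

    ``results`` is a collection of :class:`cisxpred.models.GeneFitResult`.
    Row order is deterministic (gene_id, then fold), so re-runs with the same
    inputs produce byte-identical tables.
    """
    results = list(results)
    if not results:
        raise DatasetError("no results")
    os.makedirs(out_dir, exist_ok=True)
    written: List[str] = []
    by_key: Dict[tuple, list] = {}
    for r in results:
        by_key.setdefault((r.model_name, r.scheme), []).append(r)
    for (model, scheme), group in sorted(by_key.items()):
        group.sort(key=lambda r: (r.gene_id, r.fold_id))
        summary = pd.DataFrame(
            {
                "gene_id": [r.gene_id for r in group],
                "fold": [r.fold_id for r in group],
                "train_r2": [r.train_r2 for r in group],
                "test_r2": [r.test_r2 for r in group],
                "params": [
                    json.dumps(r.params, sort_keys=True, default=str) for r in group
                ],
            }
        )
        path = os.path.join(out_dir, f"results_{model}_{scheme}.tsv")
        summary.to_csv(path, sep="\t", index=False, float_format="%.10g")
        written.append(path)
        rows = []
        for r in group:
            for ind, pred in sorted(r.predictions.items()):
                rows.append((r.gene_id, r.fold_id, ind, pred))
        pred_df = pd.DataFrame(
            rows, columns=["gene_id", "fold", "individual_id", "prediction"]
        )
        ppath = os.path.join(out_dir, f"predictions_{model}_{scheme}.tsv")
        pred_df.to_csv(ppath, sep="\t", index=False, float_format="%.10g")
        written.append(ppath)
    return written
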