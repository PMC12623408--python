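"""Reading, harmonizing, filtering and merging expression matrices.

The pipeline deliberately performs **no** cross-sample normalization or batch
correction: every downstream comparison of expression values happens within a
single sample (gene A vs gene B), so matrices from heterogeneous studies can
be merged verbatim.  The only global cleaning steps are gene-ID harmonization
to a single symbol namespace and a prevalence filter that drops genes absent
from too many samples.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "ExpressionMatrix",
    "HarmonizeRecord",
    "read_expression",
    "read_annotation",
    "write_annotation",
    "harmonize_gene_ids",
    "filter_genes_by_prevalence",
    "merge_studies",
    "counts_to_tpm",
]

ANNOTATION_COLUMNS = ("sample_id", "class_label", "study_id")


@dataclasses.dataclass
class ExpressionMatrix:
    """A genes x samples numeric matrix with unique gene and sample names.

    Parameters
    ----------
    values
        DataFrame with gene symbols as the index and sample IDs as columns.
    unit
        One of ``counts``, ``TPM`` or ``logTPM``.
    """

    values: pd.DataFrame
    unit: str = "counts"

    def __post_init__(self) -> None:
        if self.unit not in ("counts", "TPM", "logTPM"):
            raise ValueError(f"unknown unit {self.unit!r}")
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dups = sorted(idx[idx.duplicated()].unique())
            raise ValueError(f"duplicate gene ids: {dups}")
        if cols.has_duplicates:
            dups = sorted(cols[cols.duplicated()].unique())
            raise ValueError(f"duplicate sample ids: {dups}")
        if len(idx) == 0 or len(cols) == 0:
            raise ValueError("expression matrix must be non-empty")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if not np.all(np.isfinite(arr)):
            raise ValueError("expression values must be finite (no NA support)")
        if arr.min() < 0:
            raise ValueError("negative expression values are not allowed")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:10]}")
        return ExpressionMatrix(self.values.loc[list(genes)], unit=self.unit)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(samples)], unit=self.unit)

    def to_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t")


@dataclasses.dataclass
class HarmonizeRecord:
    """Bookkeeping from gene-ID harmonization."""

    n_input_genes: int
    n_mapped_genes: int
    n_unmapped_dropped: int
    collisions: dict[str, list[str]]
    policy: str


def _read_table(path: Path, sep: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed expression file {path}: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def read_expression(
    path: str | Path,
    format: str | None = None,
    *,
    genes_path: str | Path | None = None,
    samples_path: str | Path | None = None,
    unit: str = "counts",
) -> ExpressionMatrix:
    """Read an expression matrix from TSV, CSV or a MatrixMarket triplet.

    For ``mtx_triplet`` the gene and sample name sidecar files default to
    ``<stem>.genes.txt`` and ``<stem>.samples.txt`` next to the ``.mtx`` file,
    one name per line.  Row/column order is preserved from the file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {".tsv": "tsv", ".csv": "csv", ".mtx": "mtx_triplet"}.get(
            path.suffix.lower(), "tsv"
        )
    if format == "tsv":
        df = _read_table(path, "\t")
    elif format == "csv":
        df = _read_table(path, ",")
    elif format == "mtx_triplet":
        genes_path = Path(genes_path) if genes_path else path.with_suffix(".genes.txt")
        samples_path = (
            Path(samples_path) if samples_path else path.with_suffix(".samples.txt")
        )
        mat = scipy.io.mmread(str(path))
        genes = Path(genes_path).read_text().split()
        samples = Path(samples_path).read_text().split()
        dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
        if dense.shape != (len(genes), len(samples)):
            raise ValueError(
                f"MTX shape {dense.shape} does not match sidecar names "
                f"({len(genes)} genes, {len(samples)} samples)"
            )
        df = pd.DataFrame(dense, index=genes, columns=samples)
    else:
        raise ValueError(f"unknown format {format!r}")
    return ExpressionMatrix(df, unit=unit)


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a sample annotation TSV with columns sample_id, class_label, study_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation file missing columns: {missing}")
    if df["sample_id"].duplicated().any():
        dups = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"])
        raise ValueError(f"duplicate sample ids in annotation: {dups}")
    return df[list(ANNOTATION_COLUMNS)]


def write_annotation(ann: pd.DataFrame, path: str | Path) -> None:
    ann[list(ANNOTATION_COLUMNS)].to_csv(path, sep="\t", index=False)


def harmonize_gene_ids(
    m: ExpressionMatrix,
    gene_map: Mapping[str, str] | pd.DataFrame,
    collision_policy: str = "sum",
) -> tuple[ExpressionMatrix, HarmonizeRecord]:
    """Map gene identifiers (e.g. Ensembl) onto target symbols (e.g. HUGO).

    Unmapped genes are dropped and counted.  When several source IDs map to
    the same target symbol, ``collision_policy`` decides: ``sum`` adds the
    rows (counts are additive), ``drop`` removes all colliding symbols,
    ``error`` raises listing them.
    """
    if collision_policy not in ("sum", "drop", "error"):
        raise ValueError(f"unknown collision_policy {collision_policy!r}")
    if isinstance(gene_map, pd.DataFrame):
        if gene_map.shape[1] < 2:
            raise ValueError("gene map table needs two columns (source, target)")
        gene_map = dict(zip(gene_map.iloc[:, 0].astype(str), gene_map.iloc[:, 1].astype(str)))
    mapped_idx = [g for g in m.gene_ids if g in gene_map]
    if not mapped_idx:
        raise ValueError("gene map covers no gene of the matrix")
    sub = m.values.loc[mapped_idx]
    targets = pd.Index([gene_map[g] for g in mapped_idx])
    collisions = {
        sym: [s for s, t in zip(mapped_idx, targets) if t == sym]
        for sym in targets[targets.duplicated()].unique()
    }
    if collisions and collision_policy == "error":
        raise ValueError(f"gene symbol collisions after mapping: {sorted(collisions)}")
    sub = sub.set_axis(targets, axis=0)
    if collision_policy == "drop" and collisions:
        sub = sub.loc[~sub.index.isin(collisions)]
        if sub.empty:
            raise ValueError("all genes dropped by collision policy")
    elif collisions:  # sum
        sub = sub.groupby(level=0, sort=False).sum()
    record = HarmonizeRecord(
        n_input_genes=m.n_genes,
        n_mapped_genes=len(mapped_idx),
        n_unmapped_dropped=m.n_genes - len(mapped_idx),
        collisions=collisions,
        policy=collision_policy,
    )
    return ExpressionMatrix(sub, unit=m.unit), record


def filter_genes_by_prevalence(
    m: ExpressionMatrix, min_nonzero_fraction: float = 0.8
) -> ExpressionMatrix:
    """Keep genes observed (strictly positive) in >= a fraction of samples.

    The comparison is inclusive: a gene seen in exactly the threshold
    fraction of samples is kept.
    """
    if not 0 < min_nonzero_fraction <= 1:
        raise ValueError("min_nonzero_fraction must be in (0, 1]")
    frac = (m.values.to_numpy() > 0).mean(axis=1)
    keep = frac >= min_nonzero_fraction
    if not keep.any():
        raise ValueError(
            "prevalence filter removed every gene; lower min_nonzero_fraction"
        )
    return ExpressionMatrix(m.values.loc[keep], unit=m.unit)


def merge_studies(
    matrices: Sequence[ExpressionMatrix],
    annotations: Sequence[pd.DataFrame],
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Merge studies on the gene intersection, copying values verbatim.

    No scaling, normalization or batch correction is applied; gene-pair rules
    only ever compare values within a sample, so raw values are merged as-is.
    """
    if len(matrices) < 2:
        raise ValueError("need at least two matrices to merge")
    if len(matrices) != len(annotations):
        raise ValueError("one annotation table per matrix required")
    common = matrices[0].values.index
    for m in matrices[1:]:
        common = common.intersection(m.values.index)
    # keep first matrix's gene order
    common = [g for g in matrices[0].gene_ids if g in set(common)]
    if not common:
        raise ValueError("empty gene intersection across studies")
    all_samples = [s for m in matrices for s in m.sample_ids]
    seen: set[str] = set()
    dups = sorted({s for s in all_samples if s in seen or seen.add(s)})
    if dups:
        raise ValueError(f"duplicate sample ids across studies: {dups}")
    merged = pd.concat([m.values.loc[common] for m in matrices], axis=1)
    ann = pd.concat([a[list(ANNOTATION_COLUMNS)] for a in annotations], ignore_index=True)
    if set(ann["sample_id"]) != set(all_samples):
        raise ValueError("annotation sample ids do not match matrix sample ids")
    unit = matrices[0].unit
    return ExpressionMatrix(merged, unit=unit), ann


def counts_to_tpm(
    m: ExpressionMatrix, gene_lengths_kb: Mapping[str, float] | pd.Series
) -> ExpressionMatrix:
    """Convert counts to transcripts per million given gene lengths in kb.

    TPM_g = 1e6 * (count_g / len_g) / sum_h (count_h / len_h), per sample.
    """
    lengths = pd.Series(gene_lengths_kb, dtype=float)
    missing = [g for g in m.gene_ids if g not in lengths.index]
    if missing:
        raise ValueError(f"gene lengths missing for: {missing[:10]}")
    lengths = lengths.loc[m.gene_ids]
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    rate = m.values.div(lengths, axis=0)
    totals = rate.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValueError(f"zero library total for samples: {zero}")
    tpm = rate.div(totals, axis=1) * 1e6
    return ExpressionMatrix(tpm, unit="TPM")
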