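"""Pseudo-bulk aggregation of single-cell counts by (sample, cell type).

Aggregating annotated cells into bulk-like profiles is how single-cell and
single-nucleus cohorts are fed to a bulk-trained classifier.  Group cell
counts are surfaced because tiny groups (a handful of cells) produce
unstable pseudo-bulk profiles and hence less reliable predictions.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse

from .expr_io import ExpressionMatrix

__all__ = ["aggregate_pseudobulk"]

CELL_ANN_COLUMNS = ("cell_id", "donor_or_sample_id", "cell_type_label")


def aggregate_pseudobulk(
    counts,
    gene_ids: Sequence[str],
    cell_ann: pd.DataFrame,
    min_cells: int = 1,
    statistic: str = "sum",
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Aggregate genes x cells counts into per-(sample, cell type) columns.

    ``statistic='sum'`` conserves total counts; ``'mean'`` averages cells.
    Groups with fewer than ``min_cells`` cells are dropped (not zero-filled)
    and recorded in the returned group metadata with ``included=False``.
    Output columns are named ``<sample>::<cell_type>``.
    """
    if statistic not in ("sum", "mean"):
        raise ValueError(f"unknown statistic {statistic!r}")
    missing = [c for c in CELL_ANN_COLUMNS if c not in cell_ann.columns]
    if missing:
        raise ValueError(f"cell annotation missing columns: {missing}")
    if cell_ann["cell_id"].duplicated().any():
        raise ValueError("duplicate cell ids in annotation")
    mat = counts.tocsc() if scipy.sparse.issparse(counts) else np.asarray(counts)
    n_genes, n_cells = mat.shape
    if n_genes != len(gene_ids):
        raise ValueError("gene_ids length does not match matrix rows")
    if n_cells != len(cell_ann):
        raise ValueError("every cell must be annotated (count mismatch)")
    cols: dict[str, np.ndarray] = {}
    meta = []
    grouped = cell_ann.reset_index(drop=True).groupby(
        ["donor_or_sample_id", "cell_type_label"], sort=True
    )
    for (sample, ctype), grp in grouped:
        idx = grp.index.to_numpy()
        name = f"{sample}::{ctype}"
        included = len(idx) >= min_cells
        meta.append(
            {
                "group": name,
                "donor_or_sample_id": sample,
                "cell_type_label": ctype,
                "n_cells": len(idx),
                "included": included,
            }
        )
        if not included:
            continue
        block = mat[:, idx]
        total = np.asarray(block.sum(axis=1)).ravel()
        cols[name] = total / len(idx) if statistic == "mean" else total
    if not cols:
        raise ValueError("no group meets min_cells; nothing to aggregate")
    df = pd.DataFrame(cols, index=list(gene_ids))
    return ExpressionMatrix(df, unit="counts"), pd.DataFrame(meta)
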