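"""Cell-level quality filtering and replicate consistency.

Thresholds are strict inequalities exactly as specified for the assay this
pipeline models: cells are kept with > 200,000 aligned reads, < 2%
ribosomal reads and > 2000 genes expressed; boundary values fail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .io_core import ExpressionMatrix

logger = logging.getLogger("kerahet")


@dataclass
class QCThresholds:
    min_aligned_reads: int = 200_000
    max_ribosomal_pct: float = 2.0
    min_genes_expressed: int = 2000
    min_replicate_correlation: float = 0.96

    def __post_init__(self) -> None:
        for name in ("min_aligned_reads", "max_ribosomal_pct",
                     "min_genes_expressed", "min_replicate_correlation"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.max_ribosomal_pct > 100:
            raise ValueError("max_ribosomal_pct cannot exceed 100")


def genes_expressed_per_cell(
    expr: ExpressionMatrix, tpm_threshold: float = 1.0
) -> pd.Series:
    """Number of genes with TPM strictly above ``tpm_threshold`` per cell."""
    if not tpm_threshold > 0:
        raise ValueError("tpm_threshold must be > 0")
    counts = (expr.values > tpm_threshold).sum(axis=0)
    return pd.Series(counts, index=expr.cells, name="genes_expressed")


def filter_cells(
    expr: ExpressionMatrix,
    qc_table: pd.DataFrame,
    thresholds: QCThresholds | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Retain cells passing all three QC rules (strict inequalities).

    ``qc_table`` needs columns ``cell_id``, ``aligned_reads`` and
    ``ribosomal_pct``; ``genes_expressed`` is computed from the matrix at
    TPM > 1 when absent.  Returns the filtered matrix and a report with one
    row per removed cell naming the violated rule(s).
    """
    if thresholds is None:
        thresholds = QCThresholds()
    qc = qc_table.set_index("cell_id")
    missing = [c for c in expr.cells if c not in qc.index]
    if missing:
        raise KeyError(f"cell {missing[0]!r} missing from QC table")
    qc = qc.loc[expr.cells]
    if "genes_expressed" not in qc.columns:
        qc = qc.assign(genes_expressed=genes_expressed_per_cell(expr).to_numpy())

    reads_ok = qc["aligned_reads"].to_numpy() > thresholds.min_aligned_reads
    ribo_ok = qc["ribosomal_pct"].to_numpy() < thresholds.max_ribosomal_pct
    genes_ok = qc["genes_expressed"].to_numpy() > thresholds.min_genes_expressed
    keep = reads_ok & ribo_ok & genes_ok

    rule_names = np.array(["aligned_reads", "ribosomal_pct", "genes_expressed"])
    rows = []
    for i, cell in enumerate(expr.cells):
        if keep[i]:
            continue
        failed = rule_names[~np.array([reads_ok[i], ribo_ok[i], genes_ok[i]])]
        rows.append(
            {
                "cell_id": cell,
                "aligned_reads": qc["aligned_reads"].iloc[i],
                "ribosomal_pct": qc["ribosomal_pct"].iloc[i],
                "genes_expressed": qc["genes_expressed"].iloc[i],
                "failed_rules": ",".join(failed),
            }
        )
    report = pd.DataFrame(
        rows,
        columns=["cell_id", "aligned_reads", "ribosomal_pct",
                 "genes_expressed", "failed_rules"],
    )
    kept_cells = [c for c, k in zip(expr.cells, keep) if k]
    logger.info("QC retained %d / %d cells", len(kept_cells), len(expr.cells))
    return expr.subset_cells(kept_cells), report


def replicate_consistency(
    expr: ExpressionMatrix,
    annotation: pd.DataFrame,
    min_correlation: float = 0.96,
) -> pd.DataFrame:
    """Pairwise Pearson r between pooled replicate profiles per condition.

    Cells are pooled by summing TPM within each replicate; correlations are
    computed on log2(pooled + 1).  Pairs below ``min_correlation`` are
    flagged.
    """
    ann = annotation.set_index("cell_id").loc[expr.cells]
    rows = []
    for cond, sub in ann.groupby("condition", sort=True):
        reps = sorted(sub["replicate"].unique())
        if len(reps) < 2:
            raise ValueError(f"condition {cond!r} has fewer than 2 replicates")
        profiles = {}
        for rep in reps:
            cells = sub.index[sub["replicate"] == rep]
            if len(cells) == 0:
                raise ValueError(f"replicate {rep!r} has no cells")
            idx = [expr.cells.index(c) for c in cells]
            profiles[rep] = np.log2(expr.values[:, idx].sum(axis=1) + 1.0)
        for a, b in combinations(reps, 2):
            r = pearsonr(profiles[a], profiles[b]).statistic
            rows.append(
                {
                    "condition": cond,
                    "replicate_a": a,
                    "replicate_b": b,
                    "pearson_r": r,
                    "flagged": bool(r < min_correlation),
                }
            )
    return pd.DataFrame(rows)
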