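"""Pseudotransition-dependent gene dynamics and TF over-representation.

Each gene's log2(TPM+1) is modelled as a smooth function of pseudotime via
a natural cubic spline basis (3 df, the classic trajectory default) and
compared against an intercept-only null with a Gaussian likelihood-ratio
test (chi-square reference, df = spline df); BH adjustment gives the FDR.
Dynamic genes are grouped into temporal patterns by Ward hierarchical
clustering of their z-scored fitted curves, and transcription factors are
scored for over-representation of their target genes among the dynamic
set with a one-sided hypergeometric test.

The TF expression filter follows the original convention of natural log:
a TF counts as expressed when its mean ln(TPM+1) exceeds the threshold in
at least one state; unexpressed TFs are removed before FDR correction.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import chi2, hypergeom

from .io_core import AnalysisConfig, ExpressionMatrix, GeneSetCollection, bh_adjust

logger = logging.getLogger("kerahet")

ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII"]


def natural_cubic_basis(
    t: np.ndarray, df: int = 3, knots: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Natural cubic spline basis with ``df`` columns (no intercept).

    Knots are the min/max of ``t`` plus ``df - 1`` interior quantiles.
    Returns ``(basis, knots)`` so the same basis can be evaluated on a
    prediction grid.
    """
    t = np.asarray(t, dtype=float)
    if knots is None:
        qs = np.linspace(0, 1, df + 1)
        knots = np.quantile(t, qs)
        knots = np.unique(knots)
        if len(knots) < 2:
            raise ValueError("pseudotime values are all identical")
    K = len(knots)

    def d(j: int, x: np.ndarray) -> np.ndarray:
        num = np.clip(x - knots[j], 0, None) ** 3 - np.clip(x - knots[K - 1], 0, None) ** 3
        return num / (knots[K - 1] - knots[j])

    cols = [t]
    for j in range(K - 2):
        cols.append(d(j, t) - d(K - 2, t))
    return np.column_stack(cols), knots


def detect_dynamic_genes(
    expr: ExpressionMatrix,
    annotation: pd.DataFrame,
    config: AnalysisConfig | None = None,
    analysis_genes: list[str] | None = None,
    spline_df: int = 3,
) -> pd.DataFrame:
    """Likelihood-ratio test of spline-of-pseudotime vs constant, per gene."""
    config = config or AnalysisConfig()
    sub = expr if analysis_genes is None else expr.subset_genes(analysis_genes)
    ann = annotation.set_index("cell_id").loc[sub.cells]
    on_path = ann["pseudotime"].notna().to_numpy()
    if on_path.sum() < 20:
        raise ValueError("need at least 20 on-path cells with pseudotime")
    t = ann["pseudotime"].to_numpy(dtype=float)[on_path]
    Y = sub.log2p1()[:, on_path]  # genes x cells
    n = len(t)
    basis, _ = natural_cubic_basis(t, df=spline_df)
    X = np.column_stack([np.ones(n), basis])
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    rss1 = np.sum((Y.T - X @ beta) ** 2, axis=0)
    rss0 = Y.var(axis=1) * n
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = n * np.log(rss0 / rss1)
    constant = rss0 <= n * 1e-12  # flat gene: both models fit exactly
    stat = np.where(constant | ~np.isfinite(stat), 0.0, np.maximum(stat, 0.0))
    df_test = X.shape[1] - 1
    p = chi2.sf(stat, df_test)
    q = bh_adjust(p)
    return pd.DataFrame(
        {
            "gene": sub.genes,
            "lrt_statistic": stat,
            "p": p,
            "fdr_q": q,
            "dynamic": q < config.dynamic_fdr,
        }
    )


def fitted_curves(
    expr: ExpressionMatrix,
    annotation: pd.DataFrame,
    genes: list[str],
    grid_size: int = 50,
    spline_df: int = 3,
) -> pd.DataFrame:
    """Spline-fitted log2(TPM+1) curves on a fixed pseudotime grid."""
    sub = expr.subset_genes(genes)
    ann = annotation.set_index("cell_id").loc[sub.cells]
    on_path = ann["pseudotime"].notna().to_numpy()
    t = ann["pseudotime"].to_numpy(dtype=float)[on_path]
    Y = sub.log2p1()[:, on_path]
    basis, knots = natural_cubic_basis(t, df=spline_df)
    X = np.column_stack([np.ones(len(t)), basis])
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    grid = np.linspace(t.min(), t.max(), grid_size)
    gbasis, _ = natural_cubic_basis(grid, df=spline_df, knots=knots)
    G = np.column_stack([np.ones(grid_size), gbasis])
    curves = (G @ beta).T  # genes x grid
    return pd.DataFrame(curves, index=genes, columns=grid)


def cluster_temporal_patterns(
    expr: ExpressionMatrix,
    annotation: pd.DataFrame,
    dynamic_genes: list[str],
    k: int = 4,
    grid_size: int = 50,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group dynamic genes into ``k`` temporal patterns.

    Fitted curves are z-scored per gene and clustered by Ward-linkage
    agglomerative clustering; clusters are numbered I.. in order of
    increasing mean peak position, and within the global ordering genes are
    sorted by the argmax of their fitted curve (``peak_pseudotime``).
    Returns ``(assignments, curves)``.
    """
    if k > len(dynamic_genes):
        raise ValueError("more clusters requested than dynamic genes")
    curves = fitted_curves(expr, annotation, dynamic_genes, grid_size=grid_size)
    grid = curves.columns.to_numpy(dtype=float)
    Z = curves.to_numpy()
    sd = Z.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    zed = (Z - Z.mean(axis=1, keepdims=True)) / sd[:, None]
    labels = fcluster(linkage(zed, method="ward"), t=k, criterion="maxclust")
    peak = grid[np.argmax(Z, axis=1)]
    # canonical numbering: cluster I peaks earliest
    order = np.argsort(
        [peak[labels == c].mean() for c in range(1, k + 1)], kind="stable"
    )
    rename = {c + 1: ROMAN[i] for i, c in enumerate(order)}
    out = pd.DataFrame(
        {
            "gene": dynamic_genes,
            "temporal_cluster": [rename[l] for l in labels],
            "peak_pseudotime": peak,
        }
    ).sort_values("peak_pseudotime", kind="stable").reset_index(drop=True)
    return out, curves


def proliferation_index(
    expr: ExpressionMatrix, s_phase_markers: list[str]
) -> pd.Series:
    """Per-cell proliferation index in [0, 1] from S-phase marker genes.

    Marker log2(TPM+1) values are z-scored across cells (zero-variance
    markers dropped with a warning), averaged per cell, then min-max
    rescaled to [0, 1].
    """
    present = [g for g in s_phase_markers if g in set(expr.genes)]
    if not present:
        raise ValueError(
            f"no S-phase markers present in matrix; missing: {s_phase_markers}"
        )
    L = expr.subset_genes(present).log2p1()
    sd = L.std(axis=1, ddof=0)
    keep = sd > 0
    if not keep.all():
        dropped = [g for g, k in zip(present, keep) if not k]
        logger.warning("dropping zero-variance S-phase markers: %s", dropped)
    if not keep.any():
        raise ValueError("all S-phase markers are constant across cells")
    Lk = L[keep]
    z = (Lk - Lk.mean(axis=1, keepdims=True)) / sd[keep][:, None]
    idx = z.mean(axis=0)
    rng_ = idx.max() - idx.min()
    if rng_ == 0:
        raise ValueError("proliferation index is constant across cells")
    scaled = (idx - idx.min()) / rng_
    return pd.Series(scaled, index=expr.cells, name="proliferation_index")


def tf_overrepresentation(
    dynamic_genes: list[str],
    universe: list[str],
    tf_targets: GeneSetCollection,
    expr: ExpressionMatrix,
    annotation: pd.DataFrame,
    config: AnalysisConfig | None = None,
    end_states: tuple[str, str] = ("A", "D"),
) -> pd.DataFrame:
    """Hypergeometric TF-target over-representation among dynamic genes.

    Per TF, the one-sided hypergeometric tail probability of the overlap
    between its target set (intersected with the universe) and the dynamic
    gene set.  TFs whose own expression never reaches mean ln(TPM+1) >
    ``tf_expression_threshold`` in any state are filtered before BH
    correction (kept in the table with ``expressed = False`` and missing
    q).  Directionality is the log2 fold change of mean TPM (+1) between
    the designated end states, with a ``direction_deadband`` neutral zone.
    """
    config = config or AnalysisConfig()
    uni = set(universe)
    dyn = set(dynamic_genes) & uni
    if not set(dynamic_genes) <= uni:
        raise ValueError("dynamic genes must be a subset of the universe")
    M, N = len(uni), len(dyn)

    ann = annotation.set_index("cell_id").loc[expr.cells]
    state_arr = ann["state"].to_numpy()
    states = sorted(pd.unique(state_arr))
    gene_pos = {g: i for i, g in enumerate(expr.genes)}
    ln1p = np.log(expr.values + 1.0)
    state_masks = {s: state_arr == s for s in states}

    rows = []
    for tf, targets in tf_targets.sets.items():
        tset = set(targets) & uni
        n_t = len(tset)
        overlap = len(tset & dyn)
        if tf in gene_pos:
            gi = gene_pos[tf]
            max_state_mean = max(
                float(ln1p[gi, m].mean()) for m in state_masks.values()
            )
            expressed = max_state_mean > config.tf_expression_threshold
            a, b = end_states
            mean_a = float(expr.values[gi, state_masks[a]].mean()) if a in state_masks else np.nan
            mean_b = float(expr.values[gi, state_masks[b]].mean()) if b in state_masks else np.nan
            lfc = float(np.log2((mean_b + 1.0) / (mean_a + 1.0)))
        else:
            logger.warning("TF %r absent from expression matrix; filtered", tf)
            expressed = False
            lfc = np.nan
        if np.isnan(lfc):
            direction = "neutral"
        elif lfc > config.direction_deadband:
            direction = "positive"
        elif lfc < -config.direction_deadband:
            direction = "negative"
        else:
            direction = "neutral"
        p = (
            float(hypergeom.sf(overlap - 1, M, n_t, N)) if n_t > 0 else np.nan
        )
        rows.append(
            {
                "tf": tf,
                "n_targets_in_universe": n_t,
                "n_targets_dynamic": overlap,
                "p": p,
                "expressed": expressed,
                "direction": direction,
                "log2_fc_endstates": lfc,
            }
        )
    out = pd.DataFrame(rows)
    q = np.full(len(out), np.nan)
    mask = out["expressed"].to_numpy(dtype=bool) & out["p"].notna().to_numpy()
    q[mask] = bh_adjust(out.loc[mask, "p"].to_numpy())
    out["q"] = q
    return out
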