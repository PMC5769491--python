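"""Heterogeneity statistics.

The core quantities are the per-cell transcriptome coefficient of variation
(TCOV: sd/mean of log2(TPM+1) across analysis genes, an intracellular
spread measure), per-gene per-state CVs (intercellular variability), the
mean-centred two-sample Kolmogorov-Smirnov differential-dispersion test
with a CV fold-change filter, and a mean-rank gene-set enrichment test on
per-gene scores.

``ks_two_sample`` is the single KS implementation used by every stage
(dispersion, TCOV state contrasts, pseudotransition densities, spatial
condition comparisons): the statistic is the exact supremum ECDF
difference and the p-value comes from the asymptotic Kolmogorov
distribution at effective sample size ``m*n/(m+n)``.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy.special import kolmogorov
from scipy.stats import norm, rankdata

from .io_core import AnalysisConfig, ExpressionMatrix, GeneSetCollection, bh_adjust

logger = logging.getLogger("kerahet")


# ---------------------------------------------------------------------------
# two-sample KS (shared primitive)
# ---------------------------------------------------------------------------


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test.

    Returns ``(D, p)`` with ``D = sup_t |F_x(t) - F_y(t)|`` evaluated
    exactly (ties handled by evaluating at run ends) and the asymptotic
    p-value ``P(K > sqrt(en) * D)`` with ``en = m n / (m + n)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    D, p = ks_two_sample_many(x[None, :], y[None, :])
    return float(D[0]), float(p[0])


def ks_two_sample_many(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise two-sample KS over paired samples ``X[i]`` vs ``Y[i]``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    m, n = X.shape[1], Y.shape[1]
    if m == 0 or n == 0:
        raise ValueError("both samples must be non-empty")
    data = np.concatenate([X, Y], axis=1)
    order = np.argsort(data, axis=1, kind="stable")
    v = np.take_along_axis(data, order, axis=1)
    from_x = order < m
    step = np.where(from_x, 1.0 / m, -1.0 / n)
    diff = np.abs(np.cumsum(step, axis=1))
    # the ECDF difference is only evaluable where the next value differs
    valid = np.ones_like(diff, dtype=bool)
    valid[:, :-1] = v[:, :-1] != v[:, 1:]
    diff = np.where(valid, diff, 0.0)
    D = diff.max(axis=1)
    en = m * n / (m + n)
    p = kolmogorov(math.sqrt(en) * D)
    return D, np.asarray(p)


# ---------------------------------------------------------------------------
# rank-sum (shared by marker detection and set enrichment)
# ---------------------------------------------------------------------------


def _tie_term_rows(X: np.ndarray) -> np.ndarray:
    """Per-row sum of t^3 - t over tied-value runs."""
    out = np.zeros(X.shape[0])
    for i in range(X.shape[0]):
        _, counts = np.unique(X[i], return_counts=True)
        t = counts[counts > 1].astype(float)
        out[i] = np.sum(t**3 - t)
    return out


def rank_sum_many(
    X: np.ndarray,
    group1: np.ndarray,
    ranks: np.ndarray | None = None,
    tie_term: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise two-sided Mann-Whitney / Wilcoxon rank-sum test.

    Normal approximation with tie correction and continuity correction,
    comparing columns where ``group1`` is True against the rest.  Returns
    ``(U1, p)``.  ``ranks`` / ``tie_term`` may be precomputed to amortise
    work across many group assignments (e.g. permutation nulls).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    group1 = np.asarray(group1, dtype=bool)
    n1 = int(group1.sum())
    n2 = int((~group1).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    N = n1 + n2
    if ranks is None:
        ranks = rankdata(X, axis=1)
    if tie_term is None:
        tie_term = _tie_term_rows(X)
    R1 = ranks[:, group1].sum(axis=1)
    U1 = R1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((N + 1) - tie_term / (N * (N - 1.0)))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (np.abs(U1 - mu) - 0.5) / np.sqrt(var)
    z = np.where(var > 0, np.maximum(z, 0.0), 0.0)
    p = np.where(var > 0, np.minimum(2.0 * norm.sf(z), 1.0), 1.0)
    return U1, p


# ---------------------------------------------------------------------------
# TCOV
# ---------------------------------------------------------------------------


def tcov(
    expr: ExpressionMatrix,
    annotation: pd.DataFrame | None = None,
    analysis_genes: list[str] | None = None,
    tpm_threshold: float = 1.0,
) -> pd.DataFrame:
    """Per-cell transcriptome coefficient of variation.

    TCOV is the sample standard deviation divided by the mean of
    log2(TPM+1) over the analysis genes; ``n_genes_expressed`` counts genes
    at TPM > ``tpm_threshold`` over the full matrix.  A cell with zero mean
    gets a missing TCOV (warned).
    """
    sub = expr if analysis_genes is None else expr.subset_genes(analysis_genes)
    if sub.shape[0] < 2:
        raise ValueError("need at least 2 analysis genes")
    L = sub.log2p1()
    mean = L.mean(axis=0)
    sd = L.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.where(mean > 0, sd / mean, np.nan)
    if np.any(mean <= 0):
        logger.warning("%d cell(s) have zero mean log-expression; TCOV missing",
                       int((mean <= 0).sum()))
    n_expr = (expr.values > tpm_threshold).sum(axis=0)
    out = pd.DataFrame(
        {"cell_id": expr.cells, "tcov": vals, "n_genes_expressed": n_expr}
    )
    if annotation is not None:
        ann = annotation.set_index("cell_id")
        out["state"] = ann.loc[out["cell_id"], "state"].to_numpy()
        out["pseudotime"] = ann.loc[out["cell_id"], "pseudotime"].to_numpy()
    return out


def loess_fit(
    x: np.ndarray,
    y: np.ndarray,
    grid: np.ndarray,
    span: float = 0.75,
    degree: int = 2,
) -> np.ndarray:
    """Locally weighted polynomial regression (tricube weights)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    k = max(int(math.ceil(span * n)), degree + 2)
    k = min(k, n)
    fitted = np.empty(len(grid))
    for i, g in enumerate(grid):
        d = np.abs(x - g)
        dmax = np.partition(d, k - 1)[k - 1]
        if dmax == 0:
            fitted[i] = y[d == 0].mean()
            continue
        w = np.clip(1.0 - (d / dmax) ** 3, 0.0, None) ** 3
        use = w > 0
        deg = min(degree, max(len(np.unique(x[use])) - 1, 0))
        coef = np.polyfit(x[use] - g, y[use], deg, w=np.sqrt(w[use]))
        fitted[i] = coef[-1]
    return fitted


def tcov_trend(
    records: pd.DataFrame,
    span: float = 0.75,
    grid_size: int = 50,
    start_state: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Loess fit of TCOV on pseudotime plus start-state KS contrasts.

    Returns ``(curve, ks_table)``: the fitted curve on a fixed [0, 1] grid
    and two-sample KS tests of TCOV between the start state (lowest mean
    pseudotime by default) and each other on-path state.
    """
    rec = records.dropna(subset=["tcov", "pseudotime"])
    if len(rec) < 10:
        raise ValueError("need at least 10 on-path cells with TCOV")
    t = rec["pseudotime"].to_numpy(dtype=float)
    if np.ptp(t) == 0:
        raise ValueError("all pseudotimes identical; no trend to fit")
    grid = np.linspace(t.min(), t.max(), grid_size)
    fit = loess_fit(t, rec["tcov"].to_numpy(dtype=float), grid, span=span)
    curve = pd.DataFrame({"pseudotime": grid, "tcov_fit": fit})

    ks_rows = []
    if "state" in rec.columns:
        means = rec.groupby("state")["pseudotime"].mean()
        if start_state is None:
            start_state = means.idxmin()
        ref = rec.loc[rec["state"] == start_state, "tcov"].to_numpy()
        for st in sorted(means.index):
            if st == start_state:
                continue
            other = rec.loc[rec["state"] == st, "tcov"].to_numpy()
            D, p = ks_two_sample(ref, other)
            ks_rows.append(
                {"state_a": start_state, "state_b": st, "ks_statistic": D, "p": p}
            )
    return curve, pd.DataFrame(ks_rows, columns=["state_a", "state_b", "ks_statistic", "p"])


# ---------------------------------------------------------------------------
# differential dispersion
# ---------------------------------------------------------------------------


def _group_cv(values: np.ndarray, scale: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene (CV, mean) for a gene x cell block; mean 0 -> CV NaN."""
    if scale == "log":
        values = np.log2(values + 1.0)
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean, np.nan)
    return cv, values.mean(axis=1) if scale == "log" else mean


def differential_dispersion(
    expr: ExpressionMatrix,
    annotation: pd.DataFrame,
    config: AnalysisConfig | None = None,
    states: list[str] | None = None,
    analysis_genes: list[str] | None = None,
) -> pd.DataFrame:
    """Per-gene, per-state differential dispersion (state vs rest).

    log2(TPM+1) values are mean-centred within each group and compared with
    the two-sample KS test; BH adjustment is applied across genes within
    each state.  CVs are computed on linear TPM (configurable).  A gene is
    differentially dispersed in a state when ``q < dispersion_alpha`` and
    ``|log2 CV ratio| > log2(cv_fold_threshold)``; genes with an undefined
    CV in either group stay in the table unflagged.

    Zero-expression handling: the non-detection class (TPM == 0) forms a
    point mass which own-group centring would shift to two slightly
    different locations (offset by the sampling noise of the group means),
    letting the KS statistic count the whole dropout mass as spurious
    signal.  Centred zeros are therefore re-aligned to a common per-gene
    location below the residual range in both groups, so a *difference in
    dropout fraction* still registers as dispersion signal while identical
    distributions stay null.  For the continuous part, own-group centring
    is slightly conservative, as for any location-adjusted KS test.
    """
    config = config or AnalysisConfig()
    sub = expr if analysis_genes is None else expr.subset_genes(analysis_genes)
    ann = annotation.set_index("cell_id").loc[sub.cells]
    state_col = ann["state"].to_numpy()
    all_states = states if states is not None else sorted(pd.unique(state_col))
    L = sub.log2p1()
    V = sub.values
    log2_fold = math.log2(config.cv_fold_threshold)

    frames = []
    for st in all_states:
        in_state = state_col == st
        n_s, n_r = int(in_state.sum()), int((~in_state).sum())
        if n_s < 3 or n_r < 3:
            logger.warning("state %r skipped: %d vs %d cells (< 3)", st, n_s, n_r)
            continue
        Ls = L[:, in_state]
        Lr = L[:, ~in_state]
        Rs = Ls - Ls.mean(axis=1, keepdims=True)
        Rr = Lr - Lr.mean(axis=1, keepdims=True)
        # align the dropout point mass across groups (see docstring)
        zero_s = V[:, in_state] == 0
        zero_r = V[:, ~in_state] == 0
        sentinel = np.minimum(Rs.min(axis=1), Rr.min(axis=1)) - 1.0
        Rs = np.where(zero_s, sentinel[:, None], Rs)
        Rr = np.where(zero_r, sentinel[:, None], Rr)
        D, p = ks_two_sample_many(Rs, Rr)
        q = bh_adjust(p)
        cv_s, mean_s = _group_cv(V[:, in_state], config.cv_scale)
        cv_r, mean_r = _group_cv(V[:, ~in_state], config.cv_scale)
        with np.errstate(divide="ignore", invalid="ignore"):
            log_cv_ratio = np.log2(cv_s / cv_r)
            log_mean_ratio = np.log2((mean_s + 1.0) / (mean_r + 1.0))
        finite = np.isfinite(log_cv_ratio)
        flag = finite & (q < config.dispersion_alpha) & (np.abs(log_cv_ratio) > log2_fold)
        frames.append(
            pd.DataFrame(
                {
                    "gene": sub.genes,
                    "state": st,
                    "cv_state": cv_s,
                    "cv_rest": cv_r,
                    "log2_cv_ratio": log_cv_ratio,
                    "mean_state": mean_s,
                    "mean_rest": mean_r,
                    "log2_mean_ratio": log_mean_ratio,
                    "ks_statistic": D,
                    "p": p,
                    "q": q,
                    "differentially_dispersed": flag,
                }
            )
        )
    if not frames:
        raise ValueError("no state had enough cells for dispersion testing")
    return pd.concat(frames, ignore_index=True)


def cv_expression_scatter(
    expr: ExpressionMatrix,
    annotation: pd.DataFrame,
    state_a: str,
    state_b: str,
    analysis_genes: list[str] | None = None,
    cv_scale: str = "linear",
) -> pd.DataFrame:
    """Per-gene log2 CV ratio vs log2 mean ratio between two states."""
    sub = expr if analysis_genes is None else expr.subset_genes(analysis_genes)
    ann = annotation.set_index("cell_id").loc[sub.cells]
    state_col = ann["state"].to_numpy()
    for st in (state_a, state_b):
        if not np.any(state_col == st):
            raise ValueError(f"state {st!r} absent from annotation")
    cv_a, mean_a = _group_cv(sub.values[:, state_col == state_a], cv_scale)
    cv_b, mean_b = _group_cv(sub.values[:, state_col == state_b], cv_scale)
    with np.errstate(divide="ignore", invalid="ignore"):
        lcv = np.log2(cv_a / cv_b)
        lmean = np.log2((mean_a + 1.0) / (mean_b + 1.0))
    out = pd.DataFrame(
        {"gene": sub.genes, "log2_cv_ratio": lcv, "log2_mean_ratio": lmean}
    )
    return out[np.isfinite(lcv)].reset_index(drop=True)


def top_cv_ratio_genes(scatter: pd.DataFrame, k: int = 10) -> tuple[list[str], list[str]]:
    """The k genes with the highest and the k with the lowest signed
    log2 CV ratio (the labelled extremes of the CV-vs-expression scatter)."""
    ordered = scatter.sort_values("log2_cv_ratio", ascending=False)
    return list(ordered["gene"].head(k)), list(ordered["gene"].tail(k)[::-1])


# ---------------------------------------------------------------------------
# mean-rank gene set enrichment
# ---------------------------------------------------------------------------


def mean_rank_enrichment(
    scores: pd.Series, sets: GeneSetCollection
) -> pd.DataFrame:
    """Mean-rank gene-set enrichment on a per-gene score vector.

    Genes are ranked by score (ascending, average ranks for ties); each set
    is tested by a two-sided Wilcoxon rank-sum comparison of in-set vs
    out-of-set ranks (normal approximation, tie and continuity corrected).
    A set equal to the whole universe has no out-group and gets p = 1; a
    set with no genes in the universe gets a missing p.  BH across sets.
    """
    scores = scores.astype(float)
    if len(scores) < 2:
        raise ValueError("need at least 2 genes with scores")
    universe = set(scores.index)
    ranks = pd.Series(rankdata(scores.to_numpy()), index=scores.index)
    members = sets.intersect_universe(universe)
    X = scores.to_numpy()[None, :]
    tie_term = _tie_term_rows(X)
    rows = []
    for name, genes in members.items():
        n1 = len(genes)
        if n1 == 0:
            rows.append({"set": name, "n_genes": 0, "mean_rank": np.nan, "p": np.nan})
            continue
        mean_rank = float(ranks.loc[genes].mean())
        if n1 == len(scores):
            rows.append({"set": name, "n_genes": n1, "mean_rank": mean_rank, "p": 1.0})
            continue
        mask = scores.index.isin(genes)
        _, p = rank_sum_many(X, mask, ranks=ranks.to_numpy()[None, :], tie_term=tie_term)
        rows.append({"set": name, "n_genes": n1, "mean_rank": mean_rank, "p": float(p[0])})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out
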