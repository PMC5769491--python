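"""Cell state map, marker genes and pseudotransition ordering.

Workflows of this kind typically build the state map and pseudotime with
DDRTree/Monocle2.  DDRTree is a published external method and is *not*
re-implemented here; this module provides a documented simplified stand-in
(PCA embedding, partitioning-around-medoids clustering, minimum-spanning-
tree pseudotime over cluster centroids).  All downstream stages accept
externally computed ``state`` / ``pseudotime`` columns, so Monocle outputs
can be substituted directly.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.decomposition import PCA

from .io_core import AnalysisConfig, ExpressionMatrix, bh_adjust
from .heterogeneity import rank_sum_many

logger = logging.getLogger("kerahet")

STATE_LETTERS = "ABCDEFGHIJ"


# ---------------------------------------------------------------------------
# analysis gene selection
# ---------------------------------------------------------------------------


def select_analysis_genes(
    expr: ExpressionMatrix,
    config: AnalysisConfig | None = None,
    cell_cycle_genes: list[str] | None = None,
) -> list[str]:
    """Expressed genes (TPM > threshold in strictly more than
    ``expressed_min_cells`` cells) minus the cell-cycle list."""
    config = config or AnalysisConfig()
    exclude = set(cell_cycle_genes or ())
    n_expr = (expr.values > config.expressed_tpm_threshold).sum(axis=1)
    keep = [
        g
        for g, n in zip(expr.genes, n_expr)
        if n > config.expressed_min_cells and g not in exclude
    ]
    if not keep:
        raise ValueError(
            "no genes pass the expression filter; lower expressed_tpm_threshold "
            "or expressed_min_cells"
        )
    return keep


# ---------------------------------------------------------------------------
# embedding + clustering (DDRTree stand-in)
# ---------------------------------------------------------------------------


def pc_scores(
    expr: ExpressionMatrix,
    genes: list[str] | None = None,
    n_components: int = 10,
    seed: int = 0,
    n_hvg: int | None = 1000,
) -> np.ndarray:
    """Cell scores on the top principal components of log2(TPM+1).

    The embedding is computed on the ``n_hvg`` most variable genes (by
    log-expression variance) of the supplied gene list, the usual
    ordering-gene restriction that keeps state structure from being
    diluted by thousands of uninformative genes.  ``n_hvg=None`` uses all
    genes.
    """
    sub = expr if genes is None else expr.subset_genes(genes)
    L = sub.log2p1()
    if n_hvg is not None and n_hvg < L.shape[0]:
        top = np.sort(np.argsort(L.var(axis=1))[::-1][:n_hvg])
        L = L[top]
    L = L.T  # cells x genes
    if np.allclose(L.var(axis=0), 0):
        raise ValueError("expression matrix has zero variance; cannot embed")
    n_components = min(n_components, L.shape[0] - 1, L.shape[1])
    pca = PCA(n_components=n_components, svd_solver="full", random_state=seed)
    scores = pca.fit_transform(L)
    # deterministic sign convention: largest-|loading| coordinate positive
    for j in range(scores.shape[1]):
        k = np.argmax(np.abs(scores[:, j]))
        if scores[k, j] < 0:
            scores[:, j] *= -1
    return scores


def _pam(dist: np.ndarray, k: int, seed: int, max_iter: int = 100) -> np.ndarray:
    """Partitioning around medoids on a precomputed distance matrix.

    Greedy BUILD initialisation followed by SWAP steps until no single
    medoid swap lowers total cost.  Deterministic given the matrix (seed is
    only used to break exact cost ties)."""
    n = dist.shape[0]
    rng = np.random.default_rng(seed)
    # BUILD: first medoid minimises total distance, then greedy additions
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    while len(medoids) < k:
        current = dist[:, medoids].min(axis=1)
        gains = np.maximum(current[None, :] - dist, 0).sum(axis=1)
        gains[medoids] = -np.inf
        best = np.flatnonzero(gains == gains.max())
        medoids.append(int(rng.choice(best)) if len(best) > 1 else int(best[0]))
    medoids = np.array(medoids)

    def cost(meds: np.ndarray) -> float:
        return float(dist[:, meds].min(axis=1).sum())

    best_cost = cost(medoids)
    for _ in range(max_iter):
        improved = False
        for mi in range(k):
            others = np.setdiff1d(np.arange(n), medoids)
            trial = medoids.copy()
            costs = np.empty(len(others))
            for j, cand in enumerate(others):
                trial[mi] = cand
                costs[j] = cost(trial)
            jbest = int(np.argmin(costs))
            if costs[jbest] < best_cost - 1e-12:
                medoids[mi] = others[jbest]
                best_cost = costs[jbest]
                improved = True
        if not improved:
            break
    return medoids


def select_ordering_genes(
    expr: ExpressionMatrix,
    labels: np.ndarray,
    genes: list[str] | None = None,
    n_per_state: int = 50,
) -> list[str]:
    """Genes most differentially expressed between provisional clusters.

    Per cluster, the ``n_per_state`` genes with the largest absolute mean
    log2(TPM+1) difference vs the rest; the union over clusters.  Unlike a
    plain high-variance selection this excludes genes whose variability
    carries no mean shift between states, so state-specific noise does not
    dominate the embedding.
    """
    sub = expr if genes is None else expr.subset_genes(genes)
    L = sub.log2p1()
    labels = np.asarray(labels)
    chosen: set[int] = set()
    for c in pd.unique(labels):
        in_c = labels == c
        d = np.abs(L[:, in_c].mean(axis=1) - L[:, ~in_c].mean(axis=1))
        chosen.update(np.argsort(d)[::-1][:n_per_state].tolist())
    idx = np.sort(np.fromiter(chosen, dtype=int))
    return [sub.genes[i] for i in idx]


def embed_and_cluster(
    expr: ExpressionMatrix,
    genes: list[str] | None = None,
    k_states: int = 5,
    seed: int = 0,
    n_components: int = 10,
) -> pd.DataFrame:
    """2-D PCA embedding plus PAM clustering into ``k_states`` states.

    Two rounds: a provisional PAM clustering on the top principal
    components of the most variable genes, then cluster-informed ordering
    genes (see :func:`select_ordering_genes`) and a final PCA + PAM on
    those.  Cluster labels are letters assigned canonically by descending
    cluster size (ties broken by medoid index), so labels are stable
    across runs.  Returns a frame with ``cell_id``, ``emb_x``, ``emb_y``,
    ``state``; the ordering genes used are attached as
    ``df.attrs['ordering_genes']`` for reuse by the pseudotransition.
    """
    if k_states < 2:
        raise ValueError("k_states must be >= 2")
    if len(expr.cells) < k_states:
        raise ValueError("fewer cells than requested states")

    def _cluster(scores: np.ndarray) -> np.ndarray:
        dist = squareform(pdist(scores))
        medoids = _pam(dist, k_states, seed=seed)
        return np.argmin(dist[:, medoids], axis=1), medoids

    scores0 = pc_scores(expr, genes, n_components=n_components, seed=seed)
    assign0, _ = _cluster(scores0)
    ordering = select_ordering_genes(expr, assign0, genes)
    scores = pc_scores(expr, ordering, n_components=n_components, seed=seed, n_hvg=None)
    assign, medoids = _cluster(scores)
    sizes = np.bincount(assign, minlength=k_states)
    order = sorted(range(k_states), key=lambda c: (-sizes[c], medoids[c]))
    relabel = {c: STATE_LETTERS[i] for i, c in enumerate(order)}
    out = pd.DataFrame(
        {
            "cell_id": expr.cells,
            "emb_x": scores[:, 0],
            "emb_y": scores[:, 1] if scores.shape[1] > 1 else 0.0,
            "state": [relabel[a] for a in assign],
        }
    )
    out.attrs["ordering_genes"] = ordering
    return out


# ---------------------------------------------------------------------------
# marker genes
# ---------------------------------------------------------------------------


def find_markers(
    expr: ExpressionMatrix,
    annotation: pd.DataFrame,
    config: AnalysisConfig | None = None,
    analysis_genes: list[str] | None = None,
) -> pd.DataFrame:
    """State-vs-rest marker genes with covariate adjustment.

    log2(TPM+1) is regressed on log10(aligned reads) and replicate (when
    those annotation columns exist); a two-sided Mann-Whitney rank test is
    applied to the residuals per gene per state, with BH adjustment across
    genes within each state.  Rows are filtered to
    ``|log2FC| > de_lfc_threshold`` (pseudocount 1 on state means) and
    ``adjusted_p < de_alpha``.
    """
    config = config or AnalysisConfig()
    sub = expr if analysis_genes is None else expr.subset_genes(analysis_genes)
    ann = annotation.set_index("cell_id").loc[sub.cells]
    states = sorted(pd.unique(ann["state"].dropna()))
    if sum((ann["state"] == s).sum() >= 3 for s in states) < 2:
        raise ValueError("need at least 2 states with >= 3 cells")

    L = sub.log2p1()  # genes x cells
    cols = [np.ones(len(sub.cells))]
    if "aligned_reads" in ann.columns:
        cols.append(np.log10(ann["aligned_reads"].to_numpy(dtype=float)))
    if "replicate" in ann.columns:
        dummies = pd.get_dummies(ann["replicate"], drop_first=True)
        cols.extend(dummies[c].to_numpy(dtype=float) for c in dummies.columns)
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, L.T, rcond=None)
    resid = (L.T - X @ beta).T  # genes x cells

    from scipy.stats import rankdata

    ranks = rankdata(resid, axis=1)
    from .heterogeneity import _tie_term_rows

    tie_term = _tie_term_rows(resid)

    frames = []
    state_arr = ann["state"].to_numpy()
    V = sub.values
    for st in states:
        in_state = state_arr == st
        if in_state.sum() < 3:
            logger.warning("state %r has < 3 cells; markers skipped", st)
            continue
        _, p = rank_sum_many(resid, in_state, ranks=ranks, tie_term=tie_term)
        lfc = np.log2(V[:, in_state].mean(axis=1) + 1.0) - np.log2(
            V[:, ~in_state].mean(axis=1) + 1.0
        )
        q = bh_adjust(p)
        keep = (np.abs(lfc) > config.de_lfc_threshold) & (q < config.de_alpha)
        frames.append(
            pd.DataFrame(
                {
                    "gene": np.asarray(sub.genes)[keep],
                    "state": st,
                    "log2_fold_change": lfc[keep],
                    "p": p[keep],
                    "adjusted_p": q[keep],
                }
            )
        )
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["gene", "state", "log2_fold_change", "p", "adjusted_p"]
    )


# ---------------------------------------------------------------------------
# pseudotransition (MST over state centroids)
# ---------------------------------------------------------------------------


def _mst_path(centroids: np.ndarray, start: int) -> list[int]:
    """Order centroid indices along a path from ``start`` through all
    on-path centroids.

    Uses the minimum spanning tree when it is a simple path from the start
    state; when sampling noise branches the MST, falls back to the
    shortest start-anchored Hamiltonian path (exact enumeration, fine for
    the handful of on-path states)."""
    from itertools import permutations

    k = centroids.shape[0]
    if k > 8:
        raise ValueError("too many on-path states for path enumeration")
    dist = cdist(centroids, centroids)
    mst = minimum_spanning_tree(dist).toarray()
    adj = [set() for _ in range(k)]
    for i in range(k):
        for j in range(k):
            if mst[i, j] > 0:
                adj[i].add(j)
                adj[j].add(i)
    # depth-first longest path from start
    best: list[int] = [start]

    def dfs(node: int, seen: list[int]) -> None:
        nonlocal best
        extended = False
        for nb in sorted(adj[node]):
            if nb not in seen:
                dfs(nb, seen + [nb])
                extended = True
        if not extended and len(seen) > len(best):
            best = seen

    dfs(start, [start])
    if len(best) == k:
        return best
    logger.warning("centroid MST branched; using shortest Hamiltonian path")
    rest = [i for i in range(k) if i != start]
    return min(
        ([start, *perm] for perm in permutations(rest)),
        key=lambda p: sum(dist[p[i], p[i + 1]] for i in range(k - 1)),
    )


def pseudotime_from_embedding(
    points: np.ndarray,
    labels: np.ndarray,
    on_path_states: list[str],
    start_state: str,
) -> np.ndarray:
    """Project cells onto the centroid MST path and return arc-length
    pseudotime scaled to [0, 1]; off-path cells get NaN.

    ``points`` may be any Euclidean cell embedding (PC scores by default);
    the result is invariant under rigid motions of that embedding.
    """
    labels = np.asarray(labels)
    on_path_states = list(on_path_states)
    if start_state not in on_path_states:
        raise ValueError("start_state must be among on_path_states")
    for st in on_path_states:
        if not np.any(labels == st):
            raise ValueError(f"on-path state {st!r} has no cells")
    if len(on_path_states) < 2:
        raise ValueError("need at least 2 on-path states")
    centroids = np.vstack(
        [points[labels == st].mean(axis=0) for st in on_path_states]
    )
    order = _mst_path(centroids, on_path_states.index(start_state))
    path = centroids[order]
    seg = np.diff(path, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    if np.any(seg_len == 0):
        raise ValueError("coincident state centroids; path degenerate")
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]

    on_path = np.isin(labels, on_path_states)
    t = np.full(len(labels), np.nan)
    pts = points[on_path]
    # arc-length position of the closest point on the polyline; the
    # terminal segments extend beyond the end centroids so cells past the
    # extreme states spread out instead of piling onto the endpoints
    best_d = np.full(len(pts), np.inf)
    best_s = np.zeros(len(pts))
    for i in range(len(seg)):
        rel = pts - path[i]
        proj = rel @ seg[i] / (seg_len[i] ** 2)
        lo = -np.inf if i == 0 else 0.0
        hi = np.inf if i == len(seg) - 1 else 1.0
        proj = np.clip(proj, lo, hi)
        foot = path[i] + proj[:, None] * seg[i]
        d = np.linalg.norm(pts - foot, axis=1)
        s = cum[i] + proj * seg_len[i]
        closer = d < best_d - 1e-12
        best_d[closer] = d[closer]
        best_s[closer] = s[closer]
    span = best_s.max() - best_s.min()
    if span == 0:
        raise ValueError("all on-path cells project to a single point")
    t[on_path] = (best_s - best_s.min()) / span
    return t


def order_pseudotransition(
    expr: ExpressionMatrix,
    annotation: pd.DataFrame,
    on_path_states: list[str],
    seed: int = 0,
    start_state: str | None = None,
    genes: list[str] | None = None,
    n_components: int = 3,
) -> pd.DataFrame:
    """Fill the ``pseudotime`` column of the annotation.

    Builds an MST over on-path cluster centroids in PC space (a few top
    components of the ordering genes, mirroring the low final
    dimensionality of the original graph embedding), projects each on-path
    cell onto the centroid path, and scales arc length to [0, 1] with the
    designated start state at 0.  Pass the ordering genes from
    :func:`embed_and_cluster` (``df.attrs['ordering_genes']``) for a path
    space consistent with the clustering.
    """
    ann = annotation.set_index("cell_id").loc[expr.cells].reset_index()
    observed = set(ann["state"].dropna())
    missing = [s for s in on_path_states if s not in observed]
    if missing:
        raise ValueError(f"on-path states not observed: {missing}")
    start = start_state or on_path_states[0]
    scores = pc_scores(expr, genes, n_components=n_components, seed=seed)
    t = pseudotime_from_embedding(
        scores, ann["state"].to_numpy(), on_path_states, start
    )
    out = ann.copy()
    out["pseudotime"] = t
    return out
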