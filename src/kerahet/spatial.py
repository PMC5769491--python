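"""Neighbour-cell quantification from high-content imaging tables.

Neighbours are all cells whose nucleus centroid lies within a radius
(default 20 um) of the index cell; the radius reading of the neighbourhood
is used because a single-nearest-neighbour reading is incompatible with a
mean neighbour count well above one in sub-confluent monolayers.  Transgene
(CellTracker+) index cells with more than ``max_shared_label_neighbours``
transgene neighbours are excluded from summaries so that dense transgene
clusters do not dominate the neighbour-effect estimates.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.spatial import cKDTree
from scipy.stats import ttest_ind

from .io_core import AnalysisConfig
from .heterogeneity import ks_two_sample

logger = logging.getLogger("kerahet")


def build_neighbour_graph(
    table: pd.DataFrame,
    radius: float = 20.0,
    wrap: tuple[float, float] | None = None,
) -> csr_matrix:
    """Symmetric adjacency of all cell pairs within ``radius`` (um).

    Uses a k-d tree, so cost is sub-quadratic in cell count.  ``wrap``
    enables toroidal boundary conditions with the given field size (used
    for edge-effect-free geometry checks).  Duplicate coordinates are
    allowed (distance-0 edges) but warned about.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    xy = table[["x_um", "y_um"]].to_numpy(dtype=float)
    n = len(xy)
    if n < 2:
        raise ValueError("need at least 2 cells")
    if not np.all(np.isfinite(xy)):
        raise ValueError("coordinates must be finite")
    if len(np.unique(xy, axis=0)) < n:
        logger.warning("duplicate cell coordinates present (distance-0 edges)")
    if wrap is not None:
        xy = np.mod(xy, np.asarray(wrap, dtype=float))
        tree = cKDTree(xy, boxsize=wrap)
    else:
        tree = cKDTree(xy)
    pairs = tree.query_pairs(r=radius, output_type="ndarray")
    if len(pairs) == 0:
        return csr_matrix((n, n), dtype=bool)
    rows = np.concatenate([pairs[:, 0], pairs[:, 1]])
    cols = np.concatenate([pairs[:, 1], pairs[:, 0]])
    return csr_matrix(
        (np.ones(len(rows), dtype=bool), (rows, cols)), shape=(n, n)
    )


def mean_neighbour_count(graph: csr_matrix) -> float:
    """Population mean number of neighbours per cell."""
    return float(np.asarray(graph.sum(axis=1)).ravel().mean())


def neighbour_summaries(
    table: pd.DataFrame,
    graph: csr_matrix,
    config: AnalysisConfig | None = None,
    channels: list[str] | None = None,
) -> pd.DataFrame:
    """Per transgene index cell: neighbour counts and per-channel mean
    intensity over non-transgene neighbours.

    An index cell is ``excluded`` when its transgene neighbour count
    exceeds ``max_shared_label_neighbours``.  Index cells without
    neighbours keep missing means and are not excluded.  The population
    mean neighbour count (all cells) is attached as
    ``df.attrs['mean_neighbours']``.
    """
    config = config or AnalysisConfig()
    if channels is None:
        skip = {"cell_id", "x_um", "y_um", "is_transgene", "condition",
                "replicate", "edu_positive"}
        channels = [c for c in table.columns
                    if c not in skip and pd.api.types.is_numeric_dtype(table[c])]
    is_tg = table["is_transgene"].to_numpy(dtype=bool)
    adj = graph.tolil().rows
    rows = []
    for i in np.flatnonzero(is_tg):
        nb = np.asarray(adj[i], dtype=int)
        n_nb = len(nb)
        tg_nb = int(is_tg[nb].sum()) if n_nb else 0
        wt_nb = nb[~is_tg[nb]] if n_nb else np.array([], dtype=int)
        row = {
            "index_cell_id": table["cell_id"].iloc[i],
            "n_neighbours": n_nb,
            "n_transgene_neighbours": tg_nb,
            "excluded": tg_nb > config.max_shared_label_neighbours,
        }
        for ch in channels:
            row[f"mean_neighbour_{ch}"] = (
                float(table[ch].to_numpy()[wt_nb].mean()) if len(wt_nb) else np.nan
            )
            row[f"index_{ch}"] = float(table[ch].iloc[i])
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["mean_neighbours"] = mean_neighbour_count(graph)
    return out


def compare_conditions(
    table: pd.DataFrame,
    summaries: pd.DataFrame,
    channel: str,
    min_values: int = 5,
) -> pd.DataFrame:
    """Two-sample KS comparisons of a channel between condition pairs.

    Replicates are pooled within condition.  Both the index-cell
    intensities and the neighbour mean intensities of non-excluded
    transgene index cells are compared for every condition pair.
    Conditions with fewer than ``min_values`` values are skipped (warned).
    """
    merged = summaries.merge(
        table[["cell_id", "condition"]],
        left_on="index_cell_id",
        right_on="cell_id",
        how="left",
    )
    merged = merged[~merged["excluded"]]
    conditions = sorted(merged["condition"].dropna().unique())
    if len(conditions) < 2:
        raise ValueError("need at least 2 conditions")
    rows = []
    for a, b in combinations(conditions, 2):
        for measure, col in (
            ("index_cell", f"index_{channel}"),
            ("neighbour_mean", f"mean_neighbour_{channel}"),
        ):
            xa = merged.loc[merged["condition"] == a, col].dropna().to_numpy()
            xb = merged.loc[merged["condition"] == b, col].dropna().to_numpy()
            if len(xa) < min_values or len(xb) < min_values:
                logger.warning(
                    "skipping %s %s vs %s: fewer than %d values",
                    measure, a, b, min_values,
                )
                continue
            D, p = ks_two_sample(xa, xb)
            rows.append(
                {
                    "condition_a": a,
                    "condition_b": b,
                    "measure": measure,
                    "channel": channel,
                    "n_a": len(xa),
                    "n_b": len(xb),
                    "ks_statistic": D,
                    "p": p,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["condition_a", "condition_b", "measure", "channel",
                 "n_a", "n_b", "ks_statistic", "p"],
    )


def marker_stratified_edu(
    table: pd.DataFrame,
    channel: str,
    config: AnalysisConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """EdU+ fraction among TF-high non-transgene cells, per replicate.

    TF-high means nuclear intensity above the configured within-replicate
    quantile (upper quartile by default) among non-transgene cells.
    Returns ``(per_replicate, comparisons)`` where comparisons hold the
    condition means +/- SD and a two-sided two-sample t-test on
    replicate-level fractions for each condition pair.  With zero variance
    in both groups the t-test is degenerate and reported as p = 1 (warned).
    """
    config = config or AnalysisConfig()
    wt = table[~table["is_transgene"].astype(bool)]
    rows = []
    for (cond, rep), sub in wt.groupby(["condition", "replicate"], sort=True):
        if config.tf_high_quantile <= 0:
            high = sub
        else:
            thr = sub[channel].quantile(config.tf_high_quantile)
            high = sub[sub[channel] > thr]
        if len(high) == 0:
            logger.warning("replicate %s/%s has no TF-high cells; skipped", cond, rep)
            continue
        rows.append(
            {
                "condition": cond,
                "replicate": rep,
                "n_tf_high": len(high),
                "edu_fraction": float(high["edu_positive"].astype(bool).mean()),
            }
        )
    per_rep = pd.DataFrame(rows)
    if per_rep.empty:
        raise ValueError("no replicate produced TF-high cells")
    comps = []
    conditions = sorted(per_rep["condition"].unique())
    for a, b in combinations(conditions, 2):
        fa = per_rep.loc[per_rep["condition"] == a, "edu_fraction"].to_numpy()
        fb = per_rep.loc[per_rep["condition"] == b, "edu_fraction"].to_numpy()
        if len(fa) < 2 or len(fb) < 2:
            raise ValueError("need at least 2 replicates per condition")
        if np.var(fa) == 0 and np.var(fb) == 0:
            logger.warning("zero variance in both conditions; degenerate t-test")
            p = 1.0
        else:
            p = float(ttest_ind(fa, fb).pvalue)
        comps.append(
            {
                "condition_a": a,
                "condition_b": b,
                "mean_a": float(fa.mean()),
                "sd_a": float(fa.std(ddof=1)),
                "mean_b": float(fb.mean()),
                "sd_b": float(fb.std(ddof=1)),
                "t_p": p,
            }
        )
    return per_rep, pd.DataFrame(comps)
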