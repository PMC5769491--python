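"""State-proportion shift tests and pseudotransition density.

Tests whether exposure to non-cell-autonomous signalling redistributes
cells among states: an overall Fisher exact test on the state x condition
contingency table, a per-state exact binomial test of the treated fraction
against the pooled expectation, and kernel density estimates of the
pseudotransition occupancy per condition compared with the two-sample KS
test.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import binomtest, fisher_exact, gaussian_kde

from .heterogeneity import ks_two_sample

logger = logging.getLogger("kerahet")


# ---------------------------------------------------------------------------
# Fisher exact test for 2 x k tables
# ---------------------------------------------------------------------------


def _log_table_prob(row1: np.ndarray, cols: np.ndarray, n: int, r1: int) -> float:
    """log P(table) under the multivariate hypergeometric null."""
    row2 = cols - row1
    return float(
        np.sum(gammaln(cols + 1))
        + gammaln(r1 + 1)
        + gammaln(n - r1 + 1)
        - gammaln(n + 1)
        - np.sum(gammaln(row1 + 1))
        - np.sum(gammaln(row2 + 1))
    )


def fisher_exact_2xk(
    table: np.ndarray,
    seed: int | None = None,
    max_tables: int = 2_000_000,
    n_mc: int = 99_999,
) -> float:
    """Fisher exact test for a 2 x k contingency table.

    The p-value is the total null probability of tables (with the observed
    margins) no more probable than the observed one.  Small tables are
    enumerated exactly; larger ones fall back to seeded Monte-Carlo
    sampling from the multivariate hypergeometric null with the standard
    (1 + hits) / (1 + draws) estimator.
    """
    table = np.asarray(table, dtype=int)
    if table.shape[0] != 2:
        raise ValueError("table must have exactly 2 rows")
    if np.any(table < 0):
        raise ValueError("table entries must be non-negative")
    if table.shape[1] == 2:
        return float(fisher_exact(table).pvalue)
    cols = table.sum(axis=0)
    n = int(table.sum())
    r1 = int(table[0].sum())
    obs_lp = _log_table_prob(table[0], cols, n, r1)
    tol = 1e-10 * abs(obs_lp)

    n_combos = np.prod(np.minimum(cols, r1) + 1.0)
    if n_combos <= max_tables:
        total = 0.0
        k = len(cols)

        def recurse(j: int, remaining: int, row1: list[int]) -> float:
            if j == k - 1:
                if remaining > cols[j]:
                    return 0.0
                lp = _log_table_prob(np.array(row1 + [remaining]), cols, n, r1)
                return math.exp(lp) if lp <= obs_lp + tol + 1e-12 else 0.0
            s = 0.0
            hi = min(cols[j], remaining)
            lo = max(0, remaining - int(cols[j + 1 :].sum()))
            for a in range(lo, hi + 1):
                s += recurse(j + 1, remaining - a, row1 + [a])
            return s

        total = recurse(0, r1, [])
        return float(min(total, 1.0))

    rng = np.random.default_rng(seed)
    draws = rng.multivariate_hypergeometric(cols, r1, size=n_mc)
    const = float(np.sum(gammaln(cols + 1)) + gammaln(r1 + 1)
                  + gammaln(n - r1 + 1) - gammaln(n + 1))
    lps = const - gammaln(draws + 1).sum(axis=1) - gammaln(cols[None, :] - draws + 1).sum(axis=1)
    hits = int(np.sum(lps <= obs_lp + tol + 1e-12))
    return float((1 + hits) / (1 + n_mc))


# ---------------------------------------------------------------------------
# state distribution shift
# ---------------------------------------------------------------------------


def state_distribution_test(
    annotation: pd.DataFrame,
    expected_treated_fraction: float | None = None,
    alpha: float = 0.05,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-state treated-vs-control proportion tests.

    The overall null of homogeneous state composition across conditions is
    tested with a Fisher exact test on the full state x condition table.
    Each state is then tested with a two-sided exact binomial test
    (minimum-likelihood convention) of its treated count against
    ``expected_treated_fraction`` (pooled treated fraction by default).
    """
    conditions = sorted(pd.unique(annotation["condition"]))
    if len(conditions) != 2:
        raise ValueError("exactly two conditions (control, treated) required")
    counts = (
        annotation.groupby(["state", "condition"]).size().unstack(fill_value=0)
    )
    if (counts.sum(axis=0) == 0).any():
        raise ValueError("a condition has zero cells")
    if len(counts) < 2:
        raise ValueError("need at least 2 states")
    ctrl, trt = ("control", "treated") if "control" in conditions else conditions
    table = counts[[ctrl, trt]].to_numpy().T  # 2 x k
    fisher_p = fisher_exact_2xk(table, seed=seed)
    n_treated_total = int(table[1].sum())
    n_total = int(table.sum())
    expected = (
        expected_treated_fraction
        if expected_treated_fraction is not None
        else n_treated_total / n_total
    )
    if not 0 < expected < 1:
        raise ValueError("expected_treated_fraction must lie in (0, 1)")
    rows = []
    for i, state in enumerate(counts.index):
        n_c, n_t = int(table[0, i]), int(table[1, i])
        p = binomtest(n_t, n_c + n_t, expected, alternative="two-sided").pvalue
        rows.append(
            {
                "state": state,
                "n_control": n_c,
                "n_treated": n_t,
                "expected_treated_fraction": expected,
                "binomial_p": p,
                "significant": bool(p < alpha),
                "overall_fisher_p": fisher_p,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pseudotransition density
# ---------------------------------------------------------------------------


def pseudotransition_density(
    annotation: pd.DataFrame,
    grid_size: int = 100,
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Per-condition pseudotime density on a shared [0, 1] grid plus a
    two-sample KS comparison of the raw pseudotimes.

    Densities use a Gaussian KDE (Silverman bandwidth) with boundary
    reflection at 0 and 1, renormalised to unit trapezoidal mass on the
    grid.  Returns ``(density_frame, (ks_D, ks_p))``.
    """
    conditions = sorted(pd.unique(annotation["condition"]))
    grid = np.linspace(0.0, 1.0, grid_size)
    series = {}
    samples = {}
    for cond in conditions:
        t = annotation.loc[
            annotation["condition"] == cond, "pseudotime"
        ].dropna().to_numpy(dtype=float)
        if len(t) == 0:
            raise ValueError(f"condition {cond!r} has no on-path cells")
        if len(t) < 5:
            raise ValueError(f"condition {cond!r} has fewer than 5 on-path cells")
        kde = gaussian_kde(t)
        dens = kde(grid) + kde(-grid) + kde(2.0 - grid)
        dens /= np.trapezoid(dens, grid)
        series[f"density_{cond}"] = dens
        samples[cond] = t
    out = pd.DataFrame({"pseudotime": grid, **series})
    if len(conditions) == 2:
        D, p = ks_two_sample(samples[conditions[0]], samples[conditions[1]])
    else:
        D, p = float("nan"), float("nan")
    return out, (D, p)
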