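"""Synthetic data with planted ground truth.

Emulates the statistical structure of a 5-state cultured keratinocyte
population profiled by single-cell RNA-seq (states A-E; A-D on a latent
differentiation path, E off-path) in a 9:1 WT:transgene co-culture, plus
high-content imaging fields of the same co-culture.  Planted features:

* treated-vs-control shifts in state occupancy concentrated in states A
  (depleted) and D (enriched);
* state-specific marker genes (default 8-fold up in their state);
* differentially dispersed genes: CV inflated by a configurable fold in a
  designated state with the marginal mean preserved (gamma-mixture scaling
  of the per-cell negative-binomial mean, unit-mean mixing distribution);
* pseudotime-dependent genes following one of four smooth temporal
  programs (early-, mid-, late-peak, monotone);
* contact-dependent fluorescence shifts and EdU-probability boosts for
  cells within an exposure radius of an activated transgene cell, removed
  under low-calcium conditions.

Everything is deterministic under the spec seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .io_core import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger("kerahet")

STATE_LETTERS = "ABCDEFGHIJ"

#: smooth temporal programs on pseudotime t in [0, 1], each with range ~[0, 1]
TEMPORAL_PATTERNS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "early": lambda t: np.exp(-0.5 * ((t - 0.10) / 0.15) ** 2),
    "mid": lambda t: np.exp(-0.5 * ((t - 0.50) / 0.15) ** 2),
    "late": lambda t: np.exp(-0.5 * ((t - 0.90) / 0.15) ** 2),
    "monotone": lambda t: t,
}


def _check_simplex(v: tuple[float, ...], n: int, name: str) -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    if arr.shape != (n,):
        raise ValueError(f"{name} must have length {n}")
    if np.any(arr < 0) or abs(arr.sum() - 1.0) > 1e-9:
        raise ValueError(f"{name} must be a probability vector summing to 1")
    return arr


@dataclass
class ExpressionSimSpec:
    """Design of a simulated co-culture scRNA-seq experiment.

    Defaults are sized to the experiment this pipeline models: ~250 cells
    (125 control, 129 treated) over five states, with enough genes that
    4000-8000 are detected as expressed (TPM > 1) per cell.
    """

    n_genes: int = 8000
    n_cells_control: int = 125
    n_cells_treated: int = 129
    n_states: int = 5
    state_proportions_control: tuple[float, ...] = (0.32, 0.20, 0.18, 0.10, 0.20)
    state_proportions_treated: tuple[float, ...] = (0.10, 0.20, 0.18, 0.32, 0.20)
    mean_log2_loc: float = 2.0
    mean_log2_scale: float = 2.0
    nb_dispersion: float = 2.0
    n_dispersed_genes: int = 200
    dispersion_fold: float = 4.0
    dispersion_state: int = 0
    n_dynamic_genes: int = 200
    dynamic_amplitude: float = 2.0
    n_marker_genes_per_state: int = 40
    marker_fold: float = 8.0
    n_replicates: int = 2
    plant_min_mean: float = 2.0
    depth_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_cells_control", "n_cells_treated"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_states < 2:
            raise ValueError("n_states must be >= 2")
        if self.dispersion_fold < 1:
            raise ValueError("dispersion_fold must be >= 1")
        if not 0 <= self.dispersion_state < self.n_states:
            raise ValueError("dispersion_state out of range")
        _check_simplex(self.state_proportions_control, self.n_states, "state_proportions_control")
        _check_simplex(self.state_proportions_treated, self.n_states, "state_proportions_treated")
        n_flagged = (
            self.n_marker_genes_per_state * self.n_states
            + self.n_dispersed_genes
            + self.n_dynamic_genes
        )
        if n_flagged > self.n_genes:
            raise ValueError(
                f"{n_flagged} flagged genes requested but only {self.n_genes} genes"
            )

    @property
    def on_path_states(self) -> list[int]:
        return list(range(min(self.n_states, 4)))


@dataclass
class SpatialSimSpec:
    """Design of a simulated high-content imaging co-culture experiment."""

    field_size: tuple[float, float] = (500.0, 500.0)
    layout: str = "poisson"  # or "hexagonal"
    lattice_spacing: float = 15.0
    n_cells: int = 2000
    transgene_fraction: float = 0.1
    exposure_radius: float = 20.0
    baseline_intensity: float = 100.0
    intensity_noise: float = 0.3
    contact_effect: float = 50.0
    low_calcium: bool = False
    edu_baseline: float = 0.18
    edu_contact_boost: float = 0.15
    n_replicates: int = 3
    conditions: tuple[str, ...] = ("control", "treated")
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.transgene_fraction <= 1:
            raise ValueError("transgene_fraction must lie in [0, 1]")
        if self.layout not in ("poisson", "hexagonal"):
            raise ValueError("layout must be 'poisson' or 'hexagonal'")
        if self.layout == "hexagonal" and self.lattice_spacing <= 0:
            raise ValueError("lattice_spacing must be > 0")
        if not 0 <= self.edu_baseline <= 1:
            raise ValueError("edu_baseline must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Planted truth accompanying a simulated dataset."""

    cells: pd.DataFrame | None = None
    genes: pd.DataFrame | None = None
    tfs: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def simulate_expression(
    spec: ExpressionSimSpec,
) -> tuple[ExpressionMatrix, pd.DataFrame, GroundTruth]:
    """Draw a TPM matrix, cell annotation and ground truth from ``spec``.

    Counts are negative-binomial around state- and pseudotime-dependent
    means, then scaled per cell to TPM (columns sum to 1e6).  Flagged gene
    sets (markers, dispersed, dynamic) are disjoint and drawn from genes
    whose baseline mean count is at least ``spec.plant_min_mean``, since a
    planted effect in a never-detected gene would be unrecoverable by any
    method and meaningless as ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    G, n_states = spec.n_genes, spec.n_states
    n_cells = spec.n_cells_control + spec.n_cells_treated

    genes = [f"G{i:05d}" for i in range(G)]
    cells = [f"C{i:04d}" for i in range(n_cells)]
    condition = np.array(
        ["control"] * spec.n_cells_control + ["treated"] * spec.n_cells_treated
    )

    # --- per-gene baseline mean counts
    base_mu = 2.0 ** rng.normal(spec.mean_log2_loc, spec.mean_log2_scale, size=G)

    # --- flagged gene sets, disjoint, restricted to plantable genes
    plantable = np.flatnonzero(base_mu >= spec.plant_min_mean)
    n_needed = (
        spec.n_marker_genes_per_state * n_states
        + spec.n_dispersed_genes
        + spec.n_dynamic_genes
    )
    if len(plantable) < n_needed:
        raise ValueError(
            f"only {len(plantable)} genes have baseline mean >= "
            f"{spec.plant_min_mean}; {n_needed} flagged genes requested"
        )
    chosen = rng.choice(plantable, size=n_needed, replace=False)
    pos = 0
    marker_state = np.full(G, -1, dtype=int)
    for s in range(n_states):
        idx = chosen[pos : pos + spec.n_marker_genes_per_state]
        marker_state[idx] = s
        pos += spec.n_marker_genes_per_state
    dispersed = np.zeros(G, dtype=bool)
    dispersed[chosen[pos : pos + spec.n_dispersed_genes]] = True
    pos += spec.n_dispersed_genes
    dynamic = np.zeros(G, dtype=bool)
    dyn_idx = chosen[pos : pos + spec.n_dynamic_genes]
    dynamic[dyn_idx] = True
    pattern_names = list(TEMPORAL_PATTERNS)
    temporal_pattern = np.full(G, "", dtype=object)
    for j, g in enumerate(dyn_idx):
        temporal_pattern[g] = pattern_names[j % len(pattern_names)]

    # --- per-cell state and pseudotime
    state = np.empty(n_cells, dtype=int)
    is_treated = condition == "treated"
    p_ctrl = np.asarray(spec.state_proportions_control)
    p_trt = np.asarray(spec.state_proportions_treated)
    state[~is_treated] = rng.choice(n_states, size=(~is_treated).sum(), p=p_ctrl)
    state[is_treated] = rng.choice(n_states, size=is_treated.sum(), p=p_trt)
    on_path = np.isin(state, spec.on_path_states)
    n_on_path_states = len(spec.on_path_states)
    width = 1.0 / n_on_path_states
    pseudotime = np.full(n_cells, np.nan)
    pseudotime[on_path] = (state[on_path] + rng.uniform(0, 1, on_path.sum())) * width

    replicate = np.empty(n_cells, dtype=object)
    for cond in ("control", "treated"):
        idx = np.flatnonzero(condition == cond)
        replicate[idx] = [f"{cond[:4]}_r{1 + i % spec.n_replicates}" for i in range(len(idx))]

    # --- mean matrix (genes x cells)
    # On-path state markers hold their full fold inside their state's
    # pseudotime interval and decay with Gaussian shoulders into the
    # neighbouring intervals: states remain distinct clusters but sit on a
    # graded differentiation continuum (neighbouring states share partial
    # marker expression).  Off-path state markers are discrete.
    mu = np.tile(base_mu[:, None], (1, n_cells))
    shoulder = 0.03
    for s in range(n_states):
        sel = marker_state == s
        if not sel.any():
            continue
        if s in spec.on_path_states and on_path.any():
            lo, hi = s * width, (s + 1) * width
            t_on = pseudotime[on_path]
            d = np.maximum.reduce([lo - t_on, t_on - hi, np.zeros_like(t_on)])
            profile = np.exp(-0.5 * (d / shoulder) ** 2)
            mu[np.ix_(sel, on_path)] *= spec.marker_fold ** profile[None, :]
        else:
            mu[np.ix_(sel, state == s)] *= spec.marker_fold
    if spec.n_dynamic_genes and on_path.any():
        t = pseudotime[on_path]
        for name, fn in TEMPORAL_PATTERNS.items():
            sel = (temporal_pattern == name) & dynamic
            if sel.any():
                factor = 2.0 ** (spec.dynamic_amplitude * fn(t))
                mu[np.ix_(sel, on_path)] *= factor[None, :]
    # --- mean-preserving CV inflation in the designated state
    r = spec.nb_dispersion
    target_cells = np.flatnonzero(state == spec.dispersion_state)
    if spec.n_dispersed_genes and spec.dispersion_fold > 1 and len(target_cells):
        didx = np.flatnonzero(dispersed)
        mu_state = mu[np.ix_(didx, target_cells)].mean(axis=1)
        f2 = spec.dispersion_fold**2
        v = (f2 - 1.0) * (1.0 / mu_state + 1.0 / r) / (1.0 + 1.0 / r)
        shape = 1.0 / v
        factors = rng.gamma(shape[:, None], 1.0 / shape[:, None],
                            size=(len(didx), len(target_cells)))
        mu[np.ix_(didx, target_cells)] *= factors

    # --- per-cell library-size factor: real single-cell libraries vary
    # severalfold in depth, which TPM normalises out in expectation but
    # which smears the per-count quantisation of TPM across cells
    size_factor = np.exp(rng.normal(0.0, spec.depth_sigma, size=n_cells))
    mu = mu * size_factor[None, :]

    # --- NB counts and TPM
    p_nb = r / (r + mu)
    counts = rng.negative_binomial(r, p_nb).astype(float)
    totals = counts.sum(axis=0)
    for j in np.flatnonzero(totals == 0):  # vanishingly rare at realistic depth
        counts[rng.integers(0, G), j] = 1.0
        totals[j] = 1.0
    tpm = counts / totals[None, :] * 1e6

    aligned_reads = np.round(
        641_000.0 * size_factor * np.exp(rng.normal(0.0, 0.1, size=n_cells))
    ).astype(int)

    annotation = pd.DataFrame(
        {
            "cell_id": cells,
            "condition": condition,
            "replicate": replicate,
            "state": [STATE_LETTERS[s] for s in state],
            "pseudotime": pseudotime,
            "aligned_reads": aligned_reads,
        }
    )
    truth_cells = annotation[["cell_id", "state", "pseudotime"]].rename(
        columns={"state": "true_state", "pseudotime": "true_pseudotime"}
    )
    truth_genes = pd.DataFrame(
        {
            "gene": genes,
            "baseline_mean": base_mu,
            "marker_state": [
                STATE_LETTERS[s] if s >= 0 else "" for s in marker_state
            ],
            "dispersed": dispersed,
            "dynamic": dynamic,
            "temporal_pattern": temporal_pattern,
        }
    )
    expr = ExpressionMatrix(genes, cells, tpm)
    return expr, annotation, GroundTruth(cells=truth_cells, genes=truth_genes)


# ---------------------------------------------------------------------------
# QC metadata
# ---------------------------------------------------------------------------


def simulate_qc_metadata(
    n_cells: int,
    fail_fraction: float,
    seed: int,
    thresholds=None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Per-cell QC covariates with exactly ``ceil(fail_fraction * n)`` planted
    failures, each violating at least one threshold; all other cells pass."""
    if not 0 <= fail_fraction <= 1:
        raise ValueError("fail_fraction must lie in [0, 1]")
    if thresholds is None:
        from .qc import QCThresholds

        thresholds = QCThresholds()
    rng = np.random.default_rng(seed)
    cells = [f"C{i:04d}" for i in range(n_cells)]
    reads = np.exp(rng.normal(math.log(641_000.0), 0.30, size=n_cells))
    reads = np.maximum(reads, thresholds.min_aligned_reads * 1.05)
    ribo = rng.beta(2.0, 200.0, size=n_cells) * 100.0
    ribo = np.minimum(ribo, thresholds.max_ribosomal_pct * 0.9)
    genes_expr = 4000.0 + 4e-3 * (reads - 641_000.0) + rng.normal(0, 500.0, n_cells)
    genes_expr = np.maximum(genes_expr, thresholds.min_genes_expressed * 1.05)

    n_fail = math.ceil(fail_fraction * n_cells)
    fail_idx = rng.choice(n_cells, size=n_fail, replace=False)
    rules = rng.integers(0, 3, size=n_fail)
    violated = np.full(n_cells, "", dtype=object)
    for i, rule in zip(fail_idx, rules):
        if rule == 0:
            reads[i] = rng.uniform(20_000, thresholds.min_aligned_reads)
            violated[i] = "aligned_reads"
        elif rule == 1:
            ribo[i] = rng.uniform(thresholds.max_ribosomal_pct, 8.0)
            violated[i] = "ribosomal_pct"
        else:
            genes_expr[i] = rng.uniform(200, thresholds.min_genes_expressed)
            violated[i] = "genes_expressed"

    table = pd.DataFrame(
        {
            "cell_id": cells,
            "aligned_reads": np.round(reads).astype(int),
            "ribosomal_pct": ribo,
            "genes_expressed": np.floor(genes_expr).astype(int),
        }
    )
    truth = pd.DataFrame(
        {"cell_id": cells, "planted_fail": violated != "", "violated_rule": violated}
    )
    return table, GroundTruth(cells=truth)


# ---------------------------------------------------------------------------
# spatial
# ---------------------------------------------------------------------------


def _hexagonal_positions(field: tuple[float, float], spacing: float) -> np.ndarray:
    w, h = field
    dy = spacing * math.sqrt(3.0) / 2.0
    rows = int(h // dy) + 1
    cols = int(w // spacing) + 1
    pts = []
    for i in range(rows):
        x0 = (spacing / 2.0) if i % 2 else 0.0
        for j in range(cols):
            x = x0 + j * spacing
            y = i * dy
            if x <= w and y <= h:
                pts.append((x, y))
    return np.asarray(pts, dtype=float)


def simulate_spatial(spec: SpatialSimSpec) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate imaging fields for each condition x replicate.

    Cells within ``exposure_radius`` of a transgene cell are geometrically
    exposed; the additive intensity shift and the EdU-probability boost act
    only in the treated condition and only when ``low_calcium`` is False
    (low-calcium medium blocks cell-cell contact, removing the effect).
    """
    rng = np.random.default_rng(spec.seed)
    frames = []
    truth_frames = []
    prefix = "low_calcium_" if spec.low_calcium else ""
    for cond in spec.conditions:
        active_cond = cond == "treated" and not spec.low_calcium
        for rep in range(1, spec.n_replicates + 1):
            if spec.layout == "hexagonal":
                xy = _hexagonal_positions(spec.field_size, spec.lattice_spacing)
            else:
                n = rng.poisson(spec.n_cells)
                xy = np.column_stack(
                    [
                        rng.uniform(0, spec.field_size[0], n),
                        rng.uniform(0, spec.field_size[1], n),
                    ]
                )
            n = len(xy)
            is_tg = rng.uniform(size=n) < spec.transgene_fraction
            exposed = np.zeros(n, dtype=bool)
            if is_tg.any():
                tree = cKDTree(xy[is_tg])
                d, _ = tree.query(xy, k=1)
                exposed = d <= spec.exposure_radius
                # transgene cells: exposed only via *another* transgene cell
                if is_tg.sum() > 1:
                    d2, _ = tree.query(xy[is_tg], k=2)
                    exposed[np.flatnonzero(is_tg)] = d2[:, 1] <= spec.exposure_radius
                else:
                    exposed[is_tg] = False
            effect = exposed & active_cond
            shift = np.where(effect, spec.contact_effect, 0.0)
            mu_log = math.log(spec.baseline_intensity)
            opp = np.exp(rng.normal(mu_log, spec.intensity_noise, n)) + shift
            bcl3 = np.exp(rng.normal(mu_log, spec.intensity_noise, n)) + shift
            p_edu = np.clip(
                spec.edu_baseline + np.where(effect, spec.edu_contact_boost, 0.0), 0, 1
            )
            edu = rng.uniform(size=n) < p_edu
            cond_name = prefix + cond
            ids = [f"{cond_name}_r{rep}_c{i:05d}" for i in range(n)]
            frames.append(
                pd.DataFrame(
                    {
                        "cell_id": ids,
                        "x_um": xy[:, 0],
                        "y_um": xy[:, 1],
                        "is_transgene": is_tg,
                        "condition": cond_name,
                        "replicate": f"r{rep}",
                        "opp": opp,
                        "bcl3_nuclear": bcl3,
                        "edu_positive": edu,
                    }
                )
            )
            truth_frames.append(
                pd.DataFrame(
                    {"cell_id": ids, "exposed": exposed, "effect_active": effect}
                )
            )
    table = pd.concat(frames, ignore_index=True)
    truth = pd.concat(truth_frames, ignore_index=True)
    return table, GroundTruth(cells=truth)


# ---------------------------------------------------------------------------
# TF target sets
# ---------------------------------------------------------------------------


def simulate_tf_targets(
    gene_truth: pd.DataFrame,
    n_tfs: int = 20,
    n_planted: int = 5,
    targets_per_tf: int = 50,
    planted_dynamic_fraction: float = 0.6,
    seed: int = 0,
) -> tuple[GeneSetCollection, pd.DataFrame]:
    """A synthetic TF->target GMT-style collection over the simulated genes.

    Planted regulators draw ``planted_dynamic_fraction`` of their targets
    from the dynamic genes; null TFs draw targets uniformly.  TF names are
    themselves (distinct, non-target-flagged) gene identifiers so the
    expression filter in :func:`kerahet.dynamics.tf_overrepresentation`
    can evaluate them.
    """
    rng = np.random.default_rng(seed)
    genes = gene_truth["gene"].to_numpy()
    dynamic = gene_truth["dynamic"].to_numpy(dtype=bool)
    expressed = gene_truth["baseline_mean"].to_numpy() >= 2.0
    dyn_pool = genes[dynamic]
    null_pool = genes[~dynamic & expressed]
    tf_names = rng.choice(null_pool, size=n_tfs, replace=False)
    sets: dict[str, list[str]] = {}
    planted_flags = []
    for i, tf in enumerate(tf_names):
        planted = i < n_planted
        if planted:
            k_dyn = int(round(planted_dynamic_fraction * targets_per_tf))
            k_dyn = min(k_dyn, len(dyn_pool))
            tgt = np.concatenate(
                [
                    rng.choice(dyn_pool, size=k_dyn, replace=False),
                    rng.choice(null_pool, size=targets_per_tf - k_dyn, replace=False),
                ]
            )
        else:
            tgt = rng.choice(genes, size=targets_per_tf, replace=False)
        sets[str(tf)] = [str(g) for g in tgt]
        planted_flags.append(planted)
    truth = pd.DataFrame({"tf": [str(t) for t in tf_names], "planted": planted_flags})
    return GeneSetCollection(sets, {t: "synthetic TF target set" for t in sets}), truth
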