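"""Core on-disk formats, configuration and shared containers.

Expression is handled throughout in transcripts-per-million (TPM); the
pipeline never re-normalises library size.  The pipeline-wide log transform
is ``log2(TPM + 1)``; a natural-log variant is used only for the
transcription-factor expression filter (see :mod:`kerahet.dynamics`).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("kerahet")

LOG_FORMAT = "%(asctime)s %(name)s %(levelname)s %(message)s"


def configure_logging(level: str = "INFO") -> None:
    """Initialise the package logger for CLI / script use."""
    logging.basicConfig(level=getattr(logging, level.upper()), format=LOG_FORMAT)


class ParseError(ValueError):
    """Raised when an on-disk input violates its format contract."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """A gene x cell abundance matrix in TPM.

    Parameters
    ----------
    genes, cells
        Ordered, unique identifiers.
    values
        ``(n_genes, n_cells)`` array of finite, non-negative abundances.
    """

    genes: list[str]
    cells: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.genes = [str(g) for g in self.genes]
        self.cells = [str(c) for c in self.cells]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.cells)):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        for kind, ids in (("gene", self.genes), ("cell", self.cells)):
            seen: set[str] = set()
            for name in ids:
                if name in seen:
                    raise ParseError(f"duplicate {kind} identifier: {name!r}")
                seen.add(name)
        if not np.all(np.isfinite(self.values)):
            raise ParseError("expression values must be finite")
        if np.any(self.values < 0):
            g, c = np.argwhere(self.values < 0)[0]
            raise ParseError(
                f"negative expression value at gene {self.genes[g]!r}, "
                f"cell {self.cells[c]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.cells)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    def gene_index(self, genes: Iterable[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.genes)}
        try:
            return np.array([lookup[g] for g in genes], dtype=int)
        except KeyError as exc:  # pragma: no cover - message path
            raise KeyError(f"gene {exc.args[0]!r} not in matrix") from exc

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = self.gene_index(genes)
        return ExpressionMatrix(list(genes), list(self.cells), self.values[idx])

    def subset_cells(self, cells: Sequence[str]) -> "ExpressionMatrix":
        lookup = {c: i for i, c in enumerate(self.cells)}
        idx = np.array([lookup[c] for c in cells], dtype=int)
        return ExpressionMatrix(list(self.genes), list(cells), self.values[:, idx])

    def log2p1(self) -> np.ndarray:
        """Pipeline-standard ``log2(TPM + 1)`` values."""
        return np.log2(self.values + 1.0)


@dataclass
class GeneSetCollection:
    """Named gene sets (GO terms, TF target maps) read from GMT files."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def intersect_universe(self, universe: Iterable[str]) -> dict[str, list[str]]:
        """Per-set members present in ``universe`` (possibly empty, flagged)."""
        uni = set(universe)
        out: dict[str, list[str]] = {}
        for name, genes in self.sets.items():
            hit = [g for g in genes if g in uni]
            if not hit:
                logger.warning("gene set %r has no genes in the analysis universe", name)
            out[name] = hit
        return out


@dataclass
class AnalysisConfig:
    """All tunable thresholds of the pipeline.

    Defaults follow the study design this pipeline reproduces: genes are
    called expressed at TPM > 1 in more than five cells; cells pass QC with
    > 200,000 aligned reads, < 2% ribosomal reads and > 2000 expressed
    genes; state markers require |log2FC| > 0.5 at adjusted p < 0.05;
    differential dispersion requires q < 0.05 and a CV fold change > 2;
    dynamic genes at FDR < 5% fall into four temporal clusters; TFs must be
    expressed at mean ln(TPM + 1) > 1 in some state; spatial neighbours lie
    within 20 um, and transgene index cells with more than two transgene
    neighbours are excluded.
    """

    expressed_tpm_threshold: float = 1.0
    expressed_min_cells: int = 5
    min_aligned_reads: int = 200_000
    max_ribosomal_pct: float = 2.0
    min_genes_expressed: int = 2000
    min_replicate_correlation: float = 0.96
    de_lfc_threshold: float = 0.5
    de_alpha: float = 0.05
    cv_fold_threshold: float = 2.0
    dispersion_alpha: float = 0.05
    dynamic_fdr: float = 0.05
    n_temporal_clusters: int = 4
    tf_expression_threshold: float = 1.0
    direction_deadband: float = 0.5
    neighbour_radius: float = 20.0
    max_shared_label_neighbours: int = 2
    tf_high_quantile: float = 0.75
    loess_span: float = 0.75
    cv_scale: str = "linear"  # "linear" or "log"; scale on which per-gene CVs are taken
    random_seed: int = 0

    def __post_init__(self) -> None:
        positive = (
            "expressed_tpm_threshold expressed_min_cells min_aligned_reads "
            "max_ribosomal_pct min_genes_expressed min_replicate_correlation "
            "de_lfc_threshold de_alpha cv_fold_threshold dispersion_alpha "
            "dynamic_fdr tf_expression_threshold neighbour_radius loess_span"
        ).split()
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValueError(f"config field {name} must be strictly positive")
        if self.n_temporal_clusters < 2:
            raise ValueError("n_temporal_clusters must be >= 2")
        if self.max_ribosomal_pct > 100:
            raise ValueError("max_ribosomal_pct cannot exceed 100")
        if self.cv_scale not in ("linear", "log"):
            raise ValueError("cv_scale must be 'linear' or 'log'")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) if path.suffix in (".yml", ".yaml") else json.load(fh)
        if raw is None:
            raw = {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParseError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_name_file(path: Path, kind: str) -> list[str]:
    if not path.exists():
        raise ParseError(f"companion {kind} name file not found: {path}")
    names = [line.strip() for line in path.read_text().splitlines() if line.strip()]
    return names


def read_expression(
    path: str | Path,
    format: str = "tsv",
    genes_path: str | Path | None = None,
    cells_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read a gene x cell TPM matrix.

    ``format='tsv'`` expects a header row of cell identifiers and a leading
    gene-identifier column.  ``format='mtx-triplet'`` expects a MatrixMarket
    coordinate file with companion plain-text gene and cell name files
    (default ``<stem>.genes.txt`` / ``<stem>.cells.txt``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        dup = df.index[df.index.duplicated()]
        if len(dup):
            raise ParseError(f"duplicate gene row name: {dup[0]!r}")
        dupc = df.columns[df.columns.duplicated()]
        if len(dupc):
            raise ParseError(f"duplicate cell column name: {dupc[0]!r}")
        try:
            values = df.to_numpy(dtype=float)
        except ValueError as exc:
            raise ParseError(f"non-numeric expression value in {path}: {exc}") from exc
        return ExpressionMatrix([str(i) for i in df.index], [str(c) for c in df.columns], values)
    if format == "mtx-triplet":
        from scipy.io import mmread

        try:
            mat = mmread(path)
        except ValueError as exc:
            raise ParseError(f"malformed MatrixMarket file {path}: {exc}") from exc
        gpath = Path(genes_path) if genes_path else path.parent / (path.stem + ".genes.txt")
        cpath = Path(cells_path) if cells_path else path.parent / (path.stem + ".cells.txt")
        genes = _read_name_file(gpath, "gene")
        cells = _read_name_file(cpath, "cell")
        dense = np.asarray(mat.todense() if hasattr(mat, "todense") else mat, dtype=float)
        return ExpressionMatrix(genes, cells, dense)
    raise ValueError(f"unknown expression format: {format!r}")


def write_expression(
    expr: ExpressionMatrix, path: str | Path, format: str = "tsv"
) -> None:
    path = Path(path)
    if format == "tsv":
        write_table(expr.to_frame().rename_axis("gene").reset_index(), path)
    elif format == "mtx-triplet":
        from scipy.io import mmwrite
        from scipy.sparse import coo_matrix

        mmwrite(str(path), coo_matrix(expr.values))
        (path.parent / (path.stem + ".genes.txt")).write_text("\n".join(expr.genes) + "\n")
        (path.parent / (path.stem + ".cells.txt")).write_text("\n".join(expr.cells) + "\n")
    else:
        raise ValueError(f"unknown expression format: {format!r}")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read gene sets in the Broad GMT dialect: name, description, genes..."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: GMT line needs >= 3 fields")
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise ParseError(f"{path}: line {lineno}: gene set {name!r} has no genes")
            if name in sets:
                raise ParseError(f"{path}: line {lineno}: duplicate set name {name!r}")
            sets[name] = genes
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def write_table(rows: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV.  Floats round-trip to 17 significant digits."""
    if rows.columns.nlevels != 1 or len(rows.columns) == 0:
        raise ValueError("table must have a flat, non-empty set of column names")
    rows.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_gene_list(path: str | Path) -> list[str]:
    """Plain-text gene list, one identifier per line; blank lines skipped."""
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def packaged_gene_list(name: str) -> list[str]:
    """A gene list shipped with the package (``cell_cycle`` or ``s_phase``)."""
    data_dir = Path(__file__).parent / "data"
    path = data_dir / f"{name}_genes.txt"
    if not path.exists():
        raise FileNotFoundError(f"no packaged gene list {name!r}")
    return [ln.strip() for ln in path.read_text().splitlines()
            if ln.strip() and not ln.startswith("#")]


# ---------------------------------------------------------------------------
# shared small statistics helpers
# ---------------------------------------------------------------------------


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values; NaNs propagate unadjusted."""
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    mask = np.isfinite(p)
    if mask.sum():
        from scipy.stats import false_discovery_control

        q[mask] = false_discovery_control(p[mask], method="bh")
    return q
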