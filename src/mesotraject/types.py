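"""Shared domain containers for the mesophyll-development pipeline.

Every stage of the pipeline exchanges one of the small dataclasses defined
here.  Conventions used throughout the package:

* count matrices are cells x genes, dense ``int64`` arrays;
* genomic intervals are BED-style 0-based half-open; GFF3 input (1-based,
  closed) is converted on read;
* pseudotime is a per-cell scalar normalized to ``[0, 1]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd


class ParameterError(ValueError):
    """A caller-supplied parameter is outside its documented range."""


class FormatError(ValueError):
    """An input file violates its format contract."""


class DegenerateTrajectoryError(RuntimeError):
    """The expression matrix carries no usable variation for ordering cells."""


class AmbiguousOrientationError(RuntimeError):
    """Origin markers do not distinguish the two ends of the trajectory."""


# ---------------------------------------------------------------------------
# expression-side containers
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Cells x genes UMI count matrix with per-gene mitochondrial flags."""

    counts: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    mito_mask: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.mito_mask = np.asarray(self.mito_mask, dtype=bool)
        n_cells, n_genes = self.counts.shape
        if len(self.cell_ids) != n_cells or len(self.gene_ids) != n_genes:
            raise FormatError("id lists do not match matrix dimensions")
        if self.mito_mask.shape != (n_genes,):
            raise FormatError("mito_mask length must equal number of genes")
        if np.any(self.counts < 0):
            raise FormatError("counts must be nonnegative")
        if len(set(self.cell_ids)) != n_cells or len(set(self.gene_ids)) != n_genes:
            raise FormatError("cell and gene ids must be unique")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def totals(self) -> np.ndarray:
        """Per-cell total counts (library size)."""
        return self.counts.sum(axis=1)

    def mito_ratio(self) -> np.ndarray:
        """Per-cell fraction of counts on mitochondrial genes."""
        tot = self.totals().astype(float)
        mito = self.counts[:, self.mito_mask].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(tot > 0, mito / tot, 0.0)
        return ratio

    def normalized(self, scale: float = 1e4, log: bool = True) -> np.ndarray:
        """Depth-normalized expression: counts per `scale` per cell, log1p'd."""
        tot = self.totals().astype(float)
        tot[tot == 0] = 1.0
        x = self.counts / tot[:, None] * scale
        return np.log1p(x) if log else x

    def gene_index(self, genes) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:5]}")
        return np.array([lookup[g] for g in genes], dtype=int)

    def subset_cells(self, mask_or_idx) -> "CountMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(
            counts=self.counts[idx],
            cell_ids=[self.cell_ids[i] for i in idx],
            gene_ids=list(self.gene_ids),
            mito_mask=self.mito_mask.copy(),
        )

    def subset_genes(self, genes) -> "CountMatrix":
        idx = self.gene_index(genes)
        return CountMatrix(
            counts=self.counts[:, idx],
            cell_ids=list(self.cell_ids),
            gene_ids=list(genes),
            mito_mask=self.mito_mask[idx],
        )


@dataclass
class ClusterAssignment:
    """Contiguous 0-based community labels for the retained cells."""

    labels: np.ndarray
    resolution: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        used = np.unique(self.labels)
        if len(used) and not np.array_equal(used, np.arange(len(used))):
            raise ValueError("labels must form a contiguous 0..k-1 range")

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0


@dataclass
class MarkerPanel:
    """(gene id, cell type, expected direction) marker entries.

    Direction is "up" for markers expected high in the cell type.
    """

    entries: list[tuple[str, str, str]]

    def genes(self) -> list[str]:
        return [g for g, _, _ in self.entries]

    def by_cell_type(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for g, ct, _ in self.entries:
            out.setdefault(ct, []).append(g)
        return out


@dataclass
class Trajectory:
    """Per-cell pseudotime in [0, 1] on a spanning-tree backbone."""

    pseudotime: np.ndarray
    state: np.ndarray
    root_cell: str
    tree_edges: list[tuple[int, int]]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.pseudotime = np.asarray(self.pseudotime, dtype=float)
        self.state = np.asarray(self.state)
        pt = self.pseudotime
        if pt.size and (abs(pt.min()) > 1e-12 or abs(pt.max() - 1.0) > 1e-12):
            raise ValueError("pseudotime must be min-max normalized to [0, 1]")

    def reversed(self) -> "Trajectory":
        """Flip orientation: pseudotime p -> 1 - p, new root at the far end."""
        pt = 1.0 - self.pseudotime
        root = self.cell_ids[int(np.argmin(pt))]
        return Trajectory(pt, self.state.copy(), root, list(self.tree_edges),
                          list(self.cell_ids))


# ---------------------------------------------------------------------------
# network-side containers
# ---------------------------------------------------------------------------

@dataclass
class PseudoBulk:
    """Cluster-pooled samples: log2(RPM + 1) expression plus mean pseudotime."""

    expr: pd.DataFrame            # samples x genes, log2(RPM + 1)
    sample_pseudotime: pd.Series  # per-sample mean pseudotime of member cells
    sample_sizes: pd.Series       # cells per sample


@dataclass
class CoexprNetwork:
    """Unsigned weighted coexpression network with topological overlap."""

    beta: float
    adjacency: pd.DataFrame
    tom: pd.DataFrame
    modules: pd.Series
    edge_threshold: float
    edges: set[frozenset]

    def has_edge(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.edges


@dataclass
class OdeGrn:
    """Latent linear-ODE fit and the run-averaged TF x TF weight matrix."""

    tf_ids: list[str]
    z: int
    W: np.ndarray                  # loadings of the final (best-RSS of last run) fit
    b: np.ndarray                  # latent rates of the final fit
    A: pd.DataFrame                # TF x TF signed weights, mean over runs
    n_runs: int
    per_run_A: Optional[np.ndarray] = None   # (n_runs, n_tf, n_tf)
    per_run_rss: Optional[np.ndarray] = None


@dataclass
class ConsensusNetwork:
    """ODE edges retained only where the coexpression network agrees."""

    edges: list[tuple[str, str, float]]       # (regulator, target, weight)
    cutoff: float
    provenance: list[dict] = field(default_factory=list)

    def node_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for a, b, _ in self.edges:
            seen.setdefault(a)
            seen.setdefault(b)
        return list(seen)


# ---------------------------------------------------------------------------
# genome-side containers
# ---------------------------------------------------------------------------

@dataclass
class GenomeAnnotation:
    """Gene catalogue on 0-based half-open coordinates.

    ``genes`` columns: gene_id, chrom, start, end, strand, tss.  The TSS of a
    minus-strand gene is its interval end - 1 in 0-based coordinates.
    ``promoters`` (optional) maps gene_id -> (chrom, start, end); promoter
    sequences are stored in genomic forward orientation.
    """

    genes: pd.DataFrame
    chrom_sizes: dict[str, int]
    promoters: dict[str, tuple[str, int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = ~self.genes["strand"].isin(["+", "-"])
        if bad.any():
            raise FormatError("gene strand must be '+' or '-'")
        for _, g in self.genes.iterrows():
            size = self.chrom_sizes.get(g["chrom"])
            if size is not None and not (0 <= g["tss"] < size):
                raise FormatError(f"TSS of {g['gene_id']} outside chromosome")

    def tss_of(self, gene_id: str) -> tuple[str, int, str]:
        row = self.genes.set_index("gene_id").loc[gene_id]
        return str(row["chrom"]), int(row["tss"]), str(row["strand"])


@dataclass
class IntervalSet:
    """BED-style intervals (0-based half-open), sorted within chromosome."""

    intervals: pd.DataFrame   # chrom, start, end, name, score
    kind: str = ""

    def __post_init__(self) -> None:
        df = self.intervals.reset_index(drop=True)
        if len(df) and (df["start"] >= df["end"]).any():
            raise FormatError("interval start must be < end")
        self.intervals = df.sort_values(["chrom", "start", "end"],
                                        kind="mergesort").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass
class LoopSet:
    """Paired-anchor chromatin loops (BEDPE)."""

    loops: pd.DataFrame   # chromA startA endA chromB startB endB name

    def __post_init__(self) -> None:
        df = self.loops.reset_index(drop=True)
        for side in ("A", "B"):
            if len(df) and (df[f"start{side}"] >= df[f"end{side}"]).any():
                raise FormatError("loop anchor start must be < end")
        self.loops = df

    def __len__(self) -> int:
        return len(self.loops)


@dataclass
class Pwm:
    """Position weight matrix: width x 4 probabilities over A, C, G, T."""

    matrix: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))
    name: str = "motif"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise FormatError("PWM must be width x 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise FormatError("PWM rows must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def reverse_complement(self) -> "Pwm":
        return Pwm(self.matrix[::-1, ::-1].copy(), self.background[::-1].copy(),
                   name=self.name)


@dataclass
class RegNetEdge:
    source: str
    target: str
    kind: str            # predicted | chip_direct | PPI | PDI
    provenance: dict


@dataclass
class RegulatoryNetwork:
    """Typed multi-evidence regulatory network with per-edge provenance."""

    edges: list[RegNetEdge]

    def edges_of_kind(self, kind: str) -> list[RegNetEdge]:
        return [e for e in self.edges if e.kind == kind]

    def pair_set(self, kind: str) -> set[tuple[str, str]]:
        return {(e.source, e.target) for e in self.edges_of_kind(kind)}


@dataclass
class MetaProfile:
    """Binned TSS-centered coverage: one row per gene group, 30 bins default."""

    profiles: pd.DataFrame    # groups x bins, mean normalized coverage
    flank: int
    bin_size: int
    n_genes: pd.Series        # genes contributing per group

    @property
    def n_bins(self) -> int:
        return self.profiles.shape[1]


@dataclass
class FootprintProfile:
    """Per-base mean coverage around aligned motif centers."""

    profile: np.ndarray
    w: int
    motif_width: int
    n_sites: int

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("a footprint profile needs at least one site")
        if len(self.profile) != 2 * self.w + self.motif_width:
            raise ValueError("profile length must be 2w + motif width")


# ---------------------------------------------------------------------------
# synthetic-truth containers
# ---------------------------------------------------------------------------

@dataclass
class GrnTruth:
    """Ground-truth TF regulatory network used by the simulator."""

    tf_ids: list[str]
    targets: list[str]
    A_true: np.ndarray
    edge_list: list[tuple[str, str, int]]   # (regulator, target, sign)
    sparsity: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.A_true)):
            raise ValueError("truth weights must be finite")
        n_off = int(np.count_nonzero(self.A_true) - np.count_nonzero(np.diag(self.A_true)))
        if n_off != len(self.edge_list):
            raise ValueError("edge_list length must match off-diagonal nonzeros")


@dataclass
class SynTruth:
    """Everything the generator knows that the pipeline must rediscover."""

    true_time: np.ndarray = field(default_factory=lambda: np.empty(0))
    cell_type: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=object))
    low_quality_flags: dict[str, str] = field(default_factory=dict)  # cell -> reason
    dynamic_gene_labels: dict[str, str] = field(default_factory=dict)
    marker_panel: Optional[MarkerPanel] = None
    motif_positions: list[tuple[str, int, str]] = field(default_factory=list)
    loop_supported_pairs: list[tuple[str, str, str]] = field(default_factory=list)
    chip_direct_pairs: list[tuple[str, str]] = field(default_factory=list)
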