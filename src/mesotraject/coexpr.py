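"""Pseudo-bulk construction and weighted coexpression networks.

Cells are pooled by fine-resolution cluster into pseudo-bulk samples
(the study uses 22), each carrying the mean pseudotime of its member
cells; expression is reads-per-million on the pooled counts, log2(RPM+1).
An unsigned weighted network is built on the top-dispersion genes:
adjacency a_ij = |cor(x_i, x_j)|^beta, topological overlap

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)

with connectivity k_i = sum_{u != i} a_iu, and modules from hierarchical
clustering of the TOM dissimilarity 1 - TOM.  "Coexpression connections"
are the gene pairs whose TOM exceeds a quantile threshold.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .types import (ClusterAssignment, CoexprNetwork, CountMatrix,
                    ParameterError, PseudoBulk, Trajectory)


def make_pseudobulk(m: CountMatrix, ca: ClusterAssignment,
                    t: Trajectory) -> PseudoBulk:
    """Pool counts per fine cluster into RPM-normalized samples.

    Each cluster becomes one sample: counts summed over member cells,
    normalized to reads per million, log2(RPM + 1); the sample pseudotime
    is the mean pseudotime of its member cells.  Empty clusters are
    excluded with a warning.
    """
    if len(ca.labels) != m.n_cells or len(t.pseudotime) != m.n_cells:
        raise ParameterError("clusters/pseudotime must cover every cell")
    rows, pts, sizes, names = [], [], [], []
    for c in range(ca.n_clusters):
        sel = ca.labels == c
        if not sel.any():  # pragma: no cover - labels contract forbids this
            warnings.warn(f"cluster {c} is empty; excluded")
            continue
        pooled = m.counts[sel].sum(axis=0).astype(float)
        total = pooled.sum()
        if total == 0:
            warnings.warn(f"cluster {c} has zero counts; excluded")
            continue
        rows.append(np.log2(pooled / total * 1e6 + 1.0))
        pts.append(float(t.pseudotime[sel].mean()))
        sizes.append(int(sel.sum()))
        names.append(f"C{c:02d}")
    expr = pd.DataFrame(rows, index=names, columns=m.gene_ids)
    return PseudoBulk(expr=expr,
                      sample_pseudotime=pd.Series(pts, index=names),
                      sample_sizes=pd.Series(sizes, index=names))


def tom_from_adjacency(adj: np.ndarray) -> np.ndarray:
    """Topological overlap of a symmetric adjacency with unit diagonal."""
    a = adj.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a                       # sum_u a_iu a_uj, u != i,j on offdiag
    num = shared + a
    den = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(tom, 1.0)
    return tom


def pick_soft_power(corr_abs: np.ndarray, betas=range(1, 21),
                    r2_target: float = 0.8, fallback: int = 6
                    ) -> tuple[int, dict[int, float]]:
    """Smallest beta whose connectivity distribution is scale-free-ish.

    For each candidate beta the connectivities k_i = sum |cor|^beta are
    binned and log10 p(k) regressed on log10 k; the first beta whose fit
    reaches R^2 >= ``r2_target`` with negative slope wins, otherwise the
    conventional default (6) is used with a warning.
    """
    fits: dict[int, float] = {}
    for beta in betas:
        k = (corr_abs ** beta).sum(axis=1) - 1.0
        if np.allclose(k, k[0]):
            fits[beta] = 0.0
            continue
        hist, edges = np.histogram(k, bins=10)
        centers = 0.5 * (edges[:-1] + edges[1:])
        ok = (hist > 0) & (centers > 0)
        if ok.sum() < 3:
            fits[beta] = 0.0
            continue
        lx, ly = np.log10(centers[ok]), np.log10(hist[ok] / hist.sum())
        slope, icpt = np.polyfit(lx, ly, 1)
        resid = ly - (slope * lx + icpt)
        ss_tot = ((ly - ly.mean()) ** 2).sum()
        r2 = 1.0 - resid @ resid / ss_tot if ss_tot > 0 else 0.0
        fits[beta] = float(r2) if slope < 0 else 0.0
        if fits[beta] >= r2_target:
            return beta, fits
    warnings.warn(f"no beta reached scale-free R^2 >= {r2_target}; "
                  f"falling back to beta = {fallback}")
    return fallback, fits


def build_coexpression(pb: PseudoBulk, top_frac: float = 0.75,
                       beta: int | str = "auto", edge_quantile: float = 0.95,
                       n_modules: int = 6) -> CoexprNetwork:
    """Unsigned weighted coexpression network on top-dispersion genes.

    Genes are filtered to the ``top_frac`` fraction with highest dispersion
    (variance/mean of log2-RPM across pseudo-bulk samples); adjacency is
    |Pearson correlation|^beta, TOM as documented in the module docstring,
    modules by average-linkage clustering of 1 - TOM cut into
    ``n_modules``, and edges are pairs whose TOM is at or above the
    ``edge_quantile`` quantile of off-diagonal TOM values.
    """
    if pb.expr.shape[0] < 4:
        raise ParameterError("need at least 4 pseudo-bulk samples")
    if not (0 < top_frac <= 1):
        raise ParameterError("top_frac must lie in (0, 1]")
    x = pb.expr.to_numpy(dtype=float)
    mean, var = x.mean(axis=0), x.var(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mean > 0, var / mean, -np.inf)
    n_keep = int(round(pb.expr.shape[1] * top_frac))
    order = pd.DataFrame({"g": pb.expr.columns, "d": disp}).sort_values(
        ["d", "g"], ascending=[False, True], kind="mergesort")
    genes = order["g"].head(n_keep).tolist()
    xs = pb.expr[genes].to_numpy(dtype=float)

    sd = xs.std(axis=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"{(~keep).sum()} constant genes dropped before correlation")
        genes = [g for g, k in zip(genes, keep) if k]
        xs = xs[:, keep]
    corr = np.corrcoef(xs, rowvar=False)
    corr_abs = np.clip(np.abs(corr), 0.0, 1.0)
    np.fill_diagonal(corr_abs, 1.0)

    if beta == "auto":
        beta_val, _ = pick_soft_power(corr_abs)
    else:
        beta_val = int(beta)
        if beta_val < 1:
            raise ParameterError("beta must be >= 1")
    adj = corr_abs ** beta_val
    np.fill_diagonal(adj, 1.0)
    tom = tom_from_adjacency(adj)

    dis = 1.0 - tom
    np.fill_diagonal(dis, 0.0)
    dis = 0.5 * (dis + dis.T)
    n_mod = min(n_modules, len(genes))
    labels = fcluster(linkage(squareform(dis, checks=False), method="average"),
                      t=n_mod, criterion="maxclust")
    modules = pd.Series([f"M{v}" for v in labels], index=genes)

    iu = np.triu_indices(len(genes), k=1)
    offdiag = tom[iu]
    threshold = float(np.quantile(offdiag, edge_quantile)) if offdiag.size else 1.0
    edges = {frozenset((genes[i], genes[j]))
             for i, j, v in zip(iu[0], iu[1], offdiag) if v >= threshold}
    return CoexprNetwork(
        beta=float(beta_val),
        adjacency=pd.DataFrame(adj, index=genes, columns=genes),
        tom=pd.DataFrame(tom, index=genes, columns=genes),
        modules=modules, edge_threshold=threshold, edges=edges)
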