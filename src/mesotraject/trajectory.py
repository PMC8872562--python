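"""Pseudotime inference, orientation and pseudotime-dependent expression.

Cells are ordered along a developmental axis (leaf base -> tip for
mesophyll cells) by projecting them onto a minimum-spanning-tree backbone
learned over cluster centroids in a low-dimensional expression space.  The
trajectory is oriented with marker genes known to be lowest at the leaf
base (AspAT, NADP-MDH, PPDK, CA, PEPC in the real data); pseudotime is
min-max normalized to [0, 1].  Genes whose expression depends on
pseudotime are detected with a negative-binomial likelihood-ratio test
against a natural cubic spline of pseudotime, and the significant genes are
grouped into k profile clusters (G1..Gk) ordered by peak time.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse.csgraph import minimum_spanning_tree, shortest_path
from scipy.spatial.distance import cdist
from scipy.stats import chi2
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .types import (AmbiguousOrientationError, CountMatrix,
                    DegenerateTrajectoryError, ParameterError, Trajectory)


# ---------------------------------------------------------------------------
# pseudotime
# ---------------------------------------------------------------------------

def infer_pseudotime(m: CountMatrix, n_components: int = 2,
                     n_centroids: int | None = None,
                     seed: int = 0) -> Trajectory:
    """Order cells along a spanning-tree backbone in reduced space.

    The matrix (already restricted to informative genes by the caller) is
    log-normalized, reduced to ``n_components`` principal components, and a
    minimum spanning tree is built over k-means centroids.  Each cell is
    projected onto its nearest tree edge; pseudotime is the geodesic
    distance from a provisional root (one end of the tree diameter) to the
    projection, min-max normalized to [0, 1].  Branch membership of the
    projected edge becomes the cell's state label.
    """
    if m.n_cells < 10:
        raise ParameterError("need at least 10 cells")
    x = m.normalized(log=True)
    if np.allclose(x.var(axis=0), 0.0):
        raise DegenerateTrajectoryError("expression matrix has no variation")
    mu, sd = x.mean(axis=0), x.std(axis=0)
    sd[sd == 0] = 1.0
    x = (x - mu) / sd
    nc = min(n_components, m.n_cells - 1, m.n_genes)
    pcs = PCA(n_components=nc, svd_solver="full").fit_transform(x)

    if n_centroids is None:
        n_centroids = int(np.clip(m.n_cells // 15, 2, 30))
    km = KMeans(n_clusters=n_centroids, n_init=10, random_state=seed).fit(pcs)
    cents = km.cluster_centers_

    dist = cdist(cents, cents)
    mst = minimum_spanning_tree(dist).toarray()
    mst = np.maximum(mst, mst.T)
    edges = [(i, j) for i, j in zip(*np.nonzero(np.triu(mst)))]

    node_d = shortest_path(mst, directed=False)
    # provisional root: one end of the tree diameter (lowest index on ties)
    ecc = node_d.max(axis=1)
    root_node = int(np.argmax(ecc))

    # project each cell onto its nearest tree edge
    pt = np.empty(m.n_cells)
    edge_of_cell = np.empty(m.n_cells, dtype=int)
    seg_u = np.array([cents[i] for i, _ in edges])
    seg_v = np.array([cents[j] for _, j in edges])
    seg_dir = seg_v - seg_u
    seg_len2 = (seg_dir ** 2).sum(axis=1)
    seg_len2[seg_len2 == 0] = 1e-12
    for c in range(m.n_cells):
        tproj = np.clip(((pcs[c] - seg_u) * seg_dir).sum(axis=1) / seg_len2,
                        0.0, 1.0)
        proj = seg_u + tproj[:, None] * seg_dir
        d2 = ((pcs[c] - proj) ** 2).sum(axis=1)
        e = int(np.argmin(d2))
        edge_of_cell[c] = e
        i, j = edges[e]
        elen = float(np.sqrt(seg_len2[e]))
        pt[c] = min(node_d[root_node, i] + tproj[e] * elen,
                    node_d[root_node, j] + (1.0 - tproj[e]) * elen)

    rng_pt = pt.max() - pt.min()
    if rng_pt <= 0:
        raise DegenerateTrajectoryError("all cells project to a single point")
    pt = (pt - pt.min()) / rng_pt

    state = _branch_labels(edges, n_centroids)[edge_of_cell]
    root_cell = m.cell_ids[int(np.argmin(pt))]
    return Trajectory(pseudotime=pt, state=state, root_cell=root_cell,
                      tree_edges=edges, cell_ids=list(m.cell_ids))


def _branch_labels(edges: list[tuple[int, int]], n_nodes: int) -> np.ndarray:
    """Label tree edges by branch: segments between degree>=3 nodes."""
    deg = np.zeros(n_nodes, dtype=int)
    for i, j in edges:
        deg[i] += 1
        deg[j] += 1
    branch_nodes = set(np.flatnonzero(deg >= 3))
    # union-find over edges sharing a non-branch endpoint
    parent = list(range(len(edges)))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    incident: dict[int, list[int]] = {}
    for e, (i, j) in enumerate(edges):
        for node in (i, j):
            if node not in branch_nodes:
                incident.setdefault(node, []).append(e)
    for elist in incident.values():
        for e in elist[1:]:
            ra, rb = find(elist[0]), find(e)
            parent[rb] = ra
    roots = sorted({find(e) for e in range(len(edges))})
    remap = {r: k for k, r in enumerate(roots)}
    return np.array([remap[find(e)] for e in range(len(edges))])


# ---------------------------------------------------------------------------
# orientation
# ---------------------------------------------------------------------------

def orient_by_score(t: Trajectory, score: np.ndarray,
                    decile: float = 0.1, rtol: float = 1e-8) -> Trajectory:
    """Choose the trajectory end where ``score`` is lowest as the root.

    ``score`` is any per-cell scalar expected to increase along real
    developmental time (e.g. mean expression of base-low markers).  The
    orientation whose lowest-pseudotime decile has the smaller mean score
    is kept; a flip maps pseudotime p -> 1 - p exactly.
    """
    score = np.asarray(score, dtype=float)
    lo = t.pseudotime <= np.quantile(t.pseudotime, decile)
    hi = t.pseudotime >= np.quantile(t.pseudotime, 1.0 - decile)
    s_lo, s_hi = float(score[lo].mean()), float(score[hi].mean())
    scale = max(1.0, abs(s_lo), abs(s_hi))
    if abs(s_lo - s_hi) <= rtol * scale:
        raise AmbiguousOrientationError(
            f"markers flat across ends (low={s_lo:.6g}, high={s_hi:.6g})")
    return t if s_lo < s_hi else t.reversed()


def orient_trajectory(t: Trajectory, m: CountMatrix,
                      origin_markers: list[str],
                      decile: float = 0.1) -> Trajectory:
    """Root the trajectory where origin markers are least expressed.

    The markers are genes reported to have their lowest expression at the
    developmental origin (leaf base); the orientation minimizing their mean
    log-normalized expression over the lowest-pseudotime decile is chosen.
    """
    idx = m.gene_index(origin_markers)
    norm = m.normalized(log=True)[:, idx]
    if not (m.counts[:, idx].sum(axis=0) > 0).any():
        raise ParameterError("origin markers unexpressed in every cell")
    return orient_by_score(t, norm.mean(axis=1), decile=decile)


# ---------------------------------------------------------------------------
# pseudotime-dependent expression
# ---------------------------------------------------------------------------

def natural_cubic_basis(x: np.ndarray, df: int = 3) -> np.ndarray:
    """Natural cubic spline basis with ``df`` columns (no intercept).

    Boundary knots at min/max of ``x``; ``df - 1`` interior knots at
    quantiles.  Linear beyond the boundary knots.
    """
    if df < 1:
        raise ParameterError("df must be >= 1")
    x = np.asarray(x, dtype=float)
    if df == 1:
        return x[:, None] - x.mean()
    qs = np.linspace(0, 1, df + 1)
    knots = np.quantile(x, qs)
    knots = np.unique(knots)
    if len(knots) < df + 1:
        raise ParameterError("too few distinct x values for the spline")
    K = len(knots)

    def d(k):
        num = (np.clip(x - knots[k], 0, None) ** 3
               - np.clip(x - knots[K - 1], 0, None) ** 3)
        return num / (knots[K - 1] - knots[k])

    cols = [x]
    dK1 = d(K - 2)
    for k in range(K - 2):
        cols.append(d(k) - dK1)
    return np.column_stack(cols)


def _nb_lrt_one_gene(y: np.ndarray, basis: np.ndarray,
                     log_sf: np.ndarray, df_spline: int) -> tuple[float, float]:
    """NB likelihood-ratio p-value for pseudotime dependence of one gene.

    Dispersion is estimated by moments from a Poisson fit of the full
    model and held fixed in both the null (intercept) and full
    (intercept + spline) negative-binomial fits, so the LRT has
    ``df_spline`` degrees of freedom.
    """
    n = len(y)
    X1 = sm.add_constant(basis)
    X0 = np.ones((n, 1))
    pois = sm.GLM(y, X1, family=sm.families.Poisson(), offset=log_sf
                  ).fit(maxiter=50, tol=1e-8)
    mu = pois.fittedvalues
    alpha = float(np.sum((y - mu) ** 2 - mu) / np.sum(mu ** 2))
    alpha = min(max(alpha, 1e-8), 10.0)
    fam = sm.families.NegativeBinomial(alpha=alpha)
    fit1 = sm.GLM(y, X1, family=fam, offset=log_sf).fit(maxiter=100, tol=1e-8)
    fit0 = sm.GLM(y, X0, family=fam, offset=log_sf).fit(maxiter=100, tol=1e-8)
    lrt = max(0.0, 2.0 * (fit1.llf - fit0.llf))
    return lrt, float(chi2.sf(lrt, df_spline))


def test_dynamic_genes(m: CountMatrix, t: Trajectory, min_mean: float = 0.1,
                       df_spline: int = 3) -> pd.DataFrame:
    """Test each expressed gene for pseudotime-dependent expression.

    Genes with mean size-factor-normalized expression > ``min_mean`` are
    tested with a negative-binomial GLM likelihood-ratio test of a natural
    cubic spline of pseudotime (df = ``df_spline``) against an
    intercept-only model; p-values come from chi-squared with
    ``df_spline`` degrees of freedom and are BH-adjusted across tested
    genes.  Returns a gene-indexed frame with columns mean_expr, tested,
    lrt_stat, p, q, cluster ("none" until profile clustering), failed.
    """
    if len(t.pseudotime) != m.n_cells:
        raise ParameterError("trajectory does not cover all cells")
    totals = m.totals().astype(float)
    sf = totals / np.median(totals)
    mean_expr = (m.counts / sf[:, None]).mean(axis=0)
    basis = natural_cubic_basis(t.pseudotime, df=df_spline)
    log_sf = np.log(sf)

    out = pd.DataFrame({"mean_expr": mean_expr,
                        "tested": mean_expr > min_mean,
                        "lrt_stat": np.nan, "p": np.nan, "q": np.nan,
                        "cluster": "none", "failed": False},
                       index=m.gene_ids)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for gi in np.flatnonzero(out["tested"].to_numpy()):
            y = m.counts[:, gi].astype(float)
            try:
                lrt, p = _nb_lrt_one_gene(y, basis, log_sf, df_spline)
                out.iloc[gi, out.columns.get_loc("lrt_stat")] = lrt
                out.iloc[gi, out.columns.get_loc("p")] = p
            except Exception:
                out.iloc[gi, out.columns.get_loc("failed")] = True
    ok = out["tested"] & ~out["failed"] & out["p"].notna()
    if ok.any():
        out.loc[ok, "q"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    return out


def cluster_gene_profiles(dyn: pd.DataFrame, m: CountMatrix, t: Trajectory,
                          k: int = 6, q_threshold: float = 0.01,
                          n_bins: int = 100) -> pd.Series:
    """Group significant dynamic genes into k profile clusters G1..Gk.

    Each significant gene's size-factor-normalized expression is averaged
    over ``n_bins`` equal-width pseudotime bins (empty bins interpolated),
    z-scored, and clustered hierarchically (Ward linkage, Euclidean).  The
    tree is cut into ``k`` clusters whose ids are ordered by the pseudotime
    bin of each cluster's mean-profile peak, so G1 peaks earliest.
    """
    sig = dyn.index[(dyn["q"] < q_threshold).fillna(False)].tolist()
    if k > len(sig):
        raise ParameterError(f"k={k} exceeds {len(sig)} significant genes")
    totals = m.totals().astype(float)
    sf = totals / np.median(totals)
    gidx = m.gene_index(sig)
    norm = m.counts[:, gidx] / sf[:, None]

    bins = np.clip((t.pseudotime * n_bins).astype(int), 0, n_bins - 1)
    prof = np.full((len(sig), n_bins), np.nan)
    for b in range(n_bins):
        sel = bins == b
        if sel.any():
            prof[:, b] = norm[sel].mean(axis=0)
    # interpolate empty bins
    centers = np.arange(n_bins) + 0.5
    for gi in range(len(sig)):
        nanm = np.isnan(prof[gi])
        if nanm.any():
            prof[gi, nanm] = np.interp(centers[nanm], centers[~nanm],
                                       prof[gi, ~nanm])
    mu = prof.mean(axis=1, keepdims=True)
    sd = prof.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (prof - mu) / sd

    raw = fcluster(linkage(z, method="ward"), t=k, criterion="maxclust")
    peaks = {c: float(np.argmax(z[raw == c].mean(axis=0)))
             for c in np.unique(raw)}
    order = sorted(peaks, key=lambda c: (peaks[c], c))
    remap = {c: f"G{r + 1}" for r, c in enumerate(order)}
    labels = pd.Series([remap[c] for c in raw], index=sig, name="cluster")
    dyn.loc[labels.index, "cluster"] = labels
    return labels
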