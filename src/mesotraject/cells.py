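"""Cell-level preprocessing: QC, variable genes, embedding, clustering.

The workflow mirrors a standard droplet scRNA-seq analysis of maize
mesophyll protoplasts: cells with fewer than 10,000 reads or a
mitochondrial read fraction above 0.2 are discarded; the top 1,500 genes by
standardized dispersion feed a 25-component PCA; a 2-D embedding is
clustered with modularity-based community detection at a coarse resolution
(0.05) for cell-type annotation and a fine resolution (0.5) for pseudo-bulk
construction.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .types import ClusterAssignment, CountMatrix, MarkerPanel, ParameterError


def qc_filter(m: CountMatrix, min_reads: int = 10_000,
              max_mito: float = 0.2) -> tuple[CountMatrix, pd.DataFrame]:
    """Drop low-quality cells; report per-cell QC for every input cell.

    A cell fails when its total read count is below ``min_reads`` (strict:
    exactly ``min_reads`` passes) or its mitochondrial ratio exceeds
    ``max_mito`` (strict: exactly ``max_mito`` passes).  Returns the
    filtered matrix (gene set unchanged) and a QC table with columns
    total_reads, mito_ratio, pass, reason.
    """
    if m.n_cells == 0:
        raise ParameterError("empty count matrix")
    totals = m.totals()
    ratio = m.mito_ratio()
    ok_reads = totals >= min_reads
    ok_mito = ratio <= max_mito
    passed = ok_reads & ok_mito
    reason = np.where(passed, "",
                      np.where(~ok_reads & ~ok_mito, "reads+mito",
                               np.where(~ok_reads, "reads", "mito")))
    qc = pd.DataFrame({"total_reads": totals, "mito_ratio": ratio,
                       "pass": passed, "reason": reason}, index=m.cell_ids)
    if not passed.any():
        counts = qc.loc[~qc["pass"], "reason"].value_counts().to_dict()
        raise RuntimeError(f"all cells failed QC; failures by reason: {counts}")
    return m.subset_cells(passed), qc


def select_hvg(m: CountMatrix, n: int = 1_500, n_bins: int = 20) -> list[str]:
    """Rank genes by standardized dispersion, return the top ``n``.

    Mean and variance are computed on depth-normalized (counts per 10,000)
    expression; dispersion = log(variance/mean) is z-scored within
    equal-frequency mean bins so highly expressed genes do not dominate.
    Ties break by gene id; never-expressed genes rank last.
    """
    if n > m.n_genes:
        raise ParameterError(f"n={n} exceeds gene count {m.n_genes}")
    x = m.normalized(log=False)
    mean = x.mean(axis=0)
    var = x.var(axis=0, ddof=1) if m.n_cells > 1 else np.zeros(m.n_genes)
    expressed = mean > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(expressed & (var > 0), np.log(var / mean), -np.inf)

    df = pd.DataFrame({"gene": m.gene_ids, "mean": mean, "disp": disp})
    usable = df[np.isfinite(df["disp"])].copy()
    k = min(n_bins, max(1, len(usable) // 2))
    if len(usable):
        usable["bin"] = pd.qcut(usable["mean"].rank(method="first"), q=k,
                                labels=False)
        grp = usable.groupby("bin")["disp"]
        mu, sd = grp.transform("mean"), grp.transform("std").fillna(0.0)
        usable["z"] = np.where(sd > 0, (usable["disp"] - mu) / sd,
                               usable["disp"] - mu)
    else:
        usable["z"] = []
    ranked = pd.concat([usable, df[~np.isfinite(df["disp"])].assign(z=-np.inf)])
    ranked = ranked.sort_values(["z", "gene"], ascending=[False, True],
                                kind="mergesort")
    return ranked["gene"].head(n).tolist()


def embed_cells(m: CountMatrix, hvg: list[str], n_pcs: int = 25,
                n_neighbors: int = 50, min_dist: float = 0.1,
                seed: int = 0, method: str = "umap") -> np.ndarray:
    """Project cells to 2-D through log-normalization, scaling and PCA.

    ``method="umap"`` applies UMAP to the top ``n_pcs`` principal
    components (the stochastic default); ``method="pca"`` returns the first
    two components directly, a strictly deterministic fallback used when
    reproducibility at byte level matters more than manifold structure.
    """
    if not hvg:
        raise ParameterError("hvg list is empty")
    if n_pcs > min(m.n_cells, len(hvg)):
        raise ParameterError("n_pcs exceeds min(cells, hvg genes)")
    x = m.subset_genes(hvg).normalized(log=True)
    mu, sd = x.mean(axis=0), x.std(axis=0)
    sd[sd == 0] = 1.0
    x = np.clip((x - mu) / sd, -10, 10)
    pcs = PCA(n_components=n_pcs, svd_solver="full").fit_transform(x)
    if method == "pca":
        return pcs[:, :2].copy()
    if method == "umap":
        import umap  # deferred: numba compilation is slow at import time
        nn = min(n_neighbors, m.n_cells - 1)
        reducer = umap.UMAP(n_components=2, n_neighbors=nn,
                            min_dist=min_dist, random_state=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return np.asarray(reducer.fit_transform(pcs), dtype=float)
    raise ParameterError(f"unknown embedding method {method!r}")


def cluster_cells(embedding: np.ndarray, resolution: float, k: int = 15,
                  seed: int = 0) -> ClusterAssignment:
    """Modularity-based communities on a kNN graph of the 2-D embedding.

    Presets: resolution 0.05 recovers the coarse cell-type structure,
    resolution 0.5 the fine clusters used for pseudo-bulk samples.  Labels
    are relabelled to a contiguous 0..k-1 range ordered by cluster size.
    """
    import igraph
    import leidenalg

    emb = np.asarray(embedding, dtype=float)
    if emb.shape[0] < 2:
        raise ParameterError("need at least 2 cells to cluster")
    if np.allclose(emb, emb[0]):
        warnings.warn("all embedding coordinates identical; single cluster")
        return ClusterAssignment(np.zeros(emb.shape[0], dtype=int), resolution)
    k_eff = min(k, emb.shape[0] - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(emb)
    _, idx = nn.kneighbors(emb)
    edges = {(min(i, j), max(i, j)) for i, row in enumerate(idx)
             for j in row[1:]}
    g = igraph.Graph(n=emb.shape[0], edges=sorted(edges))
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution, seed=seed, n_iterations=-1)
    raw = np.asarray(part.membership)
    order = pd.Series(raw).value_counts(sort=True).index.tolist()
    remap = {old: new for new, old in enumerate(order)}
    return ClusterAssignment(np.array([remap[r] for r in raw]), resolution)


def annotate_clusters(m: CountMatrix, ca: ClusterAssignment,
                      panel: MarkerPanel
                      ) -> tuple[dict[int, str], pd.DataFrame, list[str]]:
    """Assign each cluster the cell type whose markers score highest.

    Returns (cluster -> cell type map, dot-plot table, missing markers).
    The dot-plot table holds, per (cluster, marker), the mean log-normalized
    expression and the fraction of cells with a nonzero count.  Cluster
    assignment uses the cell type with the highest mean of
    across-cluster-standardized marker means.
    """
    present = [e for e in panel.entries if e[0] in set(m.gene_ids)]
    missing = [e[0] for e in panel.entries if e[0] not in set(m.gene_ids)]
    if not present:
        raise ParameterError("no panel markers present in the matrix")
    genes = [g for g, _, _ in present]
    gidx = m.gene_index(genes)
    norm = m.normalized(log=True)[:, gidx]
    detected = (m.counts[:, gidx] > 0)

    records = []
    n_k = ca.n_clusters
    means = np.zeros((n_k, len(genes)))
    for c in range(n_k):
        sel = ca.labels == c
        means[c] = norm[sel].mean(axis=0)
        fracs = detected[sel].mean(axis=0)
        for (g, ct, _), mu, fr in zip(present, means[c], fracs):
            records.append((c, g, ct, float(mu), float(fr)))
    dots = pd.DataFrame(records, columns=["cluster", "gene", "cell_type",
                                          "mean_expr", "frac_expressed"])
    sd = means.std(axis=0)
    sd[sd == 0] = 1.0
    zmeans = (means - means.mean(axis=0)) / sd
    types = sorted({ct for _, ct, _ in present})
    assignment: dict[int, str] = {}
    for c in range(n_k):
        scores = {ct: float(np.mean([zmeans[c, i] for i, (_, t, _) in
                                     enumerate(present) if t == ct]))
                  for ct in types}
        assignment[c] = max(sorted(scores), key=lambda t: scores[t])
    return assignment, dots, missing
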