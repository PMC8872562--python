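"""Linear-ODE regulatory network inference and downstream filtering.

The inference model assumes TF expression x(t) follows linear dynamics
dx/dt = A x driven by a small latent space: x ~ W z with dz/dt = diag(b) z,
so z(t) = exp(b t) componentwise and A = W diag(b) W+ (pseudo-inverse).
For each run the latent rates b are optimized by iterative random
replacement (one coordinate resampled per iteration, kept if the
least-squares reconstruction residual of x ~ W exp(b t) improves) and W is
re-fit by ordinary least squares; the reported TF x TF weight matrix is the
elementwise mean of A over ``n_runs`` random restarts (the study averages
50 runs with latent dimension z = 4).

Downstream: a consensus network keeps ODE edges with |weight| above a
cutoff that are also coexpression connections; hubs are ranked by node
degree; TF-family enrichment compares observed highly-expressed TF counts
per family against expectation with a chi-squared test.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import chi2, fisher_exact

from .types import (CoexprNetwork, ConsensusNetwork, OdeGrn, ParameterError)


# ---------------------------------------------------------------------------
# ODE inference
# ---------------------------------------------------------------------------

def _fit_W(expr: np.ndarray, Z: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares W (genes x z) for expr ~ W Z; returns (W, RSS)."""
    W, res, _rank, _sv = np.linalg.lstsq(Z.T, expr.T, rcond=None)
    fitted = W.T @ Z
    rss = float(((expr - fitted) ** 2).sum())
    return W.T, rss


def fit_ode_grn(expr: np.ndarray | pd.DataFrame, pseudotime: np.ndarray,
                z: int = 4, n_runs: int = 50, iters: int = 100,
                b_range: tuple[float, float] = (-10.0, 2.0),
                seed: int = 0, keep_runs: bool = True) -> OdeGrn:
    """Infer a signed TF x TF weight matrix from expression over pseudotime.

    Parameters
    ----------
    expr
        TF x cell expression matrix (rows named if a DataFrame).
    pseudotime
        Per-cell values in [0, 1] (the required input contract).
    z
        Latent dimension (default 4).
    n_runs
        Random restarts averaged into the reported matrix (default 50).
    iters
        Random-replacement iterations per run for optimizing b.
    """
    if isinstance(expr, pd.DataFrame):
        tf_ids = list(expr.index)
        X = expr.to_numpy(dtype=float)
    else:
        X = np.asarray(expr, dtype=float)
        tf_ids = [f"TF{i + 1:03d}" for i in range(X.shape[0])]
    t = np.asarray(pseudotime, dtype=float)
    if t.min() < 0.0 or t.max() > 1.0:
        raise ParameterError("pseudotime must lie in [0, 1]")
    n_tf = X.shape[0]
    if n_tf < z + 1:
        raise ParameterError(f"need at least z+1={z + 1} TFs")
    if X.shape[1] != len(t):
        raise ParameterError("expression columns must match pseudotime length")

    lo, hi = b_range
    child_seeds = np.random.SeedSequence(seed).spawn(n_runs)
    per_run = np.empty((n_runs, n_tf, n_tf))
    per_rss = np.empty(n_runs)
    kept = np.ones(n_runs, dtype=bool)
    W_last = b_last = None
    for r in range(n_runs):
        rng = np.random.default_rng(child_seeds[r])
        b = rng.uniform(lo, hi, size=z)
        W, rss = _fit_W(X, np.exp(np.outer(b, t)))
        for _ in range(iters):
            j = int(rng.integers(z))
            cand = b.copy()
            cand[j] = rng.uniform(lo, hi)
            W_c, rss_c = _fit_W(X, np.exp(np.outer(cand, t)))
            if rss_c < rss:
                b, W, rss = cand, W_c, rss_c
        A_r = W @ np.diag(b) @ np.linalg.pinv(W)
        if not np.all(np.isfinite(A_r)):
            warnings.warn(f"run {r}: non-finite weights; run discarded")
            kept[r] = False
            continue
        per_run[r] = A_r
        per_rss[r] = rss
        W_last, b_last = W, b
    if not kept.any():
        raise RuntimeError("every inference run was discarded")
    if not kept.all():
        warnings.warn(f"averaging over {int(kept.sum())}/{n_runs} kept runs")
    A = per_run[kept].mean(axis=0)
    return OdeGrn(tf_ids=tf_ids, z=z, W=W_last, b=b_last,
                  A=pd.DataFrame(A, index=tf_ids, columns=tf_ids),
                  n_runs=int(kept.sum()),
                  per_run_A=per_run[kept] if keep_runs else None,
                  per_run_rss=per_rss[kept] if keep_runs else None)


def edge_scores(ode: OdeGrn) -> pd.Series:
    """Off-diagonal |weight| per (regulator, target) ordered pair.

    ``A[i, j]`` is the effect of regulator j on target i, so the pair index
    is (column TF, row TF).
    """
    A = ode.A.to_numpy()
    idx, vals = [], []
    for i, tgt in enumerate(ode.tf_ids):
        for j, reg in enumerate(ode.tf_ids):
            if i != j:
                idx.append((reg, tgt))
                vals.append(abs(A[i, j]))
    return pd.Series(vals, index=pd.MultiIndex.from_tuples(
        idx, names=["regulator", "target"]))


# ---------------------------------------------------------------------------
# consensus filtering and hubs
# ---------------------------------------------------------------------------

def consensus_network(ode: OdeGrn, co: CoexprNetwork,
                      cutoff: float) -> ConsensusNetwork:
    """ODE edges with |weight| >= cutoff that the coexpression net supports.

    An ordered pair (regulator, target) survives iff |A_{target,regulator}|
    >= ``cutoff`` and {regulator, target} is a coexpression connection.
    The study applies cutoffs 0.1 (exploratory) and 0.5 (condensed).
    """
    shared = set(ode.tf_ids) & set(co.tom.columns)
    if not shared:
        warnings.warn("ODE and coexpression networks share no genes")
        return ConsensusNetwork(edges=[], cutoff=cutoff)
    A = ode.A
    edges, prov = [], []
    for reg in ode.tf_ids:
        for tgt in ode.tf_ids:
            if reg == tgt:
                continue
            w = float(A.loc[tgt, reg])
            if abs(w) >= cutoff and co.has_edge(reg, tgt):
                edges.append((reg, tgt, w))
                prov.append({"ode_weight": w,
                             "coexpr_tom": float(co.tom.loc[reg, tgt])})
    return ConsensusNetwork(edges=edges, cutoff=cutoff, provenance=prov)


def hub_nodes(net: ConsensusNetwork, top_k: int) -> pd.DataFrame:
    """Rank nodes by undirected degree over unique partners.

    Ties break by summed |edge weight| (descending), then node id.  If
    ``top_k`` exceeds the node count the full ranking is returned.
    """
    if top_k <= 0:
        raise ParameterError("top_k must be positive")
    if not net.edges:
        raise ParameterError("network is empty")
    partners: dict[str, set[str]] = {}
    wsum: dict[str, float] = {}
    for a, b, w in net.edges:
        partners.setdefault(a, set()).add(b)
        partners.setdefault(b, set()).add(a)
        wsum[a] = wsum.get(a, 0.0) + abs(w)
        wsum[b] = wsum.get(b, 0.0) + abs(w)
    rows = [(node, len(p), wsum[node]) for node, p in partners.items()]
    df = pd.DataFrame(rows, columns=["node", "degree", "weight_sum"])
    df = df.sort_values(["degree", "weight_sum", "node"],
                        ascending=[False, False, True], kind="mergesort")
    return df.head(top_k).reset_index(drop=True)


# ---------------------------------------------------------------------------
# TF-family enrichment
# ---------------------------------------------------------------------------

def tf_family_enrichment(high_M: list[str], high_BS: list[str],
                         family_map: dict[str, str],
                         alpha: float = 0.01) -> pd.DataFrame:
    """Chi-squared enrichment of TF families among highly expressed TFs.

    For each family f with n_f members out of N annotated TFs, the
    expected highly expressed count per cell type is
    ``|high| * n_f / N``; the observed (in-family, out-of-family) split is
    tested against expectation with a 1-df chi-squared.  When an expected
    cell is zero an exact (Fisher) fallback is used.  Expected counts are
    conservative: they sum to |high| across families per cell type.
    """
    for tf in list(high_M) + list(high_BS):
        if tf not in family_map:
            raise ParameterError(f"TF {tf} has no family annotation")
    fams = sorted(set(family_map.values()))
    N = len(family_map)
    n_f = {f: sum(1 for v in family_map.values() if v == f) for f in fams}
    rows = []
    for f in fams:
        row: dict = {"family": f, "n_family": n_f[f]}
        for label, high in (("M", list(high_M)), ("BS", list(high_BS))):
            H = len(high)
            obs = sum(1 for tf in high if family_map[tf] == f)
            exp = H * n_f[f] / N
            row[f"n_high_{label}"] = obs
            row[f"expected_{label}"] = exp
            row[f"ratio_{label}"] = obs / exp if exp > 0 else np.inf
            exp_out = H - exp
            if exp == 0 or exp_out == 0:
                table = [[obs, n_f[f] - obs],
                         [H - obs, (N - n_f[f]) - (H - obs)]]
                p = float(fisher_exact(np.maximum(table, 0))[1])
                stat = np.nan
            else:
                stat = (obs - exp) ** 2 / exp + ((H - obs) - exp_out) ** 2 / exp_out
                p = float(chi2.sf(stat, df=1))
            row[f"chi2_{label}"] = stat
            row[f"p_{label}"] = p
            row[f"significant_{label}"] = p < alpha
        rows.append(row)
    return pd.DataFrame(rows).set_index("family")
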