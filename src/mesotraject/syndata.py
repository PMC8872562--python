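"""Synthetic single-cell and genomic data with known ground truth.

The generator emulates the statistical structure of a droplet scRNA-seq
experiment on differentiating maize mesophyll cells plus the genomic tracks
(open chromatin, TF ChIP peaks, distal accessible regions, chromatin loops,
promoter sequences, nuclease coverage) that the downstream stages integrate.
Every planted feature is recorded in :class:`~mesotraject.types.SynTruth`
so each stage can be scored exactly.

Model sketch
------------
* A ground-truth TF network ``A_true`` with strictly negative diagonal
  (self-degradation) drives latent TF trajectories ``dz/dt = A_true z`` from
  a fixed positive initial state, integrated over developmental time
  ``t in [0, 1]``.
* Target genes follow smooth logistic/Gaussian templates of ``t``
  (increasing / decreasing / transient / flat), the same qualitative shapes
  as the six dynamic-gene clusters observed along the base-to-tip axis.
* Counts are gamma-multinomial: per-cell gene propensities are the latent
  means perturbed by gamma noise (negative-binomial-like overdispersion),
  then a multinomial draw distributes an exact per-cell library size drawn
  log-normally around ``depth_mean``.  Per-cell totals therefore equal the
  sampled library sizes exactly.
* A designated mitochondrial gene block carries ~``mito_frac`` of each
  healthy cell's reads; planted low-quality cells violate either the read
  floor or the mitochondrial ceiling used by QC.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .types import (CountMatrix, GenomeAnnotation, GrnTruth, IntervalSet,
                    LoopSet, MarkerPanel, ParameterError, Pwm, SynTruth)

_NT = np.array(list("ACGT"))

# QC thresholds the planted low-quality cells are constructed to violate.
QC_MIN_READS = 10_000
QC_MAX_MITO = 0.2


# ---------------------------------------------------------------------------
# ground-truth network
# ---------------------------------------------------------------------------

def simulate_grn(n_tf: int, density: float, weight_scale: float = 1.0,
                 decay_scale: float = 0.2, seed: int = 0) -> GrnTruth:
    """Sample a random signed TF x TF network with self-degradation.

    ``A_true[i, j]`` is the effect of regulator ``j`` on target ``i``.
    Diagonal entries are strictly negative (first-order self-degradation);
    each off-diagonal entry is nonzero with probability ``density`` with
    magnitude bounded away from zero (uniform in [0.5, 1.5] x
    ``weight_scale``) and a random sign.  ``decay_scale`` sets degradation
    relative to regulation: the default 0.2 encodes TF turnover slow
    compared with regulatory drive over the developmental window, so the
    observed dynamics are dominated by the interactions rather than by
    uniform decay.
    """
    if n_tf < 2:
        raise ParameterError("n_tf must be >= 2")
    if not (0 <= density < 1):
        raise ParameterError("density must lie in [0, 1)")
    if weight_scale <= 0 or decay_scale <= 0:
        raise ParameterError("weight_scale and decay_scale must be positive")
    rng = np.random.default_rng(seed)
    A = np.zeros((n_tf, n_tf))
    np.fill_diagonal(A, -rng.uniform(0.5, 1.5, size=n_tf)
                     * weight_scale * decay_scale)
    offdiag = rng.random((n_tf, n_tf)) < density
    np.fill_diagonal(offdiag, False)
    mags = rng.uniform(0.5, 1.5, size=(n_tf, n_tf)) * weight_scale
    signs = rng.choice([-1.0, 1.0], size=(n_tf, n_tf))
    A[offdiag] = (mags * signs)[offdiag]
    tf_ids = [f"TF{i + 1:03d}" for i in range(n_tf)]
    edges = [(tf_ids[j], tf_ids[i], int(np.sign(A[i, j])))
             for i, j in zip(*np.nonzero(A)) if i != j]
    return GrnTruth(tf_ids=tf_ids, targets=[], A_true=A, edge_list=edges,
                    sparsity=float(np.count_nonzero(A)) / A.size)


def integrate_truth(grn: GrnTruth, times: np.ndarray,
                    z0: np.ndarray | None = None) -> np.ndarray:
    """Latent TF trajectories z(t) from dz/dt = A_true z (TFs x cells)."""
    n = len(grn.tf_ids)
    if z0 is None:
        z0 = 1.0 + np.linspace(0.0, 1.0, n)
    order = np.argsort(times)
    sol = solve_ivp(lambda _t, z: grn.A_true @ z, (0.0, 1.0), z0,
                    t_eval=np.sort(times), rtol=1e-8, atol=1e-10,
                    dense_output=False)
    if not sol.success:  # pragma: no cover - damped linear systems integrate
        raise RuntimeError(f"truth integration failed: {sol.message}")
    out = np.empty((n, len(times)))
    out[:, order] = sol.y
    return out


def simulate_latent_expression(grn: GrnTruth, n_cells: int = 300,
                               seed: int = 0
                               ) -> tuple[np.ndarray, np.ndarray]:
    """TF x cell latent expression sampled straight from the truth ODE.

    Cells receive uniform developmental times; expression is the noiseless
    latent trajectory at those times.  This is the cleanest recovery
    surface for the ODE inference: the data come from exactly the model
    family the method assumes.
    """
    rng = np.random.default_rng(seed)
    times = rng.uniform(0.0, 1.0, size=n_cells)
    return integrate_truth(grn, times), times


# ---------------------------------------------------------------------------
# cells
# ---------------------------------------------------------------------------

_TEMPLATES = ("increasing", "decreasing", "transient", "flat")


def _template_profile(label: str, t: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    k = rng.uniform(6.0, 12.0)
    t0 = rng.uniform(0.3, 0.7)
    if label == "increasing":
        return 1.0 / (1.0 + np.exp(-k * (t - t0)))
    if label == "decreasing":
        return 1.0 / (1.0 + np.exp(k * (t - t0)))
    if label == "transient":
        width = rng.uniform(0.08, 0.2)
        return np.exp(-0.5 * ((t - t0) / width) ** 2)
    return np.full_like(t, 0.5)


def simulate_cells(grn: GrnTruth, n_cells: int = 500,
                   depth_mean: float = 44_805.0, mito_frac: float = 0.05,
                   n_lowq: int = 0, nb_dispersion: float = 0.2,
                   n_targets: int = 200, n_mito: int = 10,
                   bs_fraction: float = 0.15, n_markers_per_type: int = 8,
                   dynamics: str = "ode", seed: int = 0
                   ) -> tuple[CountMatrix, SynTruth]:
    """Draw a cells x genes UMI matrix along a latent developmental axis.

    Parameters
    ----------
    grn
        Ground-truth TF network; its latent trajectories drive TF means.
    depth_mean
        Mean per-cell library size (the study reports ~44,805 reads/cell).
    mito_frac
        Expected mitochondrial read share of healthy cells.
    n_lowq
        Planted low-quality cells, split between "reads" (library size below
        the 10,000-read QC floor) and "mito" (mitochondrial share above the
        0.2 QC ceiling).
    dynamics
        "ode": TF means follow the latent linear ODE (matched to the
        inference model); "logistic": TFs also use nonlinear templates, to
        probe robustness of downstream inference.
    """
    if n_lowq > n_cells:
        raise ParameterError("n_lowq cannot exceed n_cells")
    if not (0 <= mito_frac < 1):
        raise ParameterError("mito_frac must lie in [0, 1)")
    if np.any(np.diag(grn.A_true) >= 0):
        raise ParameterError("truth network must have negative diagonal")
    rng = np.random.default_rng(seed)

    n_tf = len(grn.tf_ids)
    true_time = rng.uniform(0.0, 1.0, size=n_cells)

    # --- latent per-gene mean profiles -----------------------------------
    if dynamics == "ode":
        z = integrate_truth(grn, true_time)                 # TFs x cells
        # shift (not clip) to positive means so trajectory shapes survive
        tf_means = z - min(0.0, float(z.min())) + 0.05
    elif dynamics == "logistic":
        tf_means = np.vstack([
            0.2 + _template_profile(rng.choice(_TEMPLATES[:3]), true_time, rng)
            for _ in range(n_tf)])
    else:
        raise ParameterError(f"unknown dynamics mode {dynamics!r}")

    target_ids = [f"GENE{i + 1:04d}" for i in range(n_targets)]
    labels = [_TEMPLATES[i % len(_TEMPLATES)] for i in range(n_targets)]
    target_means = np.vstack([
        0.1 + _template_profile(lab, true_time, rng) for lab in labels])

    mito_ids = [f"MT{i + 1:03d}" for i in range(n_mito)]

    gene_ids = list(grn.tf_ids) + target_ids + mito_ids
    mito_mask = np.zeros(len(gene_ids), dtype=bool)
    mito_mask[n_tf + n_targets:] = True

    # --- cell types via additive marker offsets --------------------------
    cell_type = np.where(rng.random(n_cells) < bs_fraction, "BS", "M")
    m_markers = target_ids[:n_markers_per_type]
    bs_markers = target_ids[n_markers_per_type:2 * n_markers_per_type]
    panel = MarkerPanel(entries=[(g, "M", "up") for g in m_markers]
                        + [(g, "BS", "up") for g in bs_markers])
    marker_boost = 3.0
    nuclear = np.vstack([tf_means, target_means])           # genes x cells
    for g in m_markers:
        nuclear[gene_ids.index(g)] += marker_boost * (cell_type == "M")
    for g in bs_markers:
        nuclear[gene_ids.index(g)] += marker_boost * (cell_type == "BS")

    # --- partition cell propensity between nuclear and mito blocks -------
    nuc_prop = nuclear / nuclear.sum(axis=0, keepdims=True)
    mito_prop = np.full((n_mito, n_cells), 1.0 / n_mito)

    mito_share = np.full(n_cells, mito_frac)
    lib = np.rint(rng.lognormal(np.log(depth_mean) - 0.3 ** 2 / 2, 0.3,
                                size=n_cells)).astype(int)
    lib = np.maximum(lib, int(1.2 * QC_MIN_READS))          # healthy floor

    low_quality: dict[str, str] = {}
    cell_ids = [f"CELL{i + 1:05d}" for i in range(n_cells)]
    if n_lowq:
        lowq_idx = rng.choice(n_cells, size=n_lowq, replace=False)
        for rank, ci in enumerate(lowq_idx):
            if rank % 2 == 0:
                lib[ci] = int(rng.integers(1_000, QC_MIN_READS - 500))
                low_quality[cell_ids[ci]] = "reads"
            else:
                mito_share[ci] = rng.uniform(0.3, 0.6)
                low_quality[cell_ids[ci]] = "mito"

    # --- gamma-multinomial sampling (NB-like, totals exact) ---------------
    shape = 1.0 / nb_dispersion
    counts = np.empty((n_cells, len(gene_ids)), dtype=np.int64)
    for c in range(n_cells):
        p = np.concatenate([nuc_prop[:, c] * (1.0 - mito_share[c]),
                            mito_prop[:, c] * mito_share[c]])
        p = p * rng.gamma(shape, 1.0 / shape, size=p.size)
        counts[c] = rng.multinomial(lib[c], p / p.sum())

    matrix = CountMatrix(counts=counts, cell_ids=cell_ids,
                         gene_ids=gene_ids, mito_mask=mito_mask)
    truth = SynTruth(true_time=true_time, cell_type=cell_type,
                     low_quality_flags=low_quality,
                     dynamic_gene_labels=dict(zip(target_ids, labels)),
                     marker_panel=panel)
    return matrix, truth


def simulate_gradient_cells(n_cells: int = 200, n_genes: int = 50,
                            depth: int = 20_000, noiseless: bool = False,
                            seed: int = 0) -> tuple[CountMatrix, SynTruth]:
    """Cells along a clean 1-D expression gradient (pseudotime oracle case).

    Half the genes rise linearly with developmental time, half fall; in the
    ``noiseless`` mode counts are the rounded expected values, giving an
    essentially exact orderable gradient.
    """
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 1.0, n_cells)
    up = np.linspace(0.2, 1.0, n_genes // 2)
    means = np.vstack([0.2 + 1.8 * np.outer(up, t),
                       0.2 + 1.8 * np.outer(up, 1.0 - t)])   # genes x cells
    prop = means / means.sum(axis=0, keepdims=True)
    if noiseless:
        counts = np.rint(prop.T * depth).astype(np.int64)
    else:
        counts = np.vstack([rng.multinomial(depth, prop[:, c])
                            for c in range(n_cells)])
    gene_ids = [f"G{i + 1:03d}" for i in range(means.shape[0])]
    cm = CountMatrix(counts=counts,
                     cell_ids=[f"CELL{i + 1:05d}" for i in range(n_cells)],
                     gene_ids=gene_ids,
                     mito_mask=np.zeros(len(gene_ids), dtype=bool))
    labels = {g: ("increasing" if i < n_genes // 2 else "decreasing")
              for i, g in enumerate(gene_ids)}
    return cm, SynTruth(true_time=t,
                        cell_type=np.full(n_cells, "M", dtype=object),
                        dynamic_gene_labels=labels)


# ---------------------------------------------------------------------------
# genome tracks
# ---------------------------------------------------------------------------

def consensus_pwm(consensus: str, strength: float = 0.97,
                  name: str = "motif") -> Pwm:
    """PWM from an IUPAC-ish consensus; 'n' positions get uniform columns."""
    rows = []
    for ch in consensus.upper():
        if ch == "N":
            rows.append(np.full(4, 0.25))
        else:
            col = np.full(4, (1.0 - strength) / 3.0)
            col["ACGT".index(ch)] = strength
            rows.append(col)
    return Pwm(np.vstack(rows), name=name)


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length)


_COMP = np.array([3, 2, 1, 0])


def simulate_genome_tracks(n_genes: int = 30, chrom_len: int = 400_000,
                           motif: Pwm | None = None,
                           footprint_depth: float = 0.5, n_loops: int = 6,
                           promoter_len: int = 600, gene_len: int = 1_000,
                           n_motif_promoters: int | None = None,
                           n_chip_direct: int = 4, n_dacrs_extra: int = 3,
                           tf_names: tuple[str, ...] = ("TFA", "TFB"),
                           seed: int = 0):
    """Lay out a toy chromosome with planted regulatory structure.

    Returns a dict with keys ``annotation`` (:class:`GenomeAnnotation`),
    ``mhs`` / ``tf_peaks`` (per-TF dict) / ``dacrs`` (:class:`IntervalSet`),
    ``loops`` (:class:`LoopSet`), ``promoter_seqs`` (gene_id -> str, genomic
    forward orientation), ``coverage`` (chrom -> (starts, ends, values)
    bedGraph-style step function) and ``truth`` (:class:`SynTruth` with the
    planted motif positions, loop-supported pairs and direct-binding pairs).

    Planted structure: an MNase-hypersensitivity peak spans each promoter;
    the motif consensus is planted at a recorded offset in a subset of
    promoters and the coverage inside each planted motif span is depleted by
    ``footprint_depth`` (a protein-protection footprint).  TF ChIP peaks and
    dACR-promoter loops are planted so the promoter-promoter (PPI) and
    promoter-distal (PDI) construction rules recover exactly the recorded
    pairs.
    """
    if motif is None:
        motif = consensus_pwm("AGAANNTTCT", name="HSF1")
    if motif.width >= promoter_len:
        raise ParameterError("motif must be narrower than the promoter")
    rng = np.random.default_rng(seed)

    spacing = chrom_len // (n_genes + 1)
    if spacing < gene_len + 2 * promoter_len + 4_000:
        raise ParameterError("chrom_len too small to place n_genes")
    chrom = "chrS"
    rows, promoters, prom_seqs = [], {}, {}
    for i in range(n_genes):
        gid = f"GENE{i + 1:04d}"
        anchor = spacing * (i + 1)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            start, end = anchor, anchor + gene_len
            tss = start
            pstart, pend = tss - promoter_len, tss
        else:
            start, end = anchor - gene_len, anchor
            tss = end - 1
            pstart, pend = tss + 1, tss + 1 + promoter_len
        rows.append((gid, chrom, start, end, strand, tss))
        promoters[gid] = (chrom, pstart, pend)
        prom_seqs[gid] = _random_seq(rng, promoter_len)

    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end",
                                        "strand", "tss"])
    ann = GenomeAnnotation(genes=genes, chrom_sizes={chrom: chrom_len},
                           promoters=promoters)

    # --- plant motif instances in a recorded promoter subset --------------
    if n_motif_promoters is None:
        n_motif_promoters = n_genes // 2
    consensus_idx = np.argmax(motif.matrix, axis=1)
    degenerate = np.isclose(motif.matrix.max(axis=1), 0.25)
    motif_positions: list[tuple[str, int, str]] = []
    planted_gids = [genes["gene_id"].iloc[i]
                    for i in rng.choice(n_genes, size=n_motif_promoters,
                                        replace=False)]
    for gid in planted_gids:
        offset = int(rng.integers(50, promoter_len - motif.width - 50))
        inst = consensus_idx.copy()
        inst[degenerate] = rng.integers(0, 4, size=int(degenerate.sum()))
        strand = "+" if rng.random() < 0.5 else "-"
        prom_seqs[gid][offset:offset + motif.width] = (
            inst if strand == "+" else _COMP[inst[::-1]])
        motif_positions.append((gid, offset, strand))

    # --- MHS peaks over promoters -----------------------------------------
    mhs = IntervalSet(pd.DataFrame(
        [(chrom, s, e, f"MHS_{gid}", 100) for gid, (chrom, s, e) in promoters.items()],
        columns=["chrom", "start", "end", "name", "score"]), kind="MHS")

    # --- coverage: background 1, MHS elevated, footprints depleted ---------
    breaks = {0, chrom_len}
    elevated: list[tuple[int, int]] = []
    for _, s, e in promoters.values():
        breaks.update((s, e))
        elevated.append((s, e))
    dips: list[tuple[int, int]] = []
    for gid, off, _strand in motif_positions:
        _, ps, _pe = promoters[gid]
        gs, ge = ps + off, ps + off + motif.width
        breaks.update((gs, ge))
        dips.append((gs, ge))
    bpts = np.array(sorted(breaks))
    starts, ends = bpts[:-1], bpts[1:]
    values = np.ones(len(starts))
    for s, e in elevated:
        values[(starts >= s) & (ends <= e)] = 10.0
    for s, e in dips:
        values[(starts >= s) & (ends <= e)] *= (1.0 - footprint_depth)
    coverage = {chrom: (starts, ends, values)}

    # --- loops: disjoint PPI pairs + PDI configurations --------------------
    free = [g for g in genes["gene_id"]]
    rng.shuffle(free)
    loop_rows, dacr_rows = [], []
    tf_peak_rows: dict[str, list] = {tf: [] for tf in tf_names}
    loop_pairs: list[tuple[str, str, str]] = []
    n_ppi = n_loops // 2
    n_pdi = n_loops - n_ppi
    li = 0
    for _ in range(n_ppi):
        if len(free) < 2:
            break
        a, b = free.pop(), free.pop()
        ca, sa, ea = promoters[a]
        cb, sb, eb = promoters[b]
        loop_rows.append((ca, sa, ea, cb, sb, eb, f"loop{li:03d}"))
        loop_pairs.append((a, b, "PPI"))
        li += 1
    for k in range(n_pdi):
        if not free:
            break
        g = free.pop()
        tf = tf_names[k % len(tf_names)]
        cg, sg, eg = promoters[g]
        # distal site midway into the intergenic gap upstream of the promoter
        site = max(200, sg - spacing // 2)
        dacr = (chrom, site, site + 400, f"dACR_{g}", 50)
        dacr_rows.append(dacr)
        tf_peak_rows[tf].append((chrom, site + 100, site + 300,
                                 f"{tf}_peak_{g}", 200))
        loop_rows.append((chrom, site, site + 400, cg, sg, eg, f"loop{li:03d}"))
        loop_pairs.append((tf, g, "PDI"))
        li += 1
    # decoy dACRs far from any loop/promoter
    for k in range(n_dacrs_extra):
        site = spacing // 4 + k * 700
        dacr_rows.append((chrom, site, site + 300, f"dACR_decoy{k}", 10))

    # direct TF ChIP peaks on promoters (chip_direct truth)
    chip_direct: list[tuple[str, str]] = []
    for k in range(min(n_chip_direct, len(free))):
        g = free.pop()
        tf = tf_names[k % len(tf_names)]
        _, s, e = promoters[g]
        mid = (s + e) // 2
        tf_peak_rows[tf].append((chrom, mid - 100, mid + 100,
                                 f"{tf}_direct_{g}", 150))
        chip_direct.append((tf, g))

    cols = ["chrom", "start", "end", "name", "score"]
    tf_peaks = {tf: IntervalSet(pd.DataFrame(rows_, columns=cols), kind="TF_ChIP")
                for tf, rows_ in tf_peak_rows.items()}
    dacrs = IntervalSet(pd.DataFrame(dacr_rows, columns=cols), kind="dACR")
    loops = LoopSet(pd.DataFrame(
        loop_rows, columns=["chromA", "startA", "endA",
                            "chromB", "startB", "endB", "name"]))

    truth = SynTruth(motif_positions=motif_positions,
                     loop_supported_pairs=loop_pairs,
                     chip_direct_pairs=chip_direct)
    return {
        "annotation": ann,
        "mhs": mhs,
        "tf_peaks": tf_peaks,
        "dacrs": dacrs,
        "loops": loops,
        "promoter_seqs": {g: "".join(_NT[s]) for g, s in prom_seqs.items()},
        "coverage": coverage,
        "motif": motif,
        "truth": truth,
    }
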