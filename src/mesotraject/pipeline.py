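"""End-to-end pipeline orchestration with a reproducibility manifest.

``run_pipeline`` executes the stages in order — synthetic-data generation,
cell QC/clustering, trajectory inference, pseudo-bulk coexpression,
ODE network inference with consensus filtering, and regulome integration —
writing per-stage TSV outputs and a JSON manifest of SHA-256 digests.
Identical config + seeds give byte-identical outputs; resuming after
deleting an intermediate rewrites only the missing files (all stages are
deterministic, so the digests reproduce).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cells as cells_mod
from . import coexpr as coexpr_mod
from . import grn as grn_mod
from . import io as io_mod
from . import regulome as regulome_mod
from . import syndata
from . import trajectory as traj_mod
from .types import ParameterError

__version__ = "0.1.0"
log = logging.getLogger("mesotraject")


@dataclass
class PipelineConfig:
    """Every tunable default of the pipeline, serializable to YAML."""

    # syndata
    n_tf: int = 20
    grn_density: float = 0.1
    n_cells: int = 500
    depth_mean: float = 44_805.0
    mito_frac: float = 0.05
    n_lowq: int = 25
    n_targets: int = 120
    n_genome_genes: int = 30
    chrom_len: int = 400_000
    n_loops: int = 6
    footprint_depth: float = 0.5
    # cells
    min_reads: int = 10_000
    max_mito: float = 0.2
    n_hvg: int = 1_500
    n_pcs: int = 25
    n_neighbors: int = 50
    min_dist: float = 0.1
    resolution_coarse: float = 0.05
    resolution_fine: float = 0.5
    embedding_method: str = "umap"
    knn_k: int = 15
    # trajectory
    min_mean: float = 0.1
    df_spline: int = 3
    q_dynamic: float = 0.01
    k_gene_clusters: int = 6
    # coexpr
    top_frac: float = 0.75
    coexpr_beta: str | int = "auto"
    edge_quantile: float = 0.95
    # grn
    z: int = 4
    n_runs: int = 50
    ode_iters: int = 100
    cutoff_loose: float = 0.1
    cutoff_strict: float = 0.5
    # regulome
    flank: int = 1_500
    bin_size: int = 100
    promoter_halfwidth: int = 1_000
    max_chain: int = 2
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.max_mito < 1) or not (0 < self.top_frac <= 1):
            raise ParameterError("threshold outside valid range")
        if self.min_reads <= 0 or self.n_hvg <= 0 or self.z <= 0:
            raise ParameterError("counts/dimensions must be positive")
        if not (0 <= self.grn_density < 1):
            raise ParameterError("grn_density must lie in [0, 1)")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        data.update(overrides)
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g", **kw)


def run_pipeline(config: PipelineConfig, outdir: str | Path,
                 resume: bool = False) -> dict:
    """Run every stage on synthetic inputs and return the manifest.

    With ``resume=True`` existing output files are kept (stages still
    recompute in memory — they are cheap and deterministic — but only
    missing files are rewritten).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config
    stages: list[str] = []

    def emit(path: Path, writer) -> None:
        if not (resume and path.exists()):
            writer(path)

    # --- stage: simulate --------------------------------------------------
    log.info("stage simulate: seed=%d n_cells=%d n_tf=%d",
             cfg.seed, cfg.n_cells, cfg.n_tf)
    truth_grn = syndata.simulate_grn(cfg.n_tf, cfg.grn_density, seed=cfg.seed)
    matrix, truth = syndata.simulate_cells(
        truth_grn, n_cells=cfg.n_cells, depth_mean=cfg.depth_mean,
        mito_frac=cfg.mito_frac, n_lowq=cfg.n_lowq,
        n_targets=cfg.n_targets, seed=cfg.seed + 1)
    tracks = syndata.simulate_genome_tracks(
        n_genes=cfg.n_genome_genes, chrom_len=cfg.chrom_len,
        footprint_depth=cfg.footprint_depth, n_loops=cfg.n_loops,
        seed=cfg.seed + 2)
    mtx_dir = outdir / "counts"
    if not (resume and (mtx_dir / "matrix.mtx").exists()):
        io_mod.write_counts(matrix, mtx_dir)
    emit(outdir / "genes.gff3",
         lambda p: io_mod.write_gff3(tracks["annotation"], p))
    emit(outdir / "mhs.bed", lambda p: io_mod.write_bed(tracks["mhs"], p))
    emit(outdir / "loops.bedpe",
         lambda p: io_mod.write_bedpe(tracks["loops"], p))
    emit(outdir / "coverage.bedgraph",
         lambda p: io_mod.write_bedgraph(tracks["coverage"], p))
    emit(outdir / "promoters.fasta",
         lambda p: io_mod.write_fasta(tracks["promoter_seqs"], p))
    emit(outdir / "motif.meme",
         lambda p: io_mod.write_meme([tracks["motif"]], p))
    emit(outdir / "truth.json", lambda p: p.write_text(json.dumps({
        "low_quality": truth.low_quality_flags,
        "loop_supported_pairs": truth.loop_supported_pairs,
        "chip_direct_pairs": tracks["truth"].chip_direct_pairs,
    }, indent=1, sort_keys=True)))
    stages.append("simulate")

    # --- stage: cells -----------------------------------------------------
    filtered, qc = cells_mod.qc_filter(matrix, cfg.min_reads, cfg.max_mito)
    log.info("stage cells: %d cells in, %d kept", matrix.n_cells,
             filtered.n_cells)
    hvg = cells_mod.select_hvg(filtered, n=min(cfg.n_hvg, filtered.n_genes))
    emb = cells_mod.embed_cells(
        filtered, hvg, n_pcs=min(cfg.n_pcs, len(hvg), filtered.n_cells),
        n_neighbors=cfg.n_neighbors, min_dist=cfg.min_dist,
        seed=cfg.seed, method=cfg.embedding_method)
    coarse = cells_mod.cluster_cells(emb, cfg.resolution_coarse,
                                     k=cfg.knn_k, seed=cfg.seed)
    fine = cells_mod.cluster_cells(emb, cfg.resolution_fine,
                                   k=cfg.knn_k, seed=cfg.seed)
    annot, dots, _missing = cells_mod.annotate_clusters(
        filtered, coarse, truth.marker_panel)
    emit(outdir / "qc_report.tsv", lambda p: _write_tsv(qc, p))
    emit(outdir / "embedding.tsv", lambda p: _write_tsv(
        pd.DataFrame(emb, index=filtered.cell_ids, columns=["x", "y"]), p))
    emit(outdir / "clusters.tsv", lambda p: _write_tsv(
        pd.DataFrame({"coarse": coarse.labels, "fine": fine.labels,
                      "cell_type": [annot[c] for c in coarse.labels]},
                     index=filtered.cell_ids), p))
    emit(outdir / "marker_dotplot.tsv",
         lambda p: _write_tsv(dots, p, index=False))
    stages.append("cells")

    # --- stage: trajectory ------------------------------------------------
    dyn_input = filtered.subset_genes(hvg)
    traj = traj_mod.infer_pseudotime(dyn_input, seed=cfg.seed)
    # orient with planted "increasing" target genes (base-low markers)
    markers = [g for g, lab in truth.dynamic_gene_labels.items()
               if lab == "increasing"][:5]
    traj = traj_mod.orient_trajectory(traj, filtered, markers)
    dyn = traj_mod.test_dynamic_genes(filtered, traj, min_mean=cfg.min_mean,
                                      df_spline=cfg.df_spline)
    n_sig = int((dyn["q"] < cfg.q_dynamic).sum())
    log.info("stage trajectory: %d genes tested, %d dynamic at q<%g",
             int(dyn["tested"].sum()), n_sig, cfg.q_dynamic)
    if n_sig >= cfg.k_gene_clusters:
        traj_mod.cluster_gene_profiles(dyn, filtered, traj,
                                       k=cfg.k_gene_clusters,
                                       q_threshold=cfg.q_dynamic)
    emit(outdir / "pseudotime.tsv", lambda p: _write_tsv(
        pd.DataFrame({"pseudotime": traj.pseudotime, "state": traj.state},
                     index=filtered.cell_ids), p))
    emit(outdir / "dynamic_genes.tsv", lambda p: _write_tsv(dyn, p))
    stages.append("trajectory")

    # --- stage: coexpr ----------------------------------------------------
    pb = coexpr_mod.make_pseudobulk(filtered, fine, traj)
    co = coexpr_mod.build_coexpression(pb, top_frac=cfg.top_frac,
                                       beta=cfg.coexpr_beta,
                                       edge_quantile=cfg.edge_quantile)
    log.info("stage coexpr: %d samples, beta=%g, %d edges",
             pb.expr.shape[0], co.beta, len(co.edges))
    emit(outdir / "pseudobulk.tsv", lambda p: _write_tsv(pb.expr, p))
    emit(outdir / "coexpr_edges.tsv", lambda p: _write_tsv(
        pd.DataFrame(
            [(a, b, float(co.adjacency.loc[a, b]), float(co.tom.loc[a, b]))
             for a, b in sorted(tuple(sorted(e)) for e in co.edges)],
            columns=["geneA", "geneB", "adjacency", "TOM"]), p, index=False))
    emit(outdir / "modules.tsv", lambda p: _write_tsv(
        co.modules.rename("module"), p))
    stages.append("coexpr")

    # --- stage: grn -------------------------------------------------------
    tf_expr = pd.DataFrame(
        filtered.subset_genes(truth_grn.tf_ids).normalized(log=False).T,
        index=truth_grn.tf_ids, columns=filtered.cell_ids)
    ode = grn_mod.fit_ode_grn(tf_expr, traj.pseudotime, z=cfg.z,
                              n_runs=cfg.n_runs, iters=cfg.ode_iters,
                              seed=cfg.seed, keep_runs=False)
    cons_loose = grn_mod.consensus_network(ode, co, cfg.cutoff_loose)
    cons_strict = grn_mod.consensus_network(ode, co, cfg.cutoff_strict)
    log.info("stage grn: consensus edges %d (cutoff %g) / %d (cutoff %g)",
             len(cons_loose.edges), cfg.cutoff_loose,
             len(cons_strict.edges), cfg.cutoff_strict)
    emit(outdir / "ode_network.tsv", lambda p: _write_tsv(
        ode.A.rename_axis("target"), p))
    emit(outdir / "consensus.tsv",
         lambda p: io_mod.export_network(cons_loose, p, fmt="tsv"))
    emit(outdir / "consensus.sif",
         lambda p: io_mod.export_network(cons_loose, p, fmt="sif"))
    stages.append("grn")

    # --- stage: regulome --------------------------------------------------
    ann = tracks["annotation"]
    groups = {g: "all" for g in ann.genes["gene_id"]}
    meta = regulome_mod.metagene_profile(tracks["coverage"], ann, groups,
                                         flank=cfg.flank,
                                         bin_size=cfg.bin_size)
    hits = regulome_mod.scan_motifs(tracks["motif"], tracks["promoter_seqs"])
    prom_coords = ann.promoters
    fp = regulome_mod.aggregate_footprint(tracks["coverage"], hits,
                                          prom_coords,
                                          tracks["motif"].width, w=100)
    regnet = regulome_mod.build_regulatory_network(
        ann, tracks["tf_peaks"], tracks["mhs"], tracks["dacrs"],
        tracks["loops"], consensus=cons_strict,
        promoter_halfwidth=cfg.promoter_halfwidth, max_chain=cfg.max_chain)
    log.info("stage regulome: %d motif hits, %d network edges",
             len(hits), len(regnet.edges))
    emit(outdir / "metagene.tsv", lambda p: _write_tsv(meta.profiles, p))
    emit(outdir / "motif_hits.tsv", lambda p: _write_tsv(hits, p, index=False))
    emit(outdir / "footprint.tsv", lambda p: _write_tsv(
        pd.Series(fp.profile, name="coverage").rename_axis("position"), p))
    emit(outdir / "regnet.tsv",
         lambda p: io_mod.export_network(regnet, p, fmt="tsv"))
    emit(outdir / "regnet.sif",
         lambda p: io_mod.export_network(regnet, p, fmt="sif"))
    stages.append("regulome")

    # --- manifest ---------------------------------------------------------
    files = sorted(str(p.relative_to(outdir)) for p in outdir.rglob("*")
                   if p.is_file() and p.name != "manifest.json")
    manifest = {
        "version": __version__,
        "stages": stages,
        "seed": cfg.seed,
        "config": dataclasses.asdict(cfg),
        "digests": {f: _sha256(outdir / f) for f in files},
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
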