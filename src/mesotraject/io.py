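"""Readers and writers for the pipeline's standard file formats.

Count matrices use the 10x-style MTX triplet (``matrix.mtx`` genes x
cells, ``features.tsv`` with a mitochondrial flag column, ``barcodes.tsv``)
via :mod:`scipy.io`.  Genomic tables are BED / bedGraph / BEDPE / GFF3
(GFF3 1-based closed input is converted to internal 0-based half-open),
sequences are FASTA via Biopython, motifs are MEME minimal text read back
through :mod:`Bio.motifs`.  Every writer's output is re-readable by the
matching reader.
"""

from __future__ import annotations

import urllib.parse
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .types import (ConsensusNetwork, CountMatrix, FormatError,
                    GenomeAnnotation, IntervalSet, LoopSet, ParameterError,
                    Pwm, RegNetEdge, RegulatoryNetwork)


# ---------------------------------------------------------------------------
# count matrices (10x-style triplet)
# ---------------------------------------------------------------------------

def write_counts(m: CountMatrix, outdir: str | Path) -> Path:
    """Write matrix.mtx (genes x cells) + features.tsv + barcodes.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(outdir / "matrix.mtx"),
                 sparse.coo_matrix(m.counts.T), field="integer")
    feats = pd.DataFrame({"gene_id": m.gene_ids, "gene_name": m.gene_ids,
                          "mito": np.where(m.mito_mask, "MT", "nuclear")})
    feats.to_csv(outdir / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(m.cell_ids).to_csv(outdir / "barcodes.tsv", sep="\t",
                                 header=False, index=False)
    return outdir


def read_counts(path: str | Path) -> CountMatrix:
    """Read a 10x-style MTX triplet directory into a CountMatrix.

    The MTX holds genes as rows (10x convention) and is transposed to
    cells x genes.  Mitochondrial flags come from the third features
    column when present ("MT"), else from an "MT" gene-name prefix.
    """
    path = Path(path)
    for fname in ("matrix.mtx", "features.tsv", "barcodes.tsv"):
        if not (path / fname).exists():
            raise FormatError(f"missing {fname} in {path}")
    mat = spio.mmread(str(path / "matrix.mtx")).tocoo()
    feats = pd.read_csv(path / "features.tsv", sep="\t", header=None,
                        dtype=str)
    barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None,
                           dtype=str)[0].tolist()
    if mat.shape[0] != len(feats):
        raise FormatError(
            f"matrix.mtx header says {mat.shape[0]} genes but features.tsv "
            f"has {len(feats)} lines")
    if mat.shape[1] != len(barcodes):
        raise FormatError(
            f"matrix.mtx header says {mat.shape[1]} cells but barcodes.tsv "
            f"has {len(barcodes)} lines")
    gene_ids = feats[0].tolist()
    if feats.shape[1] >= 3:
        mito = (feats[2] == "MT").to_numpy()
    else:
        mito = np.array([g.startswith("MT") for g in gene_ids])
    counts = np.asarray(mat.T.todense()).astype(np.int64)
    return CountMatrix(counts=counts, cell_ids=barcodes, gene_ids=gene_ids,
                       mito_mask=mito)


# ---------------------------------------------------------------------------
# genomic tables
# ---------------------------------------------------------------------------

_BED_COLS = ["chrom", "start", "end", "name", "score"]


def write_bed(ivs: IntervalSet, path: str | Path) -> None:
    ivs.intervals[_BED_COLS].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path, kind: str = "") -> IntervalSet:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :5]
    df.columns = _BED_COLS[:df.shape[1]]
    if "name" not in df:
        df["name"] = [f"iv{i}" for i in range(len(df))]
    if "score" not in df:
        df["score"] = 0
    return IntervalSet(intervals=df, kind=kind)


def write_bedpe(loops: LoopSet, path: str | Path) -> None:
    loops.loops.to_csv(path, sep="\t", header=False, index=False)


def read_bedpe(path: str | Path) -> LoopSet:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :7]
    cols = ["chromA", "startA", "endA", "chromB", "startB", "endB", "name"]
    df.columns = cols[:df.shape[1]]
    if "name" not in df:
        df["name"] = [f"loop{i:03d}" for i in range(len(df))]
    return LoopSet(loops=df)


def write_bedgraph(cov: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(cov):
            starts, ends, values = cov[chrom]
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{int(s)}\t{int(e)}\t{v:.6g}\n")


def read_bedgraph(path: str | Path) -> dict:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "value"])
    out = {}
    for chrom, sub in df.groupby("chrom", sort=True):
        sub = sub.sort_values("start")
        out[str(chrom)] = (sub["start"].to_numpy(), sub["end"].to_numpy(),
                           sub["value"].to_numpy(dtype=float))
    return out


def write_gff3(ann: GenomeAnnotation, path: str | Path) -> None:
    """Genes as GFF3 records (1-based closed coordinates on write)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, size in sorted(ann.chrom_sizes.items()):
            fh.write(f"##sequence-region {chrom} 1 {size}\n")
        for _, g in ann.genes.iterrows():
            fh.write(f"{g['chrom']}\tmesotraject\tgene\t{g['start'] + 1}\t"
                     f"{g['end']}\t.\t{g['strand']}\t.\t"
                     f"ID={g['gene_id']}\n")


def read_gff3(path: str | Path) -> GenomeAnnotation:
    """Parse gene features; converts to 0-based half-open and derives TSS."""
    chrom_sizes: dict[str, int] = {}
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                _, chrom, _start, end = line.split()
                chrom_sizes[chrom] = int(end)
                continue
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{ln}: expected 9 GFF3 columns")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            if ftype != "gene":
                continue
            attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            gid = attr.get("ID", f"gene{ln}")
            start0, end0 = int(start) - 1, int(end)
            tss = start0 if strand == "+" else end0 - 1
            rows.append((gid, chrom, start0, end0, strand, tss))
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end",
                                        "strand", "tss"])
    return GenomeAnnotation(genes=genes, chrom_sizes=chrom_sizes)


# ---------------------------------------------------------------------------
# sequences and motifs
# ---------------------------------------------------------------------------

def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in seqs.items()]
    seqio_write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_meme(motifs: list[Pwm], path: str | Path) -> None:
    """Emit MEME minimal motif format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = motifs[0].background if motifs else np.full(4, 0.25)
        fh.write("Background letter frequencies\n")
        fh.write(f"A {bg[0]:.5f} C {bg[1]:.5f} G {bg[2]:.5f} T {bg[3]:.5f}\n\n")
        for m in motifs:
            fh.write(f"MOTIF {m.name}\n")
            # large nsites so parsers recovering counts keep full precision
            fh.write(f"letter-probability matrix: alength= 4 w= {m.width} "
                     f"nsites= 1000000 E= 0\n")
            for row in m.matrix:
                fh.write(" ".join(f"{p:.6f}" for p in row) + "\n")
            fh.write("\n")


def read_meme(path: str | Path) -> list[Pwm]:
    from Bio import motifs as bio_motifs
    with open(path) as fh:
        records = bio_motifs.parse(fh, "minimal")
    out = []
    for rec in records:
        mat = np.column_stack([np.asarray(rec.pwm[nt], dtype=float)
                               for nt in "ACGT"])
        bg = np.array([rec.background[nt] for nt in "ACGT"], dtype=float)
        out.append(Pwm(matrix=mat / mat.sum(axis=1, keepdims=True),
                       background=bg, name=rec.name))
    return out


# ---------------------------------------------------------------------------
# network export
# ---------------------------------------------------------------------------

def _escape(s: str) -> str:
    return urllib.parse.quote(s, safe="")


def _unescape(s: str) -> str:
    return urllib.parse.unquote(s)


def export_network(net: ConsensusNetwork | RegulatoryNetwork,
                   path: str | Path, fmt: str = "tsv",
                   allow_empty: bool = True) -> None:
    """Write a network as TSV (with header) or Cytoscape-loadable SIF.

    SIF rows are ``source<TAB>relation<TAB>target``; the relation encodes
    the edge type.  Node ids are percent-encoded so whitespace and special
    characters round-trip.
    """
    if isinstance(net, ConsensusNetwork):
        rows = [(a, b, "consensus", w) for a, b, w in net.edges]
    else:
        rows = [(e.source, e.target, e.kind, "") for e in net.edges]
    if not rows and not allow_empty:
        raise ParameterError("refusing to export an empty network")
    if fmt == "tsv":
        df = pd.DataFrame(rows, columns=["source", "target", "kind", "weight"])
        df["source"] = df["source"].map(_escape)
        df["target"] = df["target"].map(_escape)
        df.to_csv(path, sep="\t", index=False)
    elif fmt == "sif":
        with open(path, "w") as fh:
            for a, b, kind, _w in rows:
                fh.write(f"{_escape(a)}\t{kind}\t{_escape(b)}\n")
    else:
        raise ParameterError(f"unknown network format {fmt!r}")


def read_network_sif(path: str | Path) -> list[tuple[str, str, str]]:
    """(source, kind, target) triples from a SIF file."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            a, kind, b = line.rstrip("\n").split("\t")
            out.append((_unescape(a), kind, _unescape(b)))
    return out


def read_network_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"weight": str})
    df["source"] = df["source"].map(_unescape)
    df["target"] = df["target"].map(_unescape)
    return df
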