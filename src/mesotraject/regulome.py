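"""Epigenomic integration: metagene profiles, motifs, footprints, networks.

Operations here consume the standard genomic inputs of the study —
MNase-hypersensitive-site (MHS) peaks, TF ChIP peaks, distal accessible
chromatin regions (dACRs), H3K4me3 HiChIP loops, promoter sequences and
nuclease coverage — and produce TSS-centered metagene profiles, motif
hits/enrichment, aggregate footprints, and the typed regulatory network
(predicted / chip_direct / PPI / PDI edges, each with provenance).

Coordinate conventions: intervals are BED-style 0-based half-open;
coverage is a per-chromosome step function (bedGraph semantics); the TSS
of a minus-strand gene is its interval end - 1.
"""

from __future__ import annotations

import warnings
from collections import deque

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .types import (ConsensusNetwork, FootprintProfile, GenomeAnnotation,
                    IntervalSet, LoopSet, MetaProfile, ParameterError, Pwm,
                    RegNetEdge, RegulatoryNetwork)

Coverage = dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]


# ---------------------------------------------------------------------------
# interval and coverage utilities
# ---------------------------------------------------------------------------

def intervals_overlapping(ivs: IntervalSet, chrom: str, start: int,
                          end: int) -> pd.DataFrame:
    """Rows of ``ivs`` overlapping [start, end) on ``chrom`` (>= 1 bp)."""
    df = ivs.intervals
    sub = df[df["chrom"] == chrom]
    return sub[(sub["start"] < end) & (sub["end"] > start)]


def _spans_overlap(s1: int, e1: int, s2: int, e2: int) -> bool:
    return s1 < e2 and s2 < e1


def coverage_total(cov: Coverage) -> float:
    return float(sum(((e - s) * v).sum() for s, e, v in cov.values()))


def extract_coverage(cov: Coverage, chrom: str, start: int,
                     end: int) -> np.ndarray:
    """Per-base coverage over [start, end); bases outside tracks are 0."""
    out = np.zeros(end - start)
    if chrom not in cov:
        return out
    starts, ends, values = cov[chrom]
    lo = np.searchsorted(ends, start, side="right")
    hi = np.searchsorted(starts, end, side="left")
    for s, e, v in zip(starts[lo:hi], ends[lo:hi], values[lo:hi]):
        a, b = max(s, start), min(e, end)
        if a < b:
            out[a - start:b - start] = v
    return out


# ---------------------------------------------------------------------------
# metagene profiles
# ---------------------------------------------------------------------------

def metagene_profile(cov: Coverage, ann: GenomeAnnotation,
                     groups: dict[str, str], flank: int = 1500,
                     bin_size: int = 100) -> MetaProfile:
    """Mean normalized coverage in bins across TSS +/- flank per gene group.

    Coverage is normalized to counts per million of the track total; each
    gene window [TSS - flank, TSS + flank) is averaged per ``bin_size``
    bin, minus-strand genes are reversed so bins run 5' -> 3', and genes in
    the same group are averaged.  Genes whose window exceeds chromosome
    bounds are skipped.
    """
    if (2 * flank) % bin_size:
        raise ParameterError("2*flank must be a multiple of bin_size")
    n_bins = (2 * flank) // bin_size
    total = coverage_total(cov)
    norm = 1e6 / total if total > 0 else 0.0
    sums: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    skipped: list[str] = []
    gtab = ann.genes.set_index("gene_id")
    for gid, grp in groups.items():
        row = gtab.loc[gid]
        chrom, tss, strand = str(row["chrom"]), int(row["tss"]), str(row["strand"])
        size = ann.chrom_sizes.get(chrom, np.inf)
        if tss - flank < 0 or tss + flank > size:
            skipped.append(gid)
            continue
        base = extract_coverage(cov, chrom, tss - flank, tss + flank) * norm
        binned = base.reshape(n_bins, bin_size).mean(axis=1)
        if strand == "-":
            binned = binned[::-1]
        sums[grp] = sums.get(grp, np.zeros(n_bins)) + binned
        counts[grp] = counts.get(grp, 0) + 1
    if skipped:
        warnings.warn(f"{len(skipped)} genes skipped (window out of bounds)")
    names = sorted(sums)
    prof = pd.DataFrame([sums[g] / counts[g] for g in names], index=names,
                        columns=[f"bin{i + 1:02d}" for i in range(n_bins)])
    return MetaProfile(profiles=prof, flank=flank, bin_size=bin_size,
                       n_genes=pd.Series({g: counts[g] for g in names}))


# ---------------------------------------------------------------------------
# motif scanning and enrichment
# ---------------------------------------------------------------------------

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3}


def _encode(seq: str) -> np.ndarray:
    return np.array([_ENC.get(ch, -1) for ch in seq.upper()], dtype=int)


def pwm_log_odds(pwm: Pwm, pseudo: float = 1e-9) -> np.ndarray:
    """width x 4 log2-odds matrix versus the PWM background."""
    return np.log2((pwm.matrix + pseudo) / pwm.background[None, :])


def max_score(pwm: Pwm) -> float:
    return float(pwm_log_odds(pwm).max(axis=1).sum())


def _scan_strand(codes: np.ndarray, lods: np.ndarray) -> np.ndarray:
    """Score every offset of one strand; non-ACGT positions score 0."""
    w = lods.shape[0]
    n = len(codes) - w + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    for k in range(w):
        col = codes[k:k + n]
        contrib = np.where(col >= 0, lods[k][np.clip(col, 0, 3)], 0.0)
        scores += contrib
    return scores


def scan_motifs(pwm: Pwm, seqs: dict[str, str],
                threshold: float | None = None) -> pd.DataFrame:
    """Log-odds scan of both strands of every sequence.

    Returns hits (seq, offset, strand, score) with score >= threshold,
    sorted by (seq, offset, strand).  Offsets index the forward strand;
    a minus-strand hit at offset o covers forward bases [o, o + width).
    The default threshold is 80% of the maximum achievable score.
    N (or any non-ACGT) positions contribute 0, i.e. background odds.
    Sequences shorter than the motif are skipped.
    """
    if threshold is None:
        threshold = 0.8 * max_score(pwm)
    lods = pwm_log_odds(pwm)
    lods_rc = pwm_log_odds(pwm.reverse_complement())
    rows = []
    for sid in sorted(seqs):
        codes = _encode(seqs[sid])
        if len(codes) < pwm.width:
            continue
        for strand, mat in (("+", lods), ("-", lods_rc)):
            scores = _scan_strand(codes, mat)
            for off in np.flatnonzero(scores >= threshold):
                rows.append((sid, int(off), strand, float(scores[off])))
    hits = pd.DataFrame(rows, columns=["seq", "offset", "strand", "score"])
    return hits.sort_values(["seq", "offset", "strand"],
                            kind="mergesort").reset_index(drop=True)


def motif_enrichment(motifs: list[Pwm], fg_seqs: dict[str, str],
                     bg_seqs: dict[str, str],
                     threshold: float | None = None) -> pd.DataFrame:
    """Fisher-exact motif enrichment of foreground vs background sequences.

    Per motif, sequences are classified by whether they carry >= 1 hit and
    the 2x2 (with-hit / without, foreground / background) table is tested
    one-sided for enrichment; p-values are BH-adjusted across motifs.
    Background sequences also present in the foreground are removed with a
    warning.
    """
    if not fg_seqs or not bg_seqs:
        raise ParameterError("both sequence sets must be nonempty")
    overlap = set(fg_seqs) & set(bg_seqs)
    if overlap:
        warnings.warn(f"{len(overlap)} background sequences overlap the "
                      "foreground; de-duplicated")
        bg_seqs = {k: v for k, v in bg_seqs.items() if k not in overlap}
        if not bg_seqs:
            raise ParameterError("background empty after de-duplication")
    rows = []
    for pwm in motifs:
        fg_hit = len(set(scan_motifs(pwm, fg_seqs, threshold)["seq"]))
        bg_hit = len(set(scan_motifs(pwm, bg_seqs, threshold)["seq"]))
        table = [[fg_hit, len(fg_seqs) - fg_hit],
                 [bg_hit, len(bg_seqs) - bg_hit]]
        odds, p = fisher_exact(table, alternative="greater")
        rows.append((pwm.name, fg_hit, len(fg_seqs), bg_hit, len(bg_seqs),
                     float(odds), float(p)))
    out = pd.DataFrame(rows, columns=["motif", "fg_with_hit", "fg_total",
                                      "bg_with_hit", "bg_total",
                                      "odds_ratio", "p"])
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out.sort_values(["p", "motif"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# footprints
# ---------------------------------------------------------------------------

def aggregate_footprint(cov: Coverage, hits: pd.DataFrame,
                        seq_coords: dict[str, tuple[str, int, int]],
                        motif_width: int, w: int = 100) -> FootprintProfile:
    """Mean per-base coverage around aligned motif hits.

    ``seq_coords`` maps sequence ids (as used in ``hits``) to their genomic
    span (chrom, start, end); sequences are stored in genomic forward
    orientation, so a hit at offset o occupies genomic bases
    [start + o, start + o + motif_width).  Coverage over
    [span - w, span + w) is extracted per hit, minus-strand hits are
    reversed, and all sites are averaged.
    """
    profiles = []
    for _, h in hits.iterrows():
        if h["seq"] not in seq_coords:
            continue
        chrom, sstart, _send = seq_coords[h["seq"]]
        gstart = sstart + int(h["offset"])
        prof = extract_coverage(cov, chrom, gstart - w,
                                gstart + motif_width + w)
        if h["strand"] == "-":
            prof = prof[::-1]
        profiles.append(prof)
    if not profiles:
        raise ParameterError("no hits mappable to genomic coordinates")
    return FootprintProfile(profile=np.mean(profiles, axis=0), w=w,
                            motif_width=motif_width, n_sites=len(profiles))


# ---------------------------------------------------------------------------
# regulatory network
# ---------------------------------------------------------------------------

def _promoter_window(gtab: pd.DataFrame, gid: str,
                     halfwidth: int) -> tuple[str, int, int]:
    row = gtab.loc[gid]
    tss = int(row["tss"])
    return str(row["chrom"]), max(0, tss - halfwidth), tss + halfwidth


def build_regulatory_network(ann: GenomeAnnotation,
                             tf_peaks: dict[str, IntervalSet],
                             mhs: IntervalSet | None,
                             dacrs: IntervalSet,
                             loops: LoopSet,
                             consensus: ConsensusNetwork | None = None,
                             promoter_halfwidth: int = 1000,
                             max_chain: int = 2) -> RegulatoryNetwork:
    """Assemble the typed multi-evidence regulatory network.

    Edge rules:

    * ``chip_direct`` TF -> gene: a ChIP peak of the TF overlaps the gene's
      promoter window [TSS - halfwidth, TSS + halfwidth).
    * ``PPI`` geneA <-> geneB: both promoters map onto loop anchors joined
      by a chain of at most ``max_chain`` loops whose anchors overlap
      ("consecutive" loops).
    * ``PDI`` TF -> gene: a TF peak overlaps a dACR lying on a loop anchor
      whose partner anchor overlaps the gene's promoter window.
    * ``predicted``: imported from the expression consensus network.

    Every edge records the peak/dACR/loop ids that justify it.
    """
    gtab = ann.genes.set_index("gene_id")
    gene_ids = list(gtab.index)
    windows = {g: _promoter_window(gtab, g, promoter_halfwidth)
               for g in gene_ids}
    edges: list[RegNetEdge] = []

    # --- chip_direct ------------------------------------------------------
    for tf, peaks in tf_peaks.items():
        for g, (chrom, ws, we) in windows.items():
            hit = intervals_overlapping(peaks, chrom, ws, we)
            for _, pk in hit.iterrows():
                edges.append(RegNetEdge(tf, g, "chip_direct",
                                        {"peak": pk["name"],
                                         "peak_span": (pk["chrom"],
                                                       int(pk["start"]),
                                                       int(pk["end"]))}))

    # --- loop plumbing ----------------------------------------------------
    L = loops.loops
    anchors = []   # (loop_idx, side, chrom, start, end)
    for li, row in L.iterrows():
        anchors.append((li, "A", row["chromA"], int(row["startA"]), int(row["endA"])))
        anchors.append((li, "B", row["chromB"], int(row["startB"]), int(row["endB"])))

    def other_side(side: str) -> str:
        return "B" if side == "A" else "A"

    def anchor_span(li: int, side: str) -> tuple[str, int, int]:
        row = L.loc[li]
        return (str(row[f"chrom{side}"]), int(row[f"start{side}"]),
                int(row[f"end{side}"]))

    # gene promoter -> anchors it overlaps
    prom_anchors: dict[str, list[tuple[int, str]]] = {g: [] for g in gene_ids}
    for li, side, chrom, s, e in anchors:
        for g, (gc, ws, we) in windows.items():
            if gc == chrom and _spans_overlap(s, e, ws, we):
                prom_anchors[g].append((li, side))

    # anchor-overlap adjacency between anchors of different loops
    anchor_keys = [(li, side) for li, side, *_ in anchors]
    anchor_adj: dict[tuple, set[tuple]] = {k: set() for k in anchor_keys}
    for i in range(len(anchors)):
        li, si, c1, s1, e1 = anchors[i]
        for j in range(i + 1, len(anchors)):
            lj, sj, c2, s2, e2 = anchors[j]
            if li != lj and c1 == c2 and _spans_overlap(s1, e1, s2, e2):
                anchor_adj[(li, si)].add((lj, sj))
                anchor_adj[(lj, sj)].add((li, si))

    anchors_of_gene: dict[str, set[tuple]] = {
        g: set(pa) for g, pa in prom_anchors.items()}

    # --- PPI: walk chains of <= max_chain consecutive loops ---------------
    # From an anchor one may (a) traverse its own loop to the partner
    # anchor, consuming one loop of the chain budget, or (b) hop to an
    # overlapping anchor of another loop for free ("consecutive" loops
    # share a spatial locus).  A pair (geneA, geneB) is connected when a
    # walk from an anchor on A's promoter reaches an anchor on B's
    # promoter having traversed 1..max_chain distinct loops.
    best_chain: dict[frozenset, list] = {}
    for ga in gene_ids:
        for start in sorted(anchors_of_gene[ga]):
            # state: (anchor, frozenset of traversed loops, ordered chain)
            queue = deque([(start, frozenset(), [])])
            visited = {(start, frozenset())}
            while queue:
                (cur, used, chain) = queue.popleft()
                li, side = cur
                if chain:
                    for gb in gene_ids:
                        if gb != ga and cur in anchors_of_gene[gb]:
                            pair = frozenset((ga, gb))
                            if pair not in best_chain or \
                                    len(chain) < len(best_chain[pair]):
                                best_chain[pair] = list(chain)
                if len(used) < max_chain and li not in used:
                    nxt = ((li, other_side(side)), used | {li}, chain + [li])
                    if (nxt[0], nxt[1]) not in visited:
                        visited.add((nxt[0], nxt[1]))
                        queue.append(nxt)
                for hop in sorted(anchor_adj[cur]):
                    if hop[0] not in used and (hop, used) not in visited:
                        visited.add((hop, used))
                        queue.append((hop, used, chain))
    for pair, chain in sorted(best_chain.items(), key=lambda kv: sorted(kv[0])):
        a, b = sorted(pair)
        edges.append(RegNetEdge(a, b, "PPI",
                                {"loops": [str(L.loc[c, "name"])
                                           for c in chain]}))

    # --- PDI: TF peak on a dACR that loops to a promoter -------------------
    for li, side, chrom, s, e in anchors:
        dhits = intervals_overlapping(dacrs, chrom, s, e)
        if dhits.empty:
            continue
        oc, os_, oe = anchor_span(li, other_side(side))
        target_genes = [g for g, (gc, ws, we) in windows.items()
                        if gc == oc and _spans_overlap(os_, oe, ws, we)]
        if not target_genes:
            continue
        for _, dacr in dhits.iterrows():
            for tf, peaks in tf_peaks.items():
                phits = intervals_overlapping(peaks, str(dacr["chrom"]),
                                              int(dacr["start"]),
                                              int(dacr["end"]))
                for _, pk in phits.iterrows():
                    for g in target_genes:
                        edges.append(RegNetEdge(tf, g, "PDI",
                                                {"peak": pk["name"],
                                                 "dacr": dacr["name"],
                                                 "loop": str(L.loc[li, "name"])}))

    # de-duplicate PDI edges produced via both anchors of a loop
    uniq: dict[tuple, RegNetEdge] = {}
    for e in edges:
        key = (e.source, e.target, e.kind, repr(sorted(e.provenance.items())))
        uniq.setdefault(key, e)
    edges = list(uniq.values())

    # --- predicted --------------------------------------------------------
    if consensus is not None:
        for reg, tgt, w in consensus.edges:
            edges.append(RegNetEdge(reg, tgt, "predicted",
                                    {"ode_weight": w,
                                     "cutoff": consensus.cutoff}))
    return RegulatoryNetwork(edges=edges)


def validate_provenance(net: RegulatoryNetwork, ann: GenomeAnnotation,
                        tf_peaks: dict[str, IntervalSet], dacrs: IntervalSet,
                        loops: LoopSet, promoter_halfwidth: int = 1000) -> bool:
    """Re-check that every edge's recorded evidence satisfies its rule."""
    gtab = ann.genes.set_index("gene_id")
    L = loops.loops.set_index("name")
    peak_index = {tf: {r["name"]: (r["chrom"], int(r["start"]), int(r["end"]))
                       for _, r in p.intervals.iterrows()}
                  for tf, p in tf_peaks.items()}
    dacr_index = {r["name"]: (r["chrom"], int(r["start"]), int(r["end"]))
                  for _, r in dacrs.intervals.iterrows()}
    for e in net.edges:
        if e.kind == "chip_direct":
            chrom, s, p_end = peak_index[e.source][e.provenance["peak"]]
            wc, ws, we = _promoter_window(gtab, e.target, promoter_halfwidth)
            if not (chrom == wc and _spans_overlap(s, p_end, ws, we)):
                return False
        elif e.kind == "PPI":
            chain = e.provenance["loops"]
            for name in chain:
                if name not in L.index:
                    return False
            first, last = L.loc[chain[0]], L.loc[chain[-1]]
            wa = _promoter_window(gtab, e.source, promoter_halfwidth)
            wb = _promoter_window(gtab, e.target, promoter_halfwidth)

            def touches(loop_row, win):
                return any(loop_row[f"chrom{s}"] == win[0]
                           and _spans_overlap(int(loop_row[f"start{s}"]),
                                              int(loop_row[f"end{s}"]),
                                              win[1], win[2])
                           for s in ("A", "B"))

            if not ((touches(first, wa) and touches(last, wb))
                    or (touches(first, wb) and touches(last, wa))):
                return False
        elif e.kind == "PDI":
            if e.provenance["dacr"] not in dacr_index:
                return False
            dc, ds, de = dacr_index[e.provenance["dacr"]]
            pc, ps, pe = peak_index[e.source][e.provenance["peak"]]
            if not (dc == pc and _spans_overlap(ds, de, ps, pe)):
                return False
            loop = L.loc[e.provenance["loop"]]
            win = _promoter_window(gtab, e.target, promoter_halfwidth)
            dacr_on_anchor = prom_on_anchor = False
            for s in ("A", "B"):
                lc = loop[f"chrom{s}"]
                ls, le = int(loop[f"start{s}"]), int(loop[f"end{s}"])
                if lc == dc and _spans_overlap(ls, le, ds, de):
                    dacr_on_anchor = True
                elif lc == win[0] and _spans_overlap(ls, le, win[1], win[2]):
                    prom_on_anchor = True
            if not (dacr_on_anchor and prom_on_anchor):
                return False
        elif e.kind == "predicted":
            if "ode_weight" not in e.provenance:
                return False
        else:
            return False
    return True


def classify_targets_by_cofactor(targets: list[str],
                                 peaks_primary: IntervalSet,
                                 peaks_cofactor: IntervalSet,
                                 ann: GenomeAnnotation,
                                 halfwidth: int = 1000
                                 ) -> tuple[list[str], list[str]]:
    """Split target genes by cofactor co-binding at their promoters.

    Subset 1 holds the targets whose promoter window (TSS +/- halfwidth)
    overlaps at least one cofactor peak; subset 2 the rest; the union is
    the input list.  (In the study this separates HSF1 targets co-bound by
    COL8 within 1 kb from those bound by HSF1 alone.)
    """
    gtab = ann.genes.set_index("gene_id")
    with_cof, without = [], []
    for g in targets:
        chrom, ws, we = _promoter_window(gtab, g, halfwidth)
        hit = intervals_overlapping(peaks_cofactor, chrom, ws, we)
        (with_cof if len(hit) else without).append(g)
    return with_cof, without
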