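"""Per-sample TF->gene regulatory networks and personalized-PageRank TF ranking.

Motif scanning uses log-odds scores with exact p-values from a dynamic
program over the discretized background score distribution. Networks carry
node weights e^z (z = expression z-score) and edge weights combining TF
expression with pooled peak intensity. The PageRank runs on the
edge-reversed graph seeded by the normalized node weights; scores are
reported per the original orientation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from epipair.differential import FeatureAnnotation, promoter_window
from epipair.io_cli.formats import GenomicInterval, Peak

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_SCORE_SCALE = 100  # log-odds discretization: integer units of 1/100 bit


@dataclass(frozen=True)
class MotifHit:
    position: int
    strand: str
    score: float
    p: float


@dataclass
class RegulatoryNetwork:
    """Directed weighted TF->gene graph with e^z node weights."""

    graph: nx.DiGraph
    tf_ids: set[str]

    @property
    def nodes(self):
        return self.graph.nodes

    def node_weight(self, node: str) -> float:
        return self.graph.nodes[node]["weight"]

    def edges_frame(self) -> pd.DataFrame:
        rows = [
            (u, v, d["weight"], d.get("provenance", ""))
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["tf", "gene", "weight", "provenance"])


@dataclass
class PPRResult:
    sample_id: str
    scores: dict[str, float]
    damping: float
    iterations: int


def _int_score_matrix(pwm: np.ndarray, background: np.ndarray) -> np.ndarray:
    probs = np.clip(np.asarray(pwm, float), 1e-4, 1.0)
    bg = np.clip(np.asarray(background, float), 1e-4, 1.0)
    logodds = np.log2(probs / bg[None, :])
    return np.round(logodds * _SCORE_SCALE).astype(int)


def _score_pvalue_table(int_scores: np.ndarray, background: np.ndarray):
    """Exact distribution of the integer motif score under the background.

    Dynamic program convolving one PWM position at a time; returns
    (offset, tail) where tail[t - offset] = P(score >= t).
    """
    lo = int(int_scores.min(axis=1).sum())
    hi = int(int_scores.max(axis=1).sum())
    cur = {0: 1.0}  # point mass at score 0, convolved position by position
    for row in int_scores:
        nxt: dict[int, float] = {}
        for s, pr in cur.items():
            for b in range(4):
                key = s + int(row[b])
                nxt[key] = nxt.get(key, 0.0) + pr * background[b]
        cur = nxt
    support = np.arange(lo, hi + 1)
    pmf = np.zeros_like(support, dtype=float)
    for s, pr in cur.items():
        pmf[s - lo] = pr
    tail = np.cumsum(pmf[::-1])[::-1]
    return lo, tail


def scan_motif(
    pwm: np.ndarray,
    sequence: str,
    p_threshold: float = 1e-4,
    background: np.ndarray | None = None,
) -> list[MotifHit]:
    """Scan both strands of a sequence for PWM hits with p <= threshold.

    Windows containing N are skipped. The p-value of a hit is the exact
    upper-tail probability of its discretized log-odds score under the
    background base composition.
    """
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    pwm = np.asarray(pwm, float)
    w = pwm.shape[0]
    if w > len(sequence) or w == 0:
        return []
    ints_fwd = _int_score_matrix(pwm, bg)
    # reverse strand: scan with the reverse-complemented matrix
    ints_rev = ints_fwd[::-1, ::-1]
    lo, tail = _score_pvalue_table(ints_fwd, bg)
    hi_idx = len(tail) - 1

    seq = sequence.upper()
    codes = np.array([_BASE_INDEX.get(b, -1) for b in seq], dtype=int)
    hits: list[MotifHit] = []
    n_pos = len(seq) - w + 1
    window_ok = np.ones(n_pos, dtype=bool)
    bad = np.flatnonzero(codes < 0)
    for b in bad:
        window_ok[max(b - w + 1, 0) : b + 1] = False

    offsets = np.arange(w)
    for strand, ints in (("+", ints_fwd), ("-", ints_rev)):
        for pos in np.flatnonzero(window_ok):
            window = codes[pos : pos + w]
            s = int(ints[offsets, window].sum())
            idx = min(max(s - lo, 0), hi_idx)
            p = float(tail[idx]) if s >= lo else 1.0
            if p <= p_threshold:
                hits.append(MotifHit(int(pos), strand, s / _SCORE_SCALE, p))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def active_promoters(
    h3k27ac_peaks: list[Peak],
    genes: pd.DataFrame,
    up: int = 4000,
    down: int = 1000,
) -> set[str]:
    """Genes whose strand-aware promoter window overlaps any H3K27ac peak."""
    active = set()
    by_chrom: dict[str, list[Peak]] = {}
    for pk in h3k27ac_peaks:
        by_chrom.setdefault(pk.interval.chrom, []).append(pk)
    for _, row in genes.iterrows():
        ws, we = promoter_window(int(row["tss"]), row["strand"], up, down)
        for pk in by_chrom.get(row["chrom"], []):
            if pk.interval.start < we and ws < pk.interval.end:
                active.add(row["gene_id"])
                break
    return active


def summit_window(
    peak: Peak, width: int = 150, chrom_length: int | None = None
) -> GenomicInterval | None:
    """Window of ``width`` bp centered on the peak summit, clipped; None if empty."""
    start = max(peak.summit - width // 2, 0)
    end = peak.summit + width // 2
    if chrom_length is not None:
        end = min(end, chrom_length)
    if end <= start:
        return None
    return GenomicInterval(peak.interval.chrom, start, end)


def build_network(
    active_genes: set[str],
    annotations: list[FeatureAnnotation],
    motif_hits_per_peak: dict[str, set[str]],
    expression_z: dict[str, float],
    peak_intensity: dict[str, float],
    tf_ids: set[str] | None = None,
) -> RegulatoryNetwork:
    """Assemble the directed TF->gene network for one sample.

    An edge tf->gene exists when the TF has a motif hit inside a peak whose
    annotation links it to the gene (promoter overlap or enhancer link) and
    the gene's promoter is active. Node weight is e^z; edge weight is
    sqrt(e^{z_tf} x I_peak / median intensity); parallel edges collapse to
    the maximum weight. Genes missing from the expression table get z=0.
    """
    ann_by_peak = {a.feature_id: a for a in annotations}
    intensities = np.array([peak_intensity[p] for p in sorted(peak_intensity)], float)
    med = float(np.median(intensities)) if len(intensities) else 1.0
    if med <= 0:
        med = 1.0

    def z_of(g: str) -> float:
        if g not in expression_z:
            warnings.warn(f"no expression for {g}; z set to 0")
            return 0.0
        return float(expression_z[g])

    graph = nx.DiGraph()
    tfs_seen: set[str] = set()
    for gene in sorted(active_genes):
        graph.add_node(gene, weight=float(np.exp(z_of(gene))))
    for peak_id, tfs in sorted(motif_hits_per_peak.items()):
        ann = ann_by_peak.get(peak_id)
        if ann is None:
            continue
        gene = ann.linked_gene
        if gene not in active_genes:
            continue
        intensity = float(peak_intensity.get(peak_id, med))
        for tf in sorted(tfs):
            if tf_ids is not None and tf not in tf_ids:
                continue
            z_tf = z_of(tf)
            weight = float(np.sqrt(np.exp(z_tf) * intensity / med))
            for node in (tf, gene):
                if node not in graph:
                    graph.add_node(node, weight=float(np.exp(z_of(node))))
            prov = f"{ann.cls}:{peak_id}"
            if graph.has_edge(tf, gene):
                if weight > graph[tf][gene]["weight"]:
                    graph[tf][gene].update(weight=weight, provenance=prov)
            else:
                graph.add_edge(tf, gene, weight=weight, provenance=prov)
            tfs_seen.add(tf)
    return RegulatoryNetwork(graph, tfs_seen)


def personalized_pagerank(
    network: RegulatoryNetwork,
    damping: float = 0.85,
    tol: float = 1e-8,
    max_iter: int = 1000,
    sample_id: str = "",
) -> PPRResult:
    """Personalized PageRank on the edge-reversed network.

    The seed vector is the node weights normalized to sum 1; the transition
    matrix is column-normalized over reversed edges using edge weights, and
    dangling mass teleports back to the seed. Scores are reported for the
    nodes of the original graph and sum to 1.
    """
    g = network.graph
    nodes = sorted(g.nodes)
    if not nodes:
        raise ValueError("empty network")
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    weights = np.array([g.nodes[v]["weight"] for v in nodes], float)
    if weights.sum() <= 0:
        raise ValueError("non-positive total node weight")
    seed = weights / weights.sum()

    # reversed edge (gene -> tf) for each original edge (tf -> gene)
    out_weight = np.zeros(n)
    edges = []
    for u, v, d in g.edges(data=True):
        w = float(d["weight"])
        edges.append((index[v], index[u], w))  # reversed: v -> u
        out_weight[index[v]] += w
    src = np.array([e[0] for e in edges], dtype=int) if edges else np.empty(0, int)
    dst = np.array([e[1] for e in edges], dtype=int) if edges else np.empty(0, int)
    wgt = np.array([e[2] for e in edges], float) if edges else np.empty(0)
    norm_w = wgt / out_weight[src] if len(edges) else wgt
    dangling = out_weight == 0

    r = seed.copy()
    for iteration in range(1, max_iter + 1):
        flow = np.zeros(n)
        if len(edges):
            np.add.at(flow, dst, norm_w * r[src])
        dangling_mass = float(r[dangling].sum())
        r_new = (1 - damping) * seed + damping * (flow + dangling_mass * seed)
        if np.abs(r_new - r).sum() < tol:
            r = r_new
            break
        r = r_new
    else:
        raise RuntimeError(f"PageRank did not converge in {max_iter} iterations")
    r = r / r.sum()
    return PPRResult(
        sample_id=sample_id,
        scores={v: float(r[index[v]]) for v in nodes},
        damping=damping,
        iterations=iteration,
    )


def ppr_rank_tfs(
    ppr_per_sample: dict[str, PPRResult],
    tf_expression_differential,
    pairs: list[tuple[str, str, str]],
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank differentially expressed TFs by |mean pairwise delta PPR|.

    ``pairs`` lists (pair_id, case_sample_id, control_sample_id). Returns the
    ranked table and a per-TF z-scored PPR matrix across samples (for
    heatmaps).
    """
    sig_tfs = [r.feature_id for r in tf_expression_differential if r.p_adj < alpha]
    sample_ids = sorted(ppr_per_sample)
    for tf in sig_tfs:
        for sid in sample_ids:
            if tf not in ppr_per_sample[sid].scores:
                raise ValueError(f"TF {tf} missing from PPR of sample {sid}")
    rows = []
    for tf in sig_tfs:
        deltas = [
            ppr_per_sample[case].scores[tf] - ppr_per_sample[ctrl].scores[tf]
            for _, case, ctrl in pairs
        ]
        mean_delta = float(np.mean(deltas)) if deltas else 0.0
        rows.append((tf, mean_delta, abs(mean_delta)))
    ranked = pd.DataFrame(rows, columns=["tf", "mean_delta", "abs_delta"])
    ranked = ranked.sort_values(["abs_delta", "tf"], ascending=[False, True]).reset_index(
        drop=True
    )
    ranked["rank"] = np.arange(1, len(ranked) + 1)

    zmat = pd.DataFrame(
        {sid: [ppr_per_sample[sid].scores.get(tf, np.nan) for tf in sig_tfs] for sid in sample_ids},
        index=sig_tfs,
    )
    mu = zmat.mean(axis=1)
    sd = zmat.std(axis=1).replace(0, np.nan)
    zscores = zmat.sub(mu, axis=0).div(sd, axis=0).fillna(0.0)
    return ranked, zscores
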