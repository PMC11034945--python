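import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from epipair import regnet_pagerank as rp
from epipair.differential import DifferentialResult, FeatureAnnotation
from epipair.io_cli.formats import GenomicInterval, Peak


def revcomp(seq):
    return seq[::-1].translate(str.maketrans("ACGT", "TGCA"))


def consensus_pwm(consensus, p=0.94):
    mat = np.full((len(consensus), 4), (1 - p) / 3)
    for i, b in enumerate(consensus):
        mat[i, "ACGT".index(b)] = p
    return mat


class TestScanMotif:
    def test_consensus_hit_at_origin(self):
        pwm = consensus_pwm("ACGTACGT")
        hits = rp.scan_motif(pwm, "ACGTACGT")
        assert len(hits) >= 1
        best = min(hits, key=lambda h: h.p)
        assert best.position == 0 and best.strand == "+"
        # maximal score: every position matches the consensus
        assert best.score == pytest.approx(8 * np.log2(0.94 / 0.25), abs=0.1)

    def test_reverse_complement_same_score(self):
        cons = "ACGGTCAT"
        pwm = consensus_pwm(cons)
        fwd = rp.scan_motif(pwm, cons)
        rev = rp.scan_motif(pwm, revcomp(cons))
        best_f = min(fwd, key=lambda h: h.p)
        best_r = min(rev, key=lambda h: h.p)
        assert best_r.strand == "-"
        assert best_r.score == pytest.approx(best_f.score, abs=1e-9)
        assert best_r.p == pytest.approx(best_f.p, abs=1e-15)

    def test_exact_pvalue_matches_kmer_enumeration(self):
        """p of the top score equals the background-weighted fraction of >= scoring 4-mers."""
        rng = np.random.default_rng(9)
        pwm = rng.dirichlet(np.ones(4) * 0.3, size=4)
        ints = rp._int_score_matrix(pwm, np.full(4, 0.25))
        hits = rp.scan_motif(pwm, "ACGT", p_threshold=1.0)
        fwd_hit = [h for h in hits if h.strand == "+"][0]
        target = int(round(fwd_hit.score * rp._SCORE_SCALE))
        total = 0.0
        for kmer in itertools.product(range(4), repeat=4):
            s = sum(int(ints[i, b]) for i, b in enumerate(kmer))
            if s >= target:
                total += 0.25 ** 4
        assert fwd_hit.p == pytest.approx(total, abs=1e-12)

    def test_window_with_n_skipped(self):
        pwm = consensus_pwm("ACGT")
        hits = rp.scan_motif(pwm, "ACNT", p_threshold=1.0)
        assert hits == []

    def test_pwm_longer_than_sequence(self):
        assert rp.scan_motif(consensus_pwm("ACGTACGT"), "ACG") == []


class TestActivePromoters:
    def test_peak_over_tss(self, toy_genes):
        pk = Peak(GenomicInterval("chr1", 9_900, 10_100), summit=10_000)
        assert rp.active_promoters([pk], toy_genes) == {"G1"}

    def test_boundary_just_outside_window(self, toy_genes):
        # + strand, window [6000, 11000); width-1 peak at 5999 misses
        pk = Peak(GenomicInterval("chr1", 5_999, 6_000), summit=5_999)
        assert rp.active_promoters([pk], toy_genes) == set()
        pk2 = Peak(GenomicInterval("chr1", 6_000, 6_001), summit=6_000)
        assert rp.active_promoters([pk2], toy_genes) == {"G1"}

    def test_no_peaks_empty(self, toy_genes):
        assert rp.active_promoters([], toy_genes) == set()


class TestSummitWindow:
    def test_centered(self):
        pk = Peak(GenomicInterval("chr1", 900, 1100), summit=1000)
        win = rp.summit_window(pk, 150)
        assert (win.start, win.end) == (925, 1075)

    def test_clipped_at_chrom_start(self):
        pk = Peak(GenomicInterval("chr1", 0, 100), summit=30)
        win = rp.summit_window(pk, 150)
        assert win.start == 0

    def test_zero_width_empty(self):
        pk = Peak(GenomicInterval("chr1", 900, 1100), summit=1000)
        assert rp.summit_window(pk, 0) is None


class TestBuildNetwork:
    def setup_args(self):
        annotations = [
            FeatureAnnotation("p1", "promoter", "G1", "overlap"),
            FeatureAnnotation("p2", "enhancer", "G2", "loop"),
        ]
        motif_hits = {"p1": {"TF1"}, "p2": {"TF1", "TF2"}}
        return annotations, motif_hits

    def test_reference_point_all_weights_one(self):
        annotations, motif_hits = self.setup_args()
        net = rp.build_network(
            {"G1", "G2", "TF1", "TF2"},
            annotations,
            motif_hits,
            expression_z={"G1": 0, "G2": 0, "TF1": 0, "TF2": 0},
            peak_intensity={"p1": 5.0, "p2": 5.0},
        )
        for node in net.graph.nodes:
            assert net.node_weight(node) == pytest.approx(1.0)
        for _, _, d in net.graph.edges(data=True):
            assert d["weight"] == pytest.approx(1.0)

    def test_doubled_intensity_scales_sqrt2(self):
        annotations, motif_hits = self.setup_args()
        kwargs = dict(
            active_genes={"G1", "G2", "TF1", "TF2"},
            annotations=annotations,
            motif_hits_per_peak=motif_hits,
            expression_z={"G1": 0, "G2": 0, "TF1": 0, "TF2": 0},
        )
        base = rp.build_network(**kwargs, peak_intensity={"p1": 4.0, "p2": 4.0})
        # doubling p1 relative to the median scales its edge weight by sqrt(2)
        doubled = rp.build_network(**kwargs, peak_intensity={"p1": 8.0, "p2": 4.0})
        w_base = base.graph["TF1"]["G1"]["weight"]
        w_doubled = doubled.graph["TF1"]["G1"]["weight"]
        med_ratio = 4.0 / np.median([8.0, 4.0])
        assert w_doubled / w_base == pytest.approx(np.sqrt(2 * med_ratio))

    def test_node_weight_is_exp_z(self):
        annotations, motif_hits = self.setup_args()
        net = rp.build_network(
            {"G1", "G2"},
            annotations,
            motif_hits,
            expression_z={"G1": 1.5, "G2": -0.5, "TF1": 0.2, "TF2": 0.0},
            peak_intensity={"p1": 1.0, "p2": 1.0},
        )
        assert net.node_weight("G1") == pytest.approx(np.exp(1.5))
        assert net.node_weight("G2") == pytest.approx(np.exp(-0.5))

    def test_missing_expression_warns_z_zero(self):
        annotations, motif_hits = self.setup_args()
        with pytest.warns(UserWarning):
            net = rp.build_network(
                {"G1", "G2"}, annotations, motif_hits,
                expression_z={"G1": 0.0, "G2": 0.0, "TF2": 0.0},
                peak_intensity={"p1": 1.0, "p2": 1.0},
            )
        assert net.node_weight("TF1") == pytest.approx(1.0)

    def test_planted_network_recovered(self, small_model):
        """Motif scan over summit windows recovers every planted edge."""
        feats = small_model.chip_features("H3K27ac")
        motif_hits = {}
        for fid, pk in feats:
            win = rp.summit_window(pk, 150, small_model.chrom_lengths[pk.interval.chrom])
            if win is None:
                continue
            seq = small_model.sequences[win.chrom][win.start:win.end]
            hits = {
                tf for tf, pwm in small_model.pwms.items()
                if rp.scan_motif(pwm, seq, p_threshold=1e-4)
            }
            if hits:
                motif_hits[fid] = hits
        annotations = []
        for fid, pk in feats:
            gene = fid.split(":", 1)[1]
            cls = "promoter" if fid.startswith("prom:") else "enhancer"
            annotations.append(FeatureAnnotation(fid, cls, gene, "overlap"))
        all_genes = set(small_model.genes["gene_id"])
        z = {g: 0.0 for g in all_genes}
        intensity = {fid: 1.0 for fid, _ in feats}
        net = rp.build_network(all_genes, annotations, motif_hits, z, intensity,
                               tf_ids=set(small_model.tf_ids))
        recovered = set(net.graph.edges())
        planted = set(small_model.true_network)
        assert planted <= recovered


class TestPersonalizedPagerank:
    def make_net(self, nodes, edges):
        g = nx.DiGraph()
        for n, w in nodes.items():
            g.add_node(n, weight=w)
        for u, v, w in edges:
            g.add_edge(u, v, weight=w)
        return rp.RegulatoryNetwork(g, set())

    def dense_oracle(self, net, damping):
        g = net.graph
        nodes = sorted(g.nodes)
        idx = {v: i for i, v in enumerate(nodes)}
        n = len(nodes)
        w = np.array([g.nodes[v]["weight"] for v in nodes])
        s = w / w.sum()
        out = np.zeros(n)
        for u, v, d in g.edges(data=True):
            out[idx[v]] += d["weight"]
        W = np.zeros((n, n))
        for u, v, d in g.edges(data=True):
            W[idx[u], idx[v]] += d["weight"] / out[idx[v]]
        for j in range(n):
            if out[j] == 0:
                W[:, j] = s
        r = np.linalg.solve(np.eye(n) - damping * W, (1 - damping) * s)
        r = r / r.sum()
        return {v: r[idx[v]] for v in nodes}

    def test_single_node(self):
        net = self.make_net({"a": 1.0}, [])
        res = rp.personalized_pagerank(net)
        assert res.scores["a"] == pytest.approx(1.0)

    def test_two_nodes_symmetric(self):
        net = self.make_net({"a": 1.0, "b": 1.0}, [("a", "b", 1.0), ("b", "a", 1.0)])
        res = rp.personalized_pagerank(net)
        assert res.scores["a"] == pytest.approx(0.5, abs=1e-8)
        assert res.scores["b"] == pytest.approx(0.5, abs=1e-8)

    def test_matches_dense_solve_random_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(2, 21))
            nodes = {f"n{i}": float(rng.uniform(0.1, 2)) for i in range(n)}
            edges = []
            for _ in range(2 * n):
                u, v = rng.integers(0, n, 2)
                if u != v:
                    edges.append((f"n{u}", f"n{v}", float(rng.uniform(0.1, 3))))
            net = self.make_net(nodes, edges)
            res = rp.personalized_pagerank(net, tol=1e-12)
            oracle = self.dense_oracle(net, 0.85)
            for v in nodes:
                assert res.scores[v] == pytest.approx(oracle[v], abs=1e-6)
            assert sum(res.scores.values()) == pytest.approx(1.0, abs=1e-8)

    def test_invariant_to_edge_weight_scaling(self):
        nodes = {"a": 1.0, "b": 2.0, "c": 0.5}
        edges = [("a", "b", 1.0), ("b", "c", 2.0), ("a", "c", 0.3)]
        net1 = self.make_net(nodes, edges)
        net2 = self.make_net(nodes, [(u, v, 10 * w) for u, v, w in edges])
        r1 = rp.personalized_pagerank(net1, tol=1e-12)
        r2 = rp.personalized_pagerank(net2, tol=1e-12)
        for v in nodes:
            assert r1.scores[v] == pytest.approx(r2.scores[v], abs=1e-10)

    def test_isolated_tiny_weight_node_negligible(self):
        nodes = {"a": 1.0, "b": 2.0}
        edges = [("a", "b", 1.0)]
        base = rp.personalized_pagerank(self.make_net(nodes, edges), tol=1e-12)
        nodes2 = dict(nodes, z=1e-12)
        aug = rp.personalized_pagerank(self.make_net(nodes2, edges), tol=1e-12)
        for v in ("a", "b"):
            assert aug.scores[v] == pytest.approx(base.scores[v], abs=1e-6)

    def test_nonconvergence_raises(self):
        net = self.make_net({"a": 1.0, "b": 1.0}, [("a", "b", 1.0)])
        with pytest.raises(RuntimeError):
            rp.personalized_pagerank(net, tol=1e-15, max_iter=2)


class TestPPRRankTFs:
    def make_inputs(self):
        scores = {
            "P1_case": {"TF1": 0.3, "TF2": 0.2, "G": 0.5},
            "P1_ctrl": {"TF1": 0.2, "TF2": 0.25, "G": 0.55},
            "P2_case": {"TF1": 0.35, "TF2": 0.2, "G": 0.45},
            "P2_ctrl": {"TF1": 0.25, "TF2": 0.22, "G": 0.53},
        }
        ppr = {
            sid: rp.PPRResult(sid, sc, 0.85, 10) for sid, sc in scores.items()
        }
        pairs = [("P1", "P1_case", "P1_ctrl"), ("P2", "P2_case", "P2_ctrl")]
        return ppr, pairs

    def diff(self, tf, p_adj):
        return DifferentialResult(tf, 1.0, 0.5, p_adj / 2, p_adj, "bh", p_adj < 0.05)

    def test_consistent_delta_ranked_first(self):
        ppr, pairs = self.make_inputs()
        ranked, _ = rp.ppr_rank_tfs(
            ppr, [self.diff("TF1", 0.01), self.diff("TF2", 0.01)], pairs
        )
        assert list(ranked["tf"]) == ["TF1", "TF2"]  # |0.1| > |-0.035|

    def test_no_significant_tfs_empty(self):
        ppr, pairs = self.make_inputs()
        ranked, _ = rp.ppr_rank_tfs(ppr, [self.diff("TF1", 0.9)], pairs)
        assert len(ranked) == 0

    def test_absolute_value_ranks(self):
        ppr, pairs = self.make_inputs()
        # TF2 deltas are negative; rank uses |mean delta|
        ranked, _ = rp.ppr_rank_tfs(
            ppr, [self.diff("TF2", 0.01)], pairs
        )
        assert ranked.iloc[0]["mean_delta"] < 0

    def test_missing_tf_rejected(self):
        ppr, pairs = self.make_inputs()
        with pytest.raises(ValueError):
            rp.ppr_rank_tfs(ppr, [self.diff("TFX", 0.01)], pairs)
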