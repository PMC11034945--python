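"""Matched-pair cohort analyses: reversal classification, regulatees, age effects.

The unit of analysis is the pairwise case-minus-control difference within
each individually matched pair. AF (antipsychotic-free) vs AT
(antipsychotic-treated) mean deltas classify features as recovered /
treatment_induced / neither; age correlations use Pearson r with the
t-distribution (df = n - 2) p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from epipair.differential import DifferentialResult, bh_adjust
from epipair.io_cli.formats import SampleMeta


@dataclass(frozen=True)
class ReversalCall:
    feature_id: str
    af_mean_delta: float
    at_mean_delta: float
    cls: str  # recovered | treatment_induced | neither
    fdr: float


def pair_samples(
    samples: list[SampleMeta], present: set[str] | None = None
) -> list[tuple[str, str, str, float]]:
    """Resolve (pair_id, case_sample_id, control_sample_id, age) tuples.

    ``present`` restricts to sample ids available in a value table; each pair
    must then contribute exactly one case and one control.
    """
    rows: dict[str, dict[str, list]] = {}
    ages: dict[str, float] = {}
    for s in samples:
        if present is not None and s.sample_id not in present:
            continue
        rows.setdefault(s.pair_id, {"case": [], "control": []})[s.group].append(s.sample_id)
        ages[s.pair_id] = s.age
    out = []
    for pair_id in sorted(rows):
        cases, controls = rows[pair_id]["case"], rows[pair_id]["control"]
        if len(cases) != 1 or len(controls) != 1:
            raise ValueError(
                f"pair {pair_id}: {len(cases)} case / {len(controls)} control samples present"
            )
        out.append((pair_id, cases[0], controls[0], ages[pair_id]))
    return out


def pairwise_diff(
    values: pd.DataFrame, samples: list[SampleMeta], feature_kind: str = "gene_expr"
) -> pd.DataFrame:
    """Case-minus-control delta per matched pair per feature.

    ``values`` is a samples x features table (index = sample_id). Returns a
    long table with columns pair_id, feature_id, feature_kind, delta, age.
    """
    pairs = pair_samples(samples, present=set(values.index))
    frames = []
    for pair_id, case, ctrl, age in pairs:
        delta = values.loc[case] - values.loc[ctrl]
        frames.append(
            pd.DataFrame(
                {
                    "pair_id": pair_id,
                    "feature_id": delta.index,
                    "feature_kind": feature_kind,
                    "delta": delta.to_numpy(),
                    "age": age,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    if not np.isfinite(out["delta"]).all():
        raise ValueError("non-finite pairwise delta")
    return out


def delta_matrix(diffs: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long pairwise-diff table to features x pairs."""
    return diffs.pivot(index="feature_id", columns="pair_id", values="delta")


def _signed_rank_p(deltas: np.ndarray, test: str) -> float:
    if np.allclose(deltas, 0):
        return 1.0
    if test == "wilcoxon":
        try:
            return float(stats.wilcoxon(deltas, alternative="two-sided").pvalue)
        except ValueError:
            return 1.0
    if test == "ttest":
        return float(stats.ttest_1samp(deltas, 0.0).pvalue)
    raise ValueError(f"unknown test {test!r}")


def classify_reversal(
    af_deltas: pd.DataFrame,
    at_deltas: pd.DataFrame,
    threshold: float = 0.5,
    alpha: float = 0.05,
    test: str = "wilcoxon",
) -> list[ReversalCall]:
    """Classify features as recovered / treatment_induced / neither.

    Inputs are features x pairs delta tables for the AF and AT cohorts. A
    feature is a candidate when the AF and AT mean deltas differ by more
    than ``threshold``; the class-defining cohort's deltas are then tested
    against 0 (two-sided signed-rank by default), BH-adjusted across
    candidates, and the class is kept only at fdr < ``alpha``.
    """
    if af_deltas.shape[1] < 2 or at_deltas.shape[1] < 2:
        raise ValueError("each cohort needs at least 2 pairs")
    features = list(af_deltas.index)
    if set(features) != set(at_deltas.index):
        raise ValueError("AF and AT delta tables cover different features")
    at_deltas = at_deltas.loc[features]

    af_mean = af_deltas.mean(axis=1)
    at_mean = at_deltas.mean(axis=1)
    candidates = []
    cand_p = []
    for fid in features:
        gap = af_mean[fid] - at_mean[fid]
        if gap > threshold:
            cls = "recovered"
            p = _signed_rank_p(af_deltas.loc[fid].to_numpy(), test)
        elif -gap > threshold:
            cls = "treatment_induced"
            p = _signed_rank_p(at_deltas.loc[fid].to_numpy(), test)
        else:
            continue
        candidates.append((fid, cls))
        cand_p.append(p)

    fdrs = bh_adjust(np.array(cand_p)) if cand_p else np.empty(0)
    fdr_map = {fid: (cls, float(q)) for (fid, cls), q in zip(candidates, fdrs)}
    calls = []
    for fid in features:
        cls, fdr = fdr_map.get(fid, ("neither", 1.0))
        if cls != "neither" and fdr >= alpha:
            cls = "neither"
        calls.append(
            ReversalCall(
                feature_id=fid,
                af_mean_delta=float(af_mean[fid]),
                at_mean_delta=float(at_mean[fid]),
                cls=cls,
                fdr=fdr,
            )
        )
    return calls


def reversal_frame(calls: list[ReversalCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [c.feature_id for c in calls],
            "af_mean_delta": [c.af_mean_delta for c in calls],
            "at_mean_delta": [c.at_mean_delta for c in calls],
            "class": [c.cls for c in calls],
            "fdr": [c.fdr for c in calls],
        }
    )


def extract_regulatees(
    networks: dict[str, "object"],
    top_tfs: list[str],
    degs: list[DifferentialResult],
    pairs: list[tuple[str, str, str]],
    min_tf_count: int = 3,
    alpha: float = 0.05,
    test: str = "wilcoxon",
) -> set[str]:
    """Dysregulated regulatees of the top TFs, by differential edge weights.

    A gene counts as a regulatee of a TF when the tf->gene edge exists in
    any sample network, its paired edge-weight deltas differ from 0
    (signed-rank, BH-adjusted over all tested edges), and the gene is a DEG.
    Returns genes regulated by at least ``min_tf_count`` of the top TFs.
    """
    if min_tf_count > len(top_tfs):
        raise ValueError(f"min_tf_count={min_tf_count} > {len(top_tfs)} top TFs")
    deg_ids = {r.feature_id for r in degs if r.significant}
    if not deg_ids:
        return set()

    def edge_weight(sample_id: str, tf: str, gene: str) -> float:
        g = networks[sample_id].graph
        return float(g[tf][gene]["weight"]) if g.has_edge(tf, gene) else 0.0

    tested: list[tuple[str, str]] = []
    pvals: list[float] = []
    for tf in top_tfs:
        targets = set()
        for net in networks.values():
            if tf in net.graph:
                targets.update(net.graph.successors(tf))
        for gene in sorted(targets & deg_ids):
            deltas = np.array(
                [edge_weight(case, tf, gene) - edge_weight(ctrl, tf, gene) for _, case, ctrl in pairs]
            )
            tested.append((tf, gene))
            pvals.append(_signed_rank_p(deltas, test))
    if not tested:
        return set()
    fdrs = bh_adjust(np.array(pvals))
    counts: dict[str, int] = {}
    for (tf, gene), q in zip(tested, fdrs):
        if q < alpha:
            counts[gene] = counts.get(gene, 0) + 1
    return {g for g, c in counts.items() if c >= min_tf_count}


def cohort_specific_sets(
    af_results: list[DifferentialResult],
    at_results: list[DifferentialResult],
) -> tuple[set[str], set[str], set[str]]:
    """(af_only, at_only, shared) significant-feature sets over a common universe."""
    af_ids = {r.feature_id for r in af_results}
    at_ids = {r.feature_id for r in at_results}
    if af_ids != at_ids:
        missing = sorted(af_ids ^ at_ids)
        raise ValueError(f"feature universes differ; mismatched: {missing[:10]}")
    af_sig = {r.feature_id for r in af_results if r.significant}
    at_sig = {r.feature_id for r in at_results if r.significant}
    return af_sig - at_sig, at_sig - af_sig, af_sig & at_sig


def age_correlation(values: pd.DataFrame, ages, mode: str = "pairwise_delta") -> pd.DataFrame:
    """Pearson age correlation per feature with the exact t-distribution p-value.

    ``values`` is a features x observations table (observations = pairs for
    pairwise_delta mode, samples for raw_expression mode); ``ages`` is one
    age per column. p = 2 P(T_{n-2} >= |t|) with t = r sqrt((n-2)/(1-r^2)).
    """
    if mode not in ("raw_expression", "pairwise_delta"):
        raise ValueError(f"unknown mode {mode!r}")
    ages = np.asarray(ages, float)
    if values.shape[1] != len(ages):
        raise ValueError("ages length must match number of columns")
    if len(ages) < 3:
        raise ValueError("need at least 3 observations")
    rows = []
    for fid, series in values.iterrows():
        v = series.to_numpy(float)
        if np.std(v) == 0 or np.std(ages) == 0:
            warnings.warn(f"zero variance for {fid}; skipped")
            continue
        r = float(np.corrcoef(v, ages)[0, 1])
        n = len(ages)
        if abs(r) >= 1.0:
            p = 0.0
        else:
            t = abs(r) * np.sqrt((n - 2) / (1.0 - r * r))
            p = float(2.0 * stats.t.sf(t, df=n - 2))
        rows.append((fid, r, p, n))
    return pd.DataFrame(rows, columns=["feature_id", "r", "p", "n"])


def age_correlated_features(
    correlations: pd.DataFrame, r_threshold: float
) -> tuple[pd.DataFrame, dict]:
    """Features with |r| >= threshold (inclusive), plus a sign summary."""
    if not 0 < r_threshold < 1:
        raise ValueError("r_threshold must be in (0, 1)")
    hits = correlations[np.abs(correlations["r"]) >= r_threshold].copy()
    n = len(hits)
    n_pos = int((hits["r"] > 0).sum())
    summary = {
        "n": n,
        "n_positive": n_pos,
        "n_negative": n - n_pos,
        "frac_positive": n_pos / n if n else float("nan"),
        "frac_negative": (n - n_pos) / n if n else float("nan"),
    }
    return hits, summary
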