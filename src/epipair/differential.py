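"""Negative-binomial differential testing, annotation, and enrichment statistics.

Covers the NB Wald test with trend-shrunk dispersions, Bonferroni/BH
adjustment, enhancer/promoter classification with loop- or nearest-gene
linking, basal-plus-extension region->gene mapping, exact hypergeometric
overlap tests, and the QQ inflation factor lambda.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats, special

from epipair.io_cli.formats import GenomicInterval, Peak
from epipair.peaks_counts import CountMatrix

_CHI2_MEDIAN_DF1 = 0.4549364231195724  # median of chi-square with 1 df


@dataclass(frozen=True)
class DifferentialResult:
    feature_id: str
    baseline_mean: float
    log2_fc: float
    p: float
    p_adj: float
    adjust_method: str
    significant: bool


@dataclass(frozen=True)
class FeatureAnnotation:
    feature_id: str
    cls: str  # enhancer | promoter
    linked_gene: str
    link_source: str  # loop | nearest | overlap


# --- multiple-testing adjustments --------------------------------------------


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, stable for ties)."""
    p = np.asarray(pvals, float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must be in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def bonferroni_adjust(pvals) -> np.ndarray:
    p = np.asarray(pvals, float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must be in [0, 1]")
    return np.minimum(p * p.size, 1.0)


# --- NB differential test ----------------------------------------------------


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    """NB2 log-likelihood with dispersion alpha (var = mu + alpha mu^2)."""
    size = 1.0 / alpha
    return float(
        np.sum(
            special.gammaln(y + size)
            - special.gammaln(size)
            - special.gammaln(y + 1)
            + size * np.log(size / (size + mu))
            + y * np.log(mu / (size + mu))
        )
    )


def _ml_dispersion(y: np.ndarray, mu: np.ndarray) -> float:
    """Maximum-likelihood NB dispersion with the mean profile held fixed."""
    if np.allclose(y, mu):
        return 1e-8

    def neg(log_alpha: float) -> float:
        return -_nb_loglik(y, mu, np.exp(log_alpha))

    res = optimize.minimize_scalar(neg, bounds=(np.log(1e-8), np.log(50.0)), method="bounded")
    return float(np.exp(res.x))


def _dispersion_trend(means: np.ndarray, alphas: np.ndarray) -> np.ndarray:
    """Median dispersion in log-mean bins, interpolated back per feature."""
    logm = np.log(np.maximum(means, 1e-8))
    n_bins = max(3, min(10, len(means) // 50))
    edges = np.quantile(logm, np.linspace(0, 1, n_bins + 1))
    edges[-1] += 1e-9
    centers, medians = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (logm >= lo) & (logm < hi)
        if mask.sum() >= 3:
            centers.append(logm[mask].mean())
            medians.append(np.median(alphas[mask]))
    if len(centers) < 2:
        return np.full_like(alphas, np.median(alphas))
    return np.interp(logm, centers, medians)


def nb_differential(
    matrix: CountMatrix,
    group_labels,
    covariates: pd.DataFrame | None = None,
    adjust_method: str = "bonferroni",
    alpha: float = 0.05,
    shrink_weight: float = 0.5,
) -> list[DifferentialResult]:
    """Per-feature NB log-linear Wald test of case vs control.

    The model uses an offset of log(library size x TMM factor); dispersions
    are estimated per feature by ML and shrunk halfway toward the
    mean-dispersion trend before the Wald test on the group coefficient.
    """
    labels = np.asarray(group_labels)
    if set(labels) - {"case", "control"}:
        raise ValueError(f"bad group labels {sorted(set(labels))}")
    if (labels == "case").sum() < 2 or (labels == "control").sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    counts = matrix.counts
    if not np.issubdtype(counts.dtype, np.integer):
        if not np.allclose(counts, np.round(counts)):
            raise ValueError("counts must be integers")
        counts = np.round(counts).astype(int)
    if adjust_method not in ("bonferroni", "bh"):
        raise ValueError(f"unknown adjust_method {adjust_method!r}")

    offset = np.log(matrix.lib_sizes_vector * matrix.tmm_vector)
    group = (labels == "case").astype(float)
    cols = [np.ones(len(labels)), group]
    if covariates is not None:
        for c in covariates.columns:
            cols.append(np.asarray(covariates[c], float))
    X = np.column_stack(cols)

    n_feat = counts.shape[0]
    mus = np.empty((n_feat, counts.shape[1]))
    betas = np.empty(n_feat)
    raw_alpha = np.empty(n_feat)
    base_means = np.empty(n_feat)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_feat):
            y = counts[i].astype(float)
            pois = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
            mus[i] = np.maximum(pois.mu, 1e-8)
            betas[i] = pois.params[1]
            raw_alpha[i] = _ml_dispersion(y, mus[i])
            base_means[i] = float(np.mean(y / np.exp(offset) * np.exp(offset).mean()))
        trend = _dispersion_trend(base_means, raw_alpha)
        alphas = shrink_weight * raw_alpha + (1.0 - shrink_weight) * trend

        pvals = np.empty(n_feat)
        log2fc = np.empty(n_feat)
        for i in range(n_feat):
            fam = sm.families.NegativeBinomial(alpha=max(alphas[i], 1e-8))
            try:
                fit = sm.GLM(counts[i].astype(float), X, family=fam, offset=offset).fit()
                coef, se = fit.params[1], fit.bse[1]
            except Exception:
                coef, se = betas[i], np.inf
            log2fc[i] = coef / np.log(2)
            z = coef / se if se > 0 and np.isfinite(se) else 0.0
            pvals[i] = 2 * stats.norm.sf(abs(z))

    adj = bonferroni_adjust(pvals) if adjust_method == "bonferroni" else bh_adjust(pvals)
    return [
        DifferentialResult(
            feature_id=matrix.feature_ids[i],
            baseline_mean=float(base_means[i]),
            log2_fc=float(log2fc[i]),
            p=float(pvals[i]),
            p_adj=float(adj[i]),
            adjust_method=adjust_method,
            significant=bool(adj[i] < alpha),
        )
        for i in range(n_feat)
    ]


def results_frame(results: list[DifferentialResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in results],
            "baseline_mean": [r.baseline_mean for r in results],
            "log2_fc": [r.log2_fc for r in results],
            "p": [r.p for r in results],
            "p_adj": [r.p_adj for r in results],
            "adjust_method": [r.adjust_method for r in results],
            "significant": [r.significant for r in results],
        }
    )


# --- annotation ---------------------------------------------------------------


def promoter_window(tss: int, strand: str, up: int = 4000, down: int = 1000) -> tuple[int, int]:
    """Strand-aware promoter window around a TSS, 0-based half-open."""
    if strand == "-":
        return max(tss - down, 0), tss + up
    return max(tss - up, 0), tss + down


def _gene_windows(genes: pd.DataFrame, up: int, down: int) -> pd.DataFrame:
    win = genes.copy()
    bounds = [
        promoter_window(t, s, up, down) for t, s in zip(genes["tss"], genes["strand"])
    ]
    win["win_start"] = [b[0] for b in bounds]
    win["win_end"] = [b[1] for b in bounds]
    return win


def classify_enhancer_promoter(
    peaks: list[Peak],
    genes: pd.DataFrame,
    loop_table: list[tuple[GenomicInterval, GenomicInterval]] | None = None,
    promoter_up: int = 4000,
    promoter_down: int = 1000,
) -> list[FeatureAnnotation]:
    """Split peaks into promoter-overlapping vs enhancer, with gene links.

    Promoter peaks link to the max-overlap promoter gene; enhancers link via
    chromatin loops when possible, else to the nearest TSS.
    """
    win = _gene_windows(genes, promoter_up, promoter_down)
    out = []
    for pk in peaks:
        iv = pk.interval
        fid = f"{iv.chrom}:{iv.start}-{iv.end}"
        cand = win[win["chrom"] == iv.chrom]
        overlap = np.minimum(cand["win_end"], iv.end) - np.maximum(cand["win_start"], iv.start)
        hits = cand[overlap > 0]
        if len(hits):
            hits = hits.assign(ov=overlap[overlap > 0])
            hits = hits.sort_values(["ov", "tss", "gene_id"], ascending=[False, True, True])
            out.append(FeatureAnnotation(fid, "promoter", hits.iloc[0]["gene_id"], "overlap"))
        else:
            gene, source = link_enhancer(
                pk, loop_table or [], genes, promoter_up, promoter_down
            )
            out.append(FeatureAnnotation(fid, "enhancer", gene, source))
    return out


def link_enhancer(
    enhancer: Peak,
    loop_table: list[tuple[GenomicInterval, GenomicInterval]],
    genes: pd.DataFrame,
    promoter_up: int = 4000,
    promoter_down: int = 1000,
) -> tuple[str, str]:
    """Link an enhancer peak to a gene via chromatin loops, else nearest TSS."""
    if len(genes) == 0:
        raise ValueError("empty gene annotation")
    iv = enhancer.interval
    win = _gene_windows(genes, promoter_up, promoter_down)
    for a, b in loop_table:
        for anchor, partner in ((a, b), (b, a)):
            if not iv.overlaps(anchor):
                continue
            cand = win[win["chrom"] == partner.chrom]
            overlap = np.minimum(cand["win_end"], partner.end) - np.maximum(
                cand["win_start"], partner.start
            )
            hits = cand[overlap > 0]
            if len(hits):
                hits = hits.assign(ov=overlap[overlap > 0])
                hits = hits.sort_values(["ov", "tss", "gene_id"], ascending=[False, True, True])
                return hits.iloc[0]["gene_id"], "loop"
    same = genes[genes["chrom"] == iv.chrom]
    if len(same) == 0:
        same = genes
    dist = np.abs(same["tss"] - iv.midpoint)
    nearest = same.assign(dist=dist).sort_values(["dist", "tss", "gene_id"])
    return nearest.iloc[0]["gene_id"], "nearest"


def great_region_gene(
    regions: list[GenomicInterval],
    genes: pd.DataFrame,
    basal_up: int = 5000,
    basal_down: int = 1000,
    max_extension: int = 1_000_000,
) -> dict[GenomicInterval, set[str]]:
    """Basal-plus-extension region->gene assignment.

    Each gene gets a strand-aware basal domain around its TSS, extended in
    both directions up to ``max_extension`` bp or until the neighboring
    gene's basal domain; a region maps to every gene whose extended domain
    it intersects.
    """
    domains: list[tuple[str, int, int, str]] = []  # chrom, left, right, gene
    for chrom, sub in genes.groupby("chrom"):
        sub = sub.sort_values(["tss", "gene_id"]).reset_index(drop=True)
        basal = [
            promoter_window(t, s, basal_up, basal_down)
            for t, s in zip(sub["tss"], sub["strand"])
        ]
        for i in range(len(sub)):
            b_start, b_end = basal[i]
            left = max(b_start - max_extension, 0)
            if i > 0:
                left = max(left, basal[i - 1][1])
            right = b_end + max_extension
            if i < len(sub) - 1:
                right = min(right, basal[i + 1][0])
            # basal domain always included even when neighbors overlap it
            left = min(left, b_start)
            right = max(right, b_end)
            domains.append((chrom, left, right, sub.loc[i, "gene_id"]))
    mapping: dict[GenomicInterval, set[str]] = {}
    for region in regions:
        hit = {
            g
            for chrom, left, right, g in domains
            if chrom == region.chrom and region.start < right and left < region.end
        }
        mapping[region] = hit
    return mapping


# --- overlap and diagnostic statistics ---------------------------------------


def hypergeometric_p(k: int, K: int, n: int, N: int) -> float:
    """Exact upper-tail P(X >= k) for Hypergeometric(N, K, n)."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent sizes K={K}, n={n}, N={N}")
    if k > min(K, n) or k < 0:
        raise ValueError(f"overlap k={k} outside [0, min({K}, {n})]")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def qq_lambda(pvals) -> float:
    """Median chi-square inflation factor of a p-value set against uniform."""
    p = np.asarray(pvals, float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if (p == 0).any():
        warnings.warn("p-values of 0 replaced with smallest positive float")
        p = np.maximum(p, np.finfo(float).tiny)
    chisq = stats.chi2.isf(p, df=1)
    return float(np.median(chisq) / _CHI2_MEDIAN_DF1)
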