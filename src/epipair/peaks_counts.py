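"""Peak calling on synthetic coverage, replicate consensus, counting and normalization.

Implements a minimal Poisson-background peak caller (a documented stand-in
for a full caller at synthetic scale), replicate high-confidence peaks,
the cross-sample master consensus set, count-matrix construction with
optional input subtraction, TMM normalization, the low-count filter, and
PC-guided covariate selection/regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from epipair.io_cli.formats import GenomicInterval, Peak


@dataclass
class CountMatrix:
    """Features x samples non-negative integer counts with library sizes."""

    feature_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    library_sizes: dict[str, int]
    tmm_factors: dict[str, float] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} != "
                f"({len(self.feature_ids)}, {len(self.sample_ids)})"
            )
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        colsums = self.counts.sum(axis=0)
        for j, sid in enumerate(self.sample_ids):
            if sid not in self.library_sizes:
                raise ValueError(f"missing library size for {sid}")
            if self.library_sizes[sid] < colsums[j]:
                raise ValueError(f"library size of {sid} below its column sum")

    @property
    def lib_sizes_vector(self) -> np.ndarray:
        return np.array([self.library_sizes[s] for s in self.sample_ids], float)

    @property
    def tmm_vector(self) -> np.ndarray:
        if self.tmm_factors is None:
            return np.ones(len(self.sample_ids))
        return np.array([self.tmm_factors[s] for s in self.sample_ids], float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.feature_ids, columns=self.sample_ids)

    def cpm(self, log: bool = True) -> np.ndarray:
        """Counts per million on effective (TMM-scaled) library sizes."""
        eff = self.lib_sizes_vector * self.tmm_vector
        vals = self.counts / eff[None, :] * 1e6
        return np.log1p(vals) if log else vals


# --- minimal Poisson peak caller ---------------------------------------------


def call_peaks_poisson(
    coverage: dict[str, np.ndarray],
    background_lambda: float | str = "global",
    q_cutoff: float = 0.05,
    bin_width: int = 1,
    local_window: int = 5000,
    merge_gap: int = 100,
) -> list[Peak]:
    """Call peaks from per-base (or binned) tag coverage.

    Per bin, a Poisson upper-tail p-value is computed against
    max(global mean, local mean over +/- ``local_window`` bp); p-values are
    BH-adjusted over all bins, and significant bins within ``merge_gap`` bp
    are merged. The summit is the max-coverage position of the merged region.
    """
    chroms = sorted(coverage)
    all_p: list[np.ndarray] = []
    lambdas: list[np.ndarray] = []
    total = sum(float(coverage[c].sum()) for c in chroms)
    n_bins = sum(len(coverage[c]) for c in chroms)
    if n_bins == 0 or total == 0:
        return []
    global_mean = total / n_bins
    half = max(1, local_window // bin_width)
    for c in chroms:
        cov = np.asarray(coverage[c], float)
        csum = np.concatenate([[0.0], np.cumsum(cov)])
        idx = np.arange(len(cov))
        lo = np.maximum(idx - half, 0)
        hi = np.minimum(idx + half + 1, len(cov))
        local_mean = (csum[hi] - csum[lo]) / (hi - lo)
        lam = np.maximum(local_mean, global_mean)
        if background_lambda != "global":
            lam = np.maximum(lam, float(background_lambda))
        # upper tail P(X >= x) = sf(x - 1)
        p = stats.poisson.sf(cov - 1, lam)
        all_p.append(p)
        lambdas.append(lam)

    from epipair.differential import bh_adjust

    q = bh_adjust(np.concatenate(all_p))
    peaks: list[Peak] = []
    offset = 0
    for ci, c in enumerate(chroms):
        cov = np.asarray(coverage[c], float)
        qc = q[offset : offset + len(cov)]
        offset += len(cov)
        sig = np.flatnonzero(qc < q_cutoff)
        if sig.size == 0:
            continue
        gap_bins = max(1, merge_gap // bin_width)
        runs: list[list[int]] = [[sig[0], sig[0]]]
        for b in sig[1:]:
            if b - runs[-1][1] <= gap_bins:
                runs[-1][1] = b
            else:
                runs.append([b, b])
        for lo_b, hi_b in runs:
            start = int(lo_b) * bin_width
            end = (int(hi_b) + 1) * bin_width
            local = cov[lo_b : hi_b + 1]
            summit_bin = lo_b + int(np.argmax(local))
            summit = summit_bin * bin_width + bin_width // 2
            score = float(-np.log10(max(qc[lo_b : hi_b + 1].min(), 1e-300)))
            peaks.append(
                Peak(
                    GenomicInterval(c, start, end),
                    summit=min(max(summit, start), end - 1),
                    score=score,
                    qvalue=float(qc[lo_b : hi_b + 1].min()),
                )
            )
    return peaks


def _merge_clusters(peaks: list[Peak]) -> list[list[Peak]]:
    """Group peaks into transitive >=1 bp overlap clusters (per chromosome)."""
    clusters: list[list[Peak]] = []
    for pk in sorted(peaks, key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end)):
        if (
            clusters
            and clusters[-1][0].interval.chrom == pk.interval.chrom
            and pk.interval.start < max(p.interval.end for p in clusters[-1])
        ):
            clusters[-1].append(pk)
        else:
            clusters.append([pk])
    return clusters


def _union_peak(cluster: list[Peak]) -> Peak:
    best = max(cluster, key=lambda p: p.score)
    start = min(p.interval.start for p in cluster)
    end = max(p.interval.end for p in cluster)
    return Peak(
        GenomicInterval(cluster[0].interval.chrom, start, end),
        summit=best.summit,
        score=best.score,
        qvalue=min(p.qvalue for p in cluster),
    )


def high_confidence_peaks(rep1: list[Peak], rep2: list[Peak]) -> list[Peak]:
    """Keep peaks supported by both technical replicates, union-merged.

    A rep1/rep2 peak pair overlapping by >=1 bp contributes the union of the
    two intervals; overlapping unions are chained. Peaks found in only one
    replicate are dropped. The summit comes from the higher-score source.
    """
    kept: list[Peak] = []
    for a in rep1:
        if any(a.interval.overlaps(b.interval) for b in rep2):
            kept.append(a)
    for b in rep2:
        if any(b.interval.overlaps(a.interval) for a in rep1):
            kept.append(b)
    return [_union_peak(c) for c in _merge_clusters(kept)]


@dataclass
class MasterPeakSet:
    """Union-merge consensus across samples, with per-peak sample support."""

    peaks: list[Peak]
    support: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.peaks)

    def intervals(self) -> list[GenomicInterval]:
        return [p.interval for p in self.peaks]


def consensus_master(per_sample_highconf: list[list[Peak]]) -> MasterPeakSet:
    """Combine per-sample high-confidence peak sets into a master consensus set."""
    if not per_sample_highconf:
        raise ValueError("need at least one sample peak set")
    tagged: list[tuple[Peak, int]] = []
    for si, peaks in enumerate(per_sample_highconf):
        tagged.extend((p, si) for p in peaks)
    clusters: list[list[tuple[Peak, int]]] = []
    for pk, si in sorted(
        tagged, key=lambda t: (t[0].interval.chrom, t[0].interval.start, t[0].interval.end)
    ):
        if (
            clusters
            and clusters[-1][0][0].interval.chrom == pk.interval.chrom
            and pk.interval.start < max(p.interval.end for p, _ in clusters[-1])
        ):
            clusters[-1].append((pk, si))
        else:
            clusters.append([(pk, si)])
    peaks = [_union_peak([p for p, _ in c]) for c in clusters]
    support = [len({si for _, si in c}) for c in clusters]
    return MasterPeakSet(peaks, support)


# --- counting -----------------------------------------------------------------


def count_tags_in_intervals(tagset, intervals: list[GenomicInterval]) -> np.ndarray:
    """Count 5' tag positions (both strands) falling inside each interval."""
    counts = np.zeros(len(intervals), dtype=int)
    by_chrom: dict[str, list[tuple[int, GenomicInterval]]] = {}
    for i, iv in enumerate(intervals):
        by_chrom.setdefault(iv.chrom, []).append((i, iv))
    for chrom, items in by_chrom.items():
        for positions in (tagset.plus.get(chrom), tagset.minus.get(chrom)):
            if positions is None or len(positions) == 0:
                continue
            pos = np.asarray(positions)
            for i, iv in items:
                counts[i] += int(
                    np.searchsorted(pos, iv.end, "left") - np.searchsorted(pos, iv.start, "left")
                )
    return counts


def count_matrix(
    sample_counts: dict[str, np.ndarray],
    master: MasterPeakSet,
    library_sizes: dict[str, int],
    input_controls: dict[str, np.ndarray] | None = None,
    min_count: int = 1,
) -> CountMatrix:
    """Build the binding-affinity matrix over master peaks.

    With an input control, count = max(ChIP - input, ``min_count``); without,
    raw ChIP counts. Library sizes are full library totals, not in-peak sums.
    """
    feature_ids = [
        f"{p.interval.chrom}:{p.interval.start}-{p.interval.end}" for p in master.peaks
    ]
    sample_ids = sorted(sample_counts)
    cols = []
    for sid in sample_ids:
        chip = np.asarray(sample_counts[sid], dtype=int)
        if len(chip) != len(master):
            raise ValueError(f"sample {sid}: {len(chip)} counts for {len(master)} peaks")
        if input_controls is not None:
            if sid not in input_controls:
                raise ValueError(f"missing input control for {sid}")
            chip = np.maximum(chip - np.asarray(input_controls[sid], dtype=int), min_count)
        cols.append(chip)
    return CountMatrix(feature_ids, sample_ids, np.column_stack(cols), dict(library_sizes))


# --- TMM normalization --------------------------------------------------------


def _tmm_pair(
    obs: np.ndarray, ref: np.ndarray, lib_obs: float, lib_ref: float,
    trim_m: float, trim_a: float,
) -> float:
    """log2 TMM factor of one sample against the reference column."""
    keep = (obs > 0) & (ref > 0)
    if keep.sum() == 0:
        return 0.0
    o, r = obs[keep].astype(float), ref[keep].astype(float)
    m = np.log2((o / lib_obs) / (r / lib_ref))
    a = 0.5 * np.log2((o / lib_obs) * (r / lib_ref))
    # asymptotic variance of M (delta method), inverse used as weight
    v = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)
    finite = np.isfinite(m) & np.isfinite(a) & (v > 0)
    m, a, v = m[finite], a[finite], v[finite]
    if m.size == 0:
        return 0.0
    n = m.size
    lo_m, hi_m = np.floor(n * trim_m) + 1, n + 1 - (np.floor(n * trim_m) + 1)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n + 1 - (np.floor(n * trim_a) + 1)
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if keep2.sum() == 0:
        return 0.0
    w = 1.0 / v[keep2]
    f = float(np.sum(w * m[keep2]) / np.sum(w))
    return f if np.isfinite(f) else 0.0


def tmm_factors(
    matrix: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05
) -> dict[str, float]:
    """Trimmed-mean-of-M-values normalization factors, geometric mean 1.

    The reference sample is the column whose upper-quartile proportion is
    closest to the mean of upper quartiles.
    """
    counts = matrix.counts.astype(float)
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    if (counts.sum(axis=0) == 0).any():
        raise ValueError("all-zero sample column")
    libs = matrix.lib_sizes_vector
    q75 = np.array([np.quantile(counts[:, j] / libs[j], 0.75) for j in range(counts.shape[1])])
    ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    log_factors = np.array(
        [
            _tmm_pair(counts[:, j], counts[:, ref_idx], libs[j], libs[ref_idx], trim_m, trim_a)
            for j in range(counts.shape[1])
        ]
    )
    factors = 2.0 ** (log_factors - log_factors.mean())  # geometric mean 1
    return {sid: float(f) for sid, f in zip(matrix.sample_ids, factors)}


def normalize_tmm(matrix: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05) -> CountMatrix:
    return replace(matrix, tmm_factors=tmm_factors(matrix, trim_m, trim_a))


def filter_low(matrix: CountMatrix, min_count: int = 20, frac: float = 0.5) -> CountMatrix:
    """Remove features with fewer than ``min_count`` reads in over ``frac`` of samples.

    The inequality is strict: a feature low in exactly half the samples is kept.
    """
    n_low = (matrix.counts < min_count).sum(axis=1)
    keep = n_low <= frac * len(matrix.sample_ids)
    return CountMatrix(
        [f for f, k in zip(matrix.feature_ids, keep) if k],
        list(matrix.sample_ids),
        matrix.counts[keep, :],
        dict(matrix.library_sizes),
        dict(matrix.tmm_factors) if matrix.tmm_factors else None,
    )


# --- PC / covariate regression ------------------------------------------------


def _encode_covariates(covariates: pd.DataFrame) -> pd.DataFrame:
    enc = {}
    for col in covariates.columns:
        vals = covariates[col]
        if vals.dtype.kind in "biufc":
            enc[col] = vals.astype(float)
        else:
            codes, _ = pd.factorize(vals)
            enc[col] = codes.astype(float)
    return pd.DataFrame(enc, index=covariates.index)


def pc_scores(values: np.ndarray, n_pcs: int) -> np.ndarray:
    """Sample scores of the top principal components of a features x samples matrix."""
    centered = values - values.mean(axis=1, keepdims=True)
    # PCs over samples: SVD of the centered matrix, right singular vectors
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    return (vt[:n_pcs, :] * s[:n_pcs, None]).T  # samples x n_pcs


def pc_covariate_select(
    values: np.ndarray,
    covariates: pd.DataFrame,
    n_pcs: int = 6,
    r_cut: float = 0.3,
    p_cut: float = 0.05,
) -> list[str]:
    """Select covariates correlated with any of the top principal components.

    ``values`` is the log-scale normalized features x samples matrix (rows in
    feature order, columns in the covariate table's row order).
    """
    if values.shape[1] != len(covariates):
        raise ValueError("sample count mismatch between matrix and covariates")
    scores = pc_scores(values, min(n_pcs, values.shape[1] - 1))
    enc = _encode_covariates(covariates)
    selected = []
    for col in enc.columns:
        v = enc[col].to_numpy()
        if np.std(v) == 0:
            warnings.warn(f"covariate {col!r} has zero variance; excluded")
            continue
        for k in range(scores.shape[1]):
            r, p = stats.pearsonr(v, scores[:, k])
            if abs(r) >= r_cut and p <= p_cut:
                selected.append(col)
                break
    return selected


def regress_out(values: np.ndarray, covariates: pd.DataFrame) -> np.ndarray:
    """OLS-residualize each feature against the covariates, keeping feature means."""
    enc = _encode_covariates(covariates)
    X = np.column_stack([np.ones(len(enc))] + [enc[c].to_numpy() for c in enc.columns])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"rank-deficient design (rank {rank} < {X.shape[1]}); "
            f"check covariates {list(enc.columns)} for collinearity"
        )
    Y = values.T  # samples x features
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return resid.T + values.mean(axis=1, keepdims=True)
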