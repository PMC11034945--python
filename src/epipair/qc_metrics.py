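"""ENCODE-style ChIP quality metrics from strand-specific tag sets.

FRiP, the PCR bottleneck coefficient (PBC1: unique-position fraction),
strand cross-correlation with NSC/RSC and fragment-length estimation,
saturation curves, replicate correlation, and the qPCR fold-enrichment
formula 2^(Cq_negative - Cq_positive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from epipair.io_cli.formats import GenomicInterval
from epipair.synthetic_data import TagSet

NSC_THRESHOLD = 1.05
RSC_THRESHOLD = 1.0


@dataclass
class QCRecord:
    sample_id: str
    n_tags: int
    frip: float
    pbc: float
    nsc: float
    rsc: float
    fragment_length_est: int
    replicate_pearson: float | None = None

    def passes(self) -> bool:
        return self.nsc >= NSC_THRESHOLD and self.rsc >= RSC_THRESHOLD


def merge_intervals(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping/adjacent intervals into a disjoint set."""
    merged: list[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda v: (v.chrom, v.start, v.end)):
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged.pop()
            merged.append(GenomicInterval(iv.chrom, last.start, max(last.end, iv.end)))
        else:
            merged.append(iv)
    return merged


def frip(tags: TagSet, peaks: list[GenomicInterval]) -> float:
    """Fraction of tag 5' positions falling inside any peak."""
    if tags.n_tags == 0:
        raise ValueError("FRiP undefined on an empty tag set")
    if not peaks:
        return 0.0
    merged = merge_intervals(peaks)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in merged:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    inside = 0
    for strand_tags in (tags.plus, tags.minus):
        for chrom, pos in strand_tags.items():
            if chrom not in by_chrom or len(pos) == 0:
                continue
            starts = np.array([iv.start for iv in by_chrom[chrom]])
            ends = np.array([iv.end for iv in by_chrom[chrom]])
            # position is inside iff the most recent interval start <= pos < its end
            idx = np.searchsorted(starts, pos, "right") - 1
            ok = idx >= 0
            inside += int(np.sum(ok & (pos < ends[np.maximum(idx, 0)])))
    return inside / tags.n_tags


def pbc(tags: TagSet) -> float:
    """PCR bottleneck coefficient PBC1: single-tag positions / distinct positions."""
    if tags.n_tags == 0:
        raise ValueError("PBC undefined on an empty tag set")
    n_distinct = 0
    n_single = 0
    for strand_tags in (tags.plus, tags.minus):
        for pos in strand_tags.values():
            if len(pos) == 0:
                continue
            _, counts = np.unique(pos, return_counts=True)
            n_distinct += len(counts)
            n_single += int((counts == 1).sum())
    return n_single / n_distinct


def _binary_coverage(positions: np.ndarray, length: int) -> np.ndarray:
    cov = np.zeros(length, dtype=np.float64)
    valid = positions[(positions >= 0) & (positions < length)]
    cov[valid] = 1.0
    return cov


def _pearson_binary(x: np.ndarray, y: np.ndarray) -> float:
    n = len(x)
    if n < 2:
        return 0.0
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()
    if vx == 0 or vy == 0:
        return 0.0
    return float((np.dot(x, y) / n - mx * my) / np.sqrt(vx * vy))


def cross_correlation(
    tags: TagSet,
    max_shift: int = 400,
    chrom_lengths: dict[str, int] | None = None,
    phantom_exclusion: int = 10,
):
    """Strand cross-correlation profile and the NSC/RSC quality statistics.

    For each shift d, the Pearson correlation between the binarized
    plus-strand coverage and the minus-strand coverage shifted left by d is
    computed per chromosome and averaged with chromosome-length weights.
    The fragment-length estimate is the argmax outside a +/-10 bp phantom
    window around the read length; NSC = cc(fragment)/min(cc) and
    RSC = (cc(fragment) - min) / (cc(read_length) - min).
    """
    if max_shift <= tags.read_length:
        raise ValueError("max_shift must exceed the read length")
    chroms = sorted(set(tags.plus) | set(tags.minus))
    if chrom_lengths is None:
        chrom_lengths = {}
        for c in chroms:
            hi = 0
            for d in (tags.plus, tags.minus):
                if c in d and len(d[c]):
                    hi = max(hi, int(d[c].max()) + 1)
            chrom_lengths[c] = hi + 1

    shifts = np.arange(0, max_shift + 1)
    profile = np.zeros(len(shifts))
    weight_sum = 0.0
    any_signal = False
    for c in chroms:
        L = chrom_lengths[c]
        x = _binary_coverage(np.asarray(tags.plus.get(c, np.empty(0, int))), L)
        y = _binary_coverage(np.asarray(tags.minus.get(c, np.empty(0, int))), L)
        if x.sum() == 0 or y.sum() == 0:
            continue
        any_signal = True
        w = float(L)
        weight_sum += w
        for i, d in enumerate(shifts):
            if d >= L:
                continue
            profile[i] += w * _pearson_binary(x[: L - d], y[d:L])
    if not any_signal:
        raise ValueError("all-zero coverage; cross-correlation undefined")
    profile /= weight_sum

    exclude = np.abs(shifts - tags.read_length) <= phantom_exclusion
    search = profile.copy()
    search[exclude] = -np.inf
    frag_est = int(shifts[int(np.argmax(search))])
    cc_min = float(profile.min())
    cc_frag = float(profile[frag_est])
    cc_read = float(profile[tags.read_length])
    # under a structureless null the profile minimum can be <= 0; the ratio
    # is then meaningless and NSC is clamped to 0 ("no enrichment")
    nsc = max(cc_frag / cc_min, 0.0) if cc_min != 0 else 0.0
    denom = cc_read - cc_min
    rsc = (cc_frag - cc_min) / denom if denom > 0 else float("inf")
    return {
        "shifts": shifts,
        "profile": profile,
        "nsc": nsc,
        "rsc": rsc,
        "fragment_length_est": frag_est,
    }


def saturation_curve(
    tags: TagSet, fractions: list[float], caller, seed: int = 0
) -> list[tuple[float, int]]:
    """Peak counts after subsampling tags without replacement at each fraction."""
    if any(f > 1 or f <= 0 for f in fractions):
        raise ValueError("fractions must be in (0, 1]")
    rng = np.random.default_rng(seed)
    entries = []  # (strand, chrom, pos)
    for strand, d in (("+", tags.plus), ("-", tags.minus)):
        for chrom, pos in d.items():
            entries.extend((strand, chrom, int(p)) for p in pos)
    n = len(entries)
    curve = []
    for frac in fractions:
        if frac == 1.0:
            sub = entries
        else:
            k = int(np.floor(frac * n))
            idx = rng.choice(n, size=k, replace=False)
            sub = [entries[i] for i in idx]
        plus: dict[str, list[int]] = {}
        minus: dict[str, list[int]] = {}
        for strand, chrom, p in sub:
            (plus if strand == "+" else minus).setdefault(chrom, []).append(p)
        subset = TagSet(
            plus={c: np.sort(np.array(v, int)) for c, v in plus.items()},
            minus={c: np.sort(np.array(v, int)) for c, v in minus.items()},
            read_length=tags.read_length,
            fragment_length=tags.fragment_length,
        )
        curve.append((frac, len(caller(subset))))
    return curve


def replicate_correlation(counts_rep1, counts_rep2) -> float:
    """Pearson correlation of log1p counts between technical replicates."""
    a = np.log1p(np.asarray(counts_rep1, float))
    b = np.log1p(np.asarray(counts_rep2, float))
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("replicate vectors must have equal length >= 3")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in replicate counts")
    r, _ = stats.pearsonr(a, b)
    return float(r)


def qpcr_enrichment(cq_negative: float, cq_positive: float) -> float:
    """ChIP-qPCR fold enrichment: 2^(Cq_negative - Cq_positive)."""
    if not (np.isfinite(cq_negative) and np.isfinite(cq_positive)):
        raise ValueError("Cq values must be finite")
    return float(2.0 ** (cq_negative - cq_positive))


def bin_tag_counts(
    tags: TagSet, chrom_lengths: dict[str, int], bin_width: int = 50
) -> dict[str, np.ndarray]:
    """Per-bin tag counts (both strands), for the minimal peak caller."""
    out = {}
    for chrom, length in chrom_lengths.items():
        n_bins = int(np.ceil(length / bin_width))
        counts = np.zeros(n_bins, dtype=int)
        for d in (tags.plus, tags.minus):
            pos = d.get(chrom)
            if pos is not None and len(pos):
                np.add.at(counts, np.minimum(pos // bin_width, n_bins - 1), 1)
        out[chrom] = counts
    return out
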