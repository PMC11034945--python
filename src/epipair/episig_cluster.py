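"""Genome-binned multi-dataset signal clustering and per-cluster enrichment.

Fixed-width bins tile the genome; per-dataset signals are depth-normalized
(CPM, log1p). Bins enriched in at least one dataset (Poisson vs the
genome-wide mean, BH per dataset) are clustered by K-means on per-dataset
standardized profiles, clusters are grouped into sections by K-means on
their centroids, and differential features are tested per cluster with the
exact hypergeometric upper tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from epipair.differential import bh_adjust, hypergeometric_p, promoter_window
from epipair.io_cli.formats import GenomicInterval
from epipair.synthetic_data import TagSet


@dataclass
class BinMatrix:
    bins: list[GenomicInterval]
    datasets: list[str]
    values: np.ndarray  # log1p CPM, bins x datasets
    raw: np.ndarray  # raw bin counts, bins x datasets

    def __post_init__(self) -> None:
        expected = (len(self.bins), len(self.datasets))
        if self.values.shape != expected or self.raw.shape != expected:
            raise ValueError("bin matrix shape mismatch")

    def subset(self, idx: np.ndarray) -> "BinMatrix":
        return BinMatrix(
            [self.bins[i] for i in idx], list(self.datasets), self.values[idx], self.raw[idx]
        )


@dataclass
class EpiCluster:
    cluster_id: int
    member_bins: list[int]  # indices into the enriched-bin list
    centroid: np.ndarray
    section_id: int | None = None


def make_bins(chrom_lengths: dict[str, int], bin_size: int = 5000) -> list[GenomicInterval]:
    """Tile the genome with fixed-width bins (last bin clipped)."""
    bins = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        for start in range(0, length, bin_size):
            bins.append(GenomicInterval(chrom, start, min(start + bin_size, length)))
    return bins


def bin_signals(
    tags_per_dataset: dict[str, TagSet],
    chrom_lengths: dict[str, int],
    bin_size: int = 5000,
) -> BinMatrix:
    """Per-bin tag counts per dataset, CPM-normalized and log1p-transformed."""
    bins = make_bins(chrom_lengths, bin_size)
    bin_index: dict[str, int] = {}
    offsets = {}
    pos = 0
    for chrom in sorted(chrom_lengths):
        offsets[chrom] = pos
        pos += int(np.ceil(chrom_lengths[chrom] / bin_size))
    datasets = sorted(tags_per_dataset)
    raw = np.zeros((len(bins), len(datasets)), dtype=int)
    for j, ds in enumerate(datasets):
        tags = tags_per_dataset[ds]
        if tags.n_tags == 0:
            raise ValueError(f"dataset {ds} has zero tags")
        for strand_tags in (tags.plus, tags.minus):
            for chrom, positions in strand_tags.items():
                if chrom not in offsets or len(positions) == 0:
                    continue
                n_bins_c = int(np.ceil(chrom_lengths[chrom] / bin_size))
                idx = np.minimum(np.asarray(positions) // bin_size, n_bins_c - 1)
                np.add.at(raw[:, j], offsets[chrom] + idx, 1)
    depth = raw.sum(axis=0).astype(float)
    cpm = raw / depth[None, :] * 1e6
    return BinMatrix(bins, datasets, np.log1p(cpm), raw)


def select_enriched(bins: BinMatrix, q_cut: float = 0.05) -> np.ndarray:
    """Indices of bins significantly enriched in at least one dataset.

    Per dataset, Poisson upper-tail p of the raw bin count against the
    genome-wide mean, BH-adjusted within the dataset.
    """
    keep = np.zeros(len(bins.bins), dtype=bool)
    for j in range(len(bins.datasets)):
        counts = bins.raw[:, j]
        lam = counts.mean()
        p = stats.poisson.sf(counts - 1, lam)
        q = bh_adjust(p)
        keep |= q < q_cut
    return np.flatnonzero(keep)


def cluster_bins(enriched: BinMatrix, n_clusters: int, seed: int = 0) -> list[EpiCluster]:
    """K-means clustering of enriched bins on per-dataset standardized profiles."""
    if n_clusters < 2:
        raise ValueError("n_clusters must be >= 2")
    if n_clusters > len(enriched.bins):
        raise ValueError("more clusters than enriched bins")
    vals = enriched.values
    mu = vals.mean(axis=0, keepdims=True)
    sd = vals.std(axis=0, keepdims=True)
    sd[sd == 0] = 1.0
    z = (vals - mu) / sd
    km = KMeans(n_clusters=n_clusters, init="k-means++", n_init=10, random_state=seed)
    labels = km.fit_predict(z)
    clusters = []
    for c in range(n_clusters):
        members = np.flatnonzero(labels == c)
        if members.size == 0:
            continue
        clusters.append(
            EpiCluster(
                cluster_id=c,
                member_bins=[int(i) for i in members],
                centroid=vals[members].mean(axis=0),
            )
        )
    return clusters


def group_sections(
    clusters: list[EpiCluster], n_sections: int = 6, seed: int = 0
) -> list[EpiCluster]:
    """Group cluster centroids into sections by K-means; numbered by mean signal.

    Section 1 has the highest mean centroid signal. Mutates and returns the
    cluster list with ``section_id`` set.
    """
    if n_sections > len(clusters):
        raise ValueError("more sections than clusters")
    centroids = np.vstack([c.centroid for c in clusters])
    km = KMeans(n_clusters=n_sections, init="k-means++", n_init=10, random_state=seed)
    labels = km.fit_predict(centroids)
    mean_signal = np.array(
        [centroids[labels == s].mean() if (labels == s).any() else -np.inf for s in range(n_sections)]
    )
    order = np.argsort(-mean_signal)  # descending
    renumber = {int(old): rank + 1 for rank, old in enumerate(order)}
    for c, lab in zip(clusters, labels):
        c.section_id = renumber[int(lab)]
    return clusters


def _interval_overlap_bases(iv: GenomicInterval, regions: list[tuple[str, int, int]]) -> int:
    total = 0
    for chrom, start, end in regions:
        if chrom == iv.chrom:
            total += max(0, min(end, iv.end) - max(start, iv.start))
    return total


def annotate_clusters(
    clusters: list[EpiCluster],
    enriched: BinMatrix,
    genes: pd.DataFrame,
    cpg_islands: list[GenomicInterval] | None = None,
    promoter_up: int = 4000,
    promoter_down: int = 1000,
) -> pd.DataFrame:
    """Per-cluster genomic annotation coverage.

    Bases of member bins are split into promoter / gene body / intergenic
    (in that priority, so the three fractions sum to 1), plus CpG-island
    coverage and per-chromosome bin fractions.
    """
    promoters = [
        (row["chrom"], *promoter_window(int(row["tss"]), row["strand"], promoter_up, promoter_down))
        for _, row in genes.iterrows()
    ]
    bodies = [
        (row["chrom"], int(row["start"]), int(row["end"])) for _, row in genes.iterrows()
    ]
    cpg = [(iv.chrom, iv.start, iv.end) for iv in (cpg_islands or [])]
    chroms = sorted({b.chrom for b in enriched.bins})
    rows = []
    for c in clusters:
        total = 0
        prom_b = body_b = cpg_b = 0
        chrom_bins = {ch: 0 for ch in chroms}
        for i in c.member_bins:
            iv = enriched.bins[i]
            size = len(iv)
            total += size
            p = min(_interval_overlap_bases(iv, promoters), size)
            b = min(_interval_overlap_bases(iv, bodies), size - p)
            prom_b += p
            body_b += b
            cpg_b += min(_interval_overlap_bases(iv, cpg), size)
            chrom_bins[iv.chrom] += 1
        n_bins = len(c.member_bins)
        row = {
            "cluster_id": c.cluster_id,
            "section_id": c.section_id,
            "n_bins": n_bins,
            "promoter_frac": prom_b / total,
            "gene_body_frac": body_b / total,
            "intergenic_frac": (total - prom_b - body_b) / total,
            "cpg_frac": cpg_b / total,
        }
        for ch in chroms:
            row[f"{ch}_frac"] = chrom_bins[ch] / n_bins
        rows.append(row)
    return pd.DataFrame(rows)


def map_tss_to_bins(genes: pd.DataFrame, bins: list[GenomicInterval]) -> dict[str, int]:
    """Map each gene to the index of the bin containing its TSS (-1 if none)."""
    out = {}
    for _, row in genes.iterrows():
        tss = int(row["tss"])
        hit = -1
        for i, iv in enumerate(bins):
            if iv.chrom == row["chrom"] and iv.start <= tss < iv.end:
                hit = i
                break
        out[row["gene_id"]] = hit
    return out


def cluster_enrichment(
    clusters: list[EpiCluster],
    differential_bins: set[int],
    universe_size: int,
    fdr_cut: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric enrichment of differential bins per cluster.

    ``differential_bins`` are indices into the enriched-bin universe; the
    result is BH-adjusted across clusters, flagged at fdr < ``fdr_cut``, and
    ranked by overlap count among selected clusters.
    """
    bad = {b for b in differential_bins if not 0 <= b < universe_size}
    if bad:
        raise ValueError(f"differential bins outside universe: {sorted(bad)[:5]}")
    n_diff = len(differential_bins)
    rows = []
    for c in clusters:
        members = set(c.member_bins)
        k = len(members & differential_bins)
        p = hypergeometric_p(k, len(members), n_diff, universe_size)
        rows.append((c.cluster_id, len(members), k, p))
    df = pd.DataFrame(rows, columns=["cluster_id", "cluster_size", "overlap", "p"])
    df["fdr"] = bh_adjust(df["p"].to_numpy())
    df["selected"] = df["fdr"] < fdr_cut
    df = df.sort_values(
        ["selected", "overlap", "cluster_id"], ascending=[False, False, True]
    ).reset_index(drop=True)
    df["rank"] = np.where(df["selected"], np.arange(1, len(df) + 1), 0)
    return df
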