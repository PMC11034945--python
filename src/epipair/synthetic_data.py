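"""Synthetic matched-pair study generator with planted ground truth.

Produces a toy genome (genes, TF motifs, a true regulatory network, distal
enhancers with loops), matched case/control cohorts split into
antipsychotic-free (AF) and antipsychotic-treated (AT) groups, negative-
binomial count matrices per assay and cell fraction with planted
AF-reversed / AT-induced / shared / age-correlated effects, and read-level
tag sets for QC metrics. All generators are pure functions of their inputs
and the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from epipair.io_cli.formats import GenomicInterval, Peak, SampleMeta, ValidationError
from epipair.peaks_counts import CountMatrix

BASES = np.frombuffer(b"ACGT", dtype="S1")

EFFECT_CLASSES = ("AF_reversed", "AT_induced", "shared", "age_correlated", "null")

_GENE_SPACING = 10_000
_MOTIF_SLOT = 12
_MAX_REGULATORS = 10  # motif slots available within one summit window


@dataclass
class GenomeModel:
    chrom_lengths: dict[str, int]
    genes: pd.DataFrame  # gene_id, chrom, tss, strand, start, end
    tf_ids: list[str]
    pwms: dict[str, np.ndarray]
    true_network: list[tuple[str, str]]
    loop_table: list[tuple[GenomicInterval, GenomicInterval]]
    enhancers: dict[str, GenomicInterval]  # gene_id -> distal enhancer
    sequences: dict[str, str]

    def promoter_peak(self, gene_id: str) -> Peak:
        row = self.genes.set_index("gene_id").loc[gene_id]
        tss = int(row["tss"])
        return Peak(
            GenomicInterval(row["chrom"], max(tss - 500, 0), tss + 500),
            summit=tss, score=100.0, qvalue=1e-6,
        )

    def enhancer_peak(self, gene_id: str) -> Peak:
        iv = self.enhancers[gene_id]
        return Peak(iv, summit=iv.midpoint, score=80.0, qvalue=1e-6)

    def chip_features(self, assay: str) -> list[tuple[str, Peak]]:
        """Ordered (feature_id, peak) list backing a ChIP count matrix."""
        feats = [(f"prom:{g}", self.promoter_peak(g)) for g in self.genes["gene_id"]]
        if assay == "H3K27ac":
            feats += [(f"enh:{g}", self.enhancer_peak(g)) for g in sorted(self.enhancers)]
        return feats


@dataclass(frozen=True)
class EffectTruth:
    feature_id: str
    feature_kind: str  # enhancer | promoter | gene | TF
    effect_class: str
    log2_effect: float
    age_slope: float

    def __post_init__(self) -> None:
        if self.effect_class not in EFFECT_CLASSES:
            raise ValueError(f"unknown effect class {self.effect_class}")
        if self.effect_class == "null" and (self.log2_effect != 0 or self.age_slope != 0):
            raise ValueError("null features must have zero effects")


@dataclass
class TagSet:
    """Strand-specific 5' tag positions, sorted per chromosome."""

    plus: dict[str, np.ndarray]
    minus: dict[str, np.ndarray]
    read_length: int
    fragment_length: int

    @property
    def n_tags(self) -> int:
        return sum(len(v) for v in self.plus.values()) + sum(
            len(v) for v in self.minus.values()
        )


@dataclass
class SimParams:
    dispersion: float = 0.1
    meanlog: float = 4.0
    sdlog: float = 1.0
    log2_effect: float = 1.0
    age_slope: float = 0.05  # log2 per year on the case-control difference
    n_af_reversed: int = 10
    n_at_induced: int = 10
    n_shared: int = 10
    n_age: int = 10
    age_min: float = 20.0
    age_max: float = 80.0
    n_replicates_chip: int = 2
    depth_sd: float = 0.2  # lognormal sd of per-sample depth factors

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


@dataclass
class TagParams:
    n_fragments: int = 20_000
    fragment_length: int = 200
    read_length: int = 36
    in_peak_frac: float = 0.5
    dup_rate: float = 0.0


def make_genome_model(n_chrom: int, n_genes: int, n_tfs: int, seed: int) -> GenomeModel:
    """Build a deterministic toy genome with planted regulatory structure.

    Every TF gets a high-information PWM (length 6-12) and at least one
    regulatee; roughly 20% of genes get a loop-linked distal enhancer. The
    consensus of each regulating TF is written into the target's promoter
    (or linked enhancer) sequence so that motif scanning can recover the
    planted network.
    """
    if n_tfs > n_genes:
        raise ValueError(f"n_tfs={n_tfs} > n_genes={n_genes}")
    if n_genes < 10:
        raise ValueError("need at least 10 genes")
    rng = np.random.default_rng(seed)

    per_chrom = int(np.ceil(n_genes / n_chrom))
    chrom_lengths = {}
    rows = []
    gi = 0
    for ci in range(n_chrom):
        chrom = f"chr{ci + 1}"
        n_here = min(per_chrom, n_genes - gi)
        chrom_lengths[chrom] = (n_here + 1) * _GENE_SPACING + 60_000
        for k in range(n_here):
            tss = (k + 1) * _GENE_SPACING
            strand = "+" if rng.random() < 0.5 else "-"
            gene_id = f"G{gi:04d}"
            start, end = (tss, tss + 2000) if strand == "+" else (max(tss - 2000, 0), tss)
            rows.append((gene_id, chrom, tss, strand, start, end))
            gi += 1
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand", "start", "end"])
    tf_ids = list(genes["gene_id"].iloc[:n_tfs])

    pwms: dict[str, np.ndarray] = {}
    consensus: dict[str, str] = {}
    for tf in tf_ids:
        # length >= 8 so a perfect consensus clears a 1e-4 scan threshold
        # (a 6-mer's best attainable p is 4^-6 ~ 2.4e-4)
        length = int(rng.integers(8, 13))
        cons = rng.integers(0, 4, size=length)
        mat = np.full((length, 4), 0.02)
        mat[np.arange(length), cons] = 0.94
        pwms[tf] = mat
        consensus[tf] = "".join("ACGT"[b] for b in cons)

    # ~20% of genes get a distal enhancer linked by a loop to the promoter
    enhancers: dict[str, GenomicInterval] = {}
    loops = []
    for _, row in genes.iterrows():
        if rng.random() < 0.2:
            offset = int(rng.integers(20_000, 50_000)) * (1 if rng.random() < 0.5 else -1)
            center = int(row["tss"]) + offset
            center = min(max(center, 600), chrom_lengths[row["chrom"]] - 600)
            enh = GenomicInterval(row["chrom"], center - 500, center + 500)
            prom = GenomicInterval(
                row["chrom"], max(int(row["tss"]) - 1000, 0), int(row["tss"]) + 1000
            )
            if not enh.overlaps(prom):
                enhancers[row["gene_id"]] = enh
                loops.append((enh, prom))

    # planted network: every TF regulates >=1 gene; in-degree capped so all
    # planted motifs fit inside one summit window
    all_genes = list(genes["gene_id"])
    in_degree = {g: 0 for g in all_genes}
    true_network: list[tuple[str, str]] = []
    for tf in tf_ids:
        out_deg = 1 + int(rng.poisson(3))
        candidates = [g for g in all_genes if g != tf and in_degree[g] < _MAX_REGULATORS]
        targets = rng.choice(
            candidates, size=min(out_deg, len(candidates)), replace=False
        )
        for g in targets:
            true_network.append((tf, str(g)))
            in_degree[str(g)] += 1

    sequences = {
        c: rng.integers(0, 4, size=length) for c, length in chrom_lengths.items()
    }
    slot_used: dict[str, int] = {}
    gene_ix = genes.set_index("gene_id")
    for tf, target in true_network:
        use_enh = target in enhancers and rng.random() < 0.3
        if use_enh:
            anchor_chrom = enhancers[target].chrom
            anchor = enhancers[target].midpoint
            key = f"enh:{target}"
        else:
            anchor_chrom = gene_ix.loc[target, "chrom"]
            anchor = int(gene_ix.loc[target, "tss"])
            key = f"prom:{target}"
        slot = slot_used.get(key, 0)
        slot_used[key] = slot + 1
        pos = anchor - 70 + slot * _MOTIF_SLOT
        cons = consensus[tf]
        seq = sequences[anchor_chrom]
        if 0 <= pos and pos + len(cons) <= len(seq):
            seq[pos : pos + len(cons)] = ["ACGT".index(b) for b in cons]

    seq_str = {c: "".join("ACGT"[b] for b in arr) for c, arr in sequences.items()}
    return GenomeModel(
        chrom_lengths=chrom_lengths,
        genes=genes,
        tf_ids=tf_ids,
        pwms=pwms,
        true_network=true_network,
        loop_table=loops,
        enhancers=enhancers,
        sequences=seq_str,
    )


def _assign_effects(
    feature_ids: list[str],
    kinds: dict[str, str],
    params: SimParams,
    rng: np.random.Generator,
) -> list[EffectTruth]:
    n_planted = params.n_af_reversed + params.n_at_induced + params.n_shared + params.n_age
    if n_planted > len(feature_ids):
        raise ValueError("more planted effects than features")
    chosen = rng.choice(len(feature_ids), size=n_planted, replace=False)
    classes = (
        ["AF_reversed"] * params.n_af_reversed
        + ["AT_induced"] * params.n_at_induced
        + ["shared"] * params.n_shared
        + ["age_correlated"] * params.n_age
    )
    truth = {}
    for idx, cls in zip(chosen, classes):
        fid = feature_ids[idx]
        sign = 1.0 if rng.random() < 0.5 else -1.0
        truth[fid] = EffectTruth(
            feature_id=fid,
            feature_kind=kinds[fid],
            effect_class=cls,
            log2_effect=0.0 if cls == "age_correlated" else sign * params.log2_effect,
            age_slope=sign * params.age_slope if cls == "age_correlated" else 0.0,
        )
    out = []
    for fid in feature_ids:
        out.append(
            truth.get(
                fid, EffectTruth(fid, kinds[fid], "null", 0.0, 0.0)
            )
        )
    return out


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
    return rng.poisson(lam)


def simulate_cohort(
    model: GenomeModel,
    n_pairs_af: int,
    n_pairs_at: int,
    params: SimParams | None = None,
    seed: int = 0,
):
    """Simulate the matched-pair study design.

    Returns (samples, matrices, truth) where ``matrices`` maps
    (assay, fraction) -> CountMatrix. Case means are shifted by the planted
    effect classes according to cohort; age-correlated features shift the
    case-control log difference linearly with the pair's shared age.
    """
    params = params or SimParams()
    if n_pairs_af + n_pairs_at < 2:
        raise ValueError("need at least 2 pairs in total")
    rng = np.random.default_rng(seed)
    age_mid = 0.5 * (params.age_min + params.age_max)

    pairs = []
    for i in range(n_pairs_af + n_pairs_at):
        cohort = "AF" if i < n_pairs_af else "AT"
        pairs.append(
            {
                "pair_id": f"P{i:02d}",
                "cohort": cohort,
                "age": float(rng.uniform(params.age_min, params.age_max)),
                "sex": "M" if rng.random() < 0.5 else "F",
            }
        )

    samples: list[SampleMeta] = []
    for p in pairs:
        for group, tag in (("case", "S"), ("control", "C")):
            subject = f"{p['pair_id']}{tag}"
            pmd = float(rng.uniform(5, 40))
            for fraction in ("NeuNpos", "NeuNneg"):
                for assay in ("RNA", "H3K27ac", "H3K4me3"):
                    n_rep = 1 if assay == "RNA" else params.n_replicates_chip
                    for rep in range(1, n_rep + 1):
                        samples.append(
                            SampleMeta(
                                sample_id=f"{subject}_{fraction}_{assay}_r{rep}",
                                subject_id=subject,
                                pair_id=p["pair_id"],
                                group=group,
                                cohort=p["cohort"],
                                fraction=fraction,
                                assay=assay,
                                replicate=rep,
                                sex=p["sex"],
                                age=p["age"],
                                pmd=pmd,
                            )
                        )

    # effect truth: planted on RNA genes and on H3K27ac peak features
    gene_ids = list(model.genes["gene_id"])
    gene_kinds = {g: ("TF" if g in set(model.tf_ids) else "gene") for g in gene_ids}
    rna_truth = _assign_effects(gene_ids, gene_kinds, params, rng)
    k27_ids = [fid for fid, _ in model.chip_features("H3K27ac")]
    k27_kinds = {fid: ("promoter" if fid.startswith("prom:") else "enhancer") for fid in k27_ids}
    k27_truth = _assign_effects(k27_ids, k27_kinds, params, rng)
    k4_ids = [fid for fid, _ in model.chip_features("H3K4me3")]
    truth = rna_truth + k27_truth

    truth_by_assay = {
        "RNA": {t.feature_id: t for t in rna_truth},
        "H3K27ac": {t.feature_id: t for t in k27_truth},
        "H3K4me3": {fid: EffectTruth(fid, "promoter", "null", 0.0, 0.0) for fid in k4_ids},
    }
    feature_ids_by_assay = {"RNA": gene_ids, "H3K27ac": k27_ids, "H3K4me3": k4_ids}

    pair_info = {p["pair_id"]: p for p in pairs}
    matrices: dict[tuple[str, str], CountMatrix] = {}
    for assay in ("RNA", "H3K27ac", "H3K4me3"):
        fids = feature_ids_by_assay[assay]
        t_map = truth_by_assay[assay]
        base_log_mu = rng.normal(params.meanlog, params.sdlog, size=len(fids))
        for fraction in ("NeuNpos", "NeuNneg"):
            cols = {}
            lib_sizes = {}
            members = [s for s in samples if s.assay == assay and s.fraction == fraction]
            for s in members:
                depth = float(np.exp(rng.normal(0.0, params.depth_sd)))
                log_mu = base_log_mu + np.log(depth)
                if s.group == "case":
                    p = pair_info[s.pair_id]
                    shift = np.zeros(len(fids))
                    for i, fid in enumerate(fids):
                        t = t_map[fid]
                        active = (
                            (t.effect_class == "AF_reversed" and p["cohort"] == "AF")
                            or (t.effect_class == "AT_induced" and p["cohort"] == "AT")
                            or t.effect_class == "shared"
                        )
                        if active:
                            shift[i] = t.log2_effect
                        elif t.effect_class == "age_correlated":
                            shift[i] = t.age_slope * (p["age"] - age_mid)
                    log_mu = log_mu + np.log(2.0) * shift
                mu = np.exp(log_mu)
                counts = _nb_draw(rng, mu, params.dispersion)
                cols[s.sample_id] = counts
                # library size = in-feature reads plus a depth-proportional
                # background component, so offsets track true depth
                background = int(round(depth * 3.0 * float(np.exp(base_log_mu).sum())))
                lib_sizes[s.sample_id] = int(counts.sum()) + background
            sample_ids = sorted(cols)
            matrices[(assay, fraction)] = CountMatrix(
                list(fids),
                sample_ids,
                np.column_stack([cols[sid] for sid in sample_ids]),
                lib_sizes,
            )
    return samples, matrices, truth


def simulate_tags(
    model: GenomeModel,
    enriched_regions: list[GenomicInterval],
    params: TagParams | None = None,
    seed: int = 0,
) -> TagSet:
    """Simulate strand-specific 5' read tags from fixed-length fragments.

    A fraction ``in_peak_frac`` of fragments start inside enriched regions,
    the rest are uniform background; duplicate tags are injected at
    ``dup_rate``. Plus-strand tags sit at fragment starts, minus-strand tags
    at fragment end - 1. Fragment starts are unique before duplication, so
    dup_rate=0 forces PBC = 1.
    """
    params = params or TagParams()
    if params.fragment_length <= params.read_length:
        raise ValueError("fragment_length must exceed read_length")
    if params.in_peak_frac > 0 and not enriched_regions:
        raise ValueError("in_peak_frac > 0 requires enriched regions")
    rng = np.random.default_rng(seed)
    chroms = sorted(model.chrom_lengths)
    lengths = np.array([model.chrom_lengths[c] for c in chroms], float)
    L = params.fragment_length

    n_in = int(round(params.n_fragments * params.in_peak_frac))
    n_bg = params.n_fragments - n_in
    used: set[tuple[str, int]] = set()
    frags: list[tuple[str, int]] = []

    region_lens = np.array([len(r) for r in enriched_regions], float) if enriched_regions else None

    def draw_in_peak() -> tuple[str, int]:
        r = enriched_regions[rng.choice(len(enriched_regions), p=region_lens / region_lens.sum())]
        lo = max(r.start - L // 2, 0)
        hi = max(min(r.end - L // 2, model.chrom_lengths[r.chrom] - L), lo + 1)
        return r.chrom, int(rng.integers(lo, hi))

    def draw_background() -> tuple[str, int]:
        ci = rng.choice(len(chroms), p=lengths / lengths.sum())
        return chroms[ci], int(rng.integers(0, model.chrom_lengths[chroms[ci]] - L))

    for n, draw in ((n_in, draw_in_peak), (n_bg, draw_background)):
        for _ in range(n):
            for _attempt in range(100):
                frag = draw()
                if frag not in used:
                    used.add(frag)
                    frags.append(frag)
                    break

    final = list(frags)
    for frag in frags:
        if params.dup_rate > 0 and rng.random() < params.dup_rate:
            final.append(frag)

    plus: dict[str, list[int]] = {c: [] for c in chroms}
    minus: dict[str, list[int]] = {c: [] for c in chroms}
    for chrom, start in final:
        plus[chrom].append(start)
        minus[chrom].append(start + L - 1)
    return TagSet(
        plus={c: np.sort(np.array(v, dtype=int)) for c, v in plus.items()},
        minus={c: np.sort(np.array(v, dtype=int)) for c, v in minus.items()},
        read_length=params.read_length,
        fragment_length=params.fragment_length,
    )


def truth_report(
    truth: list[EffectTruth], called: dict[str, set[str]]
) -> dict[str, dict[str, float]]:
    """Recovery metrics per effect class: sensitivity and false-call rate.

    ``called`` maps effect class -> set of feature ids the pipeline assigned
    to that class. The false rate is the fraction of truly-null features
    called into the class.
    """
    known = {t.feature_id for t in truth}
    for cls, ids in called.items():
        unknown = set(ids) - known
        if unknown:
            raise ValidationError(f"called features not in truth: {sorted(unknown)[:5]}")
    by_class: dict[str, set[str]] = {}
    for t in truth:
        by_class.setdefault(t.effect_class, set()).add(t.feature_id)
    null_ids = by_class.get("null", set())
    report = {}
    for cls, called_ids in called.items():
        planted = by_class.get(cls, set())
        sens = len(called_ids & planted) / len(planted) if planted else float("nan")
        false_rate = len(set(called_ids) & null_ids) / len(null_ids) if null_ids else 0.0
        report[cls] = {"sensitivity": sens, "false_rate": false_rate}
    return report


def truth_frame(truth: list[EffectTruth]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [t.feature_id for t in truth],
            "feature_kind": [t.feature_kind for t in truth],
            "effect_class": [t.effect_class for t in truth],
            "log2_effect": [t.log2_effect for t in truth],
            "age_slope": [t.age_slope for t in truth],
        }
    )
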