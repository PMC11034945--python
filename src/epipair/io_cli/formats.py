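"""Domain types and plain-text genomic file formats.

Coordinates are 0-based half-open everywhere internally; any 1-based input
is converted at the boundary by its reader.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Malformed input file (bad columns, bad coordinates)."""


class ValidationError(ValueError):
    """Well-formed input that violates a domain invariant."""


GROUPS = ("case", "control")
COHORTS = ("AF", "AT")
FRACTIONS = ("NeuNpos", "NeuNneg")
ASSAYS = ("H3K27ac", "H3K4me3", "RNA")
SEXES = ("M", "F")

SAMPLE_SHEET_COLUMNS = [
    "sample_id",
    "subject_id",
    "pair_id",
    "group",
    "cohort",
    "fraction",
    "assay",
    "replicate",
    "sex",
    "age",
    "pmd",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise FormatError(f"negative start {self.start}")
        if self.end <= self.start:
            raise FormatError(f"empty/inverted interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise FormatError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class Peak:
    """A called peak: interval + summit position + score + q-value."""

    interval: GenomicInterval
    summit: int
    score: float = 0.0
    qvalue: float = 1.0

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValidationError(
                f"summit {self.summit} outside [{self.interval.start}, {self.interval.end})"
            )


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    subject_id: str
    pair_id: str
    group: str
    cohort: str
    fraction: str
    assay: str
    replicate: int
    sex: str
    age: float
    pmd: float

    def __post_init__(self) -> None:
        for name, value, allowed in [
            ("group", self.group, GROUPS),
            ("cohort", self.cohort, COHORTS),
            ("fraction", self.fraction, FRACTIONS),
            ("assay", self.assay, ASSAYS),
            ("sex", self.sex, SEXES),
        ]:
            if value not in allowed:
                raise ValidationError(f"{name}={value!r} not in {allowed}")
        if self.replicate < 1:
            raise ValidationError(f"replicate {self.replicate} < 1")
        if self.age < 0:
            raise ValidationError(f"age {self.age} < 0")
        if self.pmd < 0:
            raise ValidationError(f"pmd {self.pmd} < 0")


def validate_pairing(samples: Iterable[SampleMeta]) -> None:
    """Enforce the matched-pair invariants across a sample sheet.

    Every pair_id maps to exactly one case and one control subject, cohort
    is constant within a pair, and (subject_id, fraction, assay, replicate)
    is unique.
    """
    samples = list(samples)
    seen = set()
    for s in samples:
        key = (s.subject_id, s.fraction, s.assay, s.replicate)
        if key in seen:
            raise ValidationError(f"duplicate library {key}")
        seen.add(key)
    by_pair: dict[str, list[SampleMeta]] = {}
    for s in samples:
        by_pair.setdefault(s.pair_id, []).append(s)
    for pair_id, members in by_pair.items():
        cohorts = {m.cohort for m in members}
        if len(cohorts) != 1:
            raise ValidationError(f"pair {pair_id} spans cohorts {sorted(cohorts)}")
        case_subjects = {m.subject_id for m in members if m.group == "case"}
        control_subjects = {m.subject_id for m in members if m.group == "control"}
        if len(case_subjects) != 1 or len(control_subjects) != 1:
            raise ValidationError(
                f"pair {pair_id} has {len(case_subjects)} case and "
                f"{len(control_subjects)} control subjects (need exactly 1 each)"
            )


def read_sample_sheet(path: str | Path) -> list[SampleMeta]:
    """Parse and validate a CSV sample sheet."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in header]
        if missing:
            raise FormatError(f"sample sheet missing columns: {missing}")
        records = []
        for row in reader:
            try:
                records.append(
                    SampleMeta(
                        sample_id=row["sample_id"],
                        subject_id=row["subject_id"],
                        pair_id=row["pair_id"],
                        group=row["group"],
                        cohort=row["cohort"],
                        fraction=row["fraction"],
                        assay=row["assay"],
                        replicate=int(row["replicate"]),
                        sex=row["sex"],
                        age=float(row["age"]),
                        pmd=float(row["pmd"]),
                    )
                )
            except (KeyError, ValueError) as exc:
                if isinstance(exc, ValidationError):
                    raise
                raise ValidationError(f"bad sample-sheet row {row}: {exc}") from exc
    validate_pairing(records)
    return records


def write_sample_sheet(samples: Iterable[SampleMeta], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(SAMPLE_SHEET_COLUMNS)
        for s in samples:
            writer.writerow([getattr(s, c) for c in SAMPLE_SHEET_COLUMNS])


def _parse_int(token: str, what: str) -> int:
    try:
        return int(token)
    except ValueError as exc:
        raise FormatError(f"non-integer {what}: {token!r}") from exc


def read_intervals(path: str | Path, format: str = "bed"):
    """Read genomic intervals from whitespace-delimited text.

    format="bed" -> list[GenomicInterval]; columns 4-6 (name, score, strand)
    optional. format="narrowPeak" -> list[Peak]; ENCODE 10-column, where a
    summit offset of -1 maps to the interval midpoint.
    format="bedpe_tsv" -> use :func:`read_loop_table`.
    """
    if format == "bedpe_tsv":
        return read_loop_table(path)
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise FormatError(f"short line: {line!r}")
            chrom = fields[0]
            start = _parse_int(fields[1], "start")
            end = _parse_int(fields[2], "end")
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "."
            iv = GenomicInterval(chrom, start, end, strand)
            if format == "bed":
                out.append(iv)
            elif format == "narrowPeak":
                if len(fields) < 10:
                    raise FormatError(f"narrowPeak needs 10 columns: {line!r}")
                score = float(fields[6])
                qval = 10 ** -float(fields[8]) if float(fields[8]) >= 0 else 1.0
                offset = _parse_int(fields[9], "summit offset")
                summit = iv.midpoint if offset == -1 else start + offset
                out.append(Peak(iv, summit, score=score, qvalue=min(qval, 1.0)))
            else:
                raise ValueError(f"unknown format {format!r}")
    return out


def write_intervals(items, path: str | Path, format: str = "bed") -> None:
    """Write BED3/BED6 intervals or 10-column narrowPeak records."""
    with open(path, "w") as fh:
        for i, item in enumerate(items):
            if format == "bed":
                iv = item
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")
            elif format == "narrowPeak":
                pk: Peak = item
                iv = pk.interval
                neglog_q = -np.log10(max(pk.qvalue, 1e-300))
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\tpeak_{i}\t"
                    f"{min(int(round(pk.score)), 1000)}\t{iv.strand}\t"
                    f"{pk.score:.6g}\t-1\t{neglog_q:.6g}\t{pk.summit - iv.start}\n"
                )
            else:
                raise ValueError(f"unknown format {format!r}")


def read_loop_table(path: str | Path) -> list[tuple[GenomicInterval, GenomicInterval]]:
    """BEDPE-style loop table: chrom1 start1 end1 chrom2 start2 end2."""
    loops = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split()
            if len(f) < 6:
                raise FormatError(f"loop table needs 6 columns: {line!r}")
            a = GenomicInterval(f[0], _parse_int(f[1], "start1"), _parse_int(f[2], "end1"))
            b = GenomicInterval(f[3], _parse_int(f[4], "start2"), _parse_int(f[5], "end2"))
            loops.append((a, b))
    return loops


def write_loop_table(loops, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in loops:
            fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}\n")


def read_count_matrix(path: str | Path) -> pd.DataFrame:
    """TSV count matrix: feature_id column + one column per sample_id."""
    df = pd.read_csv(path, sep="\t")
    if "feature_id" not in df.columns:
        raise FormatError("count matrix missing 'feature_id' column")
    return df.set_index("feature_id")


def write_count_matrix(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")


def write_tags(tagset, path: str | Path) -> None:
    """Write 5' tag positions as BED-like lines (chrom, pos, pos+1, ., 0, strand)."""
    with open(path, "w") as fh:
        fh.write(f"#read_length={tagset.read_length}\tfragment_length={tagset.fragment_length}\n")
        for strand, d in (("+", tagset.plus), ("-", tagset.minus)):
            for chrom in sorted(d):
                for pos in d[chrom]:
                    fh.write(f"{chrom}\t{pos}\t{pos + 1}\t.\t0\t{strand}\n")


def read_tags(path: str | Path, read_length: int = 36, fragment_length: int = 200):
    """Read BED-like 5' tag positions back into a TagSet."""
    from epipair.synthetic_data import TagSet

    plus: dict[str, list[int]] = {}
    minus: dict[str, list[int]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                for tok in line[1:].split():
                    k, _, v = tok.partition("=")
                    if k == "read_length":
                        read_length = int(v)
                    elif k == "fragment_length":
                        fragment_length = int(v)
                continue
            f = line.split()
            if len(f) < 6:
                raise FormatError(f"tag line needs 6 columns: {line!r}")
            target = plus if f[5] == "+" else minus
            target.setdefault(f[0], []).append(_parse_int(f[1], "position"))
    return TagSet(
        plus={c: np.sort(np.array(v, int)) for c, v in plus.items()},
        minus={c: np.sort(np.array(v, int)) for c, v in minus.items()},
        read_length=read_length,
        fragment_length=fragment_length,
    )


# --- MEME-like PWM text blocks ------------------------------------------------

_PWM_ALPHABET = "ACGT"


def _is_float(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


def write_pwms(pwms: dict[str, np.ndarray], path: str | Path,
               background: np.ndarray | None = None) -> None:
    """Write motif probability matrices as MEME-like text blocks."""
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {p:.5f}" for b, p in zip(_PWM_ALPHABET, bg)) + "\n\n")
        for tf_id in sorted(pwms):
            mat = np.asarray(pwms[tf_id], float)
            fh.write(f"MOTIF {tf_id}\n")
            fh.write(
                f"letter-probability matrix: alphet= 4 w= {mat.shape[0]} nsites= 20 E= 0\n"
                .replace("alphet", "alength")
            )
            for row in mat:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def read_pwms(path: str | Path) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Read MEME-like motif blocks; returns ({tf_id: matrix}, background)."""
    pwms: dict[str, np.ndarray] = {}
    background = np.full(4, 0.25)
    current: str | None = None
    rows: list[list[float]] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            toks = lines[i + 1].split()
            background = np.array([float(toks[j]) for j in (1, 3, 5, 7)])
            i += 2
            continue
        if line.startswith("MOTIF"):
            if current is not None:
                pwms[current] = np.array(rows)
            current = line.split()[1]
            rows = []
        elif current is not None and line:
            parts = line.split()
            if len(parts) == 4 and all(_is_float(p) for p in parts):
                rows.append([float(x) for x in parts])
        i += 1
    if current is not None and rows:
        pwms[current] = np.array(rows)
    for tf_id, mat in pwms.items():
        if not np.allclose(mat.sum(axis=1), 1.0, atol=1e-4):
            raise FormatError(f"PWM {tf_id} rows do not sum to 1")
    return pwms, background
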