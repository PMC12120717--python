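"""Genomic data model and tabular readers/writers.

Coordinate conventions
----------------------
Intervals follow the BED convention: 0-based, half-open ``[start, end)``.
CpG positions are 1-based points (CpG-report style).  A CpG at 1-based
position ``p`` lies in interval ``[s, e)`` iff ``s <= p - 1 < e``.

All tables are tab-separated with a header row (gene models are plain
BED6 without a header).  Lines starting with ``#`` are treated as
comments.  Gzip-compressed files (``.gz``) are read and written
transparently.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

STRANDS = ("+", "-", ".")


def _open_text(path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValidationError("interval chrom must be non-empty")
        if self.start < 0:
            raise ValidationError(f"interval start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValidationError(
                f"interval end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"unknown strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains_cpg(self, pos: int) -> bool:
        """True iff the 1-based CpG position ``pos`` lies in this interval."""
        return self.start <= pos - 1 < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene body interval with a strand-aware TSS.

    The TSS is the 0-based coordinate of the transcription start base:
    ``interval.start`` on the + strand, ``interval.end - 1`` on the −
    strand (unstranded genes are treated as +).
    """

    gene_id: str
    interval: GenomicInterval

    @property
    def tss(self) -> int:
        if self.interval.strand == "-":
            return self.interval.end - 1
        return self.interval.start


@dataclass
class MethylomeMatrix:
    """Per-CpG methylated/total read counts across samples.

    ``sites`` holds the sorted (chrom, pos) index; ``meth`` and ``total``
    are (n_sites, n_samples) integer arrays aligned to ``samples``.
    A missing per-sample observation is encoded as ``total == 0``
    (its beta value is NaN, never imputed).
    """

    sites: pd.DataFrame  # columns: chrom, pos (1-based)
    meth: np.ndarray
    total: np.ndarray
    samples: list[str]
    sample_meta: pd.DataFrame  # index: sample; columns: condition, pair_id

    def __post_init__(self):
        n, s = self.meth.shape
        if self.total.shape != (n, s) or len(self.sites) != n or len(self.samples) != s:
            raise ValidationError("methylome component shapes disagree")
        if np.any(self.meth < 0) or np.any(self.total < 0):
            raise ValidationError("negative counts in methylome")
        if np.any(self.meth > self.total):
            raise ValidationError("methylated_count exceeds total_count")
        missing = set(self.samples) - set(self.sample_meta.index)
        if missing:
            raise ValidationError(f"samples missing from sample_meta: {sorted(missing)}")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def beta(self) -> np.ndarray:
        """Methylation level per site/sample; NaN where total == 0."""
        with np.errstate(divide="ignore", invalid="ignore"):
            b = self.meth / np.where(self.total == 0, np.nan, self.total)
        return b

    def samples_for(self, condition: str) -> list[str]:
        meta = self.sample_meta.loc[self.samples]
        return [s for s in self.samples if meta.loc[s, "condition"] == condition]

    def sample_index(self, names: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[s] for s in names], dtype=int)
        except KeyError as e:
            raise ValidationError(f"unknown sample {e.args[0]!r}") from None

    def pairs(self) -> list[tuple[str, str]]:
        """(tumor, normal) sample-name pairs sharing a pair_id."""
        meta = self.sample_meta.loc[self.samples]
        out = []
        for pid, grp in meta.groupby("pair_id", sort=True):
            t = grp.index[grp["condition"] == "tumor"]
            n = grp.index[grp["condition"] == "normal"]
            if len(t) == 1 and len(n) == 1:
                out.append((t[0], n[0]))
        return out


@dataclass
class SurvivalTable:
    """Per-sample follow-up time (months) and event indicator (1 = death)."""

    data: pd.DataFrame  # index: sample; columns: time, event

    def __post_init__(self):
        d = self.data
        if d.index.duplicated().any():
            dup = d.index[d.index.duplicated()][0]
            raise ValidationError(f"duplicate sample id {dup!r} in survival table")
        if (d["time"] <= 0).any():
            raise ValidationError("survival time must be positive")
        if not d["event"].isin([0, 1]).all():
            raise ValidationError("survival event must be 0 or 1")

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy(float)

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy(int)

    def subset(self, samples: Sequence[str]) -> "SurvivalTable":
        return SurvivalTable(self.data.loc[list(samples)])


@dataclass
class ExpressionMatrix:
    """Gene × sample count matrix with tumor/normal pairing metadata."""

    counts: pd.DataFrame  # genes rows × sample columns, non-negative ints
    sample_meta: pd.DataFrame  # index: sample; columns: condition, pair_id

    def __post_init__(self):
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("expression counts must be non-negative")
        missing = set(self.counts.columns) - set(self.sample_meta.index)
        if missing:
            raise ValidationError(f"samples missing from sample_meta: {sorted(missing)}")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def samples_for(self, condition: str) -> list[str]:
        meta = self.sample_meta.loc[self.samples]
        return [s for s in self.samples if meta.loc[s, "condition"] == condition]

    def pairs(self) -> list[tuple[str, str]]:
        meta = self.sample_meta.loc[self.samples]
        out = []
        for pid, grp in meta.groupby("pair_id", sort=True):
            t = grp.index[grp["condition"] == "tumor"]
            n = grp.index[grp["condition"] == "normal"]
            if len(t) == 1 and len(n) == 1:
                out.append((t[0], n[0]))
        return out


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_tsv(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kw)


def read_sample_meta(path) -> pd.DataFrame:
    """Read sample metadata: columns sample, condition, pair_id."""
    df = _read_tsv(path, dtype={"sample": str, "condition": str, "pair_id": str})
    for col in ("sample", "condition", "pair_id"):
        if col not in df.columns:
            raise ParseError(f"sample metadata missing column {col!r}")
    bad = ~df["condition"].isin(["tumor", "normal"])
    if bad.any():
        raise ValidationError(
            f"unknown condition {df.loc[bad, 'condition'].iloc[0]!r} in sample metadata"
        )
    return df.set_index("sample")


def write_sample_meta(meta: pd.DataFrame, path) -> None:
    meta.reset_index().rename(columns={"index": "sample"}).to_csv(
        path, sep="\t", index=False
    )


def read_methylome(path, sample_meta: pd.DataFrame | str | Path) -> MethylomeMatrix:
    """Read a per-CpG count table.

    Expected header: ``chrom  pos  <S>_meth  <S>_total ...`` with one
    meth/total column pair per sample.  Duplicate (chrom, pos) rows and
    rows with meth > total are rejected.
    """
    if not isinstance(sample_meta, pd.DataFrame):
        sample_meta = read_sample_meta(sample_meta)
    df = _read_tsv(path, dtype={"chrom": str})
    if list(df.columns[:2]) != ["chrom", "pos"]:
        raise ParseError(f"{path}: first columns must be chrom, pos")
    count_cols = list(df.columns[2:])
    samples = []
    for col in count_cols:
        if col.endswith("_meth"):
            s = col[: -len("_meth")]
            if f"{s}_total" not in df.columns:
                raise ParseError(f"{path}: column {s}_total missing")
            samples.append(s)
        elif not col.endswith("_total"):
            raise ParseError(f"{path}: unrecognized column {col!r}")
    # numeric validation with line numbers (data line 1 = first non-header row)
    for col in ["pos"] + count_cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise ParseError(f"{path}: malformed value in column {col!r} at line {line}")
        if coerced.isna().any():
            line = int(np.flatnonzero(coerced.isna().to_numpy())[0]) + 2
            raise ParseError(f"{path}: missing value in column {col!r} at line {line}")
        df[col] = coerced.astype(np.int64)
    if df.duplicated(subset=["chrom", "pos"]).any():
        dup = df[df.duplicated(subset=["chrom", "pos"])].iloc[0]
        raise ValidationError(f"duplicate site {dup['chrom']}:{dup['pos']}")
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    meth = df[[f"{s}_meth" for s in samples]].to_numpy()
    total = df[[f"{s}_total" for s in samples]].to_numpy()
    sites = df[["chrom", "pos"]].copy()
    return MethylomeMatrix(sites, meth, total, samples, sample_meta)


def write_methylome(m: MethylomeMatrix, path, header_comment: str | None = None) -> None:
    cols = {"chrom": m.sites["chrom"], "pos": m.sites["pos"]}
    for i, s in enumerate(m.samples):
        cols[f"{s}_meth"] = m.meth[:, i]
        cols[f"{s}_total"] = m.total[:, i]
    _write_with_comment(pd.DataFrame(cols), path, header_comment)


def read_gene_models(path) -> list[GeneModel]:
    """Read BED6 gene models: chrom, start, end, gene_id, score, strand."""
    names = ["chrom", "start", "end", "gene_id", "score", "strand"]
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=names,
        dtype={"chrom": str, "gene_id": str, "strand": str},
    )
    genes = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            iv = GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand)
        except (ValidationError, ValueError) as e:
            raise ParseError(f"{path}: line {i + 1}: {e}") from None
        genes.append(GeneModel(str(row.gene_id), iv))
    return genes


def write_gene_models(genes: Sequence[GeneModel], path) -> None:
    with _open_text(path, "wt") as fh:
        for g in genes:
            iv = g.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{g.gene_id}\t.\t{iv.strand}\n")


def read_survival(path) -> SurvivalTable:
    """Read a survival table: sample, time, event."""
    df = _read_tsv(path, dtype={"sample": str})
    for col in ("sample", "time", "event"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    return SurvivalTable(df.set_index("sample")[["time", "event"]])


def write_survival(t: SurvivalTable, path, header_comment: str | None = None) -> None:
    df = t.data.reset_index().rename(columns={"index": "sample"})
    _write_with_comment(df, path, header_comment)


def read_expression(counts_path, sample_meta: pd.DataFrame | str | Path) -> ExpressionMatrix:
    """Read a gene × sample count matrix (first column: gene id)."""
    if not isinstance(sample_meta, pd.DataFrame):
        sample_meta = read_sample_meta(sample_meta)
    df = _read_tsv(counts_path, index_col=0)
    bad = df.columns[~df.columns.isin(sample_meta.index)]
    if len(bad):
        raise ValidationError(f"expression samples missing from metadata: {list(bad)}")
    return ExpressionMatrix(df, sample_meta)


def write_expression(e: ExpressionMatrix, path, header_comment: str | None = None) -> None:
    df = e.counts.rename_axis("gene").reset_index()
    _write_with_comment(df, path, header_comment)


def read_edges(path) -> pd.DataFrame:
    """Read a protein-interaction edge list: gene_a, gene_b, combined_score.

    Self-edges are dropped on load; scores must lie in [0, 1000].
    """
    df = _read_tsv(path, dtype={"gene_a": str, "gene_b": str})
    for col in ("gene_a", "gene_b", "combined_score"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    if ((df["combined_score"] < 0) | (df["combined_score"] > 1000)).any():
        raise ValidationError("combined_score outside [0, 1000]")
    return df[df["gene_a"] != df["gene_b"]].reset_index(drop=True)


def read_variants(path) -> pd.DataFrame:
    """Read a minimal variant table: chrom, pos, ref, alt, af, context."""
    df = _read_tsv(path, dtype={"chrom": str, "ref": str, "alt": str, "context": str})
    for col in ("chrom", "pos", "ref", "alt", "af"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    if ((df["af"] < 0) | (df["af"] > 1)).any():
        raise ValidationError("allele frequency outside [0, 1]")
    if (df["ref"] == df["alt"]).any():
        raise ValidationError("variant with ref == alt")
    return df


def read_gene_values(path, value_col: str) -> pd.Series:
    """Read a two-column (gene, value) table into a Series."""
    df = _read_tsv(path, dtype={"gene": str})
    if "gene" not in df.columns or value_col not in df.columns:
        raise ParseError(f"{path}: expected columns gene, {value_col}")
    return df.set_index("gene")[value_col]


def read_gene_list(path) -> list[str]:
    """Read one gene id per line (blank lines and # comments ignored)."""
    out = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def _write_with_comment(df: pd.DataFrame, path, header_comment: str | None) -> None:
    with _open_text(path, "wt") as fh:
        if header_comment:
            for ln in header_comment.splitlines():
                fh.write(f"# {ln}\n")
        df.to_csv(fh, sep="\t", index=False)


def write_table(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    """Write any result table as TSV with an optional # comment header."""
    _write_with_comment(df, path, header_comment)
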