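"""Methylome analysis: coverage filtering, region means, UMR and DMR
calling, DMR summarisation, genomic-context annotation and gene-body
metagene profiles.

UMRs (under-methylated regions) are maximal runs of CpGs whose mean
methylation stays at or below a threshold (default 10%).  DMRs are
formed by merging sign-consistent differential CpGs, tested with a
paired Wilcoxon signed-rank on per-sample region means, and filtered
by Benjamini–Hochberg FDR plus a minimum mean-difference of 0.1 over
at least 10 CpGs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._stats import bh_adjust, paired_wilcoxon_p
from .errors import UndefinedValueError, ValidationError
from .io import GeneModel, GenomicInterval, MethylomeMatrix

log = logging.getLogger(__name__)

PROMOTER = "promoter"
GENE_BODY = "gene_body"
INTERGENIC = "intergenic"


@dataclass(frozen=True)
class UMRRecord:
    interval: GenomicInterval
    n_cpgs: int
    mean_meth: float


@dataclass(frozen=True)
class DMRRecord:
    interval: GenomicInterval
    n_cpgs: int
    mean_diff: float  # tumor − normal
    p_value: float
    q_value: float

    @property
    def direction(self) -> str:
        return "hyper" if self.mean_diff > 0 else "hypo"


@dataclass(frozen=True)
class DMRSummary:
    n_hyper: int
    n_hypo: int

    @property
    def total(self) -> int:
        return self.n_hyper + self.n_hypo

    @property
    def hypo_fraction_pct(self) -> float:
        """Percentage of DMRs that are hypomethylated; NaN when empty."""
        if self.total == 0:
            return float("nan")
        return 100.0 * self.n_hypo / self.total

    @property
    def fold_ratio(self) -> float:
        """hypo/hyper count ratio; NaN when there are no hyper-DMRs."""
        if self.n_hyper == 0:
            return float("nan")
        return self.n_hypo / self.n_hyper

    @property
    def defined(self) -> bool:
        return self.total > 0


# ---------------------------------------------------------------------------
# coverage filter and region means
# ---------------------------------------------------------------------------


def filter_by_coverage(m: MethylomeMatrix, min_cov: int = 4) -> MethylomeMatrix:
    """Mask per-sample observations with fewer than ``min_cov`` reads.

    Masked cells are set to total = 0 (missing); sites left with no
    observation in any sample are dropped.
    """
    if min_cov < 0:
        raise ValidationError("min_cov must be >= 0")
    if min_cov == 0:
        return m
    low = m.total < min_cov
    total = np.where(low, 0, m.total)
    meth = np.where(low, 0, m.meth)
    keep = total.sum(axis=1) > 0
    if not keep.any():
        log.warning("coverage filter removed every site (min_cov=%d)", min_cov)
    return MethylomeMatrix(
        m.sites.loc[keep].reset_index(drop=True),
        meth[keep],
        total[keep],
        list(m.samples),
        m.sample_meta,
    )


def _site_mask(m: MethylomeMatrix, region: GenomicInterval) -> np.ndarray:
    chrom = m.sites["chrom"].to_numpy()
    pos = m.sites["pos"].to_numpy()
    return (chrom == region.chrom) & (region.start <= pos - 1) & (pos - 1 < region.end)


def region_mean_methylation(
    m: MethylomeMatrix, region: GenomicInterval, samples: Sequence[str] | None = None
) -> float:
    """Unweighted mean of per-site beta values over a region.

    Each site's beta is first averaged across the requested samples;
    sites unobserved in every requested sample are excluded.
    """
    samples = list(samples) if samples is not None else list(m.samples)
    idx = m.sample_index(samples)
    beta = m.beta()[:, idx]
    mask = _site_mask(m, region)
    if not mask.any():
        raise UndefinedValueError(f"no CpGs in region {region.chrom}:{region.start}-{region.end}")
    with np.errstate(invalid="ignore"):
        site_means = np.nanmean(beta[mask], axis=1)
    site_means = site_means[~np.isnan(site_means)]
    if site_means.size == 0:
        raise UndefinedValueError("no covered CpGs in region for requested samples")
    return float(site_means.mean())


# ---------------------------------------------------------------------------
# run segmentation helpers
# ---------------------------------------------------------------------------


def _runs(keep: np.ndarray, chrom: np.ndarray, pos: np.ndarray, max_gap_bp: int):
    """Yield (start_idx, end_idx) slices of maximal runs of kept sites on a
    single chromosome with inter-CpG gaps <= max_gap_bp."""
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        return
    # break where sites are non-adjacent in the kept set, chrom changes,
    # or the genomic gap exceeds max_gap_bp
    breaks = (
        (np.diff(idx) != 1)
        | (chrom[idx[1:]] != chrom[idx[:-1]])
        | ((pos[idx[1:]] - pos[idx[:-1]]) > max_gap_bp)
    )
    starts = np.concatenate([[0], np.flatnonzero(breaks) + 1])
    ends = np.concatenate([np.flatnonzero(breaks) + 1, [idx.size]])
    for a, b in zip(starts, ends):
        yield idx[a], idx[b - 1] + 1


# ---------------------------------------------------------------------------
# UMR calling
# ---------------------------------------------------------------------------


def call_umrs(
    m: MethylomeMatrix,
    samples: Sequence[str] | None = None,
    umr_max_meth: float = 0.10,
    umr_min_cpgs: int = 10,
    max_gap_bp: int = 1000,
) -> list[UMRRecord]:
    """Call under-methylated regions on the requested samples.

    A UMR is a maximal run of consecutive CpGs whose across-sample mean
    beta is <= ``umr_max_meth``, containing >= ``umr_min_cpgs`` CpGs with
    inter-CpG gaps <= ``max_gap_bp``; the record spans the first to the
    last CpG of the run (half-open).
    """
    if m.n_sites == 0:
        return []
    samples = list(samples) if samples is not None else list(m.samples)
    idx = m.sample_index(samples)
    with np.errstate(invalid="ignore"):
        site_mean = np.nanmean(m.beta()[:, idx], axis=1)
    keep = ~np.isnan(site_mean) & (site_mean <= umr_max_meth)
    chrom = m.sites["chrom"].to_numpy()
    pos = m.sites["pos"].to_numpy()
    out = []
    for a, b in _runs(keep, chrom, pos, max_gap_bp):
        n = b - a
        if n < umr_min_cpgs:
            continue
        iv = GenomicInterval(chrom[a], int(pos[a]) - 1, int(pos[b - 1]))
        out.append(UMRRecord(iv, int(n), float(site_mean[a:b].mean())))
    return out


# ---------------------------------------------------------------------------
# DMR calling
# ---------------------------------------------------------------------------


def call_dmrs(
    m: MethylomeMatrix,
    pairing: Sequence[tuple[str, str]] | None = None,
    min_diff: float = 0.1,
    min_cpgs: int = 10,
    fdr: float = 0.05,
    max_gap_bp: int = 1000,
    min_pairs: int = 3,
) -> list[DMRRecord]:
    """Call differentially methylated regions between paired tumor/normal
    samples.

    Candidate regions merge consecutive CpGs whose tumor − normal mean
    difference shares sign with |difference| >= ``min_diff``/2.  Candidates
    with >= ``min_cpgs`` CpGs are tested with a two-sided paired Wilcoxon
    signed-rank on per-sample region means; Benjamini–Hochberg correction
    runs across candidates.  Reported regions satisfy q < ``fdr`` and
    |region mean difference| >= ``min_diff``.
    """
    if pairing is None:
        pairing = m.pairs()
    if not pairing:
        raise ValidationError("no tumor/normal pairing metadata available")
    tumor = [t for t, _ in pairing]
    normal = [n for _, n in pairing]
    beta = m.beta()
    bt = beta[:, m.sample_index(tumor)]
    bn = beta[:, m.sample_index(normal)]
    with np.errstate(invalid="ignore"):
        diff = np.nanmean(bt, axis=1) - np.nanmean(bn, axis=1)
    chrom = m.sites["chrom"].to_numpy()
    pos = m.sites["pos"].to_numpy()

    candidates = []
    for sign in (1, -1):
        keep = ~np.isnan(diff) & (sign * diff >= min_diff / 2)
        for a, b in _runs(keep, chrom, pos, max_gap_bp):
            if b - a >= min_cpgs:
                candidates.append((a, b))
    candidates.sort()
    if not candidates:
        return []

    records, pvals = [], []
    for a, b in candidates:
        with np.errstate(invalid="ignore"):
            rt = np.nanmean(bt[a:b], axis=0)  # per-tumor-sample region mean
            rn = np.nanmean(bn[a:b], axis=0)
        ok = ~np.isnan(rt) & ~np.isnan(rn)
        if ok.sum() < min_pairs:
            continue
        d = rt[ok] - rn[ok]
        p = float(paired_wilcoxon_p(rt[ok][None, :], rn[ok][None, :])[0])
        iv = GenomicInterval(chrom[a], int(pos[a]) - 1, int(pos[b - 1]))
        records.append((iv, int(b - a), float(d.mean())))
        pvals.append(p)
    if not records:
        return []
    qvals = bh_adjust(pvals)
    out = []
    for (iv, n, md), p, q in zip(records, pvals, qvals):
        if q < fdr and abs(md) >= min_diff:
            out.append(DMRRecord(iv, n, md, float(p), float(q)))
    return out


def summarize_dmrs(dmrs: Iterable[DMRRecord]) -> DMRSummary:
    """Count DMRs by direction."""
    n_hyper = n_hypo = 0
    for d in dmrs:
        if d.direction == "hyper":
            n_hyper += 1
        else:
            n_hypo += 1
    return DMRSummary(n_hyper, n_hypo)


# ---------------------------------------------------------------------------
# genomic-context annotation
# ---------------------------------------------------------------------------


def promoter_window(
    gene: GeneModel, promoter_up: int = 1500, promoter_down: int = 500
) -> GenomicInterval:
    """Strand-aware promoter window around the TSS (upstream ``promoter_up``
    bp, downstream ``promoter_down`` bp including the TSS base)."""
    iv = gene.interval
    tss = gene.tss
    if iv.strand == "-":
        start, end = tss - promoter_down + 1, tss + promoter_up + 1
    else:
        start, end = tss - promoter_up, tss + promoter_down
    return GenomicInterval(iv.chrom, max(start, 0), max(end, 1), iv.strand)


def annotate_context(
    regions: Sequence[GenomicInterval],
    gene_models: Sequence[GeneModel],
    promoter_up: int = 1500,
    promoter_down: int = 500,
) -> list[tuple[GenomicInterval, str, str | None]]:
    """Assign each region exactly one context label with precedence
    promoter > gene_body > intergenic (overlap = >= 1 bp).

    Ties across genes break by nearest TSS, then lexicographic gene id.
    """
    promoters = [promoter_window(g, promoter_up, promoter_down) for g in gene_models]
    out = []
    for region in regions:
        best = None  # (label_rank, tss_distance, gene_id)
        for g, prom in zip(gene_models, promoters):
            if region.overlaps(prom):
                label_rank = 0
            elif region.overlaps(g.interval):
                label_rank = 1
            else:
                continue
            mid = (region.start + region.end - 1) / 2
            dist = abs(g.tss - mid)
            key = (label_rank, dist, g.gene_id)
            if best is None or key < best:
                best = key
        if best is None:
            out.append((region, INTERGENIC, None))
        else:
            out.append((region, PROMOTER if best[0] == 0 else GENE_BODY, best[2]))
    return out


# ---------------------------------------------------------------------------
# gene-body metagene profile
# ---------------------------------------------------------------------------


def gene_body_profile(
    m: MethylomeMatrix,
    gene_models: Sequence[GeneModel],
    samples: Sequence[str] | None = None,
    n_bins: int = 100,
) -> np.ndarray:
    """Average methylation across scaled gene bodies.

    Each gene body is scaled to [0, 1) strand-aware (bin 0 at the TSS);
    CpGs fall into bins by relative position; the profile is the per-bin
    mean across genes.  Bins with no contributing gene are NaN.
    """
    if n_bins < 1:
        raise ValidationError("n_bins must be >= 1")
    samples = list(samples) if samples is not None else list(m.samples)
    idx = m.sample_index(samples)
    with np.errstate(invalid="ignore"):
        site_mean = np.nanmean(m.beta()[:, idx], axis=1)
    chrom = m.sites["chrom"].to_numpy()
    pos0 = m.sites["pos"].to_numpy() - 1  # 0-based site coordinates
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    for g in gene_models:
        iv = g.interval
        mask = (chrom == iv.chrom) & (pos0 >= iv.start) & (pos0 < iv.end)
        mask &= ~np.isnan(site_mean)
        if not mask.any():
            continue
        p = pos0[mask]
        if iv.strand == "-":
            rel = (iv.end - 1 - p) / iv.length
        else:
            rel = (p - iv.start) / iv.length
        bins = np.minimum((rel * n_bins).astype(int), n_bins - 1)
        gene_bins = np.full(n_bins, np.nan)
        vals = site_mean[mask]
        for b in np.unique(bins):
            gene_bins[b] = vals[bins == b].mean()
        has = ~np.isnan(gene_bins)
        sums[has] += gene_bins[has]
        counts[has] += 1
    with np.errstate(invalid="ignore"):
        profile = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return profile


def dmrs_to_frame(dmrs: Sequence[DMRRecord]) -> pd.DataFrame:
    """DMR records as a BED6+ style DataFrame."""
    rows = []
    for i, d in enumerate(dmrs):
        rows.append(
            {
                "chrom": d.interval.chrom,
                "start": d.interval.start,
                "end": d.interval.end,
                "name": f"DMR_{i + 1}",
                "score": -np.log10(max(d.q_value, 1e-300)),
                "strand": ".",
                "mean_diff": d.mean_diff,
                "n_cpgs": d.n_cpgs,
                "p": d.p_value,
                "q": d.q_value,
                "direction": d.direction,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "name", "score", "strand",
            "mean_diff", "n_cpgs", "p", "q", "direction",
        ],
    )


def umrs_to_frame(umrs: Sequence[UMRRecord]) -> pd.DataFrame:
    rows = []
    for i, u in enumerate(umrs):
        rows.append(
            {
                "chrom": u.interval.chrom,
                "start": u.interval.start,
                "end": u.interval.end,
                "name": f"UMR_{i + 1}",
                "score": u.n_cpgs,
                "strand": ".",
                "mean_meth": u.mean_meth,
                "n_cpgs": u.n_cpgs,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "name", "score", "strand", "mean_meth", "n_cpgs"],
    )
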