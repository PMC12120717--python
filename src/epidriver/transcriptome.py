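"""Expression filtering, connectivity-based sample QC, paired differential
expression and activated/unactivated homeobox-gene classification.

Differential expression uses median-of-ratios library normalisation, a
per-gene paired two-sided Wilcoxon signed-rank test on log-scale
normalised counts, and Benjamini–Hochberg correction.  A gene is called
up (down) when its log2 fold change is >= 1 (<= −1) at q <= 0.05.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import bh_adjust, paired_wilcoxon_p
from .errors import ValidationError
from .io import ExpressionMatrix

log = logging.getLogger(__name__)

UP, DOWN, UNCHANGED = "up", "down", "unchanged"


@dataclass(frozen=True)
class GeneSetClassification:
    """Partition of a homeobox gene list into activated (aHBG: upregulated)
    and unactivated (uHBG: downregulated or unchanged) sets."""

    ahbg: frozenset[str]
    uhbg: frozenset[str]


def filter_low_expression(
    expr: ExpressionMatrix, min_count: int = 10, min_frac: float = 0.05
) -> ExpressionMatrix:
    """Keep genes with count strictly > ``min_count`` in at least
    ceil(``min_frac`` × n_samples) samples (at minimum one sample)."""
    n = len(expr.samples)
    n_req = max(1, math.ceil(min_frac * n))
    keep = (expr.counts > min_count).sum(axis=1) >= n_req
    return ExpressionMatrix(expr.counts.loc[keep], expr.sample_meta)


def sample_qc_connectivity(
    expr: ExpressionMatrix, z_thresh: float = -2.0, iterative: bool = False
) -> tuple[list[str], list[str]]:
    """Remove outlier samples by standardized network connectivity.

    Connectivity of a sample is the sum of its Pearson correlations (on
    log2(count+1) profiles) with every other sample; samples with
    standardized connectivity Z < ``z_thresh`` are removed.  When the
    connectivity spread is zero the Z score is defined as 0 for all.
    """
    samples = list(expr.samples)
    if len(samples) < 3:
        raise ValidationError("connectivity QC requires at least 3 samples")
    removed: list[str] = []
    current = samples
    while True:
        logc = np.log2(expr.counts[current].to_numpy(float) + 1)
        corr = np.corrcoef(logc, rowvar=False)
        corr = np.nan_to_num(corr, nan=0.0)
        connectivity = corr.sum(axis=0) - np.diag(corr)
        sd = connectivity.std(ddof=0)
        if sd == 0:
            z = np.zeros_like(connectivity)
        else:
            z = (connectivity - connectivity.mean()) / sd
        drop = [s for s, zi in zip(current, z) if zi < z_thresh]
        removed.extend(drop)
        current = [s for s in current if s not in drop]
        if not drop or not iterative or len(current) < 3:
            break
    return current, removed


def median_of_ratios_size_factors(counts: pd.DataFrame) -> pd.Series:
    """DESeq-style size factors: median of per-gene count/geometric-mean
    ratios over genes expressed in every sample."""
    arr = counts.to_numpy(float)
    with np.errstate(divide="ignore"):
        logs = np.log(arr)
    ok = np.all(np.isfinite(logs), axis=1)
    if ok.sum() == 0:
        log.warning("no gene expressed in all samples; size factors set to 1")
        return pd.Series(1.0, index=counts.columns)
    ref = logs[ok].mean(axis=1)
    sf = np.exp(np.median(logs[ok] - ref[:, None], axis=0))
    return pd.Series(sf, index=counts.columns)


def differential_expression(
    expr: ExpressionMatrix,
    lfc_thresh: float = 1.0,
    fdr: float = 0.05,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Paired tumor-vs-normal differential expression.

    Returns a DETable DataFrame indexed by gene with columns lfc,
    p_value, q_value, status.  lfc is the mean over pairs of
    log2((tumor + pc) / (normal + pc)) on size-factor-normalised counts;
    p comes from the paired Wilcoxon signed-rank on log2(norm + 1).
    """
    pairs = expr.pairs()
    if len(pairs) < 3:
        raise ValidationError("differential expression requires >= 3 tumor/normal pairs")
    sf = median_of_ratios_size_factors(expr.counts)
    norm = expr.counts / sf
    t = norm[[p[0] for p in pairs]].to_numpy(float)
    n = norm[[p[1] for p in pairs]].to_numpy(float)
    lfc = np.mean(np.log2((t + pseudocount) / (n + pseudocount)), axis=1)
    p = paired_wilcoxon_p(np.log2(t + 1), np.log2(n + 1))
    q = bh_adjust(p)
    status = np.where(
        (lfc >= lfc_thresh) & (q <= fdr),
        UP,
        np.where((lfc <= -lfc_thresh) & (q <= fdr), DOWN, UNCHANGED),
    )
    return pd.DataFrame(
        {"lfc": lfc, "p_value": p, "q_value": q, "status": status}, index=expr.genes
    )


def read_de_table(path) -> pd.DataFrame:
    """Accept an externally produced DE table (gene, lfc, q_value [, p_value]);
    status is (re)derived from the DETable rule."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    for col in ("lfc", "q_value"):
        if col not in df.columns:
            raise ValidationError(f"DE table missing column {col!r}")
    if "p_value" not in df.columns:
        df["p_value"] = np.nan
    df["status"] = np.where(
        (df["lfc"] >= 1) & (df["q_value"] <= 0.05),
        UP,
        np.where((df["lfc"] <= -1) & (df["q_value"] <= 0.05), DOWN, UNCHANGED),
    )
    return df[["lfc", "p_value", "q_value", "status"]]


def classify_homeobox(de: pd.DataFrame, homeobox_ids) -> GeneSetClassification:
    """Split homeobox genes into aHBG (status up) and uHBG (down or
    unchanged); ids absent from the DE table are ignored with a warning."""
    ids = list(homeobox_ids)
    if not ids:
        raise ValidationError("empty homeobox gene list")
    unknown = [g for g in ids if g not in de.index]
    if unknown:
        log.warning("%d homeobox ids absent from DE table (ignored)", len(unknown))
    known = [g for g in ids if g in de.index]
    status = de.loc[known, "status"]
    ahbg = frozenset(status.index[status == UP])
    uhbg = frozenset(status.index[status != UP])
    return GeneSetClassification(ahbg, uhbg)
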