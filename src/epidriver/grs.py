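"""The multi-omics Gene Risk Score (GRS).

For gene *i* with feature vector X_i (log2 fold change, absolute
differential methylation, minor allele frequency, regulatory network
degree) the score is the weighted sum

    GRS_i = sum_j rho_j * Z(X_ij)

where each weight rho_j is the Spearman correlation between feature j
and the per-gene missense Z constraint score, and Z(.) standardises a
feature column to zero mean and unit variance (raw mode available).
Genes with missense Z >= 3.09 are flagged as intolerant to missense
variation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

log = logging.getLogger(__name__)

FEATURE_COLUMNS = ("lfc", "abs_dm", "maf", "connectivity")
MISSENSE_Z_INTOLERANT = 3.09


@dataclass
class GRSFeatureMatrix:
    """Per-gene feature table plus missense Z; rows with any missing
    feature are dropped at assembly with a warning."""

    features: pd.DataFrame  # index gene, columns FEATURE_COLUMNS (or custom)
    missense_z: pd.Series  # aligned to features.index

    def __post_init__(self):
        if len(self.features.columns) < 1:
            raise ValidationError("feature matrix needs >= 1 column")
        if not self.features.index.equals(self.missense_z.index):
            raise ValidationError("features and missense_z indices differ")
        if self.features.isna().any().any() or self.missense_z.isna().any():
            raise ValidationError("assembled feature matrix must have no missing cells")

    @property
    def n_genes(self) -> int:
        return len(self.features)


@dataclass
class GRSResult:
    weights: pd.Series  # rho_j per feature
    scores: pd.Series  # grs_i per gene
    ranks: pd.Series  # 1 = highest score; ties broken by gene id
    constrained: pd.Series  # missense_z >= 3.09

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"grs": self.scores, "rank": self.ranks, "constrained": self.constrained}
        ).sort_values("rank")


def assemble_features(
    lfc: pd.Series,
    abs_dm: pd.Series,
    maf: pd.Series,
    connectivity: pd.Series,
    missense_z: pd.Series,
) -> GRSFeatureMatrix:
    """Join per-gene features on the genes where lfc, abs_dm and missense_z
    are all defined; MAF and connectivity default to 0 where absent
    (no variants / no qualifying edges)."""
    genes = lfc.dropna().index.intersection(abs_dm.dropna().index)
    genes = genes.intersection(missense_z.dropna().index)
    dropped = len(set(lfc.index) | set(abs_dm.index) | set(missense_z.index)) - len(genes)
    if dropped:
        log.warning("dropped %d genes with missing features at GRS assembly", dropped)
    feats = pd.DataFrame(
        {
            "lfc": lfc.reindex(genes),
            "abs_dm": abs_dm.reindex(genes),
            "maf": maf.reindex(genes).fillna(0.0),
            "connectivity": connectivity.reindex(genes).fillna(0.0),
        }
    )
    return GRSFeatureMatrix(feats, missense_z.reindex(genes))


def network_connectivity(
    edges: pd.DataFrame, genes, min_score: int = 700
) -> pd.Series:
    """Network degree: distinct interaction partners over edges with
    combined score >= ``min_score``; duplicate edges count once,
    self-edges never; genes absent from the edge list get 0."""
    genes = pd.Index(genes)
    e = edges[edges["combined_score"] >= min_score]
    e = e[e["gene_a"] != e["gene_b"]]
    a = np.minimum(e["gene_a"], e["gene_b"])
    b = np.maximum(e["gene_a"], e["gene_b"])
    uniq = pd.DataFrame({"a": a, "b": b}).drop_duplicates()
    degree = pd.concat([uniq["a"], uniq["b"]]).value_counts()
    return degree.reindex(genes).fillna(0).astype(int)


def gene_maf(variants: pd.DataFrame, gene_models) -> pd.Series:
    """Per-gene mean minor allele frequency over the gene's SNVs
    (0 for genes with no variants)."""
    chrom = variants["chrom"].to_numpy()
    pos = variants["pos"].to_numpy()
    af = variants["af"].to_numpy(float)
    af = np.minimum(af, 1 - af)  # minor allele
    out = {}
    for g in gene_models:
        iv = g.interval
        sel = (chrom == iv.chrom) & (iv.start <= pos - 1) & (pos - 1 < iv.end)
        out[g.gene_id] = float(af[sel].mean()) if sel.any() else 0.0
    return pd.Series(out)


def compute_weights(features: GRSFeatureMatrix) -> pd.Series:
    """Weight rho_j = Spearman correlation between feature column j and
    the missense Z score across genes; constant columns get weight 0."""
    if features.n_genes < 3:
        raise ValidationError("weights require >= 3 genes")
    z = features.missense_z.to_numpy(float)
    weights = {}
    for col in features.features.columns:
        x = features.features[col].to_numpy(float)
        if np.all(x == x[0]) or np.all(z == z[0]):
            log.warning("constant column %r (or constant missense_z): weight 0", col)
            weights[col] = 0.0
        else:
            weights[col] = float(stats.spearmanr(x, z).statistic)
    return pd.Series(weights)


def compute_grs(
    features: GRSFeatureMatrix, weights: pd.Series, standardize: bool = True
) -> GRSResult:
    """Score every gene as the weighted sum of (optionally z-scored)
    features; rank 1 is the highest score, ties break by gene id."""
    if not set(weights.index) == set(features.features.columns):
        raise ValidationError("weights do not match feature columns")
    X = features.features[weights.index].to_numpy(float)
    if standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
    scores = pd.Series(X @ weights.to_numpy(float), index=features.features.index)
    order = sorted(scores.index, key=lambda g: (-scores[g], g))
    ranks = pd.Series({g: i + 1 for i, g in enumerate(order)}).reindex(scores.index)
    constrained = flag_constrained(features)
    return GRSResult(weights.copy(), scores, ranks, constrained)


def rank_and_select(result: GRSResult, k: int = 15) -> list[str]:
    """Top-k genes by descending GRS (ties by lexicographic gene id)."""
    if k < 1:
        raise ValidationError("k must be >= 1")
    order = result.ranks.sort_values().index
    if k > len(order):
        log.warning("k=%d exceeds %d scored genes; returning all", k, len(order))
    return list(order[:k])


def flag_constrained(
    features: GRSFeatureMatrix, z_min: float = MISSENSE_Z_INTOLERANT
) -> pd.Series:
    """True for genes intolerant to missense variation (missense Z >= 3.09)."""
    return features.missense_z >= z_min
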