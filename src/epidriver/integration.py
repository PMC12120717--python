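"""Integration of methylation with expression and variant features:
per-gene methylation/expression deltas and their Spearman correlation,
hypergeometric set-overlap enrichment, SNV density per region, and the
pyrimidine-collapsed substitution spectrum with CpG-context flags.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._stats import hypergeom_upper, spearman
from .errors import UndefinedValueError, ValidationError
from .io import GeneModel, GenomicInterval, MethylomeMatrix
from .methylome import UMRRecord

REGION_CLASSES = ("promoter", "gene_body", "gene_body_umr")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


@dataclass(frozen=True)
class OverlapResult:
    n_a: int
    n_b: int
    n_overlap: int
    n_universe: int
    p_value: float

    @property
    def fraction_of_a_pct(self) -> float:
        if self.n_a == 0:
            return float("nan")
        return 100.0 * self.n_overlap / self.n_a


# ---------------------------------------------------------------------------
# methylation/expression delta table
# ---------------------------------------------------------------------------


def _mean_over_sites(beta_cond: np.ndarray, site_idx: np.ndarray) -> float:
    with np.errstate(invalid="ignore"):
        site_means = np.nanmean(beta_cond[site_idx], axis=1)
    site_means = site_means[~np.isnan(site_means)]
    if site_means.size == 0:
        return float("nan")
    return float(site_means.mean())


def build_gene_delta_table(
    m: MethylomeMatrix,
    gene_models: Sequence[GeneModel],
    de: pd.DataFrame,
    region_class: str = "gene_body",
    normal_umrs: Sequence[UMRRecord] | None = None,
    promoter_up: int = 1500,
    promoter_down: int = 500,
) -> pd.DataFrame:
    """Per-gene tumor − normal methylation delta over a region class,
    joined with the expression log2 fold change.

    Region classes: ``promoter`` (strand-aware TSS window), ``gene_body``
    (the gene interval) or ``gene_body_umr`` (under-methylated regions
    called on normal samples, intersected with the gene body — a fixed
    reference set so tumor hypermethylation cannot shift the region).
    Genes with no covered CpG in the class are absent from the result,
    never zero-filled.
    """
    if region_class not in REGION_CLASSES:
        raise ValidationError(f"unknown region class {region_class!r}")
    if region_class == "gene_body_umr" and normal_umrs is None:
        raise ValidationError("gene_body_umr requires UMRs called on normal samples")
    from .methylome import promoter_window  # local import to avoid cycle

    beta = m.beta()
    bt = beta[:, m.sample_index(m.samples_for("tumor"))]
    bn = beta[:, m.sample_index(m.samples_for("normal"))]
    chrom = m.sites["chrom"].to_numpy()
    pos0 = m.sites["pos"].to_numpy() - 1

    rows = []
    for g in gene_models:
        if g.gene_id not in de.index:
            continue
        if region_class == "promoter":
            regions = [promoter_window(g, promoter_up, promoter_down)]
        elif region_class == "gene_body":
            regions = [g.interval]
        else:
            regions = [
                GenomicInterval(
                    g.interval.chrom,
                    max(u.interval.start, g.interval.start),
                    min(u.interval.end, g.interval.end),
                )
                for u in normal_umrs
                if u.interval.overlaps(g.interval)
            ]
            if not regions:
                continue
        mask = np.zeros(len(pos0), dtype=bool)
        for r in regions:
            mask |= (chrom == r.chrom) & (pos0 >= r.start) & (pos0 < r.end)
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        mt = _mean_over_sites(bt, idx)
        mn = _mean_over_sites(bn, idx)
        if np.isnan(mt) or np.isnan(mn):
            continue
        rows.append({"gene": g.gene_id, "delta_meth": mt - mn, "delta_expr": float(de.loc[g.gene_id, "lfc"])})
    return pd.DataFrame(rows, columns=["gene", "delta_meth", "delta_expr"]).set_index("gene")


def methylation_expression_correlation(
    table: pd.DataFrame, gene_set: Sequence[str] | None = None
) -> tuple[float, float, int]:
    """Spearman correlation between methylation and expression deltas for
    the genes in ``gene_set`` (or all genes in the table).

    Returns (rho, two-sided p, n).  Requires n >= 3 genes with both
    deltas defined.
    """
    sub = table if gene_set is None else table.loc[table.index.intersection(list(gene_set))]
    sub = sub.dropna(subset=["delta_meth", "delta_expr"])
    n = len(sub)
    if n < 3:
        raise UndefinedValueError(f"correlation needs >= 3 genes with deltas, got {n}")
    rho, p = spearman(sub["delta_meth"].to_numpy(), sub["delta_expr"].to_numpy())
    return rho, p, n


# ---------------------------------------------------------------------------
# set-overlap enrichment
# ---------------------------------------------------------------------------


def overlap_enrichment(set_a, set_b, universe) -> OverlapResult:
    """Upper-tail hypergeometric enrichment of the overlap |A ∩ B|
    drawing |A| from a universe containing |B| successes."""
    set_a, set_b, universe = set(set_a), set(set_b), set(universe)
    if not set_a <= universe or not set_b <= universe:
        raise ValidationError("sets must be subsets of the universe")
    k = len(set_a & set_b)
    p = hypergeom_upper(k, len(universe), len(set_b), len(set_a))
    return OverlapResult(len(set_a), len(set_b), k, len(universe), p)


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------


def snv_density(variants: pd.DataFrame, regions: Sequence[GenomicInterval]) -> np.ndarray:
    """SNVs per kilobase for each region (1-based positions, half-open
    interval membership)."""
    chrom = variants["chrom"].to_numpy()
    pos = variants["pos"].to_numpy()
    out = np.empty(len(regions))
    for i, r in enumerate(regions):
        if r.length <= 0:
            raise ValidationError("zero-length region")
        n = int(np.sum((chrom == r.chrom) & (r.start <= pos - 1) & (pos - 1 < r.end)))
        out[i] = n / (r.length / 1000.0)
    return out


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))


def substitution_spectrum(variants: pd.DataFrame) -> tuple[dict, int]:
    """Counts per pyrimidine-centred substitution class × CpG-context flag.

    Purine-reference SNVs are strand-collapsed (e.g. G>A becomes C>T with
    reverse-complemented context).  The CpG flag is True iff the collapsed
    trinucleotide context carries G immediately 3' of the reference.
    Indels are excluded and returned as a separate count.
    """
    if "context" not in variants.columns:
        raise ValidationError("substitution spectrum requires a trinucleotide context column")
    counts: dict[tuple[str, bool], int] = {
        (c, f): 0 for c in SUBSTITUTION_CLASSES for f in (False, True)
    }
    n_indels = 0
    for ref, alt, ctx in zip(variants["ref"], variants["alt"], variants["context"]):
        ref, alt = str(ref).upper(), str(alt).upper()
        if len(ref) != 1 or len(alt) != 1 or ref not in "ACGT" or alt not in "ACGT":
            n_indels += 1
            continue
        ctx = str(ctx).upper()
        if ref in "AG":  # collapse to the pyrimidine strand
            ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
            ctx = _revcomp(ctx)
        cls = f"{ref}>{alt}"
        cpg = len(ctx) == 3 and ctx[1] == ref and ref == "C" and ctx[2] == "G"
        counts[(cls, cpg)] += 1
    return counts, n_indels
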