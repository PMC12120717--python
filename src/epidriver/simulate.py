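"""Seeded synthetic multi-omics generator with known ground truth.

The generator emulates the discovery setting of the pipeline: paired
tumor/normal bisulfite methylomes in which every homeobox gene carries
a gene-body under-methylated region (UMR) in normal tissue, and a
planted subset of *driver* genes gains tumor methylation inside that
UMR while being overexpressed, with consistent variant (MAF, C>T-at-CpG
spectrum), network-degree, missense-Z and survival structure.  A single
root seed drives independent substreams per data type, so regenerating
one block leaves the others identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import (
    ExpressionMatrix,
    GeneModel,
    GenomicInterval,
    MethylomeMatrix,
    SurvivalTable,
    write_expression,
    write_gene_models,
    write_methylome,
    write_sample_meta,
    write_survival,
    write_table,
)

_BASES = np.array(list("ACGT"))


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic benchmark.

    Defaults are the package's reference conditions: 2000 genes, 30
    tumor/normal pairs, 40 planted drivers among 100 homeobox genes,
    normal-tissue UMR methylation 5% on a 80% background, a planted
    tumor methylation gain of 0.3 inside driver UMRs, driver log2 fold
    change 2, and ~30x bisulfite coverage.
    """

    n_genes: int = 2000
    n_pairs: int = 30
    n_drivers: int = 40
    n_homeobox: int = 100
    gene_length: int = 3000
    intergenic_gap: int = 5000
    cpg_spacing_genic: int = 50
    cpg_spacing_intergenic: int = 500
    umr_cpgs_per_driver: int = 20
    beta_low: float = 0.05
    beta_high: float = 0.8
    delta_meth: float = 0.3
    beta_concentration: float = 30.0  # beta-binomial overdispersion control
    driver_lfc: float = 2.0
    nb_dispersion: float = 0.1
    base_mean: float = 100.0  # log-normal median of baseline expression
    mean_coverage: float = 30.0
    low_coverage_frac: float = 0.05  # cells drawn at ~2x to exercise the coverage filter
    snv_rate_per_kb: float = 1.0
    driver_snv_mult: float = 3.0
    maf_scale: float = 3.0
    driver_cpg_ct_frac: float = 0.7  # fraction of driver SNVs that are C>T at CpG
    edge_prob_driver: float = 0.05
    edge_prob_background: float = 0.002
    missense_z_driver: tuple[float, float] = (3.5, 0.5)  # mean, sd
    missense_z_background: tuple[float, float] = (0.0, 1.0)
    axis_size: int = 5  # leading drivers forming the survival axis
    axis_activity_lfc: float = 1.0  # log2 expression shift per activity unit
    survival_baseline_hazard: float = 0.02  # events per month
    hazard_ratio_per_activity: float = 2.0
    censor_window: tuple[float, float] = (12.0, 60.0)  # months
    seed: int = 1

    def validate(self) -> None:
        if not (0 < self.n_drivers <= self.n_homeobox <= self.n_genes):
            raise ValidationError("need 0 < n_drivers <= n_homeobox <= n_genes")
        for name in ("beta_low", "beta_high", "delta_meth", "low_coverage_frac",
                     "edge_prob_driver", "edge_prob_background", "driver_cpg_ct_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.beta_low + self.delta_meth > 1:
            raise ValidationError("beta_low + delta_meth must be <= 1")
        if self.n_pairs < 1 or self.gene_length < self.cpg_spacing_genic:
            raise ValidationError("invalid sizes in config")
        if self.umr_cpgs_per_driver * self.cpg_spacing_genic > self.gene_length:
            raise ValidationError("planted UMR does not fit in the gene body")
        if self.axis_size > self.n_drivers:
            raise ValidationError("axis_size must not exceed n_drivers")
        if self.seed < 0 or self.seed >= 2**31:
            raise ValidationError("seed must lie in [0, 2^31)")


@dataclass
class TruthTable:
    """Planted ground truth accompanying a bundle."""

    genes: pd.DataFrame  # index gene: is_driver, is_homeobox, lfc, delta_meth
    umrs: dict[str, GenomicInterval]  # planted normal-tissue UMR per homeobox gene
    axis_genes: list[str]
    activity: pd.Series  # true activity per tumor sample

    @property
    def drivers(self) -> list[str]:
        return list(self.genes.index[self.genes["is_driver"]])

    @property
    def homeobox(self) -> list[str]:
        return list(self.genes.index[self.genes["is_homeobox"]])


@dataclass
class Bundle:
    config: SyntheticConfig
    gene_models: list[GeneModel]
    methylome: MethylomeMatrix
    expression: ExpressionMatrix
    variants: pd.DataFrame
    edges: pd.DataFrame
    missense_z: pd.Series
    survival: SurvivalTable
    truth: TruthTable


def _substream(seed: int, block: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, block]))


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i + 1:0{width}d}" for i in range(n)]


def _layout(cfg: SyntheticConfig):
    """Gene models and CpG positions on a single synthetic chromosome."""
    ids = _gene_ids(cfg.n_genes)
    genes: list[GeneModel] = []
    positions: list[int] = []
    cursor = cfg.intergenic_gap
    for i, gid in enumerate(ids):
        # intergenic CpGs in the gap preceding this gene
        gap_start = cursor - cfg.intergenic_gap
        for p0 in range(gap_start, cursor, cfg.cpg_spacing_intergenic):
            positions.append(p0 + 1)
        strand = "+" if i % 2 == 0 else "-"
        iv = GenomicInterval("chr1", cursor, cursor + cfg.gene_length, strand)
        genes.append(GeneModel(gid, iv))
        for p0 in range(iv.start, iv.end, cfg.cpg_spacing_genic):
            positions.append(p0 + 1)
        cursor = iv.end + cfg.intergenic_gap
    pos = np.array(sorted(set(positions)), dtype=np.int64)
    return genes, pos


def generate_bundle(cfg: SyntheticConfig) -> Bundle:
    """Generate the full in-memory multi-omics bundle (deterministic in
    ``cfg.seed``).  Use :func:`write_bundle` to materialise it on disk."""
    cfg.validate()
    genes, pos = _layout(cfg)
    ids = [g.gene_id for g in genes]
    drivers = ids[: cfg.n_drivers]
    homeobox = ids[: cfg.n_homeobox]
    driver_set = set(drivers)
    homeobox_set = set(homeobox)

    # planted per-driver effect scale: methylation gain and lfc co-vary,
    # giving the positive meth/expression relation the pipeline must recover
    rng_fx = _substream(cfg.seed, 0)
    u = rng_fx.uniform(0.5, 1.5, size=cfg.n_drivers)
    delta = np.minimum(cfg.delta_meth * u, 1 - cfg.beta_low - 1e-3)
    lfc = cfg.driver_lfc * u

    truth_genes = pd.DataFrame(
        {
            "is_driver": [g in driver_set for g in ids],
            "is_homeobox": [g in homeobox_set for g in ids],
            "lfc": 0.0,
            "delta_meth": 0.0,
        },
        index=pd.Index(ids, name="gene"),
    )
    truth_genes.loc[drivers, "lfc"] = lfc
    truth_genes.loc[drivers, "delta_meth"] = delta

    # planted UMRs: central run of genic CpGs in every homeobox gene body
    umrs: dict[str, GenomicInterval] = {}
    gene_by_id = {g.gene_id: g for g in genes}
    umr_site_mask = np.zeros(len(pos), dtype=bool)
    umr_gene_of_site = np.full(len(pos), -1, dtype=int)
    for gid in homeobox:
        iv = gene_by_id[gid].interval
        genic = np.flatnonzero(
            (pos - 1 >= iv.start) & (pos - 1 < iv.end) & ((pos - 1 - iv.start) % cfg.cpg_spacing_genic == 0)
        )
        k = cfg.umr_cpgs_per_driver
        mid = len(genic) // 2
        sel = genic[mid - k // 2: mid - k // 2 + k]
        umrs[gid] = GenomicInterval("chr1", int(pos[sel[0]]) - 1, int(pos[sel[-1]]))
        umr_site_mask[sel] = True
        umr_gene_of_site[sel] = ids.index(gid)

    # ---- methylome ---------------------------------------------------
    rng_m = _substream(cfg.seed, 1)
    n_pairs = cfg.n_pairs
    tumor_samples = [f"T{i + 1:03d}" for i in range(n_pairs)]
    normal_samples = [f"N{i + 1:03d}" for i in range(n_pairs)]
    samples = tumor_samples + normal_samples
    sample_meta = pd.DataFrame(
        {
            "condition": ["tumor"] * n_pairs + ["normal"] * n_pairs,
            "pair_id": [f"P{i + 1:03d}" for i in range(n_pairs)] * 2,
        },
        index=pd.Index(samples, name="sample"),
    )

    n_sites = len(pos)
    mu = np.full((n_sites, 2 * n_pairs), cfg.beta_high, dtype=np.float64)
    umr_rows = np.flatnonzero(umr_site_mask)
    mu[umr_rows, :] = cfg.beta_low
    driver_rows = umr_rows[umr_gene_of_site[umr_rows] < cfg.n_drivers]
    d_of_row = umr_gene_of_site[driver_rows]
    mu[driver_rows, :n_pairs] = cfg.beta_low + delta[d_of_row][:, None]

    cov = rng_m.poisson(cfg.mean_coverage, size=mu.shape)
    low = rng_m.random(mu.shape) < cfg.low_coverage_frac
    cov = np.where(low, rng_m.poisson(2.0, size=mu.shape), cov)
    cov = np.maximum(cov, 1)
    c = cfg.beta_concentration
    p = rng_m.beta(mu * c, (1 - mu) * c)
    meth = rng_m.binomial(cov, p)
    sites = pd.DataFrame({"chrom": "chr1", "pos": pos})
    methylome = MethylomeMatrix(
        sites, meth.astype(np.int32), cov.astype(np.int32), samples, sample_meta
    )

    # ---- expression --------------------------------------------------
    rng_e = _substream(cfg.seed, 2)
    base = np.exp(rng_e.normal(np.log(cfg.base_mean), 1.0, size=cfg.n_genes))
    sf = rng_e.uniform(0.7, 1.3, size=2 * n_pairs)
    activity = pd.Series(rng_e.normal(0, 1, size=n_pairs), index=tumor_samples)
    mean_mat = np.outer(base, sf)
    fold = np.ones(cfg.n_genes)
    fold[: cfg.n_drivers] = 2.0 ** lfc
    mean_mat[:, :n_pairs] *= fold[:, None]
    axis_genes = drivers[: cfg.axis_size]
    for gi, gid in enumerate(axis_genes):
        mean_mat[gi, :n_pairs] *= 2.0 ** (cfg.axis_activity_lfc * activity.to_numpy())
    r = 1.0 / cfg.nb_dispersion
    counts = rng_e.negative_binomial(r, r / (r + mean_mat))
    expression = ExpressionMatrix(
        pd.DataFrame(counts, index=pd.Index(ids, name="gene"), columns=samples),
        sample_meta,
    )

    # ---- variants ----------------------------------------------------
    rng_v = _substream(cfg.seed, 3)
    rows = []
    for gi, g in enumerate(genes):
        is_driver = gi < cfg.n_drivers
        rate = cfg.snv_rate_per_kb * (cfg.driver_snv_mult if is_driver else 1.0)
        n_snv = rng_v.poisson(rate * g.interval.length / 1000.0)
        if n_snv == 0:
            continue
        vpos = rng_v.integers(g.interval.start + 1, g.interval.end + 1, size=n_snv)
        af = rng_v.beta(2, 50, size=n_snv)
        if is_driver:
            af = np.minimum(af * cfg.maf_scale, 0.5)
        for j in range(n_snv):
            if is_driver and rng_v.random() < cfg.driver_cpg_ct_frac:
                ref, alt = "C", "T"
                ctx = rng_v.choice(_BASES) + "CG"
            else:
                ref = rng_v.choice(np.array(["C", "T"]))
                alt = rng_v.choice(np.array([b for b in "ACGT" if b != ref]))
                ctx = rng_v.choice(_BASES) + ref + rng_v.choice(np.array(["A", "C", "T"]))
            rows.append(
                {
                    "chrom": "chr1",
                    "pos": int(vpos[j]),
                    "ref": ref,
                    "alt": alt,
                    "af": float(af[j]),
                    "context": ctx,
                    "gene": g.gene_id,
                }
            )
    variants = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "af", "context", "gene"]
    )

    # ---- interaction network -----------------------------------------
    rng_n = _substream(cfg.seed, 4)
    ia, ib = np.triu_indices(cfg.n_genes, k=1)
    is_drv = np.zeros(cfg.n_genes, dtype=bool)
    is_drv[: cfg.n_drivers] = True
    p_edge = np.where(
        is_drv[ia] | is_drv[ib], cfg.edge_prob_driver, cfg.edge_prob_background
    )
    keep = rng_n.random(len(ia)) < p_edge
    ea, eb = ia[keep], ib[keep]
    drv_edge = is_drv[ea] | is_drv[eb]
    scores = np.where(
        drv_edge,
        rng_n.integers(600, 1000, size=len(ea)),
        rng_n.integers(150, 1000, size=len(ea)),
    )
    id_arr = np.array(ids)
    edges = pd.DataFrame(
        {"gene_a": id_arr[ea], "gene_b": id_arr[eb], "combined_score": scores}
    )

    # ---- missense Z ---------------------------------------------------
    rng_z = _substream(cfg.seed, 5)
    mz = rng_z.normal(*cfg.missense_z_background, size=cfg.n_genes)
    mz[: cfg.n_drivers] = rng_z.normal(*cfg.missense_z_driver, size=cfg.n_drivers)
    missense_z = pd.Series(mz, index=pd.Index(ids, name="gene"), name="missense_z")

    # ---- survival -----------------------------------------------------
    rng_s = _substream(cfg.seed, 6)
    surv = simulate_survival(
        activity.to_numpy(),
        rng_s,
        baseline_hazard=cfg.survival_baseline_hazard,
        hazard_ratio=cfg.hazard_ratio_per_activity,
        censor_window=cfg.censor_window,
        sample_ids=tumor_samples,
    )

    truth = TruthTable(truth_genes, umrs, axis_genes, activity)
    return Bundle(cfg, genes, methylome, expression, variants, edges, missense_z, surv, truth)


def simulate_survival(
    activity: np.ndarray,
    rng: np.random.Generator,
    baseline_hazard: float = 0.02,
    hazard_ratio: float = 2.0,
    censor_window: tuple[float, float] = (12.0, 60.0),
    sample_ids: Sequence[str] | None = None,
) -> SurvivalTable:
    """Exponential proportional-hazards survival: hazard multiplied by
    ``hazard_ratio`` per unit of activity, uniform administrative
    censoring inside ``censor_window`` (months)."""
    n = len(activity)
    hazard = baseline_hazard * hazard_ratio ** np.asarray(activity, float)
    t_event = rng.exponential(1.0 / hazard)
    t_cens = rng.uniform(*censor_window, size=n)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    if sample_ids is None:
        sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    return SurvivalTable(
        pd.DataFrame({"time": time, "event": event}, index=pd.Index(sample_ids, name="sample"))
    )


def simulate_axis_cohort(
    n_samples: int,
    rng: np.random.Generator,
    axis_size: int = 5,
    base_mean: float = 200.0,
    nb_dispersion: float = 0.1,
    activity_lfc: float = 1.0,
    baseline_hazard: float = 0.02,
    hazard_ratio: float = 2.0,
    censor_window: tuple[float, float] = (12.0, 60.0),
):
    """A single-arm cohort for survival-axis power studies: axis-gene
    expression modulated by a latent activity, plus matching survival.

    Returns (counts DataFrame, SurvivalTable, true activity Series).
    """
    activity = rng.normal(0, 1, size=n_samples)
    sample_ids = [f"S{i + 1:03d}" for i in range(n_samples)]
    base = np.exp(rng.normal(np.log(base_mean), 0.5, size=axis_size))
    mean_mat = np.outer(base, 2.0 ** (activity_lfc * activity))
    r = 1.0 / nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mean_mat))
    genes = [f"AXIS{i + 1}" for i in range(axis_size)]
    df = pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=sample_ids)
    surv = simulate_survival(
        activity, rng, baseline_hazard, hazard_ratio, censor_window, sample_ids
    )
    return df, surv, pd.Series(activity, index=sample_ids)


# ---------------------------------------------------------------------------
# disk round-trip and truth reporting
# ---------------------------------------------------------------------------


def write_bundle(bundle: Bundle, outdir) -> dict[str, Path]:
    """Write every bundle component in the formats the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "gene_models": outdir / "gene_models.bed",
        "methylome": outdir / "methylome.tsv",
        "expression": outdir / "expression_counts.tsv",
        "sample_meta": outdir / "sample_meta.tsv",
        "variants": outdir / "variants.tsv",
        "edges": outdir / "edges.tsv",
        "missense_z": outdir / "missense_z.tsv",
        "survival": outdir / "survival.tsv",
        "homeobox": outdir / "homeobox_genes.txt",
        "truth_genes": outdir / "truth_genes.tsv",
        "truth_activity": outdir / "truth_activity.tsv",
        "config": outdir / "config.yaml",
    }
    write_gene_models(bundle.gene_models, paths["gene_models"])
    write_methylome(bundle.methylome, paths["methylome"])
    write_expression(bundle.expression, paths["expression"])
    write_sample_meta(bundle.expression.sample_meta, paths["sample_meta"])
    write_table(bundle.variants, paths["variants"])
    write_table(bundle.edges, paths["edges"])
    write_table(bundle.missense_z.rename_axis("gene").reset_index(), paths["missense_z"])
    write_survival(bundle.survival, paths["survival"])
    paths["homeobox"].write_text("\n".join(bundle.truth.homeobox) + "\n")
    tg = bundle.truth.genes.copy()
    tg["umr_start"] = [
        bundle.truth.umrs[g].start if g in bundle.truth.umrs else -1 for g in tg.index
    ]
    tg["umr_end"] = [
        bundle.truth.umrs[g].end if g in bundle.truth.umrs else -1 for g in tg.index
    ]
    write_table(tg.reset_index(), paths["truth_genes"])
    write_table(
        bundle.truth.activity.rename("activity").rename_axis("sample").reset_index(),
        paths["truth_activity"],
    )
    import yaml

    cfgd = asdict(bundle.config)
    cfgd["axis_genes"] = bundle.truth.axis_genes
    paths["config"].write_text(yaml.safe_dump(cfgd, sort_keys=True))
    return paths


def regions_jaccard(a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]) -> float:
    """Base-pair Jaccard overlap between two interval sets."""

    def merged(regions):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for r in regions:
            by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
        out = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            m = [list(ivs[0])]
            for s, e in ivs[1:]:
                if s <= m[-1][1]:
                    m[-1][1] = max(m[-1][1], e)
                else:
                    m.append([s, e])
            out[chrom] = m
        return out

    ma, mb = merged(a), merged(b)
    inter = union = 0
    for chrom in set(ma) | set(mb):
        ia = ma.get(chrom, [])
        ib = mb.get(chrom, [])
        union += sum(e - s for s, e in ia) + sum(e - s for s, e in ib)
        for s1, e1 in ia:
            for s2, e2 in ib:
                ov = min(e1, e2) - max(s1, s2)
                if ov > 0:
                    inter += ov
    union -= inter
    if union == 0:  # both sets empty
        return 1.0
    return inter / union


def truth_report(
    truth: TruthTable,
    ranked_genes: Sequence[str],
    k: int | None = None,
    called_umrs: Sequence[GenomicInterval] | None = None,
) -> dict:
    """Precision/recall of driver recovery at k, plus UMR Jaccard when
    called regions are supplied."""
    known = set(truth.genes.index)
    unknown = [g for g in ranked_genes if g not in known]
    if unknown:
        raise ValidationError(f"ranked genes not in truth table: {unknown[:5]}")
    drivers = set(truth.drivers)
    k = k if k is not None else len(drivers)
    top = list(ranked_genes)[:k]
    hits = sum(1 for g in top if g in drivers)
    report = {
        "k": k,
        "precision_at_k": hits / k if k else float("nan"),
        "recall_at_k": hits / len(drivers) if drivers else float("nan"),
    }
    if called_umrs is not None:
        report["umr_jaccard"] = regions_jaccard(
            list(truth.umrs.values()), list(called_umrs)
        )
    return report
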