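"""End-to-end orchestration: coverage filter → UMR/DMR calling → context
annotation → expression filter/QC/DE → homeobox classification →
methylation/expression integration → gene risk scoring → survival-axis
stratification, with every intermediate table written to disk."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import EpidriverError, StageError, UndefinedValueError, ValidationError
from . import io as eio
from . import methylome as emeth
from . import transcriptome as etx
from . import integration as eint
from . import grs as egrs
from . import survival as esurv

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and stage parameters for a pipeline run."""

    methylome: str
    sample_meta: str
    gene_models: str
    expression: str
    variants: str
    edges: str
    missense_z: str
    homeobox: str
    outdir: str
    survival: str | None = None  # optional: survival stage skipped when absent
    axis_genes: list[str] = field(default_factory=list)  # default: top-5 GRS genes
    # stage parameters (documented defaults of the individual modules)
    min_cov: int = 4
    umr_max_meth: float = 0.10
    umr_min_cpgs: int = 10
    umr_max_gap_bp: int = 1000
    dmr_min_diff: float = 0.1
    dmr_min_cpgs: int = 10
    dmr_fdr: float = 0.05
    promoter_up: int = 1500
    promoter_down: int = 500
    expr_min_count: int = 10
    expr_min_frac: float = 0.05
    qc_z_thresh: float = -2.0
    lfc_thresh: float = 1.0
    de_fdr: float = 0.05
    grs_top_k: int = 15
    network_min_score: int = 700
    survival_min_prop: float = 0.1
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        for name in ("methylome", "sample_meta", "gene_models", "expression",
                     "variants", "edges", "missense_z", "homeobox"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise ValidationError(f"input file for {name!r} not found: {p}")
        if self.survival is not None and not Path(self.survival).exists():
            raise ValidationError(f"survival table not found: {self.survival}")
        if not (0 <= self.umr_max_meth <= 1 and 0 <= self.dmr_fdr <= 1):
            raise ValidationError("thresholds outside documented ranges")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def params_hash(self) -> str:
        d = asdict(self)
        d.pop("outdir", None)  # fingerprint the analysis, not the destination
        blob = yaml.safe_dump(d, sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns the run report (also written as
    report.json).  A failing stage raises StageError naming the stage;
    outputs produced so far are retained next to a FAILED marker."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = (
        f"epidriver {__version__} seed={config.seed} params={config.params_hash()}"
    )
    report: dict = {"version": __version__, "seed": config.seed,
                    "params_hash": config.params_hash()}

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except EpidriverError as e:
                (outdir / "FAILED").write_text(f"{name}: {e}\n")
                raise StageError(name, e) from e
            except Exception as e:  # noqa: BLE001 — report the stage, keep cause
                (outdir / "FAILED").write_text(f"{name}: {e}\n")
                raise StageError(name, e) from e
        return deco

    # ---- load ---------------------------------------------------------
    @stage("load")
    def loaded():
        meta = eio.read_sample_meta(config.sample_meta)
        return {
            "methylome": eio.read_methylome(config.methylome, meta),
            "genes": eio.read_gene_models(config.gene_models),
            "expression": eio.read_expression(config.expression, meta),
            "variants": eio.read_variants(config.variants),
            "edges": eio.read_edges(config.edges),
            "missense_z": eio.read_gene_values(config.missense_z, "missense_z"),
            "homeobox": eio.read_gene_list(config.homeobox),
            "survival": eio.read_survival(config.survival) if config.survival else None,
        }

    genes = loaded["genes"]

    # ---- methylome ----------------------------------------------------
    @stage("methylome")
    def meth_out():
        m = emeth.filter_by_coverage(loaded["methylome"], config.min_cov)
        normal = m.samples_for("normal")
        umrs = emeth.call_umrs(
            m, normal, config.umr_max_meth, config.umr_min_cpgs, config.umr_max_gap_bp
        )
        dmrs = emeth.call_dmrs(
            m,
            min_diff=config.dmr_min_diff,
            min_cpgs=config.dmr_min_cpgs,
            fdr=config.dmr_fdr,
            max_gap_bp=config.umr_max_gap_bp,
        )
        summary = emeth.summarize_dmrs(dmrs)
        ann = emeth.annotate_context(
            [d.interval for d in dmrs], genes, config.promoter_up, config.promoter_down
        )
        eio.write_table(emeth.umrs_to_frame(umrs), outdir / "umrs.tsv", header)
        dmr_frame = emeth.dmrs_to_frame(dmrs)
        dmr_frame["context"] = [a[1] for a in ann]
        dmr_frame["context_gene"] = [a[2] or "" for a in ann]
        eio.write_table(dmr_frame, outdir / "dmrs.tsv", header)
        return m, umrs, dmrs, summary, ann

    m_filt, umrs, dmrs, dmr_summary, dmr_ann = meth_out
    report["dmr_summary"] = {
        "n_hyper": dmr_summary.n_hyper,
        "n_hypo": dmr_summary.n_hypo,
        "hypo_fraction_pct": dmr_summary.hypo_fraction_pct,
        "fold_ratio": dmr_summary.fold_ratio,
    }
    report["n_umrs"] = len(umrs)

    # ---- expression ---------------------------------------------------
    @stage("expression")
    def expr_out():
        e = etx.filter_low_expression(
            loaded["expression"], config.expr_min_count, config.expr_min_frac
        )
        kept, removed = etx.sample_qc_connectivity(e, config.qc_z_thresh)
        if removed:
            keep_meta = e.sample_meta.loc[kept]
            ok_pairs = keep_meta.groupby("pair_id")["condition"].nunique() == 2
            good = keep_meta[keep_meta["pair_id"].map(ok_pairs)].index
            e = etx.ExpressionMatrix(e.counts[list(good)], e.sample_meta)
        de = etx.differential_expression(e, config.lfc_thresh, config.de_fdr)
        sets = etx.classify_homeobox(de, loaded["homeobox"])
        eio.write_table(
            de.rename_axis("gene").reset_index(), outdir / "de_table.tsv", header
        )
        return e, de, sets, removed

    expr, de, hbg_sets, qc_removed = expr_out
    report["de"] = {
        "n_up": int((de["status"] == etx.UP).sum()),
        "n_down": int((de["status"] == etx.DOWN).sum()),
        "n_genes": len(de),
        "qc_removed": qc_removed,
    }
    report["gene_sets"] = {"n_ahbg": len(hbg_sets.ahbg), "n_uhbg": len(hbg_sets.uhbg)}

    # ---- integration --------------------------------------------------
    @stage("integrate")
    def integ_out():
        delta_body = eint.build_gene_delta_table(m_filt, genes, de, "gene_body")
        delta_umr = eint.build_gene_delta_table(
            m_filt, genes, de, "gene_body_umr", normal_umrs=umrs
        )
        correlations = {}
        for set_name, gs in (
            ("all", None),
            ("aHBG", hbg_sets.ahbg),
            ("uHBG", hbg_sets.uhbg),
        ):
            try:
                rho, p, n = eint.methylation_expression_correlation(delta_umr, gs)
                correlations[set_name] = {"rho": rho, "p": p, "n": n}
            except UndefinedValueError:
                correlations[set_name] = None
        hyper_genes = {
            gid
            for (region, label, gid), d in zip(dmr_ann, dmrs)
            if gid is not None and d.direction == "hyper"
        }
        universe = set(de.index)
        ahbg_in = set(hbg_sets.ahbg) & universe
        enr = eint.overlap_enrichment(ahbg_in, hyper_genes & universe, universe)
        spectrum, n_indels = eint.substitution_spectrum(loaded["variants"])
        gene_ivs = [g.interval for g in genes]
        dens = eint.snv_density(loaded["variants"], gene_ivs)
        dens = pd.Series(dens, index=[g.gene_id for g in genes])
        eio.write_table(
            delta_umr.reset_index(), outdir / "gene_body_umr_delta.tsv", header
        )
        return delta_body, delta_umr, correlations, enr, spectrum, n_indels, dens

    delta_body, delta_umr, correlations, enrichment, spectrum, n_indels, snv_dens = integ_out
    report["correlations"] = correlations
    report["ahbg_hyper_overlap"] = {
        "n_a": enrichment.n_a,
        "n_overlap": enrichment.n_overlap,
        "fraction_of_a_pct": enrichment.fraction_of_a_pct,
        "p_value": enrichment.p_value,
    }
    ct_cpg = spectrum.get(("C>T", True), 0)
    total_snv = sum(spectrum.values())
    report["snv"] = {
        "n_snvs": total_snv,
        "n_indels": n_indels,
        "ct_at_cpg_fraction": (ct_cpg / total_snv) if total_snv else float("nan"),
        "mean_density_ahbg": float(snv_dens.reindex(list(hbg_sets.ahbg)).dropna().mean()),
        "mean_density_uhbg": float(snv_dens.reindex(list(hbg_sets.uhbg)).dropna().mean()),
    }

    # ---- gene risk score ----------------------------------------------
    @stage("grs")
    def grs_out():
        connectivity = egrs.network_connectivity(
            loaded["edges"], de.index, config.network_min_score
        )
        maf = egrs.gene_maf(loaded["variants"], genes)
        feats = egrs.assemble_features(
            de["lfc"],
            delta_body["delta_meth"].abs(),
            maf,
            connectivity.astype(float),
            loaded["missense_z"],
        )
        weights = egrs.compute_weights(feats)
        result = egrs.compute_grs(feats, weights)
        top = egrs.rank_and_select(result, config.grs_top_k)
        eio.write_table(
            result.to_frame().rename_axis("gene").reset_index(),
            outdir / "grs.tsv",
            header,
        )
        (outdir / "grs_weights.txt").write_text(
            "\n".join(f"{k}\t{v:.6f}" for k, v in weights.items()) + "\n"
        )
        return result, top, weights

    grs_result, grs_top, grs_weights = grs_out
    report["grs"] = {
        "weights": {k: float(v) for k, v in grs_weights.items()},
        "top_genes": grs_top,
    }

    # ---- survival axis -------------------------------------------------
    if loaded["survival"] is None:
        report["survival"] = {"skipped": "no survival table supplied"}
        log.info("survival stage skipped: no survival table supplied")
    else:
        @stage("survival")
        def surv_out():
            axis = config.axis_genes or [
                g for g in grs_top if g in expr.counts.index
            ][:5]
            surv = loaded["survival"]
            # stratify on every sample with survival data (QC removal only
            # affects the paired DE design, not the survival cohort)
            full = loaded["expression"].counts
            cohort = full[[s for s in surv.data.index if s in full.columns]]
            res = esurv.stratify_by_activity(
                cohort, axis, surv.subset(cohort.columns), config.survival_min_prop
            )
            out = pd.DataFrame(
                {"activity": res.scores, "group": res.groups}
            ).rename_axis("sample").reset_index()
            eio.write_table(out, outdir / "activity_groups.tsv", header)
            for label in ("high", "low"):
                ss = surv.subset(res.groups.index[res.groups == label])
                km = esurv.km_estimate(ss)
                eio.write_table(
                    pd.DataFrame(
                        {"time": km.times, "survival": km.survival,
                         "at_risk": km.at_risk, "events": km.events}
                    ),
                    outdir / f"km_{label}.tsv",
                    header,
                )
            return axis, res

        axis_genes, activity_res = surv_out
        report["survival"] = {
            "axis_genes": list(axis_genes),
            "cutoff": activity_res.cutoff,
            "n_high": int((activity_res.groups == "high").sum()),
            "n_low": int((activity_res.groups == "low").sum()),
            "logrank_chi2": activity_res.logrank_chi2,
            "logrank_p": activity_res.logrank_p,
        }

    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    (outdir / "params.yaml").write_text(yaml.safe_dump(asdict(config), sort_keys=True))
    return report
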