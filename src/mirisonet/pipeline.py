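"""End-to-end orchestration of the analysis stages.

``run_pipeline`` reads every input from disk through the standard
readers, executes catalog -> targets -> expression -> network ->
integration -> divergence -> enrichment, writes per-stage TSVs and a
JSON manifest recording the configuration, thresholds and row counts.
Outputs are pure functions of inputs + config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .core_io import (
    attach_sequences,
    read_bed_intervals,
    read_design_tsv,
    read_expression_tsv,
    read_fasta,
    read_gff_transcripts,
    read_named_bed,
    ExpressionMatrix,
    MirnaRecord,
)
from .divergence import (
    category_proportions,
    find_giddm,
    homolog_category,
    hub_target_enrichment,
    targeted_vs_untargeted,
)
from .enrichment import enrich_terms, results_table
from .expression import de_features, fpkm, variability_filter
from .integration import bin_distribution, demtg_test, target_correlations
from .mirna_catalog import (
    annotate_te_overlap,
    catalog_table,
    de_mirna,
    tissue_presence,
    tpm_quantify,
)
from .network import build_network
from .target_scan import predict_targets

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Input paths plus every analysis threshold, with study defaults."""

    mirna_fasta: str
    isoform_fasta: str
    isoform_gff: str
    premirna_bed: str
    te_bed: str
    mirna_counts: str
    mirna_design: str
    isoform_counts: str
    isoform_design: str
    isoform_lengths: str
    outdir: str
    best_hits: dict = field(default_factory=dict)  # species -> path
    term_map: str | None = None
    reference_tissue: str | None = None  # default: last tissue in design
    length_min: int = 18
    length_max: int = 29
    fdr_threshold: float = 0.05
    log2fc_threshold: float = 1.0
    fpkm_min: float = 0.1
    cv_min: float = 2.0
    score_cutoff: float = 3.0
    beta: float = 6.0
    min_module_size: int = 600
    merge_threshold: float = 0.5
    hub_count: int = 150
    seed: int = 0


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest dictionary."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            k: getattr(config, k)
            for k in (
                "length_min", "length_max", "fdr_threshold", "log2fc_threshold",
                "fpkm_min", "cv_min", "score_cutoff", "beta",
                "min_module_size", "merge_threshold", "hub_count",
            )
        },
        "stages": {},
    }
    t_all = time.time()

    def stage(name):
        logger.info("stage %s", name)
        return time.time()

    try:
        # ---- catalog ----------------------------------------------------
        t0 = stage("catalog")
        mirna_fa = read_fasta(config.mirna_fasta)
        premirna = dict(read_named_bed(config.premirna_bed))
        te = read_bed_intervals(config.te_bed)
        pre_flags = annotate_te_overlap(premirna, te)
        mirnas = [
            MirnaRecord(mid, seq, pre_flags.get(f"pre_{mid}", False))
            for mid, seq in mirna_fa
        ]
        mirna_counts = read_expression_tsv(
            config.mirna_counts, "count", read_design_tsv(config.mirna_design)
        )
        mirna_tpm = tpm_quantify(mirna_counts)
        presence = tissue_presence(mirna_tpm)
        catalog_table(mirnas).to_csv(out / "catalog.tsv", sep="\t", index=False)
        presence.presence.to_csv(out / "presence.tsv", sep="\t")
        tissues = mirna_tpm.tissues
        ref = config.reference_tissue or tissues[-1]
        contrasts = [(t, ref) for t in tissues if t != ref]
        de_mirna_tables = {}
        for a, b in contrasts:
            tab = de_mirna(
                mirna_counts,
                (a, b),
                fdr_threshold=config.fdr_threshold,
                log2fc_threshold=config.log2fc_threshold,
            )
            tab.to_csv(out / f"de_mirna_{a}_vs_{b}.tsv", sep="\t")
            de_mirna_tables[(a, b)] = tab
        manifest["stages"]["catalog"] = {
            "n_mirnas": len(mirnas),
            "n_te_related": int(sum(m.is_te_related for m in mirnas)),
            "presence_common_all": presence.common_all,
            "seconds": round(time.time() - t0, 2),
        }

        # ---- targets ----------------------------------------------------
        t0 = stage("targets")
        skeletons = read_gff_transcripts(config.isoform_gff)
        isoforms = attach_sequences(skeletons, read_fasta(config.isoform_fasta))
        pred = predict_targets(mirnas, isoforms, cutoff=config.score_cutoff)
        sites = pred["sites"]
        sites.to_csv(out / "target_sites.tsv", sep="\t", index=False)
        pred["isoform_summary"].to_csv(
            out / "target_isoform_summary.tsv", sep="\t", index=False
        )
        manifest["stages"]["targets"] = {
            "n_sites": len(sites),
            "n_target_isoforms": int(sites["isoform_id"].nunique()),
            "gene_classes": pd.Series(pred["gene_classes"]).value_counts().to_dict(),
            "seconds": round(time.time() - t0, 2),
        }

        # ---- expression -------------------------------------------------
        t0 = stage("expression")
        iso_counts = read_expression_tsv(
            config.isoform_counts, "count", read_design_tsv(config.isoform_design)
        )
        lengths = pd.read_csv(
            config.isoform_lengths, sep="\t", index_col=0
        ).iloc[:, 0]
        iso_fpkm = fpkm(iso_counts, lengths.to_dict())
        retained, report = variability_filter(
            iso_fpkm, mean_min=config.fpkm_min, cv_min=config.cv_min
        )
        iso_fpkm.to_tsv(out / "isoform_fpkm.tsv")
        iso_tissues = iso_fpkm.tissues
        iso_ref = config.reference_tissue or iso_tissues[-1]
        de_gene_tables = {}
        for a, b in [(t, iso_ref) for t in iso_tissues if t != iso_ref]:
            tab = de_features(
                iso_counts,
                (a, b),
                fdr_threshold=config.fdr_threshold,
                log2fc_threshold=config.log2fc_threshold,
            )
            tab.to_csv(out / f"de_isoform_{a}_vs_{b}.tsv", sep="\t")
            de_gene_tables[(a, b)] = tab
        manifest["stages"]["expression"] = {
            "n_isoforms": report.n_input,
            "n_retained": report.n_retained,
            "seconds": round(time.time() - t0, 2),
        }

        # ---- network ----------------------------------------------------
        t0 = stage("network")
        filt = ExpressionMatrix(
            values=iso_fpkm.values.loc[retained],
            unit="FPKM",
            design=dict(iso_fpkm.design),
        )
        assignment = build_network(
            filt,
            beta=config.beta,
            min_module_size=config.min_module_size,
            merge_threshold=config.merge_threshold,
            hub_count=config.hub_count,
        )
        assign_tab = pd.DataFrame({"module": assignment.labels})
        if assignment.kme is not None:
            own = [
                assignment.kme.at[f, m] if m != "grey" else float("nan")
                for f, m in assignment.labels.items()
            ]
            assign_tab["own_kme"] = own
            hubset = {h for hs in assignment.hubs.values() for h in hs}
            assign_tab["hub"] = [f in hubset for f in assignment.labels.index]
        assign_tab.to_csv(out / "modules.tsv", sep="\t", index_label="isoform_id")
        if assignment.module_trait_r is not None:
            assignment.module_trait_r.to_csv(out / "module_trait_r.tsv", sep="\t")
            assignment.module_trait_p.to_csv(out / "module_trait_p.tsv", sep="\t")
        manifest["stages"]["network"] = {
            "n_modules": len(assignment.modules),
            "module_sizes": {
                m: len(assignment.members(m)) for m in assignment.modules
            },
            "seconds": round(time.time() - t0, 2),
        }

        # ---- integration ------------------------------------------------
        t0 = stage("integration")
        pair_map = sites.rename(columns={"isoform_id": "target_id"})[
            ["mirna_id", "target_id"]
        ].drop_duplicates()
        cors = target_correlations(mirna_tpm, iso_fpkm, pair_map)
        cors.to_csv(out / "pair_correlations.tsv", sep="\t", index=False)
        bins = bin_distribution(cors["r"])
        bins.rename_axis("bin").to_csv(out / "correlation_bins.tsv", sep="\t")
        gene_map = {iso.isoform_id: iso.gene_id for iso in isoforms}
        gene_target_map = sites[["mirna_id", "gene_id"]].drop_duplicates()
        all_genes = set(gene_map.values())
        demtg_rows = []
        for (a, b), mtab in de_mirna_tables.items():
            if (a, b) not in de_gene_tables:
                continue
            gtab = de_gene_tables[(a, b)]
            de_genes = {
                gene_map[i] for i in gtab.index[gtab["de"]] if i in gene_map
            }
            res = demtg_test(
                de_genes, set(mtab.index[mtab["de"]]), gene_target_map, all_genes
            )
            demtg_rows.append(
                {
                    "contrast": f"{a}_vs_{b}",
                    "p_targets": res.proportion_study,
                    "p_background": res.proportion_background,
                    "chi2": res.statistic,
                    "pvalue": res.pvalue,
                    "undefined": res.undefined,
                }
            )
        pd.DataFrame(demtg_rows).to_csv(out / "demtg.tsv", sep="\t", index=False)
        manifest["stages"]["integration"] = {
            "n_pairs": len(cors),
            "bins": bins.to_dict(),
            "seconds": round(time.time() - t0, 2),
        }

        # ---- divergence -------------------------------------------------
        t0 = stage("divergence")
        giddm = find_giddm(assignment, gene_map, sites)
        enr_rows = []
        for m in assignment.modules:
            if len(assignment.members(m)) > config.hub_count:
                res = hub_target_enrichment(assignment, sites, m)
                enr_rows.append(
                    {
                        "module": m,
                        "p_module": res.proportion_background,
                        "p_hubs": res.proportion_study,
                        "chi2": res.statistic,
                        "pvalue": res.pvalue,
                    }
                )
        pd.DataFrame(enr_rows).to_csv(out / "hub_enrichment.tsv", sep="\t", index=False)
        tvu_rows = []
        for t in iso_tissues:
            r = targeted_vs_untargeted(iso_fpkm, gene_map, sites, t)
            tvu_rows.append(
                {
                    "tissue": t,
                    "n_genes": r.n_genes,
                    "median_difference": r.median_difference,
                    "pvalue": r.pvalue,
                    "low_power": r.low_power,
                }
            )
        pd.DataFrame(tvu_rows).to_csv(
            out / "targeted_vs_untargeted.tsv", sep="\t", index=False
        )
        cat_counts = {}
        for species, path in config.best_hits.items():
            hits = pd.read_csv(path, sep="\t")
            best = {
                r.isoform_id: (r.sp_gene, r.sp_isoform)
                for r in hits.itertuples(index=False)
            }
            cats = homolog_category(gene_map, best)
            pd.DataFrame(
                {
                    "gene_id": list(cats),
                    "category": [cats[g].category for g in cats],
                }
            ).to_csv(out / f"homolog_categories_{species}.tsv", sep="\t", index=False)
            cat_counts[species] = category_proportions(cats).to_dict()
        manifest["stages"]["divergence"] = {
            "n_genes_multi_isoform_assigned": giddm.n_genes_multi_isoform_assigned,
            "n_giddm": giddm.n_giddm,
            "n_giddm_targeted": giddm.n_giddm_targeted,
            "category_proportions": cat_counts,
            "seconds": round(time.time() - t0, 2),
        }

        # ---- enrichment ---------------------------------------------------
        if config.term_map:
            t0 = stage("enrichment")
            tm = pd.read_csv(config.term_map, sep="\t")
            term_map = {
                term: set(sub.iloc[:, 0])
                for term, sub in tm.groupby(tm.columns[1])
            }
            study = set(sites["gene_id"])
            population = all_genes
            res = enrich_terms(study & population, population, term_map)
            results_table(res).to_csv(out / "enrichment.tsv", sep="\t", index=False)
            manifest["stages"]["enrichment"] = {
                "n_terms": len(res),
                "seconds": round(time.time() - t0, 2),
            }
    except Exception as exc:  # annotate which stage failed
        done = list(manifest["stages"])
        current = {
            0: "catalog", 1: "targets", 2: "expression", 3: "network",
            4: "integration", 5: "divergence", 6: "enrichment",
        }.get(len(done), "unknown")
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc

    manifest["total_seconds"] = round(time.time() - t_all, 2)
    cfg = asdict(config)
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def config_for_dataset_dir(data_dir, outdir, **overrides) -> PipelineConfig:
    """PipelineConfig pointing at a directory written by write_dataset."""
    d = Path(data_dir)
    best_hits = {
        p.stem.replace("best_hits_", ""): str(p)
        for p in sorted(d.glob("best_hits_*.tsv"))
    }
    kwargs = dict(
        mirna_fasta=str(d / "mirnas.fasta"),
        isoform_fasta=str(d / "isoforms.fasta"),
        isoform_gff=str(d / "isoforms.gff3"),
        premirna_bed=str(d / "premirna.bed"),
        te_bed=str(d / "te.bed"),
        mirna_counts=str(d / "mirna_counts.tsv"),
        mirna_design=str(d / "mirna_design.tsv"),
        isoform_counts=str(d / "isoform_counts.tsv"),
        isoform_design=str(d / "isoform_design.tsv"),
        isoform_lengths=str(d / "isoform_lengths.tsv"),
        outdir=str(outdir),
        best_hits=best_hits,
    )
    kwargs.update(overrides)
    return PipelineConfig(**kwargs)
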