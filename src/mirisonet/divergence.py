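"""Isoform divergence statistics.

* GIDDM detection: genes whose isoforms land in different co-expression
  modules.
* Hub-targeting enrichment: are module hubs more often miRNA targets
  than the module at large?
* Targeted-vs-untargeted within-gene expression comparison.
* Homolog category classification (I/II/III) from cross-species
  best-hit tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .integration import ContingencyResult, proportion_test
from .network import GREY, ModuleAssignment


@dataclass
class GiddmReport:
    per_gene_modules: dict[str, set[str]]  # non-grey modules per gene (>=2 assigned isoforms)
    giddm_genes: set[str]
    targeted_giddm_genes: set[str]

    @property
    def n_genes_multi_isoform_assigned(self) -> int:
        return len(self.per_gene_modules)

    @property
    def n_giddm(self) -> int:
        return len(self.giddm_genes)

    @property
    def n_giddm_targeted(self) -> int:
        return len(self.targeted_giddm_genes)


def find_giddm(
    assignment: ModuleAssignment,
    gene_map: Mapping[str, str],  # isoform_id -> gene_id
    target_table: pd.DataFrame | None = None,  # retained sites; column isoform_id
) -> GiddmReport:
    """Genes with isoforms distributed across different modules.

    Grey isoforms are ignored; a gene is counted only when >= 2 of its
    isoforms are assigned to (non-grey) modules, and is a GIDDM when the
    occupied modules number >= 2.  A GIDDM is 'targeted' when any of the
    gene's isoforms has a retained target site.
    """
    per_gene: dict[str, list[str]] = {}
    for isoform, module in assignment.labels.items():
        if module == GREY:
            continue
        if isoform not in gene_map:
            raise KeyError(f"isoform {isoform!r} has no gene mapping")
        per_gene.setdefault(gene_map[isoform], []).append(module)
    multi = {g: set(mods) for g, mods in per_gene.items() if len(mods) >= 2}
    giddm = {g for g, mods in multi.items() if len(mods) >= 2}

    targeted_genes: set[str] = set()
    if target_table is not None and len(target_table):
        targeted_isoforms = set(target_table["isoform_id"])
        targeted_genes = {
            gene_map[i] for i in targeted_isoforms if i in gene_map
        }
    return GiddmReport(
        per_gene_modules=multi,
        giddm_genes=giddm,
        targeted_giddm_genes=giddm & targeted_genes,
    )


def hub_target_enrichment(
    assignment: ModuleAssignment,
    target_table: pd.DataFrame,
    module: str,
    method: str = "chi2_yates",
) -> ContingencyResult:
    """Targeting rate of a module's hubs versus its non-hub members.

    The 2x2 is (hub vs non-hub member) x (targeted yes/no); the reported
    proportions are the module-wide and hub targeting rates.
    """
    if module not in assignment.modules:
        raise KeyError(f"module {module!r} not present")
    members = set(assignment.members(module))
    hubs = set(assignment.hubs.get(module, []))
    if not hubs or len(members) <= len(hubs):
        res = ContingencyResult(
            np.zeros((2, 2)), np.nan, np.nan, np.nan, np.nan, method, True
        )
        return res
    targeted = set(target_table["isoform_id"]) & members
    return enrichment_from_counts(
        n_targeted_module=len(targeted),
        module_size=len(members),
        n_targeted_hubs=len(targeted & hubs),
        hub_size=len(hubs),
        method=method,
    )


def enrichment_from_counts(
    n_targeted_module: int,
    module_size: int,
    n_targeted_hubs: int,
    hub_size: int,
    method: str = "chi2_yates",
) -> ContingencyResult:
    """Hub-vs-non-hub targeting test from summary counts.

    ``n_targeted_module`` counts targeted isoforms in the whole module
    (hubs included); the non-hub margin is derived by subtraction so hubs
    are not double-counted.
    """
    non_hub = module_size - hub_size
    targeted_non_hub = n_targeted_module - n_targeted_hubs
    res = proportion_test(
        n_targeted_hubs, hub_size, targeted_non_hub, non_hub, method
    )
    res.proportion_study = n_targeted_hubs / hub_size
    res.proportion_background = n_targeted_module / module_size
    return res


@dataclass
class PairedTestResult:
    tissue: str
    n_genes: int
    median_difference: float  # targeted minus untargeted, per-gene means
    statistic: float
    pvalue: float
    low_power: bool = False


def targeted_vs_untargeted(
    fpkm,  # ExpressionMatrix
    gene_map: Mapping[str, str],
    target_table: pd.DataFrame,
    tissue: str,
) -> PairedTestResult:
    """Within-gene comparison of targeted vs untargeted isoform expression.

    Only genes with at least one targeted and one untargeted isoform
    qualify; per gene, the mean FPKM of each class in the tissue is
    paired and tested with the Wilcoxon signed-rank test across genes.
    """
    samples = fpkm.samples_of(tissue)
    if not samples:
        raise ValueError(f"tissue {tissue!r} has no samples")
    expr = fpkm.values[samples].mean(axis=1)
    targeted_isoforms = set(target_table["isoform_id"])

    per_gene: dict[str, dict[str, list[float]]] = {}
    for isoform, gene in gene_map.items():
        if isoform not in expr.index:
            continue
        cls = "targeted" if isoform in targeted_isoforms else "untargeted"
        per_gene.setdefault(gene, {"targeted": [], "untargeted": []})[cls].append(
            float(expr[isoform])
        )
    diffs = []
    for gene, groups in per_gene.items():
        if groups["targeted"] and groups["untargeted"]:
            diffs.append(np.mean(groups["targeted"]) - np.mean(groups["untargeted"]))
    diffs = np.asarray(diffs)
    low_power = len(diffs) < 5
    if len(diffs) == 0 or np.all(diffs == 0):
        return PairedTestResult(tissue, len(diffs), 0.0, np.nan, 1.0, low_power)
    stat, p = stats.wilcoxon(diffs)
    return PairedTestResult(
        tissue, len(diffs), float(np.median(diffs)), float(stat), float(p), low_power
    )


@dataclass
class HomologCategory:
    gene_id: str
    category: str  # 'I', 'II' or 'III'
    evidence: dict[str, tuple[str, str]]  # isoform -> (species gene, species isoform)


def homolog_category(
    gene_map: Mapping[str, str],
    best_hits: Mapping[str, tuple[str, str]],  # isoform -> (sp gene, sp isoform)
) -> dict[str, HomologCategory]:
    """Classify genes by where their isoforms' closest homologs land.

    Only genes with >= 2 hit-bearing isoforms qualify.  Categories:
    I — isoforms hit different genes in the other species (precedence);
    III — same gene, different isoforms; II — all the same isoform.
    """
    per_gene: dict[str, dict[str, tuple[str, str]]] = {}
    for isoform, gene in gene_map.items():
        if isoform in best_hits:
            hit = best_hits[isoform]
            if not (isinstance(hit, tuple) and len(hit) == 2):
                raise ValueError(
                    f"isoform {isoform!r}: best hit must be a single "
                    "(species gene, species isoform) pair"
                )
            per_gene.setdefault(gene, {})[isoform] = hit
    out = {}
    for gene, evidence in per_gene.items():
        if len(evidence) < 2:
            continue
        sp_genes = {h[0] for h in evidence.values()}
        sp_isoforms = {h for h in evidence.values()}
        if len(sp_genes) >= 2:
            cat = "I"
        elif len(sp_isoforms) >= 2:
            cat = "III"
        else:
            cat = "II"
        out[gene] = HomologCategory(gene, cat, evidence)
    return out


def category_proportions(
    categories: Mapping[str, HomologCategory],
    subset: set[str] | None = None,
) -> pd.Series:
    """Fraction of qualifying genes per category (I/II/III) for a subset."""
    genes = [g for g in categories if subset is None or g in subset]
    counts = pd.Series(0.0, index=["I", "II", "III"])
    for g in genes:
        counts[categories[g].category] += 1
    total = counts.sum()
    return counts / total if total else counts


def category_shift(
    categories: Mapping[str, HomologCategory],
    subset_a: set[str],
    subset_b: set[str] | None = None,
) -> pd.DataFrame:
    """Category fractions for two gene subsets and their difference."""
    pa = category_proportions(categories, subset_a)
    pb = category_proportions(categories, subset_b)
    return pd.DataFrame({"subset": pa, "reference": pb, "difference": pa - pb})
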