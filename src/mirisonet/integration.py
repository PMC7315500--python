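"""miRNA–target expression correlation, six-level binning, and the
DEMTG (differentially-expressed-miRNA target gene) proportion test.

Correlations are computed over per-tissue mean profiles: miRNA and mRNA
libraries come from different samples, so tissue is the shared axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Ordered six-level correlation bins.  Negative bins close on their
#: lower bound; 0 belongs to weak_positive.  The partition is total on
#: [-1, 1]: [-1,-0.75] | (-0.75,-0.25] | (-0.25,0) | [0,0.25) |
#: [0.25,0.75) | [0.75,1].
BIN_LABELS = (
    "strong_negative",
    "intermediate_negative",
    "weak_negative",
    "weak_positive",
    "intermediate_positive",
    "strong_positive",
)


def bin_correlation(r: float) -> str:
    """Six-level bin label for a Pearson correlation in [-1, 1]."""
    if not -1.0 <= r <= 1.0 or not np.isfinite(r):
        raise ValueError(f"correlation {r} outside [-1, 1]")
    if r <= -0.75:
        return "strong_negative"
    if r <= -0.25:
        return "intermediate_negative"
    if r < 0:
        return "weak_negative"
    if r < 0.25:
        return "weak_positive"
    if r < 0.75:
        return "intermediate_positive"
    return "strong_positive"


def bin_distribution(r_values: Sequence[float]) -> pd.Series:
    """Counts per bin (ordered); sums to the number of input pairs."""
    counts = pd.Series(0, index=list(BIN_LABELS), dtype=int)
    for r in r_values:
        counts[bin_correlation(float(r))] += 1
    return counts


def target_correlations(
    mirna_abund,  # ExpressionMatrix (TPM)
    target_abund,  # ExpressionMatrix (FPKM)
    target_map: pd.DataFrame,  # columns: mirna_id, target_id
) -> pd.DataFrame:
    """Pearson r between each miRNA and target over shared tissue means.

    Pairs where either profile has zero variance are excluded (logged).
    Returns a DataFrame (mirna_id, target_id, r, bin).
    """
    m_means = mirna_abund.tissue_means()
    t_means = target_abund.tissue_means()
    shared = [t for t in m_means.columns if t in t_means.columns]
    if not shared:
        raise ValueError("no shared tissues between miRNA and target matrices")
    m_means, t_means = m_means[shared], t_means[shared]

    rows = []
    n_excluded = 0
    for mirna_id, target_id in target_map[["mirna_id", "target_id"]].itertuples(
        index=False
    ):
        if mirna_id not in m_means.index or target_id not in t_means.index:
            n_excluded += 1
            continue
        x = m_means.loc[mirna_id].to_numpy(dtype=float)
        y = t_means.loc[target_id].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            n_excluded += 1
            continue
        r = float(np.clip(np.corrcoef(x, y)[0, 1], -1.0, 1.0))
        rows.append(
            {"mirna_id": mirna_id, "target_id": target_id, "r": r, "bin": bin_correlation(r)}
        )
    if n_excluded:
        logger.info("excluded %d pairs (missing features or zero variance)", n_excluded)
    return pd.DataFrame(rows, columns=["mirna_id", "target_id", "r", "bin"])


@dataclass
class ContingencyResult:
    """A 2x2 association test with the proportions it compares."""

    table: np.ndarray  # 2x2 counts
    proportion_study: float
    proportion_background: float
    statistic: float
    pvalue: float
    method: str = "chi2_yates"
    undefined: bool = False


def proportion_test(
    k1: int, n1: int, k2: int, n2: int, method: str = "chi2_yates"
) -> ContingencyResult:
    """Compare k1/n1 against k2/n2 with a 2x2 chi-square (Yates) or Fisher."""
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if (table < 0).any():
        raise ValueError("negative cell in 2x2 table")
    if n1 == 0 or n2 == 0:
        return ContingencyResult(table, np.nan, np.nan, np.nan, np.nan, method, True)
    if method == "fisher":
        stat, p = stats.fisher_exact(table)
    else:
        if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
            return ContingencyResult(
                table, k1 / n1, k2 / n2, np.nan, 1.0, method, True
            )
        stat, p, _, _ = stats.chi2_contingency(table, correction=True)
    return ContingencyResult(table, k1 / n1, k2 / n2, float(stat), float(p), method)


def demtg_test(
    de_genes: set[str],
    de_mirnas: set[str],
    target_map: pd.DataFrame,  # columns mirna_id, gene_id
    all_genes: set[str],
    method: str = "chi2_yates",
) -> ContingencyResult:
    """DE enrichment among targets of DE miRNAs versus the genome background.

    p1 = |DEG ∩ targets(DE miRNAs)| / |targets(DE miRNAs)|, p2 = |DEG| /
    |all genes|; the 2x2 compares DE status of target genes vs non-target
    genes.  With no DE miRNAs the result is flagged undefined.
    """
    if not all_genes:
        raise ValueError("empty gene universe")
    targets = set(
        target_map.loc[target_map["mirna_id"].isin(de_mirnas), "gene_id"]
    ) & all_genes
    if not de_mirnas or not targets:
        return ContingencyResult(
            np.zeros((2, 2)), np.nan, np.nan, np.nan, np.nan, method, True
        )
    de_genes = de_genes & all_genes
    non_targets = all_genes - targets
    k1 = len(de_genes & targets)
    k2 = len(de_genes & non_targets)
    res = proportion_test(k1, len(targets), k2, len(non_targets), method)
    # report the background proportion over the whole genome, as printed
    res.proportion_background = len(de_genes) / len(all_genes)
    return res


def qpcr_concordance(
    mirna_profile: Mapping[str, Sequence[float]],
    qpcr_profile: Mapping[str, Sequence[float]],
    rnaseq_profile: Mapping[str, Sequence[float]],
    pairs: Sequence[tuple[str, str]],
) -> pd.DataFrame:
    """Sign agreement of miRNA–target correlations from qPCR vs RNA-seq.

    For each (mirna, target) pair, computes r(miRNA, qPCR) and r(miRNA,
    RNA-seq) over the shared sample axis and reports whether the signs
    agree.
    """
    rows = []
    for mirna, target in pairs:
        x = np.asarray(mirna_profile[mirna], dtype=float)
        rq = _cor_or_nan(x, np.asarray(qpcr_profile[target], dtype=float))
        rs = _cor_or_nan(x, np.asarray(rnaseq_profile[target], dtype=float))
        rows.append(
            {
                "mirna_id": mirna,
                "target_id": target,
                "r_qpcr": rq,
                "r_rnaseq": rs,
                "concordant": bool(np.sign(rq) == np.sign(rs))
                if np.isfinite(rq) and np.isfinite(rs)
                else False,
            }
        )
    return pd.DataFrame(rows)


def _cor_or_nan(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])
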