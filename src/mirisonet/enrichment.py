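"""Term over-representation tests for gene sets.

Without bias weights the test is the central hypergeometric upper tail.
With per-gene bias weights (e.g. transcript length) it is the Wallenius
non-central hypergeometric upper tail, with the odds parameter estimated
as the mean weight of in-term genes over the mean weight of out-of-term
genes — the length-bias-aware construction used for sequencing-derived
gene sets.  P-values are BH-adjusted across terms.

The Wallenius pmf is evaluated through its integral representation

    P(X = x) = C(m1, x) C(m2, n-x) * I,
    I = ∫_0^1 (1 - t^(w/d))^x (1 - t^(1/d))^(n-x) dt,
    d = w (m1 - x) + (m2 - (n - x)),

by adaptive quadrature, with the central hypergeometric as the exact
w = 1 special case.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import logging

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .de import bh_adjust

logger = logging.getLogger(__name__)


def wallenius_pmf(x: int, m1: int, m2: int, n: int, odds: float) -> float:
    """Wallenius non-central hypergeometric pmf.

    ``m1`` marked and ``m2`` unmarked balls, ``n`` drawn without
    replacement with weight ``odds`` on marked balls; probability of
    drawing exactly ``x`` marked.
    """
    if not (0 <= x <= min(n, m1)) or n - x > m2:
        return 0.0
    if odds <= 0:
        raise ValueError("odds must be positive")
    if abs(odds - 1.0) < 1e-12:
        return float(stats.hypergeom.pmf(x, m1 + m2, m1, n))
    d = odds * (m1 - x) + (m2 - (n - x))
    if d == 0:
        return 1.0 if (x == m1 and n - x == m2) else 0.0
    log_binoms = (
        _log_comb(m1, x) + _log_comb(m2, n - x)
    )

    def integrand(t):
        if t <= 0.0:
            return 0.0 if (x > 0 or n - x > 0) else 1.0
        a = (1.0 - t ** (odds / d)) ** x if x else 1.0
        b = (1.0 - t ** (1.0 / d)) ** (n - x) if n - x else 1.0
        return a * b

    val, _ = integrate.quad(integrand, 0.0, 1.0, epsabs=1e-12, epsrel=1e-10, limit=200)
    return float(np.exp(log_binoms) * val)


def _log_comb(n: int, k: int) -> float:
    from scipy.special import gammaln

    return float(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))


def wallenius_sf(x: int, m1: int, m2: int, n: int, odds: float) -> float:
    """Upper-tail probability P(X >= x)."""
    hi = min(n, m1)
    total = sum(wallenius_pmf(k, m1, m2, n, odds) for k in range(x, hi + 1))
    return float(min(1.0, max(total, 0.0)))


@dataclass
class EnrichmentResult:
    term_id: str
    study_count: int
    study_total: int
    population_count: int
    population_total: int
    odds: float
    pvalue: float
    fdr: float = float("nan")


def enrich_terms(
    study_set: set[str],
    population: set[str],
    term_map: Mapping[str, set[str]],  # term -> genes
    bias_weights: Mapping[str, float] | None = None,
) -> list[EnrichmentResult]:
    """Over-representation p-value per term, BH-corrected across terms.

    Genes in the population without any term are counted in the totals;
    terms with zero population count are skipped (logged).  With
    ``bias_weights`` (gene -> weight, e.g. transcript length) the
    Wallenius test replaces the central hypergeometric.
    """
    if not study_set:
        raise ValueError("empty study set")
    extra = study_set - population
    if extra:
        raise ValueError(f"study genes outside population: {sorted(extra)[:5]}")
    N = len(population)
    n = len(study_set)
    results = []
    for term, genes in term_map.items():
        term_genes = genes & population
        m1 = len(term_genes)
        if m1 == 0:
            logger.info("term %s has no population genes; skipped", term)
            continue
        x = len(study_set & term_genes)
        m2 = N - m1
        if bias_weights is None:
            p = float(stats.hypergeom.sf(x - 1, N, m1, n))
            odds = 1.0
        else:
            w_in = np.mean([bias_weights[g] for g in term_genes])
            outside = population - term_genes
            w_out = np.mean([bias_weights[g] for g in outside]) if outside else w_in
            odds = float(w_in / w_out) if w_out > 0 else 1.0
            p = wallenius_sf(x, m1, m2, n, odds)
        p = float(min(1.0, max(p, np.finfo(float).tiny)))
        results.append(
            EnrichmentResult(
                term_id=term,
                study_count=x,
                study_total=n,
                population_count=m1,
                population_total=N,
                odds=odds,
                pvalue=p,
            )
        )
    if results:
        fdrs = bh_adjust([r.pvalue for r in results])
        for r, f in zip(results, fdrs):
            r.fdr = float(f)
    return results


def results_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term_id": [r.term_id for r in results],
            "study_count": [r.study_count for r in results],
            "study_total": [r.study_total for r in results],
            "population_count": [r.population_count for r in results],
            "population_total": [r.population_total for r in results],
            "odds": [r.odds for r in results],
            "pvalue": [r.pvalue for r in results],
            "fdr": [r.fdr for r in results],
        }
    )
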