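"""Two-group differential-expression test for overdispersed count data.

The decision rule is BH-adjusted FDR < 0.05 together with |log2FC| > 1
(both strict).  The underlying count test is a negative-binomial
exact-style test: library sizes are equalised by scaling counts to the
geometric-mean library size, a common dispersion is estimated by the
method of moments, and the two group sums are compared conditionally on
their total under the NB model.  The test function is pluggable so other
count tests can stand behind the same decision rule.
"""

from __future__ import annotations

from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

FDR_THRESHOLD = 0.05
LOG2FC_THRESHOLD = 1.0


def estimate_common_dispersion(scaled: np.ndarray, groups: Sequence[np.ndarray]) -> float:
    """Method-of-moments common NB dispersion across features.

    For each feature and group with >= 2 samples, phi_hat = (s^2 - m)/m^2
    on library-size-equalised counts; the pooled estimate is the mean of
    the positive per-feature values (0 if none, i.e. Poisson-like data).
    """
    ests = []
    for idx in groups:
        if len(idx) < 2:
            continue
        sub = scaled[:, idx]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        ok = m > 0
        ests.append(((v[ok] - m[ok]) / m[ok] ** 2))
    if not ests:
        return 0.0
    allv = np.concatenate(ests)
    pos = allv[allv > 0]
    if len(pos) == 0:
        return 0.0
    return float(np.clip(pos.mean(), 0.0, 10.0))


def _nb_pmf(k: np.ndarray, mean: float, phi: float) -> np.ndarray:
    """NB pmf with mean/dispersion parameterisation; Poisson limit at phi=0."""
    if phi < 1e-8:
        return stats.poisson.pmf(k, mean)
    r = 1.0 / phi
    p = r / (r + mean)
    return stats.nbinom.pmf(k, r, p)


def nb_exact_pvalue(s1: float, s2: float, n1: int, n2: int, phi: float) -> float:
    """Two-sided conditional test of equal means given group sums s1, s2.

    Under H0 the two group sums are NB with means proportional to group
    sizes; conditioning on the total, the p-value is the summed
    probability of all splits at most as likely as the observed one
    (edgeR-style exact test).
    """
    s1, s2 = int(round(s1)), int(round(s2))
    total = s1 + s2
    if total == 0:
        return 1.0
    mu = total / (n1 + n2)
    # group-sum dispersions: sum of n iid NB(mu, phi) is NB(n*mu, phi/n)
    k = np.arange(total + 1)
    p1 = _nb_pmf(k, n1 * mu, phi / n1)
    p2 = _nb_pmf(k[::-1], n2 * mu, phi / n2)
    joint = p1 * p2
    tot = joint.sum()
    if tot <= 0:
        return 1.0
    joint /= tot
    obs = joint[s1]
    return float(min(1.0, joint[joint <= obs * (1 + 1e-12)].sum()))


def de_test(
    counts: pd.DataFrame,
    design: Mapping[str, str],
    contrast: tuple[str, str],
    *,
    test: Callable[[float, float, int, int, float], float] | None = None,
    pseudo_count: float = 1.0,
    fdr_threshold: float = FDR_THRESHOLD,
    log2fc_threshold: float = LOG2FC_THRESHOLD,
) -> pd.DataFrame:
    """Per-feature DE table for ``contrast = (group_a, group_b)``.

    log2FC is computed on per-million-normalised group means with a
    pseudo-count, positive when group_a is higher, i.e. direction is
    relative to the second (reference) group.  Columns: log2fc, pvalue,
    fdr, de, direction.
    """
    group_a, group_b = contrast
    samples_a = [s for s in counts.columns if design.get(s) == group_a]
    samples_b = [s for s in counts.columns if design.get(s) == group_b]
    if not samples_a or not samples_b:
        missing = group_a if not samples_a else group_b
        raise ValueError(f"contrast group {missing!r} has no samples in design")

    sub = counts[samples_a + samples_b].to_numpy(dtype=float)
    libsizes = sub.sum(axis=0)
    if (libsizes <= 0).any():
        raise ValueError("zero library size in contrast samples")
    target = float(np.exp(np.mean(np.log(libsizes))))
    scaled = sub / libsizes * target

    ia = np.arange(len(samples_a))
    ib = np.arange(len(samples_a), len(samples_a) + len(samples_b))
    phi = estimate_common_dispersion(scaled, [ia, ib])

    cpm = sub / libsizes * 1e6
    mean_a = cpm[:, : len(samples_a)].mean(axis=1)
    mean_b = cpm[:, len(samples_a) :].mean(axis=1)
    with np.errstate(divide="ignore"):  # -inf log2FC allowed at pseudo_count 0
        log2fc = np.log2(mean_a + pseudo_count) - np.log2(mean_b + pseudo_count)

    tester = test or nb_exact_pvalue
    pvals = np.array(
        [
            tester(
                scaled[i, ia].sum(), scaled[i, ib].sum(), len(ia), len(ib), phi
            )
            for i in range(scaled.shape[0])
        ]
    )
    fdr = multipletests(pvals, method="fdr_bh")[1]
    de = (fdr < fdr_threshold) & (np.abs(log2fc) > log2fc_threshold)
    direction = np.where(log2fc > 0, "up", np.where(log2fc < 0, "down", "none"))
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "pvalue": pvals,
            "fdr": fdr,
            "de": de,
            "direction": direction,
        },
        index=counts.index,
    )


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]
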