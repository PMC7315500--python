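"""Isoform/gene abundance normalisation, variability filtering, DE, ΔΔCt.

The variability filter reproduces the pre-network step: keep features
with mean FPKM > 0.1 and coefficient of variation of FPKM > 2, where the
C.V. is computed across per-tissue mean FPKM values (sample standard
deviation, n-1) — the filter targets cross-tissue variability, not
replicate noise.  Both choices are exposed as parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix
from .de import de_test


def fpkm(
    counts: ExpressionMatrix,
    feature_lengths: Mapping[str, float],
    library_sizes: Mapping[str, float] | None = None,
) -> ExpressionMatrix:
    """Fragments per kilobase of transcript per million mapped fragments.

    FPKM_ij = count_ij / (length_i / 1e3) / (libsize_j / 1e6).  Library
    sizes default to column sums of the count matrix.
    """
    if counts.unit != "count":
        raise ValueError(f"fpkm expects counts, got unit={counts.unit!r}")
    lengths = pd.Series(
        [feature_lengths.get(f) for f in counts.feature_ids],
        index=counts.feature_ids,
        dtype=float,
    )
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()])[:5]
        raise KeyError(f"features without length: {missing}")
    bad = lengths[lengths <= 0]
    if len(bad):
        raise ValueError(f"non-positive length for feature {bad.index[0]!r}")
    if library_sizes is None:
        libsizes = counts.values.sum(axis=0)
    else:
        libsizes = pd.Series(
            [library_sizes[s] for s in counts.sample_ids], index=counts.sample_ids
        )
    if (libsizes <= 0).any():
        raise ValueError("non-positive library size")
    values = counts.values.div(lengths / 1e3, axis=0).div(libsizes / 1e6, axis=1)
    return ExpressionMatrix(values=values, unit="FPKM", design=dict(counts.design))


@dataclass
class FilterReport:
    n_input: int
    n_pass_mean: int
    n_pass_cv: int
    n_retained: int
    stats: pd.DataFrame  # per-feature mean and cv


def variability_filter(
    fpkm_matrix: ExpressionMatrix,
    mean_min: float = 0.1,
    cv_min: float = 2.0,
    across_tissue_means: bool = True,
) -> tuple[list[str], FilterReport]:
    """Retain features with mean > mean_min AND C.V. > cv_min (both strict).

    With ``across_tissue_means`` (default) the mean and C.V. are taken
    over per-tissue mean profiles; otherwise over raw sample columns.
    """
    if len(fpkm_matrix.sample_ids) < 2:
        raise ValueError("variability filter needs >= 2 samples")
    profile = (
        fpkm_matrix.tissue_means() if across_tissue_means else fpkm_matrix.values
    )
    mean = profile.mean(axis=1)
    sd = profile.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = pd.Series(
            np.where(mean > 0, sd / mean, 0.0), index=profile.index
        )
    pass_mean = mean > mean_min
    pass_cv = cv > cv_min
    retained = list(profile.index[pass_mean & pass_cv])
    report = FilterReport(
        n_input=len(profile),
        n_pass_mean=int(pass_mean.sum()),
        n_pass_cv=int(pass_cv.sum()),
        n_retained=len(retained),
        stats=pd.DataFrame({"mean": mean, "cv": cv}),
    )
    return retained, report


def de_features(
    counts: ExpressionMatrix,
    contrast: tuple[str, str],
    **kwargs,
) -> pd.DataFrame:
    """DE table for isoforms/genes; same decision rule as the miRNA test."""
    if counts.unit != "count":
        raise ValueError("differential expression runs on raw counts")
    return de_test(counts.values, counts.design, contrast, **kwargs)


def ddct(
    ct: pd.DataFrame,
    target: str,
    reference: str,
    sample: str,
    calibrator: str,
) -> float:
    """Relative expression by the 2^(−ΔΔCt) method.

    ``ct`` is a genes x samples table of Ct values; ΔCt = Ct_target −
    Ct_reference within each sample, ΔΔCt = ΔCt_sample − ΔCt_calibrator.
    """
    for gene in (target, reference):
        if gene not in ct.index:
            raise KeyError(f"gene {gene!r} missing from Ct table")
    for col in (sample, calibrator):
        if col not in ct.columns:
            raise KeyError(f"sample {col!r} missing from Ct table")
    vals = ct.loc[[target, reference], [sample, calibrator]].to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("non-finite Ct value")
    dct_sample = ct.at[target, sample] - ct.at[reference, sample]
    dct_cal = ct.at[target, calibrator] - ct.at[reference, calibrator]
    return float(2.0 ** -(dct_sample - dct_cal))


def ddct_table(ct: pd.DataFrame, reference: str, calibrator: str) -> pd.DataFrame:
    """2^(−ΔΔCt) for every (gene, sample), relative to the calibrator sample."""
    out = {}
    for gene in ct.index:
        if gene == reference:
            continue
        out[gene] = {
            s: ddct(ct, gene, reference, s, calibrator) for s in ct.columns
        }
    return pd.DataFrame(out).T
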