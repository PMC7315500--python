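"""Mature-miRNA catalog construction.

Covers small-RNA read filtering/collapsing (18–29 nt), TE annotation of
precursor loci by interval overlap, TPM quantification, per-tissue
presence (UpSet-style marginals and intersections), differential
expression, and first-base composition summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix, GenomicInterval, MirnaRecord
from .de import de_test

logger = logging.getLogger(__name__)

LENGTH_MIN = 18
LENGTH_MAX = 29  # inclusive


def filter_and_collapse(
    reads: Iterable[str],
    length_min: int = LENGTH_MIN,
    length_max: int = LENGTH_MAX,
) -> pd.DataFrame:
    """Length-filter small-RNA reads and collapse identical sequences.

    Reads containing N are dropped; lengths outside [length_min,
    length_max] are dropped; identical sequences are collapsed with
    summed counts.  Output is sorted by count descending, then sequence.
    """
    counts: dict[str, int] = {}
    for read in reads:
        seq = read.upper().replace("T", "U")
        if "N" in seq:
            continue
        if not (length_min <= len(seq) <= length_max):
            continue
        counts[seq] = counts.get(seq, 0) + 1
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(rows, columns=["sequence", "count"])


def annotate_te_overlap(
    premirna_intervals: Mapping[str, GenomicInterval],
    te_intervals: Sequence[GenomicInterval],
) -> dict[str, bool]:
    """Flag each pre-miRNA that overlaps a TE by >= 1 bp (strand ignored)."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for te in te_intervals:
        by_chrom.setdefault(te.chrom, []).append(te)
    flags = {}
    for name, pre in premirna_intervals.items():
        tes = by_chrom.get(pre.chrom)
        if tes is None:
            logger.debug("no TE intervals on %s; %s not TE-related", pre.chrom, name)
            flags[name] = False
            continue
        flags[name] = any(pre.overlaps(te) for te in tes)
    return flags


def inherit_te_flags(
    mirna_precursors: Mapping[str, Sequence[str]],
    precursor_flags: Mapping[str, bool],
) -> dict[str, bool]:
    """A mature miRNA is TE-related if any producing precursor is flagged."""
    return {
        mirna: any(precursor_flags.get(p, False) for p in precursors)
        for mirna, precursors in mirna_precursors.items()
    }


def tpm_quantify(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Counts-per-million for small RNAs (uniform effective length).

    Every column of the result sums to 1e6.
    """
    if counts.unit != "count":
        raise ValueError(f"tpm_quantify expects counts, got {counts.unit!r}")
    totals = counts.values.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero column sum in sample {zero.index[0]!r}")
    values = counts.values / totals * 1e6
    return ExpressionMatrix(values=values, unit="TPM", design=dict(counts.design))


@dataclass
class PresenceSummary:
    presence: pd.DataFrame        # miRNA x tissue boolean
    per_tissue: pd.Series         # total present per tissue
    common_all: int               # present in every tissue
    unique_per_tissue: pd.Series  # present in exactly that one tissue


def tissue_presence(
    abundance: ExpressionMatrix, threshold: float = 0.0
) -> PresenceSummary:
    """Per-tissue presence: a miRNA is present if any replicate exceeds
    the threshold (default: TPM > 0)."""
    tissues = abundance.tissues
    for t in tissues:
        if not abundance.samples_of(t):
            raise ValueError(f"tissue {t!r} has no samples")
    cols = {}
    for t in tissues:
        sub = abundance.values[abundance.samples_of(t)]
        cols[t] = (sub > threshold).any(axis=1)
    presence = pd.DataFrame(cols)
    n_tissues = presence.sum(axis=1)
    return PresenceSummary(
        presence=presence,
        per_tissue=presence.sum(axis=0),
        common_all=int((n_tissues == len(tissues)).sum()),
        unique_per_tissue=pd.Series(
            {
                t: int(((n_tissues == 1) & presence[t]).sum())
                for t in tissues
            }
        ),
    )


def de_mirna(
    counts: ExpressionMatrix,
    contrast: tuple[str, str],
    **kwargs,
) -> pd.DataFrame:
    """Per-miRNA DE table (FDR < 0.05 and |log2FC| > 1, strict)."""
    if counts.unit != "count":
        raise ValueError("differential expression runs on raw counts")
    return de_test(counts.values, counts.design, contrast, **kwargs)


def base_composition(
    records: Sequence[MirnaRecord] | Sequence[str],
) -> pd.DataFrame:
    """Per length class, the fraction of sequences starting with each base.

    Rows are length classes, columns A/C/G/U; each row sums to 1.
    """
    seqs = [
        r.sequence if isinstance(r, MirnaRecord) else str(r).upper().replace("T", "U")
        for r in records
    ]
    if not seqs:
        raise ValueError("empty catalog")
    df = pd.DataFrame({"length": [len(s) for s in seqs], "first": [s[0] for s in seqs]})
    table = (
        df.groupby("length")["first"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
    )
    return table.reindex(columns=["A", "C", "G", "U"], fill_value=0.0)


def catalog_table(records: Sequence[MirnaRecord]) -> pd.DataFrame:
    """Flat catalog: id, sequence, length, TE flag."""
    return pd.DataFrame(
        {
            "mirna_id": [r.mirna_id for r in records],
            "sequence": [r.sequence for r in records],
            "length": [r.length for r in records],
            "is_te_related": [r.is_te_related for r in records],
        }
    )


def collapse_identical_matures(records: Sequence[MirnaRecord]) -> list[MirnaRecord]:
    """Collapse records with identical mature sequences into one, OR-ing
    the TE flag (identical matures can arise from many precursors)."""
    by_seq: dict[str, MirnaRecord] = {}
    for rec in records:
        if rec.sequence in by_seq:
            kept = by_seq[rec.sequence]
            kept.is_te_related = kept.is_te_related or rec.is_te_related
        else:
            by_seq[rec.sequence] = MirnaRecord(
                rec.mirna_id, rec.sequence, rec.is_te_related, rec.precursor_interval
            )
    return list(by_seq.values())
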