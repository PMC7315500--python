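"""Shared domain types and readers/writers for the standard formats.

All internal coordinates are 0-based half-open.  GFF3 (1-based inclusive)
is converted on read.  The internal nucleotide alphabet is RNA (ACGU);
DNA-alphabet input is normalised by mapping T to U.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO

RNA_ALPHABET = frozenset("ACGU")

VALID_UNITS = ("count", "TPM", "FPKM", "CPM")


def normalize_rna(seq: str) -> str:
    """Uppercase a nucleotide string and map T to U."""
    return seq.upper().replace("T", "U")


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval; strand '.' means unstranded."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 bp; strand is ignored."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class MirnaRecord:
    """A mature miRNA sequence with optional precursor/TE annotation."""

    mirna_id: str
    sequence: str
    is_te_related: bool = False
    precursor_interval: GenomicInterval | None = None

    def __post_init__(self):
        self.sequence = normalize_rna(self.sequence)
        bad = set(self.sequence) - RNA_ALPHABET
        if bad:
            raise ValueError(
                f"miRNA {self.mirna_id}: non-ACGU characters {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class IsoformRecord:
    """One transcript isoform with UTR/CDS segmentation.

    Segments are [start, end) in transcript coordinates and must tile the
    sequence: utr5.end == cds.start, cds.end == utr3.start,
    utr3.end == len(sequence).  Any segment may be empty.
    """

    isoform_id: str
    gene_id: str
    sequence: str
    utr5: tuple[int, int] = (0, 0)
    cds: tuple[int, int] = (0, 0)
    utr3: tuple[int, int] = (0, 0)

    def __post_init__(self):
        self.sequence = normalize_rna(self.sequence)
        n = len(self.sequence)
        if self.utr5 == (0, 0) and self.cds == (0, 0) and self.utr3 == (0, 0):
            # no segmentation given: treat whole transcript as CDS
            self.cds = (0, n)
            self.utr3 = (n, n)
        u5, c, u3 = self.utr5, self.cds, self.utr3
        if not (u5[0] == 0 and u5[1] == c[0] and c[1] == u3[0] and u3[1] == n):
            raise ValueError(
                f"isoform {self.isoform_id}: segments {u5}, {c}, {u3} do not "
                f"tile [0, {n})"
            )

    def region_of(self, start: int, end: int) -> str:
        """Label a site [start, end) as 5UTR / CDS / 3UTR by largest overlap.

        Ties are broken in favour of CDS, then toward the 3'UTR.
        """
        if not (0 <= start < end <= len(self.sequence)):
            raise ValueError(
                f"site [{start}, {end}) outside transcript "
                f"{self.isoform_id} of length {len(self.sequence)}"
            )

        def ov(seg):
            return max(0, min(end, seg[1]) - max(start, seg[0]))

        overlaps = {"5UTR": ov(self.utr5), "CDS": ov(self.cds), "3UTR": ov(self.utr3)}
        best = max(overlaps.values())
        for label in ("CDS", "3UTR", "5UTR"):  # CDS wins ties
            if overlaps[label] == best:
                return label
        raise AssertionError("unreachable")


@dataclass
class ExpressionMatrix:
    """A features x samples abundance table with a sample -> tissue design.

    ``values`` is a pandas DataFrame (index = feature ids, columns = sample
    ids); ``design`` maps every sample id to a tissue label.
    """

    values: pd.DataFrame
    unit: str
    design: Mapping[str, str]

    def __post_init__(self):
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {VALID_UNITS}")
        if (self.values.values < 0).any():
            raise ValueError("expression values must be non-negative")
        missing = [s for s in self.values.columns if s not in self.design]
        if missing:
            raise ValueError(f"samples without tissue label in design: {missing}")
        self.design = {s: self.design[s] for s in self.values.columns}

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def tissues(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.design[s], None)
        return list(seen)

    def samples_of(self, tissue: str) -> list[str]:
        return [s for s in self.sample_ids if self.design[s] == tissue]

    def tissue_means(self) -> pd.DataFrame:
        """Average replicate columns within each tissue (features x tissues)."""
        groups = pd.Series({s: self.design[s] for s in self.sample_ids})
        means = self.values.T.groupby(groups).mean().T
        return means[self.tissues]

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="feature_id")


def read_expression_tsv(path, unit: str, design: Mapping[str, str]) -> ExpressionMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(values=values, unit=unit, design=design)


def read_design_tsv(path) -> dict[str, str]:
    """Read a two-column (sample_id, tissue) TSV with a header row."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_design_tsv(design: Mapping[str, str], path) -> None:
    pd.DataFrame(
        {"sample_id": list(design), "tissue": [design[s] for s in design]}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA records as (id, RNA sequence), order preserved.

    Ids are the first whitespace-delimited header token; sequences are
    uppercased with T normalised to U.  Sequence data before the first
    header is a parse error that names the offending line.
    """
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        if not line.startswith(">"):
            raise ValueError(
                f"{path}: line {lineno}: sequence data before first FASTA header"
            )
        break
    records = SeqIO.parse(io.StringIO("".join(lines)), "fasta")
    return [(rec.id, normalize_rna(str(rec.seq))) for rec in records]


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# BED

def read_bed_intervals(path) -> list[GenomicInterval]:
    """Read BED3+ into half-open intervals (BED is natively 0-based)."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: fewer than 3 BED fields")
            chrom, start_s, end_s = fields[0], fields[1], fields[2]
            start, end = int(start_s), int(end_s)
            if start >= end:
                raise ValueError(
                    f"{path}: line {lineno}: start {start} >= end {end}"
                )
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "."
            out.append(GenomicInterval(chrom, start, end, strand))
    return out


def read_named_bed(path) -> list[tuple[str, GenomicInterval]]:
    """BED4+ reader keeping the name column (line index used if absent)."""
    out = []
    with open(path) as fh:
        raw = [
            (i, l.rstrip("\n"))
            for i, l in enumerate(fh, start=1)
            if l.strip() and not l.startswith(("#", "track", "browser"))
        ]
    intervals = read_bed_intervals(path)
    for (lineno, line), iv in zip(raw, intervals):
        fields = line.split("\t")
        name = fields[3] if len(fields) >= 4 else f"line{lineno}"
        out.append((name, iv))
    return out


def write_bed_intervals(intervals: Iterable[GenomicInterval], path, names=None) -> None:
    intervals = list(intervals)
    if names is None:
        names = [f"iv{i}" for i in range(len(intervals))]
    with open(path, "w") as fh:
        for iv, name in zip(intervals, names):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# GFF3 transcript models

_SEGMENT_TYPES = {"five_prime_UTR": "utr5", "CDS": "cds", "three_prime_UTR": "utr3"}


def read_gff_transcripts(path) -> list[IsoformRecord]:
    """Build IsoformRecord skeletons (no sequence) from a GFF3 file.

    mRNA features define transcripts; five_prime_UTR / CDS /
    three_prime_UTR children (linked by Parent) are converted to
    transcript-coordinate half-open segments, strand-aware so that utr5
    always precedes cds in transcript coordinates.  The returned records
    carry an empty sequence; callers attach sequences from FASTA and the
    stored segmentation via :func:`attach_sequences`.
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    transcripts: dict[str, dict] = {}
    for mrna in db.features_of_type("mRNA", order_by="start"):
        gene_id = mrna.attributes.get("Parent", [mrna.id])[0]
        transcripts[mrna.id] = {
            "gene_id": gene_id,
            "start": mrna.start - 1,  # to 0-based
            "end": mrna.end,
            "strand": mrna.strand,
            "segments": {"utr5": [], "cds": [], "utr3": []},
        }
    for ftype, key in _SEGMENT_TYPES.items():
        for feat in db.features_of_type(ftype, order_by="start"):
            parents = feat.attributes.get("Parent", [])
            if not parents:
                raise ValueError(f"{ftype} feature at {feat.start} has no Parent")
            for parent in parents:
                if parent not in transcripts:
                    raise ValueError(
                        f"{ftype} feature at {feat.start}: orphan Parent {parent!r}"
                    )
                transcripts[parent]["segments"][key].append((feat.start - 1, feat.end))

    out = []
    for tid, info in transcripts.items():
        t0, t1, strand = info["start"], info["end"], info["strand"]
        length = t1 - t0

        def to_tx(seg):
            # genomic [a, b) -> transcript coordinates, strand-aware
            a, b = seg
            if strand == "-":
                return (t1 - b, t1 - a)
            return (a - t0, b - t0)

        spans = {}
        for key, segs in info["segments"].items():
            tx = sorted(to_tx(s) for s in segs)
            for (a1, b1), (a2, b2) in zip(tx, tx[1:]):
                if a2 < b1:
                    raise ValueError(
                        f"transcript {tid}: overlapping {key} segments"
                    )
            spans[key] = (tx[0][0], tx[-1][1]) if tx else None

        cds = spans["cds"]
        if cds is None:
            utr5 = (0, 0)
            cds = (0, length)
            utr3 = (length, length)
        else:
            utr5 = spans["utr5"] or (cds[0], cds[0])
            utr3 = spans["utr3"] or (cds[1], cds[1])
            # introns are spliced out upstream; here segments must abut
            utr5 = (0, cds[0])
            utr3 = (cds[1], length)
        out.append(
            IsoformRecord(
                isoform_id=tid,
                gene_id=info["gene_id"],
                sequence="N" * 0 + "A" * length,  # placeholder, replaced on attach
                utr5=utr5,
                cds=cds,
                utr3=utr3,
            )
        )
    return out


def attach_sequences(
    skeletons: Sequence[IsoformRecord], fasta_records: Iterable[tuple[str, str]]
) -> list[IsoformRecord]:
    """Replace placeholder sequences of GFF-derived records with FASTA ones."""
    seqs = dict(fasta_records)
    out = []
    for rec in skeletons:
        if rec.isoform_id not in seqs:
            raise KeyError(f"no sequence for transcript {rec.isoform_id}")
        seq = seqs[rec.isoform_id]
        if len(seq) != len(rec.sequence):
            raise ValueError(
                f"transcript {rec.isoform_id}: FASTA length {len(seq)} != "
                f"GFF span {len(rec.sequence)}"
            )
        out.append(
            IsoformRecord(
                rec.isoform_id, rec.gene_id, seq, rec.utr5, rec.cds, rec.utr3
            )
        )
    return out
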