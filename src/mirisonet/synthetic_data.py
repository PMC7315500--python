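"""Seeded synthetic dataset with planted ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: six tissues with replicates; miRNAs with planted perfectly or
imperfectly complementary sites in a subset of isoforms; genes whose
isoforms differ by inclusion/exclusion of the site-bearing segment
(exon-skipping-like); block-structured tissue-specific expression with
negative miRNA-to-target coupling; TE-overlapping precursor loci; and
two pseudo-species best-hit tables planting homolog categories I/II/III.

Counts are drawn from a negative binomial (mean from the planted
profile, configurable dispersion), matching the overdispersion of real
RNA-seq count data.  The same seed always produces byte-identical
outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import (
    ExpressionMatrix,
    GenomicInterval,
    IsoformRecord,
    MirnaRecord,
    write_bed_intervals,
    write_design_tsv,
    write_fasta,
)

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

DOUBLING_LO, DOUBLING_HI = 2, 13

TISSUES = ("leaf", "petiole", "petal", "anther", "carpel_unpoll", "carpel_poll")


def rna_revcomp(seq: str) -> str:
    """Reverse complement in the RNA alphabet."""
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def _mult(pos: int) -> float:
    return 2.0 if DOUBLING_LO <= pos <= DOUBLING_HI else 1.0


def plant_site(
    isoform_sequence: str,
    mirna_sequence: str,
    position: int,
    distortions: Sequence[tuple[str, int]] = (),
) -> tuple[str, float]:
    """Splice a (possibly distorted) target site into a transcript.

    The undistorted site is the reverse complement of the miRNA, placed
    at ``position`` by replacing the underlying bases, so the transcript
    length is unchanged (an indel distortion changes the site footprint
    by one base, not the transcript length).  Distortions are
    (kind, miRNA position) pairs with kind in {'gu', 'mismatch',
    'bulge', 'gap'}; a bulge at position p inserts an extra target base
    between the partners of miRNA positions p and p+1.  Returns the
    modified transcript and the expected penalty score, computed by the
    same position-dependent penalty arithmetic the scanner applies
    (mismatch/bulge/gap 1, G:U 0.5, doubled at miRNA positions 2–13).
    """
    m = mirna_sequence.upper().replace("T", "U")
    k = len(m)
    site = list(rna_revcomp(m))  # site index t pairs miRNA position k - t
    score = 0.0
    indel: tuple[str, int] | None = None
    seen = set()
    for kind, pos in distortions:
        if pos in seen:
            raise ValueError(f"duplicate distortion position {pos}")
        seen.add(pos)
        if kind == "gu":
            if not 1 <= pos <= k:
                raise ValueError(f"G:U position {pos} outside miRNA 1..{k}")
            base = m[pos - 1]
            if base == "G":
                site[k - pos] = "U"
            elif base == "U":
                site[k - pos] = "G"
            else:
                raise ValueError(
                    f"G:U distortion impossible at position {pos}: miRNA base {base}"
                )
            score += 0.5 * _mult(pos)
        elif kind == "mismatch":
            if not 1 <= pos <= k:
                raise ValueError(f"mismatch position {pos} outside miRNA 1..{k}")
            site[k - pos] = m[pos - 1]  # identical bases never pair
            score += 1.0 * _mult(pos)
        elif kind == "bulge":
            if not 1 <= pos <= k - 1:
                raise ValueError(f"bulge position {pos} outside miRNA 1..{k - 1}")
            if indel is not None:
                raise ValueError("at most one bulge or gap per planted site")
            indel = ("bulge", pos)
            score += 1.0 * _mult(pos)
        elif kind == "gap":
            if not 1 <= pos <= k:
                raise ValueError(f"gap position {pos} outside miRNA 1..{k}")
            if indel is not None:
                raise ValueError("at most one bulge or gap per planted site")
            indel = ("gap", pos)
            score += 1.0 * _mult(pos)
        else:
            raise ValueError(f"unknown distortion kind {kind!r}")
    # indels applied after substitutions so substitution indices stay valid
    if indel is not None:
        kind, pos = indel
        if kind == "bulge":
            site.insert(k - pos, "A")
        else:
            del site[k - pos]
    site_seq = "".join(site)
    if position < 0 or position + len(site_seq) > len(isoform_sequence):
        raise ValueError(
            f"site of length {len(site_seq)} at {position} exceeds transcript "
            f"length {len(isoform_sequence)}"
        )
    new_seq = (
        isoform_sequence[:position]
        + site_seq
        + isoform_sequence[position + len(site_seq):]
    )
    return new_seq, score


@dataclass
class SimConfig:
    """Knobs of the synthetic study.

    Defaults describe the emulated design: six tissues, two replicates
    per tissue per assay, tissue-specific expression modules, and strong
    negative miRNA-to-target expression coupling.
    """

    seed: int
    n_genes: int = 60
    isoforms_per_gene: tuple[int, int] = (1, 4)  # uniform inclusive range
    n_mirnas: int = 20
    mirna_length: int = 21
    frac_te_related: float = 0.44
    tissues: tuple[str, ...] = TISSUES
    mirna_replicates: int = 2
    isoform_replicates: int = 2
    n_modules: int = 4
    flat_gene_fraction: float = 0.35  # housekeeping-like background genes
    flat_mean: float = 300.0
    targeted_gene_fraction: float = 0.5
    split_isoform_fraction: float = 0.6  # targeted multi-isoform genes with partial targeting
    giddm_fraction: float = 0.3
    repression_strength: float = 0.9  # 0 = no coupling, 1 = pure anti-profile
    dispersion: float = 0.05  # NB dispersion phi
    on_mean: float = 400.0  # mean count in the module's tissue
    off_mean: float = 4.0
    mirna_on_mean: float = 800.0
    mirna_off_mean: float = 10.0
    targeted_expression_factor: float = 2.0
    utr5_len: int = 50
    cds_core_len: int = 160
    alt_segment_len: int = 60
    utr3_len: int = 60
    distortion_probs: dict = field(
        default_factory=lambda: {
            "none": 0.55, "gu": 0.2, "mismatch": 0.15, "bulge": 0.05, "gap": 0.05
        }
    )
    site_region_probs: dict = field(
        default_factory=lambda: {"CDS": 0.75, "3UTR": 0.15, "5UTR": 0.10}
    )
    category_probs: dict = field(
        default_factory=lambda: {"I": 0.25, "II": 0.5, "III": 0.25}
    )

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.isoforms_per_gene[0] < 1 or (
            self.isoforms_per_gene[0] > self.isoforms_per_gene[1]
        ):
            raise ValueError("invalid isoforms_per_gene range")
        for frac in (
            self.frac_te_related,
            self.targeted_gene_fraction,
            self.split_isoform_fraction,
            self.giddm_fraction,
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if not 0.0 <= self.repression_strength <= 1.0:
            raise ValueError("repression_strength must lie in [0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        min_seg = min(self.alt_segment_len, self.utr3_len, self.utr5_len, self.cds_core_len // 2)
        if self.mirna_length + 2 > min_seg:
            raise ValueError(
                "site longer than the shortest plantable segment; enlarge "
                "segment lengths or shorten the miRNA"
            )
        if self.n_modules < 1 or self.n_modules > len(self.tissues):
            raise ValueError("n_modules must be in [1, n_tissues]")
        for probs in (self.distortion_probs, self.site_region_probs, self.category_probs):
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError("probability menus must sum to 1")


@dataclass
class SyntheticDataset:
    config: SimConfig
    mirnas: list[MirnaRecord]
    isoforms: list[IsoformRecord]
    premirna_intervals: dict[str, GenomicInterval]
    te_intervals: list[GenomicInterval]
    mirna_precursors: dict[str, list[str]]
    mirna_counts: ExpressionMatrix
    isoform_counts: ExpressionMatrix
    truth_targets: pd.DataFrame  # mirna_id, isoform_id, gene_id, start, end, region, score
    truth_modules: pd.Series  # isoform_id -> planted module label
    truth_homologs: dict[str, pd.DataFrame]  # species -> (isoform_id, sp_gene, sp_isoform)
    truth_categories: dict[str, dict[str, str]]  # species -> gene -> category
    truth_te: dict[str, bool]

    @property
    def gene_map(self) -> dict[str, str]:
        return {iso.isoform_id: iso.gene_id for iso in self.isoforms}


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=n))


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if phi <= 1e-9:
        return rng.poisson(mean)
    r = 1.0 / phi
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def generate_dataset(config: SimConfig) -> SyntheticDataset:
    """Generate the full dataset with planted ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_tissues = len(config.tissues)

    # ---- miRNAs, precursors, TE intervals -------------------------------
    mirna_ids = [f"mir{i + 1:03d}" for i in range(config.n_mirnas)]
    mirna_seqs = {}
    for mid in mirna_ids:
        seq = _random_seq(rng, config.mirna_length)
        while "G" not in seq and "U" not in seq:  # keep G:U distortions possible
            seq = _random_seq(rng, config.mirna_length)
        mirna_seqs[mid] = seq

    te_flags = {
        mid: bool(rng.random() < config.frac_te_related) for mid in mirna_ids
    }
    premirna: dict[str, GenomicInterval] = {}
    te_intervals: list[GenomicInterval] = []
    mirna_precursors: dict[str, list[str]] = {}
    cursor = 1000
    for mid in mirna_ids:
        pre_id = f"pre_{mid}"
        iv = GenomicInterval("chr1", cursor, cursor + 120, "+")
        premirna[pre_id] = iv
        mirna_precursors[mid] = [pre_id]
        if te_flags[mid]:
            # TE overlapping the precursor by half its length
            te_intervals.append(GenomicInterval("chr1", cursor + 60, cursor + 300, "."))
        cursor += 2000
    # decoy TEs away from any precursor
    for _ in range(5):
        start = cursor + int(rng.integers(0, 50_000))
        te_intervals.append(GenomicInterval("chr1", start, start + 500, "."))
        cursor = start + 1000

    mirnas = [
        MirnaRecord(mid, mirna_seqs[mid], te_flags[mid], premirna[f"pre_{mid}"])
        for mid in mirna_ids
    ]

    # ---- genes, isoforms, planted sites ---------------------------------
    iso_counts = rng.integers(
        config.isoforms_per_gene[0], config.isoforms_per_gene[1] + 1, config.n_genes
    )
    gene_ids = [f"g{i + 1:04d}" for i in range(config.n_genes)]
    multi_genes = [g for g, c in zip(gene_ids, iso_counts) if c >= 2]

    targeted_genes = set(
        g
        for g, u in zip(gene_ids, rng.random(config.n_genes))
        if u < config.targeted_gene_fraction
    )
    # flat background genes: stable across tissues, never miRNA-coupled
    p_flat = (
        min(1.0, config.flat_gene_fraction / (1.0 - config.targeted_gene_fraction))
        if config.targeted_gene_fraction < 1.0
        else 0.0
    )
    flat_genes = {
        g
        for g in gene_ids
        if g not in targeted_genes and rng.random() < p_flat
    }
    # iterate in sorted order: consuming rng draws while iterating a set
    # would make the stream depend on the interpreter's hash seed
    split_genes = {
        g
        for g in sorted(targeted_genes)
        if g in multi_genes and rng.random() < config.split_isoform_fraction
    }
    giddm_genes = {
        g
        for g in multi_genes
        if g not in flat_genes and rng.random() < config.giddm_fraction
    }

    dist_kinds = list(config.distortion_probs)
    dist_p = np.array([config.distortion_probs[kk] for kk in dist_kinds])
    region_kinds = list(config.site_region_probs)
    region_p = np.array([config.site_region_probs[kk] for kk in region_kinds])

    isoforms: list[IsoformRecord] = []
    truth_rows = []
    truth_modules = {}
    gene_module = {
        g: i % config.n_modules for i, g in enumerate(gene_ids)
    }
    # dedicate miRNAs to modules so each miRNA's targets share a module
    mirnas_by_module = {
        m: [mid for i, mid in enumerate(mirna_ids) if i % config.n_modules == m]
        for m in range(config.n_modules)
    }
    gene_mirna = {}
    counters = {m: 0 for m in range(config.n_modules)}
    for g in sorted(targeted_genes):
        m = gene_module[g]
        pool = mirnas_by_module[m] or mirna_ids
        gene_mirna[g] = pool[counters[m] % len(pool)]
        counters[m] += 1

    k = config.mirna_length
    for g, n_iso in zip(gene_ids, iso_counts):
        # shared backbone segments
        utr5 = _random_seq(rng, config.utr5_len)
        half = config.cds_core_len // 2
        cds_a = _random_seq(rng, half)
        cds_b = _random_seq(rng, config.cds_core_len - half)
        alt = _random_seq(rng, config.alt_segment_len)
        utr3 = _random_seq(rng, config.utr3_len)

        site_info = None
        if g in targeted_genes:
            mid = gene_mirna[g]
            kind = rng.choice(dist_kinds, p=dist_p)
            if kind == "none":
                distortions = []
            elif kind == "gu":
                cand = [
                    p + 1
                    for p, b in enumerate(mirna_seqs[mid])
                    if b in "GU"
                ]
                distortions = [("gu", int(rng.choice(cand)))]
            elif kind == "bulge":
                distortions = [("bulge", int(rng.integers(1, k)))]
            else:  # mismatch or gap
                distortions = [(kind, int(rng.integers(1, k + 1)))]
            if g in split_genes:
                region = "CDS"  # site lives in the skippable CDS segment
                segment = "alt"
            else:
                region = str(rng.choice(region_kinds, p=region_p))
                segment = {"CDS": "cds_b", "3UTR": "utr3", "5UTR": "utr5"}[region]
            seg_seq = {"alt": alt, "cds_b": cds_b, "utr3": utr3, "utr5": utr5}[segment]
            offset = int(rng.integers(0, len(seg_seq) - (k + 1) + 1))
            planted, score = plant_site(seg_seq, mirna_seqs[mid], offset, distortions)
            footprint = k + sum(
                {"bulge": 1, "gap": -1}.get(kind, 0) for kind, _ in distortions
            )
            if segment == "alt":
                alt = planted
            elif segment == "cds_b":
                cds_b = planted
            elif segment == "utr3":
                utr3 = planted
            else:
                utr5 = planted
            site_info = {
                "mirna_id": mid,
                "segment": segment,
                "offset": offset,
                "length": footprint,
                "score": score,
                "region": region,
            }

        include_alt = rng.random(n_iso) < 0.5
        if g in split_genes:
            include_alt[0], include_alt[-1] = True, False
        elif n_iso >= 1:
            include_alt[0] = True

        for j in range(n_iso):
            iso_id = f"{g}.{j + 1}"
            cds_seq = cds_a + (alt if include_alt[j] else "") + cds_b
            seq = utr5 + cds_seq + utr3
            u5 = (0, len(utr5))
            cds = (len(utr5), len(utr5) + len(cds_seq))
            u3 = (cds[1], len(seq))
            isoforms.append(IsoformRecord(iso_id, g, seq, u5, cds, u3))

            if g in flat_genes:
                truth_modules[iso_id] = "flat"
            elif g in giddm_genes:
                mod = (gene_module[g] + (j % 2)) % config.n_modules
                truth_modules[iso_id] = f"M{mod + 1}"
            else:
                truth_modules[iso_id] = f"M{gene_module[g] + 1}"

            if site_info is not None:
                seg = site_info["segment"]
                carries = seg != "alt" or include_alt[j]
                if carries:
                    if seg == "utr5":
                        start = site_info["offset"]
                    elif seg == "alt":
                        start = len(utr5) + len(cds_a) + site_info["offset"]
                    elif seg == "cds_b":
                        start = (
                            len(utr5)
                            + len(cds_a)
                            + (len(alt) if include_alt[j] else 0)
                            + site_info["offset"]
                        )
                    else:  # utr3
                        start = cds[1] + site_info["offset"]
                    truth_rows.append(
                        {
                            "mirna_id": site_info["mirna_id"],
                            "isoform_id": iso_id,
                            "gene_id": g,
                            "start": start,
                            "end": start + site_info["length"],
                            "region": site_info["region"],
                            "score": site_info["score"],
                        }
                    )

    truth_targets = pd.DataFrame(
        truth_rows,
        columns=["mirna_id", "isoform_id", "gene_id", "start", "end", "region", "score"],
    )
    truth_modules = pd.Series(truth_modules, name="module")

    # ---- expression ------------------------------------------------------
    module_tissue = {m: m % n_tissues for m in range(config.n_modules)}

    def module_profile(mod: int) -> np.ndarray:
        prof = np.full(n_tissues, config.off_mean)
        prof[module_tissue[mod]] = config.on_mean
        return prof

    iso_ids = [iso.isoform_id for iso in isoforms]
    targeted_isoforms = set(truth_targets["isoform_id"])
    iso_samples = [
        f"{t}_r{r + 1}" for t in config.tissues for r in range(config.isoform_replicates)
    ]
    iso_design = {s: s.rsplit("_r", 1)[0] for s in iso_samples}
    iso_mean = np.zeros((len(isoforms), len(iso_samples)))
    scales = rng.lognormal(0.0, 0.3, len(isoforms))
    for idx, iso in enumerate(isoforms):
        label = truth_modules[iso.isoform_id]
        if label == "flat":
            prof = np.full(n_tissues, config.flat_mean) * scales[idx]
        else:
            prof = module_profile(int(label[1:]) - 1) * scales[idx]
        if iso.isoform_id in targeted_isoforms:
            prof = prof * config.targeted_expression_factor
        for s_idx, s in enumerate(iso_samples):
            t_idx = config.tissues.index(iso_design[s])
            iso_mean[idx, s_idx] = prof[t_idx]
    iso_values = _nb_counts(rng, iso_mean, config.dispersion)
    isoform_counts = ExpressionMatrix(
        values=pd.DataFrame(iso_values, index=iso_ids, columns=iso_samples),
        unit="count",
        design=iso_design,
    )

    mir_samples = [
        f"{t}_sr{r + 1}" for t in config.tissues for r in range(config.mirna_replicates)
    ]
    mir_design = {s: s.rsplit("_sr", 1)[0] for s in mir_samples}
    # tissues where each miRNA's targeted isoforms are 'on': the miRNA is
    # kept low there and high elsewhere (anti-correlated coupling)
    on_tissues: dict[str, set[int]] = {mid: set() for mid in mirna_ids}
    for row in truth_targets.itertuples(index=False):
        mod = int(truth_modules[row.isoform_id][1:]) - 1
        on_tissues[row.mirna_id].add(module_tissue[mod])
    mir_mean = np.zeros((len(mirna_ids), len(mir_samples)))
    for idx, mid in enumerate(mirna_ids):
        if on_tissues[mid] and len(on_tissues[mid]) < n_tissues:
            anti = np.full(n_tissues, 1.0)
            anti[sorted(on_tissues[mid])] = 0.0
            s = config.repression_strength
            shape = s * anti + (1 - s) * 0.5
        else:
            shape = np.zeros(n_tissues)
            shape[int(rng.integers(0, n_tissues))] = 1.0
        prof = config.mirna_off_mean + (config.mirna_on_mean - config.mirna_off_mean) * shape
        for s_idx, sname in enumerate(mir_samples):
            t_idx = config.tissues.index(mir_design[sname])
            mir_mean[idx, s_idx] = prof[t_idx]
    mir_values = _nb_counts(rng, mir_mean, config.dispersion)
    mirna_counts = ExpressionMatrix(
        values=pd.DataFrame(mir_values, index=mirna_ids, columns=mir_samples),
        unit="count",
        design=mir_design,
    )

    # ---- pseudo-species homolog tables ----------------------------------
    cat_kinds = list(config.category_probs)
    cat_p = np.array([config.category_probs[kk] for kk in cat_kinds])
    truth_homologs = {}
    truth_categories = {}
    for species in ("speciesA", "speciesB"):
        rows = []
        cats = {}
        for g, n_iso in zip(gene_ids, iso_counts):
            sp_gene = f"{species}_{g}"
            if n_iso < 2:
                rows.append((f"{g}.1", sp_gene, f"{sp_gene}.1"))
                continue
            cat = str(rng.choice(cat_kinds, p=cat_p))
            cats[g] = cat
            for j in range(n_iso):
                iso_id = f"{g}.{j + 1}"
                if cat == "I":
                    hit_gene = f"{species}_{g}x{j % 2}"  # two distinct genes
                    rows.append((iso_id, hit_gene, f"{hit_gene}.1"))
                elif cat == "II":
                    rows.append((iso_id, sp_gene, f"{sp_gene}.1"))
                else:  # III: same gene, different isoforms
                    rows.append((iso_id, sp_gene, f"{sp_gene}.{(j % 2) + 1}"))
        truth_homologs[species] = pd.DataFrame(
            rows, columns=["isoform_id", "sp_gene", "sp_isoform"]
        )
        truth_categories[species] = cats

    return SyntheticDataset(
        config=config,
        mirnas=mirnas,
        isoforms=isoforms,
        premirna_intervals=premirna,
        te_intervals=te_intervals,
        mirna_precursors=mirna_precursors,
        mirna_counts=mirna_counts,
        isoform_counts=isoform_counts,
        truth_targets=truth_targets,
        truth_modules=truth_modules,
        truth_homologs=truth_homologs,
        truth_categories=truth_categories,
        truth_te=te_flags,
    )


def write_dataset(ds: SyntheticDataset, outdir) -> None:
    """Write the dataset as FASTA + GFF3 + BED + TSV so the pipeline can
    consume it through the same readers as real data."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta([(m.mirna_id, m.sequence) for m in ds.mirnas], out / "mirnas.fasta")
    write_fasta(
        [(i.isoform_id, i.sequence) for i in ds.isoforms], out / "isoforms.fasta"
    )
    with open(out / "isoforms.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for iso in ds.isoforms:
            chrom = f"scf_{iso.isoform_id}"
            L = len(iso.sequence)
            fh.write(
                f"{chrom}\tsim\tmRNA\t1\t{L}\t.\t+\t.\t"
                f"ID={iso.isoform_id};Parent={iso.gene_id}\n"
            )
            for (a, b), ftype in (
                (iso.utr5, "five_prime_UTR"),
                (iso.cds, "CDS"),
                (iso.utr3, "three_prime_UTR"),
            ):
                if b > a:
                    fh.write(
                        f"{chrom}\tsim\t{ftype}\t{a + 1}\t{b}\t.\t+\t.\t"
                        f"ID={iso.isoform_id}_{ftype};Parent={iso.isoform_id}\n"
                    )
    write_bed_intervals(
        ds.premirna_intervals.values(),
        out / "premirna.bed",
        names=list(ds.premirna_intervals),
    )
    write_bed_intervals(ds.te_intervals, out / "te.bed")
    ds.mirna_counts.to_tsv(out / "mirna_counts.tsv")
    ds.isoform_counts.to_tsv(out / "isoform_counts.tsv")
    write_design_tsv(ds.mirna_counts.design, out / "mirna_design.tsv")
    write_design_tsv(ds.isoform_counts.design, out / "isoform_design.tsv")
    ds.truth_targets.to_csv(out / "truth_targets.tsv", sep="\t", index=False)
    ds.truth_modules.rename_axis("isoform_id").to_csv(
        out / "truth_modules.tsv", sep="\t"
    )
    for species, table in ds.truth_homologs.items():
        table.to_csv(out / f"best_hits_{species}.tsv", sep="\t", index=False)
    pd.Series(ds.truth_te, name="is_te_related").rename_axis("mirna_id").to_csv(
        out / "truth_te.tsv", sep="\t"
    )
    lengths = pd.Series(
        {i.isoform_id: len(i.sequence) for i in ds.isoforms}, name="length"
    )
    lengths.rename_axis("isoform_id").to_csv(out / "isoform_lengths.tsv", sep="\t")
    cfg = asdict(ds.config)
    cfg["tissues"] = list(cfg["tissues"])
    cfg["isoforms_per_gene"] = list(cfg["isoforms_per_gene"])
    (out / "config.json").write_text(json.dumps(cfg, indent=2, sort_keys=True) + "\n")
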