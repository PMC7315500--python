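"""Complementarity-penalty miRNA target prediction.

A candidate site is an alignment of a miRNA against a transcript window on
the sense strand (the duplex is antiparallel: miRNA position 1 — its 5'
end — pairs with the 3'-most base of the window).  Each alignment column
is one of:

* ``WC_pair``        — Watson–Crick pair (A:U or G:C), penalty 0
* ``GU_pair``        — G:U wobble in either orientation, penalty 0.5
* ``mismatch``       — apposed but non-pairing bases, penalty 1
* ``bulge_in_target``— an extra, unpaired target nucleotide, penalty 1
* ``gap_in_target``  — a miRNA base with no target partner, penalty 1

Penalties are doubled when the column's miRNA position lies in the 5'
window [2, 13].  A bulge column has no miRNA base of its own; for the
doubling test it takes the position of the adjacent miRNA base on the 5'
side.  At most one bulge or gap is allowed per alignment.  Sites scoring
at or below the cutoff (default 3) are retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core_io import IsoformRecord, MirnaRecord

WC_PAIR = "WC_pair"
GU_PAIR = "GU_pair"
MISMATCH = "mismatch"
BULGE_IN_TARGET = "bulge_in_target"
GAP_IN_TARGET = "gap_in_target"

DOUBLING_WINDOW = (2, 13)  # inclusive miRNA positions with doubled penalties
DEFAULT_CUTOFF = 3.0

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "U"), ("U", "G")}

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3}


@dataclass(frozen=True)
class AlignmentColumn:
    """One duplex column; ``mirna_pos`` is 1-based from the miRNA 5' end.

    For ``bulge_in_target`` columns, ``mirna_pos`` is the adjacent 5'-side
    miRNA position used for the doubling test.
    """

    state: str
    mirna_pos: int


@dataclass
class DuplexAlignment:
    mirna_id: str
    isoform_id: str
    site_start: int
    site_end: int
    columns: tuple[AlignmentColumn, ...]
    score: float


@dataclass
class TargetSite:
    alignment: DuplexAlignment
    region: str  # 5UTR / CDS / 3UTR
    retained: bool

    @property
    def mirna_id(self):
        return self.alignment.mirna_id

    @property
    def isoform_id(self):
        return self.alignment.isoform_id

    @property
    def site_start(self):
        return self.alignment.site_start

    @property
    def site_end(self):
        return self.alignment.site_end

    @property
    def score(self):
        return self.alignment.score


def column_penalty(col: AlignmentColumn) -> float:
    """Penalty contribution of a single alignment column."""
    if col.state == WC_PAIR:
        base = 0.0
    elif col.state == GU_PAIR:
        base = 0.5
    elif col.state in (MISMATCH, BULGE_IN_TARGET, GAP_IN_TARGET):
        base = 1.0
    else:
        raise ValueError(f"unknown column state {col.state!r}")
    lo, hi = DOUBLING_WINDOW
    if lo <= col.mirna_pos <= hi:
        base *= 2.0
    return base


def score_duplex(columns: Sequence[AlignmentColumn]) -> float:
    """Sum position-dependent penalties over a validated column list."""
    indels = sum(1 for c in columns if c.state in (BULGE_IN_TARGET, GAP_IN_TARGET))
    if indels > 1:
        raise ValueError(
            f"invalid alignment: {indels} bulge/gap columns (at most 1 allowed)"
        )
    positions = sorted(c.mirna_pos for c in columns if c.state != BULGE_IN_TARGET)
    if positions != list(range(1, len(positions) + 1)):
        raise ValueError("miRNA positions must cover 1..len exactly once")
    return sum(column_penalty(c) for c in columns)


def pair_state(mirna_base: str, target_base: str) -> str:
    pair = (mirna_base, target_base)
    if pair in _WC:
        return WC_PAIR
    if pair in _GU:
        return GU_PAIR
    return MISMATCH


# ---------------------------------------------------------------------------
# Vectorised exhaustive scan
#
# For a miRNA of length k against a transcript T, index candidate duplexes
# by e, the transcript index paired with miRNA position 1 (the 3'-most
# target base of the window).  Gapless: miRNA position i pairs T[e-(i-1)].
# With one target bulge after miRNA position j: positions i > j shift one
# extra base 5'-ward (T[e-i]).  With a gap opposite miRNA position j:
# position j has no partner and positions i > j pair T[e-(i-2)].
# Penalties for all variants decompose into prefix/suffix sums of a single
# k x L doubled-penalty matrix, so the whole scan is O(k L) numpy work.


def _penalty_matrix(mirna: str, target: str) -> np.ndarray:
    """S[i-1, e] = doubled penalty of miRNA position i apposed to T[e-(i-1)].

    S has k + L columns so that shifted lookups (e+1) stay in bounds.
    Entries whose target index falls outside [0, L) are 0: every variant's
    feasible-e mask guarantees such entries either are never part of a
    score or cancel inside the prefix-sum differences.
    """
    k, L = len(mirna), len(target)
    m_idx = np.array([_BASE_INDEX[b] for b in mirna])
    t_idx = np.array([_BASE_INDEX[b] for b in target], dtype=int)
    # 4x4 base-penalty lookup: WC 0, GU 0.5, mismatch 1
    lut = np.ones((4, 4))
    for (a, b) in _WC:
        lut[_BASE_INDEX[a], _BASE_INDEX[b]] = 0.0
    for (a, b) in _GU:
        lut[_BASE_INDEX[a], _BASE_INDEX[b]] = 0.5
    lo, hi = DOUBLING_WINDOW
    S = np.zeros((k, L + k))
    for i in range(1, k + 1):
        mult = 2.0 if lo <= i <= hi else 1.0
        # column e holds the penalty against target index e-(i-1)
        S[i - 1, i - 1 : i - 1 + L] = lut[m_idx[i - 1], t_idx] * mult
    return S


def _best_alignments(mirna: str, target: str, allow_indels: bool = True):
    """Per 3'-end index e, the minimum score over all alignment variants.

    Returns a list of (score, variant, j, e) tuples, one per feasible e,
    where variant is 'gapless' / 'bulge' / 'gap' and j the indel position
    (bulge: extra target base between miRNA positions j and j+1, interior
    only; gap: miRNA position j unopposed, any position).
    """
    k, L = len(mirna), len(target)
    if k > L or k == 0:
        return []
    S = _penalty_matrix(mirna, target)
    # prefix sums over miRNA positions: C[j, e] = sum_{i<=j} S[i-1, e]
    C = np.vstack([np.zeros(S.shape[1]), np.cumsum(S, axis=0)])
    lo, hi = DOUBLING_WINDOW
    e_idx = np.arange(L)

    # gapless: window [e-k+1, e+1), feasible for e in [k-1, L-1]
    best_score = np.where(e_idx >= k - 1, C[k, :L], np.inf)
    best_variant = np.zeros(L, dtype=int)  # 0 gapless, 1 bulge, 2 gap
    best_j = np.zeros(L, dtype=int)

    def _update(sc, variant, j):
        upd = sc < best_score
        best_score[upd] = sc[upd]
        best_variant[upd] = variant
        best_j[upd] = j

    if allow_indels:
        # bulge between miRNA positions j and j+1 (j in 1..k-1): prefix
        # 1..j keeps 3'-end e, suffix j+1..k shifts to 3'-end e-1; the
        # bulge column takes position j for doubling; window [e-k, e+1).
        for j in range(1, k):
            pen = 2.0 if lo <= j <= hi else 1.0
            suffix = C[k, :L] - C[j, :L]
            sc = C[j, :L].copy()
            sc[1:] += suffix[:-1]  # suffix evaluated at 3'-end e-1
            sc[0] = np.inf
            sc += pen
            sc[e_idx < k] = np.inf  # needs k+1 target bases
            _update(sc, 1, j)
        # gap opposite miRNA position j (j in 1..k): prefix 1..j-1 keeps
        # 3'-end e, suffix j+1..k shifts to 3'-end e+1; window [e-k+2, e+1).
        for j in range(1, k + 1):
            pen = 2.0 if lo <= j <= hi else 1.0
            sc = C[j - 1, :L].copy()
            if j < k:
                sc += C[k, 1 : L + 1] - C[j, 1 : L + 1]  # suffix at e+1
            sc += pen
            sc[e_idx < k - 2] = np.inf
            _update(sc, 2, j)

    out = []
    for e in range(L):
        if np.isfinite(best_score[e]):
            variant = ("gapless", "bulge", "gap")[best_variant[e]]
            out.append((float(best_score[e]), variant, int(best_j[e]), e))
    return out


def _build_alignment(
    mirna: MirnaRecord, isoform: IsoformRecord, variant: str, j: int, e: int
) -> DuplexAlignment:
    """Materialise the column list for one (variant, j, e) alignment."""
    m, t = mirna.sequence, isoform.sequence
    k = len(m)
    cols: list[AlignmentColumn] = []
    if variant == "gapless":
        start = e - k + 1
        for i in range(1, k + 1):
            cols.append(AlignmentColumn(pair_state(m[i - 1], t[e - (i - 1)]), i))
    elif variant == "bulge":
        start = e - k
        for i in range(1, j + 1):
            cols.append(AlignmentColumn(pair_state(m[i - 1], t[e - (i - 1)]), i))
        cols.append(AlignmentColumn(BULGE_IN_TARGET, j))
        for i in range(j + 1, k + 1):
            cols.append(AlignmentColumn(pair_state(m[i - 1], t[e - i]), i))
    elif variant == "gap":
        start = e - k + 2
        for i in range(1, j):
            cols.append(AlignmentColumn(pair_state(m[i - 1], t[e - (i - 1)]), i))
        cols.append(AlignmentColumn(GAP_IN_TARGET, j))
        for i in range(j + 1, k + 1):
            cols.append(AlignmentColumn(pair_state(m[i - 1], t[e - (i - 2)]), i))
    else:
        raise ValueError(variant)
    score = score_duplex(cols)
    return DuplexAlignment(
        mirna_id=mirna.mirna_id,
        isoform_id=isoform.isoform_id,
        site_start=start,
        site_end=e + 1,
        columns=tuple(cols),
        score=score,
    )


def find_candidate_sites(
    mirna: MirnaRecord,
    isoform: IsoformRecord,
    cutoff: float = DEFAULT_CUTOFF,
    allow_indels: bool = True,
) -> list[TargetSite]:
    """Exhaustively scan a transcript for retained sites of one miRNA.

    Every window is evaluated under the gapless alignment plus every
    single-bulge and single-gap alignment; per window the minimum-score
    alignment is kept, windows above the cutoff are dropped, and
    overlapping surviving windows are reduced to the best-scoring one
    (ties broken leftmost).
    """
    candidates = _best_alignments(mirna.sequence, isoform.sequence, allow_indels)
    hits = [c for c in candidates if c[0] <= cutoff]
    # greedy reduction: best score first, then leftmost start
    alignments = [
        _build_alignment(mirna, isoform, variant, j, e)
        for (sc, variant, j, e) in hits
    ]
    alignments.sort(key=lambda a: (a.score, a.site_start))
    chosen: list[DuplexAlignment] = []
    for aln in alignments:
        if all(
            aln.site_end <= c.site_start or c.site_end <= aln.site_start
            for c in chosen
        ):
            chosen.append(aln)
    chosen.sort(key=lambda a: a.site_start)
    return [
        TargetSite(
            alignment=aln,
            region=isoform.region_of(aln.site_start, aln.site_end),
            retained=True,
        )
        for aln in chosen
    ]


def annotate_site_region(site: TargetSite, isoform: IsoformRecord) -> str:
    """Region label of a site: segment with the largest overlap (ties: CDS)."""
    return isoform.region_of(site.site_start, site.site_end)


def region_proportions(site_table: pd.DataFrame) -> pd.Series:
    """Percentage of sites per region over a site table; sums to 100."""
    counts = site_table["region"].value_counts()
    props = counts / counts.sum() * 100.0
    return props.reindex(["5UTR", "CDS", "3UTR"]).fillna(0.0)


def alignment_string(aln: DuplexAlignment, mirna: MirnaRecord, isoform: IsoformRecord) -> str:
    """Three-line duplex rendering: miRNA 3'->5', pairing, target 5'->3'."""
    m, t = mirna.sequence, isoform.sequence
    m_line, p_line, t_line = [], [], []
    tpos = aln.site_start
    # columns run miRNA 5'->3', i.e. target 3'->5'; render target 5'->3'
    for col in reversed(aln.columns):
        if col.state == BULGE_IN_TARGET:
            m_line.append("-")
            p_line.append(" ")
            t_line.append(t[tpos])
            tpos += 1
        elif col.state == GAP_IN_TARGET:
            m_line.append(m[col.mirna_pos - 1])
            p_line.append(" ")
            t_line.append("-")
        else:
            m_line.append(m[col.mirna_pos - 1])
            p_line.append({WC_PAIR: "|", GU_PAIR: "o", MISMATCH: " "}[col.state])
            t_line.append(t[tpos])
            tpos += 1
    return (
        "miRNA  3' " + "".join(m_line) + " 5'\n"
        "          " + "".join(p_line) + "\n"
        "target 5' " + "".join(t_line) + " 3'"
    )


def predict_targets(
    mirnas: Sequence[MirnaRecord],
    isoforms: Sequence[IsoformRecord],
    cutoff: float = DEFAULT_CUTOFF,
) -> dict:
    """Predict all retained sites and summarise per isoform and per gene.

    Returns a dict with:

    * ``sites`` — DataFrame (mirna_id, isoform_id, gene_id, start, end,
      score, region)
    * ``isoform_summary`` — per-isoform site and regulator counts
    * ``gene_classes`` — gene_id -> 'all_targeted' / 'partially_targeted'
      / 'untargeted'
    """
    ids = [iso.isoform_id for iso in isoforms]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate isoform ids: {dupes}")

    rows = []
    for iso in isoforms:
        for mir in mirnas:
            for site in find_candidate_sites(mir, iso, cutoff):
                rows.append(
                    {
                        "mirna_id": mir.mirna_id,
                        "isoform_id": iso.isoform_id,
                        "gene_id": iso.gene_id,
                        "start": site.site_start,
                        "end": site.site_end,
                        "score": site.score,
                        "region": site.region,
                    }
                )
    sites = pd.DataFrame(
        rows,
        columns=["mirna_id", "isoform_id", "gene_id", "start", "end", "score", "region"],
    )

    targeted = set(sites["isoform_id"])
    iso_rows = []
    for iso in isoforms:
        sub = sites[sites["isoform_id"] == iso.isoform_id]
        iso_rows.append(
            {
                "isoform_id": iso.isoform_id,
                "gene_id": iso.gene_id,
                "n_sites": len(sub),
                "n_regulators": sub["mirna_id"].nunique(),
            }
        )
    isoform_summary = pd.DataFrame(iso_rows)

    gene_classes: dict[str, str] = {}
    for gene, group in isoform_summary.groupby("gene_id"):
        hit = group["isoform_id"].isin(targeted)
        if hit.all():
            gene_classes[gene] = "all_targeted"
        elif hit.any():
            gene_classes[gene] = "partially_targeted"
        else:
            gene_classes[gene] = "untargeted"

    return {
        "sites": sites,
        "isoform_summary": isoform_summary,
        "gene_classes": gene_classes,
    }
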