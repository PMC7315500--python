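"""Independent brute-force oracles used only by the tests.

These re-derive expected values from first principles with naive
enumeration, deliberately sharing no code with the implementation they
check.
"""

from itertools import combinations

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "U"), ("U", "G")}


def _pen(m_base, t_base, pos):
    if (m_base, t_base) in _WC:
        p = 0.0
    elif (m_base, t_base) in _GU:
        p = 0.5
    else:
        p = 1.0
    return p * (2.0 if 2 <= pos <= 13 else 1.0)


def _indel_pen(pos):
    return 1.0 * (2.0 if 2 <= pos <= 13 else 1.0)


def brute_force_best_scores(mirna: str, target: str) -> dict:
    """Minimum duplex score per 3'-end target index, by full enumeration.

    Enumerates, for every 3'-end index e: the gapless alignment, every
    single-target-bulge alignment (extra target base between miRNA
    positions j and j+1, j = 1..k-1, doubling position j), and every
    single-gap alignment (miRNA position j unopposed, j = 1..k).
    Returns {e: best_score} for feasible e.
    """
    k, L = len(mirna), len(target)
    best = {}

    def consider(e, score):
        if e not in best or score < best[e]:
            best[e] = score

    for e in range(L):
        # gapless: miRNA position i pairs target[e - (i-1)]
        if e - k + 1 >= 0:
            s = sum(
                _pen(mirna[i - 1], target[e - (i - 1)], i) for i in range(1, k + 1)
            )
            consider(e, s)
        # bulge after miRNA position j: suffix shifts one base 5'-ward
        if e - k >= 0:
            for j in range(1, k):
                s = _indel_pen(j)
                for i in range(1, j + 1):
                    s += _pen(mirna[i - 1], target[e - (i - 1)], i)
                for i in range(j + 1, k + 1):
                    s += _pen(mirna[i - 1], target[e - i], i)
                consider(e, s)
        # gap at miRNA position j: position j has no target partner
        if e - k + 2 >= 0:
            for j in range(1, k + 1):
                ok = True
                s = _indel_pen(j)
                for i in range(1, j):
                    s += _pen(mirna[i - 1], target[e - (i - 1)], i)
                for i in range(j + 1, k + 1):
                    idx = e - (i - 2)
                    if idx >= L:
                        ok = False
                        break
                    s += _pen(mirna[i - 1], target[idx], i)
                if ok:
                    consider(e, s)
    return best


def hypergeom_tail_by_enumeration(population, term, study_size, observed):
    """P(|draw ∩ term| >= observed) over all equally likely draws."""
    population = sorted(population)
    term = set(term)
    hits = 0
    total = 0
    for draw in combinations(population, study_size):
        total += 1
        if len(term.intersection(draw)) >= observed:
            hits += 1
    return hits / total
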