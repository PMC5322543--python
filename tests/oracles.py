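"""Independent brute-force oracles, coded separately from the package.

Each oracle re-derives the quantity from first principles (explicit
pairing table, explicit pathway enumeration, exhaustive labeling search)
without importing any scoring machinery from mirdiverge.
"""

from __future__ import annotations

import itertools

# --- duplex scoring oracle -------------------------------------------------

WATSON_CRICK = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
WOBBLE = {("G", "U"), ("U", "G")}


def oracle_score(
    mirna: str,
    window: str,
    wobble_penalty: float = 0.5,
    mismatch_penalty: float = 1.0,
    seed_range: tuple[int, int] | None = None,
    seed_multiplier: float = 1.0,
    seed_scope: str = "all",
) -> float:
    """Score a duplex by walking the pairing table position by position."""
    assert len(mirna) == len(window)
    L = len(mirna)
    total = 0.0
    for i in range(1, L + 1):  # miRNA position from the 5' end
        pair = (mirna[i - 1], window[L - i])  # pairs window position L+1-i
        if pair in WATSON_CRICK:
            pen = 0.0
        elif pair in WOBBLE:
            pen = wobble_penalty
            if seed_range and seed_range[0] <= i <= seed_range[1]:
                pen *= seed_multiplier
        else:
            pen = mismatch_penalty
            if (
                seed_range
                and seed_range[0] <= i <= seed_range[1]
                and seed_scope == "all"
            ):
                pen *= seed_multiplier
        total += pen
    return total


def oracle_scan(mirna: str, transcript: str, cutoff: float, **kwargs):
    """Exhaustive window enumeration: every start, rescored independently."""
    L = len(mirna)
    hits = []
    for start in range(1, len(transcript) - L + 2):
        window = transcript[start - 1 : start - 1 + L]
        s = oracle_score(mirna, window, **kwargs)
        if s <= cutoff:
            hits.append((start, start + L - 1, s))
    return hits


# --- NG86 oracle -------------------------------------------------------------

_CODONS = {}
_B = "TCAG"
_AA = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
for _i, (_a, _b, _c) in enumerate(itertools.product(_B, _B, _B)):
    _CODONS[_a + _b + _c] = _AA[_i]


def _oracle_syn_sites(codon: str) -> float:
    aa = _CODONS[codon]
    s = 0.0
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mut = codon[:pos] + base + codon[pos + 1 :]
            if _CODONS[mut] != "*" and _CODONS[mut] == aa:
                s += 1.0 / 3.0
    return s


def _oracle_path_diffs(c1: str, c2: str) -> tuple[float, float]:
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0
    valid, fallback = [], []
    for order in itertools.permutations(positions):
        cur, sd, nd, ok = c1, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if _CODONS[nxt] == "*":
                ok = False
            if _CODONS[cur] != "*" and _CODONS[nxt] != "*" and _CODONS[cur] == _CODONS[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        (valid if ok else fallback).append((sd, nd))
    pool = valid if valid else fallback
    return (
        sum(x[0] for x in pool) / len(pool),
        sum(x[1] for x in pool) / len(pool),
    )


def oracle_ng86(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(ka, ks) by independent NG86 counting + Jukes-Cantor correction.

    Returns NaN for saturated proportions, mirroring the stated convention.
    """
    import math

    s_sites = n_sites = sd = nd = 0.0
    for i in range(0, len(codon_a), 3):
        ca, cb = codon_a[i : i + 3], codon_b[i : i + 3]
        if "-" in ca + cb or "N" in ca + cb:
            continue
        sa, sb = _oracle_syn_sites(ca), _oracle_syn_sites(cb)
        s_sites += (sa + sb) / 2
        n_sites += (3 - sa + 3 - sb) / 2
        d_s, d_n = _oracle_path_diffs(ca, cb)
        sd += d_s
        nd += d_n
    ps, pn = sd / s_sites, nd / n_sites

    def jc(p):
        return float("nan") if p >= 0.75 else -0.75 * math.log(1 - 4 * p / 3)

    return jc(pn), jc(ps)


# --- Fitch oracle ------------------------------------------------------------


def oracle_min_changes(parent_of: dict, leaf_states: dict) -> int:
    """Exhaustive minimization over all internal labelings.

    ``parent_of`` maps each non-root node id to its parent id; leaves are
    the keys of ``leaf_states``. Changes are counted on every edge.
    """
    nodes = set(parent_of) | set(parent_of.values())
    internal = sorted(nodes - set(leaf_states))
    best = float("inf")
    for assign in itertools.product((0, 1), repeat=len(internal)):
        label = dict(zip(internal, assign))
        label.update(leaf_states)
        changes = sum(
            1 for child, parent in parent_of.items() if label[child] != label[parent]
        )
        best = min(best, changes)
    return best
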