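"""Divergence statistics: enrichment chi-square, expression-correlation
contrasts, and an NG86 Ka/Ks estimator.

Ka/Ks follows Nei & Gojobori (1986): per-codon synonymous site fractions
averaged over the two sequences, pathway averaging over the orderings of
multi-hit codons (paths through stop codons excluded, falling back to all
paths when every ordering is blocked), and the Jukes-Cantor correction
d = -(3/4) ln(1 - (4/3) p) applied to both proportions. Proportions at or
beyond 3/4 are flagged as saturated. Mutations to stop codons count toward
nonsynonymous sites (S is summed from synonymous fractions; N = 3 - S).

Group contrasts use a two-sided Mann-Whitney U test: exact enumeration
when both groups have at most 20 observations and no ties, otherwise the
normal approximation with tie correction.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data.CodonTable import standard_dna_table

from .seq_model import Sequence as Seq
from .seq_model import Transcript, reverse_transcribe

logger = logging.getLogger(__name__)

_CODON_TABLE = dict(standard_dna_table.forward_table)
_STOPS = set(standard_dna_table.stop_codons)
_BASES = "ACGT"


# ---------------------------------------------------------------------------
# correlation and rank statistics


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation with pairwise deletion of missing values.

    Requires >= 3 complete pairs and nonzero variance in both arguments;
    degenerate input raises ``ValueError`` so callers can exclude the pair.
    """
    xa, ya = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("vectors must have equal length")
    keep = ~(np.isnan(xa) | np.isnan(ya))
    xa, ya = xa[keep], ya[keep]
    if xa.size < 3:
        raise ValueError(f"need >= 3 complete pairs, got {xa.size}")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("zero variance; correlation undefined")
    return float(stats.pearsonr(xa, ya).statistic)


@dataclass
class GroupComparison:
    statistic: float
    p_value: float
    median_a: float
    median_b: float
    n_a: int
    n_b: int
    method: str

    @property
    def direction(self) -> str:
        if self.median_a > self.median_b:
            return "a_greater"
        if self.median_a < self.median_b:
            return "b_greater"
        return "equal"


def compare_correlation_groups(
    same: Sequence[float], divergent: Sequence[float]
) -> GroupComparison:
    """Two-sided Mann-Whitney U contrast of two groups of statistics.

    Despite the name the helper is generic (it is also used for Ks
    contrasts). Exact enumeration for small tie-free samples, normal
    approximation with tie correction otherwise.
    """
    a = np.asarray(same, dtype=float)
    b = np.asarray(divergent, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size <= 20 and b.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupComparison(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        n_a=int(a.size),
        n_b=int(b.size),
        method=method,
    )


def chi_square_2x2(
    table: Sequence[Sequence[float]], yates: bool = False
) -> tuple[float, float]:
    """Pearson chi-square test of independence on a 2x2 count table (1 df).

    All four marginals must be positive. ``yates`` applies the continuity
    correction (off by default: expected counts in the pipeline's tables
    are large).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of nonnegative counts")
    rows, cols, n = t.sum(axis=1), t.sum(axis=0), t.sum()
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("test undefined: a marginal is zero")
    expected = np.outer(rows, cols) / n
    diff = np.abs(t - expected)
    if yates:
        diff = np.maximum(diff - 0.5, 0.0)
    statistic = float((diff**2 / expected).sum())
    return statistic, float(stats.chi2.sf(statistic, df=1))


# ---------------------------------------------------------------------------
# codon alignment


def align_proteins(a: str, b: str) -> tuple[str, str]:
    """Deterministic global protein alignment (BLOSUM62, gap open 10 / extend 0.5)."""
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aln = aligner.align(a, b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    return sa, sb


def translate_cds(cds: str) -> str:
    """Translate a DNA CDS (length divisible by 3); trailing stop dropped."""
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    aas = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if codon in _STOPS:
            if i == len(cds) - 3:
                break
            raise ValueError(f"internal stop codon {codon} at codon {i // 3 + 1}")
        aas.append(_CODON_TABLE.get(codon, "X"))
    return "".join(aas)


def _thread_codons(protein_row: str, cds: str) -> str:
    """Expand one gapped protein row to its codon-level row."""
    out, pos = [], 0
    for aa in protein_row:
        if aa == "-":
            out.append("---")
        else:
            out.append(cds[pos : pos + 3])
            pos += 3
    return "".join(out)


def align_codons(
    protein_alignment: tuple[str, str],
    cds_a: Transcript | Seq | str,
    cds_b: Transcript | Seq | str,
) -> tuple[str, str]:
    """Back-thread CDS sequences onto a global protein alignment.

    Protein gaps become codon triplet gaps; each CDS must translate to its
    alignment row (errors name the offending codon index).
    """

    def _dna(x):
        if isinstance(x, Transcript):
            x = x.seq
        if isinstance(x, Seq):
            return reverse_transcribe(x).seq
        return x.upper().replace("U", "T")

    pa, pb = protein_alignment
    rows = []
    for row, cds in ((pa, _dna(cds_a)), (pb, _dna(cds_b))):
        ungapped = row.replace("-", "")
        trans = translate_cds(cds)
        if trans[: len(ungapped)] != ungapped:
            mism = next(
                (i for i, (x, y) in enumerate(zip(trans, ungapped)) if x != y),
                min(len(trans), len(ungapped)),
            )
            raise ValueError(
                f"translation mismatch at codon {mism + 1}: "
                f"CDS gives {trans[mism:mism+1]!r}, alignment row has "
                f"{ungapped[mism:mism+1]!r}"
            )
        rows.append(_thread_codons(row, cds))
    return rows[0], rows[1]


# ---------------------------------------------------------------------------
# NG86


def _syn_fraction(codon: str, pos: int) -> float:
    """Fraction of the 3 possible changes at ``pos`` that are synonymous.

    Changes producing a stop codon are not synonymous (they fall into the
    nonsynonymous site share via N = 3 - S).
    """
    aa = _CODON_TABLE[codon]
    syn = 0
    for b in _BASES:
        if b == codon[pos]:
            continue
        mut = codon[:pos] + b + codon[pos + 1 :]
        if mut not in _STOPS and _CODON_TABLE[mut] == aa:
            syn += 1
    return syn / 3.0


def codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon; sums to 3."""
    s = sum(_syn_fraction(codon, p) for p in range(3))
    return s, 3.0 - s


def _path_differences(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences for a codon pair.

    Averages over all orderings of the differing positions, excluding
    orderings that pass through a stop codon; if every ordering is blocked,
    averages over all orderings instead.
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    valid: list[tuple[int, int]] = []
    blocked: list[tuple[int, int]] = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        sd = nd = 0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in _STOPS:
                through_stop = True
                break
            if _CODON_TABLE[cur] == _CODON_TABLE[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if through_stop:
            # re-walk counting through-stop steps as nonsynonymous
            cur, sd, nd = c1, 0, 0
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                if nxt in _STOPS or cur in _STOPS or (
                    _CODON_TABLE.get(cur) != _CODON_TABLE.get(nxt)
                ):
                    nd += 1
                else:
                    sd += 1
                cur = nxt
            blocked.append((sd, nd))
        else:
            valid.append((sd, nd))
    pool = valid if valid else blocked
    sd = sum(p[0] for p in pool) / len(pool)
    nd = sum(p[1] for p in pool) / len(pool)
    return sd, nd


def jukes_cantor(p: float) -> float:
    """JC69 distance for a proportion of differences; p >= 3/4 is saturated."""
    if p >= 0.75:
        return float("nan")
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


@dataclass
class PairStats:
    """Per-pair divergence statistics (correlation and/or Ka, Ks)."""

    pair_id: str = ""
    r: float | None = None
    ka: float | None = None
    ks: float | None = None
    ka_ks: float | None = None
    n_codons: int = 0
    flags: tuple[str, ...] = ()


def ng86_ka_ks(
    codon_alignment: tuple[str, str], pair_id: str = ""
) -> PairStats:
    """Nei-Gojobori (1986) Ka/Ks with Jukes-Cantor correction.

    Input rows are gapped codon-level DNA strings of equal length divisible
    by 3; columns containing a gap or N in either row are dropped. Internal
    stop codons raise an error. Symmetric in the two sequences.
    """
    a, b = (row.upper().replace("U", "T") for row in codon_alignment)
    if len(a) != len(b) or len(a) % 3:
        raise ValueError("codon alignment rows must be equal length, multiple of 3")
    s_sites = n_sites = 0.0
    sd = nd = 0.0
    n_codons = 0
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if "-" in ca or "-" in cb or "N" in ca or "N" in cb:
            continue
        if ca in _STOPS or cb in _STOPS:
            raise ValueError(f"internal stop codon at alignment codon {i // 3 + 1}")
        sa, na = codon_sites(ca)
        sb_, nb_ = codon_sites(cb)
        s_sites += (sa + sb_) / 2.0
        n_sites += (na + nb_) / 2.0
        d_s, d_n = _path_differences(ca, cb)
        sd += d_s
        nd += d_n
        n_codons += 1
    if n_codons == 0:
        return PairStats(pair_id=pair_id, flags=("empty_alignment",))
    flags: list[str] = []
    ps, pn = sd / s_sites, nd / n_sites
    ks, ka = jukes_cantor(ps), jukes_cantor(pn)
    if math.isnan(ks):
        flags.append("ks_saturated")
        ks = None
    if math.isnan(ka):
        flags.append("ka_saturated")
        ka = None
    ka_ks = None
    if ka is not None and ks is not None:
        if ks == 0:
            flags.append("ka_ks_undefined")
        else:
            ka_ks = ka / ks
    return PairStats(
        pair_id=pair_id,
        ka=ka,
        ks=ks,
        ka_ks=ka_ks,
        n_codons=n_codons,
        flags=tuple(flags),
    )


def kaks_for_pair(
    cds_a: Transcript | Seq | str,
    cds_b: Transcript | Seq | str,
    pair_id: str = "",
) -> PairStats:
    """Convenience wrapper: protein-align, back-thread codons, run NG86."""

    def _dna(x):
        if isinstance(x, Transcript):
            x = x.seq
        if isinstance(x, Seq):
            return reverse_transcribe(x).seq
        return x.upper().replace("U", "T")

    da, db = _dna(cds_a), _dna(cds_b)
    prot = align_proteins(translate_cds(da), translate_cds(db))
    codon_aln = align_codons(prot, da, db)
    return ng86_ka_ks(codon_aln, pair_id=pair_id)
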