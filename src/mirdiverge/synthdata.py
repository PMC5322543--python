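"""Seeded synthetic-data generator with ground truth for every stage.

The generator emulates the study's real inputs — a transcript set with
planted miRNA binding sites, duplicate pairs/triplets with controlled site
loss and young-miRNA site gain, all-vs-all similarity hits, cross-species
miRNA homolog tables, and an expression matrix whose pairwise correlation
is coupled to divergence status — entirely from one seeded RNG, so the
whole pipeline can be exercised against a known answer.

Planted sites are constructed by reverse-complementing the miRNA and then
introducing the scheduled wobbles/mismatches at positions outside the
weighted seed region, so a site of plain score <= 2.5 is predicted by all
three default profiles. Ablation rewrites five Watson-Crick-paired window
positions into mismatches (>= 5 penalty points), pushing the site past
every profile cutoff. Background false sites in random sequence are left
possible and accounted for statistically rather than excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .seq_model import MiRNA, Sequence, Transcript, reverse_complement, write_fasta
from .target_scan import (
    PLAIN_PROFILE,
    ConsensusRule,
    default_profiles,
    scan_transcript,
    score_duplex,
)

logger = logging.getLogger(__name__)

_RNA = np.array(list("ACGU"))
_SEED_LO, _SEED_HI = 2, 13  # weighted region of the default profiles


@dataclass(frozen=True)
class GenConfig:
    """Generator configuration; defaults define the emulated study conditions.

    ``n_conditions`` defaults to 63 expression columns (organs/stages);
    ``mirna_len`` to the canonical 21 nt; ``site_score_dist`` is a point
    mass at 0 with a tail to 2.5 plain-score points; ``rho_same``/``rho_div``
    couple expression correlation to the divergence verdict.
    """

    seed: int = 0
    n_pairs_wgd: int = 60
    n_pairs_td: int = 25
    n_triplets: int = 15
    n_singletons: int = 40
    tx_len: int = 300
    gc: float = 0.42
    n_mirnas: int = 20
    mirna_len: int = 21
    frac_young: float = 0.5
    site_score_dist: tuple[tuple[float, float], ...] = (
        (0.0, 0.5),
        (0.5, 0.1),
        (1.0, 0.1),
        (1.5, 0.1),
        (2.0, 0.1),
        (2.5, 0.1),
    )
    p_site_loss: float = 0.3
    p_young_gain: float = 0.1
    rho_same: float = 0.8
    rho_div: float = 0.2
    n_conditions: int = 63
    mutation_rate: float = 0.03

    def __post_init__(self) -> None:
        for p in (self.p_site_loss, self.p_young_gain, self.frac_young):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        for rho in (self.rho_same, self.rho_div):
            if not -1 < rho < 1:
                raise ValueError("rho values must lie in (-1, 1)")
        if self.mirna_len > self.tx_len:
            raise ValueError("infeasible config: mirna_len > tx_len")
        if abs(sum(p for _, p in self.site_score_dist) - 1.0) > 1e-9:
            raise ValueError("site_score_dist probabilities must sum to 1")


@dataclass
class PlantedSite:
    gene_id: str
    mirna_id: str
    start: int  # 1-based closed
    end: int
    score: float  # plain-profile score as planted (pre-ablation)
    ablated: bool = False


@dataclass
class TruthGroup:
    genes: tuple[str, ...]
    dup_class: str
    verdict: str  # same | divergent
    subtype: str  # all_same | asymmetric | different_mirnas
    mechanism: str  # none | loss | young_gain
    rho: float


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a generated bundle."""

    seed: int
    mirna_ages: dict[str, str]
    gene_status: dict[str, str]  # duplicate | singleton
    groups: list[TruthGroup]
    sites: list[PlantedSite]

    @property
    def divergent_fraction(self) -> float:
        n = len(self.groups)
        return sum(g.verdict == "divergent" for g in self.groups) / n if n else 0.0


@dataclass
class Bundle:
    """Paths of an emitted dataset bundle."""

    out_dir: Path
    mirnas: Path
    transcripts: Path
    hits: Path
    pairs: Path
    homolog_hits: Path
    expression: Path
    truth_groups: Path
    truth_sites: Path
    manifest: Path


def _random_rna(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_RNA, size=length, p=p))


def _build_site_window(
    mirna_seq: str, score: float, rng: np.random.Generator
) -> str:
    """Window sequence pairing the miRNA at exactly ``score`` plain points.

    Damage is restricted to miRNA positions outside the weighted seed
    region (position 1 and positions 14..L) so every default profile sees
    the same score. Fractional half-points come from a single G:U wobble.
    """
    L = len(mirna_seq)
    window = list(
        reverse_complement(Sequence("w", mirna_seq, "rna")).seq
    )  # perfect complement: score 0
    nonseed = [i for i in range(1, L + 1) if not (_SEED_LO <= i <= _SEED_HI)]
    n_wob = 1 if (score % 1.0) else 0
    n_mis = int(score - 0.5 * n_wob)
    if n_wob:
        wobblable = [i for i in nonseed if mirna_seq[i - 1] in "GU"]
        if not wobblable:
            raise ValueError("miRNA has no non-seed G/U position for a wobble")
        w = int(rng.choice(wobblable))
        window[L - w] = "U" if mirna_seq[w - 1] == "G" else "G"
        nonseed = [i for i in nonseed if i != w]
    mis_pos = rng.choice(nonseed, size=n_mis, replace=False)
    for i in mis_pos:
        window[L - int(i)] = mirna_seq[int(i) - 1]  # same base never pairs
    return "".join(window)


def _ablate_window(window: str, mirna_seq: str, rng: np.random.Generator) -> str:
    """Destroy a planted site: rewrite 5 Watson-Crick positions to mismatches."""
    L = len(mirna_seq)
    w = list(window)
    paired = [
        i
        for i in range(1, L + 1)
        if score_duplex(mirna_seq[i - 1], w[L - i], PLAIN_PROFILE) == 0.0
    ]
    pos = rng.choice(paired, size=5, replace=False)
    for i in pos:
        w[L - int(i)] = mirna_seq[int(i) - 1]
    return "".join(w)


def _mutate_outside(
    seq: str, protected: list[tuple[int, int]], rate: float, rng: np.random.Generator
) -> str:
    """Substitute bases at ``rate`` outside protected 1-based closed ranges."""
    s = list(seq)
    mask = np.ones(len(s), dtype=bool)
    for lo, hi in protected:
        mask[lo - 1 : hi] = False
    hit = rng.random(len(s)) < rate
    for i in np.flatnonzero(hit & mask):
        choices = [b for b in "ACGU" if b != s[i]]
        s[i] = choices[rng.integers(len(choices))]
    return "".join(s)


def generate(config: GenConfig, out_dir: str | Path) -> tuple[Bundle, SyntheticTruth]:
    """Emit a full dataset bundle plus its ground truth. Deterministic in seed."""
    rng = np.random.default_rng(config.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- miRNAs ------------------------------------------------------------
    n_young = int(round(config.frac_young * config.n_mirnas))
    mirnas: list[MiRNA] = []
    for i in range(config.n_mirnas):
        while True:
            seq = _random_rna(rng, config.mirna_len, 0.5)
            nonseed = [
                j
                for j in range(1, config.mirna_len + 1)
                if not (_SEED_LO <= j <= _SEED_HI)
            ]
            if any(seq[j - 1] in "GU" for j in nonseed):
                break
        age = "young" if i < n_young else "ancient"
        mirnas.append(MiRNA(f"ath-simR{i + 1:03d}", Sequence(f"ath-simR{i + 1:03d}", seq, "rna"), age=age))
    young_ids = [m.id for m in mirnas if m.age == "young"]
    scores, probs = zip(*config.site_score_dist)

    # --- paralog groups and transcripts ------------------------------------
    transcripts: list[Transcript] = []
    truth_groups: list[TruthGroup] = []
    truth_sites: list[PlantedSite] = []
    gene_status: dict[str, str] = {}
    pair_rows: list[tuple[str, str, str, str]] = []
    counter = 0

    def next_gene() -> str:
        nonlocal counter
        counter += 1
        return f"simG{counter:05d}"

    group_plan = (
        [("WGD", 2)] * config.n_pairs_wgd
        + [("TD", 2)] * config.n_pairs_td
        + [("triplet", 3)] * config.n_triplets
    )
    L = config.mirna_len
    for dup_class, size in group_plan:
        genes = tuple(next_gene() for _ in range(size))
        m = mirnas[rng.integers(len(mirnas))]
        score = float(rng.choice(scores, p=probs))
        window = _build_site_window(m.mature.seq, score, rng)
        start = int(rng.integers(1, config.tx_len - L + 2))
        ancestral = list(_random_rna(rng, config.tx_len, config.gc))
        ancestral[start - 1 : start - 1 + L] = window
        ancestral = "".join(ancestral)

        # mechanism draw: loss first, else young-site gain, else unchanged
        mechanism = "none"
        if rng.random() < config.p_site_loss:
            mechanism = "loss"
        elif rng.random() < config.p_young_gain and any(
            y != m.id for y in young_ids
        ):
            mechanism = "young_gain"

        gain_mirna = None
        gain_start = None
        if mechanism == "young_gain":
            options = [y for y in young_ids if y != m.id]
            gain_id = options[rng.integers(len(options))]
            gain_mirna = next(mi for mi in mirnas if mi.id == gain_id)
            while True:
                gain_start = int(rng.integers(1, config.tx_len - L + 2))
                if gain_start + L - 1 < start or gain_start > start + L - 1:
                    break

        for k, g in enumerate(genes):
            protected = [(start, start + L - 1)]
            affected = k == len(genes) - 1  # last copy carries the event
            seq = ancestral
            if affected and mechanism == "loss":
                wl = list(seq)
                wl[start - 1 : start - 1 + L] = _ablate_window(
                    seq[start - 1 : start - 1 + L], m.mature.seq, rng
                )
                seq = "".join(wl)
            if affected and mechanism == "young_gain":
                gscore = float(rng.choice(scores, p=probs))
                gwin = _build_site_window(gain_mirna.mature.seq, gscore, rng)
                sl = list(seq)
                sl[gain_start - 1 : gain_start - 1 + L] = gwin
                seq = "".join(sl)
                protected.append((gain_start, gain_start + L - 1))
                truth_sites.append(
                    PlantedSite(g, gain_mirna.id, gain_start, gain_start + L - 1, gscore)
                )
            seq = _mutate_outside(seq, protected, config.mutation_rate, rng)
            transcripts.append(Transcript(g, Sequence(g, seq, "rna")))
            gene_status[g] = "duplicate"
            truth_sites.append(
                PlantedSite(
                    g, m.id, start, start + L - 1, score,
                    ablated=(affected and mechanism == "loss"),
                )
            )

        if mechanism == "none":
            verdict, subtype = "same", "all_same"
        elif mechanism == "loss":
            verdict, subtype = "divergent", "asymmetric"
        else:
            verdict, subtype = "divergent", "different_mirnas"
        rho = config.rho_same if verdict == "same" else config.rho_div
        truth_groups.append(
            TruthGroup(genes, dup_class, verdict, subtype, mechanism, rho)
        )
        pair_rows.append(
            (genes[0], genes[1], genes[2] if size == 3 else "", dup_class)
        )

    for _ in range(config.n_singletons):
        g = next_gene()
        transcripts.append(
            Transcript(g, Sequence(g, _random_rna(rng, config.tx_len, config.gc), "rna"))
        )
        gene_status[g] = "singleton"

    # --- file emission ------------------------------------------------------
    bundle = Bundle(
        out_dir=out,
        mirnas=out / "mirnas.fa",
        transcripts=out / "transcripts.fa",
        hits=out / "hits.tsv",
        pairs=out / "pairs.tsv",
        homolog_hits=out / "homolog_hits.tsv",
        expression=out / "expression.tsv",
        truth_groups=out / "truth_groups.tsv",
        truth_sites=out / "truth_sites.tsv",
        manifest=out / "MANIFEST.tsv",
    )
    write_fasta([m.mature for m in mirnas], bundle.mirnas)
    write_fasta([t.seq for t in transcripts], bundle.transcripts)

    with open(bundle.hits, "w", encoding="utf-8") as fh:
        fh.write(f"# seed={config.seed}\n")
        for t in transcripts:
            qlen = len(t.seq)
            fh.write(
                f"{t.gene_id}\t{t.gene_id}\t100.00\t{qlen}\t0\t0\t1\t{qlen}\t1\t{qlen}"
                f"\t0.0\t1000.0\t{qlen}\n"
            )
        for ga, gb, gc_, _cls in pair_rows:
            members = [ga, gb] + ([gc_] if gc_ else [])
            lens = {g: config.tx_len for g in members}
            for q in members:
                for s in members:
                    if q == s:
                        continue
                    alen = int(0.9 * lens[q])
                    fh.write(
                        f"{q}\t{s}\t85.00\t{alen}\t{int(0.1 * alen)}\t0\t1\t{alen}"
                        f"\t1\t{alen}\t1e-50\t500.0\t{lens[q]}\n"
                    )

    with open(bundle.pairs, "w", encoding="utf-8") as fh:
        fh.write("gene_a\tgene_b\tgene_c\tclass\n")
        for row in pair_rows:
            fh.write("\t".join(row) + "\n")

    with open(bundle.homolog_hits, "w", encoding="utf-8") as fh:
        fh.write("mirna_id\tspecies\tevalue\tcoverage\n")
        for m in mirnas:
            fh.write(f"{m.id}\tArabidopsis thaliana\t1e-40\t1.00\n")
            if m.age == "young":
                fh.write(f"{m.id}\tArabidopsis lyrata\t1e-30\t0.90\n")
            else:
                fh.write(f"{m.id}\tArabidopsis lyrata\t1e-30\t0.90\n")
                fh.write(f"{m.id}\tBrassica rapa\t1e-25\t0.85\n")
                fh.write(f"{m.id}\tOryza sativa\t1e-20\t0.80\n")

    # expression: per-group equicorrelated normals, singletons independent
    with open(bundle.expression, "w", encoding="utf-8") as fh:
        cols = "\t".join(f"cond{j + 1:02d}" for j in range(config.n_conditions))
        fh.write("gene_id\t" + cols + "\n")
        emitted: dict[str, np.ndarray] = {}
        for tg in truth_groups:
            k = len(tg.genes)
            cov = np.full((k, k), tg.rho)
            np.fill_diagonal(cov, 1.0)
            z = rng.multivariate_normal(
                np.zeros(k), cov, size=config.n_conditions
            )  # (conditions, k)
            vals = np.clip(8.0 + z, 0.0, None)
            for j, g in enumerate(tg.genes):
                emitted[g] = vals[:, j]
        for g, status in gene_status.items():
            if status == "singleton":
                emitted[g] = np.clip(8.0 + rng.standard_normal(config.n_conditions), 0.0, None)
        for g in sorted(emitted):
            fh.write(g + "\t" + "\t".join(f"{v:.4f}" for v in emitted[g]) + "\n")

    with open(bundle.truth_groups, "w", encoding="utf-8") as fh:
        fh.write("genes\tdup_class\tverdict\tsubtype\tmechanism\trho\n")
        for tg in truth_groups:
            fh.write(
                f"{';'.join(tg.genes)}\t{tg.dup_class}\t{tg.verdict}\t{tg.subtype}"
                f"\t{tg.mechanism}\t{tg.rho:.2f}\n"
            )

    with open(bundle.truth_sites, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tmirna_id\tstart\tend\tscore\tablated\n")
        for s in truth_sites:
            fh.write(
                f"{s.gene_id}\t{s.mirna_id}\t{s.start}\t{s.end}\t{s.score:.1f}"
                f"\t{int(s.ablated)}\n"
            )

    with open(bundle.manifest, "w", encoding="utf-8") as fh:
        fh.write(f"# synthetic bundle, seed={config.seed}\n")
        fh.write("file\tdescription\n")
        fh.write("mirnas.fa\tmature miRNA sequences (RNA)\n")
        fh.write("transcripts.fa\ttranscript sequences with planted sites (RNA)\n")
        fh.write("hits.tsv\tall-vs-all similarity hits, 13-column tabular (qlen last)\n")
        fh.write("pairs.tsv\tlabeled paralog pairs/triplets\n")
        fh.write("homolog_hits.tsv\tcross-species miRNA homolog hits\n")
        fh.write("expression.tsv\tnormalized expression matrix (genes x conditions)\n")
        fh.write("truth_groups.tsv\tground-truth verdict per paralog group\n")
        fh.write("truth_sites.tsv\tground-truth planted binding sites\n")

    truth = SyntheticTruth(
        seed=config.seed,
        mirna_ages={m.id: m.age for m in mirnas},
        gene_status=gene_status,
        groups=truth_groups,
        sites=truth_sites,
    )
    return bundle, truth


@dataclass
class VerifyReport:
    passed: bool
    n_checked: int
    failures: list[str]


def verify_truth(bundle: Bundle, truth: SyntheticTruth) -> VerifyReport:
    """Re-scan the emitted bundle and check it is consistent with the truth.

    Planted (non-ablated) sites must be recovered at their recorded
    coordinates with their recorded plain score and be predicted by every
    default profile; ablated sites must exceed every profile cutoff.
    """
    from .seq_model import read_fasta

    mirna_seqs = {s.id: s.seq for s in read_fasta(bundle.mirnas, "rna")}
    tx_seqs = {s.id: s.seq for s in read_fasta(bundle.transcripts, "rna")}
    profiles = default_profiles()
    failures: list[str] = []
    for site in truth.sites:
        tx = tx_seqs.get(site.gene_id)
        if tx is None:
            failures.append(f"{site.gene_id}: transcript missing from bundle")
            continue
        if len(tx) < site.end:
            failures.append(f"{site.gene_id}: transcript truncated before {site.end}")
            continue
        window = tx[site.start - 1 : site.end]
        m = mirna_seqs[site.mirna_id]
        if site.ablated:
            for p in profiles:
                sc = score_duplex(m, window, p)
                if sc <= p.cutoff:
                    failures.append(
                        f"{site.gene_id}:{site.start} ablated site still predicted "
                        f"by {p.name} (score {sc})"
                    )
        else:
            sc = score_duplex(m, window, PLAIN_PROFILE)
            if sc != site.score:
                failures.append(
                    f"{site.gene_id}:{site.start} plain score {sc} != planted {site.score}"
                )
            for p in profiles:
                if score_duplex(m, window, p) > p.cutoff:
                    failures.append(
                        f"{site.gene_id}:{site.start} not predicted by {p.name}"
                    )
    return VerifyReport(passed=not failures, n_checked=len(truth.sites), failures=failures)
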