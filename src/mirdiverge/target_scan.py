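"""Plant miRNA binding-site scanner.

A binding site is an ungapped antiparallel duplex between the full mature
miRNA and a same-length transcript window. Each duplex position scores 0
for a Watson-Crick pair, ``wobble_penalty`` (default 0.5) for a G:U wobble,
and ``mismatch_penalty`` (default 1.0) otherwise; a window is a hit when the
summed penalty does not exceed the profile cutoff. Three default profiles
emulate the behaviour of the common plant target-prediction tools, and a
k-of-n consensus rule (default 2-of-3) combines them into interaction calls.

miRNA position i (counted from the 5' end) pairs with window position
L+1-i, i.e. the window is read 5'->3' on the transcript sense strand and
the miRNA binds antiparallel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
import yaml

from .seq_model import MiRNA, Sequence, Transcript, transcribe

logger = logging.getLogger(__name__)

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3, "N": 4}

# Pair class for (mirna base, window base): 0 = Watson-Crick, 1 = G:U or
# U:G wobble, 2 = mismatch. Any pairing involving N is a mismatch.
_PAIR_CLASS = np.full((5, 5), 2, dtype=np.int8)
for _m, _w in (("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")):
    _PAIR_CLASS[_BASE_INDEX[_m], _BASE_INDEX[_w]] = 0
for _m, _w in (("G", "U"), ("U", "G")):
    _PAIR_CLASS[_BASE_INDEX[_m], _BASE_INDEX[_w]] = 1

_ENCODE = np.full(128, -1, dtype=np.int8)
for _b, _i in _BASE_INDEX.items():
    _ENCODE[ord(_b)] = _i


def _encode(seq: str) -> np.ndarray:
    arr = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr < 0).any():
        raise ValueError(f"non-RNA character in sequence {seq!r}")
    return arr


@dataclass(frozen=True)
class ScanProfile:
    """One scoring configuration of the weighted-mismatch scheme.

    ``seed_range`` is a 1-based closed interval of miRNA positions (from the
    5' end) whose penalties are multiplied by ``seed_multiplier``;
    ``seed_scope`` restricts the multiplier to wobbles only ("wobble") or
    applies it to both penalty kinds ("all").
    """

    name: str
    cutoff: float
    seed_range: tuple[int, int] | None = None
    seed_multiplier: float = 1.0
    wobble_penalty: float = 0.5
    mismatch_penalty: float = 1.0
    seed_scope: str = "all"

    def __post_init__(self) -> None:
        if self.cutoff < 0:
            raise ValueError(f"profile {self.name!r}: cutoff must be >= 0")
        if self.wobble_penalty < 0 or self.mismatch_penalty < 0:
            raise ValueError(f"profile {self.name!r}: penalties must be >= 0")
        if self.seed_multiplier < 1:
            raise ValueError(f"profile {self.name!r}: seed_multiplier must be >= 1")
        if self.seed_scope not in ("all", "wobble"):
            raise ValueError(f"profile {self.name!r}: bad seed_scope")
        if self.seed_range is not None and self.seed_range[0] < 1:
            raise ValueError(f"profile {self.name!r}: seed_range must start >= 1")

    def penalty_vectors(self, length: int) -> tuple[np.ndarray, np.ndarray]:
        """Per-miRNA-position (1..L) wobble and mismatch penalty vectors."""
        wob = np.full(length, self.wobble_penalty)
        mis = np.full(length, self.mismatch_penalty)
        if self.seed_range is not None:
            lo, hi = self.seed_range
            if hi > length:
                hi = length
            sl = slice(lo - 1, hi)
            wob[sl] *= self.seed_multiplier
            if self.seed_scope == "all":
                mis[sl] *= self.seed_multiplier
        return wob, mis


PLAIN_PROFILE = ScanProfile("plain", cutoff=3.0)


def default_profiles() -> list[ScanProfile]:
    """The three default profiles combined by the 2-of-3 consensus rule."""
    return [
        ScanProfile("plain", cutoff=3.0),
        ScanProfile("seed-weighted", cutoff=3.5, seed_range=(2, 13), seed_multiplier=2.0),
        ScanProfile(
            "strict-wobble",
            cutoff=3.0,
            seed_range=(2, 13),
            seed_multiplier=2.0,
            seed_scope="wobble",
        ),
    ]


@dataclass(frozen=True)
class ConsensusRule:
    """Call an interaction when at least ``k`` of the profiles agree."""

    profiles: tuple[ScanProfile, ...] = ()
    k: int = 2

    def __post_init__(self) -> None:
        if not self.profiles:
            object.__setattr__(self, "profiles", tuple(default_profiles()))
        if not 1 <= self.k <= len(self.profiles):
            raise ValueError(f"k={self.k} outside [1, {len(self.profiles)}]")


class ScanHit(NamedTuple):
    start: int  # 1-based closed
    end: int
    score: float


@dataclass
class BindingSite:
    """A consensus-evaluated duplex between one miRNA and one transcript.

    ``score`` is always reported under the plain (unweighted) scheme;
    ``per_profile`` records each profile's verdict for the site cluster.
    """

    mirna_id: str
    gene_id: str
    start: int
    end: int
    score: float
    per_profile: dict[str, bool]
    consensus: bool


def _mirna_rna(mirna: MiRNA | Sequence | str) -> str:
    if isinstance(mirna, MiRNA):
        return mirna.mature.seq
    if isinstance(mirna, Sequence):
        return transcribe(mirna).seq
    return mirna.upper().replace("T", "U")


def _transcript_rna(t: Transcript | Sequence | str) -> str:
    if isinstance(t, Transcript):
        return transcribe(t.seq).seq
    if isinstance(t, Sequence):
        return transcribe(t).seq
    return t.upper().replace("T", "U")


def score_duplex(
    mirna: MiRNA | Sequence | str,
    window: str,
    profile: ScanProfile = PLAIN_PROFILE,
) -> float:
    """Score one miRNA against an equal-length transcript window.

    Raises ``ValueError`` on a length mismatch. N in either strand scores
    as a mismatch.
    """
    m = _mirna_rna(mirna)
    w = window.upper().replace("T", "U")
    if len(m) != len(w):
        raise ValueError(f"length mismatch: miRNA {len(m)} vs window {len(w)}")
    cls = _PAIR_CLASS[_encode(m), _encode(w)[::-1]]
    wob, mis = profile.penalty_vectors(len(m))
    return float(np.where(cls == 1, wob, np.where(cls == 2, mis, 0.0)).sum())


def _window_scores(mirna_seq: str, tx_seq: str, profile: ScanProfile) -> np.ndarray:
    """Scores of every window of length |miRNA| along the transcript."""
    m = _encode(mirna_seq)[::-1]  # reversed: column j pairs miRNA position L-j
    t = _encode(tx_seq)
    L = m.size
    windows = np.lib.stride_tricks.sliding_window_view(t, L)
    cls = _PAIR_CLASS[m[None, :], windows]
    wob, mis = profile.penalty_vectors(L)
    wob_r, mis_r = wob[::-1], mis[::-1]  # into window-column order
    pen = np.where(cls == 1, wob_r, np.where(cls == 2, mis_r, 0.0))
    return pen.sum(axis=1)


def scan_transcript(
    mirna: MiRNA | Sequence | str,
    transcript: Transcript | Sequence | str,
    profile: ScanProfile,
) -> list[ScanHit]:
    """All windows scoring at or below the profile cutoff, sorted by start.

    A transcript shorter than the miRNA yields an empty result (warned),
    matching the scanning-eligibility contract.
    """
    m = _mirna_rna(mirna)
    t = _transcript_rna(transcript)
    if len(t) < len(m):
        logger.warning(
            "transcript (%d nt) shorter than miRNA (%d nt); no scan", len(t), len(m)
        )
        return []
    scores = _window_scores(m, t, profile)
    idx = np.flatnonzero(scores <= profile.cutoff)
    L = len(m)
    return [ScanHit(int(i) + 1, int(i) + L, float(scores[i])) for i in idx]


def _cluster_hits(
    hits_by_profile: dict[str, list[ScanHit]], length: int
) -> list[tuple[int, dict[str, ScanHit]]]:
    """Group per-profile hits whose intervals share >=50% reciprocal overlap.

    Windows all have length ``length`` so reciprocal overlap >= 50% reduces
    to a start offset of at most floor(L/2). Greedy left-to-right clustering
    anchored at each cluster's leftmost hit; deterministic.
    """
    all_hits = [
        (h.start, name, h)
        for name, hits in hits_by_profile.items()
        for h in hits
    ]
    all_hits.sort(key=lambda x: (x[0], x[1]))
    clusters: list[tuple[int, dict[str, ScanHit]]] = []
    max_offset = length // 2
    for start, name, hit in all_hits:
        if clusters and start - clusters[-1][0] <= max_offset:
            members = clusters[-1][1]
            if name not in members:  # keep the leftmost hit per profile
                members[name] = hit
        else:
            clusters.append((start, {name: hit}))
    return clusters


def consensus_call(
    mirna: MiRNA,
    transcript: Transcript,
    rule: ConsensusRule | None = None,
) -> list[BindingSite]:
    """Scan under every profile and combine verdicts with the k-of-n rule.

    Each cluster of agreeing intervals yields one :class:`BindingSite`,
    reported at the representative interval of the first listed profile
    present in the cluster and scored under the plain unweighted scheme.
    """
    rule = rule or ConsensusRule()
    m = _mirna_rna(mirna)
    hits_by_profile = {
        p.name: scan_transcript(mirna, transcript, p) for p in rule.profiles
    }
    order = [p.name for p in rule.profiles]
    sites: list[BindingSite] = []
    for _, members in _cluster_hits(hits_by_profile, len(m)):
        rep = next(members[name] for name in order if name in members)
        tx_rna = _transcript_rna(transcript)
        window = tx_rna[rep.start - 1 : rep.end]
        plain_score = score_duplex(m, window, PLAIN_PROFILE)
        per_profile = {name: (name in members) for name in order}
        sites.append(
            BindingSite(
                mirna_id=mirna.id,
                gene_id=transcript.gene_id,
                start=rep.start,
                end=rep.end,
                score=plain_score,
                per_profile=per_profile,
                consensus=sum(per_profile.values()) >= rule.k,
            )
        )
    sites.sort(key=lambda s: (s.gene_id, s.start, s.mirna_id))
    return sites


def target_table(
    mirnas: Iterable[MiRNA],
    transcripts: Iterable[Transcript],
    rule: ConsensusRule | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genome-wide interaction and site tables under the consensus rule.

    Returns ``(interactions, sites)``: one interaction row per (miRNA, gene)
    with at least one consensus site, and one site row per evaluated cluster.
    Rows are sorted by (gene_id, start, mirna_id) for deterministic output.
    """
    rule = rule or ConsensusRule()
    mirnas = list(mirnas)
    site_rows = []
    for t in transcripts:
        for m in mirnas:
            for s in consensus_call(m, t, rule):
                site_rows.append(
                    {
                        "gene_id": s.gene_id,
                        "mirna_id": s.mirna_id,
                        "start": s.start,
                        "end": s.end,
                        "score": s.score,
                        "profiles_agreeing": sum(s.per_profile.values()),
                        "consensus": s.consensus,
                    }
                )
    sites = pd.DataFrame(
        site_rows,
        columns=[
            "gene_id",
            "mirna_id",
            "start",
            "end",
            "score",
            "profiles_agreeing",
            "consensus",
        ],
    )
    if not sites.empty:
        sites = sites.sort_values(
            ["gene_id", "start", "mirna_id"], kind="mergesort"
        ).reset_index(drop=True)
    cons = sites[sites["consensus"]] if not sites.empty else sites
    if cons.empty:
        interactions = pd.DataFrame(columns=["mirna_id", "gene_id", "n_sites"])
    else:
        interactions = (
            cons.groupby(["mirna_id", "gene_id"], as_index=False)
            .size()
            .rename(columns={"size": "n_sites"})
            .sort_values(["gene_id", "mirna_id"], kind="mergesort")
            .reset_index(drop=True)
        )
    return interactions, sites


def mean_sites_per_gene(interactions: pd.DataFrame) -> float:
    """Mean number of consensus sites per targeted gene."""
    if interactions.empty:
        return float("nan")
    return float(interactions.groupby("gene_id")["n_sites"].sum().mean())


def profiles_from_yaml(path: str | Path) -> list[ScanProfile]:
    """Load scan profiles from a YAML list of mappings."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    profiles = []
    for entry in raw:
        seed = entry.get("seed_range")
        profiles.append(
            ScanProfile(
                name=entry["name"],
                cutoff=float(entry["cutoff"]),
                seed_range=tuple(seed) if seed else None,
                seed_multiplier=float(entry.get("seed_multiplier", 1.0)),
                wobble_penalty=float(entry.get("wobble_penalty", 0.5)),
                mismatch_penalty=float(entry.get("mismatch_penalty", 1.0)),
                seed_scope=entry.get("seed_scope", "all"),
            )
        )
    return profiles
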