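"""Duplicate/singleton cataloguing from all-vs-all protein similarity hits.

A gene is a *duplicate* when it has at least one nonself hit with E-value
below ``dup_evalue`` (default 1e-10) and query coverage above ``dup_cov``
(default 0.5); a *singleton* when it has no nonself hit with E-value below
``singleton_evalue`` (default 1e-3). Genes satisfying neither rule are an
explicit third class, *unclassified*, excluded from enrichment counting:
the two published definitions do not partition the gene universe.

Coverage is evaluated in the query direction only (aligned length divided
by query length) — the common convention for 12-column tabular hit files;
a gene qualifies as duplicate if it passes as the query of any one hit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HIT_COLUMNS = [
    "query_id",
    "subject_id",
    "pident",
    "length",
    "mismatches",
    "gapopens",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]


@dataclass(frozen=True)
class SimilarityHit:
    """One all-vs-all similarity hit with E-value and query coverage."""

    query_id: str
    subject_id: str
    evalue: float
    query_coverage: float
    bitscore: float = 0.0

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if not 0 <= self.query_coverage <= 1:
            raise ValueError("query_coverage must lie in [0, 1]")

    @property
    def is_self(self) -> bool:
        return self.query_id == self.subject_id


@dataclass
class GeneCatalog:
    """Genome-wide duplicate/singleton/unclassified assignment."""

    assignment: dict[str, str]
    thresholds: dict[str, float] = field(default_factory=dict)

    def genes_in(self, cls: str) -> set[str]:
        return {g for g, c in self.assignment.items() if c == cls}

    @property
    def duplicates(self) -> set[str]:
        return self.genes_in("duplicate")

    @property
    def singletons(self) -> set[str]:
        return self.genes_in("singleton")

    @property
    def unclassified(self) -> set[str]:
        return self.genes_in("unclassified")

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.assignment.items())
        return pd.DataFrame(rows, columns=["gene_id", "class"])


def read_hits_tsv(
    path: str | Path,
    gene_lengths: Mapping[str, int] | None = None,
) -> list[SimilarityHit]:
    """Read a 12-column tabular hit file (optionally with a 13th qlen column).

    Query coverage = aligned length / query length. Query length comes from
    the qlen column when present, else from ``gene_lengths``.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    if df.shape[1] == 13:
        df.columns = HIT_COLUMNS + ["qlen"]
    elif df.shape[1] == 12:
        df.columns = HIT_COLUMNS
        if gene_lengths is None:
            raise ValueError(
                f"{path}: 12-column hit file needs a gene-length table "
                "to compute query coverage"
            )
        df["qlen"] = df["query_id"].map(gene_lengths)
        if df["qlen"].isna().any():
            missing = df.loc[df["qlen"].isna(), "query_id"].unique()
            raise ValueError(f"no length for genes: {sorted(missing)[:5]}")
    else:
        raise ValueError(f"{path}: expected 12 or 13 columns, got {df.shape[1]}")
    return [
        SimilarityHit(
            query_id=str(r.query_id),
            subject_id=str(r.subject_id),
            evalue=float(r.evalue),
            query_coverage=min(1.0, float(r.length) / float(r.qlen)),
            bitscore=float(r.bitscore),
        )
        for r in df.itertuples(index=False)
    ]


def classify_genes(
    hits: Iterable[SimilarityHit],
    genes: Iterable[str],
    dup_evalue: float = 1e-10,
    dup_cov: float = 0.5,
    singleton_evalue: float = 1e-3,
) -> GeneCatalog:
    """Assign every gene to duplicate / singleton / unclassified.

    Strict inequalities as published: duplicate requires a nonself hit with
    evalue < dup_evalue AND coverage > dup_cov; singleton requires no
    nonself hit with evalue < singleton_evalue. Unknown gene ids appearing
    in hits raise an error. An empty hit list makes every gene a singleton.
    """
    gene_set = set(genes)
    has_dup_hit: set[str] = set()
    has_weak_hit: set[str] = set()
    for h in hits:
        if h.query_id not in gene_set or h.subject_id not in gene_set:
            unknown = {h.query_id, h.subject_id} - gene_set
            raise ValueError(f"hit references unknown gene id(s): {sorted(unknown)}")
        if h.is_self:
            continue
        if h.evalue < dup_evalue and h.query_coverage > dup_cov:
            has_dup_hit.add(h.query_id)
        if h.evalue < singleton_evalue:
            has_weak_hit.add(h.query_id)
    assignment = {}
    for g in gene_set:
        if g in has_dup_hit:
            assignment[g] = "duplicate"
        elif g not in has_weak_hit:
            assignment[g] = "singleton"
        else:
            assignment[g] = "unclassified"
    return GeneCatalog(
        assignment,
        thresholds={
            "dup_evalue": dup_evalue,
            "dup_cov": dup_cov,
            "singleton_evalue": singleton_evalue,
        },
    )


def enrichment_table(catalog: GeneCatalog, targets: set[str]) -> np.ndarray:
    """2x2 counts: rows duplicate/singleton, columns target/non-target.

    Unclassified genes are excluded; target genes absent from the catalog
    are dropped with a warning.
    """
    if not catalog.assignment:
        raise ValueError("empty catalog")
    unknown = targets - set(catalog.assignment)
    if unknown:
        logger.warning("dropping %d target genes absent from catalog", len(unknown))
    dups, singles = catalog.duplicates, catalog.singletons
    dt = len(dups & targets)
    st = len(singles & targets)
    return np.array(
        [[dt, len(dups) - dt], [st, len(singles) - st]], dtype=np.int64
    )


def read_pair_labels(path: str | Path) -> pd.DataFrame:
    """Read the labeled paralog pair/triplet TSV.

    Columns: gene_a, gene_b, optional gene_c (empty for pairs), class in
    {WGD, TD, other, triplet}.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"gene_a", "gene_b", "class"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: missing columns {required - set(df.columns)}")
    if "gene_c" not in df.columns:
        df["gene_c"] = ""
    bad = set(df["class"]) - {"WGD", "TD", "other", "triplet"}
    if bad:
        raise ValueError(f"{path}: unknown duplication classes {sorted(bad)}")
    return df[["gene_a", "gene_b", "gene_c", "class"]]
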