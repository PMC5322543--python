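"""Classification of paralog groups by miRNA binding-site pattern.

A paralog pair (or triplet) is *divergent* when only a proper subset of its
members carry a miRNA binding site, or when all members are targeted but by
different miRNA families; it is *same* when every member is targeted by an
identical, nonempty family set; it is *not applicable* when no member is a
target. Divergence is tallied at the level of miRNA family sets rather
than site coordinates — which miRNAs target each paralog — with a
coordinate-aware mode behind a flag.

The module also classifies miRNA ages from cross-species homolog hit
tables (genus-restricted = young) and attributes divergence to young
miRNAs via the symmetric difference of the members' target sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_INGROUP = frozenset({"Arabidopsis thaliana", "Arabidopsis lyrata"})

# Declared species panel for cross-species homolog searches (ingroup plus
# a representative outgroup set; extendable via HomologHitTable).
DEFAULT_SPECIES_PANEL = (
    "Arabidopsis thaliana",
    "Arabidopsis lyrata",
    "Brassica rapa",
    "Capsella rubella",
    "Thellungiella halophila",
    "Carica papaya",
    "Populus trichocarpa",
    "Glycine max",
    "Medicago truncatula",
    "Vitis vinifera",
    "Solanum lycopersicum",
    "Oryza sativa",
    "Zea mays",
    "Sorghum bicolor",
    "Brachypodium distachyon",
    "Selaginella moellendorffii",
    "Physcomitrella patens",
)


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round half away from zero at the given precision (printed-table style)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percentage(numerator: float, denominator: float, decimals: int = 0) -> float:
    """Round-half-up percentage as printed in summary tables."""
    if denominator == 0:
        raise ZeroDivisionError("percentage of an empty denominator")
    return round_half_up(100.0 * numerator / denominator, decimals)


@dataclass
class ParalogGroup:
    """2 or 3 paralogous genes with their per-gene miRNA family sets.

    ``verdict`` and ``subtype`` are filled by :func:`classify_pair`.
    """

    genes: tuple[str, ...]
    dup_class: str  # WGD | TD | other | triplet
    target_sets: dict[str, frozenset[str]]
    verdict: str = "unclassified"
    subtype: str = "none"

    def __post_init__(self) -> None:
        self.genes = tuple(self.genes)
        if len(self.genes) not in (2, 3):
            raise ValueError(f"paralog group must have 2 or 3 genes, got {len(self.genes)}")
        if self.dup_class not in ("WGD", "TD", "other", "triplet"):
            raise ValueError(f"unknown duplication class {self.dup_class!r}")
        for g in self.genes:
            self.target_sets.setdefault(g, frozenset())
            self.target_sets[g] = frozenset(self.target_sets[g])

    @property
    def member_sets(self) -> list[frozenset[str]]:
        return [self.target_sets[g] for g in self.genes]

    @property
    def n_targeted(self) -> int:
        return sum(1 for s in self.member_sets if s)

    @property
    def involved_families(self) -> frozenset[str]:
        return frozenset().union(*self.member_sets)

    @property
    def differing_families(self) -> frozenset[str]:
        """Families not shared by every member (the divergence-causing set)."""
        union = frozenset().union(*self.member_sets)
        inter = self.member_sets[0]
        for s in self.member_sets[1:]:
            inter = inter & s
        return union - inter


def classify_pair(group: ParalogGroup) -> ParalogGroup:
    """Assign the same/divergent/not_applicable verdict and its subtype.

    Invariant under permutation of member genes. ``asymmetric`` marks a
    divergent group with at least one untargeted member; ``different_mirnas``
    a divergent group where every member is targeted.
    """
    sets = group.member_sets
    if all(not s for s in sets):
        group.verdict, group.subtype = "not_applicable", "none"
    elif all(sets[0] == s for s in sets[1:]):
        group.verdict, group.subtype = "same", "all_same"
    else:
        group.verdict = "divergent"
        group.subtype = "asymmetric" if any(not s for s in sets) else "different_mirnas"
    return group


@dataclass
class DivergenceSummary:
    """Cohort summary shaped like the published contingency tables."""

    by_class: pd.DataFrame  # rows same/divergent/total, columns dup classes + Total
    percent_divergent: dict[str, float]  # per class and "Total"
    triplet_by_targets: pd.DataFrame | None  # rows same/divergent/total per target count
    n_not_applicable: int


def summarize_groups(groups: Sequence[ParalogGroup]) -> DivergenceSummary:
    """Count same/divergent groups per duplication class.

    Percentages are round-half-up to integer, matching printed-table style.
    Triplets are additionally bucketed by the number of targeted members
    (1, 2 or 3); so are 2-gene groups (1 or 2) when any triplet is present,
    mirroring the duplicate/triplicate layout.
    """
    classed = [g for g in groups if g.verdict in ("same", "divergent")]
    n_na = sum(1 for g in groups if g.verdict == "not_applicable")
    if any(g.verdict == "unclassified" for g in groups):
        raise ValueError("summarize_groups requires classified groups")

    classes = sorted({g.dup_class for g in classed})
    counts = {c: {"same": 0, "divergent": 0} for c in classes}
    for g in classed:
        counts[g.dup_class][g.verdict] += 1
    data = {}
    for c in classes:
        data[c] = [counts[c]["same"], counts[c]["divergent"],
                   counts[c]["same"] + counts[c]["divergent"]]
    data["Total"] = [
        sum(counts[c]["same"] for c in classes),
        sum(counts[c]["divergent"] for c in classes),
        len(classed),
    ]
    by_class = pd.DataFrame(data, index=["same", "divergent", "total"])

    pct = {}
    for col in by_class.columns:
        total = by_class.loc["total", col]
        if total > 0:
            pct[col] = percentage(by_class.loc["divergent", col], total)

    trip = None
    if any(g.dup_class == "triplet" for g in classed):
        cols = [("pairs", k) for k in (1, 2)] + [("triplets", k) for k in (1, 2, 3)]
        tdata = {c: [0, 0] for c in cols}
        for g in classed:
            kind = "triplets" if len(g.genes) == 3 else "pairs"
            key = (kind, g.n_targeted)
            row = 0 if g.verdict == "same" else 1
            tdata[key][row] += 1
        trip = pd.DataFrame(
            {c: v + [sum(v)] for c, v in tdata.items()},
            index=["same", "divergent", "total"],
        )
        trip[("Total", "")] = trip.sum(axis=1)

    return DivergenceSummary(by_class, pct, trip, n_na)


@dataclass
class HomologHitTable:
    """Cross-species homolog hits for mature miRNAs.

    Rows are (mirna_id, species, evalue, coverage). ``annotation_override``
    lists miRNAs annotated as having outgroup homologs regardless of hits.
    """

    rows: list[tuple[str, str, float, float]]
    ingroup_species: frozenset[str] = DEFAULT_INGROUP
    species_panel: tuple[str, ...] = DEFAULT_SPECIES_PANEL
    annotation_override: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        panel = set(self.species_panel) | set(self.ingroup_species)
        unknown = {sp for _, sp, _, _ in self.rows} - panel
        if unknown:
            raise ValueError(
                f"unknown species {sorted(unknown)}; declared panel: "
                f"{sorted(panel)}"
            )

    @classmethod
    def from_tsv(cls, path, **kwargs) -> "HomologHitTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        rows = [
            (str(r.mirna_id), str(r.species), float(r.evalue), float(r.coverage))
            for r in df.itertuples(index=False)
        ]
        return cls(rows, **kwargs)


def classify_mirna_age(
    table: HomologHitTable,
    evalue: float = 1e-10,
    coverage: float = 0.5,
    mirna_ids: Iterable[str] | None = None,
) -> dict[str, str]:
    """Young vs ancient by genus restriction of homolog hits.

    A miRNA is *young* iff it has no hit outside the ingroup species with
    evalue < ``evalue`` and coverage > ``coverage``, and is not listed in
    the annotation override; otherwise *ancient*. miRNAs with no rows at
    all default to young (vacuously genus-restricted; logged).
    """
    ids = set(mirna_ids) if mirna_ids is not None else {r[0] for r in table.rows}
    ancient: set[str] = set(table.annotation_override) & ids
    seen: set[str] = set()
    for mid, sp, ev, cov in table.rows:
        if mid not in ids:
            continue
        seen.add(mid)
        if sp not in table.ingroup_species and ev < evalue and cov > coverage:
            ancient.add(mid)
    for mid in ids - seen:
        logger.info("miRNA %s has no homolog rows; classified young", mid)
    return {mid: ("ancient" if mid in ancient else "young") for mid in sorted(ids)}


@dataclass
class AgeAttribution:
    """Per-group young-miRNA attribution and cohort fractions."""

    per_group: pd.DataFrame
    n_divergent: int
    n_divergent_young: int
    n_same: int
    n_same_young: int

    @property
    def percent_divergent_young(self) -> float:
        return percentage(self.n_divergent_young, self.n_divergent)

    @property
    def percent_same_young(self) -> float:
        return percentage(self.n_same_young, self.n_same)


def attribute_divergence_age(
    groups: Sequence[ParalogGroup], ages: Mapping[str, str]
) -> AgeAttribution:
    """Attribute binding-site divergence to young miRNAs.

    A divergent group is ``young_attributed`` iff at least one family in the
    symmetric difference of its members' target sets is young — a shared
    ancient family must not mask a young-driven difference. Same-verdict
    groups are tallied by whether any involved family is young.
    """
    rows = []
    n_div = n_div_young = n_same = n_same_young = 0
    for g in groups:
        if g.verdict == "not_applicable":
            continue
        if g.verdict == "divergent":
            fams = g.differing_families
        elif g.verdict == "same":
            fams = g.involved_families
        else:
            raise ValueError("groups must be classified before attribution")
        missing = [f for f in fams if f not in ages]
        if missing:
            raise KeyError(f"no age for miRNA families {sorted(missing)}")
        any_young = any(ages[f] == "young" for f in fams)
        if g.verdict == "divergent":
            n_div += 1
            n_div_young += any_young
            label = "young_attributed" if any_young else "ancient_only"
        else:
            n_same += 1
            n_same_young += any_young
            label = "young_involved" if any_young else "ancient_only"
        rows.append(
            {
                "genes": ";".join(g.genes),
                "dup_class": g.dup_class,
                "verdict": g.verdict,
                "attribution": label,
            }
        )
    per_group = pd.DataFrame(
        rows, columns=["genes", "dup_class", "verdict", "attribution"]
    )
    return AgeAttribution(per_group, n_div, n_div_young, n_same, n_same_young)


def site_family_keys(
    sites: pd.DataFrame,
    fam_of: Mapping[str, str],
    coordinate_aware: bool = False,
    bin_width: int = 50,
) -> dict[str, frozenset[str]]:
    """Per-gene target-key sets from a consensus sites table.

    Default keys are miRNA family names; with ``coordinate_aware=True``
    keys are "family@bin" with the site start binned at ``bin_width`` nt,
    so paralogs targeted by the same family at distant positions compare
    as divergent.
    """
    out: dict[str, set[str]] = {}
    cons = sites[sites["consensus"]] if "consensus" in sites.columns else sites
    for rec in cons.itertuples(index=False):
        fam = fam_of[rec.mirna_id]
        key = f"{fam}@{(int(rec.start) - 1) // bin_width}" if coordinate_aware else fam
        out.setdefault(rec.gene_id, set()).add(key)
    return {g: frozenset(s) for g, s in out.items()}


def groups_from_tables(
    pair_labels: pd.DataFrame,
    gene_families: Mapping[str, frozenset[str]],
) -> list[ParalogGroup]:
    """Build classified :class:`ParalogGroup` objects from a pair-label table
    and a gene -> miRNA-family-set mapping (e.g. from the consensus scan)."""
    groups = []
    for rec in pair_labels.to_dict("records"):
        genes = [rec["gene_a"], rec["gene_b"]] + (
            [rec["gene_c"]] if rec.get("gene_c") else []
        )
        g = ParalogGroup(
            genes=tuple(genes),
            dup_class=rec["class"],
            target_sets={
                g_: frozenset(gene_families.get(g_, frozenset())) for g_ in genes
            },
        )
        groups.append(classify_pair(g))
    return groups
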