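"""Stage 3 — per-disease related networks, drug target categories, and
phase-wise rate tables.

For disease *j* with disease genes Dg_j and pooled drug targets T_j:

* ``NC_j`` — networks intersecting both Dg_j and T_j (disease-related
  networks);
* ``DNC_ij`` — the disease's drugs with a target inside network N_i;
* ``DNGT_j_s = ∪_{i∈NC_j} DNC_ij`` — drugs targeting some network that
  holds a disease gene;
* ``DNA_j`` — drugs with a target inside *any* network (target meets NA,
  the union of all network gene sets).

Each drug is placed into exactly one category, in priority order:
targets a disease gene itself; else targets a non-disease gene in a network
containing a disease gene; else targets a network without disease genes;
else targets no network gene at all. The rate table reports the three
in-network categories as percentages of |DNA_j| per (disease, phase) — the
out-of-network drugs are reported separately — and feeds the three-way
ANOVA. A config switch uses |Dd_j| as denominator with the fourth category
included.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import GeneMode, Phase, StudyUniverse


class Category(str, enum.Enum):
    DISEASE_GENE = "disease_gene"
    RELATED_NETWORK_PARTNER = "related_network_partner"
    OTHER_NETWORK = "other_network"
    NO_NETWORK = "no_network"


IN_NETWORK_CATEGORIES: tuple[Category, ...] = (
    Category.DISEASE_GENE,
    Category.RELATED_NETWORK_PARTNER,
    Category.OTHER_NETWORK,
)

# categories counted as genetically supported in the fold-change analysis
RELATED_CATEGORIES: tuple[Category, ...] = (
    Category.DISEASE_GENE,
    Category.RELATED_NETWORK_PARTNER,
)


def related_networks(
    universe: StudyUniverse,
    j: int,
    gene_mode: GeneMode | str = GeneMode.INTEGRATED,
    phase: Phase | str = Phase.ALL,
) -> frozenset[str]:
    """NC_j: networks intersecting both the disease genes and T_j."""
    dg = universe.diseases[j].disease_genes(gene_mode)
    tj = universe.union_drug_targets(j, phase)
    if not dg or not tj:
        return frozenset()
    return frozenset(
        nid
        for nid in universe.networks
        if (universe.networks[nid] & dg) and (universe.networks[nid] & tj)
    )


def drugs_on_network(
    universe: StudyUniverse,
    j: int,
    network_id: str,
    phase: Phase | str = Phase.ALL,
) -> frozenset[str]:
    """DNC_ij: disease *j*'s phase drugs with a target inside the network."""
    net = universe.networks[network_id]
    tj = universe.union_drug_targets(j, phase)
    reachable = net & tj
    if not reachable:
        return frozenset()
    return frozenset(
        k for k in universe.diseases[j].drugs(phase)
        if universe.drugs[k].targets & reachable
    )


def drugs_on_related_networks(
    universe: StudyUniverse,
    j: int,
    gene_mode: GeneMode | str = GeneMode.INTEGRATED,
    phase: Phase | str = Phase.ALL,
) -> frozenset[str]:
    """DNGT_j_s: union of DNC_ij over the disease-related networks NC_j."""
    out: set[str] = set()
    for nid in related_networks(universe, j, gene_mode, phase):
        out |= drugs_on_network(universe, j, nid, phase)
    return frozenset(out)


def drugs_on_any_network(
    universe: StudyUniverse,
    j: int,
    phase: Phase | str = Phase.ALL,
) -> frozenset[str]:
    """DNA_j: the disease's phase drugs with ≥1 target inside any network."""
    na = universe.network_gene_union()
    return frozenset(
        k for k in universe.diseases[j].drugs(phase)
        if universe.drugs[k].targets & na
    )


@dataclass
class DiseaseNetworkSets:
    """The stage-3 sets for one (disease, phase)."""

    disease_number: int
    phase: Phase
    related_networks: frozenset[str]
    drugs_on_related: dict[str, frozenset[str]]
    drugs_on_related_union: frozenset[str]
    drugs_on_any_network: frozenset[str]


def disease_network_sets(
    universe: StudyUniverse,
    j: int,
    gene_mode: GeneMode | str = GeneMode.INTEGRATED,
    phase: Phase | str = Phase.ALL,
) -> DiseaseNetworkSets:
    phase = Phase(phase)
    nc = related_networks(universe, j, gene_mode, phase)
    per_net = {nid: drugs_on_network(universe, j, nid, phase) for nid in sorted(nc)}
    union: set[str] = set()
    for drugs in per_net.values():
        union |= drugs
    return DiseaseNetworkSets(
        disease_number=j,
        phase=phase,
        related_networks=nc,
        drugs_on_related=per_net,
        drugs_on_related_union=frozenset(union),
        drugs_on_any_network=drugs_on_any_network(universe, j, phase),
    )


def categorize_drug(
    universe: StudyUniverse,
    j: int,
    drug_id: str,
    gene_mode: GeneMode | str = GeneMode.INTEGRATED,
) -> Category:
    """Single category for one drug, by priority.

    1. ``DISEASE_GENE`` — a target *is* one of the disease's genes;
    2. ``RELATED_NETWORK_PARTNER`` — a target sits in a network that also
       contains a disease gene (the target itself is not a disease gene);
    3. ``OTHER_NETWORK`` — a target sits in some network, none of which
       contain a disease gene;
    4. ``NO_NETWORK`` — no target inside any network (including drugs with
       an empty target set).
    """
    if drug_id not in universe.drugs:
        raise KeyError(f"unknown drug {drug_id!r}")
    targets = universe.drugs[drug_id].targets
    dg = universe.diseases[j].disease_genes(gene_mode)
    if targets & dg:
        return Category.DISEASE_GENE
    for nid in universe.networks:
        net = universe.networks[nid]
        if (net & dg) and (net & targets):
            return Category.RELATED_NETWORK_PARTNER
    if targets & universe.network_gene_union():
        return Category.OTHER_NETWORK
    return Category.NO_NETWORK


@dataclass
class RateTable:
    """Counts and percentages per (disease, phase, category).

    ``denominator`` is ``"dna"`` (drugs targeting ≥1 network; the three
    in-network categories exhaust it) or ``"all_drugs"`` (|Dd_j|, with the
    no-network category as a fourth level). Within every (disease, phase)
    the category percentages sum to 100 and the counts to the denominator.
    """

    gene_mode: GeneMode
    denominator: str
    categories: tuple[Category, ...]
    disease_numbers: list[int]
    phases: tuple[Phase, ...]
    cells: dict[tuple[int, Phase, Category], dict] = field(default_factory=dict)
    denominators: dict[tuple[int, Phase], int] = field(default_factory=dict)
    # drugs outside every network, reported next to (not inside) dna-based rates
    out_of_network: dict[tuple[int, Phase], int] = field(default_factory=dict)

    def percent(self, j: int, phase: Phase | str, category: Category) -> float:
        return self.cells[(j, Phase(phase), category)]["percent"]

    def count(self, j: int, phase: Phase | str, category: Category) -> int:
        return self.cells[(j, Phase(phase), category)]["count"]

    def to_anova_array(self):
        """Percent array shaped (disease, phase, category) with labels."""
        arr = np.full(
            (len(self.disease_numbers), len(self.phases), len(self.categories)), np.nan
        )
        for (j, phase, cat), cell in self.cells.items():
            arr[
                self.disease_numbers.index(j),
                self.phases.index(phase),
                self.categories.index(cat),
            ] = cell["percent"]
        levels = (
            [str(j) for j in self.disease_numbers],
            [p.value for p in self.phases],
            [c.value for c in self.categories],
        )
        return arr, ("DISEASE", "PHASE", "TARGET"), levels

    def to_rows(self) -> list[dict]:
        rows = []
        for (j, phase, cat), cell in sorted(
            self.cells.items(), key=lambda kv: (kv[0][0], kv[0][1].value, kv[0][2].value)
        ):
            rows.append({
                "disease_number": j,
                "phase": phase.value,
                "category": cat.value,
                "count": cell["count"],
                "percent": cell["percent"],
                "denominator": self.denominators[(j, phase)],
            })
        return rows


def rate_table(
    universe: StudyUniverse,
    disease_numbers: Sequence[int],
    gene_mode: GeneMode | str = GeneMode.INTEGRATED,
    phases: Sequence[Phase | str] = (Phase.ALL, Phase.CLINICAL, Phase.APPROVED),
    denominator: str = "dna",
    include_no_network: bool = True,
) -> RateTable:
    """Build the (disease × phase × category) rate table.

    With the default ``"dna"`` denominator, every cell's denominator is the
    number of the disease's phase drugs targeting at least one network; a
    zero denominator is an error naming the offending cell. With
    ``"all_drugs"`` the denominator is the full phase drug list and the
    no-network category joins the table (drop it with
    ``include_no_network=False`` to analyse only the three in-network
    categories against the full denominator — in that configuration the
    cell percentages do not sum to 100, which is what lets the factorial
    analysis detect a phase main effect).
    """
    if denominator not in ("dna", "all_drugs"):
        raise ValueError(f"denominator must be 'dna' or 'all_drugs', got {denominator!r}")
    gene_mode = GeneMode(gene_mode)
    phases = tuple(Phase(p) for p in phases)
    cats = (
        IN_NETWORK_CATEGORIES
        if denominator == "dna" or not include_no_network
        else tuple(Category)
    )
    table = RateTable(
        gene_mode=gene_mode, denominator=denominator, categories=cats,
        disease_numbers=list(disease_numbers), phases=phases,
    )
    for j in disease_numbers:
        for phase in phases:
            if denominator == "dna":
                pool = drugs_on_any_network(universe, j, phase)
            else:
                pool = universe.diseases[j].drugs(phase)
            denom = len(pool)
            if denom == 0:
                raise ValueError(
                    f"empty denominator for disease {j}, phase {phase.value} "
                    f"({denominator})"
                )
            counts = {c: 0 for c in Category}
            for drug_id in pool:
                counts[categorize_drug(universe, j, drug_id, gene_mode)] += 1
            table.denominators[(j, phase)] = denom
            table.out_of_network[(j, phase)] = len(
                universe.diseases[j].drugs(phase)
            ) - len(drugs_on_any_network(universe, j, phase))
            for c in cats:
                table.cells[(j, phase, c)] = {
                    "count": counts[c],
                    "percent": 100.0 * counts[c] / denom,
                }
    return table


def related_network_rate(
    universe: StudyUniverse,
    j: int,
    gene_mode: GeneMode | str = GeneMode.INTEGRATED,
    phase: Phase | str = Phase.ALL,
) -> tuple[int, int]:
    """(|DNGT_j_s ∩ DNA_j|, |DNA_j|): drugs targeting a disease-gene
    network over drugs targeting any network, for one phase."""
    dna = drugs_on_any_network(universe, j, phase)
    rel = drugs_on_related_networks(universe, j, gene_mode, phase)
    return len(rel & dna), len(dna)


def pipeline_fold_change(
    table: RateTable,
    j: int,
    category: Category,
    baseline: Phase | str = Phase.ALL,
    endpoint: Phase | str = Phase.APPROVED,
) -> float:
    """Endpoint/baseline percentage ratio for one disease and category.

    Returns ``nan`` (flagged, not raised) when the baseline percentage is
    zero — the fold is undefined, not infinite evidence.
    """
    base = table.percent(j, baseline, category)
    end = table.percent(j, endpoint, category)
    if base == 0.0:
        return math.nan
    return end / base
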