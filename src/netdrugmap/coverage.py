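"""Stage 1 — coverage of the two gene-set universes by disease genes and
drug targets.

For each element *i* of a universe (pathway map or network) and each
disease *j* with disease-gene set Dg_j and pooled drug-target set T_j:

* ``SPG_i = Σ_j |element_i ∩ Dg_j|`` — summed disease-gene overlap;
* ``SPT_i = Σ_j |element_i ∩ T_j|`` — summed drug-target overlap;
* ``S_i = Σ_j 1[|element_i ∩ Dg_j| > 0 and |element_i ∩ T_j| > 0]`` —
  number of diseases whose genes *and* drug targets both fall in the
  element.

The four coverage counts are the numbers of elements with SPG>0 (PG/NG),
SPT>0 (PT/NT), both>0 (PGT/NGT), and S>0 (PGT_s/NGT_s). The last is the
strictest: the disease genes and the drug targets must come from the *same*
disease.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .model import DiseaseRecord, GeneMode, GeneSetCollection, Phase, StudyUniverse
from .stats import chi_square_independence


@dataclass
class CoverageCounts:
    """Per-element score vectors and the four coverage counts for one
    universe, aligned to ``element_ids`` (sorted element order)."""

    universe_kind: str
    element_ids: list[str]
    spg: np.ndarray
    spt: np.ndarray
    same_disease: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.element_ids)
        for name in ("spg", "spt", "same_disease"):
            v = np.asarray(getattr(self, name), dtype=np.int64)
            if v.shape != (n,):
                raise ValueError(f"{name} must have length {n}")
            setattr(self, name, v)

    @property
    def element_count(self) -> int:
        return len(self.element_ids)

    @property
    def with_genes(self) -> int:
        return int(np.count_nonzero(self.spg > 0))

    @property
    def with_targets(self) -> int:
        return int(np.count_nonzero(self.spt > 0))

    @property
    def with_both(self) -> int:
        return int(np.count_nonzero((self.spg > 0) & (self.spt > 0)))

    @property
    def with_same_disease_pair(self) -> int:
        return int(np.count_nonzero(self.same_disease > 0))

    def counts(self) -> dict[str, int]:
        return {
            "with_genes": self.with_genes,
            "with_targets": self.with_targets,
            "with_both": self.with_both,
            "with_same_disease_pair": self.with_same_disease_pair,
        }

    def check_invariants(self) -> None:
        """Raise if the count chain is violated (defensive self-check)."""
        if not (
            0
            <= self.with_same_disease_pair
            <= self.with_both
            <= min(self.with_genes, self.with_targets)
            <= self.element_count
        ):
            raise AssertionError("coverage count chain violated")


def _target_unions(
    universe: StudyUniverse, phase: Phase | str
) -> dict[int, frozenset[str]]:
    return {j: universe.union_drug_targets(j, phase) for j in universe.diseases}


def spg_scores(
    collection: GeneSetCollection,
    diseases: Mapping[int, DiseaseRecord],
    gene_mode: GeneMode | str = GeneMode.INTEGRATED,
) -> np.ndarray:
    """Summed disease-gene overlap per element, in sorted element order."""
    gene_sets = [d.disease_genes(gene_mode) for _, d in sorted(diseases.items())]
    return np.array(
        [
            sum(len(collection[eid] & dg) for dg in gene_sets)
            for eid in collection.element_ids()
        ],
        dtype=np.int64,
    )


def spt_scores(
    universe: StudyUniverse,
    collection: GeneSetCollection,
    phase: Phase | str = Phase.CLINICAL,
) -> np.ndarray:
    """Summed drug-target overlap per element.

    Targets are pooled per disease (T_j, a set union) before intersecting,
    so a gene targeted by several of one disease's drugs counts once for
    that disease.
    """
    unions = _target_unions(universe, phase)
    tj = [unions[j] for j in sorted(unions)]
    return np.array(
        [sum(len(collection[eid] & t) for t in tj) for eid in collection.element_ids()],
        dtype=np.int64,
    )


def same_disease_scores(
    universe: StudyUniverse,
    collection: GeneSetCollection,
    gene_mode: GeneMode | str = GeneMode.INTEGRATED,
    phase: Phase | str = Phase.CLINICAL,
) -> np.ndarray:
    """Per element, the number of diseases contributing both a disease gene
    and a drug target to the element."""
    unions = _target_unions(universe, phase)
    per_disease = [
        (universe.diseases[j].disease_genes(gene_mode), unions[j])
        for j in sorted(universe.diseases)
    ]
    return np.array(
        [
            sum(1 for dg, t in per_disease if (collection[eid] & dg) and (collection[eid] & t))
            for eid in collection.element_ids()
        ],
        dtype=np.int64,
    )


def coverage_counts(
    universe: StudyUniverse,
    collection: GeneSetCollection,
    gene_mode: GeneMode | str = GeneMode.INTEGRATED,
    phase: Phase | str = Phase.CLINICAL,
) -> CoverageCounts:
    """Compute the three score vectors and package the four counts."""
    result = CoverageCounts(
        universe_kind=collection.kind,
        element_ids=collection.element_ids(),
        spg=spg_scores(collection, universe.diseases, gene_mode),
        spt=spt_scores(universe, collection, phase),
        same_disease=same_disease_scores(universe, collection, gene_mode, phase),
    )
    result.check_invariants()
    return result


def contingency_table(
    pathway_counts: CoverageCounts,
    network_counts: CoverageCounts,
    layout: str = "four_category",
) -> tuple[np.ndarray, list[str]]:
    """Build the universe × coverage-category table of disjoint counts.

    ``four_category``: {genes only, targets only, both, neither} per
    universe — the raw coverage counts overlap, so they are first made
    mutually exclusive. ``both_vs_rest``: 2×2 on (elements with both) vs
    (all other elements).
    """
    rows = []
    if layout == "four_category":
        categories = ["genes_only", "targets_only", "both", "neither"]
        for c in (pathway_counts, network_counts):
            both = c.with_both
            rows.append([
                c.with_genes - both,
                c.with_targets - both,
                both,
                c.element_count - (c.with_genes + c.with_targets - both),
            ])
    elif layout == "both_vs_rest":
        categories = ["both", "rest"]
        for c in (pathway_counts, network_counts):
            rows.append([c.with_both, c.element_count - c.with_both])
    else:
        raise ValueError(f"unknown layout {layout!r}")
    return np.array(rows, dtype=np.int64), categories


def compare_universes(
    pathway_counts: CoverageCounts,
    network_counts: CoverageCounts,
    layout: str = "four_category",
    yates: bool = False,
) -> dict:
    """Chi-square test of independence between universe kind and coverage
    category.

    Both :class:`CoverageCounts` must come from the same diseases and
    drugs. Categories whose *expected* count is zero in either row are an
    error; the caller should merge categories (e.g. switch to
    ``both_vs_rest``).
    """
    table, categories = contingency_table(pathway_counts, network_counts, layout)
    col_totals = table.sum(axis=0)
    if (col_totals == 0).any():
        empty = [c for c, t in zip(categories, col_totals) if t == 0]
        raise ValueError(
            f"zero expected count in categories {empty}; merge categories "
            f"(e.g. layout='both_vs_rest')"
        )
    stat, dof, p = chi_square_independence(table, yates=yates)
    return {
        "layout": layout,
        "categories": categories,
        "table": table.tolist(),
        "statistic": stat,
        "dof": dof,
        "p_value": p,
    }
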