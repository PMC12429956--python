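"""Domain types for the gene-set overlap analysis.

Everything downstream is set algebra over opaque gene identifiers: a pathway
map or a network element is nothing but its gene set, a drug is its target
set, and a disease carries a Mendelian (OMIM-derived) gene list, an optional
GWAS risk-gene list, and per-phase drug lists. Gene IDs are compared by
literal string equality; no namespace normalisation is performed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping


class Phase(str, enum.Enum):
    """Drug-development phase of a disease's drug list.

    ``CLINICAL`` and ``APPROVED`` are both subsets of ``ALL``; approved
    drugs need not be a subset of the clinical-trial set (approval may be
    recorded from drug labels without a registered trial).
    """

    ALL = "all"
    CLINICAL = "clinical"
    APPROVED = "approved"


class GeneMode(str, enum.Enum):
    """Which gene list counts as 'disease genes'.

    ``OMIM``: Mendelian genes only. ``INTEGRATED``: union of Mendelian genes
    and GWAS risk genes — the default of the rate analysis.
    """

    OMIM = "omim"
    INTEGRATED = "integrated"


def _as_phase(phase: Phase | str) -> Phase:
    try:
        return Phase(phase)
    except ValueError:
        raise ValueError(
            f"unknown phase {phase!r}; expected one of "
            f"{[p.value for p in Phase]}"
        ) from None


def _as_gene_mode(mode: GeneMode | str) -> GeneMode:
    try:
        return GeneMode(mode)
    except ValueError:
        raise ValueError(
            f"unknown gene mode {mode!r}; expected one of "
            f"{[m.value for m in GeneMode]}"
        ) from None


@dataclass
class GeneSetCollection:
    """A named family of gene sets: either pathway maps or network elements.

    Parameters
    ----------
    kind
        ``"pathway"`` or ``"network"``.
    members
        Mapping from element ID (e.g. ``"hsa04010"`` or ``"N00924"``) to its
        gene set. Every member set must be non-empty.
    """

    kind: str
    members: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        if self.kind not in ("pathway", "network"):
            raise ValueError(f"kind must be 'pathway' or 'network', got {self.kind!r}")
        self.members = {eid: frozenset(genes) for eid, genes in self.members.items()}
        empties = [eid for eid, genes in self.members.items() if not genes]
        if empties:
            raise ValueError(f"empty gene sets for elements: {sorted(empties)[:5]}")

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def __getitem__(self, element_id: str) -> frozenset[str]:
        return self.members[element_id]

    def element_ids(self) -> list[str]:
        """Element IDs in sorted order (the canonical iteration order)."""
        return sorted(self.members)

    def gene_union(self) -> frozenset[str]:
        """Union of all member gene sets (the NA universe for networks)."""
        out: set[str] = set()
        for genes in self.members.values():
            out |= genes
        return frozenset(out)


@dataclass
class DrugRecord:
    """A drug and the genes encoding its target proteins (may be empty)."""

    drug_id: str
    targets: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.targets = frozenset(self.targets)


@dataclass
class DiseaseRecord:
    """One rare/intractable disease with its gene lists and phase-wise drugs.

    ``omim_genes`` holds the Mendelian gene list; ``risk_genes`` the
    GWAS-derived list (often empty). ``drugs_by_phase`` maps each
    :class:`Phase` to a set of drug IDs; the clinical and approved sets are
    subsets of the all-drugs set, but approved drugs need not appear in the
    clinical set.
    """

    disease_number: int
    name: str
    groups: frozenset[str] = frozenset()
    omim_genes: frozenset[str] = frozenset()
    risk_genes: frozenset[str] = frozenset()
    drugs_by_phase: dict[Phase, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.groups = frozenset(self.groups)
        self.omim_genes = frozenset(self.omim_genes)
        self.risk_genes = frozenset(self.risk_genes)
        full = {p: frozenset(self.drugs_by_phase.get(p, frozenset())) for p in Phase}
        for p in (Phase.CLINICAL, Phase.APPROVED):
            extra = full[p] - full[Phase.ALL]
            if extra:
                raise ValueError(
                    f"disease {self.disease_number}: {p.value} drugs not in "
                    f"'all' set: {sorted(extra)[:5]}"
                )
        self.drugs_by_phase = full

    def disease_genes(self, mode: GeneMode | str = GeneMode.INTEGRATED) -> frozenset[str]:
        """Disease genes under the given mode: OMIM only, or OMIM ∪ GWAS."""
        mode = _as_gene_mode(mode)
        if mode is GeneMode.OMIM:
            return self.omim_genes
        return self.omim_genes | self.risk_genes

    def drugs(self, phase: Phase | str = Phase.ALL) -> frozenset[str]:
        return self.drugs_by_phase[_as_phase(phase)]


@dataclass
class StudyUniverse:
    """Container for the full study: gene-set universes, drugs, diseases.

    Invariants (enforced by :func:`netdrugmap.io.assemble_universe`): every
    gene referenced anywhere is in ``gene_universe``; every drug ID a disease
    references exists in ``drugs``.
    """

    pathways: GeneSetCollection
    networks: GeneSetCollection
    drugs: dict[str, DrugRecord]
    diseases: dict[int, DiseaseRecord]
    gene_universe: frozenset[str]

    def disease_numbers(self) -> list[int]:
        return sorted(self.diseases)

    def group_labels(self) -> list[str]:
        labels: set[str] = set()
        for d in self.diseases.values():
            labels |= d.groups
        return sorted(labels)

    def diseases_in_group(self, group: str) -> list[DiseaseRecord]:
        """Diseases carrying the group label, in disease-number order.

        A disease with several labels belongs to every group it carries.
        """
        out = [d for _, d in sorted(self.diseases.items()) if group in d.groups]
        if not out:
            raise KeyError(f"unknown or empty disease group {group!r}")
        return out

    def network_gene_union(self) -> frozenset[str]:
        """NA: the union of genes over all network elements."""
        return self.networks.gene_union()

    def union_drug_targets(self, j: int, phase: Phase | str = Phase.ALL) -> frozenset[str]:
        """T_j: union of the target genes of disease *j*'s drugs in a phase.

        Empty if the disease has no drugs in that phase.
        """
        disease = self.diseases[j]
        out: set[str] = set()
        for drug_id in disease.drugs(phase):
            out |= self.drugs[drug_id].targets
        return frozenset(out)


# Default 15-label disease-group vocabulary (three-letter codes as used for
# the Japanese designated intractable-disease categories).
DEFAULT_GROUP_VOCABULARY: frozenset[str] = frozenset({
    "Neu",   # neuromuscular
    "Endo",  # endocrine
    "Met",   # metabolic
    "Imm",   # immune
    "Card",  # cardiovascular
    "Hem",   # hematologic
    "Skin",  # skin and connective tissue
    "Bone",  # bone and joint
    "Eye",   # eye
    "Gast",  # gastrointestinal
    "Kid",   # kidney and urinary
    "Resp",  # respiratory
    "Chr",   # chromosomal and gene abnormalities
    "Hear",  # hearing and balance
    "Ear",   # ear, nose and throat
})
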