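"""Readers, writers, and cross-validation for the tabular input dialects.

All inputs are plain tab-separated text:

* link files — two columns, element ID and gene ID, one pair per line
  (the flat dialect served by pathway/network annotation APIs); ``#``
  comment lines allowed;
* disease table — ``disease_number\tname\tgroups`` with semicolon-separated
  group labels;
* gene lists — ``disease_number\tgene_id\tsource`` with source ``omim`` or
  ``gwas``;
* drug targets — ``drug_id\tgene_id`` pairs (a drug with no target rows has
  an empty target set only if declared in the drug list file);
* trial links — ``disease_number\tdrug_id\tphase``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .model import (
    DEFAULT_GROUP_VOCABULARY,
    DiseaseRecord,
    DrugRecord,
    GeneSetCollection,
    Phase,
    StudyUniverse,
)


class ParseError(ValueError):
    """Malformed input line; message carries file and line number."""


def _data_lines(path: Path) -> Iterable[tuple[int, str]]:
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def _split(path: Path, lineno: int, line: str, ncols: int) -> list[str]:
    fields = line.split("\t")
    if len(fields) != ncols:
        raise ParseError(
            f"{path}:{lineno}: expected {ncols} tab-separated columns, "
            f"got {len(fields)}"
        )
    return fields


def read_link_file(path: str | Path, kind: str) -> GeneSetCollection:
    """Read a 2-column element↔gene link file into a gene-set collection.

    Duplicate pairs are deduplicated; the result is independent of line
    order. Raises :class:`ParseError` on malformed lines and
    :class:`ValueError` if the file carries no pairs at all.
    """
    path = Path(path)
    members: dict[str, set[str]] = {}
    for lineno, line in _data_lines(path):
        element_id, gene_id = _split(path, lineno, line, 2)
        members.setdefault(element_id, set()).add(gene_id)
    if not members:
        raise ValueError(f"{path}: no element→gene pairs found")
    return GeneSetCollection(kind=kind, members={k: frozenset(v) for k, v in members.items()})


def write_link_file(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection back to the 2-column link dialect (sorted)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for element_id in collection.element_ids():
            for gene_id in sorted(collection[element_id]):
                fh.write(f"{element_id}\t{gene_id}\n")


def read_disease_table(
    path: str | Path,
    group_vocabulary: frozenset[str] | None = None,
) -> dict[int, DiseaseRecord]:
    """Read the disease table (number, name, semicolon-separated groups).

    Unknown group labels are rejected against the 15-label default
    vocabulary unless ``group_vocabulary`` overrides it. A disease with no
    group labels is permitted. Duplicate disease numbers are an error.
    """
    path = Path(path)
    vocab = DEFAULT_GROUP_VOCABULARY if group_vocabulary is None else frozenset(group_vocabulary)
    records: dict[int, DiseaseRecord] = {}
    for lineno, line in _data_lines(path):
        num_s, name, groups_s = _split(path, lineno, line, 3)
        try:
            number = int(num_s)
        except ValueError:
            raise ParseError(f"{path}:{lineno}: disease number {num_s!r} is not an integer")
        if number in records:
            raise ValueError(f"{path}:{lineno}: duplicate disease number {number}")
        groups = frozenset(g for g in groups_s.split(";") if g)
        unknown = groups - vocab
        if unknown:
            raise ValueError(
                f"{path}:{lineno}: unknown group labels {sorted(unknown)} "
                f"(override group_vocabulary to accept them)"
            )
        records[number] = DiseaseRecord(disease_number=number, name=name, groups=groups)
    return records


def read_gene_lists(path: str | Path) -> dict[int, dict[str, frozenset[str]]]:
    """Read disease→gene rows, split by source (``omim`` / ``gwas``)."""
    path = Path(path)
    acc: dict[int, dict[str, set[str]]] = {}
    for lineno, line in _data_lines(path):
        num_s, gene_id, source = _split(path, lineno, line, 3)
        if source not in ("omim", "gwas"):
            raise ParseError(f"{path}:{lineno}: gene source must be omim or gwas, got {source!r}")
        entry = acc.setdefault(int(num_s), {"omim": set(), "gwas": set()})
        entry[source].add(gene_id)
    return {
        j: {src: frozenset(genes) for src, genes in entry.items()}
        for j, entry in acc.items()
    }


def read_drug_targets(path: str | Path) -> dict[str, DrugRecord]:
    """Read drug→target pairs; a drug ID with gene ID ``-`` declares an
    otherwise target-less drug."""
    path = Path(path)
    targets: dict[str, set[str]] = {}
    for lineno, line in _data_lines(path):
        drug_id, gene_id = _split(path, lineno, line, 2)
        entry = targets.setdefault(drug_id, set())
        if gene_id != "-":
            entry.add(gene_id)
    return {d: DrugRecord(drug_id=d, targets=frozenset(t)) for d, t in targets.items()}


def read_trial_links(path: str | Path) -> list[tuple[int, str, Phase]]:
    """Read disease↔drug↔phase rows."""
    path = Path(path)
    links: list[tuple[int, str, Phase]] = []
    for lineno, line in _data_lines(path):
        num_s, drug_id, phase_s = _split(path, lineno, line, 3)
        try:
            phase = Phase(phase_s)
        except ValueError:
            raise ParseError(
                f"{path}:{lineno}: unknown phase {phase_s!r}; expected "
                f"{[p.value for p in Phase]}"
            )
        links.append((int(num_s), drug_id, phase))
    return links


@dataclass
class ValidationReport:
    """Outcome of universe assembly cross-checks."""

    n_pathways: int
    n_networks: int
    n_drugs: int
    n_diseases: int
    n_genes: int
    orphan_references: int = 0
    # disease genes appearing in no pathway and no network: retained, but
    # they can never contribute to an overlap score
    unmapped_disease_genes: int = 0
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def assemble_universe(
    pathways: GeneSetCollection,
    networks: GeneSetCollection,
    drugs: Mapping[str, DrugRecord],
    diseases: Mapping[int, DiseaseRecord],
    gene_lists: Mapping[int, Mapping[str, frozenset[str]]] | None = None,
    trial_links: Iterable[tuple[int, str, Phase]] | None = None,
) -> tuple[StudyUniverse, ValidationReport]:
    """Cross-validate the component tables into a :class:`StudyUniverse`.

    ``gene_lists`` and ``trial_links`` (when given) are merged into fresh
    copies of the disease records. Trial links naming an unknown drug or
    disease raise a :class:`ValueError` listing every offender. Disease
    genes absent from every pathway and network are retained in the gene
    universe but counted in the report — they cannot contribute to any
    overlap score.

    The result is deterministic and independent of input ordering.
    """
    diseases = {j: d for j, d in diseases.items()}

    if gene_lists is not None:
        for j, lists in gene_lists.items():
            if j not in diseases:
                raise ValueError(f"gene list references unknown disease {j}")
            d = diseases[j]
            diseases[j] = DiseaseRecord(
                disease_number=d.disease_number, name=d.name, groups=d.groups,
                omim_genes=d.omim_genes | lists.get("omim", frozenset()),
                risk_genes=d.risk_genes | lists.get("gwas", frozenset()),
                drugs_by_phase=dict(d.drugs_by_phase),
            )

    if trial_links is not None:
        offenders = sorted(
            {drug_id for j, drug_id, _ in trial_links if drug_id not in drugs}
            | {str(j) for j, _, _ in trial_links if j not in diseases}
        )
        if offenders:
            raise ValueError(f"trial links reference unknown drugs/diseases: {offenders}")
        by_disease: dict[int, dict[Phase, set[str]]] = {}
        for j, drug_id, phase in trial_links:
            by_disease.setdefault(j, {p: set() for p in Phase})[phase].add(drug_id)
        for j, phase_sets in by_disease.items():
            # clinical and approved drugs implicitly belong to the all set
            phase_sets[Phase.ALL] |= phase_sets[Phase.CLINICAL] | phase_sets[Phase.APPROVED]
            d = diseases[j]
            merged = {
                p: d.drugs_by_phase.get(p, frozenset()) | frozenset(phase_sets[p])
                for p in Phase
            }
            diseases[j] = DiseaseRecord(
                disease_number=d.disease_number, name=d.name, groups=d.groups,
                omim_genes=d.omim_genes, risk_genes=d.risk_genes,
                drugs_by_phase=merged,
            )

    mapped_genes = pathways.gene_union() | networks.gene_union()
    gene_universe: set[str] = set(mapped_genes)
    for drug in drugs.values():
        gene_universe |= drug.targets
    unmapped = 0
    warnings: list[str] = []
    for d in diseases.values():
        dg = d.omim_genes | d.risk_genes
        gene_universe |= dg
        unmapped += len(dg - mapped_genes)
        if not d.groups:
            warnings.append(f"disease {d.disease_number} carries no group label")

    missing_drugs = sorted({
        drug_id
        for d in diseases.values()
        for drug_id in d.drugs(Phase.ALL)
        if drug_id not in drugs
    })
    if missing_drugs:
        raise ValueError(f"diseases reference unknown drugs: {missing_drugs}")

    universe = StudyUniverse(
        pathways=pathways, networks=networks,
        drugs=dict(sorted(drugs.items())),
        diseases=dict(sorted(diseases.items())),
        gene_universe=frozenset(gene_universe),
    )
    report = ValidationReport(
        n_pathways=len(pathways), n_networks=len(networks),
        n_drugs=len(drugs), n_diseases=len(diseases),
        n_genes=len(gene_universe),
        orphan_references=0,
        unmapped_disease_genes=unmapped,
        warnings=warnings,
    )
    return universe, report


def union_drug_targets(universe: StudyUniverse, j: int, phase: Phase | str = Phase.ALL) -> frozenset[str]:
    """T_j for disease *j*: union of its phase drugs' target sets."""
    return universe.union_drug_targets(j, phase)


# --- directory layout: one TSV per table ----------------------------------

_FILES = {
    "pathways": "pathway_gene.tsv",
    "networks": "network_gene.tsv",
    "diseases": "diseases.tsv",
    "gene_lists": "disease_genes.tsv",
    "drug_targets": "drug_targets.tsv",
    "trial_links": "trial_links.tsv",
}


def load_universe(
    directory: str | Path,
    group_vocabulary: frozenset[str] | None = None,
) -> tuple[StudyUniverse, ValidationReport]:
    """Load and assemble a universe from a directory of the standard TSVs."""
    directory = Path(directory)
    for key, fname in _FILES.items():
        if not (directory / fname).exists():
            raise FileNotFoundError(f"missing input file {fname} in {directory}")
    pathways = read_link_file(directory / _FILES["pathways"], kind="pathway")
    networks = read_link_file(directory / _FILES["networks"], kind="network")
    diseases = read_disease_table(directory / _FILES["diseases"], group_vocabulary)
    gene_lists = read_gene_lists(directory / _FILES["gene_lists"])
    drugs = read_drug_targets(directory / _FILES["drug_targets"])
    trial_links = read_trial_links(directory / _FILES["trial_links"])
    return assemble_universe(pathways, networks, drugs, diseases, gene_lists, trial_links)


def write_universe(universe: StudyUniverse, directory: str | Path) -> None:
    """Write a universe to the standard TSV directory layout (sorted rows)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_link_file(universe.pathways, directory / _FILES["pathways"])
    write_link_file(universe.networks, directory / _FILES["networks"])
    with open(directory / _FILES["diseases"], "w", encoding="utf-8") as fh:
        for j, d in sorted(universe.diseases.items()):
            fh.write(f"{j}\t{d.name}\t{';'.join(sorted(d.groups))}\n")
    with open(directory / _FILES["gene_lists"], "w", encoding="utf-8") as fh:
        for j, d in sorted(universe.diseases.items()):
            for g in sorted(d.omim_genes):
                fh.write(f"{j}\t{g}\tomim\n")
            for g in sorted(d.risk_genes):
                fh.write(f"{j}\t{g}\tgwas\n")
    with open(directory / _FILES["drug_targets"], "w", encoding="utf-8") as fh:
        for drug_id, drug in sorted(universe.drugs.items()):
            if drug.targets:
                for g in sorted(drug.targets):
                    fh.write(f"{drug_id}\t{g}\n")
            else:
                fh.write(f"{drug_id}\t-\n")
    with open(directory / _FILES["trial_links"], "w", encoding="utf-8") as fh:
        for j, d in sorted(universe.diseases.items()):
            for phase in Phase:
                for drug_id in sorted(d.drugs(phase)):
                    fh.write(f"{j}\t{drug_id}\t{phase.value}\n")
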