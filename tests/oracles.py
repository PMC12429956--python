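"""Independent brute-force oracles for every score/count family.

Everything here is written as naive nested loops over plain dict/set
structures, deliberately sharing no code with the package implementation.
The random-universe builder is likewise independent of the package's
synthetic generator.
"""

from __future__ import annotations

import random

from netdrugmap.model import (
    DiseaseRecord,
    DrugRecord,
    GeneSetCollection,
    Phase,
    StudyUniverse,
)
from netdrugmap.io import assemble_universe


# ---------------------------------------------------------------- raw oracles
# All oracles take plain structures: elements: {eid: set(genes)},
# disease_genes: {j: set}, disease_targets: {j: set},
# disease_drugs: {j: {drug_id}}, drug_targets: {drug_id: set}.

def oracle_spg(elements, disease_genes):
    out = {}
    for eid, genes in elements.items():
        total = 0
        for j in disease_genes:
            for g in disease_genes[j]:
                if g in genes:
                    total += 1
        out[eid] = total
    return out


def oracle_spt(elements, disease_targets):
    return oracle_spg(elements, disease_targets)


def oracle_same_disease(elements, disease_genes, disease_targets):
    out = {}
    for eid, genes in elements.items():
        count = 0
        for j in disease_genes:
            has_gene = any(g in genes for g in disease_genes[j])
            has_target = any(t in genes for t in disease_targets.get(j, set()))
            if has_gene and has_target:
                count += 1
        out[eid] = count
    return out


def oracle_counts(elements, disease_genes, disease_targets):
    spg = oracle_spg(elements, disease_genes)
    spt = oracle_spt(elements, disease_targets)
    s = oracle_same_disease(elements, disease_genes, disease_targets)
    return {
        "with_genes": sum(1 for e in elements if spg[e] > 0),
        "with_targets": sum(1 for e in elements if spt[e] > 0),
        "with_both": sum(1 for e in elements if spg[e] > 0 and spt[e] > 0),
        "with_same_disease_pair": sum(1 for e in elements if s[e] > 0),
    }


def oracle_beta(network_genes, drug_targets, disease_drugs_j, disease_targets_j):
    """Number of the disease's drugs with a target in the network ∩ T_j."""
    reachable = {g for g in network_genes if g in disease_targets_j}
    count = 0
    for drug_id in disease_drugs_j:
        if any(t in reachable for t in drug_targets[drug_id]):
            count += 1
    return count


def oracle_sng(elements, group_disease_genes):
    """SNG per network over one group's diseases."""
    return oracle_spg(elements, group_disease_genes)


def oracle_snd(elements, drug_targets, group_disease_drugs, group_disease_targets):
    out = {}
    for eid, genes in elements.items():
        total = 0
        for j in group_disease_drugs:
            total += oracle_beta(
                genes, drug_targets, group_disease_drugs[j], group_disease_targets[j]
            )
        out[eid] = total
    return out


def oracle_related_networks(elements, disease_genes_j, disease_targets_j):
    return {
        eid
        for eid, genes in elements.items()
        if any(g in genes for g in disease_genes_j)
        and any(t in genes for t in disease_targets_j)
    }


def oracle_dngt(elements, drug_targets, disease_genes_j, disease_drugs_j, disease_targets_j):
    """Drugs targeting some network that holds a disease gene."""
    drugs = set()
    for eid in oracle_related_networks(elements, disease_genes_j, disease_targets_j):
        reachable = {g for g in elements[eid] if g in disease_targets_j}
        for drug_id in disease_drugs_j:
            if any(t in reachable for t in drug_targets[drug_id]):
                drugs.add(drug_id)
    return drugs


def oracle_dna(elements, drug_targets, disease_drugs_j):
    union = set()
    for genes in elements.values():
        union |= set(genes)
    return {d for d in disease_drugs_j if any(t in union for t in drug_targets[d])}


def oracle_category(elements, drug_targets_d, disease_genes_j):
    if any(t in disease_genes_j for t in drug_targets_d):
        return "disease_gene"
    for genes in elements.values():
        if any(g in genes for g in disease_genes_j) and any(t in genes for t in drug_targets_d):
            return "related_network_partner"
    union = set()
    for genes in elements.values():
        union |= set(genes)
    if any(t in union for t in drug_targets_d):
        return "other_network"
    return "no_network"


def chi2_closed_form_2x2(a, b, c, d):
    """Pearson chi-square for [[a,b],[c,d]]: n(ad-bc)^2 / product of margins."""
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    return n * (a * d - b * c) ** 2 / denom


# --------------------------------------------------- random universe builder

def random_raw_universe(rng: random.Random, max_networks=50, max_pathways=20,
                        max_diseases=20, max_drugs=100):
    """Plain-structure random universe plus its StudyUniverse counterpart."""
    n_genes = rng.randint(10, 60)
    genes = [f"g{i}" for i in range(n_genes)]
    n_networks = rng.randint(1, max_networks)
    networks = {
        f"N{i}": set(rng.sample(genes, rng.randint(1, min(6, n_genes))))
        for i in range(n_networks)
    }
    n_pathways = rng.randint(1, max_pathways)
    pathways = {
        f"P{i}": set(rng.sample(genes, rng.randint(1, min(15, n_genes))))
        for i in range(n_pathways)
    }
    n_drugs = rng.randint(1, max_drugs)
    drug_targets = {
        f"D{i}": set(rng.sample(genes, rng.randint(0, min(3, n_genes))))
        for i in range(n_drugs)
    }
    n_diseases = rng.randint(1, max_diseases)
    groups = ["Imm", "Neu", "Met"]
    raw = {
        "networks": networks,
        "pathways": pathways,
        "drug_targets": drug_targets,
        "disease_genes": {},     # integrated view (omim ∪ gwas)
        "disease_omim": {},
        "disease_gwas": {},
        "disease_drugs": {},     # per phase
        "disease_groups": {},
    }
    for j in range(1, n_diseases + 1):
        omim = set(rng.sample(genes, rng.randint(0, min(5, n_genes))))
        gwas = set(rng.sample(genes, rng.randint(0, min(3, n_genes))))
        all_drugs = set(rng.sample(sorted(drug_targets), rng.randint(0, min(10, n_drugs))))
        clinical = {d for d in all_drugs if rng.random() < 0.6}
        approved = {d for d in all_drugs if rng.random() < 0.3}
        raw["disease_omim"][j] = omim
        raw["disease_gwas"][j] = gwas
        raw["disease_genes"][j] = omim | gwas
        raw["disease_drugs"][j] = {"all": all_drugs, "clinical": clinical, "approved": approved}
        raw["disease_groups"][j] = {rng.choice(groups)} | (
            {rng.choice(groups)} if rng.random() < 0.3 else set()
        )
    return raw


def to_study_universe(raw) -> StudyUniverse:
    diseases = {
        j: DiseaseRecord(
            disease_number=j,
            name=f"toy {j}",
            groups=frozenset(raw["disease_groups"][j]),
            omim_genes=frozenset(raw["disease_omim"][j]),
            risk_genes=frozenset(raw["disease_gwas"][j]),
            drugs_by_phase={
                Phase.ALL: frozenset(raw["disease_drugs"][j]["all"]),
                Phase.CLINICAL: frozenset(raw["disease_drugs"][j]["clinical"]),
                Phase.APPROVED: frozenset(raw["disease_drugs"][j]["approved"]),
            },
        )
        for j in raw["disease_genes"]
    }
    universe, _ = assemble_universe(
        pathways=GeneSetCollection("pathway", {k: frozenset(v) for k, v in raw["pathways"].items()}),
        networks=GeneSetCollection("network", {k: frozenset(v) for k, v in raw["networks"].items()}),
        drugs={d: DrugRecord(d, frozenset(t)) for d, t in raw["drug_targets"].items()},
        diseases=diseases,
    )
    return universe


def disease_targets_from_raw(raw, phase="all"):
    """T_j per disease for a phase: union of that phase's drugs' targets."""
    out = {}
    for j, phases in raw["disease_drugs"].items():
        t = set()
        for d in phases[phase]:
            t |= set(raw["drug_targets"][d])
        out[j] = t
    return out
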