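"""Stage 2 — per-disease-group network scores and rankings.

For a disease group G and network N_i:

* ``SNG_i = Σ_{j∈G} |N_i ∩ Dg_j|`` — total disease-gene overlap;
* ``β_ij`` — the number of disease *j*'s drugs with at least one target
  inside N_i (targets restricted to the disease's pooled target set T_j);
* ``SND_i = Σ_{j∈G} β_ij`` — total count of targeting drug–disease pairs.

A drug developed for two diseases of the group contributes to both terms of
the SND sum (drug–disease pairs, not distinct drugs); ``dedup_drugs``
switches to distinct-drug counting for sensitivity analysis. The group's
``total_sum`` adds up, over its diseases, the number of drugs targeting any
network at all — the denominator-style quantity reported next to the
rankings.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import GeneMode, Phase, StudyUniverse


def sng_scores(
    universe: StudyUniverse,
    group: str,
    gene_mode: GeneMode | str = GeneMode.INTEGRATED,
) -> dict[str, int]:
    """SNG per network for one disease group. Unknown group → KeyError."""
    diseases = universe.diseases_in_group(group)
    gene_sets = [d.disease_genes(gene_mode) for d in diseases]
    return {
        nid: sum(len(universe.networks[nid] & dg) for dg in gene_sets)
        for nid in universe.networks.element_ids()
    }


def beta(
    universe: StudyUniverse,
    network_id: str,
    j: int,
    phase: Phase | str = Phase.CLINICAL,
) -> int:
    """Number of disease *j*'s phase drugs with ≥1 target in the network.

    A drug counts when its target set meets N_i ∩ T_j; since each drug's
    targets are contained in T_j, this is simply 'has a target inside the
    network'. Drugs with empty target sets never count.
    """
    net = universe.networks[network_id]
    tj = universe.union_drug_targets(j, phase)
    reachable = net & tj
    if not reachable:
        return 0
    return sum(
        1
        for drug_id in universe.diseases[j].drugs(phase)
        if universe.drugs[drug_id].targets & reachable
    )


def snd_scores(
    universe: StudyUniverse,
    group: str,
    phase: Phase | str = Phase.CLINICAL,
    dedup_drugs: bool = False,
) -> dict[str, int]:
    """SND per network for one disease group.

    Default counts drug–disease pairs; with ``dedup_drugs`` a drug shared
    between two of the group's diseases counts once per network.
    """
    diseases = universe.diseases_in_group(group)
    out: dict[str, int] = {}
    for nid in universe.networks.element_ids():
        if dedup_drugs:
            net = universe.networks[nid]
            drugs: set[str] = set()
            for d in diseases:
                reachable = net & universe.union_drug_targets(d.disease_number, phase)
                drugs |= {
                    k for k in d.drugs(phase)
                    if universe.drugs[k].targets & reachable
                }
            out[nid] = len(drugs)
        else:
            out[nid] = sum(beta(universe, nid, d.disease_number, phase) for d in diseases)
    return out


def top_k(scores: dict[str, int], k: int, strict: bool = False) -> list[tuple[str, int]]:
    """Top-k elements by descending score; zero scores are never ranked.

    Ties are broken lexicographically by element ID. By default every
    element tied with the k-th score is included (the list may exceed k);
    ``strict`` truncates to exactly k entries.
    """
    if k <= 0:
        raise ValueError("k must be >= 1")
    ranked = sorted(
        ((nid, s) for nid, s in scores.items() if s > 0),
        key=lambda item: (-item[1], item[0]),
    )
    if len(ranked) <= k:
        return ranked
    if strict:
        return ranked[:k]
    cutoff = ranked[k - 1][1]
    return [item for item in ranked if item[1] >= cutoff]


@dataclass
class GroupScoreTable:
    """All stage-2 quantities for one disease group."""

    group: str
    sng: dict[str, int]
    snd: dict[str, int]
    beta: dict[tuple[str, int], int]
    total_sum: int

    def top_by_genes(self, k: int = 3, strict: bool = False) -> list[tuple[str, int]]:
        return top_k(self.sng, k, strict)

    def top_by_drugs(self, k: int = 3, strict: bool = False) -> list[tuple[str, int]]:
        return top_k(self.snd, k, strict)


def group_score_table(
    universe: StudyUniverse,
    group: str,
    gene_mode: GeneMode | str = GeneMode.INTEGRATED,
    phase: Phase | str = Phase.CLINICAL,
) -> GroupScoreTable:
    """Compute SNG, SND, the β breakdown, and the group's total of drugs
    targeting any network."""
    from .rates import drugs_on_any_network  # late import: rates depends on model only

    diseases = universe.diseases_in_group(group)
    sng = sng_scores(universe, group, gene_mode)
    betas: dict[tuple[str, int], int] = {}
    for nid in universe.networks.element_ids():
        for d in diseases:
            b = beta(universe, nid, d.disease_number, phase)
            if b:
                betas[(nid, d.disease_number)] = b
    snd = {
        nid: sum(betas.get((nid, d.disease_number), 0) for d in diseases)
        for nid in universe.networks.element_ids()
    }
    total = sum(len(drugs_on_any_network(universe, d.disease_number, phase)) for d in diseases)
    return GroupScoreTable(group=group, sng=sng, snd=snd, beta=betas, total_sum=total)
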