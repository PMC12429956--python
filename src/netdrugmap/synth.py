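"""Synthetic study-universe generator with known ground truth.

The generator emulates the structure the analysis assumes, at desk scale:

* networks are small random gene segments (2–10 genes), every one of them
  nested inside at least one larger, overlapping pathway map;
* each of the 15 disease groups owns a designated pool of networks — only
  part of the network universe is owned, so coverage stays partial; a
  disease's genes are drawn from its group's pool with probability γ
  (``group_enrichment``) and uniformly otherwise, so disease-gene networks
  are group-characteristic while drug targets are spread uniformly;
* GWAS risk genes are drawn half from the pool and half uniformly, so the
  OMIM-only and integrated gene modes differ measurably;
* drug targets are drawn from a fixed 'druggable' subset of the gene
  universe, mirroring the concentration of real drug targets on a small
  druggable genome;
* every drug–disease pair enters the all-drugs phase; clinical-trial
  membership is an independent Bernoulli draw, and approval is a Bernoulli
  draw whose *odds* are multiplied by ρ (``approval_odds_multiplier``) when
  the drug targets a network containing that disease's genes — the
  genetic-support enrichment whose recovery the fold-change analysis tests.

Because approval is drawn independently of clinical-trial membership,
approved drugs are not always a subset of the clinical set, matching the
phase structure of real drug-development registries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np

from .model import (
    DEFAULT_GROUP_VOCABULARY,
    DiseaseRecord,
    DrugRecord,
    GeneSetCollection,
    Phase,
    StudyUniverse,
)
from .io import assemble_universe, ValidationReport


@dataclass
class SynthConfig:
    """Generator parameters. Defaults are the package's study conditions
    (a ~4×-scaled-down analogue of the real pathway/network universes)."""

    n_genes: int = 2000
    n_networks: int = 120
    network_size_range: tuple[int, int] = (2, 10)
    n_pathways: int = 30
    networks_per_pathway_range: tuple[int, int] = (2, 6)
    extra_genes_per_pathway: int = 8
    n_groups: int = 15
    diseases_per_group: int = 2
    pool_networks_per_group: int = 5
    disease_genes_per_disease: int = 8
    group_enrichment: float = 0.8        # γ: P(disease gene drawn from pool)
    gwas_genes_per_disease: int = 5
    gwas_pool_fraction: float = 0.5      # P(risk gene drawn from pool)
    druggable_fraction: float = 0.15     # share of genes that drugs can target
    n_drugs: int = 250
    targets_per_drug_range: tuple[int, int] = (1, 3)
    drugs_per_disease_range: tuple[int, int] = (30, 80)
    clinical_rate: float = 0.5           # fraction of pairs reaching trials
    approval_rate: float = 0.25          # base approval probability p0
    approval_odds_multiplier: float = 1.0  # ρ
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_networks", "n_pathways", "n_groups",
                     "diseases_per_group", "disease_genes_per_disease",
                     "n_drugs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.group_enrichment <= 1.0):
            raise ValueError("group_enrichment must be in [0, 1]")
        if not (0.0 <= self.gwas_pool_fraction <= 1.0):
            raise ValueError("gwas_pool_fraction must be in [0, 1]")
        if self.approval_odds_multiplier <= 0:
            raise ValueError("approval_odds_multiplier must be > 0")
        for name in ("clinical_rate", "approval_rate"):
            if not (0.0 < getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must be in (0, 1]")
        if not (0.0 < self.druggable_fraction <= 1.0):
            raise ValueError("druggable_fraction must be in (0, 1]")
        if self.pool_networks_per_group <= 0:
            raise ValueError("pool_networks_per_group must be positive")
        if self.network_size_range[1] > self.n_genes:
            raise ValueError("network size exceeds gene universe")
        n_druggable = max(1, int(round(self.druggable_fraction * self.n_genes)))
        if self.targets_per_drug_range[1] > n_druggable:
            raise ValueError("target count exceeds the druggable gene set")
        if self.drugs_per_disease_range[1] > self.n_drugs:
            raise ValueError("drugs per disease exceeds drug universe")
        if self.pool_networks_per_group * self.n_groups > self.n_networks:
            raise ValueError("group pools exceed the network universe")

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("network_size_range", "networks_per_pathway_range",
                    "targets_per_drug_range", "drugs_per_disease_range"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SynthConfig":
        d = dict(d)
        for key in ("network_size_range", "networks_per_pathway_range",
                    "targets_per_drug_range", "drugs_per_disease_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class GroundTruth:
    """What the generator actually did, for recovery tests."""

    config: SynthConfig
    group_pools: dict[str, frozenset[str]]        # group → pool network IDs
    disease_group: dict[int, str]
    # (disease, drug) → targets a network containing the disease's genes
    genetically_supported: dict[tuple[int, str], bool] = field(default_factory=dict)


def _approval_probability(p0: float, rho: float) -> float:
    """Approval probability after multiplying the odds by ρ."""
    if rho == 1.0:
        return p0
    odds = rho * p0 / (1.0 - p0) if p0 < 1.0 else float("inf")
    return odds / (1.0 + odds) if np.isfinite(odds) else 1.0


def _group_labels(n_groups: int) -> list[str]:
    base = sorted(DEFAULT_GROUP_VOCABULARY)
    if n_groups <= len(base):
        return base[:n_groups]
    return base + [f"G{i:02d}" for i in range(len(base) + 1, n_groups + 1)]


def generate_universe(
    config: SynthConfig, rng: np.random.Generator | None = None
) -> tuple[StudyUniverse, GroundTruth]:
    """Draw one study universe; fully reproducible from ``config.seed``.

    Returns the universe plus the ground-truth record (pool assignments and
    per-pair genetic-support flags).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    genes = np.array([f"hsa:{i}" for i in range(1, config.n_genes + 1)])

    # networks: random gene segments
    net_ids = [f"N{i:05d}" for i in range(1, config.n_networks + 1)]
    lo, hi = config.network_size_range
    networks: dict[str, frozenset[str]] = {}
    for nid in net_ids:
        size = int(rng.integers(lo, hi + 1))
        networks[nid] = frozenset(rng.choice(genes, size=size, replace=False))

    # pathways: unions of networks plus extra genes; a round-robin base
    # assignment guarantees every network sits in at least one pathway
    pw_ids = [f"hsa{40000 + i}" for i in range(1, config.n_pathways + 1)]
    order = list(rng.permutation(net_ids))
    base_chunks: dict[str, list[str]] = {pid: [] for pid in pw_ids}
    for pos, nid in enumerate(order):
        base_chunks[pw_ids[pos % config.n_pathways]].append(nid)
    plo, phi = config.networks_per_pathway_range
    pathways: dict[str, frozenset[str]] = {}
    for pid in pw_ids:
        chosen = set(base_chunks[pid])
        n_extra_nets = max(0, int(rng.integers(plo, phi + 1)) - len(chosen))
        if n_extra_nets:
            chosen |= set(rng.choice(net_ids, size=n_extra_nets, replace=False))
        gene_set: set[str] = set()
        for nid in chosen:
            gene_set |= networks[nid]
        if config.extra_genes_per_pathway:
            gene_set |= set(
                rng.choice(genes, size=config.extra_genes_per_pathway, replace=False)
            )
        pathways[pid] = frozenset(gene_set)

    # disease groups own disjoint network pools covering part of the universe
    labels = _group_labels(config.n_groups)
    pool_order = list(rng.permutation(net_ids))
    pool_size = config.pool_networks_per_group
    group_pools = {
        labels[g]: frozenset(pool_order[g * pool_size: (g + 1) * pool_size])
        for g in range(config.n_groups)
    }
    pool_genes = {
        g: np.array(sorted(set().union(*(networks[nid] for nid in pool))))
        for g, pool in group_pools.items()
    }

    # drugs: uniform target draws within the druggable subset
    n_druggable = max(1, int(round(config.druggable_fraction * config.n_genes)))
    druggable = rng.choice(genes, size=n_druggable, replace=False)
    drug_ids = [f"D{i:05d}" for i in range(1, config.n_drugs + 1)]
    tlo, thi = config.targets_per_drug_range
    drugs = {}
    for did in drug_ids:
        size = int(rng.integers(tlo, thi + 1))
        drugs[did] = DrugRecord(
            drug_id=did,
            targets=frozenset(rng.choice(druggable, size=size, replace=False)) if size else frozenset(),
        )

    # diseases: genes from the group pool with probability γ, else uniform
    gamma = config.group_enrichment
    diseases: dict[int, DiseaseRecord] = {}
    disease_group: dict[int, str] = {}
    truth = GroundTruth(config=config, group_pools=group_pools, disease_group=disease_group)
    dlo, dhi = config.drugs_per_disease_range
    j = 0
    for label in labels:
        for _ in range(config.diseases_per_group):
            j += 1
            disease_group[j] = label
            omim: set[str] = set()
            for _ in range(config.disease_genes_per_disease):
                source = pool_genes[label] if rng.random() < gamma else genes
                omim.add(str(rng.choice(source)))
            risk: set[str] = set()
            for _ in range(config.gwas_genes_per_disease):
                source = pool_genes[label] if rng.random() < config.gwas_pool_fraction else genes
                risk.add(str(rng.choice(source)))

            n_dd = int(rng.integers(dlo, dhi + 1))
            dd = [str(d) for d in rng.choice(drug_ids, size=n_dd, replace=False)]

            # genetic support: the drug targets a network holding a disease gene
            dg = frozenset(omim) | frozenset(risk)
            supported_genes: set[str] = set()
            for nid, net in networks.items():
                if net & dg:
                    supported_genes |= net
            clinical: set[str] = set()
            approved: set[str] = set()
            for did in dd:
                supported = bool(drugs[did].targets & supported_genes)
                truth.genetically_supported[(j, did)] = supported
                if rng.random() < config.clinical_rate:
                    clinical.add(did)
                p_app = _approval_probability(
                    config.approval_rate,
                    config.approval_odds_multiplier if supported else 1.0,
                )
                if rng.random() < p_app:
                    approved.add(did)

            diseases[j] = DiseaseRecord(
                disease_number=j,
                name=f"synthetic disease {j}",
                groups=frozenset({label}),
                omim_genes=frozenset(omim),
                risk_genes=frozenset(risk),
                drugs_by_phase={
                    Phase.ALL: frozenset(dd),
                    Phase.CLINICAL: frozenset(clinical),
                    Phase.APPROVED: frozenset(approved),
                },
            )

    universe, _report = assemble_universe(
        pathways=GeneSetCollection(kind="pathway", members=pathways),
        networks=GeneSetCollection(kind="network", members=networks),
        drugs=drugs,
        diseases=diseases,
    )
    return universe, truth


def expected_fold(
    config: SynthConfig,
    n_rep: int = 20,
    seed: int | None = None,
) -> float:
    """Analytic approved/all rate ratio for the genetically-supported
    category under the generator's odds model.

    With base approval probability p0, enriched probability
    p_ρ = ρ·p0 / (1 + (ρ−1)·p0), and q the fraction of genetically
    supported pairs among in-network drug–disease pairs, the expected fold
    is ``p_ρ / (q·p_ρ + (1−q)·p0)``. q depends on the random network/pool
    geometry, not on ρ, and is estimated from ``n_rep`` ρ-independent
    draws of the generator's all-phase structure. For ρ = 1 the fold is
    exactly 1 regardless of q.
    """
    rho = config.approval_odds_multiplier
    if rho == 1.0:
        return 1.0
    rng = np.random.default_rng(config.seed + 1_000_003 if seed is None else seed)
    from .rates import drugs_on_any_network, drugs_on_related_networks

    supported = 0
    in_network = 0
    for _ in range(n_rep):
        universe, _ = generate_universe(config, rng=rng)
        for j in universe.diseases:
            dna = drugs_on_any_network(universe, j, Phase.ALL)
            rel = drugs_on_related_networks(universe, j, phase=Phase.ALL)
            in_network += len(dna)
            supported += len(rel & dna)
    if in_network == 0:
        return float("nan")
    q = supported / in_network
    p0 = config.approval_rate
    p_rho = _approval_probability(p0, rho)
    return p_rho / (q * p_rho + (1.0 - q) * p0)
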