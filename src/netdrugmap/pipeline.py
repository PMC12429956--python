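"""End-to-end driver: coverage comparison, group rankings, and the
phase-wise rate analysis with its factorial statistics, over any input
directory (real exports or synthetic), plus the disease-selection rule of
the rate analysis.

All artifacts are plain TSV/JSON; a manifest records the seed and a SHA-256
checksum of every input and output, so identical inputs and seed give
byte-identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .model import GeneMode, Phase, StudyUniverse
from .io import load_universe, _FILES
from .coverage import coverage_counts, compare_universes
from .ranking import group_score_table
from .rates import (
    Category,
    disease_network_sets,
    pipeline_fold_change,
    rate_table,
)
from .stats import three_way_anova, tukey_hsd

logger = logging.getLogger("netdrugmap")


@dataclass
class SelectionRule:
    """Pick the diseases with the most clinical-trial drugs, then drop the
    weakest for the rate analysis: the ones with fewest approved drugs and
    the ones with fewest GWAS risk genes."""

    n_top: int = 9
    exclude_fewest_approved: int = 1
    exclude_fewest_risk_genes: int = 2


def select_diseases(universe: StudyUniverse, rule: SelectionRule) -> list[int]:
    """Apply the selection rule; deterministic, ties broken by ascending
    disease number. Returns disease numbers in ascending order."""
    if rule.n_top > len(universe.diseases):
        raise ValueError(
            f"rule asks for top {rule.n_top} of {len(universe.diseases)} diseases"
        )
    by_clinical = sorted(
        universe.diseases,
        key=lambda j: (-len(universe.diseases[j].drugs(Phase.CLINICAL)), j),
    )
    chosen = set(by_clinical[: rule.n_top])

    def drop(candidates: set[int], key, count: int) -> set[int]:
        if count <= 0:
            return candidates
        if count >= len(candidates):
            raise ValueError("exclusion rule would remove every disease")
        victims = sorted(candidates, key=lambda j: (key(j), j))[:count]
        return candidates - set(victims)

    chosen = drop(chosen, lambda j: len(universe.diseases[j].drugs(Phase.APPROVED)),
                  rule.exclude_fewest_approved)
    chosen = drop(chosen, lambda j: len(universe.diseases[j].risk_genes),
                  rule.exclude_fewest_risk_genes)
    return sorted(chosen)


@dataclass
class RunConfig:
    input_dir: str | Path
    output_dir: str | Path
    gene_mode: GeneMode | str = GeneMode.INTEGRATED
    phase: Phase | str = Phase.CLINICAL   # phase used for coverage + ranking
    top_k: int = 3
    diseases: Sequence[int] | None = None  # explicit list, or None → rule
    selection_rule: SelectionRule = field(default_factory=SelectionRule)
    rate_denominator: str = "dna"
    seed: int = 0
    log_level: str = "INFO"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_json(path: Path, obj) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _stage(name: str):
    """Decorator-free stage context: re-raise with the stage name."""
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
            logger.info("stage %s: done", name)
            return False
    return _Ctx()


def run_all(config: RunConfig) -> dict[str, Path]:
    """Run the three experiments and write all artifacts.

    Stage 1 compares pathway-map vs network coverage; stage 2 ranks
    networks per disease group by disease-gene and drug scores; stage 3
    builds the phase-wise rate table for the selected diseases and runs the
    three-way ANOVA with Tukey post-hocs, plus per-disease fold changes.
    Idempotent for fixed inputs and seed.
    """
    logging.basicConfig(level=getattr(logging, str(config.log_level).upper(), logging.INFO))
    in_dir = Path(config.input_dir)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gene_mode = GeneMode(config.gene_mode)
    phase = Phase(config.phase)
    logger.info("run_all: seed=%d gene_mode=%s phase=%s", config.seed, gene_mode.value, phase.value)

    artifacts: dict[str, Path] = {}

    with _stage("load"):
        universe, report = load_universe(in_dir)
        p = out_dir / "validation.json"
        p.write_text(report.to_json() + "\n", encoding="utf-8")
        artifacts["validation"] = p

    with _stage("coverage"):
        pc = coverage_counts(universe, universe.pathways, gene_mode, phase)
        nc = coverage_counts(universe, universe.networks, gene_mode, phase)
        for counts, name in ((pc, "pathway"), (nc, "network")):
            p = out_dir / f"coverage_{name}.tsv"
            with open(p, "w", encoding="utf-8") as fh:
                fh.write("element_id\tspg\tspt\tsame_disease\n")
                for i, eid in enumerate(counts.element_ids):
                    fh.write(
                        f"{eid}\t{counts.spg[i]}\t{counts.spt[i]}\t{counts.same_disease[i]}\n"
                    )
            artifacts[f"coverage_{name}"] = p
        summary = {
            "pathway": pc.counts() | {"element_count": pc.element_count},
            "network": nc.counts() | {"element_count": nc.element_count},
            "chi_square": compare_universes(pc, nc),
        }
        p = out_dir / "coverage_summary.json"
        _write_json(p, summary)
        artifacts["coverage_summary"] = p

    with _stage("ranking"):
        p = out_dir / "ranking.tsv"
        with open(p, "w", encoding="utf-8") as fh:
            fh.write("group\tscore_kind\trank\tnetwork_id\tscore\ttotal_sum\n")
            for group in universe.group_labels():
                table = group_score_table(universe, group, gene_mode, phase)
                for kind, ranked in (
                    ("genes", table.top_by_genes(config.top_k)),
                    ("drugs", table.top_by_drugs(config.top_k)),
                ):
                    for rank, (nid, score) in enumerate(ranked, start=1):
                        fh.write(
                            f"{group}\t{kind}\t{rank}\t{nid}\t{score}\t{table.total_sum}\n"
                        )
        artifacts["ranking"] = p

    with _stage("rates"):
        if config.diseases is not None:
            selected = list(config.diseases)
        else:
            selected = select_diseases(universe, config.selection_rule)
        table = rate_table(
            universe, selected, gene_mode, denominator=config.rate_denominator
        )
        p = out_dir / "rates.tsv"
        with open(p, "w", encoding="utf-8") as fh:
            fh.write("disease_number\tphase\tcategory\tcount\tpercent\tdenominator\n")
            for row in table.to_rows():
                fh.write(
                    f"{row['disease_number']}\t{row['phase']}\t{row['category']}\t"
                    f"{row['count']}\t{row['percent']:.6f}\t{row['denominator']}\n"
                )
        artifacts["rates"] = p

        sets = {
            j: {
                "related_networks": sorted(
                    disease_network_sets(universe, j, gene_mode, Phase.ALL).related_networks
                ),
            }
            for j in selected
        }
        p = out_dir / "network_sets.json"
        _write_json(p, sets)
        artifacts["network_sets"] = p

    with _stage("stats"):
        anova = three_way_anova(table)
        arr, factors, levels = table.to_anova_array()
        # Tukey over phases: each phase mean averages disease × category cells
        phase_means = {
            lev: float(arr[:, i, :].mean()) for i, lev in enumerate(levels[1])
        }
        group_size = arr.shape[0] * arr.shape[2]
        tukey = tukey_hsd(phase_means, anova.ms_error, anova.residual_df, group_size) \
            if not anova.zero_residual else None
        folds = {
            str(j): {
                cat.value: pipeline_fold_change(table, j, cat)
                for cat in table.categories
            }
            for j in selected
        }
        result = {
            "factors": list(anova.factors),
            "f_stats": anova.f_stats,
            "p_values": anova.p_values,
            "ss": anova.ss,
            "df": anova.df,
            "residual_ss": anova.residual_ss,
            "residual_df": anova.residual_df,
            "zero_residual": anova.zero_residual,
            "tukey_phase": [r for r in tukey] if tukey is not None else None,
            "fold_change_approved_vs_all": folds,
        }
        p = out_dir / "anova.json"
        _write_json(p, result)
        artifacts["anova"] = p

    with _stage("manifest"):
        manifest = {
            "seed": config.seed,
            "gene_mode": gene_mode.value,
            "phase": phase.value,
            "rate_denominator": config.rate_denominator,
            "inputs": {
                fname: _sha256(in_dir / fname) for fname in sorted(_FILES.values())
            },
            "outputs": {
                name: _sha256(path) for name, path in sorted(artifacts.items())
            },
        }
        p = out_dir / "manifest.json"
        _write_json(p, manifest)
        artifacts["manifest"] = p

    return artifacts
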