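import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from netdrugmap.model import (
    DiseaseRecord,
    DrugRecord,
    GeneSetCollection,
    Phase,
)
from netdrugmap.io import assemble_universe


@pytest.fixture
def toy_universe():
    """Hand-built universe small enough to verify every number by hand.

    Networks: N1={g1,g2}, N2={g3,g4}, N3={g5}.
    Pathways: P1=N1∪N2∪{g6}, P2=N3∪{g7}.
    Disease 1 (Imm): omim {g1}, gwas {g3}; drugs a{g2}, b{g3}, c{g9}.
    Disease 2 (Neu): omim {g5}, no gwas; drugs b{g3}, d{g5}.
    Phases: clinical ⊂ all; approved overlaps but is not nested in clinical.
    """
    networks = GeneSetCollection("network", {
        "N1": frozenset({"g1", "g2"}),
        "N2": frozenset({"g3", "g4"}),
        "N3": frozenset({"g5"}),
    })
    pathways = GeneSetCollection("pathway", {
        "P1": frozenset({"g1", "g2", "g3", "g4", "g6"}),
        "P2": frozenset({"g5", "g7"}),
    })
    drugs = {
        "a": DrugRecord("a", frozenset({"g2"})),
        "b": DrugRecord("b", frozenset({"g3"})),
        "c": DrugRecord("c", frozenset({"g9"})),
        "d": DrugRecord("d", frozenset({"g5"})),
        "e": DrugRecord("e", frozenset()),
    }
    diseases = {
        1: DiseaseRecord(
            disease_number=1, name="toy immune", groups=frozenset({"Imm"}),
            omim_genes=frozenset({"g1"}), risk_genes=frozenset({"g3"}),
            drugs_by_phase={
                Phase.ALL: frozenset({"a", "b", "c", "e"}),
                Phase.CLINICAL: frozenset({"a", "b"}),
                Phase.APPROVED: frozenset({"a", "c"}),
            },
        ),
        2: DiseaseRecord(
            disease_number=2, name="toy neuro", groups=frozenset({"Neu"}),
            omim_genes=frozenset({"g5"}), risk_genes=frozenset(),
            drugs_by_phase={
                Phase.ALL: frozenset({"b", "d"}),
                Phase.CLINICAL: frozenset({"d"}),
                Phase.APPROVED: frozenset({"d"}),
            },
        ),
    }
    universe, report = assemble_universe(pathways, networks, drugs, diseases)
    return universe


@pytest.fixture(scope="session")
def default_synth():
    from netdrugmap.synth import SynthConfig, generate_universe

    return generate_universe(SynthConfig(seed=7))
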