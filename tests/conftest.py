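import numpy as np
import pandas as pd
import pytest

from cellici import ReferenceCompendium, build_spec_table, select_markers
from cellici.simulate import SynthConfig, make_reference


@pytest.fixture
def toy_reference() -> ReferenceCompendium:
    """3 genes × 4 samples, 2 tissues; g1 is a perfect marker for tissue A."""
    expr = pd.DataFrame(
        {
            "a1": [100.0, 5.0, 50.0],
            "a2": [120.0, 6.0, 55.0],
            "b1": [2.0, 4.0, 60.0],
            "b2": [1.0, 7.0, 45.0],
        },
        index=["g1", "g2", "g3"],
    )
    labels = pd.Series({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
    return ReferenceCompendium(expression=expr, tissue_of=labels)


@pytest.fixture(scope="session")
def bench_cfg() -> SynthConfig:
    """The benchmark study conditions: 5 tissues × 4 replicates, 10 planted
    markers per tissue, 2,000 noise genes."""
    return SynthConfig(seed=0)


@pytest.fixture(scope="session")
def bench_reference(bench_cfg):
    return make_reference(bench_cfg)


@pytest.fixture(scope="session")
def bench_spec_table(bench_reference):
    ref, _ = bench_reference
    return build_spec_table(ref)


@pytest.fixture(scope="session")
def bench_markers(bench_spec_table):
    return select_markers(bench_spec_table)


@pytest.fixture(scope="session")
def bench_universe(bench_spec_table) -> list[str]:
    return list(bench_spec_table.eligible)


def call_counts(reports, truth):
    """Tally (correct single, incorrect) calls for a labeled cohort.

    Correct: a single call on the true tissue.  Incorrect: any call whose
    significant tissue set includes a tissue other than the truth.
    """
    correct = incorrect = 0
    for r in reports:
        true_t = truth[r.cell_id]
        if r.call == "single" and r.call_tissues[0] == true_t:
            correct += 1
        elif r.call_tissues and any(t != true_t for t in r.call_tissues):
            incorrect += 1
    return correct, incorrect
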