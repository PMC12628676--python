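import numpy as np
import pandas as pd
import pytest

from ecoassembly.datasets import CommunityTable, SampleFrame, read_newick
from ecoassembly.simulate import ScenarioConfig, assemble_dataset


@pytest.fixture
def four_tip_tree():
    # ((A,B),(C,D)) with simple lengths; cophenetic: A-B=2, A-C=A-D=B-C=B-D=3, C-D=2
    return read_newick("((A:1,B:1):0.5,(C:1,D:1):0.5);")


@pytest.fixture
def tiny_table():
    df = pd.DataFrame(
        [[10, 0, 5, 0], [0, 8, 0, 2], [4, 4, 4, 4]],
        index=["s1", "s2", "s3"],
        columns=["A", "B", "C", "D"],
    )
    return CommunityTable(df)


def make_meta(ecosystems, years, replicates, habitat="water"):
    rows = []
    for e in ecosystems:
        for y in years:
            for r in replicates:
                rows.append(
                    dict(
                        sample_id=f"{e}-{y}-{r}",
                        ecosystem=e,
                        year=y,
                        habitat=habitat,
                        replicate=r,
                        latitude=-62.2,
                        longitude=-58.9,
                        date=f"{y}-01-15",
                    )
                )
    return SampleFrame(pd.DataFrame(rows).set_index("sample_id"))


@pytest.fixture
def design_meta():
    return make_meta(["L1", "L2", "L3"], [2017, 2019], ["A", "B"])


@pytest.fixture(scope="session")
def small_scenario():
    """One small variable-selection dataset shared across tests."""
    cfg = ScenarioConfig(
        process="variable_selection",
        n_otus_pool=150,
        n_ecosystems=5,
        n_years=2,
        n_replicates=2,
        habitats=("water",),
        reads_per_sample=2000,
        seed=11,
    )
    return cfg, assemble_dataset(cfg)
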