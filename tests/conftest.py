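import numpy as np
import pandas as pd
import pytest

from cimsym.amplicon_filter import OtuTable
from cimsym.fixtures import load_survey_fixture


@pytest.fixture(scope="session")
def survey_fixture():
    """(host tree, genus trees, association table) from the packaged
    transcription of the survey."""
    return load_survey_fixture()


@pytest.fixture()
def small_otu_table():
    counts = pd.DataFrame(
        {
            "s1": [900, 50, 9, 41],
            "s2": [10, 500, 400, 90],
        },
        index=["OTU_wolb", "OTU_sym", "OTU_chloro", "OTU_env"],
        dtype=np.int64,
    )
    taxonomy = pd.Series(
        {
            "OTU_wolb": "Bacteria;Proteobacteria;Wolbachia",
            "OTU_sym": "Bacteria;Proteobacteria;Symbiopectobacterium",
            "OTU_chloro": "Bacteria;Cyanobacteria;Chloroplast",
            "OTU_env": "Bacteria;Firmicutes;Bacillus",
        }
    )
    return OtuTable(counts, taxonomy)


def random_topology(rng: np.random.Generator, labels: list[str]) -> str:
    """Random binary topology over ``labels`` by random pair merging."""
    nodes = list(labels)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b})")
    return nodes[0] + ";"
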