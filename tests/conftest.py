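import numpy as np
import pandas as pd
import pytest

from sedistrat import OtuTable, SampleMeta


@pytest.fixture
def tiny_samples():
    return [
        SampleMeta("s1", "core1", 0.0, 2.0, "bacteria"),
        SampleMeta("s2", "core1", 2.0, 4.0, "bacteria"),
    ]


@pytest.fixture
def tiny_table(tiny_samples):
    counts = pd.DataFrame(
        [[5, 0], [1, 2], [4, 8]],
        index=["OtuA", "OtuB", "OtuC"],
        columns=["s1", "s2"],
    )
    lineages = pd.Series(
        {
            "OtuA": "Bacteria;Proteobacteria;Deltaproteobacteria;Syntrophobacterales;Syntrophaceae;Syntrophus",
            "OtuB": "Bacteria;Caldiserica;Caldisericia;Caldisericales;Caldisericaceae;unclassified",
            "OtuC": "Bacteria;unclassified",
        }
    )
    return OtuTable(counts=counts, lineages=lineages, samples=tiny_samples)


@pytest.fixture
def random_table():
    rng = np.random.default_rng(42)
    n_otu, n_sample = 40, 6
    counts = pd.DataFrame(
        rng.integers(0, 30, size=(n_otu, n_sample)),
        index=[f"Otu{i:03d}" for i in range(n_otu)],
        columns=[f"s{j}" for j in range(n_sample)],
    )
    samples = [
        SampleMeta(f"s{j}", f"core{j % 2 + 1}", 2.0 * (j // 2), 2.0 * (j // 2) + 2.0)
        for j in range(n_sample)
    ]
    return OtuTable(counts=counts, lineages=pd.Series(dtype=object), samples=samples)
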