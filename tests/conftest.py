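import numpy as np
import pandas as pd
import pytest

from ampnet import generate_community
from ampnet.io_tables import FeatureTable, SampleMetadata, TaxonomyTable


@pytest.fixture(scope="session")
def community():
    """One deterministic synthetic community shared across tests."""
    return generate_community(seed=7)


@pytest.fixture
def tiny_table():
    counts = pd.DataFrame(
        [[5, 0, 3, 2], [1, 4, 0, 5], [2, 2, 2, 2]],
        index=["s1", "s2", "s3"],
        columns=["SV_1", "SV_2", "SV_3", "SV_4"],
    )
    return FeatureTable(counts, marker="18S")


def make_tiny_taxonomy():
    df = pd.DataFrame(
        {
            "domain": ["Eukaryota"] * 4,
            "phylum": ["Ascomycota", "Ascomycota", "Cercozoa", "NA"],
            "class": ["c1", "c1", "c2", "NA"],
            "order": ["o1", "o1", "o2", "NA"],
            "family": ["f1", "f2", "f3", "NA"],
            "genus": ["g1", "g2", "g3", "NA"],
        },
        index=pd.Index(["SV_1", "SV_2", "SV_3", "SV_4"], name="sv_id"),
    )
    return TaxonomyTable(df)


@pytest.fixture
def tiny_taxonomy():
    return make_tiny_taxonomy()


@pytest.fixture
def design_metadata():
    rows = []
    i = 0
    for field in ("field_1", "field_2"):
        for crop in ("maize", "cabbage"):
            for stage in ("early", "middle", "late"):
                for rep in (1, 2, 3):
                    i += 1
                    rows.append((f"s{i:02d}", field, crop, stage, rep))
    df = pd.DataFrame(
        rows, columns=["sample_id", "field", "crop", "stage", "replicate"]
    ).set_index("sample_id")
    return SampleMetadata(df)


def union_find_components(nodes, edges):
    """Independent union-find oracle for connected components."""
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    comps = {}
    for n in nodes:
        comps.setdefault(find(n), set()).add(n)
    return sorted((frozenset(c) for c in comps.values()), key=lambda c: (-len(c), min(c)))
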