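import numpy as np
import pandas as pd
import pytest

from cohortnet import (OtuTable, RANKS, make_taxonomy, make_truth_network,
                       simulate_timeseries)


def toy_table(counts, sample_ids=None, otu_ids=None, phases=None):
    """Build an OtuTable from a plain count array with placeholder taxonomy."""
    counts = np.asarray(counts, dtype=np.int64)
    n, d = counts.shape
    sample_ids = sample_ids or [f"s{i}" for i in range(n)]
    otu_ids = otu_ids or [f"o{j}" for j in range(d)]
    tax = pd.DataFrame(
        {r: [f"{r[:1]}x" for _ in otu_ids] for r in RANKS}, index=otu_ids)
    tax["species"] = [f"{o}_sp" for o in otu_ids]
    meta = pd.DataFrame({"date": pd.Timestamp("2010-01-01"),
                         "phase": phases or "winter",
                         "dataset": "TS"}, index=sample_ids)
    return OtuTable(pd.DataFrame(counts, index=sample_ids, columns=otu_ids),
                    tax, meta)


@pytest.fixture(scope="session")
def small_taxa():
    return make_taxonomy(20, 3, seed=11)


@pytest.fixture(scope="session")
def small_truth(small_taxa):
    return make_truth_network(small_taxa, 8, frac_negative=0.25, strength=0.9,
                              seed=12)


@pytest.fixture(scope="session")
def small_table(small_taxa, small_truth):
    return simulate_timeseries(small_taxa, small_truth, 80, depth=1500, seed=13)
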