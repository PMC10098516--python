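import numpy as np
import pandas as pd
import pytest

from mycoforage import community, synthdata
from mycoforage.cli import make_fixtures


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """Small known-truth fixture set (FASTQ, tags, reference, counts)."""
    d = tmp_path_factory.mktemp("fixtures")
    truth = make_fixtures(seed=1, outdir=d)
    return d, truth


@pytest.fixture(scope="session")
def small_design():
    return synthdata.generate_design(
        n_sites=2, cafeterias_per_site=2, loss_probability=0.0, seed=0
    )


@pytest.fixture()
def toy_table():
    """Hand-sized rel_emf genus table: 1 cafeteria, 6 bags + root, 2 genera."""
    subs = [s.substrate_id for s in synthdata.default_substrates()]
    sample_ids = [f"S01C1_{s}" for s in subs] + ["S01C1_root"]
    meta = pd.DataFrame(
        {
            "site": "S01",
            "cafeteria": "S01C1",
            "sample_type": subs + ["root"],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    data = pd.DataFrame(
        {"GenA": [0.2] * 6 + [0.05], "GenB": [0.8] * 6 + [0.95]},
        index=meta.index,
    )
    return community.AbundanceTable(data, meta, mode="rel_emf")


def make_rel_emf(values_by_sample, site="S01", cafeteria="S01C1"):
    """Build a rel_emf AbundanceTable from {sample_type: {genus: value}}."""
    ids, meta_rows, data_rows = [], [], []
    genera = sorted({g for v in values_by_sample.values() for g in v})
    for stype, vals in values_by_sample.items():
        ids.append(f"{cafeteria}_{stype}")
        meta_rows.append({"site": site, "cafeteria": cafeteria, "sample_type": stype})
        data_rows.append([vals.get(g, 0.0) for g in genera])
    idx = pd.Index(ids, name="sample_id")
    return community.AbundanceTable(
        pd.DataFrame(data_rows, index=idx, columns=genera),
        pd.DataFrame(meta_rows, index=idx),
        mode="rel_emf",
    )
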