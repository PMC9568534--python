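import numpy as np
import pandas as pd
import pytest

import hlcbench as hb


def make_counts(values, genes=None, samples=None) -> hb.CountMatrix:
    arr = np.asarray(values)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return hb.CountMatrix(pd.DataFrame(arr, index=genes, columns=samples))


def make_normalized(values, genes=None, samples=None) -> hb.NormalizedMatrix:
    arr = np.asarray(values, float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return hb.NormalizedMatrix(
        pd.DataFrame(arr, index=genes, columns=samples), ["test fixture"]
    )


def make_metadata(sources: dict[str, str], studies: dict[str, str] | None = None):
    """Metadata from sample_id -> cell_source; PHH/Liver samples are controls."""
    rows = []
    for sid, src in sources.items():
        rows.append(
            {
                "sample_id": sid,
                "study": (studies or {}).get(sid, "study1"),
                "cell_source": src,
                "role": "control" if src == "PHH/Liver" else "query",
            }
        )
    return hb.SampleMetadata(pd.DataFrame(rows).set_index("sample_id"))


@pytest.fixture(scope="session")
def default_sim():
    """One multi-study simulation at generator defaults (seed 0)."""
    config = hb.SimulationConfig(seed=0)
    counts, metadata, truth = hb.simulate_multistudy_counts(config)
    return config, counts, metadata, truth


@pytest.fixture(scope="session")
def normalized_sim(default_sim):
    """The default simulation pushed through the full normalization."""
    _, counts, metadata, truth = default_sim
    normalized, reference = hb.normalize_counts(counts)
    return normalized, reference, metadata, truth
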