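import numpy as np
import pandas as pd
import pytest

from repsel import (
    Dataset,
    SimulationConfig,
    impute_total_sperm,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def structured_config():
    """A config with real among-focal heterogeneity in every component."""
    return SimulationConfig(
        seed=101,
        sigma_ms=0.3,
        sigma_ste=0.8,
        sigma_sfe=0.5,
        tau_ms=0.1,
        tau_ste=0.2,
        tau_sfe=0.2,
        egg_prob=0.4,
        sigma_batch_f=0.2,
    )


@pytest.fixture(scope="session")
def structured_dataset(structured_config):
    ds, truth = simulate_dataset(structured_config)
    return ds, truth


@pytest.fixture(scope="session")
def imputed_dataset(structured_dataset):
    ds, _ = structured_dataset
    out, _ = impute_total_sperm(ds)
    return out


def make_two_focal_dataset():
    """Hand-built minimal dataset: 2 focals x 3 groups x 4 recipients."""
    groups = []
    recipients = []
    for f, rid in enumerate(["W1", "W2"]):
        for g, label in enumerate(["B", "C", "D"]):
            groups.append(
                {
                    "replicate_id": rid,
                    "batch": f + 1,
                    "group_label": label,
                    "total_matings": 10 + f + g,
                    "focal_matings": 4 + f,
                }
            )
            for k in range(1, 5):
                recipients.append(
                    {
                        "replicate_id": rid,
                        "group_label": label,
                        "recipient_index": k,
                        "total_sperm": 5 + k,
                        "focal_sperm": 2,
                        "egg_in_antrum": False,
                        "total_offspring": 3,
                        "focal_offspring": 1,
                    }
                )
    penetrance = pd.DataFrame(
        {
            "replicate_id": ["W1", "W2"],
            "offspring_screened": [48, 50],
            "gfp_positive": [48, 50],
        }
    )
    rec = pd.DataFrame(recipients)
    rec["total_sperm"] = rec["total_sperm"].astype(float)
    return Dataset(pd.DataFrame(groups), rec, penetrance)


@pytest.fixture
def two_focal_dataset():
    return make_two_focal_dataset()


def make_aggregates(rows):
    """Aggregates table from (m_t, m_f, s_t, s_f, o_t, o_f) tuples."""
    recs = []
    for i, (m_t, m_f, s_t, s_f, o_t, o_f) in enumerate(rows):
        recs.append(
            {
                "replicate_id": f"A{i}",
                "batch": 1,
                "m_t": m_t,
                "m_f": m_f,
                "s_t": s_t,
                "s_f": s_f,
                "o_t": o_t,
                "o_f": o_f,
            }
        )
    return pd.DataFrame(recs)
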