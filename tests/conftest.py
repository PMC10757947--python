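import numpy as np
import pandas as pd
import pytest

import lipidremodel as lr


@pytest.fixture(scope="session")
def default_sim():
    """One default synthetic lipidome (seed 1), shared across tests."""
    return lr.generate_lipidome(seed=1)


@pytest.fixture(scope="session")
def filtered_sim(default_sim):
    table, truth = default_sim
    filtered, report = lr.apply_qc_filters(table)
    return filtered, truth, report


def make_balanced_table(amounts_by_treatment, n_genotypes=2, n_blocks=3,
                        noise_sd=0.0, seed=0, qc=True):
    """Small balanced table where every sample of a treatment carries the
    stated analyte amounts (plus optional lognormal noise); handy for
    hand-computed oracles."""
    rng = np.random.default_rng(seed)
    analytes = list(next(iter(amounts_by_treatment.values())))
    rows, meta = [], []
    for gi in range(n_genotypes):
        for t, amts in amounts_by_treatment.items():
            for b in range(1, n_blocks + 1):
                sid = f"G{gi + 1}_{t}_B{b}"
                meta.append((sid, f"G{gi + 1}", t, 1, b, False))
                vals = np.array([amts[a] for a in analytes], dtype=float)
                if noise_sd:
                    vals = vals * np.exp(rng.normal(0, noise_sd, len(vals)))
                rows.append(vals)
    if qc:
        for i in range(3):
            meta.append((f"QC{i + 1}", "", "", 0, 0, True))
            rows.append(np.array([1.0] * len(analytes)))
    samples = pd.DataFrame(
        meta, columns=["sample_id", "genotype", "treatment", "run", "block",
                       "is_qc_pool"]).set_index("sample_id")
    amounts = pd.DataFrame(rows, index=samples.index, columns=analytes)
    return lr.LipidomeTable(samples, amounts)


@pytest.fixture
def balanced_table_factory():
    return make_balanced_table
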