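import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from gcimp.io import BetaMatrix, ProbeAnnotationTable, SampleSheet
from gcimp.simulate import SimulationConfig, generate_cohort

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

DEFAULT_SEED = 20190213 % (2**31)


def fast_config(seed: int, **overrides) -> SimulationConfig:
    """Default study conditions with a reduced gene panel (the β-side
    analyses do not depend on the gene count)."""
    kwargs = dict(rng_seed=seed, n_genes=100)
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition cohort, shared read-only across tests."""
    return generate_cohort(SimulationConfig(rng_seed=DEFAULT_SEED))


@pytest.fixture()
def toy_beta():
    """4 reference + 4 comparison samples, 5 probes, hand-enumerable."""
    samples = ["r1", "r2", "r3", "r4", "c1", "c2", "c3", "c4"]
    values = pd.DataFrame(
        [
            [0.80, 0.82, 0.78, 0.81, 0.40, 0.45, 0.38, 0.43],  # big drop
            [0.70, 0.72, 0.68, 0.71, 0.30, 0.32, 0.28, 0.31],  # big drop
            [0.50, 0.52, 0.48, 0.51, 0.40, 0.42, 0.38, 0.41],  # small drop
            [0.50, 0.52, 0.48, 0.51, 0.45, 0.47, 0.43, 0.46],  # tiny drop
            [0.60, 0.62, 0.58, 0.61, 0.60, 0.62, 0.58, 0.61],  # no change
        ],
        index=[f"cg{i}" for i in range(5)],
        columns=samples,
    )
    return BetaMatrix(values)


@pytest.fixture()
def toy_sheet():
    return SampleSheet(
        pd.DataFrame(
            {"group_label": ["ref"] * 4 + ["cmp"] * 4},
            index=pd.Index(["r1", "r2", "r3", "r4", "c1", "c2", "c3", "c4"],
                           name="sample_id"),
        )
    )


@pytest.fixture()
def toy_annotation():
    rows = {
        "cg0": ("chr1", 100, "OpenSea", "TSS200:GENE1", False, False),
        "cg1": ("chr1", 500, "OpenSea", "TSS1500:GENE1;1stExon:GENE2", False, False),
        "cg2": ("chr1", 900, "Shore", "5'UTR:GENE2", False, False),
        "cg3": ("chr1", 1500, "Island", "", False, False),
        "cg4": ("chrX", 2000, "Island", "TSS200:GENE3", True, True),
    }
    df = pd.DataFrame.from_dict(
        rows,
        orient="index",
        columns=["chromosome", "position", "cpg_context", "promoter_features",
                 "snp_within_5bp", "sex_chromosome"],
    )
    df.index.name = "probe_id"
    return ProbeAnnotationTable(df)
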