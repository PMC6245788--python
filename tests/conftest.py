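import numpy as np
import pandas as pd
import pytest

from twinvar.io import BetaMatrix, SampleSheet
from twinvar.simulate import SimulationConfig, generate_cell_reference, generate_cohort


def make_sheet(n_discordant=6, n_concordant=4, n_healthy=7) -> SampleSheet:
    rows = []
    spec = [
        ("D", n_discordant, ("affected", "healthy")),
        ("C", n_concordant, ("affected", "affected")),
        ("H", n_healthy, ("healthy", "healthy")),
    ]
    for prefix, n_pairs, statuses in spec:
        for k in range(1, n_pairs + 1):
            for role, status in zip(("twin_a", "twin_b"), statuses):
                rows.append(
                    {
                        "sample_id": f"{prefix}{k}_{role[-1]}",
                        "pair_id": f"{prefix}{k}",
                        "role": role,
                        "status": status,
                    }
                )
    return SampleSheet(pd.DataFrame(rows))


def make_beta(values, probes=None, samples=None) -> BetaMatrix:
    arr = np.asarray(values, dtype=float)
    probes = probes or [f"cg{i:05d}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return BetaMatrix(pd.DataFrame(arr, index=probes, columns=samples))


@pytest.fixture
def study_sheet() -> SampleSheet:
    """Sample sheet at the study design: 6 discordant, 4 concordant, 7 healthy."""
    return make_sheet()


@pytest.fixture(scope="session")
def small_cohort():
    """A small complete cohort with embedded cell reference, shared by read-only tests."""
    reference = generate_cell_reference(K=6, n_reference_probes=60, seed=11)
    config = SimulationConfig(
        n_probes=1500,
        n_outlier_probes=10,
        noise_sd=0.01,
        pair_effect_sd=0.0,
        n_composition_probes=50,
        missing_rate=0.0005,
        seed=11,
    )
    return generate_cohort(config, reference=reference), reference
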