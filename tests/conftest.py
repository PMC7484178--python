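import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")

from scpersist.qc import CountMatrix  # noqa: E402


def toy_cells(n_patients: int = 3, cells_per_patient: int = 6, time_point: str = "TN") -> pd.DataFrame:
    rows = []
    for p in range(n_patients):
        for c in range(cells_per_patient):
            rows.append(
                {
                    "cell_id": f"P{p}_c{c}",
                    "patient": f"P{p}",
                    "sample": f"P{p}_{time_point}",
                    "time_point": time_point,
                    "cell_type": "epithelial",
                    "cluster": "tumor",
                    "is_reference_control": False,
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def cohort():
    """A small seeded cohort shared by read-only tests."""
    from scpersist.simulate import default_cohort_config, simulate_expression

    config = default_cohort_config(seed=7)
    matrix, ann, genes, truth = simulate_expression(config)
    return config, matrix, ann, genes, truth


@pytest.fixture
def tiny_matrix():
    """4 genes (one spike-in) x 3 cells with hand-countable values."""
    values = np.array(
        [
            [5, 0, 2],
            [0, 3, 2],
            [1, 0, 0],
            [9, 9, 9],  # spike-in row
        ]
    )
    return CountMatrix(
        values,
        gene_ids=np.array(["g1", "g2", "g3", "ERCC-1"], dtype=object),
        cell_ids=np.array(["c1", "c2", "c3"], dtype=object),
        spikein=np.array([False, False, False, True]),
    )
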