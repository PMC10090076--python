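import numpy as np
import pytest

from drcbridge import DoseResponseCurve, SimConfig, StudyDesign, simulate


@pytest.fixture
def printed_curve() -> DoseResponseCurve:
    """The reference five-dose monotherapy example (MK-5108 on ES2 cells)."""
    return DoseResponseCurve(
        drug_id="MK-5108",
        cell_line_id="ES2",
        study_id="DEMO",
        doses=(0.0, 0.075, 0.225, 0.675, 2.0),
        responses=(0.0, -0.48, -0.47, 4.32, 20.72),
    )


@pytest.fixture(scope="session")
def small_sim():
    """A small two-study world reused by tests that only need plumbing."""
    config = SimConfig(
        studies=(
            StudyDesign("A", n_doses=5, n_combinations=80),
            StudyDesign("B", n_doses=3, dose_min=0.03, dose_max=3.0,
                        n_combinations=80),
        ),
        n_drugs=10,
        n_cell_lines=6,
        seed=11,
    )
    return simulate(config)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
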