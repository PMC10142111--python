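import numpy as np
import pandas as pd
import pytest

from ckdmrm import AbundanceMatrix, CohortDesign, generate_cohort
from ckdmrm.synthetic_cohort import PlantedMarker


@pytest.fixture(scope="session")
def default_cohort():
    """One default 69 x 177 cohort with the three planted severity markers."""
    design = CohortDesign(seed=11)
    matrix, records, truth = generate_cohort(design)
    return design, matrix, records, truth


@pytest.fixture
def small_design():
    """A tiny two-group design for fast structural tests (no planted markers)."""
    return CohortDesign(
        group_sizes={"control": 5, "sFSGS": 5},
        n_proteins=20,
        planted_markers=(),
        seed=7,
    )


@pytest.fixture
def toy_matrix():
    """Hand-countable 6-sample, 4-protein matrix over two groups.

    Groups g1/g2 of 3 samples each; presence pattern (quantified cells):
      A: g1 3/3, g2 1/3   -> panel at 2/3, not core
      B: g1 3/3, g2 3/3   -> core
      C: g1 1/3, g2 1/3   -> out
      D: g1 2/3, g2 2/3   -> core exactly at threshold
    """
    nan = np.nan
    values = pd.DataFrame(
        {
            "A": [1.0, 2.0, 3.0, 4.0, nan, nan],
            "B": [1.0, 1.0, 1.0, 2.0, 2.0, 2.0],
            "C": [nan, nan, 5.0, nan, nan, 6.0],
            "D": [1.0, 2.0, nan, 3.0, nan, 4.0],
        },
        index=[f"s{i}" for i in range(1, 7)],
    )
    groups = pd.Series(
        ["g1", "g1", "g1", "g2", "g2", "g2"], index=values.index
    )
    return AbundanceMatrix(values=values, scale_tag="ln1p", groups=groups)


@pytest.fixture
def severe_marker():
    return PlantedMarker(5, {"sFSGS": 2.0, "MN": 2.0})
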