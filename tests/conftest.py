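import numpy as np
import pytest

from cyclibind.chem import SolutionSpec, study_solution
from cyclibind.kinetics import PHTimeSeries


@pytest.fixture
def solution() -> SolutionSpec:
    return study_solution()


@pytest.fixture
def piecewise_series(solution) -> PHTimeSeries:
    """Noiseless two-regime trajectory on the study grid (knee at 30 min)."""
    t = np.array([1.0, 5.0, 10.0, 30.0, 60.0, 120.0, 300.0, 1440.0])
    ph = np.where(t <= 30, 7.14 - 0.030 * t,
                  7.14 - 0.030 * 30 - 5.7e-5 * (t - 30))
    return PHTimeSeries(times=t, pH=ph, solution=solution, label="synthetic")
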