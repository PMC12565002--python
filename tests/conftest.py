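import numpy as np
import pandas as pd
import pytest

from albisoil import TreatmentDesign, paper_profile
from albisoil.soil_tables import IndicatorTable

# the ten indicators designated for soil quality assessment (the TDS)
TDS = ["pH", "TP", "TN", "TK", "AP", "AK", "S-β-GC", "S-UE", "S-CL", "S-Lip"]


@pytest.fixture(scope="session")
def design():
    return TreatmentDesign()


@pytest.fixture(scope="session")
def profile():
    return paper_profile()


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_indicator_table(values, design=None, directions=None, n_groups=4):
    """Wrap a raw samples x indicators array in an IndicatorTable.

    Samples are assigned to treatments in blocks (round-robin over the
    design's labels) purely to satisfy the design metadata.
    """
    values = np.asarray(values, dtype=float)
    design = design or TreatmentDesign()
    n = len(values)
    k = max(1, min(len(design.treatments), n // 2))
    labels = [design.treatments[i % k] for i in range(n)]
    data = pd.DataFrame(
        values,
        index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"),
        columns=[f"ind{j}" for j in range(values.shape[1])],
    )
    return IndicatorTable(data, pd.Series(labels, index=data.index), design, directions)
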