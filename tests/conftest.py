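import numpy as np
import pandas as pd
import pytest

from iphdnet import AnalyteMatrix


def make_matrix(values, analyte_ids=None, sample_meta_rows=None, analyte_type="histone_mark"):
    """Small AnalyteMatrix builder for fixtures."""
    values = np.asarray(values, dtype=float)
    n, s = values.shape
    analyte_ids = analyte_ids or [f"a{i}" for i in range(n)]
    analyte_meta = pd.DataFrame(
        {"analyte_type": analyte_type, "parent_gene": [f"G{i}" for i in range(n)]},
        index=pd.Index(analyte_ids, name="id"),
    )
    if sample_meta_rows is None:
        sample_meta_rows = [
            {
                "sample_id": f"s{j}",
                "cell_line": "MCF7",
                "perturbagen": f"drug{j}",
                "dose": "10uM",
                "timepoint_h": 24.0,
                "replicate": 1,
                "is_control": False,
            }
            for j in range(s)
        ]
    sample_meta = pd.DataFrame(sample_meta_rows).set_index("sample_id")
    return AnalyteMatrix(values, analyte_meta, sample_meta)


def sample_row(sample_id, perturbagen, timepoint_h=24.0, replicate=1, is_control=False,
               cell_line="MCF7", dose="10uM"):
    return {
        "sample_id": sample_id,
        "cell_line": cell_line,
        "perturbagen": perturbagen,
        "dose": "0" if is_control else dose,
        "timepoint_h": timepoint_h,
        "replicate": replicate,
        "is_control": is_control,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
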