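import numpy as np
import pandas as pd
import pytest

from stiffscape.transcriptome import ProbeMatrix


def make_matrix(rows, design):
    """Build a ProbeMatrix from {(probe, gene): [values...]} and
    {sample: condition}; values are ordered as the design's samples."""
    samples = list(design)
    index = pd.MultiIndex.from_tuples(list(rows),
                                      names=["probe_set_id", "gene_id"])
    values = pd.DataFrame(np.array(list(rows.values()), dtype=float),
                          index=index, columns=samples)
    return ProbeMatrix(values, design)


@pytest.fixture
def two_cond_design():
    return {"s1": "stiff", "s2": "stiff", "s3": "soft", "s4": "soft"}
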