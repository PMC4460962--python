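import numpy as np
import pandas as pd
import pytest

from modrep.io import ExpressionCohort

# Twelve rows of a DTP "Standard Agent" screen table for NSC 740
# (methotrexate) across twelve cell lines, used as a parsing/aggregation
# fixture in the exact published column layout.
STANDARD_AGENT_ROWS = """\
NSC\tLCONC\tPANEL\tCELL\tNLOGGI50\tCompound\tCAS
740\t-5\tRenal\t786-0\t7.644\tmethotrexate\t1959-5-2
740\t-5\tRenal\tA498\t5\tmethotrexate\t1959-5-2
740\t-8.6\tNon-Small Cell Lung\tA549-ATCC\t8.602\tmethotrexate\t1959-5-2
740\t-3.6\tRenal\tACHN\t7.308\tmethotrexate\t1959-5-2
740\t-3.6\tBreast\tBT-549\t4.651\tmethotrexate\t1959-5-2
740\t-3.6\tRenal\tCAKI-1\t7.124\tmethotrexate\t1959-5-2
740\t-3.6\tLeukemia\tCCRF-CEM\t7.508\tmethotrexate\t1959-5-2
740\t-8.6\tColon\tCOLO 205\t8.602\tmethotrexate\t1959-5-2
740\t-5\tProstate\tDU-145\t7.238\tmethotrexate\t1959-5-2
740\t-8.6\tNon-Small Cell Lung\tEKVX\t8.602\tmethotrexate\t1959-5-2
740\t-5\tColon\tHCC-2998\t7.025\tmethotrexate\t1959-5-2
740\t-8.6\tColon\tHCT-116\t8.89\tmethotrexate\t1959-5-2
"""

STANDARD_AGENT_NLOGGI50 = [
    7.644, 5.0, 8.602, 7.308, 4.651, 7.124, 7.508, 8.602, 7.238, 8.602, 7.025, 8.89,
]


@pytest.fixture
def drug_table_path(tmp_path):
    path = tmp_path / "screen.tsv"
    path.write_text(STANDARD_AGENT_ROWS)
    return path


@pytest.fixture
def tiny_cohort():
    """3 genes x 4 samples, 2 good + 2 bad."""
    values = pd.DataFrame(
        [[5.0, 1.0, 2.0, 0.5], [1.0, 4.0, 1.5, 3.0], [3.0, 2.0, 0.1, 2.5]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    outcome = pd.Series(["good", "good", "bad", "bad"],
                        index=["s1", "s2", "s3", "s4"])
    return ExpressionCohort(cohort_id="tiny", values=values, outcome=outcome)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
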