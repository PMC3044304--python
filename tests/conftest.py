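import numpy as np
import pytest

from pcpselect.aaindex import PropertyRecord, PropertyTable
from pcpselect.pipeline import encode_dataset
from pcpselect.synthetic import SynthSpec, gen_property_table, gen_sequences

# one AAindex1 record, hand-written: values 1..20 in file order A R N D C Q E G H I L K M F P S T W Y V
AAINDEX_ONE_RECORD = """\
H TEST000101
D A hand-written test index (values 1..20 in file residue order)
R PMID:0000000
A Test, A.
T A test entry
J Test Journal 1 (2020)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     1.0     2.0     3.0     4.0     5.0     6.0     7.0     8.0     9.0    10.0
    11.0    12.0    13.0    14.0    15.0    16.0    17.0    18.0    19.0    20.0
//
"""

AAINDEX_NA_RECORD = """\
H TEST000201
D An incomplete index (two NA values)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     1.0      NA     3.0     4.0     5.0     6.0     7.0     8.0     9.0    10.0
    11.0    12.0    13.0      NA    15.0    16.0    17.0    18.0    19.0    20.0
//
"""


@pytest.fixture
def one_record_text():
    return AAINDEX_ONE_RECORD


@pytest.fixture
def na_record_text():
    return AAINDEX_NA_RECORD


def random_table(n: int, seed: int, groups=None) -> PropertyTable:
    """A table of n random complete property records."""
    rng = np.random.default_rng(seed)
    recs = []
    for i in range(n):
        g = groups[i % len(groups)] if groups else "unassigned"
        recs.append(
            PropertyRecord(
                accession=f"RND{i:04d}", values=rng.standard_normal(20), group=g
            )
        )
    return PropertyTable(recs)


@pytest.fixture(scope="session")
def planted_dataset():
    """The default synthetic study conditions: 60 properties (5 informative,
    effect 1.2), 100+100 sequences, encoded and scaled."""
    spec = SynthSpec()
    table, cluster_labels = gen_property_table(spec)
    seqs, truth = gen_sequences(spec, table)
    mat = encode_dataset(seqs, table)
    return spec, table, cluster_labels, seqs, truth, mat
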