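import numpy as np
import pandas as pd
import pytest

from tilscope.simulate import fixture_suite
from tilscope.tenx_io import VDJ_COLUMNS, VdjTable


@pytest.fixture(scope="session")
def fixtures():
    """The deterministic catalog of named synthetic datasets."""
    return fixture_suite()


def make_vdj(rows):
    """Build a VdjTable from (barcode, chain, cdr3_aa, productive) tuples."""
    records = []
    for i, (barcode, chain, cdr3, productive) in enumerate(rows):
        records.append(
            {
                "barcode": barcode,
                "is_cell": True,
                "high_confidence": True,
                "chain": chain,
                "v_gene": "",
                "d_gene": "",
                "j_gene": "",
                "cdr3_aa": cdr3,
                "cdr3_nt": "",
                "reads": 10,
                "umis": 1,
                "productive": productive,
                "raw_clonotype_id": f"clonotype{i}",
            }
        )
    return VdjTable(pd.DataFrame(records, columns=VDJ_COLUMNS))


def repertoire_vdj(assignment):
    """VdjTable where cell i carries one productive TRB whose CDR3 encodes
    clonotype ``assignment[i]``."""
    rows = [
        (f"CELL{i:04d}-1", "TRB", f"CASS{chr(65 + c % 26)}{c:04d}", True)
        for i, c in enumerate(assignment)
    ]
    return make_vdj(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
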