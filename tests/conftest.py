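import numpy as np
import pytest

from bpfray.io_formats import TimeSeriesTable
from bpfray.reference_data import reference_table
from bpfray.state_classifier import CLOSED, OPEN, TRANSITION, UNASSIGNED


@pytest.fixture(scope="session")
def reference_df():
    """Published per-temperature lifetime/occupancy statistics."""
    return reference_table()


def make_series(rmsd, zeta, step=0.002):
    """Uniform-step TimeSeriesTable from observable lists."""
    n = len(rmsd)
    return TimeSeriesTable.from_arrays(step * np.arange(n), rmsd, zeta, wrap=False)


def series_from_labels(code_string, step=0.002):
    """Build a table whose frames classify as the given label codes.

    ``code_string`` uses C (closed), O (open), T (transition), U (unassigned).
    """
    emit = {
        "C": (0.7, -75.0),
        "O": (5.0, 50.0),
        "T": (3.0, -75.0),
        "U": (0.5, 150.0),
    }
    rmsd, zeta = zip(*(emit[c] for c in code_string))
    return make_series(list(rmsd), list(zeta), step=step)


CODES = {"C": CLOSED, "O": OPEN, "T": TRANSITION, "U": UNASSIGNED}


def codes(label_string):
    return np.array([CODES[c] for c in label_string], dtype=np.int8)
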