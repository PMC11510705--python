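"""Published lifetime/occupancy statistics for the terminal dA-rU pair.

Mean lifetimes (ns), occurrence counts and occupancies of the closed,
open, and transition (ctc/oto) states of the terminal dA-rU base pair of
a DNA-RNA hybrid duplex, from 4000 ns of sampling at each of four
temperatures.  These printed statistics are the reference input for the
thermodynamic and kinetic extractions and for validating the pipeline's
own bookkeeping.
"""
from __future__ import annotations

from typing import Dict, List

import pandas as pd

#: Total sampling time per temperature, ns.
TOTAL_TIME_NS: float = 4000.0

#: Columns: temperature (K); per-state mean lifetime tau (ns), count n,
#: occupancy p for closed (cl), open (op) and the two failed-excursion
#: transition types (ctc, oto).
LIFETIME_TABLE: List[Dict[str, float]] = [
    {"T": 370.0, "tau_cl": 27.41, "n_cl": 78, "p_cl": 0.53,
     "tau_op": 24.18, "n_op": 77, "p_op": 0.47,
     "tau_ctc": 0.23, "n_ctc": 435, "p_ctc": 0.025,
     "tau_oto": 0.205, "n_oto": 663, "p_oto": 0.034},
    {"T": 380.0, "tau_cl": 21.21, "n_cl": 89, "p_cl": 0.47,
     "tau_op": 23.74, "n_op": 89, "p_op": 0.53,
     "tau_ctc": 0.225, "n_ctc": 441, "p_ctc": 0.025,
     "tau_oto": 0.201, "n_oto": 736, "p_oto": 0.037},
    {"T": 390.0, "tau_cl": 16.16, "n_cl": 102, "p_cl": 0.41,
     "tau_op": 23.06, "n_op": 102, "p_op": 0.59,
     "tau_ctc": 0.216, "n_ctc": 447, "p_ctc": 0.024,
     "tau_oto": 0.195, "n_oto": 762, "p_oto": 0.037},
    {"T": 400.0, "tau_cl": 12.95, "n_cl": 114, "p_cl": 0.37,
     "tau_op": 22.14, "n_op": 114, "p_op": 0.63,
     "tau_ctc": 0.211, "n_ctc": 462, "p_ctc": 0.023,
     "tau_oto": 0.188, "n_oto": 821, "p_oto": 0.039},
]


def reference_table() -> pd.DataFrame:
    """The reference statistics as a DataFrame indexed by temperature."""
    return pd.DataFrame(LIFETIME_TABLE).set_index("T", drop=False)
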