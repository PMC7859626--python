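"""Shared builders for hand-constructed fixtures."""

import numpy as np
import pandas as pd

from preemiexpr.matrix import NormalizedMatrix
from preemiexpr.oxygen import OxygenTrace


def make_trace(fio2_by_day, mode="vent", flow=0.0, bw=900.0, subject="t1"):
    days = sorted(fio2_by_day)
    daily = pd.DataFrame({
        "day": days,
        "fio2": [fio2_by_day[d] for d in days],
        "support_mode": mode,
        "flow_lpm": flow,
        "pressure_cmH2O": 0.0,
    })
    return OxygenTrace(subject, daily, bw)


def make_norm(pre_log_values, subjects=None):
    """NormalizedMatrix from pre-log normalized values with unit factors."""
    values = np.asarray(pre_log_values, dtype=float)
    subjects = subjects or [f"s{j}" for j in range(values.shape[1])]
    df = pd.DataFrame(np.log2(values + 1.0),
                      index=[f"g{i}" for i in range(values.shape[0])],
                      columns=subjects)
    ones = pd.Series(1.0, index=subjects)
    return NormalizedMatrix(df, ones, ones)
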