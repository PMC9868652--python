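"""Small statistical helpers shared across analyses."""

from __future__ import annotations

import numpy as np
from scipy import stats as _st

__all__ = ["two_sample_ttest", "mean_ci"]


def two_sample_ttest(a, b, equal_var: bool = True) -> dict:
    """Two-sample t test; returns statistic, p value and group means."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    t, p = _st.ttest_ind(a, b, equal_var=equal_var)
    return {"t": float(t), "p": float(p),
            "mean_a": float(a.mean()), "mean_b": float(b.mean())}


def mean_ci(x, level: float = 0.95) -> tuple[float, float, float]:
    """Mean with a normal-theory confidence interval (mean, lo, hi)."""
    x = np.asarray(x, dtype=float)
    m = float(x.mean())
    if len(x) < 2:
        return m, m, m
    z = _st.norm.ppf(0.5 + level / 2.0)
    se = float(x.std(ddof=1) / np.sqrt(len(x)))
    return m, m - z * se, m + z * se
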