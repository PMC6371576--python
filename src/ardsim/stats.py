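"""Correlation statistics used by the calibration and sweep stages."""

from __future__ import annotations

import numpy as np
from scipy.stats import t as t_dist


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation and its two-sided t-distribution p-value.

    Returns ``(nan, nan)`` when either vector has zero variance (the caller
    reports the undefined result explicitly rather than masking it).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    if sxx == 0.0 or syy == 0.0:
        return float("nan"), float("nan")
    r = float(xc @ yc) / np.sqrt(sxx * syy)
    r = max(min(r, 1.0), -1.0)
    n = x.size
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(t_dist.sf(abs(t), n - 2))
    return r, min(p, 1.0)
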