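"""Batched Thomas solver for the ADI sweeps.

Solves many independent tridiagonal systems at once, one per grid row or
column.  Inputs are 2-D arrays where ``axis`` is the solve direction and the
other axis is the batch; the forward/backward sweeps are vectorized over the
batch so the Python loop length is only the solve dimension.
"""

from __future__ import annotations

import numpy as np


def solve_tridiag_batched(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray, axis: int = 0
) -> np.ndarray:
    """Solve a[i] x[i-1] + b[i] x[i] + c[i] x[i+1] = d[i] along ``axis``.

    ``a[0]`` and ``c[-1]`` (along the solve axis) are ignored.  All four
    arrays share one shape.  Diagonal dominance is assumed (no pivoting),
    which the ADI discretization guarantees (b = 1 - a - c with a, c <= 0).
    """
    if axis != 0:
        a, b, c, d = (np.moveaxis(x, axis, 0) for x in (a, b, c, d))
    n = a.shape[0]
    cp = np.empty_like(b)
    dp = np.empty_like(b)
    cp[0] = c[0] / b[0]
    dp[0] = d[0] / b[0]
    for i in range(1, n):
        denom = b[i] - a[i] * cp[i - 1]
        cp[i] = c[i] / denom
        dp[i] = (d[i] - a[i] * dp[i - 1]) / denom
    x = np.empty_like(b)
    x[n - 1] = dp[n - 1]
    for i in range(n - 2, -1, -1):
        x[i] = dp[i] - cp[i] * x[i + 1]
    if axis != 0:
        x = np.moveaxis(x, 0, axis)
    return x
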