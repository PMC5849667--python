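"""Independent brute-force oracles used by the test suite.

Everything here is written with explicit loops and the standard
library's `statistics` module, deliberately sharing no code with the
package implementation.
"""

from __future__ import annotations

import statistics
from math import sqrt

from scipy.stats import norm


def pb_enumerate(x, y, level: float = 0.95):
    """Exhaustive Passing-Bablok fit on small instances.

    Returns a dict with slope, intercept, sorted slopes, offset K and,
    when the order-statistic indices are feasible, the 1-based CI
    indices and the corresponding slope/intercept bounds; infeasible
    indices yield ``ci_feasible = False``.
    """
    n = len(x)
    slopes = []
    for i in range(n):
        for j in range(i + 1, n):
            if x[j] == x[i]:
                continue
            s = (y[j] - y[i]) / (x[j] - x[i])
            if s == -1.0:
                continue
            slopes.append(s)
    if not slopes:
        raise ZeroDivisionError("no defined pairwise slopes")
    slopes.sort()
    big_n = len(slopes)
    k = sum(1 for s in slopes if s < -1.0)

    if big_n % 2 == 1:
        b = slopes[(big_n + 1) // 2 + k - 1]
    else:
        b = 0.5 * (slopes[big_n // 2 + k - 1] + slopes[big_n // 2 + k])
    a = statistics.median([y[i] - b * x[i] for i in range(n)])

    z = norm.ppf(0.5 + level / 2.0)
    c = z * sqrt(n * (n - 1) * (2 * n + 5) / 18.0)
    m1 = round((big_n - c) / 2.0)
    m2 = big_n - m1 + 1
    lo_idx, hi_idx = m1 + k, m2 + k
    out = {
        "slope": b,
        "intercept": a,
        "slopes": slopes,
        "k": k,
        "ci_feasible": 1 <= lo_idx <= big_n and 1 <= hi_idx <= big_n,
    }
    if out["ci_feasible"]:
        b_lo, b_hi = slopes[lo_idx - 1], slopes[hi_idx - 1]
        out.update(
            ci_indices=(lo_idx, hi_idx),
            slope_ci=(b_lo, b_hi),
            intercept_ci=(
                statistics.median([y[i] - b_hi * x[i] for i in range(n)]),
                statistics.median([y[i] - b_lo * x[i] for i in range(n)]),
            ),
        )
    return out
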