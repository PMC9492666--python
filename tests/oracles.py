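"""Independent brute-force oracles used only by tests.

These deliberately avoid the code paths they check: the Loewe reference is
found by bisection on the additivity equation, and the median-effect fit is
re-derived by an iteratively refined grid search over (m, intercept) in the
transformed coordinates.
"""

from __future__ import annotations

import numpy as np


def me_fa(dose: float, Dm: float, m: float) -> float:
    """Median-effect fraction affected at one dose."""
    return 1.0 / (1.0 + (Dm / dose) ** m)


def me_dose(fa: float, Dm: float, m: float) -> float:
    """Median-effect dose producing fa."""
    return Dm * (fa / (1.0 - fa)) ** (1.0 / m)


def loewe_additive_fa(
    D_total: float,
    ratio: tuple[float, float],
    a: tuple[float, float],
    b: tuple[float, float],
    tol: float = 1e-12,
) -> float:
    """Effect of a Loewe-additive mixture at total dose D, by bisection.

    Solves r1*D/Dx_a(fa) + r2*D/Dx_b(fa) = 1 for fa; the left side is
    strictly decreasing in fa, so bisection on (0, 1) converges.
    """
    r1, r2 = ratio
    (dm_a, m_a), (dm_b, m_b) = a, b

    def excess(fa: float) -> float:
        return (
            r1 * D_total / me_dose(fa, dm_a, m_a)
            + r2 * D_total / me_dose(fa, dm_b, m_b)
            - 1.0
        )

    lo, hi = 1e-12, 1.0 - 1e-12
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if excess(mid) > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


def transformed_sse(doses, fa, slope: float, intercept: float) -> float:
    """SSE of the median-effect plot line y = slope*x + intercept."""
    x = np.log10(np.asarray(doses, dtype=float))
    y = np.log10(np.asarray(fa) / (1.0 - np.asarray(fa)))
    return float(np.sum((y - (slope * x + intercept)) ** 2))


def grid_fit_median_effect(doses, fa, rounds: int = 6):
    """Brute-force least squares on the median-effect plot.

    Iteratively refined grid over (slope, intercept); returns
    (Dm, m, sse).  Independent of any closed-form OLS solution.
    """
    s_lo, s_hi = 0.05, 8.0
    b_lo, b_hi = -6.0, 6.0
    best = (None, None, np.inf)
    for _ in range(rounds):
        slopes = np.linspace(s_lo, s_hi, 61)
        intercepts = np.linspace(b_lo, b_hi, 61)
        for s in slopes:
            for b in intercepts:
                sse = transformed_sse(doses, fa, s, b)
                if sse < best[2]:
                    best = (s, b, sse)
        s_step = slopes[1] - slopes[0]
        b_step = intercepts[1] - intercepts[0]
        s_lo, s_hi = best[0] - 2 * s_step, best[0] + 2 * s_step
        b_lo, b_hi = best[1] - 2 * b_step, best[1] + 2 * b_step
    slope, intercept, sse = best
    return 10.0 ** (-intercept / slope), slope, sse
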