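"""Independent brute-force oracles shared by the test modules.

These deliberately avoid the package's vectorised implementations: weights,
marginals and chance terms are rebuilt from the defining sums with explicit
Python loops.
"""

from math import comb, sqrt

import numpy as np


def naive_coefficient(m, measure, scheme):
    """Double-loop evaluation of a chance-corrected weighted coefficient."""
    m = np.asarray(m, dtype=float)
    q = m.shape[0]
    n = m.sum()
    p = m / n

    def w(i, j):
        d = abs(i - j)
        if scheme == "unweighted":
            return 1.0 if d == 0 else 0.0
        if scheme == "linear":
            return 1.0 - d / (q - 1)
        if scheme == "quadratic":
            return 1.0 - d**2 / (q - 1) ** 2
        if scheme == "radical":
            return 1.0 - sqrt(d) / sqrt(q - 1)
        return 1.0 - comb(d + 1, 2) / comb(q, 2)

    row = [sum(p[i][j] for j in range(q)) for i in range(q)]
    col = [sum(p[i][j] for i in range(q)) for j in range(q)]
    pi = [(row[i] + col[i]) / 2 for i in range(q)]
    pa = sum(w(i, j) * p[i][j] for i in range(q) for j in range(q))
    tw = sum(w(i, j) for i in range(q) for j in range(q))
    if measure == "cohen":
        pe = sum(w(i, j) * row[i] * col[j] for i in range(q) for j in range(q))
    elif measure in ("scott", "krippendorff"):
        pe = sum(w(i, j) * pi[i] * pi[j] for i in range(q) for j in range(q))
    elif measure == "gwet_ac2":
        pe = tw / (q * (q - 1)) * sum(x * (1 - x) for x in pi)
    else:  # brennan_prediger
        pe = tw / q**2
    if measure == "krippendorff":
        pa = pa * (1 - 1 / (2 * n)) + 1 / (2 * n)
    if pa >= 1.0:
        return 1.0
    return (pa - pe) / (1 - pe)


def bvn_rectangle_quadrature(x_lo, x_hi, y_lo, y_hi, rho):
    """Rectangle probability of the standard bivariate normal by quadrature."""
    from scipy import integrate

    def density(y, x):
        z = x * x - 2 * rho * x * y + y * y
        return np.exp(-z / (2 * (1 - rho**2))) / (2 * np.pi * np.sqrt(1 - rho**2))

    val, _ = integrate.dblquad(density, x_lo, x_hi, y_lo, y_hi)
    return val
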