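"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths and any shared
helper: kappa is recomputed from first principles with dictionary counting,
and the JZS Bayes factor with a fine-grid Simpson rule over a bounded
change of variable (u = g/(1+g)), a different integrator and transform
than the implementation's adaptive quadrature over log g.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import simpson


def brute_force_kappa(a, b) -> tuple[float, float, float]:
    """(p_o, p_e, kappa) by explicit contingency counting."""
    a = list(a)
    b = list(b)
    assert len(a) == len(b) and len(a) >= 2
    n = len(a)
    agree = sum(1 for x, y in zip(a, b) if x == y)
    p_o = agree / n
    labels = set(a) | set(b)
    p_e = 0.0
    for lab in labels:
        p_e += (a.count(lab) / n) * (b.count(lab) / n)
    if p_e >= 1.0:
        return p_o, p_e, 1.0 if p_o >= 1.0 else 0.0
    return p_o, p_e, (p_o - p_e) / (1.0 - p_e)


def jzs_quadrature_oracle(
    t: float,
    n1: int,
    n2: "int | None" = None,
    r: float = np.sqrt(2) / 2,
    n_grid: int = 2_000_001,
) -> float:
    """BF10 via fine-grid Simpson quadrature of the JZS g-integral."""
    if n2 is None:
        df, n_eff = n1 - 1, float(n1)
    else:
        df, n_eff = n1 + n2 - 2, n1 * n2 / (n1 + n2)
    u = np.linspace(1e-12, 1 - 1e-12, n_grid)
    g = u / (1 - u)
    jacobian = 1.0 / (1 - u) ** 2
    prior = r / np.sqrt(2 * np.pi) * g ** -1.5 * np.exp(-(r**2) / (2 * g))
    likelihood = (1 + n_eff * g) ** -0.5 * (
        1 + t**2 / ((1 + n_eff * g) * df)
    ) ** (-(df + 1) / 2)
    numerator = simpson(likelihood * prior * jacobian, x=u)
    denominator = (1 + t**2 / df) ** (-(df + 1) / 2)
    return float(numerator / denominator)
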