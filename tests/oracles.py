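"""Independent oracles used to cross-check the implementation.

These deliberately take different algorithmic routes from the package:
the quaternion (Horn) eigenvalue method for optimal superposition versus
the package's SVD Kabsch, and brute-force numerical minimization of the
surrogate quadratics versus the closed forms.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar


def horn_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Minimum least-squares RMSD via Horn's quaternion eigenvalue method."""
    x = mobile - mobile.mean(axis=0)
    y = reference - reference.mean(axis=0)
    n = x.shape[0]
    m = x.T @ y
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    key = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam_max = np.linalg.eigvalsh(key)[-1]
    g = (x ** 2).sum() + (y ** 2).sum()
    return float(np.sqrt(max(g - 2.0 * lam_max, 0.0) / n))


def brute_force_two_state_references(k_red: float, k_ox: float, d: float,
                                     eps: float) -> dict:
    """1-D surrogate references by numerical minimization of the quadratics."""

    def e_red(x):
        return 0.5 * k_red * x ** 2

    def e_ox(x):
        return 0.5 * k_ox * (x - d) ** 2 + eps

    min_red = minimize_scalar(e_red, bounds=(-10 * abs(d) - 10, 10 * abs(d) + 10),
                              method="bounded")
    min_ox = minimize_scalar(e_ox, bounds=(-10 * abs(d) - 10, 10 * abs(d) + 10),
                             method="bounded")
    return {
        "lambda_red": e_ox(min_red.x) - e_ox(min_ox.x),
        "lambda_ox": e_red(min_ox.x) - e_red(min_red.x),
        "strain_red_on_ox": e_ox(min_red.x) - min_ox.fun,
        "strain_ox_on_red": e_red(min_ox.x) - min_red.fun,
        "delta_g_minimum": min_ox.fun - min_red.fun,
    }
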