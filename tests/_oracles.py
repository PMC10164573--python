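"""Independent numerical oracles used by the test suite.

These deliberately avoid the code paths they check: the writhe oracle is a
dense rectangle-rule evaluation of the Gauss double integral with Richardson
extrapolation (the library uses the segment-pair closed form), and the
ellipse curvature extrema are textbook closed forms.
"""

import numpy as np


def gauss_writhe(curve, n: int) -> float:
    """Writhe by direct double quadrature of the Gauss integral."""
    t = np.linspace(0.0, curve.period, n, endpoint=False)
    r = curve.position(t)
    dr = curve.velocity(t) * (curve.period / n)
    diff = r[:, None, :] - r[None, :, :]
    d3 = np.linalg.norm(diff, axis=2) ** 3
    np.fill_diagonal(d3, np.inf)
    cr = np.cross(dr[:, None, :], dr[None, :, :])
    integrand = np.einsum("ijk,ijk->ij", cr, diff) / d3
    return float(integrand.sum() / (4.0 * np.pi))


def gauss_writhe_extrapolated(curve, n: int = 800) -> float:
    """Richardson-extrapolated Gauss-integral writhe (O(h^2) error removed)."""
    w1 = gauss_writhe(curve, n)
    w2 = gauss_writhe(curve, 2 * n)
    return (4.0 * w2 - w1) / 3.0


def ellipse_curvature_extrema(a: float, b: float) -> tuple[float, float]:
    """(κ_max, κ_min) of an ellipse with semi-axes a >= b."""
    return a / b**2, b / a**2
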