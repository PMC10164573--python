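"""Canonical test curves: circles, figure-8s, perturbed loops, straight rods.

These generators produce the geometric fixtures used throughout the test
suite and demos — they are first-class library code, not test scaffolding,
and are the recommended way to build reference inputs for the hydrodynamic
and topological operations.
"""

from __future__ import annotations

import numpy as np

from .curves import ClosedCurve, build_circle
from .exceptions import InvalidParameterError

__all__ = ["generate_fixture"]


def generate_fixture(kind: str, params: dict | None = None,
                     seed: int | None = None):
    """Build a named fixture curve.

    Parameters
    ----------
    kind : {"circle", "figure8", "perturbed_loop", "straight_rod"}
    params : dict, optional
        ``circle``: contour_length (Å, default 1142.4), n_nodes (64).
        ``figure8``: contour_length, n_nodes (32), apex_separation (fraction
        of the lobe size, default 0.2), sign (±1 writhe sign, default −1).
        ``perturbed_loop``: contour_length, n_nodes (32), amplitude
        (fraction of the loop radius, default 0.1), n_modes (4).
        ``straight_rod``: length (Å), n_points (64) — returns an (n, 3)
        open polyline, not a ClosedCurve.
    seed : int, optional
        Only used by ``perturbed_loop``.
    """
    p = dict(params or {})
    if kind == "circle":
        return build_circle(p.get("contour_length", 1142.4),
                            p.get("n_nodes", 64))
    if kind == "figure8":
        return _figure8(p.get("contour_length", 1142.4),
                        p.get("n_nodes", 32),
                        p.get("apex_separation", 0.2),
                        p.get("sign", -1.0))
    if kind == "perturbed_loop":
        return _perturbed_loop(p.get("contour_length", 1142.4),
                               p.get("n_nodes", 32),
                               p.get("amplitude", 0.1),
                               p.get("n_modes", 4),
                               seed)
    if kind == "straight_rod":
        length = p.get("length", 1142.4)
        n = p.get("n_points", 64)
        z = np.linspace(0.0, length, n)
        return np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
    raise InvalidParameterError(f"unknown fixture kind {kind!r}")


def _figure8(contour_length: float, n_nodes: int, apex_separation: float,
             sign: float) -> ClosedCurve:
    """Two tangent lobes with |Wr| → 1 as the apex separation → 0."""
    from ._kernels import polygon_writhe

    t = np.linspace(0.0, 2.0 * np.pi, n_nodes, endpoint=False)
    pts = np.column_stack([np.sin(t), apex_separation * np.cos(t),
                           0.5 * np.sin(2.0 * t)])
    if polygon_writhe(np.ascontiguousarray(pts)) * sign < 0:
        pts[:, 2] *= -1.0
    curve = ClosedCurve(pts)
    return ClosedCurve(pts * (contour_length / curve.arclength()))


def _perturbed_loop(contour_length: float, n_nodes: int, amplitude: float,
                    n_modes: int, seed: int | None) -> ClosedCurve:
    """Circle plus a smooth random Fourier perturbation of bounded amplitude.

    Amplitude 0 reproduces the circle exactly.  Modes m = 2..n_modes+1 with
    1/m weighting keep the loop smooth and self-avoiding for moderate
    amplitudes.
    """
    rng = np.random.default_rng(seed)
    radius = contour_length / (2.0 * np.pi)
    theta = np.linspace(0.0, 2.0 * np.pi, n_nodes, endpoint=False)
    dr = np.zeros(n_nodes)
    dz = np.zeros(n_nodes)
    for m in range(2, 2 + max(0, n_modes)):
        ar, pr = rng.normal(), rng.uniform(0.0, 2.0 * np.pi)
        az, pz = rng.normal(), rng.uniform(0.0, 2.0 * np.pi)
        dr += ar / m * np.cos(m * theta + pr)
        dz += az / m * np.cos(m * theta + pz)
    scale = amplitude * radius
    r = radius + scale * dr
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta), scale * dz])
    curve = ClosedCurve(pts)
    return ClosedCurve(pts * (contour_length / curve.arclength()))
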