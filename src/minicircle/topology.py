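"""Linking-number bookkeeping and writhe of closed centerlines.

The topology of closed-circular DNA is summarised by the Călugăreanu
decomposition ``Lk = Tw + Wr``: the integer linking number Lk partitions into
the winding of the duplex about its own axis (twist, Tw) and the coiling of
the axis in space (writhe, Wr).  Writhe is evaluated by approximating the
centerline with straight segments and summing the exact Gauss-integral
contribution of every segment pair (Levitt's formulation), which has no
diagonal singularity.

Sign convention: a right-handed crossing counts positive, so negatively
supercoiled loops (ΔLk < 0) relax into shapes with negative writhe.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import polygon_writhe
from .curves import ClosedCurve
from .exceptions import TopologyError

__all__ = ["TopologyState", "writhe", "twist_from_lk", "excess_twist_density"]


@dataclass
class TopologyState:
    """Topological bookkeeping for one minicircle species.

    ``Lk0 = length_bp / h`` is the relaxed reference; ``dLk = Lk - Lk0``
    keeps its fractional part (covalently closed DNA has integer Lk while
    Lk0 generally does not).
    """

    length_bp: int
    helical_repeat_h: float
    Lk: float
    Tw: float | None = None
    Wr: float | None = None
    covalently_closed: bool = True

    Lk0: float = field(init=False)
    dLk: float = field(init=False)
    sigma: float = field(init=False)

    def __post_init__(self):
        if self.length_bp <= 0 or self.helical_repeat_h <= 0:
            raise ValueError("length_bp and helical_repeat_h must be positive")
        if self.covalently_closed and abs(self.Lk - round(self.Lk)) > 1e-9:
            raise TopologyError(
                "covalently closed DNA must have integer Lk; "
                "set covalently_closed=False for nicked/linear species"
            )
        self.Lk0 = self.length_bp / self.helical_repeat_h
        self.dLk = self.Lk - self.Lk0
        self.sigma = self.dLk / self.Lk0

    @classmethod
    def from_dlk(cls, length_bp: int, dlk_nominal: int,
                 helical_repeat_h: float, covalently_closed: bool = True
                 ) -> "TopologyState":
        """Build from a nominal integer ΔLk label.

        ``Lk = round(Lk0) + dlk_nominal``; the effective ΔLk then carries the
        fractional offset of Lk0 automatically (e.g. −0.2 turns for 336 bp at
        h = 10.42 bp/turn).
        """
        lk0 = length_bp / helical_repeat_h
        lk = round(lk0) + dlk_nominal
        return cls(length_bp=length_bp, helical_repeat_h=helical_repeat_h,
                   Lk=lk, covalently_closed=covalently_closed)


def writhe(curve: ClosedCurve, n_segments: int = 200) -> float:
    """Writhe of a closed curve via the segment-pair Gauss sum.

    The curve is approximated by ``n_segments`` chords equally spaced in the
    spline parameter; each non-adjacent chord pair contributes its exact Gauss
    integral in closed form.
    """
    if not isinstance(curve, ClosedCurve):
        raise TopologyError("writhe is defined only for closed curves")
    pts = np.ascontiguousarray(curve.sample(n_segments))
    return float(polygon_writhe(pts))


def writhe_of_points(points: np.ndarray) -> float:
    """Writhe of an explicit closed polygon (vertices not repeated)."""
    pts = np.ascontiguousarray(np.asarray(points, dtype=float))
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise TopologyError("need an (n>=3, 3) closed polygon")
    return float(polygon_writhe(pts))


def twist_from_lk(topology: TopologyState, wr: float) -> float:
    """Tw = Lk − Wr (Călugăreanu); updates the state in place as well."""
    tw = topology.Lk - wr
    topology.Tw = tw
    topology.Wr = wr
    return tw


def excess_twist_density(topology: TopologyState, wr: float,
                         contour_length: float) -> float:
    """Uniform residual excess twist density Ω in rad/Å.

    At elastic equilibrium the twist energy is quadratic in Ω with no
    positional coupling, so the minimiser spreads the residual twist
    uniformly: Ω = 2π (Tw − Lk0)/L = 2π (ΔLk − Wr)/L.
    """
    if contour_length <= 0:
        raise ValueError("contour_length must be positive")
    return 2.0 * np.pi * (topology.dLk - wr) / contour_length
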