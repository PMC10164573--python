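"""Elastic equilibrium shapes of closed, torsionally constrained rods.

The minicircle is modelled as an inextensible Kirchhoff rod of contour length
L, bending rigidity A = k_BT·P and geometric torsional stiffness ω (2/3 for a
circular cross section), closed into a loop with a prescribed linking-number
deficit ΔLk.  Its elastic energy is

    E = (A/2) ∫ (κ² + ω Ω²) ds,        Ω = 2π (ΔLk − Wr) / L,

where the residual excess-twist density Ω is uniform at equilibrium (the
energy is quadratic in Ω with no positional coupling) and Wr is the writhe of
the centerline.  Shapes are periodic cubic splines through a small number of
nodes; the energy is minimised by simulated annealing over node positions
with quadratic penalties enforcing the prescribed length and a hard-core
steric diameter d_s, followed by a derivative-free quench.

Stability regimes as a function of |ΔLk| (at aspect ratio d_s/L):

* ``circle_only``  — below the empirical critical deficit
  Lk_crit = sqrt(1 + 23.1 d_s/L): only the flat circle is stable.
* ``multistable``  — between Lk_crit and Lk_max = √3/ω: the circle and a
  writhed (figure-8) branch coexist.
* ``writhed_only`` — above Lk_max the flat circle is no longer a solution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy.optimize import minimize

from ._kernels import polygon_writhe, steric_scan
from .curves import ClosedCurve, build_circle
from .exceptions import InvalidParameterError, StericViolationError
from .topology import TopologyState, excess_twist_density, twist_from_lk, writhe

__all__ = [
    "ElasticParams", "MinimizerConfig", "EquilibriumShape", "EnergyDecomposition",
    "rod_energy", "minimize_shape", "lk_crit_empirical", "lk_max",
    "stability_regime", "writhe_vs_dlk_curve", "circle_shape",
]

_GL_X, _GL_W = np.polynomial.legendre.leggauss(8)


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ElasticParams:
    """Rod constants.  Lengths in Å; energies in units of k_BT.

    ``bending_rigidity_A`` is the effective rigidity in k_BT·Å and defaults
    to k_BT·P, i.e. numerically equal to the persistence length.
    """

    contour_length_L: float
    persistence_length_P: float = 500.0
    torsional_factor_omega: float = 2.0 / 3.0
    steric_thickness_ds: float = 20.0
    bending_rigidity_A: float | None = None

    def __post_init__(self):
        if self.contour_length_L <= 0 or self.persistence_length_P <= 0:
            raise InvalidParameterError("lengths must be positive")
        if self.torsional_factor_omega <= 0:
            raise InvalidParameterError("omega must be positive")
        if not 0 < self.steric_thickness_ds < self.contour_length_L:
            raise InvalidParameterError("need 0 < d_s < L")

    @property
    def A_eff(self) -> float:
        """Bending rigidity in k_BT·Å."""
        return (self.bending_rigidity_A if self.bending_rigidity_A is not None
                else self.persistence_length_P)

    @property
    def aspect_ratio(self) -> float:
        """d_s / L."""
        return self.steric_thickness_ds / self.contour_length_L

    @classmethod
    def from_bp(cls, length_bp: int, rise_per_bp: float = 3.4, **kw) -> "ElasticParams":
        return cls(contour_length_L=length_bp * rise_per_bp, **kw)


@dataclass(frozen=True)
class MinimizerConfig:
    """Knobs of the Monte-Carlo shape search (all counts positive)."""

    n_nodes: int = 16
    enforce_symmetry: bool = True     # C2 rotation about z (subgroup of dihedral)
    n_writhe_segments: int = 200
    n_steric_samples: int | None = None   # default ceil(20 L / d_s)
    steric_penalty_weight: float = 2e3    # k_BT, ramped x10 over the anneal
    length_penalty_weight: float = 1e4    # k_BT, ramped x10 over the anneal
    mc_steps: int = 6000
    temperature_start: float = 3.0        # k_BT
    temperature_end: float = 0.01
    proposal_scale_start: float = 0.10    # fraction of the loop radius L/2pi
    proposal_scale_end: float = 0.004
    quench_maxfev: int = 6000
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_nodes < 8 or self.n_nodes % 2:
            raise InvalidParameterError("n_nodes must be an even count >= 8")
        if self.mc_steps < 1 or self.n_writhe_segments < 10:
            raise InvalidParameterError("counts must be positive")
        if min(self.steric_penalty_weight, self.length_penalty_weight) < 0:
            raise InvalidParameterError("penalty weights must be >= 0")


@dataclass
class EnergyDecomposition:
    bend: float
    twist: float

    @property
    def total(self) -> float:
        return self.bend + self.twist


@dataclass
class EquilibriumShape:
    """A minimised shape with its energy decomposition (k_BT units)."""

    curve: ClosedCurve
    topology: TopologyState
    energy_bend: float
    energy_twist: float
    writhe: float
    penalty_residual: float = 0.0
    n_contacts: int = 0
    contact_type: Literal["none", "point", "line"] = "none"
    converged: bool = True
    seed: int | None = None
    branches: dict = field(default_factory=dict)

    @property
    def energy_total(self) -> float:
        return self.energy_bend + self.energy_twist


# ---------------------------------------------------------------------------
# closed-form operations
# ---------------------------------------------------------------------------

def lk_crit_empirical(ds_over_L: float) -> float:
    """Critical |ΔLk| for the onset of a stable writhed (figure-8) branch.

    Empirical fit Lk_crit = sqrt(1 + 23.1 d_s/L); tends to 1 for vanishing
    thickness (a very thin filament writhes for almost any |ΔLk| > 1).
    """
    if ds_over_L < 0:
        raise InvalidParameterError("aspect ratio must be non-negative")
    if ds_over_L >= 0.1:
        raise InvalidParameterError("empirical form is valid for d_s/L < 0.1")
    return float(np.sqrt(1.0 + 23.1 * ds_over_L))


def lk_max(omega: float) -> float:
    """Thickness-independent threshold √3/ω above which the flat circle is
    no longer an equilibrium solution."""
    if omega <= 0:
        raise InvalidParameterError("omega must be positive")
    return float(np.sqrt(3.0) / omega)


def stability_regime(dLk: float, params: ElasticParams
                     ) -> Literal["circle_only", "multistable", "writhed_only"]:
    """Classify |ΔLk| against Lk_crit(d_s/L) and Lk_max(ω)."""
    a = abs(dLk)
    crit = lk_crit_empirical(params.aspect_ratio)
    upper = lk_max(params.torsional_factor_omega)
    if a < crit:
        return "circle_only"
    if a <= upper:
        return "multistable"
    return "writhed_only"


def _bend_integral(curve: ClosedCurve) -> tuple[float, float]:
    """(∫ κ² ds, ∫ ds) by 8-point Gauss–Legendre on each spline interval."""
    n = curve.n_nodes
    base = np.arange(n)[:, None]
    t = (base + 0.5 * (_GL_X + 1.0)[None, :]).ravel()
    w = np.tile(0.5 * _GL_W, n)
    v = curve._d1(t)
    a = curve._d2(t)
    speed = np.linalg.norm(v, axis=1)
    kappa = np.linalg.norm(np.cross(v, a), axis=1) / speed**3
    return float(np.sum(w * kappa**2 * speed)), float(np.sum(w * speed))


def rod_energy(curve: ClosedCurve, topology: TopologyState,
               params: ElasticParams, n_writhe_segments: int = 200,
               check_steric: bool = True) -> EnergyDecomposition:
    """Bend/twist decomposition of the rod energy of ``curve`` in k_BT.

    bend = (A/2) ∫ κ² ds;  twist = (A ω / 2) L Ω² with the uniform residual
    twist density Ω = 2π(ΔLk − Wr)/L implied by the equilibrium condition.
    """
    kappa2_int, length = _bend_integral(curve)
    if check_steric:
        from .curves import min_self_distance
        dmin = min_self_distance(curve, n_samples=max(200, curve.n_nodes * 16),
                                 exclusion_arc=1.5 * params.steric_thickness_ds)
        if dmin < params.steric_thickness_ds - 0.1:
            raise StericViolationError(
                f"centerline self-distance {dmin:.2f} Å below steric "
                f"thickness {params.steric_thickness_ds:.2f} Å")
    wr = writhe(curve, n_writhe_segments)
    tw = twist_from_lk(topology, wr)
    omega_density = excess_twist_density(topology, wr, length)
    A = params.A_eff
    bend = 0.5 * A * kappa2_int
    twist = 0.5 * A * params.torsional_factor_omega * length * omega_density**2
    return EnergyDecomposition(bend=bend, twist=twist)


def circle_shape(dLk: float, params: ElasticParams,
                 topology: TopologyState | None = None,
                 n_nodes: int = 64) -> EquilibriumShape:
    """The flat-circle equilibrium at a given ΔLk (closed form).

    Bend energy 2π²A/L; all of ΔLk remains as twist since Wr = 0.
    """
    L = params.contour_length_L
    curve = build_circle(L, n_nodes)
    A = params.A_eff
    bend = 2.0 * np.pi**2 * A / L
    twist = 2.0 * np.pi**2 * A * params.torsional_factor_omega * dLk**2 / L
    return EquilibriumShape(curve=curve, topology=topology,
                            energy_bend=bend, energy_twist=twist,
                            writhe=0.0, n_contacts=0, contact_type="none",
                            converged=True)


# ---------------------------------------------------------------------------
# Monte-Carlo shape search
# ---------------------------------------------------------------------------

def _figure8_points(L: float, n_nodes: int, sign: float,
                    apex_frac: float = 0.15) -> np.ndarray:
    """Analytic figure-8 start: two lobes crossed with apex separation
    ``apex_frac`` of the lobe size, C2-symmetric about the z axis.

    The lemniscate is mirrored if needed so that its writhe carries the sign
    requested (negative ΔLk relaxes into negative writhe).
    """
    t = np.linspace(0.0, 2.0 * np.pi, n_nodes, endpoint=False)
    a = 1.0
    c = apex_frac * a
    pts = np.column_stack([a * np.sin(t), c * np.cos(t),
                           0.5 * a * np.sin(2.0 * t)])
    if polygon_writhe(np.ascontiguousarray(pts)) * sign < 0:
        pts[:, 2] *= -1.0
    curve = ClosedCurve(pts)
    return pts * (L / curve.arclength())


def _plectoneme_points(L: float, n_nodes: int, sign: float, winds: float,
                       r_over_w: float = 0.10) -> np.ndarray:
    """Interwound (plectonemic) start: two antiparallel strands wound about a
    common axis ``winds``·π radians each, related by the C2 rotation about z;
    the spline smoothing supplies the terminal hairpins.  Initial writhe is
    roughly −1.8·winds for sign < 0."""
    half = n_nodes // 2
    s = np.linspace(-1.0, 1.0, half)
    phi = winds * np.pi * s
    strand = np.column_stack([s, r_over_w * np.cos(phi), r_over_w * np.sin(phi)])
    pts = np.vstack([strand, strand * np.array([-1.0, -1.0, 1.0])])
    if polygon_writhe(np.ascontiguousarray(ClosedCurve(pts).sample(100))) * sign < 0:
        pts = pts * np.array([1.0, 1.0, -1.0])
    curve = ClosedCurve(pts)
    return pts * (L / curve.arclength())


class _ShapeObjective:
    """Penalised elastic energy as a function of free node coordinates.

    All sample sets (writhe polygon, steric scan, Gauss points for the bend
    and length integrals) live at fixed spline parameters, so they are
    precomputed as constant linear operators on the node array
    (see :mod:`minicircle._splinops`).  A coarse steric grid is used during
    the anneal; the full-resolution grid (20 L/d_s samples) is used for the
    quench and all reported quantities.
    """

    def __init__(self, params: ElasticParams, config: MinimizerConfig, dLk: float):
        from ._splinops import sample_operators

        self.params = params
        self.config = config
        self.dLk = dLk
        self.L = params.contour_length_L
        self.n = config.n_nodes
        self.sym = config.enforce_symmetry
        n_st = config.n_steric_samples
        if n_st is None:
            n_st = int(np.ceil(20.0 * self.L / params.steric_thickness_ds))
        self.n_steric = n_st
        n_coarse = min(n_st, 450)

        n = self.n
        n_wr_coarse = min(config.n_writhe_segments, 120)
        t_wr = np.linspace(0.0, n, config.n_writhe_segments, endpoint=False)
        t_wrc = np.linspace(0.0, n, n_wr_coarse, endpoint=False)
        t_st = np.linspace(0.0, n, n_st, endpoint=False)
        t_co = np.linspace(0.0, n, n_coarse, endpoint=False)
        base = np.arange(n)[:, None]
        t_gauss = (base + 0.5 * (_GL_X + 1.0)[None, :]).ravel()
        self.w_gauss = np.tile(0.5 * _GL_W, n)
        (self.W_wr,) = sample_operators(n, t_wr, (0,))
        (self.W_wrc,) = sample_operators(n, t_wrc, (0,))
        (self.W_st,) = sample_operators(n, t_st, (0,))
        (self.W_co,) = sample_operators(n, t_co, (0,))
        self.W_g1, self.W_g2 = sample_operators(n, t_gauss, (1, 2))

        def _window(m):
            spacing = self.L / m
            return max(1, int(np.ceil(1.5 * params.steric_thickness_ds / spacing)))

        self.window = _window(n_st)
        self.window_coarse = _window(n_coarse)
        self.w_len = config.length_penalty_weight
        self.w_st = config.steric_penalty_weight
        self.coarse = True

    # -- geometry -----------------------------------------------------------

    def expand(self, x: np.ndarray) -> np.ndarray:
        if self.sym:
            half = x.reshape(self.n // 2, 3)
            mirror = half * np.array([-1.0, -1.0, 1.0])
            return np.vstack([half, mirror])
        return x.reshape(self.n, 3)

    def reduce(self, pts: np.ndarray) -> np.ndarray:
        if self.sym:
            return pts[: self.n // 2].ravel()
        return pts.ravel()

    # -- energy -------------------------------------------------------------

    def evaluate(self, x: np.ndarray) -> dict:
        pts = self.expand(x)
        v = self.W_g1 @ pts
        a = self.W_g2 @ pts
        speed = np.linalg.norm(v, axis=1)
        if np.any(speed < 1e-9):
            return {"objective": 1e12}
        kappa = np.linalg.norm(np.cross(v, a), axis=1) / speed**3
        kappa2_int = float(np.sum(self.w_gauss * kappa**2 * speed))
        length = float(np.sum(self.w_gauss * speed))

        W_writhe = self.W_wrc if self.coarse else self.W_wr
        wr = float(polygon_writhe(np.ascontiguousarray(W_writhe @ pts)))
        A = self.params.A_eff
        bend = 0.5 * A * kappa2_int
        twist = (2.0 * np.pi**2 * A * self.params.torsional_factor_omega
                 * (self.dLk - wr) ** 2 / length)

        if self.coarse:
            st_pts = np.ascontiguousarray(self.W_co @ pts)
            pen_st, dmin = steric_scan(st_pts, self.params.steric_thickness_ds,
                                       self.window_coarse)
        else:
            st_pts = np.ascontiguousarray(self.W_st @ pts)
            pen_st, dmin = steric_scan(st_pts, self.params.steric_thickness_ds,
                                       self.window)
        pen = (self.w_st * pen_st
               + self.w_len * ((length - self.L) / self.L) ** 2)
        return {"objective": bend + twist + pen, "bend": bend, "twist": twist,
                "penalty": pen, "length": length, "writhe": wr, "dmin": dmin}

    def __call__(self, x: np.ndarray) -> float:
        return self.evaluate(x)["objective"]


def _anneal(obj: _ShapeObjective, x0: np.ndarray, config: MinimizerConfig,
            rng: np.random.Generator, steps: int | None = None,
            t_start: float | None = None) -> tuple[np.ndarray, list[float]]:
    """Simulated annealing with geometric temperature/step/weight schedules."""
    x = x0.copy()
    obj.coarse = True
    e = obj(x)
    trace = [e]
    radius = obj.L / (2.0 * np.pi)
    n_free = x.size // 3
    w_st0, w_len0 = obj.w_st, obj.w_len
    steps = config.mc_steps if steps is None else steps
    t0 = config.temperature_start if t_start is None else t_start
    for step in range(steps):
        frac = step / max(1, steps - 1)
        temp = t0 * (config.temperature_end / t0) ** frac
        sigma = radius * (config.proposal_scale_start
                          * (config.proposal_scale_end
                             / config.proposal_scale_start) ** frac)
        # penalty stiffening: x10 over the anneal
        obj.w_st = w_st0 * 10.0 ** frac
        obj.w_len = w_len0 * 10.0 ** frac
        if step % 50 == 0:
            e = obj(x)  # rebase after weight change
        k = rng.integers(n_free)
        prop = x.copy()
        prop[3 * k: 3 * k + 3] += rng.normal(scale=sigma, size=3)
        e_new = obj(prop)
        if e_new < e or rng.random() < np.exp(-(e_new - e) / max(temp, 1e-9)):
            x, e = prop, e_new
        trace.append(e)
    obj.w_st, obj.w_len = w_st0, w_len0
    return x, trace


def _finalize(obj: _ShapeObjective, x: np.ndarray, params: ElasticParams,
              config: MinimizerConfig, dLk: float,
              topology: TopologyState | None, seed: int) -> EquilibriumShape:
    """Quench, project to the exact length, and assemble the result."""
    obj.coarse = False
    obj.w_st = config.steric_penalty_weight * 10.0
    obj.w_len = config.length_penalty_weight * 10.0
    e_pre = obj(x)
    res = minimize(obj, x, method="Powell",
                   options={"maxfev": config.quench_maxfev,
                            "xtol": 1e-6, "ftol": 1e-9})
    x = res.x
    e_post = float(res.fun)
    pts = obj.expand(x)
    # uniform rescale to the exact prescribed length (writhe is scale
    # invariant; bending energy transforms exactly as 1/scale)
    curve = ClosedCurve(pts)
    scale = params.contour_length_L / curve.arclength()
    curve = ClosedCurve(pts * scale)

    kappa2_int, length = _bend_integral(curve)
    wr = float(polygon_writhe(np.ascontiguousarray(
        curve.sample(config.n_writhe_segments))))
    A = params.A_eff
    bend = 0.5 * A * kappa2_int
    twist = (2.0 * np.pi**2 * A * params.torsional_factor_omega
             * (dLk - wr) ** 2 / length)

    n_st = obj.n_steric
    st = np.ascontiguousarray(curve.sample(n_st))
    pen_st, dmin = steric_scan(st, params.steric_thickness_ds, obj.window)
    n_contacts, contact_type = _contact_summary(
        st, params.steric_thickness_ds, obj.window)

    # convergence: the search had already located the basin (the final
    # full-resolution quench changes the objective by < 1 %) and the hard
    # constraints hold on the projected shape
    steric_ok = dmin >= params.steric_thickness_ds - 0.1
    length_ok = (abs(length - params.contour_length_L)
                 / params.contour_length_L < 1e-3)
    quench_settled = (e_pre - e_post) < 0.01 * max(abs(e_post), 1.0)
    converged = bool(quench_settled and steric_ok and length_ok)
    if not steric_ok:
        warnings.warn("steric residual above tolerance in final shape",
                      stacklevel=2)
    if topology is not None:
        twist_from_lk(topology, wr)
    return EquilibriumShape(curve=curve, topology=topology, energy_bend=bend,
                            energy_twist=twist, writhe=wr,
                            penalty_residual=float(obj.w_st * pen_st),
                            n_contacts=n_contacts, contact_type=contact_type,
                            converged=converged, seed=seed)


def _contact_summary(pts: np.ndarray, ds: float, window: int,
                     slack: float = 1.10) -> tuple[int, str]:
    """Count distinct self-contact regions and classify point vs line contact.

    Sample pairs closer than ``slack * d_s`` are clustered by connectivity in
    index space; a cluster extending over more than 2 % of the contour along
    either strand is a line contact.
    """
    n = pts.shape[0]
    diff = pts[:, None, :] - pts[None, :, :]
    d = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    ii, jj = np.triu_indices(n, k=1)
    circ = np.minimum(jj - ii, n - (jj - ii))
    close = (d[ii, jj] < slack * ds) & (circ > window)
    if not np.any(close):
        return 0, "none"
    ci, cj = ii[close], jj[close]
    # cluster contact pairs: two pairs belong together if both indices are
    # within a small neighbourhood (circular)
    order = np.argsort(ci)
    ci, cj = ci[order], cj[order]
    labels = -np.ones(ci.size, dtype=int)
    current = 0
    tol = max(3, n // 50)
    for a in range(ci.size):
        if labels[a] >= 0:
            continue
        labels[a] = current
        stack = [a]
        while stack:
            b = stack.pop()
            near = np.where(
                (labels < 0)
                & (np.minimum(np.abs(ci - ci[b]), n - np.abs(ci - ci[b])) <= tol)
                & (np.minimum(np.abs(cj - cj[b]), n - np.abs(cj - cj[b])) <= tol)
            )[0]
            for m in near:
                labels[m] = current
                stack.append(m)
        current += 1
    extents = []
    for lab in range(current):
        sel = labels == lab
        span = max(np.ptp(ci[sel]), np.ptp(cj[sel]))
        extents.append(span)
    contact_type = "line" if max(extents) > 0.02 * n else "point"
    return current, contact_type


def minimize_shape(dLk: float, params: ElasticParams,
                   config: MinimizerConfig | None = None,
                   topology: TopologyState | None = None) -> EquilibriumShape:
    """Lowest-energy closed-rod shape at linking deficit ``dLk``.

    Runs the Monte-Carlo search from an analytic figure-8 start (the writhed
    branch) and compares with the exact flat-circle solution (admissible for
    |ΔLk| ≤ √3/ω); the lower minimum is returned and both branches are kept
    in ``result.branches``.  Deterministic for a fixed ``config.rng_seed``.
    """
    if not np.isfinite(dLk):
        raise InvalidParameterError("dLk must be finite")
    config = config or MinimizerConfig()
    rng = np.random.default_rng(config.rng_seed)

    circle = circle_shape(dLk, params, topology=None)
    branches: dict[str, EquilibriumShape] = {"circle": circle}
    circle_admissible = abs(dLk) <= lk_max(params.torsional_factor_omega)

    regime = stability_regime(dLk, params)
    best: EquilibriumShape
    if regime == "circle_only":
        best = circle
    else:
        sign = -1.0 if dLk < 0 else 1.0
        a = abs(dLk)
        L = params.contour_length_L
        n = config.n_nodes
        # multi-start over the writhed families: the figure-8 covers the
        # onset region; for deeper deficits, interwound starts with initial
        # writhe bracketing ~0.7 ΔLk reach the line-contact branch the
        # figure-8 basin does not connect to easily
        starts = [_figure8_points(L, n, sign)]
        if a > 2.0:
            for winds in (0.4 * a, max(0.8, 0.4 * a - 0.35)):
                starts.append(_plectoneme_points(L, n, sign, winds))
        obj = _ShapeObjective(params, config, dLk)
        steps = max(200, config.mc_steps // len(starts))
        candidates = []
        for k, pts in enumerate(starts):
            rng_k = np.random.default_rng([config.rng_seed, k])
            x, trace = _anneal(obj, obj.reduce(pts), config, rng_k, steps=steps)
            candidates.append((x, trace))
        # cheap ranking quench (coarse grids) on each anneal endpoint,
        # full-resolution quench on the winner only
        obj.coarse = True
        obj.w_st = config.steric_penalty_weight * 10.0
        obj.w_len = config.length_penalty_weight * 10.0
        scored = []
        for x, trace in candidates:
            r = minimize(obj, x, method="Powell",
                         options={"maxfev": max(300, config.quench_maxfev // 6),
                                  "xtol": 1e-4, "ftol": 1e-7})
            scored.append((r.fun, r.x, trace))
        obj.w_st = config.steric_penalty_weight
        obj.w_len = config.length_penalty_weight
        scored.sort(key=lambda z: z[0])
        _, x_best, _trace = scored[0]
        writhed = _finalize(obj, x_best, params, config, dLk, None,
                            config.rng_seed)
        branches["figure8"] = writhed
        if not writhed.converged:
            warnings.warn("shape search did not meet the convergence "
                          "criteria; returning best-so-far", stacklevel=2)
        if circle_admissible and circle.energy_total < writhed.energy_total:
            best = circle
        else:
            best = writhed

    best = replace(best, topology=topology, seed=config.rng_seed,
                   branches=branches)
    if topology is not None:
        twist_from_lk(topology, best.writhe)
    return best


def writhe_vs_dlk_curve(params: ElasticParams, dlk_grid,
                        config: MinimizerConfig | None = None):
    """Writhe and energies of minimising shapes on a grid of ΔLk values.

    Returns a pandas DataFrame with one row per ΔLk (regime, Wr, energies).
    """
    import pandas as pd

    config = config or MinimizerConfig()
    rows = []
    for d in np.atleast_1d(np.asarray(dlk_grid, dtype=float)):
        shape = minimize_shape(float(d), params, config)
        rows.append({"dLk": float(d),
                     "regime": stability_regime(float(d), params),
                     "Wr": shape.writhe,
                     "E_bend": shape.energy_bend,
                     "E_twist": shape.energy_twist,
                     "E_total": shape.energy_total,
                     "n_contacts": shape.n_contacts,
                     "contact_type": shape.contact_type})
    return pd.DataFrame(rows)
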