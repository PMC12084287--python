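"""Fixed points, stability conditions and bifurcation scans.

All analysis is phrased in the scalar reduced coordinates ``x`` with the
response functions ``f(x) = 1/(a + x^k)`` and ``g(x) = 1/(1 + b x^h)``.
The main objects are:

* the unique homogeneous fixed point ``x0`` of ``phi(x) = g(x) f(x)``;
* the two-cell anti-phase instability condition
  ``f(x0) g'(x0) - f'(x0) g(x0) < -1`` and its full-model counterpart in
  protein units, which switch sign together (the quasi-steady-state
  reduction preserves the constant term of the characteristic polynomial
  up to a positive factor);
* the non-homogeneous two-cell pair ``(x1, x2)``, fixed points of the
  second iterate of ``gamma = h^{-1} o g`` with ``h(x) = x/f(x)``, stable
  whenever it exists;
* lattice dispersion relations (the anti-phase mode ``s/N = 1/2`` is the
  most unstable in 1D; the ``r = s = N/3`` mode, matching the period-3
  uniform colouring, in 2D);
* the three-cell all-to-all system that faithfully captures the period-3
  pattern, its stationary triples and the existence boundary at which the
  stable and unstable patterned branches merge in a fold;
* bifurcation scans along the feedback-weakening scaling
  ``alpha_N -> alpha_N / s``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import ode_grid
from .lattice import HexLattice, build_hex_lattice
from .params import ModelParameters
from .reduction import (
    compute_ab,
    compute_R,
    f_reduced,
    fprime_reduced,
    g_reduced,
    gprime_reduced,
    map_x_to_P,
    x_scale,
)

__all__ = [
    "StabilityCondition",
    "StationarySet",
    "DispersionResult",
    "ThreeCellSolution",
    "homogeneous_fixed_point",
    "instability_reduced_2cell",
    "instability_full_2cell",
    "nonhomogeneous_pair",
    "pair_stability",
    "reduced_two_cell_jacobian",
    "full_two_cell_jacobian",
    "full_pair_state",
    "dispersion",
    "three_cell_stationary",
    "generic_coupled_jacobian",
    "existence_boundary",
    "bifurcation_scan",
    "stationary_set",
]

#: Eigenvalues with real part below this are treated as stable (finite
#: precision guard for marginal modes).
EIG_TOL = 1e-9


# -- scalar response helpers ---------------------------------------------------

class _Funcs:
    """Bundle of f, g and derivatives for fixed (a, b, k, h)."""

    def __init__(self, a: float, b: float, k: int, h: int):
        if a <= 0 or b < 0:
            raise ValueError("require a > 0 and b >= 0")
        self.a, self.b, self.k, self.h = a, b, int(k), int(h)

    def f(self, x):
        return f_reduced(x, self.a, self.k)

    def fp(self, x):
        return fprime_reduced(x, self.a, self.k)

    def g(self, x):
        return g_reduced(x, self.b, self.h)

    def gp(self, x):
        return gprime_reduced(x, self.b, self.h)

    def phi(self, x):
        return self.g(x) * self.f(x)

    def hfun(self, x):
        """h(x) = x / f(x) = x (a + x^k), strictly increasing on x >= 0."""
        return x * (self.a + x ** self.k)

    # dense monotone tables for fast vectorised inversion of h and H; exact
    # roots are always polished with brentq afterwards
    _XGRID = np.concatenate([np.geomspace(1e-9, 0.01, 1500), np.linspace(0.01, 1.0, 2501)])

    def _tables(self):
        if not hasattr(self, "_h_table"):
            self._h_table = self.hfun(self._XGRID)
            self._H_table = self.Hfun(self._XGRID)
        return self._h_table, self._H_table

    def hinv_vec(self, vals: np.ndarray) -> np.ndarray:
        h_tab, _ = self._tables()
        return np.interp(vals, h_tab, self._XGRID)

    def Hinv_vec(self, vals: np.ndarray) -> np.ndarray:
        _, H_tab = self._tables()
        return np.interp(vals, H_tab, self._XGRID)

    def gamma2_vec(self, x: np.ndarray) -> np.ndarray:
        return self.hinv_vec(self.g(self.hinv_vec(self.g(x))))

    def Gamma2_vec(self, x: np.ndarray) -> np.ndarray:
        return self.hinv_vec(self.g(self.Hinv_vec(self.g(x) / 2.0)))

    def hinv(self, val: float) -> float:
        hi = 1.0
        while self.hfun(hi) < val:
            hi *= 2.0
        return brentq(lambda t: self.hfun(t) - val, 0.0, hi, xtol=1e-14)

    def gamma(self, x: float) -> float:
        """The two-cell stationary map x1 = gamma(x2) = h^{-1}(g(x2))."""
        return self.hinv(float(self.g(x)))

    def gamma2(self, x: float) -> float:
        return self.gamma(self.gamma(x))

    # three-cell analogues
    def Hfun(self, x):
        return self.hfun(x) - self.g(x) / 2.0

    def Hinv(self, val: float) -> float:
        hi = 1.0
        while self.Hfun(hi) < val:
            hi *= 2.0
        return brentq(lambda t: self.Hfun(t) - val, 0.0, hi, xtol=1e-14)

    def Gamma(self, x1: float) -> float:
        return self.Hinv(float(self.g(x1)) / 2.0)

    def Gamma2(self, x1: float) -> float:
        return self.gamma(self.Gamma(x1))


def _scan_roots(fun, vec_fun, lo: float = 1e-9, hi: float = 1.0 - 1e-12) -> list[float]:
    """All sign-change roots of ``fun`` on (lo, hi).

    ``vec_fun`` is a fast vectorised (table-interpolated) version of ``fun``
    used to localise the sign changes on a dense grid; each bracket is then
    polished against the exact scalar ``fun`` with brentq.
    """
    xs = np.concatenate([np.geomspace(lo, 0.01, 800), np.linspace(0.01, hi, 1600)])
    vals = vec_fun(xs) - xs
    sign = np.sign(vals)
    idx = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    roots = []
    for i in idx:
        f_lo, f_hi = fun(xs[i]) - xs[i], fun(xs[i + 1]) - xs[i + 1]
        if f_lo == 0.0:
            roots.append(float(xs[i]))
            continue
        if f_lo * f_hi > 0:
            continue  # interpolation artefact
        roots.append(brentq(lambda x: fun(x) - x, xs[i], xs[i + 1], xtol=1e-14))
    out: list[float] = []
    for r in sorted(roots):
        if not out or abs(r - out[-1]) > 1e-9:
            out.append(float(r))
    return out


# -- result containers ---------------------------------------------------------

@dataclass(frozen=True)
class StabilityCondition:
    """Outcome of one of the linear (in)stability conditions.

    ``value`` is the left-hand side of the condition; the state is
    unstable when ``value < -1``, so ``margin = value + 1`` is negative in
    the unstable (patterning) regime.
    """

    unstable: bool
    margin: float
    value: float
    x0: float


@dataclass(frozen=True)
class DispersionResult:
    """Per-mode linear growth rates around the homogeneous state."""

    dim: str
    sizes: tuple[int, ...]
    modes: np.ndarray
    growth: np.ndarray
    most_unstable: tuple[int, ...]

    @property
    def max_growth(self) -> float:
        return float(self.growth.max())


@dataclass(frozen=True)
class ThreeCellSolution:
    """One stationary triple (x1, x2, x2) of the three-cell system."""

    x1: float
    x2: float
    stable: bool
    max_eig: float

    @property
    def homogeneous(self) -> bool:
        return abs(self.x1 - self.x2) < 1e-8


@dataclass(frozen=True)
class StationarySet:
    """Stationary solutions (reduced units and protein uM) at one scaling."""

    x0: float
    x0_stable: bool
    pair: tuple[float, float] | None
    pair_stable: bool | None
    P0: float
    P_pair: tuple[float, float] | None
    full_state0: dict
    s: float = 1.0


# -- homogeneous state and two-cell analysis -----------------------------------

def homogeneous_fixed_point(a: float, b: float, k: int, h: int) -> float:
    """The unique root of ``g(x) f(x) = x`` in (0, 1).

    Existence and uniqueness follow from ``phi(0) > 0``, ``phi(1) < 1`` and
    ``phi`` strictly decreasing.
    """
    fn = _Funcs(a, b, k, h)
    return brentq(lambda x: fn.phi(x) - x, 0.0, max(1.0, fn.phi(0.0)), xtol=1e-14)


def instability_reduced_2cell(a: float, b: float, k: int, h: int) -> StabilityCondition:
    """Anti-phase instability of the homogeneous state, reduced coordinates.

    Evaluates ``f(x0) g'(x0) - f'(x0) g(x0)``; values below -1 mean the
    two-cell periodic homogeneous state is linearly unstable and lateral
    inhibition can amplify differences between neighbours.
    """
    fn = _Funcs(a, b, k, h)
    x0 = homogeneous_fixed_point(a, b, k, h)
    value = float(fn.f(x0) * fn.gp(x0) - fn.fp(x0) * fn.g(x0))
    return StabilityCondition(unstable=value < -1.0, margin=value + 1.0, value=value, x0=x0)


def instability_full_2cell(params: ModelParameters) -> StabilityCondition:
    """Full-model two-cell instability condition in protein units.

    With ``P0`` the homogeneous protein level and ``R = prod alpha_i/mu_i``:

        -h (P0/K_n)^h / (1 + (P0/K_n)^h)
        + k P0 (P0/K_M)^k (1 + (P0/K_n)^h) / R  <  -1.

    This is the reduced condition transported through the quasi-steady
    state relations; the two conditions switch sign together.
    """
    a, b = compute_ab(params)
    x0 = homogeneous_fixed_point(a, b, params.k, params.h)
    P0 = map_x_to_P(x0, params)
    R = compute_R(params)
    k, h = params.k, params.h
    hill_n = (P0 / params.K_n) ** h
    value = float(
        -h * hill_n / (1.0 + hill_n)
        + k * P0 * (P0 / params.K_M) ** k * (1.0 + hill_n) / R
    )
    return StabilityCondition(unstable=value < -1.0, margin=value + 1.0, value=value, x0=x0)


def nonhomogeneous_pair(a: float, b: float, k: int, h: int) -> tuple[float, float] | None:
    """The anti-phase stationary pair ``x1 < x0 < x2``, or ``None``.

    Cyclic solutions of the two-cell system are fixed points of the second
    iterate of ``gamma``; when several pairs exist the one furthest from
    the homogeneous state is returned (it is the stable one).
    """
    fn = _Funcs(a, b, k, h)
    x0 = homogeneous_fixed_point(a, b, k, h)
    roots = _scan_roots(fn.gamma2, fn.gamma2_vec)
    below = [r for r in roots if r < x0 - 1e-8]
    if not below:
        return None
    x1 = min(below)  # furthest below x0
    x2 = fn.gamma(x1)
    return (float(x1), float(x2))


def reduced_two_cell_jacobian(x1: float, x2: float, a: float, b: float, k: int, h: int) -> np.ndarray:
    """Jacobian of the scalar two-cell periodic system at ``(x1, x2)``."""
    fn = _Funcs(a, b, k, h)
    return np.array(
        [
            [fn.g(x2) * fn.fp(x1) - 1.0, fn.gp(x2) * fn.f(x1)],
            [fn.gp(x1) * fn.f(x2), fn.g(x1) * fn.fp(x2) - 1.0],
        ]
    )


def pair_stability(
    pair: tuple[float, float], a: float, b: float, k: int, h: int
) -> StabilityCondition:
    """Stability of the non-homogeneous pair via the sign condition

        0 < f'_1 f'_2 g_1 g_2 - f_1 f_2 g'_1 g'_2 - f'_1 g_2 - f'_2 g_1 + 1,

    the constant term of the two-cell characteristic polynomial (all other
    coefficients are positive, so a positive constant term rules out a
    positive real eigenvalue).
    """
    fn = _Funcs(a, b, k, h)
    x1, x2 = pair
    f1, f2 = float(fn.f(x1)), float(fn.f(x2))
    fp1, fp2 = float(fn.fp(x1)), float(fn.fp(x2))
    g1, g2 = float(fn.g(x1)), float(fn.g(x2))
    gp1, gp2 = float(fn.gp(x1)), float(fn.gp(x2))
    value = fp1 * fp2 * g1 * g2 - f1 * f2 * gp1 * gp2 - fp1 * g2 - fp2 * g1 + 1.0
    x0 = homogeneous_fixed_point(a, b, k, h)
    return StabilityCondition(unstable=not (value > 0.0), margin=value, value=value, x0=x0)


# -- full-model Jacobian oracles -----------------------------------------------

def full_pair_state(x1: float, x2: float, params: ModelParameters) -> np.ndarray:
    """Full-model image (2 cells x 5 species) of a reduced two-cell pair.

    Valid at stationary pairs: each species follows from the production
    chain, with Notch driven by the *other* cell's Dll1.
    """
    p = params
    P = map_x_to_P(np.array([x1, x2]), p)
    M = p.mu_P / p.alpha_P * P
    n = p.alpha_n / p.mu_n / (1.0 + (P / p.K_n) ** p.h)
    D = p.alpha_D / p.mu_D * n
    N = p.alpha_N / p.mu_N * D[::-1]
    return np.column_stack([D, N, M, P, n])


def full_two_cell_jacobian(state: np.ndarray, params: ModelParameters) -> np.ndarray:
    """Numeric (central finite difference) 10x10 Jacobian of the full model
    on the two-cell periodic lattice at ``state`` (shape (2, 5))."""
    lattice = build_hex_lattice(1, 2, "periodic")
    flat = np.asarray(state, dtype=float).ravel()

    def fun(y):
        return ode_grid.rhs_full(y.reshape(2, 5), lattice, params).ravel()

    n = flat.size
    J = np.empty((n, n))
    for j in range(n):
        step = 1e-6 * max(abs(flat[j]), 1e-6)
        e = np.zeros(n)
        e[j] = step
        J[:, j] = (fun(flat + e) - fun(flat - e)) / (2.0 * step)
    return J


# -- dispersion relations ------------------------------------------------------

def dispersion(
    a: float, b: float, k: int, h: int, dim: str, sizes: tuple[int, ...] | int
) -> DispersionResult:
    """Linear growth rate of each spatial Fourier mode on a periodic lattice.

    1D ring of N cells: ``lambda_s = g'f cos(2 pi s/N) + g f' - 1``.
    2D hexagonal torus (M x N): ``lambda_rs = g'f A + g f' - 1`` with
    ``3A = cos(2 pi s/N) + cos(2 pi r/M) + cos(2 pi s/N + 2 pi r/M)``.
    Derivatives are evaluated at the homogeneous fixed point.
    """
    fn = _Funcs(a, b, k, h)
    x0 = homogeneous_fixed_point(a, b, k, h)
    gf = float(fn.gp(x0) * fn.f(x0))
    fg = float(fn.g(x0) * fn.fp(x0))
    if dim in ("1d", "1D"):
        (N,) = (sizes,) if np.isscalar(sizes) else tuple(sizes)
        if N < 2:
            raise ValueError("1D dispersion needs N >= 2")
        s = np.arange(N)
        growth = gf * np.cos(2 * np.pi * s / N) + fg - 1.0
        best = int(s[np.argmax(growth)])
        return DispersionResult("1d", (int(N),), s, growth, (best,))
    if dim in ("2d-hex", "2D-hex", "2d"):
        M, N = tuple(sizes)
        if min(M, N) < 3:
            raise ValueError("2D dispersion needs sizes >= 3")
        r, s = np.meshgrid(np.arange(M), np.arange(N), indexing="ij")
        A = (
            np.cos(2 * np.pi * s / N)
            + np.cos(2 * np.pi * r / M)
            + np.cos(2 * np.pi * s / N + 2 * np.pi * r / M)
        ) / 3.0
        growth = gf * A + fg - 1.0
        idx = np.unravel_index(np.argmax(growth), growth.shape)
        modes = np.stack([r, s], axis=-1)
        return DispersionResult("2d-hex", (int(M), int(N)), modes, growth, (int(idx[0]), int(idx[1])))
    raise ValueError(f"unknown dispersion dimensionality {dim!r}")


# -- three-cell analysis -------------------------------------------------------

def generic_coupled_jacobian(x: np.ndarray, W: np.ndarray, a, b, k, h) -> np.ndarray:
    """Jacobian of ``x_i' = sum_j W_ij g(x_j) f(x_i) - x_i``."""
    fn = _Funcs(a, b, k, h)
    x = np.asarray(x, dtype=float)
    coupling = W @ fn.g(x)
    J = W * fn.gp(x)[None, :] * fn.f(x)[:, None]
    J += np.diag(coupling * fn.fp(x) - 1.0)
    return J


def three_cell_stationary(
    a: float, b: float, k: int, h: int, *, system: str = "W3"
) -> list[ThreeCellSolution]:
    """All stationary triples ``(x1, x2, x2)`` of the three-cell system.

    Solutions solve ``h(x1) = g(x2)`` and ``H(x2) = g(x1)/2`` with
    ``H(x) = x/f(x) - g(x)/2``; their ``x1`` components are fixed points of
    ``Gamma2 = gamma o Gamma``.  Stability is classified by the eigenvalues
    of the all-to-all three-cell Jacobian (``system="W3"``, default).  The
    two-cell ``W2`` coupling shares the same stationary states but
    mis-classifies their stability (it admits stable near-homogeneous
    solutions never observed on real lattices); it is available behind
    ``system="W2"`` for demonstration.
    """
    from .lattice import W2, W3  # local import to avoid cycle at module load

    fn = _Funcs(a, b, k, h)
    roots = _scan_roots(fn.Gamma2, fn.Gamma2_vec)
    sols: list[ThreeCellSolution] = []
    for x1 in roots:
        x2 = fn.Gamma(x1)
        if system == "W3":
            state = np.array([x1, x2, x2])
            J = generic_coupled_jacobian(state, W3, a, b, k, h)
        elif system == "W2":
            state = np.array([x1, x2])
            J = generic_coupled_jacobian(state, W2, a, b, k, h)
        else:
            raise ValueError(f"unknown system {system!r}")
        max_eig = float(np.max(np.real(np.linalg.eigvals(J))))
        sols.append(ThreeCellSolution(x1=float(x1), x2=float(x2), stable=max_eig < EIG_TOL, max_eig=max_eig))
    return sols


def eq36_lhs(pair: tuple[float, float], a: float, b: float, k: int, h: int) -> float:
    """Left-hand side of the three-cell fold (double-root) condition.

    Equals ``Gamma2'(x1) = Gamma'(x1) gamma'(x2)``; the patterned branches
    merge where this crosses one.
    """
    fn = _Funcs(a, b, k, h)
    x1, x2 = pair
    f1, f2 = float(fn.f(x1)), float(fn.f(x2))
    fp1, fp2 = float(fn.fp(x1)), float(fn.fp(x2))
    g1, g2 = float(fn.g(x1)), float(fn.g(x2))
    gp1, gp2 = float(fn.gp(x1)), float(fn.gp(x2))
    first = gp1 * f2 / (2.0 - (fp2 * g2 + f2 * gp2) - g1 * fp2)
    second = f1 * gp2 / (1.0 - fp1 * g2)
    return first * second


def _n_patterned(params: ModelParameters, s: float) -> int:
    a, b = compute_ab(params.scale_alpha_N(s))
    x0 = homogeneous_fixed_point(a, b, params.k, params.h)
    sols = three_cell_stationary(a, b, params.k, params.h)
    return sum(1 for sol in sols if abs(sol.x1 - sol.x2) > 1e-6 and abs(sol.x1 - x0) > 1e-6)


def existence_boundary(
    params: ModelParameters, s_range: tuple[float, float] = (0.5, 50.0), *, tol: float = 1e-4
) -> float:
    """Scaling ``s*`` beyond which no patterned three-cell solution exists.

    Locates, by bisection on the count of non-homogeneous stationary
    triples, the fold at which the stable and unstable patterned branches
    collapse into a double root.  Raises when the range does not bracket
    the transition.
    """
    lo, hi = s_range
    n_lo, n_hi = _n_patterned(params, lo), _n_patterned(params, hi)
    if not (n_lo > 0 and n_hi == 0):
        raise ValueError(
            f"boundary not in range: {n_lo} patterned solutions at s={lo}, {n_hi} at s={hi}"
        )
    while hi - lo > tol * max(1.0, lo):
        mid = 0.5 * (lo + hi)
        if _n_patterned(params, mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# -- scans and bundles ---------------------------------------------------------

def default_s_grid(lo: float = 0.5, hi: float = 50.0, n: int = 200) -> np.ndarray:
    return np.geomspace(lo, hi, n)


def stationary_set(params: ModelParameters, s: float = 1.0) -> StationarySet:
    """Homogeneous and patterned two-cell stationary states at scaling ``s``."""
    ps = params.scale_alpha_N(s) if s != 1.0 else params
    a, b = compute_ab(ps)
    k, h = ps.k, ps.h
    cond = instability_reduced_2cell(a, b, k, h)
    x0 = cond.x0
    pair = nonhomogeneous_pair(a, b, k, h)
    pair_ok = None
    P_pair = None
    if pair is not None:
        pair_ok = not pair_stability(pair, a, b, k, h).unstable
        P_pair = tuple(float(p) for p in map_x_to_P(np.array(pair), ps))
    full0 = ode_grid.homogeneous_stationary_state(ps)
    return StationarySet(
        x0=float(x0),
        x0_stable=not cond.unstable,
        pair=pair,
        pair_stable=pair_ok,
        P0=float(map_x_to_P(x0, ps)),
        P_pair=P_pair,
        full_state0=full0,
        s=s,
    )


def bifurcation_scan(
    params: ModelParameters,
    s_grid: np.ndarray | None = None,
    system: str = "2cell-full",
) -> pd.DataFrame:
    """Branch table of stationary solutions along the ``alpha_N/s`` scaling.

    Each row is one solution branch at one scaling: the homogeneous branch
    (present for every ``s``) and any patterned branches, with stability
    flags, condition margins and protein-unit values.  Branch identifiers
    are assigned by nearest-neighbour continuity between consecutive grid
    points.
    """
    if s_grid is None:
        s_grid = default_s_grid()
    if np.any(np.asarray(s_grid) <= 0):
        raise ValueError("s grid must be positive")
    rows = []
    prev_branches: dict[int, float] = {}
    next_branch_id = 1
    for s in s_grid:
        ps = params.scale_alpha_N(float(s))
        a, b = compute_ab(ps)
        k, h = ps.k, ps.h
        cond_r = instability_reduced_2cell(a, b, k, h)
        cond_f = instability_full_2cell(ps)
        scale = x_scale(ps)
        rows.append(
            {
                "s": float(s), "branch_id": 0, "kind": "homogeneous",
                "x": cond_r.x0, "P": cond_r.x0 * scale,
                "stable": not cond_r.unstable,
                "margin_reduced": cond_r.margin, "margin_full": cond_f.margin,
            }
        )
        if system == "2cell-full":
            pair = nonhomogeneous_pair(a, b, k, h)
            branch_vals = []
            if pair is not None:
                st = not pair_stability(pair, a, b, k, h).unstable
                branch_vals = [(pair[0], st), (pair[1], st)]
        elif system == "3cell-reduced":
            sols = three_cell_stationary(a, b, k, h)
            branch_vals = [
                (sol.x1, sol.stable)
                for sol in sols
                if abs(sol.x1 - sol.x2) > 1e-6
            ]
            branch_vals += [
                (sol.x2, sol.stable)
                for sol in sols
                if abs(sol.x1 - sol.x2) > 1e-6
            ]
        else:
            raise ValueError(f"unknown system {system!r}")

        new_branches: dict[int, float] = {}
        for x_val, st in branch_vals:
            # continuity: reuse the closest previous branch id when available
            best_id, best_d = None, np.inf
            for bid, bx in prev_branches.items():
                d = abs(bx - x_val)
                if d < best_d and bid not in new_branches:
                    best_id, best_d = bid, d
            if best_id is None or best_d > 0.2:
                best_id = next_branch_id
                next_branch_id += 1
            new_branches[best_id] = x_val
            rows.append(
                {
                    "s": float(s), "branch_id": best_id, "kind": "patterned",
                    "x": float(x_val), "P": float(x_val) * scale, "stable": bool(st),
                    "margin_reduced": cond_r.margin, "margin_full": cond_f.margin,
                }
            )
        prev_branches = new_branches
    return pd.DataFrame(rows)
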