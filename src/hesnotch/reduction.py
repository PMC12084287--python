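"""Quasi-steady-state reductions of the five-species network.

Setting three of the five species to their quasi-steady states collapses
the network onto a planar system in a retained pair ``(x, y)``.  Seven of
the ten possible choices are closed-form reducible (those retaining at
least one of Hes1 mRNA ``M`` or protein ``P``); they come in three
structural types that differ only in where the neighbour average enters:

* type 1: ``x' = <y_in> f(x) - x``,          ``y' = v (g(x) - y)``
* type 2: ``x' = y f(x) - x``,               ``y' = v (<g(x_in)> - y)``
* type 3: ``x' = <g(y_in)> f(y) - x``,       ``y' = v (x - y)``

with the decreasing response functions ``f(x) = 1/(a + x^k)`` and
``g(x) = 1/(1 + b x^h)``.  The dimensionless ``a`` and ``b`` are identical
across all seven reductions and depend on the full parameters only through
the composite ``R = prod_i alpha_i / mu_i`` (units uM).  Time is rescaled
by the retained ``x``-species' degradation rate, so ``v = mu_y / mu_x`` is
the sole reduction-specific constant and sets the relative speed of the
``y``-relaxation (hence the timing, but not the location, of the fate
decision).

A further quasi-steady state in ``y`` yields the scalar lattice model
``x' = <g(x_in)> f(x) - x`` on which most of the analytical work is done.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lattice import HexLattice
from .params import ModelParameters

__all__ = [
    "ADMISSIBLE_PAIRS",
    "ReducedParameters",
    "compute_R",
    "compute_ab",
    "compute_v",
    "reduce_model",
    "reduction_table",
    "f_reduced",
    "g_reduced",
    "fprime_reduced",
    "gprime_reduced",
    "rhs_reduced",
    "rhs_scalar",
    "map_x_to_P",
    "x_scale",
]

#: The seven admissible retained pairs, as (type, x, y).
ADMISSIBLE_PAIRS = (
    (1, "M", "n"),
    (1, "P", "n"),
    (1, "M", "D"),
    (1, "P", "D"),
    (2, "M", "N"),
    (2, "P", "N"),
    (3, "M", "P"),
)

_PAIR_TYPE = {(x, y): t for t, x, y in ADMISSIBLE_PAIRS}


@dataclass(frozen=True)
class ReducedParameters:
    """Effective parameters of one quasi-steady-state reduction."""

    a: float
    b: float
    v: float
    k: int
    h: int
    reduction_type: int
    x: str
    y: str
    R: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.v, self.R) <= 0:
            raise ValueError("reduced parameters a, b, v, R must be positive")


def compute_R(params: ModelParameters) -> float:
    """Composite production/degradation ratio ``R = prod_i alpha_i/mu_i`` (uM)."""
    R = 1.0
    for s in ("D", "N", "M", "P", "n"):
        R *= params.alpha(s) / params.mu(s)
    return R


def compute_ab(params: ModelParameters) -> tuple[float, float]:
    """Closed-form effective parameters, identical for all seven reductions.

    ``a = (K_M/R)^(k/(k+1))`` and ``b = (K_M^(k/(k+1)) R^(1/(k+1)) / K_n)^h``.
    """
    R = compute_R(params)
    k, h = params.k, params.h
    a = (params.K_M / R) ** (k / (k + 1))
    b = (params.K_M ** (k / (k + 1)) / params.K_n * R ** (1 / (k + 1))) ** h
    return a, b


def compute_v(params: ModelParameters, pair: tuple[str, str]) -> float:
    """Effective rate ratio ``v = mu_y / mu_x`` of the retained pair."""
    if tuple(pair) not in _PAIR_TYPE:
        raise ValueError(
            f"pair {tuple(pair)!r} is not one of the admissible reductions {sorted(_PAIR_TYPE)}"
        )
    x, y = pair
    return params.mu(y) / params.mu(x)


def reduce_model(params: ModelParameters, pair: tuple[str, str] = ("M", "n")) -> ReducedParameters:
    """Bundle ``(a, b, v)`` and bookkeeping for one retained pair."""
    a, b = compute_ab(params)
    v = compute_v(params, pair)
    return ReducedParameters(
        a=a, b=b, v=v, k=params.k, h=params.h,
        reduction_type=_PAIR_TYPE[tuple(pair)], x=pair[0], y=pair[1],
        R=compute_R(params),
    )


def reduction_table(params: ModelParameters) -> pd.DataFrame:
    """All seven reductions as a tidy table of (type, x, y, a, b, v)."""
    a, b = compute_ab(params)
    rows = [
        {"type": t, "x": x, "y": y, "a": a, "b": b, "v": compute_v(params, (x, y))}
        for t, x, y in ADMISSIBLE_PAIRS
    ]
    return pd.DataFrame(rows)


# -- response functions --------------------------------------------------------

def f_reduced(x, a, k):
    """Production response ``f(x) = 1/(a + x^k)``, strictly decreasing on x>0."""
    x = np.asarray(x, dtype=float)
    return 1.0 / (a + x ** k)


def g_reduced(x, b, h):
    """Repression response ``g(x) = 1/(1 + b x^h)``, strictly decreasing on x>0."""
    x = np.asarray(x, dtype=float)
    return 1.0 / (1.0 + b * x ** h)


def fprime_reduced(x, a, k):
    x = np.asarray(x, dtype=float)
    return -k * x ** (k - 1) / (a + x ** k) ** 2


def gprime_reduced(x, b, h):
    x = np.asarray(x, dtype=float)
    return -h * b * x ** (h - 1) / (1.0 + b * x ** h) ** 2


# -- right-hand sides ----------------------------------------------------------

def rhs_reduced(
    reduction_type: int,
    lattice: HexLattice,
    x: np.ndarray,
    y: np.ndarray,
    rp: ReducedParameters,
) -> tuple[np.ndarray, np.ndarray]:
    """Planar reduced dynamics on a lattice, in units of ``1/mu_x`` time.

    The coupling placement depends on the structural type: type 1 averages
    the incoming ``y``, type 2 averages ``g`` of the incoming ``x``, and
    type 3 averages ``g`` of the incoming ``y``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    a, b, v, k, h = rp.a, rp.b, rp.v, rp.k, rp.h
    if reduction_type == 1:
        dx = lattice.neighbour_average(y) * f_reduced(x, a, k) - x
        dy = v * (g_reduced(x, b, h) - y)
    elif reduction_type == 2:
        dx = y * f_reduced(x, a, k) - x
        dy = v * (lattice.neighbour_average(g_reduced(x, b, h)) - y)
    elif reduction_type == 3:
        dx = lattice.neighbour_average(g_reduced(y, b, h)) * f_reduced(y, a, k) - x
        dy = v * (x - y)
    else:
        raise ValueError(f"reduction type must be 1, 2 or 3, got {reduction_type!r}")
    return dx, dy


def rhs_scalar(
    lattice: HexLattice,
    x: np.ndarray,
    a: float,
    b: float,
    k: int,
    h: int,
    variant: str = "avg-of-g",
) -> np.ndarray:
    """Scalar lattice dynamics ``x' = <g(x_in)> f(x) - x``.

    ``variant="avg-of-g"`` averages the repression responses of the
    neighbours (the form in which the lattice dispersion analysis is
    derived); ``variant="g-of-avg"`` applies ``g`` to the averaged signal.
    Both coincide on spatially constant states.
    """
    x = np.asarray(x, dtype=float)
    if variant == "avg-of-g":
        coupling = lattice.neighbour_average(g_reduced(x, b, h))
    elif variant == "g-of-avg":
        coupling = g_reduced(lattice.neighbour_average(x), b, h)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return coupling * f_reduced(x, a, k) - x


def x_scale(params: ModelParameters) -> float:
    """Protein scale relating reduced units to uM: ``P = (R K_M^k)^(1/(k+1)) x``.

    The coefficient is fixed by requiring that the reduced fixed-point
    relation ``x (a + x^k)(1 + b x^h) = 1`` maps onto the full-model
    homogeneous stationarity ``P (1 + (P/K_M)^k)(1 + (P/K_n)^h) = R``.
    """
    R = compute_R(params)
    k = params.k
    return (R * params.K_M ** k) ** (1.0 / (k + 1))


def map_x_to_P(x, params: ModelParameters):
    """Map reduced state ``x`` to Hes1 protein concentration in uM (linear)."""
    return x_scale(params) * np.asarray(x, dtype=float)
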