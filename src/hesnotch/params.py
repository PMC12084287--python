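"""Model parameterisation of the Hes1-Notch gene-regulatory network.

The five-species network (Dll1 ``D``, Notch ``N``, Hes1 mRNA ``M``, Hes1
protein ``P``, Ngn2 ``n``) is governed by fourteen constants: five
production rates ``alpha_i``, five degradation rates ``mu_i``, two Hill
dissociation constants ``K_M`` and ``K_n`` (micromolar) and two integer
Hill coefficients ``k`` and ``h``.  Degradation rates derive from measured
half-lives; for the transmembrane species Dll1 and Notch only the ~20%
unbound fraction is degraded, so the measured rates are multiplied
fivefold.  Central values ship with 68% uncertainty intervals for the
``alpha`` and ``mu`` entries, which drive the Monte-Carlo perturbation
sampling used in uncertainty propagation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = [
    "ModelParameters",
    "SPECIES",
    "default_parameters",
    "sample_perturbed_parameters",
]

#: Species order used throughout the package.
SPECIES = ("D", "N", "M", "P", "n")

_LN2 = math.log(2.0)

#: Names of the rate parameters that carry uncertainty intervals.
_PERTURBED = (
    "alpha_D", "alpha_N", "alpha_M", "alpha_P", "alpha_n",
    "mu_D", "mu_N", "mu_M", "mu_P", "mu_n",
)


@dataclass(frozen=True)
class ModelParameters:
    """Rate and affinity constants of the five-species network.

    Units: ``alpha_n`` is in uM/min, the remaining ``alpha_i`` are per-minute
    multipliers of their substrate, all ``mu_i`` are per-minute, ``K_M`` and
    ``K_n`` are in uM, and ``k``/``h`` are dimensionless positive integers.

    ``intervals`` maps parameter names to ``(lower, upper)`` 68% bounds for
    the perturbable entries (the Hill constants and coefficients are treated
    as fixed design constants and carry no interval).
    """

    alpha_D: float
    alpha_N: float
    alpha_M: float
    alpha_P: float
    alpha_n: float
    mu_D: float
    mu_N: float
    mu_M: float
    mu_P: float
    mu_n: float
    K_M: float
    K_n: float
    k: int
    h: int
    intervals: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in (*_PERTURBED, "K_M", "K_n", "k", "h"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"parameter {name!r} must be strictly positive, got {value!r}")
        for name in ("k", "h"):
            value = getattr(self, name)
            if int(value) != value or value < 1:
                raise ValueError(f"Hill coefficient {name!r} must be an integer >= 1, got {value!r}")
        for name, (lo, hi) in self.intervals.items():
            centre = getattr(self, name)
            if not (lo <= centre <= hi):
                raise ValueError(
                    f"interval for {name!r} must bracket the central value: "
                    f"{lo!r} <= {centre!r} <= {hi!r} fails"
                )

    def alpha(self, species: str) -> float:
        return getattr(self, f"alpha_{species}")

    def mu(self, species: str) -> float:
        return getattr(self, f"mu_{species}")

    def scale_alpha_N(self, s: float) -> "ModelParameters":
        """Weaken the trans-activation by mapping ``alpha_N -> alpha_N / s``.

        This is the one-parameter family along which the patterned states
        are continued in the bifurcation analysis.
        """
        if s <= 0:
            raise ValueError("scaling s must be positive")
        lo, hi = self.intervals.get("alpha_N", (self.alpha_N, self.alpha_N))
        new_intervals = dict(self.intervals)
        new_intervals["alpha_N"] = (lo / s, hi / s)
        return replace(self, alpha_N=self.alpha_N / s, intervals=new_intervals)

    def replace(self, **changes) -> "ModelParameters":
        return replace(self, **changes)


def _half_life_rate(t_half: float, factor: float = 1.0) -> float:
    return _LN2 / t_half * factor

def _half_life_interval(t_lo: float, t_hi: float, factor: float = 1.0) -> tuple[float, float]:
    # shorter half-life <-> faster degradation, so the bounds swap
    return (_LN2 / t_hi * factor, _LN2 / t_lo * factor)


def default_parameters() -> ModelParameters:
    """Central parameter values for the mouse neural-progenitor network.

    Degradation rates come from published component half-lives (minutes):
    Dll1 50, Notch1 40, Hes1 protein 24.1, Hes1 mRNA 22.3, Ngn2 21.9, with
    the fivefold free-fraction correction applied to Dll1 and Notch.
    Production rates were calibrated against relative component abundances.
    """
    return ModelParameters(
        alpha_D=0.018,
        alpha_N=6.0,
        alpha_M=0.017,
        alpha_P=0.14,
        alpha_n=0.0049,
        mu_D=_half_life_rate(50.0, 5.0),
        mu_N=_half_life_rate(40.0, 5.0),
        mu_M=_half_life_rate(24.1),
        mu_P=_half_life_rate(22.3),
        mu_n=_half_life_rate(21.9),
        K_M=0.050,
        K_n=0.030,
        k=1,
        h=4,
        intervals={
            "alpha_D": (0.016, 0.021),
            "alpha_N": (5.3, 6.7),
            "alpha_M": (0.016, 0.019),
            "alpha_P": (0.12, 0.16),
            "alpha_n": (0.0043, 0.0054),
            "mu_D": _half_life_interval(45.3, 55.2, 5.0),
            "mu_N": _half_life_interval(36.2, 44.2, 5.0),
            "mu_M": _half_life_interval(22.4, 25.8),
            "mu_P": _half_life_interval(19.2, 25.4),
            "mu_n": _half_life_interval(19.7, 24.1),
        },
    )


def sample_perturbed_parameters(base: ModelParameters, seed) -> ModelParameters:
    """Draw an independent random perturbation of the rate parameters.

    Each ``alpha`` and ``mu`` entry is drawn from a uniform distribution
    whose central 68% probability mass coincides with that parameter's
    printed ``(lower, upper)`` interval, i.e. the 16th/84th percentiles of
    the draw reproduce the published 68% bounds.  Parameters without an
    interval (or with a degenerate one) are returned unchanged.  The draw
    is deterministic given ``seed``.
    """
    if isinstance(seed, (np.random.Generator, np.random.SeedSequence)):
        rng = np.random.default_rng(seed)
    elif isinstance(seed, (int, np.integer)):
        rng = np.random.default_rng(int(seed))
    else:
        raise TypeError(f"seed must be an integer or numpy Generator, got {type(seed).__name__}")

    changes: dict[str, float] = {}
    new_intervals = dict(base.intervals)
    for name in _PERTURBED:
        lo, hi = base.intervals.get(name, (getattr(base, name),) * 2)
        if hi <= lo:
            continue
        # widen so that the central 68% of the uniform spans (lo, hi)
        width = (hi - lo) / 0.68
        left = lo - 0.16 * width
        value = max(left + width * rng.random(), 1e-12)
        changes[name] = value
        # the draw is a point estimate; it carries no interval of its own
        new_intervals[name] = (value, value)
    if not changes:
        return base
    return base.replace(intervals=new_intervals, **changes)
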