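"""Quantifying the quality of the lateral-inhibition fate pattern.

After the fate decision every cell sits at a high or a low Hes1 level.
For the ideal pattern — the period-3 uniform colouring of the hexagonal
tiling, one low cell in every triple — each high cell has exactly three
high and three low neighbours, so the fraction of a high cell's directed
neighbour couplings that point at another high cell is 1/2.  That
fraction, estimated over all high cells (and pooled across replicate
simulations), is the patterning coefficient ``p``: values near 1/2
indicate near-perfect patterning, values near the high-cell fraction
indicate spatially random fates.  Treating the directed couplings as
independent Bernoulli trials turns the measurement into a standard
single-parameter estimation problem with textbook confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .lattice import HexLattice

__all__ = [
    "PatterningEstimate",
    "BimodalSummary",
    "classify_high_low",
    "patterning_coefficient",
    "bernoulli_interval",
    "estimate_pattern_quality",
    "rdme_bifurcation_summary",
    "period3_labels",
]


@dataclass(frozen=True)
class PatterningEstimate:
    """Point estimate and interval for the patterning coefficient."""

    p_hat: float
    numerator: int
    denominator: int
    level: float | None = None
    lower: float | None = None
    upper: float | None = None
    replicates: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_hat <= 1.0):
            raise ValueError("p_hat must lie in [0, 1]")
        if self.numerator > self.denominator:
            raise ValueError("numerator cannot exceed denominator")
        if self.lower is not None and not (self.lower <= self.p_hat <= self.upper):
            raise ValueError("interval must contain the point estimate")


@dataclass(frozen=True)
class BimodalSummary:
    """Spread summary of a stationary field: top/bottom quartile means,
    their diameters (max - min) and a bimodality verdict."""

    top_mean: float
    bottom_mean: float
    top_diameter: float
    bottom_diameter: float
    threshold: float
    bimodal: bool


def classify_high_low(values: np.ndarray) -> tuple[np.ndarray, BimodalSummary]:
    """Label cells high/low from their stationary expression levels.

    The threshold is the midpoint between the means of the top and bottom
    expression quartiles.  The field is called bimodal when the gap between
    the two quartile samples exceeds the sum of their diameters, i.e. the
    two modes are separated by more than their own spreads.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 4:
        raise ValueError("need a flat field of at least 4 cells")
    order = np.sort(values)
    q = values.size // 4
    bottom, top = order[:q], order[-q:]
    threshold = 0.5 * (top.mean() + bottom.mean())
    # tolerance so that numerically-constant fields never label "high"
    labels = values > threshold + 1e-12 * max(abs(threshold), 1.0)
    gap = top.min() - bottom.max()
    bimodal = bool(gap > (top.max() - top.min()) + (bottom.max() - bottom.min()))
    summary = BimodalSummary(
        top_mean=float(top.mean()),
        bottom_mean=float(bottom.mean()),
        top_diameter=float(top.max() - top.min()),
        bottom_diameter=float(bottom.max() - bottom.min()),
        threshold=float(threshold),
        bimodal=bimodal,
    )
    return labels, summary


def _coupling_counts(lattice: HexLattice, labels: np.ndarray) -> tuple[int, int]:
    labels = np.asarray(labels, dtype=bool)
    if labels.shape[0] != lattice.n_nodes:
        raise ValueError("labels must cover every lattice node")
    num = den = 0
    for i in np.nonzero(labels)[0]:
        nb = lattice.neighbours(int(i))
        den += nb.size
        num += int(labels[nb].sum())
    return num, den


def patterning_coefficient(lattice: HexLattice, labels: np.ndarray) -> PatterningEstimate:
    """Fraction of directed high->neighbour couplings that are high->high."""
    num, den = _coupling_counts(lattice, labels)
    if den == 0:
        raise ValueError("patterning coefficient undefined: no high cells (or no couplings)")
    return PatterningEstimate(p_hat=num / den, numerator=num, denominator=den)


def bernoulli_interval(
    numerator: int, denominator: int, level: float = 0.95, method: str = "wald"
) -> tuple[float, float]:
    """Confidence interval for a Bernoulli proportion.

    ``method="wald"`` is the normal approximation ``p +- z sqrt(p(1-p)/n)``
    clipped to [0, 1]; ``method="clopper-pearson"`` gives the exact beta
    interval.
    """
    if denominator < 1:
        raise ValueError("denominator must be >= 1")
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    p = numerator / denominator
    if method == "wald":
        z = stats.norm.ppf(0.5 + level / 2.0)
        half = z * np.sqrt(p * (1.0 - p) / denominator)
        return (max(0.0, p - half), min(1.0, p + half))
    if method == "clopper-pearson":
        alpha = 1.0 - level
        lo = 0.0 if numerator == 0 else stats.beta.ppf(alpha / 2, numerator, denominator - numerator + 1)
        hi = 1.0 if numerator == denominator else stats.beta.ppf(
            1 - alpha / 2, numerator + 1, denominator - numerator
        )
        return (float(lo), float(hi))
    raise ValueError(f"unknown interval method {method!r}")


def estimate_pattern_quality(
    states, lattice: HexLattice, level: float = 0.95, method: str = "wald"
) -> PatterningEstimate:
    """Pooled patterning coefficient over replicate stationary states.

    Each replicate's per-cell stationary values are classified high/low;
    the high->high and high->any coupling counts are pooled across
    replicates before the Bernoulli interval is formed.
    """
    states = list(states)
    if not states:
        raise ValueError("need at least one replicate")
    num = den = 0
    for values in states:
        labels, _ = classify_high_low(np.asarray(values))
        n, d = _coupling_counts(lattice, labels)
        num += n
        den += d
    if den == 0:
        raise ValueError("patterning coefficient undefined: no high cells in any replicate")
    lo, hi = bernoulli_interval(num, den, level=level, method=method)
    return PatterningEstimate(
        p_hat=num / den, numerator=num, denominator=den,
        level=level, lower=lo, upper=hi, replicates=len(states),
    )


def rdme_bifurcation_summary(scan) -> pd.DataFrame:
    """Tabulate high/low means, spreads and bimodality along a scan.

    ``scan`` is an iterable of ``(scan_value, replicate_states)`` pairs or
    of dictionaries with a scan key (``volume`` or ``s``) and
    ``stationary_states`` (as produced by the volume scan).  The returned
    table carries one row per scan point; the ``transition`` attribute in
    ``DataFrame.attrs`` records the first scan value at which the
    bimodality verdict flips relative to the first point (or None).
    """
    rows = []
    for entry in scan:
        if isinstance(entry, dict):
            key = "volume" if "volume" in entry else "s"
            value = entry[key]
            states = entry["stationary_states"]
        else:
            value, states = entry
        pooled = np.concatenate([np.asarray(s, dtype=float) for s in states])
        _, summary = classify_high_low(pooled)
        rows.append(
            {
                "scan_value": float(value),
                "high_mean": summary.top_mean,
                "low_mean": summary.bottom_mean,
                "high_spread": summary.top_diameter,
                "low_spread": summary.bottom_diameter,
                "bimodal": summary.bimodal,
            }
        )
    if not rows:
        raise ValueError("scan output is empty")
    table = pd.DataFrame(rows)
    transition = None
    first = table["bimodal"].iloc[0]
    flips = table.index[table["bimodal"] != first]
    if len(flips):
        transition = float(table.loc[flips[0], "scan_value"])
    table.attrs["transition"] = transition
    return table


def period3_labels(lattice: HexLattice) -> np.ndarray:
    """High/low labels of the ideal period-3 colouring on a hex grid.

    Cells whose axial coordinates satisfy ``(row + col) % 3 == 0`` form the
    low (minority) fate; the rest are high.  On a periodic grid with both
    dimensions divisible by 3 this is the vertex-transitive pattern whose
    patterning coefficient is exactly 1/2.
    """
    if lattice.coords is None:
        raise ValueError("lattice has no grid coordinates")
    r, c = lattice.coords[:, 0], lattice.coords[:, 1]
    return (r + c) % 3 != 0
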